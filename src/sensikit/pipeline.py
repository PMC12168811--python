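"""Configuration-driven end-to-end runs: simulate -> analyse -> summarise.

Each stage writes its inputs and outputs under the configured output
directory, and the run manifest records the toolkit version, a hash of
the effective configuration, the seed, and a checksum for every file
written, so a run can be re-executed and verified byte for byte
(timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calcium import ResponderParams, call_cohort, summarize_coverslip, CellCallResult
from .config import RunConfig, serialize_config
from .ephys import APDetectionParams, extract_cell_features
from .imagequant import AreaRule, compute_purity
from .recording import SweepProtocol
from .synthgen import (
    CalciumSimConfig,
    ImageSimConfig,
    NeuronSimConfig,
    gen_calcium_cohort,
    gen_current_clamp,
    gen_if_image,
)

log = logging.getLogger("sensikit")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(serialize_config(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and write the run manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    A failing stage stops the run; nothing downstream executes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    files: list[Path] = []

    params = ResponderParams(
        k_sd=config.calcium_params.k_sd,
        live_min_frames=config.calcium_params.live_min_frames,
        responder_min_frames=config.calcium_params.responder_min_frames,
        onset_window_s=config.calcium_params.onset_window_s,
        min_amplitude=config.calcium_params.min_amplitude,
        responder_baseline=config.calcium_params.responder_baseline,
    )
    rule = AreaRule(
        exclude_below_um2=config.area_rule.exclude_below_um2,
        two_above_um2=config.area_rule.two_above_um2,
        three_above_um2=config.area_rule.three_above_um2,
    )
    ap_params = APDetectionParams(
        dvdt_threshold_mV_per_ms=config.ap_params.dvdt_threshold_mV_per_ms,
        min_interevent_ms=config.ap_params.min_interevent_ms,
    )

    if "calcium" in config.stages:
        log.info("[calcium] simulating cohort")
        sim = config.calcium_sim
        ccfg = CalciumSimConfig(
            n_cells=sim.n_cells,
            frac_dead=sim.frac_dead,
            frac_responders_among_live=sim.frac_responders_among_live,
            noise_sd=sim.noise_sd,
            frame_period_s=sim.frame_period_s,
            response_margin=sim.response_margin,
            seed=config.seed,
        )
        table, tl, truth = gen_calcium_cohort(ccfg, params)
        table.to_csv(out / "calcium_traces.csv", index=False)
        truth.to_csv(out / "calcium_truth.csv", index=False)
        tl.to_json(out / "calcium_timeline.json")
        calls = call_cohort(table, tl, params)
        calls.to_csv(out / "calcium_calls.csv", index=False)
        results = [
            CellCallResult(r.roi_id, bool(r.live), bool(r.responder),
                           max_pct_response=r.max_pct_response if r.responder else None)
            for r in calls.itertuples()
        ]
        summ = summarize_coverslip(results)
        (out / "calcium_summary.json").write_text(json.dumps({
            "n_rois": summ.n_rois, "pct_live": summ.pct_live,
            "pct_responders": summ.pct_responders,
            "mean_max_pct_response": summ.mean_max_pct_response,
        }, indent=2))
        files += [out / f for f in ("calcium_traces.csv", "calcium_truth.csv",
                                    "calcium_timeline.json", "calcium_calls.csv",
                                    "calcium_summary.json")]

    if "image" in config.stages:
        log.info("[image] simulating slide")
        sim = config.image_sim
        icfg = ImageSimConfig(
            image_size_px=sim.image_size_px,
            pixel_size_um=sim.pixel_size_um,
            n_nuclei=sim.n_nuclei,
            purity_fraction=sim.purity_fraction,
            n_merged_pairs=sim.n_merged_pairs,
            n_debris=sim.n_debris,
            seed=config.seed,
        )
        stack, truth = gen_if_image(icfg)
        import tifffile
        tifffile.imwrite(
            out / "if_slide.tiff", stack.astype(np.float32),
            resolution=(1.0 / sim.pixel_size_um, 1.0 / sim.pixel_size_um),
            photometric="minisblack", metadata={"unit": "um", "axes": "CYX"},
        )
        truth.to_csv(out / "if_truth.csv", index=False)
        res = compute_purity(stack, sim.pixel_size_um, rule=rule)
        (out / "if_purity.json").write_text(json.dumps({
            "n_dapi": res.n_dapi, "n_double_positive": res.n_double_positive,
            "purity_pct": res.purity_pct, "inconsistent": res.inconsistent,
        }, indent=2))
        files += [out / f for f in ("if_slide.tiff", "if_truth.csv", "if_purity.json")]

    if "ephys" in config.stages:
        log.info("[ephys] simulating %d cells", config.ephys_sim.n_cells)
        sim = config.ephys_sim
        rows = []
        for i in range(sim.n_cells):
            ncfg = NeuronSimConfig(noise_sd_mV=sim.noise_sd_mV,
                                   seed=(config.seed * 10007 + i) % (2**31))
            rec, truth = gen_current_clamp(
                ncfg, SweepProtocol(),
                gapfree_s=sim.gapfree_s or None,
            )
            rec.save(out / f"ephys_cell{i}.npz")
            held, _ = gen_current_clamp(
                ncfg, SweepProtocol(holding_mode="held_minus75"))
            feats = extract_cell_features(rec, held, ap_params)
            feats.insert(0, "cell", i)
            feats["truth_rheobase_pA"] = truth.attrs["rheobase_pA"]
            rows.append(feats)
            files.append(out / f"ephys_cell{i}.npz")
        table = pd.concat(rows, ignore_index=True)
        table.to_csv(out / "ephys_features.csv", index=False)
        files.append(out / "ephys_features.csv")

    manifest = {
        "toolkit_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
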