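"""Run configuration: schema, validation and (de)serialisation.

Configs are TOML (preferred) or JSON.  Unknown keys are rejected with
the offending field path; defaults fill in the documented analysis
parameters (k_sd = 3, dV/dt threshold = 10 mV/ms, area rule
30/130/200 um^2, ...).  Environment variables never override files.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, ValidationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CalciumParamsConfig(_Strict):
    k_sd: float = 3.0
    live_min_frames: int = 10
    responder_min_frames: int = 80
    onset_window_s: float = 300.0
    min_amplitude: float = 0.10
    responder_baseline: Literal["baseline1", "baseline2"] = "baseline1"


class AreaRuleConfig(_Strict):
    exclude_below_um2: float = 30.0
    two_above_um2: float = 130.0
    three_above_um2: float = 200.0


class APParamsConfig(_Strict):
    dvdt_threshold_mV_per_ms: float = 10.0
    min_interevent_ms: float = 2.0


class CalciumSimBlock(_Strict):
    n_cells: int = 100
    frac_dead: float = 0.1
    frac_responders_among_live: float = 0.4
    noise_sd: float = 0.01
    frame_period_s: float = 1.5
    response_margin: float = 1.5


class ImageSimBlock(_Strict):
    image_size_px: int = 900
    pixel_size_um: float = 0.62
    n_nuclei: int = 50
    purity_fraction: float = 0.9
    n_merged_pairs: int = 0
    n_debris: int = 0


class EphysSimBlock(_Strict):
    n_cells: int = 3
    gapfree_s: float = 0.0
    noise_sd_mV: float = 0.0


class RunConfig(_Strict):
    """Top-level configuration for ``sensikit run``."""

    stages: list[Literal["calcium", "image", "ephys"]] = ["calcium", "image", "ephys"]
    seed: int = 0
    out_dir: str = "sensikit_run"
    log_level: str = "INFO"
    calcium_params: CalciumParamsConfig = CalciumParamsConfig()
    area_rule: AreaRuleConfig = AreaRuleConfig()
    ap_params: APParamsConfig = APParamsConfig()
    calcium_sim: CalciumSimBlock = CalciumSimBlock()
    image_sim: ImageSimBlock = ImageSimBlock()
    ephys_sim: EphysSimBlock = EphysSimBlock()


class ConfigError(ValueError):
    pass


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML or JSON run config."""
    path = Path(path)
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(path.read_text())
        else:
            raw = tomllib.loads(path.read_text())
    except (json.JSONDecodeError, tomllib.TOMLDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return validate_config_dict(raw)


def validate_config_dict(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(x) for x in e["loc"]) + ": " + e["msg"] for e in exc.errors()
        )
        raise ConfigError(f"invalid config ({locs})") from exc


def serialize_config(config: RunConfig) -> dict:
    return config.model_dump(mode="json")
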