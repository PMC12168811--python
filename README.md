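# sensikit

Quantitative toolkit for in-vitro studies of sensory-neuron sensitization —
the question of whether inflammatory mediators ("inflammatory soup") make
cultured sensory neurons (iPSC-derived or dissociated DRG) more excitable.
It implements the three measurement arms such studies rest on, the
statistics used to compare treated and control groups, and a synthetic-data
generator that produces ground-truthed inputs for all three arms, so the
whole pipeline is testable without any microscope or rig.

**Who it is for:** labs running calcium-imaging drug-response assays,
immunofluorescence purity checks of neuronal differentiations, or
current-clamp excitability batteries, who want a scripted, deterministic
re-implementation of the standard FIJI/pClamp-style analyses.

## What it computes

**Calcium imaging** (`sensikit.calcium`). Per-ROI traces are converted to
ΔF/F = (F − F̄₀)/F̄₀ against the pre-compound baseline mean F̄₀. A second
baseline is taken in the wash just before a terminal 50 mM KCl challenge.
A cell is **live** if ≥ 10 KCl-epoch frames exceed the second baseline by
≥ 3 SD; a live cell is a **drug responder** if ≥ 80 drug-epoch frames
(~2 min at 1.5 s/frame) exceed the baseline by ≥ 3 SD, the first
suprathreshold frame falls within 5 min of compound application, and the
response reaches ≥ 10 % ΔF/F. The "max % response" is the mean of the three
largest ΔF/F values over the response timeframe. Transient shapes (slow /
intermediate / rapidly decaying / oscillatory) are characterised
descriptively.

**Immunofluorescence purity** (`sensikit.imagequant`). Maximum-intensity
projection, per-channel Otsu binarisation, 8-connected particle counting of
DAPI+ nuclei, and pairwise colocalization by mask intersection. An
area-to-count rule handles segmentation artefacts: components < 30 µm² are
excluded as debris, > 130 µm² count as 2 joined nuclei, > 200 µm² as 3.
Purity (%) = 100 · double-positive / DAPI+.

**Current clamp** (`sensikit.ephys`). Action potentials are detected where
dV/dt ≥ 10 mV/ms. From 200 ms current steps (−50 → 850 pA, 25 pA
increments) the battery measures resting membrane potential (mean of the
200 ms before the step), rheobase, f–I spike counts, firing pattern
(single/multiple), spontaneous activity from a 2-min gap-free segment, and,
holding at −75 mV, AP threshold, peak amplitude, time to peak, half-width,
and fast/medium afterhyperpolarisations. Cells that never fire up to
850 pA or rest above −40 mV are excluded. The −14 mV liquid junction
potential is corrected offline, exactly once.

**Statistics** (`sensikit.stats`). Two-group comparisons are gated on
Shapiro–Wilk normality (both normal → unpaired two-tailed t; otherwise
Mann–Whitney U), contingency outcomes use the exact Fisher test, and a
Bonferroni ledger corrects across the parameter family (14 parameters at
family α = 0.05 → displayed per-test threshold 0.003). A literature
synthesis compares per-study control/inflamed resting membrane potentials
with effect-size binning, a pooled Mann–Whitney test and a paired t test.

**Synthetic data** (`sensikit.synthgen`). Calcium cohorts with
dead/non-responder/responder truth labels built to clear every
classification threshold by a configurable safety margin; labelled
three-channel nuclei images with controllable double-positive fraction,
merged-nucleus pairs and sub-30 µm² debris; and current-clamp sweep
families from an adaptive exponential integrate-and-fire neuron whose
reset events give exact rheobase/spike-count ground truth.

## Worked example

```
$ sensikit simulate calcium --out demo --n-cells 100 --seed 7
wrote 100 traces to demo
$ sensikit calcium --traces demo/traces.csv --timeline demo/timeline.json --out demo/calls.csv
90 live / 36 responders of 100 ROIs -> demo/calls.csv
```

The simulated cohort was configured with 10 % dead cells and 40 %
responders among live cells; the classifier recovers exactly 90 live cells
(90 %) and 36 responders (40 % of live), matching the generator's truth
table label for label.

```
$ sensikit simulate image --out demo_img --n-nuclei 50 --purity 0.9 --seed 7
wrote slide (50 nuclei) to demo_img
$ sensikit imagequant --image demo_img/slide.tiff --pixel-size 0.62 --out demo_img/purity.json
purity 90.0% (45/50)
```

45 of 50 DAPI+ nuclei are double-positive for both markers — the
configured 90 % purity, recovered exactly.

Python API equivalents of every subcommand live in the modules listed
above; `sensikit run --config run.toml` drives a full simulate → analyse →
summarise pass and writes a checksummed run manifest.

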