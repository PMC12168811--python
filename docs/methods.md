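# Methods

## Calcium responder pipeline

A recording is modelled as four ordered epochs — baseline, compound
(drug), wash, terminal 50 mM KCl — on a fixed frame grid. All windows are
0-based half-open frame intervals. The default frame period is 1.5 s so
that the 80-frame responder-duration criterion spans ~2 minutes; the
default epoch layout (baseline 120 s, compound 300 s, wash 120 s, KCl
60 s) fixes the ordering but the durations themselves are package
conventions and fully configurable.

ΔF/F uses the pre-compound baseline mean; the second baseline (mean and
SD of ΔF/F over the wash window) feeds the live-cell gate. Classification
thresholds are inclusive (`>=`): a frame exactly at mean + k·SD counts as
suprathreshold, and an onset exactly at the 5-minute window edge still
qualifies. The three responder predicates are applied in a fixed order
(duration → onset → amplitude) and the first failing predicate is
recorded as the reason code (`insufficient-frames`, `late-onset`,
`sub-amplitude`; dead cells short-circuit with `dead`).

Choices where the procedure was genuinely open:

* The SD used by the responder duration predicate comes from the
  pre-compound baseline expressed in ΔF/F space (where its mean is 0 by
  construction). The wash baseline is available through
  `ResponderParams.responder_baseline="baseline2"`; both gates otherwise
  share the same machinery.
* The 80 suprathreshold frames are counted cumulatively within the drug
  epoch, not required to be consecutive.
* The "response timeframe" for the top-3 ΔF/F average runs from the
  detected onset frame to the end of the drug epoch; windows shorter
  than three frames average what they have.
* The 10 % amplitude floor is read as ΔF/F ≥ 0.10 at some frame of the
  response.
* Archetype labels are heuristics on the post-peak half-decay time
  (≥ 40 s slow, 10–40 s intermediate, < 10 s rapid) and on the count of
  distinct suprathreshold peaks (≥ 3 → oscillatory). They are
  descriptive only and never feed the responder call. A response with no
  half-decay inside the epoch (e.g. a plateau to the epoch end) is
  `unclassified`.
* Ratiometric (Fura-2 340/380) traces are accepted as raw F without
  special handling; every step is scale-invariant, which the suite
  verifies by property test.

## Calcium cohort generator

Truth labels must be unambiguous under the classifier, so responder
signals are built as a smooth pedestal plus an archetype transient. The
pedestal height is `margin · (k_sd · noise_sd + min_amplitude)` and its
duration `margin · responder_min_frames` frames, which clears the
duration and amplitude criteria by the configured margin even after
noise; the onset is drawn within `onset_window_s / margin` of compound
application. All drug-epoch signal is tapered to zero before the wash so
the second baseline stays pure noise. Live cells carry a KCl plateau
(ΔF/F 0.8–1.5) spanning nearly the whole KCl window. Dead cells carry
noise only. Traces are rendered as `F0 · (1 + signal + noise)` with
i.i.d. Gaussian noise in ΔF/F units (default SD 0.01, roughly an
indicator-level noise floor for a clearly visible transient of 0.3–0.8).

With `response_margin ≥ 1.5` and noise at or below a tenth of the
response amplitude, classification equals the truth table exactly; the
suite checks this over 20 randomised configurations and a fixed 500-cell
cohort. Margins near 2 with the default 200-frame drug epoch are the
feasibility limit (the pedestal must fit inside the epoch); the
generator raises rather than silently truncating.

The generator does not emulate bleaching, drift, motion, or correlated
noise; passing recovery tests therefore demonstrates the correctness of
the decision logic, not robustness to those artefacts.

## Immunofluorescence arm

The counting pipeline is deterministic: maximum projection, Otsu
threshold (FIJI's "Default" method is not reproduced bit-for-bit),
8-connected components, and the area rule with strict inequalities —
exactly 130 µm² counts as 1 nucleus and exactly 200 µm² as 2. The "<30"
exclusion threshold is treated as µm². Colocalization is the pixelwise
AND of the two marker masks counted under the same rule; this replaces
the interactive FIJI colocalization-threshold sequence with a
deterministic equivalent for nuclear stains.

The image generator renders nuclei as disks (radius 5 µm, area
~78.5 µm²) at 0.62 µm/px, debris at radius 2 µm (~12.6 µm², below the
exclusion threshold), and merged pairs as two disks at 1.7 r separation,
whose union (~152 µm²) falls squarely in the 2-nucleus band. Foreground
/ background intensities (200/10, noise SD 3) are far enough apart that
Otsu recovers the drawn masks; placement is rejection-sampled with
generous separation so components never touch. Double-positive nuclei
are an exact count (`round(purity_fraction · n_nuclei)`), so configured
purity is recovered exactly, not in expectation.

## Current-clamp arm

The simulator is an adaptive exponential integrate-and-fire neuron
(Euler, default 20 kHz; 10 kHz is the accepted minimum) with parameters
(C = 100 pF, g_L = 10 nS, E_L = −65 mV, V_T = −50 mV, ΔT = 2 mV,
a = 2 nS, b = 60 pA, τ_w = 120 ms, V_reset = −55 mV) chosen to put
rheobase in the low hundreds of pA under the −50…850 pA / 25 pA step
protocol, comparable to cultured sensory neurons. Reset events are the
spike ground truth; the rendered trace carries a stereotyped 2 ms
triangular spike to +30 mV pasted at each reset, whose falling flank
rejoins the post-reset model trace so the paste can never manufacture a
second dV/dt crossing. Noise is additive measurement noise applied after
integration, keeping the dynamics — and therefore the truth — exactly
deterministic. The brute-force oracle re-simulates noise-free and counts
reset events; held-at-−75 mV protocols use the analytic steady-state
bias current.

Feature conventions where the procedure was open:

* dV/dt by forward difference at the native rate, no smoothing by
  default (a Savitzky–Golay option exists); events must be ≥ 2 ms apart.
* Waveform features come from the first AP of the first suprathreshold
  sweep of the held protocol. The amplitude reference is the sweep's own
  pre-stimulus holding level (−75 mV on an uncorrected held recording),
  which makes amplitude, half-width and time-to-peak invariant under LJP
  correction while threshold and the AHPs shift by exactly the LJP.
* Half-width interpolates the half-amplitude crossings linearly.
* fAHP = minimum between the first peak and the next AP onset (or step
  end); mAHP = minimum in the 200 ms after step offset.
* The firing pattern (single vs multiple) is judged across all sweeps.
* LJP correction adds the configured value (default −14 mV) once; a
  state flag raises on double correction.
* Capacitance and input resistance are accepted as amplifier metadata
  when present; no estimator is implemented because no measurement
  protocol is defined for one.

## Statistics

The normality gate is Shapiro–Wilk at α = 0.05 per group (the gating
test itself is a package choice); the t branch assumes equal variances,
the Mann–Whitney branch uses the exact null distribution when both
groups have n ≤ 12 without ties and the tie-corrected normal
approximation otherwise. Calibration of the composite procedure is
checked empirically: over 2,000 Gaussian null draws at n = 20 per group
the rejection rate at α = 0.05 must stay within [0.035, 0.065].

The Bonferroni ledger reports both the exact per-test threshold (α/m)
and its 3-decimal truncation for display (0.05/14 → 0.003); significance
flags always use the untruncated value.

The literature RMP synthesis bins per-study effects into contiguous
magnitude bands [0, 1.5), [1.5, 10), [10, ∞) mV — closing the gaps in
the descriptive 0–1 / 2–6 / 10+ bands — and runs both a pooled
Mann–Whitney test (treating columns as independent) and a paired t test
on per-study differences; with zero-variance differences the paired p is
reported as degenerate rather than computed. Proportion summaries round
to the nearest integer percent.

## Numerical and engineering notes

* All randomness flows through `numpy.random.default_rng` seeds carried
  in the config objects; identical config + seed reproduces every
  generator bit for bit.
* Frame windows, sample windows and protocol amplitudes are validated at
  construction; degenerate inputs (empty cohort, constant image under
  Otsu, zero DAPI count, missing pre-stimulus window, non-ascending
  protocol) raise typed errors rather than returning sentinel values.
* The test suite and the acceptance script use deliberately modest
  problem sizes (500-trace cohorts, 100-nucleus slides, 20 simulated
  neurons at 10 kHz, 2,000 null simulations) — large enough to exercise
  every branch and boundary while keeping a full run in well under a
  minute per arm.
* Axon ABF ingestion is not implemented; recordings are exchanged as
  compressed numeric archives with embedded protocol JSON, plus CSV for
  tabular outputs.

## Known limitations

The generators validate decision logic, not robustness: no bleaching or
motion in calcium movies, no intensity gradients or out-of-focus planes
in the slides, no conductance-based spike shapes in the ephys traces.
The repeated-measures mixed-effects analysis of f–I curves is out of
scope by design — the toolkit exports the long-format f–I table for
external statistical software instead.
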