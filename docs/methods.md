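# Methods

## Model and assumptions

The package treats the body as a quasi-static volume conductor in which
every lead voltage is a projection of one moving cardiac dipole.  Two
consequences shape the design:

1. Within one stage of cardiac electrical activity (atrial systole,
   ventricular systole, ventricular diastole) the relation between any
   two leads is well approximated as affine and time-invariant, so a
   target lead L obeys `L ≈ a + b·I + c·II + d·V2` with stage-specific
   coefficients.
2. Across stages the dipole position moves, so a single global affine
   law is a compromise.  Fitting one coefficient matrix per stage-region
   (piecewise linear regression) is strictly more expressive and reduces
   to the global law when the regions share one relation.

The model is *personalized*: matrices fitted on one subject's recording
are only applied to that subject.  No cross-subject state exists
anywhere in the pipeline.

Lead III and the augmented leads are derived arithmetically
(`III = II − I`, `aVR = −(I+II)/2`, `aVL = I − II/2`, `aVF = II − I/2`),
which guarantees the closures `I − II + III = 0` and
`aVR + aVL + aVF = 0` exactly.  Note the first identity is equivalent to
Einthoven's law `II = I + III`; the arithmetic is chosen so all four
derived leads are mutually consistent.

## Pipeline

**Preprocessing.**  Each lead is decomposed to 8 levels with the sym5
wavelet; the level-8 approximation band (≈ 0–2 Hz at 1000 Hz sampling)
is zeroed to remove baseline wander, and every detail band is
soft-thresholded with the per-level universal threshold
`T_j = (median|d_j| / 0.6745) · sqrt(2 ln n_j)`.  The transform is the
*stationary* (undecimated) DWT: decimated shrinkage is not
shift-invariant and distorts identical beats differently depending on
their phase relative to the dyadic grid, which destabilizes the
amplitude-adaptive peak detector downstream; translation-invariant
shrinkage removes that artifact at the cost of a constant-factor more
computation.  Signals are padded symmetrically to the required block
length and cropped after reconstruction.  Signals shorter than the
configured depth allows are decomposed to the maximum feasible depth
with a logged warning.

This detrending deliberately trades some sub-2-Hz signal energy
(T-wave/fundamental content of slow rhythms) for baseline immunity; on
smooth synthetic morphology the denoised trace correlates with its
noiseless input at ≈ 0.74 (≈ 0.93 for detrending alone) while removing
better than 99 % of an injected 0.5 Hz wander.  Both sides of every
regression see the same distortion, so fitted lead relations are
unaffected; comparisons of synthesized against reference records are
made after applying the same preprocessing to the reference.

**R-peak detection.**  A detection envelope is rebuilt from the
stationary-wavelet detail levels 3–5 (≈ 15.6–125 Hz at 1000 Hz — the
band that dominates QRS energy), squared, and smoothed with a 0.15 s
moving average.  Envelope inflections (`sign(d(i)) > sign(d(i+1))`)
above the running threshold register the local envelope maximum within
a 0.10 s window as a peak.  The threshold starts at 30 % of the envelope
maximum over the first 2 s and, once three peaks exist, tracks 50 % of
the mean of the three most recent registered amplitudes (envelope units,
i.e. squared amplitude — the literal reading of registering amplitudes
before position correction).  A candidate implying an instantaneous
heart rate above 220 bpm relative to the previous registration either
replaces it (if its envelope value is larger) or is dropped.  Finally
every position is moved to the signal maximum within a 0.05 s window and
its amplitude re-read from the signal; detection runs on lead II by
default (typically the largest R amplitude).

**Segmentation.**  With M detected peaks (M ≥ 3 required), boundaries
are placed by experienced time windows: S-wave end
`B_SE(n) = peak_x(n) + round(T_RS·fs)` and T-wave end
`B_TE(n) = peak_x(n) + round(a_RT·rr(n)·fs)` for cycles 1…M−1, Q-wave
start `B_QS(n) = peak_x(n) − round(T_QR·fs)` for cycles 2…M.  Only the
R-T window scales with the R-R interval; Q-R and R-S widths are
rate-independent.  This yields a *fixed pattern* regardless of where the
recording starts or ends: M−1 ST-T fragments, M−1 R-P fragments, M−2 QRS
fragments, and one head–tail (H-T) region holding everything before
`B_SE(1)` plus everything from `B_QS(M)`.  All indices are 0-based with
half-open `[start, stop)` ranges; the four regions partition `[0, N)`
exactly, and per-cycle fragment lengths are recorded so the
reorganization is exactly invertible (verified sample-for-sample by
property tests).

**Regression and synthesis.**  ST-T, R-P and QRS matrices are fitted on
the reorganized subsequences; the H-T matrix is fitted on the complete
sequences, because head and tail are unrelated fragments of arbitrary
cardiac phase.  The solver is QR-type least squares
(`scipy.linalg.lstsq`, gelsy); the literal normal-equations /
pseudo-inverse estimator is kept as an independent test oracle and
agrees to ~1e-15 relative on well-conditioned inputs.  Synthesis
segments the 3-lead input with the same rules, applies the regional
matrices, restores full-length leads, passes the (preprocessed) source
leads through, and derives the limb leads.  No smoothing is applied at
region junctions; the resulting amplitude steps are measured (G1–G3
junction gaps) rather than hidden.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `wavelet_name` | sym5 | — | analysis wavelet for all stages |
| `decomp_levels` | 8 | — | denoising depth; approximation ≈ sub-2 Hz at 1 kHz |
| `detection_detail_levels` | {3, 4, 5} | — | QRS-band levels at 1 kHz; shifted by `round(log2(fs/1000))` at other rates so the physical band stays put |
| `init_threshold_frac` | 0.30 | — | initial threshold as fraction of first-window envelope max |
| `init_threshold_window_s` | 2.0 | s | initial-threshold window |
| `adapt_threshold_frac` | 0.50 | — | running threshold as fraction of recent peak mean |
| `adapt_peak_count` | 3 | — | peaks averaged by the adaptive threshold |
| `max_hr_bpm` | 220 | bpm | physiological heart-rate gate |
| `t_qr`, `t_rs` | 0.03, 0.04 | s | Q-R and R-S experienced windows |
| `a_rt` | 0.37 | — | R-T window as fraction of the R-R interval |
| `smooth_window_s` | 0.15 | s | envelope smoothing (≈ QRS duration) |
| `candidate_window_s` | 0.10 | s | local-max window when registering a peak |
| `correction_window_s` | 0.05 | s | position-correction window on the signal |
| `detection_lead` | II | — | lead driving detection/segmentation for all leads |

Amplitudes are µV package-wide (the 0.1 mV ST threshold is 100 µV);
time windows convert to samples by nearest-integer rounding.  The three
window widths without published values (`smooth/candidate/correction`)
were set once to values conventional for energy-envelope QRS detectors.

## Synthetic generator

Each beat of I, II and V2 is a sum of Gaussian bumps (P, Q, R, S, T)
with typical adult timings and per-lead amplitudes chosen so
`[1, I, II, V2]` is full rank.  V1 and V3–V6 are produced by applying
four distinct 4×5 mixing matrices to `[1, I, II, V2]` inside region
masks; the limb leads follow the arithmetic identities; sinusoidal
baseline (0.3 Hz), powerline (50 Hz) and white noise are added last,
all seeded.  Default region masks come from the generating wave supports
(independent of any segmentation algorithm), so segmentation accuracy
can be scored against truth the segmenter never sees.

Two generator options exist for exactness studies: `boundaries=` lets a
caller supply the region masks (e.g. the experienced-time-window
boundaries derived from the true peaks), and `consistent_ht=True`
generates the head/tail samples with the matrix a complete-sequence
least-squares fit returns — which equals the fit on the non-H-T samples,
since rows satisfying a model with zero residual cannot move its
solution.  With both, a noiseless train/synthesize round trip recovers
every regional matrix to ~1e-11 and every target lead to ~1e-13 µV RMSE,
turning the whole pipeline into an exactly checkable identity.

What the generator does **not** emulate: real QRS sharpness and
morphology variety, pathology (arrhythmia, ectopy, bundle-branch
blocks), electrode motion artifacts, and smoothly varying lead
relations.  Its relations switch discretely at mask edges, which
penalizes boundary misalignment more than real data would: when the
masks are the independent wave supports, the piecewise and global-LR
models score nearly identically, because region-assignment mismatch at
the edges cancels the piecewise advantage.  Passing tests therefore
demonstrate correctness of the mechanics and the expressiveness ordering
under aligned conditions, not a clinical effect size on real ECG.

## Numerical and degenerate-input choices

* Boundary overlaps in short/tachycardic cycles are resolved in order:
  a T-end at or past the next Q-start is pulled back to one sample
  before it (keeping R-P non-empty); a T-end before its own S-end yields
  an empty ST-T fragment; remaining degeneracies may empty R-P or QRS
  fragments but never break the partition.  Boundaries outside the
  record are clamped with a logged warning.
* Empty region fragments are carried through fitting and restoration as
  zero-length slices; restoration validates provided lengths against the
  recorded bookkeeping and reports the offending region on mismatch.
* `sign(0) = 0`, so the inflection test fires at the right edge of
  envelope plateaus.
* Soft thresholding with a zero threshold is skipped (the library
  primitive is 0/0 there); an all-zero signal passes through unchanged.
* Fitting requires more than 3 samples and a full-rank design; collinear
  source leads raise a dedicated error rather than returning a
  minimum-norm solution silently.
* WFDB output quantizes at 2000 ADC units/mV (0.5 µV/step, 16-bit);
  round trips are exact to one quantization step.

## Problem sizes

The test suite and the acceptance script run entirely on generated
data: subjects of 10–20 s for unit and exactness checks, 60 s records
for the two-record train/test protocol, a 170 s record (≈ 200 beats,
10 dB SNR) for detection robustness, and 100 randomized records for the
round-trip and estimator-oracle sweeps.  The full suite completes in a
few seconds on one CPU.

## Known limitations

* Detection has no back-search for missed beats and no interference
  subsidiary criteria; a run of sub-threshold beats lowers sensitivity
  until the adaptive threshold recovers.
* Region boundaries are rate-scaled heuristics, not delineation; ST
  measurements inherit their placement error.
* The H-T region can span up to two cardiac cycles and is modelled by
  the complete-sequence fit, which is a compromise on strongly
  region-dependent subjects.
* Junction amplitude gaps are measured but deliberately left
  unsmoothed.
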