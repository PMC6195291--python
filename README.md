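# arspl — 12-lead ECG synthesis from leads I, II and V2

Wearable and mobile ECG devices record only a few leads, but clinicians
read hearts through the standard 12-lead ECG.  Because the leads of a
12-lead system are strongly correlated projections of the same cardiac
source, the missing leads can be reconstructed from a reduced subset.
This package implements a lightweight, personalized reconstruction
pipeline that synthesizes the full 12-lead ECG from the subset
{I, II, V2}, for signal-processing researchers and engineers prototyping
reduced-lead monitoring systems.

## Method

Three of the nine missing leads are pure arithmetic (Einthoven/Goldberger
identities):

    III = II − I,   aVR = −(I + II)/2,   aVL = I − II/2,   aVF = II − I/2

The five remaining precordial leads (V1, V3–V6) are modelled as affine
combinations of the subset,

    L = a_L + b_L·I + c_L·II + d_L·V2 ,

fitted per subject by least squares, `b = (XᵀX)⁻¹XᵀR` with
`X = [1 | I | II | V2]`.  A single global fit (the common
linear-regression baseline, also provided) ignores that the cardiac
source moves through distinct electrical-activity stages within each
beat.  The piecewise method segments every cardiac cycle into four
regions anchored only on the R peak, using *experienced time windows*:

| region | spans | boundary rule |
|---|---|---|
| QRS    | ventricular systole | `B_QS(n) = peak_x(n) − T_QR·fs` to `B_SE(n) = peak_x(n) + T_RS·fs` |
| ST-T   | ventricular diastole | `B_SE(n)` to `B_TE(n) = peak_x(n) + a_RT·rr(n)·fs` |
| R-P    | resting phase + P wave | `B_TE(n)` to `B_QS(n+1)` |
| H-T    | head + tail of the record | before `B_SE(1)`, after `B_QS(M)` |

with `T_QR = 0.03 s`, `T_RS = 0.04 s`, `a_RT = 0.37`.  Same-type regions
are juxtaposed, one coefficient matrix is fitted per region type (the
H-T matrix on the complete sequences), and the synthesized fragments are
re-split by the recorded segment lengths and pasted back in cycle order —
an exactly invertible reorganization.

R peaks are found by an adaptive detector: the signal is rebuilt from the
stationary-wavelet detail levels covering the QRS band, squared and
smoothed into an energy envelope; envelope inflections above a threshold
(initially 30 % of the first-two-seconds maximum, then 50 % of the three
most recent peak amplitudes) register peaks, validated by a 220-bpm
heart-rate gate and position-corrected against the signal itself.
Preprocessing removes baseline wander and wideband noise by
translation-invariant wavelet shrinkage (sym5, 8 levels, approximation
band zeroed, per-level universal soft thresholds).

Evaluation metrics include per-lead correlation and RMSE, R-peak
detection sensitivity/precision/accuracy, inter-region amplitude gaps,
and the ST-level synthesis error `STSE = ST_syn − ST_ori` (measured 60 ms
after the J-point against a PR reference) with its critical denivelation
ratio `CDR = ER + DR`, the fraction of cycles with |STSE| > 0.1 mV.

A fully ground-truthed synthetic 12-lead generator (sum-of-Gaussians
morphology, region-dependent mixing matrices, baseline/powerline/white
noise) makes every stage testable without any data download.

## Worked example

Simulate a noisy 30 s subject, train on the first 25 s, synthesize the
12-lead record from its 3-lead subset, and score the result:

```sh
arspl --seed 5 simulate subj --duration 30 --white-uv 15 \
      --baseline-uv 150 --powerline-uv 20
arspl train subj.csv --out models.json --train-seconds 25
python -c "from arspl.io import read_record, write_record; \
  r = read_record('subj.csv', fs=1000.0); \
  write_record(r.subset(('I','II','V2')), 'subj3.csv')"
arspl synth subj3.csv --models models.json --out syn.csv
arspl detect subj.csv --truth subj.truth.json
arspl eval syn.csv subj.csv
```

which prints (detection, then evaluation):

```
TP=29 FN=0 FP=0  Se=100.00% +P=100.00% Acc=100.00%
lead,cc,rmse_uv
V1,0.9972,6.171
V3,0.9992,3.547
V4,0.9995,3.132
V5,0.9998,1.668
V6,0.9990,3.128
average,0.9989,3.529
ST (V1): CDR=0.00% ER=0.00% DR=0.00% over 27 cycles
junction gaps (µV): G1=3.7 G2=24.0 G3=0.2
```

All 29 simulated beats are detected with no false positives; the five
synthesized precordial leads correlate with the (preprocessed) reference
at 0.997–0.9998 with errors of a few µV; no cardiac cycle suffers a
critical (> 0.1 mV) ST-level shift; and the mean amplitude steps at
region junctions — an artifact of fitting regions separately — stay in
the tens of µV, below the per-lead RMSE scale.

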