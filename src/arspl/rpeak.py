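"""Adaptive R-peak detection.

The detector rebuilds the signal from the wavelet detail levels whose
bands cover the QRS energy (roughly 3–40 Hz), squares it, smooths it with
a sliding window, and then walks the smoothed energy envelope looking for
inflection points above an adaptive amplitude threshold.  Each accepted
candidate is validated against a maximum-heart-rate gate computed from the
two most recent peaks, and finally the peak positions are corrected
against the original signal, because the smoothing step can shift the
energy maximum a few samples off the true R wave.
"""

from __future__ import annotations

import math

import numpy as np
import pywt

from .core import ArsplConfig, PeakList, samples

__all__ = [
    "DetectionSequence",
    "build_detection_sequence",
    "initial_threshold",
    "detect_peaks",
    "TooFewPeaksError",
]


class TooFewPeaksError(RuntimeError):
    """Fewer than three R peaks were found; segmentation assumes M >= 3."""


class DetectionSequence:
    """Energy envelope ``r`` used for peak search plus its first difference."""

    def __init__(self, r: np.ndarray, fs: float):
        self.r = np.asarray(r, dtype=float)
        self.fs = float(fs)
        self.d = np.diff(self.r)   # d[i] = r[i+1] - r[i]

    def __len__(self) -> int:
        return self.r.size


def _detail_levels_for_fs(fs: float, cfg: ArsplConfig) -> tuple[int, ...]:
    """Shift the configured detail levels so their frequency bands stay put.

    Detail level ``j`` spans ``[fs/2^(j+1), fs/2^j]`` Hz; halving the
    sampling rate moves the same band one level shallower, so the levels
    are shifted by ``round(log2(fs/1000))``.
    """
    if fs == 1000.0:
        return cfg.detection_detail_levels
    shift = int(round(math.log2(fs / 1000.0)))
    return tuple(max(1, j + shift) for j in cfg.detection_detail_levels)


def build_detection_sequence(y: np.ndarray, fs: float,
                             cfg: ArsplConfig | None = None) -> DetectionSequence:
    """Square-and-smooth reconstruction from the QRS-band detail levels.

    The undecimated (stationary) wavelet transform is used so the envelope
    is shift-invariant: with a decimated transform the energy attributed
    to a beat depends on its phase relative to the dyadic grid, which
    makes the adaptive threshold erratic on strictly periodic rhythms.
    """
    cfg = cfg or ArsplConfig()
    y = np.asarray(y, dtype=float)
    levels = _detail_levels_for_fs(fs, cfg)
    depth = max(levels)
    if y.size < 2 ** depth:
        raise ValueError(f"input of length {y.size} too short for detail level {depth}")
    block = 2 ** depth
    pad = (-y.size) % block
    ypad = np.pad(y, (0, pad), mode="symmetric") if pad else y
    coeffs = pywt.swt(ypad, cfg.wavelet_name, level=depth, norm=False)
    # coeffs = [(cA_depth, cD_depth), ..., (cA_1, cD_1)]; keep selected details
    kept = [(np.zeros_like(ca), cd if depth - k in levels else np.zeros_like(cd))
            for k, (ca, cd) in enumerate(coeffs)]
    r = pywt.iswt(kept, cfg.wavelet_name)[: y.size]
    r = r * r
    win = max(1, samples(cfg.smooth_window_s, fs))
    kernel = np.ones(win) / win
    r = np.convolve(r, kernel, mode="same")
    return DetectionSequence(r, fs)


def initial_threshold(det: DetectionSequence, fs: float,
                      cfg: ArsplConfig | None = None) -> float:
    """Fraction of the envelope maximum over the record's opening window."""
    cfg = cfg or ArsplConfig()
    n = samples(cfg.init_threshold_window_s, fs)
    if det.r.size < n:
        raise ValueError(
            f"need at least {n} samples ({cfg.init_threshold_window_s} s at "
            f"{fs} Hz) to set the initial threshold, got {det.r.size}")
    return cfg.init_threshold_frac * float(np.max(det.r[:n]))


def detect_peaks(det: DetectionSequence, y: np.ndarray, fs: float,
                 cfg: ArsplConfig | None = None) -> PeakList:
    """Adaptive-threshold peak search with RR validation and position correction.

    Candidates are inflection points of the envelope (``sign(d[i]) >
    sign(d[i+1])``) above the running threshold.  Each candidate registers
    the envelope maximum within a local window.  A candidate closer to the
    previous registration than the maximum heart rate allows either
    replaces it (when its envelope value is larger) or is dropped.  Once
    ``adapt_peak_count`` peaks exist the threshold tracks
    ``adapt_threshold_frac`` times their recent mean amplitude.  Finally
    every position is moved to the maximum of ``y`` within the correction
    window and its amplitude re-read from ``y``.
    """
    cfg = cfg or ArsplConfig()
    y = np.asarray(y, dtype=float)
    if y.size != len(det):
        raise ValueError("detection sequence and signal lengths differ")
    r, d = det.r, det.d
    n = r.size
    threshold = initial_threshold(det, fs, cfg)
    cand_half = max(1, samples(cfg.candidate_window_s, fs) // 2)
    min_rr_samples = 60.0 / cfg.max_hr_bpm * fs

    xs: list[int] = []
    ys: list[float] = []

    def refresh_threshold() -> float:
        if len(xs) >= cfg.adapt_peak_count:
            recent = ys[-cfg.adapt_peak_count:]
            return cfg.adapt_threshold_frac * float(np.mean(recent))
        return threshold

    sign = np.sign(d)
    for i in range(n - 2):
        if not (sign[i] > sign[i + 1] and r[i] > threshold):
            continue
        lo = max(0, i - cand_half)
        hi = min(n, i + cand_half + 1)
        k = lo + int(np.argmax(r[lo:hi]))
        amp = float(r[k])
        if xs:
            if k <= xs[-1]:
                continue  # same envelope lobe as the previous registration
            if (k - xs[-1]) < min_rr_samples:
                # heart-rate gate: keep the stronger of the conflicting pair
                if amp > ys[-1]:
                    xs[-1], ys[-1] = k, amp
                    threshold = refresh_threshold()
                continue
        xs.append(k)
        ys.append(amp)
        threshold = refresh_threshold()

    if len(xs) < 3:
        raise TooFewPeaksError(f"found {len(xs)} peak(s); at least 3 are required")

    # position correction against the original signal
    corr_half = max(1, samples(cfg.correction_window_s, fs) // 2)
    cx: list[int] = []
    cy: list[float] = []
    for k in xs:
        lo = max(0, k - corr_half)
        hi = min(y.size, k + corr_half + 1)
        j = lo + int(np.argmax(y[lo:hi]))
        if cx and j <= cx[-1]:
            continue  # two envelope peaks collapsed onto one signal maximum
        cx.append(j)
        cy.append(float(y[j]))

    if len(cx) < 3:
        raise TooFewPeaksError(f"only {len(cx)} peak(s) remained after correction")
    return PeakList(np.array(cx), np.array(cy), fs)
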