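"""Evaluation metrics for synthesis quality and R-peak detection.

Synthesis fidelity is scored with the product-moment correlation
coefficient (CC) and the root-mean-square error (RMSE, µV).  Clinical
impact on the ST segment is scored via the ST-level synthesis error
``STSE = ST_syn − ST_ori`` (mV), the ST level being measured 60 ms after
the J-point against a PR-segment reference; the critical denivelation
ratio (CDR) is the fraction of cycles with |STSE| > 0.1 mV, split into
elevation (ER, STSE > 0.1 mV) and depression (DR, STSE < −0.1 mV) ratios,
so CDR = ER + DR by construction.  Detection quality uses
Se = TP/(TP+FN), +P = TP/(TP+FP) and Acc = TP/(TP+FP+FN), all as
percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EcgRecord, PeakList, RegionBoundaries, samples

__all__ = [
    "StReport", "DetectionMetrics", "GapReport",
    "correlation_coefficient", "rmse", "st_level", "st_report",
    "evaluate_detection", "detection_metrics_from_counts", "amplitude_gaps",
]

ST_OFFSET_S = 0.060          # ST measured 60 ms after the J-point
PR_OFFSET_S = 0.020          # PR reference taken 20 ms before the Q start
CRITICAL_STSE_MV = 0.1       # |STSE| above this counts as critical denivelation


@dataclass
class StReport:
    """Per-cycle ST synthesis errors and the denivelation ratios (percent)."""

    stse_mv: np.ndarray
    cdr: float
    er: float
    dr: float
    n_cycles: int


@dataclass
class DetectionMetrics:
    """Beat-level detection counts and the derived percentages."""

    tp: int
    fn: int
    fp: int
    se: float = field(init=False)
    p_plus: float = field(init=False)
    acc: float = field(init=False)

    def __post_init__(self) -> None:
        self.se = 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        self.p_plus = 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0
        denom = self.tp + self.fp + self.fn
        self.acc = 100.0 * self.tp / denom if denom else 0.0


def detection_metrics_from_counts(tp: int, fn: int, fp: int) -> DetectionMetrics:
    """Se/+P/Acc directly from TP/FN/FP beat counts."""
    return DetectionMetrics(tp=tp, fn=fn, fp=fp)


@dataclass
class GapReport:
    """Mean absolute amplitude steps across region junctions, in µV.

    g1: R-P → QRS, g2: QRS → ST-T, g3: ST-T → R-P.
    """

    g1: float
    g2: float
    g3: float
    per_lead: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def correlation_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length sequences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("inputs must share a length of at least 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.corrcoef(a, b)[0, 1])


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square difference, in the inputs' units (µV by convention)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("inputs must share a non-zero length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def st_level(y: np.ndarray, fs: float, j_point: int, pr_ref: int) -> float:
    """ST amplitude 60 ms after the J-point relative to the PR reference, in mV."""
    y = np.asarray(y, dtype=float)
    k = j_point + samples(ST_OFFSET_S, fs)
    if not (0 <= k < y.size) or not (0 <= pr_ref < y.size):
        raise IndexError(f"ST measurement index {k} or PR reference {pr_ref} "
                         f"outside the record [0, {y.size})")
    return (y[k] - y[pr_ref]) / 1000.0


def st_report(syn: EcgRecord, ori: EcgRecord, boundaries: RegionBoundaries,
              fs: float, lead: str = "V1") -> StReport:
    """Cycle-wise STSE and the denivelation ratios on one lead.

    The J-point of cycle n is approximated by the S-end boundary B_SE(n)
    and the PR reference sits 20 ms before the Q-start boundary B_QS(n);
    both exist for cycles 2…M−1, which are the cycles scored.  Inputs are
    expected to be baseline-free (the pipeline denoises before synthesis).
    """
    if syn.n_samples != ori.n_samples:
        raise ValueError("records must have equal length")
    ys, yo = syn.leads[lead], ori.leads[lead]
    b_se, b_qs = boundaries.b_se, boundaries.b_qs
    stse = []
    for k in range(1, len(b_se)):        # cycle n = k+1, n = 2…M−1
        j_point = int(b_se[k])
        pr_ref = max(0, int(b_qs[k - 1]) - samples(PR_OFFSET_S, fs))
        stse.append(st_level(ys, fs, j_point, pr_ref)
                    - st_level(yo, fs, j_point, pr_ref))
    stse = np.asarray(stse)
    n = stse.size
    if n == 0:
        raise ValueError("no scorable cycles (need M >= 3 peaks)")
    er = 100.0 * np.count_nonzero(stse > CRITICAL_STSE_MV) / n
    dr = 100.0 * np.count_nonzero(stse < -CRITICAL_STSE_MV) / n
    return StReport(stse_mv=stse, cdr=er + dr, er=er, dr=dr, n_cycles=n)


def evaluate_detection(detected: PeakList | np.ndarray, truth: np.ndarray,
                       fs: float, tol_s: float = 0.05) -> DetectionMetrics:
    """Match detected peaks to ground truth one-to-one within a tolerance.

    Each true peak is matched greedily (in time order) to the nearest
    unmatched detection within ``tol_s`` seconds; unmatched truths are
    false negatives, unmatched detections false positives.
    """
    if tol_s <= 0:
        raise ValueError("tolerance must be positive")
    det = np.sort(np.asarray(detected.peak_x if isinstance(detected, PeakList)
                             else detected, dtype=float))
    tru = np.sort(np.asarray(truth, dtype=float))
    tol = tol_s * fs
    used = np.zeros(det.size, dtype=bool)
    tp = 0
    for t in tru:
        candidates = np.nonzero(~used & (np.abs(det - t) <= tol))[0]
        if candidates.size:
            best = candidates[np.argmin(np.abs(det[candidates] - t))]
            used[best] = True
            tp += 1
    fn = tru.size - tp
    fp = det.size - tp
    return DetectionMetrics(tp=tp, fn=fn, fp=fp)


def amplitude_gaps(record: EcgRecord, boundaries: RegionBoundaries) -> GapReport:
    """Mean absolute amplitude steps at the three region-junction types.

    The step at a boundary b is ``|y[b] − y[b−1]|`` (first sample after
    minus last sample before).  Junctions scored: R-P→QRS at B_QS(n) for
    n = 2…M−1, QRS→ST-T at B_SE(n) for n = 2…M−1, ST-T→R-P at B_TE(n) for
    n = 1…M−1.
    """
    b_se, b_te, b_qs = boundaries.b_se, boundaries.b_te, boundaries.b_qs
    per_lead: dict[str, tuple[float, float, float]] = {}

    def steps(y: np.ndarray, idx: np.ndarray) -> float:
        idx = idx[(idx >= 1) & (idx < y.size)]
        if idx.size == 0:
            return 0.0
        return float(np.mean(np.abs(y[idx] - y[idx - 1])))

    for lead, y in record.leads.items():
        g1 = steps(y, b_qs[:-1])   # R-P → QRS entries, cycles 2…M−1
        g2 = steps(y, b_se[1:])    # QRS → ST-T, cycles 2…M−1
        g3 = steps(y, b_te)        # ST-T → R-P, cycles 1…M−1
        per_lead[lead] = (g1, g2, g3)
    gs = np.array(list(per_lead.values()))
    return GapReport(g1=float(gs[:, 0].mean()), g2=float(gs[:, 1].mean()),
                     g3=float(gs[:, 2].mean()), per_lead=per_lead)
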