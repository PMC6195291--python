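"""Region boundary derivation and segmentation by experienced time windows.

Each cardiac cycle is split into four regions anchored only on the R peak:

* ``B_SE(n) = peak_x(n) + T_RS*fs`` approximates the end of the S wave,
* ``B_TE(n) = peak_x(n) + a_RT*rr(n)*fs`` the end of the T wave (the R-T
  window scales with the R-R interval),
* ``B_QS(n) = peak_x(n) - T_QR*fs`` the start of the Q wave.

``B_SE``/``B_TE`` exist for cycles 1…M−1 and ``B_QS`` for cycles 2…M, so
the segmentation pattern is fixed regardless of where the recording
starts or ends: M−1 ST-T fragments, M−1 R-P fragments, M−2 QRS fragments
and a single head–tail (H-T) region.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import (ArsplConfig, EcgRecord, PeakList, RegionBoundaries,
                   SegmentLengths, SegmentationResult, samples)

__all__ = ["adjust_time_windows", "derive_boundaries", "segment",
           "region_slices", "InconsistentBoundariesError"]

log = logging.getLogger(__name__)

REGION_NAMES = ("stt", "rp", "qrs", "ht")


class InconsistentBoundariesError(ValueError):
    """Boundaries do not match the peak list or the record length."""


def adjust_time_windows(peaks: PeakList, cfg: ArsplConfig | None = None) -> np.ndarray:
    """R-T experienced windows in seconds: ``T_RT(n) = a_RT * rr(n)``."""
    cfg = cfg or ArsplConfig()
    if peaks.M < 3:
        raise ValueError(f"need at least 3 peaks, got {peaks.M}")
    return cfg.a_rt * peaks.rr


def derive_boundaries(peaks: PeakList, fs: float, cfg: ArsplConfig | None = None,
                      n_samples: int | None = None) -> RegionBoundaries:
    """Compute the three boundary families from the peak positions.

    ``n_samples`` bounds the record; boundaries falling outside it are
    clamped with a warning.  Overlapping windows in short cycles are
    resolved so the partition stays valid: the T-end is pulled back to one
    sample before the next Q-start (keeping the R-P fragment non-empty)
    and a T-end that would precede its own S-end yields an empty ST-T
    fragment.
    """
    cfg = cfg or ArsplConfig()
    if peaks.M < 3:
        raise ValueError(f"need at least 3 peaks, got {peaks.M}")
    px = peaks.peak_x
    t_rt = adjust_time_windows(peaks, cfg)

    b_se = px[:-1] + samples(cfg.t_rs, fs)
    b_te = px[:-1] + np.array([samples(t, fs) for t in t_rt])
    b_qs = px[1:] - samples(cfg.t_qr, fs)

    if n_samples is not None:
        for name, arr in (("B_SE", b_se), ("B_TE", b_te), ("B_QS", b_qs)):
            out = (arr < 0) | (arr > n_samples)
            if np.any(out):
                log.warning("%d %s boundary(ies) outside [0, %d); clamped",
                            int(out.sum()), name, n_samples)
            np.clip(arr, 0, n_samples, out=arr)
        if b_se[0] > n_samples or b_qs[-1] > n_samples:
            raise InconsistentBoundariesError("boundary exceeds record length")

    # resolve overlaps cycle by cycle (rare; short/tachycardic cycles only)
    m1 = len(b_se)
    for k in range(m1):
        if b_te[k] >= b_qs[k]:
            b_te[k] = b_qs[k] - 1
        if b_te[k] < b_se[k]:
            b_te[k] = b_se[k]          # empty ST-T fragment
        if b_qs[k] < b_te[k]:
            b_qs[k] = b_te[k]          # degenerate: empty R-P fragment
        if k + 1 < m1 and b_se[k + 1] < b_qs[k]:
            b_se[k + 1] = b_qs[k]      # degenerate: empty QRS fragment

    return RegionBoundaries(b_se, b_te, b_qs,
                            n_samples=int(n_samples) if n_samples is not None else -1)


def region_slices(boundaries: RegionBoundaries, n_samples: int
                  ) -> dict[str, list[tuple[int, int]]]:
    """Half-open ``[start, stop)`` index ranges of every fragment, in cycle order.

    ``ht`` carries exactly two entries: the head ``[0, B_SE(1))`` and the
    tail ``[B_QS(M), N)``.
    """
    b_se, b_te, b_qs = boundaries.b_se, boundaries.b_te, boundaries.b_qs
    m1 = len(b_se)
    out: dict[str, list[tuple[int, int]]] = {
        "stt": [(int(b_se[k]), int(b_te[k])) for k in range(m1)],
        "rp": [(int(b_te[k]), int(b_qs[k])) for k in range(m1)],
        "qrs": [(int(b_qs[k]), int(b_se[k + 1])) for k in range(m1 - 1)],
        "ht": [(0, int(b_se[0])), (int(b_qs[-1]), int(n_samples))],
    }
    return out


def segment(record: EcgRecord, boundaries: RegionBoundaries,
            peaks: PeakList | None = None) -> SegmentationResult:
    """Partition every lead into the four reorganized region subsequences.

    Fragments of the same region type are concatenated in cycle order; the
    H-T sequence is the head fragment followed by the tail fragment.  The
    partition is exact: every sample belongs to exactly one region.
    """
    n = record.n_samples
    if peaks is not None and boundaries.M != peaks.M:
        raise InconsistentBoundariesError(
            f"boundaries built for M={boundaries.M} peaks, got {peaks.M}")
    if boundaries.n_samples not in (-1, n):
        raise InconsistentBoundariesError(
            f"boundaries built for N={boundaries.n_samples}, record has N={n}")
    b_se, b_te, b_qs = boundaries.b_se, boundaries.b_te, boundaries.b_qs
    cuts = np.empty(3 * len(b_se), dtype=int)
    cuts[0::3], cuts[1::3], cuts[2::3] = b_se, b_te, b_qs
    if np.any(np.diff(cuts) < 0) or cuts[0] < 0 or cuts[-1] > n:
        raise InconsistentBoundariesError("boundaries are not monotone within the record")

    slices = region_slices(boundaries, n)
    lengths = SegmentLengths(
        stt=b_te - b_se,
        rp=b_qs - b_te,
        qrs=b_se[1:] - b_qs[:-1],
        head_len=int(b_se[0]),
        tail_len=int(n - b_qs[-1]),
    )
    assert lengths.total == n, "partition must conserve samples"

    regions: dict[str, dict[str, np.ndarray]] = {}
    for lead, y in record.leads.items():
        regions[lead] = {
            name: (np.concatenate([y[a:b] for a, b in frags]) if frags
                   else np.empty(0))
            for name, frags in slices.items()
        }
    return SegmentationResult(regions=regions, lengths=lengths, boundaries=boundaries)
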