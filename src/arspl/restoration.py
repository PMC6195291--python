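"""Exact inversion of region segmentation.

Given the four reorganized region subsequences of a lead and the per-cycle
fragment lengths recorded at segmentation time, the full-length sequence is
rebuilt by pasting fragments strictly in cycle order:

    head | ST-T(1) | [R-P(n) QRS(n) ST-T(n)] for n = 2…M−1 | R-P(M) | tail

where the head is the first ``head_len`` points of the H-T subsequence and
the tail is the rest of it.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .core import RegionBoundaries, SegmentLengths, SegmentationResult

__all__ = ["record_segment_lengths", "restore_lead", "restore",
           "LengthInconsistencyError"]


class LengthInconsistencyError(ValueError):
    """Provided subsequences do not match the recorded segment lengths."""


def record_segment_lengths(boundaries: RegionBoundaries) -> SegmentLengths:
    """Fragment-length bookkeeping from the boundary families.

    Requires boundaries constructed with a known record length (``n_samples``),
    since the tail length depends on it.
    """
    if boundaries.n_samples < 0:
        raise ValueError("boundaries carry no record length; cannot size the tail")
    return SegmentLengths(
        stt=boundaries.b_te - boundaries.b_se,
        rp=boundaries.b_qs - boundaries.b_te,
        qrs=boundaries.b_se[1:] - boundaries.b_qs[:-1],
        head_len=int(boundaries.b_se[0]),
        tail_len=int(boundaries.n_samples - boundaries.b_qs[-1]),
    )


def _check(region: str, provided: int, expected: int) -> None:
    if provided != expected:
        raise LengthInconsistencyError(
            f"{region} subsequence has {provided} samples but the recorded "
            f"lengths require {expected}")


def restore_lead(region_seqs: Mapping[str, np.ndarray],
                 lengths: SegmentLengths) -> np.ndarray:
    """Rebuild one lead from its ``stt``/``rp``/``qrs``/``ht`` subsequences."""
    stt = np.asarray(region_seqs["stt"], dtype=float)
    rp = np.asarray(region_seqs["rp"], dtype=float)
    qrs = np.asarray(region_seqs["qrs"], dtype=float)
    ht = np.asarray(region_seqs["ht"], dtype=float)
    _check("stt", stt.size, int(lengths.stt.sum()))
    _check("rp", rp.size, int(lengths.rp.sum()))
    _check("qrs", qrs.size, int(lengths.qrs.sum()))
    _check("ht", ht.size, lengths.head_len + lengths.tail_len)

    n = lengths.total
    out = np.empty(n)
    pos = 0
    p_stt = p_rp = p_qrs = 0

    def paste(src: np.ndarray, start: int, length: int) -> int:
        nonlocal pos
        out[pos:pos + length] = src[start:start + length]
        pos += length
        return start + length

    # head, then ST-T(1)
    paste(ht, 0, lengths.head_len)
    p_stt = paste(stt, p_stt, int(lengths.stt[0]))
    # cycles 2 … M-1: R-P(n), QRS(n), ST-T(n)
    m1 = len(lengths.stt)           # = M - 1
    for k in range(m1 - 1):         # cycle n = k + 2
        p_rp = paste(rp, p_rp, int(lengths.rp[k]))
        p_qrs = paste(qrs, p_qrs, int(lengths.qrs[k]))
        p_stt = paste(stt, p_stt, int(lengths.stt[k + 1]))
    # R-P(M), then tail
    paste(rp, p_rp, int(lengths.rp[m1 - 1]))
    paste(ht, lengths.head_len, lengths.tail_len)
    assert pos == n
    return out


def restore(region_seqs: Mapping[str, Mapping[str, np.ndarray]] | SegmentationResult,
            lengths: SegmentLengths | None = None) -> dict[str, np.ndarray]:
    """Rebuild every lead; accepts a SegmentationResult or a plain mapping."""
    if isinstance(region_seqs, SegmentationResult):
        lengths = lengths or region_seqs.lengths
        region_seqs = region_seqs.regions
    if lengths is None:
        raise ValueError("segment lengths are required")
    return {lead: restore_lead(regions, lengths)
            for lead, regions in region_seqs.items()}
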