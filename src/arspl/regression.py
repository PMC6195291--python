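"""Piecewise linear regression: model fitting and 12-lead synthesis.

Every target lead L is modelled as an affine combination of the reduced
subset, ``L = a + b*I + c*II + d*V2``.  The piecewise variant fits one
coefficient matrix per region type (ST-T, R-P, QRS), with the H-T matrix
fitted on the complete sequences, because the head and tail of a recording
are unrelated fragments of arbitrary cardiac phase.  Synthesis segments the
3-lead input with the same boundary rules, applies the regional matrices,
restores the full-length precordial leads, and derives the limb leads
arithmetically (III = II − I, aVR = −(I+II)/2, aVL = I − II/2,
aVF = II − I/2).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import scipy.linalg

from .core import (ArsplConfig, EcgRecord, PeakList, RegionModels,
                   SegmentationResult, SOURCE_LEADS, TARGET_PRECORDIAL_LEADS,
                   validate_record)
from .preprocess import denoise
from .restoration import restore_lead
from .rpeak import build_detection_sequence, detect_peaks
from .segmentation import derive_boundaries, segment

__all__ = [
    "fit_lr", "apply_lr", "derive_limb_leads", "train_arspl", "train",
    "train_global_lr", "synthesize", "synthesize_lr", "segment_source",
    "UnderdeterminedError", "SingularDesignError", "PatternMismatchError",
]

log = logging.getLogger(__name__)


class UnderdeterminedError(ValueError):
    """Fewer samples than unknowns (N must exceed the 4 coefficients' rank)."""


class SingularDesignError(ValueError):
    """The augmented design matrix [1 | source] is rank deficient."""


class PatternMismatchError(ValueError):
    """Source and target segmentations were built from different boundaries."""


def _design(source: np.ndarray) -> np.ndarray:
    source = np.atleast_2d(np.asarray(source, dtype=float))
    return np.column_stack([np.ones(source.shape[0]), source])


def fit_lr(source: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Least-squares coefficients mapping [1 | source] onto the targets.

    Solves ``min ||X b − R||_F`` with ``X = [1 | source]`` (N×4) by a
    QR-type factorization; equivalent to the normal-equations solution
    ``(XᵀX)⁻¹XᵀR`` on full-rank problems but numerically stabler.
    """
    source = np.asarray(source, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 1:
        targets = targets[:, None]
    if source.shape[0] != targets.shape[0]:
        raise ValueError("source and targets must have the same sample count")
    if source.shape[0] <= 3:
        raise UnderdeterminedError(
            f"need more than 3 samples to fit 4 coefficients, got {source.shape[0]}")
    x = _design(source)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise SingularDesignError("design matrix [1 | source] is rank deficient "
                                  "(collinear source leads)")
    b, *_ = scipy.linalg.lstsq(x, targets, lapack_driver="gelsy")
    return b


def apply_lr(source: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Synthesize targets as ``[1 | source] · b``."""
    x = _design(source)
    b = np.asarray(b, dtype=float)
    if x.shape[1] != b.shape[0]:
        raise ValueError(f"coefficient matrix expects {b.shape[0] - 1} source "
                         f"leads, got {x.shape[1] - 1}")
    return x @ b


def derive_limb_leads(lead_i: np.ndarray, lead_ii: np.ndarray) -> dict[str, np.ndarray]:
    """Arithmetic limb/augmented leads from leads I and II."""
    lead_i = np.asarray(lead_i, dtype=float)
    lead_ii = np.asarray(lead_ii, dtype=float)
    if lead_i.shape != lead_ii.shape:
        raise ValueError("leads I and II must have equal length")
    return {
        "III": lead_ii - lead_i,
        "aVR": -(lead_i + lead_ii) / 2.0,
        "aVL": lead_i - lead_ii / 2.0,
        "aVF": lead_ii - lead_i / 2.0,
    }


def train_arspl(seg3: SegmentationResult, seg_targets: SegmentationResult,
                full3: np.ndarray, full_targets: np.ndarray,
                target_leads: Sequence[str] = TARGET_PRECORDIAL_LEADS
                ) -> RegionModels:
    """Fit the four regional matrices.

    ST-T, R-P and QRS matrices are fitted on the respective reorganized
    subsequences; the H-T matrix on the complete (unsegmented) sequences.
    Source and target segmentations must share one boundary pattern.
    """
    ba, bb = seg3.boundaries, seg_targets.boundaries
    if (not np.array_equal(ba.b_se, bb.b_se) or not np.array_equal(ba.b_te, bb.b_te)
            or not np.array_equal(ba.b_qs, bb.b_qs)):
        raise PatternMismatchError("source and target segmentations disagree")
    target_leads = tuple(target_leads)

    def region_fit(region: str) -> np.ndarray:
        src = seg3.region_matrix(region, SOURCE_LEADS)
        tgt = seg_targets.region_matrix(region, target_leads)
        return fit_lr(src, tgt)

    return RegionModels(
        b_stt=region_fit("stt"),
        b_rp=region_fit("rp"),
        b_qrs=region_fit("qrs"),
        b_ht=fit_lr(full3, full_targets),
        target_leads=target_leads,
    )


def segment_source(record: EcgRecord, cfg: ArsplConfig | None = None, *,
                   peaks: PeakList | None = None, preprocess: bool = True
                   ) -> tuple[EcgRecord, PeakList, SegmentationResult]:
    """Shared front end: denoise, detect R peaks, derive boundaries, segment.

    ``peaks`` may supply externally known R positions (e.g. ground truth),
    skipping detection; ``preprocess=False`` skips wavelet denoising.
    """
    cfg = cfg or ArsplConfig()
    if preprocess:
        record = EcgRecord(record.fs, {name: denoise(y, record.fs, cfg)
                                       for name, y in record.leads.items()})
    if peaks is None:
        lead = cfg.detection_lead if cfg.detection_lead in record.leads \
            else next(iter(record.leads))
        y = record.leads[lead]
        det = build_detection_sequence(y, record.fs, cfg)
        peaks = detect_peaks(det, y, record.fs, cfg)
    boundaries = derive_boundaries(peaks, record.fs, cfg, n_samples=record.n_samples)
    return record, peaks, segment(record, boundaries, peaks)


def train(record: EcgRecord, cfg: ArsplConfig | None = None, *,
          train_seconds: float | None = None,
          target_leads: Sequence[str] = TARGET_PRECORDIAL_LEADS,
          peaks: PeakList | None = None, preprocess: bool = True) -> RegionModels:
    """End-to-end personalized training from a record carrying all leads."""
    cfg = cfg or ArsplConfig()
    validate_record(record, tuple(SOURCE_LEADS) + tuple(target_leads))
    if train_seconds is not None:
        n = min(record.n_samples, int(round(train_seconds * record.fs)))
        if n / record.fs < 10.0:
            log.warning("training on only %.1f s of data; coefficients may be "
                        "poorly conditioned", n / record.fs)
        record = EcgRecord(record.fs, {k: v[:n] for k, v in record.leads.items()})
        if peaks is not None:
            keep = peaks.peak_x < n
            peaks = PeakList(peaks.peak_x[keep], peaks.peak_y[keep], peaks.fs)
    processed, _, seg = segment_source(record, cfg, peaks=peaks,
                                       preprocess=preprocess)
    seg3 = SegmentationResult(
        regions={k: seg.regions[k] for k in SOURCE_LEADS},
        lengths=seg.lengths, boundaries=seg.boundaries)
    seg_t = SegmentationResult(
        regions={k: seg.regions[k] for k in target_leads},
        lengths=seg.lengths, boundaries=seg.boundaries)
    return train_arspl(seg3, seg_t,
                       processed.matrix(SOURCE_LEADS),
                       processed.matrix(target_leads),
                       target_leads=target_leads)


def train_global_lr(record: EcgRecord, cfg: ArsplConfig | None = None, *,
                    train_seconds: float | None = None,
                    target_leads: Sequence[str] = TARGET_PRECORDIAL_LEADS,
                    preprocess: bool = True) -> np.ndarray:
    """Baseline: one global coefficient matrix on the complete sequences."""
    cfg = cfg or ArsplConfig()
    validate_record(record, tuple(SOURCE_LEADS) + tuple(target_leads))
    if train_seconds is not None:
        n = min(record.n_samples, int(round(train_seconds * record.fs)))
        record = EcgRecord(record.fs, {k: v[:n] for k, v in record.leads.items()})
    if preprocess:
        record = EcgRecord(record.fs, {name: denoise(y, record.fs, cfg)
                                       for name, y in record.leads.items()})
    return fit_lr(record.matrix(SOURCE_LEADS), record.matrix(target_leads))


def synthesize(record3: EcgRecord, models: RegionModels,
               cfg: ArsplConfig | None = None, *,
               peaks: PeakList | None = None,
               preprocess: bool = True) -> EcgRecord:
    """Reconstruct the standard 12-lead record from leads {I, II, V2}.

    The source leads pass through (preprocessed when ``preprocess`` is on);
    the five remaining precordial leads are synthesized region by region
    and restored to full length; the limb leads follow arithmetically.
    """
    cfg = cfg or ArsplConfig()
    validate_record(record3, SOURCE_LEADS)
    processed, _, seg = segment_source(record3.subset(SOURCE_LEADS), cfg,
                                       peaks=peaks, preprocess=preprocess)
    matrices = {"stt": models.b_stt, "rp": models.b_rp,
                "qrs": models.b_qrs, "ht": models.b_ht}
    synth_regions: dict[str, dict[str, np.ndarray]] = {
        lead: {} for lead in models.target_leads}
    for region, b in matrices.items():
        src = seg.region_matrix(region, SOURCE_LEADS)
        out = apply_lr(src, b) if src.shape[0] else np.empty((0, len(models.target_leads)))
        for j, lead in enumerate(models.target_leads):
            synth_regions[lead][region] = out[:, j]
    leads: dict[str, np.ndarray] = {}
    i, ii, v2 = (processed.leads[k] for k in SOURCE_LEADS)
    limb = derive_limb_leads(i, ii)
    restored = {lead: restore_lead(regions, seg.lengths)
                for lead, regions in synth_regions.items()}
    for name in ("I", "II", "III", "aVR", "aVL", "aVF",
                 "V1", "V2", "V3", "V4", "V5", "V6"):
        if name in SOURCE_LEADS:
            leads[name] = processed.leads[name]
        elif name in limb:
            leads[name] = limb[name]
        elif name in restored:
            leads[name] = restored[name]
    return EcgRecord(record3.fs, leads)


def synthesize_lr(record3: EcgRecord, b: np.ndarray,
                  cfg: ArsplConfig | None = None, *,
                  target_leads: Sequence[str] = TARGET_PRECORDIAL_LEADS,
                  preprocess: bool = True) -> EcgRecord:
    """Baseline reconstruction with a single global coefficient matrix."""
    cfg = cfg or ArsplConfig()
    validate_record(record3, SOURCE_LEADS)
    rec = record3.subset(SOURCE_LEADS)
    if preprocess:
        rec = EcgRecord(rec.fs, {name: denoise(y, rec.fs, cfg)
                                 for name, y in rec.leads.items()})
    out = apply_lr(rec.matrix(SOURCE_LEADS), b)
    i, ii = rec.leads["I"], rec.leads["II"]
    limb = derive_limb_leads(i, ii)
    leads: dict[str, np.ndarray] = {}
    for name in ("I", "II", "III", "aVR", "aVL", "aVF",
                 "V1", "V2", "V3", "V4", "V5", "V6"):
        if name in SOURCE_LEADS:
            leads[name] = rec.leads[name]
        elif name in limb:
            leads[name] = limb[name]
        else:
            leads[name] = out[:, tuple(target_leads).index(name)]
    return EcgRecord(record3.fs, leads)
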