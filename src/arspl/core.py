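"""Domain types and configuration shared by every pipeline stage.

Conventions enforced package-wide:

* amplitudes are in microvolts (µV); the 0.1 mV ST-denivelation threshold
  is therefore 100 µV;
* sample indices are 0-based and all internal ranges are half-open
  ``[start, stop)``;
* time windows expressed in seconds are converted to samples by rounding
  ``t * fs`` to the nearest integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "EcgRecord",
    "PeakList",
    "RegionBoundaries",
    "SegmentLengths",
    "SegmentationResult",
    "RegionModels",
    "ArsplConfig",
    "validate_record",
    "SOURCE_LEADS",
    "TARGET_PRECORDIAL_LEADS",
    "STANDARD_12_LEADS",
]

#: The reduced subset every synthesis starts from.
SOURCE_LEADS = ("I", "II", "V2")

#: Precordial leads reconstructed by regression (the rest are arithmetic).
TARGET_PRECORDIAL_LEADS = ("V1", "V3", "V4", "V5", "V6")

STANDARD_12_LEADS = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)


class MissingLeadError(KeyError):
    """A required lead is absent from the record."""


class LengthMismatchError(ValueError):
    """Lead sequences of one record differ in length."""


class SamplingRateError(ValueError):
    """Sampling rate is not a positive number."""


@dataclass
class EcgRecord:
    """A sampled multi-lead ECG.

    Parameters
    ----------
    fs:
        Sampling rate in Hz, strictly positive.
    leads:
        Ordered mapping from lead name to amplitude sequence in µV.
        All sequences must share one length ``n_samples``.
    """

    fs: float
    leads: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise SamplingRateError(f"sampling rate must be > 0, got {self.fs}")
        self.leads = {name: np.asarray(y, dtype=float) for name, y in self.leads.items()}
        if not self.leads:
            raise ValueError("record has no leads")
        lengths = {name: y.shape[0] for name, y in self.leads.items()}
        if len(set(lengths.values())) != 1:
            raise LengthMismatchError(f"lead lengths differ: {lengths}")
        if self.n_samples < 1:
            raise ValueError("record must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return next(iter(self.leads.values())).shape[0]

    @property
    def lead_names(self) -> tuple[str, ...]:
        return tuple(self.leads)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def matrix(self, names: Sequence[str]) -> np.ndarray:
        """Stack the named leads into an ``n_samples × len(names)`` array."""
        missing = [n for n in names if n not in self.leads]
        if missing:
            raise MissingLeadError(f"record lacks lead(s) {missing}")
        return np.column_stack([self.leads[n] for n in names])

    def subset(self, names: Sequence[str]) -> "EcgRecord":
        return EcgRecord(self.fs, {n: self.leads[n].copy() for n in names})


def validate_record(record: EcgRecord, required_leads: Sequence[str]) -> EcgRecord:
    """Check that ``record`` carries the required leads and is well formed.

    Returns the record unchanged; raises :class:`MissingLeadError`,
    :class:`LengthMismatchError` or :class:`SamplingRateError` otherwise.
    (Length and fs invariants are re-checked so that records mutated after
    construction are still caught.)
    """
    if record.fs <= 0:
        raise SamplingRateError(f"sampling rate must be > 0, got {record.fs}")
    lengths = {name: np.asarray(y).shape[0] for name, y in record.leads.items()}
    if len(set(lengths.values())) != 1:
        raise LengthMismatchError(f"lead lengths differ: {lengths}")
    for name in required_leads:
        if name not in record.leads:
            raise MissingLeadError(f"required lead {name!r} missing from record "
                                   f"(present: {list(record.leads)})")
    return record


@dataclass
class PeakList:
    """Detected R peaks: sample indices, amplitudes and R-R intervals."""

    peak_x: np.ndarray   # sample indices, strictly increasing
    peak_y: np.ndarray   # amplitudes in µV (or detection-sequence units)
    fs: float

    def __post_init__(self) -> None:
        self.peak_x = np.asarray(self.peak_x, dtype=int)
        self.peak_y = np.asarray(self.peak_y, dtype=float)
        if self.peak_x.shape != self.peak_y.shape:
            raise ValueError("peak_x and peak_y must have equal length")
        if np.any(np.diff(self.peak_x) <= 0):
            raise ValueError("peak_x must be strictly increasing")

    @property
    def M(self) -> int:
        return int(self.peak_x.shape[0])

    @property
    def rr(self) -> np.ndarray:
        """R-R intervals in seconds, ``rr[n] = (peak_x[n+1]-peak_x[n])/fs``."""
        return np.diff(self.peak_x) / self.fs


@dataclass
class RegionBoundaries:
    """Per-cycle region boundaries, all in samples (0-based).

    ``b_se`` (end of S) and ``b_te`` (end of T) exist for cycles 1…M−1,
    ``b_qs`` (start of Q) for cycles 2…M; arrays are stored densely, so
    ``b_se[n]`` is cycle ``n+1``'s value and ``b_qs[n]`` is cycle ``n+2``'s.
    """

    b_se: np.ndarray   # length M-1
    b_te: np.ndarray   # length M-1
    b_qs: np.ndarray   # length M-1
    n_samples: int

    def __post_init__(self) -> None:
        self.b_se = np.asarray(self.b_se, dtype=int)
        self.b_te = np.asarray(self.b_te, dtype=int)
        self.b_qs = np.asarray(self.b_qs, dtype=int)
        if not (len(self.b_se) == len(self.b_te) == len(self.b_qs)):
            raise ValueError("boundary families must all have length M-1")

    @property
    def M(self) -> int:
        return int(len(self.b_se) + 1)


@dataclass
class SegmentLengths:
    """Fragment lengths in samples; the bookkeeping that makes restoration exact.

    ``stt[n] = b_te[n] - b_se[n]`` (cycles 1…M−1),
    ``rp[n] = b_qs[n] - b_te[n-1]`` (cycles 2…M),
    ``qrs[n] = b_se[n] - b_qs[n]`` (cycles 2…M−1),
    plus the head (samples before ``b_se(1)``) and tail (samples from
    ``b_qs(M)``) of the record.
    """

    stt: np.ndarray
    rp: np.ndarray
    qrs: np.ndarray
    head_len: int
    tail_len: int

    def __post_init__(self) -> None:
        self.stt = np.asarray(self.stt, dtype=int)
        self.rp = np.asarray(self.rp, dtype=int)
        self.qrs = np.asarray(self.qrs, dtype=int)
        for name, arr in (("stt", self.stt), ("rp", self.rp), ("qrs", self.qrs)):
            if np.any(arr < 0):
                raise ValueError(f"negative {name} segment length: {arr}")
        if self.head_len < 0 or self.tail_len < 0:
            raise ValueError("head/tail lengths must be non-negative")

    @property
    def total(self) -> int:
        return int(self.stt.sum() + self.rp.sum() + self.qrs.sum()
                   + self.head_len + self.tail_len)


@dataclass
class SegmentationResult:
    """Reorganized region subsequences per lead.

    ``regions[lead]`` maps region name (``"stt"``, ``"rp"``, ``"qrs"``,
    ``"ht"``) to the concatenation of that region's fragments in cycle
    order; the H-T sequence is head followed by tail.
    """

    regions: dict[str, dict[str, np.ndarray]]
    lengths: SegmentLengths
    boundaries: RegionBoundaries

    @property
    def lead_names(self) -> tuple[str, ...]:
        return tuple(self.regions)

    def region_matrix(self, region: str, names: Sequence[str]) -> np.ndarray:
        return np.column_stack([self.regions[n][region] for n in names])


@dataclass
class RegionModels:
    """The four regional 4×K transformation matrices.

    Rows correspond to (intercept, I, II, V2); columns to ``target_leads``.
    The H-T matrix is fitted on the complete (unsegmented) sequences.
    """

    b_stt: np.ndarray
    b_rp: np.ndarray
    b_qrs: np.ndarray
    b_ht: np.ndarray
    target_leads: tuple[str, ...]

    def __post_init__(self) -> None:
        mats = {"b_stt": self.b_stt, "b_rp": self.b_rp,
                "b_qrs": self.b_qrs, "b_ht": self.b_ht}
        shape = None
        for name, m in mats.items():
            m = np.asarray(m, dtype=float)
            setattr(self, name, m)
            if m.ndim != 2 or m.shape[0] != 4:
                raise ValueError(f"{name} must be 4×K, got {m.shape}")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"{name} contains non-finite entries")
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise ValueError("all four matrices must share one shape")
        if shape[1] != len(self.target_leads):
            raise ValueError("column count must match target_leads")
        self.target_leads = tuple(self.target_leads)

    def as_dict(self) -> dict:
        return {
            "target_leads": list(self.target_leads),
            "b_stt": self.b_stt.tolist(),
            "b_rp": self.b_rp.tolist(),
            "b_qrs": self.b_qrs.tolist(),
            "b_ht": self.b_ht.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RegionModels":
        return cls(
            b_stt=np.asarray(d["b_stt"], dtype=float),
            b_rp=np.asarray(d["b_rp"], dtype=float),
            b_qrs=np.asarray(d["b_qrs"], dtype=float),
            b_ht=np.asarray(d["b_ht"], dtype=float),
            target_leads=tuple(d["target_leads"]),
        )


@dataclass
class ArsplConfig:
    """Tunable parameters of the segmentation/synthesis pipeline.

    Defaults follow the published optimal operating point for 1000 Hz
    recordings: sym5 wavelet, 8 decomposition levels, detection sequence
    rebuilt from detail levels 3–5, initial threshold 30% of the maximum
    of the first two seconds, adaptive threshold 50% of the mean of the
    three most recent peak amplitudes, a 220 bpm heart-rate gate, and
    experienced time windows T_QR = 0.03 s, T_RS = 0.04 s, a_RT = 0.37.
    """

    wavelet_name: str = "sym5"
    decomp_levels: int = 8
    detection_detail_levels: tuple[int, ...] = (3, 4, 5)
    init_threshold_frac: float = 0.30
    init_threshold_window_s: float = 2.0
    adapt_threshold_frac: float = 0.50
    adapt_peak_count: int = 3
    max_hr_bpm: float = 220.0
    t_qr: float = 0.03          # Q-to-R experienced window, s
    t_rs: float = 0.04          # R-to-S experienced window, s
    a_rt: float = 0.37          # R-to-T window as a fraction of rr
    smooth_window_s: float = 0.15
    candidate_window_s: float = 0.10
    correction_window_s: float = 0.05
    detection_lead: str = "II"
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("init_threshold_window_s", "smooth_window_s",
                     "candidate_window_s", "correction_window_s",
                     "t_qr", "t_rs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("init_threshold_frac", "adapt_threshold_frac", "a_rt"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.max_hr_bpm <= 0:
            raise ValueError("max_hr_bpm must be > 0")
        self.detection_detail_levels = tuple(int(j) for j in self.detection_detail_levels)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["detection_detail_levels"] = list(self.detection_detail_levels)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ArsplConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**{k: (tuple(v) if k == "detection_detail_levels" else v)
                      for k, v in d.items()})


def samples(t_seconds: float, fs: float) -> int:
    """Convert a time window to whole samples, rounding to nearest."""
    return int(round(t_seconds * fs))
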