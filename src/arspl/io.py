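"""Record, model and sidecar persistence.

Two waveform formats are supported:

* **CSV** — a header row of lead names, one sample per row, amplitudes in
  µV.  CSV carries no sampling-rate metadata, so ``fs`` must be supplied
  when reading (default 1000 Hz, the native rate of diagnostic-quality
  recordings this package targets).
* **WFDB format 16** — a minimal codec for the PhysioNet waveform pair
  (text ``.hea`` header + little-endian 16-bit ``.dat`` signal file,
  sample-interleaved), reading and writing the header fields this package
  needs: sampling rate, sample count, per-channel gain/baseline/units and
  lead names.  Amplitudes are converted to µV on read using the
  per-channel gain.

Region models and ground-truth sidecars are plain JSON.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ArsplConfig, EcgRecord, PeakList, RegionBoundaries, RegionModels

__all__ = [
    "read_record", "write_record", "save_models", "load_models",
    "save_truth", "load_truth", "RecordParseError",
]

_DEFAULT_GAIN_PER_MV = 2000.0    # ADC units per mV -> 0.5 µV resolution
_ADC_MAX = 32767


class RecordParseError(ValueError):
    """A record file could not be parsed; the message carries file context."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        if fmt not in ("wfdb", "csv"):
            raise ValueError(f"unknown format {fmt!r} (expected 'wfdb' or 'csv')")
        return fmt
    if path.suffix == ".csv":
        return "csv"
    if path.suffix in ("", ".hea", ".dat"):
        return "wfdb"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_record(path: str | Path, fmt: str | None = None,
                fs: float = 1000.0) -> EcgRecord:
    """Read a multi-lead record from CSV or WFDB, amplitudes in µV."""
    path = Path(path)
    kind = _infer_format(path, fmt)
    return _read_csv(path, fs) if kind == "csv" else _read_wfdb(path)


def write_record(record: EcgRecord, path: str | Path, fmt: str | None = None) -> None:
    """Persist a record as CSV or as a WFDB header/signal pair."""
    path = Path(path)
    kind = _infer_format(path, fmt)
    if record.n_samples < 1:
        raise ValueError("refusing to write an empty record")
    if kind == "csv":
        pd.DataFrame({k: v for k, v in record.leads.items()}).to_csv(
            path, index=False, float_format="%.6g")
    else:
        _write_wfdb(record, path)


def _read_csv(path: Path, fs: float) -> EcgRecord:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise RecordParseError(f"{path}: {exc}") from exc
    if df.empty:
        raise RecordParseError(f"{path}: no samples")
    bad = df.columns[~df.apply(lambda c: np.issubdtype(c.dtype, np.number))]
    if len(bad):
        # locate the first offending row for the error message
        for col in bad:
            row = df[col].map(lambda v: not _is_number(v)).idxmax()
            raise RecordParseError(f"{path}: non-numeric value in column "
                                   f"{col!r} at data row {row}")
    return EcgRecord(fs, {str(c): df[c].to_numpy(dtype=float) for c in df.columns})


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


_HEA_SIGNAL_RE = re.compile(
    r"^(?P<file>\S+)\s+(?P<fmt>\d+)\s+"
    r"(?P<gain>[\d.]+)(?:\((?P<baseline>-?\d+)\))?(?:/(?P<units>\S+))?"
    r"(?:\s+\d+\s+(?P<adczero>-?\d+)\s+-?\d+\s+-?\d+\s+\d+\s*(?P<desc>.*))?$")


def _read_wfdb(path: Path) -> EcgRecord:
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise RecordParseError(f"{hea}: header file not found")
    lines = [ln.strip() for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise RecordParseError(f"{hea}: malformed record line {lines[0]!r}")
    n_sig, fs, n_samples = int(head[1]), float(head[2].split("/")[0]), int(head[3])
    if len(lines) - 1 < n_sig:
        raise RecordParseError(f"{hea}: expected {n_sig} signal lines, "
                               f"found {len(lines) - 1}")
    names, gains, baselines, unit_scale, dat_files = [], [], [], [], []
    for k, ln in enumerate(lines[1:1 + n_sig]):
        m = _HEA_SIGNAL_RE.match(ln)
        if not m or m.group("fmt") != "16":
            raise RecordParseError(f"{hea}: unsupported signal line {k + 1}: {ln!r}")
        dat_files.append(m.group("file"))
        gains.append(float(m.group("gain")) or _DEFAULT_GAIN_PER_MV)
        baselines.append(int(m.group("baseline") or m.group("adczero") or 0))
        units = (m.group("units") or "mV").lower()
        if units == "mv":
            unit_scale.append(1000.0)
        elif units in ("uv", "µv"):
            unit_scale.append(1.0)
        else:
            raise RecordParseError(f"{hea}: unsupported units {units!r}")
        desc = (m.group("desc") or "").strip()
        names.append(desc if desc else f"sig{k}")
    if len(set(dat_files)) != 1:
        raise RecordParseError(f"{hea}: multi-file signals are not supported")
    dat = hea.parent / dat_files[0]
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size < n_samples * n_sig:
        raise RecordParseError(f"{dat}: expected {n_samples * n_sig} samples, "
                               f"found {raw.size}")
    raw = raw[: n_samples * n_sig].reshape(n_samples, n_sig)
    leads = {}
    for k, name in enumerate(names):
        leads[name] = (raw[:, k].astype(float) - baselines[k]) / gains[k] * unit_scale[k]
    return EcgRecord(fs, leads)


def _write_wfdb(record: EcgRecord, path: Path) -> None:
    stem = path.with_suffix("")
    hea, dat = stem.with_suffix(".hea"), stem.with_suffix(".dat")
    gain = _DEFAULT_GAIN_PER_MV
    digital = np.empty((record.n_samples, len(record.leads)), dtype="<i2")
    sig_lines = []
    for k, (name, y) in enumerate(record.leads.items()):
        adc = np.clip(np.round(y / 1000.0 * gain), -_ADC_MAX - 1, _ADC_MAX)
        digital[:, k] = adc.astype("<i2")
        checksum = int(np.int16(adc.astype(np.int64).sum() & 0xFFFF))
        sig_lines.append(f"{dat.name} 16 {gain:g}(0)/mV 16 0 "
                         f"{int(digital[0, k])} {checksum} 0 {name}")
    header = [f"{stem.name} {len(record.leads)} {record.fs:g} {record.n_samples}"]
    hea.write_text("\n".join(header + sig_lines) + "\n")
    digital.tofile(dat)


def save_models(models: RegionModels, path: str | Path,
                cfg: ArsplConfig | None = None, fs: float | None = None) -> None:
    """Serialize the four regional matrices (+ config snapshot) to JSON."""
    doc = {"region_models": models.as_dict()}
    if cfg is not None:
        doc["config"] = cfg.as_dict()
    if fs is not None:
        doc["fs"] = fs
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def load_models(path: str | Path) -> tuple[RegionModels, ArsplConfig | None]:
    doc = json.loads(Path(path).read_text())
    models = RegionModels.from_dict(doc["region_models"])
    cfg = ArsplConfig.from_dict(doc["config"]) if "config" in doc else None
    return models, cfg


def save_truth(path: str | Path, peaks: PeakList,
               boundaries: RegionBoundaries,
               region_matrices: dict[str, np.ndarray] | None = None) -> None:
    """Ground-truth sidecar for a synthetic record."""
    doc = {
        "fs": peaks.fs,
        "peak_x": peaks.peak_x.tolist(),
        "peak_y": peaks.peak_y.tolist(),
        "b_se": boundaries.b_se.tolist(),
        "b_te": boundaries.b_te.tolist(),
        "b_qs": boundaries.b_qs.tolist(),
        "n_samples": boundaries.n_samples,
    }
    if region_matrices is not None:
        doc["region_matrices"] = {k: np.asarray(v).tolist()
                                  for k, v in region_matrices.items()}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_truth(path: str | Path) -> tuple[PeakList, RegionBoundaries, dict]:
    doc = json.loads(Path(path).read_text())
    peaks = PeakList(np.asarray(doc["peak_x"]), np.asarray(doc["peak_y"]), doc["fs"])
    boundaries = RegionBoundaries(np.asarray(doc["b_se"]), np.asarray(doc["b_te"]),
                                  np.asarray(doc["b_qs"]), doc["n_samples"])
    matrices = {k: np.asarray(v) for k, v in doc.get("region_matrices", {}).items()}
    return peaks, boundaries, matrices
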