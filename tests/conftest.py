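import numpy as np
import pytest

from arspl.core import ArsplConfig
from arspl.segmentation import derive_boundaries
from arspl.synthetic import SynthSpec, generate


@pytest.fixture(scope="session")
def cfg() -> ArsplConfig:
    return ArsplConfig()


@pytest.fixture(scope="session")
def clean_subject():
    """Noiseless 12-lead record with wave-support truth masks."""
    spec = SynthSpec(duration_s=12.0, seed=11)
    record, truth, boundaries = generate(spec)
    return spec, record, truth, boundaries


@pytest.fixture(scope="session")
def aligned_subject(cfg):
    """Noiseless record whose target-lead mixing masks coincide with the
    experienced-time-window boundaries derived from the true peaks, and whose
    head/tail samples follow the complete-sequence fit; the piecewise
    train/synthesize round trip is exact on it."""
    spec = SynthSpec(duration_s=20.0, seed=7, consistent_ht=True)
    _, truth, _ = generate(spec)
    n = int(spec.duration_s * spec.fs)
    b = derive_boundaries(truth, spec.fs, cfg, n_samples=n)
    record, truth, tb = generate(spec, boundaries=b)
    return spec, record, truth, tb


def random_record_and_boundaries(rng: np.random.Generator, cfg: ArsplConfig):
    """A random multi-lead signal with a random but gate-respecting peak
    train (occasionally tachycardic enough to exercise boundary clamping),
    plus the derived boundaries."""
    from arspl.core import EcgRecord, PeakList

    fs = float(rng.choice([250.0, 500.0, 1000.0]))
    m = int(rng.integers(3, 12))
    min_rr = 60.0 / cfg.max_hr_bpm
    rr = rng.uniform(min_rr * 1.05, 1.2, size=m - 1)
    first = rng.uniform(0.05, 0.8)
    times = first + np.concatenate([[0.0], np.cumsum(rr)])
    px = np.round(times * fs).astype(int)
    n = int(px[-1] + rng.integers(1, int(0.5 * fs)))
    leads = {name: rng.normal(size=n) for name in ("I", "II", "V2")}
    record = EcgRecord(fs, leads)
    peaks = PeakList(px, leads["II"][px], fs)
    boundaries = derive_boundaries(peaks, fs, cfg, n_samples=n)
    return record, peaks, boundaries
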