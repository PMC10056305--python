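"""Synthetic multi-subject ECG generation.

Each subject's single-lead beat is modelled as a sum of five Gaussian
deflections (P, Q, R, S, T); a record is a train of such beats with
beat-to-beat RR jitter, respiration-like amplitude modulation, sinusoidal
baseline wander and additive white noise.  Ground-truth R locations are
carried along so QRS detection and segmentation can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WAVE_NAMES = ("P", "Q", "R", "S", "T")

# Plausible lead-I parameter ranges (amplitude mV, width s) for an adult
# at rest; not fitted to any dataset.
_AMP_RANGES = {
    "P": (0.05, 0.2),
    "Q": (-0.3, -0.05),
    "R": (0.8, 1.5),
    "S": (-0.3, -0.05),
    "T": (0.1, 0.4),
}
# Gaussian sigmas; kept narrow relative to the inter-wave spacing so that
# in a noiseless beat the sampled R peak equals the R amplitude to <1%
_WIDTH_RANGES = {
    "P": (0.020, 0.035),
    "Q": (0.005, 0.009),
    "R": (0.008, 0.014),
    "S": (0.005, 0.009),
    "T": (0.025, 0.045),
}

DEFAULT_NOISE_SD = 0.02  # mV
DEFAULT_BASELINE_AMP = 0.1  # mV
BASELINE_FREQ_HZ = 0.2
RESP_FREQ_HZ = 0.25


@dataclass(frozen=True)
class Wave:
    """One Gaussian deflection: signed amplitude (mV), center as a
    fraction of the cardiac cycle in [0, 1), and width sigma (s)."""

    amplitude: float
    center: float
    width: float


@dataclass(frozen=True)
class SubjectMorphology:
    """Per-subject beat shape and variability parameters."""

    waves: dict[str, Wave]
    mean_rr: float
    rr_jitter_sd: float
    amplitude_modulation_depth: float
    subject_id: str

    def __post_init__(self) -> None:
        if set(self.waves) != set(WAVE_NAMES):
            raise ValueError(f"waves must be exactly {WAVE_NAMES}")
        amps = {k: abs(w.amplitude) for k, w in self.waves.items()}
        if any(amps["R"] <= amps[k] for k in WAVE_NAMES if k != "R"):
            raise ValueError("R amplitude must dominate all other waves")
        centers = [self.waves[k].center for k in WAVE_NAMES]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ValueError("wave centers must be ordered P < Q < R < S < T")
        if not (0.4 <= self.mean_rr <= 1.5):
            raise ValueError("mean_rr must lie in [0.4, 1.5] s")
        if any(w.width <= 0 for w in self.waves.values()):
            raise ValueError("wave widths must be positive")


@dataclass(frozen=True)
class EcgRecord:
    """A single-lead ECG trace in physical units (mV)."""

    samples: np.ndarray
    fs: float
    subject_id: str
    true_r_locations: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")
        if self.true_r_locations is not None:
            locs = np.asarray(self.true_r_locations, dtype=int)
            if locs.size and (np.any(np.diff(locs) <= 0)
                              or locs[0] < 0 or locs[-1] >= self.samples.size):
                raise ValueError("true_r_locations must be strictly increasing "
                                 "and within bounds")
            object.__setattr__(self, "true_r_locations", locs)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


def make_subject(seed: int, subject_id: str | None = None) -> SubjectMorphology:
    """Draw a random but reproducible subject morphology.

    Distinct seeds give distinct beat shapes; the same seed always gives
    the same subject.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng(np.random.PCG64(seed))

    amps = {k: rng.uniform(*_AMP_RANGES[k]) for k in WAVE_NAMES}
    widths = {k: rng.uniform(*_WIDTH_RANGES[k]) for k in WAVE_NAMES}
    c_r = rng.uniform(0.34, 0.36)
    centers = {
        "P": c_r - rng.uniform(0.16, 0.21),
        "Q": c_r - rng.uniform(0.045, 0.065),
        "R": c_r,
        "S": c_r + rng.uniform(0.045, 0.065),
        "T": c_r + rng.uniform(0.26, 0.32),
    }
    return SubjectMorphology(
        waves={k: Wave(amps[k], centers[k], widths[k]) for k in WAVE_NAMES},
        mean_rr=rng.uniform(0.7, 1.0),
        rr_jitter_sd=0.030,
        amplitude_modulation_depth=0.05,
        subject_id=subject_id if subject_id is not None else f"S{seed:04d}",
    )


def beat_waveform(subject: SubjectMorphology, fs: float) -> np.ndarray:
    """One noiseless cardiac cycle sampled at ``fs`` (length ``round(mean_rr*fs)``)."""
    n = int(round(subject.mean_rr * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for w in subject.waves.values():
        mu = w.center * subject.mean_rr
        x += w.amplitude * np.exp(-((t - mu) ** 2) / (2 * w.width**2))
    return x


def synthesize_record(
    subject: SubjectMorphology,
    n_beats: int,
    fs: float = 1000.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    baseline_amp: float = DEFAULT_BASELINE_AMP,
    seed: int = 0,
) -> EcgRecord:
    """Synthesize a record of ``n_beats`` cardiac cycles.

    Per-beat RR intervals are Normal(mean_rr, rr_jitter_sd); per-beat wave
    amplitudes are scaled by ``1 + depth * sin(2*pi*0.25Hz*t)`` to mimic
    respiration; baseline wander is a 0.2 Hz sinusoid; noise is white.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if fs < 250:
        raise ValueError("fs must be >= 250 Sa/s")
    rng = np.random.default_rng(np.random.PCG64(seed))

    rr = rng.normal(subject.mean_rr, subject.rr_jitter_sd, size=n_beats)
    rr = np.clip(rr, 0.4 * subject.mean_rr, 1.8 * subject.mean_rr)
    starts = np.concatenate([[0.0], np.cumsum(rr[:-1])])
    total = float(np.sum(rr))
    n = int(round(total * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)

    r_locs = np.empty(n_beats, dtype=int)
    for k in range(n_beats):
        t_r = starts[k] + subject.waves["R"].center * subject.mean_rr
        r_locs[k] = int(round(t_r * fs))
        scale = 1.0 + subject.amplitude_modulation_depth * np.sin(
            2 * np.pi * RESP_FREQ_HZ * t_r)
        for w in subject.waves.values():
            mu = starts[k] + w.center * subject.mean_rr
            lo = max(0, int((mu - 5 * w.width) * fs))
            hi = min(n, int((mu + 5 * w.width) * fs) + 1)
            if lo >= hi:
                continue
            x[lo:hi] += (scale * w.amplitude
                         * np.exp(-((t[lo:hi] - mu) ** 2) / (2 * w.width**2)))

    if baseline_amp:
        x += baseline_amp * np.sin(2 * np.pi * BASELINE_FREQ_HZ * t)
    if noise_sd:
        x += rng.normal(0.0, noise_sd, size=n)

    r_locs = np.clip(r_locs, 0, n - 1)
    return EcgRecord(samples=x, fs=fs, subject_id=subject.subject_id,
                     true_r_locations=r_locs)


def make_cohort(
    n_subjects: int,
    n_beats: int,
    seed: int = 0,
    fs: float = 1000.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    baseline_amp: float = DEFAULT_BASELINE_AMP,
) -> list[EcgRecord]:
    """One record per subject, reproducible and extensible.

    The global seed is split into per-subject sub-seeds with a counter
    scheme so that growing ``n_subjects`` leaves earlier subjects intact.
    """
    if n_subjects < 2:
        raise ValueError("identification needs at least 2 subjects")
    records = []
    for i in range(n_subjects):
        sub_seed = (seed * 100003 + i) % (2**31)
        subject = make_subject(sub_seed, subject_id=f"S{i:04d}")
        records.append(
            synthesize_record(subject, n_beats, fs=fs, noise_sd=noise_sd,
                              baseline_amp=baseline_amp, seed=sub_seed + 1))
    return records
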