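"""Synthetic multi-subject resting-state EEG cohorts.

Generates cohorts whose statistical structure carries the three signals the
identification pipeline exploits and must be tested against:

* a subject *fingerprint* — stable per-subject spectral shape (band gains,
  alpha-peak frequency) and inter-channel coupling (a linear mixing matrix
  over shared latent sources), constant across runs;
* a *condition* effect — eyes-closed (REC) recordings carry more 10-15 Hz
  power than eyes-open (REO) ones, via a dedicated posterior-rhythm source
  whose variance is multiplied under REC;
* *session drift* — per-run log-normal jitter on band gains and noise floor,
  standing in for electrode placement and state changes across visits
  separated by weeks.

Each channel is a linear mixture of band-limited latent oscillators
(second-order band-pass-filtered white noise at theta/alpha/beta/gamma
centers) plus broadband low-frequency latents, plus independent per-channel
sensor noise. Everything is a deterministic function of the cohort seed and
the (subject, run, condition) indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal

from .errors import ConfigError
from .montage import N_RECORDED, RECORDED_CHANNELS

REO = "REO"
REC = "REC"
CONDITIONS = (REO, REC)

# Latent sources: (name, center Hz or None for subject alpha, bandwidth Hz,
# relative amplitude). "posterior" is the 10-15 Hz rhythm boosted under REC.
_OSCILLATORS = (
    ("theta", 6.0, 2.0, 1.0),
    ("alpha", None, 1.5, 2.0),
    ("posterior", 12.5, 1.5, 1.5),
    ("beta1", 16.5, 3.0, 0.7),
    ("beta2", 25.0, 4.0, 0.5),
    ("gamma", 35.0, 4.0, 0.35),
)
_N_BROADBAND = 2
_BROADBAND_AMP = 1.2
N_SOURCES = len(_OSCILLATORS) + _N_BROADBAND

# Variance multiplier window for the eyes-closed condition effect.
_REC_BAND = (10.0, 15.0)


@dataclass(frozen=True)
class SubjectFingerprint:
    """Session-stable, subject-specific generative parameters."""

    subject_id: str
    alpha_peak_hz: float
    band_gains: np.ndarray  # (n_channels, n_sources) power multipliers, > 0
    mixing_matrix: np.ndarray  # (n_channels, n_sources)
    noise_floor: np.ndarray  # (n_channels,) sensor-noise scale

    def __post_init__(self) -> None:
        if not 8.0 <= self.alpha_peak_hz <= 13.0:
            raise ConfigError(f"alpha peak {self.alpha_peak_hz} Hz outside [8, 13]")
        if np.any(self.band_gains <= 0):
            raise ConfigError("band_gains must be strictly positive")
        if np.linalg.matrix_rank(self.mixing_matrix) < self.mixing_matrix.shape[1]:
            raise ConfigError("mixing_matrix must have full column rank")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "alpha_peak_hz": self.alpha_peak_hz,
            "band_gains": self.band_gains.tolist(),
            "mixing_matrix": self.mixing_matrix.tolist(),
            "noise_floor": self.noise_floor.tolist(),
        }


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; determined by ``seed``."""

    n_subjects: int = 10
    n_runs: int = 3
    conditions: tuple[str, ...] = CONDITIONS
    duration_s: float = 450.0
    fs: float = 100.0
    fingerprints: tuple[SubjectFingerprint, ...] = ()
    run_drift: float = 0.8
    rec_alpha_factor: float = 2.0
    seed: int = 0

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(fp.subject_id for fp in self.fingerprints)

    @property
    def run_ids(self) -> tuple[str, ...]:
        return tuple(f"RUN{i + 1}" for i in range(self.n_runs))

    def to_json(self) -> str:
        payload = {
            "n_subjects": self.n_subjects,
            "n_runs": self.n_runs,
            "conditions": list(self.conditions),
            "duration_s": self.duration_s,
            "fs": self.fs,
            "run_drift": self.run_drift,
            "rec_alpha_factor": self.rec_alpha_factor,
            "seed": self.seed,
            "fingerprints": [fp.to_dict() for fp in self.fingerprints],
        }
        return json.dumps(payload, sort_keys=True)


@dataclass
class Recording:
    """One continuous multi-channel recording for (subject, run, condition)."""

    subject_id: str
    run_id: str
    condition: str
    fs: float
    channel_labels: tuple[str, ...]
    data: np.ndarray = field(repr=False)  # (n_channels, n_samples)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be (n_channels, n_samples)")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _draw_fingerprint(
    seed: int,
    subject_index: int,
    strength: float,
    discriminative_band: tuple[float, float] | None,
) -> SubjectFingerprint:
    """One subject's fingerprint = shared cohort base + subject deviation.

    ``strength`` scales the deviation: 0 collapses every subject onto the
    shared base (a null cohort with no identity signal). When
    ``discriminative_band`` is set, deviations are zeroed for sources whose
    center lies outside that band, confining the identity signal in frequency.
    """
    base = _rng(seed, 0, 0)
    dev = _rng(seed, 0, 1 + subject_index)

    base_mixing = base.normal(0.0, 1.0, (N_RECORDED, N_SOURCES))
    base_log_gains = np.zeros((N_RECORDED, N_SOURCES))
    base_noise = 0.5 * np.exp(base.normal(0.0, 0.1, N_RECORDED))

    alpha_dev = float(dev.uniform(-2.0, 2.0))
    mixing_dev = dev.normal(0.0, 0.4, (N_RECORDED, N_SOURCES))
    gain_dev = dev.normal(0.0, 0.5, (N_RECORDED, N_SOURCES))
    noise_dev = dev.normal(0.0, 0.2, N_RECORDED)

    alpha_peak = float(np.clip(10.5 + strength * alpha_dev, 8.0, 13.0))
    centers = [c if c is not None else alpha_peak for _, c, _, _ in _OSCILLATORS]
    centers += [2.0] * _N_BROADBAND  # broadband latents live at low frequency

    mask = np.ones(N_SOURCES)
    if discriminative_band is not None:
        lo, hi = discriminative_band
        mask = np.array([1.0 if lo <= c <= hi else 0.0 for c in centers])
        if mask[1] == 0.0:  # alpha source outside the band: pin its peak too
            alpha_peak = 10.5

    mixing = base_mixing + strength * mixing_dev * mask
    band_gains = np.exp(base_log_gains + strength * gain_dev * mask)
    noise_floor = base_noise * np.exp(strength * noise_dev)
    return SubjectFingerprint(
        subject_id=f"S{subject_index + 1:02d}",
        alpha_peak_hz=alpha_peak,
        band_gains=band_gains,
        mixing_matrix=mixing,
        noise_floor=noise_floor,
    )


def make_cohort_spec(
    n_subjects: int = 10,
    n_runs: int = 3,
    seed: int = 0,
    overrides: Mapping[str, object] | None = None,
) -> CohortSpec:
    """Draw a deterministic cohort specification.

    Parameters
    ----------
    n_subjects, n_runs
        Cohort design; defaults mirror a 10-subject, 3-visit study.
    seed
        Fully determines the cohort (fingerprints included).
    overrides
        Optional keys: ``duration_s``, ``fs``, ``run_drift``,
        ``rec_alpha_factor``, ``conditions``, ``fingerprint_strength``
        (default 1.0; 0 yields a null cohort with identical fingerprints),
        ``discriminative_band`` (``(lo, hi)`` Hz window confining where
        subjects differ).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    ov = dict(overrides or {})
    strength = float(ov.pop("fingerprint_strength", 1.0))
    band = ov.pop("discriminative_band", None)
    if band is not None:
        band = (float(band[0]), float(band[1]))
    known = {"duration_s", "fs", "run_drift", "rec_alpha_factor", "conditions"}
    unknown = set(ov) - known
    if unknown:
        raise ValueError(f"unknown overrides: {sorted(unknown)}")
    fingerprints = tuple(
        _draw_fingerprint(seed, i, strength, band) for i in range(n_subjects)
    )
    kwargs = {k: ov[k] for k in known & set(ov)}
    if "conditions" in kwargs:
        kwargs["conditions"] = tuple(kwargs["conditions"])
    spec = CohortSpec(
        n_subjects=n_subjects,
        n_runs=n_runs,
        fingerprints=fingerprints,
        seed=seed,
        **kwargs,
    )
    if spec.run_drift < 0:
        raise ValueError("run_drift must be >= 0")
    return spec


def _bandlimited_noise(
    rng: np.random.Generator, center: float, bw: float, fs: float, n: int
) -> np.ndarray:
    """Second-order band-pass-filtered white noise, unit variance."""
    lo = max(center - bw, 0.5)
    hi = min(center + bw, 0.499 * fs)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n + 200))[200:]  # drop warm-up
    return x / x.std()


def _broadband_noise(rng: np.random.Generator, fs: float, n: int) -> np.ndarray:
    """Low-frequency-heavy broadband latent (AR(1)-smoothed white noise)."""
    x = signal.lfilter([1.0], [1.0, -0.95], rng.standard_normal(n + 200))[200:]
    return x / x.std()


def synthesize_recording(
    spec: CohortSpec, subject_id: str, run_id: str, condition: str
) -> Recording:
    """Render one (subject, run, condition) recording from the cohort spec.

    Subject identity enters only through the fingerprint; run identity only
    through the drift perturbation; the condition only through the 10-15 Hz
    variance factor. Deterministic in all four arguments.
    """
    if subject_id not in spec.subject_ids:
        raise KeyError(f"unknown subject {subject_id!r}")
    if run_id not in spec.run_ids:
        raise KeyError(f"unknown run {run_id!r}")
    if condition not in spec.conditions:
        raise KeyError(f"unknown condition {condition!r}")

    si = spec.subject_ids.index(subject_id)
    ri = spec.run_ids.index(run_id)
    ci = CONDITIONS.index(condition)
    fp = spec.fingerprints[si]
    fs = spec.fs
    n = int(round(spec.duration_s * fs))

    # Per-run drift: log-normal jitter on band gains and noise floor.
    drift_rng = _rng(spec.seed, 2, si, ri)
    gain_jitter = np.exp(drift_rng.normal(0.0, 1.0, fp.band_gains.shape))
    noise_jitter = np.exp(drift_rng.normal(0.0, 1.0, fp.noise_floor.shape))
    gains = fp.band_gains * gain_jitter**spec.run_drift
    noise_floor = fp.noise_floor * noise_jitter**spec.run_drift

    centers = [c if c is not None else fp.alpha_peak_hz for _, c, _, _ in _OSCILLATORS]
    bws = [bw for _, _, bw, _ in _OSCILLATORS]
    amps = [a for _, _, _, a in _OSCILLATORS]

    src_rng = _rng(spec.seed, 3, si, ri, ci)
    sources = np.empty((N_SOURCES, n))
    for k, (c, bw, a) in enumerate(zip(centers, bws, amps)):
        s = _bandlimited_noise(src_rng, c, bw, fs, n) * a
        if condition == REC and _REC_BAND[0] <= c <= _REC_BAND[1]:
            s *= np.sqrt(spec.rec_alpha_factor)
        sources[k] = s
    for k in range(_N_BROADBAND):
        sources[len(_OSCILLATORS) + k] = _broadband_noise(src_rng, fs, n) * _BROADBAND_AMP

    # channels x samples: gain-weighted mixture plus sensor noise
    weights = fp.mixing_matrix * np.sqrt(gains)
    data = weights @ sources
    data += noise_floor[:, None] * src_rng.standard_normal((N_RECORDED, n))
    return Recording(
        subject_id=subject_id,
        run_id=run_id,
        condition=condition,
        fs=fs,
        channel_labels=RECORDED_CHANNELS,
        data=data,
    )


def synthesize_cohort(spec: CohortSpec) -> dict[tuple[str, str, str], Recording]:
    """All recordings of the cohort, keyed by (subject, run, condition)."""
    out = {}
    for sid in spec.subject_ids:
        for rid in spec.run_ids:
            for cond in spec.conditions:
                out[(sid, rid, cond)] = synthesize_recording(spec, sid, rid, cond)
    return out
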