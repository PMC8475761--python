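"""Per-epoch spectral features: Welch PSD, cross-spectrum, coherence.

All four feature kinds derive from one shared computation: each 1-s epoch is
split into short windowed segments, each segment is Fourier-transformed with
the modified-periodogram scaling dt/sum(h^2) (so a white-noise input has the
same mean level whatever the taper), and segment spectra / cross-spectra are
averaged within the epoch (Welch's method).

With the default configuration — 50-sample Hamming segments, 50% overlap,
zero-padded to NFFT=100 at fs=100 Hz — each 1-s epoch yields 3 inner
segments and a 1-Hz frequency grid, of which the integer bins 1..40 Hz are
kept. A single full-length segment would make every coherence identically 1
(the magnitude-squared coherence of one segment is degenerate), so that
configuration is rejected for coherence.

Channel pairs are ordered lexicographically in the frozen montage order:
171 pairs with self-pairs (i <= j) for cross-spectrum amplitude and phase,
153 pairs without (i < j) for coherence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import ConfigError, StateError
from .preprocess import EpochArray

PSD = "PSD"
XSPEC = "XSPEC"  # complex intermediate
XSPEC_AMP = "XSPEC_AMP"
XSPEC_PHASE = "XSPEC_PHASE"
COH = "COH"

FEATURE_KINDS = (PSD, XSPEC_AMP, XSPEC_PHASE, COH)

_LOG_FLOOR = 1e-12
_FISHER_CEIL = 1.0 - 1e-12


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimator configuration.

    Defaults give 3 Hamming-windowed 50-sample segments per 1-s epoch at
    100 Hz, zero-padded to NFFT=100 (1 Hz bins), analysis band 1-40 Hz.
    """

    nfft: int = 100
    window: str = "hamming"
    segment_len: int = 50
    overlap_frac: float = 0.5
    fs: float = 100.0
    freq_lo: int = 1
    freq_hi: int = 40

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_frac < 1:
            raise ConfigError("overlap_frac must be in [0, 1)")
        if self.segment_len > self.nfft:
            raise ConfigError("segment_len must not exceed nfft")
        if self.segment_len < 2:
            raise ConfigError("segment_len must be >= 2")
        bin_hz = self.fs / self.nfft
        for f in self.freq_bins:
            k = f / bin_hz
            if abs(k - round(k)) > 1e-9:
                raise ConfigError(
                    f"frequency {f} Hz is not on the {bin_hz:g}-Hz DFT grid"
                )

    @property
    def freq_bins(self) -> np.ndarray:
        """Analysis frequencies in Hz (integer grid, DC excluded)."""
        return np.arange(self.freq_lo, self.freq_hi + 1)

    @property
    def step(self) -> int:
        return max(1, int(round(self.segment_len * (1 - self.overlap_frac))))

    def n_segments(self, epoch_len: int) -> int:
        if epoch_len < self.segment_len:
            raise ConfigError("epoch shorter than segment_len")
        return 1 + (epoch_len - self.segment_len) // self.step

    def taper(self) -> np.ndarray:
        return signal.get_window(self.window, self.segment_len)


@dataclass
class FeatureTensor:
    """trials x (channels | pairs) x frequency feature array with labels."""

    kind: str
    data: np.ndarray = field(repr=False)
    subjects: np.ndarray  # (n_trials,) subject label per trial
    runs: np.ndarray
    conditions: np.ndarray
    freqs: np.ndarray  # (n_freqs,) Hz
    axis1_labels: tuple  # channel names or (i, j) channel-name pairs
    transform_state: str = "raw"
    block_averaged: bool = False

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("feature data must be 3-D (trials, rows, freqs)")
        n = self.data.shape[0]
        if not (len(self.subjects) == len(self.runs) == len(self.conditions) == n):
            raise ValueError("trial labels must match trial count")
        if self.data.shape[1] != len(self.axis1_labels):
            raise ValueError("axis1 labels must match row count")
        if self.data.shape[2] != len(self.freqs):
            raise ValueError("frequency labels must match frequency count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def with_(self, **kw) -> "FeatureTensor":
        return replace(self, **kw)

    def select(
        self,
        subjects: tuple[str, ...] | None = None,
        runs: tuple[str, ...] | None = None,
        conditions: tuple[str, ...] | None = None,
    ) -> "FeatureTensor":
        """Trials restricted to the given subject/run/condition labels."""
        mask = np.ones(self.n_trials, dtype=bool)
        if subjects is not None:
            mask &= np.isin(self.subjects, subjects)
        if runs is not None:
            mask &= np.isin(self.runs, runs)
        if conditions is not None:
            mask &= np.isin(self.conditions, conditions)
        return self.with_(
            data=self.data[mask],
            subjects=self.subjects[mask],
            runs=self.runs[mask],
            conditions=self.conditions[mask],
        )


def channel_pairs(n_channels: int, include_self: bool) -> tuple[tuple[int, int], ...]:
    """Lexicographic (i, j) pairs; i <= j with self-pairs, i < j without."""
    k = 0 if include_self else 1
    iu = np.triu_indices(n_channels, k=k)
    return tuple(zip(iu[0].tolist(), iu[1].tolist()))


def modified_periodogram(
    segment: np.ndarray,
    window: str | np.ndarray = "hamming",
    nfft: int = 100,
    fs: float = 100.0,
    return_complex: bool = False,
):
    """Windowed periodogram of one segment, evaluated at all NFFT DFT bins.

    Returns ``(freqs, power)`` — the two-sided power density
    dt/sum(h^2) * |DFT(h*x, nfft)|^2 at the DFT frequencies — and, when
    ``return_complex`` is set, additionally the scaled complex spectrum X
    with ``power == |X|^2``.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("segment must be a non-empty 1-D array")
    if x.size > nfft:
        raise ValueError("segment longer than nfft (no truncation)")
    h = signal.get_window(window, x.size) if isinstance(window, str) else np.asarray(window)
    if h.size != x.size:
        raise ValueError("window length must equal segment length")
    scale = (1.0 / fs) / np.sum(h**2)
    spec = np.fft.fft(h * x, n=nfft) * np.sqrt(scale)
    freqs = np.fft.fftfreq(nfft, d=1.0 / fs)
    power = np.abs(spec) ** 2
    if return_complex:
        return freqs, power, spec
    return freqs, power


def _segment_spectra(epochs: EpochArray, cfg: WelchConfig) -> tuple[np.ndarray, np.ndarray]:
    """Scaled complex rFFT of every windowed inner segment.

    Returns ``(X, bin_idx)`` with X of shape
    (n_epochs, n_segments, n_channels, n_freq_bins) restricted to the
    analysis band, scaled so |X|^2 is the modified-periodogram density.
    """
    if cfg.fs != epochs.fs:
        raise ConfigError(f"config fs {cfg.fs} != epoch fs {epochs.fs}")
    n_samp = epochs.epochs.shape[2]
    n_seg = cfg.n_segments(n_samp)
    h = cfg.taper()
    starts = np.arange(n_seg) * cfg.step
    # (n_epochs, n_segments, n_channels, segment_len)
    segs = np.stack(
        [epochs.epochs[:, :, s : s + cfg.segment_len] for s in starts], axis=1
    )
    scale = (1.0 / cfg.fs) / np.sum(h**2)
    X = np.fft.rfft(segs * h, n=cfg.nfft, axis=-1) * np.sqrt(scale)
    bin_idx = np.round(cfg.freq_bins * cfg.nfft / cfg.fs).astype(int)
    return X[..., bin_idx], bin_idx


def _labels(epochs: EpochArray, n: int) -> dict:
    return {
        "subjects": np.repeat(epochs.subject_id, n),
        "runs": np.repeat(epochs.run_id, n),
        "conditions": np.repeat(epochs.condition, n),
    }


def welch_psd(epochs: EpochArray, cfg: WelchConfig | None = None) -> FeatureTensor:
    """Welch PSD per epoch and channel, restricted to the analysis band."""
    cfg = cfg or WelchConfig(fs=epochs.fs)
    X, _ = _segment_spectra(epochs, cfg)
    power = np.mean(np.abs(X) ** 2, axis=1)  # average over inner segments
    return FeatureTensor(
        kind=PSD,
        data=power,
        freqs=cfg.freq_bins.copy(),
        axis1_labels=tuple(epochs.channel_labels),
        **_labels(epochs, epochs.n_epochs),
    )


def cross_spectrum(epochs: EpochArray, cfg: WelchConfig | None = None) -> FeatureTensor:
    """Segment-averaged complex cross-spectrum for all pairs with i <= j.

    Self-pairs (i == i) are real and equal the Welch PSD of that channel.
    """
    cfg = cfg or WelchConfig(fs=epochs.fs)
    X, _ = _segment_spectra(epochs, cfg)
    n_ch = epochs.n_channels
    S = np.einsum("esif,esjf->eijf", X, X.conj()) / X.shape[1]
    iu = np.triu_indices(n_ch, k=0)
    pairs = channel_pairs(n_ch, include_self=True)
    names = tuple(
        (epochs.channel_labels[i], epochs.channel_labels[j]) for i, j in pairs
    )
    return FeatureTensor(
        kind=XSPEC,
        data=S[:, iu[0], iu[1], :],
        freqs=cfg.freq_bins.copy(),
        axis1_labels=names,
        **_labels(epochs, epochs.n_epochs),
    )


def amplitude_and_phase(xspec: FeatureTensor) -> tuple[FeatureTensor, FeatureTensor]:
    """Modulus and argument of the averaged complex cross-spectrum.

    Phase is the argument of the segment-averaged spectrum (not an average
    of per-segment arguments), wrapped to (-pi, pi]; self-pairs get exact 0.
    """
    if xspec.kind != XSPEC:
        raise ValueError("input must come from cross_spectrum")
    amp = xspec.with_(kind=XSPEC_AMP, data=np.abs(xspec.data))
    phase_vals = np.angle(xspec.data)
    self_rows = [i for i, (a, b) in enumerate(xspec.axis1_labels) if a == b]
    phase_vals[:, self_rows, :] = 0.0
    phase = xspec.with_(kind=XSPEC_PHASE, data=phase_vals)
    return amp, phase


def coherence(epochs: EpochArray, cfg: WelchConfig | None = None) -> FeatureTensor:
    """Magnitude-squared coherence |Pxy|^2 / (Pxx Pyy) for pairs with i < j.

    Requires at least 2 inner Welch segments per epoch: with a single
    segment the estimator is identically 1 for every pair and frequency.
    """
    cfg = cfg or WelchConfig(fs=epochs.fs)
    n_samp = epochs.epochs.shape[2]
    if cfg.n_segments(n_samp) < 2:
        raise ConfigError(
            "coherence needs >= 2 Welch segments per epoch; a single segment "
            "makes magnitude-squared coherence identically 1 (degenerate)"
        )
    X, _ = _segment_spectra(epochs, cfg)
    n_ch = epochs.n_channels
    S = np.einsum("esif,esjf->eijf", X, X.conj()) / X.shape[1]
    auto = np.real(np.einsum("eiif->eif", S))
    iu = np.triu_indices(n_ch, k=1)
    num = np.abs(S[:, iu[0], iu[1], :]) ** 2
    den = auto[:, iu[0], :] * auto[:, iu[1], :]
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(den > 0, num / np.maximum(den, np.finfo(float).tiny), 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    pairs = channel_pairs(n_ch, include_self=False)
    names = tuple(
        (epochs.channel_labels[i], epochs.channel_labels[j]) for i, j in pairs
    )
    return FeatureTensor(
        kind=COH,
        data=coh,
        freqs=cfg.freq_bins.copy(),
        axis1_labels=names,
        **_labels(epochs, epochs.n_epochs),
    )


def transform_features(t: FeatureTensor) -> FeatureTensor:
    """Variance-stabilizing transform per feature kind.

    PSD and cross-spectrum amplitude: log10 (floored at 1e-12). Coherence:
    Fisher-Z, atanh(sqrt(C)) with ceiling 1 - 1e-12. Phase: identity.
    """
    if t.transform_state != "raw":
        raise StateError("tensor already transformed")
    if t.kind in (PSD, XSPEC_AMP):
        data = np.log10(np.maximum(t.data, _LOG_FLOOR))
    elif t.kind == COH:
        data = np.arctanh(np.minimum(np.sqrt(np.clip(t.data, 0.0, 1.0)), _FISHER_CEIL))
    elif t.kind == XSPEC_PHASE:
        data = t.data.copy()
    else:
        raise ValueError(f"cannot transform kind {t.kind!r}")
    return t.with_(data=data, transform_state="transformed")


def block_average(t: FeatureTensor, block: int = 5) -> FeatureTensor:
    """Average consecutive non-overlapping blocks of trials.

    Blocks never straddle a (subject, run, condition) boundary; a trailing
    remainder within a group is dropped with a warning. block=1 is identity.
    """
    if block <= 0:
        raise ValueError("block must be positive")
    if t.block_averaged:
        raise StateError("tensor already block-averaged")
    keys = np.array(
        ["\x1f".join(k) for k in zip(t.subjects, t.runs, t.conditions)]
    )
    # contiguous group boundaries (trial order preserved within groups)
    change = np.flatnonzero(keys[1:] != keys[:-1]) + 1
    bounds = [0, *change.tolist(), len(keys)]
    chunks, subs, runs, conds = [], [], [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        n_blocks = (b - a) // block
        if n_blocks * block != b - a:
            warnings.warn(
                f"dropping {(b - a) - n_blocks * block} trailing trial(s) "
                f"not filling a block of {block}",
                stacklevel=2,
            )
        if n_blocks == 0:
            continue
        seg = t.data[a : a + n_blocks * block]
        chunks.append(
            seg.reshape(n_blocks, block, *seg.shape[1:]).mean(axis=1)
        )
        subs.append(np.repeat(t.subjects[a], n_blocks))
        runs.append(np.repeat(t.runs[a], n_blocks))
        conds.append(np.repeat(t.conditions[a], n_blocks))
    return t.with_(
        data=np.concatenate(chunks, axis=0),
        subjects=np.concatenate(subs),
        runs=np.concatenate(runs),
        conditions=np.concatenate(conds),
        block_averaged=True,
    )


def concat_tensors(tensors: list[FeatureTensor]) -> FeatureTensor:
    """Stack compatible tensors (same kind, rows, freqs) along the trial axis."""
    if not tensors:
        raise ValueError("nothing to concatenate")
    first = tensors[0]
    for t in tensors[1:]:
        if (
            t.kind != first.kind
            or t.axis1_labels != first.axis1_labels
            or not np.array_equal(t.freqs, first.freqs)
            or t.transform_state != first.transform_state
            or t.block_averaged != first.block_averaged
        ):
            raise ValueError("incompatible tensors")
    return first.with_(
        data=np.concatenate([t.data for t in tensors], axis=0),
        subjects=np.concatenate([t.subjects for t in tensors]),
        runs=np.concatenate([t.runs for t in tensors]),
        conditions=np.concatenate([t.conditions for t in tensors]),
    )
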