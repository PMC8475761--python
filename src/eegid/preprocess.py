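"""Preprocessing chain: resample -> mastoid re-reference -> band-pass -> epoch.

The chain reduces a 20-channel recording to 18 analysis channels referenced
to the mastoid mean (M1+M2)/2, restricted to 1-40 Hz, and cut into
non-overlapping 1-s epochs — the unit of feature extraction. Filters are
applied forward-backward (zero phase) so epoch timing is never shifted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import MontageError
from .montage import ANALYSIS_CHANNELS, REFERENCE_CHANNELS
from .synthetic_eeg import Recording


@dataclass
class EpochArray:
    """Fixed-length epochs of one preprocessed recording."""

    subject_id: str
    run_id: str
    condition: str
    fs: float
    channel_labels: tuple[str, ...]
    epochs: np.ndarray = field(repr=False)  # (n_epochs, n_channels, n_samples)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if self.epochs.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis does not match channel_labels")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


def resample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased rational-ratio resampling (polyphase FIR, Kaiser window)."""
    if target_fs > rec.fs:
        raise ValueError(f"upsampling not supported ({rec.fs} -> {target_fs} Hz)")
    if target_fs == rec.fs:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    data = signal.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    return Recording(
        subject_id=rec.subject_id,
        run_id=rec.run_id,
        condition=rec.condition,
        fs=target_fs,
        channel_labels=rec.channel_labels,
        data=data,
    )


def rereference_mastoid(
    rec: Recording, refs: tuple[str, str] = REFERENCE_CHANNELS
) -> Recording:
    """Subtract the mastoid mean and drop the reference channels.

    The output holds exactly the 18 analysis channels in the frozen order;
    re-running on an already re-referenced recording raises a MontageError
    instead of silently proceeding.
    """
    labels = list(rec.channel_labels)
    missing = [r for r in refs if r not in labels]
    if missing:
        raise MontageError(f"reference channel(s) missing: {missing}")
    missing_analysis = [ch for ch in ANALYSIS_CHANNELS if ch not in labels]
    if missing_analysis:
        raise MontageError(f"analysis channel(s) missing: {missing_analysis}")
    ref = rec.data[[labels.index(r) for r in refs]].mean(axis=0)
    data = np.stack([rec.data[labels.index(ch)] - ref for ch in ANALYSIS_CHANNELS])
    return Recording(
        subject_id=rec.subject_id,
        run_id=rec.run_id,
        condition=rec.condition,
        fs=rec.fs,
        channel_labels=ANALYSIS_CHANNELS,
        data=data,
    )


def bandpass(rec: Recording, lo: float = 1.0, hi: float = 40.0) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass, applied forward-backward."""
    nyq = rec.fs / 2.0
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"upper edge {hi} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return Recording(
        subject_id=rec.subject_id,
        run_id=rec.run_id,
        condition=rec.condition,
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        data=data,
    )


def epoch(rec: Recording, epoch_len_s: float = 1.0) -> EpochArray:
    """Cut into consecutive non-overlapping epochs; trailing remainder dropped."""
    if epoch_len_s <= 0:
        raise ValueError("epoch_len_s must be positive")
    samples_per_epoch = int(round(epoch_len_s * rec.fs))
    n_epochs = rec.n_samples // samples_per_epoch
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    usable = n_epochs * samples_per_epoch
    epochs = rec.data[:, :usable].reshape(
        len(rec.channel_labels), n_epochs, samples_per_epoch
    ).transpose(1, 0, 2)
    return EpochArray(
        subject_id=rec.subject_id,
        run_id=rec.run_id,
        condition=rec.condition,
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        epochs=epochs.copy(),
    )


def preprocess_recording(
    rec: Recording,
    target_fs: float = 100.0,
    lo: float = 1.0,
    hi: float = 40.0,
    epoch_len_s: float = 1.0,
) -> EpochArray:
    """Full chain in the canonical order: resample, re-reference, filter, epoch."""
    rec = resample(rec, target_fs) if rec.fs != target_fs else rec
    rec = rereference_mastoid(rec)
    rec = bandpass(rec, lo, hi)
    return epoch(rec, epoch_len_s)
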