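"""Average referencing, epoch segmentation, detrending and artifact rejection.

The order of operations follows the acquisition narrative: the continuous
recording is converted to the common average reference, cut into consecutive
non-overlapping fixed-length epochs, each epoch is linearly detrended per
channel, and epochs containing any detrended sample outside the rejection
window (default +/-100 uV) are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import detrend as _linear_detrend

from .io import Recording

__all__ = ["EpochSet", "to_average_reference", "segment_epochs",
           "clean_epochs", "preprocess_recording"]


@dataclass
class EpochSet:
    """Fixed-length epochs (n_epochs x channels x samples, uV) with a kept mask."""

    epochs: np.ndarray
    kept: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)
    detrended: bool = False

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.kept = np.asarray(self.kept, dtype=bool)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be n_epochs x channels x samples")
        if self.kept.shape != (self.epochs.shape[0],):
            raise ValueError("kept mask length mismatch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    @property
    def acceptance_rate(self) -> float:
        return self.n_kept / self.n_epochs if self.n_epochs else float("nan")

    def kept_epochs(self) -> np.ndarray:
        return self.epochs[self.kept]


def to_average_reference(rec: Recording) -> Recording:
    """Re-reference to the common average: subtract the instantaneous mean
    across channels from every channel.  Idempotent."""
    if rec.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data, reference="average", meta=dict(rec.meta))


def segment_epochs(rec: Recording, epoch_ms: float = 2048.0) -> EpochSet:
    """Cut consecutive non-overlapping epochs from sample 0.

    The epoch length in samples is round(epoch_ms * fs / 1000); it must be
    within 0.5 samples of ``epoch_ms * fs / 1000``.  The trailing remainder
    shorter than one epoch is discarded.  A recording shorter than one epoch
    yields an empty EpochSet with a warning.
    """
    exact = epoch_ms * rec.fs / 1000.0
    n_samp = int(round(exact))
    if abs(exact - n_samp) > 0.5:
        raise ValueError(
            f"epoch length {epoch_ms} ms is not an integer number of samples "
            f"at fs={rec.fs}")
    n_ep = rec.n_samples // n_samp
    if n_ep == 0:
        warnings.warn(
            f"recording ({rec.n_samples} samples) shorter than one "
            f"{n_samp}-sample epoch; empty EpochSet", stacklevel=2)
        epochs = np.empty((0, rec.n_channels, n_samp))
    else:
        epochs = (rec.data[:, : n_ep * n_samp]
                  .reshape(rec.n_channels, n_ep, n_samp)
                  .transpose(1, 0, 2)).copy()
    return EpochSet(epochs, np.ones(n_ep, dtype=bool), rec.fs,
                    rec.channel_labels, meta=dict(rec.meta))


def clean_epochs(es: EpochSet, limit_uv: float = 100.0) -> EpochSet:
    """Detrend each epoch per channel (least-squares line removed) and reject
    epochs with any sample outside [-limit, +limit] afterwards.

    Raises if every epoch is rejected, naming the recording.
    """
    if es.n_epochs == 0:
        raise ValueError("cannot clean an empty EpochSet")
    detrended = _linear_detrend(es.epochs, axis=-1, type="linear")
    kept = (np.abs(detrended) <= limit_uv).all(axis=(1, 2))
    if not kept.any():
        ident = es.meta or es.channel_labels[:3]
        raise ValueError(f"all epochs rejected for recording {ident}")
    return EpochSet(detrended, kept, es.fs, es.channel_labels,
                    meta=dict(es.meta), detrended=True)


def preprocess_recording(rec: Recording, epoch_ms: float = 2048.0,
                         limit_uv: float = 100.0) -> EpochSet:
    """Full preprocessing chain: average reference -> segment -> detrend/reject."""
    return clean_epochs(segment_epochs(to_average_reference(rec), epoch_ms),
                        limit_uv)
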