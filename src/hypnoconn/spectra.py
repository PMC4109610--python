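"""Welch cross-spectral estimation across epochs.

Each kept 2048-ms epoch is one Welch segment: it is Hamming-windowed per
channel and Fourier-transformed, and the full complex cross-spectral tensor
S_ij(f) = X_i(f) conj(X_j(f)) is averaged over epochs.  Using whole epochs as
the Welch segments preserves the native fs/n frequency resolution
(500 Hz / 1024 samples = 0.488 Hz).  Power is the (real, non-negative)
diagonal; amplitude is its square root, which is closer to normally
distributed than power itself.

The one-sided spectral-density normalization 2 / (fs * sum(w^2)) is applied;
coherence-type measures are invariant to it, only absolute power/amplitude
scales depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import Montage
from .preprocess import EpochSet

__all__ = ["FrequencyAxis", "SpectralEstimate", "frequency_axis",
           "epoch_cross_spectra", "band_bins", "region_average"]

# Tolerance (Hz) when matching bin centers against printed range endpoints,
# which are rounded to ~3 decimals (e.g. 44.921 for the true 44.921875).
_EDGE_TOL = 0.01


@dataclass(frozen=True)
class FrequencyAxis:
    """DFT bin centers (Hz) restricted to the analysis range; DC excluded."""

    freqs: np.ndarray          # bin centers in Hz
    resolution: float          # fs / n_samples
    lo: float                  # requested range, as printed
    hi: float
    bin_indices: np.ndarray    # integer k such that freqs = k * resolution

    @property
    def n_bins(self) -> int:
        return len(self.freqs)


@dataclass
class SpectralEstimate:
    """Epoch-averaged cross-spectral tensor with power/amplitude spectra."""

    axis: FrequencyAxis
    cross: np.ndarray          # channels x channels x bins, complex
    power: np.ndarray          # channels x bins, real >= 0
    amplitude: np.ndarray      # sqrt(power)
    n_epochs_used: int
    channel_labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)


def frequency_axis(n_samples: int, fs: float,
                   lo: float = 0.488, hi: float = 44.921) -> FrequencyAxis:
    """Frequency axis for ``n_samples``-point epochs at ``fs`` Hz.

    Resolution is fs / n_samples.  Bins k = 1 .. n/2 (DC excluded) whose
    centers fall inside [lo, hi] are retained; both endpoints are inclusive
    at printed precision (a center within 0.01 Hz of an endpoint is kept, so
    e.g. the 44.921875 Hz bin matches a printed top of 44.921 Hz).
    """
    if n_samples % 2:
        raise ValueError("n_samples must be even")
    if not fs > 0:
        raise ValueError("fs must be positive")
    if not lo < hi:
        raise ValueError("empty frequency range")
    res = fs / n_samples
    k = np.arange(1, n_samples // 2 + 1)
    centers = k * res
    mask = (centers >= lo - _EDGE_TOL) & (centers <= hi + _EDGE_TOL)
    if not mask.any():
        raise ValueError(
            f"no frequency bins inside [{lo}, {hi}] Hz at {res} Hz resolution")
    return FrequencyAxis(centers[mask], res, lo, hi, k[mask])


def epoch_cross_spectra(es: EpochSet, axis: FrequencyAxis) -> SpectralEstimate:
    """Welch cross-spectral tensor over the kept epochs.

    One Welch segment per epoch, Hamming window, one-sided density
    normalization.  The result is conjugate-symmetric in (i, j) with real
    non-negative diagonal.
    """
    kept = es.kept_epochs()
    if kept.shape[0] == 0:
        raise ValueError("no kept epochs to estimate spectra from")
    n = kept.shape[-1]
    if axis.resolution != es.fs / n:
        raise ValueError(
            f"axis resolution {axis.resolution} does not match "
            f"fs/n_samples = {es.fs / n}")
    window = np.hamming(n)
    scale = 2.0 / (es.fs * (window ** 2).sum())
    X = np.fft.rfft(kept * window, axis=-1)[..., axis.bin_indices]
    # S_ij(f) averaged over epochs
    cross = np.einsum("eif,ejf->ijf", X, X.conj()) * (scale / kept.shape[0])
    power = np.real(np.einsum("iif->if", cross)).copy()
    np.clip(power, 0.0, None, out=power)
    return SpectralEstimate(axis, cross, power, np.sqrt(power),
                            n_epochs_used=kept.shape[0],
                            channel_labels=es.channel_labels,
                            meta=dict(es.meta))


def band_bins(bands: dict[str, tuple[float, float]],
              axis: FrequencyAxis) -> dict[str, np.ndarray]:
    """Indices (into ``axis.freqs``) of each band's bins.

    A bin belongs to band [lo, hi) iff lo <= center < hi; bands are further
    clipped to the analysis range (a printed band top above the range top,
    like gamma's 45 Hz vs 44.921, simply ends at the range top).  A band with
    no bins at this resolution is an error.
    """
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in bands.items():
        idx = np.flatnonzero((axis.freqs >= lo) & (axis.freqs < hi))
        if idx.size == 0:
            raise ValueError(
                f"band {name!r} [{lo}, {hi}) contains no bins at "
                f"{axis.resolution:.6g} Hz resolution")
        out[name] = idx
    return out


def region_average(amplitude: np.ndarray, channel_labels: tuple[str, ...],
                   montage: Montage) -> pd.DataFrame:
    """Average amplitude spectra over the montage's six 4-electrode regions.

    Returns a (6 regions x bins) DataFrame in the montage's region order.
    """
    label_idx = {lab: i for i, lab in enumerate(channel_labels)}
    rows = {}
    for region, members in montage.regions.items():
        missing = [m for m in members if m not in label_idx]
        if missing:
            raise ValueError(
                f"region {region!r}: channel(s) {sorted(missing)} missing "
                "from the recording")
        idx = [label_idx[m] for m in sorted(members)]
        rows[region] = amplitude[idx].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index")
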