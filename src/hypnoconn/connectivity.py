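"""Coherency, coherence (COH) and imaginary coherence (iCOH) over channel pairs.

Coherency is the normalized cross-spectrum
``COHy_ij(f) = S_ij(f) / sqrt(S_ii(f) S_jj(f))``, a complex number whose
modulus (COH) measures phase consistency in [0, 1] and whose imaginary part
isolates phase-lagged coupling.  Volume conduction is instantaneous, so it
contributes only to the real part: |Im COHy| (iCOH) is insensitive to it,
at the price of missing genuinely zero-lag coupling.

Band values are the unweighted mean of the per-bin measure (|COHy| or
|Im COHy|) over the band's bins; since |Im z| <= |z| per bin, the band-level
inequality iCOH <= COH is preserved by averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import Montage, canonical_label
from .spectra import SpectralEstimate

__all__ = ["ConnectivityMatrix", "coherency", "band_connectivity",
           "vectorize_edges", "edge_pairs", "matrix_from_edges", "hub_degree"]

MEASURES = ("COH", "iCOH")


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel band-averaged COH or iCOH in [0, 1]."""

    measure: str
    band: str
    values: np.ndarray
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.channel_labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square, matching labels")

    @property
    def edge_vector(self) -> np.ndarray:
        vec, _ = vectorize_edges(self.values)
        return vec

    @property
    def pair_index(self) -> list[tuple[int, int]]:
        return edge_pairs(len(self.channel_labels))

    def pair_labels(self) -> list[tuple[str, str]]:
        return [(self.channel_labels[i], self.channel_labels[j])
                for i, j in self.pair_index]


def coherency(se: SpectralEstimate) -> np.ndarray:
    """Complex coherency tensor (channels x channels x bins).

    Requires strictly positive autospectra at every analysis bin; a zero
    autospectrum is reported with the channel name and frequency.
    """
    power = se.power
    zero = np.argwhere(power <= 0)
    if zero.size:
        ch, b = zero[0]
        raise ValueError(
            f"zero autospectrum for channel {se.channel_labels[ch]!r} at "
            f"{se.axis.freqs[b]:.3f} Hz")
    denom = np.sqrt(power[:, None, :] * power[None, :, :])
    return se.cross / denom


def band_connectivity(coh_tensor: np.ndarray, bins: np.ndarray, measure: str,
                      band: str, channel_labels: tuple[str, ...],
                      ) -> ConnectivityMatrix:
    """Band-average a per-bin measure of the coherency tensor.

    The per-bin measure (COH = |COHy|, iCOH = |Im COHy|) is computed first,
    then averaged (unweighted) over the band's bins.  The diagonal is set
    exactly to its theoretical value (1 for COH, 0 for iCOH).
    """
    bins = np.asarray(bins)
    if bins.size == 0:
        raise ValueError(f"band {band!r} has no bins")
    sub = coh_tensor[:, :, bins]
    if measure == "COH":
        per_bin = np.abs(sub)
        diag = 1.0
    elif measure == "iCOH":
        per_bin = np.abs(sub.imag)
        diag = 0.0
    else:
        raise ValueError(f"unknown measure {measure!r}")
    values = per_bin.mean(axis=2)
    values = 0.5 * (values + values.T)  # enforce exact symmetry
    np.fill_diagonal(values, diag)
    return ConnectivityMatrix(measure, band, values, channel_labels)


def edge_pairs(n: int) -> list[tuple[int, int]]:
    """Canonical edge order: upper triangle (i < j), row-major."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def vectorize_edges(matrix: np.ndarray, atol: float = 1e-8,
                    ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Flatten a symmetric matrix into the canonical n(n-1)/2 edge vector."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("edge vectorization needs a square matrix")
    if not np.allclose(matrix, matrix.T, atol=atol):
        raise ValueError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu], list(zip(*map(np.ndarray.tolist, iu)))


def matrix_from_edges(vec: np.ndarray, n: int, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_edges` (diagonal filled with ``diag``)."""
    vec = np.asarray(vec)
    if vec.shape != (n * (n - 1) // 2,):
        raise ValueError("edge vector length does not match n")
    out = np.full((n, n), diag, dtype=float)
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out.T[iu] = vec
    return out


def hub_degree(edges: list[tuple[str, str]], montage: Montage) -> pd.Series:
    """Number of significant edges incident to each electrode.

    Returns a Series over all montage labels (zeros included), in montage
    order, with ``series.attrs['max_labels']`` listing the electrode(s)
    attaining the maximum (ties all reported).
    """
    counts = pd.Series(0, index=list(montage.labels), dtype=int)
    for a, b in edges:
        counts[canonical_label(a)] += 1
        counts[canonical_label(b)] += 1
    if len(edges):
        top = int(counts.max())
        counts.attrs["max_labels"] = [lab for lab, c in counts.items()
                                      if c == top]
    else:
        counts.attrs["max_labels"] = []
    return counts
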