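"""Electrode montage: the 28-channel extended 10-20 layout used by the study.

The montage is the 19 standard 10-20 sites plus nine additional electrodes
(Oz, FC5/6, CP1/2, CP5/6, PO1/2), with a schematic 2-D head layout (top view,
nose up, unit head radius) for edge maps and hub plots, and the six scalp
regions used for region-averaged amplitude spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "default_montage", "canonical_label", "LABEL_ALIASES"]

# 19 standard 10-20 sites (modern T7/T8/P7/P8 naming) + 9 additional sites.
_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
    "Oz", "FC5", "FC6", "CP1", "CP2", "CP5", "CP6", "PO1", "PO2",
)

# Schematic top-view coordinates, x rightward, y toward nose, head radius 1.
_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.51), "Fz": (0.0, 0.50),
    "F4": (0.40, 0.51), "F8": (0.81, 0.59),
    "FC5": (-0.69, 0.30), "FC6": (0.69, 0.30),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.69, -0.30), "CP1": (-0.25, -0.25),
    "CP2": (0.25, -0.25), "CP6": (0.69, -0.30),
    "P7": (-0.81, -0.59), "P3": (-0.40, -0.51), "Pz": (0.0, -0.50),
    "P4": (0.40, -0.51), "P8": (0.81, -0.59),
    "PO1": (-0.18, -0.73), "PO2": (0.18, -0.73),
    "O1": (-0.31, -0.95), "Oz": (0.0, -1.0), "O2": (0.31, -0.95),
}

# Six scalp regions (4 electrodes each) used for region-averaged amplitudes.
_REGIONS: dict[str, tuple[str, str, str, str]] = {
    "Left Frontal": ("Fp1", "F7", "F3", "FC5"),
    "Right Frontal": ("Fp2", "F8", "F4", "FC6"),
    "Left Central": ("T7", "C3", "CP5", "CP1"),
    "Right Central": ("T8", "C4", "CP6", "CP2"),
    "Left Posterior": ("P7", "P3", "PO1", "O1"),
    "Right Posterior": ("P8", "P4", "PO2", "O2"),
}

# Case-insensitive alias table.  Covers the legacy temporal naming
# (T3/T4/T5/T6 for T7/T8/P7/P8), which coexists with the modern names in
# older EEG exports.  Unknown labels are errors, never warnings.
LABEL_ALIASES: dict[str, str] = {lab.upper(): lab for lab in _LABELS}
LABEL_ALIASES.update({"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"})


def canonical_label(label: str) -> str:
    """Resolve an electrode label to its canonical montage name.

    Matching is case-insensitive and maps legacy temporal-chain synonyms
    (T3->T7, T4->T8, T5->P7, T6->P8).  Raises ``KeyError`` for labels not in
    the montage.
    """
    key = label.strip().upper()
    try:
        return LABEL_ALIASES[key]
    except KeyError:
        raise KeyError(f"unknown electrode label {label!r}") from None


@dataclass(frozen=True)
class Montage:
    labels: tuple[str, ...]
    positions: dict[str, tuple[float, float]]
    regions: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        members = [m for reg in self.regions.values() for m in reg]
        if len(set(members)) != len(members):
            raise ValueError("region sets must be disjoint")
        for name, reg in self.regions.items():
            if len(reg) != 4:
                raise ValueError(f"region {name!r} must have 4 members")
            missing = reg - set(self.labels)
            if missing:
                raise ValueError(f"region {name!r} members {sorted(missing)} "
                                 "not in montage labels")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(canonical_label(label))

    def position_array(self) -> np.ndarray:
        """Channel positions as an (n_channels, 2) array in label order."""
        return np.array([self.positions[lab] for lab in self.labels])

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances between schematic positions."""
        pos = self.position_array()
        diff = pos[:, None, :] - pos[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=-1))


def default_montage() -> Montage:
    """The study montage: 28 channels, schematic positions, six regions.

    Deterministic; repeated calls return equal objects.
    """
    return Montage(
        labels=_LABELS,
        positions=dict(_POSITIONS),
        regions={name: frozenset(reg) for name, reg in _REGIONS.items()},
    )
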