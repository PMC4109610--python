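"""Recording I/O, study manifests, edge tables and analysis configuration.

Two on-disk recording formats are supported:

* EDF (European Data Format): read through :func:`mne.io.read_raw_edf`;
  written by a minimal built-in EDF writer (16-bit integer records), which is
  sufficient for round-tripping continuous multichannel data.
* Plain delimited matrix: TSV with a ``# fs=<Hz>`` comment line, a header row
  of channel labels, one row per channel and one column per sample.  This
  format round-trips bit-exactly (values serialized with ``repr``).
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .montage import canonical_label

__all__ = [
    "Recording", "StudyManifest", "Config",
    "read_recording", "write_recording",
    "write_edge_table", "read_edge_table",
]


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    ``data`` is channels x samples; ``channel_labels`` are canonical montage
    names; ``reference`` records whether the data are still against the
    original (e.g. ear) reference or have been re-referenced to the common
    average.  ``meta`` carries subject / group / condition provenance.
    """

    channel_labels: tuple[str, ...]
    fs: float
    data: np.ndarray
    reference: str = "original"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.data.shape[0]} data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            dupes = sorted({l for l in self.channel_labels
                            if list(self.channel_labels).count(l) > 1})
            raise ValueError(f"duplicate channel labels: {dupes}")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.reference not in ("original", "average"):
            raise ValueError(f"unknown reference tag {self.reference!r}")
        bad = ~np.isfinite(self.data).all(axis=1)
        if bad.any():
            names = [self.channel_labels[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"non-finite samples in channel(s) {names}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _canonicalize(labels: Iterable[str]) -> tuple[str, ...]:
    return tuple(canonical_label(lab) for lab in labels)


# ---------------------------------------------------------------------------
# Plain delimited matrix format
# ---------------------------------------------------------------------------

def _write_matrix(rec: Recording, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write(f"# reference={rec.reference}\n")
        if rec.meta:
            fh.write(f"# meta={json.dumps(rec.meta, sort_keys=True)}\n")
        fh.write("\t".join(rec.channel_labels) + "\n")
        for row in rec.data:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def _read_matrix(path: Path) -> Recording:
    fs = None
    reference = "original"
    meta: dict = {}
    header: list[str] | None = None
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                if key == "fs":
                    fs = float(val)
                elif key == "reference":
                    reference = val
                elif key == "meta":
                    meta = json.loads(val)
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append(np.array([float(v) for v in line.split("\t")]))
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=<Hz>' line")
    if header is None or not rows:
        raise ValueError(f"{path}: no channel header / data rows")
    if len(rows) != len(header):
        raise ValueError(
            f"{path}: {len(header)} labels but {len(rows)} data rows")
    return Recording(_canonicalize(header), fs, np.vstack(rows),
                     reference=reference, meta=meta)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF field {value!r} exceeds {width} bytes")
    return b.ljust(width)


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: 1-second data records, 16-bit little-endian.

    Requires an integer sampling rate; the signal is truncated to whole
    records.  Physical scaling is per-channel symmetric about zero, so
    quantization error is bounded by (physical range)/2^16.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record")
    nch = rec.n_channels
    data = rec.data[:, : n_rec * spr]

    # physical limits rounded so the 8-char header field parses back exactly
    phys_max = np.array([float(f"{m:.6g}") for m in
                         np.maximum(np.abs(data).max(axis=1) * 1.0001, 1e-6)])
    dig_max, dig_min = 32767, -32768
    # standard EDF affine: phys = phys_min + (dig - dig_min) * bitvalue
    bitvalue = 2 * phys_max / (dig_max - dig_min)
    digital = (np.clip(np.round((data + phys_max[:, None])
                                / bitvalue[:, None]), 0, dig_max - dig_min)
               + dig_min).astype("<i2")

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate 01-JAN-2000 X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (1 + nch)), 8),
        _edf_field("", 44),
        _edf_field(str(n_rec), 8),
        _edf_field("1", 8),
        _edf_field(str(nch), 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(lab, 16) for lab in rec.channel_labels),
        b"".join(_edf_field("", 80) for _ in range(nch)),
        b"".join(_edf_field("uV", 8) for _ in range(nch)),
        b"".join(_edf_field(f"{-m:.6g}"[:8], 8) for m in phys_max),
        b"".join(_edf_field(f"{m:.6g}"[:8], 8) for m in phys_max),
        b"".join(_edf_field(str(dig_min), 8) for _ in range(nch)),
        b"".join(_edf_field(str(dig_max), 8) for _ in range(nch)),
        b"".join(_edf_field("", 80) for _ in range(nch)),
        b"".join(_edf_field(str(spr), 8) for _ in range(nch)),
        b"".join(_edf_field("", 32) for _ in range(nch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            chunk = digital[:, r * spr : (r + 1) * spr]
            fh.write(chunk.tobytes())


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne loads EEG in volts
    return Recording(_canonicalize(raw.ch_names), float(raw.info["sfreq"]),
                     data_uv)


def read_recording(path: str | Path, format: str | None = None,
                   meta: dict | None = None) -> Recording:
    """Read a recording from EDF or the delimited matrix format.

    ``format`` is ``"edf"`` or ``"matrix"``; when omitted it is inferred from
    the file suffix (``.edf`` vs anything else).  Labels are canonicalized
    against the montage alias table (case-insensitive, T3/T4/T5/T6 synonyms).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        rec = _read_edf(path)
    elif format == "matrix":
        rec = _read_matrix(path)
    else:
        raise ValueError(f"unknown recording format {format!r}")
    if meta:
        rec.meta.update(meta)
    return rec


def write_recording(rec: Recording, path: str | Path,
                    format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        _write_edf(rec, path)
    elif format == "matrix":
        _write_matrix(rec, path)
    else:
        raise ValueError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# Study manifest
# ---------------------------------------------------------------------------

CONDITIONS = ("pre", "hypnosis")
GROUPS = ("high", "low")


@dataclass
class StudyManifest:
    """Maps each subject to its group and its two condition recordings.

    ``entries`` is a DataFrame with columns ``subject``, ``group``, and
    ``path_pre`` / ``path_hypnosis`` (paths or in-memory keys).
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "group", "path_pre", "path_hypnosis"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"manifest missing columns {sorted(missing)}")
        if self.entries["subject"].duplicated().any():
            raise ValueError("duplicate subjects in manifest")
        bad = set(self.entries["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group label(s) {sorted(bad)}")
        for g in GROUPS:
            if not (self.entries["group"] == g).any():
                raise ValueError(f"group {g!r} has no subjects")
        nulls = self.entries[["path_pre", "path_hypnosis"]].isna()
        if nulls.any().any():
            subj = self.entries.loc[nulls.any(axis=1), "subject"].tolist()
            raise ValueError(
                f"subject(s) {subj} missing a condition recording")

    @property
    def subjects(self) -> list[str]:
        return self.entries["subject"].tolist()

    def group_of(self, subject: str) -> str:
        row = self.entries.loc[self.entries["subject"] == subject]
        if row.empty:
            raise KeyError(f"unknown subject {subject!r}")
        return row["group"].iloc[0]

    def n_per_group(self) -> dict[str, int]:
        return self.entries["group"].value_counts().to_dict()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            self.entries.to_json(orient="records", indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyManifest":
        return cls(pd.read_json(Path(path), orient="records"))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.1, 3.9),
    "theta": (4.0, 7.9),
    "alpha": (8.0, 12.9),
    "beta1": (13.0, 19.9),
    "beta2": (20.0, 29.9),
    "gamma": (30.0, 45.0),
}


@dataclass
class Config:
    """Analysis configuration with the study's defaults.

    2048-ms epochs, +/-100 uV rejection, the canonical six-band scheme,
    0.488-44.921 Hz analysis range, 1000 permutations and 1000 bootstrap
    resamples, bootstrap-ratio threshold 2.0.
    """

    epoch_ms: float = 2048.0
    reject_uv: float = 100.0
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    freq_lo: float = 0.488
    freq_hi: float = 44.921
    n_permutations: int = 1000
    n_bootstraps: int = 1000
    bsr_threshold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, count in [("epoch_ms", self.epoch_ms),
                            ("reject_uv", self.reject_uv),
                            ("n_permutations", self.n_permutations),
                            ("n_bootstraps", self.n_bootstraps),
                            ("bsr_threshold", self.bsr_threshold)]:
            if not count > 0:
                raise ValueError(f"{name} must be positive")
        prev_hi = -np.inf
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r} has lo >= hi")
            if lo < prev_hi:
                raise ValueError("band scheme must be ordered and "
                                 f"non-overlapping (at {name!r})")
            prev_hi = hi
        if not self.freq_lo < self.freq_hi:
            raise ValueError("empty analysis frequency range")

    def to_toml(self, path: str | Path) -> None:
        lines = [
            f"epoch_ms = {self.epoch_ms}",
            f"reject_uv = {self.reject_uv}",
            f"freq_lo = {self.freq_lo}",
            f"freq_hi = {self.freq_hi}",
            f"n_permutations = {self.n_permutations}",
            f"n_bootstraps = {self.n_bootstraps}",
            f"bsr_threshold = {self.bsr_threshold}",
            f"seed = {self.seed}",
        ]
        for name, (lo, hi) in self.bands.items():
            lines.append(f"band_{name} = [{lo}, {hi}]")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "Config":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        bands = {k[len("band_"):]: tuple(v) for k, v in raw.items()
                 if k.startswith("band_")}
        kwargs = {k: v for k, v in raw.items() if not k.startswith("band_")}
        if bands:
            kwargs["bands"] = bands
        kwargs.update(overrides)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Edge tables
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ["electrode_a", "electrode_b", "band", "measure",
                 "salience_sign", "bootstrap_ratio"]


def write_edge_table(edges: pd.DataFrame, path: str | Path,
                     config: Config | None = None) -> None:
    """Write significant edges as a TSV plus a JSON sidecar with run config.

    Rows are sorted into the canonical (band, measure, electrode pair) order
    so repeated runs produce byte-identical files.
    """
    path = Path(path)
    missing = set(_EDGE_COLUMNS) - set(edges.columns)
    if missing:
        raise ValueError(f"edge table missing columns {sorted(missing)}")
    out = edges[_EDGE_COLUMNS].copy()
    out = out.sort_values(["band", "measure", "electrode_a", "electrode_b"],
                          kind="mergesort").reset_index(drop=True)
    out["bootstrap_ratio"] = out["bootstrap_ratio"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)
    if config is not None:
        sidecar = {
            "epoch_ms": config.epoch_ms, "reject_uv": config.reject_uv,
            "freq_lo": config.freq_lo, "freq_hi": config.freq_hi,
            "bands": {k: list(v) for k, v in config.bands.items()},
            "n_permutations": config.n_permutations,
            "n_bootstraps": config.n_bootstraps,
            "bsr_threshold": config.bsr_threshold, "seed": config.seed,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True))


def read_edge_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    if list(df.columns) != _EDGE_COLUMNS:
        raise ValueError(f"{path}: unexpected edge-table columns")
    return df
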