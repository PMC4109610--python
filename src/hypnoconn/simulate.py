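"""Synthetic eyes-closed resting EEG with controlled connectivity effects.

The generator emulates the statistical structure the pipeline must resolve,
not the biophysics of a real head:

* background - one independent 1/f-shaped Gaussian noise source per
  electrode, spatially mixed by an instantaneous distance-decaying kernel.
  Instantaneous mixing produces zero-lag correlations only, i.e. pure volume
  conduction: it inflates COH between neighbours but contributes nothing to
  iCOH.
* oscillators - narrowband filtered-noise rhythms (default: a posterior-
  dominant 10 Hz alpha, the signature of eyes-closed rest), generated per
  electrode and passed through the same instantaneous mixing.
* couplings - phase-lagged narrowband oscillators injected post-mixing into
  both electrodes of a pair, the second electrode receiving a copy whose
  positive-frequency phases are rotated by the requested lag.  A nonzero lag
  in (0, 180) deg yields genuine iCOH; lag -> 0 degenerates to the
  volume-conduction case (COH without iCOH).  Coupling strength is the RMS
  amplitude of the injected oscillator relative to the background RMS; the
  induced band iCOH is monotone in it.

Each coupling carries a per-cell (group x condition) strength, so state x
group effects (e.g. a theta increase confined to high susceptibles under
hypnosis) are planted exactly where requested.  Per-subject lognormal
strength jitter adds between-subject variability.

Determinism: every recording's random stream is derived from
(spec.seed, subject id, condition), so regenerating any recording of a study
is bit-identical regardless of generation order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CONDITIONS, GROUPS, Recording, StudyManifest, write_recording
from .montage import Montage, canonical_label, default_montage

__all__ = ["Coupling", "SimulationSpec", "Study", "simulate_recording",
           "make_study", "null_study", "default_effect_couplings",
           "hub_couplings", "write_study"]

Cell = tuple[str, str]  # (group, condition)


@dataclass(frozen=True)
class Coupling:
    """A phase-lagged narrowband coupling between two electrodes.

    ``strengths`` maps (group, condition) cells to the coupling strength
    (RMS of the injected oscillator as a fraction of the background RMS);
    cells not listed get strength 0.  ``lag_deg`` in (0, 180) produces
    imaginary coherence; 0 produces only instantaneous (COH-like) coupling.
    """

    pair: tuple[str, str]
    band: str
    carrier_hz: float
    bandwidth_hz: float
    lag_deg: float
    strengths: dict[Cell, float] = field(default_factory=dict)

    def strength_in(self, group: str, condition: str) -> float:
        return self.strengths.get((group, condition), 0.0)


def hub_couplings(center: str, neighbours: Sequence[str], band: str,
                  carrier_hz: float, bandwidth_hz: float, lag_deg: float,
                  strengths: dict[Cell, float]) -> list[Coupling]:
    """A star of couplings from ``center`` to each neighbour (a hub)."""
    return [Coupling((canonical_label(center), canonical_label(nb)), band,
                     carrier_hz, bandwidth_hz, lag_deg, dict(strengths))
            for nb in neighbours]


@dataclass
class SimulationSpec:
    """Generative parameters for one study's recordings.

    Defaults mirror the study conditions: 28-channel montage, 500 Hz,
    4-minute eyes-closed recordings, 1/f background with a posterior alpha
    rhythm, and moderate spatial mixing.
    """

    montage: Montage = field(default_factory=default_montage)
    fs: float = 500.0
    duration_s: float = 240.0
    background_exponent: float = 1.0
    background_rms_uv: float = 12.0
    # (carrier Hz, bandwidth Hz, RMS uV) narrowband rhythms, mixed like the
    # background; the default is an eyes-closed posterior alpha.
    oscillators: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(10.0, 2.0, 6.0)])
    couplings: list[Coupling] = field(default_factory=list)
    mixing_spread: float = 0.35     # kernel scale, head-radius units
    subject_jitter_sd: float = 0.15  # lognormal sd of per-subject strength
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s * 1000 < 8 * 2048:
            raise ValueError("duration must cover at least 8 epochs "
                             "(>= 16.4 s)")
        for c in self.couplings:
            for cell, s in c.strengths.items():
                if not 0 <= s <= 1:
                    raise ValueError(
                        f"coupling strength {s} for cell {cell} outside [0,1]")
                if s > 0 and not 0 < c.lag_deg < 180 and c.lag_deg != 0:
                    raise ValueError(
                        f"lag {c.lag_deg} deg outside [0, 180)")


@dataclass
class Study:
    """An in-memory synthetic study: manifest + recordings by (subject, cond)."""

    manifest: StudyManifest
    recordings: dict[tuple[str, str], Recording]
    spec: SimulationSpec


def _mixing_matrix(montage: Montage, spread: float) -> np.ndarray:
    """Instantaneous source-to-electrode kernel, Gaussian in electrode
    distance, rows normalized to unit power gain."""
    d = montage.distance_matrix()
    M = np.exp(-0.5 * (d / spread) ** 2)
    return M / np.linalg.norm(M, axis=1, keepdims=True)


def _one_over_f(rng: np.random.Generator, n_ch: int, n: int, fs: float,
                exponent: float) -> np.ndarray:
    """Independent 1/f^exponent noise channels, unit RMS each."""
    white = rng.standard_normal((n_ch, n))
    F = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.maximum(f, 0.1) ** (-exponent / 2.0)
    shape[0] = 0.0  # remove DC
    x = np.fft.irfft(F * shape, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _narrowband(rng: np.random.Generator, shape: tuple[int, ...], n: int,
                fs: float, carrier: float, bandwidth: float) -> np.ndarray:
    """Filtered-noise oscillator(s): Gaussian spectral bump at the carrier."""
    white = rng.standard_normal(shape + (n,))
    F = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    bump = np.exp(-0.5 * ((f - carrier) / (bandwidth / 2.0)) ** 2)
    bump[0] = 0.0
    x = np.fft.irfft(F * bump, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _phase_lagged(x: np.ndarray, lag_deg: float) -> np.ndarray:
    """Copy of ``x`` with all positive-frequency phases rotated by lag_deg
    (the analytic-signal phase shift; exact for narrowband signals)."""
    F = np.fft.rfft(x, axis=-1)
    F[..., 1:] *= np.exp(-1j * np.deg2rad(lag_deg))
    return np.fft.irfft(F, n=x.shape[-1], axis=-1)


def _recording_seed(spec_seed: int, subject: str, condition: str) -> int:
    tag = zlib.crc32(f"{subject}|{condition}".encode())
    return (spec_seed * 1_000_003 + tag) % (2 ** 31)


def simulate_recording(spec: SimulationSpec, subject: str, group: str,
                       condition: str) -> Recording:
    """Generate one recording for a subject in a group x condition cell.

    Deterministic in (spec.seed, subject, condition): the same spec and seed
    reproduce the recording bit-identically.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(
        _recording_seed(spec.seed, subject, condition))
    # per-subject coupling jitter must match across conditions
    jitter_rng = np.random.default_rng(
        _recording_seed(spec.seed, subject, "jitter"))
    n_ch = spec.montage.n_channels
    n = int(round(spec.duration_s * spec.fs))
    M = _mixing_matrix(spec.montage, spec.mixing_spread)

    sources = _one_over_f(rng, n_ch, n, spec.fs, spec.background_exponent)
    data = (M @ sources)
    data *= spec.background_rms_uv / data.std(axis=-1, keepdims=True)

    for carrier, bw, rms in spec.oscillators:
        osc = _narrowband(rng, (n_ch,), n, spec.fs, carrier, bw)
        mixed = M @ osc
        data += mixed * (rms / mixed.std(axis=-1, keepdims=True))

    for coupling in spec.couplings:
        jitter = float(np.exp(jitter_rng.normal(0.0, spec.subject_jitter_sd)))
        strength = coupling.strength_in(group, condition)
        s_max = max(coupling.strengths.values(), default=0.0)
        # rng draws are unconditional so streams stay aligned across cells
        src = _narrowband(rng, (), n, spec.fs, coupling.carrier_hz,
                          coupling.bandwidth_hz)
        indep = _narrowband(rng, (2,), n, spec.fs, coupling.carrier_hz,
                            coupling.bandwidth_hz)
        if s_max <= 0:
            continue
        # power-matched injection: cells with weaker (or no) coupling get
        # independent oscillators of compensating amplitude, so every cell
        # has identical spectral content and only the phase-lagged
        # *coupling* differs - amplitude and COH stay (near-)null while
        # iCOH carries the planted effect
        amp_c = strength * jitter * spec.background_rms_uv
        amp_i = (np.sqrt(max(s_max ** 2 - strength ** 2, 0.0)) * jitter
                 * spec.background_rms_uv)
        ia = spec.montage.index(coupling.pair[0])
        ib = spec.montage.index(coupling.pair[1])
        data[ia] += amp_c * src + amp_i * indep[0]
        data[ib] += amp_c * _phase_lagged(src, coupling.lag_deg) \
            + amp_i * indep[1]

    return Recording(spec.montage.labels, spec.fs, data,
                     meta={"subject": subject, "group": group,
                           "condition": condition})


def default_effect_couplings(theta_strength: float = 0.55,
                             beta_strength: float = 0.45,
                             beta_reduced: float = 0.15) -> list[Coupling]:
    """The study's default planted effect template.

    * theta (6 Hz carrier) iCOH increase on a Pz-centred hub, present only
      in the (high, hypnosis) cell - the central-parietal theta hub.
    * beta1 (16 Hz carrier) iCOH decrease in (high, hypnosis): Cz- and
      PO2-centred hubs carry a baseline coupling in every cell that drops
      to ``beta_reduced`` for high susceptibles under hypnosis.
    """
    theta_cells = {("high", "hypnosis"): theta_strength}
    beta_cells: dict[Cell, float] = {
        (g, c): beta_strength for g in GROUPS for c in CONDITIONS}
    beta_cells[("high", "hypnosis")] = beta_reduced
    couplings = hub_couplings(
        "Pz", ["Cz", "CP1", "CP2", "P3", "P4", "PO1", "PO2", "Oz"],
        "theta", 6.0, 2.0, 90.0, theta_cells)
    couplings += hub_couplings(
        "Cz", ["Fz", "C3", "C4", "CP1", "CP2"],
        "beta1", 16.0, 3.0, 90.0, beta_cells)
    couplings += hub_couplings(
        "PO2", ["O2", "P4", "P8", "Oz"],
        "beta1", 16.0, 3.0, 90.0, beta_cells)
    return couplings


def _build_study(spec: SimulationSpec, n_high: int, n_low: int) -> Study:
    if n_high < 2 or n_low < 2:
        raise ValueError("need at least 2 subjects per group")
    entries = []
    recordings: dict[tuple[str, str], Recording] = {}
    for group, n_g in (("high", n_high), ("low", n_low)):
        for i in range(n_g):
            subject = f"{group}{i + 1:02d}"
            for cond in CONDITIONS:
                recordings[(subject, cond)] = simulate_recording(
                    spec, subject, group, cond)
            entries.append({"subject": subject, "group": group,
                            "path_pre": f"{subject}_pre",
                            "path_hypnosis": f"{subject}_hypnosis"})
    return Study(StudyManifest(pd.DataFrame(entries)), recordings, spec)


def make_study(spec: SimulationSpec | None = None, n_high: int = 12,
               n_low: int = 11) -> Study:
    """A synthetic study with the default planted state x group effects.

    Defaults use the study sample sizes (12 high, 11 low susceptibles).  If
    ``spec`` is given its couplings are used as-is; otherwise the default
    effect template is installed.
    """
    if spec is None:
        spec = SimulationSpec(couplings=default_effect_couplings())
    return _build_study(spec, n_high, n_low)


def null_study(spec: SimulationSpec | None = None, n_high: int = 12,
               n_low: int = 11) -> Study:
    """A study whose four cells share an identical generative process
    (couplings stripped); used for type-I-error calibration."""
    if spec is None:
        spec = SimulationSpec()
    spec = replace(spec, couplings=[])
    return _build_study(spec, n_high, n_low)


def write_study(study: Study, outdir: str | Path,
                format: str = "matrix") -> None:
    """Persist a study as recording files + manifest JSON + the spec used."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".edf" if format == "edf" else ".tsv"
    entries = study.manifest.entries.copy()
    for col, cond in (("path_pre", "pre"), ("path_hypnosis", "hypnosis")):
        paths = []
        for subject in entries["subject"]:
            fname = f"{subject}_{cond}{suffix}"
            write_recording(study.recordings[(subject, cond)],
                            outdir / fname, format=format)
            paths.append(fname)
        entries[col] = paths
    StudyManifest(entries).to_json(outdir / "manifest.json")
    spec = study.spec
    (outdir / "spec.json").write_text(json.dumps({
        "fs": spec.fs, "duration_s": spec.duration_s,
        "background_exponent": spec.background_exponent,
        "background_rms_uv": spec.background_rms_uv,
        "oscillators": spec.oscillators,
        "mixing_spread": spec.mixing_spread,
        "subject_jitter_sd": spec.subject_jitter_sd,
        "seed": spec.seed,
        "couplings": [{
            "pair": list(c.pair), "band": c.band,
            "carrier_hz": c.carrier_hz, "bandwidth_hz": c.bandwidth_hz,
            "lag_deg": c.lag_deg,
            "strengths": {f"{g}|{cond}": s
                          for (g, cond), s in c.strengths.items()},
        } for c in spec.couplings],
    }, indent=2))
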