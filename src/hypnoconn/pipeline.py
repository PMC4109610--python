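"""End-to-end study analysis and report rendering.

``run_study`` takes a study (manifest + recordings) through preprocessing,
Welch cross-spectra, band connectivity (COH and iCOH in all six bands), and
one mean-centered task PLS per band x measure (12 analyses) plus one PLS of
the channel x frequency amplitude spectra.  ``render_report`` writes the
headline tables: per-band/measure percent crossblock covariance and
permutation p-values, significant-edge tables, hub-degree counts, and
group x condition cell means of iCOH over the significant edges.

Everything is deterministic given the configuration seed; permutation and
bootstrap streams are spawned per analysis in a fixed order, so adding or
removing one analysis does not disturb the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import (ConnectivityMatrix, band_connectivity, coherency,
                           edge_pairs, hub_degree, vectorize_edges)
from .io import CONDITIONS, GROUPS, Config, Recording, StudyManifest, \
    write_edge_table
from .montage import Montage, default_montage
from .pls import (PLSResult, build_feature_matrix, format_pvalue, run_pls,
                  significant_features)
from .preprocess import preprocess_recording
from .simulate import Study
from .spectra import band_bins, epoch_cross_spectra, frequency_axis

logger = logging.getLogger("hypnoconn")

__all__ = ["StudyResults", "run_study", "render_report"]


@dataclass
class StudyResults:
    """All per-band/measure PLS results plus report ingredients."""

    connectivity_pls: dict[tuple[str, str], PLSResult]  # (band, measure)
    amplitude_pls: PLSResult | None
    edge_features: dict[tuple[str, str], dict[tuple[str, str], np.ndarray]]
    pair_labels: list[tuple[str, str]]
    manifest: StudyManifest
    config: Config
    acceptance_rates: dict[tuple[str, str], float]
    bands: list[str]
    measures: tuple[str, ...]

    def significant_edges(self, band: str, measure: str, lv: int = 0,
                          ) -> list[tuple[str, str, int]]:
        """(electrode_a, electrode_b, sign) for the LV's significant edges."""
        res = self.connectivity_pls[(band, measure)]
        feats = significant_features(res, self.config.bsr_threshold)[lv]
        return [(self.pair_labels[i][0], self.pair_labels[i][1], sign)
                for i, sign in feats]


def _recording_features(rec: Recording, config: Config, bands_to_run,
                        measures) -> tuple[dict, np.ndarray, float]:
    """Per-recording band x measure edge vectors + amplitude features."""
    es = preprocess_recording(rec, config.epoch_ms, config.reject_uv)
    n_samp = es.epochs.shape[-1]
    axis = frequency_axis(n_samp, es.fs, config.freq_lo, config.freq_hi)
    se = epoch_cross_spectra(es, axis)
    coh = coherency(se)
    bb = band_bins(config.bands, axis)
    edge_vecs = {}
    for band in bands_to_run:
        for measure in measures:
            cm = band_connectivity(coh, bb[band], measure, band,
                                   rec.channel_labels)
            edge_vecs[(band, measure)] = cm.edge_vector
    return edge_vecs, se.amplitude.ravel(), es.acceptance_rate


def run_study(study: Study, config: Config | None = None,
              bands: list[str] | None = None,
              measures: tuple[str, ...] = ("COH", "iCOH"),
              amplitude: bool = True) -> StudyResults:
    """Run the full study analysis.

    ``bands`` / ``measures`` / ``amplitude`` can restrict the set of PLS
    analyses (used by the calibration experiments); defaults run all six
    bands x both measures plus the amplitude PLS.
    """
    config = config or Config()
    bands_to_run = bands if bands is not None else list(config.bands)
    unknown = set(bands_to_run) - set(config.bands)
    if unknown:
        raise ValueError(f"unknown band(s) {sorted(unknown)}")

    edge_features: dict[tuple[str, str], dict] = {
        (b, m): {} for b in bands_to_run for m in measures}
    amp_features: dict[tuple[str, str], np.ndarray] = {}
    acceptance: dict[tuple[str, str], float] = {}
    labels = None
    for (subject, cond), rec in study.recordings.items():
        try:
            vecs, amp, rate = _recording_features(rec, config, bands_to_run,
                                                  measures)
        except Exception as exc:
            raise RuntimeError(
                f"analysis failed for subject {subject!r}, "
                f"condition {cond!r}: {exc}") from exc
        labels = rec.channel_labels
        acceptance[(subject, cond)] = rate
        logger.info("preprocessed %s/%s: acceptance %.3f", subject, cond, rate)
        for key, vec in vecs.items():
            edge_features[key][(subject, cond)] = vec
        amp_features[(subject, cond)] = amp

    pairs = edge_pairs(len(labels))
    pair_labels = [(labels[i], labels[j]) for i, j in pairs]
    pair_ids = [f"{a}-{b}" for a, b in pair_labels]

    ss = np.random.SeedSequence(config.seed)
    n_analyses = len(bands_to_run) * len(measures) + 1
    streams = ss.spawn(n_analyses)

    connectivity_pls = {}
    idx = 0
    for band in bands_to_run:
        for measure in measures:
            fm = build_feature_matrix(edge_features[(band, measure)],
                                      study.manifest, pair_ids)
            res = run_pls(fm, config.n_permutations, config.n_bootstraps,
                          config.bsr_threshold, streams[idx])
            res.seed = config.seed
            connectivity_pls[(band, measure)] = res
            logger.info("PLS %s/%s: LV1 %.2f%% p=%s", band, measure,
                        res.pct_crossblock[0],
                        format_pvalue(res.perm_p[0], config.n_permutations))
            idx += 1

    amplitude_pls = None
    if amplitude:
        fm = build_feature_matrix(amp_features, study.manifest)
        amplitude_pls = run_pls(fm, config.n_permutations,
                                config.n_bootstraps, config.bsr_threshold,
                                streams[idx])
        amplitude_pls.seed = config.seed

    return StudyResults(connectivity_pls, amplitude_pls, edge_features,
                        pair_labels, study.manifest, config, acceptance,
                        list(bands_to_run), tuple(measures))


def _cell_mean_icoh(results: StudyResults, band: str,
                    edges: list[tuple[str, str, int]]) -> dict:
    """Mean iCOH over an edge set, per group x condition cell."""
    pair_pos = {pl: i for i, pl in enumerate(results.pair_labels)}
    idx = [pair_pos[(a, b)] for a, b, _ in edges]
    feats = results.edge_features[(band, "iCOH")]
    cells = {}
    for group in GROUPS:
        block = results.manifest.entries[
            results.manifest.entries["group"] == group]
        for cond in CONDITIONS:
            vals = [feats[(s, cond)][idx] for s in block["subject"]]
            cells[(group, cond)] = float(np.mean(vals)) if idx else float("nan")
    return cells


def render_report(results: StudyResults, montage: Montage | None = None,
                  outdir: str | Path = "results",
                  n_report_lv: int = 2) -> dict[str, Path]:
    """Write the study's headline report tables; returns the written paths.

    * ``pls_summary.tsv`` - band x measure x LV percent crossblock
      covariance and permutation p (the Table-2 layout), plus the amplitude
      PLS and a Bonferroni note for transparency (the per-band analyses are
      deliberately not corrected).
    * ``edges_<band>_<measure>.tsv`` - significant edges of each LV with
      p <= 0.05, with loading signs and bootstrap ratios.
    * ``hub_degree.tsv`` - per-electrode significant-edge counts, maxima
      flagged.
    * ``cell_means.tsv`` - mean iCOH over each significant edge set per
      group x condition cell.
    """
    montage = montage or default_montage()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    cfg = results.config

    rows = []
    for band in results.bands:
        for measure in results.measures:
            res = results.connectivity_pls[(band, measure)]
            for k in range(min(n_report_lv, res.n_lv)):
                rows.append({
                    "analysis": "connectivity", "band": band,
                    "measure": measure, "lv": k + 1,
                    "pct_crossblock": f"{res.pct_crossblock[k]:.2f}",
                    "perm_p": format_pvalue(res.perm_p[k],
                                            res.n_permutations),
                })
    if results.amplitude_pls is not None:
        res = results.amplitude_pls
        for k in range(min(n_report_lv, res.n_lv)):
            rows.append({
                "analysis": "amplitude", "band": "all", "measure": "amp",
                "lv": k + 1,
                "pct_crossblock": f"{res.pct_crossblock[k]:.2f}",
                "perm_p": format_pvalue(res.perm_p[k], res.n_permutations),
            })
    summary = pd.DataFrame(rows)
    path = outdir / "pls_summary.tsv"
    with open(path, "w") as fh:
        fh.write(f"# n_permutations={cfg.n_permutations} "
                 f"n_bootstraps={cfg.n_bootstraps} seed={cfg.seed}\n")
        fh.write("# per-band analyses are reported uncorrected; Bonferroni "
                 f"alpha across {len(results.bands) * len(results.measures)} "
                 "connectivity analyses would be "
                 f"{0.05 / (len(results.bands) * len(results.measures)):.5f}\n")
        summary.to_csv(fh, sep="\t", index=False)
    written["pls_summary"] = path

    band_sig_edges: dict[str, list[tuple[str, str, int]]] = {}
    cell_rows = []
    for band in results.bands:
        for measure in results.measures:
            res = results.connectivity_pls[(band, measure)]
            sig_lvs = [k for k in range(min(n_report_lv, res.n_lv))
                       if res.perm_p[k] <= 0.05]
            for k in sig_lvs:
                edges = results.significant_edges(band, measure, k)
                if not edges:
                    continue
                pair_pos = {pl: i for i, pl in
                            enumerate(results.pair_labels)}
                table = pd.DataFrame([{
                    "electrode_a": a, "electrode_b": b,
                    "band": band, "measure": measure,
                    "salience_sign": sign,
                    "bootstrap_ratio":
                        res.bootstrap_ratios[pair_pos[(a, b)], k],
                } for a, b, sign in edges])
                epath = outdir / f"edges_{band}_{measure}_lv{k + 1}.tsv"
                write_edge_table(table, epath, cfg)
                written[f"edges_{band}_{measure}_lv{k + 1}"] = epath
                if measure == "iCOH":
                    band_sig_edges.setdefault(band, []).extend(edges)
                    cells = _cell_mean_icoh(results, band, edges)
                    for (g, c), v in cells.items():
                        cell_rows.append({
                            "band": band, "lv": k + 1, "group": g,
                            "condition": c, "mean_icoh": f"{v:.6f}"})

    hub_frames = []
    for band, edges in band_sig_edges.items():
        degree = hub_degree([(a, b) for a, b, _ in edges], montage)
        hub_frames.append(pd.DataFrame({
            "band": band,
            "electrode": degree.index,
            "n_significant_edges": degree.values,
            "is_maximum": [lab in degree.attrs["max_labels"]
                           for lab in degree.index],
        }))
    hub_table = (pd.concat(hub_frames, ignore_index=True) if hub_frames
                 else pd.DataFrame(columns=["band", "electrode",
                                            "n_significant_edges",
                                            "is_maximum"]))
    path = outdir / "hub_degree.tsv"
    hub_table.to_csv(path, sep="\t", index=False)
    written["hub_degree"] = path

    path = outdir / "cell_means.tsv"
    pd.DataFrame(cell_rows, columns=["band", "lv", "group", "condition",
                                     "mean_icoh"]
                 ).to_csv(path, sep="\t", index=False)
    written["cell_means"] = path
    return written
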