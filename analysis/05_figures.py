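"""Render schematic edge-map, hub-degree and cell-mean figures.

Reads the report tables written by 02_run_pipeline.py and draws the
publication-style schematics: significant iCOH edges on the 2-D head layout (red
= positive loading, blue = negative), per-electrode significant-edge counts,
and the group x condition cell means of iCOH over the significant edges.
Figures go to scratch/figures/ (they are presentation artifacts, not
results).
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import hypnoconn as hc

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "results" / "run"


def draw_head(ax, montage):
    circle = plt.Circle((0, 0), 1.05, fill=False, lw=1.5)
    ax.add_patch(circle)
    ax.plot([-0.08, 0, 0.08], [1.04, 1.16, 1.04], "k-", lw=1.5)  # nose
    for lab, (x, y) in montage.positions.items():
        ax.plot(x, y, "ko", ms=3)
        ax.annotate(lab, (x, y), textcoords="offset points", xytext=(3, 3),
                    fontsize=6)
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")


def main() -> None:
    montage = hc.default_montage()
    outdir = ROOT / "scratch" / "figures"
    outdir.mkdir(parents=True, exist_ok=True)

    edge_files = sorted(RUN.glob("edges_*_iCOH_lv1.tsv"))
    for path in edge_files:
        edges = hc.read_edge_table(path)
        band = edges["band"].iloc[0] if len(edges) else path.stem
        fig, ax = plt.subplots(figsize=(5, 5))
        draw_head(ax, montage)
        for _, e in edges.iterrows():
            xa, ya = montage.positions[e["electrode_a"]]
            xb, yb = montage.positions[e["electrode_b"]]
            color = "crimson" if e["salience_sign"] > 0 else "royalblue"
            ax.plot([xa, xb], [ya, yb], color=color, lw=1, alpha=0.7)
        ax.set_title(f"significant iCOH edges, {band} (LV1)")
        fig.savefig(outdir / f"edges_{band}.png", dpi=150,
                    bbox_inches="tight")
        plt.close(fig)
        print(f"{band}: {len(edges)} significant edges drawn")

    hub = pd.read_csv(RUN / "hub_degree.tsv", sep="\t")
    for band, sub in hub.groupby("band"):
        fig, ax = plt.subplots(figsize=(9, 3))
        colors = ["crimson" if m else "grey" for m in sub["is_maximum"]]
        ax.bar(sub["electrode"], sub["n_significant_edges"], color=colors)
        ax.set_ylabel("significant edges")
        ax.set_title(f"{band}: significant iCOH changes per electrode")
        ax.tick_params(axis="x", rotation=60, labelsize=7)
        fig.savefig(outdir / f"hub_degree_{band}.png", dpi=150,
                    bbox_inches="tight")
        plt.close(fig)

    cells = pd.read_csv(RUN / "cell_means.tsv", sep="\t")
    if len(cells):
        bands = cells["band"].unique()
        fig, axes = plt.subplots(1, len(bands), figsize=(4 * len(bands), 3),
                                 squeeze=False)
        for ax, band in zip(axes[0], bands):
            sub = cells[cells["band"] == band]
            for group, marker in (("high", "o-"), ("low", "s--")):
                g = sub[sub["group"] == group].set_index("condition")
                ax.plot(["pre", "hypnosis"],
                        g.loc[["pre", "hypnosis"], "mean_icoh"], marker,
                        label=group)
            ax.set_title(band)
            ax.set_ylabel("mean iCOH (significant edges)")
            ax.legend()
        fig.savefig(outdir / "cell_means.png", dpi=150, bbox_inches="tight")
        plt.close(fig)
    print("figures written to", outdir)


if __name__ == "__main__":
    main()
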