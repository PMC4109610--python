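"""Power/recovery of the planted theta-hub effect over replicate studies.

Simulates 20 replicate studies carrying the default planted effect (theta
iCOH increase on the Pz hub in the (high, hypnosis) cell), analyses each,
and scores four recovery criteria per replicate: LV1 permutation p <= 0.05,
design-score contrast concentrated in the high group, at least half the
planted edges reaching |BSR| >= 2, and the hub-degree maximum at Pz.
"""

from pathlib import Path

import hypnoconn as hc

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    table = hc.recovery_experiment(n_replicates=20, n_high=8, n_low=8,
                                   duration_s=60.0, n_perm=200, n_boot=200,
                                   seed=43)
    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)
    table.to_csv(outdir / "effect_recovery.tsv", sep="\t", index=False)
    print(table.to_string(index=False,
                          columns=["replicate", "lv1_p",
                                   "frac_planted_recovered", "hub_max",
                                   "detected"]))
    print(f"\ndetected in {table['detected'].mean():.0%} of "
          f"{len(table)} replicates")


if __name__ == "__main__":
    main()
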