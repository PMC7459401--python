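"""Desiccation-survival statistics on the simulated assay counts.

Reads results/sim_data/survival.tsv (three conditions x 3 replicates x
15 animals), summarizes recovery rates as mean +/- SD, and compares all
condition pairs with the Tukey-Kramer test (the >=3-condition branch of
the auto rule; two conditions would get Student's t).  Writes tables
under results/survival/.
"""

from pathlib import Path

from tardilfq import evidence_io
from tardilfq.survival import recovery_summary, survival_test

IN = Path("results/sim_data")
OUT = Path("results/survival")


def main() -> None:
    assays = evidence_io.read_survival(IN / "survival.tsv")
    rs = recovery_summary(assays)
    tests = survival_test(assays, test="auto")

    evidence_io.write_report(
        {"recovery_summary": rs.summary, "recovery_tests": tests}, OUT
    )

    print("recovery rates (mean +/- SD):")
    for _, row in rs.summary.iterrows():
        print(f"  {row['condition']:<10s} {row['mean_rate']:.3f} +/- "
              f"{row['sd_rate']:.3f} (n={row['n']})")
    print("Tukey-Kramer pairwise comparisons:")
    for _, row in tests.iterrows():
        flag = "*" if row["p"] < 0.05 else " "
        print(f"  {row['group1']} vs {row['group2']}: "
              f"diff {row['mean_diff']:+.3f}, q {row['q']:.3f}, "
              f"p {row['p']:.4f} {flag}")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
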