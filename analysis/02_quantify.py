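"""Quantify the simulated evidence: normalize, relative expression, roll-up.

Reads results/sim_data/, runs the three-step quantification and writes
the protein-by-run relative-expression matrix plus per-cell unique
peptide counts under results/quant/.  Reports how well the totals-based
run normalization recovered the true loading factors.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tardilfq import evidence_io
from tardilfq.quant import quantify

IN = Path("results/sim_data")
OUT = Path("results/quant")


def main() -> None:
    evidence = evidence_io.read_evidence(IN / "evidence.tsv")
    db = evidence_io.read_fasta(IN / "database.fasta")

    pq, ne, uniq = quantify(evidence, db)
    evidence_io.write_report(
        {
            "protein_matrix": pq.matrix,
            "unique_peptide_counts_per_run": pq.n_peptides,
        },
        OUT,
    )

    truth = pd.read_csv(IN / "truth_scales.tsv", sep="\t").set_index("run")["scale"]
    est = 1.0 / ne.scale
    ratio = est / truth
    rel = ratio / np.exp(np.log(ratio).mean())
    print(f"quantified {pq.matrix.shape[0]} proteins x {pq.matrix.shape[1]} runs")
    print(f"excluded (no unique peptides): {len(pq.excluded)}; "
          f"unmatched peptides: {uniq.n_unmatched}")
    print(f"run-loading recovery: mean |rel err| = {np.abs(rel - 1).mean():.4f}, "
          f"max = {np.abs(rel - 1).max():.4f} "
          f"(includes the compositional shift the spike-ins impose on run "
          f"totals; in a no-effect world the mean error is <1%)")
    print(f"wrote {OUT}/protein_matrix.tsv")


if __name__ == "__main__":
    main()
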