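"""Label-free quantification: run normalization, relative expression, roll-up.

The scheme is the three-step peak-area procedure used for the tardigrade
chemical-pretreatment proteome:

1. **Run normalization.**  Each run's peak areas are rescaled using the
   areas of *all* identified peptides in that run.  The default statistic
   is the total sum: with ``T_r = sum_p A_{p,r}`` and ``Tbar`` the mean
   total over runs, every area in run ``r`` is multiplied by
   ``s_r = Tbar / T_r``, so all normalized run totals equal ``Tbar``.
   This removes per-run loading/injection differences.  A median-ratio
   alternative is available for robustness to a few dominant peptides.

2. **Peptide relative expression.**  Each peptide's normalized area in a
   run is divided by the mean of that same sequence's normalized areas
   over the runs where it was detected:
   ``E_{p,r} = Ã_{p,r} / mean_{r' in detected(p)} Ã_{p,r'}``.
   By construction the detected-run mean of ``E`` is exactly 1 for every
   peptide; undetected cells stay masked (NaN), never zero-filled.

3. **Protein roll-up.**  A protein's level in a run is the median of the
   relative expression of its *unique* peptides detected in that run
   (shared peptides never contribute).  Even-count medians are the mean
   of the two central values.  The result is a protein-by-run matrix of
   positive levels with a NaN mask, plus per-cell contributing-peptide
   counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tardilfq.evidence_io import PeptideUniqueness, ValidationError


@dataclass
class NormalizedEvidence:
    """Evidence table with a ``normalized_area`` column plus per-run scales."""

    table: pd.DataFrame  # columns: peptide, run, area, normalized_area
    scale: pd.Series  # run -> s_r

    @property
    def runs(self) -> list[str]:
        return list(self.scale.index)


@dataclass
class ProteinQuant:
    """Protein-level relative expression.

    ``matrix``: protein-by-run levels (NaN = not quantified in that run).
    ``n_peptides``: per-cell count of contributing unique peptides.
    ``excluded``: proteins matched only by shared peptides — they have no
    unique peptide anywhere and cannot be quantified under this scheme.
    """

    matrix: pd.DataFrame
    n_peptides: pd.DataFrame
    excluded: list[str]
    n_distinct: pd.Series | None = None  # distinct unique peptides per protein


def normalize_runs(evidence: pd.DataFrame, method: str = "total") -> NormalizedEvidence:
    """Normalize peak areas across LC-MS runs.

    Parameters
    ----------
    evidence:
        Long evidence table (peptide / run / area, area > 0).
    method:
        ``"total"`` (default): equalize per-run totals at the grand-mean
        total.  ``"median_ratio"``: scale by the per-run median of
        area-to-reference ratios (reference = each peptide's mean area
        across its detected runs), then rescale to the grand-mean ratio.

    Raises
    ------
    ValidationError
        If a run has zero total area.
    """
    if evidence.empty:
        raise ValidationError("evidence table is empty")
    totals = evidence.groupby("run")["area"].sum()
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValidationError(f"run {bad!r} has zero total peak area")

    if method == "total":
        scale = totals.mean() / totals
    elif method == "median_ratio":
        ref = evidence.groupby("peptide")["area"].transform("mean")
        ratios = (evidence["area"] / ref).groupby(evidence["run"]).median()
        scale = ratios.mean() / ratios
    else:
        raise ValueError(f"unknown normalization method {method!r}")

    table = evidence.copy()
    table["normalized_area"] = table["area"].to_numpy() * scale.loc[
        table["run"]
    ].to_numpy()
    scale.name = "scale"
    return NormalizedEvidence(table=table, scale=scale.sort_index())


def peptide_relative_expression(ne: NormalizedEvidence) -> pd.DataFrame:
    """Per-peptide relative expression matrix ``E`` (peptides x runs).

    Each normalized area is divided by the mean of the same peptide's
    normalized areas over its detected runs, so every row's detected-run
    mean is 1.  Undetected cells are NaN.
    """
    wide = ne.table.pivot(index="peptide", columns="run", values="normalized_area")
    wide = wide.reindex(columns=ne.runs)
    row_mean = wide.mean(axis=1, skipna=True)
    E = wide.div(row_mean, axis=0)
    E.columns.name = "run"
    return E


def protein_rollup(E: pd.DataFrame, uniqueness: PeptideUniqueness) -> ProteinQuant:
    """Roll peptide relative expression up to protein level.

    Per (protein, run): median of ``E`` over that protein's unique
    peptides detected in the run.  Proteins whose every matching peptide
    is shared are excluded and reported.

    Raises
    ------
    KeyError
        If a peptide in ``E`` has no uniqueness entry.
    """
    owner = {}
    for pep in E.index:
        prot = uniqueness.unique_protein(pep)  # KeyError if unmapped
        if prot is not None:
            owner[pep] = prot

    unique_rows = E.loc[list(owner.keys())]
    groups = pd.Series(owner, name="protein")
    matrix = unique_rows.groupby(groups).median()
    counts = unique_rows.notna().groupby(groups).sum().astype(int)

    quantified = set(matrix.index)
    excluded = sorted(uniqueness.matched_proteins() - quantified)
    matrix.index.name = "protein"
    counts.index.name = "protein"
    n_distinct = groups.value_counts().reindex(matrix.index).astype(int)
    n_distinct.name = "n_unique_peptides"
    return ProteinQuant(
        matrix=matrix, n_peptides=counts, excluded=excluded, n_distinct=n_distinct
    )


def quantify(
    evidence: pd.DataFrame,
    db: dict[str, str],
    il_equivalent: bool = True,
    method: str = "total",
) -> tuple[ProteinQuant, NormalizedEvidence, PeptideUniqueness]:
    """Full quantification: normalize, relative expression, roll-up."""
    from tardilfq.evidence_io import map_peptide_uniqueness

    ne = normalize_runs(evidence, method=method)
    uniq = map_peptide_uniqueness(
        ne.table["peptide"].unique(), db, il_equivalent=il_equivalent
    )
    E = peptide_relative_expression(ne)
    pq = protein_rollup(E, uniq)
    return pq, ne, uniq


def total_unique_peptides(pq: ProteinQuant) -> pd.Series:
    """Distinct unique peptides observed per protein across all runs."""
    if pq.n_distinct is not None:
        return pq.n_distinct
    return pq.n_peptides.max(axis=1).rename("n_unique_peptides")
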