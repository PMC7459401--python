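"""Readers, writers and validation for all external tables.

The native interchange formats are deliberately minimal and text-only:

* evidence (long): TSV with columns ``peptide``, ``run``, ``area`` — one
  quantified peak area per peptide sequence per LC-MS run.  Absence of a
  row means the peptide was not detected in that run.
* evidence (wide): TSV with a ``peptide`` column plus one intensity
  column per run (the shape most search engines export); zeros and blank
  cells mean "not detected" and are dropped on load.
* manifest: TSV with columns ``run``, ``group``, ``replicate`` mapping
  each LC-MS run to its experimental group and biological replicate.
* survival: TSV with columns ``condition``, ``replicate``, ``recovered``,
  ``total`` — desiccation-assay animal counts.
* protein database: standard FASTA; the header token up to the first
  whitespace is the protein id.

Peptide strings may carry modification annotations (parenthesised or
bracketed groups, underscores, lowercase); these are stripped to the bare
uppercase sequence on load, and peak areas of modified forms of the same
sequence in the same run are summed, since quantification aggregates by
sequence identity.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

EVIDENCE_COLUMNS = ("peptide", "run", "area")
MANIFEST_COLUMNS = ("run", "group", "replicate")
SURVIVAL_COLUMNS = ("condition", "replicate", "recovered", "total")


class FormatError(ValueError):
    """A file does not have the expected structure (e.g. missing column)."""


class ValidationError(ValueError):
    """A file parses but violates an invariant (e.g. negative peak area)."""


_ANNOTATION = re.compile(r"\([^)]*\)|\[[^\]]*\]")
_NON_LETTER = re.compile(r"[^A-Za-z]")


def strip_modifications(peptide: str) -> str:
    """Strip modification annotations, returning the bare uppercase sequence.

    Removes parenthesised / bracketed groups such as ``M(ox)`` or
    ``C[+57.02]`` and any non-letter characters (e.g. flanking
    underscores), then uppercases.  Idempotent.
    """
    bare = _ANNOTATION.sub("", peptide)
    bare = _NON_LETTER.sub("", bare)
    return bare.upper()


def _check_sequence_alphabet(seq: str, *, where: str, allow_x: bool = False) -> None:
    allowed = AMINO_ACIDS | {"X"} if allow_x else AMINO_ACIDS
    bad = set(seq) - allowed
    if bad:
        raise ValidationError(
            f"{where}: non-amino-acid characters {sorted(bad)} in {seq!r}"
        )


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_evidence(path: str | Path, dialect: str = "long") -> pd.DataFrame:
    """Read a peptide evidence table into the long form.

    Parameters
    ----------
    path:
        TSV file.
    dialect:
        ``"long"`` (columns peptide/run/area) or ``"wide"`` (column
        peptide, then one intensity column per run).

    Returns
    -------
    DataFrame with columns ``peptide``, ``run``, ``area``; one row per
    detected (peptide, run); ``area`` strictly positive.  Modification
    annotations are stripped and same-sequence forms summed within a run.
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "long":
        df = _read_tsv(path, EVIDENCE_COLUMNS)
        df = df[list(EVIDENCE_COLUMNS)].copy()
    else:
        raw = _read_tsv(path, ("peptide",))
        run_cols = [c for c in raw.columns if c != "peptide"]
        if not run_cols:
            raise FormatError(f"{path}: wide evidence table has no run columns")
        df = raw.melt(id_vars="peptide", var_name="run", value_name="area")

    df["area"] = pd.to_numeric(df["area"].replace("", "NaN"), errors="coerce")
    negative = df.index[df["area"] < 0]
    if len(negative):
        raise ValidationError(
            f"{path}: negative peak area at row {int(negative[0])}"
        )
    # zero / blank intensity cells are sentinels for "not detected"
    df = df[df["area"] > 0].copy()

    # duplicate raw (peptide, run) rows are a malformed export, not mod forms
    dup = df.duplicated(subset=["peptide", "run"])
    if dup.any():
        p, r = df.loc[dup.idxmax(), ["peptide", "run"]]
        raise ValidationError(f"{path}: duplicate rows for peptide {p!r} in run {r!r}")

    df["peptide"] = df["peptide"].map(strip_modifications)
    empty = df["peptide"] == ""
    if empty.any():
        raise ValidationError(f"{path}: empty peptide sequence after stripping")
    for pep in df["peptide"].unique():
        _check_sequence_alphabet(pep, where=str(path))

    # modified forms of one sequence in one run collapse by summed area
    out = (
        df.groupby(["peptide", "run"], as_index=False, sort=True)["area"]
        .sum()
    )
    return out[list(EVIDENCE_COLUMNS)]


def write_evidence(df: pd.DataFrame, path: str | Path) -> None:
    df[list(EVIDENCE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an ordered mapping ``protein_id -> sequence``.

    The id is the header token up to the first whitespace.  Sequences are
    uppercased; ``X`` is tolerated as an unknown residue.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in db:
            raise ValidationError(f"{path}: duplicate protein id {rec.id!r}")
        if not seq:
            raise ValidationError(f"{path}: empty sequence for {rec.id!r}")
        _check_sequence_alphabet(seq, where=f"{path}:{rec.id}", allow_x=True)
        db[rec.id] = seq
    if not db:
        raise FormatError(f"{path}: no FASTA records found")
    return db


def write_fasta(db: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in db.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class PeptideUniqueness:
    """Peptide-to-protein assignment by contiguous substring matching.

    ``proteins`` maps every queried peptide to the set of database
    proteins whose sequence contains it; a peptide is *unique* iff that
    set has exactly one member.  Only unique peptides contribute to
    protein quantification.  Peptides matching no protein are retained
    with an empty set (they never contribute anywhere) and counted in
    ``n_unmatched``.
    """

    proteins: dict[str, frozenset[str]]
    il_equivalent: bool = True
    _unique: dict[str, bool] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._unique = {p: len(s) == 1 for p, s in self.proteins.items()}

    def is_unique(self, peptide: str) -> bool:
        return self._unique[peptide]

    def unique_protein(self, peptide: str) -> str | None:
        s = self.proteins[peptide]
        return next(iter(s)) if len(s) == 1 else None

    @property
    def n_unmatched(self) -> int:
        return sum(1 for s in self.proteins.values() if not s)

    def unique_peptides(self) -> list[str]:
        return [p for p, u in self._unique.items() if u]

    def matched_proteins(self) -> set[str]:
        out: set[str] = set()
        for s in self.proteins.values():
            out |= s
        return out


def map_peptide_uniqueness(
    peptides, db: dict[str, str], il_equivalent: bool = True
) -> PeptideUniqueness:
    """Map peptides to the database proteins containing them as substrings.

    Isoleucine and leucine are treated as equivalent by default because
    they are mass-indistinguishable to the instrument class producing the
    evidence; disable with ``il_equivalent=False``.

    Implementation detail: all protein sequences are concatenated with a
    separator and each peptide located with ``str.find``, which is linear
    scanning in C — fast enough for thousands of peptides against
    thousands of proteins, and checked in the tests against a brute-force
    per-pair substring scan.
    """
    peptides = list(dict.fromkeys(peptides))
    if not peptides or not db:
        raise ValueError("peptides and database must be non-empty")

    def canon(s: str) -> str:
        return s.replace("I", "L") if il_equivalent else s

    ids = list(db.keys())
    seqs = [canon(db[i]) for i in ids]
    sep = "#"  # not an amino-acid letter; blocks cross-protein matches
    big = sep.join(seqs)
    starts = []  # start offset of each protein within `big`
    off = 0
    for s in seqs:
        starts.append(off)
        off += len(s) + 1

    mapping: dict[str, frozenset[str]] = {}
    for pep in peptides:
        cp = canon(pep)
        hits: set[str] = set()
        pos = big.find(cp)
        while pos != -1:
            hits.add(ids[bisect_right(starts, pos) - 1])
            pos = big.find(cp, pos + 1)
        mapping[pep] = frozenset(hits)
    return PeptideUniqueness(mapping, il_equivalent=il_equivalent)


GROUP_LABELS = ("untreated", "vehicle", "treatment")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the run manifest (columns run / group / replicate)."""
    df = _read_tsv(path, MANIFEST_COLUMNS)
    df = df[list(MANIFEST_COLUMNS)].copy()
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    if df["run"].duplicated().any():
        dup = df.loc[df["run"].duplicated(), "run"].iloc[0]
        raise ValidationError(f"{path}: duplicate run id {dup!r}")
    if (df["replicate"] < 1).any():
        raise ValidationError(f"{path}: replicate labels must be >= 1")
    if df.duplicated(subset=["group", "replicate"]).any():
        raise ValidationError(f"{path}: replicate labels not unique within group")
    return df


def require_groups(manifest: pd.DataFrame, labels) -> None:
    """Raise unless every label in ``labels`` appears in the manifest."""
    present = set(manifest["group"])
    missing = [g for g in labels if g not in present]
    if missing:
        raise ValidationError(f"manifest lacks required group(s) {missing}")


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df[list(MANIFEST_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read the survival-assay count table (condition/replicate/recovered/total)."""
    df = _read_tsv(path, SURVIVAL_COLUMNS)
    df = df[list(SURVIVAL_COLUMNS)].copy()
    for col in ("replicate", "recovered", "total"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    if (df["total"] <= 0).any():
        raise ValidationError(f"{path}: total animal count must be positive")
    if (df["recovered"] < 0).any() or (df["recovered"] > df["total"]).any():
        raise ValidationError(f"{path}: recovered count outside [0, total]")
    return df


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df[list(SURVIVAL_COLUMNS)].to_csv(path, sep="\t", index=False)


def write_protein_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a protein-by-run matrix; masked (undefined) cells become ``NA``."""
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="protein")


def read_protein_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col="protein", na_values=["NA"])
    return df


def write_report(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write each named table as ``<out_dir>/<name>.tsv``; return the paths.

    Tables whose name contains ``matrix`` are written with their index
    (protein ids) and ``NA`` for masked cells; all others are plain
    headered TSV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in tables.items():
        p = out_dir / f"{name}.tsv"
        if "matrix" in name or "counts_per_run" in name:
            write_protein_matrix(table, p)
        else:
            table.to_csv(p, sep="\t", index=False, na_rep="NA")
        paths[name] = p
    return paths
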