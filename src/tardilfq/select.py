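"""Differential-abundance cascade with a vehicle (solvent) control gate.

The design has three groups — untreated, vehicle (solvent only) and
treatment — each in biological triplicate.  The cascade is:

* **detected**: protein quantified anywhere (rows of the protein matrix);
* **tested**: quantified in every replicate of every group (the
  "biological triplicate" rule), so both t-tests and both fold changes
  are computable;
* **differentially regulated**: equal-variance two-sided Student's
  t-test of treatment vs untreated significant at ``alpha`` AND vehicle
  vs untreated NOT significant — a change attributable to the drug, not
  the solvent;
* **significant (up/down)**: among differentially regulated proteins,
  treatment fold change strictly beyond ``fc_threshold`` (default
  two-fold, either direction) AND vehicle fold change inside the closed
  band (default [0.8, 1.2]).

No multiple-testing correction enters the cascade — the fold-change and
vehicle-band criteria play that role — but a Benjamini-Hochberg column
is emitted for information.

Fold changes are ratios of per-group arithmetic means of the protein
level, matching mean +/- SD reporting; a geometric-mean option exists.
t-tests run on the linear protein level by default, with a
log-transform flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tardilfq.evidence_io import ValidationError, require_groups

CLASS_ORDER = (
    "not_tested",
    "tested",
    "differentially_regulated",
    "significant_up",
    "significant_down",
)


@dataclass
class SelectionConfig:
    """Thresholds and group labels for the selection cascade."""

    alpha: float = 0.05
    fc_threshold: float = 2.0
    vehicle_band: tuple[float, float] = (0.8, 1.2)
    control: str = "untreated"
    vehicle: str = "vehicle"
    treatment: str = "treatment"
    log_transform: bool = False  # t-test on log(level) instead of level
    welch: bool = False  # unequal-variance t as an alternative
    fc_method: str = "arithmetic"  # or "geometric"
    require_all_groups: bool = True  # triplicate rule over all 3 groups

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        lo, hi = self.vehicle_band
        if not lo < 1 < hi:
            raise ValueError("vehicle_band must bracket 1")
        if self.fc_method not in ("arithmetic", "geometric"):
            raise ValueError(f"unknown fc_method {self.fc_method!r}")


class TTestResult(NamedTuple):
    statistic: float
    pvalue: float
    df: float
    degenerate: bool  # pooled variance zero with unequal means


def student_t_test(a, b, welch: bool = False) -> TTestResult:
    """Equal-variance two-sample Student's t-test, two-sided.

    Degenerate inputs (zero pooled variance) resolve deterministically:
    equal means give t = 0, p = 1; unequal means give p = 0 with the
    ``degenerate`` flag set.

    With ``welch=True`` uses the unequal-variance form
    (Welch-Satterthwaite df) instead.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 observations")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)

    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            if ma == mb:
                return TTestResult(0.0, 1.0, float(na + nb - 2), False)
            return TTestResult(np.inf * np.sign(ma - mb), 0.0, float(na + nb - 2), True)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = (ma - mb) / np.sqrt(se2)
    else:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if sp2 == 0:
            if ma == mb:
                return TTestResult(0.0, 1.0, df, False)
            return TTestResult(np.inf * np.sign(ma - mb), 0.0, df, True)
        t = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))

    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(p), float(df), False)


def _groups_runs(manifest: pd.DataFrame, cfg: SelectionConfig) -> dict[str, list[str]]:
    require_groups(manifest, (cfg.control, cfg.vehicle, cfg.treatment))
    return {
        g: manifest.loc[manifest["group"] == g, "run"].tolist()
        for g in (cfg.control, cfg.vehicle, cfg.treatment)
    }


def triplicate_filter(
    matrix: pd.DataFrame,
    manifest: pd.DataFrame,
    cfg: SelectionConfig | None = None,
) -> pd.Series:
    """Boolean mask of proteins quantified in every replicate of every group.

    With ``cfg.require_all_groups=False``, only the two compared groups
    (control + vehicle, control + treatment) must be complete — which,
    with three groups, still means all of them; the flag exists for
    designs with extra, uncompared groups.
    """
    cfg = cfg or SelectionConfig()
    runs_by_group = _groups_runs(manifest, cfg)
    for g, runs in runs_by_group.items():
        if len(runs) < 3:
            raise ValidationError(f"group {g!r} has fewer than 3 replicates")
    if cfg.require_all_groups:
        needed = [r for runs in runs_by_group.values() for r in runs]
    else:
        needed = [
            r
            for g in (cfg.control, cfg.vehicle, cfg.treatment)
            for r in runs_by_group[g]
        ]
    mask = matrix[needed].notna().all(axis=1)
    mask.name = "detected_triplicate"
    return mask


def _vector_t(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided t-test for matrices a (m x na) and b (m x nb)."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    if welch:
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            t = (ma - mb) / np.sqrt(se2)
    else:
        df = np.full(len(ma), float(na + nb - 2))
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = np.where(welch, va / na + vb / nb, va + vb) == 0
    eq = ma == mb
    t = np.where(zero_var & eq, 0.0, t)
    p = np.where(zero_var & eq, 1.0, np.where(zero_var & ~eq, 0.0, p))
    return t, p


def classify_differential(
    matrix: pd.DataFrame,
    manifest: pd.DataFrame,
    cfg: SelectionConfig | None = None,
    n_unique_peptides: pd.Series | None = None,
) -> pd.DataFrame:
    """Run the cascade up to the "differentially regulated" call.

    Returns one row per protein in the matrix with per-group means and
    SDs, both p-values, both fold changes, a BH-adjusted treatment
    q-value (informational), and a ``class`` column in
    {not_tested, tested, differentially_regulated}.
    ``apply_strict_criteria`` upgrades classes to significant_up/down.
    """
    cfg = cfg or SelectionConfig()
    runs_by_group = _groups_runs(manifest, cfg)
    tested = triplicate_filter(matrix, manifest, cfg)

    res = pd.DataFrame(index=matrix.index)
    res.index.name = "protein"
    if n_unique_peptides is not None:
        res["n_unique_peptides"] = n_unique_peptides.reindex(matrix.index)
    res["detected_triplicate"] = tested

    for g, runs in runs_by_group.items():
        sub = matrix[runs]
        res[f"mean_{g}"] = sub.mean(axis=1)
        res[f"sd_{g}"] = sub.std(axis=1, ddof=1)

    if cfg.fc_method == "arithmetic":
        fc_t = res[f"mean_{cfg.treatment}"] / res[f"mean_{cfg.control}"]
        fc_v = res[f"mean_{cfg.vehicle}"] / res[f"mean_{cfg.control}"]
    else:
        gmean = lambda runs: np.exp(np.log(matrix[runs]).mean(axis=1))
        fc_t = gmean(runs_by_group[cfg.treatment]) / gmean(runs_by_group[cfg.control])
        fc_v = gmean(runs_by_group[cfg.vehicle]) / gmean(runs_by_group[cfg.control])

    sub = matrix.loc[tested]
    vals = {
        g: sub[runs].to_numpy(dtype=float) for g, runs in runs_by_group.items()
    }
    if cfg.log_transform:
        vals = {g: np.log(v) for g, v in vals.items()}
    t_t, p_t = _vector_t(vals[cfg.treatment], vals[cfg.control], cfg.welch)
    t_v, p_v = _vector_t(vals[cfg.vehicle], vals[cfg.control], cfg.welch)

    res["p_treatment"] = pd.Series(p_t, index=sub.index).reindex(matrix.index)
    res["p_vehicle"] = pd.Series(p_v, index=sub.index).reindex(matrix.index)
    res["t_treatment"] = pd.Series(t_t, index=sub.index).reindex(matrix.index)
    res["t_vehicle"] = pd.Series(t_v, index=sub.index).reindex(matrix.index)
    res["fc_treatment"] = fc_t
    res["fc_vehicle"] = fc_v

    qvals = pd.Series(np.nan, index=matrix.index, name="q_treatment_bh")
    if tested.any():
        qvals.loc[sub.index] = multipletests(p_t, method="fdr_bh")[1]
    res["q_treatment_bh"] = qvals

    diff = (
        tested
        & (res["p_treatment"] < cfg.alpha)
        & (res["p_vehicle"] >= cfg.alpha)
    )
    res["class"] = np.select(
        [diff, tested], ["differentially_regulated", "tested"], default="not_tested"
    )
    return res


def apply_strict_criteria(
    result: pd.DataFrame, cfg: SelectionConfig | None = None
) -> pd.DataFrame:
    """Upgrade differentially regulated proteins to significant_up/down.

    significant_up: treatment fold change > fc_threshold;
    significant_down: treatment fold change < 1/fc_threshold;
    both additionally require the vehicle fold change inside the closed
    band (default [0.8, 1.2]).
    """
    cfg = cfg or SelectionConfig()
    lo, hi = cfg.vehicle_band
    out = result.copy()
    diff = out["class"] == "differentially_regulated"
    in_band = (out["fc_vehicle"] >= lo) & (out["fc_vehicle"] <= hi)
    up = diff & in_band & (out["fc_treatment"] > cfg.fc_threshold)
    down = diff & in_band & (out["fc_treatment"] < 1.0 / cfg.fc_threshold)
    out.loc[up, "class"] = "significant_up"
    out.loc[down, "class"] = "significant_down"
    return out


def select_significant(result: pd.DataFrame) -> pd.DataFrame:
    """Significant proteins sorted by |log2 treatment fold change|, descending."""
    sig = result[result["class"].isin(["significant_up", "significant_down"])].copy()
    sig["log2_fc_treatment"] = np.log2(sig["fc_treatment"])
    return sig.sort_values(
        "log2_fc_treatment", key=lambda s: s.abs(), ascending=False
    )


def cascade_counts(result: pd.DataFrame) -> dict[str, int]:
    """Stage counts: detected >= tested >= differentially regulated >= significant."""
    cls = result["class"]
    n_sig = int(cls.isin(["significant_up", "significant_down"]).sum())
    n_diff = int((cls == "differentially_regulated").sum()) + n_sig
    n_tested = int((cls != "not_tested").sum())
    return {
        "detected": int(len(result)),
        "tested": n_tested,
        "differentially_regulated": n_diff,
        "significant": n_sig,
        "significant_up": int((cls == "significant_up").sum()),
        "significant_down": int((cls == "significant_down").sum()),
    }


def normalize_to_untreated(
    result: pd.DataFrame, cfg: SelectionConfig | None = None
) -> pd.DataFrame:
    """Report per-group levels relative to the untreated mean.

    For each protein, per-group means and SDs are divided by that
    protein's untreated mean, so the untreated group reports exactly 1.0
    and SDs rescale by the same factor — the convention used for
    bar-plot reporting of selected proteins.
    """
    cfg = cfg or SelectionConfig()
    ref = result[f"mean_{cfg.control}"]
    out = pd.DataFrame(index=result.index)
    out.index.name = "protein"
    for g in (cfg.control, cfg.vehicle, cfg.treatment):
        out[f"rel_mean_{g}"] = result[f"mean_{g}"] / ref
        out[f"rel_sd_{g}"] = result[f"sd_{g}"] / ref
    return out
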