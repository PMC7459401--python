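"""Spike-in simulator for the three-group LC-MS evidence world.

Generates peptide evidence tables, a protein FASTA, a run manifest and
survival counts with the statistical structure the analysis assumes,
plus ground truth, so every pipeline stage is testable without any
external download.

Generative model for the peak area of peptide p (of protein q) in run r:

    A_{p,r} = base_q * ionization_p * effect(group_r, q) * scale_r * noise

* ``base_q``: protein abundance, log-normal around the median peak area;
* ``ionization_p``: peptide-specific response factor, log-normal;
* ``effect``: 1 for null proteins; fold (or 1/fold) in the treatment
  group for treatment-only spike-ins; the same fold in BOTH vehicle and
  treatment for confounded spike-ins (solvent artefacts the vehicle
  gate must reject);
* ``scale_r``: per-run loading factor, log-uniform;
* ``noise``: log-normal biological + technical noise with the configured
  coefficient of variation, independent per (peptide, run).

Shared peptides are embedded in a second host protein and receive the
summed contribution of both hosts.  Dropout removes individual
(peptide, run) observations after area generation — by default
independent of intensity, optionally left-censoring-like (logistic in
log area).  Protein "sequences" are concatenations of the designed
tryptic peptides (C-terminal K/R) so that substring-based uniqueness
mapping recovers the designed shared/unique flags exactly; no further
sequence realism is attempted.  The peptide alphabet excludes I (so I/L
equivalence cannot merge designed-distinct peptides) and uses K/R only
terminally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

GROUPS = ("untreated", "vehicle", "treatment")

# no I (I/L-equivalent matching), no K/R except as C-terminal residue
_BODY_ALPHABET = np.array(list("ACDEFGHLMNPQSTVWY"))
_TERMINAL = np.array(list("KR"))


@dataclass
class SimConfig:
    """The stated world: sizes, noise, effects and survival design.

    Defaults mirror the experimental design being emulated: 3 groups x 3
    biological replicates, ~1500 proteins with 1-10 tryptic peptides
    each, ~10% shared peptides, log-normal areas with ~10% CV, per-run
    loading factors in [0.5, 2], 5% dropout, and desiccation assays with
    ~15 animals x 3 replicates per condition.

    Spike-in effects are opt-in (fractions default to 0, i.e. a global
    null): total-sum normalization is exact only when differential
    proteins are a negligible share of total intensity, so effect
    fractions are an experiment-level choice, set explicitly per
    benchmark.  Fold defaults are 4 in either direction.
    """

    n_proteins: int = 1500
    peptides_per_protein: tuple[int, int] = (1, 10)
    fraction_shared_peptides: float = 0.1
    n_replicates: int = 3
    median_peak_area: float = 1e6
    sigma_protein: float = 1.0  # log-normal spread of protein abundance
    sigma_peptide: float = 1.0  # log-normal spread of ionization response
    cv_biological: float = 0.10  # per-(peptide, run) noise CV
    scale_range: tuple[float, float] = (0.5, 2.0)  # log-uniform run loading
    dropout: float = 0.05
    intensity_dependent_dropout: bool = False
    frac_treatment_up: float = 0.0
    frac_treatment_down: float = 0.0
    frac_confounded: float = 0.0
    fold_treatment: float = 4.0
    fold_confounded: float = 4.0
    dropout_on_spiked: bool = True  # False exempts spike-ins from dropout
    survival_probs: dict = field(
        default_factory=lambda: {"untreated": 0.3, "vehicle": 0.3, "treatment": 0.7}
    )
    n_animals: int = 15
    n_survival_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        fractions = {
            "fraction_shared_peptides": self.fraction_shared_peptides,
            "frac_treatment_up": self.frac_treatment_up,
            "frac_treatment_down": self.frac_treatment_down,
            "frac_confounded": self.frac_confounded,
            "dropout": self.dropout,
        }
        for name, f in fractions.items():
            if not 0 <= f <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {f}")
        if self.frac_treatment_up + self.frac_treatment_down + self.frac_confounded > 1:
            raise ValueError("effect fractions sum beyond 1")
        if self.fold_treatment <= 0 or self.fold_confounded <= 0:
            raise ValueError("folds must be positive")
        if self.cv_biological < 0 or self.sigma_protein < 0 or self.sigma_peptide < 0:
            raise ValueError("spread parameters must be non-negative")
        lo, hi = self.peptides_per_protein
        if not 1 <= lo <= hi:
            raise ValueError("peptides_per_protein range invalid")
        slo, shi = self.scale_range
        if not 0 < slo <= shi:
            raise ValueError("scale_range invalid")
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ValueError("n_proteins and n_replicates must be >= 1")
        for cond, p in self.survival_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"survival probability for {cond!r} outside [0, 1]")
        if self.n_animals < 1 or self.n_survival_replicates < 1:
            raise ValueError("survival design sizes must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated proteome."""

    proteins: pd.DataFrame  # protein, effect_class, fold
    peptides: pd.DataFrame  # peptide, parents (;-joined), shared
    scales: pd.Series  # run -> true loading factor
    survival_probs: dict


@dataclass
class SimulatedProteome:
    evidence: pd.DataFrame
    manifest: pd.DataFrame
    sequences: dict[str, str]
    truth: SyntheticTruth


def _make_peptides(rng: np.random.Generator, n: int) -> list[str]:
    """n globally distinct tryptic-looking peptides (length 8-14, C-term K/R)."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        length = int(rng.integers(8, 15))
        body = "".join(rng.choice(_BODY_ALPHABET, size=length - 1))
        pep = body + str(rng.choice(_TERMINAL))
        if pep not in seen:
            seen.add(pep)
            out.append(pep)
    return out


def simulate_proteome(cfg: SimConfig | None = None) -> SimulatedProteome:
    """Simulate evidence + manifest + FASTA + truth from the stated world.

    Fully reproducible from ``cfg.seed``; identical configs give
    byte-identical outputs.
    """
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_prot = cfg.n_proteins
    protein_ids = [f"PROT{i + 1:05d}" for i in range(n_prot)]
    lo, hi = cfg.peptides_per_protein
    n_pep_per_prot = rng.integers(lo, hi + 1, size=n_prot)
    n_pep = int(n_pep_per_prot.sum())

    peptides = _make_peptides(rng, n_pep)
    parent = np.repeat(np.arange(n_prot), n_pep_per_prot)

    # a fraction of peptides get a second host protein (shared peptides)
    second_host = np.full(n_pep, -1)
    if n_prot >= 2 and cfg.fraction_shared_peptides > 0:
        n_shared = int(round(cfg.fraction_shared_peptides * n_pep))
        shared_idx = rng.choice(n_pep, size=n_shared, replace=False)
        for i in shared_idx:
            other = int(rng.integers(n_prot - 1))
            if other >= parent[i]:
                other += 1
            second_host[i] = other
    shared = second_host >= 0

    # protein sequences: own peptides then guest (shared-in) peptides
    seq_parts: list[list[str]] = [[] for _ in range(n_prot)]
    for i, pep in enumerate(peptides):
        seq_parts[parent[i]].append(pep)
    for i, pep in enumerate(peptides):
        if shared[i]:
            seq_parts[second_host[i]].append(pep)
    sequences = {protein_ids[q]: "".join(seq_parts[q]) for q in range(n_prot)}

    # effect classes
    n_up = int(round(cfg.frac_treatment_up * n_prot))
    n_down = int(round(cfg.frac_treatment_down * n_prot))
    n_conf = int(round(cfg.frac_confounded * n_prot))
    order = rng.permutation(n_prot)
    effect_class = np.array(["null"] * n_prot, dtype=object)
    effect_class[order[:n_up]] = "treatment_up"
    effect_class[order[n_up : n_up + n_down]] = "treatment_down"
    effect_class[order[n_up + n_down : n_up + n_down + n_conf]] = "confounded"
    true_fold = np.ones(n_prot)
    true_fold[effect_class == "treatment_up"] = cfg.fold_treatment
    true_fold[effect_class == "treatment_down"] = 1.0 / cfg.fold_treatment
    true_fold[effect_class == "confounded"] = cfg.fold_confounded

    # runs and manifest
    runs = [f"{g}_{j + 1}" for g in GROUPS for j in range(cfg.n_replicates)]
    run_group = np.repeat(np.arange(len(GROUPS)), cfg.n_replicates)
    manifest = pd.DataFrame(
        {
            "run": runs,
            "group": [GROUPS[gi] for gi in run_group],
            "replicate": list(range(1, cfg.n_replicates + 1)) * len(GROUPS),
        }
    )

    # per-protein x per-run effect multiplier
    n_runs = len(runs)
    eff = np.ones((n_prot, n_runs))
    in_treat = np.array([GROUPS[gi] == "treatment" for gi in run_group])
    in_vehicle = np.array([GROUPS[gi] == "vehicle" for gi in run_group])
    for q in range(n_prot):
        if effect_class[q] in ("treatment_up", "treatment_down"):
            eff[q, in_treat] = true_fold[q]
        elif effect_class[q] == "confounded":
            eff[q, in_treat] = true_fold[q]
            eff[q, in_vehicle] = true_fold[q]

    base = cfg.median_peak_area * np.exp(
        rng.normal(0.0, cfg.sigma_protein, size=n_prot)
    )
    ion = np.exp(rng.normal(0.0, cfg.sigma_peptide, size=n_pep))
    slo, shi = cfg.scale_range
    scale = np.exp(rng.uniform(np.log(slo), np.log(shi), size=n_runs))
    sigma_noise = np.sqrt(np.log1p(cfg.cv_biological**2))
    noise = np.exp(rng.normal(0.0, sigma_noise, size=(n_pep, n_runs)))

    signal = base[parent, None] * eff[parent, :]
    is_shared = np.where(shared)[0]
    signal[is_shared, :] += (
        base[second_host[is_shared], None] * eff[second_host[is_shared], :]
    )
    areas = ion[:, None] * signal * scale[None, :] * noise

    # dropout after area generation
    if cfg.dropout > 0:
        if cfg.intensity_dependent_dropout:
            # logistic left-censoring: low areas drop more; threshold set
            # at the dropout-quantile of log area so the overall rate
            # stays close to cfg.dropout
            loga = np.log(areas)
            c = np.quantile(loga, cfg.dropout)
            p_drop = 1.0 / (1.0 + np.exp((loga - c) / 0.5))
        else:
            p_drop = np.full(areas.shape, cfg.dropout)
        drop = rng.random(areas.shape) < p_drop
    else:
        drop = np.zeros(areas.shape, dtype=bool)
    if not cfg.dropout_on_spiked:
        spiked = effect_class != "null"
        protect = spiked[parent]
        protect |= shared & np.array(
            [second_host[i] >= 0 and spiked[second_host[i]] for i in range(n_pep)]
        )
        drop[protect, :] = False
    detected = ~drop

    pep_idx, run_idx = np.nonzero(detected)
    evidence = pd.DataFrame(
        {
            "peptide": np.array(peptides, dtype=object)[pep_idx],
            "run": np.array(runs, dtype=object)[run_idx],
            "area": areas[pep_idx, run_idx],
        }
    )

    parents_str = [
        ";".join(
            [protein_ids[parent[i]]]
            + ([protein_ids[second_host[i]]] if shared[i] else [])
        )
        for i in range(n_pep)
    ]
    truth = SyntheticTruth(
        proteins=pd.DataFrame(
            {
                "protein": protein_ids,
                "effect_class": effect_class,
                "fold": true_fold,
            }
        ),
        peptides=pd.DataFrame(
            {"peptide": peptides, "parents": parents_str, "shared": shared}
        ),
        scales=pd.Series(scale, index=pd.Index(runs, name="run"), name="scale"),
        survival_probs=dict(cfg.survival_probs),
    )
    return SimulatedProteome(
        evidence=evidence, manifest=manifest, sequences=sequences, truth=truth
    )


def simulate_survival(cfg: SimConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Binomial survival counts per condition and replicate.

    ``n_recovered ~ Binomial(n_animals, p_condition)``, seeded from
    ``seed`` if given, else ``cfg.seed``.
    """
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    for cond, p in cfg.survival_probs.items():
        rec = rng.binomial(cfg.n_animals, p, size=cfg.n_survival_replicates)
        for j in range(cfg.n_survival_replicates):
            rows.append(
                {
                    "condition": cond,
                    "replicate": j + 1,
                    "recovered": int(rec[j]),
                    "total": cfg.n_animals,
                }
            )
    return pd.DataFrame(rows)


def recovery_report(truth: SyntheticTruth, result: pd.DataFrame) -> dict:
    """Confusion summary of the significant-protein call against truth.

    Positives are the treatment-only spike-ins (up or down); null and
    confounded proteins are negatives (the vehicle gate is supposed to
    reject confounded effects).  ``result`` is a classified differential
    table indexed by protein with a ``class`` column; proteins absent
    from it count as not called.
    """
    truth_idx = truth.proteins.set_index("protein")
    unknown = set(result.index) - set(truth_idx.index)
    if unknown:
        raise ValueError(f"proteins absent from truth: {sorted(unknown)[:5]}")

    called = result.index[
        result["class"].isin(["significant_up", "significant_down"])
    ]
    called = set(called)
    classes = truth_idx["effect_class"]
    positives = set(classes.index[classes.isin(["treatment_up", "treatment_down"])])
    negatives = set(classes.index) - positives
    confounded = set(classes.index[classes == "confounded"])

    tp = len(called & positives)
    fp = len(called & negatives)
    fn = len(positives - called)
    tn = len(negatives - called)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": tp / len(positives) if positives else float("nan"),
        "specificity": tn / len(negatives) if negatives else float("nan"),
        "confounded_excluded": (
            len(confounded - called) / len(confounded) if confounded else float("nan")
        ),
        "n_called": len(called),
    }


def truth_tables(truth: SyntheticTruth) -> dict[str, pd.DataFrame]:
    """Truth as plain tables for writing next to the simulated inputs."""
    scales = truth.scales.reset_index()
    probs = pd.DataFrame(
        {
            "condition": list(truth.survival_probs),
            "p_recover": list(truth.survival_probs.values()),
        }
    )
    return {
        "truth_proteins": truth.proteins,
        "truth_peptides": truth.peptides,
        "truth_scales": scales,
        "truth_survival": probs,
    }


def config_dict(cfg: SimConfig) -> dict:
    """JSON-serializable echo of a config."""
    d = asdict(cfg)
    d["peptides_per_protein"] = list(d["peptides_per_protein"])
    d["scale_range"] = list(d["scale_range"])
    return d
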