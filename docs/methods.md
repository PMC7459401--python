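# Methods

## Quantification model

The pipeline consumes one peak area per (peptide sequence, LC-MS run);
absence of a value is non-detection, never zero. Modification
annotations are stripped on load and areas of modified forms of the same
sequence in a run are summed, because all downstream statistics
aggregate by bare sequence.

**Run normalization.** The per-run scale is total-sum: $s_r = \bar T /
T_r$ with $T_r$ the run's summed area over all identified peptides and
$\bar T$ the grand-mean total. This is the minimal reading of
"normalize with the peak areas of all identified peptides"; a
median-ratio alternative (per-run median of area-to-reference ratios,
reference = each peptide's mean across detected runs) is available via
`normalize_runs(..., method="median_ratio")` for robustness against a
few dominant peptides. Total-sum normalization is exactly invariant to
rescaling any run's raw areas only up to a common constant (the grand
mean moves); the constant cancels in the next step, where the invariance
becomes exact.

A known consequence of total-sum normalization: if differentially
abundant proteins carry a non-negligible share of a group's total
intensity, their change is redistributed as an opposite apparent shift
on every other protein (compositional bias). With 2% of proteins spiked
4-fold this shift reaches 5–10% of scale, enough to make the vehicle
t-test fire on unrelated proteins. The method inherits this property
from the procedure it reproduces; the simulator makes it visible
(compare `analysis/03_select.py` with `analysis/05_benchmark_recovery.py`).

**Peptide relative expression.** $E_{p,r}$ divides each normalized area
by the mean over the runs where that peptide was detected. Using the
detected-run mean (rather than treating missing runs as zero) is forced
by the data model — a non-detection is not a measurement — and gives the
exact invariant mean$_{\det}$ $E = 1$ per peptide, which the tests assert
at 1e-9.

**Protein roll-up.** The protein level in a run is the median of $E$
over the protein's unique peptides detected in that run. Uniqueness is
decided by contiguous substring matching of the peptide against the
FASTA database with isoleucine/leucine equivalence (the instrument
cannot distinguish them; configurable off). Only strictly unique
peptides contribute — razor-style assignment is deliberately not
implemented. Even-count medians are the mean of the two central values.
Missing cells stay masked; no imputation anywhere. Proteins with no
unique peptide at all are excluded and counted in the run log. The
roll-up is computed per run, yielding the protein-by-run matrix the
t-tests need.

## Selection cascade

Groups: untreated (control), vehicle (solvent only), treatment. A
protein is *tested* when quantified in every replicate of every group —
the strictest reading of "detected as biological triplicates", and the
one that guarantees both t-tests and both fold changes exist (a config
flag relaxes this to the two compared groups for designs with extra
groups). Tests are classical equal-variance Student's t, two-sided
(Welch by config); they run on the linear protein level by default with
a log-transform flag, since the source procedure does not state a
transform. Degenerate zero-variance cases resolve deterministically
(equal means: p = 1; unequal: p = 0 with a flag).

*Differentially regulated* = treatment-vs-control p < α AND
vehicle-vs-control p ≥ α. *Significant* additionally requires the
treatment fold change strictly beyond two-fold (in either direction) and
the vehicle fold change inside the closed band [0.8, 1.2]. Fold changes
are ratios of arithmetic group means (matching mean ± SD reporting;
geometric option by config). No multiple-testing correction is applied
inside the cascade — the original procedure applies none, using the
strict criteria as the reliability filter — but a Benjamini–Hochberg
q-value column is emitted for information. Under a global null with
independent tests the expected differentially-regulated fraction is
α(1 − α) ≈ 0.0475, which the null-calibration test checks by simulation.

Report levels for selected proteins are normalized to the untreated
mean (untreated reports exactly 1.0, SDs rescale identically).

## Survival statistics

Recovery rate = recovered / total per replicate dish; summaries are
mean ± sample SD (ddof = 1). Rates are analyzed untransformed, as they
are reported; an arcsine-square-root flag exists for variance
stabilization. Two conditions: Student's t-test. Three or more:
Tukey–Kramer, with $q_{ij} = |\bar y_i - \bar y_j| / \sqrt{(MSE/2)(1/n_i
+ 1/n_j)}$, MSE pooled over all groups with df = N − k.

The studentized-range tail is implemented here directly (the test is
part of the reproduced analysis, not an off-the-shelf step):
$P(Q \le q) = \int_0^\infty g_\nu(u)\, F_{\text{range}}(qu; k)\, du$,
with the inner range-CDF
$F(w;k) = k \int \varphi(z)\,[\Phi(z) - \Phi(z-w)]^{k-1} dz$ evaluated
by 240-point Gauss–Legendre quadrature on [−8, 8] and the outer integral
by adaptive quadrature on the density of $\sqrt{\chi^2_\nu/\nu}$.
Accuracy is ~1e-8 against scipy's implementation (used in tests as an
independent cross-check only) — far inside the 1e-4 requirement; k = 2
reduces to the two-sided t at $t = q/\sqrt 2$; critical values come from
bisection on the tail.

## The synthetic world

`SimConfig` defaults state the emulated design: 1500 proteins, 1–10
tryptic peptides each (uniform), 10% shared peptides, 3 groups × 3
replicates, log-normal areas (median 1e6 arbitrary units), per-run
loading factors log-uniform on [0.5, 2], 5% dropout, survival assays
with 15 animals × 3 replicates per condition. Choices not fixed by the
emulated design, made once on realism grounds: protein-abundance spread
σ = 1.0 and peptide-ionization spread σ = 1.0 (natural-log scale,
together ~2 decades of peptide intensity); per-(peptide, run) noise CV
10%; survival probabilities 0.30 / 0.30 / 0.70 for untreated / vehicle /
treatment, matching the qualitative outcome that drug-treated animals
recover at clearly higher rates than solvent controls while solvent
alone does nothing (no exact rates are published to copy).

Peak areas follow `base_protein × ionization_peptide × effect(group) ×
scale_run × lognormal noise`; shared peptides receive summed
contributions of both hosts. Effect fractions default to 0 (a null
world): because total-sum normalization is only exact when regulated
proteins carry a negligible intensity share, spike-in fractions are an
experiment-level statement, set explicitly per benchmark (the bundled
benchmarks use 2% up + 2% down treatment-only, and separately 2%
confounded, at 4-fold). Dropout is independent of intensity by default;
an intensity-dependent logistic option models left-censoring (threshold
at the dropout-quantile of log area, steepness 0.5 on the log scale, so
the overall rate stays near the nominal value). A flag exempts spiked
proteins from dropout for power benchmarks.

Protein "sequences" are concatenations of the designed peptides
(C-terminal K/R, body drawn from an alphabet without I, K, R), so
substring matching on the emitted FASTA reproduces the designed
unique/shared flags; the alphabet excludes I so that I/L-equivalent
matching cannot merge designed-distinct peptides. No further sequence
realism (tryptic specificity of the whole protein, realistic length or
composition) is attempted, and the generator does not simulate spectra,
retention times or identification error. A green end-to-end test
therefore establishes that the statistics behave as designed on data
with the assumed structure — not that the pipeline is robust to
identification errors, correlated peptide noise within a protein, or
intensity-dependent missingness (available, but off by default).

**Scale-factor recovery.** In the default (null) world, totals-based
run-scale estimates track the true loadings with mean per-run relative
error 0.3–0.8% (asserted < 1% in the tests). The worst single run can
deviate 1–2%: 5% dropout occasionally removes one heavy peptide, and
with log-normal abundance × ionization a single peptide can carry ~1% of
a run's total. That is a property of any realistic heavy-tailed world,
not an estimator bug.

## Numerical choices and degenerate inputs

- Tolerances: exact-identity invariants at 1e-9 (relative); p-value
  oracle agreement at 1e-8; studentized-range accuracy 1e-4 (achieved
  ~1e-8).
- Medians: even counts average the two central values; no interpolation
  options.
- Zero pooled variance in t-tests: p = 1 (equal means) or p = 0 with a
  degenerate flag (unequal) — relevant in noise-free simulations.
- A run with zero total area, a group with fewer than 3 replicates, a
  manifest missing one of the three groups, and counts with recovered >
  total are all hard validation errors, not warnings.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configs give byte-identical
  output files.

## Known limitations

- The original experiment's raw data are not publicly deposited, so the
  pipeline's headline counts cannot be checked against the real dataset;
  validation is by construction (oracles, invariants, spike-in recovery)
  on simulated data.
- Strictly-unique-peptide roll-up discards shared-only proteins
  entirely (reported, not imputed).
- Total-sum normalization carries the compositional bias described
  above; median-ratio is offered but is not the default because the
  reproduced procedure normalized on all identified peptides.
- The t-tests assume approximate normality of protein levels within
  groups at n = 3; the simulator's log-normal noise at 10% CV is close
  enough to normal that the null calibration test passes, but heavier
  noise would call for the log-transform flag.
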