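# Methods

This note documents the models behind each stage of `hifwnt`, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Coordinates and peak annotation

All genomic coordinates are 0-based, half-open (BED convention)
internally; GFF3 is converted at the I/O boundary (TSS = 1-based feature
start for `+` genes, feature end for `-` genes, minus one). A narrowPeak
summit offset of −1, or a BED6 record, falls back to the interval midpoint
`floor((start+end)/2)` — the standard surrogate when the caller reports no
summit.

A peak is assigned to a gene when the **summit's** signed,
transcription-direction distance from the TSS lies inside the closed
window `[-2000, +6000]` bp (negative = upstream). Two conventions here
were genuinely open and are config-switchable:

* *summit vs. any-overlap membership* — the summit rule is the default
  because the downstream architecture analysis is entirely summit-based;
* *strand-oriented vs. genomic window* — oriented by default, since an
  asymmetric upstream/downstream window is only meaningful in
  transcription direction (`oriented=False` applies it in genomic
  coordinates).

Peak files are taken as-is (no score filtering) because peak calling is
upstream of this package; an optional `min_score` filter exists for
sensitivity analyses. The representative peak per gene is the one with
minimal `|distance|`, ties broken toward the more upstream peak and then
by peak start — a deterministic rule so the co-binding pair table is
reproducible.

## Co-binding architecture

For the genes bound by both factors of a designated pair, each factor's
composite profile counts summits per offset bin (default ±400 bp in 10 bp
half-open bins) around a per-gene anchor, averaged over anchors; factors
beyond the pair (e.g. TCF4 mapped in normoxia) are profiled passively on
the same anchors.

**Anchor choice.** With a single representative summit per factor, the
per-gene mean of the two summits — the intuitive "mean peak centre" — is
unusable for asymmetric geometry: `s_A − m = −(s_B − m)` for every gene,
so the two composite profiles are exact mirror images whatever the true
layout (asserted as a property test). The architecture stage therefore
anchors profiles on the annotated TSS, an external reference that is part
of the observed data. `anchor_positions` (summit mean, rounded half-down)
remains available for symmetric questions such as the joint TSS-distance
density.

**Architecture call.** A bin is *active* for a factor when its profile
value reaches 50% of that factor's own maximum — a per-factor, scale-free
threshold, so a weakly-bound factor is not erased by a strongly-bound one.
The shared window is the longest contiguous all-active run (strict runs,
no gap tolerance; both choices configurable); each factor's specific
windows are maximal runs active for exactly that factor; offset estimates
are occupancy-weighted means over active bins. A factor whose profile is
identically zero raises an error rather than returning an empty call. A
gene "carries" the called element when each factor's representative
summit offset falls in the shared window or that factor's own flank
(half-open interval tests matching the bins).

Under the default simulation geometry — TCF1 uniform on [−40, +20), HIF-1α
on [−40, 0) ∪ [+20, +40) with weights 2/3 and 1/3 — the call recovers the
planted 40/20/20 bp partition exactly at 5000 genes, and within ±2 bins
across seeds.

## SAM differential expression

Two-class, unpaired, equal-variance SAM:
`d_i = (x̄₂ − x̄₁)/(sᵢ + s₀)`, with `sᵢ` the pooled standard error and
`s₀` selected Tusher-style as the percentile of the `sᵢ` distribution
(grid 0, 5, …, 100) minimising the coefficient of variation of the
windowed median absolute deviation of `d` across ~100 equal-occupancy
windows of `s`; below 100 genes the search is too noisy and `s₀ =
median(s)` is used. Flat genes with zero mean difference are defined as
`d = 0`.

The FDR at a symmetric cutoff pair `(−t, t)` is estimated from label
permutations: with 4 vs 4 samples all C(8,4) = 70 distinct splits are
enumerated (no Monte-Carlo noise at the study's own scale); larger designs
sample the requested number of distinct splits, excluding the identity
labelling, from the seed. The estimate is

&nbsp;&nbsp;&nbsp;&nbsp;FDR(t) = (1 + median_b #{|d*_b| ≥ t}) / #{|d| ≥ t},

and the reported significant set is the largest one with FDR ≤ 0.05. The
`+1` in the numerator is a finite-sample correction (in the spirit of
permutation-p lower bounds and the knockoff FDR estimator): the plain
median ratio hits exactly zero for cutoffs near the observed maximum in
about half of all pure-noise datasets — the observed maximum ranks
uniformly among the exchangeable permutation maxima — and would declare a
one-gene "discovery" there. With the correction, a candidate set of k
genes can never report an FDR below 1/k; measured over 40 null datasets
(1000 genes, 4 vs 4) the significant set is empty in all of them, while
planted 3·σ effects (50/1000 genes, 10 vs 10) are recovered with recall
≈ 1.0 at empirical FDR ≈ 0.03. The uncorrected estimator remains available
(`conservative=False`). No π₀ re-scaling is applied; the estimate is
deliberately conservative.

Signatures are derived by set algebra (`∩ ∪ \`, equal precedence, left to
right, parentheses) over named gene sets, with the expression recorded as
provenance; results are sorted lexicographically. Unexplained manual
reductions of a gene list are represented only as explicit user-supplied
filter lists — the package never infers them.

Fold-change summaries are medians of per-sample differences from the
reference group's per-gene median (so the reference column is identically
zero); top-N selection breaks ties lexicographically. Clustering is
agglomerative with Euclidean distance and Ward's criterion on unsquared
distances (Ward.D2), checked against exhaustive greedy agglomeration on
≤6 points.

## Burden and survival

Cohort z-scores use the n−1 denominator; constant genes get z = 0 and can
never contribute. The burden is the count of panel genes (default panel
size 44) with z **≥** 1.5; the inclusive comparison is the default because
a panel gene sitting exactly at the threshold should count as upregulated,
with strict `>` selectable. Patients split at burden ≥ 7 ("high") versus
0–6.

Kaplan–Meier curves and the two-group log-rank test are delegated to
`lifelines`; a hand-computed observed-minus-expected oracle cross-checks
the log-rank statistic in the tests. The Cox model is a purpose-built
single-binary-covariate Newton–Raphson on the Breslow partial likelihood
(ties are rare in simulated continuous times, and Breslow keeps the
likelihood simple and exactly reproducible): convergence at |score| <
1e−8 or 50 iterations. Monotone likelihoods — one group holding all early
events — make the MLE diverge; the fit is flagged (`monotone=True`,
log-HR = ±∞) whenever |log HR| exceeds 15 during iteration, a bound
chosen because the score can numerically vanish while β still grows, and
a hazard ratio beyond e¹⁵ has no finite interpretation. `lifelines` serves
as an independent cross-check on tie-free data, and a grid search over the
partial likelihood is the oracle on tiny fixtures.

The cutoff scan fits the Cox model at every candidate burden cutoff with
both strata non-empty and ≥1 event each, reports the **full** table
(degenerate cutoffs skipped with the reason recorded), and highlights the
minimal-Wald-p cutoff with a logged multiple-testing caveat — a single
"significant cutoff" is a selection over many correlated tests and is
never auto-applied silently.

## Limiting dilution

Under the single-hit Poisson model the fraction of negative wells at dose
n is `exp(−f·n)`; `f` is estimated by weighted least squares of
`ln(fraction negative)` on dose through the origin (`f̂ = −slope`).
Dose-0 rows carry no information and are excluded; all-responding rows
(zero negatives) cannot be logged and are excluded with a warning; an
assay with no negative wells at any dose errors ("frequency too high to
estimate"). Weights are inverse delta-method variances `n·p/(1−p)`; after
an initial fit with observed fractions (half-count stabilised), weights
are refreshed from the model-fitted fractions and the fit iterated to
convergence. This reweighting matters: with ~0–1 negative wells at the
highest dose, plug-in weights understate the slope variance and 95%
intervals cover the truth only ~92% of the time, versus ~94% after
reweighting (measured at f = 0.01, doses {50, 100, 200, 500} × 96 wells).
Noiseless data are recovered exactly. Condition comparisons use the
normal two-slope contrast `z = (b₁−b₂)/√(se₁²+se₂²)`.

The IHC combined score is the product of the positivity bin (0–6) and
staining intensity (0–3), range 0–18; out-of-range or non-integer inputs
are rejected.

## Synthetic data: what it emulates, and what it does not

Each simulator is a pure function of (spec, seed) and writes a `#truth`
record; recovery tests read only the simulated data. Defaults encode the
study design being emulated:

* **Annotation**: non-overlapping TSS anchors (sorted-uniform placement
  with guaranteed minimum spacing), random strands.
* **Binding**: per gene, one peak per factor with Bernoulli binding
  (default probability 0.9 for the focal factors) whose summit offset is
  drawn from a mixture of uniform intervals in transcription-direction
  coordinates and reflected for `-` genes; uniform background peaks at
  5/Mb; optionally Poisson-distributed extra peaks. The default geometry
  plants the 40 bp shared + 20/20 bp flank element.
* **Expression**: baseline 8.0 log2 units, Gaussian noise σ = 0.5,
  group-structured planted log2 effects on a signature (core silencing
  −1.5; grade gradient −0.5/−1.0/−2.0) — values in the range array studies
  report for strong differential expression.
* **Cohort burden**: each patient upregulates b ~ UniformInt(0, 14)
  randomly chosen panel genes by +3 log2 units over noise σ = 0.35; these
  defaults keep the cohort z ≥ 1.5 call of an upregulated cell nearly
  deterministic, so the planted burden is recoverable (per-patient exact
  agreement ≈ 0.9) and the survival change-point is identifiable.
* **Survival**: exponential times with log-hazard jumping by log 3 at
  burden ≥ 7, computed from the same z-burden the analysis recomputes;
  independent uniform censoring with the upper bound solved (Brent) so
  the expected censored fraction matches the target (default 0.3).
* **Dilution**: binomial negative-well counts, 96 wells per dose, doses
  0–500 cells/well.

The generators deliberately omit: multi-peak promoter clusters by default
(available as an option, unused in recovery tests), probe-level effects,
normalisation artefacts, batch and copy-number structure, correlated gene
expression, non-proportional hazards, and overdispersed well counts.
Passing recovery tests therefore demonstrates that the *pipeline's
inference is correct under its own model assumptions* — not that those
assumptions hold in any particular patient cohort.

## Problem sizes

Tests and the acceptance script use the scales the analyses are designed
around: 5000 co-bound genes × 10 seeds for architecture recovery; 20
random 200-gene × 500-peak fixtures against the all-pairs assignment
oracle; 1000-gene matrices over 40 null and 20 planted seeds for SAM;
n = 400 cohorts over 50 (cutoff scan) and 100 (CI coverage) seeds; 100
seeds for dilution coverage. The demonstration study in `analysis/` uses
1500 genes so a full run stays in the tens of seconds.

## Known limitations

* The architecture call assumes the factors share per-gene anchor points;
  it does not model nucleosome-scale offsets between cells or conditions.
* The SAM FDR uses symmetric cutoffs only; asymmetric (samr-style
  delta-table) cutoffs are not implemented.
* The Cox stage is single-covariate by design; clinical covariates and
  Efron ties are out of scope.
* Limiting-dilution inference uses the regression CI, not the full ELDA
  likelihood machinery.
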