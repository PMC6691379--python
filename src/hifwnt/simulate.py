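"""Synthetic-data generators with recorded ground truth.

Every simulator is a pure function of ``(spec, seed)``: the same inputs give
bit-identical outputs.  Each returns its data in the exact form the readers
in :mod:`hifwnt.io` produce, together with a truth record; downstream
recovery tests read only the data and touch the truth only for the final
comparison.

The generators emulate the statistical structure the analysis assumes:

* binding: per-gene summit offsets drawn from a mixture of uniform
  intervals around each gene's anchor, in transcription-direction
  coordinates (reflected for "-" strand genes), plus uniform background
  peaks — the shared-window / factor-specific-flank geometry;
* expression: group-structured Gaussian matrices with planted log2 effects
  on a signature gene set (e.g. a grade-wise silencing gradient);
* survival: exponential event times whose hazard jumps by a planted factor
  when a patient's panel-gene burden reaches a cutoff, with independent
  uniform censoring;
* limiting dilution: single-hit Poisson sphere formation — a well seeded
  with n cells stays negative with probability exp(-f*n).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import PEAK_COLUMNS, TSS_COLUMNS

__all__ = [
    "BindingSpec", "ExpressionSpec", "SurvivalSpec", "DilutionSpec",
    "simulate_annotation", "simulate_peaks", "simulate_expression",
    "simulate_cohort_expression", "simulate_survival", "simulate_dilution",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BindingSpec:
    """Planted binding behaviour of one factor in one condition.

    ``summit_offset_distribution`` is a mixture of half-open integer
    intervals ``(lo, hi, weight)`` on signed bp offsets relative to the
    per-gene anchor; offsets are in transcription-direction coordinates.
    """

    factor: str
    condition: str
    target_genes: frozenset[str]
    summit_offset_distribution: Sequence[tuple[int, int, float]]
    peak_halfwidth: int = 150
    per_gene_binding_probability: float = 1.0
    background_peaks_per_mb: float = 5.0
    extra_peaks_rate: float = 0.0  # Poisson rate of additional peaks per bound gene

    def __post_init__(self) -> None:
        w = sum(c for _, _, c in self.summit_offset_distribution)
        if not np.isclose(w, 1.0):
            raise ValueError(f"mixture weights sum to {w}, expected 1")
        for lo, hi, _ in self.summit_offset_distribution:
            if not lo < hi:
                raise ValueError(f"empty mixture interval [{lo}, {hi})")
        if not 0 <= self.per_gene_binding_probability <= 1:
            raise ValueError("per_gene_binding_probability must be in [0, 1]")
        if self.background_peaks_per_mb < 0:
            raise ValueError("background_peaks_per_mb must be >= 0")


@dataclasses.dataclass
class ExpressionSpec:
    """Group-structured expression with planted signature effects.

    ``log2_effect_per_group`` maps each non-reference group to the log2
    shift added to signature genes; groups absent from the map get 0.
    Values are ``baseline + effect + N(0, noise_sd)`` on a log2 scale.
    """

    groups: Sequence[tuple[str, int]]
    genes: Sequence[str]
    signature_genes: frozenset[str]
    log2_effect_per_group: Mapping[str, float]
    noise_sd: float = 0.5
    baseline_mean: float = 8.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for label, size in self.groups:
            if size < 2:
                raise ValueError(
                    f"group {label!r} has {size} samples; differential "
                    "testing needs >= 2 per group")
        unknown = set(self.signature_genes) - set(self.genes)
        if unknown:
            raise ValueError(f"signature genes not in universe: {sorted(unknown)[:5]}")


@dataclasses.dataclass
class SurvivalSpec:
    """Planted burden-dependent hazard for a patient cohort.

    Event times are exponential with
    ``log hazard = log(baseline_hazard) + burden_log_hazard * 1[burden >= burden_cutoff]``
    where the burden is the count of ``panel_genes`` whose cohort z-score
    reaches ``z_threshold`` in the supplied expression matrix.
    """

    panel_genes: Sequence[str]
    burden_log_hazard: float = float(np.log(3.0))
    baseline_hazard: float = 0.05
    censoring_rate: float = 0.3
    z_threshold: float = 1.5
    burden_cutoff: int = 7

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")


@dataclasses.dataclass
class DilutionSpec:
    """Single-hit Poisson limiting-dilution layout (96-well plates)."""

    true_frequency: float
    doses: Sequence[int] = (0, 50, 100, 200, 500)
    wells_per_dose: int = 96

    def __post_init__(self) -> None:
        if not 0 < self.true_frequency <= 1:
            raise ValueError("true_frequency must be in (0, 1]")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if self.wells_per_dose <= 0:
            raise ValueError("wells_per_dose must be > 0")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(n_genes: int, chrom_sizes: Mapping[str, int],
                        min_spacing: int, seed: int) -> pd.DataFrame:
    """Place ``n_genes`` non-overlapping TSS anchors with random strands.

    Genes are allocated to chromosomes proportionally to size; within a
    chromosome, anchors are drawn uniformly subject to pairwise gaps of at
    least ``min_spacing`` (sorted-uniform construction, exact).  Raises
    ``ValueError`` when the genome cannot accommodate the packing.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    capacity = {c: max(0, chrom_sizes[c] // min_spacing) for c in chroms}
    if sum(capacity.values()) < n_genes:
        raise ValueError(
            f"cannot place {n_genes} genes at spacing {min_spacing} in "
            f"{sum(chrom_sizes.values())} bp")
    total = sum(chrom_sizes.values())
    alloc = {c: min(capacity[c], int(round(n_genes * chrom_sizes[c] / total)))
             for c in chroms}
    # fix rounding drift, respecting per-chromosome capacity
    for c in itertools.cycle(chroms):
        diff = n_genes - sum(alloc.values())
        if diff == 0:
            break
        step = 1 if diff > 0 else -1
        if 0 <= alloc[c] + step <= capacity[c]:
            alloc[c] += step
    rows = []
    gene_no = 0
    for c in chroms:
        k = alloc[c]
        if k == 0:
            continue
        slack = chrom_sizes[c] - k * min_spacing
        u = np.sort(rng.uniform(0, slack, size=k))
        pos = (u + np.arange(k) * min_spacing).astype(np.int64)
        strands = rng.choice(["+", "-"], size=k)
        for p, s in zip(pos, strands):
            gene_no += 1
            rows.append((f"g{gene_no:05d}", c, int(p), s))
    return pd.DataFrame(rows, columns=TSS_COLUMNS)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def _draw_offsets(rng: np.random.Generator, mixture, size: int) -> np.ndarray:
    """Draw integer offsets from a mixture of half-open uniform intervals."""
    lows = np.array([lo for lo, _, _ in mixture])
    highs = np.array([hi for _, hi, _ in mixture])
    weights = np.array([w for _, _, w in mixture], dtype=float)
    comp = rng.choice(len(mixture), size=size, p=weights / weights.sum())
    return rng.integers(lows[comp], highs[comp])


def simulate_peaks(annotation: pd.DataFrame, spec: BindingSpec,
                   chrom_sizes: Mapping[str, int], seed: int,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one factor's peak calls plus a per-gene truth record.

    Each target gene is bound with ``per_gene_binding_probability``; a
    bound gene gets one peak whose summit offset is drawn from the mixture
    and reflected for "-" strand genes, plus optional Poisson extra peaks.
    Background peaks are placed uniformly over the genome at
    ``background_peaks_per_mb``.
    """
    rng = np.random.default_rng(seed)
    targets = annotation[annotation["gene_id"].isin(spec.target_genes)]
    bound = rng.random(len(targets)) < spec.per_gene_binding_probability
    offsets = _draw_offsets(rng, spec.summit_offset_distribution, len(targets))
    hw = spec.peak_halfwidth

    peak_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    def add_peak(chrom: str, summit: int, name: str) -> None:
        size = chrom_sizes[chrom]
        start = max(0, summit - hw)
        end = min(size, summit + hw + 1)
        summit = min(max(summit, start), end - 1)
        peak_rows.append((chrom, int(start), int(end), name, 0.0, ".",
                          int(summit), spec.factor, spec.condition))

    n_extra = (rng.poisson(spec.extra_peaks_rate, size=len(targets))
               if spec.extra_peaks_rate > 0 else np.zeros(len(targets), int))
    for i, (row, is_bound, off) in enumerate(
            zip(targets.itertuples(index=False), bound, offsets)):
        if not is_bound:
            truth_rows.append((row.gene_id, 0, np.nan, np.nan))
            continue
        sign = 1 if row.strand == "+" else -1
        summit = row.tss + sign * int(off)
        add_peak(row.chrom, summit, f"{spec.factor}_{row.gene_id}")
        truth_rows.append((row.gene_id, 1, int(off), int(summit)))
        for j in range(n_extra[i]):
            extra_off = int(_draw_offsets(
                rng, spec.summit_offset_distribution, 1)[0])
            add_peak(row.chrom, row.tss + sign * extra_off,
                     f"{spec.factor}_{row.gene_id}_x{j + 1}")

    total_bp = sum(chrom_sizes.values())
    n_bg = rng.poisson(spec.background_peaks_per_mb * total_bp / 1e6)
    if n_bg:
        chroms = sorted(chrom_sizes)
        sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
        picks = rng.choice(len(chroms), size=n_bg, p=sizes / sizes.sum())
        for j, ci in enumerate(picks):
            pos = int(rng.integers(hw, max(hw + 1, chrom_sizes[chroms[ci]] - hw)))
            add_peak(chroms[ci], pos, f"{spec.factor}_bg{j + 1}")

    peaks = pd.DataFrame(peak_rows, columns=PEAK_COLUMNS)
    peaks = peaks.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows,
                         columns=["gene_id", "bound", "offset", "summit"])
    return peaks, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(spec: ExpressionSpec, seed: int,
                        ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Group-structured matrix: baseline + planted effect + Gaussian noise.

    Returns ``(matrix, labels, truth)`` where truth records the planted
    log2 effect of every gene in every group (0 off the signature).
    """
    rng = np.random.default_rng(seed)
    genes = list(spec.genes)
    sig = np.array([g in spec.signature_genes for g in genes])
    columns, labels = [], {}
    effects = []
    for label, size in spec.groups:
        eff = spec.log2_effect_per_group.get(label, 0.0)
        for r in range(1, size + 1):
            name = f"{label}_{r}"
            columns.append(name)
            labels[name] = label
            effects.append(eff)
    values = (spec.baseline_mean
              + np.outer(sig, np.array(effects))
              + rng.normal(0.0, spec.noise_sd, size=(len(genes), len(columns))))
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                          columns=columns)
    label_s = pd.Series(labels, name="group")
    label_s.index.name = "sample"
    truth = pd.DataFrame(
        {label: np.where(sig, spec.log2_effect_per_group.get(label, 0.0), 0.0)
         for label, _ in spec.groups},
        index=matrix.index).reset_index()
    return matrix, label_s, truth


def simulate_cohort_expression(panel_genes: Sequence[str], n_patients: int,
                               seed: int, burden_range: tuple[int, int] = (0, 14),
                               upregulation_log2: float = 3.0,
                               noise_sd: float = 0.35,
                               n_background_genes: int = 156,
                               baseline_mean: float = 6.0,
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort matrix with a planted per-patient panel-gene burden.

    Each patient upregulates ``b ~ UniformInt(burden_range)`` randomly
    chosen panel genes by ``upregulation_log2``; all other cells are
    baseline plus noise.  The defaults keep the cohort-wise z-score of an
    upregulated cell above 1.5 with high probability, so the z-burden the
    analysis recomputes matches the planted burden almost everywhere.

    Returns ``(matrix, truth)``; truth holds each patient's planted burden.
    """
    rng = np.random.default_rng(seed)
    panel = list(panel_genes)
    genes = panel + [f"bg{i:04d}" for i in range(1, n_background_genes + 1)]
    patients = [f"pt{i:04d}" for i in range(1, n_patients + 1)]
    values = baseline_mean + rng.normal(
        0.0, noise_sd, size=(len(genes), n_patients))
    lo, hi = burden_range
    burdens = rng.integers(lo, hi + 1, size=n_patients)
    for j, b in enumerate(burdens):
        if b:
            chosen = rng.choice(len(panel), size=b, replace=False)
            values[chosen, j] += upregulation_log2
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                          columns=patients)
    truth = pd.DataFrame({"patient": patients, "true_burden": burdens})
    return matrix, truth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    sd = matrix.std(axis=1, ddof=1)
    z = matrix.sub(matrix.mean(axis=1), axis=0).div(sd.replace(0.0, np.inf), axis=0)
    return z


def simulate_survival(matrix: pd.DataFrame, spec: SurvivalSpec, seed: int,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exponential survival with a hazard jump at the planted burden cutoff.

    The burden driving the hazard is computed from ``matrix`` exactly as
    the analysis recomputes it (cohort z-score, count of panel genes at
    ``z >= z_threshold``), so the planted hazard ratio refers to the same
    stratification the pipeline recovers.  Censoring is independent
    uniform, with the upper bound solved so the expected censored fraction
    equals ``censoring_rate``.
    """
    rng = np.random.default_rng(seed)
    panel = [g for g in spec.panel_genes if g in matrix.index]
    z = _zscore(matrix.loc[panel])
    burden = (z >= spec.z_threshold).sum(axis=0).to_numpy()
    high = burden >= spec.burden_cutoff
    lam = spec.baseline_hazard * np.exp(spec.burden_log_hazard * high)
    times = rng.exponential(1.0 / lam)
    if spec.censoring_rate > 0:
        def mean_censored(b: float) -> float:
            # P(C < T) for C ~ U(0, b), T ~ Exp(lam): (1 - e^{-lam b}) / (lam b)
            x = lam * b
            return float(np.mean((1.0 - np.exp(-x)) / x))
        b = brentq(lambda v: mean_censored(v) - spec.censoring_rate,
                   1e-9 / lam.max(), 1e9 / lam.min())
        cens = rng.uniform(0.0, b, size=len(times))
        observed = np.minimum(times, cens)
        event = (times <= cens).astype(int)
    else:
        observed, event = times, np.ones(len(times), dtype=int)
    table = pd.DataFrame({"patient": matrix.columns,
                          "time": observed, "event": event})
    truth = pd.DataFrame({"patient": matrix.columns, "burden": burden,
                          "high_stratum": high.astype(int),
                          "hazard": lam, "latent_time": times})
    return table, truth


# ---------------------------------------------------------------------------
# limiting dilution
# ---------------------------------------------------------------------------

def simulate_dilution(spec: DilutionSpec, seed: int) -> pd.DataFrame:
    """Binomial negative-well counts under the single-hit Poisson model."""
    rng = np.random.default_rng(seed)
    rows = []
    for dose in spec.doses:
        p_neg = float(np.exp(-spec.true_frequency * dose))
        neg = int(rng.binomial(spec.wells_per_dose, p_neg))
        rows.append((int(dose), spec.wells_per_dose, neg))
    return pd.DataFrame(rows, columns=["dose", "wells", "negative"])
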