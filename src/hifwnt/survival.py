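"""Wnt-burden scoring, survival stratification and limiting dilution.

The clinical end of the pipeline: per-patient burdens (count of panel
genes whose cohort z-score reaches a threshold), Kaplan-Meier curves,
two-group log-rank tests, a single-covariate Cox model (Newton-Raphson on
the Breslow partial likelihood, as the cutoff scan needs many small,
deterministic fits), a Wald-test scan over candidate burden cutoffs, the
single-hit Poisson limiting-dilution fit, and the immunohistochemistry
combined score.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# z-scores and burdens
# ---------------------------------------------------------------------------

def zscore_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene cohort z-scores: (x - mean) / SD with the n-1 denominator.

    Genes with zero SD get z = 0 everywhere (logged); they can never
    contribute to a burden.
    """
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.info("zscore_matrix: %d constant gene(s) set to z=0",
                    int(flat.sum()))
    z = matrix.sub(mean, axis=0).div(sd.where(~flat, np.inf), axis=0)
    return z


def burden_scores(z: pd.DataFrame, panel: list[str], z_threshold: float = 1.5,
                  strict: bool = False) -> pd.Series:
    """Per-patient count of panel genes with z >= threshold.

    ``strict=True`` switches the comparison to ``>`` (both conventions
    appear in practice; the inclusive form is the default).  Panel genes
    absent from the matrix are dropped with a warning.
    """
    present = [g for g in panel if g in z.index]
    if len(present) < len(panel):
        logger.warning("burden_scores: %d/%d panel genes absent from matrix",
                       len(panel) - len(present), len(panel))
    sub = z.loc[present]
    hits = sub > z_threshold if strict else sub >= z_threshold
    burden = hits.sum(axis=0).astype(int)
    burden.name = "burden"
    return burden


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate as a step function table.

    Returns a frame with columns ``time`` and ``survival``; censored
    observations tied with events at the same time are handled after the
    events (the standard convention).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank_test(strata, times, events) -> tuple[float, float]:
    """Two-group log-rank (Mantel-Cox) chi-square (1 df) and p-value."""
    strata = np.asarray(strata)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    levels = np.unique(strata)
    if len(levels) != 2:
        raise ValueError(f"need exactly two strata, got {list(levels)}")
    a, b = strata == levels[0], strata == levels[1]
    res = _lifelines_logrank(times[a], times[b], events[a], events[b])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards, single binary covariate
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CoxResult:
    log_hr: float
    se: float
    wald: float
    p: float
    n: int
    n_events: int
    converged: bool
    monotone: bool = False      # infinite-HR sentinel
    tie_method: str = "breslow"

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    def confint(self, level: float = 0.95) -> tuple[float, float]:
        zq = stats.norm.ppf(0.5 + level / 2)
        return self.log_hr - zq * self.se, self.log_hr + zq * self.se


# |log HR| beyond this is treated as a diverging (monotone-likelihood) fit;
# the score can numerically vanish while beta still grows, so the bound is
# checked after every Newton step.
_MONOTONE_BOUND = 15.0


def cox_binary(times, events, indicator) -> CoxResult:
    """Cox partial likelihood for one binary covariate, Breslow ties.

    Newton iteration from 0 until ``|score| < 1e-8`` or 50 iterations.
    A monotone likelihood (one group holds all the early events, so the
    MLE diverges) is flagged: ``log_hr`` is ``+/-inf``, ``monotone=True``
    — never a silent failure.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(indicator, dtype=int)
    if set(np.unique(x)) - {0, 1}:
        raise ValueError("indicator must be binary 0/1")
    for level in (0, 1):
        if e[x == level].sum() < 1:
            raise ValueError(
                f"indicator level {level} has no events (or no patients)")
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    event_times = np.unique(t[e == 1])

    # per distinct event time: event counts and at-risk counts by group
    d_all = np.zeros(len(event_times))
    d1 = np.zeros(len(event_times))
    n1_risk = np.zeros(len(event_times))
    n_risk = np.zeros(len(event_times))
    for j, tj in enumerate(event_times):
        at = t == tj
        d_all[j] = (e[at] == 1).sum()
        d1[j] = ((e == 1) & at & (x == 1)).sum()
        risk = t >= tj
        n_risk[j] = risk.sum()
        n1_risk[j] = (risk & (x == 1)).sum()
    n0_risk = n_risk - n1_risk

    beta = 0.0
    converged = False
    for _ in range(50):
        eb = np.exp(beta)
        denom = n1_risk * eb + n0_risk
        pj = n1_risk * eb / denom
        score = float(np.sum(d1 - d_all * pj))
        info = float(np.sum(d_all * pj * (1 - pj)))
        if abs(score) < 1e-8:
            converged = True
            break
        if info <= 0:
            break
        beta += score / info
        if abs(beta) > _MONOTONE_BOUND:
            direction = np.sign(beta)
            logger.warning("cox_binary: monotone partial likelihood; "
                           "hazard ratio diverges to %sinf",
                           "+" if direction > 0 else "-")
            return CoxResult(log_hr=float(direction * np.inf), se=np.inf,
                             wald=np.nan, p=np.nan, n=len(t),
                             n_events=int(e.sum()), converged=False,
                             monotone=True)
    eb = np.exp(beta)
    pj = n1_risk * eb / (n1_risk * eb + n0_risk)
    info = float(np.sum(d_all * pj * (1 - pj)))
    se = float(1.0 / np.sqrt(info))
    wald = (beta / se) ** 2
    p = float(stats.chi2.sf(wald, df=1))
    return CoxResult(log_hr=float(beta), se=se, wald=float(wald), p=p,
                     n=len(t), n_events=int(e.sum()), converged=converged)


# ---------------------------------------------------------------------------
# cutoff scan
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CutoffScan:
    table: pd.DataFrame      # cutoff, n_high, n_low, log_hr, hr, wald, p, note
    best_cutoff: int | None  # minimal Wald p among testable cutoffs


def cutoff_scan(burden: pd.Series, survival: pd.DataFrame,
                cutoffs=None) -> CutoffScan:
    """Cox Wald statistics for the high/low split at every candidate cutoff.

    The whole table is reported; the minimal-p cutoff is highlighted but
    the scan never auto-selects silently — picking the best of many
    correlated tests inflates significance, which is logged as a caveat.
    Degenerate cutoffs (an empty stratum, or a stratum without events) are
    skipped with the reason recorded.
    """
    b = burden.loc[survival["patient"]].to_numpy()
    t = survival["time"].to_numpy(dtype=float)
    e = survival["event"].to_numpy(dtype=int)
    if cutoffs is None:
        cutoffs = range(int(b.min()) + 1, int(b.max()) + 1)
    rows = []
    for c in cutoffs:
        high = (b >= c).astype(int)
        n_high, n_low = int(high.sum()), int(len(high) - high.sum())
        if n_high == 0 or n_low == 0:
            rows.append((c, n_high, n_low, np.nan, np.nan, np.nan, np.nan,
                         "empty stratum"))
            continue
        try:
            res = cox_binary(t, e, high)
        except ValueError as exc:
            rows.append((c, n_high, n_low, np.nan, np.nan, np.nan, np.nan,
                         str(exc)))
            continue
        note = "monotone likelihood" if res.monotone else ""
        rows.append((c, n_high, n_low, res.log_hr, res.hr, res.wald, res.p,
                     note))
    table = pd.DataFrame(rows, columns=["cutoff", "n_high", "n_low", "log_hr",
                                        "hr", "wald", "p", "note"])
    valid = table["p"].notna()
    best = int(table.loc[valid, "cutoff"].iloc[
        int(np.argmin(table.loc[valid, "p"].to_numpy()))]) if valid.any() else None
    if best is not None:
        logger.info("cutoff_scan: minimal Wald p at cutoff %d — selected "
                    "over %d correlated tests; interpret with a "
                    "multiple-testing caveat", best, int(valid.sum()))
    return CutoffScan(table=table, best_cutoff=best)


def burden_table(burden: pd.Series, survival: pd.DataFrame,
                 burden_cutoff: int = 7) -> pd.DataFrame:
    """Join per-patient burdens to outcomes with the high/low stratum label."""
    out = survival.copy()
    out["burden"] = burden.loc[out["patient"]].to_numpy()
    out["stratum"] = np.where(out["burden"] >= burden_cutoff, "high", "low")
    return out


# ---------------------------------------------------------------------------
# limiting dilution
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DilutionFit:
    """Single-hit Poisson fit: ln(fraction negative) = -f * dose."""

    frequency: float
    slope: float
    slope_se: float
    n_doses_used: int

    def confint(self, level: float = 0.95) -> tuple[float, float]:
        """CI for the initiating-cell frequency (= -slope)."""
        zq = stats.norm.ppf(0.5 + level / 2)
        return (-self.slope - zq * self.slope_se,
                -self.slope + zq * self.slope_se)


def dilution_fit(wells: pd.DataFrame) -> DilutionFit:
    """Weighted least squares of ln(fraction negative) on dose, no intercept.

    Dose-0 rows are excluded (they carry no information under the
    single-hit model); rows where every well responded are excluded too
    (log of zero), with a warning.  Weights are inverse binomial variances
    of ln(p-hat), ``wells * p / (1 - p)``; after an initial fit with
    observed fractions (half-count stabilised) the weights are refreshed
    from the model-fitted fractions and the fit repeated to convergence —
    plug-in weights from sparse negative-well counts otherwise understate
    the slope variance.  The initiating-cell frequency is minus the slope.
    """
    sub = wells[wells["dose"] > 0].copy()
    frac = sub["negative"] / sub["wells"]
    usable = frac > 0
    if not usable.any():
        raise ValueError("frequency too high to estimate: no dose has a "
                         "negative well")
    if (~usable).any():
        logger.warning("dilution_fit: %d dose(s) with zero negative wells "
                       "excluded from the fit", int((~usable).sum()))
    sub, frac = sub[usable], frac[usable]
    if len(sub) < 2:
        raise ValueError("need >= 2 doses with 0 < fraction negative <= 1")
    x = sub["dose"].to_numpy(dtype=float)
    y = np.log(frac.to_numpy(dtype=float))
    n = sub["wells"].to_numpy(dtype=float)
    p = frac.to_numpy(dtype=float)
    w = n * p / (1.0 - p + 0.5 / n)     # 1 / Var(ln p-hat), stabilised
    slope = float(np.sum(w * x * y) / np.sum(w * x * x))
    for _ in range(25):                  # reweight from fitted fractions
        p_fit = np.clip(np.exp(slope * x), 1e-12, 1.0 - 1e-12)
        w = n * p_fit / (1.0 - p_fit)
        new = float(np.sum(w * x * y) / np.sum(w * x * x))
        if abs(new - slope) < 1e-12:
            slope = new
            break
        slope = new
    sxx = float(np.sum(w * x * x))
    se = float(1.0 / np.sqrt(sxx))
    return DilutionFit(frequency=-slope, slope=slope, slope_se=se,
                       n_doses_used=len(sub))


def compare_slopes(fit_a: DilutionFit, fit_b: DilutionFit,
                   ) -> tuple[float, float]:
    """Two-slope contrast: z statistic and two-sided p for equal slopes."""
    z = (fit_a.slope - fit_b.slope) / np.hypot(fit_a.slope_se, fit_b.slope_se)
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# immunohistochemistry
# ---------------------------------------------------------------------------

def ihc_combined_score(positivity_bin: int, intensity: int) -> int:
    """Combined IHC score: positivity bin (0-6) times intensity (0-3)."""
    if not (isinstance(positivity_bin, (int, np.integer))
            and isinstance(intensity, (int, np.integer))):
        raise TypeError("scores must be integers")
    if not 0 <= positivity_bin <= 6:
        raise ValueError(f"positivity bin {positivity_bin} outside 0-6")
    if not 0 <= intensity <= 3:
        raise ValueError(f"intensity {intensity} outside 0-3")
    return int(positivity_bin * intensity)
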