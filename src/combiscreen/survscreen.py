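"""Prognostic survival-gene screen: KM, log-rank, univariate Cox, pass rule.

The screen dichotomizes each gene's expression at the per-gene median
(ties to "low"), then requires, for a gene to pass:

* log-rank p < 0.001 between the low and high expression groups,
* univariate Cox (Wald) p < 0.001 for the high-vs-low indicator,
* an absolute difference in five-year survival probability > 0.10.

Passing genes are classed high-risk (HR > 1, poor prognosis when highly
expressed) or low-risk (HR < 1). Genes are screened marginally at fixed
alpha = 0.001 — no multiplicity correction across genes.

Estimators are implemented from scratch on sorted arrays: Kaplan-Meier
product-limit, the two-group log-rank test with hypergeometric moments,
and Newton-Raphson maximization of the Cox partial likelihood with the
Efron tie correction (Breslow available; at beta = 0 the Breslow score
statistic reproduces the log-rank statistic on untied data, which the test
suite uses as a cross-oracle).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegenerateSplitError",
    "KMCurve",
    "CoxResult",
    "GapResult",
    "ScreenCriteria",
    "median_split",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "five_year_gap",
    "screen_genes",
    "risk_gene_lists",
]

logger = logging.getLogger(__name__)

HIGH_RISK = "high_risk"
LOW_RISK = "low_risk"
NO_RISK = "none"

_MAX_ABS_BETA = 20.0  # monotone-likelihood cap
_NEWTON_TOL = 1e-8
_MAX_ITER = 50


class DegenerateSplitError(ValueError):
    """A gene with (near-)constant expression cannot be dichotomized."""


def median_split(values) -> np.ndarray:
    """Boolean high-expression indicator from a per-gene median split.

    Samples strictly above the median are "high" (True); samples at or
    below it are "low" (False), so ties go to the low group.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.unique(v).size < 2:
        raise DegenerateSplitError("degenerate split: need >= 2 distinct expression values")
    high = v > np.median(v)
    if not high.any() or high.all():
        raise DegenerateSplitError("degenerate split: one side of the median is empty")
    return high


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve.

    ``times`` are the distinct event times in increasing order; ``survival``
    is S(t) just after each; ``at_risk`` and ``events`` the corresponding
    risk-set sizes and death counts. ``max_observed`` is the largest
    observed (event or censoring) time — queries beyond it are flagged as
    extrapolated.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    max_observed: float
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); the last value is carried forward."""
        if t < 0:
            raise ValueError("time must be >= 0")
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def extrapolated(self, t: float) -> bool:
        return t > self.max_observed


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier estimate: S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Censored-only times do not create steps; they only shrink the risk set.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival data")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = t.size
    uniq, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first)
    n_at = n - first
    has_event = d > 0
    times = uniq[has_event]
    surv = np.cumprod(1.0 - d[has_event] / n_at[has_event])
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=n_at[has_event],
        events=d[has_event],
        max_observed=float(t[-1]),
        n=n,
    )


# ---------------------------------------------------------------------------
# Log-rank


def _sorted_arrays(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    order = np.argsort(t, kind="stable")
    return t[order], e[order], order


def _logrank_sorted(t: np.ndarray, e: np.ndarray, g: np.ndarray):
    """Log-rank chi-square on pre-sorted (ascending time) arrays.

    g is the boolean group-1 indicator. Returns (chi2, p).
    """
    n = t.size
    uniq, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first)
    d1 = np.add.reduceat(e * g, first)
    suffix_g = np.concatenate([np.cumsum(g[::-1])[::-1], [0]])
    n_at = n - first
    n1_at = suffix_g[first]

    has_event = d > 0
    if not has_event.any():
        logger.warning("log-rank: no events in either group; p = 1")
        return 0.0, 1.0
    d, d1, n_at, n1_at = d[has_event], d1[has_event], n_at[has_event], n1_at[has_event]

    frac = n1_at / n_at
    expected = d * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(n_at > 1, d * frac * (1 - frac) * (n_at - d) / (n_at - 1), 0.0)
    v = var.sum()
    if v == 0.0:
        return 0.0, 1.0
    chi2 = float((d1 - expected).sum() ** 2 / v)
    return chi2, float(stats.chi2.sf(chi2, 1))


def logrank_test(time_low, event_low, time_high, event_high):
    """Two-group log-rank test.

    The statistic is (sum(O - E))^2 / sum(V) with the hypergeometric
    expectation and variance of group-1 deaths at each distinct event time;
    p is from a chi-square with 1 df. Symmetric in the two groups.
    """
    t = np.concatenate([np.asarray(time_low, float), np.asarray(time_high, float)])
    e = np.concatenate([np.asarray(event_low, int), np.asarray(event_high, int)])
    g = np.concatenate([
        np.zeros(len(np.atleast_1d(time_low)), dtype=int),
        np.ones(len(np.atleast_1d(time_high)), dtype=int),
    ])
    if g.sum() == 0 or g.sum() == g.size:
        raise ValueError("both groups must be non-empty")
    order = np.argsort(t, kind="stable")
    return _logrank_sorted(t[order], e[order], g[order])


# ---------------------------------------------------------------------------
# Cox proportional hazards (single covariate)


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox fit: log hazard ratio, its SE, Wald p, HR."""

    beta: float
    hr: float
    se: float
    p: float
    converged: bool
    n_iter: int
    loglik: float = math.nan


class _CoxStructure:
    """Time-ordering and tie structure shared by every fit on one cohort."""

    def __init__(self, time, event):
        t, e, order = _sorted_arrays(time, event)
        self.t, self.e, self.order = t, e, order
        self.n = t.size
        self.n_events = int(e.sum())
        uniq, first = np.unique(t, return_index=True)
        d = np.add.reduceat(e, first)
        has_event = d > 0
        self.first = first[has_event]       # risk-set entry index per event time
        self.d = d[has_event]               # deaths per event time
        self.event_mask = e.astype(bool)
        # per-death bookkeeping (deaths in time order)
        death_time_idx = np.searchsorted(uniq[has_event], t[self.event_mask])
        self.death_group = death_time_idx
        starts = np.concatenate([[0], np.cumsum(self.d)[:-1]])
        self.l_frac = (np.arange(self.n_events) - starts[death_time_idx]) / self.d[death_time_idx]
        self.group_starts = starts

    def moments(self, x: np.ndarray, beta: float, ties: str):
        """Gradient, information and log-likelihood of the partial likelihood."""
        w = np.exp(beta * x)
        xw = x * w
        x2w = x * xw

        def suffix(a):
            return np.cumsum(a[::-1])[::-1]

        s0 = suffix(w)[self.first][self.death_group]
        s1 = suffix(xw)[self.first][self.death_group]
        s2 = suffix(x2w)[self.first][self.death_group]

        if ties == "efron":
            em = self.event_mask
            t0 = np.add.reduceat(w[em], self.group_starts)[self.death_group]
            t1 = np.add.reduceat(xw[em], self.group_starts)[self.death_group]
            t2 = np.add.reduceat(x2w[em], self.group_starts)[self.death_group]
            s0 = s0 - self.l_frac * t0
            s1 = s1 - self.l_frac * t1
            s2 = s2 - self.l_frac * t2
        elif ties != "breslow":
            raise ValueError(f"unknown tie handling '{ties}'")

        mean = s1 / s0
        u = float(x[self.event_mask].sum() - mean.sum())
        info = float((s2 / s0 - mean**2).sum())
        loglik = float(beta * x[self.event_mask].sum() - np.log(s0).sum())
        return u, info, loglik


def _cox_fit_sorted(struct: _CoxStructure, x: np.ndarray, ties: str = "efron") -> CoxResult:
    if struct.n_events == 0:
        raise ValueError("Cox fit requires at least one event")
    if np.ptp(x) == 0:
        raise ValueError("covariate does not vary")

    beta = 0.0
    converged = False
    u = info = loglik = math.nan
    for it in range(1, _MAX_ITER + 1):
        u, info, loglik = struct.moments(x, beta, ties)
        if info <= 0:
            break
        if abs(u) < _NEWTON_TOL:
            converged = True
            break
        step = u / info
        beta += float(np.clip(step, -5.0, 5.0))  # damp wild Newton steps
        if abs(beta) > _MAX_ABS_BETA:
            beta = math.copysign(_MAX_ABS_BETA, beta)
            logger.warning(
                "Cox fit: monotone partial likelihood, |beta| capped at %g", _MAX_ABS_BETA
            )
            u, info, loglik = struct.moments(x, beta, ties)
            converged = False
            break
    it_used = it

    se = 1.0 / math.sqrt(info) if info > 0 else math.inf
    z = beta / se if se > 0 and math.isfinite(se) else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxResult(
        beta=beta, hr=math.exp(beta), se=se, p=p,
        converged=converged, n_iter=it_used, loglik=loglik,
    )


def cox_fit(covariate, time, event, *, ties: str = "efron") -> CoxResult:
    """Fit a univariate Cox proportional-hazards model.

    Newton-Raphson maximization of the partial likelihood with Efron tie
    handling (default), convergence at gradient < 1e-8 within 50
    iterations; SE from the observed information, p from the Wald test.
    Monotone likelihoods (complete separation of the event order) are
    flagged non-converged with |beta| capped at 20.
    """
    x = np.asarray(covariate, dtype=float)
    struct = _CoxStructure(time, event)
    return _cox_fit_sorted(struct, x[struct.order], ties=ties)


def cox_score_test(covariate, time, event, *, ties: str = "breslow"):
    """Cox score test at beta = 0; returns (chi-square statistic, p).

    With Breslow tie handling and a binary covariate this reproduces the
    log-rank statistic (exactly so on untied data).
    """
    x = np.asarray(covariate, dtype=float)
    struct = _CoxStructure(time, event)
    u, info, _ = struct.moments(x[struct.order], 0.0, ties)
    if info <= 0:
        return 0.0, 1.0
    chi2 = u**2 / info
    return float(chi2), float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Screening


@dataclass(frozen=True)
class GapResult:
    gap: float
    extrapolated: bool


def five_year_gap(curve_low: KMCurve, curve_high: KMCurve, horizon: float) -> GapResult:
    """Absolute difference in survival probability at the horizon.

    Uses the step-function value of each curve at ``horizon``; if a curve's
    last observed time precedes the horizon its last value is carried
    forward and the result is flagged extrapolated.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    gap = abs(curve_low.survival_at(horizon) - curve_high.survival_at(horizon))
    return GapResult(
        gap=float(gap),
        extrapolated=curve_low.extrapolated(horizon) or curve_high.extrapolated(horizon),
    )


@dataclass(frozen=True)
class ScreenCriteria:
    """Pass thresholds of the prognostic screen.

    horizon defaults to five years on a day scale (1825); set it in the
    survival table's own time unit.
    """

    km_alpha: float = 0.001
    cox_alpha: float = 0.001
    min_5yr_gap: float = 0.10
    horizon: float = 1825.0

    def __post_init__(self) -> None:
        for name in ("km_alpha", "cox_alpha"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0.0 < self.min_5yr_gap < 1.0:
            raise ValueError("min_5yr_gap must be in (0, 1)")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")


def _km_survival_at_sorted(t: np.ndarray, e: np.ndarray, horizon: float):
    """S(horizon) on pre-sorted arrays; returns (value, extrapolated)."""
    mask = t <= horizon
    te, ee = t[mask], e[mask]
    n = t.size
    if not ee.any():
        return 1.0, bool(horizon > t[-1])
    uniq, first = np.unique(te, return_index=True)
    d = np.add.reduceat(ee, first)
    n_at = n - first
    keep = d > 0
    surv = float(np.prod(1.0 - d[keep] / n_at[keep]))
    return surv, bool(horizon > t[-1])


def screen_genes(
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    criteria: ScreenCriteria = ScreenCriteria(),
    *,
    cox_covariate: str = "binary",
) -> pd.DataFrame:
    """Screen every gene of an expression matrix for prognostic value.

    Parameters
    ----------
    expr : DataFrame
        Genes x samples, log2(FPKM+1)-like scale.
    surv : DataFrame
        Columns ``sample, time, event``; sample ids must match ``expr``'s
        columns exactly (any order).
    criteria : ScreenCriteria
        Alphas, minimum five-year gap and horizon.
    cox_covariate : {"binary", "continuous"}
        Fit the Cox model on the high/low indicator (default, so HR matches
        the KM grouping) or on the continuous expression value.

    Returns
    -------
    DataFrame indexed by gene: ``km_p, cox_p, hr, gap_5yr, extrapolated,
    passed, risk_class``. A gene passes iff km_p < km_alpha and
    cox_p < cox_alpha and gap_5yr > min_5yr_gap; passing genes are classed
    by HR (> 1 high_risk, < 1 low_risk; HR = 1 exactly is left unclassed
    and logged). Constant genes are skipped (NaN row) and logged.
    """
    if cox_covariate not in ("binary", "continuous"):
        raise ValueError("cox_covariate must be 'binary' or 'continuous'")
    expr_samples = set(expr.columns)
    surv_samples = set(surv["sample"])
    if expr_samples != surv_samples:
        only_expr = sorted(expr_samples - surv_samples)[:5]
        only_surv = sorted(surv_samples - expr_samples)[:5]
        raise ValueError(
            "sample-id mismatch between expression and survival tables; "
            f"expression-only: {only_expr}, survival-only: {only_surv}"
        )
    surv = surv.set_index("sample").loc[list(expr.columns)]
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)

    struct = _CoxStructure(time, event)
    t_sorted, e_sorted, order = struct.t, struct.e, struct.order

    records = []
    X = expr.to_numpy(dtype=float)
    for i, gene in enumerate(expr.index):
        values = X[i]
        try:
            high = median_split(values)
        except DegenerateSplitError:
            logger.warning("gene %s skipped: degenerate median split", gene)
            records.append({
                "gene": gene, "km_p": np.nan, "cox_p": np.nan, "hr": np.nan,
                "gap_5yr": np.nan, "extrapolated": False,
                "passed": False, "risk_class": NO_RISK,
            })
            continue

        g = high[order]
        _, km_p = _logrank_sorted(t_sorted, e_sorted, g)
        x = g.astype(float) if cox_covariate == "binary" else values[order]
        cox = _cox_fit_sorted(struct, x, ties="efron")
        s_low, ex_low = _km_survival_at_sorted(t_sorted[~g], e_sorted[~g], criteria.horizon)
        s_high, ex_high = _km_survival_at_sorted(t_sorted[g], e_sorted[g], criteria.horizon)
        gap = abs(s_low - s_high)

        passed = (
            km_p < criteria.km_alpha
            and cox.p < criteria.cox_alpha
            and gap > criteria.min_5yr_gap
        )
        if passed:
            if cox.hr > 1.0:
                risk = HIGH_RISK
            elif cox.hr < 1.0:
                risk = LOW_RISK
            else:
                logger.warning("gene %s passed with HR exactly 1; left unclassified", gene)
                risk = NO_RISK
        else:
            risk = NO_RISK
        records.append({
            "gene": gene, "km_p": km_p, "cox_p": cox.p, "hr": cox.hr,
            "gap_5yr": gap, "extrapolated": bool(ex_low or ex_high),
            "passed": passed, "risk_class": risk,
        })
    return pd.DataFrame(records).set_index("gene")


def risk_gene_lists(screen: pd.DataFrame):
    """(high_risk, low_risk) gene lists from a screen result, sorted."""
    high = sorted(screen.index[screen["risk_class"] == HIGH_RISK])
    low = sorted(screen.index[screen["risk_class"] == LOW_RISK])
    return high, low
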