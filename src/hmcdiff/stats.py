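"""Self-contained statistical kernel.

Every test used by the pipeline lives here as an explicit implementation:
Fisher's exact test on 2x2 tables, Benjamini-Hochberg FDR, Welch's t,
ordinary least squares with R^2, and Kaplan-Meier / log-rank survival
comparison.  Only numeric primitives (log-gamma, normal/t/chi-square CDFs)
come from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm
from scipy.stats import t as _t

__all__ = [
    "SurvivalRecord",
    "fisher_exact",
    "bh_fdr",
    "welch_t",
    "linear_fit",
    "KaplanMeierCurve",
    "km_curve",
    "km_logrank",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time (weeks), event flag (1=event, 0=censored)."""

    subject: str
    time: float
    event: int
    group: str

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event flag must be 0 or 1, got {self.event}")


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def _log_hypergeom_pmf(k: int, n1: int, n2: int, m: int) -> float:
    # P(X = k) drawing m items from n1 "successes" + n2 "failures"
    return (
        gammaln(n1 + 1) - gammaln(k + 1) - gammaln(n1 - k + 1)
        + gammaln(n2 + 1) - gammaln(m - k + 1) - gammaln(n2 - (m - k) + 1)
        - (gammaln(n1 + n2 + 1) - gammaln(m + 1) - gammaln(n1 + n2 - m + 1))
    )


def fisher_exact(table, alternative: str = "greater") -> tuple[float, float]:
    """Exact test of association in a 2x2 count table ``[[a, b], [c, d]]``.

    ``greater`` sums the hypergeometric upper tail at the observed ``a``;
    ``two-sided`` sums the probability of every table (fixed margins) whose
    probability does not exceed the observed one.  Returns ``(p, odds_ratio)``
    with the sample odds ratio ``ad/bc`` (inf when ``bc`` is 0 and ``ad`` > 0,
    nan for an empty table).
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n1, n2, m = a + b, c + d, a + c
    if n1 + n2 == 0:
        return math.nan, math.nan
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)

    kmin, kmax = max(0, m - n2), min(n1, m)
    logp = np.array([_log_hypergeom_pmf(k, n1, n2, m) for k in range(kmin, kmax + 1)])
    pmf = np.exp(logp - logp.max())
    pmf /= pmf.sum()
    obs = a - kmin
    if alternative == "greater":
        p = float(pmf[obs:].sum())
    elif alternative == "two-sided":
        p = float(pmf[pmf <= pmf[obs] * (1.0 + 1e-9)].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(p, 1.0), odds


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs pass through untouched."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------

def welch_t(x, y) -> tuple[float, float, float]:
    """Unequal-variance two-sample t with Welch-Satterthwaite df; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    if se2 == 0:
        # both samples constant: no evidence either way
        if x.mean() == y.mean():
            return 0.0, float(nx + ny - 2), 1.0
        return math.inf, float(nx + ny - 2), 0.0
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * float(_t.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

def linear_fit(x, y) -> tuple[float, float, float, float]:
    """Simple OLS of y on x: ``(slope, intercept, R^2, p)`` with a t-test
    on the slope (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx == 0:
        raise ValueError("x is constant")
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    ss_res = (resid**2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    # constant y carries no variance to explain: define R^2 = 0
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    sigma2 = ss_res / (n - 2)
    if sigma2 == 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        se = math.sqrt(sigma2 / sxx)
        p = 2.0 * float(_t.sf(abs(slope) / se, n - 2))
    return float(slope), float(intercept), float(r2), min(p, 1.0)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KaplanMeierCurve:
    """Product-limit estimate: right-continuous step function S(t)."""

    times: np.ndarray        # event times where the curve steps
    survival: np.ndarray     # S(t) just after each step
    median: float | None     # first t with S(t) <= 0.5, None if never reached

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times, events) -> KaplanMeierCurve:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events == 1])
    n = times.size
    s = 1.0
    step_t, step_s = [], []
    for t in uniq:
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        step_t.append(t)
        step_s.append(s)
    step_s_arr = np.array(step_s)
    median = None
    hit = np.nonzero(step_s_arr <= 0.5)[0] if step_s_arr.size else np.array([])
    if hit.size:
        median = float(step_t[int(hit[0])])
    return KaplanMeierCurve(np.array(step_t), step_s_arr, median)


def km_logrank(records: list[SurvivalRecord]):
    """Per-group Kaplan-Meier curves plus the standard (Mantel-Cox) log-rank
    chi-square with 1 df for two groups.

    Returns ``(curves, chi2, p)`` where ``curves`` maps group label to
    :class:`KaplanMeierCurve`.  With no events at all, chi2/p are NaN.
    """
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {groups}")
    curves = {}
    for g in groups:
        sub = [r for r in records if r.group == g]
        curves[g] = km_curve([r.time for r in sub], [r.event for r in sub])

    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    in_g1 = np.array([r.group == groups[0] for r in records])
    if events.sum() == 0:
        return curves, math.nan, math.nan

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & in_g1).sum())
        d_tot = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & in_g1).sum())
        o_minus_e += d1 - d_tot * n1 / n_tot
        if n_tot > 1:
            var += (
                d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
            )
    if var == 0:
        return curves, 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(_chi2.sf(chi2, 1))
    return curves, float(chi2), p


def normal_sf(z: float) -> float:
    """Upper-tail standard normal probability (exposed for the NB Wald test)."""
    return float(_norm.sf(z))
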