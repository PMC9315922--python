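"""Survival machinery for time-to-first-treatment analysis.

Implemented from first principles on numpy:

* Kaplan-Meier product-limit estimator with the R convention for the median
  (smallest time t with S(t) <= 0.5; undefined if the curve never reaches
  0.5 — several strata in practice plateau above it).
* Two-sample log-rank (Mantel-Cox) test with hypergeometric variance, and a
  pairwise variant reporting nominal p-values without multiplicity
  adjustment.
* Cox proportional-hazards regression maximising the partial likelihood by
  Newton-Raphson, with Efron's approximation for tied event times (Breslow
  available); Wald standard errors, 95% CIs and p-values.

An established survival package may be used as a cross-check in tests, but
never stands behind these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalSample",
    "KMCurve",
    "km_fit",
    "LogrankResult",
    "logrank_test",
    "pairwise_logrank",
    "CoxFit",
    "cox_fit",
    "cox_score_test",
    "ttft_report",
    "format_p",
]


@dataclass
class SurvivalSample:
    time: float  # years, > 0
    event: bool  # True = treated (event observed), False = censored
    covariates: dict[str, float] = field(default_factory=dict)


def _as_arrays(times, events):
    if events is None:
        samples = list(times)
        times = np.array([s.time for s in samples], dtype=float)
        events = np.array([s.event for s in samples], dtype=bool)
    else:
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no samples")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    return times, events


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit estimate of the survival function."""

    event_times: np.ndarray  # distinct times with >= 1 event, increasing
    survival_prob: np.ndarray  # S(t) at each event time, non-increasing
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_samples: int

    @property
    def median(self) -> float | None:
        """Smallest event time with S(t) <= 0.5, or None if never reached."""
        below = self.survival_prob <= 0.5 + 1e-12
        if not below.any():
            return None
        return float(self.event_times[np.argmax(below)])

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


def km_fit(times, events=None) -> KMCurve:
    """Kaplan-Meier estimator.

    Censored observations leave the risk set without dropping the curve.
    Accepts (times, events) arrays or a list of :class:`SurvivalSample`.
    """
    times, events = _as_arrays(times, events)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, first = np.unique(t, return_index=True)
    n = len(t)
    at_risk = n - first  # subjects with time >= uniq[j]
    d = np.add.reduceat(e.astype(int), first)
    has_event = d > 0
    surv = np.cumprod(1.0 - d[has_event] / at_risk[has_event])
    return KMCurve(
        event_times=uniq[has_event],
        survival_prob=surv,
        n_at_risk=at_risk[has_event],
        n_events=d[has_event],
        n_samples=n,
    )


def km_table(curve: KMCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": curve.event_times,
            "n_at_risk": curve.n_at_risk,
            "n_events": curve.n_events,
            "survival": curve.survival_prob,
        }
    )


# ---------------------------------------------------------------------------
# Log-rank


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float
    observed_minus_expected: float  # in the first group


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-sample log-rank (Mantel-Cox) test.

    Observed-vs-expected events in group A at every pooled event time, with
    the hypergeometric variance; the statistic is chi-square with 1 df.
    """
    ta, ea = _as_arrays(times_a, events_a)
    tb, eb = _as_arrays(times_b, events_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(len(ta), bool), np.ones(len(tb), bool)])
    if e.sum() == 0:
        raise ValueError("log-rank undefined: no events in either group")
    event_times = np.unique(t[e])
    o_minus_e = 0.0
    var = 0.0
    for tj in event_times:
        at_risk = t >= tj
        n = at_risk.sum()
        n1 = (at_risk & ~g).sum()
        dead = e & (t == tj)
        d = dead.sum()
        d1 = (dead & ~g).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = 0.0 if var == 0 else o_minus_e**2 / var
    return LogrankResult(
        chi_square=float(chi2),
        p_value=float(stats.chi2.sf(chi2, df=1)),
        observed_minus_expected=float(o_minus_e),
    )


def pairwise_logrank(groups: dict[str, tuple]) -> pd.DataFrame:
    """Nominal pairwise log-rank p-values over k strata (no adjustment).

    ``groups`` maps stratum label -> (times, events).  Pairs where the test
    is undefined (no events) get NaN.
    """
    labels = list(groups)
    out = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for i, a in enumerate(labels):
        out.loc[a, a] = 1.0
        for b in labels[i + 1 :]:
            try:
                res = logrank_test(*groups[a], *groups[b])
                p = res.p_value
            except ValueError:
                p = np.nan
            out.loc[a, b] = out.loc[b, a] = p
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    ties: str

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def wald_ci_95(self) -> np.ndarray:
        lo = np.exp(self.coef - 1.96 * self.se)
        hi = np.exp(self.coef + 1.96 * self.se)
        return np.column_stack([lo, hi])

    @property
    def p_values(self) -> np.ndarray:
        z = self.coef / self.se
        return stats.chi2.sf(z**2, df=1)

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.names, self.coef))

    def summary(self) -> pd.DataFrame:
        ci = self.wald_ci_95
        return pd.DataFrame(
            {
                "coef": self.coef,
                "hazard_ratio": self.hazard_ratios,
                "se": self.se,
                "hr_ci_lower": ci[:, 0],
                "hr_ci_upper": ci[:, 1],
                "p": self.p_values,
            },
            index=self.names,
        )


def _cox_prepare(X, times, events):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    times, events = _as_arrays(times, events)
    if X.shape[0] != len(times):
        raise ValueError("covariate matrix and times disagree in length")
    if events.sum() == 0:
        raise ValueError("Cox model requires at least one event")
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"degenerate covariate at column {j}: constant value")
    order = np.argsort(times, kind="stable")
    return X[order], times[order], events[order]


def _cox_ll_grad_hess(beta, X, times, events, ties):
    """Partial log-likelihood, score and information at ``beta``.

    Arrays must be sorted by ascending time.  ``ties`` is "efron" or
    "breslow"; with no tied event times the two coincide.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guard exp overflow; cancels in all ratios
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = wX[:, :, None] * X[:, None, :]
    # suffix sums over the risk set {i: time_i >= t}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    ll = 0.0
    U = np.zeros(p)
    info = np.zeros((p, p))
    event_times = np.unique(times[events])
    for tj in event_times:
        k = np.searchsorted(times, tj, side="left")
        D = np.nonzero(events & (times == tj))[0]
        d = len(D)
        s0r, s1r, s2r = S0[k], S1[k], S2[k]
        ll += float(eta[D].sum())
        U += X[D].sum(axis=0)
        if ties == "efron" and d > 1:
            s0d = w[D].sum()
            s1d = wX[D].sum(axis=0)
            s2d = wXX[D].sum(axis=0)
            for l in range(d):
                f = l / d
                phi0 = s0r - f * s0d
                phi1 = s1r - f * s1d
                phi2 = s2r - f * s2d
                ll -= np.log(phi0)
                m = phi1 / phi0
                U -= m
                info += phi2 / phi0 - np.outer(m, m)
        else:  # breslow (exact for d == 1)
            ll -= d * np.log(s0r)
            m = s1r / s0r
            U -= d * m
            info += d * (s2r / s0r - np.outer(m, m))
    return ll, U, info


def cox_fit(
    X,
    times,
    events,
    names: list[str] | None = None,
    ties: str = "efron",
    max_iter: int = 50,
    score_tol: float = 1e-9,
    ll_tol: float = 1e-10,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    ``X`` is (n, p) (a single covariate may be 1-D).  Exponentiated
    coefficients are hazard ratios; Wald 95% CIs are exp(coef +/- 1.96 se).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    X, times, events = _cox_prepare(X, times, events)
    p = X.shape[1]
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("one name per covariate required")

    beta = np.zeros(p)
    ll, U, info = _cox_ll_grad_hess(beta, X, times, events, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        step = np.linalg.solve(info, U)
        # step-halving keeps the partial likelihood non-decreasing
        for _ in range(30):
            new_beta = beta + step
            new_ll, new_U, new_info = _cox_ll_grad_hess(
                new_beta, X, times, events, ties
            )
            if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                break
            step /= 2.0
        rel_change = abs(new_ll - ll) / max(abs(ll), 1.0)
        beta, ll, U, info = new_beta, new_ll, new_U, new_info
        if np.max(np.abs(U)) < score_tol or rel_change < ll_tol:
            converged = True
            break
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return CoxFit(
        names=list(names),
        coef=beta,
        se=se,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        ties=ties,
    )


def cox_score_test(x, times, events, ties: str = "breslow"):
    """Cox score test at beta = 0 for a single covariate.

    With Breslow tie handling and a binary group indicator this equals the
    two-sample log-rank statistic.
    """
    X, times, events = _cox_prepare(x, times, events)
    _, U, info = _cox_ll_grad_hess(np.zeros(X.shape[1]), X, times, events, ties)
    chi2 = float(U @ np.linalg.solve(info, U))
    return chi2, float(stats.chi2.sf(chi2, df=X.shape[1]))


# ---------------------------------------------------------------------------
# Stratified TTFT reports


def format_p(p: float) -> str:
    """Display convention: nominal p, floored at '< 0.0001'."""
    if np.isnan(p):
        return "NA"
    return "< 0.0001" if p < 1e-4 else f"{p:.4f}"


def ttft_report(
    cohort: pd.DataFrame,
    by: str,
    time_col: str = "ttft_years",
    event_col: str = "event",
    order: list[str] | None = None,
) -> dict:
    """Per-stratum KM curves, medians and pairwise nominal log-rank p-values.

    ``by`` names a label column of the cohort table; strata with no
    patients are omitted.  Medians are reported in years (2-decimal display
    in the formatted table).
    """
    strata: dict[str, dict] = {}
    groups: dict[str, tuple] = {}
    labels = order if order is not None else sorted(cohort[by].dropna().unique())
    for label in labels:
        sub = cohort[cohort[by] == label]
        if sub.empty:
            continue
        curve = km_fit(sub[time_col].to_numpy(), sub[event_col].to_numpy())
        strata[label] = {
            "n": int(len(sub)),
            "n_treated": int(sub[event_col].sum()),
            "median_ttft_years": curve.median,
            "curve": curve,
        }
        groups[label] = (sub[time_col].to_numpy(), sub[event_col].to_numpy())
    pairwise = pairwise_logrank(groups) if len(groups) >= 2 else None
    return {"by": by, "strata": strata, "pairwise_p": pairwise}


def km_plot(report: dict, path) -> None:
    """Export step-function KM curves for every stratum of a report."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, s in report["strata"].items():
        c = s["curve"]
        t = np.concatenate([[0.0], c.event_times])
        surv = np.concatenate([[1.0], c.survival_prob])
        ax.step(t, surv, where="post", label=f"{label} (n={s['n']})")
    ax.set_xlabel("years")
    ax.set_ylabel("fraction untreated")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def report_table(report: dict) -> pd.DataFrame:
    rows = []
    for label, s in report["strata"].items():
        med = s["median_ttft_years"]
        rows.append(
            {
                "stratum": label,
                "n": s["n"],
                "n_treated": s["n_treated"],
                "median_ttft_years": np.nan if med is None else round(med, 2),
            }
        )
    return pd.DataFrame(rows)
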