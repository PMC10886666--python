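"""Survival-statistics harness: Kaplan–Meier curves, one-sided log-rank
tests, optimal risk cut-off search, Cox regression (univariate and subset
enumeration) with AIC and concordance, and subgroup distribution tests.

Conventions: Breslow tie handling throughout; "partial AIC" is
``2k - 2 log PL`` from the maximized Cox partial likelihood; the one-sided
log-rank alternative is "the high-risk group relapses earlier".
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import concordance_index as _ll_concordance
from scipy import stats as sps
import statsmodels.api as sm


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    event_times: np.ndarray
    survival_prob: np.ndarray  # nonincreasing, starts at 1
    at_risk: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.event_times,
                             "survival": self.survival_prob,
                             "at_risk": self.at_risk})


@dataclass
class CoxResult:
    covariates: list[str]
    hazard_ratio: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    p_value: np.ndarray
    aic: float
    c_index: float
    converged: bool = True

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.covariates,
            "hazard_ratio": self.hazard_ratio,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
            "p_value": self.p_value,
        })


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator (censored times reduce the
    at-risk set only)."""
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter().fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    return KMCurve(
        event_times=table.index.to_numpy(dtype=np.float64),
        survival_prob=surv,
        at_risk=table["at_risk"].to_numpy(dtype=np.int64),
    )


def _logrank_oe(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Observed-minus-expected events in group A and its variance."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    all_event_times = np.unique(
        np.concatenate([times_a[events_a == 1], times_b[events_b == 1]])
    )
    oe, var = 0.0, 0.0
    for t in all_event_times:
        n_a = int(np.sum(times_a >= t))
        n_b = int(np.sum(times_b >= t))
        d_a = int(np.sum((times_a == t) & (events_a == 1)))
        d_b = int(np.sum((times_b == t) & (events_b == 1)))
        n, d = n_a + n_b, d_a + d_b
        if n == 0:
            continue
        exp_a = d * n_a / n
        oe += d_a - exp_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return oe, var


def logrank_one_sided(
    times_a, events_a, times_b, events_b, two_sided: bool = False
) -> dict:
    """Log-rank test of group A (putative high-risk) vs group B.

    One-sided p is for the alternative "A relapses earlier" (more events
    observed in A than expected). Returns the chi-square statistic, the
    signed z, and the p-value.
    """
    if len(np.atleast_1d(times_a)) == 0 or len(np.atleast_1d(times_b)) == 0:
        raise ValueError("both groups must be nonempty")
    oe, var = _logrank_oe(times_a, events_a, times_b, events_b)
    if var <= 0:
        # no events at all: no evidence either way
        return {"statistic": 0.0, "z": 0.0, "p": 1.0 if two_sided else 0.5}
    z = oe / np.sqrt(var)
    chi2 = z * z
    p = float(sps.chi2.sf(chi2, 1)) if two_sided else float(sps.norm.sf(z))
    return {"statistic": float(chi2), "z": float(z), "p": p}


def best_cutoff(
    risks, times, events, min_group_frac: float = 0.1, n_permutations: int = 0,
    seed: int = 0,
) -> dict:
    """Risk cut-off minimizing the one-sided log-rank p-value.

    Candidates are midpoints between consecutive sorted unique risks; splits
    leaving either group below ``min_group_frac`` of the cohort are skipped.
    Ties in p break toward the lowest cut-off. With ``n_permutations`` > 0 a
    permutation-adjusted p (for the optimization over cut-offs) is included.
    """
    risks = np.asarray(risks, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    uniq = np.unique(risks)
    if uniq.size < 2:
        raise ValueError("all risks identical: no valid cutoff")
    n = risks.size
    min_n = max(1, int(np.ceil(min_group_frac * n)))

    def scan(r, t, e):
        best = (np.inf, None)
        for cut in (uniq_mid := (np.unique(r)[:-1] + np.unique(r)[1:]) / 2.0):
            hi = r > cut
            if hi.sum() < min_n or (~hi).sum() < min_n:
                continue
            p = logrank_one_sided(t[hi], e[hi], t[~hi], e[~hi])["p"]
            if p < best[0] - 1e-15:
                best = (p, cut)
        return best

    p_best, cut_best = scan(risks, times, events)
    if cut_best is None:
        raise ValueError("no cutoff satisfies the minimum group size")
    out = {"cutoff": float(cut_best), "p": float(p_best)}
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            p_perm, c_perm = scan(risks[perm], times, events)
            if p_perm <= p_best:
                count += 1
        out["p_adjusted"] = (count + 1) / (n_permutations + 1)
    return out


def _fit_cox(X: np.ndarray, times, events, names) -> CoxResult:
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    model = sm.PHReg(times, X, status=events, ties="breslow")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False)
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
        raise RuntimeError("Cox fit did not converge")
    z = params / bse
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    hr = np.exp(params)
    lo = np.exp(params - 1.959963984540054 * bse)
    hi = np.exp(params + 1.959963984540054 * bse)
    loglik = float(model.loglike(params))
    aic = 2.0 * len(params) - 2.0 * loglik
    lp = X @ params
    try:
        c = float(_ll_concordance(times, -lp, events))
    except ZeroDivisionError:
        c = float("nan")
    return CoxResult(list(names), hr, lo, hi, pvals, aic, c)


def cox_univariate(covariate, times, events, name: str = "covariate") -> CoxResult:
    """Univariate Cox proportional-hazards fit (Breslow ties, Wald p)."""
    X = np.asarray(covariate, dtype=np.float64).reshape(-1, 1)
    if np.ptp(X) == 0:
        raise ValueError("covariate is constant")
    return _fit_cox(X, times, events, [name])


def cox_multiple(frame: pd.DataFrame, times, events) -> CoxResult:
    """Multiple Cox regression on the columns of ``frame``."""
    X = frame.to_numpy(dtype=np.float64)
    return _fit_cox(X, times, events, list(frame.columns))


def cox_combinations(
    frame: pd.DataFrame, times, events, alpha: float = 0.05
) -> list[CoxResult]:
    """Fit every non-empty covariate subset; keep models in which every
    individual feature is significant (all Wald p < ``alpha``).

    Collinear or non-converging subsets are flagged and excluded. Results
    report hazard ratios with 95% CIs, partial AIC, and concordance.
    """
    if frame.shape[1] < 1:
        raise ValueError("at least one feature required")
    kept = []
    for r in range(1, frame.shape[1] + 1):
        for combo in itertools.combinations(frame.columns, r):
            sub = frame[list(combo)]
            if np.linalg.matrix_rank(np.corrcoef(sub.to_numpy().T).reshape(r, r)) < r:
                warnings.warn(f"collinear features {combo}; model excluded")
                continue
            try:
                res = cox_multiple(sub, times, events)
            except (RuntimeError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"model {combo} excluded: {exc}")
                continue
            if np.all(res.p_value < alpha):
                kept.append(res)
    return sorted(kept, key=lambda r: r.aic)


def group_tests(values, groups) -> dict:
    """Two-sided Mann–Whitney U (2 groups) or Kruskal–Wallis (>2 groups)."""
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    if levels.size == 2:
        stat, p = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return {"test": "mannwhitneyu", "statistic": float(stat), "p": float(p)}
    stat, p = sps.kruskal(*samples)
    return {"test": "kruskal", "statistic": float(stat), "p": float(p)}
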