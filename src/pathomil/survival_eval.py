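"""Risk stratification and survival evaluation.

Patients are split at an optimal score cutpoint (exhaustive log-rank scan, a
surrogate for X-tile-style cutpoint selection) and evaluated with the field's
standard toolbox: Kaplan-Meier curves with log-rank tests, Cox proportional
hazards models (Breslow tie handling), a mixed-effects Cox model with a
log-normal per-center frailty, Harrell's C-index, IPCW time-dependent AUC,
Cochran's Q / I-squared center heterogeneity with a DerSimonian-Laird pooled
effect, and per-stratum subgroup analyses.

Time is in months throughout; the convention for pathomics signature scores
is that LOWER scores mark HIGHER risk, so stratification supports either
orientation and Harrell's C always takes risk scores (higher = riskier).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import optimize, stats
from sksurv.metrics import concordance_index_censored, cumulative_dynamic_auc
from sksurv.util import Surv

from .fixtures import SurvivalOutcome

__all__ = [
    "SurvivalOutcome",
    "RiskStratification",
    "HeterogeneityResult",
    "StratificationError",
    "optimal_cutoff",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "mixed_effects_cox",
    "harrells_c",
    "time_dependent_auc",
    "heterogeneity_meta",
    "subgroup_analysis",
    "outcomes_to_arrays",
]

CI_LEVEL = 0.95
_Z = stats.norm.ppf(0.5 + CI_LEVEL / 2)


class StratificationError(ValueError):
    """Raised when no valid risk cutoff exists (e.g. constant scores)."""


def outcomes_to_arrays(outcomes) -> tuple[np.ndarray, np.ndarray]:
    """Accepts a list of SurvivalOutcome or a (time, event) array pair."""
    if isinstance(outcomes, tuple) and len(outcomes) == 2:
        time, event = outcomes
    else:
        time = [o.time for o in outcomes]
        event = [o.event for o in outcomes]
    return np.asarray(time, dtype=float), np.asarray(event, dtype=int)


# ---------------------------------------------------------------------------
# Breslow partial-likelihood core (shared by Cox fits and the frailty model)
# ---------------------------------------------------------------------------

def _breslow_quantities(m: np.ndarray, time: np.ndarray, event: np.ndarray, eta: np.ndarray):
    """Log partial likelihood, gradient and information for eta = M @ coef.

    Breslow tie handling: all events at a tied time share the risk set of
    subjects with time >= t. Computed with reverse cumulative sums, O(n q^2).
    """
    order = np.argsort(time, kind="stable")
    m, time, event, eta = m[order], time[order], event[order], eta[order]
    w = np.exp(eta - eta.max())  # overflow guard; constant cancels in ratios
    log_shift = eta.max()

    wm = w[:, None] * m
    wmm = w[:, None, None] * (m[:, :, None] * m[:, None, :])
    cw = np.cumsum(w[::-1])[::-1]
    cwm = np.cumsum(wm[::-1], axis=0)[::-1]
    cwmm = np.cumsum(wmm[::-1], axis=0)[::-1]

    # first index of each tied time group = risk-set entry point
    first = np.searchsorted(time, time, side="left")
    ev = np.flatnonzero(event == 1)
    if ev.size == 0:
        raise ValueError("no events in outcome data")
    r = first[ev]
    # underflow guard: a risk set whose weights all vanish marks divergence,
    # handled by the caller's step-halving / divergence checks
    wt = np.maximum(cw[r], 1e-300)
    st1, st2 = cwm[r], cwmm[r]

    loglik = float(eta[ev].sum() - np.sum(np.log(wt) + log_shift))
    mu = st1 / wt[:, None]
    grad = m[ev].sum(axis=0) - mu.sum(axis=0)
    info = (st2 / wt[:, None, None]).sum(axis=0) - np.einsum("ti,tj->ij", mu, mu)
    return loglik, grad, info


def _newton_cox(
    m: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    penalty_diag: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 60,
):
    """Newton-Raphson on the (optionally ridge-penalized) Breslow partial likelihood."""
    q = m.shape[1]
    beta = np.zeros(q) if beta0 is None else beta0.copy()
    pen = np.zeros(q) if penalty_diag is None else np.asarray(penalty_diag, dtype=float)

    def objective(b):
        ll, g, info = _breslow_quantities(m, time, event, m @ b)
        return ll - 0.5 * float(b @ (pen * b)), g - pen * b, info + np.diag(pen)

    obj, g, h = objective(beta)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("Cox information matrix is singular (separation?)") from exc
        # step halving keeps the penalized likelihood increasing
        for _ in range(30):
            new_beta = beta + step
            new_obj, new_g, new_h = objective(new_beta)
            if np.isfinite(new_obj) and new_obj >= obj - 1e-12:
                break
            step = step / 2.0
        delta = np.abs(new_beta - beta).max()
        beta, obj, g, h = new_beta, new_obj, new_g, new_h
        if delta < tol:
            break
    else:
        raise RuntimeError("Cox fit did not converge")
    if np.abs(beta).max() > 50:
        raise RuntimeError("Cox fit diverged (likely complete separation)")
    return beta, obj, g, h


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMEstimate:
    times: np.ndarray
    survival: np.ndarray
    median: float  # np.inf when the median is not reached

    def at(self, t: float) -> float:
        """Step-function value S(t); S(0) = 1."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)


def km_estimate(outcomes) -> KMEstimate:
    """Product-limit survival estimate; the median is the smallest t with S(t) <= 0.5."""
    time, event = outcomes_to_arrays(outcomes)
    if time.size == 0:
        raise ValueError("empty outcome list")
    kmf = KaplanMeierFitter().fit(time, event)
    sf = kmf.survival_function_
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=float(kmf.median_survival_time_),
    )


def logrank_test(outcomes_by_group: dict) -> tuple[float, float]:
    """K-sample log-rank test; returns (chi2, p) with k-1 degrees of freedom."""
    if len(outcomes_by_group) < 2:
        raise ValueError("log-rank test requires at least two groups")
    times, events, groups = [], [], []
    for g, outs in outcomes_by_group.items():
        t, e = outcomes_to_arrays(outs)
        if t.size == 0:
            raise ValueError(f"group {g!r} is empty")
        times.append(t), events.append(e), groups.append(np.repeat(str(g), t.size))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(groups), np.concatenate(events)
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# optimal cutpoint (X-tile-style exhaustive log-rank scan)
# ---------------------------------------------------------------------------

@dataclass
class RiskStratification:
    cutoff: float
    groups: np.ndarray  # per-patient "high" / "low"
    chi2: float
    p_value: float
    high_risk_side: str  # "below" or "above"

    def __post_init__(self) -> None:
        u = set(self.groups.tolist())
        if u != {"high", "low"}:
            raise ValueError("stratification must produce non-empty high and low groups")


def _split_groups(scores: np.ndarray, cutoff: float, high_risk_side: str) -> np.ndarray:
    below = scores <= cutoff
    high = below if high_risk_side == "below" else ~below
    return np.where(high, "high", "low")


def optimal_cutoff(
    scores,
    outcomes,
    min_group_frac: float = 0.10,
    high_risk_side: str = "auto",
) -> RiskStratification:
    """Exhaustive scan over midpoints of adjacent unique scores.

    Keeps candidates leaving at least ``min_group_frac`` of patients on each
    side, returns the cutoff maximizing the two-group log-rank chi-squared
    (ties resolved toward the smaller cutoff). The resulting chi2 is not
    corrected for the maximal selection and is optimism-prone as a p-value.

    ``high_risk_side='auto'`` labels the side with the worse survival as high
    risk; 'below' follows the pathomics convention (lower score = higher risk).
    """
    scores = np.asarray(scores, dtype=float)
    time, event = outcomes_to_arrays(outcomes)
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise StratificationError("constant scores admit no cutoff")
    if event.sum() < 2:
        raise StratificationError("need at least two events to stratify")

    n = scores.size
    min_count = min_group_frac * n
    best = None
    for cut in (uniq[:-1] + uniq[1:]) / 2.0:
        low_mask = scores <= cut
        n_below = int(low_mask.sum())
        if n_below < min_count or n - n_below < min_count:
            continue
        chi2, p = logrank_test(
            {"a": (time[low_mask], event[low_mask]), "b": (time[~low_mask], event[~low_mask])}
        )
        if best is None or chi2 > best[0] + 1e-12:
            best = (chi2, p, cut)
    if best is None:
        raise StratificationError("no cutoff satisfies the minimum group size")
    chi2, p, cutoff = best

    side = high_risk_side
    if side == "auto":
        # direction from the log-rank score: positive gradient for the
        # below-cutoff indicator means excess events below the cutoff
        ind = (scores <= cutoff).astype(float)[:, None]
        _, g, _ = _breslow_quantities(ind, time, event, np.zeros(n))
        side = "below" if g[0] > 0 else "above"
    return RiskStratification(float(cutoff), _split_groups(scores, cutoff, side), chi2, p, side)


# ---------------------------------------------------------------------------
# Cox proportional hazards (fixed effects)
# ---------------------------------------------------------------------------

def cox_fit(outcomes, covariates, strata=None) -> pd.DataFrame:
    """Cox proportional-hazards fit (Breslow ties), Wald CIs and p-values.

    ``covariates`` is a DataFrame (or array) of columns entered jointly;
    ``strata`` optionally names a grouping whose levels get separate baseline
    hazards. Returns one row per covariate: coef, HR, ci_low, ci_high, se, p.
    """
    time, event = outcomes_to_arrays(outcomes)
    x = pd.DataFrame(covariates)
    names = [str(c) for c in x.columns]
    m = x.to_numpy(dtype=float)
    if event.sum() < m.shape[1] + 1:
        raise ValueError("too few events for the number of covariates")
    if np.any(m.std(axis=0) == 0):
        raise ValueError("constant covariate column in Cox fit")

    if strata is None:
        beta, _, _, h = _newton_cox(m, time, event)
    else:
        strata = np.asarray(strata)
        # stratified fit: sum the per-stratum likelihood contributions
        def objective(b):
            ll, g, info = 0.0, np.zeros(m.shape[1]), np.zeros((m.shape[1], m.shape[1]))
            for s in np.unique(strata):
                mask = strata == s
                if event[mask].sum() == 0:
                    continue
                l_, g_, i_ = _breslow_quantities(m[mask], time[mask], event[mask], m[mask] @ b)
                ll, g, info = ll + l_, g + g_, info + i_
            return ll, g, info

        beta = np.zeros(m.shape[1])
        for _ in range(60):
            ll, g, h = objective(beta)
            step = np.linalg.solve(h, g)
            beta = beta + step
            if np.abs(step).max() < 1e-9:
                break
        else:
            raise RuntimeError("stratified Cox fit did not converge")

    se = np.sqrt(np.diag(np.linalg.inv(h)))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "coef": beta,
            "HR": np.exp(beta),
            "ci_low": np.exp(beta - _Z * se),
            "ci_high": np.exp(beta + _Z * se),
            "se": se,
            "p": p,
        },
        index=names,
    )


def cox_score_test(outcomes, covariate) -> float:
    """Score (Rao) chi-squared at beta = 0; equals the log-rank chi2 for a binary split."""
    time, event = outcomes_to_arrays(outcomes)
    m = np.asarray(covariate, dtype=float).reshape(len(time), -1)
    _, g, info = _breslow_quantities(m, time, event, np.zeros(len(time)))
    return float(g @ np.linalg.solve(info, g))


# ---------------------------------------------------------------------------
# mixed-effects Cox with log-normal center frailty
# ---------------------------------------------------------------------------

@dataclass
class FrailtyCoxResult:
    summary: pd.DataFrame  # fixed effects: coef, HR, ci_low, ci_high, se, p
    random_effect_variance: float
    frailty: pd.Series  # posterior-mode log-frailty per center
    loglik: float


def mixed_effects_cox(outcomes, covariates, center_labels) -> FrailtyCoxResult:
    """Cox model with a shared per-center log-normal frailty on the hazard.

    Estimated by penalized partial likelihood: for a given frailty variance
    theta the log-frailties b are ridge-penalized by b'b/(2*theta) and
    maximized jointly with the fixed effects; theta itself maximizes the
    Laplace-approximate marginal likelihood
    ``ppl(beta_hat, b_hat) - 0.5 * log|theta * I_bb + I|``.
    Falls back to the fixed-effects fit when only one center is present.
    """
    time, event = outcomes_to_arrays(outcomes)
    x = pd.DataFrame(covariates)
    names = [str(c) for c in x.columns]
    xm = x.to_numpy(dtype=float)
    centers = pd.Categorical(np.asarray(center_labels))
    n_centers = len(centers.categories)
    if n_centers < 2:
        warnings.warn("single center: falling back to fixed-effects Cox fit")
        summ = cox_fit((time, event), x)
        return FrailtyCoxResult(summ, 0.0, pd.Series(dtype=float), np.nan)

    z = np.eye(n_centers)[centers.codes]
    m = np.hstack([xm, z])
    p = xm.shape[1]

    def profile_loglik(log_theta: float):
        theta = float(np.exp(log_theta))
        pen = np.concatenate([np.zeros(p), np.full(n_centers, 1.0 / theta)])
        coef, ppl, _, h = _newton_cox(m, time, event, penalty_diag=pen)
        i_bb = (h - np.diag(pen))[p:, p:]  # unpenalized information, frailty block
        sign, logdet = np.linalg.slogdet(theta * i_bb + np.eye(n_centers))
        return ppl - 0.5 * logdet, coef, h

    res = optimize.minimize_scalar(
        lambda lt: -profile_loglik(lt)[0],
        bounds=(np.log(1e-4), np.log(4.0)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    best_ll, coef, h = profile_loglik(res.x)
    theta = float(np.exp(res.x))
    # compare against the no-frailty boundary; keep theta ~ 0 if it is better
    ll0, coef0, h0 = profile_loglik(np.log(1e-6))
    if ll0 >= best_ll:
        theta, coef, h, best_ll = 0.0, coef0, h0, ll0

    cov = np.linalg.inv(h)
    beta, se = coef[:p], np.sqrt(np.diag(cov)[:p])
    zstat = beta / se
    summary = pd.DataFrame(
        {
            "coef": beta,
            "HR": np.exp(beta),
            "ci_low": np.exp(beta - _Z * se),
            "ci_high": np.exp(beta + _Z * se),
            "se": se,
            "p": 2 * stats.norm.sf(np.abs(zstat)),
        },
        index=names,
    )
    frailty = pd.Series(coef[p:], index=list(centers.categories))
    return FrailtyCoxResult(summary, theta, frailty, float(best_ll))


# ---------------------------------------------------------------------------
# discrimination metrics
# ---------------------------------------------------------------------------

def harrells_c(risk_scores, outcomes) -> float:
    """Harrell's concordance of risk scores with event ordering.

    Higher risk paired with shorter survival counts as concordant; tied risk
    scores count one half. Pathomics signature scores, where LOW score means
    HIGH risk, should be negated before calling.
    """
    time, event = outcomes_to_arrays(outcomes)
    risk = np.asarray(risk_scores, dtype=float)
    try:
        c, *_ = concordance_index_censored(event.astype(bool), time, risk)
    except Exception as exc:  # sksurv NoComparablePairException
        raise ValueError("no usable pairs for concordance") from exc
    return float(c)


def time_dependent_auc(scores, outcomes, horizons) -> dict[float, float]:
    """Cumulative-case/dynamic-control AUC(t) with KM-based IPCW weights.

    Horizons beyond the observed follow-up (or before the first event) are
    reported as NaN.
    """
    time, event = outcomes_to_arrays(outcomes)
    risk = np.asarray(scores, dtype=float)
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    out: dict[float, float] = {}
    for t in horizons:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                auc, _ = cumulative_dynamic_auc(y, y, risk, [t])
            out[float(t)] = float(auc[0])
        except ValueError:
            out[float(t)] = float("nan")
    return out


# ---------------------------------------------------------------------------
# heterogeneity across centers and subgroup analyses
# ---------------------------------------------------------------------------

@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    I2: float  # percent
    p_value: float
    pooled_log_hr: float
    pooled_ci: tuple[float, float]
    tau2: float


def heterogeneity_meta(per_center_log_hr, per_center_se) -> HeterogeneityResult:
    """Cochran's Q / I-squared and a DerSimonian-Laird random-effects pool.

    Q uses fixed (inverse-variance) weights; I2 = max(0, (Q - df)/Q) * 100.
    """
    theta = np.asarray(per_center_log_hr, dtype=float)
    se = np.asarray(per_center_se, dtype=float)
    if theta.size < 2 or not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("need at least two centers with finite positive SEs")
    w = 1.0 / se**2
    theta_fixed = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_fixed) ** 2))
    df = theta.size - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    p = float(stats.chi2.sf(q, df))
    tau2 = max(0.0, (q - df) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * theta) / np.sum(w_star))
    se_pooled = float(1.0 / np.sqrt(np.sum(w_star)))
    return HeterogeneityResult(
        q, df, i2, p, pooled, (pooled - _Z * se_pooled, pooled + _Z * se_pooled), float(tau2)
    )


def subgroup_analysis(outcomes, covariate, strata_labels) -> pd.DataFrame:
    """Single-covariate Cox fit within each stratum (forest-style table).

    Strata with fewer than two events or a constant covariate are skipped
    with a warning. Columns: n, events, coef, HR, ci_low, ci_high, se, p.
    """
    time, event = outcomes_to_arrays(outcomes)
    cov = np.asarray(covariate, dtype=float)
    strata = np.asarray(strata_labels)
    rows = {}
    for s in pd.unique(strata):
        mask = strata == s
        if event[mask].sum() < 2:
            warnings.warn(f"stratum {s!r} has fewer than two events; skipped")
            continue
        if np.std(cov[mask]) == 0:
            warnings.warn(f"covariate constant within stratum {s!r}; skipped")
            continue
        try:
            fit = cox_fit((time[mask], event[mask]), pd.DataFrame({"covariate": cov[mask]}))
        except RuntimeError as exc:
            warnings.warn(f"stratum {s!r} fit failed ({exc}); skipped")
            continue
        row = fit.loc["covariate"].to_dict()
        rows[s] = {"n": int(mask.sum()), "events": int(event[mask].sum()), **row}
    return pd.DataFrame.from_dict(rows, orient="index")
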