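"""Three-tier feature selection into a sparse LASSO-Cox pathomics signature.

The 206 fused features are reduced in a fixed cascade: (1) a greedy Pearson
correlation filter (|r| > 0.9 drops the later feature in column order),
(2) a univariate Cox screen keeping features with Wald p < 0.05, and (3) an
L1-penalized Cox model whose penalty is chosen by 10-fold cross-validated
partial-likelihood deviance (Verweij-van Houwelingen form). The signature's
pathomics score is the linear predictor sum(beta_i * x_i) over the selected
features; a log-rank-optimal cutoff fitted on the training cohort completes
the model.

Features are standardized to unit variance inside the LASSO fit and the
coefficients are reported back on the original feature scale. Reference
penalty values printed for the original cohorts (lambda = 0.179 for RFS,
0.022 for OS) are cohort-dependent configuration references, not targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .survival_eval import (
    RiskStratification,
    _breslow_quantities,
    _newton_cox,
    optimal_cutoff,
    outcomes_to_arrays,
)

__all__ = [
    "SelectionConfig",
    "SignatureModel",
    "SignatureError",
    "correlation_filter",
    "univariate_cox_screen",
    "lasso_cox",
    "pathomics_score",
    "fit_signature",
]


class SignatureError(ValueError):
    """Raised when signature fitting yields no usable features."""


@dataclass(frozen=True)
class SelectionConfig:
    corr_threshold: float = 0.9
    screen_alpha: float = 0.05
    cv_folds: int = 10
    lambda_grid: tuple[float, ...] | None = None  # None -> data-driven path
    endpoint: str = "OS"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.corr_threshold <= 1:
            raise ValueError("corr_threshold must lie in (0, 1]")
        if not 0 < self.screen_alpha < 1:
            raise ValueError("screen_alpha must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.endpoint not in ("OS", "RFS"):
            raise ValueError("endpoint must be 'OS' or 'RFS'")


@dataclass
class SignatureModel:
    endpoint: str
    selected: list[str]
    beta: np.ndarray
    lambda_opt: float
    cutoff: float | None = None
    high_risk_side: str = "above"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.selected) == 0:
            raise SignatureError("a signature needs at least one selected feature")
        if self.beta.shape != (len(self.selected),):
            raise ValueError("one coefficient per selected feature required")
        if np.any(self.beta == 0):
            raise ValueError("signature coefficients must be nonzero")

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "selected": list(self.selected),
            "beta": self.beta.tolist(),
            "lambda_opt": self.lambda_opt,
            "cutoff": self.cutoff,
            "high_risk_side": self.high_risk_side,
            "provenance": {k: list(v) for k, v in self.provenance.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        return cls(
            d["endpoint"], list(d["selected"]), np.asarray(d["beta"]), d["lambda_opt"],
            d.get("cutoff"), d.get("high_risk_side", "above"),
            {k: list(v) for k, v in d.get("provenance", {}).items()},
        )


# ---------------------------------------------------------------------------
# stage 1: correlation filter
# ---------------------------------------------------------------------------

def correlation_filter(table: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Greedy collinearity pruning in fixed column order.

    Zero-variance columns are dropped first (with a warning); then each
    feature is kept unless its absolute Pearson correlation with an
    already-retained feature exceeds ``threshold`` (first kept wins).
    """
    if table.shape[0] < 2:
        raise ValueError("correlation filter needs at least two patients")
    variances = table.var(axis=0, ddof=0)
    cols = [c for c in table.columns if variances[c] > 0]
    if len(cols) < table.shape[1]:
        warnings.warn(f"dropped {table.shape[1] - len(cols)} zero-variance feature(s)")
    if not cols:
        return []
    corr = np.corrcoef(table[cols].to_numpy(dtype=float), rowvar=False)
    corr = np.atleast_2d(corr)
    kept: list[int] = []
    for j in range(len(cols)):
        if all(abs(corr[j, k]) <= threshold for k in kept):
            kept.append(j)
    return [cols[j] for j in kept]


# ---------------------------------------------------------------------------
# stage 2: univariate Cox screen
# ---------------------------------------------------------------------------

def univariate_cox_screen(
    table: pd.DataFrame, outcomes, alpha: float = 0.05
) -> pd.Series:
    """Per-feature single-covariate Cox fits; keep Wald p < alpha.

    Continuous feature values are used unbinned. Features whose fit does not
    converge (or with zero variance) are dropped with a warning. Returns the
    p-values of the retained features, in column order.
    """
    time, event = outcomes_to_arrays(outcomes)
    if event.sum() < 2:
        raise ValueError("univariate screen needs at least two events")
    from scipy import stats

    pvals = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        if x.std() == 0:
            warnings.warn(f"zero-variance feature {col!r} dropped from screen")
            continue
        m = ((x - x.mean()) / x.std()).reshape(-1, 1)
        try:
            beta, _, _, h = _newton_cox(m, time, event)
        except RuntimeError as exc:
            warnings.warn(f"feature {col!r} failed to converge ({exc}); dropped")
            continue
        se = float(np.sqrt(1.0 / h[0, 0]))
        p = float(2 * stats.norm.sf(abs(beta[0] / se)))
        if p < alpha:
            pvals[col] = p
    return pd.Series(pvals, dtype=float)


# ---------------------------------------------------------------------------
# stage 3: LASSO-Cox with cross-validated penalty
# ---------------------------------------------------------------------------

def _fit_coxnet(x, y, alphas):
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=alphas, normalize=False, fit_baseline_model=False,
        max_iter=500000, tol=1e-10,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, y)
    return model


def _coef_path(model, alphas) -> np.ndarray:
    """Coefficients aligned to the requested penalty grid (NaN where the
    solver truncated the path)."""
    fitted = np.asarray(model.alphas_)
    out = np.full((model.coef_.shape[0], len(alphas)), np.nan)
    for i, a in enumerate(alphas):
        j = int(np.argmin(np.abs(fitted - a)))
        if abs(fitted[j] - a) <= 1e-8 * max(a, 1e-12):
            out[:, i] = model.coef_[:, j]
    return out


def _cv_deviance(x, time, event, alphas, folds):
    """Verweij-van Houwelingen cross-validated partial-likelihood deviance.

    For fold k with coefficients beta_k fitted without it, the contribution is
    -2 * [pl_full(beta_k) - pl_without_k(beta_k)], summed over folds.
    Penalties the solver could not fit in some fold get infinite deviance.
    """
    y_all = Surv.from_arrays(event=event.astype(bool), time=time)
    dev = np.zeros(len(alphas))
    dummy = np.zeros((len(time), 1))
    for tr_idx, _ in folds:
        path = _coef_path(_fit_coxnet(x[tr_idx], y_all[tr_idx], alphas), alphas)
        for a_i in range(len(alphas)):
            beta = path[:, a_i]
            if np.any(np.isnan(beta)):
                dev[a_i] = np.inf
                continue
            eta_full = x @ beta
            ll_full, *_ = _breslow_quantities(dummy, time, event, eta_full)
            ll_train, *_ = _breslow_quantities(
                dummy[tr_idx], time[tr_idx], event[tr_idx], eta_full[tr_idx]
            )
            dev[a_i] += -2.0 * (ll_full - ll_train)
    return dev


def lasso_cox(
    table: pd.DataFrame,
    outcomes,
    cfg: SelectionConfig | None = None,
    allow_empty: bool = False,
) -> tuple[pd.Series, float, pd.DataFrame]:
    """L1-penalized Cox over a penalty path with 10-fold CV penalty choice.

    Features are standardized internally; returned coefficients are on the
    original feature scale. The path defaults to 100 log-spaced penalties
    spanning four decades down from the smallest all-zero penalty. Returns
    (beta, lambda_opt, cv_curve); raises :class:`SignatureError` if the
    cross-validation optimum selects no features (unless ``allow_empty``).
    """
    cfg = cfg or SelectionConfig()
    time, event = outcomes_to_arrays(outcomes)
    if event.sum() < cfg.cv_folds:
        raise ValueError("need at least as many events as CV folds")
    mu = table.mean(axis=0).to_numpy()
    sd = table.std(axis=0, ddof=0).to_numpy()
    if np.any(sd == 0):
        raise ValueError("zero-variance feature passed to lasso_cox")
    x = (table.to_numpy(dtype=float) - mu) / sd
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    if cfg.lambda_grid is not None:
        alphas = np.sort(np.maximum(np.asarray(cfg.lambda_grid, dtype=float), 1e-10))[::-1]
    else:
        probe = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=100, alpha_min_ratio=1e-4, normalize=False,
            fit_baseline_model=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probe.fit(x, y)
        alphas = np.asarray(probe.alphas_)

    final_path = _coef_path(_fit_coxnet(x, y, alphas), alphas)
    if len(alphas) > 1:
        kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
        dev = _cv_deviance(x, time, event, alphas, list(kf.split(x)))
        dev[np.any(np.isnan(final_path), axis=0)] = np.inf
    else:
        dev = np.zeros(1)
    best = int(np.argmin(dev))
    lambda_opt = float(alphas[best])
    beta_std = final_path[:, best]
    beta = pd.Series(beta_std / sd, index=table.columns)
    cv_curve = pd.DataFrame({"lambda": alphas, "mean_cv_deviance": dev / cfg.cv_folds})
    if not allow_empty and np.all(beta.to_numpy() == 0):
        raise SignatureError("no features selected at the cross-validated penalty")
    return beta, lambda_opt, cv_curve


# ---------------------------------------------------------------------------
# the pathomics score and the composed pipeline
# ---------------------------------------------------------------------------

def pathomics_score(model: SignatureModel, x) -> float:
    """Linear pathomics score sum(beta_i * x_i) over the selected features.

    ``x`` may be a FusedFeatureVector, a pandas Series, or a mapping from
    feature name to value; every selected feature must be present.
    """
    if hasattr(x, "names") and hasattr(x, "values"):
        lookup = dict(zip(x.names, np.asarray(x.values, dtype=float)))
    elif isinstance(x, pd.Series):
        lookup = x.to_dict()
    else:
        lookup = dict(x)
    missing = [f for f in model.selected if f not in lookup]
    if missing:
        raise ValueError(f"missing selected features: {missing}")
    return float(sum(b * float(lookup[f]) for f, b in zip(model.selected, model.beta)))


def score_table(model: SignatureModel, table: pd.DataFrame) -> pd.Series:
    """Pathomics scores for every row of a feature table."""
    missing = [f for f in model.selected if f not in table.columns]
    if missing:
        raise ValueError(f"missing selected features: {missing}")
    return table[model.selected] @ pd.Series(model.beta, index=model.selected)


def fit_signature(
    table: pd.DataFrame, outcomes, cfg: SelectionConfig | None = None
) -> SignatureModel:
    """Compose the three selection stages and fit the risk cutoff.

    correlation_filter -> univariate_cox_screen -> lasso_cox, in that order;
    the per-stage retained feature lists are recorded in the model's
    provenance. The cutoff is the log-rank-optimal split of the training
    scores (direction determined by the data: with Cox-style coefficients a
    higher score generally marks higher risk).
    """
    cfg = cfg or SelectionConfig()
    stage1 = correlation_filter(table, cfg.corr_threshold)
    if not stage1:
        raise SignatureError("no features survive the correlation filter")
    screened = univariate_cox_screen(table[stage1], outcomes, cfg.screen_alpha)
    stage2 = list(screened.index)
    if not stage2:
        raise SignatureError("no features survive the univariate Cox screen")
    beta, lambda_opt, _ = lasso_cox(table[stage2], outcomes, cfg)
    nonzero = beta[beta != 0]
    model = SignatureModel(
        endpoint=cfg.endpoint,
        selected=list(nonzero.index),
        beta=nonzero.to_numpy(),
        lambda_opt=lambda_opt,
        provenance={
            "after_correlation_filter": stage1,
            "after_univariate_screen": stage2,
            "selected": list(nonzero.index),
        },
    )
    scores = score_table(model, table)
    try:
        strat: RiskStratification = optimal_cutoff(scores.to_numpy(), outcomes)
        model.cutoff = strat.cutoff
        model.high_risk_side = strat.high_risk_side
    except Exception as exc:  # degenerate training scores: leave cutoff unset
        warnings.warn(f"risk cutoff not fitted: {exc}")
    return model
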