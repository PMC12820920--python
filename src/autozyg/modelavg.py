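"""AICc-based multimodel inference over GLMM candidate sets.

All subsets of the fixed predictors (random intercepts always retained)
are fitted, the four best-supported models by AICc are selected, and
Akaike weights over that set drive full-model (zero-substitution)
averaging: a predictor absent from a model contributes a coefficient of 0
to the average, shrinking weakly supported effects toward zero. The
adjusted standard error is the usual model-averaging estimator
sqrt(sum_i w_i (var_i + (beta_i - beta_bar)^2)), relative importance is
the summed weight of averaged models containing the predictor, and a
predictor is flagged as strongly supported when its 95% confidence
interval excludes zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import GLMMResult, ModelSpec, fit_glmm

log = logging.getLogger(__name__)

__all__ = ["ModelAverageResult", "model_average", "vif", "trait_spec"]


def trait_spec(trait: str) -> ModelSpec:
    """Canonical model specification per reproductive trait.

    Count traits (clutch size, hatching success) are Poisson with
    individual and year random intercepts, one row per female-year-clutch;
    egg volume is Gaussian per egg with individual, year and clutch random
    intercepts. Age is excluded from egg-volume models (collinear with
    generation).
    """
    if trait == "clutch_size":
        return ModelSpec(
            "clutch_size", "poisson",
            fixed=("froh", "age", "generation"),
            random=("female_id", "year"),
        )
    if trait == "hatching_success":
        return ModelSpec(
            "eggs_hatched", "poisson",
            fixed=("froh", "age", "generation"),
            random=("female_id", "year"),
        )
    if trait == "egg_volume":
        return ModelSpec(
            "egg_volume_ml", "gaussian",
            fixed=("froh", "generation"),
            random=("female_id", "year", "clutch_id"),
        )
    raise ValueError(f"unknown trait {trait!r}")


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R^2) per predictor column.

    Perfectly collinear predictors report ``inf``.
    """
    out = {}
    X = design.to_numpy(dtype=float)
    for j, name in enumerate(design.columns):
        others = np.column_stack(
            [np.ones(len(design))] + [X[:, k] for k in range(X.shape[1]) if k != j]
        )
        yj = X[:, j]
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        ss_res = np.sum(resid**2)
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class ModelAverageResult:
    """Averaged coefficients with adjusted SEs, CIs, relative importance and
    support flags, plus the candidate-model table."""

    coefficients: pd.DataFrame  # index: predictor; beta, se, ci_lo, ci_hi, ri, supported
    models: pd.DataFrame  # per candidate: terms, loglik, k, aicc, delta, weight, selected
    fits: list[GLMMResult]

    def __repr__(self) -> str:  # pragma: no cover
        return f"ModelAverageResult(\n{self.coefficients}\n)"


def model_average(
    data: pd.DataFrame,
    spec: ModelSpec,
    top_k: int = 4,
    literal_highest: bool = False,
    conditional: bool = False,
    ci_level: float = 0.95,
) -> ModelAverageResult:
    """Fit all fixed-predictor subsets of ``spec`` and average the best
    ``top_k`` by AICc.

    ``literal_highest=True`` selects the numerically largest AICc values
    instead (audit switch; these are the *worst*-supported models).
    ``conditional=True`` averages each coefficient only over models that
    contain it instead of substituting zero.
    """
    fits: list[GLMMResult] = []
    rows = []
    for r in range(len(spec.fixed) + 1):
        for terms in itertools.combinations(spec.fixed, r):
            sub = ModelSpec(spec.response, spec.family, terms, spec.random)
            fit = fit_glmm(data, sub)
            if fit.n_obs - fit.k_params - 1 <= 0:
                log.warning(
                    "model_average: dropping %s (n <= k+1)", terms or "(null)"
                )
                continue
            fits.append(fit)
            rows.append(
                {
                    "terms": "+".join(terms) or "1",
                    "loglik": fit.loglik,
                    "k": fit.k_params,
                    "aicc": fit.aicc,
                }
            )
    if not fits:
        raise ValueError("no fittable candidate models")
    table = pd.DataFrame(rows)
    order = np.argsort(table["aicc"].to_numpy(), kind="stable")
    if literal_highest:
        order = order[::-1]
    selected = order[: min(top_k, len(order))]
    sel_mask = np.zeros(len(table), dtype=bool)
    sel_mask[selected] = True
    delta = table["aicc"] - table.loc[sel_mask, "aicc"].min()
    raw_w = np.where(sel_mask, np.exp(-0.5 * delta), 0.0)
    weights = raw_w / raw_w.sum()
    table["delta"] = delta
    table["weight"] = weights
    table["selected"] = sel_mask

    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    predictors = ["(Intercept)", *spec.fixed]
    coef_rows = []
    for name in predictors:
        betas = np.zeros(len(fits))
        variances = np.zeros(len(fits))
        contains = np.zeros(len(fits), dtype=bool)
        for i, fit in enumerate(fits):
            if name in fit.beta.index:
                contains[i] = True
                betas[i] = fit.beta[name]
                variances[i] = fit.cov_beta.loc[name, name]
        w = weights.copy()
        if conditional and name != "(Intercept)":
            w = np.where(contains, w, 0.0)
            if w.sum() == 0:
                coef_rows.append(
                    {"predictor": name, "beta": np.nan, "se": np.nan,
                     "ci_lo": np.nan, "ci_hi": np.nan, "ri": 0.0,
                     "supported": False}
                )
                continue
            w = w / w.sum()
        beta_bar = float(np.sum(w * betas))
        se = float(np.sqrt(np.sum(w * (variances + (betas - beta_bar) ** 2))))
        lo, hi = beta_bar - z * se, beta_bar + z * se
        ri = float(weights[contains & sel_mask].sum()) if name != "(Intercept)" else np.nan
        coef_rows.append(
            {
                "predictor": name,
                "beta": beta_bar,
                "se": se,
                "ci_lo": lo,
                "ci_hi": hi,
                "ri": ri,
                "supported": bool(lo > 0 or hi < 0),
            }
        )
    coefficients = pd.DataFrame(coef_rows).set_index("predictor")
    return ModelAverageResult(coefficients=coefficients, models=table, fits=fits)
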