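"""Per-study regressions of biodiversity measures on environmental predictors.

Each study gets its own model ``y_i = alpha + beta * x_i + eps``: Poisson
with log link for species richness, Gaussian for log abundance and evenness.
Compositional similarity uses the pairwise distance-decay form
``logit(sorensen) ~ env_difference + log10(distance)``.

Explained variance is the squared Pearson correlation between fitted and
observed values for Gaussian fits, and the deviance pseudo-R²
``1 - dev/null_dev`` for Poisson fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

GAUSSIAN = "gaussian"
POISSON = "poisson-log"

_VAR_TOL = 1e-12


@dataclass
class FitResult:
    """A fitted per-study model.

    ``beta`` has one entry for single-predictor measures and two
    (environmental difference, log distance) for composition.
    """

    measure: str
    predictor: str
    family: str
    alpha: float = np.nan
    beta: tuple = ()
    se: tuple = ()
    r2: float = np.nan
    n_obs: int = 0
    degenerate: bool = False
    degenerate_reason: str = ""
    study_id: str = ""


def fit_measure_model(y: Sequence[float], x: Sequence[float], family: str,
                      measure: str = "", predictor: str = "",
                      study_id: str = "") -> FitResult:
    """Fit one measure against one predictor by maximum likelihood."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x):
        raise ValueError("y and x must have equal length")
    if len(y) < 3:
        raise ValueError(f"need >= 3 observations, got {len(y)}")
    if family not in (GAUSSIAN, POISSON):
        raise ValueError(f"unknown family {family!r}")

    result = FitResult(measure=measure, predictor=predictor, family=family,
                       n_obs=len(y), study_id=study_id)
    if np.var(x) < _VAR_TOL:
        result.degenerate = True
        result.degenerate_reason = "zero-variance predictor"
        return result

    design = sm.add_constant(x)
    if family == POISSON:
        if not np.allclose(y, np.round(y), atol=1e-8):
            raise ValueError("Poisson family requires integer responses")
        with warnings.catch_warnings():
            # constant responses trigger a perfect-separation note; the fit
            # itself is well defined (slope ~ 0)
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, design, family=sm.families.Poisson()).fit()
        r2 = (1.0 - fit.deviance / fit.null_deviance
              if fit.null_deviance > 0 else 0.0)
    else:
        fit = sm.OLS(y, design).fit()
        fitted = fit.fittedvalues
        if np.var(fitted) < _VAR_TOL or np.var(y) < _VAR_TOL:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)

    result.alpha = float(fit.params[0])
    result.beta = (float(fit.params[1]),)
    result.se = (float(fit.bse[1]),)
    result.r2 = float(np.clip(r2, 0.0, 1.0))
    return result


def fit_composition_model(pairs, which_predictor: str,
                          study_id: str = "") -> FitResult:
    """Distance-decay model of pairwise similarity.

    ``pairs`` needs columns ``sim_logit``, ``log_dist`` and the environmental
    difference column selected by ``which_predictor`` (``"evi"`` uses
    ``abs_evi_diff``, ``"specvar"`` uses ``centroid_dist``).
    """
    env_col = {"evi": "abs_evi_diff", "specvar": "centroid_dist"}[which_predictor]
    if len(pairs) < 4:
        raise ValueError(f"need >= 4 pairs, got {len(pairs)}")
    y = pairs["sim_logit"].to_numpy(dtype=float)
    env = pairs[env_col].to_numpy(dtype=float)
    dist = pairs["log_dist"].to_numpy(dtype=float)

    result = FitResult(measure="composition", predictor=which_predictor,
                       family=GAUSSIAN, n_obs=len(y), study_id=study_id)
    if np.var(env) < _VAR_TOL or np.var(dist) < _VAR_TOL:
        result.degenerate = True
        result.degenerate_reason = "zero-variance predictor"
        return result
    corr = np.corrcoef(env, dist)[0, 1]
    if abs(corr) > 1.0 - 1e-10:
        result.degenerate = True
        result.degenerate_reason = "collinear predictors"
        return result

    design = sm.add_constant(np.column_stack([env, dist]))
    fit = sm.OLS(y, design).fit()
    result.alpha = float(fit.params[0])
    result.beta = (float(fit.params[1]), float(fit.params[2]))
    result.se = (float(fit.bse[1]), float(fit.bse[2]))
    fitted = fit.fittedvalues
    if np.var(fitted) < _VAR_TOL or np.var(y) < _VAR_TOL:
        result.r2 = 0.0
    else:
        result.r2 = float(np.clip(np.corrcoef(fitted, y)[0, 1] ** 2, 0.0, 1.0))
    return result


def predict_measure(fit: FitResult, x_new) -> np.ndarray:
    """Response-scale predictions from a fitted model.

    For composition, ``x_new`` is an (n, 2) array of (environmental
    difference, log distance); otherwise a 1-d predictor vector.  Poisson
    predictions are ``exp(alpha + beta x)``; Gaussian predictions stay on
    the (transformed) measure scale.
    """
    if fit.degenerate:
        raise ValueError(f"cannot predict from degenerate fit: "
                         f"{fit.degenerate_reason}")
    x_new = np.asarray(x_new, dtype=float)
    if len(fit.beta) == 2:
        if x_new.ndim != 2 or x_new.shape[1] != 2:
            raise ValueError("composition fits need (n, 2) predictors")
        eta = fit.alpha + x_new @ np.asarray(fit.beta)
    else:
        eta = fit.alpha + fit.beta[0] * x_new
    if fit.family == POISSON:
        return np.exp(eta)
    return eta
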