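"""Meta-regression: which study properties explain prediction error?

Per-study mean sMAPE is modelled as ``smape_j = a + a_k + b x_j + eps`` with
a random intercept ``a_k`` for the methodology group, pooling studies of
comparable methodology.  Covariates (sampling extent, duration, number of
sites, per-site sampling effort, accessibility, missing-data fraction,
terrain ruggedness) are standardized to mean 0 / SD 1 so coefficients are
comparable across units.

All covariate subsets (plus an extent x effort interaction, included only
with both main effects) are fitted by maximum likelihood, ranked by AICc,
and the best 5% averaged with equal weights, treating a term absent from a
model as a zero coefficient (full averaging).  Variance explained is
reported as marginal R² (fixed effects only) and conditional R² (fixed plus
random effects) of the full model.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

META_COVARIATES = ["extent", "duration", "n_sites", "effort",
                   "accessibility", "missing_frac", "ruggedness"]
INTERACTION = ("extent", "effort")
TOP_FRAC = 0.05


def build_meta_design(
    errors: pd.DataFrame,
    studies: pd.DataFrame,
    sites: pd.DataFrame,
    predictors: pd.DataFrame,
    groups: pd.DataFrame,
    mode: str = "transferability",
    measure: Optional[str] = None,
) -> pd.DataFrame:
    """Assemble the per-study design table for the meta-regression.

    The response is the study's mean sMAPE over permutation sets (and over
    measures and predictors unless ``measure`` restricts it) for the given
    ``mode``.  Covariates are raw (unstandardized) study properties; call
    :func:`standardize` before fitting.
    """
    sel = errors[errors["mode"] == mode]
    if measure is not None:
        sel = sel[sel["measure"] == measure]
    if sel.empty:
        raise ValueError(f"no error records for mode={mode!r}")
    response = sel.groupby("study_id")["smape"].mean().rename("smape")

    per_study = sites.groupby("study_id").agg(
        extent=("extent_m", "median"),
        n_sites=("site_id", "size"),
        effort=("sampling_effort", "mean"))
    missing = predictors.groupby("study_id")["missing_frac"].mean()

    design = (studies.set_index("study_id")
              [["duration_days", "accessibility_m", "ruggedness"]]
              .rename(columns={"duration_days": "duration",
                               "accessibility_m": "accessibility"})
              .join(per_study).join(missing.rename("missing_frac"))
              .join(response, how="inner")
              .join(groups.set_index("study_id")["group_id"]))
    design["missing_frac"] = design["missing_frac"].fillna(0.0)
    return design.reset_index()[["study_id", "group_id", "smape"]
                                + META_COVARIATES]


def standardize(design: pd.DataFrame,
                covariates: Sequence[str] = META_COVARIATES) -> pd.DataFrame:
    """Standardize covariates to mean 0 / SD 1; drop constant columns."""
    out = design.copy()
    for col in covariates:
        if col not in out.columns:
            continue
        sd = out[col].std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"dropping zero-variance covariate {col!r}")
            out = out.drop(columns=[col])
            continue
        out[col] = (out[col] - out[col].mean()) / out[col].std(ddof=0)
    return out


def fit_random_intercept_lmm(design: pd.DataFrame, response: str,
                             covariates: Sequence[str], group: str,
                             reml: bool = True):
    """REML (or ML) fit of ``response ~ covariates + (1 | group)``.

    With a single group level, partial pooling is impossible and the model
    degrades to ordinary least squares (a warning is emitted; the returned
    object then has no random-effect variance).
    """
    y = design[response].to_numpy(dtype=float)
    x = sm.add_constant(design[list(covariates)].to_numpy(dtype=float)) \
        if covariates else np.ones((len(design), 1))
    if design[group].nunique() < 2:
        warnings.warn("single methodology group: falling back to OLS")
        return sm.OLS(y, x).fit()
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        return _fit_mixed(y, x, design[group].to_numpy(), reml)



def _fit_mixed(y, x, grp, reml: bool):
    """MixedLM fit with an optimizer fallback chain."""
    model = sm.MixedLM(y, x, groups=grp)
    last = None
    for kwargs in ({}, {"method": "powell"}, {"method": "lbfgs"}):
        try:
            return model.fit(reml=reml, maxiter=300, **kwargs)
        except Exception as exc:  # singular profile likelihood, etc.
            last = exc
    raise last


def aicc(llf: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        return math.inf
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def r2_from_variances(var_fixed: float, var_group: float,
                      var_resid: float) -> Tuple[float, float]:
    """Marginal and conditional R² from a variance partition."""
    total = var_fixed + var_group + var_resid
    if total <= 0:
        return 0.0, 0.0
    return var_fixed / total, (var_fixed + var_group) / total


def r2_mixed(fit) -> Tuple[float, float]:
    """Variance-partition R² of a fitted random-intercept model.

    Marginal: variance of the fixed-effect predictor over (fixed + group +
    residual) variance; conditional adds the random-intercept variance to
    the numerator.
    """
    if hasattr(fit, "cov_re"):  # MixedLM
        eta = fit.model.exog @ fit.fe_params
        var_fixed = float(np.var(eta))
        var_group = float(np.asarray(fit.cov_re)[0, 0])
        var_resid = float(fit.scale)
    else:  # OLS fallback
        var_fixed = float(np.var(fit.fittedvalues))
        var_group = 0.0
        var_resid = float(fit.mse_resid)
    return r2_from_variances(var_fixed, var_group, var_resid)


@dataclass
class AveragedModel:
    """Equal-weight average of the top-AICc candidate models."""

    coefficients: Dict[str, float]
    ranks: pd.DataFrame
    n_candidates: int
    n_selected: int
    r2_marginal: float
    r2_conditional: float


def _candidate_terms(covariates: Sequence[str],
                     interaction: Optional[Tuple[str, str]]) -> List[Tuple[str, ...]]:
    cands: List[Tuple[str, ...]] = []
    for r in range(len(covariates) + 1):
        for subset in itertools.combinations(covariates, r):
            cands.append(subset)
            if (interaction and interaction[0] in subset
                    and interaction[1] in subset):
                cands.append(subset + (f"{interaction[0]}:{interaction[1]}",))
    return cands


def _design_matrix(design: pd.DataFrame, terms: Tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(design))]
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append((design[a] * design[b]).to_numpy(dtype=float))
        else:
            cols.append(design[t].to_numpy(dtype=float))
    return np.column_stack(cols)


def subset_average(
    design: pd.DataFrame,
    response: str = "smape",
    covariates: Sequence[str] = META_COVARIATES,
    group: str = "group_id",
    interaction: Optional[Tuple[str, str]] = INTERACTION,
    top_frac: float = TOP_FRAC,
) -> AveragedModel:
    """All-subsets mixed-model fitting, AICc ranking and top-5% averaging.

    Candidate models are every subset of the standardized covariates (the
    extent x effort interaction only alongside both main effects), each with
    a random intercept for the methodology group, fitted by maximum
    likelihood for AICc comparability.  The best ``ceil(top_frac * M)``
    models are refit by REML and their coefficients averaged with equal
    weights, counting a covariate absent from a model as zero.  R² values
    come from the REML fit of the full model.
    """
    covariates = [c for c in covariates if c in design.columns]
    if interaction and not all(c in covariates for c in interaction):
        interaction = None
    candidates = _candidate_terms(covariates, interaction)
    if not candidates:
        raise ValueError("no candidate models")

    y = design[response].to_numpy(dtype=float)
    grp = design[group].to_numpy()
    n = len(design)
    single_group = design[group].nunique() < 2

    records = []
    for terms in candidates:
        x = _design_matrix(design, terms)
        try:
            with warnings.catch_warnings(), np.errstate(all="ignore"):
                warnings.simplefilter("ignore")
                if single_group:
                    fit = sm.OLS(y, x).fit()
                    k = x.shape[1] + 1
                else:
                    fit = _fit_mixed(y, x, grp, reml=False)
                    k = x.shape[1] + 2  # + group variance + residual variance
                llf = float(fit.llf)  # lazy in statsmodels; keep it quiet here
        except Exception:
            continue
        if not np.isfinite(llf):
            continue
        records.append({"terms": terms, "llf": llf, "k": k,
                        "aicc": aicc(llf, k, n)})
    if not records:
        raise ValueError("no candidate model could be fitted")

    ranks = (pd.DataFrame(records).sort_values("aicc", kind="mergesort")
             .reset_index(drop=True))
    ranks["rank"] = np.arange(1, len(ranks) + 1)
    n_selected = max(1, math.ceil(top_frac * len(ranks)))
    selected = ranks.head(n_selected)

    all_terms = covariates + ([f"{interaction[0]}:{interaction[1]}"]
                              if interaction else [])
    sums = {t: 0.0 for t in all_terms}
    sums["intercept"] = 0.0
    for terms in selected["terms"]:
        x = _design_matrix(design, terms)
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            if single_group:
                fit = sm.OLS(y, x).fit()
                params = fit.params
            else:
                try:
                    fit = _fit_mixed(y, x, grp, reml=True)
                except Exception:  # REML refit failed; keep the ML estimates
                    fit = _fit_mixed(y, x, grp, reml=False)
                params = fit.fe_params
        sums["intercept"] += float(params[0])
        for i, t in enumerate(terms):
            sums[t] += float(params[i + 1])
    coefficients = {t: v / n_selected for t, v in sums.items()}

    # R² from the full model; if it cannot be fitted (more parameters than
    # studies), fall back to the best-ranked candidate
    full_terms = candidates[-1] if interaction else tuple(covariates)
    r2m = r2c = np.nan
    for terms in (full_terms, tuple(ranks.iloc[0]["terms"])):
        try:
            with warnings.catch_warnings(), np.errstate(all="ignore"):
                warnings.simplefilter("ignore")
                x_t = _design_matrix(design, terms)
                if single_group:
                    fit = sm.OLS(y, x_t).fit()
                else:
                    fit = _fit_mixed(y, x_t, grp, reml=True)
            r2m, r2c = r2_mixed(fit)
            break
        except Exception:
            continue

    return AveragedModel(coefficients=coefficients, ranks=ranks,
                         n_candidates=len(ranks), n_selected=n_selected,
                         r2_marginal=r2m, r2_conditional=r2c)
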