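"""Environmental predictors from multi-band monthly reflectance series.

Two per-site predictors are derived from the 12 months of 7-band reflectance
preceding biodiversity sampling:

* mean photosynthetic activity — the arithmetic mean of the two-band
  Enhanced Vegetation Index, ``EVI2 = 2.5 (NIR - red) / (NIR + 2.4 red + 1)``,
* spectral variability — site-months are pooled per study, bands centred and
  scaled, projected on the first two principal components; each site's
  variability is the mean Euclidean distance of its 12 monthly scores to
  their centroid (the centroid itself is kept for pairwise comparisons).

Before the window is selected, missing months are imputed with a Kalman
smoother (a local level + trend state-space model fitted per site and band
by maximum likelihood), falling back to linear interpolation when the
likelihood optimization does not converge.  Only gap runs of at most four
consecutive months are filled; sites with six or more missing months, or
with an unfillable run, are excluded with a recorded reason.
"""

from __future__ import annotations

import warnings
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from ecotransfer.simulate import N_BANDS, RED_BAND, NIR_BAND

#: runs of more than this many consecutive missing months are not filled
MAX_FILL_RUN = 4
#: sites with at least this many missing months are excluded
EXCLUDE_MISSING_MONTHS = 6


def monthly_aggregate(raw: pd.DataFrame) -> pd.DataFrame:
    """Aggregate sub-monthly observations to monthly means per site/band.

    ``raw`` needs columns ``site_id, month_index, band, reflectance`` where
    several rows may share a (site, month, band).  Months with no
    observations for a site are emitted as missing (NaN) so the series stays
    regular.
    """
    agg = (raw.dropna(subset=["reflectance"])
              .groupby(["site_id", "month_index", "band"], as_index=False)
              ["reflectance"].mean())
    months = np.arange(raw["month_index"].min(), raw["month_index"].max() + 1)
    full = pd.MultiIndex.from_product(
        [sorted(raw["site_id"].unique()), months, range(1, N_BANDS + 1)],
        names=["site_id", "month_index", "band"])
    out = (agg.set_index(["site_id", "month_index", "band"])
              .reindex(full).reset_index())
    return out


def _gap_runs(missing: np.ndarray) -> list[Tuple[int, int]]:
    """(start_index, length) of each run of True in a boolean vector."""
    runs, start = [], None
    for i, m in enumerate(missing):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(missing) - start))
    return runs


def _kalman_fill(y: np.ndarray) -> Tuple[np.ndarray, bool]:
    """Smoothed signal from a local level + trend model; (values, converged)."""
    from statsmodels.tsa.statespace.structural import UnobservedComponents

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = UnobservedComponents(y, level="local linear trend")
            res = model.fit(method="lbfgs", maxiter=100, disp=0)
            converged = bool(res.mle_retvals.get("converged", False))
            smoothed = np.asarray(res.smoothed_state[0])
            if not np.all(np.isfinite(smoothed)):
                return y, False
            return smoothed, converged
        except Exception:
            return y, False


def _linear_fill(y: np.ndarray) -> np.ndarray:
    idx = np.arange(len(y))
    ok = np.isfinite(y)
    return np.interp(idx, idx[ok], y[ok])


def impute_gaps(series: pd.DataFrame,
                method: str = "kalman") -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing months per site/band; exclude sites with heavy gaps.

    Returns ``(filled_series, exclusions)`` where ``exclusions`` has columns
    ``site_id, reason``.  A site is excluded when it has six or more missing
    months in total, or a run of five or more consecutive missing months
    (only runs of up to four months are filled).  ``method`` is ``"kalman"``
    (state-space smoother with linear fallback) or ``"linear"``.
    """
    months = np.sort(series["month_index"].unique())
    if len(months) < 13:
        raise ValueError(f"series has {len(months)} months; need >= 13")

    wide = series.pivot_table(index=["site_id", "band"], columns="month_index",
                              values="reflectance", dropna=False)
    wide = wide.reindex(columns=months)

    filled_parts, exclusions = [], []
    for site_id in wide.index.get_level_values("site_id").unique():
        block = wide.loc[site_id].to_numpy()  # bands x months
        missing = ~np.isfinite(block).all(axis=0)
        n_missing = int(missing.sum())
        runs = _gap_runs(missing)
        if n_missing >= EXCLUDE_MISSING_MONTHS:
            exclusions.append({"site_id": site_id,
                               "reason": "ge6_missing_months"})
            continue
        if any(length > MAX_FILL_RUN for _, length in runs):
            exclusions.append({"site_id": site_id,
                               "reason": "gap_run_over_4_months"})
            continue
        out_block = block.copy()
        if n_missing:
            for b in range(out_block.shape[0]):
                y = out_block[b]
                if method == "kalman":
                    smoothed, converged = _kalman_fill(y)
                    fill = smoothed if converged else _linear_fill(y)
                else:
                    fill = _linear_fill(y)
                y[~np.isfinite(y)] = fill[~np.isfinite(y)]
        filled_parts.append(pd.DataFrame({
            "site_id": site_id,
            "month_index": np.repeat(months, out_block.shape[0]),
            "band": np.tile(np.arange(1, out_block.shape[0] + 1), len(months)),
            "reflectance": out_block.T.ravel(),
        }))

    filled = (pd.concat(filled_parts, ignore_index=True) if filled_parts
              else series.iloc[0:0].copy())
    return filled, pd.DataFrame(exclusions, columns=["site_id", "reason"])


def select_window(series: pd.DataFrame, starts: pd.Series) -> pd.DataFrame:
    """Keep, per site, the 12 calendar months preceding sampling start.

    ``starts`` maps site_id to the sampling start month; the returned window
    covers months ``start-12 .. start-1``.  Raises if a site's series does
    not cover the full window.
    """
    parts = []
    for site_id, grp in series.groupby("site_id", sort=True):
        start = int(starts[site_id])
        lo, hi = start - 12, start - 1
        window = grp[(grp["month_index"] >= lo) & (grp["month_index"] <= hi)]
        n_months = window["month_index"].nunique()
        if lo < 1 or n_months < 12:
            raise ValueError(
                f"site {site_id!r}: series does not cover the 12 months "
                f"before sampling start month {start}")
        parts.append(window)
    return pd.concat(parts, ignore_index=True)


def evi2(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    """Two-band Enhanced Vegetation Index."""
    nir, red = np.asarray(nir, float), np.asarray(red, float)
    denom = nir + 2.4 * red + 1.0
    if np.any(denom <= 0):
        raise ValueError("EVI2 denominator <= 0; corrupt reflectance values")
    return 2.5 * (nir - red) / denom


def evi2_mean(window: pd.DataFrame) -> pd.Series:
    """Per-site mean EVI2 over a gap-filled 12-month window."""
    wide = window.pivot_table(index=["site_id", "month_index"],
                              columns="band", values="reflectance")
    values = evi2(wide[NIR_BAND].to_numpy(), wide[RED_BAND].to_numpy())
    return (pd.Series(values, index=wide.index, name="evi_mean")
              .groupby("site_id").mean())


def spectral_variability(window: pd.DataFrame,
                         standardize: bool = True) -> pd.DataFrame:
    """Per-site spectral variability from a study-wide PCA.

    All site-months of the study are pooled into an (observations x 7 bands)
    matrix, centred (and scaled unless ``standardize=False``), and projected
    on the first two principal components.  Per site: ``pc_centroid`` is the
    mean score of its months and ``spectral_variability`` the mean Euclidean
    distance of its monthly scores to that centroid.  ``pct_var_2pc`` is the
    variance fraction captured by the two components (in percent).
    """
    wide = window.pivot_table(index=["site_id", "month_index"],
                              columns="band", values="reflectance")
    if len(wide) < 3:
        raise ValueError("need at least 3 pooled site-months for a PCA")
    x = wide.to_numpy()
    if standardize:
        x = StandardScaler().fit_transform(x)
    else:
        x = x - x.mean(axis=0)
    pca = PCA(n_components=2)
    with np.errstate(invalid="ignore"):  # zero-variance input is legal here
        scores = pca.fit_transform(x)
    total_var = float(np.var(x, axis=0, ddof=1).sum())
    if total_var > 0:
        pct = float(100.0 * pca.explained_variance_ratio_.sum())
    else:
        pct = 100.0  # degenerate: no variance at all, trivially captured

    site_ids = wide.index.get_level_values("site_id")
    rows = []
    for sid in site_ids.unique():
        s = scores[site_ids == sid]
        centroid = s.mean(axis=0)
        dist = np.linalg.norm(s - centroid, axis=1).mean()
        rows.append({"site_id": sid,
                     "spectral_variability": float(dist),
                     "pc1_centroid": float(centroid[0]),
                     "pc2_centroid": float(centroid[1]),
                     "pct_var_2pc": pct})
    return pd.DataFrame(rows)


def site_predictors(spectra: pd.DataFrame, sites: pd.DataFrame,
                    impute_method: str = "kalman") -> pd.DataFrame:
    """Full predictor pipeline: impute, window, EVI2 mean, spectral variability.

    Returns one row per site with ``evi_mean``, ``spectral_variability``,
    ``pc1_centroid``, ``pc2_centroid``, ``pct_var_2pc``, ``missing_frac``
    (fraction of missing months before gap filling) and ``excluded`` /
    ``exclusion_reason`` flags.  The PCA is fitted per study.
    """
    n_months = spectra["month_index"].nunique()
    miss = (spectra.assign(miss=spectra["reflectance"].isna())
                   .groupby(["site_id", "month_index"])["miss"].all()
                   .groupby("site_id").mean())
    filled, excl = impute_gaps(spectra, method=impute_method)
    excl = excl.set_index("site_id")["reason"] if len(excl) else pd.Series(dtype=object)

    rows = []
    starts = sites.set_index("site_id")["sampling_start_month"]
    for study_id, grp in sites.groupby("study_id", sort=True):
        keep = [sid for sid in grp["site_id"] if sid not in excl.index]
        if not keep:
            continue
        sub = filled[filled["site_id"].isin(keep)]
        window = select_window(sub, starts)
        evi = evi2_mean(window)
        sv = spectral_variability(window).set_index("site_id")
        for sid in keep:
            rows.append({
                "site_id": sid, "study_id": study_id,
                "evi_mean": float(evi[sid]),
                "spectral_variability": float(sv.at[sid, "spectral_variability"]),
                "pc1_centroid": float(sv.at[sid, "pc1_centroid"]),
                "pc2_centroid": float(sv.at[sid, "pc2_centroid"]),
                "pct_var_2pc": float(sv.at[sid, "pct_var_2pc"]),
                "missing_frac": float(miss.get(sid, 0.0)),
                "excluded": False, "exclusion_reason": "",
            })
    site_study = sites.set_index("site_id")["study_id"]
    for sid, reason in excl.items():
        rows.append({"site_id": sid, "study_id": site_study[sid],
                     "evi_mean": np.nan, "spectral_variability": np.nan,
                     "pc1_centroid": np.nan, "pc2_centroid": np.nan,
                     "pct_var_2pc": np.nan,
                     "missing_frac": float(miss.get(sid, 0.0)),
                     "excluded": True, "exclusion_reason": reason})
    out = pd.DataFrame(rows)
    return out.sort_values("site_id").reset_index(drop=True)


def pairwise_env_diff(predictors: pd.DataFrame,
                      pairs: pd.DataFrame) -> pd.DataFrame:
    """Attach absolute EVI difference and centroid distance to site pairs.

    Both members of a pair must be non-excluded sites of the same study (the
    centroid coordinates only compare within one study's PCA space); pairs
    with an excluded member are dropped.
    """
    pred = predictors.set_index("site_id")
    rows = []
    for _, pair in pairs.iterrows():
        si, sj = pair["site_i"], pair["site_j"]
        if si not in pred.index or sj not in pred.index:
            continue
        a, b = pred.loc[si], pred.loc[sj]
        if a["study_id"] != b["study_id"]:
            raise ValueError(f"pair ({si!r}, {sj!r}) spans two studies")
        if a["excluded"] or b["excluded"]:
            continue
        row = dict(pair)
        row["abs_evi_diff"] = abs(a["evi_mean"] - b["evi_mean"])
        row["centroid_dist"] = float(np.hypot(
            a["pc1_centroid"] - b["pc1_centroid"],
            a["pc2_centroid"] - b["pc2_centroid"]))
        rows.append(row)
    cols = list(pairs.columns) + ["abs_evi_diff", "centroid_dist"]
    return pd.DataFrame(rows, columns=cols)
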