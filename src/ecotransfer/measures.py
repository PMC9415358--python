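"""Site-based biodiversity measures and pairwise compositional similarity.

Four measures per site ``i`` of study ``j``:

* species richness ``S_i`` (count of taxa with positive measurement),
* total abundance on the ``log10(A_i + 1)`` scale,
* assemblage evenness as the arcsine-square-root transformed probability of
  interspecific encounter (Hurlbert's PIE with the ``N/(N-1)`` correction),
* pairwise Sørensen similarity between sites, logit transformed, together
  with the log10 great-circle distance used by distance-decay models.

Abundances are assumed to scale linearly with sampling effort, so studies
whose effort varies among sites are rescaled to the maximum-effort site
before abundance is computed.  PIE is computed on raw counts (it is a
function of individual counts, which effort rescaling would distort).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
#: clamp applied to Sørensen similarity before the logit transform
LOGIT_EPS = 1e-3
#: offset (km) added to great-circle distance before log10
DIST_OFFSET_KM = 0.05


def fill_missing_extents(sites: pd.DataFrame, studies: pd.DataFrame) -> pd.DataFrame:
    """Fill missing site sampling extents from comparable studies.

    Missing values are replaced by the mean extent over studies sharing, in
    fallback order: sampling method AND taxon group; method only; taxon only;
    finally the global mean.  The level used is recorded in a new
    ``extent_fill_level`` column (``"observed"`` for non-missing values).
    """
    out = sites.merge(
        studies[["study_id", "sampling_method", "taxon_group"]],
        on="study_id", how="left", validate="many_to_one")
    if out["extent_m"].isna().all():
        raise ValueError("all sampling extents are missing; nothing to average")

    obs = out[out["extent_m"].notna()]
    global_mean = obs["extent_m"].mean()
    by_mt = obs.groupby(["sampling_method", "taxon_group"])["extent_m"].mean()
    by_m = obs.groupby("sampling_method")["extent_m"].mean()
    by_t = obs.groupby("taxon_group")["extent_m"].mean()

    level = np.where(out["extent_m"].notna(), "observed", "global").astype(object)
    filled = out["extent_m"].to_numpy(copy=True)
    for idx in np.nonzero(out["extent_m"].isna().to_numpy())[0]:
        method = out.at[idx, "sampling_method"]
        taxon = out.at[idx, "taxon_group"]
        if (method, taxon) in by_mt.index:
            filled[idx], level[idx] = by_mt[(method, taxon)], "method+taxon"
        elif method in by_m.index:
            filled[idx], level[idx] = by_m[method], "method"
        elif taxon in by_t.index:
            filled[idx], level[idx] = by_t[taxon], "taxon"
        else:
            filled[idx], level[idx] = global_mean, "global"

    result = sites.copy()
    result["extent_m"] = filled
    result["extent_fill_level"] = level
    return result


def effort_correct(assemblage: pd.DataFrame, sites: pd.DataFrame,
                   studies: pd.DataFrame) -> pd.DataFrame:
    """Rescale abundances of unequal-effort studies to the maximum effort.

    Within each abundance study whose sampling effort varies among sites,
    measurements are divided by the site's effort rescaled to the study
    maximum, so the maximum-effort site is unchanged and lower-effort sites
    are scaled up.  Occurrence studies and equal-effort studies pass through
    unchanged.
    """
    effort = sites.set_index("site_id")["sampling_effort"]
    if (effort <= 0).any():
        bad = effort[effort <= 0].index[0]
        raise ValueError(f"non-positive sampling effort at site {bad!r}")

    site_study = sites.set_index("site_id")["study_id"]
    is_abund = studies.set_index("study_id")["is_abundance"]
    max_effort = (sites.groupby("study_id")["sampling_effort"].max())

    out = assemblage.copy()
    study_of_row = out["site_id"].map(site_study)
    rel_effort = (out["site_id"].map(effort)
                  / study_of_row.map(max_effort)).to_numpy()
    varies = sites.groupby("study_id")["sampling_effort"].nunique() > 1
    apply_row = (study_of_row.map(is_abund) & study_of_row.map(varies)).to_numpy()
    vals = out["measurement"].to_numpy(copy=True)
    vals[apply_row] = vals[apply_row] / rel_effort[apply_row]
    out["measurement"] = vals
    return out


def hurlbert_pie(counts: np.ndarray) -> float:
    """Hurlbert's probability of interspecific encounter.

    ``PIE = N/(N-1) * (1 - sum((n_s/N)^2))`` — the probability that two
    individuals drawn without replacement belong to different species.
    Defined as 0 when the total count ``N <= 1``.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n_total = counts.sum()
    if n_total <= 1:
        return 0.0
    p = counts / n_total
    return float(n_total / (n_total - 1.0) * (1.0 - np.sum(p ** 2)))


def site_measures(assemblage: pd.DataFrame, raw_assemblage: pd.DataFrame,
                  sites: pd.DataFrame, studies: pd.DataFrame) -> pd.DataFrame:
    """Compute per-site richness, log abundance and evenness.

    ``assemblage`` is the effort-corrected table (drives abundance);
    ``raw_assemblage`` the uncorrected one (drives PIE).  Sites with no
    records get ``S = 0``, ``logA = 0`` and evenness flagged invalid
    (undefined by convention).  Occurrence-only studies have ``logA`` and
    evenness flagged invalid.
    """
    if (assemblage["measurement"] < 0).any():
        raise ValueError("negative measurements in assemblage table")

    is_abund = studies.set_index("study_id")["is_abundance"]
    pos = assemblage[assemblage["measurement"] > 0]
    richness = pos.groupby("site_id")["taxon_id"].nunique()
    total = assemblage.groupby("site_id")["measurement"].sum()
    pie_by_site = {
        sid: hurlbert_pie(grp["measurement"].to_numpy())
        for sid, grp in raw_assemblage.groupby("site_id")
    }

    rows = []
    for _, site in sites.iterrows():
        sid = site["site_id"]
        abund_study = bool(is_abund[site["study_id"]])
        s = int(richness.get(sid, 0))
        a = float(total.get(sid, 0.0))
        pie = pie_by_site.get(sid, 0.0)
        rows.append({
            "site_id": sid,
            "study_id": site["study_id"],
            "S": s,
            "logA": float(np.log10(a + 1.0)) if abund_study else np.nan,
            "evenness": float(np.arcsin(np.sqrt(np.clip(pie, 0.0, 1.0))))
            if abund_study else np.nan,
            "valid_abundance": abund_study,
            "valid_evenness": abund_study and s > 0,
        })
    return pd.DataFrame(rows)


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine great-circle distance (km) on a sphere of radius 6371 km."""
    lat1, lon1, lat2, lon2 = (np.asarray(v, dtype=float)
                              for v in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude out of range [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180.0):
            raise ValueError("longitude out of range [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def sorensen(taxa_i: set, taxa_j: set) -> float:
    """Sørensen similarity 2a/(2a+b+c) on presence/absence sets."""
    a = len(taxa_i & taxa_j)
    b = len(taxa_i - taxa_j)
    c = len(taxa_j - taxa_i)
    if 2 * a + b + c == 0:
        return 0.0
    return 2.0 * a / (2.0 * a + b + c)


def logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def pairwise_composition(assemblage: pd.DataFrame,
                         sites: pd.DataFrame) -> pd.DataFrame:
    """All unordered within-study site pairs with similarity and distance.

    Sørensen similarity is computed on binarized data (presence/absence) and
    clamped to ``[eps, 1-eps]`` before the logit; distance enters as
    ``log10(gc_km + 0.05)``.  Studies with fewer than 2 sites contribute no
    pairs.
    """
    pos = assemblage[assemblage["measurement"] > 0]
    taxa_by_site = pos.groupby("site_id")["taxon_id"].agg(set).to_dict()
    coords = sites.set_index("site_id")[["lat", "lon"]]

    rows = []
    for study_id, grp in sites.groupby("study_id", sort=True):
        ids = sorted(grp["site_id"])
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                si, sj = ids[i], ids[j]
                sim = sorensen(taxa_by_site.get(si, set()),
                               taxa_by_site.get(sj, set()))
                sim_c = min(max(sim, LOGIT_EPS), 1.0 - LOGIT_EPS)
                gc = float(great_circle_km(coords.at[si, "lat"],
                                           coords.at[si, "lon"],
                                           coords.at[sj, "lat"],
                                           coords.at[sj, "lon"]))
                rows.append({
                    "study_id": study_id, "site_i": si, "site_j": sj,
                    "sorensen": sim, "sim_logit": logit(sim_c),
                    "gc_km": gc,
                    "log_dist": float(np.log10(gc + DIST_OFFSET_KM)),
                })
    return pd.DataFrame(rows, columns=["study_id", "site_i", "site_j",
                                       "sorensen", "sim_logit", "gc_km",
                                       "log_dist"])
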