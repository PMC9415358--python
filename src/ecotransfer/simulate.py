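"""Synthetic biodiversity-database generator.

Emulates the hierarchical structure of global site-based biodiversity
databases: *studies* with their own sampling methodology, species pool and
biodiversity-environment relationship, each containing spatially clustered
*sites* at which species assemblages were sampled with study-specific effort.

The generating model plants recoverable parameters at every level:

* study ``j`` draws an intercept ``alpha_j`` and slope ``beta_j``; the log
  expected abundance of species ``s`` at site ``i`` is
  ``alpha_j + beta_j * v_i + gamma_js`` where ``v_i`` is the site's latent
  mean vegetation signal and ``gamma_js`` a per-species offset,
* realized counts are Poisson draws thinned binomially with detection
  probability ``1 - exp(-detection_rate * samples_per_site)``,
* seven monthly reflectance bands are built so that the two-band vegetation
  index EVI2 of (NIR, red) equals the site's latent seasonal vegetation
  signal plus noise, with whole months masked missing at random.

Because every quantity downstream of the generator (measures, predictors,
regressions, cross-validation errors) has a planted counterpart, the whole
pipeline is testable without external data.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from ecotransfer.config import SimConfig

N_BANDS = 7
#: MODIS land-band convention: band 1 = red, band 2 = NIR
RED_BAND, NIR_BAND = 1, 2

_TAXA = ["birds", "plants", "insects", "mammals", "fungi", "reptiles",
         "amphibians", "spiders"]
_METHODS = ["point_counts", "transects", "pitfall_traps", "quadrats",
            "flight_traps", "soil_cores"]
_UNITS = ["individuals", "occurrence", "area"]

# loadings of the five nuisance bands (3..7) on the latent vegetation signal
_NUISANCE_BASE = np.array([0.05, 0.30, 0.25, 0.20, 0.15])
_NUISANCE_LOAD = np.array([0.10, 0.45, -0.20, 0.35, -0.10])


def _methodology_labels(n_groups: int) -> list[tuple[str, str, str]]:
    combos = []
    for i in range(n_groups):
        combos.append((
            _TAXA[i % len(_TAXA)],
            _METHODS[(i // len(_TAXA) + i) % len(_METHODS)],
            _UNITS[i % len(_UNITS)],
        ))
    # labels must be distinct so groups are well defined
    assert len(set(combos)) == n_groups, "too many methodology groups requested"
    return combos


def evi2_to_nir(evi: np.ndarray, red: np.ndarray) -> np.ndarray:
    """Invert EVI2 = 2.5 (NIR - red) / (NIR + 2.4 red + 1) for NIR."""
    return (2.5 * red + evi * (2.4 * red + 1.0)) / (2.5 - evi)


def generate_dataset(config: SimConfig) -> Dict[str, object]:
    """Generate one synthetic database.

    Returns a dict with keys ``studies``, ``sites``, ``assemblage``,
    ``spectra`` (all :class:`pandas.DataFrame`) and ``truth`` (the planted
    parameters, see :func:`planted_truth`).
    """
    rng = np.random.default_rng(config.seed)
    labels = _methodology_labels(config.n_methodology_groups)

    study_rows, site_rows, assemblage_rows = [], [], []
    truth_study_rows, truth_site_rows = [], []
    spectra_parts, gap_rows = [], []

    # draw study covariates first so the optional detection links can be
    # standardized across the database
    n = config.n_studies
    log_access = rng.normal(config.accessibility_log_mean,
                            config.accessibility_log_sd, n)
    log_rugged = rng.normal(config.ruggedness_log_mean,
                            config.ruggedness_log_sd, n)
    z_access = _zscore(log_access)
    z_rugged = _zscore(log_rugged)

    n_occurrence = int(round(config.occurrence_fraction * n))
    occurrence_ids = set(rng.choice(n, size=n_occurrence, replace=False).tolist())

    for j in range(n):
        study_id = f"ST{j:03d}"
        taxon, method, unit = labels[j % config.n_methodology_groups]
        alpha = rng.normal(config.intercept_mean, config.intercept_sd)
        beta = rng.normal(config.slope_mean, config.slope_sd)
        phase = rng.uniform(0, 2 * np.pi)
        gamma = rng.normal(0.0, config.species_effect_sd,
                           config.species_pool_per_study)

        lo, hi = config.sites_per_study
        n_sites = int(rng.integers(lo, hi + 1))
        centre_lat = rng.uniform(-50.0, 50.0)
        centre_lon = rng.uniform(-170.0, 170.0)

        s_lo, s_hi = config.samples_per_site
        mean_samples = float(np.exp(rng.uniform(np.log(s_lo), np.log(s_hi))))
        detect_intensity = config.detection_rate * float(np.exp(
            config.detect_link_accessibility * z_access[j]
            + config.detect_link_ruggedness * z_rugged[j]))

        start_month = int(rng.integers(13, config.months + 1))
        duration = float(np.exp(rng.normal(config.duration_log_mean,
                                           config.duration_log_sd)))
        is_abundance = j not in occurrence_ids

        study_rows.append({
            "study_id": study_id, "taxon_group": taxon,
            "sampling_method": method, "sampling_unit": unit,
            "is_abundance": is_abundance,
            "sampling_start_month": start_month,
            "duration_days": duration,
            "accessibility_m": float(np.exp(log_access[j])),
            "ruggedness": float(np.exp(log_rugged[j])),
        })
        truth_study_rows.append({
            "study_id": study_id, "alpha": alpha, "beta": beta,
            "seasonal_phase": phase, "mean_samples": mean_samples,
            "detect_intensity": detect_intensity,
        })

        lat = centre_lat + rng.normal(0.0, config.site_scatter_deg, n_sites)
        lon = centre_lon + rng.normal(0.0, config.site_scatter_deg, n_sites)
        lat = np.clip(lat, -89.9, 89.9)
        samples = np.clip(rng.poisson(mean_samples, n_sites),
                          s_lo, s_hi).astype(int)
        p_detect = 1.0 - np.exp(-detect_intensity * samples)
        extent = np.exp(rng.normal(config.extent_log_mean,
                                   config.extent_log_sd, n_sites))
        latent_v = rng.uniform(0.10, 0.55, n_sites)

        months = np.arange(1, config.months + 1)
        seasonal = config.seasonal_amp * np.sin(2 * np.pi * months / 12.0 + phase)

        for i in range(n_sites):
            site_id = f"{study_id}_S{i:03d}"
            site_rows.append({
                "site_id": site_id, "study_id": study_id,
                "lat": float(lat[i]), "lon": float(lon[i]),
                "sampling_start_month": start_month,
                "sampling_effort": int(samples[i]),
                "extent_m": float(extent[i]),
            })

            # species counts: Poisson(lambda) thinned by detection
            log_lam = np.clip(alpha + beta * latent_v[i] + gamma, None, 10.0)
            lam = np.exp(log_lam)
            if config.deterministic_counts:
                detected = lam * p_detect[i]
                true_counts = lam
            else:
                true_counts = rng.poisson(lam)
                detected = rng.binomial(true_counts, p_detect[i])
            present = detected > 0
            for s in np.nonzero(present)[0]:
                value = detected[s] if is_abundance else 1.0
                assemblage_rows.append({
                    "site_id": site_id,
                    "taxon_id": f"{study_id}_sp{s:03d}",
                    "measurement": float(value),
                })
            truth_site_rows.append({
                "site_id": site_id, "study_id": study_id,
                "latent_v": float(latent_v[i]),
                "true_abundance": float(np.sum(true_counts)),
                "true_richness": int(np.sum(np.asarray(true_counts) > 0)),
            })

            # 7-band monthly reflectance; EVI2(red, NIR) = latent signal + noise
            evi = latent_v[i] + seasonal
            evi_obs = evi + rng.normal(0.0, config.evi_noise_sd, config.months)
            evi_obs = np.clip(evi_obs, -0.2, 0.95)
            red = np.clip(config.red_base
                          + rng.normal(0.0, 0.5 * config.band_noise_sd,
                                       config.months), 0.01, 0.35)
            nir = evi2_to_nir(evi_obs, red)
            bands = np.empty((N_BANDS, config.months))
            bands[RED_BAND - 1] = red
            bands[NIR_BAND - 1] = nir
            for k in range(5):
                bands[k + 2] = (_NUISANCE_BASE[k] + _NUISANCE_LOAD[k] * evi
                                + rng.normal(0.0, config.band_noise_sd,
                                             config.months))
            bands = np.clip(bands, -0.1, 1.1)

            missing = rng.random(config.months) < config.gap_rate
            bands[:, missing] = np.nan
            for m in months[missing]:
                gap_rows.append({"site_id": site_id, "month_index": int(m)})

            spectra_parts.append(pd.DataFrame({
                "site_id": site_id,
                "month_index": np.repeat(months, N_BANDS),
                "band": np.tile(np.arange(1, N_BANDS + 1), config.months),
                "reflectance": bands.T.ravel(),
            }))

    studies = pd.DataFrame(study_rows)
    sites = pd.DataFrame(site_rows)
    assemblage = pd.DataFrame(
        assemblage_rows, columns=["site_id", "taxon_id", "measurement"])
    spectra = pd.concat(spectra_parts, ignore_index=True)
    truth = {
        "studies": pd.DataFrame(truth_study_rows),
        "sites": pd.DataFrame(truth_site_rows),
        "gaps": pd.DataFrame(gap_rows, columns=["site_id", "month_index"]),
    }
    return {"studies": studies, "sites": sites, "assemblage": assemblage,
            "spectra": spectra, "truth": truth}


def planted_truth(dataset: Dict[str, object]) -> Dict[str, pd.DataFrame]:
    """Return the planted parameters of a generated dataset.

    ``studies`` holds per-study ``alpha``/``beta``; ``sites`` the latent
    vegetation signal and pre-detection abundance/richness; ``gaps`` the
    injected missing months.
    """
    return dataset["truth"]


def inject_gaps(
    spectra: pd.DataFrame,
    gap_rate: float,
    max_run: int = 1,
    seed: int = 0,
    force_runs: Optional[Dict[str, Tuple[int, int]]] = None,
) -> pd.DataFrame:
    """Mask additional whole months in a spectral series, at random.

    Gaps are injected as runs of 1..``max_run`` consecutive months until each
    site has at least ``round(gap_rate * n_months)`` extra missing months.
    ``force_runs`` maps ``site_id -> (start_month, run_length)`` to plant a
    specific run (e.g. a 6-month gap to trigger the exclusion rule).
    """
    if not 0.0 <= gap_rate < 1.0:
        raise ValueError(f"gap_rate must be in [0, 1), got {gap_rate}")
    out = spectra.copy()
    rng = np.random.default_rng(seed)
    months = np.sort(spectra["month_index"].unique())
    for site_id, grp in out.groupby("site_id", sort=True):
        target = int(round(gap_rate * len(months)))
        to_mask: set[int] = set()
        if force_runs and site_id in force_runs:
            start, length = force_runs[site_id]
            to_mask.update(range(start, start + length))
        guard = 0
        while len(to_mask) < target and guard < 10_000:
            guard += 1
            run = int(rng.integers(1, max_run + 1))
            start = int(rng.choice(months))
            to_mask.update(m for m in range(start, start + run)
                           if m <= months[-1])
        if to_mask:
            mask = (out["site_id"] == site_id) & out["month_index"].isin(to_mask)
            out.loc[mask, "reflectance"] = np.nan
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd == 0 or len(x) < 2:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd
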