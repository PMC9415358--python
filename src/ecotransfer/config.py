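"""Simulation configuration.

A :class:`SimConfig` describes one synthetic "database": how many studies,
how sites scatter around study centres, how the latent vegetation signal maps
to species abundances, how detection depends on sampling effort, and how the
seven-band reflectance series (and their data gaps) are generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Tuple

import yaml


@dataclass
class SimConfig:
    """Parameters of the synthetic biodiversity database generator.

    Counts are per study or per site as noted.  All randomness derives from
    ``seed``; the same config and seed reproduce the dataset bit-for-bit.
    """

    #: number of studies in the database
    n_studies: int = 20
    #: sites per study, inclusive integer range (lo, hi)
    sites_per_study: Tuple[int, int] = (8, 30)
    #: number of distinct methodology groups (taxon x method x unit labels)
    n_methodology_groups: int = 6
    #: species pool size per study (pools are disjoint between studies)
    species_pool_per_study: int = 40

    #: study intercept alpha_j ~ Normal(intercept_mean, intercept_sd);
    #: log expected per-species abundance at latent vegetation signal 0
    intercept_mean: float = 2.0
    intercept_sd: float = 0.5
    #: study slope beta_j ~ Normal(slope_mean, slope_sd); links latent
    #: vegetation signal to log abundance
    slope_mean: float = 2.0
    slope_sd: float = 0.5
    #: spread of per-species abundance offsets (creates rare species so
    #: richness responds to the vegetation signal instead of saturating)
    species_effect_sd: float = 1.5

    #: per-sample detection intensity; detection probability at a site with
    #: k samples is 1 - exp(-detection_rate * k)
    detection_rate: float = 0.15
    #: range of the study-level mean number of samples per site (log-uniform)
    samples_per_site: Tuple[int, int] = (1, 25)
    #: replace Poisson draws and binomial thinning by their expectations
    #: (deterministic counts; used for noiseless recovery checks)
    deterministic_counts: bool = False
    #: fraction of studies reporting occurrence (presence/absence) only
    occurrence_fraction: float = 0.0

    #: length of the monthly reflectance series (>= 13 so that a 12-month
    #: pre-sampling window exists)
    months: int = 36
    #: fraction of site-months masked missing, completely at random
    gap_rate: float = 0.05
    #: sd of the month-to-month noise on the two-band vegetation index
    evi_noise_sd: float = 0.02
    #: amplitude of the 12-month seasonal harmonic of the vegetation signal
    seasonal_amp: float = 0.08
    #: sd of per-band reflectance noise (nuisance bands and the red band)
    band_noise_sd: float = 0.02
    #: baseline red-band reflectance
    red_base: float = 0.08

    #: sd (degrees) of the isotropic Gaussian site scatter around the centre
    site_scatter_deg: float = 0.05

    # study attributes for the meta-model, log-normal(mean of log, sd of log)
    extent_log_mean: float = 4.25  # median ~ 70 m
    extent_log_sd: float = 1.0
    duration_log_mean: float = 4.5  # median ~ 90 days
    duration_log_sd: float = 0.8
    accessibility_log_mean: float = 9.9  # median ~ 20 km to nearest city
    accessibility_log_sd: float = 1.0
    ruggedness_log_mean: float = 3.0
    ruggedness_log_sd: float = 0.7
    #: optional planted links: per-study detection intensity is multiplied by
    #: exp(coef * z) where z is the standardized log covariate
    detect_link_accessibility: float = 0.0
    detect_link_ruggedness: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.sites_per_study = _as_range(self.sites_per_study, "sites_per_study")
        self.samples_per_site = _as_range(self.samples_per_site, "samples_per_site")
        for name in ("n_studies", "n_methodology_groups", "species_pool_per_study"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("intercept_sd", "slope_sd", "species_effect_sd",
                     "evi_noise_sd", "band_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError(f"gap_rate must be in [0, 1), got {self.gap_rate}")
        if not 0.0 <= self.occurrence_fraction <= 1.0:
            raise ValueError("occurrence_fraction must be in [0, 1]")
        if self.months < 13:
            raise ValueError(
                f"months must be >= 13 so a 12-month pre-sampling window "
                f"exists, got {self.months}"
            )
        if self.detection_rate <= 0:
            raise ValueError("detection_rate must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        """Load a config from a flat YAML key-value file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sites_per_study"] = list(self.sites_per_study)
        d["samples_per_site"] = list(self.samples_per_site)
        return d


def _as_range(value, name: str) -> Tuple[int, int]:
    if isinstance(value, (int, float)):
        value = (int(value), int(value))
    lo, hi = int(value[0]), int(value[1])
    if lo < 1 or hi < lo:
        raise ValueError(f"{name} must be a range (lo, hi) with 1 <= lo <= hi")
    return (lo, hi)
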