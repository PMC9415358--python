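"""End-to-end pipeline: simulate -> measures -> features -> cv -> meta.

Every stage writes its output table as CSV into the run directory, plus a
``manifest.json`` recording the seed, a hash of the configuration, the
package version, per-stage row counts and the skip/exclusion logs.  All
randomness flows from the single top-level seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

import ecotransfer
from ecotransfer import cv as cv_mod
from ecotransfer import measures as measures_mod
from ecotransfer import meta as meta_mod
from ecotransfer import rs_features
from ecotransfer.config import SimConfig
from ecotransfer.io import write_manifest, write_tables
from ecotransfer.simulate import generate_dataset

_SEED_MOD = 2 ** 31


def run_pipeline(
    config: SimConfig,
    out_dir,
    seed: Optional[int] = None,
    n_sets: int = cv_mod.N_SETS_DEFAULT,
    test_frac: float = cv_mod.TEST_FRAC_DEFAULT,
    impute_method: str = "kalman",
    dataset: Optional[Dict[str, pd.DataFrame]] = None,
    run_meta: bool = True,
) -> Dict[str, object]:
    """Run the whole analysis and write all outputs to ``out_dir``.

    ``seed`` overrides ``config.seed`` when given.  ``dataset`` may supply
    pre-loaded input tables (ingest mode); otherwise data are simulated.
    Returns a dict with every intermediate and final table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = SimConfig(**{**config.to_dict(), "seed": int(seed)})
    base_seed = config.seed

    try:
        if dataset is None:
            dataset = generate_dataset(config)
        studies, sites = dataset["studies"], dataset["sites"]
        assemblage, spectra = dataset["assemblage"], dataset["spectra"]
        write_tables(dataset, out_dir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {exc}") from exc

    try:
        sites = measures_mod.fill_missing_extents(sites, studies)
        corrected = measures_mod.effort_correct(assemblage, sites, studies)
        site_meas = measures_mod.site_measures(corrected, assemblage, sites,
                                               studies)
        pairs = measures_mod.pairwise_composition(corrected, sites)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'measures' failed: {exc}") from exc

    try:
        predictors = rs_features.site_predictors(spectra, sites,
                                                 impute_method=impute_method)
        pairs_env = rs_features.pairwise_env_diff(predictors, pairs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'features' failed: {exc}") from exc

    try:
        groups = cv_mod.build_methodology_groups(studies)
        plan_pred = cv_mod.make_permutation_sets(
            "predictability", studies, sites, groups,
            n_sets=n_sets, test_frac=test_frac,
            seed=(base_seed + 1) % _SEED_MOD)
        plans = [plan_pred]
        if groups["eligible"].any():
            plans.append(cv_mod.make_permutation_sets(
                "transferability", studies, sites, groups,
                n_sets=n_sets, test_frac=test_frac,
                seed=(base_seed + 2) % _SEED_MOD))
        plan = pd.concat(plans, ignore_index=True)
        errors, skips = cv_mod.run_cv(plan, site_meas, predictors, pairs_env,
                                      studies)
        summaries = cv_mod.summarize_errors(errors, studies)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'cv' failed: {exc}") from exc

    averaged = None
    meta_design = None
    if run_meta and (errors["mode"] == "transferability").any():
        try:
            meta_design = meta_mod.build_meta_design(
                errors, studies, sites, predictors, groups,
                mode="transferability")
            std_design = meta_mod.standardize(meta_design)
            averaged = meta_mod.subset_average(std_design)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'meta' failed: {exc}") from exc

    outputs: Dict[str, object] = {
        "studies": studies, "sites": sites, "assemblage": assemblage,
        "spectra": spectra, "truth": dataset.get("truth"),
        "site_measures": site_meas, "pairs": pairs_env,
        "predictors": predictors, "groups": groups, "plan": plan,
        "errors": errors, "skips": skips, "summaries": summaries,
        "meta_design": meta_design, "averaged_model": averaged,
    }

    tables_out = {
        "site_measures": site_meas, "pairs": pairs_env,
        "predictors": predictors, "groups": groups, "plan": plan,
        "errors": errors, "skips": skips,
        "summary_by_measure": summaries["by_measure"],
        "summary_by_taxon": summaries["by_taxon"],
        "summary_delta": summaries["delta"],
    }
    if meta_design is not None:
        tables_out["meta_design"] = meta_design
    for name, df in tables_out.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    if averaged is not None:
        coef = pd.DataFrame(sorted(averaged.coefficients.items()),
                            columns=["term", "coefficient"])
        coef.to_csv(out_dir / "meta_coefficients.csv", index=False)
        with open(out_dir / "meta_r2.json", "w") as fh:
            json.dump({"r2_marginal": averaged.r2_marginal,
                       "r2_conditional": averaged.r2_conditional,
                       "n_candidates": averaged.n_candidates,
                       "n_selected": averaged.n_selected}, fh, indent=2)
            fh.write("\n")

    config_dict = config.to_dict()
    manifest = {
        "seed": base_seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()).hexdigest(),
        "version": ecotransfer.__version__,
        "row_counts": {name: int(len(df)) for name, df in tables_out.items()},
        "matched_fraction": groups.attrs.get("matched_fraction"),
        "n_excluded_sites": int(predictors["excluded"].sum()),
        "n_skips": int(len(skips)),
    }
    write_manifest(out_dir / "manifest.json", manifest)
    return outputs
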