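"""Permutation-based evaluation of predictability and transferability.

*Predictability*: per study, ten permutation sets each hold out 33% of sites
(sampled with probability proportional to their distance from the study's
spatial centroid, favouring spatially peripheral sites); models are fitted
on the remaining 66% and errors measured on the hold-out.

*Transferability*: studies are grouped by methodology (taxon group x
sampling method x sampling unit); for each focal study, 33% of a partner
study's sites from the same group are held out, the model is fitted on the
focal study's own sites, and the error measured on the partner's hold-out.
Partner choice is inversely weighted by how often a study has already served
as partner, with a final repair pass so that over the ten sets every study
in an eligible group is used for testing at least once.

Errors are symmetric mean absolute percentage errors (sMAPE, bounded
0-100%), computed on each model's response scale.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ecotransfer.measures import great_circle_km
from ecotransfer.study_models import (
    GAUSSIAN, POISSON, FitResult, fit_composition_model, fit_measure_model,
    predict_measure,
)

N_SETS_DEFAULT = 10
TEST_FRAC_DEFAULT = 0.33
MIN_SITES = 3
MIN_PAIRS = 4

_PREDICTOR_COL = {"evi": "evi_mean", "specvar": "spectral_variability"}
_PAIR_ENV_COL = {"evi": "abs_evi_diff", "specvar": "centroid_dist"}


def build_methodology_groups(studies: pd.DataFrame) -> pd.DataFrame:
    """Assign each study to its methodology group.

    The group id concatenates taxon group, sampling method and sampling
    unit.  Groups with fewer than two member studies are flagged ineligible
    for transferability (their members remain usable for predictability).
    The fraction of studies with at least one comparable partner is stored
    in ``result.attrs["matched_fraction"]``.
    """
    needed = ["taxon_group", "sampling_method", "sampling_unit"]
    for col in needed:
        missing = studies[studies[col].isna()]
        if len(missing):
            raise ValueError(
                f"study {missing.iloc[0]['study_id']!r} has no {col}")
    out = studies[["study_id"]].copy()
    out["group_id"] = (studies["taxon_group"].astype(str) + "|"
                       + studies["sampling_method"].astype(str) + "|"
                       + studies["sampling_unit"].astype(str))
    sizes = out.groupby("group_id")["study_id"].transform("size")
    out["group_size"] = sizes
    out["eligible"] = sizes >= 2
    out.attrs["matched_fraction"] = float(out["eligible"].mean())
    return out


def smape(y_obs, y_pred) -> float:
    """Symmetric mean absolute percentage error, in percent (0-100).

    ``100/n * sum(|pred - obs| / (|obs| + |pred|))``; a term where both
    observed and predicted are zero contributes zero.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("observed and predicted vectors differ in length")
    if y_obs.size == 0:
        raise ValueError("empty vectors")
    denom = np.abs(y_obs) + np.abs(y_pred)
    num = np.abs(y_pred - y_obs)
    terms = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    return float(100.0 * terms.mean())


def _study_centroid_distances(site_grp: pd.DataFrame) -> np.ndarray:
    clat = site_grp["lat"].mean()
    clon = site_grp["lon"].mean()
    return np.asarray(great_circle_km(site_grp["lat"], site_grp["lon"],
                                      clat, clon), dtype=float)


def make_permutation_sets(
    mode: str,
    studies: pd.DataFrame,
    sites: pd.DataFrame,
    groups: Optional[pd.DataFrame] = None,
    n_sets: int = N_SETS_DEFAULT,
    test_frac: float = TEST_FRAC_DEFAULT,
    seed: int = 0,
) -> pd.DataFrame:
    """Construct the train/test site assignments for all permutation sets.

    Returns a long DataFrame with columns ``set_id, mode, focal_study,
    partner_study, site_id, role`` (role in {train, test}).  For
    predictability ``partner_study == focal_study``; for transferability the
    training rows are all sites of the focal study and the test rows come
    from the partner.
    """
    if mode not in ("predictability", "transferability"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    site_groups = {sid: grp for sid, grp in sites.groupby("study_id")}
    usable = [s for s in sorted(studies["study_id"])
              if len(site_groups.get(s, ())) >= MIN_SITES]

    rows: List[dict] = []
    if mode == "predictability":
        for set_id in range(1, n_sets + 1):
            for study_id in usable:
                grp = site_groups[study_id]
                ids = grp["site_id"].to_numpy()
                n_test = max(1, int(round(test_frac * len(ids))))
                dist = _study_centroid_distances(grp)
                weights = (dist / dist.sum() if dist.sum() > 0
                           else np.full(len(ids), 1.0 / len(ids)))
                test = set(rng.choice(ids, size=n_test, replace=False,
                                      p=weights))
                for sid in ids:
                    rows.append({"set_id": set_id, "mode": mode,
                                 "focal_study": study_id,
                                 "partner_study": study_id, "site_id": sid,
                                 "role": "test" if sid in test else "train"})
        return pd.DataFrame(rows)

    if groups is None:
        groups = build_methodology_groups(studies)
    ginfo = groups.set_index("study_id")
    eligible = [s for s in usable
                if s in ginfo.index and ginfo.at[s, "eligible"]]
    if not eligible:
        raise ValueError("no eligible methodology groups for transferability")
    members: Dict[str, List[str]] = {}
    for s in eligible:
        members.setdefault(ginfo.at[s, "group_id"], []).append(s)

    # partner assignment with inverse-frequency weights + coverage repair
    times_partnered = {s: 0 for s in eligible}
    partner_of: Dict[Tuple[int, str], str] = {}
    for set_id in range(1, n_sets + 1):
        for focal in eligible:
            cands = [s for s in members[ginfo.at[focal, "group_id"]]
                     if s != focal]
            w = np.array([1.0 / (1 + times_partnered[c]) for c in cands])
            partner = str(rng.choice(cands, p=w / w.sum()))
            partner_of[(set_id, focal)] = partner
            times_partnered[partner] += 1
    for orphan in [s for s in eligible if times_partnered[s] == 0]:
        gid = ginfo.at[orphan, "group_id"]
        for (set_id, focal), partner in sorted(partner_of.items()):
            if (focal != orphan and ginfo.at[focal, "group_id"] == gid
                    and times_partnered[partner] > 1):
                times_partnered[partner] -= 1
                partner_of[(set_id, focal)] = orphan
                times_partnered[orphan] += 1
                break

    for (set_id, focal), partner in sorted(partner_of.items()):
        for sid in site_groups[focal]["site_id"]:
            rows.append({"set_id": set_id, "mode": mode, "focal_study": focal,
                         "partner_study": partner, "site_id": sid,
                         "role": "train"})
        pids = site_groups[partner]["site_id"].to_numpy()
        n_test = max(1, int(round(test_frac * len(pids))))
        test = rng.choice(pids, size=n_test, replace=False)
        for sid in test:
            rows.append({"set_id": set_id, "mode": mode, "focal_study": focal,
                         "partner_study": partner, "site_id": sid,
                         "role": "test"})
    return pd.DataFrame(rows)


def _measure_series(measures: pd.DataFrame, measure: str) -> pd.Series:
    if measure == "richness":
        return measures.set_index("site_id")["S"]
    if measure == "abundance":
        m = measures[measures["valid_abundance"]]
        return m.set_index("site_id")["logA"]
    if measure == "evenness":
        m = measures[measures["valid_evenness"]]
        return m.set_index("site_id")["evenness"]
    raise ValueError(measure)


def run_cv(
    plans: pd.DataFrame,
    measures: pd.DataFrame,
    predictors: pd.DataFrame,
    pairs: pd.DataFrame,
    studies: pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Fit, predict and score every plan x measure x predictor combination.

    Returns ``(errors, skips)``.  ``errors`` has one row per focal study,
    permutation set, mode, measure and predictor with the hold-out sMAPE;
    ``skips`` records every combination that could not be evaluated and why
    (too few sites, degenerate fit, occurrence-only study, ...).
    """
    pred_ok = predictors[~predictors["excluded"]].set_index("site_id")
    err_rows: List[dict] = []
    skip_rows: List[dict] = []

    def skip(set_id, mode, study, measure, predictor, reason):
        skip_rows.append({"set_id": set_id, "mode": mode, "study_id": study,
                          "measure": measure, "predictor": predictor,
                          "reason": reason})

    pair_groups = {s: g for s, g in pairs.groupby("study_id")} if len(pairs) else {}

    for (set_id, mode, focal, partner), grp in plans.groupby(
            ["set_id", "mode", "focal_study", "partner_study"], sort=True):
        train_ids = [s for s in grp.loc[grp["role"] == "train", "site_id"]
                     if s in pred_ok.index]
        test_ids = [s for s in grp.loc[grp["role"] == "test", "site_id"]
                    if s in pred_ok.index]
        for predictor in ("evi", "specvar"):
            xcol = _PREDICTOR_COL[predictor]
            for measure in ("richness", "abundance", "evenness"):
                y = _measure_series(measures, measure)
                tr = [s for s in train_ids if s in y.index]
                te = [s for s in test_ids if s in y.index]
                if len(tr) < MIN_SITES or not te:
                    skip(set_id, mode, focal, measure, predictor,
                         "too few usable train/test sites")
                    continue
                family = POISSON if measure == "richness" else GAUSSIAN
                y_tr = y.loc[tr].to_numpy()
                if family == POISSON:
                    y_tr = np.round(y_tr)
                fit = fit_measure_model(
                    y_tr, pred_ok.loc[tr, xcol].to_numpy(), family,
                    measure=measure, predictor=predictor, study_id=focal)
                if fit.degenerate:
                    skip(set_id, mode, focal, measure, predictor,
                         f"degenerate fit: {fit.degenerate_reason}")
                    continue
                y_hat = predict_measure(fit, pred_ok.loc[te, xcol].to_numpy())
                err_rows.append({
                    "study_id": focal, "set_id": set_id, "mode": mode,
                    "measure": measure, "predictor": predictor,
                    "smape": smape(y.loc[te].to_numpy(), y_hat),
                    "n_test": len(te)})

            # composition: pairwise distance-decay model
            train_pairs = pair_groups.get(focal)
            test_pairs = pair_groups.get(partner)
            if train_pairs is None or test_pairs is None:
                skip(set_id, mode, focal, "composition", predictor,
                     "no within-study pairs")
                continue
            tr_set, te_set = set(train_ids), set(test_ids)
            env_col = _PAIR_ENV_COL[predictor]
            tp = train_pairs[train_pairs["site_i"].isin(tr_set)
                             & train_pairs["site_j"].isin(tr_set)]
            hp = test_pairs[test_pairs["site_i"].isin(te_set)
                            | test_pairs["site_j"].isin(te_set)]
            hp = hp[hp["site_i"].isin(pred_ok.index)
                    & hp["site_j"].isin(pred_ok.index)]
            if len(tp) < MIN_PAIRS or not len(hp):
                skip(set_id, mode, focal, "composition", predictor,
                     "too few usable train/test pairs")
                continue
            fit = fit_composition_model(tp, predictor, study_id=focal)
            if fit.degenerate:
                skip(set_id, mode, focal, "composition", predictor,
                     f"degenerate fit: {fit.degenerate_reason}")
                continue
            x_new = hp[[env_col, "log_dist"]].to_numpy()
            y_hat = predict_measure(fit, x_new)
            err_rows.append({
                "study_id": focal, "set_id": set_id, "mode": mode,
                "measure": "composition", "predictor": predictor,
                "smape": smape(hp["sim_logit"].to_numpy(), y_hat),
                "n_test": len(hp)})

    errors = pd.DataFrame(err_rows, columns=["study_id", "set_id", "mode",
                                             "measure", "predictor", "smape",
                                             "n_test"])
    skips = pd.DataFrame(skip_rows, columns=["set_id", "mode", "study_id",
                                             "measure", "predictor", "reason"])
    return errors, skips


def summarize_errors(errors: pd.DataFrame,
                     studies: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Mean/SD error summaries and the transferability-predictability gap.

    Returns ``by_measure`` (mode x measure x predictor), ``by_taxon``
    (mode x measure x taxon group) and ``delta`` (mean transferability minus
    mean predictability sMAPE per measure and predictor, with the fraction
    of study-level errors above 50%).
    """
    if errors.empty:
        raise ValueError("empty error table")
    merged = errors.merge(studies[["study_id", "taxon_group"]], on="study_id",
                          how="left")

    def agg(df, keys):
        out = (df.groupby(keys)["smape"]
                 .agg(mean_smape="mean", sd_smape="std", n="size",
                      frac_gt50=lambda s: float((s > 50).mean()))
                 .reset_index())
        out["sd_smape"] = out["sd_smape"].fillna(0.0)
        return out

    by_measure = agg(merged, ["mode", "measure", "predictor"])
    by_taxon = agg(merged, ["mode", "measure", "taxon_group"])

    wide = by_measure.pivot_table(index=["measure", "predictor"],
                                  columns="mode", values="mean_smape")
    delta = wide.reset_index()
    if {"predictability", "transferability"} <= set(wide.columns):
        delta["delta_smape"] = (delta["transferability"]
                                - delta["predictability"])
    else:
        delta["delta_smape"] = 0.0
    return {"by_measure": by_measure, "by_taxon": by_taxon, "delta": delta}
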