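"""End-to-end pipeline orchestration and table rendering.

``run_pipeline`` executes the stages in claims order — cohort construction,
episode classification, CVAD identification, comorbidity scoring, HCRU
summarization, propensity-matched relative-risk estimation — and renders a
human-readable markdown report with four table analogues (baseline
characteristics; mutually exclusive medication-usage categories; CVAD
complication prevalence; crude stratified HCRU rates) plus the adjusted
relative-risk estimate, together with a JSON summary of headline numbers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import comorbidity, cvad, hcru, matching
from . import episodes as episodes_mod
from .schema import C1INH_IV_PRODUCTS, CINRYZE, BERINERT, ClaimsDataset, SC_PRODUCTS

logger = logging.getLogger(__name__)

TABLE2_LABELS = {
    "sc_only": "Icatibant and/or ecallantide only",
    "cinryze_only": "C1-INH(IV)/Cinryze",
    "cinryze_sc": "C1-INH(IV)/Cinryze + icatibant/ecallantide",
    "berinert_only": "C1-INH(IV)/Berinert",
    "berinert_sc": "C1-INH(IV)/Berinert + icatibant/ecallantide",
    "both_c1inh_sc": "C1-INH(IV)/Cinryze + C1-INH(IV)/Berinert + icatibant/ecallantide",
    "both_c1inh": "C1-INH(IV)/Cinryze + C1-INH(IV)/Berinert",
}


@dataclass
class PipelineConfig:
    """Every numeric default of the pipeline, overridable from YAML."""

    input_dir: str | None = None
    output_dir: str = "out"
    seed: int = 0
    grace_days: int = 0
    month_days: int = 30
    iu_per_week_threshold: float = 1500.0
    min_weeks: int = 13
    continuity_gap_days: int = 45
    terminal_coverage_days: int = 7
    cci_window_days: int = 180
    follow_up_days: int = 365
    complication_window_days: int = 30
    caliper_sd: float = 0.2
    min_level_size: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def cohort_config(self) -> cohort_mod.CohortConfig:
        return cohort_mod.CohortConfig(month_days=self.month_days,
                                       grace_days=self.grace_days)

    @property
    def episode_config(self) -> episodes_mod.EpisodeConfig:
        return episodes_mod.EpisodeConfig(
            iu_per_week_threshold=self.iu_per_week_threshold,
            min_weeks=self.min_weeks,
            continuity_gap_days=self.continuity_gap_days,
            terminal_coverage_days=self.terminal_coverage_days)


def patient_product_flags(pharmacy: pd.DataFrame) -> pd.DataFrame:
    """Per-patient booleans: any Cinryze / Berinert / SC on-demand fill."""
    out = pd.DataFrame({
        "cinryze": pharmacy.groupby("patient_id")["product"]
            .apply(lambda s: (s == CINRYZE).any()),
        "berinert": pharmacy.groupby("patient_id")["product"]
            .apply(lambda s: (s == BERINERT).any()),
        "sc": pharmacy.groupby("patient_id")["product"]
            .apply(lambda s: s.isin(SC_PRODUCTS).any()),
    })
    out["c1inh_iv"] = out["cinryze"] | out["berinert"]
    return out


def usage_category(cinryze: bool, berinert: bool, sc: bool) -> str:
    """Assign one of the seven mutually exclusive usage categories."""
    if cinryze and berinert:
        return "both_c1inh_sc" if sc else "both_c1inh"
    if cinryze:
        return "cinryze_sc" if sc else "cinryze_only"
    if berinert:
        return "berinert_sc" if sc else "berinert_only"
    if sc:
        return "sc_only"
    raise ValueError("patient with no HAE-specific fills has no usage category")


def render_table2(dataset: ClaimsDataset, cohort: pd.DataFrame) -> pd.DataFrame:
    """Medication-usage category counts over the overall cohort.

    The seven categories partition the cohort: counts sum to N and no
    patient appears in two rows.
    """
    members = cohort.loc[cohort["in_overall"], "patient_id"]
    flags = patient_product_flags(
        dataset.pharmacy[dataset.pharmacy["patient_id"].isin(members)])
    cats = flags.apply(
        lambda r: usage_category(r["cinryze"], r["berinert"], r["sc"]), axis=1)
    n = len(members)
    rows = []
    for key, label in TABLE2_LABELS.items():
        count = int((cats == key).sum())
        rows.append({"category": key, "label": label, "n": count,
                     "pct": round(100.0 * count / n, 1) if n else None})
    rows.append({"category": "any_c1inh_iv", "label": "Any use C1-INH(IV)",
                 "n": int(flags["c1inh_iv"].sum()),
                 "pct": round(100.0 * flags["c1inh_iv"].sum() / n, 1) if n else None})
    return pd.DataFrame(rows)


def render_table1(dataset: ClaimsDataset, cohort: pd.DataFrame,
                  cci: pd.DataFrame) -> dict:
    """Baseline characteristics of the overall cohort."""
    members = set(cohort.loc[cohort["in_overall"], "patient_id"])
    pats = dataset.patients[dataset.patients["patient_id"].isin(members)]
    idx = cohort.set_index("patient_id")["index_date"]
    ages = pats.apply(
        lambda r: pd.Timestamp(idx[r["patient_id"]]).year - r["birth_year"], axis=1)
    out = {
        "n": len(pats),
        "pct_female": round(100.0 * (pats["sex"] == "F").mean(), 1) if len(pats) else None,
        "mean_age": round(float(ages.mean()), 1) if len(pats) else None,
        "region": pats["region"].value_counts().to_dict(),
        "payer": pats["payer"].value_counts().to_dict(),
        "mean_cci": round(float(
            cci.set_index("patient_id").reindex(sorted(members))["cci_score"].mean()), 2)
            if len(cci) else None,
    }
    return out


def _initial_treatment_course(dataset: ClaimsDataset, cohort: pd.DataFrame) -> pd.Series:
    """Product class of the index-date claim: C1INH_IV vs SC_ON_DEMAND."""
    courses = {}
    for _, rec in cohort.iterrows():
        fills = dataset.pharmacy[
            (dataset.pharmacy["patient_id"] == rec["patient_id"])
            & (dataset.pharmacy["fill_date"] == rec["index_date"])]
        iv = fills["product"].isin(C1INH_IV_PRODUCTS).any()
        courses[rec["patient_id"]] = "C1INH_IV" if iv else "SC_ON_DEMAND"
    return pd.Series(courses, name="initial_treatment_course")


def run_pipeline(dataset: ClaimsDataset,
                 config: PipelineConfig | None = None) -> dict:
    """Execute every stage and return the full result bundle as a dict."""
    config = config or PipelineConfig()
    results: dict = {"config": asdict(config)}
    stage = "cohort"
    try:
        cohort, attrition = cohort_mod.build_cohorts(dataset, config.cohort_config)
        results["cohort"], results["attrition"] = cohort, attrition
        logger.info("stage cohort: %d candidates -> %d overall / %d hcru",
                    len(cohort), cohort["in_overall"].sum(), cohort["in_hcru"].sum())

        stage = "episodes"
        eps = episodes_mod.build_episodes(dataset, config.episode_config)
        results["episodes"] = episodes_mod.episodes_frame(eps)
        results["episode_summary"] = episodes_mod.summarize_episodes(eps)

        stage = "cvad"
        cvads = cvad.build_cvads(dataset, cohort, config.episode_config,
                                 config.grace_days, config.complication_window_days)
        results["cvads"] = cvads
        results["complication_summary"] = cvad.complication_summary(cvads)

        stage = "comorbidity"
        overall = cohort[cohort["in_overall"]]
        cci = comorbidity.cci_table(dataset.medical, overall, config.cci_window_days)
        results["cci"] = cci

        stage = "hcru"
        summaries = hcru.summarize_hcru(
            dataset, cohort, hcru.HcruConfig(config.follow_up_days, config.grace_days))
        results["hcru"] = summaries
        flags = patient_product_flags(dataset.pharmacy)
        related_cvad_ids = set(
            cvads.loc[cvads["related"] == True, "patient_id"])  # noqa: E712
        c1_user = flags["c1inh_iv"].reindex(summaries["patient_id"]).fillna(False)
        c1_user.index = summaries["patient_id"]
        cvad_user = pd.Series(
            [pid in related_cvad_ids for pid in summaries["patient_id"]],
            index=summaries["patient_id"])
        results["table4"] = hcru.crude_rate_table(summaries, c1_user, cvad_user)

        stage = "table2"
        results["table2"] = render_table2(dataset, cohort)
        results["table1"] = render_table1(dataset, overall, cci)

        stage = "stats_matching"
        results.update(_rr_stage(dataset, cohort, cci, summaries,
                                 cvad_user, config))
    except Exception:
        logger.error("pipeline stage %r failed", stage)
        results["failed_stage"] = stage
        raise
    return results


def _rr_stage(dataset, cohort, cci, summaries, cvad_user, config: PipelineConfig) -> dict:
    """Propensity fit, matching, balance and RR on the HCRU cohort."""
    out: dict = {}
    hcru_cohort = cohort[cohort["in_hcru"]].set_index("patient_id")
    ids = summaries["patient_id"]
    if len(ids) == 0 or cvad_user.sum() == 0 or (~cvad_user).sum() == 0:
        out["rr"] = {"skipped": "needs exposed and unexposed patients with follow-up"}
        return out
    pats = dataset.patients.set_index("patient_id").reindex(ids)
    cci_s = cci.set_index("patient_id")["cci_score"].reindex(ids).fillna(0)
    course = _initial_treatment_course(dataset, cohort[cohort["in_hcru"]])
    covars = pd.DataFrame({
        "age": [pd.Timestamp(hcru_cohort.loc[pid, "index_date"]).year - pats.loc[pid, "birth_year"]
                for pid in ids],
        "region": pats["region"].values,
        "payer": pats["payer"].values,
        "insurance_type": pats["insurance_type"].values,
        "pharmacy_benefit": pats["pharmacy_benefit"].values,
        "initial_treatment_course": course.reindex(ids).values,
        "cci": cci_s.values,
    }, index=ids)
    exposure = cvad_user.astype(bool)
    outcome = (summaries["any_hosp"] | summaries["any_ed"]).astype(int)
    outcome.index = ids

    fit = matching.fit_propensity(covars, exposure, config.min_level_size)
    out["propensity"] = {"converged": fit.converged, "separation": fit.separation}
    matched = matching.match_pairs(fit, exposure, seed=config.seed,
                                   caliper_sd=config.caliper_sd)
    out["matched"] = {"n_pairs": len(matched.pairs),
                      "n_unmatched_exposed": len(matched.unmatched_exposed),
                      "caliper": matched.caliper}
    out["smd"] = matching.balance_diagnostics(covars, exposure, matched)

    estimates = {}
    m_ids = matched.exposed_ids + matched.control_ids
    if m_ids and outcome.loc[m_ids].sum() > 0:
        try:
            cov_m = covars.loc[m_ids]
            n_events = int(outcome.loc[m_ids].sum())
            n_params = matching.build_design(cov_m, config.min_level_size).shape[1]
            if n_params * 5 > n_events:
                # small matched sets cannot support the full dummy expansion;
                # adjust for the continuous covariates only (~5 events/param)
                cov_m = cov_m[["age", "cci"]]
            est = matching.estimate_rr(outcome.loc[m_ids], exposure.loc[m_ids],
                                       cov_m)
            if est.se_log_rr > 10 or not np.isfinite(est.rr):
                est.unstable = True
            estimates["matched_adjusted"] = est.as_dict()
        except Exception as exc:  # tiny matched sets can defeat adjustment
            logger.warning("adjusted matched RR failed (%s); reporting crude", exc)
        try:
            estimates.setdefault("matched_crude", matching.estimate_rr(
                outcome.loc[m_ids], exposure.loc[m_ids]).as_dict())
        except Exception as exc:
            logger.warning("crude matched RR failed: %s", exc)
    if outcome.sum() > 0:
        try:
            estimates["full_adjusted"] = matching.estimate_rr(
                outcome, exposure, covars).as_dict()
        except Exception as exc:
            logger.warning("full-cohort adjusted RR failed: %s", exc)
    out["rr"] = estimates
    return out


# ---------------------------------------------------------------------------
# rendering

def _df_to_markdown(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join("" if pd.isna(v) else str(v) for v in row) + " |")
    return "\n".join(lines)


def render_report(results: dict) -> str:
    """Markdown report body (no timestamps: reruns are byte-identical)."""
    parts = ["# HAE claims analysis report", ""]
    t1 = results.get("table1", {})
    parts += ["## Baseline characteristics", "",
              f"- Patients in overall cohort: {t1.get('n')}",
              f"- Female: {t1.get('pct_female')}%",
              f"- Mean age at index: {t1.get('mean_age')}",
              f"- Mean Charlson score (6-month pre-index): {t1.get('mean_cci')}", ""]
    parts += ["## Attrition", "", _df_to_markdown(results["attrition"]), ""]
    parts += ["## Medication usage categories", "",
              _df_to_markdown(results["table2"]), ""]
    es = results["episode_summary"]
    parts += ["## C1-INH(IV) treatment episodes", "",
              f"- Prophylactic episodes: {es['n_prophylactic']} in "
              f"{es['n_patients_prophylactic']} patients",
              f"- On-demand episodes: {es['n_on_demand']}; "
              f"unclassified (<13 weeks): {es['n_unclassified']}",
              f"- Episodes with >=1 rescue fill: {es['n_prophylactic_with_rescue']}"
              f" ({es['pct_prophylactic_with_rescue']}%)",
              f"- Prophylactic duration mean/median (days): "
              f"{es['duration_mean_days']}/{es['duration_median_days']}", ""]
    cs = results["complication_summary"]
    parts += ["## CVAD complications (related devices)", "",
              f"- Patients with a related CVAD: {cs['n_cvad_patients']}",
              f"- Any major complication: {cs['any_complication']['n']} "
              f"({cs['any_complication']['pct']}%)",
              f"- Mechanical: {cs['mechanical']['n']} ({cs['mechanical']['pct']}%)"
              f"; replacement: {cs['replacement']['n']} ({cs['replacement']['pct']}%)"
              f"; infection (other/unspec): {cs['infection_other_unspec']['n']}"
              f" ({cs['infection_other_unspec']['pct']}%)"
              f"; infection (local): {cs['infection_local']['n']}"
              f" ({cs['infection_local']['pct']}%)", ""]
    parts += ["## Crude HCRU rates (study period)", "",
              _df_to_markdown(results["table4"]), ""]
    rr = results.get("rr", {})
    parts += ["## Relative risk of hospitalization and/or ED visit "
              "(CVAD vs no CVAD, 12-month follow-up)", ""]
    if isinstance(rr, dict):
        for key in ("matched_adjusted", "matched_crude", "full_adjusted"):
            if key in rr:
                e = rr[key]
                parts.append(
                    f"- {key}: RR {e['rr']:.2f} (95% CI {e['ci_low']:.2f}, "
                    f"{e['ci_high']:.2f}); n={e['n_exposed']}+{e['n_control']}"
                    + (" [unstable]" if e.get("unstable") else ""))
        if "skipped" in rr:
            parts.append(f"- skipped: {rr['skipped']}")
    parts.append("")
    return "\n".join(parts)


def headline_summary(results: dict) -> dict:
    """JSON-serializable summary of the headline numbers."""
    es = results["episode_summary"]
    cs = results["complication_summary"]
    t4 = results["table4"].set_index("stratum")
    return {
        "n_overall": int(results["cohort"]["in_overall"].sum()),
        "n_hcru": int(results["cohort"]["in_hcru"].sum()),
        "n_prophylactic_episodes": es["n_prophylactic"],
        "n_patients_prophylactic": es["n_patients_prophylactic"],
        "pct_prophylactic_with_rescue": es["pct_prophylactic_with_rescue"],
        "n_cvad_patients": cs["n_cvad_patients"],
        "pct_cvad_any_complication": cs["any_complication"]["pct"],
        "table4": {s: {"n": int(t4.loc[s, "n"]),
                       "pct_hosp": t4.loc[s, "pct_hospitalization"],
                       "pct_ed": t4.loc[s, "pct_ed_visit"]}
                   for s in t4.index},
        "rr": results.get("rr", {}),
    }


def write_outputs(results: dict, outdir) -> None:
    """Write stage CSVs, the markdown report and the JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("cohort", "attrition", "episodes", "cvads", "cci",
                 "hcru", "table2", "table4"):
        if name in results and isinstance(results[name], pd.DataFrame):
            results[name].to_csv(outdir / f"{name}.csv", index=False)
    if "smd" in results and isinstance(results["smd"], pd.DataFrame):
        results["smd"].to_csv(outdir / "smd.csv", index=False)
    (outdir / "report.md").write_text(render_report(results))
    (outdir / "summary.json").write_text(
        json.dumps(headline_summary(results), indent=2, default=str))
    if "rr" in results:
        (outdir / "rr.json").write_text(
            json.dumps(results["rr"], indent=2, default=str))
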