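"""End-to-end orchestration: generation/ingest -> QC -> scoring -> statistics.

The stage order is fixed: scan QC, 3-SD outlier exclusion, calibration fit
on the designated calibration arm, out-of-sample MGR scoring, EMA filtering
and summarization, then the statistical report.  Every excluded record
lands in the exclusion ledger with its reasons, so input counts reconcile
with analyzed counts at each stage.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import ema as ema_mod
from . import io as io_mod
from . import markers, mgr as mgr_mod, mrs, stats, synthetic
from .config import (EMA_GROUPS, GROUP_MDD, GROUP_NSC, GROUPS, STRESS_GROUPS,
                     PipelineConfig)


class EmptySampleError(RuntimeError):
    def __init__(self, message, ledger=None):
        super().__init__(message)
        self.ledger = ledger or []


def load_tables(config: PipelineConfig) -> dict:
    config.validate()
    if config.input_dir is not None:
        return io_mod.read_study(config.input_dir)
    return synthetic.simulate_study(config.generator)


def score_tables(tables: dict, config: PipelineConfig) -> dict:
    """QC, percent change, outlier flags, calibration, MGR, EMA scoring.

    Returns scored tables plus the exclusion ledger.  The calibration line
    is fitted only on the named calibration arm (after QC and outlier
    exclusion) and applied out-of-sample to the other stressed arms.
    """
    participants = tables["participants"]
    ledger = []

    changes = mrs.metabolite_changes(
        tables["mrs_scans"], min_snr=config.min_snr, max_fwhm=config.max_fwhm,
        max_crlb_glu=config.max_crlb_glu)
    for _, row in changes.loc[~changes["qc_pass"]].iterrows():
        ledger.append({"stage": "scan_qc", "id": row["id"],
                       "reasons": row["exclusion_reasons"]})
    if changes["qc_pass"].sum() >= 2:
        changes = mrs.flag_change_outliers(changes, "pct_change_glu",
                                           z_thresh=config.outlier_z)
    else:
        changes["outlier"] = False
    for _, row in changes.loc[changes["outlier"]].iterrows():
        ledger.append({"stage": "outlier", "id": row["id"],
                       "reasons": f"pct_change_glu beyond "
                                  f"{config.outlier_z} SD"})
    changes["analyzable"] = changes["qc_pass"] & ~changes["outlier"]

    analyzable = participants.merge(
        changes.loc[changes["analyzable"]], on="id")
    calib = analyzable[analyzable["group"] == config.calibration_group]
    if len(calib) < 3:
        raise EmptySampleError("calibration sample has fewer than 3 "
                               "analyzable participants", ledger)
    model = mgr_mod.fit_calibration(calib["pss"], calib["pct_change_glu"],
                                    sample_label=config.calibration_group)
    scored = analyzable[analyzable["group"].isin(EMA_GROUPS)]
    mgr_table = mgr_mod.score_mgr(scored, scored, model)

    out = {
        "changes": changes,
        "calibration": model,
        "mgr": mgr_table,
        "cortisol_scored": markers.cortisol_percent_change(tables["cortisol"]),
        "vams_scored": markers.vams_negative_score(tables["vams"]),
        "ledger": ledger,
    }

    if "ema_surveys" in tables and len(tables["ema_surveys"]):
        filtered = ema_mod.filter_surveys(tables["ema_surveys"])
        pairs = ema_mod.build_matched_pairs(filtered)
        summaries = ema_mod.summarize_all(
            filtered, pairs, min_usable=config.min_usable_surveys)
        for _, row in summaries.loc[~summaries["included"]].iterrows():
            ledger.append({"stage": "ema_usable", "id": row["id"],
                           "reasons": f"{row['n_valid_surveys']} usable "
                                      f"surveys < {config.min_usable_surveys}"})
        out.update({"ema_filtered": filtered, "ema_pairs": pairs,
                    "ema_summaries": summaries})
    return out


EMA_VARIABLES = ("mean_expected", "mean_experienced", "inaccuracy",
                 "pessimistic_mean", "optimistic_mean", "prop_accurate",
                 "prop_pessimistic", "prop_optimistic", "positive_affect",
                 "negative_affect")


def run_analysis(config: PipelineConfig) -> dict:
    """Compute the full report: manipulation checks, metabolite statistics,
    calibration/MGR, and EMA associations, plus the exclusion ledger."""
    config.validate()
    tables = load_tables(config)
    if len(tables["participants"]) == 0:
        raise EmptySampleError("no participants in input")
    scored = score_tables(tables, config)
    participants = tables["participants"]
    changes = scored["changes"]
    analyzable = participants.merge(changes.loc[changes["analyzable"]],
                                    on="id")
    if analyzable.empty:
        raise EmptySampleError("no analyzable participants after QC",
                               scored["ledger"])

    report = {"config": {"seed": config.seed,
                         "calibration_group": config.calibration_group},
              "n_input": int(len(participants)),
              "n_analyzable": int(len(analyzable))}

    report["manipulation_checks"] = _manipulation_checks(
        participants, scored, tables)
    report["metabolites"] = _metabolite_stats(analyzable)
    report["mgr"] = {
        "calibration": scored["calibration"].to_dict(),
        "n_scored": int(len(scored["mgr"])),
        "mean_mgr": float(scored["mgr"]["mgr"].mean())
        if len(scored["mgr"]) else None,
    }
    if "ema_summaries" in scored:
        report["ema"] = _ema_stats(participants, scored, config)
    report["exclusions"] = scored["ledger"]
    report["n_excluded"] = int(changes["analyzable"].eq(False).sum())
    return report


def _diag(group: str) -> str:
    if group == GROUP_NSC:
        return "nsc"
    return "mdd" if group == GROUP_MDD else "hc_stress"


def _manipulation_checks(participants, scored, tables) -> dict:
    out = {}
    pmap = participants.set_index("id")

    vams = scored["vams_scored"].copy()
    vams["arm"] = pmap.loc[vams["id"], "group"].map(_diag).to_numpy()
    out["vams_anova"] = stats.rm_anova_gg(
        vams, dv="negative_affect", within="timepoint", subject="id",
        between="arm", correction="always").to_dict()

    cort = scored["cortisol_scored"]
    cort = cort[cort["scorable"]].copy()
    long = cort.melt(id_vars="id",
                     value_vars=["pct_pre_mast", "pct_post1", "pct_post2"],
                     var_name="timepoint", value_name="pct")
    long["arm"] = pmap.loc[long["id"], "group"].map(_diag).to_numpy()
    out["cortisol_anova"] = stats.rm_anova_gg(
        long, dv="pct", within="timepoint", subject="id", between="arm",
        correction="always").to_dict()
    stress_ids = participants.loc[
        participants["group"].isin(STRESS_GROUPS), "id"]
    stress_cort = cort[cort["id"].isin(stress_ids)]
    if len(stress_cort) >= 2:
        out["cortisol_d"] = markers.standardized_mean_change(
            np.zeros(len(stress_cort)), stress_cort["pct_post1"].to_numpy())
        out["cortisol_t_stress"] = stats.paired_t(
            np.zeros(len(stress_cort)),
            stress_cort["pct_post1"].to_numpy()).to_dict()

    ratings = {}
    for col in ("rating_stress", "rating_unpleasant", "rating_difficulty"):
        cells = [participants.loc[participants["group"].map(_diag) == a, col]
                 .dropna().to_numpy() for a in ("nsc", "hc_stress", "mdd")]
        if all(len(c) >= 2 for c in cells):
            from scipy.stats import f_oneway
            F, p = f_oneway(*cells)
            ratings[col] = {"F": float(F), "p": float(p)}
    out["ratings_anova"] = ratings
    return out


def _metabolite_stats(analyzable: pd.DataFrame) -> dict:
    out = {"per_group_spearman": {}}
    for group in GROUPS:
        sub = analyzable[analyzable["group"] == group]
        if len(sub) < 4:
            continue
        gout = {}
        for metric in ("pct_change_glu", "pct_change_glx", "pct_change_cho"):
            try:
                gout[metric] = stats.spearman_correlation(
                    sub["pss"], sub[metric]).to_dict()
            except ValueError:
                pass
        out["per_group_spearman"][group] = gout

    # moderation by acute stress among healthy controls
    hc = analyzable[analyzable["group"] != GROUP_MDD].copy()
    if len(hc) >= 10:
        out["stress_interaction"] = _moderation(
            hc, dummy=(hc["condition"] == "stress").astype(float),
            dummy_name="acute_stress")
    # moderation by diagnosis among stressed participants
    stressed = analyzable[analyzable["condition"] == "stress"].copy()
    if len(stressed) >= 10:
        out["diagnosis_interaction"] = _moderation(
            stressed, dummy=(stressed["group"] == GROUP_MDD).astype(float),
            dummy_name="mdd")
        out["quadratic_pss"] = stats.quadratic_term_model(
            stressed["pct_change_glu"].to_numpy(),
            stressed["pss"].to_numpy()).to_dict()
    return out


def _moderation(df: pd.DataFrame, dummy: pd.Series, dummy_name: str) -> dict:
    pss_c = df["pss"] - df["pss"].mean()
    age_c = df["age"] - df["age"].mean()
    block1 = pd.DataFrame({"pss": pss_c.to_numpy(),
                           dummy_name: dummy.to_numpy()})
    block2 = pd.DataFrame({
        "site": (df["site"] == "emory").astype(float).to_numpy(),
        "age": age_c.to_numpy(),
        "sex": (df["sex"] == "F").astype(float).to_numpy(),
        f"pss_x_{dummy_name}": (pss_c * dummy.to_numpy()).to_numpy(),
    })
    # drop constant candidates (e.g. single-site subsets)
    block2 = block2.loc[:, block2.std() > 0]
    return stats.hierarchical_stepwise_regression(
        df["pct_change_glu"].to_numpy(), block1, block2).to_dict()


def _ema_stats(participants, scored, config: PipelineConfig) -> dict:
    summaries = scored["ema_summaries"]
    included = summaries[summaries["included"]].merge(
        participants[["id", "group", "age", "sex", "pss"]], on="id")
    included["mdd"] = (included["group"] == GROUP_MDD).astype(float)
    included = included.merge(scored["mgr"][["id", "mgr"]], on="id",
                              how="left")
    out = {"n_included": int(len(included)),
           "group_means": {}, "group_tests": {}, "mgr_partial": {}}

    hc = included[included["mdd"] == 0]
    mdd = included[included["mdd"] == 1]
    for var in EMA_VARIABLES:
        a, b = mdd[var].dropna(), hc[var].dropna()
        out["group_means"][var] = {"hc": float(b.mean()) if len(b) else None,
                                   "mdd": float(a.mean()) if len(a) else None}
        if len(a) >= 2 and len(b) >= 2:
            try:
                out["group_tests"][var] = stats.independent_t(a, b).to_dict()
            except ZeroDivisionError:
                pass

    covars = ["age", "sex_f", "mdd"]
    included["sex_f"] = (included["sex"] == "F").astype(float)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    for var in EMA_VARIABLES:
        sub = included.dropna(subset=[var, "mgr"])
        if len(sub) < len(covars) + 4:
            continue
        try:
            res = stats.pearson_partial_correlation(
                sub["mgr"], sub[var], sub[covars], covariate_labels=covars)
        except ValueError:
            continue
        if config.bootstrap_B > 0:
            data = sub[["mgr", var] + covars].to_numpy(dtype=float)
            def stat(d):
                return stats.pearson_partial_correlation(
                    d[:, 0], d[:, 1], d[:, 2:]).r
            boot = stats.bootstrap_ci(stat, data, B=config.bootstrap_B,
                                      rng=rng)
            res.ci95 = (boot.ci_low, boot.ci_high)
        out["mgr_partial"][var] = res.to_dict()

    # pessimistic-expectation association, additionally controlling PSS
    sub = included.dropna(subset=["pessimistic_mean", "mgr", "pss"])
    if len(sub) >= 8:
        out["mgr_pessimism_pss_controlled"] = \
            stats.pearson_partial_correlation(
                sub["mgr"], sub["pessimistic_mean"],
                sub[covars + ["pss"]],
                covariate_labels=covars + ["pss"]).to_dict()

    # Steiger comparison restricted to subjects with both directions present
    both = included.dropna(subset=["pessimistic_mean", "optimistic_mean",
                                   "mgr"])
    if len(both) >= len(covars) + 5:
        r_pess = stats.pearson_partial_correlation(
            both["mgr"], both["pessimistic_mean"], both[covars]).r
        r_opt = stats.pearson_partial_correlation(
            both["mgr"], both["optimistic_mean"], both[covars]).r
        r_po = stats.pearson_partial_correlation(
            both["pessimistic_mean"], both["optimistic_mean"], both[covars]).r
        out["steiger"] = stats.steiger_z(
            r_pess, r_opt, r_po, len(both)).to_dict()
    return out


# ---------------------------------------------------------------------------
# serialization


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def save_report(report: dict, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / "report.json"
    path.write_text(json.dumps(_jsonify(report), indent=2, allow_nan=False))
    (directory / "report.txt").write_text(render_report(report))
    return path


def render_report(report: dict) -> str:
    """Human-readable digest mirroring the result sections."""
    lines = ["Stress-glutamate analysis report",
             "=" * 36,
             f"participants: {report['n_input']} "
             f"(analyzable {report['n_analyzable']})"]
    cal = report["mgr"]["calibration"]
    lines.append(f"calibration line: expected %dGlu = "
                 f"{cal['intercept']:.3f} + ({cal['slope']:.3f}) * PSS "
                 f"(n={cal['n_calibration']}, {cal['sample_label']})")
    spear = report["metabolites"]["per_group_spearman"]
    lines.append("")
    lines.append("PSS vs %dGlu (Spearman):")
    for group, gout in spear.items():
        if "pct_change_glu" in gout:
            r = gout["pct_change_glu"]
            lines.append(f"  {group:24s} r={r['r']:+.3f} "
                         f"df={r['df']} p={r['p']:.4f}")
    if "ema" in report:
        lines.append("")
        lines.append(f"EMA participants included: {report['ema']['n_included']}")
        for var, res in report["ema"].get("mgr_partial", {}).items():
            lines.append(f"  MGR ~ {var:18s} r_partial={res['r']:+.3f} "
                         f"df={res['df']} p={res['p']:.4f}")
    lines.append("")
    lines.append(f"exclusions: {len(report['exclusions'])} record(s)")
    for e in report["exclusions"]:
        lines.append(f"  [{e['stage']}] {e['id']}: {e['reasons']}")
    return "\n".join(lines) + "\n"


def simulate_to_dir(config: PipelineConfig, directory) -> dict:
    tables = load_tables(config)
    return io_mod.write_tables(tables, directory)


def score_to_dir(config: PipelineConfig, directory) -> dict:
    """Write scored intermediate tables (changes, MGR, EMA tables)."""
    tables = load_tables(config)
    scored = score_tables(tables, config)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    scored["changes"].to_csv(directory / "metabolite_changes.csv", index=False)
    paths["metabolite_changes"] = directory / "metabolite_changes.csv"
    scored["mgr"].to_csv(directory / "mgr.csv", index=False)
    paths["mgr"] = directory / "mgr.csv"
    (directory / "calibration.json").write_text(
        json.dumps(scored["calibration"].to_dict(), indent=2))
    paths["calibration"] = directory / "calibration.json"
    for key, fname in (("ema_filtered", "ema_valid.csv"),
                       ("ema_pairs", "ema_pairs.csv"),
                       ("ema_summaries", "ema_summaries.csv")):
        if key in scored:
            scored[key].to_csv(directory / fname, index=False)
            paths[key] = directory / fname
    return paths
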