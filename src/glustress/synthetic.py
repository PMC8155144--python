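"""Synthetic cohort, scan, cortisol, mood, and EMA stream generator.

The generator writes down a fully specified "stated world": four study arms
with the published group sizes and perceived-stress moments, a linear
PSS -> %dGlu law (with the published coefficients) active only in stressed
healthy controls, cortisol and mood responses present only under the acute
stressor, and EMA streams whose latent pessimistic-expectation magnitude is
coupled to each subject's maladaptive glutamate response through a Gaussian
copula.  All randomness flows through one seeded generator consumed in a
fixed order, so identical configurations yield byte-identical tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ema as ema_mod
from .config import (EMA_GROUPS, GROUP_MDD, GROUPS, STRESS_GROUPS,
                     GeneratorConfig)

EMA_START_DATE = np.datetime64("2021-03-01")

#: VAMS bipolar items with the stored position of the positive mood pole.
#: Items listed positive-pole-low are stored on a negativity scale directly;
#: the mixed orientations exercise the reflection step downstream.
VAMS_ITEMS = (
    ("happy_sad", "high"),
    ("relaxed_tense", "high"),
    ("friendly_hostile", "low"),
    ("sociable_withdrawn", "low"),
    ("quickwitted_slow", "high"),
)


def generate_cohort(config: GeneratorConfig):
    """Participants, scan pairs, cortisol series, and mood series.

    Returns ``(participants, scans, cortisol, vams)`` DataFrames.  The
    post-stress metabolite ratio is derived from the baseline ratio and the
    target percent change ``multiplier * (intercept + slope * PSS) + noise``,
    so the percent-change equation recovers the generating value exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    participants, scans, cortisol, vams = [], [], [], []
    counter = 0
    for group in GROUPS:
        gp = config.groups[group]
        for _ in range(gp.n):
            counter += 1
            pid = f"S{counter:04d}"
            stress = group in STRESS_GROUPS
            z_age = rng.standard_normal()
            age = float(np.clip(gp.age_mean + gp.age_sd * z_age,
                                *config.age_range))
            sex = "F" if rng.random() < gp.female_frac else "M"
            pss = gp.pss_mean + gp.pss_sd * rng.standard_normal()
            if config.pss_clip:
                pss = float(np.clip(pss, 0.0, 40.0))
            # post-scan manipulation ratings, 1-5
            base = 3.4 if stress else 1.5
            ratings = np.clip(np.round(base + 0.8 * rng.standard_normal(3)),
                              1, 5)
            row = {
                "id": pid, "group": group,
                "condition": "stress" if stress else "no_stress",
                "site": gp.site, "age": round(age, 1), "sex": sex,
                "pss": round(float(pss), 3),
                "rating_stress": int(ratings[0]),
                "rating_unpleasant": int(ratings[1]),
                "rating_difficulty": int(ratings[2]),
            }
            if gp.site == "emory":
                row["strain_acute_count"] = int(rng.poisson(6))
                row["strain_chronic_count"] = int(rng.poisson(4))
            else:
                row["strain_acute_count"] = np.nan
                row["strain_chronic_count"] = np.nan
            participants.append(row)
            scans.extend(_scan_pair(rng, config, pid, z_age, pss,
                                    gp.slope_multiplier))
            cortisol.extend(_cortisol_series(rng, config, pid, stress))
            vams.extend(_vams_series(rng, config, pid, group, stress))
    return (pd.DataFrame(participants), pd.DataFrame(scans),
            pd.DataFrame(cortisol), pd.DataFrame(vams))


def _scan_pair(rng, config, pid, z_age, pss, multiplier):
    # age / baseline-glutamate Gaussian copula
    rho = config.age_glu_corr
    z_glu = rho * z_age + np.sqrt(1.0 - rho * rho) * rng.standard_normal()
    glu_pre = max(config.baseline_glu_mean + config.baseline_glu_sd * z_glu,
                  0.05)
    glx_pre = max(config.baseline_glx_mean
                  + config.baseline_glx_sd * rng.standard_normal(), 0.05)
    cho_pre = max(config.baseline_cho_mean
                  + config.baseline_cho_sd * rng.standard_normal(), 0.01)
    pct_glu = (multiplier * (config.intercept + config.slope * pss)
               + config.residual_sd * rng.standard_normal())
    pct_glu = max(pct_glu, -95.0)      # keep the post ratio positive
    pct_glx = (config.glx_glu_coupling * pct_glu
               + config.glx_extra_sd * rng.standard_normal())
    pct_glx = max(pct_glx, -95.0)
    pct_cho = max(config.cho_change_sd * rng.standard_normal(), -95.0)
    rows = []
    for session, f_glu, f_glx, f_cho in (
            ("pre", 1.0, 1.0, 1.0),
            ("post", 1.0 + pct_glu / 100.0, 1.0 + pct_glx / 100.0,
             1.0 + pct_cho / 100.0)):
        snr = config.snr_mean + config.snr_sd * rng.standard_normal()
        fwhm = max(config.fwhm_mean + config.fwhm_sd * rng.standard_normal(),
                   0.02)
        crlb = max(config.crlb_mean + config.crlb_sd * rng.standard_normal(),
                   1.0)
        if config.qc_fail_fraction and rng.random() < config.qc_fail_fraction:
            kind = rng.integers(3)
            if kind == 0:
                snr = 6.0
            elif kind == 1:
                fwhm = 0.25
            else:
                crlb = 30.0
        rows.append({"id": pid, "session": session,
                     "glu_cr": glu_pre * f_glu, "glx_cr": glx_pre * f_glx,
                     "cho_cr": cho_pre * f_cho, "snr": snr, "fwhm": fwhm,
                     "crlb_glu": crlb})
    return rows


def _cortisol_series(rng, config, pid, stress):
    base = config.cortisol_baseline_mean * np.exp(
        config.cortisol_baseline_sigma * rng.standard_normal())
    if stress:
        rises = (config.cortisol_peak_rise, config.cortisol_late_rise)
    else:
        rises = config.cortisol_nsc_drift
    pcts = [max(r + config.cortisol_noise_sd * rng.standard_normal(), -95.0)
            for r in rises]
    return [
        {"id": pid, "timepoint": "pre_mast", "nmol_per_l": base},
        {"id": pid, "timepoint": "post1",
         "nmol_per_l": base * (1 + pcts[0] / 100.0)},
        {"id": pid, "timepoint": "post2",
         "nmol_per_l": base * (1 + pcts[1] / 100.0)},
    ]


def _vams_series(rng, config, pid, group, stress):
    traj = np.array(config.vams_stress_traj if stress
                    else config.vams_nsc_traj)
    if group == GROUP_MDD:
        traj = traj + config.vams_mdd_offset
    offset = config.vams_subject_sd * rng.standard_normal()
    rows = []
    for t, level in enumerate(traj, start=1):
        for item, pole in VAMS_ITEMS:
            neg = np.clip(level + offset
                          + config.vams_item_sd * rng.standard_normal(),
                          0.0, 100.0)
            score = 100.0 - neg if pole == "high" else neg
            rows.append({"id": pid, "timepoint": t, "item": item,
                         "score": round(float(score), 1),
                         "positive_pole": pole})
    return rows


def true_mgr(participants: pd.DataFrame, scans: pd.DataFrame,
             config: GeneratorConfig) -> pd.DataFrame:
    """Generating-law maladaptive response for the EMA arms.

    The latent maladaptive response is the deviation of the realized percent
    glutamate change from the healthy calibration law (multiplier 1) at the
    subject's PSS — the quantity the analysis estimates with a fitted line.
    """
    wide = scans.pivot(index="id", columns="session", values="glu_cr")
    pct = 100.0 * (wide["post"] - wide["pre"]) / wide["pre"]
    sub = participants[participants["group"].isin(EMA_GROUPS)]
    expected = config.intercept + config.slope * sub["pss"].to_numpy()
    return pd.DataFrame({
        "id": sub["id"].to_numpy(),
        "mgr": pct.loc[sub["id"]].to_numpy() - expected,
    })


def generate_ema_streams(participants: pd.DataFrame, mgr_values: pd.DataFrame,
                         config: GeneratorConfig) -> pd.DataFrame:
    """Four-week alternate-day survey streams coupled to the MGR.

    Every participant in ``mgr_values`` gets up to ``n_days`` active days of
    six two-hourly surveys with send/start/completion timestamps, affect
    items, an expectation, and an outcome referring to the previous valid
    survey's planned activity.  The per-subject latent pessimistic-delta
    magnitude is ``pess_magnitude_mean + pess_magnitude_sd * z_p`` where
    ``z_p`` correlates with the group-standardized MGR at ``coupling``
    (Gaussian copula), so the configured coupling is the target
    group-adjusted correlation between MGR and the scored pessimistic mean.
    A configurable fraction of surveys is corrupted with labeled validity
    violations; the ``corruption`` and ``expected_valid`` columns record the
    injected label and the validity the scoring filter should reproduce.
    """
    config.validate()
    ep = config.ema
    missing = set(mgr_values["id"]) - set(participants["id"])
    if missing:
        raise ValueError(f"unknown participant id(s): {sorted(missing)}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7_919]))
    info = participants.set_index("id")
    merged = mgr_values.merge(participants[["id", "group"]], on="id")
    merged["diag"] = np.where(merged["group"] == GROUP_MDD, "mdd", "hc")
    # group-standardize the MGR before coupling
    z = merged.groupby("diag")["mgr"].transform(
        lambda s: (s - s.mean()) / s.std(ddof=1) if s.std(ddof=1) > 0
        else s * 0.0)
    c = ep.coupling
    z_p = c * z.to_numpy() + np.sqrt(1 - c * c) * rng.standard_normal(len(z))
    pess_mag = np.maximum(
        ep.pess_magnitude_mean + ep.pess_magnitude_sd * z_p, 0.5)
    df = _survey_frame(rng, ep, merged["id"].to_numpy(),
                       merged["diag"].to_numpy(), pess_mag)
    # determine validity with the scoring filter itself, then chain
    # expectation -> outcome over valid surveys so the scored pairing
    # recovers the generated prediction errors
    flagged = ema_mod.filter_surveys(df.drop(columns=["corruption"]))
    df = df.iloc[flagged.index].reset_index(drop=True)  # same order
    df["expected_valid"] = flagged["valid"].to_numpy()
    df = _chain_outcomes(rng, ep, df)
    return df


def _survey_frame(rng, ep, ids, diags, pess_mags) -> pd.DataFrame:
    """All subjects' survey rows (timestamps, affect, expectations),
    without outcome chaining and with corruption injected."""
    n_sub = len(ids)
    per_day = ep.surveys_per_day
    n_per = ep.n_days * per_day
    N = n_sub * n_per
    day = np.tile(np.repeat(np.arange(ep.n_days), per_day), n_sub)
    k = np.tile(np.tile(np.arange(1, per_day + 1), ep.n_days), n_sub)
    dates = EMA_START_DATE + 2 * day
    sent = (dates.astype("datetime64[s]")
            + np.timedelta64(9 * 3600, "s")
            + ((k - 1) * 7200).astype("timedelta64[s]"))
    completed_flag = rng.random(N) < ep.completion_prob
    started = sent + rng.uniform(0, 300, N).astype("timedelta64[s]")
    completed = started + rng.uniform(60, 240, N).astype("timedelta64[s]")

    corruption = np.full(N, "", dtype=object)
    schedule_index = k.copy()
    corrupt = completed_flag & (rng.random(N) < ep.invalid_fraction)
    kinds = rng.integers(0, 4, N)
    kinds[(k == 1) & (kinds == 3)] = rng.integers(0, 3)  # no prior to crowd
    names = np.array(["too_fast", "too_late", "beyond_sixth", "off_schedule"])
    for i in np.flatnonzero(corrupt):
        kind = names[kinds[i]]
        if kind == "off_schedule":
            # land < 1 h after the previous completed survey of the day;
            # with no prior completion the spacing rule cannot fire, so
            # degrade to a too-fast violation instead
            anchor = None
            j = i - 1
            while j >= 0 and day[j] == day[i] and j // n_per == i // n_per:
                if completed_flag[j]:
                    anchor = completed[j]
                    break
                j -= 1
            if anchor is None:
                kind = "too_fast"
            else:
                completed[i] = anchor + np.timedelta64(30 * 60, "s")
        if kind == "too_fast":
            completed[i] = started[i] + np.timedelta64(10, "s")
        elif kind == "too_late":
            completed[i] = sent[i] + np.timedelta64(25 * 3600, "s")
        elif kind == "beyond_sixth":
            schedule_index[i] = 7
        corruption[i] = kind

    pos_mean = np.array([ep.pos_affect_mean[d] for d in diags])
    neg_mean = np.array([ep.neg_affect_mean[d] for d in diags])
    exp_mean = np.array([ep.expectation_mean[d] for d in diags])
    rep = np.repeat
    df = pd.DataFrame({
        "id": rep(ids, n_per),
        "date": np.datetime_as_string(dates, unit="D"),
        "schedule_index": schedule_index,
        "sent_at": np.datetime_as_string(sent, unit="s"),
        "started_at": np.datetime_as_string(started, unit="s"),
        "completed_at": np.datetime_as_string(completed, unit="s"),
        "corruption": corruption,
        "_pess_mag": rep(pess_mags, n_per),
        "_diag": rep(diags, n_per),
    })
    for item in ema_mod.POSITIVE_AFFECT_ITEMS:
        df[item] = np.clip(np.round(
            rep(pos_mean, n_per) + ep.affect_sd * rng.standard_normal(N)),
            1, 5)
    for item in ema_mod.NEGATIVE_AFFECT_ITEMS:
        df[item] = np.clip(np.round(
            rep(neg_mean, n_per) + ep.affect_sd * rng.standard_normal(N)),
            1, 5)
    df["expectation"] = np.clip(np.round(
        rep(exp_mean, n_per) + ep.expectation_sd * rng.standard_normal(N)),
        -4, 4)
    df["happened"] = False       # resolved by the chaining pass
    df["outcome"] = np.nan
    # unanswered surveys carry only delivery metadata
    miss = ~completed_flag
    for col in ("started_at", "completed_at", "corruption"):
        df.loc[miss, col] = ""
    for col in ema_mod.AFFECT_ITEMS + ("expectation", "outcome"):
        df.loc[miss, col] = np.nan
    return df


def _chain_outcomes(rng, ep, df: pd.DataFrame) -> pd.DataFrame:
    """Assign happened/outcome by walking valid surveys within each day."""
    df = df.copy()
    probs = {d: np.asarray(ep.class_probs[d]) for d in ep.class_probs}
    valid = df["expected_valid"].to_numpy()
    ids = df["id"].to_numpy()
    dates = df["date"].to_numpy()
    expectation = df["expectation"].to_numpy()
    pess_mag = df["_pess_mag"].to_numpy()
    diag = df["_diag"].to_numpy()
    happened = np.zeros(len(df), dtype=bool)
    outcome = np.full(len(df), np.nan)
    prev_exp = None
    prev_key = None
    for i in range(len(df)):
        key = (ids[i], dates[i])
        if key != prev_key:
            prev_exp, prev_key = None, key
        if not valid[i]:
            continue
        if prev_exp is not None and rng.random() < ep.happened_prob:
            cls = rng.choice(3, p=probs[diag[i]])
            if cls == 0:
                delta = 0
            elif cls == 1:
                delta = max(1, round(pess_mag[i] + ep.delta_noise_sd
                                     * rng.standard_normal()))
            else:
                delta = min(-1, round(ep.opt_magnitude_mean
                                      + ep.delta_noise_sd
                                      * rng.standard_normal()))
            happened[i] = True
            outcome[i] = int(np.clip(prev_exp + delta, -4, 4))
        prev_exp = expectation[i]
    df["happened"] = happened
    df["outcome"] = outcome
    return df.drop(columns=["_pess_mag", "_diag"])


def simulate_study(config: GeneratorConfig):
    """Full synthetic study: cohort plus coupled EMA streams.

    Returns a dict of tables keyed by the fixture file stems.
    """
    participants, scans, cortisol, vams = generate_cohort(config)
    mgr_true = true_mgr(participants, scans, config)
    surveys = generate_ema_streams(participants, mgr_true, config)
    return {"participants": participants, "mrs_scans": scans,
            "cortisol": cortisol, "vams": vams, "ema_surveys": surveys}
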