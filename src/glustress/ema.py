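"""Ecological-momentary-assessment scoring: validity filters, matched
expectation-outcome pairs, and per-participant summary variables.

Each survey carries current affect (six 1-5 items), an expectation for the
activity planned in the next two hours (-4..+4), and — referring back to the
activity planned at the previous survey — whether it happened and how it
went (-4..+4).  Scoring proceeds in three steps:

1. ``filter_surveys`` flags invalid surveys (incomplete, beyond the sixth of
   the day, filled in under 30 s, completed more than 24 h after delivery,
   or spaced outside 1-3 h from the prior completed survey of the day).
2. ``build_matched_pairs`` pairs each valid survey's reported outcome with
   the expectation recorded at the immediately preceding *valid* survey of
   the same day; the signed difference delta = outcome - expectation is a
   prediction error, classified pessimistic (delta > 0), accurate (0), or
   optimistic (delta < 0).
3. ``summarize_participant`` computes the per-participant summary variables
   (mean expectation, mean experienced outcome, expectation inaccuracy
   = mean |delta|, signed directional means, class proportions, mean
   positive/negative affect) and the >= 20 usable-surveys inclusion flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

POSITIVE_AFFECT_ITEMS = ("enthusiastic", "cheerful", "relaxed")
NEGATIVE_AFFECT_ITEMS = ("irritable", "anxious", "sad")
AFFECT_ITEMS = POSITIVE_AFFECT_ITEMS + NEGATIVE_AFFECT_ITEMS

MIN_DURATION_S = 30.0
MAX_LATENCY_H = 24.0
SPACING_H = (1.0, 3.0)
MAX_SCHEDULE_INDEX = 6
MIN_USABLE_SURVEYS = 20

#: exclusion-reason labels emitted by the filter
REASONS = ("incomplete", "bad_timestamp", "beyond_sixth", "too_fast",
           "too_late", "spacing")


def _to_ts(col: pd.Series) -> pd.Series:
    return pd.to_datetime(col, errors="coerce", format="ISO8601")


def _as_bool(col: pd.Series) -> pd.Series:
    """Coerce a happened-style column (bool, yes/no, 1/0, blank) to bool."""
    if col.dtype == bool:
        return col
    mapping = {True: True, False: False, "yes": True, "no": False,
               "true": True, "false": False, 1: True, 0: False,
               1.0: True, 0.0: False}
    return col.map(lambda v: mapping.get(
        v.lower() if isinstance(v, str) else v, False))


def filter_surveys(stream: pd.DataFrame, *,
                   min_duration_s: float = MIN_DURATION_S,
                   max_latency_h: float = MAX_LATENCY_H,
                   spacing_h: tuple = SPACING_H,
                   max_index: int = MAX_SCHEDULE_INDEX) -> pd.DataFrame:
    """Annotate every survey with ``valid`` and ``exclusion_reasons``.

    No rows are dropped; reasons enumerate every fired rule.  The filling
    duration is measured started -> completed, staleness sent -> completed,
    and the 1-3 h spacing (inclusive bounds) between the completion times of
    consecutive completed surveys within the same day — an unanswered survey
    therefore invalidates the next one by opening the gap, mirroring the
    study's usable-survey yield.  The filter is a pure annotation, so
    re-filtering its own output is a no-op.
    """
    df = stream.reset_index(drop=True).copy()
    sent = _to_ts(df["sent_at"])
    started = _to_ts(df["started_at"])
    completed = _to_ts(df["completed_at"])
    answered = (df["completed_at"].notna() & (df["completed_at"] != "")
                if df["completed_at"].dtype == object
                else df["completed_at"].notna())

    # sort by delivery time within participant-day before the spacing rule
    order = np.lexsort((sent.values.astype("datetime64[ns]"),
                        df["date"].to_numpy(), df["id"].to_numpy()))
    df = df.iloc[order].reset_index(drop=False)
    sent, started, completed = (s.iloc[order].reset_index(drop=True)
                                for s in (sent, started, completed))
    answered = answered.iloc[order].reset_index(drop=True).to_numpy()

    duration_s = (completed - started).dt.total_seconds().to_numpy()
    latency_h = ((completed - sent).dt.total_seconds() / 3600.0).to_numpy()
    # previous completed survey's completion time within the same day
    keys = [df["id"], df["date"]]
    prev_comp = (completed.groupby(keys, sort=False).ffill()
                 .groupby(keys, sort=False).shift())
    gap_h = ((completed - prev_comp).dt.total_seconds() / 3600.0).to_numpy()

    required = list(AFFECT_ITEMS) + ["expectation"]
    missing_fields = df[required].isna().any(axis=1).to_numpy()
    # an outcome is required whenever the activity is reported to have happened
    happened = _as_bool(df["happened"]).to_numpy()
    missing_fields |= happened & df["outcome"].isna().to_numpy()

    with np.errstate(invalid="ignore"):
        rule_matrix = np.column_stack([
            ~answered | (answered & missing_fields),                # incomplete
            answered & (completed.isna() | started.isna()
                        | sent.isna()).to_numpy(),                  # bad ts
            df["schedule_index"].to_numpy() > max_index,            # beyond 6th
            np.isfinite(duration_s) & (duration_s < min_duration_s),
            np.isfinite(latency_h) & (latency_h > max_latency_h),
            np.isfinite(gap_h) & ~((spacing_h[0] <= gap_h)
                                   & (gap_h <= spacing_h[1])),      # spacing
        ])
    labels = np.array(["incomplete", "bad_timestamp", "beyond_sixth",
                       "too_fast", "too_late", "spacing"])
    df = df.set_index("index").rename_axis(None)
    df["exclusion_reasons"] = [";".join(labels[m]) for m in rule_matrix]
    df["valid"] = ~rule_matrix.any(axis=1)
    return df


def classify_pair(delta: float) -> str:
    """Pessimistic if the outcome beat the expectation, optimistic if it
    fell short, accurate on exact agreement."""
    if delta > 0:
        return "pessimistic"
    if delta < 0:
        return "optimistic"
    return "accurate"


def build_matched_pairs(filtered: pd.DataFrame) -> pd.DataFrame:
    """Expectation-outcome pairs from the valid surveys.

    For each valid survey after the first valid survey of its day whose
    activity happened, the reported outcome is paired with the expectation
    recorded at the immediately preceding valid survey (invalid surveys are
    transparent).  Surveys whose activity did not happen, and first-of-day
    outcomes with no prior expectation, contribute no pair.
    """
    valid = filtered.loc[filtered["valid"]].copy()
    if valid.empty:
        return pd.DataFrame(columns=["id", "date", "expectation", "outcome",
                                     "delta", "cls"])
    sent = _to_ts(valid["sent_at"])
    valid = valid.iloc[np.lexsort((sent.values.astype("datetime64[ns]"),
                                   valid["date"].to_numpy(),
                                   valid["id"].to_numpy()))]
    prev_exp = valid.groupby(["id", "date"], sort=False)["expectation"].shift()
    happened = _as_bool(valid["happened"])
    mask = happened & prev_exp.notna() & valid["outcome"].notna()
    pairs = pd.DataFrame({
        "id": valid.loc[mask, "id"].to_numpy(),
        "date": valid.loc[mask, "date"].to_numpy(),
        "expectation": prev_exp.loc[mask].astype(float).to_numpy(),
        "outcome": valid.loc[mask, "outcome"].astype(float).to_numpy(),
    })
    pairs["delta"] = pairs["outcome"] - pairs["expectation"]
    pairs["cls"] = [classify_pair(d) for d in pairs["delta"]]
    return pairs


def summarize_participant(surveys: pd.DataFrame, pairs: pd.DataFrame,
                          participant_id,
                          min_usable: int = MIN_USABLE_SURVEYS) -> dict:
    """Summary variables for one participant.

    Denominators follow the variable definitions: expectations and affect
    average over all valid surveys; experienced outcome and inaccuracy over
    matched (happened) pairs; directional means over their class only, and
    are absent (NaN), not zero, when the class is empty.
    """
    s = surveys.loc[(surveys["id"] == participant_id) & surveys["valid"]]
    p = pairs.loc[pairs["id"] == participant_id]
    if len(s) < 1:
        raise ValueError(f"participant {participant_id!r} has no valid surveys")
    n_pairs = len(p)
    by_cls = {c: p.loc[p["cls"] == c, "delta"] for c in
              ("accurate", "pessimistic", "optimistic")}
    out = {
        "id": participant_id,
        "n_valid_surveys": int(len(s)),
        "n_pairs": int(n_pairs),
        "mean_expected": float(s["expectation"].astype(float).mean()),
        "mean_experienced": float(p["outcome"].mean()) if n_pairs else np.nan,
        "inaccuracy": float(p["delta"].abs().mean()) if n_pairs else np.nan,
        "pessimistic_mean": float(by_cls["pessimistic"].mean())
            if len(by_cls["pessimistic"]) else np.nan,
        "optimistic_mean": float(by_cls["optimistic"].mean())
            if len(by_cls["optimistic"]) else np.nan,
        "prop_accurate": len(by_cls["accurate"]) / n_pairs if n_pairs else np.nan,
        "prop_pessimistic": len(by_cls["pessimistic"]) / n_pairs if n_pairs else np.nan,
        "prop_optimistic": len(by_cls["optimistic"]) / n_pairs if n_pairs else np.nan,
        "positive_affect": float(
            s[list(POSITIVE_AFFECT_ITEMS)].astype(float).to_numpy().mean()),
        "negative_affect": float(
            s[list(NEGATIVE_AFFECT_ITEMS)].astype(float).to_numpy().mean()),
    }
    out["included"] = include_participant(out, min_usable=min_usable)
    return out


def include_participant(summary: dict, min_usable: int = MIN_USABLE_SURVEYS) -> bool:
    """Participants with fewer than ``min_usable`` valid surveys are excluded."""
    return summary["n_valid_surveys"] >= min_usable


def summarize_all(filtered: pd.DataFrame, pairs: pd.DataFrame,
                  min_usable: int = MIN_USABLE_SURVEYS) -> pd.DataFrame:
    """Participant-level summary table over every id with >= 1 valid survey."""
    ids = filtered.loc[filtered["valid"], "id"].unique()
    rows = [summarize_participant(filtered, pairs, pid, min_usable=min_usable)
            for pid in sorted(ids)]
    return pd.DataFrame(rows)
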