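"""Shared fixtures: a hand-scored EMA stream and small cohort configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

AFFECT = {"enthusiastic": 4, "cheerful": 4, "relaxed": 4,
          "irritable": 2, "anxious": 2, "sad": 2}


def survey_row(pid, date, k, sent, start=None, comp=None, expectation=np.nan,
               happened=False, outcome=np.nan, affect=True, **extra):
    row = {"id": pid, "date": date, "schedule_index": k,
           "sent_at": f"{date}T{sent}" if "T" not in sent else sent,
           "started_at": (f"{date}T{start}" if start and "T" not in start
                          else (start or "")),
           "completed_at": (f"{date}T{comp}" if comp and "T" not in comp
                            else (comp or "")),
           "expectation": expectation, "happened": happened,
           "outcome": outcome}
    for item, v in AFFECT.items():
        row[item] = float(v) if affect else np.nan
    row.update(extra)
    return row


@pytest.fixture
def hand_ema_stream():
    """Twelve surveys covering every validity violation and pair class.

    Hand-scored expectations are in ``hand_ema_expected``: six valid
    surveys; four matched pairs with deltas +1 (pessimistic), 0 (accurate),
    -3 and -1 (optimistic).
    """
    d1, d2 = "2021-03-01", "2021-03-03"
    rows = [
        # day 1
        survey_row("P1", d1, 1, "09:00:00", "09:05:00", "09:08:00",
                   expectation=2),                                   # valid
        survey_row("P1", d1, 2, "11:00:00", "11:03:00", "11:03:25",
                   expectation=0, happened=True, outcome=0),         # too_fast
        survey_row("P1", d1, 3, "13:00:00", "13:04:00", "13:06:00",
                   expectation=1, happened=True, outcome=3),         # valid
        survey_row("P1", d1, 4, "15:00:00", affect=False),           # incomplete
        survey_row("P1", d1, 5, "17:00:00", "17:02:00", "17:04:00",
                   expectation=0, happened=True, outcome=2),         # spacing
        survey_row("P1", d1, 6, "19:00:00", "19:01:00", "19:03:00",
                   expectation=1, happened=True, outcome=1),         # valid
        # day 2
        survey_row("P1", d2, 1, "09:00:00", "09:10:00", "09:12:00",
                   expectation=-1, happened=True, outcome=4),        # valid
        survey_row("P1", d2, 2, "11:00:00", "11:00:30", "11:02:00",
                   expectation=3, happened=True, outcome=-4),        # valid
        survey_row("P1", d2, 7, "13:00:00", "13:00:30", "13:02:00",
                   expectation=0),                                   # beyond 6th
        survey_row("P1", d2, 4, "15:00:00", "15:01:00", "15:03:00",
                   expectation=0, happened=True, outcome=2),         # valid
        survey_row("P1", d2, 5, "17:00:00", "17:05:00",
                   "2021-03-04T18:00:00", expectation=0),            # too_late
        survey_row("P1", d2, 6, "19:00:00", "19:02:00", "19:04:00",
                   expectation=2),                                   # spacing
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def hand_ema_expected():
    return {
        "n_valid_surveys": 6,
        "n_pairs": 4,
        "pair_deltas": [1.0, 0.0, -3.0, -1.0],
        "mean_expected": 1.0,
        "mean_experienced": 0.5,
        "inaccuracy": 1.25,
        "pessimistic_mean": 1.0,
        "optimistic_mean": -2.0,
        "prop_accurate": 0.25,
        "prop_pessimistic": 0.25,
        "prop_optimistic": 0.5,
        "positive_affect": 4.0,
        "negative_affect": 2.0,
        "included": False,
        "invalid_reasons": {1: "too_fast", 3: "incomplete", 4: "spacing",
                            8: "beyond_sixth", 10: "too_late", 11: "spacing"},
    }


def one_per_day_stream(pid, n_days, expectation=1, outcome=None):
    """n valid surveys, one per day (no spacing interactions)."""
    rows = []
    for d in range(n_days):
        date = str(np.datetime64("2021-03-01") + d)
        rows.append(survey_row(pid, date, 1, "09:00:00", "09:05:00",
                               "09:08:00", expectation=expectation,
                               happened=outcome is not None,
                               outcome=outcome if outcome is not None
                               else np.nan))
    return pd.DataFrame(rows)
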