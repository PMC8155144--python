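"""Manipulation-check scoring: salivary cortisol, mood ratings, effect size.

Cortisol reactivity is expressed as percent change from the pre-stressor
sample at each post-stressor timepoint.  Visual-analogue mood scale (VAMS)
items are bipolar 0-100 ratings; items whose positive mood pole sits at the
high end of the stored scale are reflected so that higher always means more
negative affect, then averaged per timepoint.  The magnitude of the
within-subject cortisol response is summarized by the standardized mean
change d = mean(post - pre) / sd(post - pre).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CORTISOL_TIMEPOINTS = ("pre_mast", "post1", "post2")


def cortisol_percent_change(cortisol: pd.DataFrame) -> pd.DataFrame:
    """Per-participant percent change from the pre-stressor timepoint.

    ``cortisol`` is long (id, timepoint, nmol_per_l).  Participants lacking
    any of the three timepoints, or with a non-positive baseline, are
    flagged ``scorable=False`` instead of being silently dropped.  The
    pre-stressor value maps to exactly 0 by construction.
    """
    rows = []
    for pid, grp in cortisol.groupby("id", sort=True):
        vals = grp.set_index("timepoint")["nmol_per_l"]
        row = {"id": pid}
        have_all = all(t in vals.index for t in CORTISOL_TIMEPOINTS)
        pre = vals.get("pre_mast", np.nan)
        if not have_all or not np.isfinite(pre) or pre <= 0:
            row.update({"scorable": False, "pct_pre_mast": np.nan,
                        "pct_post1": np.nan, "pct_post2": np.nan})
        else:
            row["scorable"] = True
            row["pct_pre_mast"] = 0.0
            for t in ("post1", "post2"):
                row[f"pct_{t}"] = 100.0 * (vals[t] - pre) / pre
        rows.append(row)
    return pd.DataFrame(rows)


def vams_negative_score(vams: pd.DataFrame) -> pd.DataFrame:
    """Mean negative-affect score per participant and timepoint.

    ``vams`` is long (id, timepoint, item, score, positive_pole) with scores
    on 0-100 and ``positive_pole`` in {"high", "low"} declaring where the
    positive mood pole sits on the stored scale.  Items with the positive
    pole at the high end are reflected (100 - x) before averaging, so the
    result increases with negative emotional experience.
    """
    poles = set(vams["positive_pole"].unique())
    unknown = poles - {"high", "low"}
    if unknown:
        raise ValueError(f"unknown item orientation(s): {sorted(unknown)}")
    if ((vams["score"] < 0) | (vams["score"] > 100)).any():
        raise ValueError("VAMS scores must lie in [0, 100]")
    coded = vams.copy()
    flip = coded["positive_pole"] == "high"
    coded.loc[flip, "score"] = 100.0 - coded.loc[flip, "score"]
    out = (coded.groupby(["id", "timepoint"], sort=True)["score"]
           .mean().rename("negative_affect").reset_index())
    return out


def standardized_mean_change(pre, post, *, standardizer: str = "change") -> float:
    """Standardized mean-change effect size for paired measurements.

    With ``standardizer="change"`` (default) the denominator is the sample
    SD of the change scores; ``"pre"`` uses the SD of the pre scores
    instead.  A zero-variance denominator with a nonzero mean change is
    undefined and raises; with zero mean change it returns 0.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be paired 1-d vectors")
    if len(pre) < 2:
        raise ValueError("need at least 2 pairs")
    change = post - pre
    if standardizer == "change":
        sd = change.std(ddof=1)
    elif standardizer == "pre":
        sd = pre.std(ddof=1)
    else:
        raise ValueError("standardizer must be 'change' or 'pre'")
    m = change.mean()
    if sd == 0:
        if m == 0:
            return 0.0
        raise ZeroDivisionError("zero-variance denominator with nonzero change")
    return float(m / sd)
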