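"""Maladaptive glutamate response (MGR): out-of-sample residual scoring.

In stressed healthy controls, percent change in mPFC glutamate falls
linearly with recent perceived stress (PSS).  That line, fitted by ordinary
least squares on the designated calibration sample only, defines the
*expected* change for any PSS score; a scored subject's MGR is

    MGR = %dGlu_observed - %dGlu_expected,

positive when glutamate rose more than the healthy calibration predicts.
The fit is on raw (uncentered) PSS so the intercept is the expected change
at PSS = 0, matching the published form of the line.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd


@dataclass
class CalibrationModel:
    intercept: float        # percent, expected change at PSS = 0
    slope: float            # percent per PSS unit
    n_calibration: int
    sample_label: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def fit_calibration(pss, pct_change_glu, sample_label: str = "") -> CalibrationModel:
    """OLS fit of percent glutamate change on PSS over the calibration sample.

    Residuals sum to zero over the fitted sample by construction.  Raises on
    fewer than 3 pairs or constant PSS.
    """
    pss = np.asarray(pss, dtype=float)
    y = np.asarray(pct_change_glu, dtype=float)
    if pss.shape != y.shape or pss.ndim != 1:
        raise ValueError("pss and pct_change_glu must be paired 1-d vectors")
    mask = np.isfinite(pss) & np.isfinite(y)
    pss, y = pss[mask], y[mask]
    if len(pss) < 3:
        raise ValueError("need at least 3 calibration pairs")
    if np.ptp(pss) == 0:
        raise ValueError("PSS is constant; the line is unidentifiable")
    slope, intercept = np.polyfit(pss, y, 1)
    return CalibrationModel(intercept=float(intercept), slope=float(slope),
                            n_calibration=int(len(pss)),
                            sample_label=sample_label)


def expected_change(pss, model: CalibrationModel):
    """Expected percent glutamate change at the given PSS score(s)."""
    pss = np.asarray(pss, dtype=float)
    out = model.intercept + model.slope * pss
    return float(out) if out.ndim == 0 else out


def compute_mgr(observed, expected):
    """Observed minus expected percent change (both finite, percent scale)."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    out = observed - expected
    return float(out) if out.ndim == 0 else out


def score_mgr(participants: pd.DataFrame, changes: pd.DataFrame,
              model: CalibrationModel) -> pd.DataFrame:
    """Per-subject MGR table for the given participants.

    ``participants`` needs ``id`` and ``pss``; ``changes`` needs ``id`` and
    ``pct_change_glu``.  The model must have been fitted on a disjoint
    calibration sample; this function never refits.
    """
    merged = participants[["id", "pss"]].merge(
        changes[["id", "pct_change_glu"]], on="id", how="inner")
    merged = merged.dropna(subset=["pss", "pct_change_glu"])
    exp = expected_change(merged["pss"].to_numpy(), model)
    obs = merged["pct_change_glu"].to_numpy()
    return pd.DataFrame({
        "id": merged["id"].to_numpy(),
        "pct_change_glu_observed": obs,
        "pct_change_glu_expected": exp,
        "mgr": compute_mgr(obs, exp),
    })
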