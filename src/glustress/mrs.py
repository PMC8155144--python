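"""Percent change in creatine-normalized MRS metabolites, with scan QC.

The core quantity is the relative change of a metabolite/creatine ratio
between a pre-stress and a post-stress acquisition,

    pct_change = 100 * (post - pre) / pre   (percent),

applied identically to Glu/Cr, Glx/Cr, and Cho/Cr.  Scans failing quality
control (low SNR, broad linewidth, or high glutamate CRLB) are excluded, as
are participants whose glutamate change is a 3-standard-deviation outlier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SESSIONS = ("pre", "post")
#: metabolite column stems handled by the one percent-change code path
METABOLITES = ("glu_cr", "glx_cr", "cho_cr")

# Strict-inequality QC rules: boundary values are retained.
DEFAULT_MIN_SNR = 9.0
DEFAULT_MAX_FWHM = 0.15
DEFAULT_MAX_CRLB_GLU = 20.0


def percent_change(pre, post):
    """Percent change of a positive ratio, on the 0-100 scale.

    Accepts scalars or arrays.  Raises ``ValueError`` on non-positive
    pre-stress values (the ratio scale has no meaningful zero crossing).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if np.any(pre <= 0):
        raise ValueError("pre-stress ratio must be strictly positive")
    out = 100.0 * (post - pre) / pre
    return float(out) if out.ndim == 0 else out


def apply_scan_qc(scans: pd.DataFrame, *, min_snr: float = DEFAULT_MIN_SNR,
                  max_fwhm: float = DEFAULT_MAX_FWHM,
                  max_crlb_glu: float = DEFAULT_MAX_CRLB_GLU) -> pd.DataFrame:
    """Flag individual scans against the quality thresholds.

    A scan fails iff snr < min_snr OR fwhm > max_fwhm OR crlb_glu >
    max_crlb_glu (all strict, so boundary values pass).  Returns a copy with
    ``qc_pass`` and ``qc_reasons`` (semicolon-joined labels) columns.
    """
    required = {"snr", "fwhm", "crlb_glu"}
    missing = required - set(scans.columns)
    if missing:
        raise ValueError(f"missing quality fields: {sorted(missing)}")
    if scans[list(required)].isna().any().any():
        raise ValueError("quality fields contain missing values")
    out = scans.copy()
    reasons = []
    for snr, fwhm, crlb in zip(out["snr"], out["fwhm"], out["crlb_glu"]):
        r = []
        if snr < min_snr:
            r.append("snr")
        if fwhm > max_fwhm:
            r.append("fwhm")
        if crlb > max_crlb_glu:
            r.append("crlb_glu")
        reasons.append(";".join(r))
    out["qc_reasons"] = reasons
    out["qc_pass"] = [r == "" for r in reasons]
    return out


def metabolite_changes(scans: pd.DataFrame, **qc_kwargs) -> pd.DataFrame:
    """Participant-level percent changes with QC propagation.

    Expects one ``pre`` and one ``post`` row per participant (columns:
    ``id``, ``session``, metabolite ratios, quality fields).  A participant
    passes QC only if both sessions are present and both pass the scan-level
    rules; percent-change columns are NaN otherwise and
    ``exclusion_reasons`` lists every violated rule prefixed by session.
    """
    bad = set(scans["session"]) - set(SESSIONS)
    if bad:
        raise ValueError(f"unknown session labels: {sorted(bad)}")
    flagged = apply_scan_qc(scans, **qc_kwargs)
    rows = []
    for pid, grp in flagged.groupby("id", sort=True):
        by_sess = {s: g for s, g in grp.groupby("session")}
        reasons = []
        for s in SESSIONS:
            if s not in by_sess:
                reasons.append(f"{s}:missing")
            elif len(by_sess[s]) > 1:
                raise ValueError(f"participant {pid}: duplicate {s} session")
            else:
                rec = by_sess[s].iloc[0]
                if not rec["qc_pass"]:
                    reasons.extend(f"{s}:{r}" for r in rec["qc_reasons"].split(";"))
        row = {"id": pid, "qc_pass": not reasons,
               "exclusion_reasons": ";".join(reasons)}
        for met in METABOLITES:
            key = "pct_change_" + met.replace("_cr", "")
            if reasons:
                row[key] = np.nan
            else:
                row[key] = percent_change(by_sess["pre"].iloc[0][met],
                                          by_sess["post"].iloc[0][met])
        rows.append(row)
    return pd.DataFrame(rows)


def flag_change_outliers(changes: pd.DataFrame, metric: str = "pct_change_glu",
                         z_thresh: float = 3.0) -> pd.DataFrame:
    """Flag participants whose change is > z_thresh sample SDs from the mean.

    The mean and (n-1) SD are computed over QC-passing participants only; a
    zero-SD pool flags nobody.  Flagged participants are excluded from all
    downstream statistics by the pipeline.
    """
    out = changes.copy()
    pool = out.loc[out["qc_pass"], metric].dropna()
    if len(pool) < 2:
        raise ValueError("need at least 2 finite values to flag outliers")
    sd = pool.std(ddof=1)
    if sd == 0:
        out["outlier"] = False
        return out
    z = (out[metric] - pool.mean()).abs() / sd
    out["outlier"] = out["qc_pass"] & (z > z_thresh)
    return out


@dataclass
class IccResult:
    """Single-measure two-way mixed absolute-agreement ICC (McGraw-Wong A,1)."""

    icc: float
    F: float
    df1: float
    df2: float
    p: float
    n: int


def icc_absolute_agreement(measurements) -> IccResult:
    """Test-retest reliability of two repeated sessions per subject.

    ``measurements`` is an (n, 2) array-like or a DataFrame with two session
    columns, one row per subject, no missing cells.  Computed from the
    two-way mean squares; absolute agreement penalizes systematic session
    offsets, unlike the consistency variant.  The significance test is
    F = MSR/MSE on (n-1, (n-1)(k-1)) df.
    """
    from scipy import stats

    arr = np.asarray(measurements, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n_subjects, 2) table of sessions")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not np.isfinite(arr).all():
        raise ValueError("missing cells are not allowed")
    n, k = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((arr - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else np.nan
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0:
        F, p = np.inf, 0.0
    else:
        F = msr / mse
        p = float(stats.f.sf(F, df1, df2))
    return IccResult(icc=float(icc), F=float(F), df1=float(df1),
                     df2=float(df2), p=p, n=n)
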