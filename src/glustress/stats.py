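"""Statistical battery: correlations, repeated-measures ANOVA with
Greenhouse-Geisser correction, hierarchical stepwise regression, dependent-
correlation comparison (Steiger's Z), percentile bootstrap, and t tests.

Conventions: all tests two-tailed; correlations report df = n - 2 - k for k
covariates; percent-style quantities stay on whatever scale the caller uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps


# ---------------------------------------------------------------------------
# result records


@dataclass
class CorrelationResult:
    method: str
    r: float
    n: int
    df: int
    p: float
    covariates: tuple = ()
    ci95: Optional[tuple] = None

    def to_dict(self) -> dict:
        d = {"method": self.method, "r": self.r, "n": self.n,
             "df": self.df, "p": self.p}
        if self.covariates:
            d["covariates"] = list(self.covariates)
        if self.ci95 is not None:
            d["ci95"] = list(self.ci95)
        return d


@dataclass
class EffectRow:
    name: str
    F: float
    df1: float
    df2: float
    p: float
    eps: Optional[float] = None
    p_sphericity: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass
class AnovaResult:
    effects: list            # of EffectRow
    contrasts: list = field(default_factory=list)   # of EffectRow

    def effect(self, name: str) -> EffectRow:
        for e in self.effects + self.contrasts:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {"effects": [e.to_dict() for e in self.effects],
                "contrasts": [e.to_dict() for e in self.contrasts]}


@dataclass
class TermResult:
    name: str
    coef: float
    beta: float
    t: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class RegressionResult:
    terms: list                      # of TermResult (final model, no const)
    r2: float
    adj_r2: float
    f: float
    f_df: tuple
    f_p: float
    r2_block1: float
    delta_r2: float
    f_change: float
    f_change_df: tuple
    f_change_p: float
    entry_trace: list = field(default_factory=list)

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {"terms": [t.to_dict() for t in self.terms],
                "r2": self.r2, "adj_r2": self.adj_r2, "f": self.f,
                "f_df": list(self.f_df), "f_p": self.f_p,
                "r2_block1": self.r2_block1, "delta_r2": self.delta_r2,
                "f_change": self.f_change,
                "f_change_df": list(self.f_change_df),
                "f_change_p": self.f_change_p,
                "entry_trace": list(self.entry_trace)}


@dataclass
class ZComparisonResult:
    r_xy: float
    r_xz: float
    r_yz: float
    n: int
    z: float
    p: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TTestResult:
    kind: str
    t: float
    df: float
    p: float
    mean_diff: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    B: int
    n_redrawn: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# correlations


def _corr_p(r: float, df: int) -> float:
    if df <= 0:
        return np.nan
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


def pearson_correlation(x, y) -> CorrelationResult:
    x, y = _paired(x, y)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult("pearson", float(r), len(x), len(x) - 2, float(p))


def spearman_correlation(x, y) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties), t-approximation p."""
    x, y = _paired(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no rank correlation")
    rho, _ = sps.spearmanr(x, y)
    df = len(x) - 2
    return CorrelationResult("spearman", float(rho), len(x), df,
                             _corr_p(float(rho), df))


def _paired(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    return x, y


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def pearson_partial_correlation(x, y, covariates=None,
                                covariate_labels: Sequence[str] = ()) -> CorrelationResult:
    """Partial Pearson correlation via double OLS residualization.

    ``covariates`` is an (n, k) array (or None/empty for plain Pearson).
    Complete-case on the (x, y, covariates) set; df = n - 2 - k.  If either
    variable is an exact linear function of the covariates the residual
    vector is degenerate and a ValueError is raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((len(x), 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(cov).all(axis=1)
    x, y, cov = x[mask], y[mask], cov[mask]
    n, k = len(x), cov.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete cases, have {n}")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate set")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("a variable is collinear with the covariates")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - k
    return CorrelationResult("pearson_partial" if k else "pearson", r, n, df,
                             _corr_p(r, df), covariates=tuple(covariate_labels))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k within-factor covariance.

    Equals (sum of eigenvalues)^2 / ((k-1) * sum of squared eigenvalues) of
    the double-centered covariance; 1 exactly under compound symmetry and
    bounded below by 1/(k-1).
    """
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    H = np.eye(k) - np.ones((k, k)) / k
    Sc = H @ S @ H
    tr = np.trace(Sc)
    denom = (k - 1) * np.sum(Sc * Sc)
    if denom == 0:
        return 1.0
    return float(tr * tr / denom)


def _poly_contrasts(k: int) -> np.ndarray:
    """Orthonormal polynomial contrast matrix, rows = degree 1..k-1."""
    t = np.arange(k, dtype=float)
    V = np.vander(t, k, increasing=True)
    Q, _ = np.linalg.qr(V)
    C = Q[:, 1:].T
    # fix signs so the linear contrast increases with the level index
    for i in range(C.shape[0]):
        if C[i, -1] < 0:
            C[i] *= -1
    return C


def rm_anova_gg(data: pd.DataFrame, dv: str, within: str, subject: str,
                between: Optional[str] = None,
                correction: str = "auto") -> AnovaResult:
    """Split-plot / repeated-measures ANOVA with GG-corrected p values.

    ``correction``: "auto" applies the Greenhouse-Geisser correction when
    the within factor has more than two levels and Mauchly's test rejects at
    0.05; "always" applies it whenever eps < 1; "never" reports uncorrected
    tests.  Polynomial (linear/quadratic) contrasts of the within factor,
    and their interaction with the between factor when present, are reported
    alongside.
    """
    if correction not in ("auto", "always", "never"):
        raise ValueError("correction must be auto, always, or never")
    wide = data.pivot_table(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("missing cells in the within-factor design")
    k = wide.shape[1]
    eps = gg_epsilon(np.cov(wide.to_numpy(), rowvar=False)) if k > 2 else 1.0

    effects = []
    if between is None:
        table = pg.rm_anova(data=data, dv=dv, within=within, subject=subject,
                            correction=True, detailed=True)
        row = table.iloc[0]
        err = table.iloc[1]
        p_spher = float(row["p_spher"]) if k > 2 else np.nan
        use_gg = _use_gg(correction, k, p_spher, eps)
        df1, df2 = float(row["DF"]), float(err["DF"])
        if use_gg:
            df1, df2 = df1 * eps, df2 * eps
        F = float(row.get("F", np.nan))
        F = F if np.isfinite(F) else 0.0
        p = float(sps.f.sf(F, df1, df2)) if F > 0 else 1.0
        effects.append(EffectRow(within, F, df1, df2, p,
                                 eps=eps, p_sphericity=p_spher))
    else:
        table = pg.mixed_anova(data=data, dv=dv, within=within,
                               subject=subject, between=between,
                               correction=True)
        trow = table.set_index("Source")
        p_spher = float(trow.loc[within, "p_spher"]) if k > 2 else np.nan
        use_gg = _use_gg(correction, k, p_spher, eps)
        for name, label in ((between, between), (within, within),
                            ("Interaction", f"{within}*{between}")):
            row = trow.loc[name]
            df1, df2 = float(row["DF1"]), float(row["DF2"])
            corrected = use_gg and name != between
            if corrected:
                df1, df2 = df1 * eps, df2 * eps
            F = float(row.get("F", np.nan))
            F = F if np.isfinite(F) else 0.0
            p = float(sps.f.sf(F, df1, df2)) if F > 0 else 1.0
            effects.append(EffectRow(
                label, F, df1, df2, p,
                eps=eps if name == within else None,
                p_sphericity=p_spher if name == within else None))

    contrasts = _within_contrasts(wide, data, subject, between, within)
    return AnovaResult(effects=effects, contrasts=contrasts)


def _use_gg(correction: str, k: int, p_spher: float, eps: float) -> bool:
    if k <= 2 or correction == "never":
        return False
    if correction == "always":
        return eps < 1.0
    return np.isfinite(p_spher) and p_spher < 0.05


def _within_contrasts(wide: pd.DataFrame, data: pd.DataFrame, subject: str,
                      between: Optional[str], within: str) -> list:
    """Linear/quadratic trend tests from per-subject contrast scores.

    Each subject's profile is projected onto the orthonormal polynomial
    contrast; the trend F is the test that the (unweighted) grand mean score
    differs from zero, and with a between factor the score-by-group ANOVA F
    is the trend x group interaction.
    """
    k = wide.shape[1]
    C = _poly_contrasts(k)
    names = {1: "linear", 2: "quadratic"}
    out = []
    if between is not None:
        gmap = (data[[subject, between]].drop_duplicates()
                .set_index(subject)[between])
        groups = gmap.loc[wide.index].to_numpy()
    for deg in (1, 2):
        if deg > k - 1:
            break
        scores = wide.to_numpy() @ C[deg - 1]
        label = names[deg]
        if between is None:
            n = len(scores)
            se = scores.std(ddof=1) / np.sqrt(n)
            F = (scores.mean() / se) ** 2 if se > 0 else 0.0
            out.append(EffectRow(f"{within}_{label}", float(F), 1.0,
                                 float(n - 1),
                                 float(sps.f.sf(F, 1, n - 1)) if F > 0 else 1.0))
        else:
            levels = pd.unique(groups)
            cells = [scores[groups == g] for g in levels]
            n = len(scores)
            dfe = n - len(levels)
            sse = sum(((c - c.mean()) ** 2).sum() for c in cells)
            mse = sse / dfe
            # unweighted grand mean: within-factor trend averaged over groups
            gm = np.mean([c.mean() for c in cells])
            se2 = mse / len(levels) ** 2 * sum(1.0 / len(c) for c in cells)
            F_main = gm * gm / se2 if se2 > 0 else 0.0
            out.append(EffectRow(
                f"{within}_{label}", float(F_main), 1.0, float(dfe),
                float(sps.f.sf(F_main, 1, dfe)) if F_main > 0 else 1.0))
            ssb = sum(len(c) * (c.mean() - scores.mean()) ** 2 for c in cells)
            dfb = len(levels) - 1
            F_int = (ssb / dfb) / mse if mse > 0 else 0.0
            out.append(EffectRow(
                f"{within}_{label}*{between}", float(F_int), float(dfb),
                float(dfe),
                float(sps.f.sf(F_int, dfb, dfe)) if F_int > 0 else 1.0))
    return out


# ---------------------------------------------------------------------------
# regression


def _ols(y: np.ndarray, X: pd.DataFrame):
    """Plain OLS with intercept; returns (coef, r2, resid_df, se, mse)."""
    n = len(y)
    design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("collinear design matrix")
    fitted = design @ coef
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    dfe = n - design.shape[1]
    mse = sse / dfe if dfe > 0 else np.nan
    XtXinv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.clip(np.diag(XtXinv), 0, None) * mse)
    return coef, r2, dfe, se, mse


def _term_results(y, X: pd.DataFrame) -> list:
    coef, r2, dfe, se, _ = _ols(y, X)
    sy = y.std(ddof=1)
    out = []
    for j, name in enumerate(X.columns, start=1):
        b = coef[j]
        t = b / se[j] if se[j] > 0 else np.inf
        beta = b * X[name].std(ddof=1) / sy if sy > 0 else np.nan
        out.append(TermResult(name, float(b), float(beta), float(t), int(dfe),
                              float(2 * sps.t.sf(abs(t), dfe))))
    return out


def f_change(r2_small: float, r2_big: float, k_added: int, dfe_big: int):
    """Nested-model R-squared increment test."""
    if k_added == 0:
        return 0.0, 1.0
    num = (r2_big - r2_small) / k_added
    den = (1.0 - r2_big) / dfe_big
    F = num / den if den > 0 else np.inf
    return float(F), float(sps.f.sf(F, k_added, dfe_big))


def hierarchical_stepwise_regression(y, block1: pd.DataFrame,
                                     block2: pd.DataFrame,
                                     p_enter: float = 0.05,
                                     p_remove: float = 0.10) -> RegressionResult:
    """Block 1 forced, block 2 entered by p-of-F stepwise selection.

    Continuous predictors should be mean-centered by the caller before
    products are formed.  At each step the candidate with the smallest
    entry p < ``p_enter`` joins the model; entered candidates whose p rises
    above ``p_remove`` are dropped.  The R-squared-change F test compares
    the block-1-only model against the final model.
    """
    y = np.asarray(y, dtype=float)
    _, r2_1, _, _, _ = _ols(y, block1)
    selected: list = []
    trace: list = []
    while True:
        changed = False
        candidates = [c for c in block2.columns if c not in selected]
        best = None
        for c in candidates:
            X = pd.concat([block1, block2[selected + [c]]], axis=1)
            try:
                terms = _term_results(y, X)
            except ValueError:      # collinear candidate
                continue
            p = terms[-1].p
            if best is None or p < best[1]:
                best = (c, p)
        if best is not None and best[1] < p_enter:
            selected.append(best[0])
            trace.append(("enter", best[0], best[1]))
            changed = True
        if selected:
            X = pd.concat([block1, block2[selected]], axis=1)
            terms = {t.name: t for t in _term_results(y, X)}
            worst = max(selected, key=lambda c: terms[c].p)
            if terms[worst].p > p_remove:
                selected.remove(worst)
                trace.append(("remove", worst, terms[worst].p))
                changed = True
        if not changed:
            break
    X_final = pd.concat([block1, block2[selected]], axis=1)
    terms = _term_results(y, X_final)
    coef, r2, dfe, _, _ = _ols(y, X_final)
    kf = X_final.shape[1]
    F_model = (r2 / kf) / ((1 - r2) / dfe) if r2 < 1 else np.inf
    adj = 1 - (1 - r2) * (len(y) - 1) / dfe
    Fc, pc = f_change(r2_1, r2, len(selected), dfe)
    return RegressionResult(
        terms=terms, r2=float(r2), adj_r2=float(adj), f=float(F_model),
        f_df=(kf, dfe),
        f_p=float(sps.f.sf(F_model, kf, dfe)) if np.isfinite(F_model) else 0.0,
        r2_block1=float(r2_1), delta_r2=float(r2 - r2_1), f_change=Fc,
        f_change_df=(len(selected), dfe), f_change_p=pc, entry_trace=trace)


def quadratic_term_model(y, pss) -> RegressionResult:
    """Test curvature of y on a predictor: y ~ x vs y ~ x + x^2, x centered."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(pss, dtype=float)
    xc = x - x.mean()
    block1 = pd.DataFrame({"pss": xc})
    block2 = pd.DataFrame({"pss_sq": xc ** 2})
    # forced-entry nested comparison (no selection involved)
    _, r2_1, _, _, _ = _ols(y, block1)
    X = pd.concat([block1, block2], axis=1)
    terms = _term_results(y, X)
    _, r2, dfe, _, _ = _ols(y, X)
    Fc, pc = f_change(r2_1, r2, 1, dfe)
    kf = X.shape[1]
    F_model = (r2 / kf) / ((1 - r2) / dfe) if r2 < 1 else np.inf
    adj = 1 - (1 - r2) * (len(y) - 1) / dfe
    return RegressionResult(
        terms=terms, r2=float(r2), adj_r2=float(adj), f=float(F_model),
        f_df=(kf, dfe),
        f_p=float(sps.f.sf(F_model, kf, dfe)) if np.isfinite(F_model) else 0.0,
        r2_block1=float(r2_1), delta_r2=float(r2 - r2_1), f_change=Fc,
        f_change_df=(1, dfe), f_change_p=pc,
        entry_trace=[("force", "pss_sq", pc)])


# ---------------------------------------------------------------------------
# dependent correlations, bootstrap, t tests


def steiger_z(r_xy: float, r_xz: float, r_yz: float, n: int) -> ZComparisonResult:
    """Steiger's Z1* for two dependent correlations sharing variable x.

    Fisher-transforms r_xy and r_xz and standardizes their difference using
    the common-element covariance evaluated at the pooled (averaged)
    correlation.  Antisymmetric in the two compared correlations; exactly
    zero when they agree.
    """
    for r in (r_xy, r_xz, r_yz):
        if abs(r) >= 1.0:
            raise ValueError("correlations must satisfy |r| < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    rbar = 0.5 * (r_xy + r_xz)
    rbar2 = rbar * rbar
    cov = (r_yz * (1.0 - 2.0 * rbar2)
           - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - r_yz * r_yz)) / (1.0 - rbar2) ** 2
    z = (np.arctanh(r_xy) - np.arctanh(r_xz)) * np.sqrt(
        (n - 3.0) / (2.0 - 2.0 * cov))
    return ZComparisonResult(r_xy, r_xz, r_yz, int(n), float(z),
                             float(2.0 * sps.norm.sf(abs(z))))


def bootstrap_ci(statistic: Callable, data, B: int = 1000,
                 seed: Optional[int] = None, rng=None,
                 max_redraws: int = 10000) -> BootstrapResult:
    """Percentile 95% CI from B case resamples.

    ``data`` is indexed along its first axis; ``statistic`` maps a resample
    to a scalar.  Resamples on which the statistic is undefined (non-finite
    or raising) are redrawn and counted.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    data = np.asarray(data)
    n = data.shape[0]
    est = float(statistic(data))
    vals = np.empty(B)
    redrawn = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, n)
        try:
            v = float(statistic(data[idx]))
        except (ValueError, ZeroDivisionError, FloatingPointError):
            v = np.nan
        if np.isfinite(v):
            vals[b] = v
            b += 1
        else:
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError("statistic undefined on too many resamples")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return BootstrapResult(est, float(lo), float(hi), B, redrawn)


def paired_t(pre, post) -> TTestResult:
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) < 2 or pre.shape != post.shape:
        raise ValueError("need paired vectors of length >= 2")
    diff = post - pre
    if diff.std(ddof=1) == 0:
        raise ZeroDivisionError("zero-variance paired differences")
    t, p = sps.ttest_rel(post, pre)
    return TTestResult("paired", float(t), float(len(pre) - 1), float(p),
                       float(diff.mean()))


def independent_t(a, b) -> TTestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per sample")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ZeroDivisionError("zero variance in both samples")
    t, p = sps.ttest_ind(a, b)
    return TTestResult("independent", float(t), float(len(a) + len(b) - 2),
                       float(p), float(a.mean() - b.mean()))
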