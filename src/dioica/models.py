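"""Linear modelling: pentad×sex models, AICc all-subsets selection,
random-intercept support check, normality gate, stepwise climate regression.

Responses (pentad-level BAI or Δ¹³C) are modelled with candidate terms
pentad (numeric start year), sex (sum-to-zero coded), an ecological-memory
covariate (the tree's previous-pentad value of the response), historical
stem diameter, and the pentad×sex interaction (only ever considered with
both main effects present).  Candidate subsets are ranked by the
small-sample-corrected Akaike criterion

    AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1),

with k counting intercept, slopes and the error variance; a model is
declared superior only when it undercuts the runner-up by ≥ 2 units, and the
winner is validated against the intercept-only null.  A tree-level
random-intercept structure is screened first (ML mixed fit vs. OLS, same
AICc rule).  Chronology-level climate regressions use p-value stepwise
selection with a variance-inflation-factor bar against collinear predictors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GateError, SelectionError, ValidationError

__all__ = [
    "SEX_CODE",
    "ModelSpec",
    "ModelFitResult",
    "build_design",
    "fit_ols",
    "aicc",
    "SelectionResult",
    "all_subsets_select",
    "RandomInterceptResult",
    "random_intercept_support",
    "normality_gate",
    "variance_inflation",
    "StepwiseResult",
    "stepwise_regression",
    "bai_vs_delta13c",
]

#: sum-to-zero coding for the two sexes
SEX_CODE = {"male": 1.0, "female": -1.0}


@dataclass
class ModelSpec:
    """Candidate-term specification for a pentad-level response model."""

    response: str  # "bai_mean" or "delta13c"
    memory: str  # "bai_prev" or "delta13c_prev"
    include_size: bool = True

    @property
    def candidate_terms(self) -> list[str]:
        terms = ["pentad", "sex", self.memory]
        if self.include_size:
            terms.append("dbh_hist")
        terms.append("pentad:sex")
        return terms


@dataclass
class ModelFitResult:
    """OLS fit summary: coefficients, CIs, fit statistics and type-III tests."""

    terms: tuple[str, ...]
    params: pd.Series
    conf_int: pd.DataFrame  # columns low, high (95 %)
    r2: float
    r2_adj: float
    fvalue: float
    f_pvalue: float
    type3: pd.DataFrame  # index term; columns F, p, df
    aicc: float
    n: int
    k: int
    rss: float
    loglike: float
    residuals: np.ndarray
    transform_applied: str = "none"

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "beta": self.params,
                "ci_low": self.conf_int["low"],
                "ci_high": self.conf_int["high"],
            }
        )
        return out


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample Akaike criterion from a residual sum of squares.

    k counts intercept, slopes and the error variance.  Returns +inf when
    the correction denominator n − k − 1 is nonpositive, so such models sort
    last in any ranking.
    """
    if n - k - 1 <= 0:
        return float("inf")
    if rss <= 0:
        return float("-inf")
    return n * float(np.log(rss / n)) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _term_columns(term: str, data: pd.DataFrame, pentad_center: float) -> pd.Series:
    """Numeric design column for one term (sum-to-zero sex, centered interaction)."""
    if term == "sex":
        return data["sex"].map(SEX_CODE).astype(float)
    if term == "pentad":
        return data["pentad_start_year"].astype(float)
    if term == "pentad:sex":
        return (data["pentad_start_year"].astype(float) - pentad_center) * data[
            "sex"
        ].map(SEX_CODE).astype(float)
    if term not in data.columns:
        raise ValidationError(f"unknown model term {term!r}")
    return data[term].astype(float)


def build_design(
    data: pd.DataFrame, terms: Sequence[str]
) -> pd.DataFrame:
    """Design matrix (with intercept) for the given terms.

    Sex is coded +1 male / −1 female; the numeric pentad covariate is
    mean-centered inside the interaction column so the interaction is
    orthogonal to the sex main effect under balance.  Interactions require
    both parents (marginality).
    """
    for term in terms:
        if ":" in term:
            parents = term.split(":")
            if any(p not in terms for p in parents):
                raise ValidationError(
                    f"interaction {term!r} requires its main effects"
                )
    pentad_center = float(data["pentad_start_year"].mean()) if "pentad_start_year" in data else 0.0
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for term in terms:
        X[term] = _term_columns(term, data, pentad_center).to_numpy()
    return X


def fit_ols(
    X: pd.DataFrame, y: pd.Series | np.ndarray, transform_applied: str = "none"
) -> ModelFitResult:
    """Ordinary least squares with type-III term tests.

    The type-III F for each non-intercept column compares the full model
    with the model dropping that column (sum-to-zero contrasts make this the
    conventional type-III test for the categorical terms).
    """
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if n <= p:
        raise ValidationError(f"n={n} too small for {p} coefficients")
    rank = np.linalg.matrix_rank(Xv)
    if rank < p:
        raise ValidationError(
            f"design is rank deficient (rank {rank} < {p} columns "
            f"{list(X.columns)})"
        )
    beta, _, _, _ = np.linalg.lstsq(Xv, y, rcond=None)
    fitted = Xv @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df_resid = n - p
    sigma2 = rss / df_resid
    XtX_inv = np.linalg.inv(Xv.T @ Xv)
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    tcrit = stats.t.ppf(0.975, df_resid)
    params = pd.Series(beta, index=X.columns)
    ci = pd.DataFrame(
        {"low": beta - tcrit * se, "high": beta + tcrit * se}, index=X.columns
    )
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid if tss > 0 else np.nan
    # whole-model F against intercept-only
    n_slopes = p - 1
    if n_slopes > 0 and tss > rss:
        fval = ((tss - rss) / n_slopes) / sigma2
        fp = float(stats.f.sf(fval, n_slopes, df_resid))
    elif n_slopes > 0:
        fval, fp = 0.0, 1.0
    else:
        fval, fp = np.nan, np.nan
    # type-III: drop each column in turn
    rows = []
    for j, col in enumerate(X.columns):
        if col == "Intercept":
            continue
        keep = [c for c in range(p) if c != j]
        b_r, _, _, _ = np.linalg.lstsq(Xv[:, keep], y, rcond=None)
        rss_r = float(((y - Xv[:, keep] @ b_r) ** 2).sum())
        F = (rss_r - rss) / sigma2
        rows.append(
            {"term": col, "F": F, "p": float(stats.f.sf(F, 1, df_resid)), "df": 1}
        )
    type3 = pd.DataFrame(rows).set_index("term") if rows else pd.DataFrame(
        columns=["F", "p", "df"]
    )
    k = p + 1  # + error variance
    loglike = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    return ModelFitResult(
        terms=tuple(c for c in X.columns if c != "Intercept"),
        params=params,
        conf_int=ci,
        r2=r2,
        r2_adj=r2_adj,
        fvalue=float(fval),
        f_pvalue=fp,
        type3=type3,
        aicc=aicc(rss, n, k),
        n=n,
        k=k,
        rss=rss,
        loglike=float(loglike),
        residuals=resid,
        transform_applied=transform_applied,
    )


def _marginal_subsets(candidates: Sequence[str]) -> list[tuple[str, ...]]:
    """All subsets of candidate terms in which interactions have both parents."""
    mains = [t for t in candidates if ":" not in t]
    inters = [t for t in candidates if ":" in t]
    out: list[tuple[str, ...]] = []
    for r in range(len(mains) + 1):
        for combo in itertools.combinations(mains, r):
            base = tuple(combo)
            out.append(base)
            for ir in range(1, len(inters) + 1):
                for icombo in itertools.combinations(inters, ir):
                    if all(
                        all(p in combo for p in term.split(":")) for term in icombo
                    ):
                        out.append(base + icombo)
    return out


@dataclass
class SelectionResult:
    """Outcome of AICc all-subsets selection."""

    table: pd.DataFrame  # terms, k, aicc, delta_aicc (vs best)
    best_terms: tuple[str, ...]
    best_fit: ModelFitResult
    superior: bool  # best beats runner-up by >= 2 AICc units
    aicc_null: float
    delta_null_best: float


def all_subsets_select(
    data: pd.DataFrame, spec: ModelSpec, aicc_delta: float = 2.0
) -> SelectionResult:
    """Exhaustive marginality-respecting AICc model selection.

    All candidate subsets are fitted on the same complete-case rows (fixed
    once, so every AICc is comparable), ranked by AICc; the best model is
    refitted in full and compared with the intercept-only null.
    """
    candidates = spec.candidate_terms
    needed = {"pentad_start_year", "sex", spec.memory, spec.response}
    if spec.include_size:
        needed.add("dbh_hist")
    missing = needed - set(data.columns)
    if missing:
        raise SelectionError(f"data missing columns: {sorted(missing)}")
    rows = data.dropna(subset=sorted(needed))
    max_k = len(candidates) + 2
    if len(rows) < max_k + 2:
        raise SelectionError(
            f"only {len(rows)} complete cases for a {max_k}-parameter model"
        )
    y = rows[spec.response].to_numpy(dtype=float)
    full_X = build_design(rows, candidates)
    n = len(rows)
    records = []
    for terms in _marginal_subsets(candidates):
        cols = ["Intercept", *terms]
        Xv = full_X[cols].to_numpy()
        beta, _, _, _ = np.linalg.lstsq(Xv, y, rcond=None)
        rss = float(((y - Xv @ beta) ** 2).sum())
        k = len(cols) + 1
        records.append({"terms": terms, "k": k, "aicc": aicc(rss, n, k)})
    table = pd.DataFrame(records).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    best_terms = tuple(table["terms"].iloc[0])
    superior = bool(
        len(table) > 1 and table["aicc"].iloc[1] - table["aicc"].iloc[0] >= aicc_delta
    )
    best_fit = fit_ols(full_X[["Intercept", *best_terms]], y)
    aicc_null = float(table.loc[table["terms"].apply(len) == 0, "aicc"].iloc[0])
    return SelectionResult(
        table=table,
        best_terms=best_terms,
        best_fit=best_fit,
        superior=superior,
        aicc_null=aicc_null,
        delta_null_best=aicc_null - float(table["aicc"].iloc[0]),
    )


@dataclass
class RandomInterceptResult:
    """AICc comparison of OLS vs. tree-level random-intercept mixed model.

    ``aicc_mixed`` and ``delta`` are None when the mixed fit degenerated at
    the variance boundary (which counts as "no support", not a failure).
    """

    aicc_ols: float
    aicc_mixed: float | None
    delta: float | None  # aicc_ols - aicc_mixed; >= 2 favours the mixed model
    support: bool
    re_variance: float


def random_intercept_support(
    data: pd.DataFrame, spec: ModelSpec, group_col: str = "tree_id"
) -> RandomInterceptResult:
    """Screen whether a tree-identity random intercept is warranted.

    Both models carry the full candidate fixed-effect structure and are
    compared on likelihood-based AICc (ML, not REML, so fixed effects are
    comparable); k counts the random-intercept variance for the mixed model.
    A variance estimate at the boundary (≈ 0) reports "no support" rather
    than failing.
    """
    import statsmodels.api as sm

    candidates = spec.candidate_terms
    needed = sorted(
        {"pentad_start_year", "sex", spec.memory, spec.response, group_col}
        | ({"dbh_hist"} if spec.include_size else set())
    )
    rows = data.dropna(subset=[c for c in needed if c in data.columns])
    groups = rows[group_col]
    if groups.nunique() < 5 or (groups.value_counts() >= 2).sum() < 5:
        raise SelectionError("need >= 5 trees with >= 2 pentads each")
    X = build_design(rows, candidates)
    y = rows[spec.response].to_numpy(dtype=float)
    n, p = X.shape
    ols_fit = fit_ols(X, y)
    ll_ols = ols_fit.loglike
    k_ols = p + 1
    aicc_ols = -2 * ll_ols + 2 * k_ols + 2 * k_ols * (k_ols + 1) / (n - k_ols - 1)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixed = sm.MixedLM(y, X.to_numpy(), groups=groups.to_numpy()).fit(
                reml=False
            )
    except (np.linalg.LinAlgError, ValueError):
        # singular Hessian: the variance estimate collapsed to the boundary
        return RandomInterceptResult(
            aicc_ols=float(aicc_ols), aicc_mixed=None, delta=None,
            support=False, re_variance=0.0,
        )
    ll_mix = float(mixed.llf)
    re_var = float(np.asarray(mixed.cov_re).ravel()[0]) * float(mixed.scale)
    k_mix = p + 2
    aicc_mix = -2 * ll_mix + 2 * k_mix + 2 * k_mix * (k_mix + 1) / (n - k_mix - 1)
    delta = aicc_ols - aicc_mix
    boundary = re_var <= 1e-8 * (np.var(y) + 1e-12)
    return RandomInterceptResult(
        aicc_ols=float(aicc_ols),
        aicc_mixed=float(aicc_mix),
        delta=float(delta),
        support=bool(delta >= 2.0 and not boundary),
        re_variance=re_var,
    )


def normality_gate(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    alpha: float = 0.05,
) -> ModelFitResult:
    """Fit, Shapiro–Wilk the residuals, and refit on log(response) if needed.

    With residual non-normality (p < alpha) and a strictly positive
    response, the model is refitted on the natural log and flagged
    ``transform_applied='log'``.  A triggered transform on a nonpositive
    response raises :class:`GateError`.  Fewer than 3 residuals skips the
    gate with a warning.
    """
    y = np.asarray(y, dtype=float)
    fit = fit_ols(X, y)
    if len(y) < 3:
        warnings.warn("normality gate skipped: fewer than 3 observations")
        return fit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(stats.shapiro(fit.residuals).pvalue)
    if p >= alpha:
        return fit
    if np.any(y <= 0):
        raise GateError("log transform required but response has nonpositive values")
    return fit_ols(X, np.log(y), transform_applied="log")


def variance_inflation(X: pd.DataFrame) -> pd.Series:
    """VIF of each non-intercept column: 1/(1 − R²) against the others."""
    cols = [c for c in X.columns if c != "Intercept"]
    out = {}
    for col in cols:
        others = [c for c in X.columns if c != col]
        y = X[col].to_numpy(dtype=float)
        Z = X[others].to_numpy(dtype=float)
        beta, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        tss = float(((y - y.mean()) ** 2).sum())
        rss = float(resid @ resid)
        if tss == 0:
            out[col] = np.inf
        else:
            r2 = 1.0 - rss / tss
            out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class StepwiseResult:
    """Final stepwise model plus the full selection trace."""

    fit: ModelFitResult
    selected: list[str]
    trace: pd.DataFrame  # step, action, term, p, max_vif


def stepwise_regression(
    candidates: pd.DataFrame,
    response: pd.Series | np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    vif_max: float = 5.0,
) -> StepwiseResult:
    """P-value stepwise multiple regression with a collinearity bar.

    Forward steps enter the candidate with the smallest coefficient p-value
    below ``p_enter``, skipping any whose entry would push the maximum VIF
    of the design above ``vif_max``; each entry is followed by backward
    removal of included predictors whose p-value exceeds ``p_remove`` (the
    just-entered term is exempt within its own step, which guarantees
    termination).  An empty opening step yields the intercept-only model.
    """
    if p_enter > p_remove:
        raise ValidationError("p_enter must be <= p_remove")
    y = np.asarray(response, dtype=float)
    data = candidates.copy()
    if isinstance(response, pd.Series):
        data = data.loc[response.index]
    keep = np.isfinite(y) & np.isfinite(data.to_numpy(dtype=float)).all(axis=1)
    data = data.loc[keep]
    y = y[keep]
    selected: list[str] = []
    trace_rows = []
    step = 0

    def design(terms: list[str]) -> pd.DataFrame:
        X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
        for t in terms:
            X[t] = data[t].to_numpy(dtype=float)
        return X

    def coef_pvalues(terms: list[str]) -> pd.Series:
        X = design(terms).to_numpy(dtype=float)
        n, p = X.shape
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = n - p
        if df <= 0:
            return pd.Series(np.nan, index=terms)
        sigma2 = float(resid @ resid) / df
        try:
            cov = np.linalg.inv(X.T @ X) * sigma2
        except np.linalg.LinAlgError:
            return pd.Series(np.nan, index=terms)
        se = np.sqrt(np.diag(cov))
        tvals = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
        return pd.Series(pvals[1:], index=terms)

    while True:
        step += 1
        # forward entry
        entry_p = {}
        for cand in data.columns:
            if cand in selected:
                continue
            trial = selected + [cand]
            Xt = design(trial)
            if np.linalg.matrix_rank(Xt.to_numpy()) < Xt.shape[1]:
                continue
            pv = coef_pvalues(trial)
            if np.isfinite(pv.get(cand, np.nan)):
                entry_p[cand] = float(pv[cand])
        entered = None
        for cand in sorted(entry_p, key=entry_p.get):
            if entry_p[cand] >= p_enter:
                break
            max_vif = float(variance_inflation(design(selected + [cand])).max())
            if max_vif > vif_max:
                trace_rows.append(
                    {"step": step, "action": "barred", "term": cand,
                     "p": entry_p[cand], "max_vif": max_vif}
                )
                continue
            entered = cand
            selected.append(cand)
            trace_rows.append(
                {"step": step, "action": "enter", "term": cand,
                 "p": entry_p[cand], "max_vif": max_vif}
            )
            break
        if entered is None:
            trace_rows.append(
                {"step": step, "action": "stop", "term": "", "p": np.nan,
                 "max_vif": np.nan}
            )
            break
        # backward removal (just-entered term exempt this step)
        while True:
            pv = coef_pvalues(selected)
            removable = pv.drop(index=entered, errors="ignore")
            removable = removable[removable > p_remove]
            if removable.empty:
                break
            worst = removable.idxmax()
            selected.remove(worst)
            trace_rows.append(
                {"step": step, "action": "remove", "term": worst,
                 "p": float(pv[worst]), "max_vif": np.nan}
            )
    fit = fit_ols(design(selected), y)
    return StepwiseResult(
        fit=fit, selected=list(selected), trace=pd.DataFrame(trace_rows)
    )


def bai_vs_delta13c(pentad_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sex OLS of sex-mean pentad BAI on sex-mean pentad Δ¹³C.

    Returns a frame indexed by sex with slope, intercept, r2, p (two-tailed
    slope test) and n (pentads).
    """
    rows = {}
    for sex, sub in pentad_table.dropna(subset=["bai_mean", "delta13c"]).groupby("sex"):
        means = sub.groupby("pentad_start_year")[["bai_mean", "delta13c"]].mean()
        if len(means) < 4:
            raise ValidationError(f"{sex}: need >= 4 pentads, got {len(means)}")
        if np.ptp(means["delta13c"].to_numpy()) == 0:
            raise ValidationError(f"{sex}: zero variance in delta13c")
        res = stats.linregress(means["delta13c"], means["bai_mean"])
        rows[sex] = {
            "slope": res.slope,
            "intercept": res.intercept,
            "r2": res.rvalue**2,
            "p": res.pvalue,
            "n": len(means),
        }
    return pd.DataFrame(rows).T
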