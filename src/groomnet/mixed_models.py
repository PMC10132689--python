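"""Linear mixed-model battery for individual grooming network metrics.

For each network metric (the response) the full model contains sex, age
(mean-centered, linear and quadratic), rearing history, group size and sex
ratio, plus the two-way interactions of sex with each other predictor, and
random intercepts for individual identity (repeated observations of the same
bonobo across group compositions) and for group identity.

Workflow mirrors standard practice: Rosner's generalized-ESD outlier screen
per response, VIF collinearity check (threshold 5), backward single-term AIC
reduction under maximum likelihood with marginality respected (interactions
before their main effects, the quadratic age term before the linear one),
final refit by REML, Shapiro-Wilk and residual/QQ diagnostics, and
Tukey-adjusted pairwise contrasts for factor cells.

The solver is statsmodels' MixedLM.  When the data contain repeated
individuals the two random intercepts are crossed; this is expressed as
variance components within a single grouping stratum.  Reported degrees of
freedom are residual df (n - p); the paper-style Satterthwaite fractions are
solver-specific and not reproduced here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .data_model import ValidationError
from .network_metrics import MIN_INDIRECT_GROUP_SIZE

logger = logging.getLogger(__name__)

INDIRECT_RESPONSES = {"affinity", "eigenvector", "affinity_scaled",
                      "eigenvector_scaled"}

MAIN_TERMS = ["male", "age_c", "age_sq", "atypical", "group_size",
              "sex_ratio"]
FULL_TERMS = MAIN_TERMS + ["male:age_c", "male:age_sq", "male:atypical",
                           "male:group_size", "male:sex_ratio"]
# standardized responses already account for group size
STANDARDIZED_TERMS = [t for t in FULL_TERMS if "group_size" not in t]

VIF_THRESHOLD = 5.0


# ---------------------------------------------------------------------------
# outlier screen
# ---------------------------------------------------------------------------

def rosner_outliers(values, max_k: int = 5, alpha: float = 0.05) -> list[int]:
    """Positional indices of outliers by the generalized ESD (Rosner) test.

    Iteratively removes the most extreme studentized value and compares each
    test statistic R_i against its critical value lambda_i; the declared
    outliers are the first i_max removals where i_max is the largest i with
    R_i > lambda_i.
    """
    x = np.asarray(values, dtype=float)
    finite = np.flatnonzero(np.isfinite(x))
    x = x[finite]
    n = x.size
    if max_k < 1:
        raise ValidationError("max_k must be >= 1")
    if n < 3 or np.std(x, ddof=1) == 0:
        return []
    max_k = min(max_k, n - 2)
    if n < 10:
        logger.warning("Rosner's test on n=%d (< 10 recommended)", n)
    remaining = np.arange(n)
    removed: list[int] = []
    R = np.empty(max_k)
    lam = np.empty(max_k)
    for i in range(max_k):
        sub = x[remaining]
        sd = np.std(sub, ddof=1)
        if sd == 0:
            max_k = i
            break
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        R[i] = dev[j] / sd
        removed.append(int(remaining[j]))
        remaining = np.delete(remaining, j)
        m = n - i  # sample size at this step
        p = 1.0 - alpha / (2.0 * m)
        t = stats.t.ppf(p, m - 2)
        lam[i] = (m - 1) * t / np.sqrt((m - 2 + t ** 2) * m)
    n_out = 0
    for i in range(max_k):
        if R[i] > lam[i]:
            n_out = i + 1
    return [int(finite[k]) for k in removed[:n_out]]


# ---------------------------------------------------------------------------
# design preparation
# ---------------------------------------------------------------------------

@dataclass
class DesignTable:
    """Model-ready table for one response, plus screening bookkeeping."""

    response: str
    df: pd.DataFrame
    removed_outliers: list[tuple[str, str]] = field(default_factory=list)
    n_dropped_missing: int = 0


def prepare_design(metrics: pd.DataFrame, response: str,
                   screen_outliers: bool = True, alpha: float = 0.05,
                   max_k: int = 5,
                   min_indirect_group_size: int = MIN_INDIRECT_GROUP_SIZE,
                   ) -> DesignTable:
    """Build the analysis table for one response.

    Encodes sex and rearing as treatment dummies (reference levels: female,
    mother-reared), drops rows with a missing response (and, for indirect
    responses, rows from groups below the size threshold), applies the Rosner
    screen to the response, then mean-centers age over the retained rows and
    adds its square.
    """
    if response not in metrics.columns:
        raise ValidationError(f"response {response!r} not in metrics table")
    df = metrics.copy()
    if response in INDIRECT_RESPONSES:
        df = df[df["group_size"] >= min_indirect_group_size]
    n0 = len(df)
    df = df[np.isfinite(df[response])]
    n_missing = n0 - len(df)
    if n_missing:
        logger.info("response %s: dropped %d row(s) with missing values",
                    response, n_missing)
    if df.empty:
        raise ValidationError(f"response {response!r} is entirely missing")

    removed: list[tuple[str, str]] = []
    if screen_outliers:
        idx = rosner_outliers(df[response].to_numpy(), max_k=max_k,
                              alpha=alpha)
        if idx:
            rows = df.iloc[idx]
            removed = list(zip(rows["group_id"], rows["individual_id"]))
            logger.info("response %s: Rosner screen removed %d outlier(s): "
                        "%s", response, len(idx), removed)
            df = df.drop(df.index[idx])

    df = df.reset_index(drop=True)
    out = pd.DataFrame({
        "y": df[response].astype(float),
        "male": (df["sex"] == "male").astype(int),
        "atypical": (df["rearing"] == "atypically_reared").astype(int),
        "group_size": df["group_size"].astype(float),
        "sex_ratio": df["sex_ratio"].astype(float),
        "group_id": df["group_id"].astype(str),
        "individual_id": df["individual_id"].astype(str),
    })
    age = df["age"].astype(float)
    out["age_c"] = age - age.mean()
    out["age_sq"] = out["age_c"] ** 2
    return DesignTable(response=response, df=out, removed_outliers=removed,
                       n_dropped_missing=n_missing)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    response: str
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: float
    aic: float
    loglik: float
    n_obs: int
    reml: bool
    converged: bool
    singular: bool
    shapiro_p: float | None = None
    result: object = None  # underlying statsmodels results

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.bse,
                             "t": self.tvalues, "p": self.pvalues})


def _has_repeats(df: pd.DataFrame) -> bool:
    return bool(df["individual_id"].duplicated().any())


def fit_lmm(design: DesignTable, terms: list[str] | None = None,
            reml: bool = True,
            include_individual_re: bool | None = None) -> FitResult:
    """Fit one linear mixed model.

    Random structure: intercepts for group and individual.  If no individual
    repeats exist (each bonobo observed once) the individual intercept is
    unidentifiable from the residual and is dropped with a log note; with
    repeats, both intercepts are fitted as crossed variance components.
    """
    df = design.df
    terms = list(FULL_TERMS) if terms is None else list(terms)
    _check_marginality(terms)
    if df["group_id"].nunique() < 2:
        raise ValidationError("need >= 2 groups for the group intercept")
    formula = "y ~ " + (" + ".join(terms) if terms else "1")
    if include_individual_re is None:
        include_individual_re = _has_repeats(df)
        if not include_individual_re:
            logger.info("no repeated individuals; individual random "
                        "intercept dropped (unidentifiable)")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if include_individual_re:
            # crossed intercepts expressed as variance components in a
            # single stratum
            data = df.assign(_one=1)
            model = smf.mixedlm(
                formula, data, groups="_one", re_formula="0",
                vc_formula={"group": "0 + C(group_id)",
                            "individual": "0 + C(individual_id)"})
        else:
            model = smf.mixedlm(formula, df, groups="group_id")
        res = None
        for method in ("lbfgs", "bfgs", "powell", "cg"):
            try:
                trial = model.fit(reml=reml, method=method, maxiter=1000)
            except Exception:
                continue
            if res is None:
                res = trial
            if trial.converged:
                res = trial
                break
        if res is None:
            raise RuntimeError(
                f"mixed model for {design.response!r}: every optimizer "
                f"failed")
    singular = bool(np.any(np.asarray(res.vcomp if res.vcomp.size
                                      else np.diag(res.cov_re)) < 1e-8))
    if singular:
        logger.warning("singular fit for response %s (a variance component "
                       "is ~0)", design.response)
    fe = res.fe_params
    k_fixed = len(fe)
    n = len(df)
    n_var_par = len(res.params) - k_fixed
    bse = res.bse_fe
    loglik = float(res.llf)
    if np.isnan(bse).any() or not res.converged:
        # every random variance is at the boundary: the model degenerates to
        # ordinary least squares, which supplies well-defined standard
        # errors; the boundary variance components are reported as 0
        import statsmodels.formula.api as _smf

        ols = _smf.ols(formula, df).fit()
        if np.isnan(bse).any():
            logger.warning("response %s: variance components on the "
                           "boundary; standard errors from the degenerate "
                           "(OLS) model", design.response)
            res = ols
            fe = ols.params
            bse = ols.bse
            loglik = float(ols.llf)
            singular = True
        else:
            logger.warning("response %s: optimizer reported non-convergence "
                           "(often a boundary solution); fit retained with "
                           "converged=False", design.response)
    df_resid = float(n - k_fixed)
    tvals = fe / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    aic = -2.0 * loglik + 2.0 * (k_fixed + n_var_par)
    if reml:
        # AIC under REML is not comparable across fixed structures; recorded
        # for completeness only.
        logger.debug("AIC computed from a REML fit")
    return FitResult(
        response=design.response, terms=terms, params=fe, bse=bse,
        tvalues=pd.Series(tvals, index=fe.index),
        pvalues=pd.Series(pvals, index=fe.index), df_resid=df_resid,
        aic=float(aic), loglik=loglik, n_obs=n, reml=reml,
        converged=bool(getattr(res, "converged", True)), singular=singular,
        result=res)


# ---------------------------------------------------------------------------
# marginality-aware backward AIC reduction
# ---------------------------------------------------------------------------

def _requirements(term: str) -> set[str]:
    """Terms that must stay in the model while ``term``'s dependents do."""
    req: set[str] = set()
    if ":" in term:
        a, b = term.split(":")
        req.update({a, b})
        if b == "age_sq":
            req.add(f"{a}:age_c")
    elif term == "age_sq":
        req.add("age_c")
    return req


def _check_marginality(terms: list[str]) -> None:
    present = set(terms)
    for t in terms:
        missing = _requirements(t) - present
        if missing:
            raise ValidationError(
                f"term {t!r} requires {sorted(missing)} in the model")


def removable_terms(terms: list[str]) -> list[str]:
    """Terms whose removal keeps the model hierarchical."""
    present = set(terms)
    needed: set[str] = set()
    for t in present:
        needed |= _requirements(t)
    return sorted(present - needed)


@dataclass
class EliminationStep:
    dropped: str
    aic_before: float
    aic_after: float


def aic_backward_reduction(design: DesignTable,
                           full_terms: list[str] | None = None,
                           include_individual_re: bool | None = None,
                           ) -> tuple[FitResult, list[EliminationStep]]:
    """Backward single-term elimination under ML, final refit under REML.

    At each step the removable term whose removal lowers AIC the most is
    dropped (ties broken alphabetically); the procedure stops when no
    removal lowers AIC.  The returned fit is the REML refit of the final
    fixed structure.
    """
    terms = list(FULL_TERMS) if full_terms is None else list(full_terms)
    current = fit_lmm(design, terms, reml=False,
                      include_individual_re=include_individual_re)
    path: list[EliminationStep] = []
    while True:
        candidates = removable_terms(current.terms)
        if not candidates:
            break
        trials = []
        for term in sorted(candidates):
            reduced = [t for t in current.terms if t != term]
            fit = fit_lmm(design, reduced, reml=False,
                          include_individual_re=include_individual_re)
            trials.append((fit.aic, term, fit))
        best_aic, best_term, best_fit = min(trials, key=lambda t: (t[0], t[1]))
        if best_aic < current.aic - 1e-9:
            path.append(EliminationStep(dropped=best_term,
                                        aic_before=current.aic,
                                        aic_after=best_aic))
            current = best_fit
        else:
            break
    final = fit_lmm(design, current.terms, reml=True,
                    include_individual_re=include_individual_re)
    final.aic = current.aic  # report the comparable ML AIC
    return final, path


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------

def vif_check(design: DesignTable | pd.DataFrame,
              terms: list[str] | None = None,
              threshold: float = VIF_THRESHOLD) -> pd.Series:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    Each predictor column is regressed on the others (with intercept);
    perfectly collinear columns report ``inf`` and are flagged.
    """
    df = design.df if isinstance(design, DesignTable) else design
    terms = [t for t in (terms or MAIN_TERMS) if ":" not in t]
    X = df[terms].to_numpy(dtype=float)
    vifs = {}
    for j, term in enumerate(terms):
        others = np.column_stack([np.ones(len(X)),
                                  np.delete(X, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        ss_tot = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        ss_res = np.sum(resid ** 2)
        if ss_tot == 0 or ss_res / ss_tot < 1e-12:
            vifs[term] = np.inf
        else:
            vifs[term] = 1.0 / (ss_res / ss_tot)
    out = pd.Series(vifs)
    for term, v in out.items():
        if v > threshold:
            logger.warning("VIF(%s) = %.2f exceeds %.1f", term, v, threshold)
    return out


# ---------------------------------------------------------------------------
# post-hoc contrasts
# ---------------------------------------------------------------------------

def tukey_contrasts(fit: FitResult, design: DesignTable,
                    factors: tuple[str, str] = ("male", "atypical"),
                    ) -> pd.DataFrame:
    """Tukey-adjusted pairwise contrasts of factor-cell marginal means.

    Cell means are evaluated at the mean of every covariate (estimated
    marginal means); p-values use the studentized range distribution over
    the number of cells, on residual df.
    """
    df = design.df
    fe = fit.params
    res = fit.result
    design_info = res.model.data.design_info
    from patsy import build_design_matrices

    base = {col: [df[col].mean()] for col in df.columns
            if col not in ("y", "group_id", "individual_id")}
    cells = []
    for a in sorted(df[factors[0]].unique()):
        for b in sorted(df[factors[1]].unique()):
            row = {k: list(v) for k, v in base.items()}
            row[factors[0]] = [a]
            row[factors[1]] = [b]
            cell_df = pd.DataFrame(row)
            (L,) = build_design_matrices([design_info], cell_df)
            if np.asarray(L).size == 0:
                logger.warning("empty cell (%s=%s, %s=%s) dropped",
                               factors[0], a, factors[1], b)
                continue
            cells.append(((a, b), np.asarray(L)[0]))
    cov = np.asarray(res.cov_params())[:len(fe), :len(fe)]
    k = len(cells)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            (ci, Li), (cj, Lj) = cells[i], cells[j]
            d = Li - Lj
            est = float(d @ fe.to_numpy())
            se = float(np.sqrt(d @ cov @ d))
            q = abs(est) / se * np.sqrt(2.0) if se > 0 else np.inf
            p = float(stats.studentized_range.sf(q, k, fit.df_resid))
            t = est / se if se > 0 else np.inf
            rows.append({
                "cell_a": f"{factors[0]}={ci[0]},{factors[1]}={ci[1]}",
                "cell_b": f"{factors[0]}={cj[0]},{factors[1]}={cj[1]}",
                "estimate": est, "se": se, "t": t, "p_tukey": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def residual_diagnostics(fit: FitResult, outdir: str | Path | None = None,
                         ) -> dict:
    """Shapiro-Wilk on residuals plus residual-vs-fitted and QQ plots."""
    res = fit.result
    try:
        resid = np.asarray(res.resid)
        fitted = np.asarray(res.fittedvalues)
    except Exception:
        # singular random-effects covariance: use marginal residuals
        fitted = res.model.exog @ np.asarray(fit.params)
        resid = np.asarray(res.model.endog) - fitted
    sw_stat, sw_p = stats.shapiro(resid)
    fit.shapiro_p = float(sw_p)
    report = {"shapiro_w": float(sw_stat), "shapiro_p": float(sw_p),
              "n_resid": int(resid.size)}
    if outdir is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(fitted, resid, s=8)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("fitted")
        ax.set_ylabel("residual")
        rv = outdir / f"{fit.response}_resid_vs_fitted.png"
        fig.tight_layout()
        fig.savefig(rv)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(4, 3))
        sm.qqplot(resid, line="s", ax=ax)
        qq = outdir / f"{fit.response}_qq.png"
        fig.tight_layout()
        fig.savefig(qq)
        plt.close(fig)
        report["resid_vs_fitted_plot"] = str(rv)
        report["qq_plot"] = str(qq)
    return report
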