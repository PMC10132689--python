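import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from groomnet.mixed_models import (FULL_TERMS, MAIN_TERMS, DesignTable,
                                   aic_backward_reduction, fit_lmm,
                                   prepare_design, removable_terms,
                                   residual_diagnostics, rosner_outliers,
                                   tukey_contrasts, vif_check)


# ---------------------------------------------------------------------------
# Rosner / generalized ESD
# ---------------------------------------------------------------------------

def gesd_oracle(x, max_k, alpha):
    """Independent generalized-ESD implementation (plain loops)."""
    x = list(map(float, x))
    removed = []
    stats_list = []
    work = x[:]
    n = len(x)
    for i in range(max_k):
        mean = sum(work) / len(work)
        sd = (sum((v - mean) ** 2 for v in work) / (len(work) - 1)) ** 0.5
        devs = [abs(v - mean) for v in work]
        j = devs.index(max(devs))
        R = devs[j] / sd
        m = n - i
        p = 1 - alpha / (2 * m)
        t = stats.t.ppf(p, m - 2)
        lam = (m - 1) * t / ((m - 2 + t ** 2) * m) ** 0.5
        stats_list.append((R, lam))
        removed.append(work[j])
        del work[j]
    n_out = 0
    for i, (R, lam) in enumerate(stats_list):
        if R > lam:
            n_out = i + 1
    return sorted(removed[:n_out])


def test_rosner_flags_single_gross_outlier():
    x = [1, 2, 3, 2, 1, 2, 3, 2, 1, 100]
    idx = rosner_outliers(x, max_k=3, alpha=0.05)
    assert [x[i] for i in idx] == [100]


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_rosner_agrees_with_independent_oracle(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=40)
    x[:2] += rng.choice([-8, 8], size=2)  # plant up to two outliers
    got = sorted(x[i] for i in rosner_outliers(x, max_k=5, alpha=0.05))
    assert got == pytest.approx(gesd_oracle(x, 5, 0.05))


def test_rosner_null_flag_rate_at_most_alpha():
    """On clean Gaussian samples the flag rate stays near/below alpha."""
    rng = np.random.default_rng(99)
    flagged = sum(bool(rosner_outliers(rng.normal(size=50), max_k=3,
                                       alpha=0.05))
                  for _ in range(300))
    rate = flagged / 300
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 300)


def test_rosner_degenerate_inputs():
    assert rosner_outliers(np.ones(20), max_k=3) == []
    assert rosner_outliers([1.0, 2.0], max_k=1) == []


# ---------------------------------------------------------------------------
# design preparation
# ---------------------------------------------------------------------------

def toy_metrics(n=40, seed=0, n_groups=8):
    rng = np.random.default_rng(seed)
    sizes = rng.integers(4, 12, n_groups)
    ratios = rng.uniform(0.3, 1.8, n_groups)
    gidx = np.arange(n) % n_groups
    df = pd.DataFrame({
        "group_id": [f"G{i}" for i in gidx],
        "individual_id": [f"I{i}" for i in range(n)],
        "sex": rng.choice(["male", "female"], n),
        "age": rng.uniform(7, 45, n),
        "rearing": rng.choice(["mother_reared", "atypically_reared"], n,
                              p=[0.75, 0.25]),
        "group_size": sizes[gidx].astype(float),
        "sex_ratio": ratios[gidx],
    })
    df["out_strength"] = rng.normal(0.08, 0.03, n)
    return df


def test_prepare_design_centers_age_and_encodes_dummies():
    metrics = toy_metrics()
    metrics.loc[:2, "age"] = [10.0, 20.0, 30.0]
    design = prepare_design(metrics, "out_strength", screen_outliers=False)
    assert design.df["age_c"].mean() == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(design.df["age_sq"], design.df["age_c"] ** 2)
    assert set(design.df["male"].unique()) <= {0, 1}
    a = design.df.loc[0, "age_c"]
    assert design.df.loc[0, "age_sq"] == pytest.approx(a ** 2)


def test_prepare_design_indirect_subset_from_reference(reference_table):
    """Eigenvector models: 126 analysis rows from the 20 groups of >= 5."""
    design = prepare_design(reference_table, "eigenvector",
                            screen_outliers=False)
    assert len(design.df) == 126
    assert design.df["group_id"].nunique() == 20


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

def test_vif_orthogonal_and_collinear():
    n = 64
    rng = np.random.default_rng(4)
    a = np.repeat([1.0, -1.0], n // 2)
    b = np.tile([1.0, -1.0], n // 2)
    df = pd.DataFrame({"a": a, "b": b, "c": rng.normal(size=n)})
    vifs = vif_check(df, ["a", "b"])
    assert vifs["a"] == pytest.approx(1.0)
    dup = pd.DataFrame({"a": a, "b": a.copy()})
    assert np.isinf(vif_check(dup, ["a", "b"])).all()


def test_vif_centering_resolves_age_quadratic_collinearity():
    """Raw age with its square is collinear (VIF > 5); centering fixes it."""
    age = np.linspace(7, 45, 60)
    raw = pd.DataFrame({"age": age, "age2": age ** 2})
    assert vif_check(raw, ["age", "age2"]).max() > 5
    centered = pd.DataFrame({"age_c": age - age.mean(),
                             "age_sq": (age - age.mean()) ** 2})
    assert vif_check(centered, ["age_c", "age_sq"]).max() < 5


# ---------------------------------------------------------------------------
# marginality and AIC reduction
# ---------------------------------------------------------------------------

def test_removable_terms_respect_marginality():
    assert "age_c" not in removable_terms(["age_c", "age_sq"])
    assert removable_terms(["age_c", "age_sq"]) == ["age_sq"]
    terms = ["male", "sex_ratio", "male:sex_ratio"]
    assert removable_terms(terms) == ["male:sex_ratio"]
    # quadratic marginality extends inside the sex interaction
    terms = ["male", "age_c", "age_sq", "male:age_c", "male:age_sq"]
    assert set(removable_terms(terms)) == {"male:age_sq"}


def planted_design(n=240, seed=5, beta_age_sq=-4e-5, beta_atypical=-0.03):
    rng = np.random.default_rng(seed)
    metrics = toy_metrics(n=n, seed=seed, n_groups=20)
    design = prepare_design(metrics, "out_strength", screen_outliers=False)
    df = design.df
    df["y"] = (0.08 + beta_age_sq * df["age_sq"]
               + beta_atypical * df["atypical"]
               + rng.normal(0, 0.02, len(df)))
    return design


def test_fit_lmm_recovers_planted_coefficients():
    design = planted_design()
    fit = fit_lmm(design, MAIN_TERMS, reml=True)
    assert fit.params["age_sq"] == pytest.approx(-4e-5,
                                                 abs=3 * fit.bse["age_sq"])
    assert fit.params["atypical"] == pytest.approx(
        -0.03, abs=3 * fit.bse["atypical"])
    assert fit.n_obs == 240


def test_aic_reduction_lowers_aic_and_keeps_hierarchy():
    design = planted_design()
    full = fit_lmm(design, FULL_TERMS, reml=False)
    final, path = aic_backward_reduction(design, FULL_TERMS)
    assert final.aic <= full.aic + 1e-9
    for step in path:
        assert step.aic_after < step.aic_before
    # hierarchy: age_c may only be present without age_sq if dropped later
    if "age_sq" in final.terms:
        assert "age_c" in final.terms
    for t in final.terms:
        if ":" in t:
            a, b = t.split(":")
            assert a in final.terms and b in final.terms


def test_fit_matches_lme4_oracle(tmp_path):
    """statsmodels mixed fit agrees with R lme4 on a small REML fit."""
    rng = np.random.default_rng(17)
    n, g = 80, 8
    group = np.repeat(np.arange(g), n // g)
    u = rng.normal(0, 0.5, g)
    x = rng.normal(size=n)
    y = 1.0 + 0.5 * x + u[group] + rng.normal(0, 0.3, n)
    df = pd.DataFrame({"y": y, "male": x, "group_id": group.astype(str),
                       "individual_id": [f"I{i}" for i in range(n)],
                       "age_c": 0.0, "age_sq": 0.0, "atypical": 0,
                       "group_size": 6.0, "sex_ratio": 1.0})
    design = DesignTable(response="y", df=df)
    fit = fit_lmm(design, ["male"], reml=True)

    csv = tmp_path / "d.csv"
    df[["y", "male", "group_id"]].to_csv(csv, index=False)
    rscript = tmp_path / "fit.R"
    rscript.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- lmer(y ~ male + (1 | group_id), data = d, REML = TRUE)
        cf <- summary(m)$coefficients
        cat(sprintf("%.10f %.10f %.10f %.10f\\n",
            cf[1,1], cf[2,1], cf[1,2], cf[2,2]))
    """))
    out = subprocess.run(["Rscript", "--vanilla", str(rscript)],
                         capture_output=True, text=True, check=True)
    b0, b1, se0, se1 = map(float, out.stdout.split())
    assert fit.params["Intercept"] == pytest.approx(b0, abs=1e-6)
    assert fit.params["male"] == pytest.approx(b1, abs=1e-6)
    assert fit.bse["Intercept"] == pytest.approx(se0, rel=1e-3)
    assert fit.bse["male"] == pytest.approx(se1, rel=1e-3)


# ---------------------------------------------------------------------------
# contrasts and diagnostics
# ---------------------------------------------------------------------------

def test_tukey_contrasts_cell_count_and_null_behavior():
    design = planted_design(beta_atypical=0.0)
    fit = fit_lmm(design, ["male", "atypical", "male:atypical"], reml=True)
    table = tukey_contrasts(fit, design)
    assert len(table) == 6  # 2x2 cells -> C(4,2) pairs
    assert ((table["p_tukey"] > 0) & (table["p_tukey"] <= 1)).all()


def test_residual_diagnostics_writes_plots(tmp_path):
    design = planted_design()
    fit = fit_lmm(design, MAIN_TERMS, reml=True)
    report = residual_diagnostics(fit, tmp_path)
    assert 0 < report["shapiro_p"] <= 1
    from pathlib import Path
    assert Path(report["qq_plot"]).stat().st_size > 0
    assert Path(report["resid_vs_fitted_plot"]).stat().st_size > 0
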