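"""Mixed-model estimation and Wald term tests against independent oracles."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from mitosleep.mixed_models import (
    ModelSpec,
    _build_V,
    fit_binomial_glmm,
    fit_lmm,
    wald_statistic,
    wald_term_tests,
)


def _one_way(seed=42, k=8, n0=30, line_sd=2.0, noise_sd=1.5):
    rng = np.random.default_rng(seed)
    lines = np.repeat([f"L{i}" for i in range(k)], n0)
    le = dict(zip(sorted(set(lines)), rng.normal(0, line_sd, k)))
    y = np.array([le[l] for l in lines]) + rng.normal(0, noise_sd, len(lines))
    return pd.DataFrame({"y": y, "line": lines})


def _factorial(seed=1, k=8, n0=30, line_sd=0.0, sex_eff=0.0, inter_sd=0.0, block_sd=0.3):
    rng = np.random.default_rng(seed)
    rows = []
    le = {f"L{i}": rng.normal(0, line_sd) for i in range(k)}
    ie = {(f"L{i}", s): rng.normal(0, inter_sd) for i in range(k) for s in "fm"}
    be = {f"B{b}": rng.normal(0, block_sd) for b in range(5)}
    for i in range(k):
        for s in "fm":
            for r in range(n0 // 2):
                block = f"B{r % 5}"
                rows.append(
                    {
                        "line": f"L{i}",
                        "sex": s,
                        "block": block,
                        "y": le[f"L{i}"]
                        + sex_eff * (s == "m")
                        + ie[(f"L{i}", s)]
                        + be[block]
                        + rng.normal(),
                    }
                )
    return pd.DataFrame(rows)


class TestLMM:
    def test_intercept_only_matches_closed_form(self):
        df = _one_way()
        fit = fit_lmm(df, ModelSpec("y", [], []))
        assert fit.params.iloc[0] == pytest.approx(df["y"].mean())
        assert fit.residual_variance == pytest.approx(df["y"].var(ddof=1))

    def test_balanced_one_way_matches_moment_estimator(self):
        df = _one_way()
        fit = fit_lmm(df, ModelSpec("y", [], ["line"]))
        group_means = df.groupby("line")["y"].mean()
        n0 = 30
        ms_between = n0 * group_means.var(ddof=1)
        ms_within = df.groupby("line")["y"].var(ddof=1).mean()
        mom = (ms_between - ms_within) / n0
        assert fit.varcomp["line"] == pytest.approx(mom, rel=0.01)
        assert fit.residual_variance == pytest.approx(ms_within, rel=0.01)

    def test_zero_block_effect_flagged_singular(self):
        df = _one_way(line_sd=3.0)
        df["block"] = np.tile([f"B{i}" for i in range(5)], len(df) // 5)
        fit = fit_lmm(df, ModelSpec("y", [], ["line", "block"]))
        assert fit.singular
        assert fit.varcomp["block"] == pytest.approx(0.0, abs=1e-3)

    def test_single_level_random_factor_rejected(self):
        df = _one_way()
        df["block"] = "B1"
        with pytest.raises(ValueError, match="level"):
            fit_lmm(df, ModelSpec("y", [], ["block"]))

    def test_missing_column_named_in_error(self):
        df = _one_way()
        with pytest.raises(KeyError, match="sex"):
            fit_lmm(df, ModelSpec("y", ["sex"], ["line"]))

    def test_binomial_spec_rejected(self):
        with pytest.raises(ValueError, match="gaussian"):
            fit_lmm(_one_way(), ModelSpec("y", [], ["line"], family="binomial"))


@pytest.fixture(scope="module")
def r_results(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("lme4")
    df = _one_way()
    df["block"] = np.tile([f"B{i}" for i in range(5)], len(df) // 5)
    df["sex"] = np.tile(["f", "m"], len(df) // 2)
    df.to_csv(tmp / "lmm.csv", index=False)
    rng = np.random.default_rng(7)
    n = np.full(160, 200)
    lines = np.repeat([f"L{i}" for i in range(8)], 20)
    le = dict(zip(sorted(set(lines)), rng.normal(0, 0.5, 8)))
    sex = np.tile(["f", "m"], 80)
    eta = -0.3 + 0.5 * (sex == "m") + np.array([le[l] for l in lines])
    s = rng.binomial(n, 1 / (1 + np.exp(-eta)))
    gdf = pd.DataFrame({"s": s, "n": n, "line": lines, "sex": sex})
    gdf.to_csv(tmp / "glmm.csv", index=False)
    script = tmp / "oracle.R"
    script.write_text(
        """
        suppressMessages({library(lme4); library(jsonlite)})
        args <- commandArgs(trailingOnly=TRUE)
        d <- read.csv(file.path(args[1], "lmm.csv"))
        m <- lmer(y ~ sex + (1|line) + (1|block), data=d, REML=TRUE)
        vc <- as.data.frame(VarCorr(m))
        g <- read.csv(file.path(args[1], "glmm.csv"))
        gm <- glmer(cbind(s, n - s) ~ sex + (1|line), data=g, family=binomial)
        vg <- as.data.frame(VarCorr(gm))
        out <- list(lmm_fixef=unname(fixef(m)), lmm_vc=vc$vcov,
                    glmm_fixef=unname(fixef(gm)), glmm_se=unname(sqrt(diag(as.matrix(vcov(gm))))),
                    glmm_vc=vg$vcov)
        cat(toJSON(out, digits=10))
        """
    )
    proc = subprocess.run(
        ["Rscript", "--vanilla", str(script), str(tmp)],
        capture_output=True,
        text=True,
        timeout=300,
    )
    assert proc.returncode == 0, proc.stderr
    return df, gdf, json.loads(proc.stdout)

def test_gaussian_crossed_fit_matches_lmer(r_results):
    df, _, r = r_results
    fit = fit_lmm(df, ModelSpec("y", ["sex"], ["line", "block"]))
    np.testing.assert_allclose(fit.params.to_numpy(), r["lmm_fixef"], rtol=1e-3)
    line_vc, block_vc, resid = r["lmm_vc"]
    assert fit.varcomp["line"] == pytest.approx(line_vc, rel=1e-3)
    assert fit.varcomp["block"] == pytest.approx(block_vc, abs=1e-4)
    assert fit.residual_variance == pytest.approx(resid, rel=1e-3)

def test_binomial_laplace_fit_matches_glmer(r_results):
    _, gdf, r = r_results
    spec = ModelSpec("s", ["sex"], ["line"], family="binomial",
                     successes="s", trials="n")
    fit = fit_binomial_glmm(gdf, spec)
    np.testing.assert_allclose(fit.params.to_numpy(), r["glmm_fixef"], rtol=5e-3)
    np.testing.assert_allclose(
        np.sqrt(np.diag(fit.cov_params)), r["glmm_se"], rtol=5e-3
    )
    assert fit.varcomp["line"] == pytest.approx(r["glmm_vc"][0], rel=0.02)


class TestBinomialGLMM:
    def test_intercept_at_logit_of_pooled_proportion(self):
        df = pd.DataFrame({"s": [50] * 20, "n": [100] * 20,
                           "g": ["a", "b"] * 10})
        spec = ModelSpec("s", [], [], family="binomial", successes="s", trials="n")
        fit = fit_binomial_glmm(df, spec)
        assert fit.params.iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_sex_effect_recovered_at_study_size(self):
        rng = np.random.default_rng(12)
        n = np.full(480, 864)
        sex = np.repeat(["f", "m"], 240)
        block = np.tile([f"B{i}" for i in range(5)], 96)
        be = dict(zip(sorted(set(block)), rng.normal(0, 0.2, 5)))
        eta = 0.2 + 0.5 * (sex == "m") + np.array([be[b] for b in block]) \
            + rng.normal(0, 0.3, 480)  # per-fly overdispersion
        s = rng.binomial(n, 1 / (1 + np.exp(-eta)))
        df = pd.DataFrame({"s": s, "n": n, "sex": sex, "block": block})
        spec = ModelSpec("s", ["sex"], ["block"], family="binomial",
                         successes="s", trials="n")
        fit = fit_binomial_glmm(df, spec)
        est = fit.params["C(sex)[T.m]"]
        se = np.sqrt(fit.cov_params.loc["C(sex)[T.m]", "C(sex)[T.m]"])
        # binomial SE understates fly-level noise, so allow the empirical spread
        assert est == pytest.approx(0.5, abs=0.1)
        assert se > 0

    def test_complete_separation_flagged(self):
        df = pd.DataFrame(
            {
                "s": [100] * 10 + [40] * 10,
                "n": [100] * 20,
                "line": ["L1"] * 10 + ["L2"] * 10,
                "block": ["B1", "B2"] * 10,
            }
        )
        spec = ModelSpec("s", ["line"], ["block"], family="binomial",
                         successes="s", trials="n")
        fit = fit_binomial_glmm(df, spec)
        assert fit.separation


class TestWald:
    def test_zero_coefficients_give_zero_statistic(self):
        stat, df = wald_statistic(np.zeros(3), np.eye(3) * 2.0)
        assert stat == 0.0
        assert df == 3
        assert chi2.sf(stat, df) == 1.0

    def test_one_df_statistic_is_squared_z(self):
        df = _factorial(sex_eff=0.4)
        fit = fit_lmm(df, ModelSpec("y", ["sex"], ["block"]))
        wt = wald_term_tests(fit)
        z = fit.params["C(sex)[T.m]"] / np.sqrt(
            fit.cov_params.loc["C(sex)[T.m]", "C(sex)[T.m]"]
        )
        assert wt.loc[0, "chisq"] == pytest.approx(z**2, rel=1e-8)

    def test_type_ii_matches_independent_gls(self):
        """Brute-force GLS of the sex contrast assembled with raw numpy."""
        df = _factorial(seed=5, line_sd=0.5, sex_eff=0.3, inter_sd=0.2)
        spec = ModelSpec("y", ["line", "sex", "line:sex"], ["block"])
        fit = fit_lmm(df, spec)
        wt = wald_term_tests(fit).set_index("term")
        # independent path: explicit dummy coding, V from the fitted comps
        y = df["y"].to_numpy()
        lines = sorted(df["line"].unique())
        L = np.stack([(df["line"] == l).to_numpy(float) for l in lines[1:]], axis=1)
        s = (df["sex"] == "m").to_numpy(float)[:, None]
        X_sub = np.hstack([np.ones((len(df), 1)), L, s])  # sex after line, no interaction
        V = _build_V(df, fit.varcomp, fit.residual_variance)
        Vc = cho_factor(V)
        A = X_sub.T @ cho_solve(Vc, X_sub)
        beta = np.linalg.solve(A, X_sub.T @ cho_solve(Vc, y))
        cov = np.linalg.inv(A)
        j = X_sub.shape[1] - 1
        stat = beta[j] ** 2 / cov[j, j]
        assert wt.loc["sex", "chisq"] == pytest.approx(stat, rel=1e-8)

    def test_invariant_to_reference_level(self):
        df = _factorial(seed=9, line_sd=0.5, sex_eff=0.3, inter_sd=0.2)
        spec = ModelSpec("y", ["line", "sex", "line:sex"], ["block"])
        wt1 = wald_term_tests(fit_lmm(df, spec)).set_index("term")
        relabel = {f"L{i}": f"Z{7 - i}" for i in range(8)}  # reverses sort order
        df2 = df.assign(line=df["line"].map(relabel))
        wt2 = wald_term_tests(fit_lmm(df2, spec)).set_index("term")
        for term in ("line", "sex", "line:sex"):
            assert wt1.loc[term, "chisq"] == pytest.approx(
                wt2.loc[term, "chisq"], rel=1e-6
            )

    def test_type_iii_interaction_agrees_with_type_ii(self):
        # the highest-order term is tested identically under both conventions
        df = _factorial(seed=3, line_sd=0.4, sex_eff=0.3, inter_sd=0.3)
        spec = ModelSpec("y", ["line", "sex", "line:sex"], ["block"])
        fit = fit_lmm(df, spec)
        w2 = wald_term_tests(fit, anova_type=2).set_index("term")
        w3 = wald_term_tests(fit, anova_type=3).set_index("term")
        assert w2.loc["line:sex", "chisq"] == pytest.approx(
            w3.loc["line:sex", "chisq"], rel=1e-6
        )

    def test_interaction_detected_when_present(self):
        df = _factorial(seed=21, line_sd=0.3, sex_eff=0.2, inter_sd=1.0)
        fit = fit_lmm(df, ModelSpec("y", ["line", "sex", "line:sex"], ["block"]))
        wt = wald_term_tests(fit).set_index("term")
        assert wt.loc["line:sex", "p"] < 1e-6
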