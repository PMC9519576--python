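"""Linear and binomial mixed models with Wald chi-square term tests.

The analysis fits, per panel, models of each phenotype with line, sex and
their interaction as categorical fixed effects and experimental block as a
random intercept (the estimable reduction of a replicate-within-block
random term when there is a single datum per fly).  Gaussian responses
(total and awake activity) are fitted by REML through
:class:`statsmodels.regression.mixed_linear_model.MixedLM`; the proportion
of time asleep is fitted as a binomial GLMM on successes = sleep bins out
of trials = total bins, with a logit link and a Laplace approximation to
the marginal likelihood (fixed effects profiled with the random-effect
modes in the inner optimisation).

Fixed-effect terms are tested with marginality-respecting (type II) Wald
chi-square statistics: each term is tested in the model containing every
term that does not contain it, with the variance parameters held at the
full-model estimates.  This is the convention of the car::Anova ecosystem
and is invariant to the factor coding.  Type III tests with sum-to-zero
coding are available via ``anova_type=3``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, gammaln
from scipy.stats import chi2 as chi2_dist

GAUSSIAN_RESPONSES = {"total_activity", "mean_awake_activity"}
BINOMIAL_RESPONSE = "prop_asleep"


@dataclass
class ModelSpec:
    """Declarative description of one mixed model."""

    response: str
    fixed: list[str]  # factor terms, e.g. ["line", "sex", "line:sex"]
    random: list[str] = field(default_factory=lambda: ["block"])
    family: str = "gaussian"  # gaussian | binomial
    successes: str = "n_sleep_bins"
    trials: str = "n_bins"

    def __post_init__(self) -> None:
        if self.family not in {"gaussian", "binomial"}:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class ModelFit:
    """A fitted mixed model with everything term tests need."""

    spec: ModelSpec
    data: pd.DataFrame  # rows actually used (response non-missing)
    params: pd.Series  # fixed-effect estimates
    cov_params: pd.DataFrame  # covariance of the fixed effects
    varcomp: dict  # grouping factor -> variance (latent scale for binomial)
    residual_variance: float | None  # gaussian only
    loglik: float
    converged: bool
    singular: bool  # some variance component at the boundary
    separation: bool = False  # binomial only: a fixed-effect cell all-0/all-1
    _glmm: "object | None" = None  # Laplace fitter, for penalised refits


def _patsy_term(term: str, coding: str = "treatment") -> str:
    suffix = ", Sum" if coding == "sum" else ""
    return ":".join(f"C({f}{suffix})" for f in term.split(":"))


def _rhs(terms: Sequence[str], coding: str = "treatment") -> str:
    if not terms:
        return "1"
    return "1 + " + " + ".join(_patsy_term(t, coding) for t in terms)


def _design(data: pd.DataFrame, terms: Sequence[str], coding: str = "treatment"):
    """Design matrix plus a map from our term names to column slices."""
    X = patsy.dmatrix(_rhs(terms, coding), data, return_type="dataframe")
    info = X.design_info
    slices = {t: info.term_name_slices[_patsy_term(t, coding)] for t in terms}
    return np.asarray(X, dtype=float), list(X.columns), slices


def _term_contains(container: str, term: str) -> bool:
    return set(term.split(":")) <= set(container.split(":"))


def _check_factors(data: pd.DataFrame, spec: ModelSpec) -> None:
    needed = sorted({f for t in spec.fixed for f in t.split(":")} | set(spec.random))
    if spec.family == "binomial":
        needed += [spec.successes, spec.trials]
    else:
        needed += [spec.response]
    for col in needed:
        if col not in data.columns:
            raise KeyError(f"model requires column {col!r}, absent from the data")
    for t in spec.fixed:
        for f in t.split(":"):
            if data[f].nunique() < 2:
                raise ValueError(f"fixed factor {f!r} has fewer than 2 levels")
    for rf in spec.random:
        n_levels = data[rf].nunique()
        if n_levels < 2:
            raise ValueError(f"random factor {rf!r} has {n_levels} level(s); need >= 2")


def _dummies(data: pd.DataFrame, factor: str) -> np.ndarray:
    return pd.get_dummies(data[factor].astype(str)).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Gaussian LMM


def _gls(X: np.ndarray, y: np.ndarray, V_chol) -> tuple[np.ndarray, np.ndarray]:
    """GLS estimate and covariance given a Cholesky factor of V."""
    ViX = cho_solve(V_chol, X)
    A = X.T @ ViX
    beta = np.linalg.solve(A, ViX.T @ y)
    cov = np.linalg.inv(A)
    return beta, cov


def _build_V(data: pd.DataFrame, varcomp: dict, residual: float) -> np.ndarray:
    n = len(data)
    V = residual * np.eye(n)
    for rf, vc in varcomp.items():
        if vc > 0:
            Z = _dummies(data, rf)
            V += vc * (Z @ Z.T)
    return V


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit a gaussian mixed model by REML.

    Random intercepts per grouping factor; crossed factors are handled as
    variance components.  A variance estimated at (numerically) zero is
    returned flagged ``singular``, not raised.  With ``spec.random`` empty
    the model degenerates to ordinary least squares with the REML residual
    variance RSS/(n-p).
    """
    if spec.family != "gaussian":
        raise ValueError("fit_lmm requires a gaussian spec")
    _check_factors(data, spec)
    data = data.dropna(subset=[spec.response]).reset_index(drop=True)
    y = data[spec.response].to_numpy(dtype=float)
    X, colnames, _ = _design(data, spec.fixed)
    n, p = X.shape

    if not spec.random:
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / (n - p)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        ll = -0.5 * (n - p) * (1 + np.log(2 * np.pi * sigma2))
        return ModelFit(
            spec=spec,
            data=data,
            params=pd.Series(beta, index=colnames),
            cov_params=pd.DataFrame(cov, index=colnames, columns=colnames),
            varcomp={},
            residual_variance=sigma2,
            loglik=ll,
            converged=True,
            singular=False,
        )

    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(spec.random) == 1:
            rf = spec.random[0]
            model = sm.MixedLM(y, X, groups=data[rf].astype(str).to_numpy())
            res = model.fit(reml=True, method="powell", maxiter=2000)
            varcomp = {rf: float(np.asarray(res.cov_re)[0, 0])}
        else:
            # one covering group; crossed factors enter as variance components
            from statsmodels.regression.mixed_linear_model import VCSpec

            names, colnames_vc, mats = [], [], []
            for rf in spec.random:
                Z = _dummies(data, rf)
                names.append(rf)
                colnames_vc.append([[f"{rf}[{i}]" for i in range(Z.shape[1])]])
                mats.append([Z])
            vcs = VCSpec(names, colnames_vc, mats)
            groups = np.zeros(n)
            model = sm.MixedLM(y, X, groups=groups, exog_vc=vcs)
            # derivative-free search: the profiled objective is flat near
            # zero-variance boundaries, where gradient methods stall
            res = model.fit(reml=True, method="powell", maxiter=2000)
            varcomp = {
                rf: float(vc) for rf, vc in zip(names, np.atleast_1d(res.vcomp))
            }
    residual = float(res.scale)
    singular = any(vc <= max(1e-12, 1e-6 * np.var(y)) for vc in varcomp.values())
    # fixed effects and covariance from GLS at the REML variance estimates,
    # so full-model and submodel Wald tests share one code path
    V_chol = cho_factor(_build_V(data, varcomp, residual))
    beta, cov = _gls(X, y, V_chol)
    return ModelFit(
        spec=spec,
        data=data,
        params=pd.Series(beta, index=colnames),
        cov_params=pd.DataFrame(cov, index=colnames, columns=colnames),
        varcomp=varcomp,
        residual_variance=residual,
        loglik=float(res.llf),
        converged=bool(res.converged),
        singular=singular,
    )


# ---------------------------------------------------------------------------
# Binomial GLMM (Laplace)


class _LaplaceGLMM:
    """Random-intercept binomial GLMM fitted by a Laplace approximation.

    The inner step jointly maximises the penalised log-likelihood over
    fixed effects and random-effect modes by damped Newton iterations; the
    outer step optimises the Laplace objective over the log standard
    deviations of the variance components.  Deterministic: fixed starting
    values, no randomness.
    """

    def __init__(self, s: np.ndarray, n: np.ndarray, X: np.ndarray,
                 Z_blocks: list[tuple[str, np.ndarray]]):
        self.s = np.asarray(s, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.X = X
        self.names = [name for name, _ in Z_blocks]
        self.Z = np.hstack([Z for _, Z in Z_blocks]) if Z_blocks else np.zeros((len(s), 0))
        self.q_sizes = [Z.shape[1] for _, Z in Z_blocks]
        self.const = float(
            np.sum(gammaln(self.n + 1) - gammaln(self.s + 1) - gammaln(self.n - self.s + 1))
        )

    def _dinv(self, theta: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [np.full(q, np.exp(-2.0 * th)) for q, th in zip(self.q_sizes, theta)]
        ) if self.q_sizes else np.zeros(0)

    def _pen_ll(self, X, beta, u, dinv) -> float:
        eta = np.clip(X @ beta + self.Z @ u, -30, 30)
        ll = float(self.s @ eta - self.n @ np.logaddexp(0, eta))
        return ll - 0.5 * float(u @ (dinv * u))

    def inner(self, theta: np.ndarray, X: np.ndarray | None = None,
              tol: float = 1e-9, maxiter: int = 200):
        """Joint Newton maximisation of the penalised log-likelihood."""
        if X is None:
            X = self.X
        p, q = X.shape[1], self.Z.shape[1]
        dinv = self._dinv(theta)
        beta = np.zeros(p)
        # start the intercept at the logit of the pooled proportion
        pbar = np.clip(self.s.sum() / self.n.sum(), 1e-6, 1 - 1e-6)
        beta[0] = np.log(pbar / (1 - pbar))
        u = np.zeros(q)
        f = self._pen_ll(X, beta, u, dinv)
        H = None
        for _ in range(maxiter):
            eta = np.clip(X @ beta + self.Z @ u, -30, 30)
            mu = expit(eta)
            W = self.n * mu * (1 - mu) + 1e-12
            r = self.s - self.n * mu
            g = np.concatenate([X.T @ r, self.Z.T @ r - dinv * u])
            XtW = X.T * W
            H = np.empty((p + q, p + q))
            H[:p, :p] = XtW @ X
            H[:p, p:] = XtW @ self.Z
            H[p:, :p] = H[:p, p:].T
            H[p:, p:] = (self.Z.T * W) @ self.Z + np.diag(dinv)
            if np.max(np.abs(g)) < tol * (1 + abs(f)):
                break
            try:
                delta = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(H, g, rcond=None)[0]
            step = 1.0
            while step > 1e-10:
                nb = beta + step * delta[:p]
                nu = u + step * delta[p:]
                nf = self._pen_ll(X, nb, nu, dinv)
                if nf >= f - 1e-12:
                    beta, u, f = nb, nu, nf
                    break
                step /= 2.0
            else:
                break
        eta = np.clip(X @ beta + self.Z @ u, -30, 30)
        mu = expit(eta)
        W = self.n * mu * (1 - mu) + 1e-12
        return beta, u, W, dinv, f, H

    def nll(self, theta: np.ndarray) -> float:
        beta, u, W, dinv, pen_ll, _ = self.inner(theta)
        if self.Z.shape[1]:
            Hu = (self.Z.T * W) @ self.Z + np.diag(dinv)
            sign, ld_Hu = np.linalg.slogdet(Hu)
            ld_D = sum(2.0 * th * q for th, q in zip(theta, self.q_sizes))
            lap = pen_ll - 0.5 * ld_Hu - 0.5 * ld_D
        else:
            lap = pen_ll
        return -lap

    def fit(self, theta0: float = np.log(0.3)):
        k = len(self.q_sizes)
        if k == 0:
            theta = np.zeros(0)
            res_success = True
        else:
            res = optimize.minimize(
                self.nll,
                np.full(k, theta0),
                method="L-BFGS-B",
                bounds=[(-6.0, 3.0)] * k,
                options={"ftol": 1e-12, "gtol": 1e-8},
            )
            theta = res.x
            res_success = bool(res.success)
        beta, u, W, dinv, pen_ll, H = self.inner(theta)
        p = self.X.shape[1]
        cov_all = np.linalg.inv(H)
        cov_beta = cov_all[:p, :p]
        loglik = -self.nll(theta) + self.const
        return {
            "theta": theta,
            "beta": beta,
            "u": u,
            "cov_beta": cov_beta,
            "loglik": loglik,
            "converged": res_success,
        }

    def refit_beta(self, theta: np.ndarray, X: np.ndarray):
        """Penalised re-estimate of beta for a submodel design, with the
        variance parameters fixed; returns (beta, cov_beta)."""
        beta, u, W, dinv, pen_ll, H = self.inner(theta, X=X)
        p = X.shape[1]
        cov_beta = np.linalg.inv(H)[:p, :p]
        return beta, cov_beta


def _detect_separation(data: pd.DataFrame, spec: ModelSpec) -> bool:
    factors = sorted({f for t in spec.fixed for f in t.split(":")})
    if not factors:
        return False
    g = data.groupby(factors, observed=True)
    agg = g.agg(s=(spec.successes, "sum"), n=(spec.trials, "sum"))
    return bool(((agg["s"] == 0) | (agg["s"] == agg["n"])).any())


def fit_binomial_glmm(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit a binomial-logit GLMM of sleep bins out of total bins.

    Variance components are reported on the latent (logit) scale.  A fixed-
    effect cell with all-0 or all-1 proportions flags the fit as separated;
    the fit is still returned (the boundary estimate is clipped by the
    linear-predictor bounds).
    """
    if spec.family != "binomial":
        raise ValueError("fit_binomial_glmm requires a binomial spec")
    _check_factors(data, spec)
    data = data.dropna(subset=[spec.successes, spec.trials]).reset_index(drop=True)
    s = data[spec.successes].to_numpy(dtype=float)
    n_tr = data[spec.trials].to_numpy(dtype=float)
    X, colnames, _ = _design(data, spec.fixed)
    Z_blocks = [(rf, _dummies(data, rf)) for rf in spec.random]
    fitter = _LaplaceGLMM(s, n_tr, X, Z_blocks)
    out = fitter.fit()
    varcomp = {
        rf: float(np.exp(2 * th)) for rf, th in zip(fitter.names, out["theta"])
    }
    singular = any(v <= 1e-5 for v in varcomp.values())
    fit = ModelFit(
        spec=spec,
        data=data,
        params=pd.Series(out["beta"], index=colnames),
        cov_params=pd.DataFrame(out["cov_beta"], index=colnames, columns=colnames),
        varcomp=varcomp,
        residual_variance=None,
        loglik=float(out["loglik"]),
        converged=out["converged"],
        singular=singular,
        separation=_detect_separation(data, spec),
        _glmm=(fitter, out["theta"]),
    )
    return fit


# ---------------------------------------------------------------------------
# Wald term tests


def wald_statistic(beta: np.ndarray, cov: np.ndarray) -> tuple[float, int]:
    """Wald chi-square and df for H0: beta = 0 given its covariance.

    Rank-deficient covariances are handled by a pseudo-inverse with the df
    reduced to the rank.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    rank = int(np.linalg.matrix_rank(cov))
    if rank < len(beta):
        warnings.warn("rank-deficient contrast; df reduced to rank")
        stat = float(beta @ np.linalg.pinv(cov) @ beta)
    else:
        stat = float(beta @ np.linalg.solve(cov, beta))
    return max(stat, 0.0), rank


def wald_term_tests(fit: ModelFit, anova_type: int = 2) -> pd.DataFrame:
    """Marginality-respecting Wald chi-square tests of each fixed term.

    Type II (default): each term is tested in the model that omits every
    term containing it, holding variance parameters at the full-model
    estimates.  Type III: each term's block is tested in the full model
    under sum-to-zero coding.  Returns a table with columns
    ``term, chisq, df, p``.
    """
    if anova_type not in (2, 3):
        raise ValueError("anova_type must be 2 or 3")
    spec, data = fit.spec, fit.data
    terms = list(spec.fixed)
    gaussian = spec.family == "gaussian"
    if gaussian:
        y = data[spec.response].to_numpy(dtype=float)
        V_chol = cho_factor(
            _build_V(data, fit.varcomp, fit.residual_variance)
        )
    else:
        fitter, theta = fit._glmm

    rows = []
    if anova_type == 3:
        X, _, slices = _design(data, terms, coding="sum")
        if gaussian:
            beta, cov = _gls(X, y, V_chol)
        else:
            beta, cov = fitter.refit_beta(theta, X)
        for t in terms:
            sl = slices[t]
            stat, df = wald_statistic(beta[sl], cov[sl, sl])
            rows.append((t, stat, df, chi2_dist.sf(stat, df)))
    else:
        for t in terms:
            keep = [x for x in terms if x != t and not _term_contains(x, t)]
            X, _, slices = _design(data, keep + [t])
            if gaussian:
                beta, cov = _gls(X, y, V_chol)
            else:
                beta, cov = fitter.refit_beta(theta, X)
            sl = slices[t]
            stat, df = wald_statistic(beta[sl], cov[sl, sl])
            rows.append((t, stat, df, chi2_dist.sf(stat, df)))
    return pd.DataFrame(rows, columns=["term", "chisq", "df", "p"])


# ---------------------------------------------------------------------------
# The study's model battery

_RESPONSES = [
    ("total_activity", "gaussian"),
    ("prop_asleep", "binomial"),
    ("mean_awake_activity", "gaussian"),
]

_DISPLAY = {
    "line": "Line",
    "sex": "Sex",
    "line:sex": "Line × Sex",
    "genome_type": "Type",
    "genome_type:sex": "Type × Sex",
    "haplogroup": "Haplogroup",
    "haplogroup:sex": "Haplogroup × Sex",
}


def _fit(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    if spec.family == "binomial":
        return fit_binomial_glmm(data, spec)
    return fit_lmm(data, spec)


def run_study_models(
    data: pd.DataFrame, anova_type: int = 2
) -> dict[str, tuple[ModelFit, pd.DataFrame]]:
    """Run the study's full model battery on a phenotype table.

    Per panel (original = coevolved, cybrid): each response on line, sex
    and line:sex with block random.  Combined: type (coevolved vs cybrid),
    sex and type:sex with line random nested within type, plus block.
    Haplogroup contrasts per panel: haplogroup, sex, haplogroup:sex with
    line and block random.  Returns ``analysis name -> (fit, Wald table)``.
    """
    for col in ("line", "sex", "genome_type", "haplogroup", "block"):
        if col not in data.columns:
            raise KeyError(f"phenotype table lacks required column {col!r}")
    out: dict[str, tuple[ModelFit, pd.DataFrame]] = {}
    panels = {"original": "coevolved", "cybrid": "cybrid"}
    for pname, gtype in panels.items():
        sub = data[data["genome_type"] == gtype]
        for resp, fam in _RESPONSES:
            spec = ModelSpec(resp, ["line", "sex", "line:sex"], ["block"], fam)
            fitted = _fit(sub, spec)
            out[f"{pname}_{resp}"] = (fitted, wald_term_tests(fitted, anova_type))
    combined = data.copy()
    combined["type_line"] = (
        combined["genome_type"].astype(str) + ":" + combined["line"].astype(str)
    )
    for resp, fam in _RESPONSES:
        spec = ModelSpec(
            resp,
            ["genome_type", "sex", "genome_type:sex"],
            ["type_line", "block"],
            fam,
        )
        fitted = _fit(combined, spec)
        out[f"type_{resp}"] = (fitted, wald_term_tests(fitted, anova_type))
    for pname, gtype in panels.items():
        sub = data[data["genome_type"] == gtype]
        for resp, fam in _RESPONSES:
            spec = ModelSpec(
                resp,
                ["haplogroup", "sex", "haplogroup:sex"],
                ["line", "block"],
                fam,
            )
            fitted = _fit(sub, spec)
            out[f"haplogroup_{pname}_{resp}"] = (
                fitted,
                wald_term_tests(fitted, anova_type),
            )
    return out


def wald_report(results: dict[str, tuple[ModelFit, pd.DataFrame]]) -> pd.DataFrame:
    """Flatten a model battery into a table shaped like the study's
    fixed-effect summaries: analysis, response, term, chisq, df, p."""
    rows = []
    for name, (fitted, wt) in results.items():
        analysis, _, response = name.partition("_")
        if name.startswith("haplogroup_"):
            parts = name.split("_", 2)
            analysis, response = f"{parts[0]}_{parts[1]}", parts[2]
        for _, r in wt.iterrows():
            rows.append(
                {
                    "analysis": analysis,
                    "response": response,
                    "term": _DISPLAY.get(r["term"], r["term"]),
                    "chisq": r["chisq"],
                    "df": int(r["df"]),
                    "p": r["p"],
                    "converged": fitted.converged,
                    "singular": fitted.singular,
                }
            )
    return pd.DataFrame(rows)
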