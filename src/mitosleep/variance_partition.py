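"""Among-line variance per panel and the cybrid/original variance ratio.

In a cybrid panel every line shares one nuclear background, so the
among-line variance there isolates the mtDNA contribution; in the original
(coevolved) panel it reflects mtDNA and nuclear variation jointly.  The
ratio sigma2_line(cybrid) / sigma2_line(original) therefore estimates the
fraction of the among-line trait variance attributable to mtDNA.

Line variance is the random-effect variance from a mixed model with sex
fixed and line and block random: gaussian on the response scale for the
activity traits, binomial-logit for the proportion of time asleep (whose
variance is read on the latent logit scale).  Uncertainty comes from a
cluster bootstrap that resamples whole lines -- the unit of inference --
within each panel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed_models import ModelSpec, fit_binomial_glmm, fit_lmm

TRAITS = ["total_activity", "mean_awake_activity", "prop_asleep"]
_PANEL_GENOME = {"original": "coevolved", "cybrid": "cybrid"}


@dataclass
class LineVariance:
    trait: str
    panel: str
    variance: float
    singular: bool


def _spec_for(trait: str) -> ModelSpec:
    family = "binomial" if trait == "prop_asleep" else "gaussian"
    return ModelSpec(trait, fixed=["sex"], random=["line", "block"], family=family)


def among_line_variance(
    data: pd.DataFrame, panel: str, trait: str, include_sex: bool = True
) -> LineVariance:
    """Estimate the among-line variance component for one panel and trait.

    Requires at least 3 lines in the panel.  A variance estimated at the
    zero boundary is returned as 0 with ``singular=True``.
    """
    if panel not in _PANEL_GENOME:
        raise ValueError(f"panel must be one of {sorted(_PANEL_GENOME)}; got {panel!r}")
    sub = data[data["genome_type"] == _PANEL_GENOME[panel]]
    if sub.empty:
        raise ValueError(f"no rows for panel {panel!r}")
    n_lines = sub["line"].nunique()
    if n_lines < 3:
        raise ValueError(f"panel {panel!r} has {n_lines} lines; need >= 3")
    spec = _spec_for(trait)
    if not include_sex:
        spec.fixed = []
    if spec.family == "binomial":
        fit = fit_binomial_glmm(sub, spec)
        scale_ref = 1.0  # latent logit scale
    else:
        fit = fit_lmm(sub, spec)
        scale_ref = float(np.var(sub[trait].dropna()))
    v = float(fit.varcomp["line"])
    singular = v <= max(1e-12, 1e-6 * scale_ref)
    return LineVariance(trait=trait, panel=panel, variance=0.0 if singular else v,
                        singular=singular)


def variance_table(data: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Among-line variances per trait and panel plus their ratio.

    Shaped like the study's variance-components table: one row per trait
    with the original and cybrid line variances (latent logit scale for
    sleep) and the cybrid/original ratio, both at full precision and
    rounded to 2 decimals for display.  A zero original-panel variance
    leaves the ratio undefined (NaN, flagged).
    """
    traits = traits or TRAITS
    rows = []
    for trait in traits:
        orig = among_line_variance(data, "original", trait)
        cyb = among_line_variance(data, "cybrid", trait)
        ratio = mtdna_variance_ratio(orig.variance, cyb.variance)
        rows.append(
            {
                "trait": trait,
                "original_variance": orig.variance,
                "cybrid_variance": cyb.variance,
                "ratio": ratio,
                "ratio_2dp": round(ratio, 2) if math.isfinite(ratio) else math.nan,
                "flagged": orig.singular or cyb.singular or not math.isfinite(ratio),
            }
        )
    return pd.DataFrame(rows)


def mtdna_variance_ratio(original_variance: float, cybrid_variance: float) -> float:
    """Cybrid/original among-line variance ratio; NaN when undefined."""
    if original_variance <= 0:
        warnings.warn("original-panel line variance is 0; ratio undefined")
        return math.nan
    return cybrid_variance / original_variance


def ratio_uncertainty(
    data: pd.DataFrame,
    trait: str,
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Cluster-bootstrap percentile interval for the variance ratio.

    Lines are resampled with replacement within each panel (keeping panel
    sizes); each replicate re-estimates both among-line variances and the
    ratio.  Deterministic given ``seed``.  Replicates with a zero
    original-panel variance are dropped from the percentiles; if more than
    half the replicates are degenerate a wide-interval warning is issued.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    panels = {p: data[data["genome_type"] == g] for p, g in _PANEL_GENOME.items()}
    lines = {p: sorted(d["line"].unique()) for p, d in panels.items()}
    ratios = []
    n_degenerate = 0
    for _ in range(n_boot):
        vs = {}
        for p, d in panels.items():
            chosen = rng.choice(lines[p], size=len(lines[p]), replace=True)
            parts = []
            for i, ln in enumerate(chosen):
                part = d[d["line"] == ln].copy()
                part["line"] = f"{ln}.bs{i}"  # duplicates stay distinct clusters
                parts.append(part)
            boot = pd.concat(parts, ignore_index=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vs[p] = among_line_variance(boot, p, trait).variance
        if vs["original"] <= 0:
            n_degenerate += 1
            continue
        ratios.append(vs["cybrid"] / vs["original"])
    if n_degenerate > n_boot / 2:
        warnings.warn(
            f"{n_degenerate}/{n_boot} bootstrap replicates had zero original-panel "
            "variance; interval is unreliable (too few informative lines)"
        )
    alpha = (1 - level) / 2
    ratios = np.array(ratios)
    lo, hi = (
        (float(np.quantile(ratios, alpha)), float(np.quantile(ratios, 1 - alpha)))
        if len(ratios)
        else (math.nan, math.nan)
    )
    return {
        "trait": trait,
        "n_boot": n_boot,
        "n_used": int(len(ratios)),
        "level": level,
        "lower": lo,
        "upper": hi,
    }
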