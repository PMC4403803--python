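"""Plot-level comparative statistics.

One row per plot (richness, PD, density, percent alien, Mantel r); a
one-way ANOVA compares forest with grassland for any per-plot variable,
and four Gaussian GLMs (identity link, i.e. ordinary least squares)
model Mantel r as vegetation × covariate for each of the four covariates:
richness, PD, plant density, and log-transformed percent alien. Four
models × three non-intercept terms give the twelve hypothesis tests of
the comparative stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

__all__ = [
    "PlotSummary",
    "ModelFit",
    "anova_oneway",
    "fit_mantel_glms",
    "log_pct_alien",
    "summaries_to_frame",
]

GLM_COVARIATES = ("richness", "pd", "density", "log_pct_alien")


@dataclass
class PlotSummary:
    plot_id: str
    vegetation: str
    richness: int
    pd: float
    density: float
    pct_alien: float
    log_pct_alien: float
    mantel_r: float | None
    mantel_p: float | None
    pd_classification: str | None = None


@dataclass
class ModelFit:
    """Coefficient table of one fitted model."""

    response: str
    model_id: str
    terms: list[tuple[str, float, float, float, float]]  # name, est, se, t, p
    residual_df: int

    def term(self, name: str):
        for t in self.terms:
            if t[0] == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.terms, columns=["term", "estimate", "std_error", "t", "p"]
        ).assign(model=self.model_id)


def anova_oneway(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p for per-plot values by group label.

    Raises ValueError when fewer than two groups, any group has fewer than
    two observations, or within-group variance is zero (F undefined).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("one-way ANOVA needs >= 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs >= 2 observations")
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ssw == 0:
        raise ValueError("zero within-group variance: F undefined")
    f, p = scipy.stats.f_oneway(*samples)
    return float(f), float(p)


def log_pct_alien(pct: float, offset: float = 1.0) -> float:
    """ln(pct + offset): log-transform of percent alien, 0 maps to 0.

    The +1 offset keeps plots with no alien plants representable.
    """
    if pct < 0:
        raise ValueError("percentage must be >= 0")
    return float(np.log(pct + offset))


def summaries_to_frame(summaries: list[PlotSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def fit_mantel_glms(
    summaries: list[PlotSummary],
    covariates: tuple[str, ...] = GLM_COVARIATES,
    full_model: bool = False,
) -> list[ModelFit]:
    """Fit the per-covariate Gaussian GLMs for Mantel r.

    One ordinary-least-squares fit per covariate with terms
    {intercept, vegetation, covariate, vegetation × covariate}; with four
    covariates this yields twelve non-intercept P values. With
    ``full_model=True`` a single additive model with all covariates plus
    vegetation is fitted instead (not the default: twenty plots cannot
    support the full interaction surface).
    """
    df = summaries_to_frame(summaries).dropna(subset=["mantel_r"])
    if len(df) < 6:
        raise ValueError(f"need >= 6 plots with a defined Mantel r, have {len(df)}")

    fits = []
    formulas = (
        [("full", "mantel_r ~ vegetation + " + " + ".join(covariates))]
        if full_model
        else [(cov, f"mantel_r ~ vegetation * {cov}") for cov in covariates]
    )
    for model_id, formula in formulas:
        res = smf.ols(formula, data=df).fit()
        if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
            raise np.linalg.LinAlgError(f"singular design in model {model_id!r}")
        terms = [
            (name, float(res.params[name]), float(res.bse[name]),
             float(res.tvalues[name]), float(res.pvalues[name]))
            for name in res.params.index
        ]
        fits.append(
            ModelFit(
                response="mantel_r",
                model_id=model_id,
                terms=terms,
                residual_df=int(res.df_resid),
            )
        )
    return fits
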