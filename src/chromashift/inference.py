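"""Model selection and inference for colour-shift data.

The statistical procedure operates on per-individual colour shifts and asks
which of genetic line, treatment (social context or infection) and time
explain them, allowing for repeated measures through a per-individual
random intercept:

1. fit a small ladder of candidate models — main effects vs. full
   interactions, with and without the random intercept — by maximum
   likelihood;
2. compare them by AIC, treating models within 2 AIC units as equivalent
   and preferring the simplest of an equivalent set;
3. simplify the chosen model by backward elimination (drop the term whose
   removal lowers AIC the most, respecting marginality, until no removal
   helps);
4. test the random intercept by a likelihood-ratio chi-square between
   otherwise identical models;
5. follow up factor effects with estimated-marginal-mean (least-squares
   means) pairwise comparisons, Tukey-adjusted.

Model fitting is delegated to statsmodels (``MixedLM`` for random-intercept
specifications, ``OLS`` otherwise); everything above that — the AIC ladder,
the 2-unit rule, elimination, the LRT and the post hocs — lives here.

Conventions recorded in output metadata: AIC is 2k - 2 logLik with k
counting fixed coefficients plus variance parameters (random-intercept
variance if present, plus the residual variance); fixed-effect t tests use
residual degrees of freedom (n - k_fixed), a documented approximation for
mixed models; selection is by ML, final variance estimates by REML.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.formula.api as smf

from .shift_assembly import INTERVALS

__all__ = [
    "ModelSpec",
    "ModelFit",
    "ModelComparison",
    "RandomEffectTest",
    "PairwiseComparison",
    "default_ladder",
    "prepare_model_frame",
    "fit_model",
    "compare_models",
    "simplify_model",
    "test_random_effect",
    "posthoc_means",
]

logger = logging.getLogger(__name__)

_FACTORS = ("line", "treatment", "time")
_CONVERGENCE_TOL = 1e-8
_BOUNDARY_VAR = 1e-10


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: response attribute, fixed terms, random intercept.

    ``fixed`` is a tuple of terms, each a tuple of factor names from
    {"line", "treatment", "time"}; interactions are multi-factor tuples and
    every factor in an interaction must also appear as a main effect.
    """

    response: str
    fixed: tuple[tuple[str, ...], ...]
    random_intercept: bool = True

    def __post_init__(self) -> None:
        mains = {t[0] for t in self.fixed if len(t) == 1}
        for term in self.fixed:
            for f in term:
                if f not in _FACTORS:
                    raise ValueError(f"unknown factor {f!r}; expected one of {_FACTORS}")
            if len(term) > 1 and not set(term) <= mains:
                raise ValueError(
                    f"interaction {term} requires all its factors as main effects"
                )
        if len(set(self.fixed)) != len(self.fixed):
            raise ValueError("duplicate fixed terms")

    def label(self) -> str:
        rhs = " + ".join(":".join(t) for t in self.fixed) or "1"
        re = " + (1|individual)" if self.random_intercept else ""
        return f"{self.response} ~ {rhs}{re}"

    @property
    def n_interactions(self) -> int:
        return sum(1 for t in self.fixed if len(t) > 1)


def default_ladder(response: str) -> list[ModelSpec]:
    """The four standard candidates: {main effects, full interactions} x
    {with, without the individual random intercept}."""
    mains = (("line",), ("treatment",), ("time",))
    full = mains + (
        ("line", "treatment"),
        ("line", "time"),
        ("treatment", "time"),
        ("line", "treatment", "time"),
    )
    return [
        ModelSpec(response=response, fixed=fixed, random_intercept=ri)
        for fixed in (mains, full)
        for ri in (False, True)
    ]


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


def prepare_model_frame(
    shifts: pd.DataFrame, response: str, time_coding: str = "continuous"
) -> pd.DataFrame:
    """Extract one attribute from the long shift table and encode covariates.

    ``time`` becomes the interval-end hour (continuous coding, the default)
    or the interval label as a three-level category (reference 0-24).
    """
    sub = shifts[shifts["attribute"] == response].copy()
    if sub.empty:
        raise ValueError(f"no rows for attribute {response!r}")
    if time_coding == "continuous":
        sub["time"] = sub["interval"].map(lambda s: INTERVALS[s][1]).astype(float)
    elif time_coding == "categorical":
        sub["time"] = pd.Categorical(sub["interval"], categories=list(INTERVALS))
    else:
        raise ValueError(f"unknown time_coding {time_coding!r}")
    return sub.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelFit:
    """A fitted candidate with its coefficient table and AIC bookkeeping.

    ``params`` has one row per fixed term with columns estimate, std_error,
    df, t_value, p_value (the standard coefficient-table layout).
    """

    spec: ModelSpec
    method: str
    formula: str
    params: pd.DataFrame
    loglik: float
    k_params: int
    aic: float
    n_obs: int
    sigma_resid: float
    sigma_u: float | None = None
    converged: bool = True
    boundary: bool = False
    elimination_path: tuple[tuple[str, float, float], ...] = ()
    result: object = field(default=None, repr=False, compare=False)

    def label(self) -> str:
        return self.spec.label()


def _canonical(term: str) -> str:
    """Normalise patsy coefficient names: line[T.R] -> line[R]."""
    return term.replace("[T.", "[")


def _formula(spec: ModelSpec) -> str:
    rhs = " + ".join(":".join(t) for t in spec.fixed) or "1"
    return f"delta ~ {rhs}"


def fit_model(data: pd.DataFrame, spec: ModelSpec, method: str = "ML") -> ModelFit:
    """Fit one candidate model.

    Random-intercept specifications use a linear mixed model grouped by
    ``individual_id``; specifications without random terms use ordinary
    least squares.  ``method`` is "ML" (required for AIC comparison) or
    "REML" (for final variance estimates; ignored for OLS, whose
    log-likelihood is always the ML one).
    """
    if method not in ("ML", "REML"):
        raise ValueError(f"method must be 'ML' or 'REML', got {method!r}")
    if not np.isfinite(data["delta"]).all():
        raise ValueError("response contains non-finite values")
    formula = _formula(spec)

    if spec.random_intercept:
        cell_counts = data.groupby(
            [c for c in ("line", "treatment") if c in data.columns]
        )["individual_id"].nunique()
        if (cell_counts < 2).any():
            raise ValueError("need >= 2 individuals per modelled cell")
        model = smf.mixedlm(formula, data, groups=data["individual_id"])
        res = None
        # optimiser fallback chain: variance components near zero can make
        # the Hessian singular for a given optimiser
        for opt in ({"method": "lbfgs"}, {}, {"method": "cg"}):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    candidate = model.fit(reml=(method == "REML"), maxiter=500, **opt)
            except (np.linalg.LinAlgError, ValueError):
                continue
            res = candidate
            if res.converged:
                break
        if res is None:
            raise RuntimeError(f"mixed model failed to converge: {spec.label()}")
        fe = res.fe_params
        k_fe = len(fe)
        var_u = float(np.asarray(res.cov_re)[0, 0])
        sigma_u = float(np.sqrt(max(var_u, 0.0)))
        sigma_resid = float(np.sqrt(res.scale))
        boundary = var_u < _BOUNDARY_VAR
        if boundary:
            logger.warning("boundary fit: random-intercept variance ~ 0 for %s", spec.label())
        k = k_fe + 2  # random-intercept variance + residual variance
        df_t = float(res.nobs - k_fe)  # residual-df approximation, recorded in metadata
        se = res.bse_fe
        converged = bool(res.converged)
        llf = float(res.llf)
        n_obs = int(res.nobs)
    else:
        res = smf.ols(formula, data).fit()
        fe = res.params
        k_fe = len(fe)
        sigma_u = None
        sigma_resid = float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0
        boundary = False
        k = k_fe + 1  # residual variance
        df_t = float(res.df_resid)
        se = res.bse
        converged = True
        llf = float(res.llf)
        n_obs = int(res.nobs)

    est = np.asarray(fe, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, est / se, np.nan)
    pval = 2.0 * stats.t.sf(np.abs(tval), df_t)
    params = pd.DataFrame(
        {
            "estimate": est,
            "std_error": se,
            "df": df_t,
            "t_value": tval,
            "p_value": pval,
        },
        index=pd.Index([_canonical(t) for t in fe.index], name="term"),
    )
    return ModelFit(
        spec=spec,
        method=method,
        formula=formula,
        params=params,
        loglik=llf,
        k_params=k,
        aic=2.0 * k - 2.0 * llf,
        n_obs=n_obs,
        sigma_resid=sigma_resid,
        sigma_u=sigma_u,
        converged=converged,
        boundary=boundary,
        result=res,
    )


# ---------------------------------------------------------------------------
# AIC comparison with the 2-unit rule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelComparison:
    """Outcome of an AIC ladder: per-candidate table and the chosen model."""

    fits: tuple[ModelFit, ...]
    table: pd.DataFrame
    chosen: ModelFit
    equivalence: dict[tuple[int, int], bool]


def _complexity_key(fit: ModelFit) -> tuple:
    # fewest parameters, then fewest interaction terms, then no-random first
    return (fit.k_params, fit.spec.n_interactions, fit.spec.random_intercept)


def compare_models(fits: Sequence[ModelFit]) -> ModelComparison:
    """Rank candidates by AIC; within 2 units the simplest model wins.

    All fits must be by ML on the same number of observations.  Ties are
    broken deterministically: fewest parameters, then fewest interaction
    terms, then the model without a random intercept.
    """
    fits = tuple(fits)
    if not fits:
        raise ValueError("no fits to compare")
    methods = {f.method for f in fits}
    if methods != {"ML"}:
        raise ValueError(f"model comparison requires ML fits only, got methods {sorted(methods)}")
    if len({f.n_obs for f in fits}) != 1:
        raise ValueError("fits were not computed on identical observations")

    aics = np.array([f.aic for f in fits])
    best = aics.min()
    equivalent = [f for f, a in zip(fits, aics) if a - best < 2.0]
    chosen = min(equivalent, key=_complexity_key)

    table = pd.DataFrame(
        {
            "candidate": [f.label() for f in fits],
            "k": [f.k_params for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": aics,
            "delta_aic": aics - best,
            "chosen": [f is chosen for f in fits],
        }
    )
    equivalence = {
        (i, j): bool(abs(aics[i] - aics[j]) < 2.0)
        for i, j in itertools.combinations(range(len(fits)), 2)
    }
    return ModelComparison(fits=fits, table=table, chosen=chosen, equivalence=equivalence)


# ---------------------------------------------------------------------------
# Backward simplification
# ---------------------------------------------------------------------------


def _removable_terms(fixed: tuple[tuple[str, ...], ...]) -> list[tuple[str, ...]]:
    """Terms not contained in any higher-order term (marginality)."""
    return [
        t
        for t in fixed
        if not any(set(t) < set(other) for other in fixed if other != t)
    ]


def simplify_model(fit: ModelFit, data: pd.DataFrame) -> ModelFit:
    """Backward-eliminate fixed terms by AIC.

    Repeatedly refits the model with each currently removable term (one not
    marginal to a retained interaction) dropped, removes the term whose
    removal lowers AIC the most, and stops when no removal lowers AIC.  The
    elimination path is recorded on the returned fit and logged.
    """
    current = fit if fit.method == "ML" else fit_model(data, fit.spec, method="ML")
    path: list[tuple[str, float, float]] = []
    while True:
        candidates = []
        for term in _removable_terms(current.spec.fixed):
            reduced_fixed = tuple(t for t in current.spec.fixed if t != term)
            reduced = fit_model(data, replace(current.spec, fixed=reduced_fixed), method="ML")
            candidates.append((term, reduced))
        if not candidates:
            break
        term, best = min(candidates, key=lambda c: c[1].aic)
        if best.aic < current.aic - _CONVERGENCE_TOL:
            path.append((":".join(term), current.aic, best.aic))
            logger.info(
                "dropped %s: AIC %.3f -> %.3f", ":".join(term), current.aic, best.aic
            )
            current = best
        else:
            break
    return replace(current, elimination_path=tuple(path))


# ---------------------------------------------------------------------------
# Random-effect likelihood-ratio test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomEffectTest:
    """Likelihood-ratio test of the individual random intercept."""

    statistic: float
    df: int
    p_value: float
    fit_with: ModelFit
    fit_without: ModelFit


def test_random_effect(
    data: pd.DataFrame, spec_with_id: ModelSpec, spec_without_id: ModelSpec
) -> RandomEffectTest:
    """Compare otherwise identical models with and without the random intercept.

    chi2 = 2 (logLik_full - logLik_reduced) under ML, with degrees of
    freedom equal to the parameter-count difference.  A materially negative
    statistic indicates a convergence failure and raises.
    """
    if spec_with_id.fixed != spec_without_id.fixed or spec_with_id.response != spec_without_id.response:
        raise ValueError("specs must be identical apart from the random intercept")
    if not spec_with_id.random_intercept or spec_without_id.random_intercept:
        raise ValueError("expected one spec with and one without the random intercept")
    full = fit_model(data, spec_with_id, method="ML")
    reduced = fit_model(data, spec_without_id, method="ML")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        raise RuntimeError(
            f"likelihood-ratio statistic is negative ({stat:.3g}); "
            "the full model did not converge"
        )
    stat = max(stat, 0.0)
    df = full.k_params - reduced.k_params
    return RandomEffectTest(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        fit_with=full,
        fit_without=reduced,
    )


# ---------------------------------------------------------------------------
# Estimated marginal means and Tukey post hocs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseComparison:
    """One pairwise difference of estimated marginal means."""

    factor: str
    level_a: str
    level_b: str
    estimate: float
    std_error: float
    df: float
    t_value: float
    p_raw: float
    p_adjusted: float


def _fe_cov(fit: ModelFit) -> np.ndarray:
    cov = np.asarray(fit.result.cov_params())
    k_fe = len(fit.params)
    return cov[:k_fe, :k_fe]


def posthoc_means(fit: ModelFit, factor: str) -> list[PairwiseComparison]:
    """All pairwise estimated-marginal-mean differences for one factor.

    Marginal means are model predictions averaged (equal weights) over a
    reference grid spanning every level of the other categorical factors,
    with continuous covariates held at their observed mean.  Pairwise
    differences carry Tukey (studentized-range) adjusted p-values; with only
    two levels the adjusted p equals the raw p.
    """
    if fit.result is None:
        raise ValueError("fit carries no underlying model result")
    frame = fit.result.model.data.frame
    design_info = fit.result.model.data.design_info
    model_factors = {f for term in fit.spec.fixed for f in term}
    if factor not in model_factors:
        raise ValueError(f"factor {factor!r} is not in the fitted model {fit.spec.label()}")

    def levels_of(name: str):
        col = frame[name]
        if isinstance(col.dtype, pd.CategoricalDtype):
            return [l for l in col.cat.categories if l in set(col)]
        return sorted(col.unique())

    if pd.api.types.is_numeric_dtype(frame[factor]):
        raise ValueError(
            f"factor {factor!r} is continuous in this fit; post hoc means need a categorical factor"
        )

    grid_axes: dict[str, list] = {}
    for name in sorted(model_factors):
        if pd.api.types.is_numeric_dtype(frame[name]):
            grid_axes[name] = [float(frame[name].mean())]
        else:
            grid_axes[name] = list(levels_of(name))
    keys = list(grid_axes)
    grid = pd.DataFrame(
        [dict(zip(keys, combo)) for combo in itertools.product(*grid_axes.values())]
    )
    X = np.asarray(patsy.build_design_matrices([design_info], grid)[0])

    beta = fit.params["estimate"].to_numpy()
    cov = _fe_cov(fit)
    df_t = float(fit.params["df"].iloc[0])
    levels = grid_axes[factor]
    k_levels = len(levels)
    if k_levels < 2:
        raise ValueError(f"factor {factor!r} has fewer than two levels")

    rows_for = {l: X[(grid[factor] == l).to_numpy()].mean(axis=0) for l in levels}
    out = []
    for a, b in itertools.combinations(levels, 2):
        c = rows_for[a] - rows_for[b]
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        t = est / se if se > 0 else np.nan
        p_raw = float(2.0 * stats.t.sf(abs(t), df_t))
        p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k_levels, df_t))
        out.append(
            PairwiseComparison(
                factor=factor,
                level_a=str(a),
                level_b=str(b),
                estimate=est,
                std_error=se,
                df=df_t,
                t_value=t,
                p_raw=p_raw,
                p_adjusted=max(p_adj, p_raw),
            )
        )
    return out
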