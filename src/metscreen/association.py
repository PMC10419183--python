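"""Odds-ratio estimation for dichotomized indices.

Each index is cut at its sex-specific Youden-optimal threshold
(``value >= cutoff`` defines the exposed group, mirroring the ROC
classification rule) and entered in a binary logistic regression against
metabolic syndrome or one of its components.  Unadjusted models contain the
exposure alone; adjusted models add the study covariate set (age, education,
marital status, residence, smoking, drinking, social activities, exercise,
chronic-disease count band — sex is dropped inside sex strata).

The maximum-likelihood fit is delegated to statsmodels' Logit (Newton
iterations, observed-information covariance); this module owns the design
coding (reference-level indicators for categorical covariates), the
separation and convergence diagnostics, and the Wald OR / CI / p-value
reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "dichotomize_index",
    "fit_logistic",
    "odds_ratio_table",
    "LogisticFit",
    "AssociationResult",
    "DEFAULT_ADJUSTMENT",
]

#: adjustment covariate list (categorical unless noted; age is continuous)
DEFAULT_ADJUSTMENT: tuple[str, ...] = (
    "age",
    "education",
    "marital_status",
    "residence",
    "smoking",
    "drinking",
    "activities",
    "exercise",
    "chronic_disease_band",
)


def dichotomize_index(values, cutoff: float) -> np.ndarray:
    """Boolean exposure: ``value >= cutoff`` (same rule as ROC scoring)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return np.asarray(values, float) >= cutoff


@dataclass
class LogisticFit:
    """Fitted logistic model with diagnostics.

    ``params``/``bse`` are indexed by design column name.  ``converged`` is
    the optimizer's own flag; ``separation`` marks (quasi-)separated fits
    whose estimates are unusable.
    """

    params: pd.Series
    bse: pd.Series
    converged: bool
    separation: bool
    n_obs: int

    @property
    def ok(self) -> bool:
        return self.converged and not self.separation

    def odds_ratio(self, term: str) -> tuple[float, tuple[float, float], float]:
        """Wald OR, 95% CI and p-value for one design column."""
        beta = float(self.params[term])
        se = float(self.bse[term])
        ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
        from scipy.stats import norm

        p = float(2.0 * norm.sf(abs(beta) / se)) if se > 0 else 0.0
        return float(np.exp(beta)), ci, p


_SEPARATION_SE = 50.0  # |beta| or SE beyond this on a binary design => separation


def fit_logistic(outcome, design: pd.DataFrame, maxiter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic regression with diagnostics.

    Parameters
    ----------
    outcome
        Boolean response with both classes present.
    design
        Numeric design matrix **without** intercept (one is added).

    Raises
    ------
    ValueError
        Single-class outcome.
    """
    y = np.asarray(outcome, float)
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    X = sm.add_constant(design.astype(float), has_constant="add")
    separation = False
    converged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=maxiter)
        converged = bool(fit.mle_retvals.get("converged", False))
        params = fit.params
        bse = fit.bse
        # huge coefficients / SEs on a logit scale signal separation
        if np.any(np.abs(params) > _SEPARATION_SE) or np.any(~np.isfinite(bse)) or np.any(
            bse > _SEPARATION_SE
        ):
            separation = True
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separation = True
        params = pd.Series(np.nan, index=X.columns)
        bse = pd.Series(np.nan, index=X.columns)
    return LogisticFit(
        params=pd.Series(params, index=X.columns),
        bse=pd.Series(bse, index=X.columns),
        converged=converged,
        separation=separation,
        n_obs=len(y),
    )


def code_covariates(
    cohort: pd.DataFrame, covariates: tuple[str, ...] = DEFAULT_ADJUSTMENT
) -> pd.DataFrame:
    """Reference-level indicator coding for the adjustment covariates.

    The reference for each categorical covariate is its first level in the
    cohort's category ordering (or sorted order for plain object columns);
    ``age`` passes through as a continuous column.  ``sex`` is coded
    male=reference when requested explicitly.
    """
    cols = []
    for name in covariates:
        if name == "age":
            cols.append(cohort["age"].astype(float).rename("age"))
            continue
        if name == "sex":
            cols.append((cohort["sex"] == "female").astype(float).rename("sex[female]"))
            continue
        series = cohort[name]
        if isinstance(series.dtype, pd.CategoricalDtype):
            levels = list(series.cat.categories)
        else:
            levels = sorted(series.dropna().unique())
        for level in levels[1:]:
            cols.append((series == level).astype(float).rename(f"{name}[{level}]"))
    return pd.concat(cols, axis=1)


@dataclass
class AssociationResult:
    """One dichotomized index vs one outcome, unadjusted and adjusted."""

    index_name: str
    sex_stratum: str
    outcome: str
    or_unadj: float | None
    ci_unadj: tuple[float, float] | None
    p_unadj: float | None
    or_adj: float | None
    ci_adj: tuple[float, float] | None
    p_adj: float | None
    covariate_set: tuple[str, ...]
    flag: str = ""

    def as_row(self) -> dict:
        return {
            "index_name": self.index_name,
            "sex_stratum": self.sex_stratum,
            "outcome": self.outcome,
            "or_unadj": self.or_unadj,
            "ci_unadj_lo": self.ci_unadj[0] if self.ci_unadj else None,
            "ci_unadj_hi": self.ci_unadj[1] if self.ci_unadj else None,
            "p_unadj": self.p_unadj,
            "or_adj": self.or_adj,
            "ci_adj_lo": self.ci_adj[0] if self.ci_adj else None,
            "ci_adj_hi": self.ci_adj[1] if self.ci_adj else None,
            "p_adj": self.p_adj,
            "covariates": "+".join(self.covariate_set),
            "flag": self.flag,
        }


def odds_ratio_table(
    cohort: pd.DataFrame,
    exposures: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_ADJUSTMENT,
    strata: tuple[str, ...] = ("male", "female"),
) -> pd.DataFrame:
    """Unadjusted and adjusted ORs for every exposure × outcome × stratum.

    ``exposures`` holds boolean columns (dichotomized indices),
    ``outcomes`` boolean columns (MetS and its components); both aligned to
    the cohort.  Complete-case analysis: rows with a missing covariate are
    dropped from the adjusted fit (count retained in ``flag``).
    """
    rows = []
    for sex in strata:
        mask = cohort["sex"] == sex
        sub = cohort.loc[mask]
        design_adj = code_covariates(sub, covariates)
        complete = design_adj.notna().all(axis=1)
        n_dropped = int((~complete).sum())
        for out_name in outcomes.columns:
            y = outcomes.loc[mask, out_name]
            for exp_name in exposures.columns:
                x = exposures.loc[mask, exp_name].astype(float).rename("exposure")
                result = AssociationResult(
                    index_name=exp_name,
                    sex_stratum=sex,
                    outcome=out_name,
                    or_unadj=None,
                    ci_unadj=None,
                    p_unadj=None,
                    or_adj=None,
                    ci_adj=None,
                    p_adj=None,
                    covariate_set=covariates,
                )
                flags = []
                if n_dropped:
                    flags.append(f"dropped {n_dropped} incomplete")
                try:
                    unadj = fit_logistic(y, x.to_frame())
                    if unadj.ok:
                        (
                            result.or_unadj,
                            result.ci_unadj,
                            result.p_unadj,
                        ) = unadj.odds_ratio("exposure")
                    else:
                        flags.append("unadjusted: separation/non-convergence")
                    adj = fit_logistic(
                        y[complete],
                        pd.concat([x, design_adj], axis=1)[complete],
                    )
                    if adj.ok:
                        result.or_adj, result.ci_adj, result.p_adj = adj.odds_ratio(
                            "exposure"
                        )
                    else:
                        flags.append("adjusted: separation/non-convergence")
                except ValueError as err:
                    flags.append(str(err))
                result.flag = "; ".join(flags)
                rows.append(result.as_row())
    return pd.DataFrame(rows)
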