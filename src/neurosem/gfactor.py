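"""Measurement models: the cognitive g factor and the white-matter general
factors.

The g factor is a one-factor CFA of Matrix Reasoning, Symbol-Digit,
Verbal-Numerical Reasoning and Trail-Making B time (negative loading),
estimated with FIML.  When the preregistered-style fit thresholds
(CFI, TLI > 0.95; RMSEA, SRMR < 0.05) are not met, modification indices are
consulted and the top residual covariance is freed, up to a small cap.

gFA and gMD are one-factor CFAs over the 27 tract-averaged FA (resp. MD)
values with per-subject factor scores computed by the regression (Thomson)
method, which shrinks scores toward zero (SD < 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sem
from .cohort import COGNITIVE_TESTS, fa_columns, md_columns
from .sem import FitResult, build_model, fit_model, modification_indices

__all__ = ["GFactorModel", "fit_g_cfa", "variance_explained",
           "derive_gfa_gmd", "g_model_definition"]

FIT_THRESHOLDS = dict(cfi=0.95, tli=0.95, rmsea=0.05, srmr=0.05)


def g_model_definition(covariates=(), residual_pairs=(), tests=None) -> str:
    """Model text for the 4-test g CFA with optional covariate attachment."""
    tests = list(tests) if tests is not None else list(COGNITIVE_TESTS)
    lines = ["g =~ " + " + ".join(tests)]
    for a, b in residual_pairs:
        lines.append(f"{a} ~~ {b}")
    if covariates:
        rhs = " + ".join(covariates)
        for t in tests:
            lines.append(f"{t} ~ {rhs}")
    return "\n".join(lines)


@dataclass
class GFactorModel:
    """A fitted g measurement model."""

    fit: FitResult
    residual_pairs: list = field(default_factory=list)
    covariates: tuple = ()
    meets_thresholds: bool = False
    flagged: bool = False

    @property
    def loadings(self) -> pd.Series:
        return self.fit.loadings("g")

    @property
    def variance_explained(self) -> float:
        return variance_explained(self.loadings.to_numpy())

    def summary_table(self) -> pd.DataFrame:
        t = self.fit.params.copy()
        t["residual_pairs"] = "; ".join(f"{a}~~{b}"
                                        for a, b in self.residual_pairs)
        return t


def fit_g_cfa(cohort: pd.DataFrame, covariates=(), auto_respecify=True,
              cap: int = 3, min_tests: int = 1, thresholds=None,
              residual_pairs=(), compute_se: bool = True) -> GFactorModel:
    """Fit the one-factor g CFA with FIML, MI-respecifying if needed.

    Subjects contribute when at least ``min_tests`` of the four tests are
    observed.  ``residual_pairs`` seeds the model with already-established
    residual covariances (e.g. carrying the pair found on the uncorrected
    model into the covariate-adjusted one).  With ``auto_respecify``, while
    any fit threshold fails the top-modification-index residual covariance
    is freed and the model refitted, at most ``cap`` times; if thresholds
    are still unmet the best fit is returned flagged.
    """
    thresholds = dict(thresholds or FIT_THRESHOLDS)
    tests = [t for t in COGNITIVE_TESTS if t in cohort.columns]
    if len(tests) < 3:
        raise ValueError("cohort lacks the cognitive test columns")
    n_obs = cohort[tests].notna().sum(axis=1)
    data = cohort[n_obs >= min_tests]
    pairs: list[tuple[str, str]] = [tuple(p) for p in residual_pairs]
    fit = None
    for _ in range(cap + 1):
        model = build_model(
            g_model_definition(covariates, pairs, tests),
            fixed_x=list(covariates))
        fit = fit_model(model, data, compute_se=compute_se)
        if fit.meets(**thresholds) or not auto_respecify:
            break
        if len(pairs) >= cap:
            break
        mis = modification_indices(fit)
        if not mis or mis[0].mi <= 0:
            break
        top = mis[0].parameter.split("~~")
        pairs.append((top[0], top[1]))
    meets = fit.meets(**thresholds)
    return GFactorModel(fit=fit, residual_pairs=pairs,
                        covariates=tuple(covariates),
                        meets_thresholds=meets,
                        flagged=not (meets and fit.converged))


def variance_explained(loadings) -> float:
    """Mean squared standardized loading: the share of indicator variance
    the factor accounts for."""
    lam = np.asarray(loadings, float)
    if lam.size == 0:
        raise ValueError("empty loading vector")
    return float(np.mean(lam ** 2))


def _factor_scores(fit: FitResult, cohort: pd.DataFrame, columns):
    """Regression-method scores for a fitted one-factor model (no x)."""
    obj = fit._internal["objective"]
    theta = fit._internal["theta"]
    gd = obj.groups[0]
    A, S, G, nu = obj.matrices(theta, 0)
    Sigma, _, a, IA, Sigma_v = sem._group_moments(A, S, G, nu, fit.model.ny)
    # latent-observed covariance (scaled metric): rows y, single latent
    lam_cov = (IA @ S @ IA.T)[:fit.model.ny, fit.model.ny]
    Y = (cohort[columns].to_numpy(float) - gd.y_means) / gd.y_sds
    scores = np.full(len(Y), np.nan)
    obs_mask = ~np.isnan(Y)
    codes = obs_mask @ (1 << np.arange(len(columns), dtype=np.int64))
    for code in np.unique(codes):
        if code == 0:
            continue
        rows = np.where(codes == code)[0]
        o = np.where(obs_mask[rows[0]])[0]
        So = Sigma[np.ix_(o, o)]
        w = np.linalg.solve(So, lam_cov[o])
        scores[rows] = (Y[np.ix_(rows, o)] - a[o]) @ w
    return scores


def derive_gfa_gmd(cohort: pd.DataFrame, tracts=None,
                   compute_fit: bool = False) -> pd.DataFrame:
    """Add gFA and gMD general-factor score columns to the cohort.

    One-factor CFA per modality over the tract-averaged values (all 27
    tracts by default, configurable subset), FIML over subjects with at
    least one tract value, regression-method scores centred at 0.
    """
    out = cohort.copy()
    for name, all_cols in (("gfa", fa_columns()), ("gmd", md_columns())):
        cols = [c for c in all_cols
                if tracts is None or c.split("_", 1)[1] in tracts]
        cols = [c for c in cols if c in cohort.columns]
        if len(cols) < 2:
            raise ValueError(f"too few tract columns for {name}")
        data = cohort[cohort[cols].notna().any(axis=1)]
        model = build_model("f =~ " + " + ".join(cols))
        fit = fit_model(model, data, compute_fit=compute_fit,
                        compute_se=False)
        if not fit.converged:
            raise RuntimeError(f"general-factor CFA for {name} did not "
                               "converge")
        # orient the factor so most loadings are positive
        lam = fit.loadings("f").to_numpy()
        flip = -1.0 if (lam < 0).sum() > (lam > 0).sum() else 1.0
        scores = flip * _factor_scores(fit, cohort, cols)
        finite = np.isfinite(scores)
        scores[finite] = scores[finite] - scores[finite].mean()
        out[name] = scores
    return out
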