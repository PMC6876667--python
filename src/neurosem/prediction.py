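"""Out-of-sample prediction of g from multivariate regional MRI.

A MIMIC SEM is trained on one site (regional measures, bilaterally averaged
for parsimony, jointly predicting latent g with in-model covariates); the
standardized beta weights define a weighted composite score that is applied
to the held-out site on the training-sample standardization.  A two-sample
SEM with g loadings and the MR-VNR residual correlation fixed across sites
then compares the composite-g association between training and test data.

Two total-brain-volume correction variants are available: adjusting each
ROI for TBV inside the training model before weights are estimated
(``tbv_mode="roi_adjusted"``), or entering TBV as a covariate in the
structural regression at evaluation time (``tbv_covariate=True``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .associations import AssociationRow, HEAD_COVARIATES
from .cohort import COGNITIVE_TESTS
from .gfactor import FIT_THRESHOLDS, g_model_definition
from .sem import build_model, fit_model, modification_indices

__all__ = ["CompositeModel", "EvaluationReport", "average_bilateral",
           "averaged_roi_columns", "train_composite", "evaluate_composite"]

_PAIRED_PREFIXES = ("fa_", "md_", "cortical_", "subcortical_")


def average_bilateral(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add per-structure left/right mean columns.

    Columns ``<prefix>_<structure>_l`` / ``..._r`` produce
    ``<prefix>_<structure>``; when one side is missing the available side is
    used.  Unpaired (commissural/brainstem) columns already carry the
    structure name and are left as-is.
    """
    out = cohort.copy()
    lefts = [c for c in cohort.columns
             if c.endswith("_l") and c.startswith(_PAIRED_PREFIXES)]
    for lc in lefts:
        rc = lc[:-2] + "_r"
        base = lc[:-2]
        if rc not in cohort.columns:
            raise ValueError(f"unpairable column {lc!r}: no {rc!r}")
        out[base] = cohort[[lc, rc]].mean(axis=1)
    return out


def averaged_roi_columns(family: str):
    """Bilaterally averaged ROI names per family (48/15/15/7)."""
    from .cohort import (_BILATERAL_TRACTS, _SINGLE_TRACTS, CORTICAL_REGIONS,
                         SUBCORTICAL_STRUCTURES)
    if family == "cortical":
        return [f"cortical_{r}" for r in CORTICAL_REGIONS]
    if family == "subcortical":
        return [f"subcortical_{s}" for s in SUBCORTICAL_STRUCTURES]
    if family in ("fa", "md"):
        return ([f"{family}_{t}" for t in _BILATERAL_TRACTS]
                + [f"{family}_{t}" for t in _SINGLE_TRACTS])
    raise ValueError(f"unknown ROI family {family!r}")


@dataclass
class CompositeModel:
    """Weighted-composite recipe learned on the training site."""

    family: str
    roi_columns: list
    weights: dict                     # ROI -> training standardized beta
    means: dict                       # ROI -> training mean (post TBV adj.)
    sds: dict
    tbv_mode: str = "none"            # none | roi_adjusted
    tbv_slopes: dict = field(default_factory=dict)
    tbv_mean: float = np.nan
    covariates: tuple = ("age", "sex")
    training_site: str | None = None
    training_n: int = 0
    fit_indices: dict = field(default_factory=dict)
    residual_pairs: list = field(default_factory=list)
    flagged: bool = False

    def composite(self, cohort: pd.DataFrame) -> np.ndarray:
        """Sum of weighted training-standardized ROI z-scores; NaN when no
        ROI is available."""
        Z = np.zeros((len(cohort), len(self.roi_columns)))
        obs = np.zeros_like(Z, bool)
        for j, c in enumerate(self.roi_columns):
            x = cohort[c].to_numpy(float)
            if self.tbv_mode == "roi_adjusted":
                x = x - self.tbv_slopes[c] * (
                    cohort["tbv"].to_numpy(float) - self.tbv_mean)
            z = (x - self.means[c]) / self.sds[c]
            m = np.isfinite(z)
            Z[m, j] = z[m] * self.weights[c]
            obs[:, j] = m
        score = Z.sum(axis=1)
        score[~obs.any(axis=1)] = np.nan
        return score

    def to_json(self, path=None):
        d = {k: getattr(self, k) for k in
             ("family", "roi_columns", "weights", "means", "sds",
              "tbv_mode", "tbv_slopes", "tbv_mean", "training_site",
              "training_n", "fit_indices", "residual_pairs", "flagged")}
        d["covariates"] = list(self.covariates)
        d["tbv_mean"] = None if not np.isfinite(self.tbv_mean) \
            else self.tbv_mean
        if path is None:
            return json.dumps(d, indent=2, default=float)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=float)


def train_composite(train_cohort: pd.DataFrame, roi_family: str,
                    tbv_mode: str = "none", covariates=("age", "sex"),
                    cap: int = 10, thresholds=None, rois=None,
                    training_site=None) -> CompositeModel:
    """Fit the training MIMIC SEM and return the composite recipe.

    The ROIs (complete cases, bilaterally averaged) enter as exogenous
    predictors of g under the conditional likelihood — exactly equivalent
    to maximum likelihood with a saturated exogenous block, so their
    covariances are unrestricted by construction.  Covariates (age, sex and
    head coordinates) are attached to the cognitive manifests and define
    the partialled metric of the standardized weights.  If the fit misses
    the thresholds, top-modification-index residual covariances among the
    cognitive indicators are freed, up to ``cap``; a model still short of
    thresholds is returned flagged.
    """
    if tbv_mode not in ("none", "roi_adjusted"):
        raise ValueError("tbv_mode must be 'none' or 'roi_adjusted'")
    thresholds = dict(thresholds or FIT_THRESHOLDS)
    avg = average_bilateral(train_cohort)
    if rois is None:
        rois = [c for c in averaged_roi_columns(roi_family)
                if c in avg.columns]
    if not rois:
        raise ValueError(f"no ROI columns for family {roi_family!r}")
    cov = list(covariates) + [h for h in HEAD_COVARIATES
                              if h not in covariates]
    cov = [c for c in cov if c in avg.columns]
    cogs = [c for c in COGNITIVE_TESTS if c in avg.columns]
    need = rois + cov + (["tbv"] if tbv_mode == "roi_adjusted" else [])
    rows = avg[avg[need].notna().all(axis=1)
               & avg[cogs].notna().any(axis=1)].copy()

    tbv_slopes, tbv_mean = {}, np.nan
    if tbv_mode == "roi_adjusted":
        tbv = rows["tbv"].to_numpy(float)
        tbv_mean = float(tbv.mean())
        tc = tbv - tbv_mean
        for c in rois:
            x = rows[c].to_numpy(float)
            b = float(tc @ (x - x.mean()) / (tc @ tc))
            tbv_slopes[c] = b
            rows[c] = x - b * tc

    means = {c: float(rows[c].mean()) for c in rois}
    sds = {c: float(rows[c].std(ddof=0)) for c in rois}

    pairs = [("matrix_reasoning", "vnr")]
    fit = None
    for _ in range(cap + 1):
        lines = [g_model_definition(cov, pairs, cogs),
                 "g ~ " + " + ".join(rois)]
        model = build_model("\n".join(lines), fixed_x=cov + rois,
                            covariates=cov)
        fit = fit_model(model, rows)
        if fit.meets(**thresholds) or len(pairs) - 1 >= cap:
            break
        mis = modification_indices(fit)
        if not mis or mis[0].mi <= 0:
            break
        top = mis[0].parameter.split("~~")
        pairs.append((top[0], top[1]))

    weights = {c: float(fit.param(f"g~{c}")["std"]) for c in rois}
    return CompositeModel(
        family=roi_family, roi_columns=rois, weights=weights, means=means,
        sds=sds, tbv_mode=tbv_mode, tbv_slopes=tbv_slopes, tbv_mean=tbv_mean,
        covariates=tuple(cov), training_site=training_site,
        training_n=fit.n, fit_indices=fit.indices_dict(),
        residual_pairs=pairs[1:],
        flagged=not (fit.converged and fit.meets(**thresholds)))


@dataclass
class EvaluationReport:
    """Training/test comparison of the composite-g association."""

    rows: list                       # AssociationRow per site
    n_excluded: dict
    tbv_covariate: bool
    fit_indices: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "group": r.group, "beta": r.beta, "se": r.se, "p": r.p,
            "ci_lower": r.ci[0], "ci_upper": r.ci[1], "n": r.n}
            for r in self.rows])


def evaluate_composite(cohort: pd.DataFrame, model: CompositeModel,
                       tbv_covariate: bool = False,
                       sites=("manchester", "newcastle"),
                       site_column: str = "site",
                       covariates=("age", "sex")) -> EvaluationReport:
    """Two-sample SEM of latent g on the weighted composite.

    g loadings and the MR-VNR residual correlation are constrained equal
    across sites (the group-2 latent variance is freed); the composite-g
    path is free per site.  With ``tbv_covariate`` TBV additionally enters
    the structural regression.
    """
    avg = average_bilateral(cohort)
    data = avg[avg[site_column].isin(sites)].copy()
    data["composite"] = model.composite(data)
    cogs = [c for c in COGNITIVE_TESTS if c in data.columns]
    preds = ["composite"] + (["tbv"] if tbv_covariate else [])
    usable = (data["composite"].notna() & data[cogs].notna().any(axis=1)
              & data[preds].notna().all(axis=1))
    n_excluded = {s: int(((data[site_column] == s) & ~usable).sum())
                  for s in sites}
    data = data[usable]

    cov = [c for c in covariates if c in data.columns]
    lines = [g_model_definition(cov, [("matrix_reasoning", "vnr")], cogs),
             "g ~ " + " + ".join(preds)]
    m = build_model("\n".join(lines), fixed_x=cov + preds, covariates=cov)
    fit = fit_model(m, data, group=site_column,
                    equal=("loadings", "matrix_reasoning~~vnr"))
    rows = []
    for s in fit.group_labels:
        r = fit.param("g~composite", group=s)
        n_s = int((data[site_column] == s).sum())
        rows.append(AssociationRow(
            variable=f"composite[{model.family}]", beta=float(r["std"]),
            se=float(r["std_se"]), p=float(r["p"]), group=str(s), n=n_s))
    return EvaluationReport(rows=rows, n_excluded=n_excluded,
                            tbv_covariate=tbv_covariate,
                            fit_indices=fit.indices_dict())
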