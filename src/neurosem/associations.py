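"""Brain-g association models: global, regional, invariance and moderation.

Every association is estimated inside a structural equation model in which
the four cognitive tests measure latent *g* (with the MR-VNR residual
correlation), the brain measure predicts *g* (MIMIC orientation — for a
single standardized predictor the path equals the latent correlation), and
covariates are attached to the manifest variables within the model.
Cognitive manifests are adjusted for age and sex; brain manifests also for
the three scanner head-position coordinates.  When a model is grouped by
age, age is dropped from the covariates (likewise sex when grouping by sex).

FDR families follow the analysis plan exactly: the 6 global bivariate
tests; the simultaneous (MIMIC) path set; and per-family regional scans of
96 cortical, 27 FA, 27 MD and 14 subcortical tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (COGNITIVE_TESTS, TRACT_CLASSES, cortical_columns,
                     fa_columns, md_columns, subcortical_columns)
from .gfactor import FIT_THRESHOLDS, g_model_definition
from .preprocess import age_split
from .sem import (bh_fdr, build_model, compare_nested, congruence,
                  fit_model, modification_indices)

__all__ = ["AssociationRow", "AssociationTable", "GLOBAL_MEASURES",
           "bivariate_brain_g", "global_bivariate_scan", "mimic_global",
           "invariance_test", "moderation_test", "regional_scan",
           "tract_class_summary", "REGION_FAMILIES"]

GLOBAL_MEASURES = ["tbv", "gm", "nawm", "wmh", "gfa", "gmd"]
HEAD_COVARIATES = ("head_x", "head_y", "head_z")

REGION_FAMILIES = {
    "cortical": cortical_columns,
    "fa": fa_columns,
    "md": md_columns,
    "subcortical": subcortical_columns,
}

DEFAULT_RESIDUAL_PAIRS = (("matrix_reasoning", "vnr"),)


@dataclass
class AssociationRow:
    """One standardized brain-g association."""

    variable: str
    beta: float
    se: float
    p: float
    q: float | None = None
    context: str = "individual"          # individual | simultaneous
    group: str = "all"
    r2: float | None = None
    n: int | None = None
    converged: bool = True

    @property
    def ci(self):
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)


@dataclass
class AssociationTable:
    rows: list
    family: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "variable": r.variable, "beta": r.beta, "se": r.se, "p": r.p,
            "q": r.q, "context": r.context, "group": r.group, "n": r.n,
            "converged": r.converged} for r in self.rows])

    def apply_fdr(self):
        ok = [r for r in self.rows if np.isfinite(r.p)]
        if ok:
            qs = bh_fdr([r.p for r in ok])
            for r, q in zip(ok, qs):
                r.q = float(q)
        return self


def _covariate_sets(covariates, grouping=None, available=None):
    cov = [c for c in covariates]
    if grouping == "age":
        cov = [c for c in cov if c != "age"]
    elif grouping == "sex":
        cov = [c for c in cov if c != "sex"]
    brain_cov = cov + [h for h in HEAD_COVARIATES if h not in cov]
    if available is not None:
        cov = [c for c in cov if c in available]
        brain_cov = [c for c in brain_cov if c in available]
    return cov, brain_cov


def _brain_g_definition(brain_vars, covariates=("age", "sex"),
                        grouping=None, predictor_covs="none",
                        available=None):
    """Model text: g CFA + g regressed on brain variables (endogenous)."""
    cog_cov, brain_cov = _covariate_sets(covariates, grouping, available)
    lines = [g_model_definition(cog_cov, DEFAULT_RESIDUAL_PAIRS).replace(
        "g =~", "g =~")]
    lines.append("g ~ " + " + ".join(brain_vars))
    for b in brain_vars:
        if brain_cov:
            lines.append(f"{b} ~ " + " + ".join(brain_cov))
    if predictor_covs == "free":
        for i, a in enumerate(brain_vars):
            for b in brain_vars[i + 1:]:
                lines.append(f"{a} ~~ {b}")
    fixed_x = sorted(set(cog_cov) | set(brain_cov))
    return "\n".join(lines), fixed_x


def _analysis_rows(cohort, brain_vars):
    """Rows with >=1 cognitive test and >=1 of the brain variables."""
    cogs = [c for c in COGNITIVE_TESTS if c in cohort.columns]
    has_cog = cohort[cogs].notna().any(axis=1)
    has_brain = cohort[list(brain_vars)].notna().any(axis=1)
    return cohort[has_cog & has_brain]


def bivariate_brain_g(cohort: pd.DataFrame, brain_var: str,
                      covariates=("age", "sex"), grouping=None,
                      compute_se: bool = True) -> AssociationRow:
    """Standardized association between latent g and one brain measure."""
    data = _analysis_rows(cohort, [brain_var])
    defn, fixed_x = _brain_g_definition([brain_var], covariates, grouping,
                                        available=set(cohort.columns))
    model = build_model(defn, fixed_x=fixed_x)
    fit = fit_model(model, data, compute_se=compute_se)
    row = fit.param(f"g~{brain_var}")
    return AssociationRow(variable=brain_var, beta=float(row["std"]),
                          se=float(row["std_se"]), p=float(row["p"]),
                          n=fit.n, converged=fit.converged)


def global_bivariate_scan(cohort: pd.DataFrame, covariates=("age", "sex"),
                          measures=None) -> AssociationTable:
    """The six separate global brain-g SEMs, FDR-corrected as one family."""
    measures = list(measures or GLOBAL_MEASURES)
    rows = []
    for m in measures:
        try:
            rows.append(bivariate_brain_g(cohort, m, covariates))
        except Exception as exc:                      # record, continue
            rows.append(AssociationRow(variable=m, beta=np.nan, se=np.nan,
                                       p=np.nan, converged=False))
            rows[-1].context = f"error: {exc}"
    return AssociationTable(rows=rows, family="global").apply_fdr()


def mimic_global(cohort: pd.DataFrame,
                 predictors=("gm", "nawm", "wmh", "gfa", "gmd"),
                 covariates=("age", "sex"), grouping=None, cap: int = 10,
                 thresholds=None, predictor_covs: str = "free"):
    """Simultaneous MIMIC model: all predictors contribute to g variance.

    TBV is excluded from the default predictor set (part-whole overlap with
    the tissue volumes).  Predictors are modelled endogenously with freely
    correlated residuals by default (the standard treatment of exogenous
    brain measures; with ``predictor_covs="diagonal"`` they start
    uncorrelated instead).  While the fit thresholds are unmet, residual
    correlations suggested by modification indices — among predictors and
    between predictors and indicators — are added, up to ``cap``.

    Returns ``(fit, AssociationTable, r2)``.
    """
    predictors = list(predictors)
    if not predictors:
        raise ValueError("MIMIC model needs at least one predictor")
    thresholds = dict(thresholds or FIT_THRESHOLDS)
    data = _analysis_rows(cohort, predictors)
    P = data[predictors].dropna()
    if len(predictors) > 1 and len(P) > len(predictors):
        cond = np.linalg.cond(np.corrcoef(P.to_numpy(), rowvar=False))
        if cond > 1e4:
            import warnings
            warnings.warn(f"predictors nearly collinear (cond={cond:.1e})")
    extra_pairs: list[tuple[str, str]] = []
    if predictor_covs == "free":
        extra_pairs = [(a, b) for i, a in enumerate(predictors)
                       for b in predictors[i + 1:]]
    n_start = len(extra_pairs)
    fit = None
    for _ in range(cap + 1):
        defn, fixed_x = _brain_g_definition(predictors, covariates, grouping,
                                            available=set(cohort.columns))
        for a, b in extra_pairs:
            defn += f"\n{a} ~~ {b}"
        model = build_model(defn, fixed_x=fixed_x)
        fit = fit_model(model, data)
        if fit.meets(**thresholds) or len(extra_pairs) - n_start >= cap:
            break
        mis = modification_indices(fit)
        if not mis or mis[0].mi <= 0:
            break
        top = mis[0].parameter.split("~~")
        extra_pairs.append((top[0], top[1]))
    rows = []
    for m in predictors:
        r = fit.param(f"g~{m}")
        rows.append(AssociationRow(variable=m, beta=float(r["std"]),
                                   se=float(r["std_se"]), p=float(r["p"]),
                                   context="simultaneous", n=fit.n,
                                   converged=fit.converged))
    table = AssociationTable(rows=rows, family="mimic").apply_fdr()
    r2 = float(next(iter(fit.r_squared("g").values())))
    for r in rows:
        r.r2 = r2
    return fit, table, r2


# ---------------------------------------------------------------------------
# Invariance and moderation
# ---------------------------------------------------------------------------

def _group_column(cohort, grouping, boundary=None):
    out = cohort.copy()
    if grouping == "age":
        if boundary is None:
            _, _, boundary = age_split(cohort)
        out["_group"] = np.where(out["age"] <= boundary, "middle", "older")
    elif grouping == "sex":
        out["_group"] = np.where(out["sex"] == 0, "female", "male")
    else:
        raise ValueError(f"unknown grouping: {grouping!r}")
    return out


def invariance_test(cohort: pd.DataFrame, grouping: str = "age",
                    level: str = "weak", covariates=("age", "sex"),
                    boundary=None):
    """Measurement invariance of g across age or sex groups.

    weak: loadings constrained equal (group-2 latent variance freed),
    Δdf = 3 with four indicators; strong: loadings and intercepts equal
    (group-2 latent variance and mean freed), Δdf = 6.  Returns
    ``(ComparisonResult, details)`` where details carries both fits and,
    for the weak test, the congruence coefficient between the freely
    estimated loading vectors.
    """
    if level not in ("weak", "strong"):
        raise ValueError("level must be 'weak' or 'strong'")
    data = _group_column(cohort, grouping, boundary)
    cogs = [c for c in COGNITIVE_TESTS if c in data.columns]
    data = data[data[cogs].notna().any(axis=1)]
    counts = data["_group"].value_counts()
    if counts.min() < 50:
        raise ValueError("a group is too small for identification")
    cov, _ = _covariate_sets(covariates, grouping,
                             available=set(cohort.columns))
    defn = g_model_definition(cov, DEFAULT_RESIDUAL_PAIRS)
    model = build_model(defn, fixed_x=cov)
    free = fit_model(model, data, group="_group")
    equal = ("loadings",) if level == "weak" else ("loadings", "intercepts")
    constrained = fit_model(model, data, group="_group", equal=equal)
    comp = compare_nested(free, constrained)
    details = {"free": free, "constrained": constrained}
    g1, g2 = free.group_labels
    lv1 = free.loadings("g", group=g1).reindex(cogs)
    lv2 = free.loadings("g", group=g2).reindex(cogs)
    details["loadings"] = {g1: lv1, g2: lv2}
    details["congruence"] = congruence(lv1.to_numpy(), lv2.to_numpy())
    return comp, details


def moderation_test(cohort: pd.DataFrame, grouping: str = "age",
                    brain_model: str = "tbv", covariates=("age", "sex"),
                    boundary=None):
    """Do brain-g associations differ across age (or sex) groups?

    Two multi-group SEMs with g loadings set to equality: brain paths
    freely estimated versus constrained equal.  ``brain_model`` is "tbv",
    "multi" (GM, NAWM, WMH, gFA, gMD simultaneously) or any single measure
    name.  Returns ``(ComparisonResult, per-group AssociationTable,
    per-group R^2 dict)``.
    """
    if brain_model == "multi":
        brain_vars = ["gm", "nawm", "wmh", "gfa", "gmd"]
        predictor_covs = "free"
    else:
        brain_vars = [brain_model]
        predictor_covs = "none"
    data = _group_column(cohort, grouping, boundary)
    data = _analysis_rows(data, brain_vars)
    defn, fixed_x = _brain_g_definition(brain_vars, covariates, grouping,
                                        predictor_covs=predictor_covs,
                                        available=set(cohort.columns))
    model = build_model(defn, fixed_x=fixed_x)
    free = fit_model(model, data, group="_group", equal=("loadings",))
    path_names = tuple(f"g~{b}" for b in brain_vars)
    constrained = fit_model(model, data, group="_group",
                            equal=("loadings",) + path_names)
    comp = compare_nested(free, constrained)
    rows = []
    r2 = {str(k): float(v) for k, v in free.r_squared("g").items()}
    for glab in free.group_labels:
        for b in brain_vars:
            r = free.param(f"g~{b}", group=glab)
            rows.append(AssociationRow(
                variable=b, beta=float(r["std"]), se=float(r["std_se"]),
                p=float(r["p"]), group=str(glab), r2=r2[glab], n=free.n,
                context="simultaneous" if len(brain_vars) > 1
                else "individual"))
    table = AssociationTable(rows=rows, family=f"moderation-{grouping}")
    return comp, table.apply_fdr(), r2


# ---------------------------------------------------------------------------
# Regional scans
# ---------------------------------------------------------------------------

def regional_scan(cohort: pd.DataFrame, family: str,
                  covariates=("age", "sex"),
                  compute_se: bool = True) -> AssociationTable:
    """One bivariate SEM per region in a family, FDR within the family.

    Effect signs are stored as estimated — any valence flipping (e.g. MD)
    is presentation-only and not applied here.  Per-region non-convergence
    is recorded and the scan continues.
    """
    if family not in REGION_FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of "
                         f"{sorted(REGION_FAMILIES)}")
    columns = [c for c in REGION_FAMILIES[family]() if c in cohort.columns]
    rows = []
    for col in columns:
        try:
            row = bivariate_brain_g(cohort, col, covariates,
                                    compute_se=compute_se)
        except Exception:
            row = AssociationRow(variable=col, beta=np.nan, se=np.nan,
                                 p=np.nan, converged=False)
        rows.append(row)
    return AssociationTable(rows=rows, family=family).apply_fdr()


def tract_class_summary(table: AssociationTable, classes=None) -> dict:
    """Mean standardized association per tract class for one modality."""
    classes = dict(classes or TRACT_CLASSES)
    sums: dict[str, list] = {}
    for r in table.rows:
        tract = r.variable.split("_", 1)[1]
        if tract not in classes:
            raise ValueError(f"tract {tract!r} has no class assignment")
        sums.setdefault(classes[tract], []).append(r.beta)
    return {k: float(np.mean(v)) for k, v in sums.items()}
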