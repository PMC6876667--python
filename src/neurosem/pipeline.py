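"""Run configuration, phenotype I/O and the end-to-end pipeline.

Stages (in dependency order): ``simulate`` -> ``preprocess`` (implicit) ->
``g`` -> ``global`` -> ``regional`` -> ``predict``.  Every stage writes its
tables under the output directory and contributes to ``report.json``; the
log is JSON-lines with a human-readable console mirror.  Identical
configuration and seed give byte-identical reports.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import (global_bivariate_scan, invariance_test,
                           mimic_global, moderation_test, regional_scan,
                           tract_class_summary)
from .cohort import (COGNITIVE_TESTS, default_population_spec,
                     generate_cohort, write_cohort, write_spec)
from .gfactor import derive_gfa_gmd, fit_g_cfa
from .preprocess import age_split, clean_cohort
from .prediction import evaluate_composite, train_composite
from .sem import pca_first_component

__all__ = ["RunConfig", "read_phenotypes", "run_pipeline", "STAGES"]

STAGES = ["simulate", "g", "global", "regional", "predict"]

MANDATORY_COLUMNS = ["age", "sex"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out: str = "neurosem-out"
    stages: list = field(default_factory=lambda: list(STAGES))
    input: str | None = None          # phenotype CSV; None -> simulate
    seed: int = 0
    scale: float = 1.0                # scales the simulated cohort size
    covariates: list = field(default_factory=lambda: ["age", "sex"])
    fdr_q: float = 0.05
    families: list = field(default_factory=lambda: ["fa", "md", "cortical",
                                                    "subcortical"])
    predict_families: list | None = None
    train_site: str = "manchester"
    test_site: str = "newcastle"

    def __post_init__(self):
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must be in (0, 1)")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if self.input is None and "simulate" not in self.stages \
                and self.stages:
            # later stages will fall back to <out>/cohort.csv
            pass

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def read_phenotypes(path, dictionary: dict | None = None) -> pd.DataFrame:
    """Read a phenotype CSV into a typed cohort table.

    ``dictionary`` optionally maps file column names to canonical field
    names.  Cells that are empty or "NA" are missing; unparseable numerics
    become missing with a count.  Mandatory columns: age, sex.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    if dictionary:
        df = df.rename(columns=dictionary)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks mandatory columns: "
                         f"{missing}")
    n_unparseable = 0
    for c in df.columns:
        if c in ("site", "subject_id"):
            continue
        if df[c].dtype == object:
            coerced = pd.to_numeric(df[c], errors="coerce")
            n_unparseable += int((coerced.isna() & df[c].notna()).sum())
            df[c] = coerced
    df.attrs["n_unparseable"] = n_unparseable
    return df


class _Logger:
    def __init__(self, path):
        self.fh = open(path, "w")

    def __call__(self, event, **kw):
        rec = {"event": event, **kw}
        self.fh.write(json.dumps(rec, default=str, sort_keys=True) + "\n")
        self.fh.flush()
        detail = " ".join(f"{k}={v}" for k, v in kw.items())
        print(f"[neurosem] {event} {detail}", file=sys.stderr)

    def close(self):
        self.fh.close()


def _assoc_tsv(table, path):
    table.to_frame().to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and return the run report."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    log = _Logger(out / "run.log")
    report: dict = {"version": __version__, "seed": config.seed,
                    "scale": config.scale, "stages": list(config.stages),
                    "fdr_q": config.fdr_q, "warnings": []}
    try:
        cohort = None
        # ---- simulate / load -------------------------------------------
        if "simulate" in config.stages:
            n = max(int(round(29_004 * config.scale)), 200)
            spec = default_population_spec(n=n, seed=config.seed)
            log("simulate.start", n=n, seed=config.seed)
            cohort = generate_cohort(spec)
            write_cohort(cohort, out / "cohort.csv")
            write_spec(spec, out / "population.yaml")
            report["simulate"] = {"n": n,
                                  "overlap": _overlap_count(cohort)}
            log("simulate.done", overlap=report["simulate"]["overlap"])
        elif config.stages:
            src = config.input or out / "cohort.csv"
            log("load.start", path=str(src))
            cohort = read_phenotypes(src)
            report["input"] = {"path": str(src), "n": len(cohort),
                               "unparseable_cells":
                               cohort.attrs.get("n_unparseable", 0)}

        if cohort is not None and set(config.stages) - {"simulate"}:
            cohort, cleaning = clean_cohort(cohort)
            cleaning.to_json(out / "cleaning.json")
            report["cleaning"] = json.loads(cleaning.to_json())

        # ---- g measurement ---------------------------------------------
        need_g = {"g", "global", "regional", "predict"} & set(config.stages)
        if need_g:
            log("g.start")
            cohort = derive_gfa_gmd(cohort)
            gm_raw = fit_g_cfa(cohort, covariates=())
            gm_adj = fit_g_cfa(cohort, covariates=tuple(config.covariates),
                               residual_pairs=gm_raw.residual_pairs)
            pca = pca_first_component(cohort[COGNITIVE_TESTS])
            gm_adj.summary_table().to_csv(out / "g_model.tsv", sep="\t",
                                          index=False)
            report["g"] = {
                "uncorrected": {
                    "loadings": gm_raw.loadings.round(4).to_dict(),
                    "variance_explained": round(gm_raw.variance_explained,
                                                4),
                    "residual_pairs": [list(p) for p in
                                       gm_raw.residual_pairs],
                    "fit": _round(gm_raw.fit.indices_dict()),
                },
                "corrected": {
                    "loadings": gm_adj.loadings.round(4).to_dict(),
                    "variance_explained": round(gm_adj.variance_explained,
                                                4),
                    "residual_pairs": [list(p) for p in
                                       gm_adj.residual_pairs],
                    "fit": _round(gm_adj.fit.indices_dict()),
                },
                "pca_first_component": {
                    "loadings": [round(float(v), 4) for v in pca[0]],
                    "proportion": round(pca[1], 4)},
                "gfa_sd": round(float(np.nanstd(cohort["gfa"])), 4),
                "gmd_sd": round(float(np.nanstd(cohort["gmd"])), 4),
            }
            log("g.done",
                varexp=report["g"]["corrected"]["variance_explained"])

        # ---- global associations ---------------------------------------
        if "global" in config.stages:
            log("global.start")
            cov = tuple(config.covariates)
            scan = global_bivariate_scan(cohort, covariates=cov)
            _assoc_tsv(scan, out / "global_individual.tsv")
            mfit, mtable, r2 = mimic_global(cohort, covariates=cov)
            _assoc_tsv(mtable, out / "global_simultaneous.tsv")
            _, _, boundary = age_split(cohort)
            inv_age, inv_det = invariance_test(cohort, "age", "weak",
                                               boundary=boundary)
            mod_tbv, mt_tbv, _ = moderation_test(cohort, "age", "tbv",
                                                 boundary=boundary)
            mod_multi, mt_multi, r2_age = moderation_test(
                cohort, "age", "multi", boundary=boundary)
            inv_sex, _ = invariance_test(cohort, "sex", "strong")
            mod_sex, mt_sex, _ = moderation_test(cohort, "sex", "tbv")
            report["global"] = {
                "individual": _rows(scan),
                "simultaneous": {"rows": _rows(mtable),
                                 "r2": round(r2, 4),
                                 "fit": _round(mfit.indices_dict())},
                "age_boundary": round(boundary, 2),
                "age_invariance_weak": _comp(inv_age,
                                             inv_det["congruence"]),
                "age_moderation_tbv": _comp(mod_tbv),
                "age_moderation_multi": {**_comp(mod_multi),
                                         "r2_by_group": _round(r2_age)},
                "sex_invariance_strong": _comp(inv_sex),
                "sex_moderation_tbv": {**_comp(mod_sex),
                                       "rows": _rows(mt_sex)},
            }
            log("global.done", r2=round(r2, 4))

        # ---- regional scans --------------------------------------------
        if "regional" in config.stages:
            report["regional"] = {}
            for family in config.families:
                log("regional.start", family=family)
                table = regional_scan(cohort, family,
                                      covariates=tuple(config.covariates))
                _assoc_tsv(table, out / f"regional_{family}.tsv")
                fam = {"n_rows": len(table.rows),
                       "n_significant": sum(
                           1 for r in table.rows
                           if r.q is not None and r.q < config.fdr_q),
                       "n_failed": sum(1 for r in table.rows
                                       if not r.converged)}
                if family in ("fa", "md"):
                    fam["class_means"] = _round(tract_class_summary(table))
                report["regional"][family] = fam
                log("regional.done", family=family, **fam)

        # ---- out-of-sample prediction ----------------------------------
        if "predict" in config.stages:
            report["prediction"] = {}
            pfams = config.predict_families or config.families
            for family in pfams:
                log("predict.start", family=family)
                train = cohort[cohort["site"] == config.train_site]
                cm = train_composite(train, family,
                                     training_site=config.train_site)
                cm.to_json(out / f"composite_{family}.json")
                ev = evaluate_composite(
                    cohort, cm, sites=(config.train_site, config.test_site))
                fam_rep = {"weights_n": len(cm.weights),
                           "flagged": cm.flagged,
                           "evaluation": _rows_eval(ev)}
                if family in ("cortical", "subcortical"):
                    ev_tbv = evaluate_composite(
                        cohort, cm, tbv_covariate=True,
                        sites=(config.train_site, config.test_site))
                    fam_rep["evaluation_tbv_covariate"] = _rows_eval(ev_tbv)
                    fam_rep["tbv_attenuation_pct"] = _attenuation(ev, ev_tbv)
                report["prediction"][family] = fam_rep
                log("predict.done", family=family)

        report["status"] = "ok"
    except Exception as exc:
        report["status"] = "failed"
        report["error"] = f"{type(exc).__name__}: {exc}"
        _write_report(report, out)
        log("failed", error=report["error"])
        log.close()
        raise
    _write_report(report, out)
    log("report.written", path=str(out / "report.json"))
    log.close()
    return report


def _overlap_count(cohort) -> int:
    cogs = [c for c in COGNITIVE_TESTS if c in cohort.columns]
    return int((cohort["gm"].notna()
                & cohort[cogs].notna().any(axis=1)).sum())


def _write_report(report, out: Path):
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)


def _round(d, nd=4):
    return {k: (round(v, nd) if isinstance(v, float) else v)
            for k, v in d.items()}


def _rows(table):
    return [{"variable": r.variable, "beta": _r4(r.beta), "se": _r4(r.se),
             "p": _r4(r.p), "q": _r4(r.q), "group": r.group, "n": r.n}
            for r in table.rows]


def _rows_eval(ev):
    return [{"group": r.group, "beta": _r4(r.beta), "se": _r4(r.se),
             "ci": [_r4(r.ci[0]), _r4(r.ci[1])], "p": _r4(r.p), "n": r.n}
            for r in ev.rows]


def _attenuation(ev, ev_tbv):
    out = {}
    for a, b in zip(ev.rows, ev_tbv.rows):
        if np.isfinite(a.beta) and a.beta != 0:
            out[a.group] = _r4(100.0 * (a.beta - b.beta) / a.beta)
    return out


def _comp(comp, congr=None):
    d = {"delta_chisq": _r4(comp.delta_chisq), "delta_df": comp.delta_df,
         "p": _r4(comp.pvalue), "delta_aic": _r4(comp.delta_aic),
         "delta_sabic": _r4(comp.delta_sabic)}
    if congr is not None:
        d["congruence"] = _r4(congr)
    return d


def _r4(v):
    return None if v is None or not np.isfinite(v) else round(float(v), 4)
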