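"""Synthetic cohort generator.

Generates per-subject phenotype tables with the statistical structure the
latent-variable analysis assumes: a four-indicator general-intelligence
factor (with a Matrix-Reasoning / Verbal-Numerical-Reasoning residual
correlation), global and regional brain measures tied to *g* by standardized
paths, covariate confounding (age, sex, scanner head position), a three-site
structure, and blockwise missingness (enhanced cognitive battery, structural
MRI, diffusion MRI).

The generating model, per subject, on the standardized scale::

    g ~ N(0, 1)
    u_j = beta_j * g + (structure factors) + e_j        Var(u_j) = 1
    z_j = gamma_j' c + u_j                              c: standardized covariates
    value_j = mean_j + sd_j * z_j / sqrt(1 + |gamma_j|^2)

Positively skewed variables (Trail-Making B completion time, white matter
hyperintensity volume) are produced by exponentiating a latent normal; the
exact normal-theory attenuation of linear correlations under exponentiation,
``kappa = sigma / sqrt(exp(sigma^2) - 1)``, is compensated in the generating
path so the observed-scale correlation equals its target.  Cognitive scores
are integer-binned to their instrument ranges after the correlation targets
are set (the <1% binning attenuation is accepted).

Missingness is MCAR by construction: block availability is assigned
independently of every generated value, so FIML estimation downstream is
consistent.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "PopulationSpec",
    "COGNITIVE_TESTS", "GLOBAL_MRI", "TRACTS", "TRACT_CLASSES",
    "CORTICAL_REGIONS", "SUBCORTICAL_STRUCTURES",
    "fa_columns", "md_columns", "cortical_columns", "subcortical_columns",
    "default_population_spec", "null_population_spec", "overlap_sample_spec",
    "generate_cohort", "validate_spec", "write_spec", "read_spec",
    "write_cohort", "lognormal_attenuation",
]

COGNITIVE_TESTS = ["matrix_reasoning", "symbol_digit", "vnr", "tmtb_time"]
GLOBAL_MRI = ["tbv", "gm", "nawm", "wmh"]
COVARIATES = ["age", "sex", "head_x", "head_y", "head_z"]

# AutoPtx white matter tracts: 12 bilateral pairs + 3 commissural/brainstem
_BILATERAL_TRACTS = ["ar", "atr", "cgc", "cgh", "cst", "ifo", "ilf", "ml",
                     "ptr", "slf", "str", "unc"]
_SINGLE_TRACTS = ["fmaj", "fmin", "mcp"]
TRACTS = ([f"{t}_{h}" for t in _BILATERAL_TRACTS for h in ("l", "r")]
          + _SINGLE_TRACTS)                       # 27 tracts

#: tract -> class used for class-level summaries; thalamic radiations,
#: association fibres (incl. forceps minor), projection fibres (incl.
#: forceps major).  Editable/overridable in tract_class_summary.
TRACT_CLASSES = {}
for _t in ("atr", "ptr", "str"):
    TRACT_CLASSES[f"{_t}_l"] = TRACT_CLASSES[f"{_t}_r"] = "thalamic"
for _t in ("slf", "ilf", "ifo", "unc", "cgc", "cgh"):
    TRACT_CLASSES[f"{_t}_l"] = TRACT_CLASSES[f"{_t}_r"] = "association"
TRACT_CLASSES["fmin"] = "association"
for _t in ("cst", "ar", "ml"):
    TRACT_CLASSES[f"{_t}_l"] = TRACT_CLASSES[f"{_t}_r"] = "projection"
TRACT_CLASSES["fmaj"] = TRACT_CLASSES["mcp"] = "projection"

# Harvard-Oxford cortical atlas: 48 regions x 2 hemispheres = 96 volumes
CORTICAL_REGIONS = [
    "frontal_pole", "insular_cortex", "superior_frontal_gyrus",
    "middle_frontal_gyrus", "inferior_frontal_gyrus_pars_triangularis",
    "inferior_frontal_gyrus_pars_opercularis", "precentral_gyrus",
    "temporal_pole", "superior_temporal_gyrus_anterior",
    "superior_temporal_gyrus_posterior", "middle_temporal_gyrus_anterior",
    "middle_temporal_gyrus_posterior",
    "middle_temporal_gyrus_temporooccipital",
    "inferior_temporal_gyrus_anterior", "inferior_temporal_gyrus_posterior",
    "inferior_temporal_gyrus_temporooccipital", "postcentral_gyrus",
    "superior_parietal_lobule", "supramarginal_gyrus_anterior",
    "supramarginal_gyrus_posterior", "angular_gyrus",
    "lateral_occipital_cortex_superior", "lateral_occipital_cortex_inferior",
    "intracalcarine_cortex", "frontal_medial_cortex",
    "juxtapositional_lobule", "subcallosal_cortex", "paracingulate_gyrus",
    "cingulate_gyrus_anterior", "cingulate_gyrus_posterior",
    "precuneous_cortex", "cuneal_cortex", "frontal_orbital_cortex",
    "parahippocampal_gyrus_anterior", "parahippocampal_gyrus_posterior",
    "lingual_gyrus", "temporal_fusiform_cortex_anterior",
    "temporal_fusiform_cortex_posterior", "temporal_occipital_fusiform",
    "occipital_fusiform_gyrus", "frontal_operculum_cortex",
    "central_opercular_cortex", "parietal_operculum_cortex", "planum_polare",
    "heschls_gyrus", "planum_temporale", "supracalcarine_cortex",
    "occipital_pole",
]

SUBCORTICAL_STRUCTURES = ["accumbens", "amygdala", "caudate", "hippocampus",
                          "pallidum", "putamen", "thalamus"]


def fa_columns():
    return [f"fa_{t}" for t in TRACTS]


def md_columns():
    return [f"md_{t}" for t in TRACTS]


def cortical_columns():
    return [f"cortical_{r}_{h}" for r in CORTICAL_REGIONS for h in ("l", "r")]


def subcortical_columns():
    return [f"subcortical_{s}_{h}" for s in SUBCORTICAL_STRUCTURES
            for h in ("l", "r")]


def lognormal_attenuation(sigma: float) -> float:
    """Attenuation of linear correlations when exp(sigma * Z) replaces Z."""
    return sigma / math.sqrt(math.expm1(sigma ** 2))


# ---------------------------------------------------------------------------
# Population spec
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Generating parameters of a synthetic cohort.

    All loadings and paths are standardized on the covariate-partialled
    metric (the metric on which the analysis reports them).
    """

    n: int
    loadings: dict                       # 4 cognitive loadings on g
    resid_corr: float                    # MR-VNR residual correlation
    brain_paths: dict                    # brain variable -> g path
    brain_resid_corr: list               # residual corr among global volumes
    covariate_effects: dict              # variable class -> covariate -> beta
    site_probs: dict
    missing_blocks: dict | None
    tmtb_family: dict
    wmh_family: dict
    structure: dict                      # shared-factor coefficients
    age: dict                            # per-site mean; sd; range
    sex_p_female: float
    head_sd: dict
    scales: dict                         # variable -> (mean, sd) natural units
    seed: int = 0

    def copy(self, **updates) -> "PopulationSpec":
        d = dataclasses.asdict(self)
        d.update(updates)
        return PopulationSpec(**d)

    def complete(self) -> "PopulationSpec":
        """Same population, no missing data."""
        return self.copy(missing_blocks=None)


_GLOBAL_SCALES = {
    "tbv": (1_167_674.0, 110_960.0),
    "gm": (617_300.0, 55_448.0),
    "nawm": (545_541.0, 61_737.0),
}

_REGION_PATH_DEFAULT = 0.116    # mean cortical association, SD ~0.036
_CORTICAL_PATHS = {             # regions with explicitly emulated magnitudes
    "frontal_pole": (0.206, 0.216),
    "frontal_orbital_cortex": (0.186, 0.190),
    "subcallosal_cortex": (0.166, 0.172),
    "insular_cortex": (0.194, 0.205),
    "paracingulate_gyrus": (0.150, 0.154),
    "superior_temporal_gyrus_anterior": (0.152, 0.148),
    "temporal_pole": (0.146, 0.142),
    "lateral_occipital_cortex_superior": (0.156, 0.150),
    "precuneous_cortex": (0.126, 0.130),
    "lingual_gyrus": (0.110, 0.112),
    "superior_parietal_lobule": (0.082, 0.080),
    "angular_gyrus": (0.072, 0.070),
    "supramarginal_gyrus_anterior": (0.066, 0.068),
    "cuneal_cortex": (0.078, 0.080),
    "occipital_pole": (0.065, 0.068),
    "inferior_temporal_gyrus_temporooccipital": (0.062, 0.066),
}
_SUBCORTICAL_PATHS = {
    "thalamus": (0.251, 0.256),
    "amygdala": (0.075, 0.062),
    "accumbens": (0.125, 0.122),
    "caudate": (0.138, 0.141),
    "hippocampus": (0.152, 0.149),
    "pallidum": (0.112, 0.109),
    "putamen": (0.148, 0.151),
}
#: class-mean tract paths (FA, MD)
_TRACT_CLASS_PATHS = {
    "thalamic": (0.078, -0.091),
    "association": (0.062, -0.049),
    "projection": (0.039, 0.027),
}


def default_population_spec(n: int = 29_004, seed: int = 0) -> PopulationSpec:
    """The default generating population.

    Loadings, the MR-VNR residual correlation, global brain paths and the
    regional path profile are set to the study's printed estimates; the
    demographic and site structure follows the published participant table;
    block-missingness probabilities are calibrated so the expected
    MRI-with-cognition overlap is 18,426 of 29,004.
    """
    brain_paths = {"tbv": 0.276, "gm": 0.281, "nawm": 0.246, "wmh": -0.106,
                   "gfa": 0.090, "gmd": -0.066}
    for region in CORTICAL_REGIONS:
        bl, br = _CORTICAL_PATHS.get(region,
                                     (_REGION_PATH_DEFAULT,
                                      _REGION_PATH_DEFAULT))
        brain_paths[f"cortical_{region}_l"] = bl
        brain_paths[f"cortical_{region}_r"] = br
    for s in SUBCORTICAL_STRUCTURES:
        bl, br = _SUBCORTICAL_PATHS[s]
        brain_paths[f"subcortical_{s}_l"] = bl
        brain_paths[f"subcortical_{s}_r"] = br

    scales = dict(_GLOBAL_SCALES)
    for c in cortical_columns():
        scales[c] = (4_000.0, 650.0)
    for s in subcortical_columns():
        scales[s] = (4_500.0, 550.0)
    scales["subcortical_thalamus_l"] = (8_000.0, 800.0)
    scales["subcortical_thalamus_r"] = (7_900.0, 790.0)
    for c in fa_columns():
        scales[c] = (0.45, 0.028)
    for c in md_columns():
        scales[c] = (0.75, 0.045)       # units of 1e-3 mm^2/s

    return PopulationSpec(
        n=n,
        loadings={"matrix_reasoning": 0.505, "symbol_digit": 0.479,
                  "vnr": 0.592, "tmtb_time": -0.666},
        resid_corr=0.170,
        brain_paths=brain_paths,
        # residual correlations among (tbv, gm, nawm, wmh) beyond g
        brain_resid_corr=[[1.00, 0.92, 0.82, 0.05],
                          [0.92, 1.00, 0.65, 0.00],
                          [0.82, 0.65, 1.00, -0.15],
                          [0.05, 0.00, -0.15, 1.00]],
        covariate_effects={
            # per-test effects: speeded tests decline fastest with age,
            # Trail-Making *time* rises; the verbal-numerical test is the
            # most age-stable.  Differential (non-rank-1) age structure is
            # what the one-factor model cannot absorb.
            "matrix_reasoning": {"age": -0.18, "sex": 0.0},
            "symbol_digit": {"age": -0.38, "sex": 0.0},
            "vnr": {"age": -0.05, "sex": 0.0},
            "tmtb_time": {"age": 0.40, "sex": 0.0},
            "volume": {"age": -0.15, "sex": 0.30, "head_x": 0.05,
                       "head_y": 0.05, "head_z": 0.05},
            "wmh": {"age": 0.25, "sex": -0.05, "head_x": 0.05,
                    "head_y": 0.05, "head_z": 0.05},
            "fa": {"age": -0.20, "sex": 0.05, "head_x": 0.05,
                   "head_y": 0.05, "head_z": 0.05},
            "md": {"age": 0.25, "sex": -0.05, "head_x": 0.05,
                   "head_y": 0.05, "head_z": 0.05},
        },
        site_probs={"manchester": 22_037 / 29_004, "reading": 866 / 29_004,
                    "newcastle": 6_101 / 29_004},
        missing_blocks={
            "mri_by_site": {"manchester": 0.7815, "reading": 0.0,
                            "newcastle": 0.5088},
            "dmri_given_mri": 0.9069,
            "vnr_given_mri": 0.9063,
            "vnr_without_mri": 0.986,
            "enhanced_given_vnr": 0.576,
        },
        tmtb_family={"dist": "lognormal", "median": 496.0, "sigma": 0.349},
        wmh_family={"dist": "lognormal", "median": 2_622.0, "sigma": 0.95},
        structure={
            "tract_common_loading": 0.70,   # loading on modality factor
            "tract_pair_loading": 0.35,     # L/R homologue factor
            "cortical_common": 0.45,
            "cortical_pair": 0.35,
            "cortical_tbv_share": 0.35,
            "subcortical_common": 0.45,
            "subcortical_pair": 0.35,
            "subcortical_tbv_share": 0.30,
        },
        age={"mean_by_site": {"manchester": 62.818, "reading": 65.202,
                              "newcastle": 63.962},
             "sd": 7.48, "min": 44.0, "max": 81.0},
        sex_p_female=15_024 / 29_004,
        head_sd={"head_x": 3.5, "head_y": 4.5, "head_z": 6.0},
        scales=scales,
        seed=seed,
    )


def null_population_spec(n: int = 10_000, seed: int = 0) -> PopulationSpec:
    """A population with every loading and brain path set to zero."""
    spec = default_population_spec(n=n, seed=seed)
    spec.loadings = {k: 0.0 for k in spec.loadings}
    spec.resid_corr = 0.0
    spec.brain_paths = {k: 0.0 for k in spec.brain_paths}
    spec.brain_resid_corr = np.eye(4).tolist()
    spec.covariate_effects = {k: {c: 0.0 for c in v}
                              for k, v in spec.covariate_effects.items()}
    spec.structure = {k: 0.0 for k in spec.structure}
    return spec


def overlap_sample_spec(n: int = 18_426, seed: int = 0) -> PopulationSpec:
    """Default population restricted to the MRI-with-cognition analysis
    sample: MRI and dMRI available for everyone, Verbal-Numerical Reasoning
    nearly universal, the enhanced battery for somewhat under half."""
    spec = default_population_spec(n=n, seed=seed)
    spec.missing_blocks = {
        "mri_by_site": {s: 1.0 for s in spec.site_probs},
        "dmri_given_mri": 1.0,
        "vnr_given_mri": 0.994,
        "vnr_without_mri": 0.994,
        "enhanced_given_vnr": 0.44,
    }
    return spec


def validate_spec(spec: PopulationSpec):
    """Raise ValueError on an internally inconsistent population spec."""
    for k, lam in spec.loadings.items():
        if abs(lam) >= 1:
            raise ValueError(f"|loading| must be < 1 for {k}")
    for k, b in spec.brain_paths.items():
        if abs(b) >= 1:
            raise ValueError(f"|brain path| must be < 1 for {k}")
    R = np.asarray(spec.brain_resid_corr, float)
    if R.shape != (4, 4) or not np.allclose(R, R.T) \
            or not np.allclose(np.diag(R), 1.0):
        raise ValueError("brain_resid_corr must be symmetric with unit "
                         "diagonal")
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("brain_resid_corr is not positive semi-definite")
    tot = sum(spec.site_probs.values())
    if abs(tot - 1.0) > 1e-8:
        raise ValueError(f"site probabilities sum to {tot}, not 1")
    if spec.missing_blocks is not None:
        mb = spec.missing_blocks
        probs = list(mb["mri_by_site"].values()) + [
            mb["dmri_given_mri"], mb["vnr_given_mri"],
            mb["vnr_without_mri"], mb["enhanced_given_vnr"]]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("block missingness probabilities outside [0,1]")
    # every structural equation must leave positive unique variance
    s = spec.structure
    kap_t = lognormal_attenuation(spec.tmtb_family["sigma"])
    lam_t = spec.loadings["tmtb_time"] / kap_t
    if abs(lam_t) >= 1:
        raise ValueError("TMTb loading infeasible after skew compensation")
    kap_w = lognormal_attenuation(spec.wmh_family["sigma"])
    if abs(spec.brain_paths["wmh"] / kap_w) >= 1:
        raise ValueError("WMH path infeasible after skew compensation")
    for fam, common, pair, share in (
            ("cortical", s["cortical_common"], s["cortical_pair"],
             s["cortical_tbv_share"]),
            ("subcortical", s["subcortical_common"], s["subcortical_pair"],
             s["subcortical_tbv_share"])):
        worst = max(abs(v) for k, v in spec.brain_paths.items()
                    if k.startswith(fam))
        if worst ** 2 + common ** 2 + pair ** 2 + share ** 2 >= 1:
            raise ValueError(f"{fam} structure coefficients leave no unique "
                             "variance")
    return True


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_cohort(spec: PopulationSpec, seed: int | None = None
                    ) -> pd.DataFrame:
    """Generate one cohort table from a population spec.

    Identical (spec, seed) pairs give identical output.  ``seed`` overrides
    ``spec.seed`` when given.
    """
    validate_spec(spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n

    # --- demographics and covariates ------------------------------------
    sites = np.array(list(spec.site_probs))
    site = rng.choice(sites, size=n, p=list(spec.site_probs.values()))
    age = np.empty(n)
    for s in sites:
        m = site == s
        age[m] = _truncnorm(rng, spec.age["mean_by_site"][s], spec.age["sd"],
                            spec.age["min"], spec.age["max"], int(m.sum()))
    sex = (rng.random(n) >= spec.sex_p_female).astype(int)   # 1 = male
    head = {k: rng.normal(0.0, sd, n) for k, sd in spec.head_sd.items()}

    # standardized covariates used by the effect equations
    p_m = 1.0 - spec.sex_p_female
    cov_std = {
        "age": (age - 63.13) / spec.age["sd"],
        "sex": (sex - p_m) / math.sqrt(p_m * (1 - p_m)),
        "head_x": head["head_x"] / spec.head_sd["head_x"],
        "head_y": head["head_y"] / spec.head_sd["head_y"],
        "head_z": head["head_z"] / spec.head_sd["head_z"],
    }

    def cov_part(klass):
        eff = spec.covariate_effects.get(klass, {})
        z = np.zeros(n)
        for c, gamma in eff.items():
            z += gamma * cov_std[c]
        scale = math.sqrt(1.0 + sum(g * g for g in eff.values()))
        return z, scale

    # --- latent system ---------------------------------------------------
    g = rng.standard_normal(n)
    st = spec.structure

    def common(path_to_g):
        """A standard-normal factor correlating with g at `path_to_g`."""
        return path_to_g * g + math.sqrt(1 - path_to_g ** 2) * \
            rng.standard_normal(n)

    g_fa = common(spec.brain_paths["gfa"])
    g_md = common(spec.brain_paths["gmd"])

    cols: dict[str, np.ndarray] = {}

    # --- cognitive indicators -------------------------------------------
    lam = spec.loadings
    kap_t = lognormal_attenuation(spec.tmtb_family["sigma"])
    lam_eff = dict(lam)
    lam_eff["tmtb_time"] = lam["tmtb_time"] / kap_t
    rho = spec.resid_corr
    eps = {t: rng.standard_normal(n) for t in COGNITIVE_TESTS}
    # correlate the MR and VNR residuals at rho
    eps["vnr"] = rho * eps["matrix_reasoning"] + \
        math.sqrt(max(1 - rho ** 2, 0.0)) * eps["vnr"]
    cog_z = {}
    for t in COGNITIVE_TESTS:
        lt = lam_eff[t]
        u = lt * g + math.sqrt(1 - lt ** 2) * eps[t]
        zc, sc = cov_part(t)
        cog_z[t] = (zc + u) / sc
    cols["matrix_reasoning"] = np.clip(
        np.round(8.007 + 2.115 * cog_z["matrix_reasoning"]), 0, 15)
    cols["symbol_digit"] = np.clip(
        np.round(19.005 + 5.247 * cog_z["symbol_digit"]), 0, None)
    cols["vnr"] = np.clip(np.round(6.713 + 2.061 * cog_z["vnr"]), 0, 13)
    cols["tmtb_time"] = np.round(np.exp(
        math.log(spec.tmtb_family["median"])
        + spec.tmtb_family["sigma"] * cog_z["tmtb_time"]))

    # --- global brain volumes -------------------------------------------
    b = np.array([spec.brain_paths[v] for v in GLOBAL_MRI])
    kap_w = lognormal_attenuation(spec.wmh_family["sigma"])
    b_eff = b.copy()
    b_eff[3] = b[3] / kap_w
    R = np.asarray(spec.brain_resid_corr, float)
    w, V = np.linalg.eigh(R)
    L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    eta = rng.standard_normal((n, 4)) @ L.T       # corr(eta) = R
    D = np.sqrt(1.0 - b_eff ** 2)
    u_glob = g[:, None] * b_eff + eta * D
    zc_v, sc_v = cov_part("volume")
    zc_w, sc_w = cov_part("wmh")
    for k, v in enumerate(("tbv", "gm", "nawm")):
        mean, sd = spec.scales[v]
        cols[v] = mean + sd * (zc_v + u_glob[:, k]) / sc_v
    wmh_z = (zc_w + u_glob[:, 3]) / sc_w
    cols["wmh"] = np.exp(math.log(spec.wmh_family["median"])
                         + spec.wmh_family["sigma"] * wmh_z)
    cols["wm"] = cols["nawm"] + cols["wmh"]
    eta_tbv = eta[:, 0]          # the TBV-specific standard-normal residual

    # --- white matter tracts --------------------------------------------
    lc = st["tract_common_loading"]
    lp = st["tract_pair_loading"]
    pair_f = {t: rng.standard_normal(n) for t in _BILATERAL_TRACTS}
    for modality, gfac, gpath, col_md in (
            ("fa", g_fa, spec.brain_paths["gfa"], False),
            ("md", g_md, spec.brain_paths["gmd"], True)):
        zc_m, sc_m = cov_part(modality)
        for t in TRACTS:
            base = t[:-2] if t[-2:] in ("_l", "_r") else t
            klass = TRACT_CLASSES[t]
            target = _TRACT_CLASS_PATHS[klass][1 if col_md else 0]
            d = target - lc * gpath          # tract-specific g path
            vpair = pair_f.get(base)
            psign = -lp if col_md else lp    # opposite sign links FA and MD
            pair_term = psign * vpair if vpair is not None else 0.0
            var_explained = (d ** 2 + lc ** 2 + 2 * d * lc * gpath
                             + (lp ** 2 if vpair is not None else 0.0))
            e_sd = math.sqrt(max(1.0 - var_explained, 1e-6))
            u = d * g + lc * gfac + pair_term + e_sd * rng.standard_normal(n)
            mean, sd = spec.scales[f"{modality}_{t}"]
            vals = mean + sd * (zc_m + u) / sc_m
            if modality == "fa":
                vals = np.clip(vals, 0.0, 1.0)
            cols[f"{modality}_{t}"] = vals

    # --- regional volumes -------------------------------------------------
    for family, names, klass_common, klass_pair, klass_share in (
            ("cortical", CORTICAL_REGIONS, "cortical_common",
             "cortical_pair", "cortical_tbv_share"),
            ("subcortical", SUBCORTICAL_STRUCTURES, "subcortical_common",
             "subcortical_pair", "subcortical_tbv_share")):
        cfac = rng.standard_normal(n)
        c1, c2, c3 = st[klass_common], st[klass_pair], st[klass_share]
        zc_r, sc_r = cov_part("volume")
        for name in names:
            vpair = rng.standard_normal(n)
            for h in ("l", "r"):
                col = f"{family}_{name}_{h}"
                br = spec.brain_paths[col]
                e_sd = math.sqrt(max(
                    1.0 - br ** 2 - c1 ** 2 - c2 ** 2 - c3 ** 2, 1e-6))
                u = (br * g + c1 * cfac + c2 * vpair + c3 * eta_tbv
                     + e_sd * rng.standard_normal(n))
                mean, sd = spec.scales[col]
                cols[col] = mean + sd * (zc_r + u) / sc_r

    # --- assemble ---------------------------------------------------------
    head_cols = {k: head[k] for k in ("head_x", "head_y", "head_z")}
    order = (COGNITIVE_TESTS + ["tbv", "gm", "wm", "wmh", "nawm"]
             + fa_columns() + md_columns() + cortical_columns()
             + subcortical_columns())
    df = pd.DataFrame({"subject_id": np.arange(1, n + 1),
                       "age": age, "sex": sex, "site": site,
                       **head_cols, **{c: cols[c] for c in order}})

    # --- blockwise missingness -------------------------------------------
    if spec.missing_blocks is not None:
        mb = spec.missing_blocks
        p_mri = np.array([mb["mri_by_site"][s] for s in site])
        has_mri = rng.random(n) < p_mri
        has_dmri = has_mri & (rng.random(n) < mb["dmri_given_mri"])
        p_vnr = np.where(has_mri, mb["vnr_given_mri"],
                         mb["vnr_without_mri"])
        has_vnr = rng.random(n) < p_vnr
        has_enh = has_vnr & (rng.random(n) < mb["enhanced_given_vnr"])
        mri_cols = (["tbv", "gm", "wm", "wmh", "nawm"]
                    + cortical_columns() + subcortical_columns())
        df.loc[~has_mri, mri_cols] = np.nan
        df.loc[~has_dmri, fa_columns() + md_columns()] = np.nan
        df.loc[~has_vnr, "vnr"] = np.nan
        df.loc[~has_enh, ["matrix_reasoning", "symbol_digit",
                          "tmtb_time"]] = np.nan
    return df


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path):
    cohort.to_csv(path, index=False, na_rep="NA")


def write_spec(spec: PopulationSpec, path):
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(spec), fh, sort_keys=False)


def read_spec(path) -> PopulationSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["scales"] = {k: tuple(v) for k, v in d.get("scales", {}).items()}
    spec = PopulationSpec(**d)
    validate_spec(spec)
    return spec
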