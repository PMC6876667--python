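"""Generator tests: determinism, spec validation, rosters, missingness
calibration, and moment agreement with an independent covariance-algebra
oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from neurosem.cohort import (CORTICAL_REGIONS, TRACT_CLASSES, TRACTS,
                             cortical_columns, default_population_spec,
                             fa_columns, generate_cohort,
                             lognormal_attenuation, md_columns,
                             null_population_spec, overlap_sample_spec,
                             read_spec, subcortical_columns, validate_spec,
                             write_cohort, write_spec)
from neurosem.pipeline import read_phenotypes


class TestRosters:
    def test_family_sizes(self):
        assert len(TRACTS) == 27
        assert len(fa_columns()) == 27
        assert len(md_columns()) == 27
        assert len(cortical_columns()) == 96
        assert len(subcortical_columns()) == 14
        assert len(CORTICAL_REGIONS) == 48

    def test_every_tract_has_a_class(self):
        assert set(TRACT_CLASSES) == set(TRACTS)
        assert set(TRACT_CLASSES.values()) == {"thalamic", "association",
                                               "projection"}
        # 6 thalamic radiations, 13 association (incl. forceps minor),
        # 8 projection (incl. forceps major)
        counts = pd.Series(TRACT_CLASSES).value_counts()
        assert counts["thalamic"] == 6
        assert counts["association"] == 13
        assert counts["projection"] == 8


class TestSpecValidation:
    def test_default_spec_is_valid_and_carries_printed_values(self):
        spec = default_population_spec()
        assert validate_spec(spec)
        assert spec.loadings == {"matrix_reasoning": 0.505,
                                 "symbol_digit": 0.479, "vnr": 0.592,
                                 "tmtb_time": -0.666}
        assert spec.resid_corr == 0.170
        assert spec.brain_paths["tbv"] == 0.276
        assert spec.brain_paths["gm"] == 0.281
        assert spec.brain_paths["wmh"] == -0.106
        assert spec.brain_paths["subcortical_thalamus_r"] == 0.256
        assert math.isclose(sum(spec.site_probs.values()), 1.0)
        assert spec.age["min"] == 44 and spec.age["max"] == 81

    def test_non_psd_residual_matrix_rejected(self):
        spec = default_population_spec()
        spec.brain_resid_corr = [[1, .99, .99, 0], [.99, 1, 0, 0],
                                 [.99, 0, 1, 0], [0, 0, 0, 1]]
        with pytest.raises(ValueError, match="positive semi-definite"):
            validate_spec(spec)

    def test_bad_site_probs_rejected(self):
        spec = default_population_spec()
        spec.site_probs = {"a": 0.6, "b": 0.6}
        with pytest.raises(ValueError, match="sum"):
            validate_spec(spec)

    def test_excessive_loading_rejected(self):
        spec = default_population_spec()
        spec.loadings["vnr"] = 1.2
        with pytest.raises(ValueError, match="loading"):
            validate_spec(spec)

    def test_impossible_block_probability_rejected(self):
        spec = default_population_spec()
        spec.missing_blocks["dmri_given_mri"] = 1.4
        with pytest.raises(ValueError, match="probabilities"):
            validate_spec(spec)


class TestGeneration:
    def test_determinism_byte_identical(self, tmp_path):
        spec = default_population_spec(n=800, seed=5)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        pd.testing.assert_frame_equal(a, b)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(a, pa)
        write_cohort(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_value_invariants(self):
        coh = generate_cohort(default_population_spec(n=3000, seed=2))
        both = coh["wm"].notna() & coh["wmh"].notna()
        assert np.allclose(coh.loc[both, "nawm"],
                           coh.loc[both, "wm"] - coh.loc[both, "wmh"])
        t = coh["tmtb_time"].dropna()
        assert (t > 0).all()
        for c in fa_columns()[:5]:
            v = coh[c].dropna()
            assert ((v >= 0) & (v <= 1)).all()
        assert coh["age"].between(44, 81).all()
        assert coh["site"].isin(["manchester", "reading",
                                 "newcastle"]).all()
        # integer-range instruments
        assert coh["matrix_reasoning"].dropna().between(0, 15).all()
        assert coh["vnr"].dropna().between(0, 13).all()

    def test_mri_cognitive_overlap_calibration(self):
        """Expected MRI-with-cognition overlap of 18,426 at n = 29,004,
        within 2%."""
        coh = generate_cohort(default_population_spec(n=29_004, seed=1))
        cogs = ["matrix_reasoning", "symbol_digit", "vnr", "tmtb_time"]
        overlap = (coh["gm"].notna() & coh[cogs].notna().any(axis=1)).sum()
        assert abs(overlap - 18_426) <= 0.02 * 18_426

    def test_reading_site_has_no_mri(self):
        coh = generate_cohort(default_population_spec(n=20_000, seed=3))
        assert coh.loc[coh["site"] == "reading", "gm"].isna().all()

    def test_null_population_is_uncorrelated(self):
        spec = null_population_spec(n=10_000, seed=4).complete()
        coh = generate_cohort(spec)
        cols = ["matrix_reasoning", "symbol_digit", "vnr", "tbv", "gm",
                "fa_atr_l", "subcortical_thalamus_r"]
        R = np.corrcoef(coh[cols].to_numpy(), rowvar=False)
        off = R[np.triu_indices(len(cols), 1)]
        assert np.all(np.abs(off) < 3 / math.sqrt(10_000) + 0.01)


def _gamma(spec, var):
    """Standardized covariate-effect vector of one variable, keyed by
    covariate."""
    if var in spec.covariate_effects:
        return dict(spec.covariate_effects[var])
    if var in ("tbv", "gm", "nawm") or var.startswith(("cortical_",
                                                       "subcortical_")):
        return dict(spec.covariate_effects["volume"])
    if var == "wmh":
        return dict(spec.covariate_effects["wmh"])
    if var.startswith("fa_"):
        return dict(spec.covariate_effects["fa"])
    if var.startswith("md_"):
        return dict(spec.covariate_effects["md"])
    raise KeyError(var)


def _oracle_corr(spec, va, vb):
    """Model-implied observed-scale correlation between two variables,
    computed directly from the generating equations (independent of the
    generator code path)."""
    gam_a, gam_b = _gamma(spec, va), _gamma(spec, vb)
    s = {v: math.sqrt(1 + sum(g * g for g in gam.values()))
         for v, gam in ((va, gam_a), (vb, gam_b))}
    dot = sum(gam_a.get(c, 0) * gam_b.get(c, 0) for c in gam_a)
    kap_t = lognormal_attenuation(spec.tmtb_family["sigma"])
    kap_w = lognormal_attenuation(spec.wmh_family["sigma"])

    def gpath(v):
        lam = dict(spec.loadings)
        if v in lam:
            eff = lam[v]
            return eff / kap_t if v == "tmtb_time" else eff
        b = spec.brain_paths
        if v in ("tbv", "gm", "nawm"):
            return b[v]
        if v == "wmh":
            return b["wmh"] / kap_w
        if v in b:
            return b[v]
        if v.startswith(("fa_", "md_")):
            mod, tract = v.split("_", 1)
            klass = TRACT_CLASSES[tract]
            target = {"fa": {"thalamic": 0.078, "association": 0.062,
                             "projection": 0.039},
                      "md": {"thalamic": -0.091, "association": -0.049,
                             "projection": 0.027}}[mod][klass]
            return target
        raise KeyError(v)

    # latent (pre-exponential) correlation of the u-parts
    u_corr = gpath(va) * gpath(vb)
    # extra shared structure for specific pairs
    if {va, vb} == {"matrix_reasoning", "vnr"}:
        u_corr += spec.resid_corr * math.sqrt(1 - gpath(va) ** 2) * \
            math.sqrt(1 - gpath(vb) ** 2)
    globals_ = ["tbv", "gm", "nawm", "wmh"]
    if va in globals_ and vb in globals_:
        R = np.asarray(spec.brain_resid_corr)
        i, j = globals_.index(va), globals_.index(vb)
        u_corr += math.sqrt(1 - gpath(va) ** 2) * \
            math.sqrt(1 - gpath(vb) ** 2) * R[i, j]
    if va.startswith("fa_") and vb.startswith("fa_"):
        lc = spec.structure["tract_common_loading"]
        lp = spec.structure["tract_pair_loading"]
        rho_fa = spec.brain_paths["gfa"]
        da = gpath(va) - lc * rho_fa
        db = gpath(vb) - lc * rho_fa
        # shared modality factor + L/R homologue factor, minus the g part
        # already counted
        u_corr += da * db + lc * lc + lc * rho_fa * (da + db) - \
            gpath(va) * gpath(vb)
        if va.rsplit("_", 1)[0] == vb.rsplit("_", 1)[0]:
            u_corr += lp * lp

    z_corr = (u_corr + dot) / (s[va] * s[vb])
    for v in (va, vb):
        if v == "tmtb_time":
            z_corr *= kap_t
        if v == "wmh":
            z_corr *= kap_w
    return z_corr


@pytest.fixture(scope="module")
def big_cohort():
    spec = default_population_spec(n=50_000, seed=20).complete()
    return spec, generate_cohort(spec)


class TestMomentMatch:
    """Empirical covariances of a large complete-data cohort agree with the
    covariance-algebra oracle within 4 Monte-Carlo standard errors (plus the
    documented ~1% integer-binning attenuation)."""

    PAIRS = [
        ("matrix_reasoning", "symbol_digit"),
        ("matrix_reasoning", "vnr"),
        ("symbol_digit", "tmtb_time"),
        ("matrix_reasoning", "tbv"),
        ("vnr", "subcortical_thalamus_r"),
        ("matrix_reasoning", "fa_atr_l"),
        ("tbv", "gm"),
        ("tbv", "nawm"),
        ("tbv", "wmh"),
        ("fa_atr_l", "fa_atr_r"),
        ("fa_atr_l", "fa_ptr_r"),
    ]

    @pytest.mark.parametrize("va, vb", PAIRS)
    def test_pair(self, big_cohort, va, vb):
        spec, coh = big_cohort
        emp = np.corrcoef(coh[va], coh[vb])[0, 1]
        exp = _oracle_corr(spec, va, vb)
        tol = 4 / math.sqrt(len(coh)) + 0.012
        assert emp == pytest.approx(exp, abs=tol), (va, vb)


class TestSpecIO:
    def test_yaml_roundtrip(self, tmp_path):
        spec = default_population_spec(n=1234, seed=9)
        p = tmp_path / "spec.yaml"
        write_spec(spec, p)
        back = read_spec(p)
        assert back == spec

    def test_cohort_csv_roundtrip(self, tmp_path):
        coh = generate_cohort(overlap_sample_spec(n=300, seed=6))
        p = tmp_path / "cohort.csv"
        write_cohort(coh, p)
        back = read_phenotypes(p)
        assert len(back) == len(coh)
        for c in ("age", "tbv", "tmtb_time"):
            a = coh[c].to_numpy(float)
            b = back[c].to_numpy(float)
            assert np.allclose(a, b, equal_nan=True, rtol=1e-9)
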