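import numpy as np
import pandas as pd
import pytest

from neurosem.cohort import (default_population_spec, generate_cohort,
                             overlap_sample_spec)
from neurosem.gfactor import derive_gfa_gmd
from neurosem.preprocess import clean_cohort

PRINTED_LOADINGS_UNCORRECTED = np.array([0.550, 0.626, 0.532, -0.794])
PRINTED_LOADINGS_CORRECTED = np.array([0.505, 0.479, 0.592, -0.666])
PRINTED_LOADINGS_MIDDLE = np.array([0.506, 0.539, 0.614, -0.719])
PRINTED_LOADINGS_OLDER = np.array([0.522, 0.492, 0.569, -0.701])


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (block missingness, three sites), cleaned."""
    spec = default_population_spec(n=29_004, seed=7)
    cohort, _ = clean_cohort(generate_cohort(spec))
    return cohort


@pytest.fixture(scope="session")
def overlap_cohort():
    """MRI-with-cognition analysis-sample cohort with gFA/gMD derived."""
    spec = overlap_sample_spec(n=20_000, seed=42)
    cohort, _ = clean_cohort(generate_cohort(spec))
    return derive_gfa_gmd(cohort)


@pytest.fixture()
def factor_frame():
    """Builder for clean one-factor data with optional residual correlation
    and an optional brain variable with a known g path."""

    def build(n=20_000, loadings=(0.505, 0.479, 0.592, -0.666),
              resid_corr=0.0, resid_pair=(0, 2), brain_path=None, seed=0,
              columns=("matrix_reasoning", "symbol_digit", "vnr",
                       "tmtb_time")):
        rng = np.random.default_rng(seed)
        lam = np.asarray(loadings, float)
        g = rng.standard_normal(n)
        e = rng.standard_normal((n, len(lam)))
        if resid_corr:
            i, j = resid_pair
            e[:, j] = resid_corr * e[:, i] + \
                np.sqrt(1 - resid_corr ** 2) * e[:, j]
        Y = lam * g[:, None] + np.sqrt(1 - lam ** 2) * e
        df = pd.DataFrame(Y, columns=list(columns)[:len(lam)])
        if brain_path is not None:
            df["brain"] = brain_path * g + \
                np.sqrt(1 - brain_path ** 2) * rng.standard_normal(n)
        df.attrs["g"] = g
        return df

    return build
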