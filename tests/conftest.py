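import numpy as np
import pytest

from ssapdiv import (AlignmentMap, DdgMatrix, FitnessModelSpec, SiteRecord,
                     PreferenceProfile, ddg_to_preferences)
from ssapdiv.synthetic_data import SyntheticSpec, generate_ddg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_simplex(gen, n_rows, n_cols=20):
    x = gen.gamma(1.0, 1.0, size=(n_rows, n_cols))
    return x / x.sum(axis=1, keepdims=True)


def make_profile(gen, n_sites=8, protein_id="p"):
    values = random_simplex(gen, n_sites)
    sites = [SiteRecord(i, i + 1, "A") for i in range(n_sites)]
    return PreferenceProfile(protein_id, sites, values)


def make_ddg(gen, n_sites=5, scale=1.0, protein_id="d"):
    sites = [SiteRecord(i, i + 1, "ACDEFGHIKLMNPQRSTVWY"[i % 20])
             for i in range(n_sites)]
    values = gen.normal(1.0, scale, size=(n_sites, 20))
    from ssapdiv.io_formats import AA_INDEX
    for rec in sites:
        values[rec.site_index, AA_INDEX[rec.wildtype_aa]] = 0.0
    return DdgMatrix(protein_id, sites, values)


@pytest.fixture
def small_profile(rng):
    return make_profile(rng, n_sites=8)


@pytest.fixture
def synthetic_profile_56():
    """A 56-site profile derived from a synthetic ΔΔG matrix (threshold model)."""
    ddg, _ = generate_ddg(SyntheticSpec(n_sites=56, seed=7))
    return ddg_to_preferences(ddg, FitnessModelSpec())


@pytest.fixture
def identity_alignment_56():
    return AlignmentMap.identity(56)
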