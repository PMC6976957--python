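"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

from svpopgen import simdata
from svpopgen.geno_io import MISSING, GenotypeMatrix


@pytest.fixture(scope="session")
def study_like():
    """Study-emulating simulation at test scale (500 background + 13 SV loci)."""
    cfg = simdata.SimConfig(n_loci_background=500, seed=1)
    g, meta, truth = simdata.simulate_dataset(cfg)
    return g, meta, truth


@pytest.fixture(scope="session")
def study_like_ld(study_like):
    from svpopgen import ldnet

    g, _, _ = study_like
    return ldnet.ld_matrix(g)


@pytest.fixture(scope="session")
def fixed_block():
    """All-fixed SV block, no leakage, no missingness: deterministic LD."""
    cfg = simdata.SimConfig(
        n_loci_background=120,
        n_sv_loci=13,
        n_fixed_diff=13,
        leakage_eps=0.0,
        missing_rate=0.0,
        sv_hap_freq=0.5,
        seed=11,
    )
    g, meta, truth = simdata.simulate_dataset(cfg)
    return g, meta, truth


def toy_matrix(dosages, n_collections=1):
    """Wrap a dosage array into a GenotypeMatrix with generated ids."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, L = dosages.shape
    return GenotypeMatrix(
        dosages,
        [f"L{j}" for j in range(L)],
        [f"ind{i}" for i in range(n)],
        [("A", "T")] * L,
    )
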