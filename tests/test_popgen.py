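"""Estimator correctness against independent scalar oracles.

The Weir-Cockerham oracle re-derives the 1984 variance components a, b, c
for a single locus in plain scalar code; the Hardy-Weinberg oracle
enumerates Levene's conditional distribution with exact rational
arithmetic.  Both are kept deliberately naive and independent of the
vectorized implementations they check.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from svpopgen.geno_io import MISSING
from svpopgen.popgen import (
    allele_freq,
    hwe_exact_test,
    nei_stats,
    pairwise_fst,
    wc_theta,
)

from conftest import toy_matrix


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dosages, freq, n",
    [
        ([0, 1, 2], 0.5, 3),
        ([2, 2], 1.0, 2),
        ([0, MISSING, 1], 0.25, 2),
    ],
)
def test_allele_freq(dosages, freq, n):
    f, nn = allele_freq(np.array(dosages)[:, None])
    assert f[0] == pytest.approx(freq)
    assert nn[0] == n


def test_allele_freq_all_missing_flagged():
    f, n = allele_freq(np.array([MISSING, MISSING])[:, None])
    assert np.isnan(f[0]) and n[0] == 0


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test vs full enumeration
# ---------------------------------------------------------------------------

def _levene_pvalue_oracle(n_aa, n_ab, n_bb):
    """Exact-rational enumeration of Levene's conditional distribution."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return Fraction(1)
    f = math.factorial

    def prob(h):
        aa = (n_a - h) // 2
        bb = (n_b - h) // 2
        return Fraction(f(n) * 2**h * f(n_a) * f(n_b), f(aa) * f(h) * f(bb) * f(2 * n))

    hs = range(min(n_a, n_b) % 2, min(n_a, n_b) + 1, 2)
    probs = {h: prob(h) for h in hs}
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs)


def test_hwe_exact_matches_enumeration_all_small_configs():
    for n_aa, n_ab, n_bb in itertools.product(range(11), repeat=3):
        if not 1 <= n_aa + n_ab + n_bb <= 10:
            continue
        expected = float(_levene_pvalue_oracle(n_aa, n_ab, n_bb))
        assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
            expected, abs=1e-10
        ), (n_aa, n_ab, n_bb)


def test_hwe_exact_edge_cases():
    assert hwe_exact_test(7, 0, 0) == 1.0  # monomorphic
    assert hwe_exact_test(5, 0, 5) < 0.01  # complete heterozygote deficit
    assert hwe_exact_test(25, 50, 25) > 0.5  # maximum-probability configuration
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta vs scalar oracle
# ---------------------------------------------------------------------------

def _wc_abc_oracle(genotype_lists):
    """Scalar W&C (1984) components for one biallelic locus, r samples."""
    r = len(genotype_lists)
    n_i = [len(g) for g in genotype_lists]
    p_i = [sum(g) / (2 * n) for g, n in zip(genotype_lists, n_i)]
    h_i = [sum(1 for x in g if x == 1) / n for g, n in zip(genotype_lists, n_i)]
    n_bar = sum(n_i) / r
    n_c = (r * n_bar - sum(n**2 for n in n_i) / (r * n_bar)) / (r - 1)
    p_bar = sum(n * p for n, p in zip(n_i, p_i)) / (r * n_bar)
    s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, h in zip(n_i, h_i)) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def test_wc_theta_matches_scalar_oracle_with_missing():
    rng = np.random.default_rng(12)
    for _ in range(25):
        n, L = 12, 4
        d = rng.integers(0, 3, size=(n, L)).astype(np.int8)
        d[rng.random((n, L)) < 0.1] = MISSING
        labels = np.array(["p1"] * 5 + ["p2"] * 4 + ["p3"] * 3)
        theta_loc, theta_multi = wc_theta(d, labels)
        num = den = 0.0
        for j in range(L):
            groups = []
            for lab in ("p1", "p2", "p3"):
                col = d[labels == lab, j]
                groups.append([int(x) for x in col if x != MISSING])
            if sum(len(g) > 0 for g in groups) < 2:
                continue
            groups = [g for g in groups if g]
            a, b, c = _wc_abc_oracle(groups)
            if a + b + c != 0 and np.isfinite(theta_loc[j]):
                assert theta_loc[j] == pytest.approx(a / (a + b + c), abs=1e-10)
                num += a
                den += a + b + c
        if den:
            assert theta_multi == pytest.approx(num / den, abs=1e-10)


def test_theta_invariant_to_allele_relabeling():
    rng = np.random.default_rng(5)
    d = rng.integers(0, 3, size=(30, 6)).astype(np.int8)
    labels = np.array(["a"] * 15 + ["b"] * 15)
    _, t1 = wc_theta(d, labels)
    d2 = d.copy()
    d2[:, 2] = 2 - d2[:, 2]  # swap ref/alt at one locus
    _, t2 = wc_theta(d2, labels)
    assert t1 == pytest.approx(t2, abs=1e-12)


def test_theta_limits():
    rng = np.random.default_rng(8)
    same = rng.integers(0, 3, size=(20, 10)).astype(np.int8)
    d = np.vstack([same, same])
    labels = ["a"] * 20 + ["b"] * 20
    _, theta = wc_theta(d, labels)
    assert theta < 0.01  # may be slightly negative

    fixed = np.vstack([np.zeros((50, 5)), np.full((50, 5), 2)]).astype(np.int8)
    _, theta_fix = wc_theta(fixed, ["a"] * 50 + ["b"] * 50)
    assert theta_fix == pytest.approx(1.0, abs=1e-12)

    with pytest.raises(ValueError):
        wc_theta(same, ["a"] * 20)


# ---------------------------------------------------------------------------
# pairwise FST
# ---------------------------------------------------------------------------

def test_pairwise_fst_structure_and_no_perm_flag():
    rng = np.random.default_rng(3)
    d = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
    g = toy_matrix(d)
    labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
    pf = pairwise_fst(g, labels, n_perm=0)
    assert np.allclose(np.diag(pf.theta.to_numpy()), 0)
    assert pf.theta.equals(pf.theta.T)
    assert pf.p_values.isna().all().all()


def test_pairwise_fst_detects_structure():
    from svpopgen import simdata

    cfg = simdata.SimConfig(
        n_loci_background=300,
        n_sv_blocks=0,
        fst_background=0.05,
        missing_rate=0.0,
        collections=[
            simdata.Collection("P1", "A1", 0.0, 55.0, 30),
            simdata.Collection("P2", "A2", 5.0, 57.0, 30),
        ],
        seed=4,
    )
    g, meta, _ = simdata.simulate_dataset(cfg)
    pf = pairwise_fst(g, meta["collection"].to_numpy(), n_perm=99, seed=0)
    assert pf.theta.loc["P1", "P2"] == pytest.approx(0.05, abs=0.02)
    assert pf.p_values.loc["P1", "P2"] <= 0.05


def test_pairwise_fst_excludes_tiny_groups():
    d = np.zeros((5, 4), dtype=np.int8)
    d[:, 0] = [0, 1, 2, 1, 0]
    g = toy_matrix(d)
    with pytest.warns(UserWarning, match="size < 2"):
        pf = pairwise_fst(g, ["a", "a", "b", "b", "c"], n_perm=0)
    assert pf.groups == ["a", "b"]


# ---------------------------------------------------------------------------
# Nei / Chesser diversity
# ---------------------------------------------------------------------------

def _nei_oracle_one_locus(groups):
    """Scalar Nei-Chesser statistics for one locus, list of dosage lists."""
    npop = len(groups)
    n_k = [len(g) for g in groups]
    p_k = [sum(g) / (2 * n) for g, n in zip(groups, n_k)]
    ho_k = [sum(1 for x in g if x == 1) / n for g, n in zip(groups, n_k)]
    n_tilde = npop / sum(1 / n for n in n_k)
    ho = sum(ho_k) / npop
    mean_sq = sum(p**2 + (1 - p) ** 2 for p in p_k) / npop
    hs = n_tilde / (n_tilde - 1) * (1 - mean_sq - ho / (2 * n_tilde))
    p_bar = sum(p_k) / npop
    ht = (
        1
        - (p_bar**2 + (1 - p_bar) ** 2)
        + hs / (n_tilde * npop)
        - ho / (2 * n_tilde * npop)
    )
    return ho, hs, ht


def test_nei_stats_match_scalar_oracle():
    d = np.array([[0, 1], [1, 1], [2, 0], [1, 2], [0, 1], [2, 2]], dtype=np.int8)
    g = toy_matrix(d)
    labels = ["a", "a", "a", "b", "b", "b"]
    ds = nei_stats(g, labels)
    for j in range(2):
        groups = [d[:3, j].tolist(), d[3:, j].tolist()]
        ho, hs, ht = _nei_oracle_one_locus(groups)
        assert ds.per_locus["Ho"].iloc[j] == pytest.approx(ho, abs=1e-12)
        assert ds.per_locus["Hs"].iloc[j] == pytest.approx(hs, abs=1e-12)
        assert ds.per_locus["Ht"].iloc[j] == pytest.approx(ht, abs=1e-12)


def test_nei_stats_limits():
    rng = np.random.default_rng(0)
    d = rng.binomial(2, 0.5, size=(400, 50)).astype(np.int8)
    ds = nei_stats(toy_matrix(d), ["a"] * 200 + ["b"] * 200)
    assert ds.overall["Ht"] == pytest.approx(0.5, abs=0.03)
    assert abs(ds.overall["Fst"]) < 0.01

    fixed = np.vstack([np.zeros((40, 5)), np.full((40, 5), 2)]).astype(np.int8)
    ds2 = nei_stats(toy_matrix(fixed), ["a"] * 40 + ["b"] * 40)
    assert ds2.overall["Fst"] > 0.95
    assert ds2.overall["Fstp"] > ds2.overall["Fst"] - 1e-12
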