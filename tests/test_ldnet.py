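"""Two-locus EM r2 and LD-network cluster extraction.

The EM oracle maximizes the two-locus multinomial likelihood directly over
the one free haplotype frequency with a scalar golden-section search —
a slower, independent route to the same maximum-likelihood r2.
"""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from svpopgen.geno_io import MISSING
from svpopgen.ldnet import (
    e_min_auto,
    ld_matrix,
    ldna_clusters,
    r2_composite,
    r2_em,
)

from conftest import toy_matrix


# ---------------------------------------------------------------------------
# r2
# ---------------------------------------------------------------------------

def test_r2_identical_vectors_is_one():
    a = np.array([0, 1, 2, 1, 0, 2, 1, 0], dtype=np.int8)
    assert r2_em(a, a) == pytest.approx(1.0, abs=1e-9)
    assert r2_composite(a, a) == pytest.approx(1.0, abs=1e-12)


def test_r2_dmax_from_phased_haplotypes():
    """Dosages built from perfectly coupled haplotypes at frequency 0.5."""
    haps = np.array([[1, 1]] * 8 + [[0, 0]] * 8)  # 16 haplotypes, D = 0.25
    rng = np.random.default_rng(0)
    rng.shuffle(haps)
    a = haps[0::2, 0] + haps[1::2, 0]
    b = haps[0::2, 1] + haps[1::2, 1]
    assert r2_em(a, b) == pytest.approx(1.0, abs=1e-9)


def test_r2_no_double_het_equals_direct_counting():
    """Without double heterozygotes, phase is unambiguous and EM must equal
    plain haplotype counting."""
    rng = np.random.default_rng(1)
    for _ in range(20):
        a = rng.integers(0, 3, size=40)
        b = rng.integers(0, 3, size=40)
        b[(a == 1) & (b == 1)] = 0  # remove phase ambiguity
        if len(set(a)) < 2 or len(set(b)) < 2:
            continue
        # direct counting oracle
        hap = {"00": 0.0, "01": 0.0, "10": 0.0, "11": 0.0}
        for ga, gb in zip(a, b):
            a_copies = [1] * ga + [0] * (2 - ga)
            b_copies = [1] * gb + [0] * (2 - gb)
            if ga == 1 and gb == 1:
                raise AssertionError("unreachable")
            # for unambiguous genotypes any pairing gives the same counts
            if ga == 1:
                for ac in a_copies:
                    hap[f"{ac}{b_copies[0]}"] += 1
            else:
                for bc in b_copies:
                    hap[f"{a_copies[0]}{bc}"] += 1
        tot = sum(hap.values())
        p11 = hap["11"] / tot
        pa = (hap["10"] + hap["11"]) / tot
        pb = (hap["01"] + hap["11"]) / tot
        d = p11 - pa * pb
        expected = d * d / (pa * (1 - pa) * pb * (1 - pb))
        assert r2_em(a, b) == pytest.approx(expected, abs=1e-7)


def _r2_ml_oracle(a, b):
    """Maximize the two-locus likelihood over p11 by scalar search."""
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    n = len(a)
    pa = a.sum() / (2 * n)
    pb = b.sum() / (2 * n)

    def negloglik(p11):
        p10 = pa - p11
        p01 = pb - p11
        p00 = 1 - pa - pb + p11
        if min(p10, p01, p00, p11) < 0:
            return 1e12
        probs = np.array([[p00, p01], [p10, p11]])
        ll = 0.0
        for ga, gb in zip(a, b):
            tot = 0.0
            for h1a in range(2):
                for h1b in range(2):
                    h2a, h2b = ga - h1a, gb - h1b
                    if h2a in (0, 1) and h2b in (0, 1):
                        tot += probs[h1a, h1b] * probs[h2a, h2b]
            ll += np.log(max(tot, 1e-300))
        return -ll

    lo = max(0.0, pa + pb - 1)
    hi = min(pa, pb)
    res = minimize_scalar(
        negloglik, bounds=(lo + 1e-9, hi - 1e-9), method="bounded",
        options={"xatol": 1e-10},
    )
    d = res.x - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def test_r2_em_matches_likelihood_maximization():
    rng = np.random.default_rng(7)
    checked = 0
    while checked < 10:
        a = rng.integers(0, 3, size=12).astype(np.int8)
        b = rng.integers(0, 3, size=12).astype(np.int8)
        if len(set(a)) < 2 or len(set(b)) < 2:
            continue
        r_em = r2_em(a, b)
        r_ml = _r2_ml_oracle(a, b)
        assert r_em == pytest.approx(r_ml, abs=1e-5)
        checked += 1


def test_r2_monomorphic_flagged():
    assert np.isnan(r2_em(np.zeros(10, dtype=np.int8), np.array([0, 1, 2] * 3 + [1], dtype=np.int8)))


# ---------------------------------------------------------------------------
# full matrix
# ---------------------------------------------------------------------------

def test_ld_matrix_symmetric_three_loci():
    rng = np.random.default_rng(2)
    d = rng.integers(0, 3, size=(50, 3)).astype(np.int8)
    ld = ld_matrix(toy_matrix(d))
    v = ld.values
    assert v.shape == (3, 3)
    assert np.allclose(v, v.T, equal_nan=True)
    assert np.allclose(np.diag(v), 1.0)
    assert ld.summary()["n_pairs"] == 3
    for i in range(3):
        for j in range(i + 1, 3):
            assert v[i, j] == pytest.approx(r2_em(d[:, i], d[:, j]), abs=1e-9)


def test_ld_matrix_respects_missing_pairwise_deletion():
    rng = np.random.default_rng(3)
    d = rng.integers(0, 3, size=(60, 4)).astype(np.int8)
    d[rng.random(d.shape) < 0.15] = MISSING
    ld = ld_matrix(toy_matrix(d))
    assert ld.values[0, 1] == pytest.approx(r2_em(d[:, 0], d[:, 1]), abs=1e-9)


def test_ld_matrix_all_monomorphic_errors():
    with pytest.raises(ValueError, match="monomorphic"):
        ld_matrix(toy_matrix(np.zeros((10, 3), dtype=np.int8)))


def test_ld_matrix_pair_budget():
    d = np.zeros((4, 100), dtype=np.int8)
    d[0] = 1
    with pytest.raises(ValueError, match="max_pairs"):
        ld_matrix(toy_matrix(d), max_pairs=10)


# ---------------------------------------------------------------------------
# network clustering
# ---------------------------------------------------------------------------

def test_e_min_auto_one_percent_rule():
    assert e_min_auto(2522) == 26
    assert e_min_auto(500) == 5
    assert e_min_auto(99) == 1


def _ld_from_matrix(vals):
    from svpopgen.ldnet import LDMatrix

    vals = np.asarray(vals, dtype=float)
    return LDMatrix(values=vals, locus_ids=[f"L{i}" for i in range(len(vals))])


def test_merger_tree_matches_manual_single_linkage():
    """Six loci with hand-chosen r2: {0,1} pair at 0.9 joined by 2 at 0.8;
    {3,4} pair at 0.7; the two clusters merge (with 5) at 0.1."""
    v = np.full((6, 6), 0.1)
    np.fill_diagonal(v, 1.0)

    def setv(i, j, x):
        v[i, j] = v[j, i] = x

    setv(0, 1, 0.9)
    setv(0, 2, 0.8)
    setv(1, 2, 0.75)
    setv(3, 4, 0.7)
    tree = ldna_clusters(_ld_from_matrix(v), e_min=1, phi=4)
    by_members = {tuple(c.members): c for c in tree.clusters}
    assert (0, 1) in by_members and by_members[(0, 1)].threshold == pytest.approx(0.9)
    assert (0, 1, 2) in by_members and by_members[(0, 1, 2)].threshold == pytest.approx(0.8)
    assert (3, 4) in by_members and by_members[(3, 4)].threshold == pytest.approx(0.7)
    root = tree.root
    assert sorted(root.members) == [0, 1, 2, 3, 4, 5]
    assert root.threshold == pytest.approx(0.1)
    # nesting: child members are subsets of parents, thresholds decrease
    for c in tree.clusters:
        if c.parent is not None:
            assert set(c.members) <= set(c.parent.members)
            assert c.threshold >= c.parent.threshold


def test_soc_recovery_in_embedded_block(study_like, study_like_ld):
    g, _, truth = study_like
    sv = set(truth.sv_locus_indices[0])
    tree = ldna_clusters(study_like_ld, e_min="auto", phi=4)
    assert len(tree.socs) == 1
    members = set(tree.socs[0].members)
    assert len(members & sv) >= 12
    assert len(members - sv) == 0


def test_cluster_membership_invariant_to_locus_order(study_like):
    from svpopgen.ldnet import ld_matrix as ldm

    g, _, truth = study_like
    rng = np.random.default_rng(0)
    perm = rng.permutation(g.n_loci)
    g2 = g.subset_loci(perm)
    tree2 = ldna_clusters(ldm(g2), e_min="auto", phi=4)
    tree1 = ldna_clusters(ldm(g), e_min="auto", phi=4)
    ids1 = {frozenset(g.locus_ids[i] for i in c.members) for c in tree1.socs}
    ids2 = {frozenset(g2.locus_ids[i] for i in c.members) for c in tree2.socs}
    assert ids1 == ids2


def test_phi_monotonicity(study_like_ld):
    counts = []
    for phi in (2.0, 4.0, 8.0, 1e9):
        tree = ldna_clusters(study_like_ld, e_min="auto", phi=phi)
        counts.append(sum(c.is_outlier for c in tree.clusters))
    assert counts == sorted(counts, reverse=True)
    assert counts[-1] == 0


def test_degenerate_equal_ld_no_outliers():
    v = np.full((8, 8), 0.4)
    np.fill_diagonal(v, 1.0)
    with pytest.warns(UserWarning, match="zero MAD"):
        tree = ldna_clusters(_ld_from_matrix(v), e_min=1, phi=4)
    assert tree.socs == []


def test_invalid_parameters():
    v = np.eye(3)
    with pytest.raises(ValueError):
        ldna_clusters(_ld_from_matrix(v), e_min=0, phi=4)
    with pytest.raises(ValueError):
        ldna_clusters(_ld_from_matrix(v), e_min=1, phi=0)
    with pytest.raises(ValueError):
        ldna_clusters(_ld_from_matrix(v), e_min="frobnicate", phi=4)
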