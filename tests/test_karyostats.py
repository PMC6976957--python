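"""Karyotype calling against simulation truth and karyotype-level tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svpopgen import simdata
from svpopgen.karyostats import (
    CHI2_CRIT_1DF,
    call_karyotypes,
    cluster_contrasts,
    h_obs_per_individual,
    karyo_freq_table,
    karyotype_hwe,
)
from svpopgen.strucpca import find_clusters, pca


def _call(g, meta, truth):
    sv = truth.sv_locus_indices[0]
    res = pca(g.subset_loci(np.array(sv)), n_components=3)
    clusters = find_clusters(res.scores, k_max=5, n_pcs=1, seed=0)
    karyo = call_karyotypes(g, sv, res, clusters, meta=meta)
    return karyo, res, clusters


def _accuracy(karyo, g, truth):
    true_k = np.array([truth.karyotypes[0][i] for i in g.individual_ids])
    called = karyo.table["karyotype"].to_numpy()
    flip = {"AA": "BB", "AB": "AB", "BB": "AA"}  # A/B orientation is arbitrary
    flipped = np.array([flip[k] for k in called])
    return max((called == true_k).mean(), (flipped == true_k).mean())


def test_karyotype_hwe_hand_values():
    chi2, reject = karyotype_hwe(25, 50, 25)
    assert chi2 == pytest.approx(0.0, abs=1e-12) and not reject
    chi2, reject = karyotype_hwe(30, 40, 30)
    assert chi2 == pytest.approx(4.0, abs=1e-12) and reject
    assert CHI2_CRIT_1DF == pytest.approx(3.84, abs=0.005)


def test_karyotype_hwe_degenerate_and_errors():
    assert karyotype_hwe(10, 0, 0) == (0.0, False)
    assert karyotype_hwe(0, 0, 7) == (0.0, False)
    with pytest.raises(ValueError):
        karyotype_hwe(0, 0, 0)
    with pytest.raises(ValueError):
        karyotype_hwe(-1, 1, 1)


@settings(deadline=None, max_examples=50)
@given(
    st.integers(min_value=0, max_value=200),
    st.integers(min_value=0, max_value=200),
    st.integers(min_value=0, max_value=200),
)
def test_karyotype_hwe_relabel_symmetry(n_aa, n_ab, n_bb):
    """Swapping the A/B haplotype labels swaps AA/BB counts and leaves
    the chi-square statistic unchanged."""
    if n_aa + n_ab + n_bb == 0:
        return
    c1, r1 = karyotype_hwe(n_aa, n_ab, n_bb)
    c2, r2 = karyotype_hwe(n_bb, n_ab, n_aa)
    assert c1 == pytest.approx(c2, abs=1e-9)
    assert r1 == r2


def test_fixed_block_heterozygosity_and_calling(fixed_block):
    g, meta, truth = fixed_block
    karyo, _, _ = _call(g, meta, truth)
    assert karyo.labelling_consistent
    assert _accuracy(karyo, g, truth) == 1.0
    tab = karyo.table
    assert np.allclose(tab.loc[tab["karyotype"] == "AB", "h_obs"], 1.0)
    assert np.allclose(tab.loc[tab["karyotype"] != "AB", "h_obs"], 0.0)


def test_study_like_calling_accuracy(study_like):
    g, meta, truth = study_like
    karyo, _, _ = _call(g, meta, truth)
    assert _accuracy(karyo, g, truth) >= 0.98
    assert karyo.labelling_consistent


def test_heterokaryote_h_obs_matches_closed_form(study_like):
    """Mean H_obs of true heterokaryotypes over the SV loci equals the
    analytic expectation from the generator parameters: for a fixed locus
    P(het) = (1-e)^2 + e^2, for an intermediate locus p1(1-p2) + p2(1-p1)
    with p_i the leakage-mixed allele frequencies."""
    g, meta, truth = study_like
    cfg = truth.config
    e = cfg.leakage_eps
    p1 = (1 - e) * cfg.sv_freq_a + e * cfg.sv_freq_b
    p2 = (1 - e) * cfg.sv_freq_b + e * cfg.sv_freq_a
    h_fix = (1 - e) ** 2 + e**2
    h_int = p1 * (1 - p2) + p2 * (1 - p1)
    k = cfg.n_sv_loci
    expected = (cfg.n_fixed_diff * h_fix + (k - cfg.n_fixed_diff) * h_int) / k
    b = np.array([truth.b_dosage[0][i] for i in g.individual_ids])
    h = h_obs_per_individual(g, truth.sv_locus_indices[0])
    observed = np.nanmean(h[b == 1])
    n_ab = int((b == 1).sum())
    mc_se = np.sqrt(expected * (1 - expected) / (n_ab * k))
    assert abs(observed - expected) < 4 * mc_se


def test_refuses_wrong_cluster_count(study_like):
    g, meta, truth = study_like
    sv = truth.sv_locus_indices[0]
    res = pca(g.subset_loci(np.array(sv)), n_components=2)
    clusters = find_clusters(res.scores, k_max=5, n_pcs=1, seed=0, k=2)
    with pytest.raises(ValueError, match="k=2"):
        call_karyotypes(g, sv, res, clusters)


def test_freq_table_counts_and_qhat(study_like):
    g, meta, truth = study_like
    karyo, _, _ = _call(g, meta, truth)
    ft = karyo_freq_table(karyo, by="collection").table
    assert (ft[["n_AA", "n_AB", "n_BB"]].sum(axis=1) == ft["n"]).all()
    assert ft["q_hat"].between(0, 1).all()
    # q_hat should track the generator's per-collection haplotype frequency
    q_true = truth.config.sv_hap_freq
    q_est = dict(zip(ft["collection"], ft["q_hat"]))
    diffs = [abs(q_est[c] - q_true[c]) for c in q_est]
    if np.mean(list(q_est.values())) - np.mean(list(q_true.values())) > 0.3:
        diffs = [abs((1 - q_est[c]) - q_true[c]) for c in q_est]  # flipped orientation
    assert np.mean(diffs) < 0.08


def test_qhat_equals_mean_b_allele_frequency(fixed_block):
    """On fixed-difference blocks the karyotype-based q equals the mean
    B-associated allele frequency over the block loci."""
    g, meta, truth = fixed_block
    karyo, _, _ = _call(g, meta, truth)
    sv = truth.sv_locus_indices[0]
    freq_b = g.dosages[:, sv].mean() / 2  # no missing in this fixture
    q_overall = (karyo.table["karyotype"] == "AB").mean() / 2 + (
        karyo.table["karyotype"] == "BB"
    ).mean()
    assert abs(min(q_overall, 1 - q_overall) - min(freq_b, 1 - freq_b)) < 1e-9


def test_cluster_contrasts_fixed_block(fixed_block):
    g, meta, truth = fixed_block
    karyo, _, _ = _call(g, meta, truth)
    sv = truth.sv_locus_indices[0]
    rep = cluster_contrasts(g, karyo, sv)
    assert rep["theta_AA_BB_soc"] == pytest.approx(1.0, abs=1e-9)
    assert rep["theta_AA_BB_background"] < 0.05
    assert rep["mean_h_obs_soc"]["AB"] == pytest.approx(1.0, abs=1e-12)
    assert 0 < rep["theta_AB_AA_soc"] < 1


def test_cluster_contrast_per_locus_theta_oracle():
    """AB vs AA at a locus fixed between backgrounds (freqs 0.5 and 0)
    matches the scalar Weir-Cockerham value computed in test_popgen style."""
    from svpopgen.popgen import wc_theta

    n = 40
    d = np.concatenate([np.ones(n, dtype=np.int8), np.zeros(n, dtype=np.int8)])
    labels = ["AB"] * n + ["AA"] * n
    theta_loc, _ = wc_theta(d[:, None], labels)
    # scalar evaluation of the 1984 components for this configuration
    r, n_bar = 2, n
    p1, p2 = 0.5, 0.0
    h1, h2 = 1.0, 0.0
    n_c = n_bar
    p_bar = (p1 + p2) / 2
    s2 = (n * (p1 - p_bar) ** 2 + n * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (h1 + h2) / 2
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - s2 / 2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 / 2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    assert theta_loc[0] == pytest.approx(a / (a + b + c), abs=1e-12)


def test_contrasts_empty_class_errors(fixed_block):
    g, meta, truth = fixed_block
    karyo, _, _ = _call(g, meta, truth)
    karyo.table.loc[karyo.table["karyotype"] == "AB", "karyotype"] = "AA"
    with pytest.raises(ValueError, match="empty"):
        cluster_contrasts(g, karyo, truth.sv_locus_indices[0])
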