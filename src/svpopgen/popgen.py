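"""Core population-genetic statistics.

Allele frequencies, observed/expected heterozygosities, the Levene exact
Hardy-Weinberg test, Nei/Chesser diversity statistics with the
population-number-corrected fixation index (Fst'), and the Weir & Cockerham
(1984) theta estimator of FST with permutation tests.

Missing genotypes are excluded locus-wise throughout; no imputation happens
in any estimator here.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .geno_io import MISSING, GenotypeMatrix

__all__ = [
    "allele_freq",
    "hwe_exact_test",
    "wc_theta",
    "pairwise_fst",
    "nei_stats",
    "DiversityStats",
    "PairwiseFst",
]


def _group_indices(labels: Sequence[str] | np.ndarray) -> dict[str, np.ndarray]:
    labels = np.asarray(labels)
    return {g: np.flatnonzero(labels == g) for g in pd.unique(labels)}


def allele_freq(
    g: GenotypeMatrix | np.ndarray, rows: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Alternate-allele frequency and non-missing sample size per locus.

    Returns ``(freq, n)`` where ``n`` counts non-missing genotypes; loci with
    no calls get ``freq = nan``.
    """
    dosages = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g)
    if dosages.ndim == 1:
        dosages = dosages[:, None]
    if rows is not None:
        dosages = dosages[np.asarray(rows)]
    called = dosages != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
    return freq, n


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Levene's conditional distribution)
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact HWE p-value for one biallelic locus.

    Conditions on the allele counts and sums the probabilities of every
    heterozygote count whose conditional probability under Hardy-Weinberg
    equilibrium is <= that of the observed configuration (probability
    ordering, no mid-p).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one individual")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    n_rare = min(n_a, n_b)
    # log P(n_het | allele counts) up to a shared constant:
    # P propto 2^h / (h! * n_aa! * n_bb!) with n_aa=(n_a-h)/2 etc.
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    lg = math.lgamma
    logp = np.array(
        [
            h * math.log(2.0)
            - lg(h + 1)
            - lg((n_rare - h) // 2 + 1)
            - lg((2 * n - n_rare - h) // 2 + 1)
            for h in hets
        ]
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hets == n_ab)[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta
# ---------------------------------------------------------------------------

def _wc_components(
    dosages: np.ndarray, groups: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus variance components (a, b, c) for r groups of diploids.

    a: among populations; b: among individuals within populations;
    c: within individuals.  Loci where fewer than two groups have data get
    nan components.
    """
    r = len(groups)
    n_loci = dosages.shape[1]
    n_i = np.empty((r, n_loci))
    p_i = np.empty((r, n_loci))
    h_i = np.empty((r, n_loci))
    for k, rows in enumerate(groups):
        d = dosages[rows]
        called = d != MISSING
        n = called.sum(axis=0)
        n_i[k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(n > 0, np.where(called, d, 0).sum(axis=0) / (2 * np.maximum(n, 1)), np.nan)
            h_i[k] = np.where(n > 0, (d == 1).sum(axis=0) / np.maximum(n, 1), np.nan)

    valid = (n_i > 0).sum(axis=0) >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        # restrict to groups with data, locus-wise
        w = np.where(n_i > 0, n_i, 0.0)
        r_eff = (n_i > 0).sum(axis=0).astype(float)
        n_tot = w.sum(axis=0)
        n_bar = n_tot / r_eff
        n_c = (n_tot - (w**2).sum(axis=0) / n_tot) / (r_eff - 1)
        p_bar = np.nansum(w * p_i, axis=0) / n_tot
        s2 = np.nansum(w * (p_i - p_bar) ** 2, axis=0) / ((r_eff - 1) * n_bar)
        h_bar = np.nansum(w * h_i, axis=0) / n_tot

        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - ((r_eff - 1) / r_eff) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r_eff - 1) / r_eff) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2.0

    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def wc_theta(
    g: GenotypeMatrix | np.ndarray,
    labels: Sequence[str] | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Weir & Cockerham theta per locus and multi-locus (ratio of sums).

    Negative per-locus estimates are retained.  Loci whose components are
    undefined (monomorphic everywhere, or data in < 2 groups) are skipped in
    the multi-locus ratio.  Returns ``(theta_per_locus, theta_multilocus)``.
    """
    dosages = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g)
    groups = list(_group_indices(labels).values())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    a, b, c = _wc_components(dosages, groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        theta = np.where(np.abs(denom) > 0, a / denom, np.nan)
    ok = np.isfinite(a) & np.isfinite(denom) & (np.abs(denom) > 0)
    if not ok.any():
        return theta, float("nan")
    multi = float(np.nansum(a[ok]) / np.nansum(denom[ok]))
    return theta, multi


@dataclasses.dataclass
class PairwiseFst:
    """Pairwise multi-locus theta matrix with permutation p-values."""

    groups: list[str]
    theta: pd.DataFrame
    p_values: pd.DataFrame
    n_permutations: int
    seed: int | None


def pairwise_fst(
    g: GenotypeMatrix,
    labels: Sequence[str] | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> PairwiseFst:
    """Multi-locus theta for every group pair plus permutation p-values.

    p = (1 + #{permuted theta >= observed}) / (n_perm + 1), permuting
    individuals' group labels within the pair (add-one estimator).  With
    ``n_perm == 0`` p-values are NaN.  Groups of size < 2 are excluded.
    """
    labels = np.asarray(labels)
    idx = _group_indices(labels)
    names = [k for k, v in idx.items() if v.size >= 2]
    dropped = set(idx) - set(names)
    if dropped:
        import warnings

        warnings.warn(f"excluding groups of size < 2: {sorted(dropped)}")
    rng = np.random.default_rng(seed)
    k = len(names)
    theta = np.zeros((k, k))
    pmat = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            rows = np.concatenate([idx[names[i]], idx[names[j]]])
            sub = g.dosages[rows]
            lab = np.concatenate(
                [np.zeros(idx[names[i]].size, int), np.ones(idx[names[j]].size, int)]
            )
            _, obs = wc_theta(sub, lab)
            theta[i, j] = theta[j, i] = obs
            if n_perm > 0 and np.isfinite(obs):
                count = 0
                for _ in range(n_perm):
                    perm = rng.permutation(lab)
                    _, t = wc_theta(sub, perm)
                    if np.isfinite(t) and t >= obs:
                        count += 1
                p = (1 + count) / (n_perm + 1)
                pmat[i, j] = pmat[j, i] = p
    return PairwiseFst(
        groups=names,
        theta=pd.DataFrame(theta, index=names, columns=names),
        p_values=pd.DataFrame(pmat, index=names, columns=names),
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Nei / Chesser diversity statistics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DiversityStats:
    """Per-locus and overall Nei-style diversity statistics.

    ``per_locus`` has columns Ho, Hs, Ht, Dst, Htp, Dstp, Fst, Fstp.
    Overall values: Ho/Hs/Ht are per-locus means; overall Fst and Fst' are
    ratios of the mean components (mean Dst / mean Ht, mean Dst' / mean Ht'),
    excluding loci with Ht = 0.
    """

    per_locus: pd.DataFrame
    overall: dict[str, float]


def nei_stats(
    g: GenotypeMatrix | np.ndarray, labels: Sequence[str] | np.ndarray
) -> DiversityStats:
    """Sample-size-corrected Nei & Chesser statistics per locus.

    For np populations with per-population non-missing sizes n_k at a locus
    (harmonic mean n_tilde), observed heterozygosity Ho (mean over pops),
    within-population gene diversity

        Hs = n_tilde/(n_tilde-1) * (1 - mean_k(p_k^2 + q_k^2) - Ho/(2 n_tilde))

    overall diversity

        Ht = 1 - (p_bar^2 + q_bar^2) + Hs/(n_tilde np) - Ho/(2 n_tilde np)

    with p_bar the unweighted mean frequency over populations; Dst = Ht - Hs,
    Fst = Dst/Ht, and the population-number-corrected variant
    Dst' = np/(np-1) Dst, Ht' = Hs + Dst', Fst' = Dst'/Ht'.
    """
    dosages = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g)
    idx = _group_indices(labels)
    npop = len(idx)
    if npop < 2:
        raise ValueError("need at least two groups")
    n_loci = dosages.shape[1]
    p_k = np.empty((npop, n_loci))
    ho_k = np.empty((npop, n_loci))
    n_k = np.empty((npop, n_loci))
    for k, rows in enumerate(idx.values()):
        d = dosages[rows]
        called = d != MISSING
        n = called.sum(axis=0)
        n_k[k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_k[k] = np.where(n > 0, np.where(called, d, 0).sum(axis=0) / (2 * np.maximum(n, 1)), np.nan)
            ho_k[k] = np.where(n > 0, (d == 1).sum(axis=0) / np.maximum(n, 1), np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_tilde = npop / np.nansum(1.0 / np.where(n_k > 0, n_k, np.nan), axis=0)
        ho = np.nanmean(ho_k, axis=0)
        mean_sq = np.nanmean(p_k**2 + (1 - p_k) ** 2, axis=0)
        hs = (n_tilde / (n_tilde - 1)) * (1 - mean_sq - ho / (2 * n_tilde))
        p_bar = np.nanmean(p_k, axis=0)
        ht = (
            1
            - (p_bar**2 + (1 - p_bar) ** 2)
            + hs / (n_tilde * npop)
            - ho / (2 * n_tilde * npop)
        )
        dst = ht - hs
        dstp = npop / (npop - 1) * dst
        htp = hs + dstp
        fst = np.where(ht > 0, dst / ht, np.nan)
        fstp = np.where(htp > 0, dstp / htp, np.nan)

    per_locus = pd.DataFrame(
        {
            "Ho": ho,
            "Hs": hs,
            "Ht": ht,
            "Dst": dst,
            "Htp": htp,
            "Dstp": dstp,
            "Fst": fst,
            "Fstp": fstp,
        },
        index=g.locus_ids if isinstance(g, GenotypeMatrix) else None,
    )
    poly = ht > 0
    overall = {
        "Ho": float(np.nanmean(ho)),
        "Hs": float(np.nanmean(hs)),
        "Ht": float(np.nanmean(ht)),
        "Fst": float(np.nansum(dst[poly]) / np.nansum(ht[poly])) if poly.any() else float("nan"),
        "Fstp": float(np.nansum(dstp[poly]) / np.nansum(htp[poly])) if poly.any() else float("nan"),
    }
    return DiversityStats(per_locus=per_locus, overall=overall)
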