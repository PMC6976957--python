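"""Karyotype calling from PC1 clusters over the SV-associated loci, and
karyotype-level statistics.

An individual's karyotype is its diploid combination of the two SV
haplotypes: homokaryotypes AA and BB at the extremes of PC1 (computed from
the high-LD loci only) and heterokaryotypes AB in the middle, carrying one
copy of each divergent haplotype and hence elevated heterozygosity across
the block.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import MISSING, GenotypeMatrix
from .popgen import wc_theta
from .strucpca import ClusterAssignment, PCAResult

#: 95th percentile of the chi-square distribution with 1 df.
CHI2_CRIT_1DF = float(stats.chi2.ppf(0.95, 1))

KARYOTYPE_LABELS = ("AA", "AB", "BB")


def h_obs_per_individual(g: GenotypeMatrix, loci: Sequence[int]) -> np.ndarray:
    """Observed heterozygosity per individual over a locus set:
    heterozygous genotypes / non-missing genotypes (NaN when all missing)."""
    sub = g.dosages[:, np.asarray(loci)]
    called = sub != MISSING
    n = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, (sub == 1).sum(axis=1) / np.maximum(n, 1), np.nan)


@dataclasses.dataclass
class KaryotypeTable:
    """Per-individual karyotype call with PC1 score and block heterozygosity."""

    table: pd.DataFrame  # individual_id, karyotype, pc1, h_obs, collection, area
    soc_loci: list[int]
    labelling_consistent: bool

    def counts(self, by: str | None = None) -> pd.DataFrame:
        group = [by] if by else []
        out = (
            self.table.groupby(group + ["karyotype"], sort=False, observed=True)
            .size()
            .unstack("karyotype", fill_value=0)
            .reindex(columns=list(KARYOTYPE_LABELS), fill_value=0)
        )
        return out


def call_karyotypes(
    g: GenotypeMatrix,
    soc_loci: Sequence[int],
    pca_on_soc: PCAResult,
    clusters: ClusterAssignment,
    meta: pd.DataFrame | None = None,
) -> KaryotypeTable:
    """Label the three PC1 clusters AA / AB / BB (ascending PC1).

    Requires exactly three clusters.  The middle cluster must show the
    highest mean observed heterozygosity over the SV loci; if it does not,
    the labelling is flagged inconsistent (returned, not raised).
    """
    if clusters.k != 3:
        raise ValueError(
            f"karyotype calling needs exactly 3 PC1 clusters, got k={clusters.k}; "
            "inspect the BIC trace or override k"
        )
    soc_loci = list(soc_loci)
    h_obs = h_obs_per_individual(g, soc_loci)
    labels = np.asarray(clusters.labels)
    karyo = np.array(KARYOTYPE_LABELS)[labels - 1]
    mean_h = {lab: np.nanmean(h_obs[karyo == lab]) for lab in KARYOTYPE_LABELS}
    consistent = mean_h["AB"] >= max(mean_h["AA"], mean_h["BB"])

    df = pd.DataFrame(
        {
            "individual_id": g.individual_ids,
            "karyotype": karyo,
            "pc1": pca_on_soc.scores[:, 0],
            "h_obs": h_obs,
        }
    )
    if meta is not None:
        meta_idx = meta.set_index("individual_id")
        df["collection"] = meta_idx.loc[df["individual_id"], "collection"].to_numpy()
        df["area"] = meta_idx.loc[df["individual_id"], "area"].to_numpy()
    return KaryotypeTable(table=df, soc_loci=soc_loci, labelling_consistent=bool(consistent))


# ---------------------------------------------------------------------------
# karyotype Hardy-Weinberg chi-square test
# ---------------------------------------------------------------------------

def karyotype_hwe(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, bool]:
    """Chi-square HWE test on karyotype counts against the 3.84 criterion.

    q_hat = (n_AB + 2 n_BB) / 2n; expected counts (n(1-q)^2, 2nq(1-q), nq^2);
    chi2 = sum (obs-exp)^2/exp with 1 df, no continuity correction.
    Returns ``(chi2, reject)`` with reject True iff chi2 > 3.84.  Monomorphic
    samples (q in {0, 1}) give chi2 = 0 and pass.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("counts must be nonnegative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one individual")
    q = (n_ab + 2 * n_bb) / (2 * n)
    if q in (0.0, 1.0):
        return 0.0, False
    exp = np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, chi2 > CHI2_CRIT_1DF


@dataclasses.dataclass
class KaryoFreqTable:
    """Karyotype counts, haplotype-B frequency and HWE verdict per group."""

    table: pd.DataFrame  # group, n_AA, n_AB, n_BB, n, q_hat, chi2, hwe_reject
    by: str


def karyo_freq_table(karyo: KaryotypeTable, by: str = "collection") -> KaryoFreqTable:
    """Per-collection (or per-area) karyotype counts with q_hat and HWE test."""
    if by not in karyo.table.columns:
        raise ValueError(f"karyotype table has no {by!r} column; pass metadata at calling time")
    rows = []
    for group, sub in karyo.table.groupby(by, sort=False):
        n_aa = int((sub["karyotype"] == "AA").sum())
        n_ab = int((sub["karyotype"] == "AB").sum())
        n_bb = int((sub["karyotype"] == "BB").sum())
        n = n_aa + n_ab + n_bb
        q = (n_ab + 2 * n_bb) / (2 * n)
        chi2, reject = karyotype_hwe(n_aa, n_ab, n_bb)
        rows.append((group, n_aa, n_ab, n_bb, n, q, chi2, reject))
    df = pd.DataFrame(
        rows, columns=[by, "n_AA", "n_AB", "n_BB", "n", "q_hat", "chi2", "hwe_reject"]
    )
    return KaryoFreqTable(table=df, by=by)


# ---------------------------------------------------------------------------
# cluster contrasts
# ---------------------------------------------------------------------------

def cluster_contrasts(
    g: GenotypeMatrix,
    karyo: KaryotypeTable,
    soc_loci: Sequence[int],
    background_loci: Sequence[int] | None = None,
) -> dict:
    """Differentiation and heterozygosity contrasts among karyotype classes.

    Weir-Cockerham theta between AA and BB over the SV loci (expected near 1
    for well-differentiated haplotypes) and over the background loci
    (expected near the background level: karyotype classes are not
    populations), theta of AB against each homokaryotype class, and mean
    observed heterozygosity per class with and without the SV loci.
    """
    soc_loci = np.asarray(list(soc_loci))
    if background_loci is None:
        background_loci = np.setdiff1d(np.arange(g.n_loci), soc_loci)
    else:
        background_loci = np.asarray(list(background_loci))
    karyo_lab = karyo.table["karyotype"].to_numpy()
    for lab in KARYOTYPE_LABELS:
        if (karyo_lab == lab).sum() == 0:
            raise ValueError(f"karyotype class {lab} is empty")

    def theta_between(class_a: str, class_b: str, loci: np.ndarray) -> float:
        rows = np.isin(karyo_lab, [class_a, class_b])
        sub = g.subset_individuals(np.flatnonzero(rows)).subset_loci(loci)
        _, multi = wc_theta(sub, karyo_lab[rows])
        return multi

    h_soc = h_obs_per_individual(g, soc_loci)
    h_bg = h_obs_per_individual(g, background_loci)
    report = {
        "theta_AA_BB_soc": theta_between("AA", "BB", soc_loci),
        "theta_AA_BB_background": theta_between("AA", "BB", background_loci),
        "theta_AB_AA_soc": theta_between("AB", "AA", soc_loci),
        "theta_AB_BB_soc": theta_between("AB", "BB", soc_loci),
        "mean_h_obs_soc": {
            lab: float(np.nanmean(h_soc[karyo_lab == lab])) for lab in KARYOTYPE_LABELS
        },
        "mean_h_obs_background": {
            lab: float(np.nanmean(h_bg[karyo_lab == lab])) for lab in KARYOTYPE_LABELS
        },
    }
    return report
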