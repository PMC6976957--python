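"""Hierarchical analysis of molecular variance (AMOVA).

Partitions allelic variance across a four-level nesting — among areas,
among locations within areas, among individuals within locations, within
individuals — from per-locus allele mismatches between allele copies
(Excoffier, Smouse & Quattro style sums of squares), with Phi-statistics
and permutation tests per level.

Each diploid individual is expanded to two allele copies per locus; the
squared distance between two copies is the number of mismatching loci.
Because each locus contributes independently to the distance, the arbitrary
assignment of an unphased heterozygote's alleles to copies has no effect on
any distance (unit-tested).  With 0/1 allele codes the mismatch distance is
squared Euclidean, so all sums of squares reduce to variance decompositions
around copy means.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .geno_io import MISSING, GenotypeMatrix

__all__ = ["amova", "AmovaTable", "expand_allele_copies"]

LEVELS = [
    "among_areas",
    "among_locations_within_areas",
    "among_individuals_within_locations",
    "within_individuals",
]


@dataclasses.dataclass
class AmovaTable:
    """Hierarchical variance components with Phi-statistics and p-values.

    ``table`` rows follow :data:`LEVELS`; columns: df, SS, MS,
    variance_component, pct_variation (components truncated at zero for the
    percentage display only), phi, p_value.  Phi conventions:
    Phi_CT (areas / total), Phi_SC (locations / within-areas),
    Phi_IS (individuals / within-locations), Phi_IT (all but within-ind /
    total), attached to the four rows in that order.
    """

    table: pd.DataFrame
    n_permutations: int
    seed: int | None
    loci: list[int] | None
    n_imputed: int


def expand_allele_copies(g: GenotypeMatrix, loci: Sequence[int] | None = None,
                         collection: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """(2n x L) 0/1 allele-copy matrix; heterozygotes contribute one of each.

    Missing dosages are imputed with the per-collection rounded mean dosage
    (global mean when no collection labels are given) so every pairwise
    distance is defined; the imputation count is returned.
    """
    sub = g.dosages if loci is None else g.dosages[:, np.asarray(loci)]
    sub = sub.astype(float)
    miss = sub == MISSING
    n_imp = int(miss.sum())
    if n_imp:
        sub = sub.copy()
        groups = (
            [np.arange(sub.shape[0])]
            if collection is None
            else [np.flatnonzero(collection == c) for c in pd.unique(collection)]
        )
        for rows in groups:
            block = sub[rows]
            m = block == MISSING
            if not m.any():
                continue
            called = ~m
            col_mean = np.where(
                called.sum(axis=0) > 0,
                np.where(m, 0, block).sum(axis=0) / np.maximum(called.sum(axis=0), 1),
                0.0,
            )
            fill = np.clip(np.rint(col_mean), 0, 2)
            block[m] = np.broadcast_to(fill, block.shape)[m]
            sub[rows] = block
    n, L = sub.shape
    copies = np.zeros((2 * n, L))
    copies[0::2] = (sub >= 1).astype(float)  # first copy carries alt if dosage >= 1
    copies[1::2] = (sub == 2).astype(float)  # second copy only when homozygous alt
    return copies, n_imp


def _ss_between(x: np.ndarray, groups: list[np.ndarray], grand_mean: np.ndarray) -> float:
    return float(
        sum(len(rows) * ((x[rows].mean(axis=0) - grand_mean) ** 2).sum() for rows in groups)
    )


def _amova_decomposition(
    copies: np.ndarray,
    area: np.ndarray,
    loc: np.ndarray,
    ind: np.ndarray,
) -> dict:
    """Sums of squares, df, variance components and Phi for one labelling."""
    x = copies
    n_copies = x.shape[0]
    grand = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())

    areas = pd.unique(area)
    locs = pd.unique(loc)
    inds = pd.unique(ind)

    rows_of_area = {a: np.flatnonzero(area == a) for a in areas}
    rows_of_loc = {l: np.flatnonzero(loc == l) for l in locs}
    rows_of_ind = {i: np.flatnonzero(ind == i) for i in inds}

    ss_aa = _ss_between(x, list(rows_of_area.values()), grand)
    # among locations within areas
    ss_al = 0.0
    for a, rows in rows_of_area.items():
        amean = x[rows].mean(axis=0)
        sub_locs = [r for l, r in rows_of_loc.items() if area[r[0]] == a]
        ss_al += _ss_between(x, sub_locs, amean)
    # among individuals within locations
    ss_ai = 0.0
    for l, rows in rows_of_loc.items():
        lmean = x[rows].mean(axis=0)
        sub_inds = [r for i, r in rows_of_ind.items() if loc[r[0]] == l]
        ss_ai += _ss_between(x, sub_inds, lmean)
    # within individuals
    ss_wi = 0.0
    for rows in rows_of_ind.values():
        imean = x[rows].mean(axis=0)
        ss_wi += float(((x[rows] - imean) ** 2).sum())

    n_area = len(areas)
    n_loc = len(locs)
    n_ind = len(inds)
    df = np.array([n_area - 1, n_loc - n_area, n_ind - n_loc, n_ind], dtype=float)
    ss = np.array([ss_aa, ss_al, ss_ai, ss_wi])
    with np.errstate(invalid="ignore", divide="ignore"):
        ms = np.where(df > 0, ss / np.where(df > 0, df, 1), np.nan)

    # expected-mean-square coefficients (copy counts; 2 copies/individual)
    n_g = np.array([rows_of_area[a].size for a in areas], dtype=float)
    n_l = np.array([rows_of_loc[l].size for l in locs], dtype=float)
    area_of_loc = np.array([area[rows_of_loc[l][0]] for l in locs])
    n_tot = float(n_copies)
    sum_nl2_over_ng = sum(
        (n_l[area_of_loc == a] ** 2).sum() / rows_of_area[a].size for a in areas
    )
    n1 = (n_tot - sum_nl2_over_ng) / df[1] if df[1] > 0 else np.nan
    n2 = (sum_nl2_over_ng - (n_l**2).sum() / n_tot) / df[0] if df[0] > 0 else np.nan
    n3 = (n_tot - (n_g**2).sum() / n_tot) / df[0] if df[0] > 0 else np.nan

    # levels without replication (df = 0) are undefined (NaN) but contribute
    # zero to the expected mean squares of the levels above them
    sigma_wi = ms[3]
    sigma_ai = (ms[2] - sigma_wi) / 2.0 if df[2] > 0 else np.nan
    ai_eff = sigma_ai if df[2] > 0 else 0.0
    sigma_al = (ms[1] - sigma_wi - 2 * ai_eff) / n1 if df[1] > 0 else np.nan
    al_eff = sigma_al if df[1] > 0 else 0.0
    sigma_aa = (
        (ms[0] - sigma_wi - 2 * ai_eff - (n2 if df[1] > 0 else 0.0) * al_eff) / n3
        if df[0] > 0
        else np.nan
    )
    comps = np.array([sigma_aa, sigma_al, sigma_ai, sigma_wi])
    total = np.nansum(comps)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_ct = sigma_aa / total
        phi_sc = sigma_al / (sigma_al + sigma_ai + sigma_wi)
        phi_is = sigma_ai / (sigma_ai + sigma_wi)
        phi_it = (sigma_aa + sigma_al + sigma_ai) / total
    return {
        "df": df,
        "ss": ss,
        "ms": ms,
        "components": comps,
        "ss_total": ss_total,
        "phi": np.array([phi_ct, phi_sc, phi_is, phi_it]),
    }


def amova(
    g: GenotypeMatrix,
    meta: pd.DataFrame,
    loci: Sequence[int] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    exclude_collections: Sequence[str] = (),
    perm_levels: Sequence[str] = ("area", "location", "individual"),
) -> AmovaTable:
    """Four-level AMOVA with permutation tests.

    ``meta`` must align with the genotype rows (columns ``individual_id``,
    ``collection``, ``area``).  Permutation schemes per level: whole
    locations among areas (among-areas test), individuals among locations
    within areas (among-locations test), allele copies among individuals
    within location (among-individuals test); p-values use the add-one
    estimator.  The within-individuals row carries Phi_IT and its p-value
    from the copies-within-individuals scheme.  ``perm_levels`` restricts
    which schemes run (the others report NaN p-values).
    """
    meta = meta.set_index("individual_id").loc[g.individual_ids].reset_index()
    keep = ~meta["collection"].isin(list(exclude_collections))
    g = g.subset_individuals(np.flatnonzero(keep.to_numpy()))
    meta = meta.loc[keep].reset_index(drop=True)
    area_i = meta["area"].to_numpy()
    loc_i = meta["collection"].to_numpy()
    if len(pd.unique(area_i)) < 2:
        raise ValueError("need at least two areas")

    copies, n_imp = expand_allele_copies(g, loci, collection=loc_i)
    n_ind = g.n_individuals
    area = np.repeat(area_i, 2)
    loc = np.repeat(loc_i, 2)
    ind = np.repeat(np.arange(n_ind), 2)

    obs = _amova_decomposition(copies, area, loc, ind)
    rng = np.random.default_rng(seed)
    p_values = [np.nan] * 4

    locs = pd.unique(loc_i)
    area_of_loc = {l: area_i[loc_i == l][0] for l in locs}
    # level tests are undefined without replication
    testable_area = len(locs) > len(pd.unique(area_i))
    testable_loc = any((loc_i == l).sum() > 1 for l in locs) and len(locs) > 1

    if n_perm > 0:
        # (ii) whole locations among areas -> Phi_CT
        if "area" in perm_levels and testable_area and np.isfinite(obs["phi"][0]):
            count = 0
            area_sizes = [area_of_loc[l] for l in locs]
            for _ in range(n_perm):
                perm_area_of_loc = dict(zip(locs, rng.permutation(area_sizes)))
                area_p = np.array([perm_area_of_loc[l] for l in loc_i])
                d = _amova_decomposition(copies, np.repeat(area_p, 2), loc, ind)
                if np.isfinite(d["phi"][0]) and d["phi"][0] >= obs["phi"][0]:
                    count += 1
            p_values[0] = (1 + count) / (n_perm + 1)
        # (i) individuals among locations within areas -> Phi_SC
        if "location" in perm_levels and testable_loc and np.isfinite(obs["phi"][1]):
            count = 0
            for _ in range(n_perm):
                loc_p = loc_i.copy()
                for a in pd.unique(area_i):
                    rows = np.flatnonzero(area_i == a)
                    loc_p[rows] = rng.permutation(loc_p[rows])
                d = _amova_decomposition(copies, area, np.repeat(loc_p, 2), ind)
                if np.isfinite(d["phi"][1]) and d["phi"][1] >= obs["phi"][1]:
                    count += 1
            p_values[1] = (1 + count) / (n_perm + 1)
        # (iii) allele copies within locations among individuals -> Phi_IS, Phi_IT
        if "individual" in perm_levels and np.isfinite(obs["phi"][2]):
            count_is = 0
            count_it = 0
            for _ in range(n_perm):
                copies_p = copies.copy()
                for l in locs:
                    rows = np.flatnonzero(loc == l)
                    copies_p[rows] = copies_p[rng.permutation(rows)]
                d = _amova_decomposition(copies_p, area, loc, ind)
                if np.isfinite(d["phi"][2]) and d["phi"][2] >= obs["phi"][2]:
                    count_is += 1
                if np.isfinite(d["phi"][3]) and d["phi"][3] >= obs["phi"][3]:
                    count_it += 1
            p_values[2] = (1 + count_is) / (n_perm + 1)
            p_values[3] = (1 + count_it) / (n_perm + 1)

    comps = obs["components"]
    clipped = np.where(np.isnan(comps), 0.0, np.clip(comps, 0, None))
    if clipped.sum() > 0:
        pct = 100 * clipped / clipped.sum()
    else:
        # no variance anywhere: by convention all of it is within individuals
        pct = np.array([0.0, 0.0, 0.0, 100.0])
    table = pd.DataFrame(
        {
            "level": LEVELS,
            "df": obs["df"].astype(int),
            "SS": obs["ss"],
            "MS": obs["ms"],
            "variance_component": comps,
            "pct_variation": pct,
            "phi": obs["phi"],
            "p_value": p_values,
        }
    )
    return AmovaTable(
        table=table,
        n_permutations=n_perm,
        seed=seed,
        loci=list(loci) if loci is not None else None,
        n_imputed=n_imp,
    )
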