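"""Pairwise r2 from unphased genotypes and LD-network cluster analysis.

r2 is the squared correlation between allelic states at two loci,
D^2 / (pA(1-pA) pB(1-pB)), with two-locus haplotype frequencies estimated by
an EM algorithm over the double-heterozygote phase ambiguity (the classic
maximum-likelihood approach for unphased diploid data).  A composite
(Burrows) estimator is available behind a flag.

The network analysis sweeps an r2 threshold downward; at each threshold the
loci whose pairwise r2 reaches it form graph edges, connected components are
clusters, and cluster mergers are recorded into a tree.  Each merging
cluster gets a lambda score — the drop from its median within-cluster r2 to
the median r2 across the merger boundary, scaled by cluster size — and
clusters with at least e_min edges whose lambda is an extreme outlier
(median + phi * MAD over all merger events) are outliers.  Nested outliers
along one ancestry chain describe the same block and are resolved to the
maximal-lambda cluster, whose weakly attached members are pruned; the
result is one single outlier cluster (SOC) per block.  In a dataset
harbouring a non-recombining haplotype block the SOC recovers the block's
loci.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Sequence

import numpy as np

from .geno_io import MISSING, GenotypeMatrix

__all__ = [
    "r2_em",
    "r2_composite",
    "ld_matrix",
    "ldna_clusters",
    "e_min_auto",
    "LDMatrix",
    "LDCluster",
    "LDClusterTree",
]

_MAD_SCALE = 1.4826  # consistency constant for a normal distribution


def e_min_auto(n_loci: int) -> int:
    """Minimum outlier edge count as 1% of the locus panel (rounded up)."""
    return int(math.ceil(0.01 * n_loci))


# ---------------------------------------------------------------------------
# two-locus r2 by EM
# ---------------------------------------------------------------------------

def _counts_3x3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts over individuals complete at both loci."""
    ok = (a != MISSING) & (b != MISSING)
    return np.bincount(3 * a[ok].astype(int) + b[ok].astype(int), minlength=9).reshape(3, 3)


def _em_from_counts(n: np.ndarray, max_iter: int = 1000, tol: float = 1e-8) -> float:
    """r2 from a 3x3 genotype count table via EM haplotype frequencies.

    Returns NaN when either locus is monomorphic among complete pairs.
    """
    n = np.asarray(n, dtype=float)
    n_tot = n.sum()
    if n_tot == 0:
        return float("nan")
    pa = (n[1, :].sum() + 2 * n[2, :].sum()) / (2 * n_tot)
    pb = (n[:, 1].sum() + 2 * n[:, 2].sum()) / (2 * n_tot)
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    # unambiguous haplotype contributions; haplotype order (00, 01, 10, 11)
    c00 = 2 * n[0, 0] + n[0, 1] + n[1, 0]
    c01 = 2 * n[0, 2] + n[0, 1] + n[1, 2]
    c10 = 2 * n[2, 0] + n[1, 0] + n[2, 1]
    c11 = 2 * n[2, 2] + n[2, 1] + n[1, 2]
    dh = n[1, 1]  # double heterozygotes: (11,00) or (10,01)
    f = np.array(
        [(1 - pa) * (1 - pb), (1 - pa) * pb, pa * (1 - pb), pa * pb]
    )
    two_n = 2 * n_tot
    for _ in range(max_iter):
        denom = f[0] * f[3] + f[1] * f[2]
        coup = 0.5 if denom == 0 else f[0] * f[3] / denom
        new = np.array(
            [
                c00 + dh * coup,
                c01 + dh * (1 - coup),
                c10 + dh * (1 - coup),
                c11 + dh * coup,
            ]
        ) / two_n
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    d = f[3] - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def r2_em(
    a: Sequence[int] | np.ndarray,
    b: Sequence[int] | np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> float:
    """EM-based r2 between two dosage vectors (pairwise-complete cases)."""
    a = np.asarray(a)
    b = np.asarray(b)
    return _em_from_counts(_counts_3x3(a, b), max_iter=max_iter, tol=tol)


def r2_composite(a: Sequence[int] | np.ndarray, b: Sequence[int] | np.ndarray) -> float:
    """Composite (Burrows) r2: squared Pearson correlation of dosages."""
    a = np.asarray(a)
    b = np.asarray(b)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# full LD matrix (vectorized EM over all pairs)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LDMatrix:
    """Symmetric loci x loci r2 matrix; undefined entries are NaN."""

    values: np.ndarray
    locus_ids: list[str]

    def summary(self) -> dict[str, float]:
        iu = np.triu_indices(self.values.shape[0], k=1)
        v = self.values[iu]
        v = v[np.isfinite(v)]
        return {
            "n_pairs": int(v.size),
            "mean": float(np.mean(v)) if v.size else float("nan"),
            "median": float(np.median(v)) if v.size else float("nan"),
            "max": float(np.max(v)) if v.size else float("nan"),
            "n_gt_0.5": int((v > 0.5).sum()),
        }

    def to_long(self):
        import pandas as pd

        iu = np.triu_indices(len(self.locus_ids), k=1)
        return pd.DataFrame(
            {
                "locus_a": [self.locus_ids[i] for i in iu[0]],
                "locus_b": [self.locus_ids[j] for j in iu[1]],
                "r2": self.values[iu],
            }
        )


def ld_matrix(
    g: GenotypeMatrix,
    loci: Sequence[int] | None = None,
    method: str = "em",
    max_pairs: int = 10_000_000,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> LDMatrix:
    """All-pairs r2 matrix.

    The EM across all pairs is vectorized: joint genotype counts come from a
    one-hot tensor product, then all pairs iterate the EM update in lockstep
    (converged pairs frozen).  Refuses panels whose pair count exceeds
    ``max_pairs`` unless the caller raises the budget.
    """
    if loci is not None:
        g = g.subset_loci(np.asarray(loci))
    L = g.n_loci
    if L * (L - 1) // 2 > max_pairs:
        raise ValueError(
            f"{L} loci imply {L * (L - 1) // 2} pairs > max_pairs={max_pairs}; "
            "raise max_pairs explicitly to proceed"
        )
    dos = g.dosages
    onehot = np.stack([(dos.T == k).astype(np.float32) for k in range(3)], axis=1)
    # counts[i, j, a, b] = #individuals with dosage a at locus i and b at j
    counts = np.einsum("iam,jbm->ijab", onehot, onehot, optimize=True).astype(float)

    iu, ju = np.triu_indices(L, k=1)
    n = counts[iu, ju]  # (P, 3, 3)
    n_tot = n.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = (n[:, 1, :].sum(axis=1) + 2 * n[:, 2, :].sum(axis=1)) / (2 * n_tot)
        pb = (n[:, :, 1].sum(axis=1) + 2 * n[:, :, 2].sum(axis=1)) / (2 * n_tot)
    poly = (n_tot > 0) & (pa > 0) & (pa < 1) & (pb > 0) & (pb < 1)

    r2 = np.full(iu.size, np.nan)
    if poly.any():
        if method == "composite":
            r2[poly] = _composite_batch(dos, iu[poly], ju[poly])
        elif method == "em":
            r2[poly] = _em_batch(n[poly], pa[poly], pb[poly], max_iter, tol)
        else:
            raise ValueError(f"unknown method {method!r}")
    if not np.isfinite(r2).any():
        raise ValueError("all loci monomorphic: no defined r2 values")

    values = np.full((L, L), np.nan)
    values[iu, ju] = r2
    values[ju, iu] = r2
    np.fill_diagonal(values, 1.0)
    return LDMatrix(values=values, locus_ids=list(g.locus_ids))


def _em_batch(n: np.ndarray, pa: np.ndarray, pb: np.ndarray, max_iter: int, tol: float) -> np.ndarray:
    c00 = 2 * n[:, 0, 0] + n[:, 0, 1] + n[:, 1, 0]
    c01 = 2 * n[:, 0, 2] + n[:, 0, 1] + n[:, 1, 2]
    c10 = 2 * n[:, 2, 0] + n[:, 1, 0] + n[:, 2, 1]
    c11 = 2 * n[:, 2, 2] + n[:, 2, 1] + n[:, 1, 2]
    dh = n[:, 1, 1]
    two_n = 2 * n.sum(axis=(1, 2))
    f = np.stack(
        [(1 - pa) * (1 - pb), (1 - pa) * pb, pa * (1 - pb), pa * pb], axis=1
    )
    active = np.ones(f.shape[0], dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        fa = f[active]
        denom = fa[:, 0] * fa[:, 3] + fa[:, 1] * fa[:, 2]
        coup = np.where(denom > 0, fa[:, 0] * fa[:, 3] / np.where(denom > 0, denom, 1.0), 0.5)
        new = np.stack(
            [
                c00[active] + dh[active] * coup,
                c01[active] + dh[active] * (1 - coup),
                c10[active] + dh[active] * (1 - coup),
                c11[active] + dh[active] * coup,
            ],
            axis=1,
        ) / two_n[active, None]
        done = np.max(np.abs(new - fa), axis=1) < tol
        f[active] = new
        idx = np.flatnonzero(active)
        active[idx[done]] = False
    d = f[:, 3] - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def _composite_batch(dos: np.ndarray, iu: np.ndarray, ju: np.ndarray) -> np.ndarray:
    out = np.empty(iu.size)
    for k, (i, j) in enumerate(zip(iu, ju)):
        out[k] = r2_composite(dos[:, i], dos[:, j])
    return out


# ---------------------------------------------------------------------------
# LD network clustering
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LDCluster:
    """One node of the merger tree (clusters of >= 2 loci)."""

    name: str
    members: list[int]
    threshold: float
    n_edges: int
    median_r2: float
    lam: float | None = None  # defined once the cluster merges into a parent
    parent: "LDCluster | None" = None
    children: list["LDCluster"] = dataclasses.field(default_factory=list)
    is_outlier: bool = False
    is_soc: bool = False

    def descendants(self) -> Iterable["LDCluster"]:
        for ch in self.children:
            yield ch
            yield from ch.descendants()


@dataclasses.dataclass
class LDClusterTree:
    """Full merger tree with outlier flags and the extraction parameters."""

    clusters: list[LDCluster]
    root: LDCluster | None
    socs: list[LDCluster]
    e_min: int
    phi: float
    threshold_step: float
    lambda_median: float
    lambda_mad: float

    def soc_loci(self, ld: LDMatrix | None = None) -> list[list[int]]:
        return [sorted(c.members) for c in self.socs]


class _DisjointSet:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _member_median(values: np.ndarray, members: list[int]) -> float:
    """Median r2 over the upper triangle of a member set (NaN pairs excluded)."""
    if len(members) < 2:
        return 0.0
    sub = values[np.ix_(members, members)]
    iu = np.triu_indices(len(members), k=1)
    v = sub[iu]
    v = v[np.isfinite(v)]
    return float(np.median(v)) if v.size else 0.0


def ldna_clusters(
    ld: LDMatrix,
    e_min: int | str = "auto",
    phi: float = 4.0,
    threshold_step: float = 0.01,
) -> LDClusterTree:
    """Descending-threshold single-linkage LD network clustering.

    Sweeps t from 1.0 down to 0.0 in steps of ``threshold_step``; at each t
    every pair with r2 >= t is an edge and connected components are
    clusters.  Merger events form a tree (ties at a step are one multi-way
    merge).  For each cluster C merging into parent P,
    lambda(C) = (median r2 within C - median r2 of P's boundary pairs) * |C|,
    where the boundary pairs are P's member pairs with at least one locus
    outside C: lambda measures the LD drop across the merger boundary,
    scaled by cluster size, so it spikes when a tight haplotype block
    dissolves into the genomic background.

    Outliers are clusters with edge count |E| >= e_min (member pairs with
    r2 >= the cluster's formation threshold) whose lambda exceeds
    median(lambda) + phi * MAD(lambda), the reference distribution being all
    scored merger events (the genome-wide merger noise).  Because single
    linkage records every growth step of a tight block, nested outliers
    along one ancestry chain describe a single block; each maximal chain is
    resolved to the cluster with the largest lambda (the merger with the
    strongest LD drop defines the block boundary).  Members that joined
    through a single weak edge (median r2 to the rest below a third of
    the cluster median) are pruned.  The resulting single outlier clusters
    (SOCs) are named "size_threshold".
    """
    values = ld.values
    L = values.shape[0]
    if isinstance(e_min, str):
        if e_min != "auto":
            raise ValueError("e_min must be an integer or 'auto'")
        e_min = e_min_auto(L)
    if e_min < 1:
        raise ValueError("e_min must be >= 1")
    if phi <= 0:
        raise ValueError("phi must be > 0")

    iu, ju = np.triu_indices(L, k=1)
    r2 = values[iu, ju]
    defined = np.isfinite(r2)
    iu, ju, r2 = iu[defined], ju[defined], r2[defined]
    # bin each edge to the highest grid threshold it reaches
    n_steps = int(round(1.0 / threshold_step))
    bins = np.minimum((r2 / threshold_step + 1e-9).astype(int), n_steps)

    ds = _DisjointSet(L)
    node_of_root: dict[int, LDCluster | None] = {i: None for i in range(L)}
    members_of_root: dict[int, list[int]] = {i: [i] for i in range(L)}
    clusters: list[LDCluster] = []

    order = np.argsort(-bins, kind="stable")
    pos = 0
    for step in range(n_steps, -1, -1):
        t = step * threshold_step
        merged_roots: dict[int, set[int]] = {}
        while pos < order.size and bins[order[pos]] == step:
            e = order[pos]
            pos += 1
            ra, rb = ds.find(iu[e]), ds.find(ju[e])
            if ra == rb:
                continue
            ds.union(ra, rb)
            rnew = ds.find(ra)
            parts = merged_roots.pop(ra, {ra}) | merged_roots.pop(rb, {rb})
            merged_roots[rnew] = parts
        for rnew, parts in merged_roots.items():
            members: list[int] = []
            child_nodes: list[LDCluster] = []
            for r in parts:
                members.extend(members_of_root.pop(r))
                node = node_of_root.pop(r)
                if node is not None:
                    child_nodes.append(node)
            med = _member_median(values, members)
            sub = values[np.ix_(members, members)]
            tri = sub[np.triu_indices(len(members), k=1)]
            n_edges = int(np.sum(tri[np.isfinite(tri)] >= t))
            new_node = LDCluster(
                name=f"{len(members)}_{t:.2f}",
                members=sorted(members),
                threshold=t,
                n_edges=n_edges,
                median_r2=med,
            )
            member_arr = np.array(sorted(members))
            for ch in child_nodes:
                ch.parent = new_node
                outside = np.setdiff1d(member_arr, ch.members)
                cross = values[np.ix_(ch.members, outside)].ravel()
                if len(outside) > 1:
                    sub_o = values[np.ix_(outside, outside)]
                    cross = np.concatenate(
                        [cross, sub_o[np.triu_indices(len(outside), k=1)]]
                    )
                cross = cross[np.isfinite(cross)]
                boundary_med = float(np.median(cross)) if cross.size else 0.0
                ch.lam = (ch.median_r2 - boundary_med) * len(ch.members)
                new_node.children.append(ch)
            clusters.append(new_node)
            members_of_root[rnew] = members
            node_of_root[rnew] = new_node

    roots = [n for n in node_of_root.values() if n is not None and n.parent is None]
    root = max(roots, key=lambda n: len(n.members)) if roots else None

    scored = [c for c in clusters if c.lam is not None]
    lams = np.array([c.lam for c in scored])
    if lams.size == 0:
        warnings.warn("zero MAD of lambda: no scored merger events, no outliers")
        return LDClusterTree(clusters, root, [], e_min, phi, threshold_step, float("nan"), float("nan"))
    med_lam = float(np.median(lams))
    mad = float(_MAD_SCALE * np.median(np.abs(lams - med_lam)))
    if mad == 0:
        warnings.warn("zero MAD of lambda: degenerate LD structure, no outliers")
        return LDClusterTree(clusters, root, [], e_min, phi, threshold_step, med_lam, mad)
    cutoff = med_lam + phi * mad
    for c in scored:
        c.is_outlier = c.lam > cutoff and c.n_edges >= e_min
    # resolve each maximal ancestry chain of outliers to its max-lambda node
    outliers = [c for c in scored if c.is_outlier]
    socs: list[LDCluster] = []
    for c in outliers:
        anc = c.parent
        has_outlier_ancestor = False
        while anc is not None:
            if anc.is_outlier:
                has_outlier_ancestor = True
                break
            anc = anc.parent
        if not has_outlier_ancestor:
            chain = [c] + [d for d in c.descendants() if d.is_outlier]
            best = max(chain, key=lambda n: n.lam)
            pruned = _prune_weak_members(values, best)
            pruned.is_soc = True
            socs.append(pruned)
    return LDClusterTree(clusters, root, socs, e_min, phi, threshold_step, med_lam, mad)


def _prune_weak_members(values: np.ndarray, cluster: LDCluster) -> LDCluster:
    """Drop members connected to the rest only through single weak edges.

    Single linkage lets a locus chain onto a tight block through one
    borderline pair just before the block dissolves; such members have a
    median r2 to the other members far below the block level.  Iteratively
    removes members whose median r2 to the rest is < a third of the
    cluster median (block members sit at the block level, chained strays at
    the genome-wide background level, typically an order of magnitude apart).  Returns a new node (same tree position) with the pruned
    member set.
    """
    members = list(cluster.members)
    while len(members) > 2:
        med = _member_median(values, members)
        if med <= 0:
            break
        strength = []
        for m in members:
            others = [o for o in members if o != m]
            v = values[m, others]
            v = v[np.isfinite(v)]
            strength.append(np.median(v) if v.size else 0.0)
        weak = [m for m, s in zip(members, strength) if s < med / 3.0]
        if not weak:
            break
        members = [m for m in members if m not in weak]
    if members == list(cluster.members):
        return cluster
    med = _member_median(values, members)
    sub = values[np.ix_(members, members)]
    tri = sub[np.triu_indices(len(members), k=1)]
    n_edges = int(np.sum(tri[np.isfinite(tri)] >= cluster.threshold))
    node = LDCluster(
        name=f"{len(members)}_{cluster.threshold:.2f}",
        members=sorted(members),
        threshold=cluster.threshold,
        n_edges=n_edges,
        median_r2=med,
        lam=cluster.lam,
        parent=cluster.parent,
        children=cluster.children,
        is_outlier=True,
    )
    return node
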