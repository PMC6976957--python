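"""Genotype and metadata I/O plus post-genotyping quality filters.

Genotypes are held as alternate-allele dosages (0/1/2) in a dense integer
matrix with a sentinel for missing calls.  All downstream statistics treat
the sentinel explicitly; nothing in this package silently zero-fills.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.  Distinct from every valid dosage.
MISSING: int = -1

METADATA_COLUMNS = ["individual_id", "collection", "area", "year", "lon", "lat"]


@dataclasses.dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci alternate-allele dosage matrix.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_loci)`` integer array with values in
        ``{0, 1, 2, MISSING}``.
    locus_ids, individual_ids
        Unique identifiers for columns and rows.
    alleles
        Per-locus ``(ref, alt)`` symbols.
    """

    dosages: np.ndarray
    locus_ids: list[str]
    individual_ids: list[str]
    alleles: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.locus_ids = list(self.locus_ids)
        self.individual_ids = list(self.individual_ids)
        self.alleles = [tuple(a) for a in self.alleles]
        n_ind, n_loc = self.dosages.shape
        if len(self.individual_ids) != n_ind:
            raise ValueError("individual_ids length does not match dosage rows")
        if len(self.locus_ids) != n_loc or len(self.alleles) != n_loc:
            raise ValueError("locus_ids/alleles length does not match dosage columns")
        if len(set(self.individual_ids)) != n_ind:
            raise ValueError("duplicated individual identifiers")
        if len(set(self.locus_ids)) != n_loc:
            raise ValueError("duplicated locus identifiers")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or MISSING")

    # -- basic views -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the call is missing."""
        return self.dosages == MISSING

    def masked(self) -> np.ma.MaskedArray:
        """Dosages as a float masked array (missing masked)."""
        return np.ma.masked_array(
            self.dosages.astype(float), mask=self.missing_mask()
        )

    def subset_loci(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[:, idx],
            [self.locus_ids[i] for i in idx],
            list(self.individual_ids),
            [self.alleles[i] for i in idx],
        )

    def subset_individuals(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[idx, :],
            list(self.locus_ids),
            [self.individual_ids[i] for i in idx],
            list(self.alleles),
        )

    def locus_index(self, locus_ids: Sequence[str]) -> np.ndarray:
        lookup = {l: i for i, l in enumerate(self.locus_ids)}
        return np.array([lookup[l] for l in locus_ids], dtype=int)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (count logged).  Phase
    separators ``/`` and ``|`` are both accepted; phase is discarded.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    rows: list[np.ndarray] = []
    locus_ids: list[str] = []
    alleles: list[tuple[str, str]] = []
    n_skipped = 0
    for var in vcf:
        if (
            len(var.ALT) != 1
            or len(var.REF) != 1
            or len(var.ALT[0]) != 1
            or var.ALT[0] not in "ACGT"
            or var.REF not in "ACGT"
        ):
            n_skipped += 1
            continue
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types)
        dos = np.where(gt == 3, 2, gt).astype(np.int8)
        dos[gt == 2] = MISSING
        rows.append(dos)
        locus_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        alleles.append((var.REF, var.ALT[0]))
    vcf.close()
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    g = GenotypeMatrix(np.array(rows).T, locus_ids, individual_ids, alleles)
    g.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return g


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write an uncompressed VCF v4.2 with GT-only genotype fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(g.n_loci):
            ref, alt = g.alleles[j]
            calls = "\t".join(gt_map[int(d)] for d in g.dosages[:, j])
            fh.write(f"1\t{j + 1}\t{g.locus_ids[j]}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------

def write_genotype_csv(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        g.dosages.astype(float), index=g.individual_ids, columns=g.locus_ids
    ).replace(float(MISSING), np.nan)
    df.to_csv(path, na_rep="NA")


def read_genotype_csv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    dos = df.to_numpy(dtype=float)
    dos = np.where(np.isnan(dos), MISSING, dos).astype(np.int8)
    alleles = [("A", "T")] * df.shape[1]
    return GenotypeMatrix(dos, [str(c) for c in df.columns], [str(i) for i in df.index], alleles)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def align_metadata(g: GenotypeMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Return metadata reindexed to the genotype rows (one row per individual)."""
    meta = meta.set_index("individual_id", drop=False)
    missing = [i for i in g.individual_ids if i not in meta.index]
    if missing:
        raise ValueError(f"{len(missing)} genotyped individuals lack metadata, e.g. {missing[:3]}")
    return meta.loc[g.individual_ids].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FilterReport:
    """Per-rule removal counts and the thresholds used."""

    loci_removed: dict[str, int]
    individuals_removed: dict[str, int]
    thresholds: dict[str, float]
    removed_locus_ids: dict[str, list[str]]
    removed_individual_ids: dict[str, list[str]]
    n_loci_in: int
    n_individuals_in: int
    n_loci_out: int
    n_individuals_out: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        lines = [
            f"input: {self.n_individuals_in} individuals x {self.n_loci_in} loci",
        ]
        for rule, n in self.loci_removed.items():
            lines.append(f"  loci removed by {rule}: {n}")
        for rule, n in self.individuals_removed.items():
            lines.append(f"  individuals removed by {rule}: {n}")
        lines.append(
            f"output: {self.n_individuals_out} individuals x {self.n_loci_out} loci"
        )
        return "\n".join(lines)


def _observed_het(dosages: np.ndarray) -> np.ndarray:
    """Per-locus observed heterozygosity among non-missing calls."""
    called = dosages != MISSING
    het = dosages == 1
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, het.sum(axis=0) / np.maximum(n, 1), np.nan)


def _maf(dosages: np.ndarray) -> np.ndarray:
    called = dosages != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
    return np.minimum(p, 1 - p)


def apply_filters(
    g: GenotypeMatrix,
    collections: Mapping[str, str] | pd.Series | Sequence[str],
    call_rate_min: float = 0.80,
    het_max: float = 0.80,
    maf_min: float = 0.01,
    ind_missing_max: float = 0.10,
    hwe_alpha: float = 0.05,
    tags: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the post-genotyping quality filters, in order.

    1. locus call rate >= ``call_rate_min`` across all individuals;
    2. drop loci with observed heterozygosity > ``het_max`` (paralog proxy);
    2b. when ``tags`` is given, keep only the first SNP per tag;
    3. drop loci with MAF <= ``maf_min`` (non-missing calls);
    4. drop individuals with missingness > ``ind_missing_max``;
    5. drop loci out of Hardy-Weinberg equilibrium (exact test) in *every*
       collection after within-collection Bonferroni correction over loci.

    ``collections`` maps individual id -> collection code (or is a sequence
    aligned with the genotype rows).
    """
    from .popgen import hwe_exact_test

    if isinstance(collections, (pd.Series, dict)):
        coll = np.array([collections[i] for i in g.individual_ids])
    else:
        coll = np.asarray(list(collections))
        if coll.shape[0] != g.n_individuals:
            raise ValueError("collections length does not match individuals")

    removed_loci: dict[str, list[str]] = {}
    removed_inds: dict[str, list[str]] = {}
    report_in = (g.n_individuals, g.n_loci)

    # 1. locus call rate
    call_rate = (g.dosages != MISSING).mean(axis=0)
    keep = call_rate >= call_rate_min
    removed_loci["call_rate"] = [g.locus_ids[j] for j in np.flatnonzero(~keep)]
    g = g.subset_loci(np.flatnonzero(keep))
    if tags is not None:
        tags = [tags_j for tags_j, k in zip(tags, keep) if k]

    # 2. excess heterozygosity
    het = _observed_het(g.dosages)
    keep = ~(het > het_max)
    removed_loci["het_excess"] = [g.locus_ids[j] for j in np.flatnonzero(~keep)]
    g = g.subset_loci(np.flatnonzero(keep))
    if tags is not None:
        tags = [t for t, k in zip(tags, keep) if k]

    # 2b. one SNP per tag (no-op without tag metadata)
    if tags is not None:
        seen: set[str] = set()
        keep_idx = []
        drop_ids = []
        for j, t in enumerate(tags):
            if t in seen:
                drop_ids.append(g.locus_ids[j])
            else:
                seen.add(t)
                keep_idx.append(j)
        removed_loci["one_snp_per_tag"] = drop_ids
        g = g.subset_loci(np.array(keep_idx, dtype=int))
    else:
        removed_loci["one_snp_per_tag"] = []

    # 3. minor allele frequency
    maf = _maf(g.dosages)
    keep = maf > maf_min
    removed_loci["maf"] = [g.locus_ids[j] for j in np.flatnonzero(~keep)]
    g = g.subset_loci(np.flatnonzero(keep))

    # 4. individual missingness
    ind_missing = (g.dosages == MISSING).mean(axis=1)
    keep_ind = ind_missing <= ind_missing_max
    removed_inds["missingness"] = [
        g.individual_ids[i] for i in np.flatnonzero(~keep_ind)
    ]
    g = g.subset_individuals(np.flatnonzero(keep_ind))
    coll = coll[keep_ind]

    # 5. per-collection HWE, Bonferroni within collection over loci,
    #    removal requires significance in every collection
    uniq = np.unique(coll)
    n_loci = g.n_loci
    sig_all = np.ones(n_loci, dtype=bool)
    for c in uniq:
        rows = g.dosages[coll == c]
        alpha_adj = hwe_alpha / max(n_loci, 1)
        sig_c = np.zeros(n_loci, dtype=bool)
        for j in range(n_loci):
            d = rows[:, j]
            d = d[d != MISSING]
            if d.size == 0:
                continue
            n_het = int((d == 1).sum())
            n_hom_alt = int((d == 2).sum())
            n_hom_ref = int((d == 0).sum())
            p = hwe_exact_test(n_hom_ref, n_het, n_hom_alt)
            sig_c[j] = p < alpha_adj
        sig_all &= sig_c
    removed_loci["hwe"] = [g.locus_ids[j] for j in np.flatnonzero(sig_all)]
    g = g.subset_loci(np.flatnonzero(~sig_all))

    if g.n_loci == 0 or g.n_individuals == 0:
        raise ValueError("filtering removed all loci or all individuals")

    report = FilterReport(
        loci_removed={k: len(v) for k, v in removed_loci.items()},
        individuals_removed={k: len(v) for k, v in removed_inds.items()},
        thresholds={
            "call_rate_min": call_rate_min,
            "het_max": het_max,
            "maf_min": maf_min,
            "ind_missing_max": ind_missing_max,
            "hwe_alpha": hwe_alpha,
        },
        removed_locus_ids=removed_loci,
        removed_individual_ids=removed_inds,
        n_loci_in=report_in[1],
        n_individuals_in=report_in[0],
        n_loci_out=g.n_loci,
        n_individuals_out=g.n_individuals,
    )
    logger.info("apply_filters:\n%s", report.summary())
    return g, report
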