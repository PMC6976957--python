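"""Synthetic SNP datasets with weak background structure and embedded
non-recombining haplotype blocks (putative structural variants).

The generator emulates a marine RADseq study design: many collections of
diploid individuals nested in a few management areas, thousands of nearly
unstructured background SNPs (Balding-Nichols model with a single FST knob),
and one or two small blocks of SNPs segregating as two divergent
haplotype backgrounds A and B.  Every individual carries two haplotype
labels drawn in Hardy-Weinberg proportions within its collection, so the
three karyotypes AA/AB/BB arise naturally.  Full ground truth is returned.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geno_io import MISSING, GenotypeMatrix, METADATA_COLUMNS

ENV_COVARIATES = ["T_ZMAX", "T_SBT", "D_ZMAX", "C_ZMAX"]


@dataclasses.dataclass
class Collection:
    """One sampling collection: a named site nested in a management area."""

    name: str
    area: str
    lon: float
    lat: float
    n_individuals: int
    year: int = 2016


def default_collections() -> list[Collection]:
    """Eleven North-Sea-style collections in four areas plus one outgroup."""
    spec = [
        ("WB16", "SA4", -1.5, 57.7, 40),
        ("TB16", "SA4", -0.8, 57.2, 40),
        ("FF16", "SA1r", 1.0, 56.5, 40),
        ("DW15", "SA1r", 1.6, 54.8, 39, 2015),
        ("DW16", "SA1r", 1.6, 54.8, 40),
        ("DS15", "SA1r", 2.6, 54.4, 39, 2015),
        ("DS16", "SA1r", 2.6, 54.4, 40),
        ("OS15", "SA2r", 4.5, 55.3, 39, 2015),
        ("EB16", "SA2r", 5.0, 56.2, 40),
        ("DJ16", "SA3r", 7.5, 57.3, 40),
        ("Ru16", "NOR", 10.5, 63.5, 32),
    ]
    return [Collection(*s) for s in spec]


def default_hap_freqs(collections: Sequence[Collection]) -> dict[str, float]:
    """Haplotype-B frequencies varying among collections (mean ~0.3)."""
    base = [0.55, 0.45, 0.30, 0.25, 0.25, 0.22, 0.22, 0.20, 0.25, 0.15, 0.35]
    return {c.name: base[i % len(base)] for i, c in enumerate(collections)}


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    Defaults emulate the study conditions the analysis assumes: 2,509
    background SNPs + one 13-SNP SV block (11 fixed differences between
    haplotype backgrounds), 11 collections of ~40 fish in 4 areas + an
    outgroup, background FST 0.002, 2% missing calls, and per-haplotype
    per-locus background leakage 0.11 giving median within-block genotype
    r2 near 0.29.
    """

    n_loci_background: int = 2509
    n_sv_loci: int = 13
    n_sv_blocks: int = 1
    collections: list[Collection] = dataclasses.field(default_factory=default_collections)
    fst_background: float = 0.002
    sv_hap_freq: dict[str, float] | float | None = None
    n_fixed_diff: int = 11
    sv_freq_a: float = 0.15
    sv_freq_b: float = 0.85
    leakage_eps: float = 0.11
    missing_rate: float = 0.02
    maf_min_ancestral: float = 0.05
    hwe_f: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fixed_diff > self.n_sv_loci:
            raise ValueError("n_fixed_diff must be <= n_sv_loci")
        if self.n_sv_blocks not in (0, 1, 2):
            raise ValueError("n_sv_blocks must be 0, 1 or 2")
        for name in ("fst_background", "missing_rate", "leakage_eps", "maf_min_ancestral"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        for name in ("sv_freq_a", "sv_freq_b"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.collections:
            raise ValueError("need at least one collection")
        for c in self.collections:
            if c.n_individuals < 1:
                raise ValueError(f"collection {c.name} has no individuals")
        if self.sv_hap_freq is None:
            self.sv_hap_freq = default_hap_freqs(self.collections)
        if isinstance(self.sv_hap_freq, (int, float)):
            self.sv_hap_freq = {c.name: float(self.sv_hap_freq) for c in self.collections}
        for q in self.sv_hap_freq.values():
            if not 0 <= q <= 1:
                raise ValueError("sv_hap_freq values must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclasses.dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    sv_locus_indices: list[list[int]]
    karyotypes: list[dict[str, str]]  # per block: individual_id -> AA/AB/BB
    b_dosage: list[dict[str, int]]  # per block: individual_id -> 0/1/2
    config: SimConfig

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "sv_locus_indices": self.sv_locus_indices,
            "karyotypes": self.karyotypes,
            "b_dosage": self.b_dosage,
            "config": self.config.to_dict(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _simulate_background(
    rng: np.random.Generator, cfg: SimConfig, n_per_coll: list[int]
) -> np.ndarray:
    """Balding-Nichols background genotypes for all collections stacked."""
    L = cfg.n_loci_background
    p_anc = rng.uniform(cfg.maf_min_ancestral, 1 - cfg.maf_min_ancestral, size=L)
    fst = cfg.fst_background
    blocks = []
    for n_ind in n_per_coll:
        if fst > 0:
            a = p_anc * (1 - fst) / fst
            b = (1 - p_anc) * (1 - fst) / fst
            p_coll = rng.beta(a, b)
        else:
            p_coll = p_anc
        blocks.append(rng.binomial(2, p_coll, size=(n_ind, L)))
    return np.vstack(blocks).astype(np.int8)


def _simulate_sv_block(
    rng: np.random.Generator, cfg: SimConfig, coll_names: list[str], n_per_coll: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """One SV block: returns (genotypes, b_dosage per individual).

    Each individual draws two haplotype labels iid Bernoulli(q_collection)
    (or with inbreeding-like disequilibrium hwe_f if set); each haplotype
    copy swaps background per locus with probability leakage_eps; allele
    frequency is 0/1 on A/B for fixed-difference loci and sv_freq_a/sv_freq_b
    for the remainder.
    """
    L = cfg.n_sv_loci
    freq_a = np.full(L, cfg.sv_freq_a)
    freq_b = np.full(L, cfg.sv_freq_b)
    freq_a[: cfg.n_fixed_diff] = 0.0
    freq_b[: cfg.n_fixed_diff] = 1.0

    genos = []
    b_dos = []
    for name, n_ind in zip(coll_names, n_per_coll):
        q = cfg.sv_hap_freq[name]
        if cfg.hwe_f == 0:
            haps = rng.random((n_ind, 2)) < q  # True = background B
        else:
            # inbreeding-style disequilibrium: P(AB) = 2q(1-q)(1-F)
            p_bb = q * q + cfg.hwe_f * q * (1 - q)
            p_ab = 2 * q * (1 - q) * (1 - cfg.hwe_f)
            u = rng.random(n_ind)
            n_b = np.where(u < p_bb, 2, np.where(u < p_bb + p_ab, 1, 0))
            haps = np.zeros((n_ind, 2), dtype=bool)
            haps[n_b >= 1, 0] = True
            haps[n_b == 2, 1] = True
        b_dos.append(haps.sum(axis=1).astype(np.int8))
        # leakage: each haplotype copy independently swaps background per locus
        g = np.zeros((n_ind, L), dtype=np.int8)
        for copy in range(2):
            is_b = haps[:, copy][:, None]
            swap = rng.random((n_ind, L)) < cfg.leakage_eps
            eff_b = is_b ^ swap
            p = np.where(eff_b, freq_b[None, :], freq_a[None, :])
            g += (rng.random((n_ind, L)) < p).astype(np.int8)
        genos.append(g)
    return np.vstack(genos), np.concatenate(b_dos)


def simulate_dataset(
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Simulate genotypes, sample metadata and ground truth.

    Deterministic given ``config.seed``.  SV loci are placed at the end of
    the locus list (their indices are in the truth object); locus order
    carries no information for any downstream analysis.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    coll_names = [c.name for c in cfg.collections]
    n_per_coll = [c.n_individuals for c in cfg.collections]
    n_total = sum(n_per_coll)

    individual_ids = []
    meta_rows = []
    for c in cfg.collections:
        for i in range(c.n_individuals):
            iid = f"{c.name}_{i + 1:03d}"
            individual_ids.append(iid)
            meta_rows.append((iid, c.name, c.area, c.year, c.lon, c.lat))
    meta = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)

    parts = [_simulate_background(rng, cfg, n_per_coll)]
    sv_indices: list[list[int]] = []
    b_dosages: list[np.ndarray] = []
    offset = cfg.n_loci_background
    for _ in range(cfg.n_sv_blocks):
        g_sv, b_dos = _simulate_sv_block(rng, cfg, coll_names, n_per_coll)
        parts.append(g_sv)
        sv_indices.append(list(range(offset, offset + cfg.n_sv_loci)))
        b_dosages.append(b_dos)
        offset += cfg.n_sv_loci

    dosages = np.hstack(parts)
    if cfg.missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.missing_rate
        dosages = np.where(miss, MISSING, dosages).astype(np.int8)

    n_loci = dosages.shape[1]
    locus_ids = [f"bg_{j + 1:05d}" for j in range(cfg.n_loci_background)]
    for b, block in enumerate(sv_indices):
        locus_ids += [f"sv{b + 1}_{k + 1:02d}" for k in range(len(block))]
    alleles = [("A", "T")] * n_loci

    g = GenotypeMatrix(dosages, locus_ids, individual_ids, alleles)
    karyo_label = {0: "AA", 1: "AB", 2: "BB"}
    truth = SimTruth(
        sv_locus_indices=sv_indices,
        karyotypes=[
            {iid: karyo_label[int(d)] for iid, d in zip(individual_ids, b_dos)}
            for b_dos in b_dosages
        ],
        b_dosage=[
            {iid: int(d) for iid, d in zip(individual_ids, b_dos)}
            for b_dos in b_dosages
        ],
        config=cfg,
    )
    return g, meta, truth


# ---------------------------------------------------------------------------
# Environmental covariates
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EnvEffect:
    """A programmed logit-linear link between haplotype frequency and one
    covariate: logit(q) = intercept + slope * z, z the standardized covariate."""

    covariate: str = "T_SBT"
    slope: float = 2.0
    intercept: float = -0.8


def simulate_env_table(
    sites: pd.DataFrame,
    effect: EnvEffect | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Site-level environmental covariate table (T_ZMAX, T_SBT, D_ZMAX, C_ZMAX).

    ``sites`` needs columns ``site``, ``lon``, ``lat`` (and ``q`` when an
    effect is programmed).  Covariates are drawn with a mild latitudinal
    trend plus noise; with ``effect`` set, the chosen covariate is derived
    deterministically from logit(q) so the programmed link holds exactly.
    """
    if not {"site", "lon", "lat"}.issubset(sites.columns):
        raise ValueError("sites needs columns site, lon, lat")
    rng = np.random.default_rng(seed)
    n = len(sites)
    lat = sites["lat"].to_numpy(float)
    lat_z = (lat - lat.mean()) / (lat.std() + 1e-12)
    env = pd.DataFrame({"site": sites["site"].to_numpy(),
                        "lon": sites["lon"].to_numpy(float),
                        "lat": lat})
    scales = {"T_ZMAX": (10.0, 1.5), "T_SBT": (8.0, 1.2),
              "D_ZMAX": (25.0, 8.0), "C_ZMAX": (4.0, 1.0)}
    for name, (mu, sd) in scales.items():
        env[name] = mu - 0.5 * sd * lat_z + sd * rng.standard_normal(n)
    if effect is not None:
        if effect.covariate not in ENV_COVARIATES:
            raise ValueError(f"unknown covariate {effect.covariate}")
        if "q" not in sites.columns:
            raise ValueError("programmed effect requires a q column in sites")
        q = np.clip(sites["q"].to_numpy(float), 1e-6, 1 - 1e-6)
        z = (np.log(q / (1 - q)) - effect.intercept) / effect.slope
        mu, sd = scales[effect.covariate]
        env[effect.covariate] = mu + sd * z
    return env


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

def _haversine_km(lon1, lat1, lon2, lat2) -> float:
    r = 6371.0
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * r * np.arcsin(np.sqrt(a)))


def simulate_connectivity(
    sites: pd.DataFrame,
    decay_scale: float = 150.0,
    seed: int | None = None,
    retention: float = 0.8,
) -> pd.DataFrame:
    """Directional larval-transport probability matrix between sites.

    Transport probability decays exponentially in great-circle distance with
    e-folding scale ``decay_scale`` (km); asymmetric lognormal noise makes
    the matrix directional.  Rows are sources, scaled to sum to
    ``retention`` (<= 1, the rest is larval loss).
    """
    if len(sites) < 3:
        raise ValueError("need at least 3 sites")
    rng = np.random.default_rng(seed)
    names = list(sites["site"])
    lon = sites["lon"].to_numpy(float)
    lat = sites["lat"].to_numpy(float)
    n = len(names)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dist[i, j] = _haversine_km(lon[i], lat[i], lon[j], lat[j])
    base = np.exp(-dist / decay_scale)
    noise = rng.lognormal(mean=0.0, sigma=0.3, size=(n, n))
    conn = base * noise
    conn *= retention / conn.sum(axis=1, keepdims=True)
    return pd.DataFrame(conn, index=names, columns=names)


def write_connectivity(conn: pd.DataFrame, path: str | Path) -> None:
    conn.to_csv(path)


def write_env_table(env: pd.DataFrame, path: str | Path) -> None:
    env.to_csv(path, sep="\t", index=False)


def sites_from_metadata(meta: pd.DataFrame, hap_freq: dict[str, float] | None = None) -> pd.DataFrame:
    """One row per collection with coordinates (and q when provided)."""
    sites = (
        meta.groupby("collection", sort=False)
        .agg(lon=("lon", "first"), lat=("lat", "first"), area=("area", "first"))
        .reset_index()
        .rename(columns={"collection": "site"})
    )
    if hap_freq is not None:
        sites["q"] = [hap_freq[s] for s in sites["site"]]
    return sites
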