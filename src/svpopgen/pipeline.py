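"""End-to-end orchestration: filter -> diversity stats -> LD network ->
PCA/karyotypes -> AMOVA -> environmental GLMs -> connectivity Mantel test.

Every stage's randomness draws from a per-stage seed derived from the master
seed through ``numpy.random.SeedSequence(master).spawn`` in a fixed stage
order, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import amova as amova_mod
from . import connect as connect_mod
from . import envassoc, geno_io, karyostats, ldnet, popgen, strucpca

logger = logging.getLogger(__name__)

STAGE_ORDER = ["filter", "stats", "fst", "ldna", "pca", "karyotype", "amova", "env", "mantel"]


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    vcf: str
    metadata: str
    out_dir: str
    env_table: str | None = None
    connectivity: str | None = None
    call_rate_min: float = 0.80
    het_max: float = 0.80
    maf_min: float = 0.01
    ind_missing_max: float = 0.10
    hwe_alpha: float = 0.05
    e_min: int | str = "auto"
    phi: float = 4.0
    threshold_step: float = 0.01
    n_components: int = 10
    scan_K: int = 1
    scan_fdr: float = 0.01
    k_max: int = 5
    amova_exclude: list[str] = dataclasses.field(default_factory=list)
    amova_n_perm: int = 1000
    fst_n_perm: int = 99
    mantel_n_perm: int = 999
    mantel_fst_loci: str = "soc"  # "soc" or "all"
    run_env: bool = True
    run_mantel: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("vcf", "metadata"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.run_env and self.env_table is None:
            raise ValueError("env stage enabled but no env_table configured")
        if self.run_env and not Path(self.env_table).exists():
            raise FileNotFoundError(f"env_table file not found: {self.env_table}")
        if self.run_mantel and self.connectivity is None:
            raise ValueError("mantel stage enabled but no connectivity configured")
        if self.run_mantel and not Path(self.connectivity).exists():
            raise FileNotFoundError(f"connectivity file not found: {self.connectivity}")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Per-stage 31-bit seeds spawned from the master seed, fixed order."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGE_ORDER))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(STAGE_ORDER, children)
    }


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute all stages in order, persisting every intermediate artifact.

    Returns the machine-readable summary (also written to summary.json).
    Any stage failure raises :class:`StageFailure`; artifacts of completed
    stages remain on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    summary: dict[str, Any] = {
        "version": __version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "stages": {},
    }
    timings: dict[str, float] = {}

    def _run(stage: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # persist what we know, then abort
            (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
            raise StageFailure(stage, exc) from exc
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s finished in %.2fs", stage, timings[stage])
        return result

    # ---- filter ----
    def _filter():
        g0 = geno_io.read_vcf(config.vcf)
        meta0 = geno_io.read_metadata(config.metadata)
        meta0 = geno_io.align_metadata(g0, meta0)
        g, report = geno_io.apply_filters(
            g0,
            collections=meta0["collection"].to_numpy(),
            call_rate_min=config.call_rate_min,
            het_max=config.het_max,
            maf_min=config.maf_min,
            ind_missing_max=config.ind_missing_max,
            hwe_alpha=config.hwe_alpha,
        )
        meta = meta0[meta0["individual_id"].isin(g.individual_ids)].reset_index(drop=True)
        report.to_json(out / "filter_report.json")
        geno_io.write_genotype_csv(g, out / "genotypes_filtered.csv")
        summary["stages"]["filter"] = {
            "n_loci_kept": g.n_loci,
            "n_individuals_kept": g.n_individuals,
        }
        return g, meta

    g, meta = _run("filter", _filter)
    collections = meta["collection"].to_numpy()

    # ---- basic stats ----
    def _stats():
        ds = popgen.nei_stats(g, collections)
        ds.per_locus.to_csv(out / "diversity_per_locus.tsv", sep="\t")
        summary["stages"]["stats"] = ds.overall
        return ds

    _run("stats", _stats)

    # ---- pairwise FST (all loci, collections) ----
    def _fst():
        pf = popgen.pairwise_fst(g, collections, n_perm=config.fst_n_perm, seed=seeds["fst"])
        pf.theta.to_csv(out / "pairwise_fst_collections.csv")
        pf.p_values.to_csv(out / "pairwise_fst_collections_p.csv")
        summary["stages"]["fst"] = {
            "max_theta": float(np.nanmax(pf.theta.to_numpy())),
            "n_permutations": pf.n_permutations,
        }
        return pf

    _run("fst", _fst)

    # ---- LD network ----
    def _ldna():
        ld = ldnet.ld_matrix(g)
        tree = ldnet.ldna_clusters(
            ld, e_min=config.e_min, phi=config.phi, threshold_step=config.threshold_step
        )
        ld.to_long().to_csv(out / "ld_pairs.tsv.gz", sep="\t", index=False)
        soc_report = [
            {"name": c.name, "members": [ld.locus_ids[i] for i in c.members],
             "median_r2": c.median_r2, "lambda": c.lam, "n_edges": c.n_edges}
            for c in tree.socs
        ]
        (out / "ldna_clusters.json").write_text(json.dumps(
            {"e_min": tree.e_min, "phi": tree.phi, "socs": soc_report}, indent=2))
        summary["stages"]["ldna"] = {
            "ld_summary": ld.summary(),
            "n_socs": len(tree.socs),
            "soc_sizes": [len(c.members) for c in tree.socs],
        }
        return ld, tree

    ld, tree = _run("ldna", _ldna)
    if not tree.socs:
        raise StageFailure("ldna", RuntimeError("no single outlier cluster found"))
    soc = max(tree.socs, key=lambda c: len(c.members))
    soc_loci = sorted(soc.members)

    # ---- PCA (all loci + SOC loci) ----
    def _pca():
        res_all = strucpca.pca(g, n_components=config.n_components)
        g_soc = g.subset_loci(np.array(soc_loci))
        res_soc = strucpca.pca(g_soc, n_components=min(config.n_components, len(soc_loci)))
        pd.DataFrame(
            res_soc.scores, index=g.individual_ids
        ).to_csv(out / "pca_soc_scores.tsv", sep="\t")
        outliers, _ = strucpca.pcadapt_scan(g, K=config.scan_K, fdr=config.scan_fdr)
        summary["stages"]["pca"] = {
            "variance_explained_all_pc1_pc2": [float(v) for v in res_all.variance_explained[:2]],
            "variance_explained_soc_pc1_pc2": [float(v) for v in res_soc.variance_explained[:2]],
            "n_scan_outliers": int(outliers.size),
            "scan_outliers_in_soc": int(np.isin(outliers, soc_loci).sum()),
        }
        return res_all, res_soc

    res_all, res_soc = _run("pca", _pca)

    # ---- karyotypes ----
    def _karyotype():
        clusters = strucpca.find_clusters(
            res_soc.scores, k_max=config.k_max, n_pcs=1, seed=seeds["karyotype"]
        )
        if clusters.k != 3:
            clusters = strucpca.find_clusters(
                res_soc.scores, k_max=config.k_max, n_pcs=1, seed=seeds["karyotype"], k=3
            )
        karyo = karyostats.call_karyotypes(g, soc_loci, res_soc, clusters, meta=meta)
        karyo.table.to_csv(out / "karyotypes.tsv", sep="\t", index=False)
        freqs = karyostats.karyo_freq_table(karyo, by="collection")
        freqs.table.to_csv(out / "karyotype_freqs_by_collection.tsv", sep="\t", index=False)
        freqs_area = karyostats.karyo_freq_table(karyo, by="area")
        freqs_area.table.to_csv(out / "karyotype_freqs_by_area.tsv", sep="\t", index=False)
        contrasts = karyostats.cluster_contrasts(g, karyo, soc_loci)
        (out / "cluster_contrasts.json").write_text(json.dumps(contrasts, indent=2))
        summary["stages"]["karyotype"] = {
            "cluster_sizes": karyo.table["karyotype"].value_counts().to_dict(),
            "labelling_consistent": karyo.labelling_consistent,
            "theta_AA_BB_soc": contrasts["theta_AA_BB_soc"],
            "n_hwe_rejections": int(freqs.table["hwe_reject"].sum()),
        }
        return karyo, freqs

    karyo, freqs = _run("karyotype", _karyotype)

    # ---- AMOVA on SOC loci ----
    def _amova():
        table = amova_mod.amova(
            g,
            meta,
            loci=soc_loci,
            n_perm=config.amova_n_perm,
            seed=seeds["amova"],
            exclude_collections=config.amova_exclude,
        )
        table.table.to_csv(out / "amova.tsv", sep="\t", index=False)
        summary["stages"]["amova"] = {
            "df": table.table["df"].tolist(),
            "pct_variation": table.table["pct_variation"].round(4).tolist(),
            "p_values": table.table["p_value"].tolist(),
        }
        return table

    _run("amova", _amova)

    # ---- environmental GLMs ----
    if config.run_env:
        def _env():
            env = pd.read_csv(config.env_table, sep="\t")
            screen = envassoc.env_screen(freqs.table, env)
            screen.to_csv(out / "env_screen.tsv", sep="\t", index=False)
            summary["stages"]["env"] = {
                "best_model": screen.loc[screen["AIC"].idxmin(), "model"],
                "min_lrt_p": float(np.nanmin(screen["lrt_p"].to_numpy())),
            }
            return screen

        _run("env", _env)

    # ---- Mantel ----
    if config.run_mantel:
        def _mantel():
            conn = pd.read_csv(config.connectivity, index_col=0)
            conn_sym = connect_mod.symmetrize(conn)
            loci = soc_loci if config.mantel_fst_loci == "soc" else None
            g_m = g.subset_loci(np.array(loci)) if loci is not None else g
            pf = popgen.pairwise_fst(g_m, collections, n_perm=0)
            fst = pf.theta
            r, p = connect_mod.mantel(
                fst, conn_sym, n_perm=config.mantel_n_perm, seed=seeds["mantel"]
            )
            (out / "mantel.json").write_text(json.dumps(
                {"r": r, "p": p, "n_permutations": config.mantel_n_perm,
                 "fst_loci": config.mantel_fst_loci}, indent=2))
            summary["stages"]["mantel"] = {"r": r, "p": p}
            return r, p

        _run("mantel", _mantel)

    summary["wall_time_s"] = {k: round(v, 3) for k, v in timings.items()}
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
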