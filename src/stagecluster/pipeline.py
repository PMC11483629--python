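"""End-to-end orchestration of the expression analysis.

``run_pipeline`` chains normalize -> per-tissue DEG -> co-expression
network -> Louvain clustering -> cluster profiles and intersections, and
writes every stage output plus a machine-readable manifest (parameters,
seeds, per-stage row counts, file checksums).  One top-level seed is split
deterministically into named per-stage substreams so any stage can be
re-run in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .community import louvain
from .data import CountMatrix, ValidationError
from .deg import lrt_stage
from .network import build_graph, permutation_threshold, scale_profiles
from .normalize import estimate_size_factors, expression_filter, remove_batch, transform
from .profiles import adjusted_rand_index, cluster_intersections, stage_zscore_profiles
from .simulate import _substream

logger = logging.getLogger("stagecluster")


@dataclass
class PipelineConfig:
    """Run parameters; the defaults are the analysis' published constants."""

    out_dir: str = "stagecluster_run"
    deg_fdr: float = 0.001
    expr_threshold: float = 50.0
    apply_expression_filter: bool = True
    include_batch: bool = False
    permutation_reps: int = 1000
    permutation_quantile: float = 0.99995
    pairs_per_rep: int = 200_000
    min_degree: int = 50
    resolution: float = 0.75
    top_k_intersections: int = 25
    stats_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.deg_fdr < 1) or not (0 < self.permutation_quantile < 1):
            raise ValidationError("thresholds out of range")
        if self.min_degree < 0 or self.resolution <= 0:
            raise ValidationError("min_degree must be >= 0 and resolution > 0")
        if self.permutation_reps < 1 or self.top_k_intersections < 1:
            raise ValidationError("counts must be positive")


def run_pipeline(
    counts: CountMatrix,
    config: PipelineConfig,
    truth=None,
    phenotypes: pd.DataFrame | None = None,
    naf: pd.DataFrame | None = None,
) -> dict:
    """Execute all stages and write outputs under ``config.out_dir``.

    Returns the manifest.  When a :class:`SyntheticTruth` with module
    membership is supplied, the manifest additionally records the adjusted
    Rand index between recovered clusters and planted modules per tissue.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": asdict(config),
        "stages": {},
        "files": {},
        "notices": [],
    }

    def _emit(name: str, writer, *args) -> None:
        path = out / name
        writer(*args, path)
        manifest["files"][name] = sha256_of_file(path)

    def sha256_of_file(path):
        return sio.sha256_of(path)

    # --- normalization -----------------------------------------------------
    size_factors = estimate_size_factors(counts)
    norm = transform(counts, size_factors)
    if counts.sample_meta["batch"].nunique() > 1:
        norm = remove_batch(norm)
        manifest["stages"]["batch_correction"] = {"applied": True}
    _emit("size_factors.tsv", lambda sf, p: sf.to_frame().to_csv(p, sep="\t", index_label="sample_id"), size_factors)
    _emit("normalized.tsv", lambda v, p: v.to_csv(p, sep="\t", index_label="gene_id"), norm.values)
    manifest["stages"]["normalize"] = {
        "n_genes": counts.n_genes,
        "n_samples": counts.n_samples,
    }

    if config.apply_expression_filter:
        expressed = expression_filter(norm, threshold=config.expr_threshold)
    else:
        expressed = counts.gene_ids
    manifest["stages"]["expression_filter"] = {
        "threshold": config.expr_threshold,
        "n_expressed": int(len(expressed)),
    }

    tissues = list(pd.unique(counts.sample_meta["tissue"]))
    assignments_rows = []
    ari_per_tissue: dict = {}
    deg_counts: dict = {}
    for tissue in tissues:
        cm_t = counts.subset_tissue(tissue)
        deg = lrt_stage(
            cm_t,
            include_batch=config.include_batch
            and cm_t.sample_meta["batch"].nunique() > 1,
            fdr_threshold=config.deg_fdr,
            size_factors=size_factors.loc[cm_t.sample_ids],
        )
        _emit(
            f"deg_{tissue}.tsv",
            lambda d, p: d.to_csv(p, sep="\t", index_label="gene_id"),
            deg,
        )
        deg_genes = deg.index[deg["is_deg"]]
        deg_genes = deg_genes.intersection(expressed)
        deg_counts[tissue] = int(len(deg_genes))
        if len(deg_genes) < max(config.min_degree + 1, 2):
            msg = f"tissue {tissue}: {len(deg_genes)} DEGs, network/cluster skipped"
            logger.info(msg)
            manifest["notices"].append(msg)
            continue

        norm_t = norm.subset_tissue(tissue)
        profiles = scale_profiles(norm_t, genes=deg_genes)
        thr_seed = _substream(config.seed, f"threshold:{tissue}")
        threshold = permutation_threshold(
            profiles,
            replications=config.permutation_reps,
            quantile=config.permutation_quantile,
            pairs_per_rep=config.pairs_per_rep,
            seed=thr_seed,
        )
        graph = build_graph(profiles, threshold, min_degree=config.min_degree)
        edges = pd.DataFrame(
            [
                {"gene_a": u, "gene_b": v, "r": d["weight"]}
                for u, v, d in graph.graph.edges(data=True)
            ]
        )
        _emit(f"edges_{tissue}.tsv", lambda e, p: e.to_csv(p, sep="\t", index=False), edges)
        sio.write_json(
            {
                "tissue": tissue,
                "threshold": threshold,
                "replications": config.permutation_reps,
                "quantile": config.permutation_quantile,
                "seed": thr_seed,
                "removed_nodes": len(graph.removed),
            },
            out / f"network_{tissue}.json",
        )
        manifest["files"][f"network_{tissue}.json"] = sio.sha256_of(
            out / f"network_{tissue}.json"
        )
        if graph.n_edges == 0 or graph.n_nodes == 0:
            msg = f"tissue {tissue}: empty graph after filtering, cluster skipped"
            logger.info(msg)
            manifest["notices"].append(msg)
            continue

        part = louvain(
            graph,
            resolution=config.resolution,
            seed=_substream(config.seed, f"louvain:{tissue}"),
        )
        clusters = pd.DataFrame(
            {
                "gene_id": list(part.membership),
                "tissue": tissue,
                "cluster": [part.membership[g] for g in part.membership],
            }
        )
        _emit(
            f"clusters_{tissue}.tsv",
            lambda c, p: c.to_csv(p, sep="\t", index=False),
            clusters,
        )
        assignments_rows.append(clusters)
        prof = stage_zscore_profiles(norm, part, tissue)
        _emit(
            f"profiles_{tissue}.tsv",
            lambda c, p: c.to_csv(p, sep="\t", index=False),
            prof,
        )
        manifest["stages"].setdefault("network", {})[tissue] = {
            "threshold": threshold,
            "n_nodes": graph.n_nodes,
            "n_edges": graph.n_edges,
            "n_removed": len(graph.removed),
            "n_clusters": part.n_communities,
            "modularity": part.modularity,
        }

        if truth is not None and truth.module_membership is not None:
            planted = truth.module_membership
            planted_t = planted[planted["tissue"] == tissue].set_index("gene_id")[
                "module"
            ]
            common = [g for g in part.membership if g in planted_t.index]
            if common:
                recovered = {g: part.membership[g] for g in common}
                expected = {g: int(planted_t[g]) for g in common}
                ari_per_tissue[tissue] = adjusted_rand_index(recovered, expected)

    manifest["stages"]["deg"] = deg_counts
    if ari_per_tissue:
        manifest["stages"]["module_recovery_ari"] = ari_per_tissue

    if assignments_rows:
        assignments = pd.concat(assignments_rows, ignore_index=True)
        inter = cluster_intersections(assignments, top_k=config.top_k_intersections)
        inter_df = inter.patterns.copy()
        inter_df["pattern"] = inter_df["pattern"].map(lambda t: "|".join(t))
        _emit(
            "intersections.tsv",
            lambda d, p: d.to_csv(p, sep="\t", index=False),
            inter_df,
        )
        manifest["stages"]["intersections"] = {
            "universe": inter.universe_size,
            "n_patterns_reported": int(len(inter.patterns)),
        }

    if phenotypes is not None:
        from .stats import phenotype_anova

        pheno = phenotype_anova(phenotypes, alpha=config.stats_alpha)
        _emit(
            "phenotype_stats.tsv",
            lambda d, p: d.to_csv(p, sep="\t", index=False),
            pheno,
        )
        manifest["stages"]["phenotype_stats"] = {
            "n_models": int(len(pheno)),
            "n_significant": int(pheno["significant"].sum()),
        }
    if naf is not None:
        from .stats import naf_test

        naf_out = naf_test(naf, alpha=config.stats_alpha)
        _emit(
            "naf_stats.tsv", lambda d, p: d.to_csv(p, sep="\t", index=False), naf_out
        )
        manifest["stages"]["naf_stats"] = {
            "n_models": int(len(naf_out)),
            "n_significant": int(naf_out["significant"].sum()),
        }

    sio.write_json(manifest, out / "manifest.json")
    return manifest
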