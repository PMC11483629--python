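"""Cluster stage-profile summaries, UpSet intersection counts, and ARI.

Stage profiles follow the heatmap convention: per gene, average the
transformed expression over the samples of each stage, z-score those
per-stage averages across stages, then summarize a cluster as the
per-stage mean of its members' z-scores.  Intersections use exclusive
UpSet semantics: every gene counts toward exactly the pattern of all
tissue-cluster sets that contain it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb

from .data import NormalizedMatrix, ValidationError


def gene_stage_zscores(
    norm: NormalizedMatrix, genes=None, stages=None
) -> pd.DataFrame:
    """Per-gene z-scores (across stages) of the per-stage mean expression.

    Constant rows map to all-zero z-scores.
    """
    values = norm.values if genes is None else norm.values.loc[list(genes)]
    stage = norm.sample_meta["stage"].astype(str)
    if stages is None:
        stages = list(pd.unique(stage))
    means = np.column_stack(
        [
            values.loc[:, stage.index[stage == s]].mean(axis=1).to_numpy()
            for s in stages
        ]
    )
    if means.shape[1] == 0 or np.isnan(means).any():
        raise ValidationError("a stage has no samples")
    center = means - means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, ddof=1)
    z = np.divide(center, sd[:, None], out=np.zeros_like(center), where=sd[:, None] > 0)
    return pd.DataFrame(z, index=values.index, columns=stages)


def stage_zscore_profiles(
    norm: NormalizedMatrix, partition, tissue: str
) -> pd.DataFrame:
    """Cluster-level stage profiles for one tissue.

    Returns one row per (tissue, cluster, stage) with the mean member
    z-score and the cluster size.
    """
    sub = norm.subset_tissue(tissue)
    membership = partition.membership if hasattr(partition, "membership") else dict(partition)
    genes = [g for g in membership if g in sub.values.index]
    if len(genes) < len(membership):
        missing = sorted(set(membership) - set(genes))
        raise ValidationError(f"partition genes absent from matrix: {missing[:10]}")
    z = gene_stage_zscores(sub, genes=genes)
    clusters = pd.Series({g: membership[g] for g in genes}, name="cluster")
    rows = []
    for c, idx in clusters.groupby(clusters).groups.items():
        prof = z.loc[list(idx)].mean(axis=0)
        for stage, val in prof.items():
            rows.append(
                {
                    "tissue": tissue,
                    "cluster": c,
                    "stage": stage,
                    "z": float(val),
                    "size": len(idx),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class IntersectionTable:
    """Exclusive intersection counts plus per-set totals."""

    patterns: pd.DataFrame  # columns: pattern (tuple of labels), count
    set_totals: pd.Series
    universe_size: int


def cluster_intersections(assignments: pd.DataFrame, top_k: int = 25) -> IntersectionTable:
    """Exclusive (UpSet) intersection counts over tissue-cluster sets.

    ``assignments`` has columns ``gene_id``, ``tissue``, ``cluster``; a
    gene may appear in at most one cluster per tissue.  Each gene counts
    toward exactly one pattern: the set of all ``tissue:cluster`` labels
    containing it.  Returns the ``top_k`` largest patterns (all patterns
    when fewer) and per-set totals; pattern counts over the full table
    partition the gene universe.
    """
    required = {"gene_id", "tissue", "cluster"}
    if not required.issubset(assignments.columns):
        raise ValidationError(f"assignments need columns {sorted(required)}")
    dup = assignments.duplicated(subset=["gene_id", "tissue"])
    if dup.any():
        genes = assignments.loc[dup, "gene_id"].unique()
        raise ValidationError(
            f"gene(s) assigned twice within one tissue: {list(genes[:10])}"
        )
    labels = assignments["tissue"].astype(str) + ":" + assignments["cluster"].astype(str)
    frame = pd.DataFrame({"gene_id": assignments["gene_id"], "label": labels})
    patterns = (
        frame.groupby("gene_id")["label"]
        .apply(lambda s: tuple(sorted(s)))
        .rename("pattern")
    )
    counts = patterns.value_counts()
    table = pd.DataFrame(
        {"pattern": counts.index.to_list(), "count": counts.to_numpy()}
    )
    table = table.sort_values(
        by=["count", "pattern"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    set_totals = frame["label"].value_counts().sort_index()
    return IntersectionTable(
        patterns=table.head(top_k).reset_index(drop=True),
        set_totals=set_totals,
        universe_size=int(patterns.shape[0]),
    )


def adjusted_rand_index(partition_a, partition_b) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    Both arguments are mappings (or Partition objects) over the same
    element universe.  Returns 1 for identical partitions, ~0 at chance.
    """
    a = partition_a.membership if hasattr(partition_a, "membership") else dict(partition_a)
    b = partition_b.membership if hasattr(partition_b, "membership") else dict(partition_b)
    if set(a) != set(b):
        raise ValidationError("partitions cover different element universes")
    elements = list(a)
    n = len(elements)
    if n == 0:
        raise ValidationError("empty universe")
    table: dict = {}
    row_sums: dict = {}
    col_sums: dict = {}
    for e in elements:
        key = (a[e], b[e])
        table[key] = table.get(key, 0) + 1
        row_sums[a[e]] = row_sums.get(a[e], 0) + 1
        col_sums[b[e]] = col_sums.get(b[e], 0) + 1
    sum_ij = sum(comb(v, 2, exact=True) for v in table.values())
    sum_a = sum(comb(v, 2, exact=True) for v in row_sums.values())
    sum_b = sum(comb(v, 2, exact=True) for v in col_sums.values())
    total = comb(n, 2, exact=True)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0  # both partitions trivial (all-singletons or one block)
    return float((sum_ij - expected) / (max_index - expected))
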