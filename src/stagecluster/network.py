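"""Co-expression graph construction with a permutation-calibrated threshold.

Gene profiles (transformed expression across the samples of one tissue)
are centered and scaled per gene, then all pairwise Pearson correlations
are compared against a null threshold obtained by permutation: in each of
1,000 replications every gene's values are permuted independently across
samples (destroying all between-gene correlation while preserving
marginals), the 99.995% quantile of the resulting correlations is taken,
and the threshold is the median of the replication quantiles.  Edges are
drawn for pairs whose signed correlation exceeds the threshold strictly,
and nodes with fewer than ``min_degree`` edges are removed in one pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data import NormalizedMatrix, ValidationError


@dataclass
class ScaledProfileMatrix:
    """Per-gene standardized expression profiles (mean 0, SD 1, ddof=1)."""

    values: pd.DataFrame
    dropped: list = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def scale_profiles(norm: NormalizedMatrix, genes=None) -> ScaledProfileMatrix:
    """Center and scale each gene row; constant rows are dropped with a warning."""
    values = norm.values if genes is None else norm.values.loc[list(genes)]
    if values.shape[1] < 3:
        raise ValidationError("profile scaling requires >= 3 samples")
    mat = values.to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=1)
    constant = sd == 0
    if np.any(constant):
        warnings.warn(
            f"dropping {int(constant.sum())} constant profile(s)", stacklevel=2
        )
    keep = ~constant
    scaled = (mat[keep] - mat[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return ScaledProfileMatrix(
        values=pd.DataFrame(scaled, index=values.index[keep], columns=values.columns),
        dropped=list(values.index[constant]),
    )


def _permute_rows(mat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each row across columns."""
    idx = np.argsort(rng.random(mat.shape), axis=1)
    return np.take_along_axis(mat, idx, axis=1)


def permutation_threshold(
    profiles: ScaledProfileMatrix,
    replications: int = 1000,
    quantile: float = 0.99995,
    pairs_per_rep: int = 200_000,
    seed: int = 0,
) -> float:
    """Median over replications of the null-correlation quantile.

    Per replication the standardized profile rows are permuted
    independently, Pearson correlations are computed for all gene pairs
    (or a random subset of ``pairs_per_rep`` pairs when the full set is
    larger), and the configured quantile of those correlations is taken.
    Deterministic under ``seed``.
    """
    G, n = profiles.n_genes, profiles.n_samples
    if G < 2:
        raise ValidationError("permutation threshold needs >= 2 genes")
    if not (0 < quantile < 1):
        raise ValidationError("quantile must lie in (0, 1)")
    n_pairs_total = G * (G - 1) // 2
    use_all = n_pairs_total <= pairs_per_rep
    n_pairs = n_pairs_total if use_all else pairs_per_rep
    if n_pairs < 1.0 / (1.0 - quantile):
        warnings.warn(
            f"{n_pairs} pairs per replication resolve the {quantile:.5%} "
            "quantile poorly",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    mat = profiles.values.to_numpy(dtype=float)
    iu = np.triu_indices(G, k=1) if use_all else None
    quantiles = np.empty(replications)
    for rep in range(replications):
        perm = _permute_rows(mat, rng)
        # rows stay standardized under permutation, so r = dot / (n - 1)
        if use_all:
            corr = (perm @ perm.T) / (n - 1)
            r = corr[iu]
        else:
            a = rng.integers(0, G, size=pairs_per_rep)
            b = rng.integers(0, G - 1, size=pairs_per_rep)
            b = np.where(b >= a, b + 1, b)  # b != a, uniform over off-diagonal
            r = np.einsum("ij,ij->i", perm[a], perm[b]) / (n - 1)
        quantiles[rep] = np.quantile(r, quantile)
    return float(np.median(quantiles))


@dataclass
class CoexpressionGraph:
    """Thresholded co-expression graph plus its construction parameters."""

    graph: nx.Graph
    threshold: float
    min_degree: int
    removed: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_graph(
    profiles: ScaledProfileMatrix,
    threshold: float,
    min_degree: int = 50,
    absolute: bool = False,
    iterate: bool = False,
) -> CoexpressionGraph:
    """Draw edges for pairs with r > threshold, then apply the degree filter.

    The comparison is strict and signed by default (positive co-regulation
    only); ``absolute=True`` thresholds |r| instead.  The degree filter is
    a single removal pass of all nodes below ``min_degree``;
    ``iterate=True`` repeats the pass to a fixed point.
    """
    if profiles.n_genes == 0:
        raise ValidationError("empty profile set")
    if not (-1 < threshold <= 1):
        raise ValidationError("threshold must lie in (-1, 1]")
    mat = profiles.values.to_numpy(dtype=float)
    n = profiles.n_samples
    corr = (mat @ mat.T) / (n - 1)
    crit = np.abs(corr) if absolute else corr
    np.fill_diagonal(crit, -np.inf)
    genes = list(profiles.values.index)
    g = nx.Graph()
    g.add_nodes_from(genes)
    ia, ib = np.nonzero(np.triu(crit > threshold, k=1))
    g.add_weighted_edges_from(
        (genes[i], genes[j], float(corr[i, j])) for i, j in zip(ia, ib)
    )
    removed: list = []
    while True:
        low = [v for v, d in g.degree() if d < min_degree]
        if not low:
            break
        g.remove_nodes_from(low)
        removed.extend(low)
        if not iterate:
            break
    return CoexpressionGraph(
        graph=g, threshold=threshold, min_degree=min_degree, removed=removed
    )
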