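"""Library-size normalization, log transform, expression filter, batch removal.

Size factors use the median-of-ratios estimator: for each sample, the
median over genes (expressed in every sample) of its count divided by the
gene's geometric mean across samples, rescaled so the factors have
geometric mean 1.  The variance-stabilizing transform used downstream is
the monotone surrogate ``log2(count / size_factor + 1)``; every consumer
takes the transformed matrix generically, so the transform is swappable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import CountMatrix, NormalizedMatrix, ValidationError


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, geometric mean 1.

    Raises
    ------
    ValidationError
        If no gene has strictly positive counts in every sample (the
        reference geometric means would all be zero).
    """
    mat = counts.counts.to_numpy(dtype=float)
    all_positive = np.all(mat > 0, axis=1)
    if not np.any(all_positive):
        raise ValidationError(
            "size-factor estimation requires at least one gene with "
            "positive counts in every sample"
        )
    ref = mat[all_positive]
    log_geo = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo[:, None]
    log_sf = np.median(ratios, axis=0)
    log_sf -= log_sf.mean()  # anchor geometric mean at 1
    return pd.Series(np.exp(log_sf), index=counts.sample_ids, name="size_factor")


def transform(counts: CountMatrix, size_factors: pd.Series) -> NormalizedMatrix:
    """Apply the log2(count / size_factor + 1) transform."""
    if list(size_factors.index) != list(counts.sample_ids):
        raise ValidationError("size factors do not match sample ids")
    sf = size_factors.to_numpy(dtype=float)
    if np.any(sf <= 0):
        raise ValidationError("size factors must be positive")
    values = np.log2(counts.counts.to_numpy(dtype=float) / sf[None, :] + 1.0)
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=counts.gene_ids, columns=counts.sample_ids),
        size_factors=size_factors.copy(),
        sample_meta=counts.sample_meta.copy(),
    )


def expression_filter(
    norm: NormalizedMatrix,
    threshold: float = 50.0,
    by: tuple[str, ...] | None = ("tissue", "stage"),
) -> pd.Index:
    """Genes whose mean normalized count reaches ``threshold`` somewhere.

    The mean is taken on the linear normalized scale (count / size factor)
    within each condition group; a gene is kept when its mean meets the
    threshold in at least one condition.  ``by=None`` treats every sample
    as its own group (a global per-sample filter).
    """
    linear = norm.linear_counts()
    if by is None:
        groups = pd.Series(norm.sample_ids, index=norm.sample_ids)
    else:
        cols = [norm.sample_meta[c].astype(str) for c in by]
        groups = cols[0]
        for c in cols[1:]:
            groups = groups + ":" + c
    if groups.isna().any():
        raise ValidationError("condition grouping has missing values")
    means = linear.T.groupby(groups).mean().T
    if means.shape[1] == 0:
        raise ValidationError("empty condition grouping")
    keep = (means >= threshold).any(axis=1)
    return norm.gene_ids[keep]


def remove_batch(norm: NormalizedMatrix) -> NormalizedMatrix:
    """Subtract per-gene batch offsets estimated by least squares.

    The condition design (tissue x stage) is retained in the model so only
    the batch contribution is removed; the per-gene grand mean is
    preserved.  A single batch level returns the input unchanged; a batch
    factor confounded 1:1 with condition raises.
    """
    meta = norm.sample_meta
    batches = meta["batch"].astype(str)
    levels = sorted(batches.unique())
    if len(levels) < 2:
        return NormalizedMatrix(
            values=norm.values.copy(),
            size_factors=norm.size_factors.copy(),
            sample_meta=norm.sample_meta.copy(),
        )
    condition = (meta["tissue"].astype(str) + ":" + meta["stage"].astype(str))
    cond_dummies = pd.get_dummies(condition, dtype=float)
    batch_dummies = pd.get_dummies(batches, drop_first=True, dtype=float)
    X = np.column_stack([cond_dummies.to_numpy(), batch_dummies.to_numpy()])
    rank_full = np.linalg.matrix_rank(X)
    if rank_full < X.shape[1]:
        raise ValidationError(
            "batch is confounded with tissue:stage condition; "
            "batch effect is not identifiable"
        )
    Y = norm.values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    n_cond = cond_dummies.shape[1]
    batch_effect = batch_dummies.to_numpy() @ beta[n_cond:]  # samples x genes
    batch_effect -= batch_effect.mean(axis=0, keepdims=True)  # keep grand mean
    corrected = Y - batch_effect.T
    return NormalizedMatrix(
        values=pd.DataFrame(corrected, index=norm.gene_ids, columns=norm.sample_ids),
        size_factors=norm.size_factors.copy(),
        sample_meta=norm.sample_meta.copy(),
    )
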