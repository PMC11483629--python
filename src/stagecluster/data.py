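"""Core tabular containers shared across the pipeline.

A :class:`CountMatrix` holds gene-level integer counts (genes x samples)
together with the per-sample annotations (tissue, developmental stage,
experimental batch, replicate plant).  A :class:`NormalizedMatrix` holds the
library-size-corrected, log-transformed expression values plus the size
factors that produced them.  Both validate their invariants on construction
so downstream stages can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns every sample table must provide
REQUIRED_META_COLUMNS = ("tissue", "stage", "batch", "replicate")


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate {what}: {dups[:10]}")


@dataclass
class CountMatrix:
    """Raw gene-level counts with sample annotations.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = gene ids, columns =
        sample ids.
    sample_meta
        DataFrame indexed by sample id with at least the columns
        ``tissue``, ``stage``, ``batch``, ``replicate``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_unique(self.counts.index, "gene ids")
        _check_unique(self.counts.columns, "sample ids")
        missing = [c for c in REQUIRED_META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValidationError(f"sample metadata missing columns: {missing}")
        uncovered = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if uncovered:
            raise ValidationError(
                f"metadata does not cover samples: {uncovered[:10]}"
            )
        vals = self.counts.to_numpy()
        if vals.size and (np.any(vals < 0) or np.any(vals != np.floor(vals))):
            raise ValidationError("counts must be non-negative integers")
        # keep metadata aligned to the count columns; normalize index names
        self.sample_meta = self.sample_meta.loc[self.counts.columns]
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None
        self.sample_meta.index.name = "sample_id"

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(
            counts=self.counts[sample_ids].copy(),
            sample_meta=self.sample_meta.loc[sample_ids].copy(),
        )

    def subset_tissue(self, tissue: str) -> "CountMatrix":
        keep = self.sample_meta.index[self.sample_meta["tissue"] == tissue]
        if len(keep) == 0:
            raise ValidationError(f"no samples for tissue {tissue!r}")
        return self.subset_samples(keep)

    def condition_labels(self, by=("tissue", "stage")) -> pd.Series:
        """Per-sample condition label built from metadata columns."""
        if by is None:  # every sample its own group
            return pd.Series(self.sample_ids, index=self.sample_ids)
        cols = [self.sample_meta[c].astype(str) for c in by]
        lab = cols[0]
        for c in cols[1:]:
            lab = lab + ":" + c
        return lab


@dataclass
class NormalizedMatrix:
    """Transformed expression values (log2 scale) with their size factors."""

    values: pd.DataFrame
    size_factors: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        sf = self.size_factors.to_numpy(dtype=float)
        if np.any(sf <= 0) or not np.all(np.isfinite(sf)):
            raise ValidationError("size factors must be finite and > 0")
        if list(self.size_factors.index) != list(self.values.columns):
            raise ValidationError("size-factor index must match value columns")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValidationError("normalized values must be finite")
        self.sample_meta = self.sample_meta.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def linear_counts(self) -> pd.DataFrame:
        """Normalized counts on the linear scale (count / size factor)."""
        return 2.0 ** self.values - 1.0

    def subset_samples(self, sample_ids) -> "NormalizedMatrix":
        sample_ids = list(sample_ids)
        return NormalizedMatrix(
            values=self.values[sample_ids].copy(),
            size_factors=self.size_factors.loc[sample_ids].copy(),
            sample_meta=self.sample_meta.loc[sample_ids].copy(),
        )

    def subset_tissue(self, tissue: str) -> "NormalizedMatrix":
        keep = self.sample_meta.index[self.sample_meta["tissue"] == tissue]
        if len(keep) == 0:
            raise ValidationError(f"no samples for tissue {tissue!r}")
        return self.subset_samples(keep)
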