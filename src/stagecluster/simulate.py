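"""Synthetic data generator emulating a multi-tissue, staged RNA-seq study.

The generator mirrors the design of a source--sink experiment on a storage
root crop: five tissues (source leaf, bark, wood, fibrous root, storage
root) sampled at three developmental stages of root bulking (pre-bulking
PB, early-bulking EB, during-bulking DB) with a handful of replicate plants
per stage.  Counts are negative-binomially distributed around a per-gene
baseline, scaled by per-sample library-size factors, with planted
co-expressed gene modules whose expected expression follows one of four
stage-profile templates (monotone up, monotone down, EB peak, EB dip).
Phenotype measurements (non-structural carbohydrates in mg per g dry
weight) are Gamma-distributed with a log-link mean structure, and
subcellular compartment fractions are Dirichlet-distributed compositions.

Every draw is accompanied by a :class:`SyntheticTruth` record so that
recovery of size factors, differential genes, module memberships, and
effect sizes can be tested against known ground truth.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import CountMatrix, ValidationError

DEFAULT_TISSUES = ("SoL", "Bark", "Wood", "FR", "SR")
DEFAULT_STAGES = ("PB", "EB", "DB")
DEFAULT_ANALYTES = ("glucose", "fructose", "sucrose", "starch")
DEFAULT_TEMPLATES = ("up", "down", "peak", "dip")
NAF_COMPARTMENTS = ("vacuole", "plastid", "cytosol")
NAF_SUGARS = ("glucose", "fructose", "sucrose")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study design the pipeline targets: 5 tissues x 3
    stages x 4 replicate plants, ~150-count median gene baselines, NB
    dispersions around 0.05 (well-replicated bulk RNA-seq), 4 planted
    modules of 100 genes per tissue with a 4-fold stage effect, and
    vacuole/plastid/cytosol sugar fractions near (0.40, 0.35, 0.25).
    """

    n_genes: int = 2000
    tissues: Sequence[str] = DEFAULT_TISSUES
    stages: Sequence[str] = DEFAULT_STAGES
    replicates_per_stage: int = 4
    baseline_logmean_params: tuple[float, float] = (5.0, 1.0)
    dispersion_params: tuple[float, float] = (math.log(0.05), 0.5)
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    modules_per_tissue: int = 4
    module_size: int = 100
    module_fold_change: float = 4.0
    profile_templates: Sequence[str] = DEFAULT_TEMPLATES
    batch_levels: int = 1
    batch_sd: float = 0.1
    # phenotype generator
    analytes: Sequence[str] = DEFAULT_ANALYTES
    phenotype_shape: float = 10.0
    phenotype_baseline: float = 10.0
    phenotype_fold_change: float = 4.0
    phenotype_means: Mapping[tuple[str, str, str], float] | None = None
    # NAF generator
    naf_mean: tuple[float, float, float] = (0.40, 0.35, 0.25)
    naf_concentration: float = 200.0
    naf_replicates: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if self.replicates_per_stage <= 0:
            raise ValidationError("replicates_per_stage must be positive")
        if len(self.tissues) == 0 or len(self.stages) < 2:
            raise ValidationError("need >= 1 tissue and >= 2 stages")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValidationError("size_factor_range must be a positive interval")
        if self.module_fold_change < 1:
            raise ValidationError("module_fold_change must be >= 1")
        if self.modules_per_tissue < 0 or self.module_size <= 0:
            raise ValidationError("module dimensions must be positive")
        if self.modules_per_tissue * self.module_size > self.n_genes:
            raise ValidationError(
                "modules exceed gene count: "
                f"{self.modules_per_tissue} x {self.module_size} > {self.n_genes}"
            )
        if self.batch_levels < 1:
            raise ValidationError("batch_levels must be >= 1")
        if self.phenotype_shape <= 0 or self.phenotype_baseline <= 0:
            raise ValidationError("phenotype shape and baseline must be positive")
        if self.phenotype_fold_change <= 0:
            raise ValidationError("phenotype_fold_change must be positive")
        mean = np.asarray(self.naf_mean, dtype=float)
        if np.any(mean <= 0) or abs(mean.sum() - 1.0) > 1e-9:
            raise ValidationError("naf_mean must lie on the open simplex")
        if self.naf_concentration <= 0 or self.naf_replicates < 1:
            raise ValidationError("invalid NAF concentration/replicates")
        unknown = set(self.profile_templates) - set(DEFAULT_TEMPLATES)
        if unknown:
            raise ValidationError(f"unknown profile templates: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying one synthetic draw."""

    size_factors: pd.Series | None = None
    module_membership: pd.DataFrame | None = None  # gene_id, tissue, module, template
    deg_flags: pd.DataFrame | None = None  # genes x tissues bool
    dispersions: pd.Series | None = None
    baselines: pd.Series | None = None  # per-gene expected base mean
    phenotype_means: pd.DataFrame | None = None  # tissue, stage, analyte, mean
    naf_proportions: pd.Series | None = None  # per-compartment simplex vector


def template_multipliers(template: str, n_stages: int, fold: float) -> np.ndarray:
    """Stage multipliers for one profile template.

    ``fold`` is the max/min ratio of the expected expression across stages.
    For three stages: up = (1, sqrt(f), f), down its mirror, peak = (1, f, 1)
    and dip = (f, 1, f); all multipliers are strictly positive.
    """
    t = np.linspace(0.0, 1.0, n_stages)
    if template == "up":
        expo = t
    elif template == "down":
        expo = 1.0 - t
    elif template == "peak":
        expo = 1.0 - 2.0 * np.abs(t - 0.5)
    elif template == "dip":
        expo = 2.0 * np.abs(t - 0.5)
    else:
        raise ValidationError(f"unknown template {template!r}")
    return fold**expo


def _sample_grid(config: SimConfig) -> pd.DataFrame:
    rows = []
    for tissue in config.tissues:
        for stage in config.stages:
            for rep in range(1, config.replicates_per_stage + 1):
                rows.append(
                    {
                        "sample_id": f"{tissue}_{stage}_r{rep}",
                        "tissue": tissue,
                        "stage": stage,
                        "batch": f"b{(rep - 1) % config.batch_levels + 1}",
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _draw_size_factors(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Log-uniform size factors rescaled to geometric mean 1."""
    log_sf = rng.uniform(math.log(lo), math.log(hi), size=n)
    log_sf -= log_sf.mean()
    return np.exp(log_sf)


def generate_counts(config: SimConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw an NB count matrix with planted stage-dependent modules.

    Counts follow NB(mean = size_factor x baseline x stage multiplier,
    var = mu + alpha mu^2).  Within a tissue, each planted module's genes
    share one profile template; background genes are flat across stages.
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    meta = _sample_grid(config)
    n_genes, n_samples = config.n_genes, len(meta)
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene_id")

    loc_b, scale_b = config.baseline_logmean_params
    baselines = rng.lognormal(loc_b, scale_b, size=n_genes)
    loc_d, scale_d = config.dispersion_params
    dispersions = rng.lognormal(loc_d, scale_d, size=n_genes)
    size_factors = _draw_size_factors(
        rng, n_samples, *config.size_factor_range
    )

    n_stages = len(config.stages)
    stage_index = meta["stage"].map({s: i for i, s in enumerate(config.stages)}).to_numpy()
    tissue_of_sample = meta["tissue"].to_numpy()

    # per-gene per-sample stage multiplier, default flat
    multiplier = np.ones((n_genes, n_samples))
    membership_rows = []
    effective_fold = config.module_fold_change
    for tissue in config.tissues:
        if config.modules_per_tissue == 0:
            continue
        chosen = rng.choice(
            n_genes,
            size=config.modules_per_tissue * config.module_size,
            replace=False,
        )
        cols = np.flatnonzero(tissue_of_sample == tissue)
        for k in range(config.modules_per_tissue):
            genes_k = chosen[k * config.module_size : (k + 1) * config.module_size]
            template = config.profile_templates[k % len(config.profile_templates)]
            mult = template_multipliers(template, n_stages, effective_fold)
            if effective_fold != 1.0:
                multiplier[np.ix_(genes_k, cols)] = mult[stage_index[cols]][None, :]
            for g in genes_k:
                membership_rows.append(
                    {
                        "gene_id": gene_ids[g],
                        "tissue": tissue,
                        "module": k,
                        "template": template,
                    }
                )

    mu = baselines[:, None] * multiplier * size_factors[None, :]

    if config.batch_levels > 1:
        batch_codes = meta["batch"].astype("category").cat.codes.to_numpy()
        offsets = rng.lognormal(0.0, config.batch_sd, size=(n_genes, config.batch_levels))
        mu = mu * offsets[:, batch_codes]

    r = 1.0 / np.maximum(dispersions, 1e-12)
    p = r[:, None] / (r[:, None] + mu)
    counts = rng.negative_binomial(r[:, None], p)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=meta.index)
    membership = pd.DataFrame(
        membership_rows, columns=["gene_id", "tissue", "module", "template"]
    )
    deg_flags = pd.DataFrame(
        False, index=gene_ids, columns=list(config.tissues)
    )
    if effective_fold != 1.0 and len(membership):
        for tissue, grp in membership.groupby("tissue"):
            deg_flags.loc[grp["gene_id"], tissue] = True

    truth = SyntheticTruth(
        size_factors=pd.Series(size_factors, index=meta.index, name="size_factor"),
        module_membership=membership,
        deg_flags=deg_flags,
        dispersions=pd.Series(dispersions, index=gene_ids, name="dispersion"),
        baselines=pd.Series(baselines, index=gene_ids, name="baseline"),
    )
    return CountMatrix(counts=counts_df, sample_meta=meta), truth


def default_phenotype_means(config: SimConfig) -> pd.DataFrame:
    """Expected analyte content per tissue x stage (mg per g DW).

    Emulates the qualitative pattern of storage-root bulking: all analytes
    rise ``phenotype_fold_change``-fold at the final stage in the storage
    root, wood starch declines over time, everything else is flat.
    """
    f = config.phenotype_fold_change
    n_stages = len(config.stages)
    rows = []
    for tissue in config.tissues:
        for analyte in config.analytes:
            if tissue == "SR":
                profile = config.phenotype_baseline * template_multipliers(
                    "up", n_stages, f
                )
            elif tissue == "Wood" and analyte == "starch":
                profile = config.phenotype_baseline * template_multipliers(
                    "down", n_stages, f
                )
            else:
                profile = np.full(n_stages, config.phenotype_baseline)
            for stage, mean in zip(config.stages, profile):
                if config.phenotype_means is not None:
                    mean = config.phenotype_means.get(
                        (tissue, stage, analyte), mean
                    )
                rows.append(
                    {"tissue": tissue, "stage": stage, "analyte": analyte, "mean": float(mean)}
                )
    return pd.DataFrame(rows)


def generate_phenotypes(config: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw Gamma-distributed phenotype measurements.

    Each (tissue, stage, analyte) cell yields ``replicates_per_stage``
    values from Gamma(shape = k, scale = mean / k), i.e. a log-link mean
    structure with constant shape; all values are strictly positive.
    """
    rng = np.random.default_rng(_substream(config.seed, "phenotypes"))
    means = default_phenotype_means(config)
    k = config.phenotype_shape
    rows = []
    for _, cell in means.iterrows():
        draws = rng.gamma(shape=k, scale=cell["mean"] / k, size=config.replicates_per_stage)
        for rep, val in enumerate(draws, start=1):
            rows.append(
                {
                    "tissue": cell["tissue"],
                    "stage": cell["stage"],
                    "replicate": rep,
                    "analyte": cell["analyte"],
                    "value": float(val),
                }
            )
    table = pd.DataFrame(rows)
    truth = SyntheticTruth(phenotype_means=means)
    return table, truth


def generate_naf(config: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw Dirichlet compartment fractions per sugar and replicate.

    Each replicate composition over (vacuole, plastid, cytosol) is drawn
    from Dirichlet(concentration x mean); rows sum to 1 exactly up to
    floating point.
    """
    rng = np.random.default_rng(_substream(config.seed, "naf"))
    mean = np.asarray(config.naf_mean, dtype=float)
    alpha = config.naf_concentration * mean
    rows = []
    for sugar in NAF_SUGARS:
        draws = rng.dirichlet(alpha, size=config.naf_replicates)
        for rep in range(config.naf_replicates):
            for comp, frac in zip(NAF_COMPARTMENTS, draws[rep]):
                rows.append(
                    {
                        "replicate": rep + 1,
                        "sugar": sugar,
                        "compartment": comp,
                        "fraction": float(frac),
                    }
                )
    table = pd.DataFrame(rows)
    truth = SyntheticTruth(
        naf_proportions=pd.Series(mean, index=list(NAF_COMPARTMENTS), name="proportion")
    )
    return table, truth


def _substream(seed: int, label: str) -> int:
    """Deterministic sub-seed (< 2^31) for a named generator stream."""
    tag = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed), int(tag)])
    return int(ss.generate_state(1)[0] % (2**31))
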