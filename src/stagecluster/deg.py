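"""Per-tissue negative-binomial GLM likelihood-ratio tests for stage effects.

Each gene is modelled as NB(mu, alpha) with ``var = mu + alpha mu^2``, a
log link, and a log(size factor) offset.  The stage effect is tested by a
likelihood-ratio test of the full model (stage, optionally plus batch)
against the intercept-only reduced model (plus batch), with the statistic
referred to chi^2 on ``levels(stage) - 1`` degrees of freedom.  Genes at
FDR < 0.001 (Benjamini--Hochberg) are called differentially expressed.

Dispersion estimation is deliberately simple: a per-gene method-of-moments
estimate on normalized counts, averaged over condition groups, floored at
1e-8.  There is no empirical-Bayes shrinkage; this is the main numerical
deviation from heavyweight DE packages and is acceptable here because the
pipeline's validation is calibration- and recovery-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .data import CountMatrix, ValidationError

DISPERSION_FLOOR = 1e-8


def estimate_dispersions(
    counts: CountMatrix,
    size_factors: pd.Series,
    by: tuple[str, ...] = ("stage",),
) -> pd.Series:
    """Method-of-moments NB dispersions on normalized counts.

    Per condition group with >= 2 replicates, compute ``(s^2 - m) / m^2``
    of the normalized counts and average across groups; the result is
    floored at 1e-8 (genes with no usable group, e.g. all-zero genes, sit
    at the floor).
    """
    sf = size_factors.loc[counts.sample_ids].to_numpy(dtype=float)
    x = counts.counts.to_numpy(dtype=float) / sf[None, :]
    labels = counts.condition_labels(by=by)
    est = np.zeros(counts.n_genes)
    n_groups = np.zeros(counts.n_genes)
    for _, idx in labels.groupby(labels).groups.items():
        cols = counts.sample_ids.get_indexer(idx)
        if len(cols) < 2:
            continue
        sub = x[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        contrib = np.zeros(counts.n_genes)
        contrib[ok] = (v[ok] - m[ok]) / m[ok] ** 2
        est += np.where(ok, contrib, 0.0)
        n_groups += ok
    if not np.any(n_groups > 0):
        raise ValidationError("dispersion estimation needs a condition with >= 2 replicates")
    with np.errstate(invalid="ignore"):
        alpha = np.where(n_groups > 0, est / np.maximum(n_groups, 1), DISPERSION_FLOOR)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=counts.gene_ids, name="dispersion")


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB log-likelihood with var = mu + alpha mu^2."""
    r = 1.0 / max(alpha, DISPERSION_FLOOR)
    mu = np.maximum(mu, 1e-12)
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return float(ll.sum())


@dataclass
class NBFit:
    """Result of one NB GLM fit."""

    coef: np.ndarray
    loglik: float
    fitted: np.ndarray
    converged: bool
    n_iter: int


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    size_factors: np.ndarray,
    dispersion: float,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> NBFit:
    """Fit an NB GLM with log link and log(size factor) offset by IRLS.

    The design must be full rank.  Convergence is declared when the
    log-likelihood change falls below ``tol`` (relative); non-convergence
    is flagged and callers exclude such genes from DEG calls.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    offset = np.log(np.asarray(size_factors, dtype=float))
    alpha = max(float(dispersion), DISPERSION_FLOOR)

    mu = np.clip((y + y.mean()) / 2.0, 1e-4, None)
    eta = np.log(mu)
    beta, *_ = np.linalg.lstsq(X, eta - offset, rcond=None)
    ll_old = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        eta = X @ beta + offset
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        beta = beta_new
        mu = np.exp(np.clip(X @ beta + offset, -30.0, 30.0))
        ll = nb_loglik(y, mu, alpha)
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return NBFit(coef=beta, loglik=ll_old, fitted=mu, converged=converged, n_iter=it)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini--Hochberg step-up adjustment.

    NaN entries are passed through and excluded from the number of tests.
    Raises for values outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[mask] = adj
    return out


def lrt_stage(
    counts: CountMatrix,
    tissue: str | None = None,
    include_batch: bool = False,
    fdr_threshold: float = 0.001,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Stage-effect LRT for every gene of one tissue.

    Full model: stage (+ batch); reduced model: intercept (+ batch).  The
    statistic ``2 (l_full - l_reduced)`` is referred to chi^2 with
    ``levels(stage) - 1`` df, p-values are BH-adjusted, and ``is_deg``
    marks genes below ``fdr_threshold``.  Per-stage mean normalized counts
    are reported alongside.
    """
    cm = counts.subset_tissue(tissue) if tissue is not None else counts
    stages = cm.sample_meta["stage"].astype(str)
    stage_levels = list(pd.unique(stages))
    if len(stage_levels) < 2:
        raise ValidationError("stage factor needs >= 2 levels with samples")
    if size_factors is None:
        from .normalize import estimate_size_factors

        size_factors = estimate_size_factors(cm)
    sf = size_factors.loc[cm.sample_ids].to_numpy(dtype=float)
    if dispersions is None:
        by = ("stage", "batch") if include_batch else ("stage",)
        dispersions = estimate_dispersions(cm, size_factors.loc[cm.sample_ids], by=by)
    alphas = dispersions.loc[cm.gene_ids].to_numpy(dtype=float)

    n = cm.n_samples
    intercept = np.ones((n, 1))
    stage_dummies = pd.get_dummies(stages, dtype=float)[stage_levels].to_numpy()[:, 1:]
    blocks_full = [intercept, stage_dummies]
    blocks_red = [intercept]
    if include_batch:
        batch_dummies = pd.get_dummies(
            cm.sample_meta["batch"].astype(str), drop_first=True, dtype=float
        ).to_numpy()
        blocks_full.append(batch_dummies)
        blocks_red.append(batch_dummies)
    X_full = np.column_stack(blocks_full)
    X_red = np.column_stack(blocks_red)
    df = len(stage_levels) - 1

    mat = cm.counts.to_numpy(dtype=float)
    norm_counts = mat / sf[None, :]
    stage_means = {
        s: norm_counts[:, (stages == s).to_numpy()].mean(axis=1) for s in stage_levels
    }

    stats = np.full(cm.n_genes, np.nan)
    pvals = np.full(cm.n_genes, np.nan)
    flags = np.zeros(cm.n_genes, dtype=bool)
    for i in range(cm.n_genes):
        y = mat[i]
        if y.sum() == 0:
            continue  # all-zero gene: p = NA, never a DEG
        full = fit_nb_glm(y, X_full, sf, alphas[i])
        red = fit_nb_glm(y, X_red, sf, alphas[i])
        if not (full.converged and red.converged):
            flags[i] = True
            continue
        stats[i] = max(2.0 * (full.loglik - red.loglik), 0.0)
        pvals[i] = chi2.sf(stats[i], df)

    fdr = adjust_fdr(pvals)
    table = pd.DataFrame(
        {
            "stat": stats,
            "df": df,
            "pvalue": pvals,
            "fdr": fdr,
            "is_deg": (fdr < fdr_threshold) & ~np.isnan(fdr),
            "nonconverged": flags,
        },
        index=cm.gene_ids,
    )
    for s in stage_levels:
        table[f"mean_{s}"] = stage_means[s]
    return table
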