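"""Phenotype statistics: Gamma GLM, type-II ANOVA, Tukey letters, NAF model.

Non-structural-carbohydrate measurements (strictly positive, mg per g dry
weight) are modelled per tissue x analyte by a Gamma GLM with a log link;
the stage effect is tested by a type-II ANOVA (for the single-factor model
this is the full-vs-intercept likelihood-ratio test on the scaled
deviance), p-values are BH-adjusted across all models, and significant
models receive a Tukey-HSD compact letter display computed on the link
scale.  Subcellular compartment fractions from non-aqueous fractionation
are tested per sugar with an ordinary linear model followed by the same
Tukey letter machinery.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, studentized_range

from .data import ValidationError
from .deg import adjust_fdr


@dataclass
class GammaFit:
    """Fitted Gamma GLM for one factor, treatment-coded with intercept."""

    result: object  # statsmodels GLMResults
    levels: list
    values: np.ndarray
    groups: np.ndarray

    @property
    def dispersion(self) -> float:
        """Pearson chi^2 / df estimate of the Gamma dispersion."""
        return float(self.result.scale)

    def level_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Link-scale estimated means per level and their covariance."""
        k = len(self.levels)
        L = np.zeros((k, k))
        L[:, 0] = 1.0
        for i in range(1, k):
            L[i, i] = 1.0
        means = L @ self.result.params
        cov = L @ self.result.cov_params() @ L.T
        return means, cov


def fit_gamma_glm(values, groups) -> GammaFit:
    """Fit value ~ factor with a Gamma family and log link (IRLS).

    Raises for non-positive values, naming the offending rows.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape:
        raise ValidationError("values and groups must align")
    bad = np.flatnonzero(~(y > 0))
    if bad.size:
        raise ValidationError(
            f"Gamma GLM requires strictly positive values; offending rows: {bad[:10].tolist()}"
        )
    levels = list(pd.unique(g))
    if len(levels) < 1:
        raise ValidationError("no factor levels")
    X = np.ones((y.size, len(levels)))
    for i, lev in enumerate(levels[1:], start=1):
        X[:, i] = (g == lev).astype(float)
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    result = model.fit()
    return GammaFit(result=result, levels=levels, values=y, groups=g)


def anova_typeII(fit: GammaFit) -> pd.DataFrame:
    """Type-II test of the factor: likelihood-ratio chi^2 on scaled deviance.

    For the single-factor model this reduces to the full-vs-intercept
    test; the statistic is the deviance difference divided by the full
    model's Pearson dispersion, referred to chi^2 with (levels - 1) df.
    """
    k = len(fit.levels)
    if k < 2:
        raise ValidationError("type-II ANOVA needs >= 2 factor levels")
    reduced = sm.GLM(
        fit.values,
        np.ones((fit.values.size, 1)),
        family=sm.families.Gamma(link=sm.families.links.Log()),
    ).fit()
    phi = fit.dispersion
    stat = max((reduced.deviance - fit.result.deviance) / phi, 0.0)
    df = k - 1
    p = float(chi2.sf(stat, df))
    return pd.DataFrame(
        [{"term": "group", "stat": stat, "df": df, "pvalue": p}]
    )


def fdr_across_models(p_values) -> np.ndarray:
    """BH adjustment across a family of per-model ANOVA p-values."""
    return adjust_fdr(p_values)


def _pairwise_tukey(means: np.ndarray, cov: np.ndarray, df_resid: float, k: int):
    """Tukey-HSD p-values for all level pairs from link-scale means."""
    pvals = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(cov[i, i] + cov[j, j] - 2.0 * cov[i, j])
            if se == 0:
                p = 0.0 if means[i] != means[j] else 1.0
            else:
                q = abs(means[i] - means[j]) / se * np.sqrt(2.0)
                p = float(studentized_range.sf(q, k, df_resid))
            pvals[i, j] = pvals[j, i] = p
    return pvals


def letters_from_significance(levels, sig: np.ndarray, order=None) -> dict:
    """Compact letter display by insert-and-absorb.

    ``sig[i, j]`` is True when levels i and j differ significantly.  The
    returned mapping satisfies: two levels share a letter iff they are not
    significantly different (the final columns are exactly the maximal
    cliques of the non-significance graph).
    """
    k = len(levels)
    columns: list[set] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            new_cols = []
            for col in columns:
                if i in col and j in col:
                    new_cols.append(col - {i})
                    new_cols.append(col - {j})
                else:
                    new_cols.append(col)
            # drop duplicates and absorbed (subset) columns
            uniq = []
            for col in new_cols:
                if col and not any(col < other or col == other for other in uniq):
                    uniq = [o for o in uniq if not o < col]
                    uniq.append(col)
            columns = uniq
    if order is None:
        order = list(range(k))
    columns.sort(key=lambda col: (min(order.index(i) for i in col), -len(col), sorted(col)))
    letters = {lev: "" for lev in levels}
    alphabet = string.ascii_lowercase
    for idx, col in enumerate(columns):
        ch = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for i in sorted(col):
            letters[levels[i]] += ch
    _check_letters(levels, letters, sig)
    return letters


def _check_letters(levels, letters: dict, sig: np.ndarray) -> None:
    """Verify the iff-invariant of the letter display against ``sig``."""
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            share = bool(set(letters[levels[i]]) & set(letters[levels[j]]))
            if share == bool(sig[i, j]):
                raise AssertionError(
                    f"letter display violates significance structure for "
                    f"({levels[i]}, {levels[j]})"
                )


def tukey_letters(fit: GammaFit, alpha: float = 0.05) -> dict:
    """Compact letter display from Tukey-HSD contrasts on the link scale.

    Pairwise p-values use the studentized range distribution with the
    model's residual df; levels sharing a letter are not significantly
    different at ``alpha``.
    """
    k = len(fit.levels)
    if k < 2:
        raise ValidationError("letter display needs >= 2 levels")
    means, cov = fit.level_means()
    df_resid = float(fit.result.df_resid)
    pvals = _pairwise_tukey(means, cov, df_resid, k)
    sig = pvals <= alpha
    np.fill_diagonal(sig, False)
    order = list(np.argsort(-means, kind="mergesort"))
    return letters_from_significance(fit.levels, sig, order=order)


def tukey_pvalues(fit: GammaFit) -> pd.DataFrame:
    """All pairwise Tukey-HSD p-values (long format)."""
    means, cov = fit.level_means()
    pvals = _pairwise_tukey(means, cov, float(fit.result.df_resid), len(fit.levels))
    rows = []
    for i in range(len(fit.levels)):
        for j in range(i + 1, len(fit.levels)):
            rows.append(
                {"level_a": fit.levels[i], "level_b": fit.levels[j], "pvalue": pvals[i, j]}
            )
    return pd.DataFrame(rows)


def phenotype_anova(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Gamma-GLM stage ANOVA per tissue x analyte with cross-model FDR.

    Returns one row per model with the ANOVA p-value, the BH-adjusted
    value across all models, and Tukey letters (joined per stage as
    ``stage=letters``) for models passing the FDR gate.
    """
    required = {"tissue", "stage", "replicate", "analyte", "value"}
    if not required.issubset(table.columns):
        raise ValidationError(f"phenotype table needs columns {sorted(required)}")
    rows = []
    fits = []
    for (tissue, analyte), grp in table.groupby(["tissue", "analyte"], sort=True):
        fit = fit_gamma_glm(grp["value"].to_numpy(), grp["stage"].to_numpy())
        p = float(anova_typeII(fit)["pvalue"].iloc[0])
        rows.append({"tissue": tissue, "analyte": analyte, "pvalue": p})
        fits.append(fit)
    out = pd.DataFrame(rows)
    out["fdr"] = fdr_across_models(out["pvalue"].to_numpy())
    out["significant"] = out["fdr"] < alpha
    letter_col = []
    for fit, sig in zip(fits, out["significant"]):
        if sig:
            letters = tukey_letters(fit, alpha=alpha)
            letter_col.append(";".join(f"{lev}={letters[lev]}" for lev in fit.levels))
        else:
            letter_col.append("")
    out["letters"] = letter_col
    return out


def naf_test(naf: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Linear model on compartment fractions per sugar, with Tukey letters.

    Per sugar: OLS ``fraction ~ compartment``, ANOVA F p-value, BH across
    sugars, and a compact letter display for significant models.  The
    per-(replicate, sugar) fractions must sum to 1 within 1e-9.
    """
    required = {"replicate", "sugar", "compartment", "fraction"}
    if not required.issubset(naf.columns):
        raise ValidationError(f"NAF table needs columns {sorted(required)}")
    sums = naf.groupby(["replicate", "sugar"])["fraction"].sum()
    off = sums[(sums - 1.0).abs() > 1e-9]
    if len(off):
        raise ValidationError(
            f"fractions do not sum to 1 for: {off.index.tolist()[:5]}"
        )
    rows = []
    fits = []
    for sugar, grp in naf.groupby("sugar", sort=True):
        levels = list(pd.unique(grp["compartment"]))
        y = grp["fraction"].to_numpy(dtype=float)
        g = grp["compartment"].to_numpy()
        X = np.ones((y.size, len(levels)))
        for i, lev in enumerate(levels[1:], start=1):
            X[:, i] = (g == lev).astype(float)
        res = sm.OLS(y, X).fit()
        p = float(res.f_pvalue) if len(levels) > 1 else np.nan
        rows.append({"sugar": sugar, "pvalue": p})
        fits.append((res, levels))
    out = pd.DataFrame(rows)
    out["fdr"] = fdr_across_models(out["pvalue"].to_numpy())
    out["significant"] = out["fdr"] < alpha
    letter_col = []
    for (res, levels), sig in zip(fits, out["significant"]):
        if not sig:
            letter_col.append("")
            continue
        k = len(levels)
        L = np.zeros((k, k))
        L[:, 0] = 1.0
        for i in range(1, k):
            L[i, i] = 1.0
        means = L @ res.params
        cov = L @ res.cov_params() @ L.T
        pvals = _pairwise_tukey(means, cov, float(res.df_resid), k)
        sig_mat = pvals <= alpha
        np.fill_diagonal(sig_mat, False)
        order = list(np.argsort(-means, kind="mergesort"))
        letters = letters_from_significance(levels, sig_mat, order=order)
        letter_col.append(";".join(f"{lev}={letters[lev]}" for lev in levels))
    out["letters"] = letter_col
    return out
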