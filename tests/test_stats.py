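"""Gamma GLM fitting, type-II ANOVA, Tukey compact letters, NAF model."""

import numpy as np
import pandas as pd
import pytest

import stagecluster as sc
from stagecluster.stats import (
    _pairwise_tukey,
    anova_typeII,
    letters_from_significance,
    tukey_pvalues,
)


def brute_force_letters(levels, sig):
    """Independent oracle: all maximal cliques of the non-significance graph."""
    k = len(levels)
    cliques = []
    for mask in range(1, 1 << k):
        members = [i for i in range(k) if mask >> i & 1]
        if any(sig[i][j] for i in members for j in members if i < j):
            continue
        cliques.append(set(members))
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    return {frozenset(c) for c in maximal}


class TestGammaGLM:
    def test_one_group_intercept_is_log_mean(self):
        y = np.array([2.0, 4.0, 9.0, 5.0])
        fit = sc.fit_gamma_glm(y, np.array(["A"] * 4))
        assert fit.result.params[0] == pytest.approx(np.log(y.mean()), abs=1e-8)

    def test_effect_recovery(self):
        rng = np.random.default_rng(7)
        y = np.concatenate([rng.gamma(10, 1.0, 100), rng.gamma(10, 2.0, 100)])
        g = np.array(["A"] * 100 + ["B"] * 100)
        fit = sc.fit_gamma_glm(y, g)
        assert fit.result.params[1] == pytest.approx(np.log(2), rel=0.10)

    def test_zero_value_rejected(self):
        with pytest.raises(sc.ValidationError, match="positive"):
            sc.fit_gamma_glm(np.array([1.0, 0.0, 2.0]), np.array(["A", "A", "B"]))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        y = rng.gamma(10, 2.0, 60)
        g = np.repeat(["A", "B", "C"], 20)
        f1 = sc.fit_gamma_glm(y, g)
        f2 = sc.fit_gamma_glm(y * 7.0, g)
        assert f2.result.params[0] == pytest.approx(f1.result.params[0] + np.log(7), abs=1e-6)
        assert np.allclose(f2.result.params[1:], f1.result.params[1:], atol=1e-6)
        p1 = float(anova_typeII(f1)["pvalue"].iloc[0])
        p2 = float(anova_typeII(f2)["pvalue"].iloc[0])
        assert p1 == pytest.approx(p2, abs=1e-8)


class TestANOVA:
    def test_identical_groups_null(self):
        y = np.tile([5.0, 6.0, 7.0, 8.0], 2)  # groups share the same values
        g = np.repeat(["A", "B"], 4)
        fit = sc.fit_gamma_glm(y, g)
        out = anova_typeII(fit)
        assert out["stat"].iloc[0] == pytest.approx(0.0, abs=1e-8)
        assert out["pvalue"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_single_factor_equals_full_vs_intercept_lrt(self):
        import statsmodels.api as sm
        from scipy.stats import chi2

        rng = np.random.default_rng(9)
        y = np.concatenate([rng.gamma(10, 1.0, 15), rng.gamma(10, 1.6, 15)])
        g = np.repeat(["A", "B"], 15)
        fit = sc.fit_gamma_glm(y, g)
        reduced = sm.GLM(
            y, np.ones((30, 1)), family=sm.families.Gamma(sm.families.links.Log())
        ).fit()
        stat = (reduced.deviance - fit.result.deviance) / fit.dispersion
        expected = float(chi2.sf(stat, 1))
        assert float(anova_typeII(fit)["pvalue"].iloc[0]) == pytest.approx(expected)

    def test_null_calibration_quick(self):
        rng_hits = 0
        n_sims = 200
        for s in range(n_sims):
            r = np.random.default_rng(40_000 + s)
            y = r.gamma(10, 1.0, 150)
            g = np.repeat(["A", "B", "C"], 50)
            p = float(anova_typeII(sc.fit_gamma_glm(y, g))["pvalue"].iloc[0])
            rng_hits += p < 0.05
        assert 0.01 <= rng_hits / n_sims <= 0.10


class TestLetters:
    def test_separated_groups_distinct_letters(self):
        rng = np.random.default_rng(1)
        y = np.concatenate(
            [rng.gamma(200, m / 200, 10) for m in (1.0, 10.0, 100.0)]
        )
        g = np.repeat(["lo", "mid", "hi"], 10)
        letters = sc.tukey_letters(sc.fit_gamma_glm(y, g))
        assert len({letters[k] for k in ("lo", "mid", "hi")}) == 3

    def test_identical_groups_share_letter(self):
        rng = np.random.default_rng(2)
        y = rng.gamma(10, 1.0, 30)
        g = np.repeat(["A", "B", "C"], 10)
        letters = sc.tukey_letters(sc.fit_gamma_glm(y, g))
        assert set(letters["A"]) & set(letters["B"]) & set(letters["C"])

    def test_insert_absorb_equals_maximal_cliques(self):
        # random significance patterns, letters vs brute-force cliques
        rng = np.random.default_rng(3)
        for _ in range(200):
            k = int(rng.integers(2, 6))
            sig = np.zeros((k, k), dtype=bool)
            for i in range(k):
                for j in range(i + 1, k):
                    sig[i, j] = sig[j, i] = rng.random() < 0.4
            levels = [f"L{i}" for i in range(k)]
            letters = letters_from_significance(levels, sig)
            groups = {}
            for i, lev in enumerate(levels):
                for ch in letters[lev]:
                    groups.setdefault(ch, set()).add(i)
            assert {frozenset(g) for g in groups.values()} == brute_force_letters(
                levels, sig
            )

    def test_pairwise_p_symmetric(self):
        rng = np.random.default_rng(4)
        y = rng.gamma(10, 1.0, 40)
        g = np.repeat(["A", "B", "C", "D"], 10)
        fit = sc.fit_gamma_glm(y, g)
        tab = tukey_pvalues(fit)
        assert ((tab["pvalue"] >= 0) & (tab["pvalue"] <= 1)).all()
        assert len(tab) == 6


class TestPhenotypeAnova:
    def test_detects_planted_stage_effect(self):
        cfg = sc.SimConfig(replicates_per_stage=6, phenotype_fold_change=6.0, seed=3)
        ph, _ = sc.generate_phenotypes(cfg)
        out = sc.phenotype_anova(ph)
        sr = out[out["tissue"] == "SR"]
        assert sr["significant"].all()
        assert (sr["letters"] != "").all()
        flat = out[(out["tissue"] == "SoL")]
        assert not flat["significant"].all() or (out["fdr"] >= out["pvalue"] - 1e-12).all()

    def test_fdr_at_least_pvalue(self):
        cfg = sc.SimConfig(seed=5)
        ph, _ = sc.generate_phenotypes(cfg)
        out = sc.phenotype_anova(ph)
        assert (out["fdr"] >= out["pvalue"] - 1e-12).all()


class TestNAF:
    def test_forced_separation(self):
        rows = []
        rng = np.random.default_rng(6)
        for rep in range(1, 8):
            fr = np.array([0.40, 0.35, 0.25]) + rng.normal(0, 1e-3, 3)
            fr /= fr.sum()
            for comp, f in zip(("vacuole", "plastid", "cytosol"), fr):
                rows.append(
                    {"replicate": rep, "sugar": "sucrose", "compartment": comp, "fraction": f}
                )
        out = sc.naf_test(pd.DataFrame(rows))
        letters = dict(
            item.split("=") for item in out["letters"].iloc[0].split(";")
        )
        assert not set(letters["vacuole"]) & set(letters["cytosol"])

    def test_equal_compartments_share_letter(self):
        rows = []
        rng = np.random.default_rng(7)
        for rep in range(1, 8):
            fr = np.full(3, 1 / 3) + rng.normal(0, 1e-4, 3)
            fr /= fr.sum()
            for comp, f in zip(("vacuole", "plastid", "cytosol"), fr):
                rows.append(
                    {"replicate": rep, "sugar": "glucose", "compartment": comp, "fraction": f}
                )
        out = sc.naf_test(pd.DataFrame(rows))
        assert not out["significant"].iloc[0] or len(set(out["letters"].iloc[0])) > 0

    def test_simplex_violation_rejected(self):
        rows = [
            {"replicate": 1, "sugar": "glucose", "compartment": c, "fraction": 0.5}
            for c in ("vacuole", "plastid", "cytosol")
        ]
        with pytest.raises(sc.ValidationError, match="sum to 1"):
            sc.naf_test(pd.DataFrame(rows))

    def test_generated_naf_letters_match_truth_ordering(self):
        cfg = sc.SimConfig(naf_concentration=5000.0, seed=8)
        naf, _ = sc.generate_naf(cfg)
        out = sc.naf_test(naf)
        assert out["significant"].all()
        for s in out["letters"]:
            letters = dict(item.split("=") for item in s.split(";"))
            assert not set(letters["vacuole"]) & set(letters["cytosol"])
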