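"""Size factors, the log transform, the expression filter, batch removal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import stagecluster as sc
from tests.conftest import make_count_matrix


class TestSizeFactors:
    def test_exact_doubling(self):
        a = np.array([[10], [20], [30], [40]])
        cm = make_count_matrix(np.hstack([a, 2 * a]), stages=["PB", "PB"])
        sf = sc.estimate_size_factors(cm)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)

    def test_identical_samples_give_unit_factors(self):
        a = np.array([[10], [20], [30]])
        cm = make_count_matrix(np.hstack([a, a, a]), stages=["PB", "EB", "DB"])
        assert np.allclose(sc.estimate_size_factors(cm), 1.0)

    def test_no_universally_expressed_gene_errors(self):
        cm = make_count_matrix(np.array([[0, 5], [5, 0]]), stages=["PB", "EB"])
        with pytest.raises(sc.ValidationError, match="positive counts in every sample"):
            sc.estimate_size_factors(cm)

    def test_recovery_on_generated_data(self):
        cfg = sc.SimConfig(
            n_genes=1000, tissues=("SR",), replicates_per_stage=4,
            modules_per_tissue=0, seed=9,
        )
        cm, truth = sc.generate_counts(cfg)
        sf = sc.estimate_size_factors(cm)
        rel = np.abs(sf.to_numpy() / truth.size_factors.to_numpy() - 1)
        assert rel.max() < 0.10

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(c=st.floats(min_value=0.2, max_value=5.0))
    def test_scaling_equivariance(self, c):
        # scaling one sample's counts by c scales its factor by c relative
        # to the others (geometric-mean anchoring rescales all uniformly)
        rng = np.random.default_rng(0)
        base = rng.integers(5, 200, size=(400, 6))
        cm = make_count_matrix(base, stages=["PB"] * 3 + ["EB"] * 3)
        sf0 = sc.estimate_size_factors(cm).to_numpy()
        scaled = base.astype(float).copy()
        scaled[:, 2] = np.floor(scaled[:, 2] * c)
        cm2 = make_count_matrix(scaled.astype(int), stages=["PB"] * 3 + ["EB"] * 3)
        sf1 = sc.estimate_size_factors(cm2).to_numpy()
        ratios = sf1 / sf0
        others = np.delete(ratios, 2)
        assert np.allclose(others, others[0], rtol=0.05)
        assert ratios[2] / others[0] == pytest.approx(c, rel=0.1)


class TestTransform:
    def test_closed_forms(self):
        cm = make_count_matrix(np.array([[0, 7], [3, 1]]), stages=["PB", "EB"])
        sf = pd.Series([1.0, 1.0], index=cm.sample_ids)
        norm = sc.transform(cm, sf)
        assert norm.values.iloc[0, 0] == 0.0
        assert norm.values.iloc[0, 1] == pytest.approx(3.0)  # log2(7+1)

    def test_size_factor_monotonicity(self):
        counts = np.array([[4, 4], [9, 9], [19, 19]])
        cm = make_count_matrix(counts, stages=["PB", "EB"])
        lo = sc.transform(cm, pd.Series([1.0, 1.0], index=cm.sample_ids))
        hi = sc.transform(cm, pd.Series([1.0, 2.0], index=cm.sample_ids))
        # doubling a sample's size factor lowers its values, order preserved
        assert (hi.values.iloc[:, 1] < lo.values.iloc[:, 1]).all()
        assert hi.values.iloc[:, 1].is_monotonic_increasing

    def test_round_trip_linear_counts(self):
        cm = make_count_matrix(np.array([[0, 7], [3, 1]]), stages=["PB", "EB"])
        sf = pd.Series([0.5, 2.0], index=cm.sample_ids)
        norm = sc.transform(cm, sf)
        expected = cm.counts.to_numpy() / sf.to_numpy()[None, :]
        assert np.allclose(norm.linear_counts(), expected)


class TestExpressionFilter:
    def _norm(self, counts, stages):
        cm = make_count_matrix(counts, stages=stages)
        sf = pd.Series(1.0, index=cm.sample_ids)
        return sc.transform(cm, sf)

    def test_all_zero_gene_excluded(self):
        norm = self._norm(np.array([[0, 0, 0, 0], [60, 60, 60, 60]]),
                          ["PB", "PB", "EB", "EB"])
        kept = sc.expression_filter(norm, threshold=50)
        assert list(kept) == ["g1"]

    def test_boundary_mean_included(self):
        # mean exactly 50 in one condition, 0 elsewhere -> included
        norm = self._norm(np.array([[40, 60, 0, 0]]), ["PB", "PB", "EB", "EB"])
        assert list(sc.expression_filter(norm, threshold=50)) == ["g0"]

    def test_zero_threshold_keeps_all(self):
        norm = self._norm(np.array([[0, 0], [1, 0]]), ["PB", "EB"])
        assert len(sc.expression_filter(norm, threshold=0)) == 2

    def test_per_sample_grouping(self):
        # by=None: each sample its own condition
        norm = self._norm(np.array([[100, 0, 0, 0]]), ["PB", "PB", "EB", "EB"])
        assert list(sc.expression_filter(norm, threshold=60, by=None)) == ["g0"]


class TestRemoveBatch:
    def test_single_batch_is_identity(self):
        cm = make_count_matrix(np.array([[5, 9, 14, 2]]), stages=["PB"] * 4)
        norm = sc.transform(cm, pd.Series(1.0, index=cm.sample_ids))
        out = sc.remove_batch(norm)
        pd.testing.assert_frame_equal(out.values, norm.values)

    def test_additive_offset_removed_exactly(self):
        # noiseless gene + condition structure, pure +delta on batch 2:
        # the batch coefficient is exactly identified and removed
        rng = np.random.default_rng(1)
        gene_level = rng.normal(8, 1, size=(50, 1))
        stage_effect = rng.normal(0, 1, size=(50, 1))
        is_eb = np.array([0, 0, 1, 1, 0, 0, 1, 1], dtype=float)
        base = gene_level + stage_effect * is_eb[None, :]
        delta = 1.5
        shifted = base.copy()
        shifted[:, 4:] += delta  # batch 2 offset, balanced over stages
        stages = ["PB", "PB", "EB", "EB"] * 2
        batches = ["b1"] * 4 + ["b2"] * 4
        cm = make_count_matrix(np.ones((50, 8), dtype=int), stages=stages, batches=batches)
        norm = sc.NormalizedMatrix(
            values=pd.DataFrame(shifted, index=cm.gene_ids, columns=cm.sample_ids),
            size_factors=pd.Series(1.0, index=cm.sample_ids),
            sample_meta=cm.sample_meta,
        )
        out = sc.remove_batch(norm)
        centered = base + delta / 2  # grand mean preserved
        assert np.allclose(out.values.to_numpy(), centered, atol=1e-8)

    def test_batchwise_means_align_after_adjustment(self):
        cfg = sc.SimConfig(
            n_genes=200, tissues=("SR",), replicates_per_stage=4,
            modules_per_tissue=0, batch_levels=2, batch_sd=0.3, seed=4,
        )
        cm, _ = sc.generate_counts(cfg)
        norm = sc.transform(cm, sc.estimate_size_factors(cm))
        out = sc.remove_batch(norm)
        # residual batch effect after accounting for condition ~ 0
        meta = out.sample_meta
        resid = out.values.copy()
        cond = meta["tissue"].astype(str) + ":" + meta["stage"].astype(str)
        for c in cond.unique():
            cols = meta.index[cond == c]
            resid[cols] = resid[cols].sub(resid[cols].mean(axis=1), axis=0)
        b1 = meta.index[meta["batch"] == "b1"]
        b2 = meta.index[meta["batch"] == "b2"]
        gap = (resid[b1].mean(axis=1) - resid[b2].mean(axis=1)).abs()
        assert gap.max() < 1e-8

    def test_confounded_batch_errors(self):
        stages = ["PB", "PB", "EB", "EB"]
        batches = ["b1", "b1", "b2", "b2"]  # batch == stage
        cm = make_count_matrix(np.ones((3, 4), dtype=int), stages=stages, batches=batches)
        norm = sc.transform(cm, pd.Series(1.0, index=cm.sample_ids))
        with pytest.raises(sc.ValidationError, match="confounded"):
            sc.remove_batch(norm)
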