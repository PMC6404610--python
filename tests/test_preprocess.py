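"""Normalization, variance filtering, VST and surrogate-variable removal."""

import math

import numpy as np
import pandas as pd
import pytest

import coexnet as cx
from coexnet.preprocess import ExpressionMatrix


def frame(values, genes=None, samples=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = frame([[10, 10], [5, 5], [100, 100]])
        assert np.allclose(cx.size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_matches_hand_computation(self):
        """sample2 = 2 x sample1: geometric-mean reference gives factors
        (1/sqrt(2), sqrt(2))."""
        counts = frame([[10, 20], [4, 8], [100, 200]])
        f = cx.size_factors(counts)
        assert f.to_numpy() == pytest.approx([1 / math.sqrt(2), math.sqrt(2)])

    def test_scale_equivariance_of_factor_ratios(self):
        """Scaling one sample's counts by c scales its factor relative
        to every other sample by exactly c (all factors also shift by
        the common geometric-mean renormalization c^(-1/n), so the
        normalized counts of the other samples are unchanged up to a
        global constant)."""
        rng = np.random.default_rng(0)
        counts = frame(rng.integers(1, 500, size=(40, 6)))
        base = cx.size_factors(counts)
        scaled = counts.copy()
        scaled.iloc[:, 2] *= 7
        f = cx.size_factors(scaled)
        ratios = (f / base).to_numpy()
        assert ratios[2] / ratios[0] == pytest.approx(7.0)
        others = [i for i in range(6) if i != 2]
        assert np.allclose(ratios[others], ratios[0])
        assert ratios[0] == pytest.approx(7 ** (-1 / 6))

    def test_no_reference_gene_names_samples(self):
        counts = frame([[0, 5], [3, 0]], samples=["sampleA", "sampleB"])
        with pytest.raises(ValueError, match="sample"):
            cx.size_factors(counts)


class TestVst:
    def test_closed_form_values(self):
        counts = frame([[0, 7]], samples=["a", "b"])
        out = cx.vst(counts, pd.Series([1.0, 1.0], index=["a", "b"]))
        assert out.data.iloc[0, 0] == 0.0
        assert out.data.iloc[0, 1] == pytest.approx(3.0)  # log2(8)
        assert out.transform_log[-1].startswith("vst:")

    def test_monotone_and_finite(self):
        rng = np.random.default_rng(1)
        counts = frame(np.sort(rng.integers(0, 10000, size=(1, 50))))
        out = cx.vst(counts, pd.Series(np.ones(50), index=counts.columns))
        row = out.data.iloc[0].to_numpy()
        assert np.isfinite(row).all() and (np.diff(row) >= 0).all()

    def test_variance_stabilized_for_nb_counts(self):
        """Across mean bins of NB-simulated genes with large means, the
        VST variance shows no systematic trend with the mean."""
        rng = np.random.default_rng(2)
        means = np.exp(rng.uniform(np.log(200), np.log(5000), size=400))
        alpha = 0.05
        n = 1 / alpha
        counts = rng.negative_binomial(n, n / (n + means[:, None]), size=(400, 60))
        out = cx.vst(frame(counts), pd.Series(np.ones(60), index=[f"s{j}" for j in range(60)]))
        v = out.data.var(axis=1).to_numpy()
        m = out.data.mean(axis=1).to_numpy()
        slope = np.polyfit(m, v, 1)[0]
        assert abs(slope) < 0.05


class TestFilterLowVariance:
    def test_retains_ceil_fraction(self):
        rng = np.random.default_rng(3)
        expr = ExpressionMatrix(frame(rng.standard_normal((10, 8))))
        out = cx.filter_low_variance(expr, 0.4)
        assert out.data.shape[0] == 6
        assert "filter_low_variance" in out.transform_log[-1]

    def test_constant_gene_dropped(self):
        values = np.vstack([np.random.default_rng(4).standard_normal((5, 8)),
                            np.zeros((1, 8))])
        expr = ExpressionMatrix(frame(values))
        out = cx.filter_low_variance(expr, 0.3)
        assert "g5" not in out.data.index

    def test_ties_resolved_by_stable_order_matches_sort_oracle(self):
        """7-gene toy with 3 tied variances: retained set equals a
        brute-force stable sort on (-variance, position)."""
        base = np.array([
            [0, 2, 0, 2],   # var tied (A)
            [5, 5, 5, 5],   # constant
            [0, 4, 0, 4],   # high var
            [1, 3, 1, 3],   # var tied (A)
            [0, 1, 0, 1],   # low var
            [2, 4, 2, 4],   # var tied (A)
            [0, 6, 0, 6],   # highest
        ], dtype=float)
        expr = ExpressionMatrix(frame(base))
        out = cx.filter_low_variance(expr, 0.4)  # keep ceil(0.6*7)=5
        variances = base.var(axis=1, ddof=1)
        order = sorted(range(7), key=lambda i: (-variances[i], i))
        expected = sorted(order[:5])
        assert list(out.data.index) == [f"g{i}" for i in expected]

    def test_gene_order_preserved(self):
        rng = np.random.default_rng(5)
        expr = ExpressionMatrix(frame(rng.standard_normal((20, 6))))
        out = cx.filter_low_variance(expr, 0.25)
        positions = [list(expr.data.index).index(g) for g in out.data.index]
        assert positions == sorted(positions)


class TestSurrogateVariables:
    def test_orthonormal_columns(self, full_metadata):
        rng = np.random.default_rng(6)
        expr = ExpressionMatrix(
            frame(rng.standard_normal((200, 48)), samples=list(full_metadata.index)),
            metadata=full_metadata,
        )
        sva = cx.estimate_surrogate_variables(expr, full_metadata, n_sv=3, seed=0)
        sv = sva.sv.to_numpy()
        assert np.allclose(sv.T @ sv, np.eye(3), atol=1e-8)

    def test_zero_residual_flags_no_meaningful_sv(self, full_metadata):
        """Expression exactly equal to its design fit leaves nothing for
        SVA to find."""
        temp_contrast = (full_metadata["temperature"] == 30).astype(float).to_numpy()
        values = np.outer(np.arange(1, 21), temp_contrast)
        expr = ExpressionMatrix(frame(values, samples=list(full_metadata.index)))
        sva = cx.estimate_surrogate_variables(expr, full_metadata, n_sv=1, seed=0)
        assert not sva.meaningful
        assert sva.n_sv == 0

    def test_too_many_components_rejected(self, full_metadata):
        rng = np.random.default_rng(7)
        expr = ExpressionMatrix(
            frame(rng.standard_normal((50, 48)), samples=list(full_metadata.index))
        )
        with pytest.raises(ValueError, match="n_sv"):
            cx.estimate_surrogate_variables(expr, full_metadata, n_sv=45)

    def test_recovers_planted_batch_factor(self):
        """A single strong planted batch factor is recovered by the top
        surrogate variable with |r| >= 0.9."""
        design = cx.SimulationDesign(
            modules=[cx.module_archetype("SHARED_PLASTICITY", 100)],
            n_background_genes=900, n_batch_factors=1, batch_effect_sd=1.0,
            rng_seed=8,
        )
        counts, meta, truth = cx.simulate_counts(design)
        expr = cx.vst(counts, metadata=meta)
        sva = cx.estimate_surrogate_variables(expr, meta, n_sv=1, seed=0)
        r = np.corrcoef(sva.sv["SV1"], truth.batch_factors["batch1"])[0, 1]
        assert abs(r) >= 0.9


class TestRemoveLatentEffects:
    def test_all_zero_sv_is_identity(self, full_metadata):
        rng = np.random.default_rng(9)
        expr = ExpressionMatrix(
            frame(rng.standard_normal((30, 48)), samples=list(full_metadata.index))
        )
        out = cx.remove_latent_effects(expr, np.zeros((48, 2)))
        assert np.allclose(out.data, expr.data)

    def test_exact_fit_leaves_constant(self):
        sv = np.linspace(-1, 1, 12)[:, None]
        values = (3.0 * sv[:, 0] + 5.0)[None, :]
        expr = ExpressionMatrix(frame(values))
        out = cx.remove_latent_effects(expr, sv)
        assert np.allclose(out.data.to_numpy(), 5.0, atol=1e-10)

    def test_residuals_orthogonal_to_sv(self):
        rng = np.random.default_rng(10)
        sv = rng.standard_normal((30, 3))
        expr = ExpressionMatrix(frame(rng.standard_normal((40, 30))))
        out = cx.remove_latent_effects(expr, sv)
        design = np.hstack([np.ones((30, 1)), sv])
        beta, *_ = np.linalg.lstsq(design, out.data.to_numpy().T, rcond=None)
        assert np.abs(beta[1:]).max() < 1e-8

    def test_rank_deficient_rejected(self):
        rng = np.random.default_rng(11)
        sv = rng.standard_normal((20, 1))
        sv = np.hstack([sv, 2 * sv])
        expr = ExpressionMatrix(frame(rng.standard_normal((5, 20))))
        with pytest.raises(ValueError, match="rank deficient"):
            cx.remove_latent_effects(expr, sv)

    def test_batch_correlation_shrinks_after_removal(self):
        """Removing the estimated surrogate variables cuts the mean
        |correlation| between genes and the planted batch vector by at
        least a factor of 5 at batch SD 1."""
        design = cx.SimulationDesign(
            modules=[cx.module_archetype("SHARED_PLASTICITY", 100)],
            n_background_genes=900, n_batch_factors=1, batch_effect_sd=1.0,
            rng_seed=12,
        )
        counts, meta, truth = cx.simulate_counts(design)
        expr = cx.vst(counts, metadata=meta)
        batch = truth.batch_factors["batch1"].to_numpy()

        def mean_abs_r(data):
            z = data.to_numpy()
            z = z - z.mean(axis=1, keepdims=True)
            b = batch - batch.mean()
            num = z @ b
            den = np.sqrt((z**2).sum(axis=1) * (b**2).sum())
            ok = den > 0
            return np.abs(num[ok] / den[ok]).mean()

        before = mean_abs_r(expr.data)
        sva = cx.estimate_surrogate_variables(expr, meta, n_sv=1, seed=0)
        after = mean_abs_r(cx.remove_latent_effects(expr, sva.sv).data)
        assert before / after >= 5


def test_sva_rescues_module_recovery_under_strong_batch():
    """With strong planted batch factors, surrogate-variable removal
    yields better downstream module recovery than ignoring them."""
    from coexnet.network import build_network_modules

    for seed in (1, 42):
        design = cx.default_study_design(seed=seed)
        design.batch_effect_sd = 1.0
        counts, meta, truth = cx.simulate_counts(design)
        expr = cx.vst(counts, metadata=meta)
        expr = cx.filter_low_variance(expr, 0.4)
        ari_no_sva = cx.evaluate_recovery(build_network_modules(expr), truth).ari
        sva = cx.estimate_surrogate_variables(expr, meta, n_sv="auto", seed=1)
        cleaned = cx.remove_latent_effects(expr, sva.sv)
        ari_sva = cx.evaluate_recovery(build_network_modules(cleaned), truth).ari
        assert ari_sva >= ari_no_sva
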