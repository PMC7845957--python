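"""Exponential fitting, dataset assembly, screening and standardisation."""

import numpy as np
import pandas as pd
import pytest

import biospeckle as bs
from biospeckle.features import (FeatureDataset, apply_reciprocal,
                                 build_feature_matrix, fit_exponential,
                                 pairwise_correlation, select_features,
                                 standardize)
from biospeckle.simulate import SurfaceSpec


def tiny_images(n=3, size=24, seed=0):
    """Small labelled speckle images for fast assembly tests."""
    spec = SurfaceSpec(ra_target=10.0, grid_size=(size, size))
    ra = np.linspace(100, 2000, n)
    return bs.generate_dataset(ra, seed=seed, surface=spec)


class TestExponentialFit:
    def test_noiseless_recovery(self):
        x = np.arange(1.0, 11.0)
        y = 2.0 + 3.0 * np.exp(-0.5 * x)
        fit = fit_exponential(x, y)
        assert fit.converged
        assert fit.y0 == pytest.approx(2.0, abs=1e-6)
        assert fit.A == pytest.approx(3.0, abs=1e-6)
        assert fit.B == pytest.approx(0.5, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_growth_curve_recovery(self):
        x = np.arange(1.0, 11.0)
        y = 5.0 - 4.0 * np.exp(-0.8 * x)   # A < 0: exponential growth
        fit = fit_exponential(x, y)
        assert fit.A == pytest.approx(-4.0, abs=1e-6)
        assert fit.B == pytest.approx(0.8, abs=1e-6)

    def test_constant_input_convention(self):
        fit = fit_exponential(np.arange(1.0, 6.0), np.full(5, 7.0))
        assert (fit.y0, fit.A) == (7.0, 0.0)
        assert fit.r_squared == 1.0 and fit.converged

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_exponential([1, 2, 3], [1, 2, 3])          # too few points
        with pytest.raises(ValueError):
            fit_exponential([1, 2, 2, 3], [1, 2, 3, 4])    # not increasing


class TestAssembly:
    def test_full_default_dataset_shape(self, study):
        ds = study.dataset
        assert ds.frame.shape == (12, 352)
        for parameter in bs.PARAMETERS:
            assert len(ds.blocks[parameter]) == 44

    def test_small_configuration_shape(self):
        images = tiny_images(n=2)
        ds = build_feature_matrix(images, distances=range(1, 11),
                                  directions=[0], parameters=["CON"], levels=256)
        assert ds.frame.shape == (2, 11)  # 10 distances + y0

    @pytest.mark.parametrize("n_dist, n_dir, n_par", [(4, 1, 2), (5, 2, 3)])
    def test_column_count_arithmetic(self, n_dist, n_dir, n_par):
        images = tiny_images(n=2)
        ds = build_feature_matrix(images, distances=range(1, n_dist + 1),
                                  directions=[0, 90][:n_dir],
                                  parameters=bs.PARAMETERS[1:1 + n_par])
        assert ds.n_features == n_par * (n_dir * n_dist + n_dir)

    def test_column_order_is_parameter_major(self, study):
        cols = study.dataset.columns
        assert cols[0] == "ASM_0_d1"
        assert cols[10] == "ASM_0_y0"
        assert cols[11] == "ASM_45_d1"
        assert cols[44] == "CON_0_d1"

    def test_needs_two_images(self):
        with pytest.raises(ValueError):
            build_feature_matrix(tiny_images(n=1))

    def test_assembly_deterministic(self, tmp_path):
        images = tiny_images(n=3)
        paths = []
        for k in (0, 1):
            ds = build_feature_matrix(images, distances=range(1, 5),
                                      directions=[0], parameters=["ASM", "CON"])
            path = tmp_path / f"features_{k}.csv"
            ds.to_csv(path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]


class TestReciprocal:
    def test_values_inverted(self):
        frame = pd.DataFrame({"ASM_0_d1": [0.5, 0.25], "CON_0_d1": [2.0, 4.0]})
        ds = FeatureDataset(frame=frame, blocks={"ASM": ["ASM_0_d1"],
                                                 "CON": ["CON_0_d1"]})
        out = apply_reciprocal(ds, blocks=["ASM"])
        assert list(out.frame["ASM_0_d1"]) == [2.0, 4.0]
        assert list(out.frame["CON_0_d1"]) == [2.0, 4.0]  # untouched

    def test_involution(self, study):
        twice = apply_reciprocal(apply_reciprocal(study.dataset))
        np.testing.assert_allclose(twice.values, study.dataset.values,
                                   rtol=1e-12)

    def test_near_zero_cell_rejected(self):
        frame = pd.DataFrame({"ASM_0_d1": [0.5, 1e-15]})
        ds = FeatureDataset(frame=frame, blocks={"ASM": ["ASM_0_d1"]})
        with pytest.raises(ValueError, match="ASM_0_d1"):
            apply_reciprocal(ds, blocks=["ASM"])

    def test_alignment_gives_common_rating(self, study):
        """After the reciprocal transform, ASM features trend with Ra in the
        same direction as CON features (Spearman signs agree)."""
        from scipy.stats import spearmanr

        rec = study.reciprocal
        ra = study.ra
        sign_asm = np.sign(spearmanr(rec.frame["ASM_0_d1"], ra).statistic)
        sign_con = np.sign(spearmanr(rec.frame["CON_0_d1"], ra).statistic)
        assert sign_asm == sign_con


class TestCorrelation:
    def _dataset(self, matrix, names):
        return FeatureDataset(frame=pd.DataFrame(matrix, columns=names),
                              blocks={n: [n] for n in names})

    def test_diagonal_is_unity(self, study):
        diag = np.diag(study.correlation.values)
        np.testing.assert_allclose(diag, 1.0, atol=1e-12)

    def test_negated_column(self, rng):
        x = rng.random(6)
        ds = self._dataset(np.column_stack([x, -x]), ["a", "b"])
        R = pairwise_correlation(ds)
        assert R.values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_proportional_columns(self):
        ds = self._dataset(np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]]),
                           ["a", "b"])
        assert pairwise_correlation(ds).values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_numpy_corrcoef(self, rng):
        data = rng.random((10, 6))
        ds = self._dataset(data, [f"c{k}" for k in range(6)])
        np.testing.assert_allclose(pairwise_correlation(ds).values,
                                   np.corrcoef(data, rowvar=False), atol=1e-12)

    def test_zero_variance_column_rejected(self):
        ds = self._dataset(np.array([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]]),
                           ["a", "flat"])
        with pytest.raises(ValueError, match="flat"):
            pairwise_correlation(ds)


class TestSelection:
    def test_explicit_corr_exclusion(self, study):
        selected, report = select_features(study.reciprocal, study.correlation,
                                           mode="explicit", blocks=["CORR"])
        assert selected.n_features == 308
        assert len(report["dropped_columns"]) == 44

    def test_block_rule_drops_weak_block(self, study):
        """Replacing CORR by pure noise: the automated rule must drop exactly
        that block and keep 308 columns."""
        noisy = study.reciprocal.frame.copy()
        noise_rng = np.random.default_rng(3)
        for col in study.reciprocal.blocks["CORR"]:
            noisy[col] = noise_rng.random(len(noisy))
        ds = FeatureDataset(frame=noisy, blocks=study.reciprocal.blocks)
        selected, report = select_features(ds, pairwise_correlation(ds),
                                           mode="block", threshold=0.8)
        assert report["dropped_blocks"] == ["CORR"]
        assert selected.n_features == 308

    def test_zero_threshold_keeps_everything(self, study):
        selected, report = select_features(study.reciprocal, study.correlation,
                                           mode="block", threshold=0.0)
        assert selected.n_features == study.reciprocal.n_features
        assert report["dropped_blocks"] == []

    def test_dropping_everything_rejected(self, study):
        with pytest.raises(ValueError):
            select_features(study.reciprocal, study.correlation,
                            mode="explicit", blocks=list(bs.PARAMETERS))

    def test_retained_blocks_remain_strongly_correlated(self, study):
        """Mirror of the screening premise: every retained feature pair keeps
        |r| above the 0.8 threshold on the synthetic study."""
        cols = study.correlation.columns
        keep = [k for k, c in enumerate(cols) if not c.startswith("CORR_")]
        sub = np.abs(study.correlation.values[np.ix_(keep, keep)])
        assert sub.min() > 0.8


class TestStandardisation:
    def test_hand_example(self):
        ds = FeatureDataset(frame=pd.DataFrame({"a": [1.0, 2.0, 3.0]}),
                            blocks={"a": ["a"]})
        out, constants = standardize(ds)
        np.testing.assert_allclose(out.frame["a"], [-1.0, 0.0, 1.0])
        assert constants.means["a"] == 2.0
        assert constants.stds["a"] == 1.0

    def test_zero_mean_unit_variance(self, study):
        values = study.standardized.values
        assert np.abs(values.mean(axis=0)).max() < 1e-10
        assert np.abs(values.var(axis=0, ddof=1) - 1.0).max() < 1e-10

    def test_idempotent(self, study):
        again, _ = standardize(study.standardized)
        np.testing.assert_allclose(again.values, study.standardized.values,
                                   atol=1e-10)
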