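import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdmtv.errors import (
    DegenerateRegressorError,
    EmptySignatureError,
    InsufficientBinsError,
)
from mdmtv.qmaps_io import ROIVoxelSample
from mdmtv.relaxivity import (
    BinnedProfile,
    BinningConfig,
    MinVoxelPolicy,
    REASON_BELOW_THRESHOLD,
    aggregate_signatures,
    bin_by_mtv,
    compute_signature,
    fit_dependency,
    transform_regressor,
)
from mdmtv.synth import BrainSpec, simulate_brain

from conftest import make_region_spec


def make_sample(mtv, q, param="R1"):
    return ROIVoxelSample(
        region="test", values={"MTV": np.asarray(mtv, float), param: np.asarray(q, float)}
    )


class TestRegressor:
    def test_mtv_mode_is_identity(self):
        x = np.array([0.1, 0.2, 0.3])
        np.testing.assert_array_equal(transform_regressor(x, "MTV"), x)

    def test_inv_wc_value(self):
        assert transform_regressor(np.array([0.2]), "INV_WC")[0] == pytest.approx(1.25)

    def test_inv_wc_domain_error_at_one(self):
        with pytest.raises(ValueError):
            transform_regressor(np.array([1.0]), "INV_WC")


class TestBinning:
    def test_default_bin_width(self, default_binning):
        assert default_binning.bin_width == pytest.approx((0.40 - 0.05) / 36)

    def test_uniform_voxels_all_bins_below_4pct(self, default_binning):
        # 3600 voxels uniform over [0.05, 0.40): ~100/bin = 2.78% < 4%
        rng = np.random.default_rng(0)
        mtv = rng.uniform(0.05, 0.40, size=3600)
        with pytest.raises(InsufficientBinsError):
            bin_by_mtv(make_sample(mtv, np.ones(3600)), "R1", default_binning)

    def test_five_concentrated_bins_match_sort_median_oracle(self, default_binning):
        rng = np.random.default_rng(1)
        width = default_binning.bin_width
        chosen = [2, 9, 17, 25, 33]
        mtv_parts, q_parts = [], []
        for b in chosen:
            lo = 0.05 + b * width
            mtv_parts.append(rng.uniform(lo, lo + width * 0.999, size=200))
            q_parts.append(rng.normal(b, 0.1, size=200))
        mtv = np.concatenate(mtv_parts)
        q = np.concatenate(q_parts)
        profile = bin_by_mtv(make_sample(mtv, q), "R1", default_binning)
        assert profile.n_bins == 5
        # brute-force oracle: sort raw voxels into bins, take medians
        for j, b in enumerate(chosen):
            lo = 0.05 + b * width
            sel = (mtv >= lo) & (mtv < lo + width)
            assert profile.q_median[j] == pytest.approx(np.median(q[sel]), abs=1e-12)
            assert profile.regressor_median[j] == pytest.approx(np.median(mtv[sel]), abs=1e-12)
            med = np.median(q[sel])
            assert profile.q_mad[j] == pytest.approx(np.median(np.abs(q[sel] - med)), abs=1e-12)

    def test_out_of_range_voxels_excluded_from_denominator(self):
        cfg = BinningConfig(n_bins=5, lo=0.1, hi=0.2, min_bin_frac=0.04)
        mtv = np.concatenate([np.full(50, 0.15), np.full(1000, 0.9)])
        profile = bin_by_mtv(make_sample(mtv, np.ones_like(mtv)), "R1", cfg)
        assert profile.total_voxels == 50  # out-of-range bulk not counted
        assert profile.counts.sum() == 50

    def test_final_bin_closed_at_hi(self):
        cfg = BinningConfig(n_bins=5, lo=0.0, hi=0.5, min_bin_frac=0.0)
        mtv = np.array([0.5] * 10)  # exactly at hi
        profile = bin_by_mtv(make_sample(mtv, np.ones(10)), "R1", cfg)
        assert profile.counts.sum() == 10


class TestFit:
    def _line_profile(self, x, y, counts=None, config=None):
        config = config or BinningConfig()
        x, y = np.asarray(x, float), np.asarray(y, float)
        counts = np.full(len(x), 100) if counts is None else np.asarray(counts)
        return BinnedProfile(
            param="R1", regressor_median=x, q_median=y,
            q_mad=np.zeros(len(x)), counts=counts,
            total_voxels=int(counts.sum()), config=config,
        )

    def test_exact_line_recovered(self):
        x = np.linspace(0.05, 0.4, 8)
        dep = fit_dependency(self._line_profile(x, 2.0 * x + 0.5))
        assert dep.slope == pytest.approx(2.0, abs=1e-12)
        assert dep.intercept == pytest.approx(0.5, abs=1e-12)
        assert dep.r2_adj == pytest.approx(1.0, abs=1e-12)

    def test_flat_line_zero_slope_zero_r2(self):
        x = np.linspace(0.05, 0.4, 10)
        dep = fit_dependency(self._line_profile(x, np.full(10, 3.3)))
        assert dep.slope == pytest.approx(0.0, abs=1e-12)
        assert dep.r2 == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        x = np.linspace(0.05, 0.4, 10)
        y = 1.5 * x + 0.2 + rng.normal(0, 0.01, size=10)
        dep = fit_dependency(self._line_profile(x, y))
        # independent closed-form normal-equations solve
        A = np.column_stack([x, np.ones(10)])
        slope_o, intercept_o = np.linalg.solve(A.T @ A, A.T @ y)
        assert dep.slope == pytest.approx(slope_o, abs=1e-10)
        assert dep.intercept == pytest.approx(intercept_o, abs=1e-10)

    def test_too_few_bins_raises(self):
        x = np.array([0.1, 0.2, 0.3])
        with pytest.raises(InsufficientBinsError):
            fit_dependency(self._line_profile(x, x))

    def test_zero_regressor_variance_raises(self):
        x = np.full(6, 0.2)
        with pytest.raises(DegenerateRegressorError):
            fit_dependency(self._line_profile(x, np.arange(6.0)))

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 100))
    def test_unit_scaling_scales_slope_and_intercept(self, scale, seed):
        rng = np.random.default_rng(seed)
        x = np.linspace(0.05, 0.4, 8)
        y = 1.2 * x + 0.3 + rng.normal(0, 0.02, 8)
        base = fit_dependency(self._line_profile(x, y))
        scaled = fit_dependency(self._line_profile(x, y * scale))
        assert scaled.slope == pytest.approx(base.slope * scale, rel=1e-9)
        assert scaled.intercept == pytest.approx(base.intercept * scale, rel=1e-9)
        assert scaled.r2_adj == pytest.approx(base.r2_adj, abs=1e-9)


class TestVoxelDensityInvariance:
    def test_duplicating_voxels_leaves_fit_unchanged(self):
        rng = np.random.default_rng(3)
        mtv = rng.uniform(0.08, 0.38, size=1200)
        q = 2.0 * mtv + 0.1 + rng.normal(0, 0.05, size=1200)
        cfg = BinningConfig(min_bin_frac=0.01)
        base = fit_dependency(bin_by_mtv(make_sample(mtv, q), "R1", cfg))
        doubled = fit_dependency(
            bin_by_mtv(
                make_sample(np.repeat(mtv, 2), np.repeat(q, 2)), "R1", cfg
            )
        )
        assert doubled.slope == pytest.approx(base.slope, abs=1e-12)
        assert doubled.intercept == pytest.approx(base.intercept, abs=1e-12)


class TestSignature:
    def test_noiseless_recovery(self, noiseless_brain):
        maps, labels = noiseless_brain
        sig = compute_signature(
            maps, labels, 1, params=("R1", "MTsat"), erosion_depth=0
        )
        assert sig.fits["R1"].slope == pytest.approx(1.2, abs=1e-8)
        assert sig.fits["R1"].intercept == pytest.approx(0.4, abs=1e-8)
        assert sig.fits["MTsat"].slope == pytest.approx(3.0, abs=1e-8)

    def test_regions_recover_distinct_planted_slopes(self, noiseless_brain):
        maps, labels = noiseless_brain
        s1 = compute_signature(maps, labels, 1, ("R1", "MTsat"), erosion_depth=0)
        s2 = compute_signature(maps, labels, 2, ("R1", "MTsat"), erosion_depth=0)
        assert s2.fits["R1"].slope - s1.fits["R1"].slope == pytest.approx(1.2, abs=1e-8)
        assert s2.fits["MTsat"].slope - s1.fits["MTsat"].slope == pytest.approx(6.0, abs=1e-8)

    def test_small_roi_excludes_high_threshold_params_only(self):
        spec = BrainSpec(
            regions=(
                make_region_spec(
                    "small", 1, n_voxels=400,
                    laws={"R1": (2.0, 0.5), "MTsat": (12.0, -0.1), "R2": (30.0, 4.0)},
                    noise_sd={"R1": 0.0, "MTsat": 0.0, "R2": 0.0},
                ),
            ),
            block_width=8,
        )
        maps, labels = simulate_brain(spec, seed=0)
        sig = compute_signature(
            maps, labels, 1, params=("R1", "MTsat", "R2"), erosion_depth=0
        )
        assert sig.excluded["R1"] == REASON_BELOW_THRESHOLD  # 400 < 500
        assert sig.excluded["MTsat"] == REASON_BELOW_THRESHOLD
        assert "R2" in sig.fits  # 400 >= 50

    def test_all_excluded_raises_empty_signature(self):
        spec = BrainSpec(
            regions=(make_region_spec("tiny", 1, n_voxels=100),), block_width=5
        )
        maps, labels = simulate_brain(spec, seed=0)
        with pytest.raises(EmptySignatureError):
            compute_signature(maps, labels, 1, params=("R1", "MTsat"), erosion_depth=0)

    def test_inv_wc_slopes_rank_correlated_with_mtv_slopes(self):
        # physiological range: 1/(1-MTV) is near-linear in MTV, so slope
        # ordering across regions should survive the regressor swap
        from scipy.stats import spearmanr

        laws = [(1.0, 0.4), (2.0, 0.3), (3.5, 0.2), (5.0, 0.1), (7.0, 0.0)]
        slopes_mtv, slopes_inv = [], []
        for i, (a, b) in enumerate(laws):
            spec = BrainSpec(
                regions=(
                    make_region_spec(
                        f"r{i}", 1, n_voxels=4000, laws={"R1": (a, b), "MTsat": (1.0, 0.0)}
                    ),
                )
            )
            maps, labels = simulate_brain(spec, seed=i)
            for mode, store in (("MTV", slopes_mtv), ("INV_WC", slopes_inv)):
                sig = compute_signature(
                    maps, labels, 1, params=("R1",),
                    config=BinningConfig(regressor_mode=mode), erosion_depth=0,
                )
                store.append(sig.fits["R1"].slope)
        rho = spearmanr(slopes_mtv, slopes_inv).statistic
        assert rho == pytest.approx(1.0)

    def test_aggregate_is_median_of_subject_slopes(self, noiseless_brain):
        maps, labels = noiseless_brain
        sigs = [
            compute_signature(maps, labels, 1, ("R1",), erosion_depth=0, subject=f"s{i}")
            for i in range(3)
        ]
        sigs[1].fits["R1"].slope = 99.0  # perturb one subject
        agg = aggregate_signatures(sigs)
        assert agg.fits["R1"].slope == pytest.approx(sigs[0].fits["R1"].slope)


class TestMinVoxelPolicy:
    def test_defaults(self):
        policy = MinVoxelPolicy()
        assert policy.minimum("MTsat") == 500
        assert policy.minimum("R1") == 500
        assert policy.minimum("MD") == 150
        assert policy.minimum("R2") == 50

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            MinVoxelPolicy(thresholds=(("R1", 0),))
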