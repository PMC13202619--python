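"""Regional-signal conditioning and connectome estimation."""

import numpy as np
import pytest

from bwage.preprocess import (
    RegionalTimeSeries,
    bandpass,
    concatenate,
    connectome_from_scans,
    detrend,
    flag_outlier_frames,
    global_signal_regress,
    legendre_trend_columns,
    normalize,
    oas_shrink,
    oas_shrinkage_intensity,
    pearson_connectome,
    regress_nuisance,
)
from bwage.synthdata import generate_timeseries
from conftest import random_spd

TR = 0.7275


def ts(data, tr=TR):
    return RegionalTimeSeries(np.asarray(data, dtype=float), tr=tr)


class TestDetrend:
    def test_pure_line_and_constant_become_zero(self):
        t = np.arange(100.0)
        data = np.column_stack([3.0 + 0.5 * t, np.full(100, 7.0)])
        out = detrend(ts(data))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_recovers_sinusoid_on_top_of_trend(self):
        t = np.arange(2000.0)
        wave = np.sin(2 * np.pi * t / 50)
        data = (wave + 0.01 * t + 5.0)[:, None]
        # least-squares oracle: residual of regression on [1, t]
        X = np.column_stack([np.ones_like(t), t])
        oracle = data - X @ np.linalg.lstsq(X, data, rcond=None)[0]
        np.testing.assert_allclose(detrend(ts(data)).data, oracle, atol=1e-8)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            detrend(ts(np.ones((2, 3))))


class TestBandpass:
    def amplitude(self, x):
        return (x.max() - x.min()) / 2

    def test_in_band_sinusoid_passes(self):
        t = np.arange(4000) * TR
        x = np.sin(2 * np.pi * 0.05 * t)[:, None]
        out = bandpass(ts(x)).data[500:-500]
        assert self.amplitude(out) == pytest.approx(1.0, rel=0.05)

    def test_dc_is_removed(self):
        out = bandpass(ts(np.full((1000, 2), 5.0)))
        assert np.abs(out.data).max() < 1e-6

    def test_out_of_band_sinusoid_attenuated(self):
        t = np.arange(4000) * TR
        x = np.sin(2 * np.pi * 0.3 * t)[:, None]
        out = bandpass(ts(x)).data[500:-500]
        assert self.amplitude(out) < 0.2  # >80% reduction

    def test_infeasible_band(self):
        with pytest.raises(ValueError, match="infeasible"):
            bandpass(ts(np.zeros((100, 1)), tr=10.0))


class TestScrubbing:
    def test_clean_scan_has_empty_mask(self):
        mask = flag_outlier_frames(np.zeros(50), np.full(50, 10.0))
        assert not mask.any()

    def test_position_jump_flags_later_frame(self):
        pos = np.zeros(20)
        pos[10:] = 5.0  # single 5 mm jump between frames 9 and 10
        mask = flag_outlier_frames(pos, np.ones(20))
        assert list(np.flatnonzero(mask)) == [10]

    def test_intensity_spike_flagged(self):
        intensity = np.ones(200)
        intensity[37] = 2.0  # far beyond 3 SD of the scan's own spread
        mask = flag_outlier_frames(np.zeros(200), intensity)
        assert mask[37] and mask.sum() == 1


class TestNuisanceRegression:
    def test_ts_equal_to_regressor_vanishes(self, rng):
        N = np.column_stack([np.ones(50), rng.standard_normal(50)])
        out = regress_nuisance(ts(N[:, 1:2]), N)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_orthogonal_signal_unchanged(self):
        t = np.arange(64.0)
        N = legendre_trend_columns(64, degree=1)
        sig = np.sin(2 * np.pi * t / 8)[:, None]
        sig -= N @ np.linalg.lstsq(N, sig, rcond=None)[0]  # orthogonalize exactly
        out = regress_nuisance(ts(sig), N)
        np.testing.assert_allclose(out.data, sig, atol=1e-10)

    def test_matches_projection_oracle_and_orthogonality(self, rng):
        Y = rng.standard_normal((80, 4))
        N = np.column_stack([legendre_trend_columns(80), rng.standard_normal((80, 3))])
        out = regress_nuisance(ts(Y), N)
        oracle = Y - N @ np.linalg.lstsq(N, Y, rcond=None)[0]
        np.testing.assert_allclose(out.data, oracle, atol=1e-10)
        assert np.abs(N.T @ out.data).max() < 1e-8

    def test_masked_frames_interpolated_to_model(self, rng):
        Y = rng.standard_normal((60, 2))
        N = legendre_trend_columns(60)
        mask = np.zeros(60, dtype=bool)
        mask[[10, 30]] = True
        out = regress_nuisance(ts(Y), N, mask)
        np.testing.assert_allclose(out.data[mask], 0.0, atol=1e-12)
        assert np.abs(N.T @ out.data).max() < 1e-8

    def test_rank_deficiency_reported(self):
        N = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(ValueError, match="collinear columns"):
            regress_nuisance(ts(np.random.default_rng(0).standard_normal((30, 2))), N)


class TestGlobalSignalRegression:
    def test_identical_regions_vanish(self, rng):
        x = rng.standard_normal(40)
        out = global_signal_regress(ts(np.column_stack([x, x, x])))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_antisymmetric_pair_unchanged(self, rng):
        x = rng.standard_normal(40)
        data = np.column_stack([x, -x])
        out = global_signal_regress(ts(data))
        np.testing.assert_allclose(out.data, data, atol=1e-12)

    def test_matches_projection_oracle(self, rng):
        Y = rng.standard_normal((100, 5))
        g = Y.mean(axis=1, keepdims=True)
        oracle = Y - g @ (np.linalg.lstsq(g, Y, rcond=None)[0])
        out = global_signal_regress(ts(Y))
        np.testing.assert_allclose(out.data, oracle, atol=1e-10)
        assert np.abs(g.T @ out.data).max() < 1e-8


class TestNormalizeAndConcatenate:
    def test_hand_example(self):
        out = normalize(ts(np.array([[1.0], [2.0], [3.0]])))
        expected = np.array([-1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)])
        np.testing.assert_allclose(out.data[:, 0], expected, atol=1e-12)

    def test_idempotent(self, rng):
        a = normalize(ts(rng.standard_normal((30, 4))))
        b = normalize(a)
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_zero_variance_region_named(self):
        data = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        with pytest.raises(ValueError, match="r1"):
            normalize(ts(data))

    def test_single_scan_concat_equals_normalize(self, rng):
        scan = ts(rng.standard_normal((50, 3)))
        np.testing.assert_allclose(
            concatenate([scan]).data, normalize(scan).data, atol=1e-12
        )

    def test_two_identical_scans_scale_by_sqrt2(self, rng):
        scan = ts(rng.standard_normal((50, 3)))
        single = normalize(scan).data
        out = concatenate([scan, scan]).data
        np.testing.assert_allclose(out[:50], single / np.sqrt(2), atol=1e-12)
        np.testing.assert_allclose(out[50:], single / np.sqrt(2), atol=1e-12)

    def test_mismatched_regions_rejected(self, rng):
        a = ts(rng.standard_normal((20, 3)))
        b = RegionalTimeSeries(rng.standard_normal((20, 3)), TR, ["a", "b", "c"])
        with pytest.raises(ValueError, match="mismatched"):
            concatenate([a, b])


class TestPearsonConnectome:
    def test_identical_and_orthogonal_columns(self):
        t = np.arange(64.0)
        x = np.sin(2 * np.pi * t / 16)
        y = np.cos(2 * np.pi * t / 16)
        C = pearson_connectome(ts(np.column_stack([x, x, y]))).matrix
        assert C[0, 1] == pytest.approx(1.0, abs=1e-10)
        assert C[0, 2] == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_matches_corrcoef_oracle(self, rng):
        Y = rng.standard_normal((200, 6))
        C = pearson_connectome(ts(Y)).matrix
        np.testing.assert_allclose(C, np.corrcoef(Y, rowvar=False), atol=1e-10)


def oas_rho_oracle_2x2(c: float, n: int) -> float:
    """Independent scalar evaluation of the published OAS closed form for a
    2x2 correlation matrix with off-diagonal c."""
    p = 2
    tr = 2.0
    tr2 = 2.0 + 2.0 * c * c  # sum of squared entries
    num = (1 - 2 / p) * tr2 + tr**2
    den = (n + 1 - 2 / p) * (tr2 - tr**2 / p)
    return min(1.0, num / den)


class TestOAS:
    def test_identity_is_fixed_point(self):
        from bwage.preprocess import Connectome

        C = Connectome(np.eye(4), "correlation")
        np.testing.assert_allclose(oas_shrink(C, n=50).matrix, np.eye(4))

    def test_forced_full_shrinkage_gives_identity_target(self, correlation_connectome):
        out = oas_shrink(correlation_connectome, n=50, rho=1.0)
        np.testing.assert_allclose(out.matrix, np.eye(6), atol=1e-12)

    def test_2x2_matches_independent_closed_form(self):
        from bwage.preprocess import Connectome

        c, n = 0.5, 50
        C = Connectome(np.array([[1.0, c], [c, 1.0]]), "correlation")
        rho = oas_rho_oracle_2x2(c, n)
        expected = (1 - rho) * C.matrix + rho * np.eye(2)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(oas_shrink(C, n=n).matrix, expected, atol=1e-12)
        assert oas_shrinkage_intensity(C.matrix, n) == pytest.approx(rho, abs=1e-12)

    def test_shrinkage_moves_toward_truth_on_average(self, rng):
        """Closer to the population correlations, on average, in the
        estimator's own regime (weak structure, short scans); strong
        correlations at tiny n are over-shrunk toward identity."""
        truth = np.full((6, 6), 0.2)
        np.fill_diagonal(truth, 1.0)
        L = np.linalg.cholesky(truth)
        n, reps = 40, 250
        d_raw, d_oas = [], []
        from bwage.preprocess import Connectome

        for _ in range(reps):
            X = rng.standard_normal((n, 6)) @ L.T
            C = np.corrcoef(X, rowvar=False)
            Cs = oas_shrink(Connectome(C, "correlation"), n=n).matrix
            d_raw.append(np.linalg.norm(C - truth))
            d_oas.append(np.linalg.norm(Cs - truth))
        assert np.mean(d_oas) <= np.mean(d_raw)


class TestFullChain:
    def test_known_covariance_recovered_as_scan_grows(self, rng):
        truth = random_spd(5, rng)
        d = np.sqrt(np.diag(truth))
        truth_corr = truth / np.outer(d, d)
        errs = []
        for T in (300, 3000):
            scan = generate_timeseries(truth, n_frames=T, tr=TR, seed=11)
            C = connectome_from_scans([scan], gsr=False, oas=False)
            errs.append(np.linalg.norm(C.matrix - truth_corr))
        assert errs[1] < errs[0]
        assert errs[1] < 0.35
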