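"""Nine feature subtypes vs independent oracles and spectral identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmripredict import (
    FilterSpec,
    GraphSignal,
    build_feature_matrix,
    coupled_fc,
    decoupled_fc,
    falff,
    fc,
    gft,
    graph_filter,
    graph_psd,
    harmonic_basis,
    igft,
    mssd,
    normalized_laplacian,
    regional_mean,
    regional_sd,
    sdi,
)
from fmripredict.features import concat_sessions, default_cutoff

from conftest import random_connected_graph

TR = 0.72


def rand_ts(n_regions=10, n_frames=50, seed=0):
    return np.random.default_rng(seed).normal(size=(n_regions, n_frames))


class TestFC:
    def test_duplicate_region_perfect_correlation(self):
        ts = rand_ts(3, 40, seed=1)
        ts[2] = ts[1]
        edges = fc(ts)
        # upper-triangle row-major: (0,1), (0,2), (1,2)
        assert edges[2] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self):
        ts = rand_ts(4, 30, seed=2)
        expected = []
        for i in range(4):
            for j in range(i + 1, 4):
                xi, xj = ts[i] - ts[i].mean(), ts[j] - ts[j].mean()
                expected.append(
                    float(xi @ xj / np.sqrt((xi @ xi) * (xj @ xj)))
                )
        np.testing.assert_allclose(fc(ts), expected, atol=1e-12)

    def test_zero_variance_region_rejected(self):
        ts = rand_ts(3, 20, seed=3)
        ts[0] = 5.0
        with pytest.raises(ValueError, match="variance"):
            fc(ts)

    def test_range(self):
        edges = fc(rand_ts(10, 50, seed=4))
        assert edges.min() >= -1.0 and edges.max() <= 1.0


class TestRegionalStats:
    def test_hand_values(self):
        ts = np.array([[3.0, 3.0, 3.0], [0.0, 2.0, 1.0]])
        np.testing.assert_allclose(regional_mean(ts), [3.0, 1.0])
        assert regional_sd(ts)[0] == 0.0
        ts2 = np.array([[0.0, 2.0]])
        assert regional_mean(ts2)[0] == 1.0
        assert regional_sd(ts2)[0] == pytest.approx(np.sqrt(2.0))

    def test_matches_loop_oracle(self):
        ts = rand_ts(10, 50, seed=5)
        for r in range(10):
            assert regional_mean(ts)[r] == pytest.approx(np.mean(ts[r]))
            assert regional_sd(ts)[r] == pytest.approx(np.std(ts[r], ddof=1))

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            regional_sd(np.zeros((3, 1)))


class TestMSSD:
    def test_constant_zero(self):
        assert mssd(np.full((2, 10), 7.0)).max() == 0.0

    def test_alternating_series(self):
        # {0,2,0,2,0}: four successive diffs of +-2, mean of squares = 4
        ts = np.array([[0.0, 2.0, 0.0, 2.0, 0.0]])
        assert mssd(ts)[0] == pytest.approx(4.0)

    def test_matches_loop_oracle(self):
        ts = rand_ts(10, 40, seed=6)
        got = mssd(ts)
        for r in range(10):
            n = ts.shape[1]
            acc = sum((ts[r, i + 1] - ts[r, i]) ** 2 for i in range(n - 1))
            assert got[r] == pytest.approx(acc / (n - 1))


class TestFALFF:
    # 1250 frames x 0.72 s = 900 s, so 0.04 Hz and 0.3 Hz sit exactly on
    # periodogram bins (coherent sampling: no leakage blurs the oracle)
    def test_pure_low_frequency_sinusoid(self):
        t = np.arange(1250) * TR
        ts = np.sin(2 * np.pi * 0.04 * t)[None, :]
        assert falff(ts, TR)[0] >= 0.95

    def test_pure_high_frequency_sinusoid(self):
        t = np.arange(1250) * TR
        ts = np.sin(2 * np.pi * 0.3 * t)[None, :]
        assert falff(ts, TR)[0] <= 0.05

    def test_white_noise_matches_bin_fraction(self):
        # flat expected spectrum: fALFF ~ (#bins in band) / (#positive bins)
        n = 4096
        freqs = np.fft.rfftfreq(n, d=TR)
        pos = freqs > 0
        band = pos & (freqs >= 0.01) & (freqs <= 0.08)
        expected = band.sum() / pos.sum()
        vals = falff(rand_ts(20, n, seed=7), TR)
        assert abs(vals.mean() - expected) < 0.03

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            falff(rand_ts(2, 128), TR, band=(0.01, 1.0))

    def test_values_in_unit_interval(self):
        vals = falff(rand_ts(5, 256, seed=8), TR)
        assert (vals >= 0).all() and (vals <= 1).all()


class TestGFT:
    def test_single_harmonic_indicator(self, basis12):
        x = basis12.eigenvectors[:, [4]]
        coeff = gft(x, basis12).coefficients
        expected = np.zeros((12, 1))
        expected[4] = 1.0
        np.testing.assert_allclose(coeff, expected, atol=1e-12)

    def test_round_trip_identity(self, basis12):
        ts = rand_ts(12, 30, seed=9)
        back = igft(gft(ts, basis12), basis12)
        assert np.abs(back - ts).max() < 1e-8

    def test_parseval_per_frame(self, basis12):
        ts = rand_ts(12, 25, seed=10)
        coeff = gft(ts, basis12).coefficients
        e_region = np.square(ts).sum(axis=0)
        e_graph = np.square(coeff).sum(axis=0)
        np.testing.assert_allclose(e_graph, e_region, rtol=1e-8)

    def test_dimension_mismatch(self, basis12):
        with pytest.raises(ValueError):
            gft(rand_ts(5, 10), basis12)


class TestGraphPSD:
    def test_constant_coefficients(self):
        gs = GraphSignal(np.ones((6, 16)))
        np.testing.assert_allclose(graph_psd(gs), np.full(6, 4.0))

    def test_signal_on_single_harmonic(self, basis12):
        ts = basis12.eigenvectors[:, [0]] @ np.random.default_rng(0).normal(size=(1, 20))
        psd = graph_psd(gft(ts, basis12))
        assert np.abs(psd[1:]).max() < 1e-10

    def test_total_energy_identity(self, basis12):
        ts = rand_ts(12, 40, seed=11)
        psd = graph_psd(gft(ts, basis12))
        assert np.square(psd).sum() == pytest.approx(np.square(ts).sum(), rel=1e-8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            graph_psd(GraphSignal(np.zeros((4, 0))))


class TestGraphFilter:
    def test_low_span_preserved(self, basis12):
        rng = np.random.default_rng(12)
        ts = basis12.eigenvectors[:, :5] @ rng.normal(size=(5, 15))
        spec = FilterSpec(5, "low")
        np.testing.assert_allclose(graph_filter(ts, basis12, spec), ts, atol=1e-10)
        high = graph_filter(ts, basis12, FilterSpec(5, "high"))
        assert np.abs(high).max() < 1e-10

    def test_complementarity(self, basis12):
        ts = rand_ts(12, 20, seed=13)
        for cut in (1, 4, 6, 11):
            low = graph_filter(ts, basis12, FilterSpec(cut, "low"))
            high = graph_filter(ts, basis12, FilterSpec(cut, "high"))
            assert np.abs(low + high - ts).max() < 1e-8

    def test_idempotence(self, basis12):
        ts = rand_ts(12, 20, seed=14)
        spec = FilterSpec(6, "low")
        once = graph_filter(ts, basis12, spec)
        twice = graph_filter(once, basis12, spec)
        np.testing.assert_allclose(twice, once, atol=1e-10)

    def test_matches_projection_oracle(self, basis12):
        # brute force: project each frame onto the kept eigenvector subset
        ts = rand_ts(12, 10, seed=15)
        cut = 7
        u = basis12.eigenvectors
        expected = np.zeros_like(ts)
        for t in range(ts.shape[1]):
            for k in range(cut):
                expected[:, t] += (u[:, k] @ ts[:, t]) * u[:, k]
        got = graph_filter(ts, basis12, FilterSpec(cut, "low"))
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_invalid_cutoff(self, basis12):
        with pytest.raises(ValueError):
            graph_filter(rand_ts(12, 5), basis12, FilterSpec(0, "low"))


class TestCoupledDecoupledFC:
    def test_identity_cutoff_equals_fc(self, basis12):
        ts = rand_ts(12, 40, seed=16)
        np.testing.assert_allclose(
            coupled_fc(ts, basis12, cutoff_index=12), fc(ts), atol=1e-10
        )

    def test_edge_dimension(self, basis12):
        ts = rand_ts(12, 40, seed=17)
        assert coupled_fc(ts, basis12).shape == (66,)
        assert decoupled_fc(ts, basis12).shape == (66,)

    def test_pure_low_signal_breaks_decoupled(self, basis12):
        rng = np.random.default_rng(18)
        ts = basis12.eigenvectors[:, :3] @ rng.normal(size=(3, 30))
        with pytest.raises(ValueError):
            decoupled_fc(ts, basis12)


class TestSDI:
    def test_pure_low_signal_zero(self, basis12):
        rng = np.random.default_rng(19)
        ts = basis12.eigenvectors[:, :4] @ rng.normal(size=(4, 25))
        np.testing.assert_allclose(sdi(ts, basis12), 0.0, atol=1e-10)

    def test_equal_band_norms_give_one(self):
        # on a 2-node graph with equal weights both harmonics have equal
        # per-region magnitude, so equal coefficient norms -> SDI = 1
        basis = harmonic_basis(normalized_laplacian(np.array([[0.0, 1.0], [1.0, 0.0]])))
        rng = np.random.default_rng(20)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        b *= np.linalg.norm(a) / np.linalg.norm(b)
        ts = basis.eigenvectors[:, [0]] * a[None, :] + basis.eigenvectors[:, [1]] * b[None, :]
        np.testing.assert_allclose(sdi(ts, basis), 1.0, atol=1e-10)

    def test_matches_projection_oracle(self, basis12):
        ts = rand_ts(12, 30, seed=21)
        cut = default_cutoff(12)
        u = basis12.eigenvectors
        low = u[:, :cut] @ (u[:, :cut].T @ ts)
        high = u[:, cut:] @ (u[:, cut:].T @ ts)
        expected = np.linalg.norm(high, axis=1) / np.linalg.norm(low, axis=1)
        np.testing.assert_allclose(sdi(ts, basis12), expected, atol=1e-10)

    def test_pure_high_signal_rejected(self, basis12):
        rng = np.random.default_rng(22)
        ts = basis12.eigenvectors[:, 8:] @ rng.normal(size=(4, 25))
        with pytest.raises(ValueError, match="low-pass"):
            sdi(ts, basis12)


class TestBuildFeatureMatrix:
    def test_dimensions(self, small_cohort, basis12):
        regional = build_feature_matrix(small_cohort, "sd")
        assert regional.values.shape == (24, 12)
        edges = build_feature_matrix(small_cohort, "fc")
        assert edges.values.shape == (24, 66)
        gsp = build_feature_matrix(small_cohort, "psd", basis=basis12)
        assert gsp.values.shape == (24, 12)
        assert not np.isnan(gsp.values).any()

    def test_single_subject(self, small_cohort):
        fm = build_feature_matrix(small_cohort[:1], "mssd")
        assert fm.values.shape == (1, 12)

    def test_subject_order_invariance(self, small_cohort, basis12):
        fm = build_feature_matrix(small_cohort, "sdi", basis=basis12)
        rev = build_feature_matrix(small_cohort[::-1], "sdi", basis=basis12)
        np.testing.assert_allclose(fm.values, rev.values[::-1])
        assert fm.subject_ids == rev.subject_ids[::-1]

    def test_missing_basis_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="basis"):
            build_feature_matrix(small_cohort, "coupled_fc")

    def test_nonnegative_features(self, small_cohort, basis12):
        for name in ("sd", "mssd", "falff", "psd", "sdi"):
            fm = build_feature_matrix(small_cohort, name, basis=basis12)
            assert (fm.values >= 0).all(), name


class TestConcatSessions:
    def test_full_concatenation(self):
        sessions = [np.ones((3, 10)), 2 * np.ones((3, 10))]
        out = concat_sessions(sessions)
        assert out.shape == (3, 20)

    def test_fractional_prefix(self):
        sessions = [np.arange(40.0).reshape(4, 10), np.zeros((4, 10))]
        out = concat_sessions(sessions, 0.25)
        assert out.shape == (4, 2)
        np.testing.assert_array_equal(out, sessions[0][:, :2])

    def test_amount_exceeds_sessions(self):
        with pytest.raises(ValueError):
            concat_sessions([np.zeros((2, 5))], 2.0)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    seed=st.integers(0, 10_000),
    n=st.integers(4, 16),
    frames=st.integers(5, 40),
    cut=st.data(),
)
def test_parseval_and_complementarity_property(seed, n, frames, cut):
    """For any connected graph and signal: GFT conserves energy and the
    low/high split reconstructs the signal for any cutoff."""
    basis = harmonic_basis(normalized_laplacian(random_connected_graph(n, seed=seed)))
    ts = np.random.default_rng(seed + 1).normal(size=(n, frames))
    cutoff = cut.draw(st.integers(1, n - 1))
    coeff = gft(ts, basis).coefficients
    assert np.square(coeff).sum() == pytest.approx(np.square(ts).sum(), rel=1e-8)
    low = graph_filter(ts, basis, FilterSpec(cutoff, "low"))
    high = graph_filter(ts, basis, FilterSpec(cutoff, "high"))
    assert np.abs(low + high - ts).max() < 1e-8
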