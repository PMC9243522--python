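"""Temporal spectra, phasor transform, segmentation, branches and rendering."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from dqobm import (
    PhaseMovie,
    PhasorParams,
    SpectrumStack,
    colorize,
    fit_branches,
    phasor_histogram,
    phasor_transform,
    segment_cells,
    semicircle_residual,
    temporal_spectrum,
)
from dqobm.dynamics import (
    BranchModel,
    branch_hue,
    default_prior_tau,
    default_tau,
    smooth_spectra,
    white_noise_phasor,
)


def movie_from_traces(traces, dt=1.0):
    """(T, n) traces -> a PhaseMovie with one row of n pixels."""
    return PhaseMovie(values=traces[:, None, :], dt=dt, pixel_size=0.2)


def single_bin_spectrum(f0, freqs, weight=1.0):
    mags = np.zeros((freqs.size, 1, 1))
    mags[np.argmin(np.abs(freqs - f0)), 0, 0] = weight
    return SpectrumStack(magnitudes=mags, freqs=freqs)


def exponential_spectrum(fc, n=100_000, fmax_factor=50.0):
    f = np.linspace(1e-7, fmax_factor * fc, n)
    return SpectrumStack(magnitudes=np.exp(-f / fc)[:, None, None], freqs=f)


class TestTemporalSpectrum:
    def test_constant_trace_zero_spectrum(self):
        movie = movie_from_traces(np.full((16, 3), 2.5))
        st = temporal_spectrum(movie)
        np.testing.assert_allclose(st.magnitudes, 0.0, atol=1e-12)

    def test_on_bin_cosine_matches_naive_dft(self):
        T, j = 32, 5
        t = np.arange(T)
        trace = np.cos(2 * np.pi * j * t / T)
        st = temporal_spectrum(movie_from_traces(trace[:, None]))
        # independent O(T^2) DFT oracle
        naive = np.array(
            [abs(sum(trace[k] * np.exp(-2j * np.pi * m * k / T) for k in range(T)))
             for m in range(1, T // 2 + 1)]
        )
        np.testing.assert_allclose(st.magnitudes[:, 0, 0], naive, atol=1e-9)
        assert st.magnitudes[j - 1, 0, 0] == pytest.approx(T / 2)
        off = np.delete(st.magnitudes[:, 0, 0], j - 1)
        np.testing.assert_allclose(off, 0.0, atol=1e-9)

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        traces = rng.standard_normal((32, 4))
        a = temporal_spectrum(movie_from_traces(traces))
        b = temporal_spectrum(movie_from_traces(traces + 17.0))
        np.testing.assert_allclose(a.magnitudes, b.magnitudes, atol=1e-10)

    def test_frequency_grid(self):
        st = temporal_spectrum(movie_from_traces(np.random.default_rng(1).random((32, 2)), dt=0.5))
        assert st.freqs[0] == pytest.approx(1 / (32 * 0.5))
        assert st.freqs[-1] == pytest.approx(1.0)  # 1/(2 dt)
        assert np.all(np.diff(st.freqs) > 0)

    def test_linear_detrend_removes_ramp(self):
        t = np.arange(64, dtype=float)
        movie = movie_from_traces((0.3 * t)[:, None])
        st = temporal_spectrum(movie, detrend="linear")
        assert st.magnitudes.max() < 1.0  # ramp leakage suppressed

    def test_nonfinite_rejected(self):
        bad = np.ones((16, 1, 1))
        bad[3] = np.nan
        with pytest.raises(ValueError):
            temporal_spectrum(PhaseMovie(values=bad, dt=1.0, pixel_size=0.2))


class TestPhasorTransform:
    def test_tau_zero_limit(self):
        rng = np.random.default_rng(2)
        st = SpectrumStack(magnitudes=rng.random((16, 2, 2)) + 0.1, freqs=np.arange(1, 17) * 0.01)
        ph = phasor_transform(st, PhasorParams(tau=0.0))
        np.testing.assert_allclose(ph.g, 1.0)
        np.testing.assert_allclose(ph.s, 0.0)

    def test_single_component_on_unit_circle(self):
        freqs = np.arange(1, 33) * 0.01
        f0, tau = 0.11, 3.0
        ph = phasor_transform(single_bin_spectrum(f0, freqs), PhasorParams(tau=tau))
        assert ph.g[0, 0] == pytest.approx(np.cos(2 * np.pi * f0 * tau))
        assert ph.s[0, 0] == pytest.approx(np.sin(2 * np.pi * f0 * tau))

    def test_exponential_closed_form(self):
        fc, tau = 0.01, 4.0
        ph = phasor_transform(exponential_spectrum(fc), PhasorParams(tau=tau))
        beta = 2 * np.pi * tau * fc
        assert abs(ph.g[0, 0] - 1 / (1 + beta**2)) < 1e-3
        assert abs(ph.s[0, 0] - beta / (1 + beta**2)) < 1e-3

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        mags = rng.random((16, 2, 2)) + 0.1
        freqs = np.arange(1, 17) * 0.01
        a = phasor_transform(SpectrumStack(magnitudes=mags, freqs=freqs), PhasorParams(2.0))
        b = phasor_transform(SpectrumStack(magnitudes=37.0 * mags, freqs=freqs), PhasorParams(2.0))
        np.testing.assert_allclose(a.g, b.g, atol=1e-12)
        np.testing.assert_allclose(a.s, b.s, atol=1e-12)

    def test_mixture_lies_on_chord_with_amplitude_weights(self):
        # rectangle rule makes mixture linearity exact
        rng = np.random.default_rng(4)
        freqs = np.arange(1, 65) * 0.01
        A = rng.random(64) + 0.05
        B = rng.random(64) + 0.05
        w = 0.3
        mags = np.stack([A, B, w * A + (1 - w) * B], axis=-1)[:, None, :]
        ph = phasor_transform(SpectrumStack(magnitudes=mags, freqs=freqs), PhasorParams(2.5))
        lam = w * A.sum() / (w * A.sum() + (1 - w) * B.sum())
        np.testing.assert_allclose(
            ph.g[0, 2], lam * ph.g[0, 0] + (1 - lam) * ph.g[0, 1], atol=1e-12
        )
        np.testing.assert_allclose(
            ph.s[0, 2], lam * ph.s[0, 0] + (1 - lam) * ph.s[0, 1], atol=1e-12
        )

    def test_all_zero_rejected_and_invalid_flagged(self):
        freqs = np.arange(1, 17) * 0.01
        with pytest.raises(ValueError):
            phasor_transform(
                SpectrumStack(magnitudes=np.zeros((16, 2, 2)), freqs=freqs), PhasorParams(1.0)
            )
        mags = np.zeros((16, 1, 2))
        mags[:, 0, 0] = 1.0
        ph = phasor_transform(SpectrumStack(magnitudes=mags, freqs=freqs), PhasorParams(1.0))
        assert not ph.invalid[0, 0] and ph.invalid[0, 1]
        assert ph.g[0, 1] == 0.0 and ph.s[0, 1] == 0.0

    def test_default_tau_tracks_net_rate(self):
        assert default_tau(1.0) == 4.0
        assert default_tau(8.0) == 0.5
        assert default_prior_tau(1.0) == 2.6
        assert default_prior_tau(8.0) == 0.33


class TestSemicircle:
    def test_endpoint_and_arithmetic(self):
        assert semicircle_residual(1.0, 0.0) == pytest.approx(0.0)
        assert semicircle_residual(0.5, 0.6) == pytest.approx(0.11)

    def test_exponential_phasor_on_semicircle(self):
        fc, tau = 0.01, 4.0
        ph = phasor_transform(exponential_spectrum(fc), PhasorParams(tau=tau))
        assert abs(semicircle_residual(ph.g, ph.s)[0, 0]) < 1e-3

    def test_white_noise_phasor_matches_flat_spectrum(self):
        freqs = np.arange(1, 241) / 480.0
        flat = SpectrumStack(magnitudes=np.ones((240, 1, 1)), freqs=freqs)
        ph = phasor_transform(flat, PhasorParams(tau=2.6))
        gw, sw = white_noise_phasor(freqs, 2.6)
        assert ph.g[0, 0] == pytest.approx(gw, abs=0.02)
        assert ph.s[0, 0] == pytest.approx(sw, abs=0.02)


class TestSegmentation:
    def test_all_static_movie_empty_mask(self, caplog):
        movie = PhaseMovie(values=np.ones((16, 8, 8)), dt=1.0, pixel_size=0.2)
        st = temporal_spectrum(movie)
        with caplog.at_level("WARNING"):
            mask = segment_cells(st)
        assert not mask.any()

    def test_dynamic_disk_recovered(self):
        # noiseless movie: exponential dynamics inside a disk, static outside
        rng = np.random.default_rng(5)
        T, H, W = 128, 48, 48
        y, x = np.mgrid[:H, :W]
        disk = (y - 24) ** 2 + (x - 24) ** 2 <= 12**2
        from dqobm.synthetic import exponential_noise_traces

        traces = exponential_noise_traces(int(disk.sum()), T, 1.0, 0.05, rng)
        values = np.zeros((T, H, W))
        values[:, disk] = 0.15 * traces
        st = temporal_spectrum(PhaseMovie(values=values, dt=1.0, pixel_size=0.2))
        mask = segment_cells(st, prior_tau=2.6, amplitude_quantile=0.5)
        jac = (mask & disk).sum() / (mask | disk).sum()
        assert jac >= 0.9

    def test_invariant_to_global_offset(self):
        rng = np.random.default_rng(6)
        values = rng.standard_normal((32, 8, 8)) * 0.1
        a = segment_cells(temporal_spectrum(PhaseMovie(values, 1.0, 0.2)))
        b = segment_cells(temporal_spectrum(PhaseMovie(values + 5.0, 1.0, 0.2)))
        np.testing.assert_array_equal(a, b)


class TestPhasorHistogram:
    def test_single_pixel_and_conservation(self):
        freqs = np.arange(1, 17) * 0.01
        rng = np.random.default_rng(7)
        mags = rng.random((16, 4, 4)) + 0.1
        ph = phasor_transform(SpectrumStack(magnitudes=mags, freqs=freqs), PhasorParams(2.0))
        mask = np.zeros((4, 4), bool)
        mask[1, 2] = True
        hist = phasor_histogram(ph, mask, bins=16)
        assert hist.counts.sum() == 1
        full = phasor_histogram(ph, np.ones((4, 4), bool), bins=32)
        assert full.counts.sum() == 16

    def test_two_delta_populations_two_bins(self):
        freqs = np.arange(1, 33) * 0.01
        mags = np.zeros((32, 1, 6))
        mags[4, 0, :3] = 1.0  # population A: single bin
        mags[20, 0, 3:] = 1.0  # population B: another bin
        ph = phasor_transform(SpectrumStack(magnitudes=mags, freqs=freqs), PhasorParams(2.0))
        hist = phasor_histogram(ph, np.ones((1, 6), bool), bins=64)
        assert (hist.counts > 0).sum() == 2

    def test_minimum_bins_enforced(self):
        freqs = np.arange(1, 17) * 0.01
        mags = np.ones((16, 2, 2))
        ph = phasor_transform(SpectrumStack(magnitudes=mags, freqs=freqs), PhasorParams(2.0))
        with pytest.raises(ValueError):
            phasor_histogram(ph, None, bins=8)


def two_cluster_phasors(rng, n=400):
    """PhasorMap-like fixture with two synthetic clusters and its histogram."""
    from dqobm.dynamics import PhasorMap

    a = np.array([0.9, 0.15]) + 0.02 * rng.standard_normal((n, 2))
    b = np.array([0.4, 0.5]) + 0.02 * rng.standard_normal((n, 2))
    pts = np.concatenate([a, b])
    g = pts[:, 0][None, :]
    s = pts[:, 1][None, :]
    ph = PhasorMap(
        g=g, s=s, amplitude=np.ones_like(g), tau=4.0, invalid=np.zeros_like(g, bool)
    )
    mask = np.ones_like(g, bool)
    hist = phasor_histogram(ph, mask, bins=64)
    return ph, mask, hist, np.array([1] * n + [2] * n)


class TestBranches:
    def test_manual_endmember_positions(self):
        from dqobm.dynamics import PhasorMap

        g = np.array([[0.9, 1.0, 0.4]])
        s = np.array([[0.15, 0.0, 0.5]])
        ph = PhasorMap(g=g, s=s, amplitude=np.ones_like(g), tau=4.0,
                       invalid=np.zeros_like(g, bool))
        mask = np.ones_like(g, bool)
        hist = phasor_histogram(ph, mask, bins=16)
        model = fit_branches(
            hist, ph, mask, mode="manual_rois",
            root=(1.0, 0.0), endmembers=[(0.9, 0.15), (0.4, 0.5)],
        )
        assert model.positions[0, 0] == pytest.approx(1.0)  # at endmember 1
        assert model.labels[0, 0] == 1
        assert model.positions[0, 1] == pytest.approx(0.0)  # at the root
        assert model.positions[0, 2] == pytest.approx(1.0)  # at endmember 2
        assert model.labels[0, 2] == 2

    def test_degenerate_geometry_rejected(self):
        from dqobm.dynamics import PhasorMap

        g = np.array([[0.5]])
        s = np.array([[0.2]])
        ph = PhasorMap(g=g, s=s, amplitude=np.ones_like(g), tau=4.0,
                       invalid=np.zeros_like(g, bool))
        mask = np.ones_like(g, bool)
        hist = phasor_histogram(ph, mask, bins=16)
        with pytest.raises(ValueError, match="degenerate"):
            fit_branches(hist, ph, mask, mode="manual_rois",
                         root=(1.0, 0.0), endmembers=[(1.0, 0.0), (0.4, 0.5)])

    def test_auto_mode_recovers_two_clusters(self):
        rng = np.random.default_rng(8)
        ph, mask, hist, truth = two_cluster_phasors(rng)
        model = fit_branches(hist, ph, mask, mode="auto")
        lab = model.labels[mask]
        ok = lab > 0
        acc = max(
            ((lab == 1) & (truth == 1)).sum() + ((lab == 2) & (truth == 2)).sum(),
            ((lab == 1) & (truth == 2)).sum() + ((lab == 2) & (truth == 1)).sum(),
        ) / ok.sum()
        assert acc >= 0.95
        # branch 1 is the slower cluster (closer to the static point)
        e1, e2 = np.asarray(model.endmembers)
        assert np.hypot(e1[0] - 1, e1[1]) < np.hypot(e2[0] - 1, e2[1])

    def test_mixture_positions_monotone_in_weight(self):
        # pixels built as w*A + (1-w)*B spectra: positions along the A->B
        # chord must be monotone in w (Spearman rho > 0.99)
        from dqobm.dynamics import PhasorMap

        freqs = np.arange(1, 129) * 0.005
        A = np.exp(-freqs / 0.005)
        B = np.exp(-freqs / 0.05)
        ws = np.linspace(0, 1, 51)
        mags = np.stack([w * A + (1 - w) * B for w in ws], axis=-1)[:, None, :]
        ph = phasor_transform(
            SpectrumStack(magnitudes=mags, freqs=freqs), PhasorParams(4.0)
        )
        mask = np.ones_like(ph.g, bool)
        hist = phasor_histogram(ph, mask, bins=32)
        pa = (float(ph.g[0, -1]), float(ph.s[0, -1]))  # pure A (w=1)
        pb = (float(ph.g[0, 0]), float(ph.s[0, 0]))  # pure B (w=0)
        model = fit_branches(hist, ph, mask, mode="manual_rois", root=pa,
                             endmembers=[pb, (1.0, 0.0)])
        rho = spearmanr(ws, model.positions[0]).statistic
        assert rho < -0.99  # position decreases as w (share of A) grows


class TestColorize:
    def _model(self, shape, labels, positions):
        return BranchModel(root=(1.0, 0.0), endmembers=((0.9, 0.15), (0.4, 0.5)),
                           labels=labels, positions=positions)

    def test_background_is_black_and_cells_saturated(self):
        from dqobm.dynamics import PhasorMap

        g = np.array([[0.9, 0.4]])
        ph = PhasorMap(g=g, s=g, amplitude=np.ones_like(g), tau=4.0,
                       invalid=np.zeros_like(g, bool))
        mask = np.array([[True, False]])
        labels = np.array([[1, 0]])
        pos = np.array([[0.0, 0.0]])
        img = colorize(ph, mask, self._model(mask.shape, labels, pos))
        np.testing.assert_array_equal(img.rgb[0, 1], [0, 0, 0])
        assert img.value[0, 0] == 1.0 and img.value[0, 1] == 0.0
        assert img.saturation[0, 0] == 1.0
        # branch 1 at position 0 renders red
        np.testing.assert_allclose(img.rgb[0, 0], [1, 0, 0], atol=1e-12)

    def test_hue_monotone_in_position(self):
        pos = np.linspace(0, 1, 11)
        h1 = branch_hue(1, pos) * 360
        assert np.all(np.diff(h1) > 0)
        assert h1[0] == 0.0 and h1[-1] == pytest.approx(240.0)
        h2 = np.array([branch_hue(2, p) * 360 for p in pos[1:]])
        assert np.all(np.diff(h2) < 0)  # red -> magenta -> purple, decreasing
        assert h2[-1] == pytest.approx(300.0)

    def test_spectral_smoothing_preserves_total_mass(self):
        rng = np.random.default_rng(9)
        st = SpectrumStack(magnitudes=rng.random((16, 16, 16)), freqs=np.arange(1, 17) * 0.01)
        sm = smooth_spectra(st, 2.0)
        assert sm.magnitudes.sum() == pytest.approx(st.magnitudes.sum(), rel=1e-6)


class TestPhasorProperties:
    """Hypothesis property tests for the phasor transform invariants."""

    def test_phasor_inside_unit_disk_and_scale_invariant(self):
        from hypothesis import given, settings, strategies as st
        from hypothesis.extra import numpy as hnp

        freqs = np.arange(1, 33) * 0.01

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(
            mags=hnp.arrays(
                float, (32, 1, 1),
                elements=st.floats(0.0, 10.0, allow_nan=False),
            ).filter(lambda a: a.sum() > 1e-6),
            tau=st.floats(0.0, 20.0, allow_nan=False),
            scale=st.floats(1e-3, 1e3),
        )
        def check(mags, tau, scale):
            st_ = SpectrumStack(magnitudes=mags, freqs=freqs)
            ph = phasor_transform(st_, PhasorParams(tau=tau))
            # normalized moments of a nonnegative measure stay in the unit disk
            assert ph.g[0, 0] ** 2 + ph.s[0, 0] ** 2 <= 1 + 1e-9
            scaled = phasor_transform(
                SpectrumStack(magnitudes=scale * mags, freqs=freqs),
                PhasorParams(tau=tau),
            )
            assert abs(scaled.g[0, 0] - ph.g[0, 0]) < 1e-9
            assert abs(scaled.s[0, 0] - ph.s[0, 0]) < 1e-9

        check()
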