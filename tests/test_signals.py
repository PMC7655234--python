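"""Surrogate-signal extraction: trimming, tracking, PCA, resampling."""

import numpy as np
import pytest
from scipy.special import erf

from cinemotion.exceptions import MaskError, SteadyStateError, TrackingError
from cinemotion.grid import ControlPointGrid
from cinemotion.series import CineSeries
from cinemotion.signals import (
    SurrogateSignal,
    derivative_signal,
    diaphragm_signal,
    discard_pre_steady_state,
    make_body_mask,
    pca_cpd,
    pca_intensity,
    resample_signal,
    select_reference_frame,
    skin_signal,
    track_edge,
)

SP = 1.98


def edge_series(shifts_px, shape=(40, 40), axis="SI", sigma=1.2, noise=0.0, seed=0):
    """Frames containing an erf-profile edge at analytically known positions."""
    rng = np.random.default_rng(seed)
    frames = []
    base = 20.0
    for s in shifts_px:
        coord = np.arange(shape[0] if axis == "SI" else shape[1], dtype=float)
        profile = 0.5 * (1.0 + erf((coord - (base + s)) / (sigma * np.sqrt(2))))
        if axis == "SI":
            frame = np.tile(profile[:, None], (1, shape[1]))
        else:
            frame = np.tile(profile[None, :], (shape[0], 1))
        frames.append(frame + rng.normal(0, noise, shape))
    return CineSeries(np.stack(frames), np.arange(len(shifts_px), dtype=float), SP)


class TestSteadyState:
    def test_constant_series_discards_nothing(self):
        frames = np.ones((10, 8, 8))
        series = CineSeries(frames, np.arange(10.0), SP)
        trimmed, n = discard_pre_steady_state(series)
        assert n == 0 and len(trimmed) == 10

    def test_three_inflated_leading_frames_detected(self):
        """Oracle: direct mean-intensity scan of the constructed series."""
        frames = np.ones((20, 8, 8))
        for i, f in enumerate([1.2, 1.2, 1.2]):
            frames[i] *= f
        series = CineSeries(frames, np.arange(20.0), SP)
        trimmed, n = discard_pre_steady_state(series, relative_threshold=0.05)
        assert n == 3
        assert np.allclose(trimmed.mean_intensities(), 1.0)

    def test_interior_bright_frame_is_kept(self):
        frames = np.ones((20, 8, 8))
        frames[0] *= 1.3
        frames[10] *= 1.3  # not leading: must stay
        series = CineSeries(frames, np.arange(20.0), SP)
        trimmed, n = discard_pre_steady_state(series, 0.05)
        assert n == 1 and len(trimmed) == 19

    def test_realistic_acquisition_discards_a_few_frames(self, small_dataset):
        trimmed, n = discard_pre_steady_state(small_dataset.surrogate)
        assert 2 <= n <= 5

    def test_no_steady_state_is_an_error(self):
        # a cutoff below every frame mean means no steady state is ever reached
        frames = np.ones((5, 8, 8))
        series = CineSeries(frames, np.arange(5.0), SP)
        with pytest.raises(SteadyStateError):
            discard_pre_steady_state(series, relative_threshold=-0.5)


class TestTrackEdge:
    def test_static_frames_give_zero_signal(self):
        series = edge_series(np.zeros(8))
        sig = track_edge(series, (20, 20), (16, 8), axis="SI")
        assert np.abs(sig.sample_values).max() < 1e-9

    def test_half_pixel_steps_recovered_subpixel(self):
        """Oracle: the erf edge is placed at analytically known positions."""
        shifts = 0.5 * np.arange(8)
        series = edge_series(shifts)
        sig = track_edge(series, (21, 20), (16, 8), axis="SI", positive_direction=1)
        recovered_px = sig.sample_values / SP
        err = (recovered_px - recovered_px.mean()) - (shifts - shifts.mean())
        assert np.sqrt(np.mean(err**2)) < 0.1

    def test_window_size_honoured_and_bounds_checked(self):
        series = edge_series(np.zeros(3))
        track_edge(series, (20, 20), (20, 6), axis="SI")  # fits
        with pytest.raises(ValueError):
            track_edge(series, (20, 20), (50, 6), axis="SI")  # SI extent too large

    def test_flat_window_reports_failing_frames(self):
        series = edge_series(np.zeros(3))
        with pytest.raises(TrackingError, match="frame"):
            track_edge(series, (8, 32), (6, 6), axis="SI")  # windows far from the edge

    def test_intensity_offset_invariance(self):
        series = edge_series(0.3 * np.arange(6))
        shifted = CineSeries(series.frames + 11.0, series.times_s, SP)
        a = track_edge(series, (21, 20), (16, 8), axis="SI")
        b = track_edge(shifted, (21, 20), (16, 8), axis="SI")
        assert np.abs(a.sample_values - b.sample_values).max() < 1e-9

    def test_translation_equivariance(self):
        series = edge_series(0.3 * np.arange(6))
        rolled = CineSeries(np.roll(series.frames, 3, axis=1), series.times_s, SP)
        a = track_edge(series, (21, 20), (16, 8), axis="SI")
        b = track_edge(rolled, (24, 20), (16, 8), axis="SI")
        assert np.abs(a.sample_values - b.sample_values).max() < 1e-9
        assert np.allclose(b.positions_px - a.positions_px, 3.0, atol=1e-9)


class TestAnatomicalSignals:
    def test_diaphragm_signal_matches_ground_truth_excursion(self, small_dataset):
        """Oracle: the ground-truth DVF at the diaphragm point."""
        ds = small_dataset
        sig = diaphragm_signal(ds.surrogate, ds.phantom.diaphragm_seed_point)
        r, c = ds.phantom.diaphragm_seed_point
        truth = np.array(
            [
                -ds.ground_truth.dvf_at(t).displacements[r, c, 0]
                for t in ds.surrogate.times_s
            ]
        )
        truth -= truth.mean()
        assert np.ptp(sig.sample_values) == pytest.approx(np.ptp(truth), rel=0.10)
        assert np.corrcoef(sig.sample_values, truth)[0, 1] > 0.99
        assert abs(sig.sample_values.mean()) < 1e-9

    def test_skin_signal_positive_at_exhale(self, small_dataset):
        ds = small_dataset
        sig = skin_signal(ds.surrogate, ds.phantom.skin_seed_point)
        p, _ = ds.trace.value_at(ds.surrogate.times_s)
        assert np.corrcoef(sig.sample_values, p)[0, 1] > 0.9

    def test_zero_motion_signal_below_noise_bound(self, phantom):
        frames = np.stack([phantom.reference_image] * 10)
        rng = np.random.default_rng(0)
        frames = frames + rng.normal(0, 0.02 * np.ptp(frames), frames.shape)
        series = CineSeries(frames, np.arange(10.0), SP)
        sig = diaphragm_signal(series, phantom.diaphragm_seed_point)
        assert sig.sample_values.std() < 0.2 * SP


class TestBodyMask:
    def test_phantom_mask_covers_body_and_excludes_corners(self, phantom, rng):
        frame = phantom.reference_image + rng.normal(0, 0.01, phantom.reference_image.shape)
        mask = make_body_mask(frame, closing_radius_px=30)
        from scipy.ndimage import binary_erosion

        core = binary_erosion(phantom.body_mask, iterations=31)
        assert np.all(mask[core])
        assert not mask[:4, :4].any() and not mask[-4:, -4:].any()

    def test_constant_image_is_an_error(self):
        with pytest.raises(MaskError):
            make_body_mask(np.ones((32, 32)))

    def test_closing_radius_controls_lung_inclusion(self, phantom):
        lung_px = (40, 55)
        small = make_body_mask(phantom.reference_image, closing_radius_px=0)
        large = make_body_mask(phantom.reference_image, closing_radius_px=30)
        assert not small[lung_px]
        assert large[lung_px]


class TestReferenceFrame:
    def _sig(self, values):
        return SurrogateSignal("diaphragm", np.arange(len(values), dtype=float), np.asarray(values, float))

    def test_linear_drift_returns_middle(self):
        values = np.linspace(0, 10, 30)
        series = CineSeries(np.zeros((30, 4, 4)), np.arange(30.0), SP)
        idx = select_reference_frame(series, self._sig(values), k=30)
        assert idx in (14, 15)

    def test_constant_returns_first_by_tiebreak(self):
        series = CineSeries(np.zeros((30, 4, 4)), np.arange(30.0), SP)
        assert select_reference_frame(series, self._sig(np.ones(30)), k=30) == 0

    def test_sinusoid_matches_direct_argmin(self):
        t = np.arange(40.0)
        values = 7.5 * np.sin(2 * np.pi * t / 10)  # whole cycles in k=30
        series = CineSeries(np.zeros((40, 4, 4)), t, SP)
        idx = select_reference_frame(series, self._sig(values), k=30)
        head = values[:30]
        assert idx == int(np.argmin(np.abs(head - head.mean())))
        assert abs(values[idx] - head.mean()) < 0.05 * 7.5 * 2

    def test_short_series_warns_and_uses_all(self):
        series = CineSeries(np.zeros((10, 4, 4)), np.arange(10.0), SP)
        with pytest.warns(UserWarning):
            select_reference_frame(series, self._sig(np.arange(10.0)), k=30)


class TestPca:
    def test_rank_one_series_recovered(self, rng):
        pattern = rng.normal(size=(12, 12))
        alphas = rng.normal(size=9)
        frames = np.stack([a * pattern for a in alphas]) + 3.0
        series = CineSeries(frames, np.arange(9.0), SP)
        res = pca_intensity(series, n_components=2)
        assert res.explained_variance_fraction[0] > 0.999
        corr = np.corrcoef(res.coefficient_maps[0].ravel(), pattern.ravel())[0, 1]
        assert abs(corr) > 0.9999

    def test_matches_covariance_eigendecomposition(self, rng):
        """Oracle: direct eigensolve of the feature covariance matrix."""
        frames = rng.normal(size=(6, 5, 5))
        series = CineSeries(frames, np.arange(6.0), SP)
        res = pca_intensity(series, n_components=3)
        flat = frames.reshape(6, -1)
        centred = flat - flat.mean(axis=0)
        cov = centred.T @ centred
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        for j in range(3):
            v = evecs[:, order[j]]
            mine = res.coefficient_maps[j].ravel()
            sign = np.sign(v @ mine)
            assert np.abs(mine - sign * v).max() < 1e-8
            scores = centred @ (sign * v)
            assert np.abs(scores - res.component_scores[:, j]).max() < 1e-8

    def test_variance_spectrum_sums_to_one(self, rng):
        frames = rng.normal(size=(8, 6, 6))
        res = pca_intensity(CineSeries(frames, np.arange(8.0), SP), 3)
        assert abs(res.variance_spectrum.sum() - 1.0) < 1e-9
        assert np.all(np.diff(res.explained_variance_fraction) <= 1e-12)

    def test_scores_have_zero_mean(self, rng):
        frames = rng.normal(size=(8, 6, 6))
        res = pca_intensity(CineSeries(frames, np.arange(8.0), SP), 3)
        assert np.abs(res.component_scores.mean(axis=0)).max() < 1e-8

    def test_too_few_frames_rejected(self, rng):
        frames = rng.normal(size=(3, 6, 6))
        with pytest.raises(ValueError):
            pca_intensity(CineSeries(frames, np.arange(3.0), SP), 3)


def _cpd_series(rng, n_frames=8, shape=(6, 7), rank2=True):
    base = ControlPointGrid(np.array([-10.0, -10.0]), np.array([10.0, 10.0]), np.zeros(shape + (2,)))
    m1 = rng.normal(size=shape + (2,))
    m2 = rng.normal(size=shape + (2,))
    grids = []
    for i in range(n_frames):
        a, b = np.sin(i), np.cos(2 * i)
        disp = a * m1 + (b * m2 if rank2 else 0)
        grids.append(base.with_displacements(disp))
    return grids


class TestPcaCpd:
    def test_rank_two_cpds_need_two_components(self, rng):
        grids = _cpd_series(rng)
        mask = np.ones((64, 64), bool)
        res = pca_cpd(grids, mask, (1.98, 1.98), n_components=3)
        assert res.explained_variance_fraction[:2].sum() > 0.999

    def test_zero_motion_gives_zero_scores(self, rng):
        grids = _cpd_series(rng)
        for g in grids:
            g.displacements[:] = 0
        res = pca_cpd(grids, np.ones((64, 64), bool), (1.98, 1.98), n_components=2)
        assert np.abs(res.component_scores).max() < 1e-12

    def test_body_mask_excludes_outside_points(self, rng):
        grids = _cpd_series(rng)
        mask = np.zeros((64, 64), bool)
        mask[0:25, 0:25] = True  # only a corner of control points inside
        res = pca_cpd(grids, mask, (1.98, 1.98), n_components=2)
        assert res.retained_mask.sum() < np.prod(grids[0].grid_shape)
        # loadings vanish on excluded points
        assert np.abs(res.coefficient_maps[0][~res.retained_mask]).max() == 0.0

    def test_empty_mask_is_an_error(self, rng):
        grids = _cpd_series(rng)
        with pytest.raises(MaskError):
            pca_cpd(grids, np.zeros((64, 64), bool), (1.98, 1.98))

    def test_pc1_tracks_true_primary_on_default_study(self, default_run):
        """End-to-end invariant: PCA on CPD_s recovers the breathing mode."""
        ex = default_run["extraction"]
        ds = default_run["dataset"]
        surr = ex["surrogate_trimmed"]
        p, _ = ds.trace.value_at(surr.times_s)
        r = np.corrcoef(ex["pca_cpd"].component_scores[:, 0], p)[0, 1]
        assert abs(r) > 0.95
        assert r > 0  # sign convention: positive peaks at end-exhale


class TestResampling:
    def test_zero_smoothing_interpolates_samples(self, rng):
        t = np.linspace(0, 10, 25)
        sig = SurrogateSignal("x", t, rng.normal(size=25))
        out, rejected = resample_signal(sig, t, smoothing_level=0.0)
        assert rejected == []
        assert np.abs(out.sample_values - sig.sample_values).max() < 1e-9

    def test_cubic_polynomial_reproduced_at_midpoints(self):
        t = np.linspace(0, 10, 30)
        poly = lambda x: 0.3 * x**3 - x**2 + 2 * x - 1
        sig = SurrogateSignal("p", t, poly(t))
        mid = 0.5 * (t[:-1] + t[1:])
        out, _ = resample_signal(sig, mid, smoothing_level=0.0)
        assert np.abs(out.sample_values - poly(mid)).max() < 1e-6

    def test_out_of_span_targets_rejected_not_clipped(self):
        t = np.linspace(0, 10, 20)
        sig = SurrogateSignal("x", t, np.sin(t))
        out, rejected = resample_signal(sig, np.array([-1.0, 5.0, 10.5]))
        assert rejected == [0, 2]
        assert np.array_equal(out.sample_times_s, [5.0])


class TestDerivative:
    def test_constant_signal_has_zero_derivative(self):
        t = np.linspace(0, 10, 30)
        sig, _ = resample_signal(SurrogateSignal("c", t, np.full(30, 3.3)), t)
        d = derivative_signal(sig)
        assert np.abs(d.sample_values).max() < 1e-9
        assert d.units == "mm/s"

    def test_sine_derivative_matches_closed_form(self):
        f = 0.25
        t = np.linspace(0, 12, 400)
        sig, _ = resample_signal(SurrogateSignal("s", t, np.sin(2 * np.pi * f * t)), t)
        d = derivative_signal(sig)
        expected = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        interior = slice(10, -10)
        rms = np.sqrt(np.mean((d.sample_values[interior] - expected[interior]) ** 2))
        assert rms < 0.02 * (2 * np.pi * f)

    def test_derivative_orthogonal_to_cosine_over_whole_cycles(self):
        t = np.linspace(0, 8, 500)  # two whole cycles of f=0.25
        sig, _ = resample_signal(SurrogateSignal("c", t, np.cos(2 * np.pi * 0.25 * t)), t)
        d = derivative_signal(sig)
        r = np.corrcoef(sig.sample_values, d.sample_values)[0, 1]
        assert abs(r) < 0.05

    def test_unfitted_signal_rejected(self):
        sig = SurrogateSignal("raw", np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError):
            derivative_signal(sig)
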