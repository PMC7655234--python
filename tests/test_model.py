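"""Linear correspondence models: design matrices, OLS fit, prediction."""

import numpy as np
import pytest

from cinemotion.grid import ControlPointGrid, SlidingTransform, compose_sliding_dvf
from cinemotion.model import (
    ModelSpec,
    SignalTerm,
    build_design_matrix,
    default_model_zoo,
    estimate,
    fit,
    no_model_baseline,
    predict_displacements,
)
from cinemotion.signals import SurrogateSignal, resample_signal

GRID_SHAPE = (5, 6)


def _signal(name, t, v):
    sig, _ = resample_signal(SurrogateSignal(name, t, v), t, smoothing_level=0.0)
    sig.name = name
    return sig


def _transforms(design, coeffs, seg_shape=(32, 32)):
    """Exact linear transforms: CPD = design @ coeffs per component."""
    base = ControlPointGrid(np.array([-12.0, -12.0]), np.array([12.0, 12.0]),
                           np.zeros(GRID_SHAPE + (2,)))
    seg = np.zeros(seg_shape, bool)
    seg[8:24, 8:24] = True
    out = []
    values = np.einsum("tk,krijd->trijd", design, coeffs)
    for t in range(design.shape[0]):
        grids = [base.with_displacements(values[t, :, :, :, :][r]) for r in range(2)]
        out.append(SlidingTransform(grids, seg))
    return out, seg


@pytest.fixture
def true_coeffs(rng):
    # (k+1, regions, gr, gc, 2) with k = 2 signals
    return rng.normal(0, 3, (3, 2) + GRID_SHAPE + (2,))


class TestDesignMatrix:
    def test_columns_follow_spec_order_plus_intercept(self):
        t = np.linspace(0, 6, 8)
        signals = {
            "diaphragm": _signal("diaphragm", t, np.sin(t)),
            "skin": _signal("skin", t, np.cos(t)),
        }
        spec = ModelSpec("dia+skin", (SignalTerm("diaphragm"), SignalTerm("skin")))
        times = t[:4]
        design = build_design_matrix(spec, signals, times)
        assert design.shape == (4, 3)
        assert np.abs(design[:, 0] - np.sin(times)).max() < 1e-9
        assert np.abs(design[:, 1] - np.cos(times)).max() < 1e-9
        assert np.array_equal(design[:, 2], np.ones(4))

    def test_derivative_of_constant_flags_rank_deficiency(self, true_coeffs):
        t = np.linspace(0, 6, 10)
        signals = {"diaphragm": _signal("diaphragm", t, np.full_like(t, 2.0))}
        spec = ModelSpec(
            "dia+deriv", (SignalTerm("diaphragm"), SignalTerm("diaphragm", derivative=True))
        )
        design = build_design_matrix(spec, signals, t)
        assert np.abs(design[:, 1]).max() < 1e-9
        transforms, _ = _transforms(design, true_coeffs)
        with pytest.warns(UserWarning, match="collinear"):
            model = fit(spec, design, transforms)
        assert model.fit_warnings

    def test_zoo_has_ten_models(self):
        zoo = default_model_zoo()
        assert len(zoo) == 10
        assert sum(spec.n_signals == 2 for spec in zoo) == 7
        assert sum(spec.n_signals == 3 for spec in zoo) == 3
        assert len({spec.name for spec in zoo}) == 10

    def test_out_of_span_times_rejected(self):
        t = np.linspace(0, 6, 8)
        signals = {"diaphragm": _signal("diaphragm", t, np.sin(t))}
        spec = ModelSpec("d", (SignalTerm("diaphragm"),))
        with pytest.raises(ValueError, match="span"):
            build_design_matrix(spec, signals, np.array([7.0]))


class TestFit:
    def test_exact_linear_targets_recover_coefficients(self, rng, true_coeffs):
        t = np.linspace(0, 10, 12)
        design = np.column_stack([np.sin(t), np.cos(2 * t), np.ones_like(t)])
        transforms, _ = _transforms(design, true_coeffs)
        spec = ModelSpec("true2", (SignalTerm("s1"), SignalTerm("s2")))
        model = fit(spec, design, transforms)
        recovered = np.moveaxis(model.coefficients, -1, 0)
        assert np.abs(recovered - true_coeffs).max() < 1e-8
        assert model.training_residual_rms < 1e-8

    def test_intercept_only_fit_is_the_mean(self, rng, true_coeffs):
        design = np.ones((7, 1))
        transforms, _ = _transforms(
            np.column_stack([np.arange(7.0), np.zeros(7), np.ones(7)]), true_coeffs
        )
        spec = ModelSpec("none", ())
        model = fit(spec, design, transforms)
        target_mean = np.mean(
            [np.stack([tr.region_grids[r].displacements for r in range(2)]) for tr in transforms],
            axis=0,
        )
        assert np.abs(model.coefficients[..., 0] - target_mean).max() < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        """Oracle: explicit (X^T X)^-1 X^T y on a well-conditioned design."""
        design = rng.normal(size=(12, 3))
        targets = rng.normal(size=(12, 40))
        coef_oracle = np.linalg.inv(design.T @ design) @ design.T @ targets
        base = ControlPointGrid(np.array([-12.0, -12.0]), np.array([12.0, 12.0]),
                               np.zeros((2, 5, 2)))
        seg = np.zeros((16, 16), bool)
        transforms = [
            SlidingTransform(
                [base.with_displacements(targets[t, :20].reshape(2, 5, 2)),
                 base.with_displacements(targets[t, 20:].reshape(2, 5, 2))], seg
            )
            for t in range(12)
        ]
        spec = ModelSpec("r", (SignalTerm("a"), SignalTerm("b")))
        model = fit(spec, design, transforms)
        flat = model.coefficients.reshape(-1, 3).T  # (k+1, components)
        assert np.abs(flat - coef_oracle).max() < 1e-8

    def test_underdetermined_fit_rejected(self, true_coeffs):
        design = np.ones((2, 3))
        transforms, _ = _transforms(np.ones((2, 3)), true_coeffs)
        with pytest.raises(ValueError, match="cannot fit"):
            fit(ModelSpec("x", (SignalTerm("a"), SignalTerm("b"))), design, transforms)

    def test_residuals_orthogonal_to_design(self, rng, true_coeffs):
        t = np.linspace(0, 10, 15)
        design = np.column_stack([np.sin(t), np.cos(2 * t), np.ones_like(t)])
        transforms, _ = _transforms(design, true_coeffs)
        noisy = []
        for tr in transforms:
            tr2 = tr.copy()
            for g in tr2.region_grids:
                g.displacements += rng.normal(0, 0.5, g.displacements.shape)
            noisy.append(tr2)
        spec = ModelSpec("n", (SignalTerm("a"), SignalTerm("b")))
        model = fit(spec, design, noisy)
        targets = np.stack(
            [np.concatenate([g.displacements.ravel() for g in tr.region_grids]) for tr in noisy]
        )
        coef = model.coefficients.reshape(-1, 3).T
        resid = targets - design @ coef
        scale = np.abs(targets).max()
        assert np.abs(design.T @ resid).max() < 1e-6 * scale

    def test_prediction_invariant_to_signal_rescaling(self, rng, true_coeffs):
        t = np.linspace(0, 10, 14)
        s1, s2 = np.sin(t), np.cos(2 * t)
        design = np.column_stack([s1, s2, np.ones_like(t)])
        transforms, _ = _transforms(design, true_coeffs)
        spec = ModelSpec("m", (SignalTerm("a"), SignalTerm("b")))
        model_a = fit(spec, design, transforms)
        design_b = np.column_stack([3.0 * s1 - 2.0, s2, np.ones_like(t)])
        model_b = fit(spec, design_b, transforms)
        test_rows_a = np.array([[0.3, -0.4, 1.0], [0.9, 0.1, 1.0]])
        test_rows_b = test_rows_a.copy()
        test_rows_b[:, 0] = 3.0 * test_rows_a[:, 0] - 2.0
        pa = predict_displacements(model_a, test_rows_a)
        pb = predict_displacements(model_b, test_rows_b)
        assert np.abs(pa - pb).max() < 1e-8

    def test_third_signal_never_increases_training_residual(self, rng, true_coeffs):
        t = np.linspace(0, 10, 16)
        design3 = np.column_stack([np.sin(t), np.cos(2 * t), np.sin(3 * t), np.ones_like(t)])
        transforms, _ = _transforms(design3[:, [0, 1, 3]], true_coeffs)
        noisy = []
        for tr in transforms:
            tr2 = tr.copy()
            for g in tr2.region_grids:
                g.displacements += rng.normal(0, 0.5, g.displacements.shape)
            noisy.append(tr2)
        m2 = fit(ModelSpec("two", (SignalTerm("a"), SignalTerm("b"))), design3[:, [0, 1, 3]], noisy)
        m3 = fit(
            ModelSpec("three", (SignalTerm("a"), SignalTerm("b"), SignalTerm("c"))), design3, noisy
        )
        assert m3.training_residual_rms <= m2.training_residual_rms + 1e-12

    def test_coefficient_recovery_unbiased_under_noise(self, true_coeffs):
        """Stochastic: mean recovery error over 200 noisy refits is ~zero."""
        t = np.linspace(0, 10, 12)
        design = np.column_stack([np.sin(t), np.cos(2 * t), np.ones_like(t)])
        clean, _ = _transforms(design, true_coeffs)
        sigma = 0.8
        spec = ModelSpec("m", (SignalTerm("a"), SignalTerm("b")))
        errors = []
        for seed in range(200):
            local = np.random.default_rng(seed)
            noisy = []
            for tr in clean:
                tr2 = tr.copy()
                for g in tr2.region_grids:
                    g.displacements += local.normal(0, sigma, g.displacements.shape)
                noisy.append(tr2)
            model = fit(spec, design, noisy)
            errors.append(np.moveaxis(model.coefficients, -1, 0) - true_coeffs)
        mean_err = np.abs(np.mean(errors, axis=0))
        assert mean_err.max() < 0.1 * sigma


class TestEstimateAndBaseline:
    def test_zero_signals_return_intercepts(self, rng, true_coeffs):
        t = np.linspace(0, 10, 12)
        design = np.column_stack([np.sin(t), np.cos(2 * t), np.ones_like(t)])
        transforms, _ = _transforms(design, true_coeffs)
        spec = ModelSpec("m", (SignalTerm("a"), SignalTerm("b")))
        model = fit(spec, design, transforms)
        est = estimate(model, np.zeros(2))
        for r in range(2):
            assert np.abs(
                est.region_grids[r].displacements - model.coefficients[r][..., -1]
            ).max() < 1e-8

    def test_training_inputs_reproduce_training_cpds(self, rng, true_coeffs):
        t = np.linspace(0, 10, 12)
        design = np.column_stack([np.sin(t), np.cos(2 * t), np.ones_like(t)])
        transforms, _ = _transforms(design, true_coeffs)
        spec = ModelSpec("m", (SignalTerm("a"), SignalTerm("b")))
        model = fit(spec, design, transforms)
        est = estimate(model, design[4, :2])
        for r in range(2):
            assert np.abs(
                est.region_grids[r].displacements - transforms[4].region_grids[r].displacements
            ).max() < 1e-8

    def test_unit_basis_vector_isolates_one_coefficient(self, rng, true_coeffs):
        t = np.linspace(0, 10, 12)
        design = np.column_stack([np.sin(t), np.cos(2 * t), np.ones_like(t)])
        transforms, _ = _transforms(design, true_coeffs)
        model = fit(ModelSpec("m", (SignalTerm("a"), SignalTerm("b"))), design, transforms)
        est = estimate(model, np.array([1.0, 0.0]))
        expected = model.coefficients[..., 0] + model.coefficients[..., -1]
        for r in range(2):
            assert np.abs(est.region_grids[r].displacements - expected[r]).max() < 1e-10

    def test_wrong_signal_count_rejected(self, rng, true_coeffs):
        design = np.column_stack([np.sin(np.arange(8.0)), np.ones(8)])
        transforms, _ = _transforms(design, true_coeffs[:2])
        model = fit(ModelSpec("m", (SignalTerm("a"),)), design, transforms)
        with pytest.raises(ValueError):
            estimate(model, np.zeros(3))

    def test_no_model_baseline_composes_to_zero_dvf(self, rng, true_coeffs):
        design = np.column_stack([np.sin(np.arange(8.0)), np.ones(8)])
        transforms, seg = _transforms(design, true_coeffs[:2])
        baseline = no_model_baseline(transforms[0])
        dvf = compose_sliding_dvf(baseline, seg.shape, (1.98, 1.98))
        assert np.abs(dvf.displacements).max() == 0.0
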