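"""Linear surrogate-driven correspondence models.

Each component of the control-point displacement (every control point x
displacement direction x sliding region) is modelled as a linear function
of two or three surrogate signals,

    M_i(s_1, s_2)      = c_2 s_2 + c_1 s_1 + c_0
    M_i(s_1, s_2, s_3) = c_3 s_3 + c_2 s_2 + c_1 s_1 + c_0,

with the coefficients determined by an ordinary least squares fit to the
training motion measurements.  Signals enter raw (no centering or
standardization); the intercept absorbs offsets, so the fit is equivariant
under affine re-scaling of any signal.  The standard model zoo pairs each
signal with either its temporal derivative or an independent second
signal, plus a no-model baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import SlidingTransform
from .signals import SurrogateSignal, derivative_signal

__all__ = [
    "SignalTerm",
    "ModelSpec",
    "CorrespondenceModel",
    "build_design_matrix",
    "fit",
    "estimate",
    "no_model_baseline",
    "default_model_zoo",
]

CONDITION_WARN_THRESHOLD = 1e10


@dataclass(frozen=True)
class SignalTerm:
    """One design column: a surrogate signal or its temporal derivative."""

    signal: str
    derivative: bool = False

    def label(self) -> str:
        return self.signal + ("_deriv" if self.derivative else "")


@dataclass(frozen=True)
class ModelSpec:
    """A named combination of surrogate signals driving one motion model."""

    name: str
    terms: tuple

    @property
    def n_signals(self) -> int:
        return len(self.terms)

    @property
    def uses_derivative(self) -> bool:
        return any(t.derivative for t in self.terms)

    @property
    def signal_names(self) -> tuple:
        return tuple(t.signal for t in self.terms)

    @property
    def internal_only(self) -> bool:
        """True when every driving signal reflects internal anatomy.

        The skin surface is the body-surface surrogate (the analogue of an
        external optical marker); every other signal is internal.
        """
        return all(t.signal != "skin" for t in self.terms)


def default_model_zoo() -> list[ModelSpec]:
    """The standard zoo: 7 two-signal and 3 three-signal models.

    The no-model baseline is handled separately by
    :func:`no_model_baseline` and the evaluation layer.
    """

    def d(name):
        return SignalTerm(name, derivative=True)

    def s(name):
        return SignalTerm(name)

    return [
        ModelSpec("pc1_cpd+deriv", (s("pc1_cpd"), d("pc1_cpd"))),
        ModelSpec("pc1_int+deriv", (s("pc1_int"), d("pc1_int"))),
        ModelSpec("diaphragm+deriv", (s("diaphragm"), d("diaphragm"))),
        ModelSpec("skin+deriv", (s("skin"), d("skin"))),
        ModelSpec("diaphragm+skin", (s("diaphragm"), s("skin"))),
        ModelSpec("pc1+pc2_cpd", (s("pc1_cpd"), s("pc2_cpd"))),
        ModelSpec("pc1+pc2_int", (s("pc1_int"), s("pc2_int"))),
        ModelSpec("diaphragm+deriv+skin", (s("diaphragm"), d("diaphragm"), s("skin"))),
        ModelSpec("pc1+pc2+pc3_cpd", (s("pc1_cpd"), s("pc2_cpd"), s("pc3_cpd"))),
        ModelSpec("pc1+pc2+pc3_int", (s("pc1_int"), s("pc2_int"), s("pc3_int"))),
    ]


def _term_values(term: SignalTerm, signals: dict, times: np.ndarray) -> np.ndarray:
    if term.signal not in signals:
        raise KeyError(f"signal {term.signal!r} not available")
    sig: SurrogateSignal = signals[term.signal]
    if term.derivative:
        sig = derivative_signal(sig)
    if sig.spline is not None:
        lo, hi = sig.sample_times_s[0], sig.sample_times_s[-1]
        if times.min() < lo - 1e-9 or times.max() > hi + 1e-9:
            raise ValueError(
                f"times outside the span of signal {term.signal!r}; "
                "discard out-of-span motion frames first"
            )
        return np.asarray(sig.spline(times), float)
    # no spline: exact sample lookup only
    idx = np.searchsorted(sig.sample_times_s, times)
    idx = np.clip(idx, 0, len(sig.sample_times_s) - 1)
    if not np.allclose(sig.sample_times_s[idx], times, atol=1e-9):
        raise ValueError(
            f"signal {term.signal!r} has no spline and is not sampled at the requested times"
        )
    return sig.sample_values[idx]


def build_design_matrix(spec: ModelSpec, signals: dict, times) -> np.ndarray:
    """Design matrix for a model spec: one column per signal term plus intercept."""
    times = np.asarray(times, float)
    cols = [_term_values(term, signals, times) for term in spec.terms]
    cols.append(np.ones_like(times))
    return np.column_stack(cols)


@dataclass
class CorrespondenceModel:
    """Fitted per-component linear coefficients for both sliding regions.

    ``coefficients`` has shape ``(2 regions, grid_rows, grid_cols,
    2 directions, n_signals + 1)``; the last axis is ordered like the
    design columns (signal terms first, intercept last).
    """

    spec: ModelSpec
    coefficients: np.ndarray
    grid_template: object
    source_segmentation: np.ndarray
    training_times: np.ndarray
    condition_number: float = np.nan
    training_residual_rms: float = np.nan
    fit_warnings: list = field(default_factory=list)


def _stack_targets(transforms: list) -> np.ndarray:
    return np.stack(
        [
            np.concatenate([g.displacements.ravel() for g in t.region_grids])
            for t in transforms
        ]
    )


def fit(
    spec: ModelSpec,
    design: np.ndarray,
    training_transforms: list,
    training_times=None,
) -> CorrespondenceModel:
    """Ordinary least squares fit of every CPD component to the design.

    All components are solved in one multi-right-hand-side minimum-norm
    least-squares factorization, which is mathematically identical to
    fitting each scalar component independently.  A condition number above
    ``1e10`` (near-collinear columns, e.g. a derivative during a
    breath-hold) is recorded as a warning rather than an error.
    """
    design = np.asarray(design, float)
    n_rows, n_cols = design.shape
    if n_cols != spec.n_signals + 1:
        raise ValueError(
            f"design has {n_cols} columns but spec {spec.name!r} needs {spec.n_signals + 1}"
        )
    if n_rows < n_cols:
        raise ValueError(f"cannot fit {n_cols} coefficients from {n_rows} rows")
    if len(training_transforms) != n_rows:
        raise ValueError("one training transform per design row is required")

    targets = _stack_targets(training_transforms)
    coef, _, _, sv = np.linalg.lstsq(design, targets, rcond=None)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    fit_warnings = []
    if cond > CONDITION_WARN_THRESHOLD:
        msg = f"design matrix for {spec.name!r} is near-collinear (cond={cond:.3g})"
        fit_warnings.append(msg)
        warnings.warn(msg)

    residual = design @ coef - targets
    template = training_transforms[0].region_grids[0]
    gr, gc = template.grid_shape
    coefficients = (
        coef.T.reshape(2, gr, gc, 2, n_cols)
    )
    return CorrespondenceModel(
        spec=spec,
        coefficients=coefficients,
        grid_template=template,
        source_segmentation=training_transforms[0].source_segmentation,
        training_times=np.asarray(
            training_times if training_times is not None else np.arange(n_rows), float
        ),
        condition_number=cond,
        training_residual_rms=float(np.sqrt(np.mean(residual**2))),
        fit_warnings=fit_warnings,
    )


def predict_displacements(model: CorrespondenceModel, design_rows: np.ndarray) -> np.ndarray:
    """Predicted CPDs for a batch of design rows, shape (n, 2, gr, gc, 2)."""
    design_rows = np.atleast_2d(np.asarray(design_rows, float))
    if design_rows.shape[1] != model.coefficients.shape[-1]:
        raise ValueError(
            f"expected {model.coefficients.shape[-1]} design values per row, "
            f"got {design_rows.shape[1]}"
        )
    return np.einsum("rijdk,nk->nrijd", model.coefficients, design_rows)


def estimate(model: CorrespondenceModel, signal_values) -> SlidingTransform:
    """Sliding transform estimated from one vector of signal values.

    The intercept column is appended automatically; the values must be in
    the spec's term order.
    """
    signal_values = np.asarray(signal_values, float)
    if signal_values.ndim != 1 or len(signal_values) != model.spec.n_signals:
        raise ValueError(
            f"expected {model.spec.n_signals} signal values, got {signal_values.shape}"
        )
    if not np.all(np.isfinite(signal_values)):
        raise ValueError("signal values must be finite")
    row = np.append(signal_values, 1.0)
    disp = predict_displacements(model, row)[0]
    grids = [model.grid_template.with_displacements(disp[r]) for r in range(2)]
    return SlidingTransform(grids, model.source_segmentation)


def no_model_baseline(template: SlidingTransform) -> SlidingTransform:
    """The no-model case: estimated motion identically zero."""
    zeros = np.zeros(template.region_grids[0].displacements.shape)
    grids = [template.region_grids[r].with_displacements(zeros.copy()) for r in range(2)]
    return SlidingTransform(grids, template.source_segmentation)
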