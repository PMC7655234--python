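"""End-to-end study orchestration on synthetic datasets.

One call chain reproduces the whole experiment at desk scale: simulate an
interleaved surrogate/motion acquisition with known ground-truth sliding
motion, extract the local and global surrogate signals from the surrogate
series, fit the model zoo over the training-size protocol, and evaluate
every model against the ground-truth motion via the deformation field
error.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluation import fold_average, run_experiment
from .model import default_model_zoo
from .register import register_ffd
from .signals import (
    diaphragm_signal,
    discard_pre_steady_state,
    make_body_mask,
    pca_cpd,
    pca_intensity,
    resample_signal,
    select_reference_frame,
    skin_signal,
)
from .synthetic import (
    AcquisitionConfig,
    BreathingConfig,
    CoefficientSpec,
    PhantomConfig,
    generate_breathing,
    generate_ground_truth,
    make_phantom,
    render_series,
)

__all__ = [
    "RegistrationConfig",
    "StudyConfig",
    "SyntheticDataset",
    "simulate_dataset",
    "extract_signals",
    "extract_signals_from_series",
    "run_study",
    "with_breath_hold",
    "qualitative_metrics",
]


@dataclass
class RegistrationConfig:
    """Settings of the surrogate-slice (CPD_s) registration."""

    levels_px: tuple = (20, 10, 5)
    bend_weight: float = 0.005
    lncc_sigma_px: float = 2.0
    max_iter: int = 40
    warm_max_iter: int = 8  # budget when warm-started from the previous frame


@dataclass
class StudyConfig:
    """All parameters of one synthetic study run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    breathing: BreathingConfig = field(default_factory=BreathingConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    coefficients: CoefficientSpec = field(default_factory=CoefficientSpec)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    cp_spacing_mm: float = 10.0
    steady_state_threshold: float = 0.05
    body_mask_closing_px: int = 30
    reference_frames_k: int = 30
    n_pca_components: int = 3


def with_breath_hold(
    config: StudyConfig, start_s: float = 28.0, duration_s: float = 12.0
) -> StudyConfig:
    """A copy of the configuration with one temporary breath-hold.

    The hold stops the waveform clock, freezing the respiratory state at
    whatever phase the breathing happens to be in when the hold begins —
    the irregular-breathing scenario under which models driven by a signal
    and its temporal derivative are expected to struggle.
    """
    breathing = replace(config.breathing, breath_holds=((start_s, duration_s),))
    return replace(config, breathing=breathing)


@dataclass
class SyntheticDataset:
    """A simulated acquisition plus its generating ground truth."""

    phantom: object
    trace: object
    ground_truth: object
    surrogate: object
    motion: object
    seed: int


def simulate_dataset(config: StudyConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Simulate one interleaved surrogate/motion acquisition."""
    cfg = config or StudyConfig()
    ss = np.random.SeedSequence(seed)
    seed_trace, seed_render = (int(s) for s in ss.generate_state(2) >> np.uint32(1))

    phantom = make_phantom(cfg.phantom)
    trace = generate_breathing(
        cfg.acquisition.duration_s,
        cfg.acquisition.frame_rate_hz,
        cfg.breathing,
        seed=seed_trace,
    )
    dt = 1.0 / cfg.acquisition.frame_rate_hz
    motion_times = trace.times_s + 0.5 * dt
    motion_times = motion_times[motion_times < cfg.acquisition.duration_s]
    ground_truth = generate_ground_truth(
        phantom,
        trace,
        motion_times,
        cp_spacing_mm=cfg.cp_spacing_mm,
        coeff_spec=cfg.coefficients,
        seed=seed,
    )
    surrogate, motion = render_series(phantom, ground_truth, cfg.acquisition, seed=seed_render)
    return SyntheticDataset(phantom, trace, ground_truth, surrogate, motion, seed)


def _register_surrogate_cpds(surr, reference_index, reg: RegistrationConfig):
    """CPD_s per surrogate frame: non-sliding FFD against the reference frame.

    Frames are registered outward from the reference frame, each
    warm-started from its temporal neighbour (consecutive cine frames
    differ by a fraction of a breath), which keeps the finest-level
    optimization short.
    """
    spacing = surr.pixel_spacing_mm
    ref = surr.frames[reference_index]
    cpds = [None] * len(surr)
    traces = []

    def run(i, init):
        res = register_ffd(
            ref,
            surr.frames[i],
            spacing,
            levels_px=reg.levels_px,
            bend_weight=reg.bend_weight,
            lncc_sigma_px=reg.lncc_sigma_px,
            max_iter=reg.max_iter if init is None else reg.warm_max_iter,
            init_grid=init,
        )
        traces.append(res)
        return res.grid

    cpds[reference_index] = run(reference_index, None)
    for i in range(reference_index + 1, len(surr)):
        cpds[i] = run(i, cpds[i - 1])
    for i in range(reference_index - 1, -1, -1):
        cpds[i] = run(i, cpds[i + 1])
    return cpds, traces


def extract_signals(dataset: SyntheticDataset, config: StudyConfig | None = None) -> dict:
    """Extract, resample and package every surrogate signal of a dataset."""
    return extract_signals_from_series(
        dataset.surrogate,
        dataset.motion.times_s,
        dataset.phantom.diaphragm_seed_point,
        dataset.phantom.skin_seed_point,
        config,
    )


def extract_signals_from_series(
    surrogate_series,
    motion_times,
    diaphragm_seed,
    skin_seed,
    config: StudyConfig | None = None,
) -> dict:
    """Extract, resample and package every surrogate signal.

    Returns the resampled signals (at the retained motion-frame times),
    the retained motion-frame indices, and extraction diagnostics.
    """
    cfg = config or StudyConfig()
    surr, n_discarded = discard_pre_steady_state(
        surrogate_series, cfg.steady_state_threshold
    )

    dia = diaphragm_signal(surr, tuple(diaphragm_seed))
    skin = skin_signal(surr, tuple(skin_seed))
    ref_idx = select_reference_frame(surr, dia, k=cfg.reference_frames_k)
    body = make_body_mask(surr.frames[ref_idx], cfg.body_mask_closing_px)

    pca_int = pca_intensity(surr, cfg.n_pca_components, align_with=dia.sample_values)
    cpds, reg_traces = _register_surrogate_cpds(surr, ref_idx, cfg.registration)
    pca_c = pca_cpd(
        cpds,
        body,
        surr.pixel_spacing_mm,
        cfg.n_pca_components,
        align_with=dia.sample_values,
    )

    raw = {"diaphragm": dia, "skin": skin}
    for j in range(cfg.n_pca_components):
        raw[f"pc{j + 1}_int"] = pca_int.score_signal(j, surr.times_s, f"pc{j + 1}_int")
        raw[f"pc{j + 1}_cpd"] = pca_c.score_signal(j, surr.times_s, f"pc{j + 1}_cpd")

    # motion frames outside the surrogate span cannot be interpolated and
    # are discarded rather than extrapolated
    motion_times = np.asarray(motion_times, float)
    inside = (motion_times >= surr.times_s[0]) & (motion_times <= surr.times_s[-1])
    retained = np.nonzero(inside)[0]
    kept_times = motion_times[retained]

    signals = {}
    for name, sig in raw.items():
        resampled, rejected = resample_signal(sig, kept_times)
        assert not rejected
        signals[name] = resampled

    return {
        "signals": signals,
        "motion_indices": retained,
        "motion_times": kept_times,
        "n_discarded": n_discarded,
        "n_rejected_motion_frames": int(len(motion_times) - len(retained)),
        "reference_index": ref_idx,
        "body_mask": body,
        "pca_intensity": pca_int,
        "pca_cpd": pca_c,
        "cpd_series": cpds,
        "registration_traces": reg_traces,
        "surrogate_trimmed": surr,
    }


def run_study(
    config: StudyConfig | None = None,
    seed: int = 0,
    dataset_name: str = "synthetic",
    collect_per_frame: bool = False,
    model_zoo: list | None = None,
) -> dict:
    """Simulate, extract signals, fit and evaluate the full model zoo."""
    cfg = config or StudyConfig()
    dataset = simulate_dataset(cfg, seed)
    extraction = extract_signals(dataset, cfg)
    retained = extraction["motion_indices"]
    reference_transforms = [dataset.ground_truth.transforms[i] for i in retained]
    results = run_experiment(
        signals=extraction["signals"],
        motion_times=extraction["motion_times"],
        reference_transforms=reference_transforms,
        masks={
            "evaluation": dataset.phantom.evaluation_mask,
            "tumour": dataset.phantom.tumour_mask,
        },
        image_shape=dataset.phantom.reference_image.shape,
        pixel_spacing_mm=dataset.phantom.pixel_spacing_mm,
        model_zoo=model_zoo if model_zoo is not None else default_model_zoo(),
        dataset=dataset_name,
        collect_per_frame=collect_per_frame,
    )
    return {
        "results": results,
        "summary": fold_average(results),
        "dataset": dataset,
        "extraction": extraction,
        "seed": seed,
    }


# --- study-level summary metrics -------------------------------------------

DERIVATIVE_2SIGNAL = ["pc1_cpd+deriv", "pc1_int+deriv", "diaphragm+deriv", "skin+deriv"]
INDEPENDENT_2SIGNAL = ["diaphragm+skin", "pc1+pc2_cpd", "pc1+pc2_int"]
NESTED_PAIRS = [
    ("diaphragm+deriv+skin", "diaphragm+skin"),
    ("pc1+pc2+pc3_cpd", "pc1+pc2_cpd"),
    ("pc1+pc2+pc3_int", "pc1+pc2_int"),
]


def _eval_summary(summary: pd.DataFrame, mask: str = "evaluation") -> pd.DataFrame:
    return summary[summary["mask"] == mask]


def qualitative_metrics(summary: pd.DataFrame, n_reference: int = 10) -> dict:
    """Headline comparisons of one study run (fold-averaged, evaluation mask).

    * per-model mean DFE at the reference training size,
    * the no-model baseline mean DFE,
    * Spearman rank correlation of mean DFE with training-set size per model,
    * mean DFE ratio of derivative-driven vs independent-signal 2-signal models,
    * mean DFE ratio of each 3-signal model vs its nested 2-signal model at n=6.
    """
    from scipy.stats import spearmanr

    ev = _eval_summary(summary)
    baseline = float(ev.loc[ev["model"] == "no_model", "mean_dfe_mm"].iloc[0])
    at_ref = ev[ev["n_train"] == n_reference].set_index("model")["mean_dfe_mm"].to_dict()

    spearman = {}
    for model, sub in ev[ev["model"] != "no_model"].groupby("model"):
        rho = spearmanr(sub["n_train"], sub["mean_dfe_mm"]).statistic
        spearman[model] = float(rho)

    deriv = np.mean([at_ref[m] for m in DERIVATIVE_2SIGNAL])
    indep = np.mean([at_ref[m] for m in INDEPENDENT_2SIGNAL])

    at6 = ev[ev["n_train"] == 6].set_index("model")["mean_dfe_mm"].to_dict()
    nested_ratios = {f"{m3} / {m2}": at6[m3] / at6[m2] for m3, m2 in NESTED_PAIRS}
    three_sig = [m for m, _ in NESTED_PAIRS]
    two_sig = DERIVATIVE_2SIGNAL + INDEPENDENT_2SIGNAL
    group_ratio_n6 = float(
        np.mean([at6[m] for m in three_sig]) / np.mean([at6[m] for m in two_sig])
    )

    return {
        "baseline_mean_dfe_mm": baseline,
        "model_mean_dfe_mm": at_ref,
        "spearman_by_model": spearman,
        "derivative_over_independent": float(deriv / indep),
        "nested_3sig_over_2sig_at_n6": nested_ratios,
        "threesig_over_twosig_at_n6": group_ratio_n6,
    }
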