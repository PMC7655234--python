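"""Experimental protocol: splits, deformation field error, result tables.

The acquisition's motion frames are divided into a building set (the
first 80) and a test set (the remainder).  Training subsets of
n = 20, 19, ..., 6 evenly spaced frames are drawn from the building set
in a 4-fold cross-validation whose folds at n = 20 partition the
building set exactly; for smaller n the earliest frames are discarded so
the frames closest to the test set are retained.  Models are always
evaluated on the full test set via the deformation field error (DFE),
the per-pixel L2 norm of the difference between the model-estimated and
reference DVFs, summarized by mean and 95th percentile within the
evaluation and tumour masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .exceptions import MaskError
from .grid import (
    Dvf,
    bspline_support,
    compose_sliding_dvf,
    invert_dvf,
    warp_mask,
)
from .model import (
    build_design_matrix,
    default_model_zoo,
    fit,
    predict_displacements,
)

__all__ = [
    "SplitPlan",
    "make_split",
    "compute_dfe",
    "DfeReport",
    "masked_stats",
    "transport_masks",
    "run_experiment",
    "fold_average",
]


@dataclass
class SplitPlan:
    """Building/test split with evenly spaced cross-validation subsets.

    Frame indices are 1-based in this public container, matching the way
    acquisition protocols count frames; use :meth:`training_indices` with
    ``zero_based=True`` for array indexing.
    """

    n_motion_frames: int
    n_building: int = 80
    n_folds: int = 4
    n_grid: tuple = tuple(range(20, 5, -1))

    def __post_init__(self) -> None:
        if self.n_motion_frames <= self.n_building:
            raise ValueError(
                f"need more than {self.n_building} motion frames, got {self.n_motion_frames}"
            )

    @property
    def building_indices(self) -> np.ndarray:
        return np.arange(1, self.n_building + 1)

    @property
    def test_indices(self) -> np.ndarray:
        return np.arange(self.n_building + 1, self.n_motion_frames + 1)

    @property
    def folds(self) -> np.ndarray:
        return np.arange(1, self.n_folds + 1)

    @property
    def n_max(self) -> int:
        return self.n_building // self.n_folds

    def training_indices(self, n: int, fold: int, zero_based: bool = False) -> np.ndarray:
        """Evenly spaced training frames for a subset size and fold offset.

        Fold ``f`` at the maximal size is ``[f, f + 4, ..., f + 76]``; for
        smaller ``n`` the earliest frames are discarded and the frames
        closest to the test set retained.
        """
        if not 1 <= fold <= self.n_folds:
            raise ValueError(f"fold must be in 1..{self.n_folds}")
        if not 2 <= n <= self.n_max:
            raise ValueError(f"training size must be in 2..{self.n_max}, got {n}")
        full = np.arange(fold, self.n_building + 1, self.n_folds)
        idx = full[self.n_max - n :]
        return idx - 1 if zero_based else idx


def make_split(n_motion_frames: int, n_building: int = 80, n_folds: int = 4) -> SplitPlan:
    """Standard split: building = first 80 frames, 4 folds, n = 20..6."""
    return SplitPlan(n_motion_frames, n_building=n_building, n_folds=n_folds)


def compute_dfe(estimated: Dvf, reference: Dvf) -> np.ndarray:
    """Per-pixel deformation field error in mm (L2 norm of the difference)."""
    if estimated.shape != reference.shape:
        raise ValueError(f"shape mismatch {estimated.shape} vs {reference.shape}")
    diff = estimated.displacements - reference.displacements
    return np.sqrt(np.sum(diff**2, axis=-1))


@dataclass
class DfeReport:
    """Per-frame and pooled DFE statistics within one mask."""

    pooled_mean: float
    pooled_p95: float
    per_frame: pd.DataFrame
    mask_name: str = "evaluation"
    model_name: str = ""
    n_train: int | None = None
    fold: int | None = None

    def __post_init__(self) -> None:
        if self.pooled_mean > self.pooled_p95 + 1e-12:
            raise ValueError("pooled mean cannot exceed the pooled 95th percentile")


def masked_stats(
    dfe_maps: list,
    masks: list,
    mask_name: str = "evaluation",
    model_name: str = "",
    n_train: int | None = None,
    fold: int | None = None,
) -> DfeReport:
    """Pool DFE values over all masked pixels of all test frames.

    Pixels are pooled across frames before taking the mean and the
    95th percentile (linear-interpolation definition); per-frame values
    are reported alongside.  Frames with an empty mask are skipped with a
    warning; if every frame is empty that is an error.
    """
    pooled = []
    rows = []
    for i, (dfe, mask) in enumerate(zip(dfe_maps, masks)):
        mask = np.asarray(mask, bool)
        values = np.asarray(dfe)[mask]
        if values.size == 0:
            warnings.warn(f"mask {mask_name!r} empty in frame {i}; frame skipped")
            continue
        pooled.append(values)
        rows.append(
            {
                "frame": i,
                "mean_mm": float(values.mean()),
                "p95_mm": float(np.percentile(values, 95)),
                "n_pixels": int(values.size),
            }
        )
    if not pooled:
        raise MaskError(f"mask {mask_name!r} empty in every frame")
    allv = np.concatenate(pooled)
    return DfeReport(
        pooled_mean=float(allv.mean()),
        pooled_p95=float(np.percentile(allv, 95)),
        per_frame=pd.DataFrame(rows),
        mask_name=mask_name,
        model_name=model_name,
        n_train=n_train,
        fold=fold,
    )


def transport_masks(source_mask: np.ndarray, reference_dvfs: list) -> list:
    """Warp a source-image mask to each test frame via its reference motion.

    Each forward reference DVF is numerically inverted and the mask
    transported by nearest-neighbour pull-back.
    """
    out = []
    for dvf in reference_dvfs:
        inv = invert_dvf(dvf)
        out.append(warp_mask(source_mask, inv))
    return out


def _sliding_basis(
    pixels: np.ndarray, segmentation: np.ndarray, grid, pixel_spacing_mm
) -> sparse.csr_matrix:
    """Sparse matrix mapping stacked two-region CPDs to masked-pixel values.

    Row ``p`` holds the 16 tensor-product B-spline weights of pixel
    ``pixels[p]``, placed in the block of the region that pixel belongs
    to; multiplying by the flattened ``(2, gr, gc)`` CPD component gives
    exactly the sliding-composed displacement at those pixels.
    """
    gr, gc = grid.grid_shape
    pr, pc = pixels[:, 0], pixels[:, 1]
    i0r, wr = bspline_support(
        pr * pixel_spacing_mm[0], grid.origin_mm[0], grid.spacing_mm[0], gr
    )
    i0c, wc = bspline_support(
        pc * pixel_spacing_mm[1], grid.origin_mm[1], grid.spacing_mm[1], gc
    )
    region = segmentation[pr, pc].astype(int)
    n_pix = len(pr)
    w16 = (wr[:, :, None] * wc[:, None, :]).reshape(n_pix, 16)
    di, dj = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
    cols = (
        region[:, None] * (gr * gc)
        + (i0r[:, None] + di.ravel()[None, :]) * gc
        + (i0c[:, None] + dj.ravel()[None, :])
    )
    rows = np.repeat(np.arange(n_pix), 16)
    return sparse.csr_matrix(
        (w16.ravel(), (rows, cols.ravel())), shape=(n_pix, 2 * gr * gc)
    )


def _pooled(values: np.ndarray) -> tuple[float, float]:
    return float(values.mean()), float(np.percentile(values, 95))


def run_experiment(
    *,
    signals: dict,
    motion_times: np.ndarray,
    reference_transforms: list,
    masks: dict,
    image_shape,
    pixel_spacing_mm,
    model_zoo: list | None = None,
    split: SplitPlan | None = None,
    dataset: str = "synthetic",
    collect_per_frame: bool = False,
) -> pd.DataFrame:
    """Fit and evaluate the model zoo over the full training-size protocol.

    For every (model spec, training size n, fold) the model is fitted on
    its training subset, motion is estimated at every test time, DVFs are
    composed and compared against the reference DVFs, and masked DFE
    statistics collected for each mask (transported to each test frame by
    the reference motion).  The no-model baseline (estimated motion zero)
    is evaluated once.  Returns a long-format table keyed by
    ``(model, n_train, fold, mask)``.
    """
    motion_times = np.asarray(motion_times, float)
    pixel_spacing_mm = np.broadcast_to(np.asarray(pixel_spacing_mm, float), (2,))
    zoo = default_model_zoo() if model_zoo is None else model_zoo
    plan = make_split(len(motion_times)) if split is None else split
    test_idx = plan.test_indices - 1
    n_test = len(test_idx)
    template = reference_transforms[0].region_grids[0]
    seg = reference_transforms[0].source_segmentation

    # reference DVFs (full grid, needed once for mask transport) and CPDs
    ref_dvfs = [
        compose_sliding_dvf(reference_transforms[i], image_shape, pixel_spacing_mm)
        for i in test_idx
    ]
    ref_cpds = np.stack(
        [
            np.stack([reference_transforms[i].region_grids[r].displacements for r in range(2)])
            for i in test_idx
        ]
    )  # (n_test, 2, gr, gc, 2)

    frame_masks = {name: transport_masks(m, ref_dvfs) for name, m in masks.items()}

    union = np.zeros(tuple(image_shape), bool)
    for per_frame in frame_masks.values():
        for m in per_frame:
            union |= m
    pixels = np.argwhere(union)
    basis = _sliding_basis(pixels, seg, template, pixel_spacing_mm)
    membership = {
        name: np.stack([m[union] for m in per_frame])
        for name, per_frame in frame_masks.items()
    }

    def masked_dfe_values(cpd_batch):
        """DFE at union pixels for a batch of (2, gr, gc, 2) CPD residuals."""
        flat_r = cpd_batch[..., 0].reshape(len(cpd_batch), -1)
        flat_c = cpd_batch[..., 1].reshape(len(cpd_batch), -1)
        ur = (basis @ flat_r.T).T
        uc = (basis @ flat_c.T).T
        return np.sqrt(ur**2 + uc**2)  # (n_frames, n_union_pixels)

    records = []

    def add_rows(dfe_vals, model_name, n_train, fold):
        for mask_name, member in membership.items():
            if not member.any():
                warnings.warn(f"mask {mask_name!r} empty in every test frame")
                continue
            mean, p95 = _pooled(dfe_vals[member])
            rec = {
                "dataset": dataset,
                "model": model_name,
                "n_train": n_train,
                "fold": fold,
                "mask": mask_name,
                "pooled_mean_mm": mean,
                "pooled_p95_mm": p95,
                "n_test_frames": n_test,
            }
            if collect_per_frame:
                rec["per_frame_mean_mm"] = [
                    float(dfe_vals[f][member[f]].mean()) if member[f].any() else np.nan
                    for f in range(n_test)
                ]
            records.append(rec)

    # no-model baseline: estimated motion identically zero, so the DFE is
    # the magnitude of the reference motion itself
    add_rows(masked_dfe_values(ref_cpds), "no_model", 0, 0)

    for spec in zoo:
        design_all = build_design_matrix(spec, signals, motion_times)
        design_test = design_all[test_idx]
        for n in plan.n_grid:
            for fold in plan.folds:
                train_idx = plan.training_indices(n, fold, zero_based=True)
                model = fit(
                    spec,
                    design_all[train_idx],
                    [reference_transforms[i] for i in train_idx],
                    training_times=motion_times[train_idx],
                )
                predicted = predict_displacements(model, design_test)
                dfe_vals = masked_dfe_values(predicted - ref_cpds)
                add_rows(dfe_vals, spec.name, n, int(fold))

    return pd.DataFrame.from_records(records)


def fold_average(results: pd.DataFrame) -> pd.DataFrame:
    """Average pooled statistics over the cross-validation folds."""
    grouped = (
        results.groupby(["dataset", "model", "n_train", "mask"], as_index=False)
        .agg(
            mean_dfe_mm=("pooled_mean_mm", "mean"),
            p95_dfe_mm=("pooled_p95_mm", "mean"),
            n_folds=("fold", "nunique"),
        )
        .sort_values(["dataset", "model", "mask", "n_train"])
        .reset_index(drop=True)
    )
    return grouped
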