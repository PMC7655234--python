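"""File formats: NIfTI series/grids/masks, CSV signals, YAML manifests.

A dataset on disk is tied together by a YAML manifest naming the
surrogate and motion series (3D NIfTI, slices = time), the binary masks,
the frame timestamps, and — when reference motion is available as files —
the per-frame, per-region control-point displacement grids (5D NIfTI,
``grid_rows x grid_cols x 1 x 1 x 2`` components, grid origin and spacing
in the affine).
"""

from __future__ import annotations

import pathlib

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .grid import ControlPointGrid
from .series import CineSeries
from .signals import SurrogateSignal

__all__ = [
    "read_series",
    "write_series",
    "read_cpd",
    "write_cpd",
    "read_mask",
    "write_mask",
    "read_signal_csv",
    "write_signal_csv",
    "read_manifest",
    "write_manifest",
    "write_dataset",
    "load_dataset",
]


def write_series(series: CineSeries, path) -> None:
    """Write a cine series as 3D NIfTI (rows x cols x frames).

    In-plane spacing and the nominal frame period go in the header; the
    exact timestamps belong in the dataset manifest.
    """
    data = np.moveaxis(series.frames, 0, -1)
    dt = float(np.median(np.diff(series.times_s))) if len(series) > 1 else 1.0
    affine = np.diag([series.pixel_spacing_mm[0], series.pixel_spacing_mm[1], dt, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header["pixdim"][3] = dt
    img.header["descrip"] = f"cine {series.role} {series.orientation}".encode()
    nib.save(img, str(path))


def read_series(path, times_s=None, orientation="sagittal", role="surrogate") -> CineSeries:
    """Read a cine series written by :func:`write_series`.

    When ``times_s`` is not given, uniform times are reconstructed from
    the header frame period; duplicated or non-monotone timestamps are
    rejected.
    """
    path = pathlib.Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as err:
        raise ConfigurationError(f"cannot read series {path}: {err}") from err
    if data.ndim != 3:
        raise ConfigurationError(f"{path}: expected 3D series, got shape {data.shape}")
    frames = np.moveaxis(data, -1, 0)
    spacing = np.asarray(img.header["pixdim"][1:3], float)
    if times_s is None:
        dt = float(img.header["pixdim"][3]) or 1.0
        times_s = np.arange(frames.shape[0]) * dt
    times_s = np.asarray(times_s, float)
    if len(times_s) != len(frames):
        raise ConfigurationError(f"{path}: {len(times_s)} timestamps for {len(frames)} frames")
    if len(times_s) > 1 and np.any(np.diff(times_s) <= 0):
        raise ConfigurationError(f"{path}: frame times must be strictly increasing")
    desc = img.header["descrip"].tobytes().decode(errors="ignore")
    if "motion" in desc:
        role = "motion"
    if "coronal" in desc:
        orientation = "coronal"
    return CineSeries(frames, times_s, spacing, orientation, role)


def write_cpd(grid: ControlPointGrid, path) -> None:
    """Write a control-point grid as 5D NIfTI (rows x cols x 1 x 1 x 2)."""
    data = grid.displacements[:, :, None, None, :].astype(np.float32)
    affine = np.array(
        [
            [grid.spacing_mm[0], 0, 0, grid.origin_mm[0]],
            [0, grid.spacing_mm[1], 0, grid.origin_mm[1]],
            [0, 0, 1, 0],
            [0, 0, 0, 1],
        ]
    )
    img = nib.Nifti1Image(data, affine)
    img.header["descrip"] = b"control point displacements (mm)"
    nib.save(img, str(path))


def read_cpd(path) -> ControlPointGrid:
    path = pathlib.Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as err:
        raise ConfigurationError(f"cannot read CPD grid {path}: {err}") from err
    if data.ndim != 5 or data.shape[2:4] != (1, 1) or data.shape[4] != 2:
        raise ConfigurationError(
            f"{path}: expected 5D grid (rows x cols x 1 x 1 x 2), got {data.shape}"
        )
    affine = img.affine
    origin = np.array([affine[0, 3], affine[1, 3]])
    spacing = np.array([affine[0, 0], affine[1, 1]])
    return ControlPointGrid(origin, spacing, data[:, :, 0, 0, :])


def write_mask(mask: np.ndarray, path, pixel_spacing_mm=(1.0, 1.0)) -> None:
    affine = np.diag([pixel_spacing_mm[0], pixel_spacing_mm[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, np.uint8), affine), str(path))


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def write_signal_csv(signal: SurrogateSignal, path) -> None:
    pd.DataFrame(
        {
            "time_s": signal.sample_times_s,
            "value": signal.sample_values,
            "units": signal.units,
        }
    ).to_csv(path, index=False)


def read_signal_csv(path, name=None) -> SurrogateSignal:
    df = pd.read_csv(path)
    units = str(df["units"].iloc[0]) if "units" in df and len(df) else "a.u."
    return SurrogateSignal(
        name or pathlib.Path(path).stem,
        df["time_s"].to_numpy(),
        df["value"].to_numpy(),
        units=units,
    )


def _interleaved(times_a, times_b) -> bool:
    """True when the two time vectors strictly alternate."""
    merged = np.concatenate(
        [np.column_stack([times_a, np.zeros(len(times_a))]),
         np.column_stack([times_b, np.ones(len(times_b))])]
    )
    merged = merged[np.argsort(merged[:, 0])]
    labels = merged[:, 1]
    return bool(np.all(labels[1:] != labels[:-1]))


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path, check_files: bool = True) -> dict:
    """Load and validate a dataset manifest.

    Checks that every referenced file exists and that the surrogate and
    motion timestamps strictly alternate (interleaved acquisition).
    """
    path = pathlib.Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict):
        raise ConfigurationError(f"{path}: manifest must be a mapping")
    base = path.parent
    required = ["surrogate_series", "motion_series", "pixel_spacing_mm",
                "surrogate_times_s", "motion_times_s"]
    for key in required:
        if key not in manifest:
            raise ConfigurationError(f"{path}: missing manifest key {key!r}")
    if check_files:
        file_keys = ["surrogate_series", "motion_series"]
        for key in file_keys:
            target = base / manifest[key]
            if not target.exists():
                raise ConfigurationError(f"{path}: referenced file missing: {target}")
        for name, rel in (manifest.get("masks") or {}).items():
            if not (base / rel).exists():
                raise ConfigurationError(f"{path}: mask file missing: {base / rel}")
    st = np.asarray(manifest["surrogate_times_s"], float)
    mt = np.asarray(manifest["motion_times_s"], float)
    if not _interleaved(st, mt):
        raise ConfigurationError(f"{path}: surrogate and motion times do not interleave")
    manifest["_base"] = str(base)
    return manifest


def write_dataset(dataset, out_dir, write_reference_cpds: bool = True) -> pathlib.Path:
    """Write a synthetic dataset (series, masks, truth, manifest) to a directory.

    Reference motion is stored as one 5D CPD NIfTI per sliding region per
    motion frame; the true breathing components go to a CSV
    (``time_s, primary, secondary``).  Returns the manifest path.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ph = dataset.phantom
    sp = ph.pixel_spacing_mm

    write_series(dataset.surrogate, out / "surrogate.nii.gz")
    write_series(dataset.motion, out / "motion.nii.gz")
    masks = {
        "region": ph.region_mask,
        "body": ph.body_mask,
        "tumour": ph.tumour_mask,
        "evaluation": ph.evaluation_mask,
    }
    for name, mask in masks.items():
        write_mask(mask, out / f"mask_{name}.nii.gz", sp)

    p, s = dataset.trace.value_at(dataset.surrogate.times_s)
    pd.DataFrame(
        {"time_s": dataset.surrogate.times_s, "primary": p, "secondary": s}
    ).to_csv(out / "true_signals.csv", index=False)

    cpd_entries = []
    if write_reference_cpds:
        cpd_dir = out / "reference_cpds"
        cpd_dir.mkdir(exist_ok=True)
        for i, transform in enumerate(dataset.ground_truth.transforms):
            for r in (0, 1):
                rel = f"reference_cpds/cpd_m_f{i:03d}_r{r}.nii.gz"
                write_cpd(transform.region_grids[r], out / rel)
                cpd_entries.append(rel)

    manifest = {
        "dataset": f"synthetic_seed{dataset.seed}",
        "pixel_spacing_mm": [float(sp[0]), float(sp[1])],
        "orientation": dataset.motion.orientation,
        "surrogate_series": "surrogate.nii.gz",
        "motion_series": "motion.nii.gz",
        "surrogate_times_s": [float(t) for t in dataset.surrogate.times_s],
        "motion_times_s": [float(t) for t in dataset.motion.times_s],
        "masks": {name: f"mask_{name}.nii.gz" for name in masks},
        "seed_points": {
            "diaphragm": [int(v) for v in ph.diaphragm_seed_point],
            "skin": [int(v) for v in ph.skin_seed_point],
        },
        "true_signals": "true_signals.csv",
        "reference_cpds": cpd_entries,
        "seed": int(dataset.seed),
    }
    write_manifest(manifest, out / "manifest.yaml")
    return out / "manifest.yaml"


def load_dataset(manifest_path) -> dict:
    """Load a dataset directory back into in-memory objects.

    Returns series, masks, seed points, and (when present) the per-frame
    reference :class:`~cinemotion.grid.SlidingTransform` list rebuilt from
    the stored CPD grids and region segmentation.
    """
    from .grid import SlidingTransform

    manifest = read_manifest(manifest_path)
    base = pathlib.Path(manifest["_base"])
    surrogate = read_series(
        base / manifest["surrogate_series"],
        times_s=manifest["surrogate_times_s"],
        orientation=manifest.get("orientation", "sagittal"),
        role="surrogate",
    )
    motion = read_series(
        base / manifest["motion_series"],
        times_s=manifest["motion_times_s"],
        orientation=manifest.get("orientation", "sagittal"),
        role="motion",
    )
    masks = {
        name: read_mask(base / rel) for name, rel in (manifest.get("masks") or {}).items()
    }

    transforms = None
    entries = manifest.get("reference_cpds") or []
    if entries:
        if "region" not in masks:
            raise ConfigurationError("reference CPDs require a region mask in the manifest")
        by_frame: dict = {}
        for rel in entries:
            stem = pathlib.Path(rel).name
            frame = int(stem.split("_f")[1].split("_")[0])
            region = int(stem.split("_r")[1].split(".")[0])
            by_frame.setdefault(frame, {})[region] = read_cpd(base / rel)
        transforms = []
        for frame in sorted(by_frame):
            pair = by_frame[frame]
            transforms.append(SlidingTransform([pair[0], pair[1]], masks["region"]))

    return {
        "manifest": manifest,
        "surrogate": surrogate,
        "motion": motion,
        "masks": masks,
        "seed_points": manifest.get("seed_points", {}),
        "reference_transforms": transforms,
    }
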