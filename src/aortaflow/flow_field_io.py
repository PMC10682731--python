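"""I/O and preprocessing for time-resolved voxel velocity fields.

On-disk layout: one uncompressed NIfTI 4D volume (x, y, z, t) per velocity
component, named ``<stem>_vx.nii`` / ``<stem>_vy.nii`` / ``<stem>_vz.nii``,
plus a JSON sidecar ``<stem>.json`` carrying spacing, frame interval,
velocity-encoding limits and the on-disk velocity unit.  Segmentation masks
and derived scalar maps are single 3D NIfTI volumes.

Velocity component axes are the grid axes; orientation matrices beyond
spacing/origin are ignored.  Voxel centers sit at ``origin + (index + 0.5)
* spacing`` (millimetres).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VelocityField4D",
    "SegmentationMask",
    "AnalysisConfig",
    "BOUNDARY_POLICIES",
    "read_velocity_field",
    "load_field",
    "write_velocity_field",
    "read_mask",
    "write_mask",
    "write_voxel_map",
    "read_voxel_map",
    "unwrap_velocity",
]

#: Gradient schemes at mask edges: ``central_one_sided`` falls back to a
#: one-sided difference when only one axis-neighbour is inside the mask;
#: ``central_only`` leaves such voxels undefined.
BOUNDARY_POLICIES = ("central_one_sided", "central_only")

_COMPONENT_SUFFIXES = ("_vx", "_vy", "_vz")


@dataclass(frozen=True)
class AnalysisConfig:
    """Numerical parameters of the quantification pipeline.

    mu
        Dynamic blood viscosity in Pa*s.
    boundary_policy
        One of :data:`BOUNDARY_POLICIES`.
    include_divergence_term
        Subtract the compressibility correction -(2/3)*mu*(div v)^2 from
        the dissipation rate.  Irrelevant on divergence-free fields.
    seed
        RNG seed used by stochastic steps (particle seeding).
    """

    mu: float = 3.2e-3
    boundary_policy: str = "central_one_sided"
    include_divergence_term: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.boundary_policy not in BOUNDARY_POLICIES:
            raise ValueError(
                f"boundary_policy must be one of {BOUNDARY_POLICIES}, "
                f"got {self.boundary_policy!r}"
            )


@dataclass
class VelocityField4D:
    """Three-component velocity on a regular voxel grid over time.

    data
        Array of shape ``(nx, ny, nz, nt, 3)`` in m/s.
    spacing
        Per-axis voxel size in mm, shape ``(3,)``.
    dt
        Frame interval in ms.
    venc
        Per-component velocity-encoding limit in cm/s, shape ``(3,)``.
    origin
        World offset of the grid corner in mm, shape ``(3,)``.
    """

    data: np.ndarray
    spacing: np.ndarray
    dt: float
    venc: np.ndarray
    origin: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.venc = np.broadcast_to(
            np.asarray(self.venc, dtype=np.float64), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.data.ndim != 5 or self.data.shape[-1] != 3:
            raise ValueError(
                f"data must have shape (nx, ny, nz, nt, 3), got {self.data.shape}"
            )
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if np.any(self.venc <= 0):
            raise ValueError(f"venc must be positive, got {self.venc}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def nt(self) -> int:
        return self.data.shape[3]

    @property
    def venc_ms(self) -> np.ndarray:
        """Encoding limits converted from cm/s to m/s."""
        return self.venc / 100.0

    def voxel_volume_m3(self) -> float:
        return float(np.prod(self.spacing * 1e-3))

    def frame(self, t: int) -> np.ndarray:
        """Velocity components at one frame, shape ``(nx, ny, nz, 3)``."""
        return self.data[:, :, :, t, :]


@dataclass
class SegmentationMask:
    """Binary voxel mask aligned to a velocity-field grid."""

    voxels: np.ndarray
    label: str = "whole-aorta"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.voxels.shape}")
        if not self.voxels.any():
            raise ValueError("mask is empty (no voxels set)")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_matches(self, field: VelocityField4D) -> None:
        if self.voxels.shape != field.grid_shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} does not match "
                f"field grid {field.grid_shape}"
            )

    def check_subset_of(self, other: "SegmentationMask") -> None:
        if self.voxels.shape != other.voxels.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.voxels & ~other.voxels):
            raise ValueError(
                f"{self.label!r} mask is not a subset of {other.label!r} mask"
            )


# ---------------------------------------------------------------------------
# NIfTI helpers


def _load_volume(path: Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
    return data, zooms


def _save_volume(
    data: np.ndarray, spacing: Sequence[float], origin: Sequence[float], path: Path
) -> None:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = spacing
    affine[:3, 3] = origin
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(
        tuple(spacing) + ((1.0,) * (data.ndim - 3) if data.ndim > 3 else ())
    )
    nib.save(img, str(path))


def read_velocity_field(
    component_paths: Sequence[str | Path], meta: Mapping
) -> VelocityField4D:
    """Read three per-component 4D volumes into a :class:`VelocityField4D`.

    ``meta`` must supply ``spacing_mm``, ``dt_ms`` and ``venc_cms``;
    ``units`` ("m/s" default, or "cm/s") declares the on-disk velocity unit,
    which is converted to m/s on load.  ``origin_mm`` is optional.
    """
    if len(component_paths) != 3:
        raise ValueError("expected exactly three component paths (vx, vy, vz)")
    for key in ("spacing_mm", "dt_ms", "venc_cms"):
        if key not in meta:
            raise ValueError(f"metadata missing required field {key!r}")

    volumes = []
    for path in component_paths:
        data, _ = _load_volume(Path(path))
        if data.ndim == 3:
            data = data[..., np.newaxis]
        if data.ndim != 4:
            raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
        volumes.append(data)
    shapes = {v.shape for v in volumes}
    if len(shapes) != 1:
        raise ValueError(
            "component volumes have mismatched dimensions: "
            + ", ".join(str(v.shape) for v in volumes)
        )

    data = np.stack(volumes, axis=-1)
    units = meta.get("units", "m/s")
    if units == "cm/s":
        data = data / 100.0
    elif units != "m/s":
        raise ValueError(f"unsupported velocity unit {units!r}")

    return VelocityField4D(
        data=data,
        spacing=np.asarray(meta["spacing_mm"], dtype=float),
        dt=float(meta["dt_ms"]),
        venc=np.asarray(meta["venc_cms"], dtype=float),
        origin=np.asarray(meta.get("origin_mm", (0.0, 0.0, 0.0)), dtype=float),
    )


def load_field(stem: str | Path) -> VelocityField4D:
    """Load ``<stem>_vx/_vy/_vz.nii`` plus the ``<stem>.json`` sidecar."""
    stem = Path(stem)
    sidecar = stem.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar metadata not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    paths = [stem.parent / f"{stem.name}{suf}.nii" for suf in _COMPONENT_SUFFIXES]
    return read_velocity_field(paths, meta)


def write_velocity_field(field: VelocityField4D, stem: str | Path) -> list[Path]:
    """Write the three component volumes and the JSON sidecar; returns paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for c, suf in enumerate(_COMPONENT_SUFFIXES):
        path = stem.parent / f"{stem.name}{suf}.nii"
        _save_volume(field.data[..., c], field.spacing, field.origin, path)
        written.append(path)
    sidecar = stem.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "spacing_mm": field.spacing.tolist(),
                "dt_ms": field.dt,
                "venc_cms": field.venc.tolist(),
                "origin_mm": field.origin.tolist(),
                "units": "m/s",
            },
            indent=2,
        )
    )
    written.append(sidecar)
    return written


def read_mask(
    path: str | Path, field: VelocityField4D, label: str = "whole-aorta"
) -> SegmentationMask:
    """Read and binarize (>0) a mask volume; shape-checked against the field."""
    data, _ = _load_volume(Path(path))
    if data.ndim != 3:
        raise ValueError(f"{path}: mask must be 3D, got {data.ndim}D")
    mask = SegmentationMask(voxels=data > 0, label=label)
    mask.check_matches(field)
    return mask


def write_mask(mask: SegmentationMask, field: VelocityField4D, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _save_volume(mask.voxels.astype(np.uint8), field.spacing, field.origin, path)
    return path


def write_voxel_map(voxel_map, path: str | Path) -> Path:
    """Write a per-voxel scalar map (NaN outside mask preserved) to NIfTI.

    Accepts any object with ``values``, ``spacing`` and ``origin`` attributes
    (see :class:`aortaflow.hemodynamics.VoxelScalarMap`).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _save_volume(voxel_map.values, voxel_map.spacing, voxel_map.origin, path)
    return path


def read_voxel_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a scalar map back; returns (values, spacing_mm)."""
    return _load_volume(Path(path))


# ---------------------------------------------------------------------------
# Velocity anti-aliasing


def unwrap_velocity(field: VelocityField4D) -> VelocityField4D:
    """Correct single velocity wraps against the per-voxel temporal median.

    Any voxel-frame value differing from the temporal median at that voxel
    by more than the component venc is shifted by +-2*venc toward the
    median.  At most one wrap is corrected per voxel-frame; already
    consistent data pass through unchanged, making the operation idempotent.
    """
    data = field.data
    venc = field.venc_ms  # (3,) m/s
    median = np.median(data, axis=3, keepdims=True)
    delta = data - median
    wrapped = np.abs(delta) > venc
    corrected = data - np.sign(delta) * (2.0 * venc) * wrapped
    return VelocityField4D(
        data=corrected,
        spacing=field.spacing.copy(),
        dt=field.dt,
        venc=field.venc.copy(),
        origin=field.origin.copy(),
    )
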