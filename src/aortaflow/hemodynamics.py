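"""Voxelwise flow quantification: dissipation, vorticity, ROI summaries, pathlines.

All spatial derivatives are finite differences on the voxel grid with the
mask-aware scheme described in :func:`velocity_gradient`.  Velocities are in
m/s and spacings in mm; gradients are converted to SI (1/s) internally, so
the viscous energy loss rate (VELR) comes out in W/m^3 and vorticity in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .flow_field_io import AnalysisConfig, SegmentationMask, VelocityField4D

__all__ = [
    "VoxelScalarMap",
    "VoxelVectorMap",
    "HemodynamicSummary",
    "PathlineSet",
    "detect_peak_systole",
    "velocity_gradient",
    "compute_velr_map",
    "compute_vorticity_map",
    "summarize_roi",
    "trace_pathlines",
]


@dataclass
class VoxelScalarMap:
    """Per-voxel scalar at one frame; NaN marks voxels outside the mask."""

    values: np.ndarray
    quantity: str  # velr_density | vorticity_magnitude | velocity_magnitude
    frame: int
    spacing: np.ndarray
    origin: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class VoxelVectorMap:
    """Per-voxel 3-vector (e.g. vorticity, 1/s) at one frame."""

    values: np.ndarray  # (nx, ny, nz, 3)
    quantity: str
    frame: int
    spacing: np.ndarray
    origin: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    def magnitude(self) -> VoxelScalarMap:
        return VoxelScalarMap(
            values=np.linalg.norm(self.values, axis=-1),
            quantity=f"{self.quantity}_magnitude",
            frame=self.frame,
            spacing=self.spacing,
            origin=self.origin,
        )


@dataclass(frozen=True)
class HemodynamicSummary:
    """ROI aggregates at one frame, in reporting units.

    total_velr in mW, velr_density in W/m^3, mean_vorticity in 1/s,
    roi_volume in m^3.  By construction
    ``total_velr / 1000 == velr_density * roi_volume``.
    """

    peak_frame: int
    total_velr: float
    velr_density: float
    mean_vorticity: float
    roi_volume: float


@dataclass
class PathlineSet:
    """Particle trajectories: per particle an (n, 4) array of (t_ms, x, y, z mm)."""

    trajectories: list[np.ndarray]
    seed_interval_ms: float
    seed_times_ms: np.ndarray

    def __len__(self) -> int:
        return len(self.trajectories)


# ---------------------------------------------------------------------------


def detect_peak_systole(field: VelocityField4D, mask: SegmentationMask) -> int:
    """Frame maximising the mean in-mask speed; ties resolve to the earliest."""
    mask.check_matches(field)
    speed = np.linalg.norm(field.data, axis=-1)  # (nx, ny, nz, nt)
    mean_speed = speed[mask.voxels].mean(axis=0)  # (nt,)
    return int(np.argmax(mean_speed))


def _shift_bool(mask: np.ndarray, axis: int, step: int) -> np.ndarray:
    """Mask shifted by ``step`` along ``axis`` with False fill (no wraparound)."""
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if step > 0:
        src[axis] = slice(step, None)
        dst[axis] = slice(None, -step)
    else:
        src[axis] = slice(None, step)
        dst[axis] = slice(-step, None)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def velocity_gradient(
    field: VelocityField4D,
    frame: int,
    mask: SegmentationMask,
    boundary_policy: str = "central_one_sided",
) -> np.ndarray:
    """Per-voxel velocity-gradient tensor G[i, j] = dv_i/dx_j in 1/s.

    Central differences where both axis-neighbours are in-mask, one-sided
    where exactly one is (under the default policy), NaN where neither is.
    Returns shape ``(nx, ny, nz, 3, 3)``; out-of-mask voxels are all-NaN.
    """
    mask.check_matches(field)
    if not 0 <= frame < field.nt:
        raise IndexError(f"frame {frame} out of range for nt={field.nt}")
    v = field.frame(frame)  # (nx, ny, nz, 3) m/s
    m = mask.voxels
    h_m = field.spacing * 1e-3  # mm -> m

    grad = np.full(m.shape + (3, 3), np.nan)
    for j in range(3):
        has_plus = _shift_bool(m, j, +1)
        has_minus = _shift_bool(m, j, -1)
        v_plus = np.roll(v, -1, axis=j)
        v_minus = np.roll(v, 1, axis=j)

        dv = np.full(v.shape, np.nan)
        central = m & has_plus & has_minus
        dv[central] = (v_plus[central] - v_minus[central]) / (2.0 * h_m[j])
        if boundary_policy == "central_one_sided":
            fwd = m & has_plus & ~has_minus
            dv[fwd] = (v_plus[fwd] - v[fwd]) / h_m[j]
            bwd = m & ~has_plus & has_minus
            dv[bwd] = (v[bwd] - v_minus[bwd]) / h_m[j]
        grad[..., :, j] = dv
    return grad


def compute_velr_map(
    grad: np.ndarray,
    config: AnalysisConfig,
    spacing: np.ndarray,
    frame: int = 0,
    origin: np.ndarray | None = None,
) -> VoxelScalarMap:
    """Viscous energy loss rate per voxel (W/m^3) from the gradient tensor.

    VELR = 2*mu * S:S with S the strain-rate tensor 0.5*(G + G^T); with
    ``include_divergence_term`` the correction -(2/3)*mu*(tr G)^2 is
    subtracted.  Results are clamped at zero.
    """
    if config.mu <= 0:
        raise ValueError("mu must be positive")
    strain = 0.5 * (grad + np.swapaxes(grad, -1, -2))
    velr = 2.0 * config.mu * np.sum(strain * strain, axis=(-2, -1))
    if config.include_divergence_term:
        div = np.trace(grad, axis1=-2, axis2=-1)
        velr = velr - (2.0 / 3.0) * config.mu * div**2
    with np.errstate(invalid="ignore"):
        velr = np.where(velr < 0, 0.0, velr)
    return VoxelScalarMap(
        values=velr,
        quantity="velr_density",
        frame=frame,
        spacing=np.asarray(spacing, dtype=float),
        origin=np.zeros(3) if origin is None else np.asarray(origin, dtype=float),
    )


def compute_vorticity_map(
    grad: np.ndarray,
    spacing: np.ndarray,
    frame: int = 0,
    origin: np.ndarray | None = None,
) -> VoxelVectorMap:
    """Vorticity vector (curl of velocity) per voxel in 1/s."""
    omega = np.stack(
        [
            grad[..., 2, 1] - grad[..., 1, 2],
            grad[..., 0, 2] - grad[..., 2, 0],
            grad[..., 1, 0] - grad[..., 0, 1],
        ],
        axis=-1,
    )
    return VoxelVectorMap(
        values=omega,
        quantity="vorticity",
        frame=frame,
        spacing=np.asarray(spacing, dtype=float),
        origin=np.zeros(3) if origin is None else np.asarray(origin, dtype=float),
    )


def summarize_roi(
    velr: VoxelScalarMap,
    vort: VoxelVectorMap,
    roi: SegmentationMask,
) -> HemodynamicSummary:
    """Aggregate VELR and vorticity over an ROI.

    total VELR = sum of voxelwise VELR times voxel volume (reported in mW);
    VELR density = total / ROI volume (W/m^3); mean vorticity = volume-
    normalised sum of vorticity magnitude (on a uniform grid, the voxel
    average of the in-ROI magnitudes); ROI volume = voxel count * voxel
    volume (m^3).  Voxels with undefined maps contribute zero to the sums.
    """
    if velr.values.shape != roi.voxels.shape:
        raise ValueError(
            f"VELR map grid {velr.values.shape} does not match ROI {roi.voxels.shape}"
        )
    if vort.values.shape[:3] != roi.voxels.shape:
        raise ValueError(
            f"vorticity grid {vort.values.shape[:3]} does not match ROI "
            f"{roi.voxels.shape}"
        )
    if not np.allclose(velr.spacing, vort.spacing):
        raise ValueError("map spacings disagree")
    if velr.frame != vort.frame:
        raise ValueError("maps computed at different frames")

    dv = float(np.prod(velr.spacing * 1e-3))  # voxel volume, m^3
    roi_volume = roi.n_voxels * dv

    velr_in = velr.values[roi.voxels]
    total_velr_w = float(np.nansum(velr_in) * dv)
    velr_density = total_velr_w / roi_volume

    vmag = np.linalg.norm(vort.values, axis=-1)[roi.voxels]
    mean_vorticity = float(np.nansum(vmag) * dv / roi_volume)

    return HemodynamicSummary(
        peak_frame=velr.frame,
        total_velr=total_velr_w * 1e3,
        velr_density=velr_density,
        mean_vorticity=mean_vorticity,
        roi_volume=roi_volume,
    )


# ---------------------------------------------------------------------------
# Pathline tracing


class _FieldSampler:
    """Trilinear (space) x linear (time) velocity interpolation in mm/ms units.

    1 m/s == 1 mm/ms, so velocities sampled here advance positions given in
    mm over times given in ms without further conversion.
    """

    def __init__(self, field: VelocityField4D, mask: SegmentationMask):
        self.data = field.data  # (nx, ny, nz, nt, 3) m/s
        self.spacing = field.spacing
        self.origin = field.origin
        self.dt = field.dt
        self.nt = field.nt
        self.shape = np.array(field.grid_shape)
        self.mask = mask.voxels

    def in_mask(self, pos: np.ndarray) -> np.ndarray:
        idx = np.floor((pos - self.origin) / self.spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < self.shape), axis=-1)
        out = np.zeros(len(pos), dtype=bool)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def _sample_frame(self, pos: np.ndarray, t_idx: int) -> np.ndarray:
        # fractional voxel-centre coordinates; clamp to border for interpolation
        f = (pos - self.origin) / self.spacing - 0.5
        f = np.clip(f, 0.0, self.shape - 1.000001)
        i0 = np.floor(f).astype(int)
        w = f - i0
        vol = self.data[:, :, :, t_idx, :]
        acc = np.zeros((len(pos), 3))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wx = w[:, 0] if dx else 1.0 - w[:, 0]
                    wy = w[:, 1] if dy else 1.0 - w[:, 1]
                    wz = w[:, 2] if dz else 1.0 - w[:, 2]
                    acc += (wx * wy * wz)[:, None] * vol[
                        np.minimum(i0[:, 0] + dx, self.shape[0] - 1),
                        np.minimum(i0[:, 1] + dy, self.shape[1] - 1),
                        np.minimum(i0[:, 2] + dz, self.shape[2] - 1),
                    ]
        return acc

    def velocity(self, pos: np.ndarray, t_ms: float) -> np.ndarray:
        if self.nt == 1:
            return self._sample_frame(pos, 0)
        ft = t_ms / self.dt
        k0 = int(np.clip(np.floor(ft), 0, self.nt - 2))
        a = ft - k0
        a = min(max(a, 0.0), 1.0)
        v0 = self._sample_frame(pos, k0)
        v1 = self._sample_frame(pos, k0 + 1)
        return (1.0 - a) * v0 + a * v1


def trace_pathlines(
    field: VelocityField4D,
    mask: SegmentationMask,
    n_particles: int = 400,
    seed_interval_ms: float = 40.0,
    rng_seed: int = 0,
    step_ms: float | None = None,
    duration_ms: float | None = None,
) -> PathlineSet:
    """Advect massless particles through the time-resolved field.

    ``n_particles`` particles in total are divided as evenly as possible
    across seeding epochs at 0, ``seed_interval_ms``, 2*``seed_interval_ms``,
    ... within the traced window.  Seeding positions are uniform inside the
    mask.  Integration is classical RK4 at a fixed step (default dt/8) with
    trilinear spatial and linear temporal interpolation; a particle
    terminates when its position leaves the mask or time runs out.
    Single-frame fields are treated as steady.
    """
    mask.check_matches(field)
    if seed_interval_ms <= 0:
        raise ValueError("seed_interval_ms must be positive")
    if n_particles <= 0:
        raise ValueError("n_particles must be positive")
    if duration_ms is None:
        duration_ms = field.dt * (field.nt - 1) if field.nt > 1 else field.dt
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    h = field.dt / 8.0 if step_ms is None else float(step_ms)
    if h <= 0:
        raise ValueError("step_ms must be positive")

    rng = np.random.default_rng(rng_seed)
    sampler = _FieldSampler(field, mask)

    seed_times = np.arange(0.0, duration_ms, seed_interval_ms)
    counts = np.full(len(seed_times), n_particles // len(seed_times))
    counts[: n_particles % len(seed_times)] += 1

    mask_idx = np.argwhere(mask.voxels)
    trajectories: list[np.ndarray] = []
    for t0, count in zip(seed_times, counts):
        if count == 0:
            continue
        pick = rng.integers(0, len(mask_idx), size=count)
        offsets = rng.random((count, 3))
        pos = field.origin + (mask_idx[pick] + offsets) * field.spacing

        n_alive = count
        alive = np.ones(count, dtype=bool)
        paths: list[list[tuple]] = [[(t0, *p)] for p in pos]
        t = t0
        while n_alive > 0 and t < duration_ms - 1e-9:
            step = min(h, duration_ms - t)
            p = pos[alive]
            k1 = sampler.velocity(p, t)
            k2 = sampler.velocity(p + 0.5 * step * k1, t + 0.5 * step)
            k3 = sampler.velocity(p + 0.5 * step * k2, t + 0.5 * step)
            k4 = sampler.velocity(p + step * k3, t + step)
            p_new = p + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += step

            still_in = sampler.in_mask(p_new)
            alive_idx = np.flatnonzero(alive)
            pos[alive] = p_new
            for local, gi in enumerate(alive_idx):
                if still_in[local]:
                    paths[gi].append((t, *p_new[local]))
                else:
                    alive[gi] = False
            n_alive = int(alive.sum())
        trajectories.extend(np.asarray(p) for p in paths)

    return PathlineSet(
        trajectories=trajectories,
        seed_interval_ms=seed_interval_ms,
        seed_times_ms=seed_times,
    )
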