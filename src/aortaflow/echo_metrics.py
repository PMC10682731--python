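"""Transthoracic-echo valvular metrics from Doppler velocity envelopes.

Conventions: velocities in m/s (forward flow positive), times in seconds,
velocity-time integrals in cm, pressure gradients in mmHg via the
simplified Bernoulli relation dP = 4*v^2, areas in cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DopplerTrace",
    "ValveSpec",
    "EchoMetrics",
    "detect_ejection_window",
    "compute_vti",
    "compute_tpv_tpg",
    "compute_eoa",
    "compute_eoai_and_dc",
    "evaluate_echo",
]


@dataclass
class DopplerTrace:
    """Sampled Doppler velocity envelope over one or more cardiac cycles."""

    t: np.ndarray  # sample times, s
    v: np.ndarray  # velocity envelope, m/s
    modality: str  # "CW" | "PW"
    site: str = "aortic-valve"  # "aortic-valve" | "LVOT"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise ValueError("t and v must be 1D arrays of equal length")
        if len(self.t) < 2:
            raise ValueError("trace needs at least two samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.max(dt) > 1.01 * np.min(dt):
            raise ValueError("sampling jitter exceeds 1%")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("velocity envelope contains non-finite values")
        if self.modality not in ("CW", "PW"):
            raise ValueError(f"modality must be 'CW' or 'PW', got {self.modality!r}")

    @classmethod
    def from_csv(cls, path) -> "DopplerTrace":
        """Read a trace CSV with columns t_s, v_ms, modality, site."""
        df = pd.read_csv(path)
        for col in ("t_s", "v_ms"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        modality = str(df["modality"].iloc[0]) if "modality" in df.columns else "CW"
        site = str(df["site"].iloc[0]) if "site" in df.columns else "aortic-valve"
        return cls(
            t=df["t_s"].to_numpy(),
            v=df["v_ms"].to_numpy(),
            modality=modality,
            site=site,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "t_s": self.t,
                "v_ms": self.v,
                "modality": self.modality,
                "site": self.site,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ValveSpec:
    """Prosthesis geometry from the manufacturer specification sheet."""

    label_size: float  # mm
    goa: float  # geometric orifice area, cm^2
    model: str = "On-X"  # On-X | SJM | CM

    def __post_init__(self) -> None:
        if self.goa <= 0:
            raise ValueError(f"geometric orifice area must be positive, got {self.goa}")


@dataclass(frozen=True)
class EchoMetrics:
    tpv: float  # m/s
    mean_tpg: float  # mmHg
    peak_tpg: float  # mmHg
    vti_av: float  # cm
    vti_lvot: float  # cm
    eoa: float  # cm^2
    eoai: float | None = None  # cm^2 / m^2
    discharge_coefficient: float | None = None


def detect_ejection_window(
    trace: DopplerTrace, threshold_fraction: float = 0.1
) -> tuple[float, float]:
    """Longest contiguous interval with v above a fraction of the envelope max.

    Start and end are located at the threshold crossings by linear
    interpolation between samples.
    """
    vmax = float(np.max(trace.v))
    if vmax <= 0:
        raise ValueError("trace has no forward flow (all-zero or negative)")
    thr = threshold_fraction * vmax

    above = trace.v > thr
    # contiguous runs of above-threshold samples
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))

    best = None
    for s, e in zip(starts, ends):
        t_start = _cross_time(trace, s, thr, rising=True)
        t_end = _cross_time(trace, e - 1, thr, rising=False)
        if best is None or (t_end - t_start) > (best[1] - best[0]):
            best = (t_start, t_end)
    assert best is not None
    return best


def _cross_time(trace: DopplerTrace, idx: int, thr: float, rising: bool) -> float:
    """Interpolated time where v crosses thr adjacent to sample idx."""
    t, v = trace.t, trace.v
    if rising:
        if idx == 0 or v[idx - 1] > thr:
            return float(t[idx])
        a, b = idx - 1, idx
    else:
        if idx == len(v) - 1 or v[idx + 1] > thr:
            return float(t[idx])
        a, b = idx, idx + 1
    frac = (thr - v[a]) / (v[b] - v[a])
    return float(t[a] + frac * (t[b] - t[a]))


def _window_samples(
    trace: DopplerTrace, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Samples inside the window with linearly interpolated endpoint values."""
    t_start, t_end = window
    if t_end <= t_start:
        raise ValueError(f"empty window ({t_start}, {t_end})")
    if t_start < trace.t[0] - 1e-12 or t_end > trace.t[-1] + 1e-12:
        raise ValueError("window extends beyond the trace")
    t_start = max(t_start, float(trace.t[0]))
    t_end = min(t_end, float(trace.t[-1]))
    inside = (trace.t > t_start) & (trace.t < t_end)
    tt = np.concatenate(([t_start], trace.t[inside], [t_end]))
    vv = np.concatenate(
        (
            [np.interp(t_start, trace.t, trace.v)],
            trace.v[inside],
            [np.interp(t_end, trace.t, trace.v)],
        )
    )
    return tt, vv


def compute_vti(trace: DopplerTrace, window: tuple[float, float]) -> float:
    """Velocity-time integral over the window (trapezoidal), in cm."""
    tt, vv = _window_samples(trace, window)
    return float(np.trapezoid(vv, tt) * 100.0)


def compute_tpv_tpg(
    trace: DopplerTrace, window: tuple[float, float]
) -> tuple[float, float, float]:
    """Peak velocity and Bernoulli pressure gradients over the window.

    tpv = max velocity (m/s); peak TPG = 4*tpv^2 (mmHg); mean TPG =
    time-average of 4*v(t)^2 over the window (mmHg).  Transvalvular
    gradients require a continuous-wave trace.
    """
    if trace.modality != "CW":
        raise ValueError(
            "transvalvular gradients require a CW Doppler trace, "
            f"got {trace.modality}"
        )
    tt, vv = _window_samples(trace, window)
    tpv = float(np.max(vv))
    peak_tpg = 4.0 * tpv**2
    mean_tpg = float(np.trapezoid(4.0 * vv**2, tt) / (tt[-1] - tt[0]))
    return tpv, mean_tpg, peak_tpg


def compute_eoa(lvot_diameter: float, vti_lvot: float, vti_av: float) -> float:
    """Continuity-equation effective orifice area (cm^2).

    EOA = (LVOT cross-section * VTI_LVOT) / VTI_AV with the LVOT modelled
    as a circle of the measured diameter (cm).
    """
    for name, val in (
        ("lvot_diameter", lvot_diameter),
        ("vti_lvot", vti_lvot),
        ("vti_av", vti_av),
    ):
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    lvot_area = np.pi * (lvot_diameter / 2.0) ** 2
    return float(lvot_area * vti_lvot / vti_av)


def compute_eoai_and_dc(
    eoa: float, bsa: float, spec: ValveSpec
) -> tuple[float, float]:
    """EOA indexed to body surface area, and the discharge coefficient
    (EOA over the geometric orifice area)."""
    if eoa <= 0:
        raise ValueError(f"eoa must be positive, got {eoa}")
    if bsa <= 0:
        raise ValueError(f"bsa must be positive, got {bsa}")
    return eoa / bsa, eoa / spec.goa


def evaluate_echo(
    av_trace: DopplerTrace,
    lvot_trace: DopplerTrace,
    lvot_diameter: float,
    bsa: float | None = None,
    spec: ValveSpec | None = None,
) -> EchoMetrics:
    """Full TTE metric set from an aortic-valve CW trace and an LVOT PW trace."""
    av_window = detect_ejection_window(av_trace)
    lvot_window = detect_ejection_window(lvot_trace)
    vti_av = compute_vti(av_trace, av_window)
    vti_lvot = compute_vti(lvot_trace, lvot_window)
    tpv, mean_tpg, peak_tpg = compute_tpv_tpg(av_trace, av_window)
    eoa = compute_eoa(lvot_diameter, vti_lvot, vti_av)
    eoai = eoa / bsa if bsa else None
    dc = eoa / spec.goa if spec else None
    return EchoMetrics(
        tpv=tpv,
        mean_tpg=mean_tpg,
        peak_tpg=peak_tpg,
        vti_av=vti_av,
        vti_lvot=vti_lvot,
        eoa=eoa,
        eoai=eoai,
        discharge_coefficient=dc,
    )
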