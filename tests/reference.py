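"""Naive triple-loop reference implementations used as independent oracles.

Deliberately unvectorized and structured differently from the package code:
explicit per-voxel loops, per-axis neighbour inspection, scalar arithmetic.
"""

import numpy as np


def brute_force_gradient(v, mask, spacing_mm, one_sided=True):
    """Per-voxel velocity-gradient tensor by explicit looping.

    v: (nx, ny, nz, 3) m/s; mask: bool (nx, ny, nz); spacing in mm.
    Returns (nx, ny, nz, 3, 3) with G[i, j] = dv_i/dx_j in 1/s, NaN where
    undefined.
    """
    nx, ny, nz, _ = v.shape
    h = np.asarray(spacing_mm, dtype=float) * 1e-3
    G = np.full((nx, ny, nz, 3, 3), np.nan)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if not mask[ix, iy, iz]:
                    continue
                idx = (ix, iy, iz)
                for j in range(3):
                    plus = list(idx)
                    plus[j] += 1
                    minus = list(idx)
                    minus[j] -= 1
                    has_plus = 0 <= plus[j] < v.shape[j] and mask[tuple(plus)]
                    has_minus = 0 <= minus[j] < v.shape[j] and mask[tuple(minus)]
                    for i in range(3):
                        if has_plus and has_minus:
                            d = (v[tuple(plus)][i] - v[tuple(minus)][i]) / (2 * h[j])
                        elif has_plus and one_sided:
                            d = (v[tuple(plus)][i] - v[idx][i]) / h[j]
                        elif has_minus and one_sided:
                            d = (v[idx][i] - v[tuple(minus)][i]) / h[j]
                        else:
                            continue
                        G[ix, iy, iz, i, j] = d
    return G


def brute_force_velr(G, mu, include_divergence=False):
    """Dissipation rate per voxel from the gradient tensor, looped."""
    nx, ny, nz = G.shape[:3]
    out = np.full((nx, ny, nz), np.nan)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                g = G[ix, iy, iz]
                if np.isnan(g).all():
                    continue
                total = 0.0
                for i in range(3):
                    for j in range(3):
                        s = 0.5 * (g[i, j] + g[j, i])
                        total += 2.0 * mu * s * s
                if include_divergence:
                    div = g[0, 0] + g[1, 1] + g[2, 2]
                    total -= (2.0 / 3.0) * mu * div * div
                out[ix, iy, iz] = max(total, 0.0) if not np.isnan(total) else np.nan
    return out


def brute_force_vorticity(G):
    """Curl per voxel from the gradient tensor, looped."""
    nx, ny, nz = G.shape[:3]
    out = np.full((nx, ny, nz, 3), np.nan)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                g = G[ix, iy, iz]
                out[ix, iy, iz, 0] = g[2, 1] - g[1, 2]
                out[ix, iy, iz, 1] = g[0, 2] - g[2, 0]
                out[ix, iy, iz, 2] = g[1, 0] - g[0, 1]
    return out


def poiseuille_exact_voxel_integral(mask_ij, spacing_mm, center_mm, R_mm, U, mu, L_m):
    """Exact integral of the parabolic-pipe dissipation over a set of voxels.

    Dissipation density is mu * (2*U*r/R^2)^2 = 4*mu*U^2*(x^2+y^2)/R^4; its
    integral over an axis-aligned voxel column is closed-form.  ``mask_ij``
    is a 2D boolean cross-section selection; the z-extent contributes the
    factor ``L_m``.
    """
    hx, hy = spacing_mm[0] * 1e-3, spacing_mm[1] * 1e-3
    cx, cy = center_mm[0] * 1e-3, center_mm[1] * 1e-3
    R = R_mm * 1e-3
    total = 0.0
    nx, ny = mask_ij.shape
    for ix in range(nx):
        for iy in range(ny):
            if not mask_ij[ix, iy]:
                continue
            x0 = ix * hx - cx
            x1 = (ix + 1) * hx - cx
            y0 = iy * hy - cy
            y1 = (iy + 1) * hy - cy
            integral_x2 = (x1**3 - x0**3) / 3.0 * (y1 - y0)
            integral_y2 = (y1**3 - y0**3) / 3.0 * (x1 - x0)
            total += 4.0 * mu * U**2 / R**4 * (integral_x2 + integral_y2)
    return total * L_m
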