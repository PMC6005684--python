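"""Numba-compiled inner loops for slice interpolation and the pose-grid search.

These kernels are the only performance-critical code in the package: the
per-particle likelihood evaluation visits every (rotation, translation) grid
point for every retained Fourier pixel, and the reconstruction scatters every
pixel of every significant pose onto 8 voxels of the 3D accumulators.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False, fastmath=True)
def trilinear_sample(fvol, x, y, z):
    """Trilinear interpolation of a complex cube at fractional coordinates."""
    n = fvol.shape[0]
    x0 = int(np.floor(x))
    y0 = int(np.floor(y))
    z0 = int(np.floor(z))
    if x0 < 0 or y0 < 0 or z0 < 0 or x0 >= n - 1 or y0 >= n - 1 or z0 >= n - 1:
        return 0.0 + 0.0j
    fx = x - x0
    fy = y - y0
    fz = z - z0
    c000 = fvol[x0, y0, z0]
    c100 = fvol[x0 + 1, y0, z0]
    c010 = fvol[x0, y0 + 1, z0]
    c110 = fvol[x0 + 1, y0 + 1, z0]
    c001 = fvol[x0, y0, z0 + 1]
    c101 = fvol[x0 + 1, y0, z0 + 1]
    c011 = fvol[x0, y0 + 1, z0 + 1]
    c111 = fvol[x0 + 1, y0 + 1, z0 + 1]
    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


@njit(cache=False, fastmath=True)
def grid_log_likelihood(fvol, rotations, s_tilde, ctf, inv_sigma2,
                        kx, ky, trans_phase, out):
    """Negative squared-error log-likelihood over a factored pose grid.

    Parameters
    ----------
    fvol : complex (D, D, D) centred 3D transform of the (COM-centred) body.
    rotations : (n_rot, 3, 3) effective rotation matrices (consensus o residual).
    s_tilde : complex (n_px,) subtracted image pixels, pre-multiplied by the
        conjugate of the pose-independent phase shift.
    ctf : (n_px,) CTF values.
    inv_sigma2 : (n_px,) reciprocal per-pixel noise variance.
    kx, ky : (n_px,) centred integer frequency coordinates.
    trans_phase : complex (n_trans, n_px) extra phase for each candidate
        in-plane translation.
    out : (n_rot, n_trans) array, filled with -sum |S - CTF P V|^2 / sigma^2.
    """
    n_rot = rotations.shape[0]
    n_trans = trans_phase.shape[0]
    n_px = kx.shape[0]
    c = fvol.shape[0] // 2
    for ir in range(n_rot):
        R = rotations[ir]
        for t in range(n_trans):
            out[ir, t] = 0.0
        for j in range(n_px):
            qx = c + kx[j] * R[0, 0] + ky[j] * R[1, 0]
            qy = c + kx[j] * R[0, 1] + ky[j] * R[1, 1]
            qz = c + kx[j] * R[0, 2] + ky[j] * R[1, 2]
            v = trilinear_sample(fvol, qx, qy, qz)
            w = ctf[j] * v
            s = s_tilde[j]
            iv = inv_sigma2[j]
            for t in range(n_trans):
                d = s - w * trans_phase[t, j]
                out[ir, t] -= (d.real * d.real + d.imag * d.imag) * iv


@njit(cache=False, fastmath=True)
def scatter_slice(num, den, vals, den_weights, kx, ky, R):
    """Adjoint interpolation: spread 2D samples onto the 3D accumulators.

    ``vals`` already carries the numerator weights (Gamma * CTF / sigma^2
    times the un-phase-shifted image); ``den_weights`` carries
    Gamma * CTF^2 / sigma^2.  Trilinear weights distribute each sample over
    its 8 neighbouring voxels of both accumulators in place.
    """
    n = num.shape[0]
    c = n // 2
    n_px = kx.shape[0]
    for j in range(n_px):
        qx = c + kx[j] * R[0, 0] + ky[j] * R[1, 0]
        qy = c + kx[j] * R[0, 1] + ky[j] * R[1, 1]
        qz = c + kx[j] * R[0, 2] + ky[j] * R[1, 2]
        x0 = int(np.floor(qx))
        y0 = int(np.floor(qy))
        z0 = int(np.floor(qz))
        if x0 < 0 or y0 < 0 or z0 < 0 or x0 >= n - 1 or y0 >= n - 1 or z0 >= n - 1:
            continue
        fx = qx - x0
        fy = qy - y0
        fz = qz - z0
        v = vals[j]
        w = den_weights[j]
        for dx in range(2):
            wx = fx if dx == 1 else 1.0 - fx
            for dy in range(2):
                wy = fy if dy == 1 else 1.0 - fy
                for dz in range(2):
                    wz = fz if dz == 1 else 1.0 - fz
                    ww = wx * wy * wz
                    num[x0 + dx, y0 + dy, z0 + dz] += v * ww
                    den[x0 + dx, y0 + dy, z0 + dz] += w * ww
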