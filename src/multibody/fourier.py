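"""Fourier-space machinery: central-slice extraction and insertion, CTF
evaluation, Fourier shell correlation with solvent correction, and
signal-power (tau^2) estimation.

All transforms use centred frequency grids (`fftshift` layout) with the phase
origin at the box-centre voxel D/2 and orthonormal FFT normalisation, so
power is preserved between real and Fourier space.  A projection with pose
(R, sx, sy) is the central section of the 3D transform on the plane spanned
by the rotated x/y axes, phase-shifted by the in-plane translation:

    F_2D(k) = F_3D(R^T (kx, ky, 0)) * exp(-2 pi i (kx sx + ky sy) / D)

which corresponds in real space to rotating the volume by R, projecting
along z, and shifting the projection by (sx, sy) pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from . import _kernels

__all__ = [
    "CTFParams",
    "fft2_centered",
    "ifft2_centered",
    "fft3_centered",
    "ifft3_centered",
    "freq_grid_2d",
    "shell_indices_2d",
    "shell_indices_3d",
    "extract_slice",
    "insert_slice",
    "translate_image",
    "evaluate_ctf",
    "electron_wavelength",
    "compute_fsc",
    "solvent_correct_fsc",
    "estimate_tau2",
    "resolution_at_threshold",
    "shell_average_power",
]


# ---------------------------------------------------------------------------
# centred FFTs

def fft2_centered(img: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img), norm="ortho"))


def ifft2_centered(F: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(F), norm="ortho"))


def fft3_centered(vol: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vol), norm="ortho"))


def ifft3_centered(F: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(F), norm="ortho"))


def freq_grid_2d(box: int) -> tuple[np.ndarray, np.ndarray]:
    """Centred integer frequency coordinates (kx, ky) with array axes (x, y)."""
    k = np.arange(box) - box // 2
    return np.meshgrid(k, k, indexing="ij")


def shell_indices_2d(box: int) -> np.ndarray:
    kx, ky = freq_grid_2d(box)
    return np.rint(np.sqrt(kx**2 + ky**2)).astype(np.int64)


def shell_indices_3d(box: int) -> np.ndarray:
    k = np.arange(box) - box // 2
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    return np.rint(np.sqrt(kx**2 + ky**2 + kz**2)).astype(np.int64)


# ---------------------------------------------------------------------------
# slice extraction / insertion

def translate_image(F: np.ndarray, sx: float, sy: float) -> np.ndarray:
    """Phase-shift a centred 2D transform by (sx, sy) pixels."""
    box = F.shape[0]
    kx, ky = freq_grid_2d(box)
    return F * np.exp(-2j * np.pi * (kx * sx + ky * sy) / box)


def extract_slice(
    fvol: np.ndarray,
    R: np.ndarray,
    sx: float = 0.0,
    sy: float = 0.0,
    rmax: float | None = None,
) -> np.ndarray:
    """Central-section slice of a centred 3D transform at rotation R.

    Trilinear interpolation; frequencies beyond ``rmax`` (default: the
    largest radius fully inside the cube) are set to zero.  The slice is
    phase-shifted by the in-plane translation (sx, sy).
    """
    box = fvol.shape[0]
    c = box // 2
    if rmax is None:
        rmax = c - 1
    kx, ky = freq_grid_2d(box)
    R = np.asarray(R, dtype=float)
    # q = R^T (kx, ky, 0): sample coordinates in the volume frame
    coords = np.empty((3, box, box))
    for ax in range(3):
        coords[ax] = c + kx * R[0, ax] + ky * R[1, ax]
    out = ndimage.map_coordinates(fvol, coords, order=1, mode="constant", cval=0.0)
    out[kx**2 + ky**2 > rmax**2] = 0.0
    if sx != 0.0 or sy != 0.0:
        out = translate_image(out, sx, sy)
    return out


def insert_slice(
    accumulator_num: np.ndarray,
    accumulator_den: np.ndarray,
    image: np.ndarray,
    R: np.ndarray,
    sx: float = 0.0,
    sy: float = 0.0,
    num_weight: np.ndarray | float = 1.0,
    den_weight: np.ndarray | float = 1.0,
    rmax: float | None = None,
) -> None:
    """Adjoint of :func:`extract_slice`: spread a weighted 2D slice into 3D.

    Each 2D sample (un-phase-shifted by the pose translation) is distributed
    over its 8 neighbouring 3D voxels with trilinear weights.  The numerator
    accumulates ``image * num_weight``, the denominator ``den_weight``
    (typically Gamma * CTF / sigma^2 and Gamma * CTF^2 / sigma^2).
    Accumulators are modified in place.
    """
    box = accumulator_num.shape[0]
    c = box // 2
    if rmax is None:
        rmax = c - 1
    kx, ky = freq_grid_2d(box)
    sel = (kx**2 + ky**2 <= rmax**2).ravel()
    kxf = kx.ravel()[sel].astype(np.float64)
    kyf = ky.ravel()[sel].astype(np.float64)
    vals = image.ravel()[sel].astype(np.complex128)
    if sx != 0.0 or sy != 0.0:
        vals = vals * np.exp(2j * np.pi * (kxf * sx + kyf * sy) / box)
    if np.ndim(num_weight):
        nw = np.asarray(num_weight, dtype=np.float64).ravel()[sel]
    else:
        nw = np.full(kxf.shape, float(num_weight))
    if np.ndim(den_weight):
        dw = np.asarray(den_weight, dtype=np.float64).ravel()[sel]
    else:
        dw = np.full(kxf.shape, float(den_weight))
    _kernels.scatter_slice(
        accumulator_num, accumulator_den, vals * nw, dw,
        kxf, kyf, np.ascontiguousarray(np.asarray(R, dtype=np.float64)),
    )


# ---------------------------------------------------------------------------
# CTF

def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom for a voltage in kV."""
    v = voltage_kv * 1e3
    return 12.2643247 / np.sqrt(v * (1.0 + v * 0.978466e-6))


@dataclass(frozen=True)
class CTFParams:
    """Standard phase-contrast CTF parameters.

    defocus_u/defocus_v in Angstrom (positive = underfocus), astigmatism
    angle in degrees, voltage in kV, spherical aberration Cs in mm,
    amplitude contrast as a fraction, optional B-factor envelope in A^2.
    """

    defocus_u: float = 15000.0
    defocus_v: float = 15000.0
    astig_angle: float = 0.0
    voltage: float = 300.0
    cs: float = 2.7
    amplitude_contrast: float = 0.1
    bfactor: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.amplitude_contrast <= 1.0):
            raise ValueError("amplitude contrast must be in [0, 1]")


def evaluate_ctf(params: CTFParams, box: int, voxel_size: float) -> np.ndarray:
    """Evaluate the CTF on a centred (box, box) frequency grid.

    CTF(g) = -(sqrt(1 - A^2) sin(chi) + A cos(chi)), with the aberration
    phase chi(g) = pi lambda dz(alpha) g^2 - (pi/2) Cs lambda^3 g^4 and the
    astigmatic defocus dz(alpha).  At g = 0 the value is -A.
    """
    lam = electron_wavelength(params.voltage)
    kx, ky = freq_grid_2d(box)
    gx = kx / (box * voxel_size)
    gy = ky / (box * voxel_size)
    g2 = gx**2 + gy**2
    alpha = np.arctan2(gy, gx)
    dz_avg = 0.5 * (params.defocus_u + params.defocus_v)
    dz_dif = 0.5 * (params.defocus_u - params.defocus_v)
    dz = dz_avg + dz_dif * np.cos(2.0 * (alpha - np.deg2rad(params.astig_angle)))
    cs = params.cs * 1e7  # mm -> Angstrom
    chi = np.pi * lam * dz * g2 - 0.5 * np.pi * cs * lam**3 * g2**2
    a = params.amplitude_contrast
    ctf = -(np.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))
    if params.bfactor:
        ctf = ctf * np.exp(-params.bfactor * g2 / 4.0)
    return ctf


# ---------------------------------------------------------------------------
# FSC, solvent correction, tau^2, resolution

def _fsc_from_transforms(F1: np.ndarray, F2: np.ndarray) -> np.ndarray:
    box = F1.shape[0]
    shells = shell_indices_3d(box).ravel()
    n_shells = box // 2 + 1
    keep = shells < n_shells
    s = shells[keep]
    a = F1.ravel()[keep]
    b = F2.ravel()[keep]
    num = np.bincount(s, weights=(a * np.conj(b)).real, minlength=n_shells)
    p1 = np.bincount(s, weights=np.abs(a) ** 2, minlength=n_shells)
    p2 = np.bincount(s, weights=np.abs(b) ** 2, minlength=n_shells)
    den = np.sqrt(p1 * p2)
    fsc = np.ones(n_shells)
    ok = den > 0
    fsc[ok] = num[ok] / den[ok]
    return np.clip(fsc, -1.0, 1.0)


def compute_fsc(half_map_1: np.ndarray, half_map_2: np.ndarray) -> np.ndarray:
    """Per-shell normalised cross-correlation of two real-space volumes."""
    if half_map_1.shape != half_map_2.shape:
        raise ValueError("half maps must have the same shape")
    return _fsc_from_transforms(fft3_centered(half_map_1), fft3_centered(half_map_2))


def _randomize_phases(F: np.ndarray, from_shell: int, rng: np.random.Generator) -> np.ndarray:
    """Replace phases beyond a shell with Hermitian-symmetric random phases."""
    box = F.shape[0]
    noise = fft3_centered(rng.standard_normal((box, box, box)))
    phase = np.exp(1j * np.angle(noise))
    out = F.copy()
    beyond = shell_indices_3d(box) >= from_shell
    out[beyond] = np.abs(F[beyond]) * phase[beyond]
    return out


def solvent_correct_fsc(
    half1: np.ndarray,
    half2: np.ndarray,
    mask: np.ndarray,
    randomize_from_shell: int | None = None,
    seed: int = 17,
) -> np.ndarray:
    """Masked FSC corrected for mask-convolution effects by phase randomization.

    The phases of both half maps are randomized beyond ``randomize_from_shell``
    (default: the first shell where the unmasked FSC drops below 0.8); the
    corrected curve is (FSC_masked - FSC_rand) / (1 - FSC_rand) beyond that
    shell and the plain masked FSC below it.
    """
    m1 = half1 * mask
    m2 = half2 * mask
    if not (np.any(m1) and np.any(m2)):
        raise ValueError("masked half maps are empty")
    fsc_masked = compute_fsc(m1, m2)
    if randomize_from_shell is None:
        fsc_plain = compute_fsc(half1, half2)
        below = np.nonzero(fsc_plain < 0.8)[0]
        randomize_from_shell = int(below[0]) if len(below) else len(fsc_plain) - 1
    randomize_from_shell = max(int(randomize_from_shell), 1)
    rng = np.random.default_rng(seed)
    F1r = _randomize_phases(fft3_centered(half1), randomize_from_shell, rng)
    F2r = _randomize_phases(fft3_centered(half2), randomize_from_shell, rng)
    r1 = ifft3_centered(F1r).real * mask
    r2 = ifft3_centered(F2r).real * mask
    fsc_rand = compute_fsc(r1, r2)
    corrected = fsc_masked.copy()
    beyond = np.arange(len(fsc_masked)) >= randomize_from_shell
    fr = np.clip(fsc_rand[beyond], -1.0, 0.999)
    corrected[beyond] = (fsc_masked[beyond] - fr) / (1.0 - fr)
    return np.clip(corrected, -1.0, 1.0)


def shell_average_power(vol: np.ndarray) -> np.ndarray:
    """Mean squared Fourier amplitude per integer shell of a real volume."""
    F = fft3_centered(vol)
    box = F.shape[0]
    shells = shell_indices_3d(box).ravel()
    n_shells = box // 2 + 1
    keep = shells < n_shells
    s = shells[keep]
    power = np.bincount(s, weights=np.abs(F.ravel()[keep]) ** 2, minlength=n_shells)
    counts = np.bincount(s, minlength=n_shells)
    return power / np.maximum(counts, 1)


def estimate_tau2(
    fsc_corrected: np.ndarray,
    reconstruction_power: np.ndarray,
    fsc_cap: float = 0.999,
) -> np.ndarray:
    """Per-shell signal power from the half-set FSC: tau^2 = FSC/(1-FSC) * power.

    The FSC is clipped to [0, fsc_cap] before the ratio; shells with
    non-positive FSC get zero signal power.
    """
    fsc = np.clip(np.asarray(fsc_corrected, dtype=float), 0.0, fsc_cap)
    tau2 = fsc / (1.0 - fsc) * np.asarray(reconstruction_power, dtype=float)
    tau2[fsc <= 0] = 0.0
    return tau2


class Resolution(NamedTuple):
    resolution: float  # Angstrom
    limited: bool  # True if the curve never crossed the threshold (Nyquist)


def resolution_at_threshold(
    fsc: np.ndarray,
    voxel_size: float,
    box: int,
    threshold: float = 0.143,
) -> Resolution:
    """Resolution at the first crossing of the FSC below a threshold.

    Linear interpolation between shells; if the curve never drops below the
    threshold, the Nyquist resolution (2 * voxel size) is returned flagged.
    """
    fsc = np.asarray(fsc, dtype=float)
    n = min(len(fsc), box // 2 + 1)
    for k in range(1, n):
        if fsc[k] < threshold:
            f_prev, f_here = fsc[k - 1], fsc[k]
            frac = (f_prev - threshold) / (f_prev - f_here) if f_prev != f_here else 0.0
            shell = (k - 1) + frac
            shell = max(shell, 1e-6)
            return Resolution(resolution=box * voxel_size / shell, limited=False)
    return Resolution(resolution=2.0 * voxel_size, limited=True)
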