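"""Polarization indirect microscopic imaging (PIMI): forward model and demodulation.

A PIMI acquisition records one camera frame per orientation of a rotating
linear polarizer.  Each pixel then traces the modulation law

    I(theta) = (1/2) * I0 * [1 + sin(delta) * sin(2*(theta - phi))]

where ``I0`` sets the mean level, ``sin(delta)`` is the sine of the phase
difference between the two orthogonal polarization components of the
reflected light, and ``phi`` is the polarization-ellipse orientation.
Because the modulation is a pure second harmonic in ``theta``, the three
parameters are recovered per pixel by closed-form harmonic regression
(exact least squares on the sampled angles), not by iterative fitting.

Conventions
-----------
* ``sindelta`` is reported non-negative; the sign is folded into ``phi``,
  which is reported in [0, 180) degrees.
* ``i0`` equals twice the fitted mean level, so the modulation law above
  holds with the returned parameters verbatim.
* Pixels where the fit is degenerate are flagged, never raised on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FLAG_OK",
    "FLAG_NONPOS_I0",
    "FLAG_SINDELTA_GT1",
    "FLAG_PHI_UNDEFINED",
    "PolarizationFrameStack",
    "PimiParameterMaps",
    "DemodResult",
    "forward_intensity",
    "demodulate_series",
    "demodulate_stack",
]

# Per-pixel quality flags (bitmask).
FLAG_OK = 0
FLAG_NONPOS_I0 = 1       # fitted mean level <= 0; sindelta forced to 0
FLAG_SINDELTA_GT1 = 2    # noise pushed the modulation depth above 1 (kept, not clamped)
FLAG_PHI_UNDEFINED = 4   # no modulation detected; phi set to 0 by convention

_MIN_SAMPLES = 5


def _check_angles(angles_deg: np.ndarray) -> None:
    if angles_deg.ndim != 1 or angles_deg.size < _MIN_SAMPLES:
        raise ValueError(
            f"need at least {_MIN_SAMPLES} polarization angles, got {angles_deg.size}"
        )
    folded = np.sort(np.mod(angles_deg, 180.0))
    gaps = np.diff(folded)
    # wrap-around gap closes the circle
    gaps = np.append(gaps, 180.0 - (folded[-1] - folded[0]))
    if np.any(gaps[:-1] < 1e-9):
        raise ValueError("polarization angles must be pairwise distinct modulo 180 deg")


@dataclass(frozen=True)
class PolarizationFrameStack:
    """Ordered intensity frames with their incident polarization angles.

    The default acquisition protocol is 10 frames stepped by 18 degrees
    over a half turn of the polarizer.
    """

    frames: np.ndarray                      # (n_angles, H, W), camera units
    angles_deg: np.ndarray                  # (n_angles,)
    pixel_size_nm: float
    wavelength_nm: float = 600.0
    bandwidth_nm: float = 35.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        angles = np.asarray(self.angles_deg, dtype=float)
        if frames.ndim != 3:
            raise ValueError("frames must be a (n_angles, H, W) array")
        if frames.shape[0] != angles.size:
            raise ValueError(
                f"{frames.shape[0]} frames but {angles.size} angles"
            )
        _check_angles(angles)
        if not np.all(np.isfinite(frames)):
            raise ValueError("frame intensities must be finite")
        if np.any(frames < 0):
            raise ValueError("frame intensities must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "angles_deg", angles)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class PimiParameterMaps:
    """Per-pixel parametric maps recovered from one modulation series."""

    i0_map: np.ndarray
    sindelta_map: np.ndarray
    phi_map: np.ndarray          # degrees, in [0, 180)
    residual_map: np.ndarray     # RMS misfit, same units as the frames
    flag_map: np.ndarray         # uint8 bitmask of FLAG_* values

    def __post_init__(self) -> None:
        shape = self.i0_map.shape
        for name in ("sindelta_map", "phi_map", "residual_map", "flag_map"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shape}")


@dataclass(frozen=True)
class DemodResult:
    i0: float
    sindelta: float
    phi_deg: float
    residual_rms: float
    flag: int = FLAG_OK


def forward_intensity(i0, sindelta, phi_deg, theta_deg):
    """Intensity under the PIMI modulation law.

    All arguments broadcast; angles are in degrees.  Raises on a negative
    mean level or a modulation depth outside [0, 1].
    """
    i0 = np.asarray(i0, dtype=float)
    sindelta = np.asarray(sindelta, dtype=float)
    if np.any(i0 < 0):
        raise ValueError("i0 must be non-negative")
    if np.any((sindelta < 0) | (sindelta > 1)):
        raise ValueError("sindelta must lie in [0, 1]")
    arg = 2.0 * np.deg2rad(np.asarray(theta_deg, dtype=float) - np.asarray(phi_deg, dtype=float))
    out = 0.5 * i0 * (1.0 + sindelta * np.sin(arg))
    if out.ndim == 0:
        return float(out)
    return out


def _design_matrix(angles_deg: np.ndarray) -> np.ndarray:
    two_theta = 2.0 * np.deg2rad(angles_deg)
    return np.column_stack([np.ones_like(two_theta), np.sin(two_theta), np.cos(two_theta)])


def _params_from_coeffs(a, s, c):
    """Map harmonic-regression coefficients (a, s, c) to (i0, sindelta, phi, flag).

    The model is I = a + s*sin(2t) + c*cos(2t) with
    a = i0/2, s = (i0/2)*sindelta*cos(2*phi), c = -(i0/2)*sindelta*sin(2*phi).
    Vectorized over arrays.
    """
    a = np.asarray(a, dtype=float)
    s = np.asarray(s, dtype=float)
    c = np.asarray(c, dtype=float)
    amp = np.hypot(s, c)
    # least-squares dust on an unmodulated series is not signal
    amp[amp <= 1e-12 * np.abs(a)] = 0.0
    flag = np.zeros(a.shape, dtype=np.uint8)

    pos = a > 0
    sindelta = np.zeros_like(a)
    np.divide(amp, a, out=sindelta, where=pos)
    flag[~pos] |= FLAG_NONPOS_I0
    flag[pos & (sindelta > 1)] |= FLAG_SINDELTA_GT1

    phi = 0.5 * np.rad2deg(np.arctan2(-c, s))
    phi = np.mod(phi, 180.0)
    undef = ~pos | (amp == 0)
    phi[undef] = 0.0
    flag[undef] |= FLAG_PHI_UNDEFINED
    sindelta[~pos] = 0.0
    return 2.0 * a, sindelta, phi, flag


def demodulate_series(
    intensities: Sequence[float], angles_deg: Sequence[float]
) -> DemodResult:
    """Recover (i0, sindelta, phi) from one pixel's modulation series.

    Closed-form second-harmonic least squares; exact on noiseless data for
    any non-degenerate angle set and optimal in the least-squares sense
    otherwise.
    """
    y = np.asarray(intensities, dtype=float)
    angles = np.asarray(angles_deg, dtype=float)
    if y.shape != angles.shape:
        raise ValueError("intensities and angles must have equal length")
    _check_angles(angles)
    X = _design_matrix(angles)
    coeffs, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coeffs
    i0, sindelta, phi, flag = _params_from_coeffs(
        coeffs[:1], coeffs[1:2], coeffs[2:3]
    )
    return DemodResult(
        i0=float(i0[0]),
        sindelta=float(sindelta[0]),
        phi_deg=float(phi[0]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        flag=int(flag[0]),
    )


def demodulate_stack(stack: PolarizationFrameStack) -> PimiParameterMaps:
    """Demodulate every pixel of a frame stack independently.

    The harmonic design matrix is shared by all pixels, so the whole stack
    reduces to one (3 x n_angles) pseudo-inverse applied to the flattened
    frames; degenerate pixels are flagged rather than raised on.
    """
    n, h, w = stack.frames.shape
    X = _design_matrix(stack.angles_deg)
    pinv = np.linalg.pinv(X)                       # (3, n)
    y = stack.frames.reshape(n, h * w)
    coeffs = pinv @ y                              # (3, H*W)
    resid = y - X @ coeffs
    residual_rms = np.sqrt(np.mean(resid**2, axis=0))
    i0, sindelta, phi, flag = _params_from_coeffs(coeffs[0], coeffs[1], coeffs[2])
    return PimiParameterMaps(
        i0_map=i0.reshape(h, w),
        sindelta_map=sindelta.reshape(h, w),
        phi_map=phi.reshape(h, w),
        residual_map=residual_rms.reshape(h, w),
        flag_map=flag.reshape(h, w),
    )
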