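"""Segmentation of a parametric map into lattice-registered topological units.

The detection array is a rectangular lattice of split-ring nanodots at
1 um pitch; the analysis operates on equal-size square patches ("units")
centered on the ring centers.  The lattice geometry is either supplied
directly or estimated from the image itself: the pitch from the
autocorrelation peak near a user-supplied guess, and the unit centers from
the self-convolution peak (the rendered unit pattern is symmetric about
its center, so the map's convolution with itself peaks where two symmetry
centers align).  Crops are aligned to the nearest pixel — the downstream
statistics are pixelwise sums, and resampling would blur them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["ArrayLayout", "UnitGrid", "estimate_layout", "segment_units"]


@dataclass(frozen=True)
class ArrayLayout:
    """Geometry of the unit lattice on the pixel grid (sub-pixel allowed)."""

    origin_px: tuple[float, float]   # (row, col) of the (0, 0) unit center
    pitch_px: float
    rows: int
    cols: int
    unit_px: int

    def __post_init__(self) -> None:
        # crops are nearest-pixel aligned, so sub-pixel overlap is harmless
        if self.pitch_px < self.unit_px - 0.5:
            raise ValueError("pitch_px must be >= unit_px (up to half-pixel rounding)")
        if self.rows < 1 or self.cols < 1 or self.unit_px < 1:
            raise ValueError("rows, cols and unit_px must be positive")

    def center(self, i: int, j: int) -> tuple[float, float]:
        return (
            self.origin_px[0] + i * self.pitch_px,
            self.origin_px[1] + j * self.pitch_px,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ArrayLayout":
        d = json.loads(text)
        d["origin_px"] = tuple(d["origin_px"])
        return cls(**d)


@dataclass
class UnitGrid:
    """rows x cols arrangement of equal-size unit patches plus validity mask."""

    units: np.ndarray        # (rows, cols, unit_px, unit_px)
    valid_mask: np.ndarray   # (rows, cols) bool
    layout: ArrayLayout

    @property
    def shape(self) -> tuple[int, int]:
        return self.units.shape[:2]


def _parabolic_peak(values: np.ndarray, idx: int) -> float:
    """Sub-pixel peak location by 3-point parabola around integer idx."""
    if idx <= 0 or idx >= values.size - 1:
        return float(idx)
    y0, y1, y2 = values[idx - 1], values[idx], values[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(idx)
    return idx + 0.5 * (y0 - y2) / denom


def _axis_pitch(ac: np.ndarray, approx: float, axis: int) -> float:
    """Pitch along one axis from the autocorrelation slice through zero lag."""
    profile = ac[:, 0] if axis == 0 else ac[0, :]
    lo = max(int(round(0.75 * approx)), 2)
    hi = min(int(round(1.25 * approx)) + 1, profile.size // 2)
    if hi - lo < 3:
        raise ValueError("map too small to search for the lattice pitch")
    window = profile[lo:hi]
    peak = int(np.argmax(window)) + lo
    if profile[peak] < 0.2 * profile[0]:
        raise ValueError("no periodic lattice signal near the requested pitch")
    return _parabolic_peak(profile, peak)


def estimate_layout(map_: np.ndarray, approx_pitch_px: float, unit_px: int | None = None) -> ArrayLayout:
    """Estimate the lattice geometry of a parametric map.

    ``approx_pitch_px`` seeds the autocorrelation search (refined to
    sub-pixel by parabolic interpolation); unit centers come from the peak
    of the map's circular self-convolution.  ``unit_px`` defaults to
    round(pitch).  Raises if the map spans fewer than three pitches or no
    periodic signal is found.
    """
    m = np.asarray(map_, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D map")
    if min(m.shape) < 3 * approx_pitch_px:
        raise ValueError("map must span at least 3 x 3 lattice pitches")

    z = m - m.mean()
    F = np.fft.fft2(z)
    ac = np.fft.ifft2(F * np.conj(F)).real
    pitch = 0.5 * (_axis_pitch(ac, approx_pitch_px, 0) + _axis_pitch(ac, approx_pitch_px, 1))

    # Self-convolution peaks at twice a symmetry center (mod map size).
    conv = np.fft.ifft2(F * F).real
    py, px = np.unravel_index(np.argmax(conv), conv.shape)
    cy2 = _parabolic_peak(np.take(conv[:, px], np.arange(conv.shape[0])), int(py))
    cx2 = _parabolic_peak(conv[py, :], int(px))
    # candidates differ by half a pitch (self-convolution sign ambiguity)
    cy = _resolve_center(m, cy2 / 2.0, pitch, axis=0)
    cx = _resolve_center(m, cx2 / 2.0, pitch, axis=1)

    u = unit_px if unit_px is not None else int(round(pitch))
    origin_y, rows = _first_and_count(cy, pitch, m.shape[0])
    origin_x, cols = _first_and_count(cx, pitch, m.shape[1])
    if rows < 1 or cols < 1:
        raise ValueError("no complete lattice unit fits in the map")
    return ArrayLayout(
        origin_px=(origin_y, origin_x), pitch_px=pitch, rows=rows, cols=cols, unit_px=u
    )


def _resolve_center(m: np.ndarray, candidate: float, pitch: float, axis: int) -> float:
    """Pick between the two half-pitch-separated center candidates.

    The unit motif is bright at its center, so the candidate whose pitch-
    periodic comb collects more mean intensity is the ring center.
    """
    profile = m.mean(axis=1 - axis)
    n = profile.size

    def comb_mass(c0: float) -> float:
        c = np.mod(c0, pitch)
        centers = np.arange(c, n, pitch)
        idx = np.clip(np.round(centers).astype(int), 0, n - 1)
        half = max(int(round(pitch / 4)), 1)
        total = 0.0
        for k in idx:
            lo, hi = max(k - half, 0), min(k + half + 1, n)
            total += profile[lo:hi].mean()
        return total / idx.size

    a = np.mod(candidate, pitch)
    b = np.mod(candidate + pitch / 2.0, pitch)
    return a if comb_mass(a) >= comb_mass(b) else b


def _first_and_count(center_mod: float, pitch: float, extent: int) -> tuple[float, int]:
    """First whole-unit center >= half a pitch from the edge, and how many fit."""
    c = np.mod(center_mod, pitch)
    half = pitch / 2.0
    first = c if c >= half - 0.5 else c + pitch
    count = int(np.floor((extent - half - 0.5 - first) / pitch)) + 1
    return float(first), max(count, 0)


def segment_units(map_: np.ndarray, layout: ArrayLayout) -> UnitGrid:
    """Crop the unit patch around every lattice center (nearest-pixel aligned).

    Units whose crop would leave the image are kept as zero patches and
    marked invalid; raises only if no unit is valid at all.
    """
    m = np.asarray(map_, dtype=float)
    u = layout.unit_px
    units = np.zeros((layout.rows, layout.cols, u, u), dtype=m.dtype)
    valid = np.zeros((layout.rows, layout.cols), dtype=bool)
    for i in range(layout.rows):
        for j in range(layout.cols):
            cy, cx = layout.center(i, j)
            y0 = int(round(cy - (u - 1) / 2.0))
            x0 = int(round(cx - (u - 1) / 2.0))
            if y0 < 0 or x0 < 0 or y0 + u > m.shape[0] or x0 + u > m.shape[1]:
                continue
            units[i, j] = m[y0 : y0 + u, x0 : x0 + u]
            valid[i, j] = True
    if not valid.any():
        raise ValueError("no lattice unit lies fully inside the map")
    return UnitGrid(units=units, valid_mask=valid, layout=layout)
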