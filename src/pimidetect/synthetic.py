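"""Ground-truthed synthetic scenes of a split-ring nanodot array.

The generator emulates what a PIMI microscope sees over a rectangular
array of gold split-ring nanocavities at 1 um pitch:

* each lattice unit carries a "dipole" sin(delta) pattern — two
  mirror-symmetric Gaussian lobes along the longitudinal (vertical image)
  axis on a low baseline;
* a virus anchored at one gap attenuates the lobe on that side and lowers
  the whole unit's baseline (weaker lobe, deeper valley);
* smooth field-wide background unevenness, per-unit fabrication jitter,
  and additive Gaussian camera noise on every frame.

Scenes are rendered first as ground-truth parametric maps (i0, sindelta,
phi) and then forward-modelled into a polarization frame stack through the
PIMI modulation law, so the full analysis chain can be exercised against a
known answer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .pimi import PolarizationFrameStack, forward_intensity

__all__ = [
    "VirusPlacement",
    "SceneSpec",
    "render_clean_unit",
    "render_virus_unit",
    "build_scene",
    "render_stack",
    "simulate_scene",
    "split_curve_y",
]

Side = Literal["top", "bottom"]


@dataclass(frozen=True)
class VirusPlacement:
    """One virus anchored at a gap of unit (i, j).

    ``side`` names the longitudinal gap (image top or bottom row-wise);
    ``attenuation`` in (0, 1] multiplies that lobe; ``baseline_drop``
    lowers the whole unit's sin(delta) floor.
    """

    i: int
    j: int
    side: Side
    attenuation: float = 0.5
    baseline_drop: float = 0.02

    def __post_init__(self) -> None:
        if self.side not in ("top", "bottom"):
            raise ValueError(f"side must be 'top' or 'bottom', got {self.side!r}")
        if not 0.0 < self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in (0, 1]")
        if self.baseline_drop < 0:
            raise ValueError("baseline_drop must be >= 0")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic array scene.

    Defaults describe a 10 x 10 array at 1 um pitch sampled at 15.625 nm
    per pixel (64 px per unit), imaged with 10 polarizer angles stepped by
    18 degrees, a mean camera level of 1000 counts and 2 counts of
    Gaussian read noise per frame.
    """

    rows: int = 10
    cols: int = 10
    pitch_nm: float = 1000.0
    pixel_size_nm: float = 15.625
    unit_px: int = 64
    lobe_amplitude: float = 0.5
    lobe_sigma_px: float = 6.0
    lobe_offset_px: float = 13.0   # ~200 nm: gap position for a 130 nm-radius ring
    baseline: float = 0.1
    virus_placements: tuple[VirusPlacement, ...] = ()
    background_gradient: float = 0.02   # corner-to-corner sindelta trend
    fab_jitter: float = 0.02            # sd of per-unit lobe amplitude factor
    noise_sigma: float = 2.0            # camera counts, per pixel per frame
    i0_level: float = 1000.0            # mean camera level (counts)
    n_angles: int = 10
    angle_step_deg: float = 18.0
    wavelength_nm: float = 600.0
    bandwidth_nm: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        placements = tuple(
            p if isinstance(p, VirusPlacement) else VirusPlacement(*p)
            for p in self.virus_placements
        )
        object.__setattr__(self, "virus_placements", placements)
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.unit_px < 8:
            raise ValueError("unit_px must be >= 8")
        if self.pitch_nm / self.pixel_size_nm < self.unit_px - 1e-9:
            raise ValueError("pitch must span at least unit_px pixels")
        seen = set()
        for p in placements:
            if not (0 <= p.i < self.rows and 0 <= p.j < self.cols):
                raise ValueError(f"placement ({p.i}, {p.j}) outside the lattice")
            if (p.i, p.j) in seen:
                # two viruses on one split-ring is treated as negligible
                raise ValueError(f"duplicate placement at unit ({p.i}, {p.j})")
            seen.add((p.i, p.j))

    @property
    def pitch_px(self) -> float:
        return self.pitch_nm / self.pixel_size_nm

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * self.angle_step_deg


def _lobes(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """The two unit-height Gaussian lobes on the unit patch grid."""
    u = spec.unit_px
    if spec.lobe_offset_px + 2.0 * spec.lobe_sigma_px > (u - 1) / 2.0:
        raise ValueError("lobes exceed the unit patch bounds")
    c = (u - 1) / 2.0
    y = np.arange(u, dtype=float)[:, None] - c
    x = np.arange(u, dtype=float)[None, :] - c
    r2_x = x**2
    s2 = 2.0 * spec.lobe_sigma_px**2
    top = np.exp(-((y + spec.lobe_offset_px) ** 2 + r2_x) / s2)
    bottom = np.exp(-((y - spec.lobe_offset_px) ** 2 + r2_x) / s2)
    return top, bottom


def render_clean_unit(spec: SceneSpec) -> np.ndarray:
    """sin(delta) patch of a bare split-ring: baseline + two symmetric lobes."""
    top, bottom = _lobes(spec)
    return spec.baseline + spec.lobe_amplitude * (top + bottom)


def render_virus_unit(
    spec: SceneSpec, side: Side, attenuation: float, baseline_drop: float
) -> np.ndarray:
    """sin(delta) patch of a split-ring with a virus at one gap.

    The lobe on ``side`` is multiplied by ``attenuation`` and the whole
    patch is lowered by ``baseline_drop`` (floored at zero).
    """
    if not 0.0 < attenuation <= 1.0:
        raise ValueError("attenuation must lie in (0, 1]")
    if baseline_drop < 0:
        raise ValueError("baseline_drop must be >= 0")
    top, bottom = _lobes(spec)
    a_top = attenuation if side == "top" else 1.0
    a_bot = attenuation if side == "bottom" else 1.0
    patch = spec.baseline + spec.lobe_amplitude * (a_top * top + a_bot * bottom)
    return np.maximum(patch - baseline_drop, 0.0)


def split_curve_y(x_nm):
    """Height profile (nm) of the omega-shaped curve splitting the gold disk.

    Layout/documentation geometry only; the quartic vanishes at x = ±60 nm
    where the curve sits at its 20 nm floor.
    """
    x = np.asarray(x_nm, dtype=float)
    out = 1.5e-6 * (x**2 - 3600.0) ** 2 + 20.0
    return float(out) if out.ndim == 0 else out


def build_scene(spec: SceneSpec) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Render the field-wide parametric maps and the ground-truth table.

    Returns ``(maps, truth)`` where ``maps`` holds ``i0``, ``sindelta`` and
    ``phi`` (degrees) arrays of shape (rows*tile, cols*tile), and ``truth``
    has one row per lattice unit with columns i, j, virus, side.
    """
    tile = int(round(spec.pitch_px))
    h, w = spec.rows * tile, spec.cols * tile
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))

    sind = np.full((h, w), spec.baseline, dtype=float)
    clean_top, clean_bottom = _lobes(spec)
    placed = {(p.i, p.j): p for p in spec.virus_placements}

    # per-unit lobe-amplitude factor: fabrication variability of the rings
    jitter = rng.normal(1.0, spec.fab_jitter, size=(spec.rows, spec.cols))

    pad = (tile - spec.unit_px) // 2
    rows_idx = np.arange(spec.rows, dtype=float)
    cols_idx = np.arange(spec.cols, dtype=float)
    gy = rows_idx / max(spec.rows - 1, 1)
    gx = cols_idx / max(spec.cols - 1, 1)

    truth_rows = []
    for i in range(spec.rows):
        for j in range(spec.cols):
            p = placed.get((i, j))
            amp = spec.lobe_amplitude * jitter[i, j]
            if p is None:
                patch = spec.baseline + amp * (clean_top + clean_bottom)
            else:
                a_top = p.attenuation if p.side == "top" else 1.0
                a_bot = p.attenuation if p.side == "bottom" else 1.0
                patch = spec.baseline + amp * (a_top * clean_top + a_bot * clean_bottom)
                patch = patch - p.baseline_drop
            # smooth background trend, affine in unit index
            patch = patch + spec.background_gradient * 0.5 * (gy[i] + gx[j])
            y0, x0 = i * tile + pad, j * tile + pad
            sind[y0 : y0 + spec.unit_px, x0 : x0 + spec.unit_px] = patch
            truth_rows.append(
                {"i": i, "j": j, "virus": p is not None, "side": p.side if p else "none"}
            )

    np.clip(sind, 0.0, 1.0, out=sind)

    # plausible smooth illumination / reflectivity fields
    yy = np.linspace(-1.0, 1.0, h)[:, None]
    xx = np.linspace(-1.0, 1.0, w)[None, :]
    i0 = spec.i0_level * (1.0 - 0.05 * (yy**2 + xx**2) / 2.0)
    phi = np.mod(30.0 + 10.0 * xx + 5.0 * yy, 180.0)

    maps = {"i0": i0, "sindelta": sind, "phi": phi}
    truth = pd.DataFrame(truth_rows, columns=["i", "j", "virus", "side"])
    return maps, truth


def render_stack(maps: dict[str, np.ndarray], spec: SceneSpec) -> PolarizationFrameStack:
    """Forward-model parametric maps into a noisy polarization frame stack.

    One frame per polarizer angle via the PIMI modulation law, plus seeded
    additive Gaussian camera noise; ``noise_sigma = 0`` gives exact frames.
    Negative noisy intensities are clipped at zero (a camera cannot report
    negative counts).
    """
    shapes = {m.shape for m in maps.values()}
    if len(shapes) != 1:
        raise ValueError("all parametric maps must share one shape")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    angles = spec.angles_deg
    frames = np.stack(
        [
            forward_intensity(maps["i0"], maps["sindelta"], maps["phi"], theta)
            for theta in angles
        ]
    )
    if spec.noise_sigma > 0:
        frames = frames + rng.normal(0.0, spec.noise_sigma, size=frames.shape)
        np.clip(frames, 0.0, None, out=frames)
    return PolarizationFrameStack(
        frames=frames,
        angles_deg=angles,
        pixel_size_nm=spec.pixel_size_nm,
        wavelength_nm=spec.wavelength_nm,
        bandwidth_nm=spec.bandwidth_nm,
    )


def simulate_scene(
    spec: SceneSpec,
) -> tuple[PolarizationFrameStack, dict[str, np.ndarray], pd.DataFrame]:
    """Convenience wrapper: build the maps and render the stack in one call."""
    maps, truth = build_scene(spec)
    stack = render_stack(maps, spec)
    return stack, maps, truth
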