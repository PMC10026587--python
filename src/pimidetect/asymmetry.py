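"""Extended Laplace background suppression and the per-unit asymmetry statistic.

The array is periodic, so every unit sees near-identical neighbours.  The
*extended Laplace operator* exploits this: each unit patch has the
pixelwise mean of its 8 adjacent unit patches subtracted,

    L(i, j) = U(i, j) - (1/8) * sum of the 8 neighbouring U,

which cancels the repeating ring pattern and any background varying
affinely with lattice index, leaving only what is unique to the unit.

A virus at one longitudinal gap weakens that side's dipole lobe and
lowers the unit's floor.  The asymmetry statistic quantifies this on a
unit patch split at the transverse midline into an upper half (sum A) and
a lower half (sum B):

    As = Isum * (A/B + B/A - 2),

with Isum the sum of the patch's positive pixels.  A mirror-symmetric
unit scores exactly 0; |As| above a threshold (default 7) calls a virus.
The formula is symmetric in A and B, so the attachment side is carried by
a separate ``direction`` field (the weaker half) and by ``signed_score``
(= |score|, positive for a top-side deficit, negative for bottom-side),
which is the signed rendering used in reports.

By default the statistic is evaluated on the raw sin(delta) unit patch
(whose halves are bounded away from zero, keeping the ratio stable) with
unit validity taken from the Laplace neighbourhood; ``source="laplace"``
evaluates it on the background-subtracted patch instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .grid import UnitGrid

__all__ = [
    "LaplaceGrid",
    "AsymmetryRecord",
    "extended_laplace",
    "asymmetry_score",
    "score_units",
    "call_units",
    "summarize",
    "threshold_from_clean",
    "records_to_frame",
]

ScoreSource = Literal["sindelta", "laplace"]


@dataclass
class LaplaceGrid:
    """Unit patches after extended-Laplace background subtraction.

    A unit is valid only when it and all 8 neighbours were valid inputs,
    so the border ring is always invalid.
    """

    units: np.ndarray        # (rows, cols, u, u); values may be negative
    valid_mask: np.ndarray   # (rows, cols) bool


@dataclass(frozen=True)
class AsymmetryRecord:
    i: int
    j: int
    A: float
    B: float
    i_sum: float
    score: float             # Isum * (A/B + B/A - 2); nan when invalid
    signed_score: float      # |score| signed by the deficit side (+top / -bottom)
    valid: bool
    call: bool = False
    direction: str = "none"  # 'top' | 'bottom' | 'none'


def extended_laplace(grid: UnitGrid | np.ndarray, valid_mask: np.ndarray | None = None) -> LaplaceGrid:
    """Subtract the 8-neighbour mean patch from every unit patch.

    Accepts a UnitGrid or a raw (rows, cols, u, u) array with an optional
    validity mask.  Requires at least a 3 x 3 lattice.
    """
    if isinstance(grid, UnitGrid):
        units, valid = grid.units, grid.valid_mask
    else:
        units = np.asarray(grid, dtype=float)
        valid = (
            np.ones(units.shape[:2], dtype=bool) if valid_mask is None else valid_mask
        )
    rows, cols = units.shape[:2]
    if rows < 3 or cols < 3:
        raise ValueError("extended Laplace needs at least a 3 x 3 unit grid")

    out = np.zeros_like(units, dtype=float)
    out_valid = np.zeros((rows, cols), dtype=bool)
    for i in range(1, rows - 1):
        for j in range(1, cols - 1):
            nb = [
                (i + di, j + dj)
                for di in (-1, 0, 1)
                for dj in (-1, 0, 1)
                if (di, dj) != (0, 0)
            ]
            if not (valid[i, j] and all(valid[a, b] for a, b in nb)):
                continue
            acc = np.zeros(units.shape[2:], dtype=float)
            for a, b in nb:
                acc += units[a, b]
            out[i, j] = units[i, j] - acc / 8.0
            out_valid[i, j] = True
    return LaplaceGrid(units=out, valid_mask=out_valid)


def asymmetry_score(patch: np.ndarray, i: int = -1, j: int = -1) -> AsymmetryRecord:
    """Score one unit patch for longitudinal asymmetry.

    A is the sum of the rows above the transverse midline, B below it (an
    odd middle row belongs to neither).  Isum sums the strictly positive
    pixels.  A zero half-sum leaves the ratio undefined: the record is
    returned invalid instead of raising.  A patch with no positive pixels
    scores 0 and stays valid.
    """
    p = np.asarray(patch, dtype=float)
    h = p.shape[0]
    half = h // 2
    A = float(p[:half].sum())
    B = float(p[h - half :].sum())
    i_sum = float(p[p > 0].sum())
    if A == 0.0 or B == 0.0:
        return AsymmetryRecord(
            i=i, j=j, A=A, B=B, i_sum=i_sum, score=float("nan"),
            signed_score=float("nan"), valid=False,
        )
    score = i_sum * (A / B + B / A - 2.0)
    if score == 0.0:
        # includes half sums differing only by summation-order rounding
        return AsymmetryRecord(
            i=i, j=j, A=A, B=B, i_sum=i_sum, score=0.0,
            signed_score=0.0, valid=True, direction="none",
        )
    if A < B:
        direction = "top"
        signed = abs(score)
    elif B < A:
        direction = "bottom"
        signed = -abs(score)
    else:
        direction = "none"
        signed = 0.0
    return AsymmetryRecord(
        i=i, j=j, A=A, B=B, i_sum=i_sum, score=score,
        signed_score=signed, valid=True, direction=direction,
    )


def score_units(
    unit_grid: UnitGrid,
    laplace: LaplaceGrid | None = None,
    source: ScoreSource = "sindelta",
) -> list[AsymmetryRecord]:
    """Score every unit with a complete, valid 8-neighbourhood.

    ``source`` selects the patch the statistic is evaluated on: the raw
    sin(delta) unit (default) or the extended-Laplace output; validity
    always requires the full Laplace neighbourhood so both variants report
    the same interior units.
    """
    if laplace is None:
        laplace = extended_laplace(unit_grid)
    if source not in ("sindelta", "laplace"):
        raise ValueError(f"unknown score source {source!r}")
    patches = unit_grid.units if source == "sindelta" else laplace.units
    records = []
    rows, cols = unit_grid.shape
    for i in range(rows):
        for j in range(cols):
            if not laplace.valid_mask[i, j]:
                records.append(
                    AsymmetryRecord(
                        i=i, j=j, A=0.0, B=0.0, i_sum=0.0, score=float("nan"),
                        signed_score=float("nan"), valid=False,
                    )
                )
            else:
                records.append(asymmetry_score(patches[i, j], i, j))
    return records


def call_units(
    records: Iterable[AsymmetryRecord], threshold: float = 7.0
) -> list[AsymmetryRecord]:
    """Apply the virus call rule: virus iff valid and |score| > threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = []
    for r in records:
        call = bool(r.valid and np.isfinite(r.score) and abs(r.score) > threshold)
        out.append(replace(r, call=call))
    return out


def threshold_from_clean(
    records: Iterable[AsymmetryRecord], margin: float = 2.0
) -> float:
    """Recalibrate the call threshold from units known to be clean.

    Returns ``margin`` times the largest |score| observed on the valid
    clean units — a simple null-envelope rule for arrays whose noise
    differs from the defaults.
    """
    scores = [abs(r.score) for r in records if r.valid and np.isfinite(r.score)]
    if not scores:
        raise ValueError("no valid records to calibrate on")
    return margin * max(scores)


def records_to_frame(records: Sequence[AsymmetryRecord]) -> pd.DataFrame:
    cols = ["i", "j", "A", "B", "i_sum", "score", "signed_score", "valid", "call", "direction"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


def summarize(
    records: Sequence[AsymmetryRecord], truth: pd.DataFrame | None = None
) -> dict:
    """Counts of calls; with ground truth, the confusion table and the
    empirical misdetection fraction (missed / attached), the plug-in
    estimator of the detection model's P2."""
    valid = [r for r in records if r.valid]
    out = {
        "n_units": len(records),
        "n_valid": len(valid),
        "n_called": sum(r.call for r in valid),
    }
    if truth is None:
        return out
    truth_map = {(int(t.i), int(t.j)): bool(t.virus) for t in truth.itertuples()}
    tp = fp = fn = tn = 0
    for r in valid:
        is_virus = truth_map.get((r.i, r.j), False)
        if r.call and is_virus:
            tp += 1
        elif r.call:
            fp += 1
        elif is_virus:
            fn += 1
        else:
            tn += 1
    out.update(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        p_mis_hat=fn / (tp + fn) if tp + fn else float("nan"),
    )
    return out
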