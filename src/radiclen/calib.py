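"""Pixel-to-physical scale calibration against a printed reference grid.

Images of germination dishes are photographed over 1 cm grid paper; the pixel
side length of a grid square (the *pixel pitch*) converts between millimetres
and pixels:

    length_px = length_mm * pitch_px / grid_mm

The pitch is estimated as the mean Euclidean distance over several manually
clicked endpoint pairs, one pair per measured grid side.  When no grid is
present in an image, a pitch must be supplied externally; the package does
not attempt reference-free scale recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRID_MM_DEFAULT = 10.0


@dataclass(frozen=True)
class GridMeasurement:
    """Endpoint pairs of measured grid sides and the derived pixel pitch."""

    endpoint_pairs: tuple  # ((x1,y1),(x2,y2)) per measured side
    pitch_px: float
    grid_mm: float = GRID_MM_DEFAULT


@dataclass(frozen=True)
class LengthRecord:
    length_mm: float
    length_px: float


def grid_pixel_pitch(endpoint_pairs) -> float:
    """Mean Euclidean endpoint distance over the measured grid sides."""
    pairs = list(endpoint_pairs)
    if len(pairs) < 1:
        raise ValueError("at least one endpoint pair is required")
    dists = []
    for i, (a, b) in enumerate(pairs):
        d = float(np.linalg.norm(np.asarray(b, dtype=float) - np.asarray(a, dtype=float)))
        if d == 0.0:
            raise ValueError(f"endpoint pair {i} has coincident endpoints {a!r}")
        dists.append(d)
    return float(np.mean(dists))


def measure_grid(endpoint_pairs, grid_mm: float = GRID_MM_DEFAULT) -> GridMeasurement:
    return GridMeasurement(tuple(tuple(map(tuple, p)) for p in endpoint_pairs),
                           grid_pixel_pitch(endpoint_pairs), grid_mm)


def _check_scale(pitch_px: float, grid_mm: float) -> None:
    if pitch_px <= 0:
        raise ValueError(f"pitch_px must be positive, got {pitch_px}")
    if grid_mm <= 0:
        raise ValueError(f"grid_mm must be positive, got {grid_mm}")


def mm_to_px(length_mm, pitch_px: float, grid_mm: float = GRID_MM_DEFAULT):
    """Convert physical length (mm) to image pixels via the grid pitch."""
    _check_scale(pitch_px, grid_mm)
    return length_mm * pitch_px / grid_mm


def px_to_mm(length_px, pitch_px: float, grid_mm: float = GRID_MM_DEFAULT):
    """Exact inverse of :func:`mm_to_px`."""
    _check_scale(pitch_px, grid_mm)
    return length_px * grid_mm / pitch_px
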