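"""Closed-form morphometric measurements.

Matrix-degradation ratio: the area of proteolytically cleaved DQ-collagen
signal in excess of the cell footprint, relative to the cell area,

    ratio = (cleaved_area - cell_area) / cell_area,

with the cleaved area always measured as the union of the cleaved signal and
the cell footprint so the quantity is the *extracellular* degradation halo
and can never be negative.

Caliper-based tumor volume for an ellipsoid-like xenograft,

    V = 4/3 pi * L * W * (L + W)/2 * 1/8,

which reduces to the sphere volume when L = W.  Length and width are
canonicalized so L >= W.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .exceptions import ParameterError
from .synthetic import ROLE_CELL_MARKER, ROLE_DQ


@dataclasses.dataclass
class DegradationResult:
    cell_area: int  # px
    cleaved_area: int  # px, includes the cell footprint
    ratio: float

    @property
    def percent(self) -> float:
        return 100.0 * self.ratio


def degradation_ratio(cleaved_mask, cell_mask) -> DegradationResult:
    """Extracellular degradation area relative to the cell area.

    The cleaved area is taken as |cleaved_mask ∪ cell_mask|, so the ratio is
    0 when the cleaved signal does not extend beyond the cell.
    """
    cell = np.asarray(cell_mask, dtype=bool)
    cleaved = np.asarray(cleaved_mask, dtype=bool) | cell
    cell_area = int(cell.sum())
    if cell_area == 0:
        raise ParameterError("cell_mask is empty; ratio undefined")
    cleaved_area = int(cleaved.sum())
    return DegradationResult(
        cell_area=cell_area,
        cleaved_area=cleaved_area,
        ratio=(cleaved_area - cell_area) / cell_area,
    )


def measure_degradation(scene, smooth_sigma: float = 0.0) -> DegradationResult:
    """Segment a two-channel degradation scene (Otsu) and compute the ratio.

    No pre-smoothing by default: the masks of interest can be only tens of
    pixels across, where the curvature bias of even a 1 px Gaussian blur
    shifts areas by several percent.
    """
    from skimage import filters  # local import keeps module load light

    masks = {}
    for role in (ROLE_CELL_MARKER, ROLE_DQ):
        if role not in scene.channels:
            raise ParameterError(f"scene lacks the {role!r} channel")
        channel = np.asarray(scene.channels[role], dtype=float)
        if smooth_sigma > 0:
            channel = ndimage.gaussian_filter(channel, smooth_sigma)
        masks[role] = channel > filters.threshold_otsu(channel)
    return degradation_ratio(masks[ROLE_DQ], masks[ROLE_CELL_MARKER])


@dataclasses.dataclass
class TumorMeasurement:
    length: float  # mm, >= width
    width: float  # mm
    volume: float  # mm^3


def tumor_volume(length: float, width: float) -> TumorMeasurement:
    """Caliper tumor volume V = 4/3 pi * L * W * (L + W)/2 / 8 (mm^3)."""
    if not (length > 0 and width > 0):
        raise ParameterError("length and width must be > 0")
    long_, short = (length, width) if length >= width else (width, length)
    volume = (4.0 / 3.0) * math.pi * long_ * short * (long_ + short) / 2.0 / 8.0
    return TumorMeasurement(length=long_, width=short, volume=volume)
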