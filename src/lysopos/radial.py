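"""Radial partition of a cell from centrosome to membrane.

Each cell is mapped onto a normalized radial coordinate r in [0, 1] that is 0
at the centrosome (the microtubule-organizing center, marked by gamma-tubulin)
and 1 at the plasma membrane (outer edge of the alpha-tubulin mask).  The
coordinate is

    r(p) = Dc(p) / (Dc(p) + Db(p)),

where Dc is the Euclidean distance from pixel p to the centrosome pixel and Db
is the Euclidean distance from p to the nearest background (non-mask) pixel.
For a strip or a disk with a central centrosome this equals the fractional
position along the centrosome-to-membrane segment, and unlike ray casting it
stays well defined for non-convex cell outlines.

The cell is then split into five equal-width shells (region 0 = innermost 20%
of the coordinate, region 4 = outermost 20%), and the fraction of lysosomal
(LAMP1) intensity falling in each shell is the per-cell readout.  The
peripheral score - the fraction of intensity in regions 3 and 4 - summarizes
outward lysosome displacement in a single number.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DegenerateCellError, EmptyGroupError, ParameterError

logger = logging.getLogger(__name__)

N_REGIONS = 5
#: half-open bin edges of the five shells; the last bin is closed at 1.0
REGION_EDGES = np.linspace(0.0, 1.0, N_REGIONS + 1)

#: pixels by which the cell mask is dilated before sampling the background
#: level outside the cell (keeps bleed-over out of the background estimate)
BACKGROUND_EXCLUSION_PX = 5


@dataclasses.dataclass
class RadialProfile:
    """Per-cell fractions of LAMP1 intensity in the five radial regions."""

    fractions: np.ndarray  # shape (5,), sums to 1
    peripheral_score: float  # fractions[3] + fractions[4]
    total_intensity: float  # background-corrected whole-cell intensity
    n_pixels: int
    cell_id: object = None
    group: object = None

    @property
    def percentages(self) -> np.ndarray:
        return 100.0 * self.fractions


def normalized_radius_map(cell_mask: np.ndarray, centrosome) -> np.ndarray:
    """Normalized radial coordinate r = Dc / (Dc + Db) on the cell mask.

    Parameters
    ----------
    cell_mask : 2D bool array
        Binary cell footprint.
    centrosome : (row, col)
        Pixel coordinate of the centrosome; must lie inside ``cell_mask``.

    Returns
    -------
    2D float array with r in [0, 1] on the mask and NaN outside.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.ndim != 2:
        raise ParameterError("cell_mask must be a 2D binary image")
    r0, c0 = int(round(centrosome[0])), int(round(centrosome[1]))
    if not (0 <= r0 < mask.shape[0] and 0 <= c0 < mask.shape[1]) or not mask[r0, c0]:
        raise ParameterError(
            f"centrosome {tuple(centrosome)} lies outside the cell mask"
        )
    rr, cc = np.indices(mask.shape)
    dc = np.hypot(rr - r0, cc - c0)
    db = ndimage.distance_transform_edt(mask)
    rmap = np.full(mask.shape, np.nan)
    rmap[mask] = dc[mask] / (dc[mask] + db[mask])
    np.clip(rmap, 0.0, 1.0, out=rmap)
    return rmap


def region_of(r) -> np.ndarray:
    """Region index (0-4) of normalized radius values.

    Bins are half-open [0.2k, 0.2(k+1)) except region 4, which is closed at
    1.0 so every boundary pixel receives a label.
    """
    r = np.asarray(r, dtype=float)
    return np.minimum(np.floor(r * N_REGIONS), N_REGIONS - 1).astype(np.int8)


def partition_regions(radius_map: np.ndarray) -> np.ndarray:
    """Label every mask pixel with its radial region; -1 outside the mask."""
    rmap = np.asarray(radius_map, dtype=float)
    labels = np.full(rmap.shape, -1, dtype=np.int8)
    on = np.isfinite(rmap)
    labels[on] = region_of(rmap[on])
    return labels


def _background_level(channel: np.ndarray, mask: np.ndarray, policy: str) -> float:
    if policy == "none":
        return 0.0
    if policy != "median":
        raise ParameterError(f"unknown background policy {policy!r}")
    exclusion = ndimage.binary_dilation(mask, iterations=BACKGROUND_EXCLUSION_PX)
    outside = ~exclusion
    if not outside.any():
        logger.warning("no pixels outside the cell; background set to 0")
        return 0.0
    return float(np.median(channel[outside]))


def compute_radial_profile(
    lamp1_channel: np.ndarray,
    region_labels: np.ndarray,
    background_policy: str = "median",
    cell_id=None,
    group=None,
) -> RadialProfile:
    """Fraction of background-corrected LAMP1 intensity per radial region.

    The per-cell background (median channel intensity outside the dilated
    cell mask, or 0 under ``background_policy='none'``) is subtracted and the
    corrected intensity clamped at zero before the region sums are normalized
    by the whole-cell total.

    Raises
    ------
    DegenerateCellError
        If the corrected whole-cell intensity is not positive.
    """
    channel = np.asarray(lamp1_channel, dtype=float)
    labels = np.asarray(region_labels)
    if channel.shape != labels.shape:
        raise ParameterError("channel and region labels have different shapes")
    mask = labels >= 0
    background = _background_level(channel, mask, background_policy)
    corrected = np.clip(channel - background, 0.0, None)
    total = float(corrected[mask].sum())
    if total <= 0.0:
        raise DegenerateCellError(
            f"cell {cell_id!r}: background-corrected LAMP1 intensity is not positive"
        )
    sums = np.bincount(
        labels[mask].astype(np.int64), weights=corrected[mask], minlength=N_REGIONS
    )[:N_REGIONS]
    fractions = sums / total
    return RadialProfile(
        fractions=fractions,
        peripheral_score=float(fractions[3] + fractions[4]),
        total_intensity=total,
        n_pixels=int(mask.sum()),
        cell_id=cell_id,
        group=group,
    )


_FRACTION_COLS = [f"f{k}" for k in range(N_REGIONS)]
_PERCENT_COLS = [f"percent_region{k}" for k in range(N_REGIONS)]


def profiles_to_table(profiles: Sequence[RadialProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"cell_id": p.cell_id, "group": p.group}
        row.update(dict(zip(_FRACTION_COLS, p.fractions)))
        row.update(dict(zip(_PERCENT_COLS, p.percentages)))
        row["peripheral_score"] = p.peripheral_score
        row["n_pixels"] = p.n_pixels
        row["total_intensity"] = p.total_intensity
        rows.append(row)
    return pd.DataFrame(rows)


def profile_table(
    scenes,
    segmentations,
    groups=None,
    cell_ids=None,
    background_policy: str = "median",
    lamp1_role: str = "lamp1",
) -> pd.DataFrame:
    """Per-cell radial profiles for a collection of scenes.

    Cells failing :func:`compute_radial_profile` are dropped with a logged
    reason.  If every cell of a labeled group drops, :class:`EmptyGroupError`
    is raised.
    """
    scenes = list(scenes)
    segmentations = list(segmentations)
    if len(scenes) != len(segmentations):
        raise ParameterError("one segmentation per scene is required")
    if groups is None:
        groups = [None] * len(scenes)
    if cell_ids is None:
        cell_ids = list(range(len(scenes)))
    profiles = []
    for scene, seg, group, cid in zip(scenes, segmentations, groups, cell_ids):
        try:
            rmap = normalized_radius_map(seg.cell_mask, seg.centrosome)
            labels = partition_regions(rmap)
            profiles.append(
                compute_radial_profile(
                    scene.channels[lamp1_role],
                    labels,
                    background_policy=background_policy,
                    cell_id=cid,
                    group=group,
                )
            )
        except (DegenerateCellError, ParameterError) as exc:
            logger.warning("cell %r dropped: %s", cid, exc)
    table = profiles_to_table(profiles)
    wanted = {g for g in groups if g is not None}
    present = set(table["group"].dropna().unique()) if len(table) else set()
    missing = wanted - present
    if missing:
        raise EmptyGroupError(f"all cells dropped in group(s) {sorted(missing)!r}")
    return table


def report_view(table: pd.DataFrame) -> pd.DataFrame:
    """Reporting view with region 0 suppressed (fractions stay whole-cell).

    The innermost region is conventionally left out of plots because the
    centrosome-proximal signal is dominated by the perinuclear lysosome pool;
    the stored table keeps f0 and no renormalization is applied.
    """
    drop = ["f0", "percent_region0"]
    return table.drop(columns=[c for c in drop if c in table.columns])


def group_summary(table: pd.DataFrame) -> dict:
    """Figure-style summary: per-group mean and SEM per region (region 0
    excluded) plus the peripheral score."""
    out = {}
    cols = _PERCENT_COLS[1:] + ["peripheral_score"]
    for group, sub in table.groupby("group", dropna=False):
        entry = {}
        for col in cols:
            vals = sub[col].to_numpy(dtype=float)
            entry[col] = {
                "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"),
                "n": int(len(vals)),
            }
        out[str(group)] = entry
    return out
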