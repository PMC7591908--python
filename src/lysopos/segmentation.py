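"""Recovery of the geometric primitives the radial score needs.

From a multichannel scene: the cell mask (thresholded alpha-tubulin, largest
connected component, hole-filled and lightly smoothed), the nucleus mask
(thresholded nuclear counterstain intersected with the cell), the centrosome
coordinate (peak of the smoothed gamma-tubulin signal inside the cell), and
the LAMP1 puncta (Laplacian-of-Gaussian enhancement, threshold, connected
components, size filter).

Thresholds are Otsu on the smoothed channel by default, which makes every
step invariant to a positive rescaling of the intensities; an absolute
override is accepted for real data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage import filters, measure, morphology

from .exceptions import CentrosomeNotFoundError, ParameterError, SegmentationError
from .synthetic import ROLE_CENTROSOME, ROLE_LAMP1, ROLE_NUCLEUS, ROLE_TUBULIN

#: Gaussian pre-smoothing (px) applied to structural channels before Otsu
SMOOTH_SIGMA = 1.0
#: default LoG scale (px); matches the simulator's spot width
LOG_SIGMA = 2.0
#: default minimum punctum size (px)
MIN_PUNCTUM_AREA = 3
#: robust z-score cut of the LoG response under the "mad" threshold policy
MAD_K = 5.0


@dataclasses.dataclass
class CellSegmentation:
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    centrosome: tuple | None = None  # (row, col)


@dataclasses.dataclass
class PunctaSet:
    """Detected lysosomal puncta.

    ``table`` columns: row, col (intensity-weighted centroid), area_px,
    intensity (integrated, background-subtracted).
    """

    table: pd.DataFrame
    channel_role: str = ROLE_LAMP1

    def __len__(self):
        return len(self.table)


def _threshold(channel: np.ndarray, policy) -> float:
    """Relative ("otsu", "mad") or absolute threshold of a channel.

    "otsu" suits bimodal foreground/background splits (cell and nucleus
    masks); "mad" - median plus MAD_K robust standard deviations - suits
    sparse spot responses whose histogram is dominated by background noise.
    Both are invariant to a positive rescaling of the intensities.
    """
    if isinstance(policy, (int, float)) and not isinstance(policy, bool):
        return float(policy)
    if np.ptp(channel) == 0:
        raise SegmentationError("<constant>", "channel is constant; no threshold")
    if policy == "otsu":
        return float(filters.threshold_otsu(channel))
    if policy == "mad":
        med = float(np.median(channel))
        mad = float(np.median(np.abs(channel - med)))
        if mad == 0:
            # no noise floor to estimate (e.g. noise-free synthetic data);
            # fall back to the bimodal split
            return float(filters.threshold_otsu(channel))
        return med + MAD_K * 1.4826 * mad
    raise ParameterError(f"unknown threshold policy {policy!r}")


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))

def segment_cell(scene, threshold_policy="otsu") -> CellSegmentation:
    """Cell and nucleus masks from the alpha-tubulin and nuclear channels.

    The cell mask is the largest thresholded alpha-tubulin component, lightly
    smoothed (binary opening) and hole-filled; the nucleus is the largest
    thresholded nuclear component intersected with the cell mask.

    Raises
    ------
    SegmentationError
        If thresholding leaves no foreground on a required channel.
    """
    for role in (ROLE_TUBULIN, ROLE_NUCLEUS):
        if role not in scene.channels:
            raise ParameterError(f"scene lacks the {role!r} channel")

    def _mask_of(role):
        channel = np.asarray(scene.channels[role], dtype=float)
        smoothed = ndimage.gaussian_filter(channel, SMOOTH_SIGMA)
        if np.ptp(smoothed) == 0:
            raise SegmentationError(role)
        mask = smoothed > _threshold(smoothed, threshold_policy)
        if not mask.any():
            raise SegmentationError(role)
        return mask

    cell = _largest_component(_mask_of(ROLE_TUBULIN))
    cell = ndimage.binary_opening(cell, structure=morphology.disk(1))
    cell = ndimage.binary_fill_holes(_largest_component(cell))
    if not cell.any():
        raise SegmentationError(ROLE_TUBULIN)
    nucleus = _largest_component(_mask_of(ROLE_NUCLEUS))
    nucleus = ndimage.binary_fill_holes(nucleus) & cell
    return CellSegmentation(cell_mask=cell, nucleus_mask=nucleus)


def detect_centrosome(scene, cell_mask, nucleus_mask=None, sigma=LOG_SIGMA) -> tuple:
    """Peak of the Gaussian-smoothed gamma-tubulin signal inside the cell.

    Ties between equal peaks are broken toward the nucleus centroid (when a
    nucleus mask is given), then lexicographically by (row, col).
    """
    if ROLE_CENTROSOME not in scene.channels:
        raise ParameterError(f"scene lacks the {ROLE_CENTROSOME!r} channel")
    mask = np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        raise ParameterError("cell_mask is empty")
    smoothed = ndimage.gaussian_filter(
        np.asarray(scene.channels[ROLE_CENTROSOME], dtype=float), sigma
    )
    values = smoothed[mask]
    if np.ptp(values) == 0:
        raise CentrosomeNotFoundError("gamma-tubulin channel is flat inside the cell")
    peak = values.max()
    rows, cols = np.nonzero(mask & (smoothed == peak))
    if rows.size > 1 and nucleus_mask is not None and np.any(nucleus_mask):
        cy, cx = ndimage.center_of_mass(np.asarray(nucleus_mask, dtype=float))
        d2 = (rows - cy) ** 2 + (cols - cx) ** 2
        keep = d2 == d2.min()
        rows, cols = rows[keep], cols[keep]
    order = np.lexsort((cols, rows))
    return int(rows[order[0]]), int(cols[order[0]])


def detect_puncta(
    scene,
    cell_mask=None,
    min_punctum_area: int = MIN_PUNCTUM_AREA,
    threshold_policy="mad",
    log_sigma: float = LOG_SIGMA,
) -> PunctaSet:
    """LAMP1 puncta via LoG enhancement, thresholding, and size filtering.

    The default "mad" threshold policy cuts the LoG response at a robust
    z-score (spots occupy far too small a fraction of the image for a
    bimodal split to be reliable).  Touching puncta that merge into one
    component are counted once.  An empty result is valid (a zero-signal
    channel yields no detections).
    """
    if ROLE_LAMP1 not in scene.channels:
        raise ParameterError(f"scene lacks the {ROLE_LAMP1!r} channel")
    channel = np.asarray(scene.channels[ROLE_LAMP1], dtype=float)
    response = -ndimage.gaussian_laplace(channel, log_sigma)
    empty = PunctaSet(
        pd.DataFrame(columns=["row", "col", "area_px", "intensity"])
    )
    if np.ptp(response) == 0:
        return empty
    try:
        thr = _threshold(response, threshold_policy)
    except SegmentationError:
        return empty
    fg = response > max(thr, 0.0)
    if cell_mask is not None:
        fg &= np.asarray(cell_mask, dtype=bool)
    labels, n = ndimage.label(fg)
    if n == 0:
        return empty
    background = float(
        np.median(channel[~np.asarray(cell_mask, dtype=bool)])
        if cell_mask is not None and not np.asarray(cell_mask, dtype=bool).all()
        else np.median(channel)
    )
    corrected = np.clip(channel - background, 0.0, None)
    records = []
    for region in measure.regionprops(labels, intensity_image=corrected):
        if region.area < min_punctum_area:
            continue
        if region.image_intensity.sum() > 0:
            r, c = region.centroid_weighted
        else:
            r, c = region.centroid
        records.append(
            {
                "row": float(r),
                "col": float(c),
                "area_px": int(region.area),
                "intensity": float(region.image_intensity.sum()),
            }
        )
    return PunctaSet(pd.DataFrame(records, columns=["row", "col", "area_px", "intensity"]))


def puncta_summary(puncta: PunctaSet):
    """(count, mean area, median area); area statistics are NaN when empty."""
    n = len(puncta)
    if n == 0:
        return 0, float("nan"), float("nan")
    areas = puncta.table["area_px"].to_numpy(dtype=float)
    return n, float(areas.mean()), float(np.median(areas))


@dataclasses.dataclass
class PunctaMatch:
    n_true_positive: int
    n_false_positive: int
    n_false_negative: int
    mean_distance: float  # over matched pairs

    @property
    def f1(self) -> float:
        tp, fp, fn = self.n_true_positive, self.n_false_positive, self.n_false_negative
        return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")


def match_puncta(detected: pd.DataFrame, truth: pd.DataFrame, max_dist=3.0) -> PunctaMatch:
    """Hungarian assignment of detections to planted puncta within max_dist px."""
    if len(detected) == 0 or len(truth) == 0:
        return PunctaMatch(0, len(detected), len(truth), float("nan"))
    d = np.hypot(
        detected["row"].to_numpy()[:, None] - truth["row"].to_numpy()[None, :],
        detected["col"].to_numpy()[:, None] - truth["col"].to_numpy()[None, :],
    )
    ri, ci = optimize.linear_sum_assignment(d)
    matched = d[ri, ci] <= max_dist
    tp = int(matched.sum())
    return PunctaMatch(
        n_true_positive=tp,
        n_false_positive=len(detected) - tp,
        n_false_negative=len(truth) - tp,
        mean_distance=float(d[ri, ci][matched].mean()) if tp else float("nan"),
    )
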