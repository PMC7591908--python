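"""Synthetic fluorescence scenes and patient cohorts with known ground truth.

A scene emulates a single-cell, four-channel immunofluorescence image of the
kind used to score lysosome positioning: a LAMP1 (lysosome) channel made of
Gaussian puncta, an alpha-tubulin channel filling the cell body, a
gamma-tubulin channel with one dominant centrosome spot, and a nuclear
counterstain.  The cell outline is a star-convex radial function
r(theta) = R * (1 + irregularity * low-order Fourier perturbation), which
guarantees a single closed region at any irregularity < 1.  Puncta radii are
drawn from a Beta(alpha, beta) distribution on the same normalized radial
coordinate the analysis pipeline measures, so planted distributions are
recoverable exactly.  The camera model is Poisson(signal + background) plus
Gaussian read noise.

Cohorts emulate the table structure of a clinical expression/survival data
set: per-patient log-normal gene expression, exponential event times with a
group-dependent hazard, independent exponential censoring, and binomial
lymph-node counts.  The planted high-risk group is exactly the set selected
by the combined expression stratification, so downstream recovery is exact
by construction.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import radial, survival
from .exceptions import ParameterError

# channel role names used throughout the package
ROLE_LAMP1 = "lamp1"
ROLE_TUBULIN = "alpha_tubulin"
ROLE_CENTROSOME = "gamma_tubulin"
ROLE_NUCLEUS = "dapi"
SCENE_ROLES = (ROLE_LAMP1, ROLE_TUBULIN, ROLE_CENTROSOME, ROLE_NUCLEUS)

# fixed fill levels (photons) of the structural channels
_TUBULIN_LEVEL = 80.0
_NUCLEUS_LEVEL = 150.0
_CENTROSOME_AMPLITUDE = 3000.0  # integrated photons of the gamma-tubulin spot

#: |r_pixel - u| tolerance when mapping a planted radius onto the pixel grid
_PLACEMENT_TOL = 0.02
_PLACEMENT_TRIES = 200


@dataclass
class Scene:
    """A multichannel 2D image with named channel roles."""

    channels: dict  # role -> 2D float array
    pixel_size_um: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class SceneParams:
    """Parameters of a single-cell scene.

    ``radial_alpha``/``radial_beta`` shape the Beta distribution of planted
    normalized puncta radii (mean alpha/(alpha+beta)); ``punctum_amplitude``
    is the integrated photon count per punctum.  ``shot_noise=False`` renders
    the noise-free expectation image (read noise can be zeroed separately).
    ``min_separation`` enforces a minimum center-to-center distance between
    puncta (0 disables).
    """

    image_size: tuple = (512, 512)
    cell_radius_mean: float = 150.0
    cell_radius_jitter: float = 8.0
    boundary_irregularity: float = 0.08
    nucleus_radius_frac: float = 0.35
    centrosome_offset_frac: float = 0.10
    n_puncta: int = 60
    radial_alpha: float = 2.0
    radial_beta: float = 2.0
    punctum_sigma: float = 2.0
    punctum_amplitude: float = 500.0
    min_separation: float = 0.0
    background_level: float = 10.0
    gaussian_read_noise_sd: float = 2.0
    shot_noise: bool = True
    seed: int = 0

    def validate(self):
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ParameterError("image_size must be positive")
        if self.n_puncta < 0:
            raise ParameterError("n_puncta must be >= 0")
        if self.radial_alpha <= 0 or self.radial_beta <= 0:
            raise ParameterError("radial_alpha and radial_beta must be > 0")
        if self.background_level < 0 or self.gaussian_read_noise_sd < 0:
            raise ParameterError("noise levels must be >= 0")
        if not 0 <= self.boundary_irregularity < 1:
            raise ParameterError("boundary_irregularity must be in [0, 1)")
        if not 0 < self.nucleus_radius_frac < 1:
            raise ParameterError("nucleus_radius_frac must be in (0, 1)")
        if self.nucleus_radius_frac >= 1 - self.boundary_irregularity:
            raise ParameterError("nucleus larger than the cell interior")
        if self.centrosome_offset_frac < 0:
            raise ParameterError("centrosome_offset_frac must be >= 0")
        reach = self.nucleus_radius_frac + self.centrosome_offset_frac
        if reach >= (1 - self.boundary_irregularity) * 0.95:
            raise ParameterError("centrosome outside the cell boundary")
        r_max = self.cell_radius_mean * (1 + self.boundary_irregularity)
        if r_max + self.cell_radius_jitter + 2 >= min(h, w) / 2:
            raise ParameterError("cell does not fit inside image_size")

    @classmethod
    def small(cls, **overrides) -> "SceneParams":
        """Desk-scale scene (128 px, 42 px cell) for fast simulation studies."""
        base = dict(
            image_size=(128, 128),
            cell_radius_mean=42.0,
            cell_radius_jitter=3.0,
            n_puncta=40,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SceneTruth:
    """Planted ground truth of a synthetic scene."""

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    centrosome: tuple  # (row, col)
    puncta: pd.DataFrame  # columns: row, col, normalized_radius, amplitude
    expected_region_fractions: np.ndarray  # 5 entries summing to 1
    radius_map: np.ndarray


def _star_convex_mask(rng, params, center):
    """Cell mask bounded by r(theta) = R * (1 + irregularity * perturbation)."""
    h, w = params.image_size
    R = params.cell_radius_mean + params.cell_radius_jitter * rng.uniform(-1, 1)
    modes = np.arange(2, 6)
    amp = rng.normal(size=modes.size)
    phase = rng.uniform(0, 2 * np.pi, size=modes.size)

    def perturbation(theta):
        t = np.asarray(theta)[..., None]
        f = np.sum(amp * np.cos(modes * t + phase), axis=-1)
        return f

    # scale so the perturbation peaks at exactly +-irregularity
    grid = np.linspace(0, 2 * np.pi, 1440, endpoint=False)
    peak = np.max(np.abs(perturbation(grid)))
    scale = params.boundary_irregularity / peak if peak > 0 else 0.0

    rr, cc = np.indices((h, w))
    dy, dx = rr - center[0], cc - center[1]
    theta = np.arctan2(dy, dx)
    boundary = R * (1 + scale * perturbation(theta))
    mask = np.hypot(dy, dx) <= boundary
    return mask, R


def _place_puncta(rng, params, truth_masks, rmap, centrosome):
    """Map planted Beta radii onto pixels of the cell via ray casting.

    The radius u is kept; the ray angle is resampled until a cytoplasmic
    pixel whose measured normalized radius is within _PLACEMENT_TOL of u is
    found, so nucleus exclusion does not distort the planted distribution.
    """
    cell_mask, nucleus_mask = truth_masks
    h, w = cell_mask.shape
    valid = cell_mask & ~nucleus_mask
    max_len = params.cell_radius_mean * (1 + params.boundary_irregularity) + \
        params.cell_radius_jitter + 2
    ts = np.arange(0.0, max_len, 0.5)
    u_all = rng.beta(params.radial_alpha, params.radial_beta, size=params.n_puncta)
    rows, cols, radii = [], [], []
    for u in u_all:
        best = None  # (err, row, col)
        for _ in range(_PLACEMENT_TRIES):
            theta = rng.uniform(0, 2 * np.pi)
            ii = np.round(centrosome[0] + ts * np.sin(theta)).astype(int)
            jj = np.round(centrosome[1] + ts * np.cos(theta)).astype(int)
            inb = (ii >= 0) & (ii < h) & (jj >= 0) & (jj < w)
            ii, jj = ii[inb], jj[inb]
            inside = cell_mask[ii, jj]
            stop = np.argmin(inside) if not inside.all() else inside.size
            ii, jj = ii[:stop], jj[:stop]
            ok = valid[ii, jj]
            if params.min_separation > 0 and rows:
                d = np.hypot(
                    ii[:, None] - np.asarray(rows), jj[:, None] - np.asarray(cols)
                )
                ok &= d.min(axis=1) >= params.min_separation
            if not ok.any():
                continue
            ii, jj = ii[ok], jj[ok]
            err = np.abs(rmap[ii, jj] - u)
            k = int(np.argmin(err))
            if best is None or err[k] < best[0]:
                best = (float(err[k]), int(ii[k]), int(jj[k]))
            if best[0] <= _PLACEMENT_TOL:
                break
        if best is None:
            raise ParameterError(
                "could not place a punctum; min_separation too large for the cell"
            )
        rows.append(best[1])
        cols.append(best[2])
        radii.append(float(rmap[best[1], best[2]]))
    return pd.DataFrame(
        {
            "row": np.asarray(rows, dtype=int),
            "col": np.asarray(cols, dtype=int),
            "normalized_radius": np.asarray(radii, dtype=float),
            "amplitude": np.full(params.n_puncta, params.punctum_amplitude),
        }
    )


def _camera(rng, expectation, params):
    """Poisson shot noise plus Gaussian read noise (both optional)."""
    img = (
        rng.poisson(expectation).astype(float)
        if params.shot_noise
        else expectation.astype(float)
    )
    if params.gaussian_read_noise_sd > 0:
        img = img + rng.normal(0.0, params.gaussian_read_noise_sd, img.shape)
    return img


def _spot_image(shape, rows, cols, amplitudes, sigma):
    img = np.zeros(shape)
    np.add.at(img, (rows, cols), amplitudes)
    return ndimage.gaussian_filter(img, sigma, truncate=4.0)


def generate_cell_scene(params: SceneParams):
    """Render one synthetic cell and return (Scene, SceneTruth)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    center = ((h - 1) / 2.0, (w - 1) / 2.0)

    cell_mask, R = _star_convex_mask(rng, params, center)
    rr, cc = np.indices((h, w))
    nucleus_radius = params.nucleus_radius_frac * R
    nucleus_mask = np.hypot(rr - center[0], cc - center[1]) <= nucleus_radius
    nucleus_mask &= cell_mask

    phi = rng.uniform(0, 2 * np.pi)
    dist = nucleus_radius + max(params.centrosome_offset_frac * R, 1.5)
    centrosome = (
        int(round(center[0] + dist * np.sin(phi))),
        int(round(center[1] + dist * np.cos(phi))),
    )
    if not cell_mask[centrosome] or nucleus_mask[centrosome]:
        raise ParameterError("centrosome placement failed (outside cytoplasm)")

    rmap = radial.normalized_radius_map(cell_mask, centrosome)
    puncta = _place_puncta(rng, params, (cell_mask, nucleus_mask), rmap, centrosome)

    if len(puncta):
        regions = radial.region_of(puncta["normalized_radius"].to_numpy())
        weights = puncta["amplitude"].to_numpy()
        sums = np.bincount(regions, weights=weights, minlength=radial.N_REGIONS)
        expected = sums / weights.sum()
    else:
        # pure-background cell: residual intensity is uniform in expectation
        labels = radial.partition_regions(rmap)
        counts = np.bincount(labels[labels >= 0], minlength=radial.N_REGIONS)
        expected = counts / counts.sum()

    lamp1 = params.background_level + _spot_image(
        (h, w),
        puncta["row"].to_numpy(),
        puncta["col"].to_numpy(),
        puncta["amplitude"].to_numpy(),
        params.punctum_sigma,
    )
    tubulin = params.background_level + _TUBULIN_LEVEL * ndimage.gaussian_filter(
        cell_mask.astype(float), 1.0
    )
    gamma = params.background_level + _spot_image(
        (h, w), [centrosome[0]], [centrosome[1]], [_CENTROSOME_AMPLITUDE],
        params.punctum_sigma,
    )
    dapi = params.background_level + _NUCLEUS_LEVEL * ndimage.gaussian_filter(
        nucleus_mask.astype(float), 1.0
    )

    channels = {}
    for role, expectation in (
        (ROLE_LAMP1, lamp1),
        (ROLE_TUBULIN, tubulin),
        (ROLE_CENTROSOME, gamma),
        (ROLE_NUCLEUS, dapi),
    ):
        channels[role] = _camera(rng, expectation, params)

    scene = Scene(channels=channels, meta={"params": dataclasses.asdict(params)})
    truth = SceneTruth(
        cell_mask=cell_mask,
        nucleus_mask=nucleus_mask,
        centrosome=centrosome,
        puncta=puncta,
        expected_region_fractions=expected,
        radius_map=rmap,
    )
    return scene, truth


@dataclass
class GroupExperiment:
    """A labeled two-group collection of synthetic scenes."""

    scenes: list
    truths: list
    labels: list  # group label per scene
    seed: int


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-item seeds derived from a master seed."""
    ss = np.random.SeedSequence(seed)
    return np.array([int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)])


def generate_group_experiment(
    params_a: SceneParams,
    params_b: SceneParams,
    n_cells_per_group: int,
    seed: int,
    labels=("a", "b"),
) -> GroupExperiment:
    """2 * n_cells_per_group scenes with per-scene seeds spawned from ``seed``."""
    if n_cells_per_group < 1:
        raise ParameterError("n_cells_per_group must be >= 1")
    seeds = child_seeds(seed, 2 * n_cells_per_group)
    scenes, truths, out_labels = [], [], []
    for i, (params, label) in enumerate(
        [(params_a, labels[0])] * n_cells_per_group
        + [(params_b, labels[1])] * n_cells_per_group
    ):
        scene, truth = generate_cell_scene(
            dataclasses.replace(params, seed=int(seeds[i]))
        )
        scenes.append(scene)
        truths.append(truth)
        out_labels.append(label)
    return GroupExperiment(scenes=scenes, truths=truths, labels=out_labels, seed=seed)


# ---------------------------------------------------------------------------
# matrix-degradation scenes

ROLE_CELL_MARKER = "cell_marker"
ROLE_DQ = "dq_collagen"


@dataclass
class DegradationTruth:
    cell_mask: np.ndarray
    cleaved_mask: np.ndarray
    cell_area_px: int
    cleaved_area_px: int


def generate_degradation_scene(
    cell_area_px: int,
    halo_area_px: int,
    image_size=(256, 256),
    seed: int = 0,
    background_level: float = 10.0,
    read_noise_sd: float = 2.0,
):
    """Two-channel scene of a cell plus a halo of cleaved collagen signal.

    Masks are built by ranking pixels by distance from the image center, so
    the planted areas are exact: the cell is the ``cell_area_px`` innermost
    pixels and the cleaved region additionally includes the next
    ``halo_area_px`` pixels (cleaved = cell footprint union halo).
    """
    if cell_area_px < 1:
        raise ParameterError("cell_area_px must be >= 1")
    if halo_area_px < 0:
        raise ParameterError("halo_area_px must be >= 0")
    h, w = image_size
    if cell_area_px + halo_area_px > h * w:
        raise ParameterError("requested areas exceed the image")
    rng = np.random.default_rng(seed)
    rr, cc = np.indices((h, w))
    d = np.hypot(rr - (h - 1) / 2.0, cc - (w - 1) / 2.0)
    order = np.lexsort((cc.ravel(), rr.ravel(), d.ravel()))
    cell_mask = np.zeros(h * w, dtype=bool)
    cell_mask[order[:cell_area_px]] = True
    cleaved_mask = np.zeros(h * w, dtype=bool)
    cleaved_mask[order[: cell_area_px + halo_area_px]] = True
    cell_mask = cell_mask.reshape(h, w)
    cleaved_mask = cleaved_mask.reshape(h, w)

    # hard-edged fills: the planted areas are the quantity of interest
    cell_chan = background_level + 120.0 * cell_mask
    dq_chan = background_level + 100.0 * cleaved_mask
    channels = {}
    for role, expectation in ((ROLE_CELL_MARKER, cell_chan), (ROLE_DQ, dq_chan)):
        img = rng.poisson(expectation).astype(float)
        if read_noise_sd > 0:
            img = img + rng.normal(0.0, read_noise_sd, img.shape)
        channels[role] = img
    scene = Scene(channels=channels)
    truth = DegradationTruth(
        cell_mask=cell_mask,
        cleaved_mask=cleaved_mask,
        cell_area_px=int(cell_area_px),
        cleaved_area_px=int(cell_area_px + halo_area_px),
    )
    return scene, truth


# ---------------------------------------------------------------------------
# synthetic patient cohorts

@dataclass(frozen=True)
class CohortParams:
    """Parameters of a synthetic expression/survival cohort.

    Event times are exponential with hazard ``hazard_baseline`` (multiplied
    by ``hazard_ratio_high`` in the planted high-risk group); censoring times
    are exponential with rate ``censor_rate`` (0 disables censoring).  The
    planted high-risk group is the set selected by the combined expression
    stratification (top ``top_fraction`` by the first gene, then top within
    that stratum by the second gene until ``combined_fraction`` of all
    patients).  Lymph-node totals are uniform over ``node_total_range`` and
    positives are binomial with a group-dependent probability.
    """

    n_patients: int = 1075
    expression_genes: tuple = ("ARL8B", "BLOC1S2")
    log_expression_sd: float = 1.0
    hazard_baseline: float = 0.012  # events per month: median ~58 months
    hazard_ratio_high: float = 2.0
    censor_rate: float = 0.012
    node_total_range: tuple = (1, 30)
    node_positive_prob_low: float = 0.15
    node_positive_prob_high: float = 0.40
    top_fraction: float = 0.15
    combined_fraction: float = 0.03
    seed: int = 0

    def validate(self):
        if self.n_patients < 2:
            raise ParameterError("n_patients must be >= 2")
        for p in (self.node_positive_prob_low, self.node_positive_prob_high):
            if not 0 <= p <= 1:
                raise ParameterError("node probabilities must be in [0, 1]")
        if self.hazard_baseline <= 0 or self.hazard_ratio_high <= 0:
            raise ParameterError("hazard terms must be > 0")
        if self.censor_rate < 0:
            raise ParameterError("censor_rate must be >= 0")
        if not 0 < self.combined_fraction <= self.top_fraction < 1:
            raise ParameterError(
                "require 0 < combined_fraction <= top_fraction < 1"
            )
        lo, hi = self.node_total_range
        if lo < 1 or hi < lo:
            raise ParameterError("node_total_range must satisfy 1 <= min <= max")
        if len(self.expression_genes) < 1:
            raise ParameterError("at least one expression gene is required")


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Synthetic cohort table; the ``planted_high`` column marks ground truth.

    Columns: patient_id, time, event, nodes_positive, nodes_total, one column
    per gene, planted_high.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    genes = list(params.expression_genes)
    expr = np.exp(rng.normal(0.0, params.log_expression_sd, size=(n, len(genes))))
    df = pd.DataFrame(expr, columns=genes)
    df.insert(0, "patient_id", [f"P{i:05d}" for i in range(n)])

    if len(genes) >= 2:
        strata = survival.stratify_combined(
            df, genes[0], genes[1], params.top_fraction, params.combined_fraction
        )
        high = strata.labels.to_numpy() == "combined_high"
    else:
        strata = survival.stratify_top_fraction(df, genes[0], params.combined_fraction)
        high = strata.labels.to_numpy() == "high"

    hazard = params.hazard_baseline * np.where(high, params.hazard_ratio_high, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    if params.censor_rate > 0:
        censor_time = rng.exponential(1.0 / params.censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    lo, hi = params.node_total_range
    nodes_total = rng.integers(lo, hi + 1, size=n)
    p_pos = np.where(
        high, params.node_positive_prob_high, params.node_positive_prob_low
    )
    nodes_positive = rng.binomial(nodes_total, p_pos)

    df["time"] = np.maximum(time, 1e-9)
    df["event"] = event
    df["nodes_positive"] = nodes_positive
    df["nodes_total"] = nodes_total
    df["planted_high"] = high
    return df
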