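"""Scene and truth serialization.

A scene is written as a multipage TIFF (one page per channel) with a JSON
sidecar holding the channel-role map, pixel size, and - for synthetic scenes
- the planted truth (centrosome, expected region fractions).  Truth masks go
into a companion multipage TIFF and the puncta table into a CSV, so every
artifact stays in a plain, tool-friendly format.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import Scene, SceneTruth

_SIDE = ".json"
_MASKS = "_masks.tif"
_PUNCTA = "_puncta.csv"


def save_scene(directory, name: str, scene: Scene, truth: SceneTruth | None = None):
    """Write ``<name>.tif`` plus sidecar(s) under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    roles = list(scene.channels)
    stack = np.stack([scene.channels[r] for r in roles]).astype(np.float32)
    tifffile.imwrite(directory / f"{name}.tif", stack, photometric="minisblack")
    sidecar = {
        "channels": roles,
        "pixel_size_um": scene.pixel_size_um,
    }
    if truth is not None:
        sidecar["truth"] = {
            "centrosome": [int(truth.centrosome[0]), int(truth.centrosome[1])],
            "expected_region_fractions": [
                float(f) for f in truth.expected_region_fractions
            ],
        }
        tifffile.imwrite(
            directory / f"{name}{_MASKS}",
            np.stack(
                [truth.cell_mask, truth.nucleus_mask]
            ).astype(np.uint8),
            photometric="minisblack",
        )
        truth.puncta.to_csv(directory / f"{name}{_PUNCTA}", index=False)
    (directory / f"{name}{_SIDE}").write_text(json.dumps(sidecar, indent=2))


def load_scene(directory, name: str):
    """Read a scene (and truth, if present) written by :func:`save_scene`.

    Returns ``(Scene, SceneTruth | None)``; the reloaded truth has no radius
    map (recompute it with :func:`lysopos.radial.normalized_radius_map`).
    """
    directory = Path(directory)
    sidecar = json.loads((directory / f"{name}{_SIDE}").read_text())
    stack = tifffile.imread(directory / f"{name}.tif")
    channels = {
        role: np.asarray(stack[i], dtype=float)
        for i, role in enumerate(sidecar["channels"])
    }
    scene = Scene(channels=channels, pixel_size_um=sidecar.get("pixel_size_um", 1.0))
    truth = None
    if "truth" in sidecar:
        masks = tifffile.imread(directory / f"{name}{_MASKS}").astype(bool)
        puncta = pd.read_csv(directory / f"{name}{_PUNCTA}")
        info = sidecar["truth"]
        truth = SceneTruth(
            cell_mask=masks[0],
            nucleus_mask=masks[1],
            centrosome=tuple(info["centrosome"]),
            puncta=puncta,
            expected_region_fractions=np.asarray(
                info["expected_region_fractions"], dtype=float
            ),
            radius_map=None,
        )
    return scene, truth
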