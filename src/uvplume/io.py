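"""File round-trips for the pipeline's on-disk formats.

Specimen images are written as 16-bit multi-page TIFF (one page per
channel, order visR, visG, visB, uvR, uvB) with the truth mask as 8-bit
PNG (0/255) and a YAML sidecar holding the intensity scale, lighting
gain, seed and grey-standard rectangles.  Polygon label sets are YAML;
trees are Newick; trait tables are CSV keyed by ``species``.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .polygons import LabelPolygonSet
from .specimen import SpecimenImage

_U16 = 65535


def save_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def save_specimen(directory, image: SpecimenImage, stem: str = "specimen") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    peak = float(image.channels.max())
    scale = _U16 / peak if peak > 0 else 1.0
    pages = np.clip(np.rint(image.channels * scale), 0, _U16).astype(np.uint16)
    tifffile.imwrite(directory / f"{stem}.tiff", pages)
    save_mask(directory / f"{stem}_mask.png", image.truth_mask)
    meta = {
        "scale": scale,
        "gain": float(image.lighting_gain),
        "noise_sd": float(image.noise_sd),
        "seed": int(image.seed),
        "standard_regions": [list(map(int, box)) for box in image.standard_regions],
        "standard_nominals": [float(v) for v in image.standard_nominals],
    }
    (directory / f"{stem}.yaml").write_text(yaml.safe_dump(meta))


def load_specimen(directory, stem: str = "specimen") -> SpecimenImage:
    directory = Path(directory)
    meta = yaml.safe_load((directory / f"{stem}.yaml").read_text())
    pages = tifffile.imread(directory / f"{stem}.tiff").astype(float)
    channels = pages / meta["scale"]
    mask = load_mask(directory / f"{stem}_mask.png")
    return SpecimenImage(
        channels=channels,
        standard_regions=[tuple(box) for box in meta["standard_regions"]],
        standard_nominals=tuple(meta["standard_nominals"]),
        truth_mask=mask,
        truth_spectra=np.zeros(mask.shape, dtype=np.int16),
        region_spectra={},
        lighting_gain=meta["gain"],
        noise_sd=meta["noise_sd"],
        seed=meta["seed"],
        meta={"loaded_from": str(directory / stem)},
    )


def save_polygons(path, polys: LabelPolygonSet) -> None:
    data = [
        {"class": p.label, "vertices": [list(v) for v in p.vertices]} for p in polys
    ]
    Path(path).write_text(yaml.safe_dump(data))


def load_polygons(path) -> LabelPolygonSet:
    data = yaml.safe_load(Path(path).read_text()) or []
    polys = LabelPolygonSet()
    for entry in data:
        polys.add(entry["class"], entry["vertices"])
    return polys
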