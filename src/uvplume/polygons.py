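"""Polygon ground-truth labels and their rasterisation to binary masks.

Expert labels are polygons of two classes, ``plumage`` and
``non_plumage``; non-plumage polygons may nest inside plumage polygons
(eyes, feet) and punch holes in the mask.  Rasterisation uses a
pixel-centre point-in-polygon test: pixel (row, col) is tested at
(x, y) = (col + 0.5, row + 0.5), row 0 at the top, and a centre exactly
on a polygon edge counts as outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .errors import BoundsError

PLUMAGE = "plumage"
NON_PLUMAGE = "non_plumage"


@dataclass(frozen=True)
class LabelPolygon:
    label: str  # PLUMAGE or NON_PLUMAGE
    vertices: tuple  # ((x, y), ...) in pixel coordinates

    def __post_init__(self):
        if self.label not in (PLUMAGE, NON_PLUMAGE):
            raise ValueError(f"unknown polygon class {self.label!r}")
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")


@dataclass
class LabelPolygonSet:
    polygons: list = field(default_factory=list)

    def add(self, label: str, vertices) -> None:
        self.polygons.append(LabelPolygon(label, tuple(map(tuple, vertices))))

    def __iter__(self):
        return iter(self.polygons)

    def __len__(self):
        return len(self.polygons)


def polygons_to_mask(polys: LabelPolygonSet, shape: tuple) -> np.ndarray:
    """Rasterise labelled polygons to a boolean plumage mask.

    A pixel is plumage iff its centre lies strictly inside at least one
    plumage polygon and inside no non-plumage polygon.
    """
    h, w = shape
    for poly in polys:
        xs, ys = zip(*poly.vertices)
        if min(xs) < 0 or min(ys) < 0 or max(xs) > w or max(ys) > h:
            raise BoundsError(f"polygon vertices outside image bounds {shape}")

    mask = np.zeros(shape, dtype=bool)
    if len(polys) == 0:
        return mask
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    xs = cols.ravel() + 0.5
    ys = rows.ravel() + 0.5

    inside_plumage = np.zeros(h * w, dtype=bool)
    inside_hole = np.zeros(h * w, dtype=bool)
    for poly in polys:
        geom = shapely.Polygon(poly.vertices)
        hits = shapely.contains_xy(geom, xs, ys)
        if poly.label == PLUMAGE:
            inside_plumage |= hits
        else:
            inside_hole |= hits
    mask.ravel()[...] = inside_plumage & ~inside_hole
    return mask
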