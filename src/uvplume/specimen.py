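"""Synthetic specimen images with ground truth.

Emulates the museum imaging layout: a bird specimen photographed against
a near-black background with a row of five grey standards (2, 40, 60, 80
and 99% reflectance, arranged left to right) below the specimen.  The
specimen is a body ellipse plus head disc; an eye disc and a label
rectangle can be added as non-plumage structures.  Every pixel carries a
known reflectance spectrum, so the ground-truth mask and per-pixel
cone catches are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LayoutError
from .spectral import CHANNELS, SpectralWorld, camera_response, make_spectrum

#: Nominal reflectances of the five grey standards, left to right.
STANDARD_NOMINALS = (0.02, 0.40, 0.60, 0.80, 0.99)

# truth_spectra region codes
BACKGROUND, BODY, HEAD, EYE, LABEL = 0, 1, 2, 3, 4
_STANDARD_BASE = 10  # standards get codes 10..14


@dataclass(frozen=True)
class SpecimenLayout:
    """Geometry of the synthetic photograph (row, col pixel coordinates)."""

    shape: tuple = (220, 300)
    body_center: tuple = (90.0, 160.0)
    body_axes: tuple = (52.0, 95.0)
    head_center: tuple = (70.0, 70.0)
    head_radius: float = 28.0
    eye_center: tuple = (62.0, 62.0)
    eye_radius: float = 6.0
    label_box: tuple = (150, 172, 130, 185)  # r0, r1, c0, c1 (half-open)
    standard_top: int = 182
    standard_height: int = 26
    standard_width: int = 42
    standard_gap: int = 10
    standard_left: int = 22

    def standard_boxes(self) -> list:
        boxes = []
        for i in range(5):
            c0 = self.standard_left + i * (self.standard_width + self.standard_gap)
            boxes.append((self.standard_top, self.standard_top + self.standard_height,
                          c0, c0 + self.standard_width))
        return boxes


@dataclass
class SpecimenImage:
    """Five-channel synthetic photograph plus exact ground truth."""

    channels: np.ndarray  # (5, H, W), order spectral.CHANNELS
    standard_regions: list  # [(r0, r1, c0, c1), ...] left to right
    standard_nominals: tuple
    truth_mask: np.ndarray  # bool (H, W); True = plumage
    truth_spectra: np.ndarray  # int (H, W) region codes
    region_spectra: dict  # region code -> reflectance spectrum on the world grid
    lighting_gain: float
    noise_sd: float = 0.0
    seed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        return self.channels.shape[1:]


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def default_spectra(world: SpectralWorld) -> dict:
    """Region spectra for a bright carotenoid-bodied, UV-headed specimen."""
    return {
        "body": make_spectrum(world, "uv_plus_yellow", uv=0.25, vis=0.55),
        "head": make_spectrum(world, "uv_peak", height=0.45),
    }


def make_specimen_image(
    world: SpectralWorld,
    layout: SpecimenLayout | None = None,
    spectra: dict | None = None,
    gain: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    eye: bool = True,
    label: bool = False,
    background_level: float = 0.005,
) -> SpecimenImage:
    """Render a synthetic specimen photograph with exact ground truth.

    Each pixel's five channels are ``camera_response(spectrum, gain)``
    plus zero-mean Gaussian noise (sd ``noise_sd``, clipped at 0).  The
    truth mask marks plumage pixels only: body and head minus the eye;
    label, standards and background are non-plumage.
    """
    if layout is None:
        layout = SpecimenLayout()
    if spectra is None:
        spectra = default_spectra(world)
    if gain <= 0:
        raise ValueError("gain must be positive")
    shape = layout.shape
    rng = np.random.default_rng(seed)

    body = _ellipse_mask(shape, layout.body_center, layout.body_axes)
    head = _ellipse_mask(shape, layout.head_center, (layout.head_radius,) * 2)
    specimen = body | head

    region = np.full(shape, BACKGROUND, dtype=np.int16)
    region[body] = BODY
    region[head] = HEAD
    if eye:
        eye_mask = _ellipse_mask(shape, layout.eye_center, (layout.eye_radius,) * 2)
        if not (eye_mask & specimen).any():
            raise LayoutError("eye disc lies outside the specimen")
        region[eye_mask] = EYE
    if label:
        r0, r1, c0, c1 = layout.label_box
        label_mask = np.zeros(shape, dtype=bool)
        label_mask[r0:r1, c0:c1] = True
        if (label_mask & specimen).any():
            raise LayoutError("label rectangle overlaps the specimen")
        region[label_mask] = LABEL

    boxes = layout.standard_boxes()
    for i, (r0, r1, c0, c1) in enumerate(boxes):
        if r1 > shape[0] or c1 > shape[1]:
            raise LayoutError("standards row falls outside the canvas")
        box = np.zeros(shape, dtype=bool)
        box[r0:r1, c0:c1] = True
        if (box & (region != BACKGROUND)).any():
            raise LayoutError("grey standard overlaps another region")
        region[box] = _STANDARD_BASE + i

    region_spectra = {
        BACKGROUND: make_spectrum(world, "dark", level=background_level),
        BODY: np.asarray(spectra["body"], dtype=float),
        HEAD: np.asarray(spectra.get("head", spectra["body"]), dtype=float),
        EYE: make_spectrum(world, "dark", level=0.002),
        LABEL: make_spectrum(world, "flat", level=0.85),
    }
    for i, nominal in enumerate(STANDARD_NOMINALS):
        region_spectra[_STANDARD_BASE + i] = make_spectrum(world, "flat", level=nominal)

    channels = np.empty((len(CHANNELS),) + shape, dtype=float)
    for code, spec in region_spectra.items():
        sel = region == code
        if not sel.any():
            continue
        channels[:, sel] = camera_response(spec, world, gain)[:, None]
    if noise_sd > 0:
        channels = channels + rng.normal(0.0, noise_sd, size=channels.shape)
        channels = np.clip(channels, 0.0, None)

    truth_mask = specimen & ~np.isin(region, (EYE, LABEL))
    return SpecimenImage(
        channels=channels,
        standard_regions=boxes,
        standard_nominals=STANDARD_NOMINALS,
        truth_mask=truth_mask,
        truth_spectra=region,
        region_spectra=region_spectra,
        lighting_gain=gain,
        noise_sd=noise_sd,
        seed=seed,
        meta={"eye": eye, "label": label},
    )
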