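"""Synthetic spectral world: illuminant, receptor and camera sensitivities.

The world lives on a fixed 300-700 nm grid (5 nm step).  Receptor
sensitivities model an average ultraviolet-sensitive (UVS) avian visual
system with four single-cone classes (u, s, m, l).  The camera model has
five channels: three visible (behind a UV/IR-cut filter, zero below
400 nm) and two UV (behind a UV-pass filter, zero above 400 nm).  The
camera's UV-range green channel is deliberately absent: its sensitivity
in the UV is too low to carry usable information, so only the red and
blue UV responses are modelled.

Band integrals use the midpoint rule on the grid, which is exact for the
piecewise-constant curves used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateStimulus

#: Channel order used for every 5-vector of camera responses.
CHANNELS = ("visR", "visG", "visB", "uvR", "uvB")
#: Receptor order used for every 4-vector of cone catches.
RECEPTORS = ("u", "s", "m", "l")

WL_START, WL_STOP, WL_STEP = 300.0, 700.0, 5.0

_RECEPTOR_PEAKS = {"u": 370.0, "s": 445.0, "m": 508.0, "l": 565.0}
_RECEPTOR_WIDTHS = {"u": 16.0, "s": 22.0, "m": 26.0, "l": 30.0}
_CAMERA_PEAKS = {"visR": 600.0, "visG": 548.0, "visB": 462.0, "uvR": 345.0, "uvB": 368.0}
_CAMERA_WIDTHS = {"visR": 42.0, "visG": 36.0, "visB": 32.0, "uvR": 13.0, "uvB": 13.0}
_UV_CUTOFF = 400.0  # nm; UV-pass above, UV/IR-cut below


def _gaussian(wl: np.ndarray, peak: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - peak) / width) ** 2)


@dataclass(frozen=True)
class SpectralWorld:
    """Wavelength grid plus illuminant, receptor and camera curves.

    Receptor curves are normalised to unit integral; camera curves are
    scaled so a perfect white reflector under the reference illuminant
    yields a response of exactly 1.0 per channel at gain 1.
    """

    wavelengths: np.ndarray
    illuminant: np.ndarray
    receptor_sensitivities: dict = field(default_factory=dict)
    camera_sensitivities: dict = field(default_factory=dict)

    @property
    def dl(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def validate(self) -> None:
        wl = self.wavelengths
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.illuminant < 0):
            raise ValueError("illuminant must be non-negative")
        for name, curve in self.receptor_sensitivities.items():
            if curve.shape != wl.shape or np.any(curve < 0):
                raise ValueError(f"receptor curve {name!r} invalid")
            if curve.sum() * self.dl <= 0:
                raise ValueError(f"receptor curve {name!r} has zero integral")
        for name, curve in self.camera_sensitivities.items():
            if curve.shape != wl.shape or np.any(curve < 0):
                raise ValueError(f"camera curve {name!r} invalid")
        uv = wl > _UV_CUTOFF
        for name in ("uvR", "uvB"):
            if self.camera_sensitivities[name][uv].sum() != 0:
                raise ValueError(f"{name} must be zero above {_UV_CUTOFF:.0f} nm")
        for name in ("visR", "visG", "visB"):
            if self.camera_sensitivities[name][wl < _UV_CUTOFF].sum() != 0:
                raise ValueError(f"{name} must be zero below {_UV_CUTOFF:.0f} nm")


def make_world(seed: int = 0) -> SpectralWorld:
    """Build a seeded spectral world on the 300-700 nm, 5 nm grid.

    The seed perturbs receptor and camera peak positions by a couple of
    nanometres so distinct worlds exist, while keeping the qualitative
    structure (UVS-type u cone near 370 nm, UV camera channels confined
    below 400 nm) fixed.  Identical seeds give bit-identical worlds.
    """
    rng = np.random.default_rng(seed)
    wl = np.arange(WL_START, WL_STOP + WL_STEP, WL_STEP)
    dl = WL_STEP
    illuminant = np.ones_like(wl)

    receptors = {}
    for name in RECEPTORS:
        peak = _RECEPTOR_PEAKS[name] + rng.uniform(-2.0, 2.0)
        width = _RECEPTOR_WIDTHS[name] * rng.uniform(0.95, 1.05)
        curve = _gaussian(wl, peak, width)
        receptors[name] = curve / (curve.sum() * dl)

    cameras = {}
    for name in CHANNELS:
        peak = _CAMERA_PEAKS[name] + rng.uniform(-2.0, 2.0)
        width = _CAMERA_WIDTHS[name] * rng.uniform(0.95, 1.05)
        curve = _gaussian(wl, peak, width)
        if name.startswith("uv"):
            curve = np.where(wl > _UV_CUTOFF, 0.0, curve)
        else:
            curve = np.where(wl < _UV_CUTOFF, 0.0, curve)
        # unit white response at gain 1 under the reference illuminant
        cameras[name] = curve / (np.sum(illuminant * curve) * dl)

    world = SpectralWorld(
        wavelengths=wl,
        illuminant=illuminant,
        receptor_sensitivities=receptors,
        camera_sensitivities=cameras,
    )
    world.validate()
    return world


def make_spectrum(world: SpectralWorld, kind: str, **params) -> np.ndarray:
    """Build a reflectance spectrum (proportions in [0, 1]) on the world grid.

    Kinds
    -----
    flat(level)
        Constant reflectance ``level``.
    uv_peak(height, center=350, width=18)
        Gaussian bump confined to 300-400 nm, zero above.
    carotenoid(level, cutoff=510, steepness=18)
        Long-wavelength sigmoidal step rising to ``level`` (yellow/red-like).
    uv_plus_yellow(uv, vis, ...)
        Sum of a UV bump (height ``uv``) and a long-pass sigmoid
        (asymptote ``vis``), clipped to 1 - the classic UV-yellow shape.
    dark(level=0.005)
        Constant reflectance below 1% (near-black background, eyes).
    """
    wl = world.wavelengths

    def _check(name, value, lo=0.0, hi=1.0):
        if not (lo <= value <= hi):
            raise ValueError(f"{kind}: parameter {name}={value} outside [{lo}, {hi}]")
        return float(value)

    if kind == "flat":
        level = _check("level", params.pop("level"))
        spec = np.full_like(wl, level)
    elif kind == "uv_peak":
        height = _check("height", params.pop("height"))
        center = params.pop("center", 350.0)
        width = params.pop("width", 18.0)
        spec = height * _gaussian(wl, center, width)
        spec = np.where(wl > _UV_CUTOFF, 0.0, spec)
    elif kind == "carotenoid":
        level = _check("level", params.pop("level"))
        cutoff = params.pop("cutoff", 510.0)
        steepness = params.pop("steepness", 18.0)
        spec = level / (1.0 + np.exp(-(wl - cutoff) / steepness))
    elif kind == "uv_plus_yellow":
        uv = _check("uv", params.pop("uv"))
        vis = _check("vis", params.pop("vis"))
        center = params.pop("center", 350.0)
        width = params.pop("width", 18.0)
        cutoff = params.pop("cutoff", 510.0)
        steepness = params.pop("steepness", 18.0)
        bump = uv * np.where(wl > _UV_CUTOFF, 0.0, _gaussian(wl, center, width))
        spec = bump + vis / (1.0 + np.exp(-(wl - cutoff) / steepness))
    elif kind == "dark":
        level = _check("level", params.pop("level", 0.005), hi=0.01)
        spec = np.full_like(wl, level)
    else:
        raise ValueError(f"unknown spectrum kind {kind!r}")
    if params:
        raise TypeError(f"unused parameters for kind {kind!r}: {sorted(params)}")
    return np.clip(spec, 0.0, 1.0)


def camera_response(spec: np.ndarray, world: SpectralWorld, gain: float = 1.0) -> np.ndarray:
    """Five-channel camera response to a reflectance spectrum.

    channel_c = gain * sum_lambda illuminant * spec * camera_c * dl,
    linear in both gain and reflectance.
    """
    spec = np.asarray(spec, dtype=float)
    if spec.shape != world.wavelengths.shape:
        raise ValueError("spectrum is not on the world wavelength grid")
    weighted = world.illuminant * spec
    return gain * np.array(
        [np.sum(weighted * world.camera_sensitivities[c]) * world.dl for c in CHANNELS]
    )


def raw_cone_catch(spec: np.ndarray, world: SpectralWorld) -> np.ndarray:
    """Unnormalised quantum catches (u, s, m, l) by the same integral form."""
    spec = np.asarray(spec, dtype=float)
    if spec.shape != world.wavelengths.shape:
        raise ValueError("spectrum is not on the world wavelength grid")
    weighted = world.illuminant * spec
    return np.array(
        [np.sum(weighted * world.receptor_sensitivities[r]) * world.dl for r in RECEPTORS]
    )


def true_cone_catch(spec: np.ndarray, world: SpectralWorld) -> np.ndarray:
    """Relative quantum catches (u, s, m, l), normalised to sum to 1."""
    raw = raw_cone_catch(spec, world)
    total = raw.sum()
    if total <= 0:
        raise DegenerateStimulus("all receptor catches are zero")
    return raw / total


def band_mean(spec: np.ndarray, world: SpectralWorld, lo: float, hi: float) -> float:
    """Mean reflectance over the [lo, hi] nm band (inclusive, midpoint rule)."""
    sel = (world.wavelengths >= lo) & (world.wavelengths <= hi)
    return float(np.mean(np.asarray(spec)[sel]))
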