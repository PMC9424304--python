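"""UV colouration metrics per specimen view and species-level aggregation.

Three metrics per sampled-pixel table:

* mean u — average relative UV cone catch across the plumage;
* peak u — mean of the top fraction (default upper 25%) of u values,
  capturing small UV patches; fractions 50% and 10% are used for
  sensitivity checks;
* UV+ colouration — presence of colours with a detectable UV component,
  possibly combined with longer-wavelength reflectance (UV-yellow,
  UV-red).  A pixel is UV+ iff (1) its u quantum catch exceeds 0.05 of
  a theoretical 100% white standard, (2) its UV-band reflectance
  exceeds 3%, and (3) its UV-band reflectance exceeds the minimum
  visible-channel reflectance.  A specimen view shows UV+ colouration
  if more than 5% (alternatives 1% and 10%) of sampled pixels are UV+.

In camera space the UV band is the mean of the two normalised UV
channels and the visible minimum is the minimum over the three
normalised visible channels.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .colour import ConeCatchMapper
from .errors import EmptyInput
from .spectral import CHANNELS

PEAK_FRACTIONS = (0.50, 0.25, 0.10)
PRESENCE_THRESHOLDS = (0.01, 0.05, 0.10)
U_WHITE_THRESHOLD = 0.05
UV_BAND_THRESHOLD = 0.03
_EPS = 1e-9  # guards the strict band comparison against float noise

_VIS = list(CHANNELS[:3])
_UV = list(CHANNELS[3:])


def _u_values(pixels) -> np.ndarray:
    if isinstance(pixels, pd.DataFrame):
        u = pixels["u"].to_numpy(dtype=float)
    else:
        u = np.asarray(pixels, dtype=float)
        if u.ndim == 2:  # (n, 4) catch table
            u = u[:, 0]
    if u.size == 0:
        raise EmptyInput("no pixels")
    return u


def mean_u(pixels) -> float:
    """Arithmetic mean of relative u across sampled pixels."""
    return float(_u_values(pixels).mean())


def peak_u(pixels, fraction: float = 0.25) -> float:
    """Mean of the ceil(fraction * n) largest u values."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    u = np.sort(_u_values(pixels))[::-1]
    k = math.ceil(fraction * u.size)
    return float(u[:k].mean())


def uv_plus_pixel(uv_band_mean, vis_min, u_rel_white) -> np.ndarray:
    """Vectorised UV+ test from band reflectances and white-relative u catch."""
    uv_band_mean = np.asarray(uv_band_mean, dtype=float)
    vis_min = np.asarray(vis_min, dtype=float)
    u_rel_white = np.asarray(u_rel_white, dtype=float)
    return (
        (u_rel_white > U_WHITE_THRESHOLD)
        & (uv_band_mean > UV_BAND_THRESHOLD)
        & (uv_band_mean > vis_min + _EPS)
    )


def uv_plus_flags(table: pd.DataFrame, mapper: ConeCatchMapper) -> np.ndarray:
    """UV+ flag per sampled pixel of a colour-pipeline table.

    The white reference pushes a flat 100% reflector through the same
    camera/mapping path, so the u-catch ratio is internally consistent.
    """
    channels = table[list(CHANNELS)].to_numpy(dtype=float)
    uv_band = table[_UV].to_numpy(dtype=float).mean(axis=1)
    vis_min = table[_VIS].to_numpy(dtype=float).min(axis=1)
    u_raw = mapper.predict_raw(channels)[:, 0]
    u_rel = u_raw / mapper.white_reference_u()
    return uv_plus_pixel(uv_band, vis_min, u_rel)


def uv_plus_presence(flags, threshold: float = 0.05):
    """(fraction of UV+ pixels, present iff fraction strictly exceeds threshold)."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        raise EmptyInput("no pixel flags")
    fraction = float(flags.mean())
    return fraction, fraction > threshold


def specimen_metrics(
    table: pd.DataFrame,
    mapper: ConeCatchMapper,
    specimen: str = "",
    species: str = "",
    sex: str = "",
    view: str = "",
) -> dict:
    """All UV metrics for one specimen view (one sampled-pixel table)."""
    flags = uv_plus_flags(table, mapper)
    rec = {
        "specimen": specimen,
        "species": species,
        "sex": sex,
        "view": view,
        "mean_u": mean_u(table),
        "uv_plus_fraction": uv_plus_presence(flags)[0],
    }
    for f in PEAK_FRACTIONS:
        rec[f"peak_u_{int(f * 100)}"] = peak_u(table, f)
    for t in PRESENCE_THRESHOLDS:
        rec[f"uv_plus_present_{int(t * 100)}"] = uv_plus_presence(flags, t)[1]
    return rec


def species_aggregate(records) -> pd.DataFrame:
    """Species x sex x view table from specimen-level records.

    Continuous metrics are averaged over specimens; presence flags are
    averaged and thresholded at 0.5 (strict majority).  Side views are
    dropped: back and belly already cover the plumage they show.
    """
    df = pd.DataFrame.from_records(records) if not isinstance(records, pd.DataFrame) else records.copy()
    df = df[df["view"].isin(["back", "belly"])]
    if df.empty:
        raise EmptyInput("no back/belly records to aggregate")
    flag_cols = [c for c in df.columns if c.startswith("uv_plus_present")]
    value_cols = [
        c
        for c in df.columns
        if c not in flag_cols + ["specimen", "species", "sex", "view"]
    ]
    grouped = df.groupby(["species", "sex", "view"], sort=True)
    out = grouped[value_cols].mean()
    for c in flag_cols:
        out[c] = grouped[c].mean() > 0.5
    return out.reset_index()
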