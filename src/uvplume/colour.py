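"""Calibrated colour extraction: grey-standard normalisation, polynomial
cone-catch mapping, achromatic re-citing, block aggregation and sampling.

The two fitted stages follow the scikit-learn estimator protocol:

* :class:`GreyStandardNormalizer` — fit a per-channel linear map from
  raw intensity to reflectance using the five grey standards in an
  image, removing per-image lighting variation.
* :class:`ConeCatchMapper` — fit per-receptor least squares on a
  polynomial basis (second-order terms and three-way channel
  interactions) mapping normalised camera channels to relative avian
  cone catches (u, s, m, l).

Pixel tables are pandas DataFrames with the five channel columns
(``visR`` ... ``uvB``) and, after mapping, the four catch columns.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ShortSampleWarning, SingularFit, StandardOrderError
from .spectral import (
    CHANNELS,
    RECEPTORS,
    SpectralWorld,
    camera_response,
    make_spectrum,
    raw_cone_catch,
)
from .specimen import SpecimenImage

ACHROMATIC = np.array([0.25, 0.25, 0.25, 0.25])


class GreyStandardNormalizer(BaseEstimator, TransformerMixin):
    """Per-channel linear normalisation through the five grey standards.

    For each channel an ordinary least-squares line of nominal
    reflectance (0.02 ... 0.99) on mean standard intensity is fitted and
    applied to every pixel, so a pixel matching a standard's mean maps
    to that standard's nominal reflectance (up to fit residual) and a
    global lighting gain cancels exactly.

    Attributes
    ----------
    coef_, intercept_ : (5,) arrays, the fitted line per channel.
    standard_means_ : (5 channels, 5 standards) mean raw intensities.
    """

    def fit(self, image: SpecimenImage, y=None):
        means = np.empty((len(CHANNELS), len(image.standard_regions)))
        for j, (r0, r1, c0, c1) in enumerate(image.standard_regions):
            patch = image.channels[:, r0:r1, c0:c1]
            if patch[0].size < 4:
                raise ValueError("standard region smaller than 4 pixels")
            means[:, j] = patch.reshape(len(CHANNELS), -1).mean(axis=1)
        if not np.all(np.diff(means, axis=1) > 0):
            raise StandardOrderError(
                "standard mean intensities not increasing with nominal reflectance"
            )
        nominal = np.asarray(image.standard_nominals, dtype=float)
        self.coef_ = np.empty(len(CHANNELS))
        self.intercept_ = np.empty(len(CHANNELS))
        for c in range(len(CHANNELS)):
            slope, intercept = np.polyfit(means[c], nominal, 1)
            self.coef_[c] = slope
            self.intercept_[c] = intercept
        self.standard_means_ = means
        return self

    def transform(self, X) -> np.ndarray:
        """Map raw intensities to normalised reflectance.

        ``X`` may be a SpecimenImage, a (5, H, W) channel stack, or an
        (n, 5) pixel table; the output keeps the input layout.
        """
        check_is_fitted(self, "coef_")
        if isinstance(X, SpecimenImage):
            X = X.channels
        X = np.asarray(X, dtype=float)
        if X.ndim == 3 and X.shape[0] == len(CHANNELS):
            return self.coef_[:, None, None] * X + self.intercept_[:, None, None]
        if X.ndim == 2 and X.shape[1] == len(CHANNELS):
            return self.coef_[None, :] * X + self.intercept_[None, :]
        if X.ndim == 1 and X.shape[0] == len(CHANNELS):
            return self.coef_ * X + self.intercept_
        raise ValueError("expected a (5, H, W) stack or (n, 5) pixel table")


def normalize(image: SpecimenImage) -> np.ndarray:
    """Fit the grey-standard normalisation on ``image`` and apply it."""
    return GreyStandardNormalizer().fit(image).transform(image)


def polynomial_basis(X: np.ndarray) -> np.ndarray:
    """Mapping basis: 1, channels, squared channels, pairwise and
    three-way products of distinct channels (31 terms for 5 channels)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    cols = [np.ones(n)]
    cols += [X[:, i] for i in range(k)]
    cols += [X[:, i] ** 2 for i in range(k)]
    cols += [X[:, i] * X[:, j] for i, j in itertools.combinations(range(k), 2)]
    cols += [
        X[:, i] * X[:, j] * X[:, m] for i, j, m in itertools.combinations(range(k), 3)
    ]
    return np.column_stack(cols)


def basis_feature_names(channels=CHANNELS) -> list:
    names = ["1"]
    names += list(channels)
    names += [f"{c}^2" for c in channels]
    names += [f"{a}*{b}" for a, b in itertools.combinations(channels, 2)]
    names += [f"{a}*{b}*{c}" for a, b, c in itertools.combinations(channels, 3)]
    return names


class ConeCatchMapper(BaseEstimator):
    """Polynomial mapping from normalised camera channels to cone catches.

    One least-squares fit per receptor (u, s, m, l) on the shared
    polynomial basis, targeting the *raw* quantum catches; relative
    catches are obtained in :meth:`predict` by clipping the raw
    predictions at zero and renormalising each pixel to sum 1.  The
    UV-range green channel never enters: the camera model carries only
    visR, visG, visB, uvR, uvB.

    Attributes
    ----------
    coef_ : (n_terms, 4) per-receptor coefficient vectors.
    r2_ : dict receptor -> training R² (raw-catch scale).
    max_residual_ : dict receptor -> max |training residual| (raw catch).
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(CHANNELS):
            raise ValueError(f"X must be (n, {len(CHANNELS)})")
        if y.shape != (X.shape[0], len(RECEPTORS)):
            raise ValueError(f"y must be (n, {len(RECEPTORS)})")
        basis = polynomial_basis(X)
        n, k = basis.shape
        if n < 2 * k:
            raise ValueError(
                f"need at least {2 * k} calibration samples for {k} basis terms, got {n}"
            )
        coef, _, rank, _ = np.linalg.lstsq(basis, y, rcond=None)
        if rank < k:
            raise SingularFit(f"design rank {rank} < {k} basis terms")
        fitted = basis @ coef
        resid = y - fitted
        ss_res = (resid**2).sum(axis=0)
        ss_tot = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
        self.coef_ = coef
        self.feature_names_ = basis_feature_names()
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
        self.r2_ = dict(zip(RECEPTORS, r2))
        self.max_residual_ = dict(zip(RECEPTORS, np.abs(resid).max(axis=0)))
        self.n_recited_ = 0
        return self

    def predict_raw(self, X) -> np.ndarray:
        """Unclipped polynomial catches, one column per receptor."""
        check_is_fitted(self, "coef_")
        return polynomial_basis(X) @ self.coef_

    def predict(self, X) -> np.ndarray:
        """Relative cone catches: clipped at 0 and renormalised to sum 1.

        Pixels whose raw catches are all non-positive are re-cited to
        the achromatic centre and counted in ``n_recited_``.
        """
        raw = np.clip(self.predict_raw(X), 0.0, None)
        total = raw.sum(axis=1)
        bad = total <= 0
        self.n_recited_ += int(bad.sum())
        raw[bad] = ACHROMATIC
        total[bad] = 1.0
        return raw / total[:, None]

    def white_reference_u(self) -> float:
        """Raw u catch of a theoretical 100% white (all channels at 1)."""
        return float(self.predict_raw(np.ones((1, len(CHANNELS))))[0, 0])


def make_calibration(world: SpectralWorld, n_spectra: int = 250, seed: int = 0):
    """Random calibration set: channel reflectances and raw cone catches.

    Spectra are random mixtures of the generator's families (flat, UV
    bumps, long-pass sigmoids and their sums) spanning dark to bright
    plumage, with the smoothness of real pigmentary/structural
    reflectance curves (UV bump sigma 18-35 nm, i.e. FWHM roughly
    40-80 nm; sigmoid transition scale 20-45 nm; a small broadband
    pedestal on chromatic spectra).  Channel values are
    reflectance-equivalents, i.e. the camera response divided by the
    response to a perfect white, matching the output scale of
    grey-standard normalisation; targets are the unnormalised quantum
    catches of each spectrum.
    """
    rng = np.random.default_rng(seed)
    white = camera_response(make_spectrum(world, "flat", level=1.0), world)
    X = np.empty((n_spectra, len(CHANNELS)))
    Y = np.empty((n_spectra, len(RECEPTORS)))
    specs = []
    for i in range(n_spectra):
        kind = rng.integers(0, 4)
        if kind == 0:
            spec = make_spectrum(world, "flat", level=rng.uniform(0.02, 0.99))
        elif kind == 1:
            spec = make_spectrum(
                world,
                "uv_peak",
                height=rng.uniform(0.05, 0.9),
                center=rng.uniform(335, 380),
                width=rng.uniform(18, 35),
            )
            spec = spec + rng.uniform(0.02, 0.06)
        elif kind == 2:
            spec = make_spectrum(
                world,
                "carotenoid",
                level=rng.uniform(0.1, 0.95),
                cutoff=rng.uniform(440, 600),
                steepness=rng.uniform(20, 45),
            )
            spec = spec + rng.uniform(0.02, 0.06)
        else:
            spec = make_spectrum(
                world,
                "uv_plus_yellow",
                uv=rng.uniform(0.05, 0.8),
                vis=rng.uniform(0.1, 0.9),
                center=rng.uniform(335, 380),
                width=rng.uniform(18, 35),
                cutoff=rng.uniform(460, 580),
                steepness=rng.uniform(20, 45),
            )
            spec = spec + rng.uniform(0.0, 0.03)
        spec = np.clip(spec, 0.0, 1.0)
        X[i] = camera_response(spec, world) / white
        Y[i] = raw_cone_catch(spec, world)
        specs.append(spec)
    return X, Y, specs


def fit_mapping(X, y) -> ConeCatchMapper:
    """Fit the polynomial cone-catch mapping (thin estimator wrapper)."""
    return ConeCatchMapper().fit(X, y)


def apply_mapping(model: ConeCatchMapper, pixels) -> np.ndarray:
    """Apply a fitted mapping to an (n, 5) normalised pixel table."""
    return model.predict(np.asarray(pixels, dtype=float))


def recite_achromatic(pixels, catches, threshold: float = 0.01) -> np.ndarray:
    """Re-cite low-reflectance pixels to the achromatic centre.

    Any pixel whose mean normalised reflectance across the five channels
    is strictly below ``threshold`` (default 1%) gets u = s = m = l =
    0.25; all other pixels keep their catches.
    """
    pixels = np.atleast_2d(np.asarray(pixels, dtype=float))
    catches = np.atleast_2d(np.asarray(catches, dtype=float))
    if pixels.shape[0] != catches.shape[0]:
        raise ValueError("pixels and catches are not aligned")
    out = catches.copy()
    out[pixels.mean(axis=1) < threshold] = ACHROMATIC
    return out


def aggregate_and_sample(
    norm_pixels: np.ndarray,
    mask: np.ndarray,
    target: int = 500,
    max_factor: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Block-aggregate masked pixels and sample ``target`` cells.

    Candidate aggregation factors are enumerated from ``max_factor``
    down to 1 over the mask's bounding box (blocks anchored at its
    top-left corner; partial edge blocks allowed).  A cell is valid if
    it contains at least one plumage pixel and its value is the mean of
    those pixels per channel.  The first factor yielding at least
    ``target`` valid cells is used — i.e. the largest factor keeping
    enough cells, maximising denoising — and ``target`` cells are then
    sampled uniformly without replacement.  If even factor 1 yields
    fewer than ``target`` cells, all cells are returned with a
    :class:`ShortSampleWarning`.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    rows, cols = np.nonzero(mask)
    r0, c0 = rows.min(), cols.min()
    rr, cc = rows - r0, cols - c0
    values = norm_pixels[:, rows, cols]  # (5, n_px)

    chosen = None
    for f in range(max_factor, 0, -1):
        n_bc = cc.max() // f + 1
        cell_ids = (rr // f) * n_bc + (cc // f)
        uniq = np.unique(cell_ids)
        if uniq.size >= target or f == 1:
            chosen = (f, cell_ids, uniq, n_bc)
            break
    f, cell_ids, uniq, n_bc = chosen

    order = np.argsort(cell_ids, kind="stable")
    sorted_ids = cell_ids[order]
    starts = np.searchsorted(sorted_ids, uniq, side="left")
    ends = np.searchsorted(sorted_ids, uniq, side="right")
    sums = np.add.reduceat(values[:, order], starts, axis=1)
    counts = ends - starts
    means = sums / counts

    df = pd.DataFrame(means.T, columns=list(CHANNELS))
    df.insert(0, "cell_col", (uniq % n_bc) + 0)
    df.insert(0, "cell_row", uniq // n_bc)
    df.insert(0, "factor", f)

    if len(df) < target:
        warnings.warn(
            f"only {len(df)} aggregated cells available (target {target})",
            ShortSampleWarning,
            stacklevel=2,
        )
        return df.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    take = np.sort(rng.choice(len(df), size=target, replace=False))
    return df.iloc[take].reset_index(drop=True)


def extract_colour(
    image: SpecimenImage,
    mapper: ConeCatchMapper,
    mask: np.ndarray | None = None,
    target: int = 500,
    seed: int = 0,
    recite_threshold: float = 0.01,
) -> pd.DataFrame:
    """Full per-image chain: normalise, aggregate/sample, map, re-cite.

    Returns a table with the five normalised channel columns and the
    four relative catch columns for the sampled cells.
    """
    if mask is None:
        mask = image.truth_mask
    norm = normalize(image)
    table = aggregate_and_sample(norm, mask, target=target, seed=seed)
    channels = table[list(CHANNELS)].to_numpy()
    catches = mapper.predict(channels)
    catches = recite_achromatic(channels, catches, threshold=recite_threshold)
    for j, r in enumerate(RECEPTORS):
        table[r] = catches[:, j]
    return table
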