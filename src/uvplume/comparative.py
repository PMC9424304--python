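"""Simulated comparative datasets: species traits on a phylogeny with a
chosen phylogenetic heritability and fixed-effect structure.

A pure-birth tree is simulated and scaled to unit height; phylogenetic
effects are drawn with covariance sigma2_a * A (A the shared-path
correlation matrix) and the response is X beta + a + e, or its sign
indicator for the binary (probit-generated) variant.  Each species
contributes one row per sex x view combination sharing a single
phylogenetic effect, matching the observation-level layout used when
sex and view enter as fixed effects.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import product

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .pmm import phylo_correlation

#: Column order that a beta vector maps onto (missing tail = zero effect).
PREDICTOR_NAMES = (
    "uvb",
    "temperature",
    "solar",
    "forest",
    "strata",
    "visual_system",
    "sex_M",
    "view_back",
)


@dataclass
class ComparativeDataset:
    tree: dendropy.Tree
    traits: pd.DataFrame  # species, sex, view, response, predictors
    true_params: dict  # beta (full vector), sigma2_a, sigma2_e, h2
    A: np.ndarray
    species: list


def simulate_tree(n_species: int, seed: int = 0) -> dendropy.Tree:
    """Pure-birth tree with ``n_species`` tips, scaled to unit height."""
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=random.Random(int(seed)),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:04d}"
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    height = max(depths)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height
    return tree


def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std(ddof=0)
    return (col - col.mean()) / sd if sd > 0 else np.zeros_like(col, dtype=float)


def make_comparative_dataset(
    n_species: int,
    beta=(),
    sigma2_a: float = 1.0,
    sigma2_e: float = 1.0,
    binary: bool = False,
    seed: int = 0,
    sexes=("M", "F"),
    views=("back", "belly"),
    tree: dendropy.Tree | None = None,
) -> ComparativeDataset:
    """Simulate a trait table on a pure-birth phylogeny.

    ``beta`` maps onto :data:`PREDICTOR_NAMES` in order; a shorter
    vector leaves the remaining effects at zero.  For the binary
    variant the residual variance is fixed at 1 (probit scale) and the
    response is the sign indicator of the latent value.  A pre-built
    unit-height tree with ``n_species`` tips may be supplied to hold
    the phylogeny fixed across replicate datasets.
    """
    if n_species < 10:
        raise ValueError("need at least 10 species")
    if sigma2_a < 0 or sigma2_e < 0:
        raise ValueError("variances must be non-negative")
    rng = np.random.default_rng(seed)
    if tree is None:
        tree = simulate_tree(n_species, seed=int(rng.integers(2**31 - 1)))
    A, labels = phylo_correlation(tree)

    # species-level predictors; the three climate variables share a
    # latent factor so they are realistically collinear
    climate = rng.normal(size=n_species)
    sp_pred = {
        "uvb": 0.8 * climate + 0.6 * rng.normal(size=n_species),
        "temperature": 0.7 * climate + 0.7 * rng.normal(size=n_species),
        "solar": 0.75 * climate + 0.65 * rng.normal(size=n_species),
        "forest": rng.binomial(1, 0.5, size=n_species).astype(float),
        "strata": rng.beta(2.0, 2.0, size=n_species),
        "visual_system": rng.binomial(1, 0.3, size=n_species).astype(float),
    }

    rows = list(product(range(n_species), sexes, views))
    n = len(rows)
    sp_idx = np.array([r[0] for r in rows])
    sex_col = np.array([r[1] for r in rows])
    view_col = np.array([r[2] for r in rows])

    X = np.empty((n, len(PREDICTOR_NAMES)))
    for j, name in enumerate(PREDICTOR_NAMES):
        if name == "sex_M":
            raw = (sex_col == "M").astype(float)
        elif name == "view_back":
            raw = (view_col == "back").astype(float)
        else:
            raw = sp_pred[name][sp_idx]
        X[:, j] = _standardize(raw)

    beta_full = np.zeros(len(PREDICTOR_NAMES))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if beta.size > len(PREDICTOR_NAMES):
        raise ValueError(f"beta longer than {len(PREDICTOR_NAMES)} predictors")
    beta_full[: beta.size] = beta

    if binary:
        sigma2_e = 1.0
    chol = np.linalg.cholesky(A + 1e-10 * np.eye(n_species))
    a = np.sqrt(sigma2_a) * (chol @ rng.standard_normal(n_species))
    e = np.sqrt(sigma2_e) * rng.standard_normal(n)
    latent = X @ beta_full + a[sp_idx] + e
    response = (latent > 0).astype(int) if binary else latent

    traits = pd.DataFrame(
        {
            "species": [labels[i] for i in sp_idx],
            "sex": sex_col,
            "view": view_col,
            "response": response,
        }
    )
    for j, name in enumerate(PREDICTOR_NAMES):
        traits[name] = X[:, j]

    total = sigma2_a + sigma2_e
    true_params = {
        "beta": beta_full,
        "sigma2_a": float(sigma2_a),
        "sigma2_e": float(sigma2_e),
        "h2": float(sigma2_a / total) if total > 0 else 0.0,
    }
    return ComparativeDataset(
        tree=tree, traits=traits, true_params=true_params, A=A, species=labels
    )
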