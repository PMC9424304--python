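"""Bayesian phylogenetic mixed models (the "animal model") by Gibbs sampling.

Model: y = X beta + a + e with a ~ N(0, sigma2_a * A) over species and
e ~ N(0, sigma2_e * I) over observations, where A is the phylogenetic
correlation matrix (shared root-to-tip path proportions under Brownian
motion).  beta carries a flat improper prior; each variance carries a
scaled inverse-chi-square prior with scale V and degree of belief nu,
i.e. inverse-gamma(shape nu/2, rate nu*V/2) — the univariate reading of
the usual (V, nu) inverse-Wishart parameterisation, defaulting to the
weakly informative V = 1, nu = 0.002.

The sampler exploits a fixed eigen-rotation of Z A Z': beta is drawn
from its marginal full conditional (phylogenetic effects integrated
out, diagonal covariance in the rotated basis) and the effects are then
drawn conditionally, which together constitute an exact joint conjugate
(beta, a) update.  Binary responses use probit data augmentation with
the residual variance fixed at 1.

Observations may repeat species (e.g. species x sex x view rows sharing
one phylogenetic effect) via ``species_idx``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

from .errors import (
    ChainError,
    LabelError,
    SeparationWarning,
    SpecError,
    TransformError,
)

_EIG_FLOOR = 1e-8


@dataclass(frozen=True)
class VarPrior:
    """Scaled inverse-chi-square prior on one variance component."""

    V: float = 1.0
    nu: float = 0.002
    fix: bool = False

    def __post_init__(self):
        if self.V <= 0 or self.nu < 0:
            raise ValueError("prior needs V > 0 and nu >= 0")


@dataclass(frozen=True)
class PMMPrior:
    residual: VarPrior = field(default_factory=VarPrior)
    phylo: VarPrior = field(default_factory=VarPrior)


@dataclass(frozen=True)
class ChainSettings:
    """Desk-scale default: one-tenth of the full 110,000/25/10,000 chain."""

    iterations: int = 11000
    thin: int = 25
    burn_in: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.iterations) or self.thin < 1:
            raise ValueError("need burn_in < iterations and thin >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Sampled fixed effects and variance components, with tree provenance."""

    df: pd.DataFrame  # beta_* columns, sigma2_a, sigma2_e, tree
    beta_names: tuple

    @property
    def beta(self) -> np.ndarray:
        return self.df[[f"beta_{n}" for n in self.beta_names]].to_numpy()

    @property
    def sigma2_a(self) -> np.ndarray:
        return self.df["sigma2_a"].to_numpy()

    @property
    def sigma2_e(self) -> np.ndarray:
        return self.df["sigma2_e"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class PosteriorSummary:
    """Per-parameter medians and 95% credible intervals, plus derived ratios."""

    table: pd.DataFrame  # index parameter; columns median, lo95, hi95
    h2: dict | None = None
    r2_marginal: dict | None = None
    r2_conditional: dict | None = None


def phylo_correlation(tree, taxa_order=None):
    """Phylogenetic correlation matrix A from a rooted dendropy tree.

    A[i, j] is the shared root-to-tip path length of tips i and j
    divided by tree height, so an ultrametric tree has unit diagonal.
    Returns (A, labels) with labels in ``taxa_order`` if given.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if taxa_order is not None:
        if set(taxa_order) != set(labels):
            raise LabelError("tree tip labels do not match requested taxa")
        labels = list(taxa_order)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)

    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        edge = node.edge.length or 0.0
        depth[node] = depth[node.parent_node] + edge
    height = max(depth[lf] for lf in leaves)
    if height <= 0:
        raise ValueError("tree has zero height")

    A = np.zeros((n, n))
    tips_below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            A[i, i] = depth[node]
            tips_below[node] = [i]
            continue
        child_sets = [tips_below.pop(ch) for ch in node.child_nodes()]
        for a_idx in range(len(child_sets)):
            for b_idx in range(a_idx + 1, len(child_sets)):
                ia = np.array(child_sets[a_idx])
                ib = np.array(child_sets[b_idx])
                A[np.ix_(ia, ib)] = depth[node]
                A[np.ix_(ib, ia)] = depth[node]
        tips_below[node] = [i for s in child_sets for i in s]
    return A / height, labels


def prepare_response(table: pd.DataFrame, metric: str, predictors) -> tuple:
    """Model inputs from a species-level metric table.

    Continuous responses (mean u, peak u) are log10-transformed and then
    standardised; the binary UV+ presence response passes through as
    0/1.  Predictors are standardised (mean 0, sd 1); ``sex`` and
    ``view`` string columns become male/back indicator variables before
    standardisation.  Returns (y, X DataFrame with intercept, species).
    """
    df = table.copy()
    binary = metric.startswith("uv_plus_present")
    y = df[metric].to_numpy()
    if binary:
        y = y.astype(float)
    else:
        y = y.astype(float)
        bad = np.nonzero(y <= 0)[0]
        if bad.size:
            raise TransformError(
                f"{metric}: non-positive values cannot be log10-transformed",
                rows=df.index[bad].tolist(),
            )
        y = np.log10(y)
        y = (y - y.mean()) / y.std(ddof=0)

    X = pd.DataFrame({"intercept": np.ones(len(df))})
    for p in predictors:
        if p == "sex":
            col, name = (df["sex"] == "M").astype(float), "sex_M"
        elif p == "view":
            col, name = (df["view"] == "back").astype(float), "view_back"
        else:
            col, name = df[p].astype(float), p
        sd = col.std(ddof=0)
        X[name] = (col - col.mean()) / sd if sd > 0 else 0.0
    species = df["species"].to_numpy()
    return y, X, species


def _draw_inv_gamma(rng, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


def _check_separation(X, y, names):
    y = np.asarray(y)
    for j, name in enumerate(names):
        x0, x1 = X[y == 0, j], X[y == 1, j]
        if x0.size == 0 or x1.size == 0 or x0.max() < x1.min() or x1.max() < x0.min():
            warnings.warn(
                f"predictor {name!r} perfectly separates the binary response",
                SeparationWarning,
                stacklevel=3,
            )


class _PhyloMMBase(BaseEstimator):
    def __init__(self, prior=None, iterations=11000, thin=25, burn_in=1000, random_state=0):
        self.prior = prior
        self.iterations = iterations
        self.thin = thin
        self.burn_in = burn_in
        self.random_state = random_state

    _binary = False

    def fit(self, X, y, A=None, species_idx=None, tree_id=0, feature_names=None):
        """Run the Gibbs chain.

        X : (n, p) design including any intercept column.
        y : (n,) gaussian response, or 0/1 for the binary model.
        A : (q, q) phylogenetic correlation matrix (identity if None).
        species_idx : (n,) map from observation to species row of A;
            identity when omitted (then n must equal q).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.size != n:
            raise ValueError("X and y lengths differ")
        prior = self.prior or PMMPrior(
            residual=VarPrior(1.0, 0.002, fix=self._binary), phylo=VarPrior(1.0, 0.002)
        )
        chain = ChainSettings(self.iterations, self.thin, self.burn_in, self.random_state)
        if A is None:
            A = np.eye(n if species_idx is None else int(np.max(species_idx)) + 1)
        A = np.asarray(A, dtype=float)
        q = A.shape[0]
        if species_idx is None:
            if n != q:
                raise ValueError("without species_idx, need one observation per species")
            species_idx = np.arange(n)
        species_idx = np.asarray(species_idx, dtype=int)
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(p)]
        if self._binary:
            if not set(np.unique(y)) <= {0.0, 1.0}:
                raise ValueError("binary model needs a 0/1 response")
            _check_separation(X, y, feature_names)

        rng = np.random.default_rng(self.random_state)

        # fixed eigen-rotations (see module docstring)
        w_A, U_A = np.linalg.eigh(A)
        w_A = np.clip(w_A, _EIG_FLOOR, None)
        L = U_A * np.sqrt(w_A)  # A ~= L L'
        Zt = L[species_idx, :]  # (n, q)
        d_K, U_K = np.linalg.eigh(Zt @ Zt.T)
        d_K = np.clip(d_K, 0.0, None)
        lam, P = np.linalg.eigh(Zt.T @ Zt)
        lam = np.clip(lam, 0.0, None)
        Xs = U_K.T @ X
        RtX = Zt.T @ X
        if not self._binary:
            ys = U_K.T @ y
            Zty = Zt.T @ y

        sa2 = prior.phylo.V
        se2 = prior.residual.V
        z = np.where(y > 0, 0.5, -0.5) if self._binary else y
        a_obs = np.zeros(n)
        beta = np.zeros(p)

        n_rec = chain.n_draws
        beta_out = np.empty((n_rec, p))
        sa2_out = np.empty(n_rec)
        se2_out = np.empty(n_rec)
        k = 0
        for it in range(1, chain.iterations + 1):
            if self._binary:
                mu = X @ beta + a_obs
                u = rng.uniform(size=n)
                p0 = np.clip(ndtr(-mu), 1e-12, 1.0 - 1e-12)
                arg = np.where(y > 0, p0 + u * (1.0 - p0), u * p0)
                z = mu + ndtri(np.clip(arg, 1e-12, 1.0 - 1e-12))
                ys = U_K.T @ z
                Zty = Zt.T @ z

            # joint (beta, a) update: marginal beta, then a | beta
            iv = 1.0 / (sa2 * d_K + se2)
            Wx = Xs * iv[:, None]
            G = Xs.T @ Wx
            cG = cho_factor(G, lower=True)
            mean_b = cho_solve(cG, Wx.T @ ys)
            beta = mean_b + solve_triangular(
                cG[0].T, rng.standard_normal(p), lower=False
            )
            rhs = (Zty - RtX @ beta) / se2
            prec = lam / se2 + 1.0 / sa2
            t = P.T @ rhs
            a_tilde = P @ (t / prec + rng.standard_normal(q) / np.sqrt(prec))
            a_obs = (L @ a_tilde)[species_idx]

            sa2 = _draw_inv_gamma(
                rng,
                (prior.phylo.nu + q) / 2.0,
                (prior.phylo.nu * prior.phylo.V + a_tilde @ a_tilde) / 2.0,
            )
            if prior.residual.fix:
                se2 = prior.residual.V
            else:
                resid = z - X @ beta - a_obs
                se2 = _draw_inv_gamma(
                    rng,
                    (prior.residual.nu + n) / 2.0,
                    (prior.residual.nu * prior.residual.V + resid @ resid) / 2.0,
                )
            if not (np.isfinite(beta).all() and np.isfinite(sa2) and np.isfinite(se2)):
                raise ChainError("non-finite draw", iteration=it)
            if it > chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
                beta_out[k] = beta
                sa2_out[k] = sa2
                se2_out[k] = se2
                k += 1

        df = pd.DataFrame(beta_out[:k], columns=[f"beta_{m}" for m in feature_names])
        df["sigma2_a"] = sa2_out[:k]
        df["sigma2_e"] = se2_out[:k]
        df["tree"] = tree_id
        self.draws_ = PosteriorDraws(df=df, beta_names=tuple(feature_names))
        self.n_features_in_ = p
        return self


class PhyloMMGaussian(_PhyloMMBase):
    """Gaussian phylogenetic mixed model (conjugate Gibbs sampler)."""

    _binary = False


class PhyloMMBinary(_PhyloMMBase):
    """Binary phylogenetic mixed model via probit data augmentation.

    The residual (probit latent) variance is fixed at 1, mirroring the
    fixed-residual prior used for categorical responses.
    """

    _binary = True


def fit_pmm_gaussian(y, X, A, prior=None, chain=None, species_idx=None, tree_id=0,
                     feature_names=None) -> PosteriorDraws:
    chain = chain or ChainSettings()
    est = PhyloMMGaussian(
        prior=prior, iterations=chain.iterations, thin=chain.thin,
        burn_in=chain.burn_in, random_state=chain.seed,
    )
    est.fit(X, y, A=A, species_idx=species_idx, tree_id=tree_id,
            feature_names=feature_names)
    return est.draws_


def fit_pmm_binary(y01, X, A, prior=None, chain=None, species_idx=None, tree_id=0,
                   feature_names=None) -> PosteriorDraws:
    chain = chain or ChainSettings()
    if prior is not None and not prior.residual.fix:
        raise ValueError("binary model requires the residual variance fixed")
    est = PhyloMMBinary(
        prior=prior, iterations=chain.iterations, thin=chain.thin,
        burn_in=chain.burn_in, random_state=chain.seed,
    )
    est.fit(X, y01, A=A, species_idx=species_idx, tree_id=tree_id,
            feature_names=feature_names)
    return est.draws_


def _ci(x):
    # inverted-CDF quantiles: summaries depend only on the multiset of
    # draws, so pooling identical draw sets leaves them unchanged
    x = np.asarray(x)
    return (
        float(np.median(x)),
        float(np.quantile(x, 0.025, method="inverted_cdf")),
        float(np.quantile(x, 0.975, method="inverted_cdf")),
    )


def summarize(draws: PosteriorDraws) -> PosteriorSummary:
    rows = {}
    for name in draws.beta_names:
        rows[f"beta_{name}"] = _ci(draws.df[f"beta_{name}"])
    rows["sigma2_a"] = _ci(draws.sigma2_a)
    rows["sigma2_e"] = _ci(draws.sigma2_e)
    table = pd.DataFrame(rows, index=["median", "lo95", "hi95"]).T
    return PosteriorSummary(table=table)


def estimate_H2(draws: PosteriorDraws) -> PosteriorSummary:
    """Phylogenetic heritability from an intercept-only fit.

    Per draw, H2 = sigma2_a / (sigma2_a + sigma2_e); summarised by the
    posterior median and 95% credible interval.
    """
    h2 = draws.sigma2_a / (draws.sigma2_a + draws.sigma2_e)
    med, lo, hi = _ci(h2)
    summary = summarize(draws)
    summary.h2 = {"median": med, "lo95": lo, "hi95": hi, "draws": h2}
    return summary


def pool_over_trees(per_tree_draws) -> PosteriorDraws:
    """Concatenate per-tree posterior draws (tree id retained)."""
    per_tree_draws = list(per_tree_draws)
    if not per_tree_draws:
        raise SpecError("nothing to pool")
    names = per_tree_draws[0].beta_names
    for d in per_tree_draws[1:]:
        if d.beta_names != names:
            raise SpecError("mismatched parameter sets across trees")
    df = pd.concat([d.df for d in per_tree_draws], ignore_index=True)
    return PosteriorDraws(df=df, beta_names=names)


def r2_marginal_conditional(draws: PosteriorDraws, X) -> PosteriorSummary:
    """Marginal and conditional R2 over the posterior.

    Per draw, var_f = var(X beta) over the observed design;
    R2_marginal = var_f / (var_f + sigma2_a + sigma2_e) and
    R2_conditional = (var_f + sigma2_a) / (same denominator).
    """
    X = np.asarray(X, dtype=float)
    linpred = X @ draws.beta.T  # (n, ndraw)
    var_f = linpred.var(axis=0, ddof=0)
    denom = var_f + draws.sigma2_a + draws.sigma2_e
    r2m = var_f / denom
    r2c = (var_f + draws.sigma2_a) / denom
    summary = summarize(draws)
    for attr, vals in (("r2_marginal", r2m), ("r2_conditional", r2c)):
        med, lo, hi = _ci(vals)
        setattr(summary, attr, {"median": med, "lo95": lo, "hi95": hi, "draws": vals})
    return summary
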