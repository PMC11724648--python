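"""Gaussian mixture regression (GMR) on a joint (X, Y) space.

A Gaussian mixture is fitted on the concatenation of an input block X
(e.g. generative-model latents) and an output block Y (e.g. logP, QED, SAS).
Because the mixture models the *joint* density p(x, y), regression in either
direction is exact conditioning: the forward model p(y|x) predicts properties
from latents, and the inverse model p(x|y) generates latents directly from
multi-property targets ("direct inverse analysis").  Each conditional is again
a Gaussian mixture whose component means/covariances follow the conditional
multivariate-normal (Schur complement) formulas and whose weights are the
component marginal densities of the query, renormalized.

Both blocks are standardized to zero mean / unit variance before fitting;
all public entry points accept and return raw-scale values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import KFold

from .errors import (
    DegenerateQueryError,
    DimensionError,
    FitError,
    StandardizationError,
    UndefinedMetricError,
)

Block = Literal["on_x", "on_y"]

__all__ = [
    "Standardizer",
    "JointGaussianMixture",
    "ConditionalMixture",
    "RegressionMetrics",
    "fit_joint",
    "condition",
    "point_estimate",
    "predict_forward",
    "inverse_estimate",
    "sample_conditional",
    "swap_blocks",
    "cross_validated_r2",
    "select_hyperparameters",
    "regression_metrics",
]


# ---------------------------------------------------------------------------
# standardization


@dataclass
class Standardizer:
    """Per-column affine transform v -> (v - center) / scale."""

    center: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, data: np.ndarray, names: Sequence[str] | None = None) -> "Standardizer":
        data = np.asarray(data, dtype=float)
        center = data.mean(axis=0)
        scale = data.std(axis=0, ddof=0)
        bad = np.flatnonzero(scale <= 0.0)
        if bad.size:
            j = int(bad[0])
            label = names[j] if names is not None else f"column {j}"
            raise StandardizationError(f"zero-variance column: {label}")
        return cls(center=center, scale=scale)

    def transform(self, v: np.ndarray) -> np.ndarray:
        return (np.asarray(v, dtype=float) - self.center) / self.scale

    def inverse(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, dtype=float) * self.scale + self.center

    def to_dict(self) -> dict:
        return {"center": self.center.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Standardizer":
        return cls(center=np.asarray(d["center"], float), scale=np.asarray(d["scale"], float))


# ---------------------------------------------------------------------------
# model containers


@dataclass
class JointGaussianMixture:
    """A mixture fitted on standardized concatenated (X, Y) data.

    ``block_split = (d_x, d_y)``; X occupies the first ``d_x`` coordinates of
    every mean/covariance.  ``x_standardizer`` / ``y_standardizer`` map raw
    values into the fitted space and back.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    block_split: tuple[int, int]
    x_standardizer: Standardizer
    y_standardizer: Standardizer
    ridge: float = 1e-6
    seed: int = 0

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def d_x(self) -> int:
        return self.block_split[0]

    @property
    def d_y(self) -> int:
        return self.block_split[1]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.means = np.asarray(self.means, float)
        self.covariances = np.asarray(self.covariances, float)
        d_x, d_y = self.block_split
        if d_x < 1 or d_y < 1:
            raise DimensionError("both blocks must have dimension >= 1")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise FitError("mixture weights must sum to 1")
        if (self.weights < 0).any():
            raise FitError("mixture weights must be non-negative")

    def block_indices(self, block: Block) -> np.ndarray:
        d_x, d_y = self.block_split
        if block == "on_x":
            return np.arange(d_x)
        if block == "on_y":
            return np.arange(d_x, d_x + d_y)
        raise ValueError(f"unknown block {block!r}")

    def standardizer(self, block: Block) -> Standardizer:
        return self.x_standardizer if block == "on_x" else self.y_standardizer

    def log_likelihood(self, x: np.ndarray, y: np.ndarray) -> float:
        """Total log-likelihood of raw-scale (x, y) data under the mixture."""
        z = np.column_stack(
            [self.x_standardizer.transform(np.atleast_2d(x)),
             self.y_standardizer.transform(np.atleast_2d(y))]
        )
        comp = np.stack(
            [multivariate_normal.logpdf(z, mean=m, cov=c)
             for m, c in zip(self.means, self.covariances)],
            axis=-1,
        )
        return float(logsumexp(comp + np.log(self.weights), axis=-1).sum())

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format": "gmrdesign.joint_gmm.v1",
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),  # row-major per component
            "block_split": list(self.block_split),
            "x_standardizer": self.x_standardizer.to_dict(),
            "y_standardizer": self.y_standardizer.to_dict(),
            "ridge": self.ridge,
            "seed": self.seed,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "JointGaussianMixture":
        doc = json.loads(text)
        return cls(
            weights=np.asarray(doc["weights"], float),
            means=np.asarray(doc["means"], float),
            covariances=np.asarray(doc["covariances"], float),
            block_split=tuple(doc["block_split"]),
            x_standardizer=Standardizer.from_dict(doc["x_standardizer"]),
            y_standardizer=Standardizer.from_dict(doc["y_standardizer"]),
            ridge=float(doc["ridge"]),
            seed=int(doc["seed"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "JointGaussianMixture":
        return cls.from_json(Path(path).read_text())


@dataclass
class ConditionalMixture:
    """The mixture p(out | in = query), in standardized coordinates.

    ``to_raw`` maps points in the output block back to raw scale.
    """

    conditioned_block: Block
    query: np.ndarray
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    out_standardizer: Standardizer = field(repr=False)

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def to_raw(self, points: np.ndarray) -> np.ndarray:
        return self.out_standardizer.inverse(points)

    def logpdf(self, points: np.ndarray) -> np.ndarray:
        """Conditional log-density at standardized output-block points."""
        pts = np.atleast_2d(np.asarray(points, float))
        comp = np.stack(
            [multivariate_normal.logpdf(pts, mean=m, cov=c, allow_singular=True)
             for m, c in zip(self.means, self.covariances)],
            axis=-1,
        )
        with np.errstate(divide="ignore"):
            logw = np.log(self.weights)
        out = logsumexp(np.atleast_2d(comp) + logw, axis=-1)
        return out if np.ndim(points) > 1 else out[0]


# ---------------------------------------------------------------------------
# fitting


def fit_joint(
    x_matrix: np.ndarray,
    y_matrix: np.ndarray,
    n_components: int,
    seed: int = 0,
    ridge: float = 1e-6,
    n_init: int = 10,
    x_names: Sequence[str] | None = None,
    y_names: Sequence[str] | None = None,
) -> JointGaussianMixture:
    """Fit a full-covariance Gaussian mixture on standardized [X | Y] data.

    EM is initialized with k-means++ under ``seed``; the best of ``n_init``
    restarts (by log-likelihood) is kept.  ``ridge`` is added to covariance
    diagonals for invertibility.
    """
    x = np.asarray(x_matrix, dtype=float)
    y = np.asarray(y_matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if x.shape[0] != y.shape[0]:
        raise DimensionError(f"X has {x.shape[0]} rows but Y has {y.shape[0]}")
    n = x.shape[0]
    if n_components < 1:
        raise FitError("n_components must be >= 1")
    if n < n_components:
        raise FitError(f"cannot fit {n_components} components on {n} samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise FitError("X and Y must be finite with no missing values")
    if ridge < 0:
        raise FitError("ridge must be non-negative")

    x_std = Standardizer.fit(x, x_names)
    y_std = Standardizer.fit(y, y_names)
    z = np.column_stack([x_std.transform(x), y_std.transform(y)])

    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        reg_covar=max(ridge, 1e-10),
        n_init=n_init,
        init_params="k-means++",
        random_state=seed,
        max_iter=500,
    )
    gm.fit(z)

    covs = gm.covariances_.copy()
    covs += ridge * np.eye(covs.shape[-1])
    # renormalize defensively: sklearn weights sum to 1 up to float error
    w = gm.weights_ / gm.weights_.sum()
    model = JointGaussianMixture(
        weights=w,
        means=gm.means_.copy(),
        covariances=covs,
        block_split=(x.shape[1], y.shape[1]),
        x_standardizer=x_std,
        y_standardizer=y_std,
        ridge=ridge,
        seed=seed,
    )
    if not np.isfinite(model.log_likelihood(x, y)):
        raise FitError("training log-likelihood is not finite")
    return model


def swap_blocks(model: JointGaussianMixture) -> JointGaussianMixture:
    """Return the same mixture with the X and Y blocks interchanged.

    Conditioning the swapped model on its X block is identical to conditioning
    the original on its Y block — the X/Y symmetry behind direct inverse
    analysis.
    """
    d_x, d_y = model.block_split
    perm = np.concatenate([np.arange(d_x, d_x + d_y), np.arange(d_x)])
    return JointGaussianMixture(
        weights=model.weights.copy(),
        means=model.means[:, perm],
        covariances=model.covariances[:, perm][:, :, perm],
        block_split=(d_y, d_x),
        x_standardizer=model.y_standardizer,
        y_standardizer=model.x_standardizer,
        ridge=model.ridge,
        seed=model.seed,
    )


# ---------------------------------------------------------------------------
# conditioning


def condition(
    model: JointGaussianMixture, conditioned_block: Block, value: np.ndarray
) -> ConditionalMixture:
    """Condition the joint mixture on one block at a raw-scale value.

    Per component k the conditional is normal with

        m_k = mu_out + S_oi S_ii^{-1} (v - mu_in)
        S_k = S_oo - S_oi S_ii^{-1} S_io

    and the component weight is pi_k times the marginal density of the query
    under component k, renormalized (computed in log space with log-sum-exp).
    The identical code path serves p(y|x) and p(x|y).
    """
    if conditioned_block not in ("on_x", "on_y"):
        raise ValueError(f"conditioned_block must be 'on_x' or 'on_y', got {conditioned_block!r}")
    in_idx = model.block_indices(conditioned_block)
    out_block: Block = "on_y" if conditioned_block == "on_x" else "on_x"
    out_idx = model.block_indices(out_block)

    v_raw = np.asarray(value, dtype=float).ravel()
    if v_raw.shape[0] != in_idx.shape[0]:
        raise DimensionError(
            f"query has dimension {v_raw.shape[0]}, block {conditioned_block} has {in_idx.shape[0]}"
        )
    if not np.isfinite(v_raw).all():
        raise DimensionError("query value must be finite")
    v = model.standardizer(conditioned_block).transform(v_raw)

    K = model.n_components
    d_out = out_idx.shape[0]
    cond_means = np.empty((K, d_out))
    cond_covs = np.empty((K, d_out, d_out))
    log_w = np.empty(K)
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.weights)

    for k in range(K):
        mu = model.means[k]
        cov = model.covariances[k]
        s_ii = cov[np.ix_(in_idx, in_idx)]
        s_oi = cov[np.ix_(out_idx, in_idx)]
        s_oo = cov[np.ix_(out_idx, out_idx)]
        chol = cho_factor(s_ii, lower=True)
        dev = v - mu[in_idx]
        cond_means[k] = mu[out_idx] + s_oi @ cho_solve(chol, dev)
        s_k = s_oo - s_oi @ cho_solve(chol, s_oi.T)
        cond_covs[k] = 0.5 * (s_k + s_k.T)  # exact symmetry
        log_w[k] = log_pi[k] + multivariate_normal.logpdf(v, mean=mu[in_idx], cov=s_ii)

    if not np.isfinite(log_w).any():
        raise DegenerateQueryError(
            "query lies in a region of vanishing density for every component"
        )
    weights = np.exp(log_w - logsumexp(log_w))
    weights /= weights.sum()

    return ConditionalMixture(
        conditioned_block=conditioned_block,
        query=v_raw,
        weights=weights,
        means=cond_means,
        covariances=cond_covs,
        out_standardizer=model.standardizer(out_block),
    )


PointMethod = Literal["highest_weight", "weighted_mean"]


def point_estimate(cmix: ConditionalMixture, method: PointMethod = "weighted_mean") -> np.ndarray:
    """Collapse a conditional mixture to a single vector.

    ``highest_weight`` returns the mean of the heaviest component (ties broken
    by lowest component index, via argmax-first-max); ``weighted_mean`` returns
    the weight-averaged mean.
    """
    if cmix.weights.sum() <= 0:
        raise DegenerateQueryError("all conditional weights are zero")
    if method == "highest_weight":
        return cmix.means[int(np.argmax(cmix.weights))].copy()
    if method == "weighted_mean":
        return cmix.weights @ cmix.means
    raise ValueError(f"unknown point-estimate method {method!r}")


def predict_forward(
    model: JointGaussianMixture, x: np.ndarray, method: PointMethod = "weighted_mean"
) -> np.ndarray:
    """Predict raw-scale properties Y for one latent vector or a batch of rows."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2:
        return np.vstack([predict_forward(model, row, method) for row in arr])
    cmix = condition(model, "on_x", arr)
    return cmix.to_raw(point_estimate(cmix, method))


def inverse_estimate(
    model: JointGaussianMixture, y_target: np.ndarray, method: PointMethod = "weighted_mean"
) -> np.ndarray:
    """Direct inverse analysis: the raw-scale latent X estimated from a target Y."""
    arr = np.asarray(y_target, dtype=float)
    if arr.ndim == 2:
        return np.vstack([inverse_estimate(model, row, method) for row in arr])
    cmix = condition(model, "on_y", arr)
    return cmix.to_raw(point_estimate(cmix, method))


def sample_conditional(cmix: ConditionalMixture, n: int, seed: int = 0) -> np.ndarray:
    """Draw n points from the conditional mixture (standardized coordinates).

    A component index is drawn from the weights, then a Gaussian draw is taken
    from that component.  Use ``cmix.to_raw`` for raw-scale points.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    d = cmix.means.shape[1]
    if n == 0:
        return np.empty((0, d))
    rng = np.random.default_rng(seed)
    ks = rng.choice(cmix.n_components, size=n, p=cmix.weights)
    out = np.empty((n, d))
    for k in np.unique(ks):
        sel = ks == k
        out[sel] = rng.multivariate_normal(
            cmix.means[k], cmix.covariances[k], size=int(sel.sum()), method="eigh"
        )
    return out


# ---------------------------------------------------------------------------
# metrics


@dataclass
class RegressionMetrics:
    """Per-column regression quality: r2, rmse and mae are length-d arrays."""

    r2: np.ndarray
    rmse: np.ndarray
    mae: np.ndarray

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame({"r2": self.r2, "rmse": self.rmse, "mae": self.mae})


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> RegressionMetrics:
    """R^2 (1 - SSres/SStot), RMSE and MAE, computed per output column."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.ndim == 1:
        yt = yt[:, None]
    if yp.ndim == 1:
        yp = yp[:, None]
    if yt.shape != yp.shape:
        raise DimensionError(f"shape mismatch: {yt.shape} vs {yp.shape}")
    if yt.shape[0] < 2:
        raise DimensionError("need at least 2 samples")
    ss_tot = ((yt - yt.mean(axis=0)) ** 2).sum(axis=0)
    zero = np.flatnonzero(ss_tot == 0.0)
    if zero.size:
        raise UndefinedMetricError(f"r2 undefined for zero-variance truth column {int(zero[0])}")
    res = yt - yp
    ss_res = (res**2).sum(axis=0)
    return RegressionMetrics(
        r2=1.0 - ss_res / ss_tot,
        rmse=np.sqrt((res**2).mean(axis=0)),
        mae=np.abs(res).mean(axis=0),
    )


# ---------------------------------------------------------------------------
# hyperparameter selection


def cross_validated_r2(
    x_matrix: np.ndarray,
    y_matrix: np.ndarray,
    n_components: int,
    ridge: float,
    n_folds: int = 5,
    seed: int = 0,
    method: PointMethod = "weighted_mean",
    n_init: int = 10,
) -> float:
    """Mean held-out forward-prediction r2 (averaged over folds and Y columns).

    Deterministic given (data, config, n_folds, seed).  A fold on which the
    mixture cannot be fitted scores the whole configuration as -inf.
    """
    x = np.asarray(x_matrix, float)
    y = np.asarray(y_matrix, float)
    if y.ndim == 1:
        y = y[:, None]
    if x.ndim == 1:
        x = x[:, None]
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = []
    for train, test in kf.split(x):
        try:
            model = fit_joint(x[train], y[train], n_components, seed=seed, ridge=ridge,
                              n_init=n_init)
            pred = predict_forward(model, x[test], method=method)
            m = regression_metrics(y[test], pred)
        except (FitError, StandardizationError, UndefinedMetricError, np.linalg.LinAlgError):
            return float("-inf")
        scores.append(float(m.r2.mean()))
    return float(np.mean(scores))


def _expand_search_space(search_space: Mapping[str, Iterable] | Sequence[tuple] | None):
    if search_space is None:
        search_space = {
            "n_components": range(1, 31),
            "ridge": np.logspace(-8, -3, 6),
        }
    if isinstance(search_space, Mapping):
        ks = [int(k) for k in search_space["n_components"]]
        rs = [float(r) for r in search_space["ridge"]]
        cands = list(product(ks, rs))
    else:
        cands = [(int(k), float(r)) for k, r in search_space]
    if not cands:
        raise ValueError("empty hyperparameter search space")
    return cands


def select_hyperparameters(
    x_matrix: np.ndarray,
    y_matrix: np.ndarray,
    search_space: Mapping[str, Iterable] | Sequence[tuple] | None = None,
    n_folds: int = 5,
    n_trials: int = 30,
    seed: int = 0,
) -> tuple[dict, float]:
    """Pick (n_components, ridge) maximizing cross-validated forward r2.

    Candidates are scored by ``cross_validated_r2``.  When the candidate set
    fits inside ``n_trials`` it is searched exhaustively; otherwise a
    Gaussian-process surrogate with expected improvement proposes candidates
    (Bayesian optimization over the discrete grid).  Returns the best config
    and its cv score, which is recomputable via ``cross_validated_r2`` with
    the same seed.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    cands = _expand_search_space(search_space)

    def objective(cfg: tuple[int, float]) -> float:
        return cross_validated_r2(
            x_matrix, y_matrix, cfg[0], cfg[1], n_folds=n_folds, seed=seed
        )

    scores: dict[int, float] = {}
    if len(cands) <= n_trials:
        for i in range(len(cands)):
            scores[i] = objective(cands[i])
    else:
        rng = np.random.default_rng(seed)
        n_init = min(max(5, n_trials // 4), n_trials)
        init_idx = rng.choice(len(cands), size=n_init, replace=False)
        for i in init_idx:
            scores[int(i)] = objective(cands[int(i)])
        # encode candidates for the surrogate: (K, log10 ridge), min-max scaled
        enc = np.array([[k, np.log10(r)] for k, r in cands], float)
        enc = (enc - enc.min(axis=0)) / np.maximum(np.ptp(enc, axis=0), 1e-12)
        from scipy.stats import norm
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, WhiteKernel

        while len(scores) < n_trials:
            idx = np.array(sorted(scores))
            vals = np.array([scores[i] for i in idx])
            finite = np.isfinite(vals)
            if not finite.any():
                # nothing fit so far: fall back to a random proposal
                remaining = [i for i in range(len(cands)) if i not in scores]
                pick = int(rng.choice(remaining))
                scores[pick] = objective(cands[pick])
                continue
            floor = vals[finite].min() - 1.0
            vals = np.where(finite, vals, floor)
            gp = GaussianProcessRegressor(
                kernel=RBF(length_scale=0.3) + WhiteKernel(noise_level=1e-4),
                normalize_y=True,
                random_state=seed,
            )
            gp.fit(enc[idx], vals)
            remaining = np.array([i for i in range(len(cands)) if i not in scores])
            mu, sd = gp.predict(enc[remaining], return_std=True)
            best = vals.max()
            sd = np.maximum(sd, 1e-12)
            z = (mu - best) / sd
            ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
            pick = int(remaining[int(np.argmax(ei))])
            scores[pick] = objective(cands[pick])

    best_i = max(sorted(scores), key=lambda i: (scores[i], -i))
    k, r = cands[best_i]
    return {"n_components": k, "ridge": r}, scores[best_i]
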