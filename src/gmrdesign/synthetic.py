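"""Synthetic fixtures: ground-truth mixtures, a perfect mock codec, fixture
molecules, and black-box oracles with known optima.

These generators emulate the three ingredients the pipeline needs from the
real world — (a) a joint latent/property distribution with mixture structure
and informative cross-covariance, (b) a decodable latent space with exact
round trip, and (c) a scalar structure-activity oracle (standing in for a
docking-affinity calculation) — so that every module is testable without
training a deep model or running external software.  Everything is fully
determined by (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.stats import qmc

from .chem import canonicalize
from .errors import GmrDesignError
from .generative.codec import DEFAULT_ALPHABET, INVALID

__all__ = [
    "GroundTruthMixture",
    "MockCodec",
    "SyntheticOracle",
    "make_ground_truth",
    "sample_joint",
    "fixture_molecules",
    "make_mock_codec",
    "make_synthetic_oracle",
]


# ---------------------------------------------------------------------------
# ground-truth joint mixtures


@dataclass
class GroundTruthMixture:
    """A known mixture over concatenated (X, Y) space, for recovery tests."""

    weights: np.ndarray
    means: np.ndarray  # K x (d_x + d_y)
    covariances: np.ndarray  # K x d x d
    block_split: tuple[int, int]
    seed: int

    @property
    def n_components(self) -> int:
        return len(self.weights)


def make_ground_truth(
    d_x: int,
    d_y: int,
    n_components: int = 3,
    separation: float = 8.0,
    cross_corr: float = 0.6,
    seed: int = 0,
) -> GroundTruthMixture:
    """Build a mixture whose component means are >= ``separation`` apart and
    whose per-component covariance couples the X and Y blocks with correlation
    magnitude ``cross_corr`` (so conditioning either way is informative).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if not abs(cross_corr) < 1:
        raise GmrDesignError("cross-correlation magnitude must be < 1 for a PSD covariance")
    rng = np.random.default_rng(seed)
    d = d_x + d_y

    # place means on random directions, rescaled until pairwise-separated
    means = np.zeros((n_components, d))
    for k in range(1, n_components):
        while True:
            cand = rng.normal(scale=max(separation, 1.0), size=d)
            if all(np.linalg.norm(cand - means[j]) >= separation for j in range(k)):
                means[k] = cand
                break

    covs = np.empty((n_components, d, d))
    for k in range(n_components):
        cov = np.eye(d)
        # couple x_i with y_(i mod d_y): a banded cross block keeps things PSD
        for i in range(d_x):
            j = d_x + (i % d_y)
            cov[i, j] = cov[j, i] = cross_corr / max(1, int(np.ceil(d_x / d_y)))
        # verify feasibility up front
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise GmrDesignError("requested correlation structure is not positive definite")
        covs[k] = cov

    w = rng.dirichlet(np.full(n_components, 5.0))
    return GroundTruthMixture(
        weights=w, means=means, covariances=covs, block_split=(d_x, d_y), seed=seed
    )


def sample_joint(
    truth: GroundTruthMixture, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (x_matrix, y_matrix, component_labels) from the ground truth."""
    if n < 0:
        raise ValueError("n must be >= 0")
    d_x, d_y = truth.block_split
    if n == 0:
        return np.empty((0, d_x)), np.empty((0, d_y)), np.empty(0, dtype=int)
    rng = np.random.default_rng(seed)
    labels = rng.choice(truth.n_components, size=n, p=truth.weights)
    z = np.empty((n, d_x + d_y))
    for k in np.unique(labels):
        sel = labels == k
        z[sel] = rng.multivariate_normal(
            truth.means[k], truth.covariances[k], size=int(sel.sum()), method="eigh"
        )
    return z[:, :d_x], z[:, d_x:], labels


# ---------------------------------------------------------------------------
# fixture molecules (synthetic stand-in for a curated drug-like set)


def fixture_molecules(n: int = 300, seed: int = 7) -> list[str]:
    """A deterministic set of ``n`` small valid molecules (synthetic fixture).

    Token strings over the validity-guaranteed fragment alphabet are
    enumerated, parsed and deduplicated by canonical SMILES, then subsampled
    under ``seed``.  The returned strings are the token-string forms (all
    tokenizable by the reference codec); they are NOT real drugs — they are
    a synthetic stand-in for a drug-like fixture set.
    """
    seen: set[str] = set()
    pool: list[str] = []
    # lengths 2..4 over the 7-token alphabet: ~2.8k candidates before dedup
    for length in (2, 3, 4):
        for combo in product(DEFAULT_ALPHABET, repeat=length):
            s = "".join(combo)
            try:
                canon = canonicalize(s)
            except GmrDesignError:  # pragma: no cover - alphabet guarantees validity
                continue
            if canon not in seen:
                seen.add(canon)
                pool.append(s)
    if n > len(pool):
        raise ValueError(f"only {len(pool)} distinct fixture molecules available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# mock codec


class MockCodec:
    """A perfect codec: a bijection between molecules and latent anchor points.

    ``encode`` returns the molecule's anchor with zero posterior variance;
    ``decode`` maps any finite latent to the nearest anchor's molecule.  An
    optional failure schedule makes chosen decode calls return the invalid
    sentinel — used by attempt-accounting tests.
    """

    def __init__(
        self,
        molecules: Sequence[str],
        anchors: np.ndarray,
        failure_schedule: Callable[[int], bool] | None = None,
    ):
        self.molecules = list(molecules)
        self.anchors = np.asarray(anchors, float)
        self.latent_dim = self.anchors.shape[1]
        self.failure_schedule = failure_schedule
        self.decode_calls = 0
        self._index = {m: i for i, m in enumerate(self.molecules)}

    def encode(self, molecules: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        rows = []
        for m in molecules:
            if m not in self._index:
                raise GmrDesignError(f"molecule not in mock codebook: {m!r}")
            rows.append(self.anchors[self._index[m]])
        mu = np.asarray(rows).reshape(len(rows), self.latent_dim)
        return mu, np.zeros_like(mu)

    def nearest_anchor(self, latent: np.ndarray) -> int:
        z = np.asarray(latent, float).ravel()
        return int(np.argmin(((self.anchors - z) ** 2).sum(axis=1)))

    def decode(self, latents: np.ndarray) -> list[str]:
        z = np.atleast_2d(np.asarray(latents, float))
        out = []
        for row in z:
            self.decode_calls += 1
            if self.failure_schedule is not None and self.failure_schedule(self.decode_calls):
                out.append(INVALID)
            elif not np.isfinite(row).all():
                out.append(INVALID)
            else:
                out.append(self.molecules[self.nearest_anchor(row)])
        return out


def make_mock_codec(
    molecules: Sequence[str],
    d_x: int = 2,
    placement: Literal["grid", "random"] = "grid",
    seed: int = 0,
    failure_schedule: Callable[[int], bool] | None = None,
) -> MockCodec:
    """Build a MockCodec with distinct anchors for distinct molecules.

    ``grid`` placement uses a scrambled Sobol' low-discrepancy sequence over
    [-3, 3]^d (stable nearest-neighbor cells); ``random`` places anchors
    i.i.d. normal.
    """
    canon = [canonicalize(m) for m in molecules]
    if len(set(canon)) != len(canon):
        raise GmrDesignError("mock codec molecules must be distinct after canonicalization")
    n = len(molecules)
    if placement == "grid":
        sob = qmc.Sobol(d=d_x, scramble=True, seed=seed)
        m = int(np.ceil(np.log2(max(n, 2))))
        anchors = 6.0 * sob.random_base2(m)[:n] - 3.0
    elif placement == "random":
        anchors = np.random.default_rng(seed).normal(size=(n, d_x))
    else:
        raise ValueError(f"unknown placement {placement!r}")
    return MockCodec(molecules, anchors, failure_schedule=failure_schedule)


# ---------------------------------------------------------------------------
# synthetic oracles


class SyntheticOracle:
    """Deterministic black-box score over a mock codec's latent anchors.

    Stands in for an external structure-activity evaluation (e.g. a docking
    run returning kcal/mol): molecule in, scalar out, lower is better, with a
    known optimum for testing optimization loops.
    """

    def __init__(
        self,
        codec: MockCodec,
        fn: Callable[[np.ndarray], float],
        lower_is_better: bool = True,
    ):
        self._codec = codec
        self._fn = fn
        self.lower_is_better = lower_is_better
        self.calls = 0

    def score(self, molecule: str) -> float:
        self.calls += 1
        mu, _ = self._codec.encode([molecule])
        return float(self._fn(mu[0]))


def make_synthetic_oracle(
    kind: Literal["gaussian_well", "quadratic"],
    optimum_location: np.ndarray,
    optimum_value: float = -12.2,
    codec: MockCodec | None = None,
    width: float = 2.0,
    baseline: float = -6.0,
    curvature: float = 1.0,
) -> SyntheticOracle:
    """A smooth score of the molecule's anchor latent, minimized at
    ``optimum_location`` with value ``optimum_value``.

    ``gaussian_well``: baseline - depth * exp(-||z - z*||^2 / (2 width^2));
    ``quadratic``:     optimum_value + curvature * ||z - z*||^2.
    """
    if codec is None:
        raise ValueError("a MockCodec is required")
    opt = np.asarray(optimum_location, float).ravel()
    lo = codec.anchors.min(axis=0)
    hi = codec.anchors.max(axis=0)
    if not ((opt >= lo - 1e-9).all() and (opt <= hi + 1e-9).all()):
        raise GmrDesignError("optimum_location must lie within the codec anchor hull")

    if kind == "gaussian_well":
        depth = baseline - optimum_value
        if depth <= 0:
            raise ValueError("baseline must exceed optimum_value for a well")

        def fn(z: np.ndarray) -> float:
            return baseline - depth * np.exp(
                -((z - opt) ** 2).sum() / (2.0 * width**2)
            )

    elif kind == "quadratic":

        def fn(z: np.ndarray) -> float:
            return optimum_value + curvature * ((z - opt) ** 2).sum()

    else:
        raise ValueError(f"unknown oracle kind {kind!r}")

    return SyntheticOracle(codec, fn, lower_is_better=True)
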