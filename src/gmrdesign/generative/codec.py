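"""Latent molecular codec contract, reference token VAE, and joint training.

``LatentCodec`` is the contract any latent generative model must satisfy to
plug into the GMR pipeline: encode molecules to a Gaussian posterior over a
fixed-dimension latent space, decode latent vectors back to molecule strings.
A hierarchical graph VAE can be wrapped behind this contract; the package
ships ``TokenVaeCodec``, a small feedforward token VAE over a restricted
SMILES fragment alphabet in which *every* token sequence parses to a valid
molecule — validity by construction, mirroring at desk scale the property
that makes graph decoders attractive for inverse design.

Joint training minimizes the negative ELBO (token reconstruction
cross-entropy + KL to the unit-normal prior) plus lambda times the MSE of a
property-prediction head that reads the latent code.  Training the latent
space against properties is what makes downstream mixture regression on it
accurate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from ..errors import DimensionError, GmrDesignError
from .nn import MLP, Adam, softmax_cross_entropy

INVALID = ""  # sentinel for a failed decode

#: fragment alphabet in which any concatenation is a parseable molecule
DEFAULT_ALPHABET: tuple[str, ...] = ("C", "N", "O", "S", "c1ccccc1", "C(C)", "C(=O)")

__all__ = [
    "INVALID",
    "DEFAULT_ALPHABET",
    "LatentCodec",
    "PropertyHead",
    "JointTrainConfig",
    "TokenVaeCodec",
    "tokenize",
    "joint_loss",
    "property_head_forward",
    "train_joint",
    "encode_dataset",
]


def tokenize(smiles: str, alphabet: Sequence[str] = DEFAULT_ALPHABET) -> list[str] | None:
    """Greedy longest-match tokenization; None if any part is outside the alphabet."""
    toks: list[str] = []
    i = 0
    ordered = sorted(alphabet, key=len, reverse=True)
    while i < len(smiles):
        for t in ordered:
            if smiles.startswith(t, i):
                toks.append(t)
                i += len(t)
                break
        else:
            return None
    return toks


@runtime_checkable
class LatentCodec(Protocol):
    """Encoder/decoder contract between molecules and latent vectors."""

    latent_dim: int

    def encode(self, molecules: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Posterior (means, variances), each n x latent_dim."""
        ...

    def decode(self, latents: np.ndarray) -> list[str]:
        """Molecule strings, one per latent row; INVALID marks a failed decode.

        Must not raise on finite input.
        """
        ...


@dataclass
class JointTrainConfig:
    """Training configuration for a codec with a property head.

    Defaults follow the reference full-scale configuration (hidden/embedding width
    250, latent dimension 32, T=15 message-passing steps for graph codecs
    honoring the contract); desk-scale runs pass smaller dims explicitly.
    ``property_loss_weight`` is the lambda multiplying the property MSE on
    top of the negative ELBO.
    """

    hidden_dim: int = 250
    embedding_dim: int = 250
    latent_dim: int = 32
    message_passing_T: int = 15
    property_loss_weight: float = 1.0
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    kl_anneal_epochs: int = 0  # 0 = no annealing
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden_dim, self.embedding_dim, self.latent_dim) < 1:
            raise ValueError("all dimensions must be positive")
        if self.property_loss_weight < 0:
            raise ValueError("property_loss_weight must be >= 0")


class PropertyHead:
    """MLP predicting properties from a latent code.

    Three hidden layers of 67 neurons with ReLU and dropout 0.15 by default.
    ``y_center``/``y_scale`` (set during joint training) map the head's
    standardized outputs back to raw property units; they default to the
    identity.
    """

    def __init__(
        self,
        latent_dim: int,
        n_properties: int,
        hidden: int = 67,
        n_hidden: int = 3,
        dropout: float = 0.15,
        seed: int = 0,
    ):
        sizes = [latent_dim] + [hidden] * n_hidden + [n_properties]
        self.mlp = MLP(sizes, activation="relu", dropout=dropout, seed=seed)
        self.latent_dim = latent_dim
        self.n_properties = n_properties
        self.y_center = np.zeros(n_properties)
        self.y_scale = np.ones(n_properties)

    def forward(
        self, latent: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        z = np.atleast_2d(np.asarray(latent, float))
        if z.shape[1] != self.latent_dim:
            raise DimensionError(
                f"latent has dimension {z.shape[1]}, head expects {self.latent_dim}"
            )
        out = self.mlp.forward(z, training=training, rng=rng)
        return out if np.ndim(latent) > 1 else out[0]

    def predict(self, latent: np.ndarray) -> np.ndarray:
        """Deterministic raw-scale property prediction (dropout off)."""
        return self.forward(latent) * self.y_scale + self.y_center


def property_head_forward(
    head: PropertyHead,
    latent: np.ndarray,
    training_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Head output for one latent or a batch; deterministic when not training."""
    if training_mode and rng is None:
        rng = np.random.default_rng(0)
    return head.forward(latent, training=training_mode, rng=rng)


def joint_loss(
    reconstruction_loss: float,
    kl_divergence: float,
    y_pred: np.ndarray,
    y_true: np.ndarray,
    property_loss_weight: float = 1.0,
) -> float:
    """Negative ELBO plus weighted property MSE (mean over samples and columns)."""
    yp = np.atleast_2d(np.asarray(y_pred, float))
    yt = np.atleast_2d(np.asarray(y_true, float))
    if yp.shape != yt.shape:
        raise DimensionError(f"shape mismatch: {yp.shape} vs {yt.shape}")
    vals = [reconstruction_loss, kl_divergence]
    if not np.isfinite(vals).all() or not (np.isfinite(yp).all() and np.isfinite(yt).all()):
        raise GmrDesignError("joint_loss requires finite inputs")
    mse = float(((yp - yt) ** 2).mean())
    return float(reconstruction_loss + kl_divergence) + property_loss_weight * mse


class TokenVaeCodec:
    """Feedforward one-hot token VAE over a validity-guaranteed alphabet.

    Sequences are padded to ``max_len`` with a PAD symbol; decoding takes the
    argmax token per position and truncates at the first PAD.  Because every
    alphabet concatenation is a valid SMILES, decode output always parses
    (an all-PAD decode falls back to methane).  Molecules whose SMILES cannot
    be tokenized over the alphabet are outside the codec's vocabulary and are
    skipped (and counted) by training and batch encoding.
    """

    def __init__(
        self,
        latent_dim: int = 8,
        hidden_dim: int = 64,
        max_len: int = 8,
        alphabet: Sequence[str] = DEFAULT_ALPHABET,
        seed: int = 0,
    ):
        self.latent_dim = int(latent_dim)
        self.hidden_dim = int(hidden_dim)
        self.max_len = int(max_len)
        self.alphabet = tuple(alphabet)
        self.vocab = self.alphabet + ("<pad>",)
        self.pad_id = len(self.vocab) - 1
        self.seed = int(seed)
        v = len(self.vocab)
        self.encoder = MLP(
            [self.max_len * v, hidden_dim, 2 * self.latent_dim], activation="tanh", seed=seed
        )
        self.decoder = MLP(
            [self.latent_dim, hidden_dim, self.max_len * v], activation="tanh", seed=seed + 1
        )

    # -- tokens -------------------------------------------------------------

    def token_ids(self, smiles: str) -> np.ndarray | None:
        toks = tokenize(smiles, self.alphabet)
        if toks is None or len(toks) > self.max_len:
            return None
        ids = [self.alphabet.index(t) for t in toks]
        ids += [self.pad_id] * (self.max_len - len(ids))
        return np.asarray(ids, dtype=int)

    def _one_hot(self, ids: np.ndarray) -> np.ndarray:
        v = len(self.vocab)
        out = np.zeros((ids.shape[0], self.max_len, v))
        out[np.arange(ids.shape[0])[:, None], np.arange(self.max_len)[None, :], ids] = 1.0
        return out.reshape(ids.shape[0], -1)

    # -- contract -----------------------------------------------------------

    def encode(self, molecules: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        ids = []
        for m in molecules:
            t = self.token_ids(m)
            if t is None:
                raise GmrDesignError(f"molecule outside codec vocabulary: {m!r}")
            ids.append(t)
        if not ids:
            return np.empty((0, self.latent_dim)), np.empty((0, self.latent_dim))
        out = self.encoder.forward(self._one_hot(np.stack(ids)))
        mu, logvar = out[:, : self.latent_dim], out[:, self.latent_dim :]
        return mu, np.exp(logvar)

    def decode(self, latents: np.ndarray) -> list[str]:
        z = np.atleast_2d(np.asarray(latents, float))
        if z.shape[1] != self.latent_dim:
            raise DimensionError(f"latent dim {z.shape[1]} != codec dim {self.latent_dim}")
        result: list[str] = []
        finite = np.isfinite(z).all(axis=1)
        logits = self.decoder.forward(np.where(finite[:, None], z, 0.0))
        v = len(self.vocab)
        ids = logits.reshape(-1, self.max_len, v).argmax(axis=2)
        for row, ok in zip(ids, finite):
            if not ok:
                result.append(INVALID)
                continue
            toks = []
            for i in row:
                if i == self.pad_id:
                    break
                toks.append(self.alphabet[i])
            result.append("".join(toks) if toks else "C")
        return result

    # -- persistence ----------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write a weights blob plus a JSON sidecar (config, vocabulary, seed)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        sidecar = {
            "latent_dim": self.latent_dim,
            "hidden_dim": self.hidden_dim,
            "max_len": self.max_len,
            "alphabet": list(self.alphabet),
            "seed": self.seed,
        }
        (d / "codec.json").write_text(json.dumps(sidecar, indent=2))
        blob = {f"enc.{k}": v for k, v in self.encoder.state().items()}
        blob |= {f"dec.{k}": v for k, v in self.decoder.state().items()}
        np.savez(d / "weights.npz", **blob)

    @classmethod
    def load(cls, directory: str | Path) -> "TokenVaeCodec":
        d = Path(directory)
        sidecar = json.loads((d / "codec.json").read_text())
        codec = cls(
            latent_dim=sidecar["latent_dim"],
            hidden_dim=sidecar["hidden_dim"],
            max_len=sidecar["max_len"],
            alphabet=tuple(sidecar["alphabet"]),
            seed=sidecar["seed"],
        )
        with np.load(d / "weights.npz") as blob:
            codec.encoder.load_state(
                {k[4:]: blob[k] for k in blob.files if k.startswith("enc.")}
            )
            codec.decoder.load_state(
                {k[4:]: blob[k] for k in blob.files if k.startswith("dec.")}
            )
        return codec


def train_joint(
    codec: TokenVaeCodec,
    head: PropertyHead,
    molecules: Sequence[str],
    y_matrix: np.ndarray,
    config: JointTrainConfig,
) -> tuple[TokenVaeCodec, PropertyHead, dict]:
    """Train codec and property head jointly on (negative ELBO + lambda MSE).

    Properties are standardized internally (the scaler is stored on the
    head); history records per-epoch reconstruction, KL, property-MSE and
    total loss plus the config used and the count of skipped molecules.
    """
    y = np.atleast_2d(np.asarray(y_matrix, float))
    if y.shape[0] != len(molecules):
        raise DimensionError(f"{len(molecules)} molecules but {y.shape[0]} property rows")
    if len(molecules) == 0:
        raise GmrDesignError("empty training set")

    ids_list, keep = [], []
    for i, m in enumerate(molecules):
        t = codec.token_ids(m)
        if t is not None:
            ids_list.append(t)
            keep.append(i)
    n_skipped = len(molecules) - len(keep)
    if not keep:
        raise GmrDesignError("no molecule in the training set is tokenizable by the codec")
    ids = np.stack(ids_list)
    y = y[keep]
    n, d_y = y.shape

    y_center = y.mean(axis=0)
    y_scale = np.where(y.std(axis=0) > 0, y.std(axis=0), 1.0)
    y_std = (y - y_center) / y_scale
    head.y_center, head.y_scale = y_center, y_scale

    lam = config.property_loss_weight
    x_onehot = codec._one_hot(ids)
    v = len(codec.vocab)
    L = codec.max_len
    rng = np.random.default_rng(config.seed)
    params = codec.encoder.params() + codec.decoder.params() + head.mlp.params()
    opt = Adam(params, lr=config.learning_rate)

    history = {
        "reconstruction": [],
        "kl": [],
        "property_mse": [],
        "total": [],
        "config": asdict(config),
        "n_skipped": n_skipped,
        "n_used": n,
    }
    bs = min(config.batch_size, n)

    for epoch in range(config.epochs):
        kl_w = 1.0
        if config.kl_anneal_epochs > 0:
            kl_w = min(1.0, (epoch + 1) / config.kl_anneal_epochs)
        order = rng.permutation(n)
        ep = {"recon": 0.0, "kl": 0.0, "prop": 0.0, "nb": 0}
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, tb, yb = x_onehot[idx], ids[idx], y_std[idx]
            B = len(idx)

            enc_out = codec.encoder.forward(xb, training=True, rng=rng)
            mu = enc_out[:, : codec.latent_dim]
            logvar = np.clip(enc_out[:, codec.latent_dim :], -10.0, 10.0)
            eps = rng.standard_normal(mu.shape)
            z = mu + eps * np.exp(0.5 * logvar)

            logits = codec.decoder.forward(z, training=True, rng=rng)
            ce, dflat = softmax_cross_entropy(logits.reshape(B * L, v), tb.ravel())
            recon = ce * L  # sum over positions, mean over batch
            dlogits = (dflat * L).reshape(B, L * v)  # grad of that same quantity

            kl = float(-0.5 * (1 + logvar - mu**2 - np.exp(logvar)).sum(axis=1).mean())

            y_pred = head.mlp.forward(z, training=True, rng=rng)
            prop = float(((y_pred - yb) ** 2).mean())

            grad_z = codec.decoder.backward(dlogits)
            # with lam == 0 this contributes exactly zero to every gradient,
            # so the rng stream and update sequence match the lam > 0 runs
            dyp = lam * 2.0 * (y_pred - yb) / (B * d_y)
            grad_z = grad_z + head.mlp.backward(dyp)

            grad_mu = grad_z + kl_w * mu / B
            grad_logvar = (
                grad_z * eps * 0.5 * np.exp(0.5 * logvar)
                + kl_w * 0.5 * (np.exp(logvar) - 1.0) / B
            )
            codec.encoder.backward(np.concatenate([grad_mu, grad_logvar], axis=1))

            grads = codec.encoder.grads() + codec.decoder.grads() + head.mlp.grads()
            opt.step(grads)

            ep["recon"] += recon
            ep["kl"] += kl
            ep["prop"] += prop
            ep["nb"] += 1

        nb = ep["nb"]
        history["reconstruction"].append(ep["recon"] / nb)
        history["kl"].append(ep["kl"] / nb)
        history["property_mse"].append(ep["prop"] / nb)
        history["total"].append(
            (ep["recon"] + ep["kl"]) / nb + lam * ep["prop"] / nb
        )

    return codec, head, history


def encode_dataset(
    codec: TokenVaeCodec, molecules: Sequence[str]
) -> tuple[np.ndarray, list[int]]:
    """Posterior-mean latents for a molecule list.

    Untokenizable molecules are excluded; the returned index map gives, for
    each latent row, the position of its molecule in the input list.
    """
    keep, ok_molecules = [], []
    for i, m in enumerate(molecules):
        if codec.token_ids(m) is not None:
            keep.append(i)
            ok_molecules.append(m)
    if not ok_molecules:
        return np.empty((0, codec.latent_dim)), []
    mu, _ = codec.encode(ok_molecules)
    return mu, keep
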