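"""Inverse-design pipeline: targets -> latents -> molecules -> metrics.

A multi-property target (e.g. logP fixed at 2.00, QED at the training
maximum, SAS at the training minimum) is resolved against the training
property table, latents are drawn from the conditional p(x | y*) of the
fitted joint mixture, decoded, and the generated set is scored: hit counting
against closed-interval thresholds (1 <= logP <= 3, QED >= 0.8, SAS <= 3.0
in the reference configuration), diversity (mean pairwise Tanimoto distance
of Morgan fingerprints over the hits) and novelty (fraction of generated
molecules absent from the training set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from . import chem
from .errors import GmrDesignError, UndefinedMetricError
from .generative.codec import INVALID, LatentCodec
from .gmr import JointGaussianMixture, condition, sample_conditional

__all__ = [
    "TargetRule",
    "TargetSpec",
    "ThresholdSpec",
    "DesignRunResult",
    "REFERENCE_THRESHOLDS",
    "resolve_targets",
    "generate_for_target",
    "filter_hits",
    "diversity",
    "novelty",
]


@dataclass(frozen=True)
class TargetRule:
    """One property's target: a fixed value, or the dataset max/min."""

    kind: Literal["fixed", "dataset_max", "dataset_min"]
    value: float | None = None

    @classmethod
    def fixed(cls, value: float) -> "TargetRule":
        return cls("fixed", float(value))

    @classmethod
    def dataset_max(cls) -> "TargetRule":
        return cls("dataset_max")

    @classmethod
    def dataset_min(cls) -> "TargetRule":
        return cls("dataset_min")


TargetSpec = Mapping[str, TargetRule]

#: reference threshold window: 1 <= logP <= 3, QED >= 0.8, SAS <= 3
REFERENCE_THRESHOLDS: dict[str, tuple[float, float]] = {
    "logP": (1.0, 3.0),
    "QED": (0.8, math.inf),
    "SAS": (-math.inf, 3.0),
}

ThresholdSpec = Mapping[str, tuple[float, float]]


@dataclass
class DesignRunResult:
    """Outcome of one inverse-generation run for a single target vector."""

    requested_n: int
    attempts: int
    molecules: list[chem.MoleculeRecord]
    hits: list[chem.MoleculeRecord]
    diversity: float | None
    novelty: float | None
    seed: int
    target: dict[str, float]
    truncated: bool = False

    def dedup_molecules(self) -> list[chem.MoleculeRecord]:
        """Reporting view with duplicate canonical SMILES removed (first kept)."""
        seen: set[str] = set()
        out = []
        for r in self.molecules:
            if r.smiles not in seen:
                seen.add(r.smiles)
                out.append(r)
        return out


def resolve_targets(
    spec: TargetSpec,
    training_y: np.ndarray | None = None,
    property_names: Sequence[str] = chem.PROPERTY_NAMES,
) -> np.ndarray:
    """Concrete target vector y* in the order of ``property_names``."""
    y = None if training_y is None else np.atleast_2d(np.asarray(training_y, float))
    out = np.empty(len(property_names))
    for j, name in enumerate(property_names):
        if name not in spec:
            raise GmrDesignError(f"no target rule for property {name!r}")
        rule = spec[name]
        if rule.kind == "fixed":
            out[j] = rule.value
        else:
            if y is None or y.shape[0] == 0:
                raise GmrDesignError(
                    f"target rule {rule.kind} for {name!r} needs non-empty training data"
                )
            col = y[:, j]
            out[j] = col.max() if rule.kind == "dataset_max" else col.min()
    return out


def generate_for_target(
    gmr_model: JointGaussianMixture,
    codec: LatentCodec,
    y_target: np.ndarray,
    requested_n: int = 1000,
    max_attempts: int | None = None,
    seed: int = 0,
    thresholds: ThresholdSpec = REFERENCE_THRESHOLDS,
    training_smiles: Sequence[str] | None = None,
    property_names: Sequence[str] = chem.PROPERTY_NAMES,
    compute_props: bool = True,
) -> DesignRunResult:
    """Generate ``requested_n`` molecules for one multi-property target.

    Latents are sampled from p(x | y*); every decoder invocation counts as
    one attempt; invalid decodes are discarded; duplicates are kept (the
    dedup view lives on the result).  If ``max_attempts`` (default
    500 x requested_n) is exhausted first, a truncated partial result is
    returned rather than an exception.
    """
    if requested_n < 1:
        raise ValueError("requested_n must be >= 1")
    if max_attempts is None:
        max_attempts = 500 * requested_n
    if max_attempts < requested_n:
        raise ValueError("max_attempts must be >= requested_n")

    y_target = np.asarray(y_target, float).ravel()
    cmix = condition(gmr_model, "on_y", y_target)

    records: list[chem.MoleculeRecord] = []
    attempts = 0
    batch_no = 0
    while len(records) < requested_n and attempts < max_attempts:
        n_draw = min(requested_n - len(records), max_attempts - attempts)
        z_std = sample_conditional(cmix, n_draw, seed=seed + batch_no)
        z = cmix.to_raw(z_std)
        decoded = codec.decode(z)
        attempts += len(decoded)
        batch_no += 1
        for s in decoded:
            if s == INVALID:
                continue
            canon = chem.canonicalize(s)
            props: dict[str, float] = {}
            if compute_props:
                props = dict(zip(chem.PROPERTY_NAMES, chem.compute_properties(canon)))
            records.append(
                chem.MoleculeRecord(smiles=canon, properties=props, source="generated")
            )
            if len(records) >= requested_n:
                break

    hits = filter_hits(records, thresholds) if compute_props else []
    div = None
    if len(hits) >= 2:
        div = diversity(hits)
    nov = None
    if training_smiles is not None:
        nov = novelty([r.smiles for r in records], training_smiles)
    return DesignRunResult(
        requested_n=requested_n,
        attempts=attempts,
        molecules=records,
        hits=hits,
        diversity=div,
        novelty=nov,
        seed=seed,
        target=dict(zip(property_names, y_target.tolist())),
        truncated=len(records) < requested_n,
    )


def filter_hits(
    molecules: Sequence[chem.MoleculeRecord], thresholds: ThresholdSpec = REFERENCE_THRESHOLDS
) -> list[chem.MoleculeRecord]:
    """Molecules whose properties fall inside every closed threshold interval."""
    out = []
    for rec in molecules:
        ok = True
        for name, (lo, hi) in thresholds.items():
            if name not in rec.properties:
                raise GmrDesignError(f"molecule {rec.smiles!r} lacks property {name!r}")
            v = rec.properties[name]
            if not (lo <= v <= hi):
                ok = False
                break
        if ok:
            out.append(rec)
    return out


def _fingerprints(records: Sequence[chem.MoleculeRecord]) -> list[np.ndarray]:
    fps = []
    for r in records:
        if r.fingerprint is None:
            r.fingerprint = chem.fingerprint(r.smiles)
        fps.append(r.fingerprint)
    return fps


def diversity(hits: Sequence[chem.MoleculeRecord]) -> float:
    """Mean pairwise Tanimoto distance over all unordered hit pairs."""
    if len(hits) < 2:
        raise UndefinedMetricError("diversity needs at least 2 hits")
    fps = _fingerprints(list(hits))
    total = 0.0
    count = 0
    for i in range(len(fps)):
        for j in range(i + 1, len(fps)):
            total += chem.tanimoto_distance(fps[i], fps[j])
            count += 1
    return total / count


def novelty(generated: Sequence[str], training_smiles: Sequence[str]) -> float:
    """Fraction of generated molecules absent from the training set
    (membership by canonical SMILES equality)."""
    if len(generated) == 0:
        raise UndefinedMetricError("novelty of an empty generated set is undefined")
    train = {chem.canonicalize(s) for s in training_smiles}
    gen = [chem.canonicalize(s) for s in generated]
    return sum(1 for s in gen if s not in train) / len(gen)
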