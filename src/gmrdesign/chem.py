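"""Molecule handling: canonicalization, drug-likeness properties, fingerprints.

Properties follow the conventions of the molecular-design literature:
``logP`` is the Crippen octanol/water partition coefficient, ``QED`` the
quantitative estimate of drug-likeness in [0, 1] (1 = most drug-like), and
``SAS`` the synthetic accessibility score in [1, 10] (1 = easiest to make).
Similarity uses Morgan (circular) fingerprints and the Tanimoto distance.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem, RDConfig, RDLogger
from rdkit.Chem import AllChem, Crippen, QED

from .errors import DimensionError, InvalidMoleculeError

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib synthetic-accessibility scorer)

RDLogger.DisableLog("rdApp.*")

PROPERTY_NAMES = ("logP", "QED", "SAS")

__all__ = [
    "MoleculeRecord",
    "PROPERTY_NAMES",
    "canonicalize",
    "compute_properties",
    "compute_property_table",
    "fingerprint",
    "tanimoto_distance",
    "read_smiles_file",
]


@dataclass
class MoleculeRecord:
    """One molecule with its canonical SMILES, computed properties and origin."""

    smiles: str
    properties: dict[str, float] = field(default_factory=dict)
    fingerprint: np.ndarray | None = None
    source: str = "generated"  # training | generated | oracle_pool


def _parse(smiles_in: str) -> Chem.Mol:
    # strip ALL whitespace: SMILES printed in papers often carry line-wrap spaces
    cleaned = "".join(str(smiles_in).split())
    if not cleaned:
        raise InvalidMoleculeError(smiles_in, "empty string")
    mol = Chem.MolFromSmiles(cleaned)
    if mol is None:
        raise InvalidMoleculeError(smiles_in)
    return mol


def canonicalize(smiles_in: str) -> str:
    """Canonical SMILES of the input (idempotent); whitespace is removed first."""
    return Chem.MolToSmiles(_parse(smiles_in))


def compute_properties(smiles: str) -> tuple[float, float, float]:
    """(logP, QED, SAS) for one molecule; SAS is clamped to [1, 10]."""
    mol = _parse(smiles)
    logp = float(Crippen.MolLogP(mol))
    qed = float(QED.qed(mol))
    sas = float(np.clip(sascorer.calculateScore(mol), 1.0, 10.0))
    return logp, qed, sas


def compute_property_table(smiles_list: Sequence[str]):
    """Property rows (logP, QED, SAS) for a batch, in input order, as a DataFrame."""
    import pandas as pd

    rows = [compute_properties(s) for s in smiles_list]
    return pd.DataFrame(rows, columns=list(PROPERTY_NAMES), index=range(len(rows))).assign(
        smiles=list(smiles_list)
    )[["smiles", *PROPERTY_NAMES]]


def fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Morgan fingerprint as a uint8 0/1 vector of length ``n_bits``."""
    mol = _parse(smiles)
    bv = AllChem.GetMorganFingerprintAsBitVect(mol, radius, nBits=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto_distance(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """1 - |a AND b| / |a OR b| on bit vectors.

    Two all-zero fingerprints are identical empty sets: distance 0.
    """
    a = np.asarray(fp_a).astype(bool)
    b = np.asarray(fp_b).astype(bool)
    if a.shape != b.shape:
        raise DimensionError(f"fingerprint lengths differ: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    inter = int(np.logical_and(a, b).sum())
    return 1.0 - inter / union


def read_smiles_file(path) -> tuple[list[str], int]:
    """Read a .smi-style file (one SMILES per line, optional name after
    whitespace) or a CSV with a ``smiles`` column.

    Returns (smiles list, number of blank lines skipped).
    """
    from pathlib import Path

    text = Path(path).read_text()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    if "," in first and "smiles" in first.lower():
        import pandas as pd

        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        smiles = [str(s) for s in df[cols["smiles"]].tolist()]
        return smiles, 0
    out: list[str] = []
    blank = 0
    for line in text.splitlines():
        token = line.split()
        if not token:
            blank += 1
            continue
        out.append(token[0])
    return out, blank
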