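"""Comparator linear QSPR model: a PBT index from four molecular descriptors.

The index is a multiple-linear-regression surface, index = intercept +
sum(coefficient_i * descriptor_i), thresholded into a binary PBT call.
The shipped default configuration is a synthetic placeholder — descriptor
names drawn from the toolkit's 2-D set with round-number coefficients — so
the module is testable on structure alone; a real parameterization must be
transcribed from its original publication before head-to-head comparisons
carry meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import yaml
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chemprep import MoleculeRecord


@dataclass
class QsprConfig:
    descriptor_names: list[str] = field(
        default_factory=lambda: ["MolLogP", "MolWt", "NumHAcceptors", "NumAromaticRings"]
    )
    coefficients: list[float] = field(default_factory=lambda: [1.0, 0.005, -0.5, 0.5])
    intercept: float = -4.0
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.descriptor_names):
            raise ValueError("need exactly one coefficient per descriptor")

    @classmethod
    def from_yaml(cls, path) -> "QsprConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "descriptor_names": self.descriptor_names,
                    "coefficients": list(self.coefficients),
                    "intercept": self.intercept,
                    "threshold": self.threshold,
                },
                fh,
            )


def _descriptor(mol: Chem.Mol, name: str) -> float:
    fn = getattr(Descriptors, name, None)
    if fn is None:
        raise ValueError(f"unknown descriptor {name!r}")
    value = fn(mol)
    if value != value:  # NaN
        raise ValueError(f"descriptor {name!r} not computable")
    return float(value)


def pbt_index(mol: MoleculeRecord | Chem.Mol | str, cfg: QsprConfig) -> float:
    """index = intercept + sum_i coefficient_i * descriptor_i(mol)."""
    if isinstance(mol, MoleculeRecord):
        mol = mol.smiles_canonical or mol.smiles_raw
    if isinstance(mol, str):
        m = Chem.MolFromSmiles(mol)
        if m is None:
            raise ValueError(f"unparseable SMILES {mol!r}")
    else:
        m = mol
    return cfg.intercept + sum(
        c * _descriptor(m, name) for c, name in zip(cfg.coefficients, cfg.descriptor_names)
    )


def classify_qspr(index: float, threshold: float) -> int:
    """1 (PBT) iff index >= threshold."""
    return int(index >= threshold)


def predict_qspr(records: Sequence[MoleculeRecord], cfg: QsprConfig) -> list[int]:
    return [classify_qspr(pbt_index(r, cfg), cfg.threshold) for r in records]
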