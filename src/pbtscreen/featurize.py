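"""Molecular graph and global-descriptor featurization.

A molecule becomes (i) a directed molecular graph — per-atom and per-bond
feature vectors plus directed-edge incidence maps, the input of the
message-passing network — and (ii) a fixed-length vector of 2-D
physicochemical/topological descriptors capturing global properties that
local message passing can miss (molecular weight, calculated logP, TPSA,
ring counts, connectivity indices, ...).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.ML.Descriptors.MoleculeDescriptors import MolecularDescriptorCalculator

from .chemprep import MoleculeRecord

_ELEMENTS = ["B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"]
_HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
_MAX_DEGREE = 6
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]

ATOM_FDIM = len(_ELEMENTS) + 1 + (_MAX_DEGREE + 1) + 1 + len(_HYBRIDIZATIONS) + 1 + 1 + 1
BOND_FDIM = len(_BOND_TYPES) + 2


@dataclass
class MolGraph:
    """Directed molecular graph.

    Every bond contributes two directed edges; ``rev[e]`` is the index of
    edge e's reverse orientation (an involution), used by the network to
    exclude back-flow of a message along the bond it just traversed.
    """

    atom_features: np.ndarray  # (n_atoms, ATOM_FDIM)
    bond_features: np.ndarray  # (n_edges, BOND_FDIM), per directed edge
    src: np.ndarray            # (n_edges,) source atom of each directed edge
    dst: np.ndarray            # (n_edges,) target atom
    rev: np.ndarray            # (n_edges,) index of the reverse edge

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.src.shape[0]


def _one_hot(value, choices) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def _atom_features(atom: Chem.Atom) -> list[float]:
    feats = _one_hot(atom.GetSymbol(), _ELEMENTS)
    feats += _one_hot(atom.GetDegree(), list(range(_MAX_DEGREE)))
    feats.append(float(atom.GetFormalCharge()))
    feats += _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
    feats.append(float(atom.GetIsAromatic()))
    feats.append(atom.GetMass() / 100.0)
    return feats


def _bond_features(bond: Chem.Bond) -> list[float]:
    feats = _one_hot(bond.GetBondType(), _BOND_TYPES)[:-1]  # 4 types, no "other"
    feats.append(float(bond.GetIsConjugated()))
    feats.append(float(bond.IsInRing()))
    return feats


def mol_to_graph(mol: MoleculeRecord | Chem.Mol | str) -> MolGraph:
    """Build the directed graph of a sanitized molecule."""
    m = _as_mol(mol)
    n = m.GetNumAtoms()
    atom_feats = np.array([_atom_features(a) for a in m.GetAtoms()], dtype=np.float64)
    if n == 0:
        raise ValueError("empty molecule")
    src, dst, bfeats = [], [], []
    for bond in m.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bf = _bond_features(bond)
        src += [u, v]
        dst += [v, u]
        bfeats += [bf, bf]
    n_edges = len(src)
    rev = np.arange(n_edges) ^ 1 if n_edges else np.zeros(0, dtype=int)
    return MolGraph(
        atom_features=atom_feats,
        bond_features=np.array(bfeats, dtype=np.float64).reshape(n_edges, BOND_FDIM),
        src=np.array(src, dtype=np.intp),
        dst=np.array(dst, dtype=np.intp),
        rev=np.asarray(rev, dtype=np.intp),
    )


def _as_mol(mol) -> Chem.Mol:
    if isinstance(mol, MoleculeRecord):
        mol = mol.smiles_canonical or mol.smiles_raw
    if isinstance(mol, str):
        m = Chem.MolFromSmiles(mol)
        if m is None:
            raise ValueError(f"unparseable SMILES {mol!r}")
        return m
    return mol


# ---------------------------------------------------------------------------
# Global descriptors

def default_descriptor_names(n: int = 200) -> list[str]:
    """The toolkit's standard 2-D descriptor list, ordered by name, first n."""
    names = sorted(name for name, _fn in Descriptors.descList)
    return names[:n]


def descriptor_list_hash(names: Sequence[str]) -> str:
    return hashlib.sha256("|".join(names).encode()).hexdigest()[:16]


class DescriptorCalculator:
    """Evaluates an ordered descriptor-name list to fixed-length vectors.

    Non-finite values are replaced by 0 (the affected names are recorded in
    ``last_flagged``); vector length always equals the configured list length.
    """

    def __init__(self, names: Optional[Sequence[str]] = None):
        self.names = list(names) if names is not None else default_descriptor_names()
        if not self.names:
            raise ValueError("descriptor list must be non-empty")
        self._calc = MolecularDescriptorCalculator(self.names)
        self.hash = descriptor_list_hash(self.names)
        self._cache: dict[str, np.ndarray] = {}
        self.last_flagged: list[str] = []

    def __call__(self, mol: MoleculeRecord | Chem.Mol | str) -> np.ndarray:
        m = _as_mol(mol)
        smi = Chem.MolToSmiles(m)
        if smi in self._cache:
            return self._cache[smi].copy()
        values = np.array(self._calc.CalcDescriptors(m), dtype=np.float64)
        bad = ~np.isfinite(values)
        self.last_flagged = [self.names[i] for i in np.flatnonzero(bad)]
        values[bad] = 0.0
        self._cache[smi] = values
        return values.copy()

    def matrix(self, records: Sequence[MoleculeRecord]) -> np.ndarray:
        return np.stack([self(r) for r in records])


@dataclass
class Normalizer:
    """Per-dimension z-scoring with training-set statistics.

    Zero-variance dimensions pass through centered at 0.
    """

    mean: np.ndarray
    std: np.ndarray

    def __call__(self, x: np.ndarray) -> np.ndarray:
        safe_std = np.where(self.std > 0, self.std, 1.0)
        return (x - self.mean) / safe_std


def fit_normalizer(train_matrix: np.ndarray) -> Normalizer:
    X = np.asarray(train_matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training vectors")
    return Normalizer(mean=X.mean(axis=0), std=X.std(axis=0, ddof=0))
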