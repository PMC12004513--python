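"""Synthetic labeled molecule sets with planted PBT structure.

Molecules are built by decorating aromatic scaffolds with substituents at
open aromatic CH positions.  Labels are drawn from a logistic model over
planted structural motifs — halogen count, a tricyclic-scaffold indicator,
and a crude lipophilicity proxy — plus Bernoulli label noise, so that every
downstream stage (splitting, training, applicability domain, enrichment,
rationales) can be validated against known ground truth.

The defaults emulate the study conditions of a compiled PBT dataset:
roughly balanced classes (~50:50), scaffold families with structural
singletons, and hazard labels driven by halogenated aromatics and fused
tricyclic systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemprep import MoleculeRecord

# scaffold name -> (SMILES, is_tricyclic)
SCAFFOLDS: dict[str, tuple[str, bool]] = {
    "benzene": ("c1ccccc1", False),
    "biphenyl": ("c1ccc(-c2ccccc2)cc1", False),
    "naphthalene": ("c1ccc2ccccc2c1", False),
    "anthracene": ("c1ccc2cc3ccccc3cc2c1", True),
    "acridine": ("c1ccc2nc3ccccc3cc2c1", True),
    "pyridine": ("c1ccncc1", False),
}

# substituent name -> SMILES fragment; atom 0 is the attachment point
SUBSTITUENTS: dict[str, str] = {
    "F": "F",
    "Cl": "Cl",
    "Br": "Br",
    "methyl": "C",
    "hydroxyl": "O",
    "carboxyl": "C(=O)O",
    "ethyl": "CC",
    "propyl": "CCC",
    "butyl": "CCCC",
}

HALOGENS = {"F", "Cl", "Br", "I"}

# structurally isolated chemotypes used as designated singletons; all are
# neutral, stereo-free and pairwise dissimilar at the 0.6 Tanimoto level
SINGLETON_LIBRARY: tuple[str, ...] = (
    "CCCCCCCCCCCC",                       # dodecane
    "OCC(O)C(O)C(O)C(O)CO",               # hexitol
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",       # xanthine alkaloid
    "C1C2CC3CC1CC(C2)C3",                 # adamantane
    "CC1(C)C2CCC1(C)C(=O)C2",             # bicyclic ketone
    "C1COCCN1",                           # morpholine
    "CS(=O)CC(C)C",                       # branched sulfoxide
    "CC(C)CC(C)(C)O",                     # branched alcohol
    "O=C1CCCCC1",                         # cyclohexanone
    "CCOC(=O)CC(=O)OCC",                  # malonate diester
    "C1CCC2(CC1)OCCO2",                   # spiro ketal
    "NC(=O)C1CCCN1C",                     # proline amide
    "CCCCOP(=O)(OCCCC)OCCCC",             # trialkyl phosphate
    "CN(C)C(=O)N(C)C",                    # tetramethylurea
    "CC(C)OC(C)C",                        # diisopropyl ether
    "OCC1CCCO1",                          # tetrahydrofurfuryl alcohol
    "CCCCCCCC(=O)OC",                     # methyl octanoate
    "O=S1(=O)CCCC1",                      # sulfolane
    "NCCCCCCN",                           # hexanediamine
    "CC(=O)NC1CCCCC1N",                   # diamine amide
)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic dataset generator.

    label_weights: intercept w0, per-halogen weight, tricyclic-indicator
    weight and per-unit logP-proxy weight of the logistic labeling model
    P(PBT) = sigmoid(w0 + w_hal*nHal + w_tri*I(tricyclic) + w_logp*proxy).
    """

    n_molecules: int = 1000
    scaffold_weights: dict[str, float] = field(
        default_factory=lambda: {name: 1.0 / len(SCAFFOLDS) for name in SCAFFOLDS}
    )
    substituent_weights: dict[str, float] = field(
        default_factory=lambda: {name: 1.0 / len(SUBSTITUENTS) for name in SUBSTITUENTS}
    )
    n_substituent_range: tuple[int, int] = (0, 4)
    label_weights: dict[str, float] = field(
        default_factory=lambda: {
            "w0": -11.8, "w_halogen": 3.6, "w_tricyclic": 4.5, "w_logp": 1.5,
        }
    )
    label_noise: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        for weights in (self.scaffold_weights, self.substituent_weights):
            total = sum(weights.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"probabilities must sum to 1, got {total}")


def logp_proxy(mol: Chem.Mol) -> float:
    """Crude lipophilicity proxy: 0.5*C + 0.5*halogens - (O + N).

    Monotone in carbon/halogen content and penalizing polar heteroatoms;
    gives the global-descriptor channel signal that pure topology lacks.
    """
    n_c = n_hal = n_on = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "C":
            n_c += 1
        elif sym in HALOGENS:
            n_hal += 1
        elif sym in ("O", "N"):
            n_on += 1
    return 0.5 * n_c + 0.5 * n_hal - 1.0 * n_on


def _open_positions(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]


def decorate_scaffold(
    scaffold_smiles: str,
    substituents: Sequence[str],
    rng: np.random.Generator,
    positions: Optional[Sequence[int]] = None,
) -> Chem.Mol:
    """Attach substituent fragments at open aromatic CH positions.

    Raises ValueError when more substituents are requested than open
    positions exist.
    """
    mol = Chem.MolFromSmiles(scaffold_smiles)
    if mol is None:
        raise ValueError(f"bad scaffold SMILES {scaffold_smiles!r}")
    open_pos = _open_positions(mol)
    if len(substituents) > len(open_pos):
        raise ValueError(
            f"{len(substituents)} substituents requested but only "
            f"{len(open_pos)} open aromatic positions"
        )
    if positions is None:
        chosen = list(rng.choice(open_pos, size=len(substituents), replace=False))
    else:
        chosen = list(positions)
    rw = Chem.RWMol(mol)
    for pos, sub_smiles in zip(chosen, substituents):
        frag = Chem.MolFromSmiles(sub_smiles)
        offset = rw.GetNumAtoms()
        rw.InsertMol(frag)
        rw.AddBond(int(pos), offset, Chem.BondType.SINGLE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def _label_probability(weights: dict[str, float], n_hal: int,
                       tricyclic: bool, proxy: float) -> float:
    z = (weights["w0"] + weights["w_halogen"] * n_hal
         + weights["w_tricyclic"] * float(tricyclic)
         + weights["w_logp"] * proxy)
    return float(1.0 / (1.0 + np.exp(-z)))


def generate_dataset(
    cfg: GeneratorConfig,
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Sample decorated scaffolds and logistic-model labels.

    Returns sanitized-equivalent records (already neutral, single-fragment,
    stereo-free canonical SMILES) and a truth table with per-molecule motif
    counts, the planted label probability, the clean label and the emitted
    (possibly noise-flipped) label.
    """
    rng = np.random.default_rng(cfg.seed)
    scaffold_names = sorted(cfg.scaffold_weights)
    scaffold_p = np.array([cfg.scaffold_weights[s] for s in scaffold_names])
    sub_names = sorted(cfg.substituent_weights)
    sub_p = np.array([cfg.substituent_weights[s] for s in sub_names])
    lo, hi = cfg.n_substituent_range

    records: list[MoleculeRecord] = []
    truth_rows: list[dict] = []
    for i in range(cfg.n_molecules):
        for _attempt in range(20):
            scaf = scaffold_names[int(rng.choice(len(scaffold_names), p=scaffold_p))]
            scaf_smiles, tricyclic = SCAFFOLDS[scaf]
            n_sub = int(rng.integers(lo, hi + 1))
            subs = [sub_names[int(j)] for j in rng.choice(len(sub_names), size=n_sub, p=sub_p)]
            try:
                mol = decorate_scaffold(scaf_smiles, [SUBSTITUENTS[s] for s in subs], rng)
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not satisfy substitution request after 20 retries")
        smi = Chem.MolToSmiles(mol)
        n_hal = sum(1 for s in subs if s in ("F", "Cl", "Br"))
        proxy = logp_proxy(mol)
        p = _label_probability(cfg.label_weights, n_hal, tricyclic, proxy)
        label_clean = int(rng.random() < p)
        flip = rng.random() < cfg.label_noise
        label = 1 - label_clean if flip else label_clean
        ident = f"syn{i:05d}"
        records.append(
            MoleculeRecord(id=ident, smiles_raw=smi, smiles_canonical=smi, label=label)
        )
        truth_rows.append({
            "id": ident, "smiles": smi, "scaffold": scaf,
            "n_halogen": n_hal, "tricyclic": tricyclic,
            "logp_proxy": proxy, "p_label": p,
            "label_clean": label_clean, "label": label,
        })
    return records, pd.DataFrame(truth_rows)


@dataclass
class ClusterPlantConfig:
    """Request k scaffold families (size >= 2 each) plus s isolated singletons."""

    n_families: int
    family_size: int
    n_singletons: int
    seed: int = 0


def plant_cluster_structure(
    cfg: ClusterPlantConfig,
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Build a dataset with known cluster structure.

    Each family shares a scaffold plus a fixed substituent core; members
    differ by one small varying substituent, keeping within-family Tanimoto
    similarity high.  Singletons are drawn from a library of unrelated
    chemotypes sharing no scaffold with any family.
    """
    rng = np.random.default_rng(cfg.seed)
    family_scaffolds = sorted(SCAFFOLDS)
    if cfg.n_families > len(family_scaffolds):
        raise ValueError(
            f"{cfg.n_families} families exceed scaffold library size {len(family_scaffolds)}"
        )
    if cfg.n_singletons > len(SINGLETON_LIBRARY):
        raise ValueError(
            f"{cfg.n_singletons} singletons exceed library size {len(SINGLETON_LIBRARY)}"
        )
    # each family = scaffold + a family-specific 2-substituent core at fixed
    # positions; members vary a long-chain substituent (length / terminal
    # group), keeping within-family Tanimoto similarity above ~0.65 while
    # distinct cores keep cross-family similarity low
    family_cores = [
        ["Cl", "Cl"], ["Br", "O"], ["C(=O)O", "C"],
        ["F", "F"], ["Cl", "O"], ["Br", "C"],
    ]
    chain_variants = [
        "CCCCCC", "CCCCCCC", "CCCCCCO", "CCCCCCCC", "CCCCCCCO",
        "CCCCC(C)C", "CCCCCCCCC", "CCCCCCC(C)C",
    ]
    records: list[MoleculeRecord] = []
    rows: list[dict] = []
    for fam in range(cfg.n_families):
        scaf_smiles, _ = SCAFFOLDS[family_scaffolds[fam]]
        core = family_cores[fam % len(family_cores)]
        base = Chem.MolFromSmiles(scaf_smiles)
        open_pos = _open_positions(base)
        pos = open_pos[: len(core) + 1]
        for m in range(cfg.family_size):
            var = chain_variants[m % len(chain_variants)]
            mol = decorate_scaffold(scaf_smiles, core + [var], rng, positions=pos)
            smi = Chem.MolToSmiles(mol)
            ident = f"fam{fam}_{m}"
            records.append(MoleculeRecord(id=ident, smiles_raw=smi, smiles_canonical=smi))
            rows.append({"id": ident, "smiles": smi, "family": fam, "singleton": False})
    chosen = rng.choice(len(SINGLETON_LIBRARY), size=cfg.n_singletons, replace=False)
    for j, lib_i in enumerate(sorted(int(x) for x in chosen)):
        smi_raw = SINGLETON_LIBRARY[lib_i]
        mol = Chem.MolFromSmiles(smi_raw)
        smi = Chem.MolToSmiles(mol)
        ident = f"single{j}"
        records.append(MoleculeRecord(id=ident, smiles_raw=smi, smiles_canonical=smi))
        rows.append({"id": ident, "smiles": smi, "family": -1, "singleton": True})
    return records, pd.DataFrame(rows)


def motif_atoms(mol: Chem.Mol) -> set[int]:
    """Atom indices of planted PBT motifs: halogens with their aromatic
    attachment atoms, and atoms of fused ring systems spanning >= 3 rings."""
    atoms: set[int] = set()
    for atom in mol.GetAtoms():
        if atom.GetSymbol() in HALOGENS:
            atoms.add(atom.GetIdx())
            for nb in atom.GetNeighbors():
                if nb.GetIsAromatic():
                    atoms.add(nb.GetIdx())
    ri = mol.GetRingInfo()
    rings = [set(r) for r in ri.AtomRings()]
    # union fused ring systems
    systems: list[set[int]] = []
    for ring in rings:
        merged = ring
        rest = []
        for sysa in systems:
            if merged & sysa:
                merged = merged | sysa
            else:
                rest.append(sysa)
        systems = rest + [merged]
    for sysa in systems:
        n_rings = sum(1 for r in rings if r <= sysa)
        if n_rings >= 3:
            atoms |= sysa
    return atoms
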