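"""Model rationales: substructures that alone drive a positive prediction.

A Monte-Carlo tree search explores connected subgraphs of a molecule
reachable by deletion moves — removing a peripheral (degree-1, non-ring)
atom, or a whole peripheral ring — so states never contain partial rings
and always remain connected, chemically meaningful fragments.  Each state
small enough (<= max_atoms) is scored by running the extracted fragment
through the trained classifier (open valences are hydrogen-capped; global
descriptors, when the model uses them, are recomputed on the fragment).
The emitted rationale is the highest-scoring visited state with at least
``min_atoms`` atoms and score >= ``prop_delta``; if no state qualifies the
search reports that no explanation could be derived.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, rdBase
from rdkit.Chem import rdFMCS

from .chemprep import MoleculeRecord
from .dmpnn import TrainedModel, forward
from .featurize import DescriptorCalculator, mol_to_graph


@dataclass
class SearchConfig:
    """MCTS parameters (reference defaults: 20 rollouts, fragments of 4-20
    atoms, acceptance score 0.5)."""

    rollout: int = 20
    min_atoms: int = 4
    max_atoms: int = 20
    prop_delta: float = 0.5
    batch_size: int = 500
    c_puct: float = 10.0

    def __post_init__(self) -> None:
        if self.min_atoms > self.max_atoms:
            raise ValueError("min_atoms must be <= max_atoms")
        if not 0.0 < self.prop_delta < 1.0:
            raise ValueError("prop_delta must be in (0, 1)")
        if self.c_puct <= 0:
            raise ValueError("exploration constant must be > 0")


@dataclass
class RationaleRecord:
    parent_id: str
    substructure: str            # canonical SMILES of the fragment
    score: float
    n_atoms: int
    atoms: frozenset = field(default_factory=frozenset)  # parent atom indices


def fragment_from_atoms(mol: Chem.Mol, atoms: frozenset) -> Optional[str]:
    """Canonical SMILES of the subgraph induced by ``atoms``; open valences
    are capped with implicit hydrogens.  None when extraction fails."""
    rw = Chem.RWMol(mol)
    for idx in sorted(set(range(mol.GetNumAtoms())) - set(atoms), reverse=True):
        rw.RemoveAtom(idx)
    frag = rw.GetMol()
    try:
        with rdBase.BlockLogs():
            Chem.SanitizeMol(frag)
    except Exception:
        return None
    smi = Chem.MolToSmiles(frag)
    return smi if smi else None


def _adjacency(mol: Chem.Mol) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {a.GetIdx(): set() for a in mol.GetAtoms()}
    for b in mol.GetBonds():
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        adj[u].add(v)
        adj[v].add(u)
    return adj


def _connected(atoms: frozenset, adj: dict[int, set[int]]) -> bool:
    if not atoms:
        return False
    seen = {next(iter(atoms))}
    stack = list(seen)
    while stack:
        a = stack.pop()
        for nb in adj[a] & atoms:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(atoms)


def legal_deletions(
    mol: Chem.Mol, state: frozenset, adj: Optional[dict[int, set[int]]] = None
) -> list[frozenset]:
    """Child states reachable by one peripheral deletion.

    Moves: (i) remove an atom of in-state degree 1 that belongs to no ring
    of the state (peripheral bond deletion); (ii) remove a whole ring's
    exclusive atoms (those not shared with another in-state ring); fusion
    atoms survive as part of their other ring.  Moves that would disconnect
    or empty the state — e.g. deleting a ring that still carries substituent
    branches — are not offered.
    """
    if adj is None:
        adj = _adjacency(mol)
    rings = [set(r) for r in mol.GetRingInfo().AtomRings() if set(r) <= state]
    ring_atoms = set().union(*rings) if rings else set()
    children: list[frozenset] = []
    seen: set[frozenset] = set()
    for a in state:
        if len(adj[a] & state) == 1 and a not in ring_atoms:
            child = state - {a}
            if child and child not in seen and _connected(child, adj):
                seen.add(child)
                children.append(child)
    for i, ring in enumerate(rings):
        other = set().union(*(r for j, r in enumerate(rings) if j != i)) if len(rings) > 1 else set()
        removable = {a for a in ring if a not in other}
        if not removable:
            continue
        child = frozenset(state - removable)
        if child and child not in seen and _connected(child, adj):
            seen.add(child)
            children.append(child)
    return children


class _Scorer:
    """Scores fragments through the trained model, with caching."""

    def __init__(self, model: TrainedModel):
        self.model = model
        self.calc = None
        if model.config.use_global_descriptors:
            self.calc = DescriptorCalculator(model.descriptor_names)
        self.cache: dict[str, Optional[float]] = {}

    def __call__(self, smiles: Optional[str]) -> Optional[float]:
        if smiles is None:
            return None
        if smiles in self.cache:
            return self.cache[smiles]
        try:
            graph = mol_to_graph(smiles)
            desc = None
            if self.calc is not None:
                desc = self.model.normalizer(self.calc(smiles))
            score = forward(self.model, graph, desc)
        except Exception:
            score = None
        self.cache[smiles] = score
        return score


def extract_rationale(
    model: TrainedModel, mol: MoleculeRecord | str, cfg: Optional[SearchConfig] = None
) -> Optional[RationaleRecord]:
    """MCTS over deletion moves; returns the best qualifying rationale or None."""
    if cfg is None:
        cfg = SearchConfig()
    if isinstance(mol, MoleculeRecord):
        parent_id = mol.id
        smiles = mol.smiles_canonical or mol.smiles_raw
    else:
        parent_id = str(mol)
        smiles = mol
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ValueError(f"unparseable molecule {smiles!r}")
    if m.GetNumAtoms() < cfg.min_atoms:
        return None
    adj = _adjacency(m)
    scorer = _Scorer(model)
    root = frozenset(range(m.GetNumAtoms()))

    visits: dict[frozenset, int] = defaultdict(int)
    total: dict[frozenset, float] = defaultdict(float)
    children_of: dict[frozenset, list[frozenset]] = {}
    state_score: dict[frozenset, Optional[float]] = {}
    best: Optional[tuple[float, frozenset]] = None

    def evaluate(state: frozenset) -> float:
        nonlocal best
        if state in state_score:
            s = state_score[state]
            return s if s is not None else 0.0
        score = scorer(fragment_from_atoms(m, state))
        state_score[state] = score
        if score is not None and len(state) >= cfg.min_atoms:
            if best is None or score > best[0]:
                best = (score, state)
        return score if score is not None else 0.0

    def rollout(state: frozenset) -> float:
        if len(state) <= cfg.max_atoms:
            value = evaluate(state)
        else:
            value = 0.0
        if len(state) <= cfg.min_atoms:
            visits[state] += 1
            total[state] += value
            return value
        if state not in children_of:
            children_of[state] = legal_deletions(m, state, adj)
        kids = children_of[state]
        if not kids:
            visits[state] += 1
            total[state] += value
            return value
        n_parent = max(visits[state], 1)
        def ucb(child):
            q = total[child] / visits[child] if visits[child] else 0.0
            u = cfg.c_puct * np.sqrt(n_parent) / (1 + visits[child])
            return q + u
        chosen = max(kids, key=ucb)
        value = max(value, rollout(chosen))
        visits[state] += 1
        total[state] += value
        return value

    for _ in range(cfg.rollout):
        rollout(root)

    if best is None or best[0] < cfg.prop_delta:
        return None
    score, state = best
    smi = fragment_from_atoms(m, state)
    return RationaleRecord(
        parent_id=parent_id, substructure=smi, score=float(score),
        n_atoms=len(state), atoms=state,
    )


def collect_rationales(
    model: TrainedModel,
    records: Sequence[MoleculeRecord],
    cfg: Optional[SearchConfig] = None,
) -> tuple[list[RationaleRecord], pd.DataFrame]:
    """Rationales for every record plus a canonicalized substructure table
    with per-substructure parent counts and a recurring flag."""
    rationales = []
    for rec in records:
        try:
            r = extract_rationale(model, rec, cfg)
        except ValueError:
            continue
        if r is not None:
            rationales.append(r)
    counts: dict[str, set[str]] = defaultdict(set)
    scores: dict[str, list[float]] = defaultdict(list)
    for r in rationales:
        counts[r.substructure].add(r.parent_id)
        scores[r.substructure].append(r.score)
    rows = [
        {
            "substructure": smi,
            "n_parents": len(parents),
            "recurring": len(parents) > 1,
            "mean_score": float(np.mean(scores[smi])),
        }
        for smi, parents in sorted(counts.items(), key=lambda kv: -len(kv[1]))
    ]
    table = pd.DataFrame(rows, columns=["substructure", "n_parents", "recurring", "mean_score"])
    return rationales, table


def group_mcs(substructures: Sequence[str], min_mcs_atoms: int = 4) -> list[dict]:
    """Greedy agglomeration of substructures sharing a maximum common
    substructure of at least ``min_mcs_atoms`` atoms (element + aromaticity
    matching, ring bonds only to ring bonds)."""
    if not substructures:
        return []
    mols = []
    for smi in substructures:
        m = Chem.MolFromSmiles(smi)
        if m is None:
            raise ValueError(f"bad substructure SMILES {smi!r}")
        mols.append(m)

    def mcs_atoms(ms) -> tuple[int, str]:
        res = rdFMCS.FindMCS(
            ms,
            atomCompare=rdFMCS.AtomCompare.CompareElements,
            bondCompare=rdFMCS.BondCompare.CompareOrderExact,
            ringMatchesRingOnly=True,
            timeout=10,
        )
        return res.numAtoms, res.smartsString

    n = len(mols)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            na, _ = mcs_atoms([mols[i], mols[j]])
            if na >= min_mcs_atoms:
                parent[find(j)] = find(i)
    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(i)
    out = []
    for members in groups.values():
        entry = {"members": [substructures[i] for i in members], "mcs": None}
        if len(members) > 1:
            _, smarts = mcs_atoms([mols[i] for i in members])
            entry["mcs"] = smarts
        out.append(entry)
    return out


def substructure_counts(
    substructure: str,
    records: Sequence[MoleculeRecord],
    label_source: str = "experimental",
    threshold: float = 0.5,
):
    """Enrichment-mode contingency counts for one substructure query.

    a = matching molecules in the PBT class, b = total PBT, c = total
    matching, d = total; the PBT class comes from experimental labels or
    thresholded predictions.
    """
    from .evalkit import EnrichmentTable

    query = Chem.MolFromSmiles(substructure)
    if query is None:
        raise ValueError(f"invalid substructure query {substructure!r}")
    a = b = c = 0
    d = len(records)
    for rec in records:
        if label_source == "experimental":
            is_pbt = rec.label == 1
        elif label_source == "predicted":
            if rec.prediction is None:
                raise ValueError(f"record {rec.id!r} has no prediction")
            is_pbt = rec.prediction >= threshold
        else:
            raise ValueError(f"unknown label source {label_source!r}")
        m = Chem.MolFromSmiles(rec.smiles_canonical or rec.smiles_raw)
        match = m is not None and m.HasSubstructMatch(query)
        b += is_pbt
        c += match
        a += is_pbt and match
    return EnrichmentTable(a=int(a), b=int(b), c=int(c), d=int(d))
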