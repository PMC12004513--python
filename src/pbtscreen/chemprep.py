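"""Molecule standardization for PBT classification datasets.

The sanitization pipeline mirrors common regulatory-dataset curation: keep the
largest fragment of multi-component SMILES (the component assumed responsible
for the hazard label), neutralize formal charges where chemically possible,
strip stereochemistry, canonicalize, and deduplicate on canonical SMILES.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from rdkit import Chem


class SanitizationError(ValueError):
    """Raised when a SMILES string cannot be parsed or standardized."""


@dataclass
class MoleculeRecord:
    """One compound with its raw and standardized structure.

    label is 1 for PBT (persistent, bioaccumulative, toxic), 0 for non-PBT,
    or None when unlabeled.  prediction, when present, is a probability of
    PBT membership in [0, 1].
    """

    id: str
    smiles_raw: str
    smiles_canonical: Optional[str] = None
    label: Optional[int] = None
    prediction: Optional[float] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the fragment with the most heavy atoms.

    Ties are broken by choosing the fragment with the lexicographically
    smallest canonical SMILES, which is deterministic and independent of
    fragment order in the input string.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]
    keyed = []
    for f in frags:
        f2 = Chem.Mol(f)
        try:
            Chem.SanitizeMol(f2)
            smi = Chem.MolToSmiles(f2)
        except Exception:
            smi = Chem.MolToSmiles(f, canonical=False)
        keyed.append((-f.GetNumHeavyAtoms(), smi, f))
    keyed.sort(key=lambda t: (t[0], t[1]))
    return keyed[0][2]


def _neutralize(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Zero formal charges by adding/removing hydrogens where valence allows.

    Returns the (possibly modified) molecule and True when residual charges
    remain (e.g. quaternary ammonium), which callers should flag rather than
    reject: a blanket no-charges rule cannot hold for permanent cations.
    """
    mol = Chem.RWMol(mol)
    for atom in mol.GetAtoms():
        q = atom.GetFormalCharge()
        if q == 0:
            continue
        hs = atom.GetTotalNumHs()
        if q > 0 and hs >= q:
            # protonated heteroatom: remove q protons
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(max(hs - q, 0))
            atom.SetNoImplicit(True)
        elif q < 0:
            # deprotonated site: add back |q| protons
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(hs - q)
            atom.SetNoImplicit(True)
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:  # pragma: no cover - defensive
        raise SanitizationError(f"neutralization broke valence: {exc}") from exc
    residual = any(a.GetFormalCharge() != 0 for a in out.GetAtoms())
    return out, residual


def sanitize_record(raw: MoleculeRecord) -> MoleculeRecord:
    """Standardize one record: largest fragment, neutral, stereo-free, canonical.

    Raises SanitizationError for unparseable SMILES.  Records whose charges
    cannot be neutralized without breaking valence keep the charge and carry
    a ``"residual_charge"`` flag.
    """
    if not raw.smiles_raw or not raw.smiles_raw.strip():
        raise SanitizationError(f"record {raw.id!r}: empty SMILES")
    mol = Chem.MolFromSmiles(raw.smiles_raw)
    if mol is None:
        raise SanitizationError(f"record {raw.id!r}: unparseable SMILES {raw.smiles_raw!r}")
    mol = _largest_fragment(mol)
    Chem.SanitizeMol(mol)
    mol, residual = _neutralize(mol)
    Chem.RemoveStereochemistry(mol)
    smi = Chem.MolToSmiles(mol)
    flags = tuple(raw.flags)
    if residual and "residual_charge" not in flags:
        flags = flags + ("residual_charge",)
    return replace(raw, smiles_canonical=smi, flags=flags)


def sanitize_dataset(
    records: Iterable[MoleculeRecord],
) -> tuple[list[MoleculeRecord], dict]:
    """Sanitize every record; unparseable ones are dropped and reported."""
    out: list[MoleculeRecord] = []
    rejected: list[dict] = []
    flagged: list[str] = []
    for rec in records:
        try:
            clean = sanitize_record(rec)
        except SanitizationError as exc:
            rejected.append({"id": rec.id, "reason": str(exc)})
            continue
        if "residual_charge" in clean.flags:
            flagged.append(clean.id)
        out.append(clean)
    report = {"n_in": len(out) + len(rejected), "n_out": len(out),
              "rejected": rejected, "residual_charge_ids": flagged}
    return out, report


def deduplicate(
    records: Sequence[MoleculeRecord],
) -> tuple[list[MoleculeRecord], dict]:
    """One record per canonical SMILES, first occurrence kept.

    The report lists removed ids and any canonical-SMILES groups whose
    members carried conflicting labels (kept label = first occurrence's).
    """
    seen: dict[str, MoleculeRecord] = {}
    labels: dict[str, set] = {}
    removed: list[str] = []
    for rec in records:
        key = rec.smiles_canonical
        if key is None:
            raise ValueError(f"record {rec.id!r} not sanitized (no canonical SMILES)")
        if key not in seen:
            seen[key] = rec
            labels[key] = set()
        else:
            removed.append(rec.id)
        if rec.label is not None:
            labels[key].add(rec.label)
    conflicts = [
        {"smiles": key, "labels": sorted(v), "kept_id": seen[key].id}
        for key, v in labels.items()
        if len(v) > 1
    ]
    report = {"n_removed": len(removed), "removed_ids": removed,
              "label_conflicts": conflicts}
    return list(seen.values()), report


# ---------------------------------------------------------------------------
# I/O

def load_dataset(
    path,
    format: str = "csv",
    *,
    id_col: str = "id",
    smiles_col: str = "smiles",
    label_col: str = "label",
) -> list[MoleculeRecord]:
    """Read records from CSV (header row) or .smi (SMILES<TAB>id)."""
    if format not in ("csv", "smi"):
        raise ValueError(f"unknown format {format!r}")
    records: list[MoleculeRecord] = []
    if format == "smi":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t")
                smi = parts[0]
                ident = parts[1] if len(parts) > 1 else f"mol{i}"
                records.append(MoleculeRecord(id=ident, smiles_raw=smi))
        if not records:
            raise ValueError(f"{path}: empty file")
        return records
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        for col in (id_col, smiles_col):
            if col not in reader.fieldnames:
                raise ValueError(f"{path}: missing mandatory column {col!r}")
        has_label = label_col in reader.fieldnames
        has_canon = "smiles_canonical" in reader.fieldnames
        for row in reader:
            label = None
            if has_label and row[label_col] not in (None, "", "NA"):
                label = int(float(row[label_col]))
            canon = row["smiles_canonical"] if has_canon and row.get("smiles_canonical") else None
            records.append(
                MoleculeRecord(id=row[id_col], smiles_raw=row[smiles_col],
                               smiles_canonical=canon, label=label)
            )
    if not records:
        raise ValueError(f"{path}: no data rows")
    return records


def write_dataset(records: Sequence[MoleculeRecord], path, format: str = "csv") -> None:
    """Write records; CSV output includes canonical SMILES and flags columns."""
    if format == "smi":
        with open(path, "w") as fh:
            for rec in records:
                fh.write(f"{rec.smiles_canonical or rec.smiles_raw}\t{rec.id}\n")
        return
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "smiles_canonical", "label", "prediction", "flags"])
        for rec in records:
            writer.writerow([
                rec.id,
                rec.smiles_raw,
                rec.smiles_canonical or "",
                "" if rec.label is None else rec.label,
                "" if rec.prediction is None else rec.prediction,
                ";".join(rec.flags),
            ])
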