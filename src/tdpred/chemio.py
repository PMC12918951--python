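"""Molecule parsing, standardization, dataset I/O and the molecular-graph data model.

Every downstream stage (fingerprints, descriptors, graph featurization for the
message-passing encoder) consumes molecules that went through :func:`standardize`,
which applies a fixed six-step cleanup: explicit-hydrogen removal, metal
disconnection, functional-group normalization, largest-organic-fragment
selection, charge neutralization and tautomer canonicalization.  The procedure
is deterministic and idempotent; molecules that cannot be parsed or
standardized are reported as rejects rather than silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

TARGET_SEPARATOR = ";"


class RejectedRecordError(ValueError):
    """A molecule could not be parsed or standardized.

    Carries the offending record id (when known) and a human-readable reason.
    """

    def __init__(self, record_id: str | None, reason: str):
        self.record_id = record_id
        self.reason = reason
        super().__init__(f"{record_id or '<unknown>'}: {reason}")


class ConfigurationError(ValueError):
    """Malformed input file or configuration (e.g. a missing mandatory column)."""


class ValidationError(ValueError):
    """Inconsistent data (e.g. duplicate compound ids)."""


@dataclass
class CompoundRecord:
    """One compound: id, raw/standardized SMILES, optional label, target annotations.

    ``label`` is 1 for compounds reported to reduce TDP-43 aggregation
    ("active"), 0 for inactives, and ``None`` for unlabeled screening
    libraries.  ``targets`` is an order-insensitive set of biological-target
    annotation identifiers; duplicates within one row collapse.
    """

    id: str
    smiles_raw: str
    smiles_std: str = ""
    label: int | None = None
    targets: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(f"label must be 0/1, got {self.label!r} for {self.id}")
        self.targets = frozenset(self.targets)


@dataclass(frozen=True)
class AtomInfo:
    element: str
    formal_charge: int
    aromatic: bool
    degree: int          # heavy-atom degree
    in_ring: bool
    num_hs: int          # total attached hydrogens


@dataclass(frozen=True)
class BondInfo:
    i: int
    j: int
    order: float         # 1.0 / 2.0 / 3.0 / 1.5 for aromatic
    aromatic: bool
    in_ring: bool
    conjugated: bool


@dataclass
class MolecularGraph:
    """Undirected simple graph over heavy atoms, attribute-complete.

    Atom order follows the SMILES atom order of the standardized string, so a
    graph rebuilt from ``smiles`` is identical (not merely isomorphic).
    """

    smiles: str
    atoms: list[AtomInfo]
    bonds: list[BondInfo]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == idx:
                out.append(b.j)
            elif b.j == idx:
                out.append(b.i)
        return out

    def to_json(self) -> str:
        return json.dumps({
            "smiles": self.smiles,
            "atoms": [vars(a) for a in self.atoms],
            "bonds": [vars(b) for b in self.bonds],
        })

    @classmethod
    def from_json(cls, payload: str) -> "MolecularGraph":
        d = json.loads(payload)
        return cls(
            smiles=d["smiles"],
            atoms=[AtomInfo(**a) for a in d["atoms"]],
            bonds=[BondInfo(**b) for b in d["bonds"]],
        )


# A single aromaticity model is fixed package-wide (RDKit's default perception);
# descriptor and fingerprint values depend on it, so it is recorded in run manifests.
AROMATICITY_MODEL = "rdkit-default"

_metal_disconnector = rdMolStandardize.MetalDisconnector()
_normalizer = rdMolStandardize.Normalizer()
_fragment_chooser = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_uncharger = rdMolStandardize.Uncharger()
_tautomer_canonicalizer = rdMolStandardize.TautomerEnumerator()


def standardize(smiles_raw: str, record_id: str | None = None) -> str:
    """Standardize a SMILES string and return its canonical form.

    Steps, in order: explicit-H removal, metal disconnection, normalization
    rules, largest-organic-fragment selection, charge neutralization, tautomer
    canonicalization.  Idempotent: ``standardize(standardize(s)) == standardize(s)``.

    Raises
    ------
    RejectedRecordError
        If the SMILES cannot be parsed, violates valence rules, or no organic
        fragment survives fragment selection.
    """
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise RejectedRecordError(record_id, f"unparseable SMILES {smiles_raw!r}")
    try:
        mol = Chem.RemoveHs(mol)
        mol = _metal_disconnector.Disconnect(mol)
        mol = _normalizer.normalize(mol)
        mol = _fragment_chooser.choose(mol)
        mol = _uncharger.uncharge(mol)
        mol = _tautomer_canonicalizer.Canonicalize(mol)
    except Exception as exc:  # rdkit raises bare Exceptions for sanitization issues
        raise RejectedRecordError(record_id, f"standardization failed: {exc}") from exc
    if mol is None or mol.GetNumAtoms() == 0:
        raise RejectedRecordError(record_id, "no atoms after standardization")
    return Chem.MolToSmiles(mol)


def _parse_targets(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(t.strip() for t in text.split(TARGET_SEPARATOR) if t.strip())


def read_dataset(path: str | Path) -> tuple[list[CompoundRecord], list[dict]]:
    """Read a delimited compound table and standardize every row.

    The file must have columns ``id`` and ``smiles``; ``label`` and ``targets``
    (a ``;``-separated identifier list) are optional.  Delimiter is
    autodetected from the extension (``.tsv`` -> tab, otherwise comma).

    Returns ``(records, rejects)`` where ``rejects`` is a list of dicts
    (id, smiles, reason) for rows that failed standardization.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str})
    for col in ("id", "smiles"):
        if col not in df.columns:
            raise ConfigurationError(f"missing mandatory column {col!r} in {path}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate ids in {path}: {dups[:5]}")
    records: list[CompoundRecord] = []
    rejects: list[dict] = []
    has_label = "label" in df.columns
    has_targets = "targets" in df.columns
    for row in df.itertuples(index=False):
        rid = str(row.id)
        smi = str(row.smiles)
        label = None
        if has_label and not pd.isna(row.label):
            label = int(row.label)
        targets = _parse_targets(row.targets) if has_targets else frozenset()
        try:
            smiles_std = standardize(smi, record_id=rid)
        except RejectedRecordError as exc:
            rejects.append({"id": rid, "smiles": smi, "reason": exc.reason})
            continue
        records.append(CompoundRecord(id=rid, smiles_raw=smi, smiles_std=smiles_std,
                                      label=label, targets=targets))
    return records, rejects


def read_sdf(path: str | Path) -> tuple[list[CompoundRecord], list[dict]]:
    """Read an SDF file; the molecule title (or ``_Name``) becomes the record id."""
    records, rejects = [], []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path), sanitize=True)):
        rid = None
        if mol is not None and mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            rid = mol.GetProp("_Name").strip()
        rid = rid or f"sdf-{i}"
        if mol is None:
            rejects.append({"id": rid, "smiles": "", "reason": "unreadable SDF record"})
            continue
        smi = Chem.MolToSmiles(mol)
        try:
            smiles_std = standardize(smi, record_id=rid)
        except RejectedRecordError as exc:
            rejects.append({"id": rid, "smiles": smi, "reason": exc.reason})
            continue
        records.append(CompoundRecord(id=rid, smiles_raw=smi, smiles_std=smiles_std))
    return records, rejects


def write_dataset(records: Sequence[CompoundRecord], path: str | Path) -> None:
    """Write records to the standard dataset CSV (id, smiles, label, targets)."""
    rows = []
    for r in records:
        rows.append({
            "id": r.id,
            "smiles": r.smiles_std or r.smiles_raw,
            "label": "" if r.label is None else r.label,
            "targets": TARGET_SEPARATOR.join(sorted(r.targets)),
        })
    pd.DataFrame(rows, columns=["id", "smiles", "label", "targets"]).to_csv(path, index=False)


def write_rejects(rejects: Sequence[dict], path: str | Path) -> None:
    pd.DataFrame(list(rejects), columns=["id", "smiles", "reason"]).to_csv(path, index=False)


def deduplicate(records: Sequence[CompoundRecord],
                reference: Sequence[CompoundRecord] | None = None) -> list[CompoundRecord]:
    """Drop duplicate standardized SMILES, keeping first occurrence.

    When ``reference`` is given (e.g. the training set while cleaning a
    screening library), any record whose standardized SMILES occurs in the
    reference is removed as well.
    """
    ref_smiles = {r.smiles_std for r in reference} if reference else set()
    seen: set[str] = set()
    out = []
    for r in records:
        if r.smiles_std in ref_smiles or r.smiles_std in seen:
            continue
        seen.add(r.smiles_std)
        out.append(r)
    return out


def mol_from_standardized(smiles_std: str, record_id: str | None = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles_std)
    if mol is None:
        raise RejectedRecordError(record_id, f"unparseable SMILES {smiles_std!r}")
    return mol


def to_graph(smiles_std: str, record_id: str | None = None) -> MolecularGraph:
    """Convert a standardized SMILES into the shared molecular-graph model.

    Atom order follows the canonical SMILES atom order (i.e. parse order of
    the input string); hydrogens are implicit and counted per atom.
    """
    mol = mol_from_standardized(smiles_std, record_id)
    atoms = [AtomInfo(element=a.GetSymbol(),
                      formal_charge=a.GetFormalCharge(),
                      aromatic=a.GetIsAromatic(),
                      degree=a.GetDegree(),
                      in_ring=a.IsInRing(),
                      num_hs=a.GetTotalNumHs())
             for a in mol.GetAtoms()]
    bonds = [BondInfo(i=b.GetBeginAtomIdx(), j=b.GetEndAtomIdx(),
                      order=b.GetBondTypeAsDouble(),
                      aromatic=b.GetIsAromatic(),
                      in_ring=b.IsInRing(),
                      conjugated=b.GetIsConjugated())
             for b in mol.GetBonds()]
    return MolecularGraph(smiles=smiles_std, atoms=atoms, bonds=bonds)


def standardize_records(records: Iterable[CompoundRecord]) -> tuple[list[CompoundRecord], list[dict]]:
    """Standardize in-memory records (used by the synthetic generator and CLI)."""
    out, rejects = [], []
    for r in records:
        try:
            smiles_std = standardize(r.smiles_raw, record_id=r.id)
        except RejectedRecordError as exc:
            rejects.append({"id": r.id, "smiles": r.smiles_raw, "reason": exc.reason})
            continue
        out.append(CompoundRecord(id=r.id, smiles_raw=r.smiles_raw, smiles_std=smiles_std,
                                  label=r.label, targets=r.targets))
    return out, rejects
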