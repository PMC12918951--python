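"""Non-GNN feature families and family-tagged feature matrices.

Three feature families are computed here: global physicochemical /
topological descriptors (via RDKit's descriptor list), folded circular
fingerprints (:mod:`tdpred.fingerprints`), and binary biological-target
annotations.  The fourth family (GNN) is produced by :mod:`tdpred.dmpnn` and
joined through :func:`assemble`.

Descriptor columns are min–max scaled to [0, 1]; the scaler is fitted on
training rows only and clips out-of-range query rows, so screening compounds
that exceed the training ranges stay inside the unit interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chemio import CompoundRecord, RejectedRecordError, mol_from_standardized
from .fingerprints import compute_ecfp


class Family(str, Enum):
    GNN = "GNN"
    DESCRIPTOR = "DESCRIPTOR"
    TARGET = "TARGET"
    FINGERPRINT = "FINGERPRINT"


@dataclass(frozen=True)
class FeatureMeta:
    name: str
    family: Family


@dataclass
class FeatureMatrix:
    """Rows = compounds, columns = named features, each tagged with a family."""

    ids: list[str]
    metas: list[FeatureMeta]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.ids), len(self.metas)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape}, "
                f"{len(self.ids)} ids x {len(self.metas)} columns")
        names = [m.name for m in self.metas]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.metas]

    @property
    def families(self) -> list[Family]:
        return [m.family for m in self.metas]

    def column_indices(self, names: Sequence[str]) -> list[int]:
        pos = {m.name: i for i, m in enumerate(self.metas)}
        return [pos[n] for n in names]

    def select_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = self.column_indices(names)
        return FeatureMatrix(list(self.ids), [self.metas[i] for i in idx],
                             self.values[:, idx])

    def select_rows(self, ids: Sequence[str]) -> "FeatureMatrix":
        pos = {rid: i for i, rid in enumerate(self.ids)}
        idx = [pos[r] for r in ids]
        return FeatureMatrix(list(ids), list(self.metas), self.values[idx])

    def family_columns(self, family: Family) -> list[str]:
        return [m.name for m in self.metas if m.family == family]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.names)

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.csv`` plus a ``<prefix>.meta.json`` family sidecar."""
        prefix = Path(prefix)
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(prefix.with_suffix(".csv"))
        meta = [{"name": m.name, "family": m.family.value} for m in self.metas]
        prefix.with_suffix(".meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, prefix: str | Path) -> "FeatureMatrix":
        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".csv"), index_col="id")
        meta = json.loads(prefix.with_suffix(".meta.json").read_text())
        metas = [FeatureMeta(m["name"], Family(m["family"])) for m in meta]
        return cls([str(i) for i in df.index], metas, df.to_numpy())


# ---------------------------------------------------------------------------
# descriptors

# Names whose presence the interpretability analyses rely on.
REQUIRED_DESCRIPTORS = ("MolLogP", "TPSA", "ExactMolWt", "qed",
                        "EState_VSA8", "SMR_VSA9")

DescriptorProvider = Callable[[Chem.Mol], dict[str, float]]


def _rdkit_descriptor_provider(mol: Chem.Mol) -> dict[str, float]:
    return Descriptors.CalcMolDescriptors(mol)


def descriptor_names(provider: DescriptorProvider | None = None) -> list[str]:
    """Frozen manifest of descriptor names for the current provider."""
    provider = provider or _rdkit_descriptor_provider
    return sorted(provider(Chem.MolFromSmiles("CCO")).keys())


@lru_cache(maxsize=100_000)
def _default_descriptor_row(smiles_std: str) -> tuple[tuple[str, float], ...]:
    mol = mol_from_standardized(smiles_std)
    return tuple((k, float(v)) for k, v in _rdkit_descriptor_provider(mol).items())


def compute_descriptors(smiles_std: str, record_id: str | None = None,
                        provider: DescriptorProvider | None = None) -> dict[str, float]:
    """Deterministic vector of named physicochemical/topological descriptors.

    Values for the default provider are cached per standardized SMILES (they
    are pure functions of the molecule).  Raises
    :class:`RejectedRecordError` when any descriptor evaluates to a non-finite
    value for the molecule.
    """
    if provider is None:
        vals = dict(_default_descriptor_row(smiles_std))
    else:
        mol = mol_from_standardized(smiles_std, record_id)
        vals = {k: float(v) for k, v in provider(mol).items()}
    bad = [k for k, v in vals.items() if not np.isfinite(v)]
    if bad:
        raise RejectedRecordError(record_id, f"non-finite descriptors: {bad[:3]}")
    return vals


def descriptor_matrix(records: Sequence[CompoundRecord],
                      provider: DescriptorProvider | None = None) -> FeatureMatrix:
    names = descriptor_names(provider)
    missing = [n for n in REQUIRED_DESCRIPTORS if n not in names]
    if missing:
        raise ValueError(f"descriptor provider lacks required names: {missing}")
    rows = np.empty((len(records), len(names)))
    for i, r in enumerate(records):
        vals = compute_descriptors(r.smiles_std, r.id, provider)
        rows[i] = [vals[n] for n in names]
    metas = [FeatureMeta(n, Family.DESCRIPTOR) for n in names]
    return FeatureMatrix([r.id for r in records], metas, rows)


# ---------------------------------------------------------------------------
# min-max scaling with clipping

@dataclass
class ScalerState:
    """Per-column min/max observed on the fitting rows; transform clips to [0,1]."""

    names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, matrix: FeatureMatrix, columns: Sequence[str] | None = None) -> "ScalerState":
        columns = list(columns) if columns is not None else matrix.family_columns(Family.DESCRIPTOR)
        idx = matrix.column_indices(columns)
        vals = matrix.values[:, idx]
        return cls(columns, vals.min(axis=0), vals.max(axis=0))

    def transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        """Scale the fitted columns to [0,1] in place-order; other columns untouched.

        Constant columns map to 0; out-of-range values are clipped.
        """
        out = matrix.values.copy()
        idx = matrix.column_indices(self.names)
        span = self.maxs - self.mins
        safe = np.where(span > 0, span, 1.0)
        scaled = (out[:, idx] - self.mins) / safe
        scaled[:, span == 0] = 0.0
        out[:, idx] = np.clip(scaled, 0.0, 1.0)
        return FeatureMatrix(list(matrix.ids), list(matrix.metas), out)

    def to_dict(self) -> dict:
        return {"names": self.names, "mins": self.mins.tolist(), "maxs": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerState":
        return cls(list(d["names"]), np.asarray(d["mins"], float), np.asarray(d["maxs"], float))


# ---------------------------------------------------------------------------
# fingerprints and targets

def fingerprint_matrix(records: Sequence[CompoundRecord], radius: int = 2,
                       nbits: int = 2048) -> FeatureMatrix:
    rows = np.zeros((len(records), nbits))
    for i, r in enumerate(records):
        rows[i] = compute_ecfp(r.smiles_std, radius=radius, nbits=nbits)
    metas = [FeatureMeta(f"ECFP_{b}", Family.FINGERPRINT) for b in range(nbits)]
    return FeatureMatrix([r.id for r in records], metas, rows)


def build_target_vocabulary(records: Sequence[CompoundRecord]) -> list[str]:
    """Ordered target-annotation vocabulary; build on training rows only."""
    vocab: set[str] = set()
    for r in records:
        vocab |= r.targets
    return sorted(vocab)


def encode_targets(records: Sequence[CompoundRecord], vocabulary: Sequence[str]) -> FeatureMatrix:
    """Binary matrix: entry (i, j) = 1 iff compound i carries annotation j.

    Annotations absent from the (train-defined) vocabulary are ignored;
    compounds without annotations get all-zero rows.
    """
    pos = {t: j for j, t in enumerate(vocabulary)}
    rows = np.zeros((len(records), len(vocabulary)))
    for i, r in enumerate(records):
        for t in r.targets:
            j = pos.get(t)
            if j is not None:
                rows[i, j] = 1.0
    metas = [FeatureMeta(f"TARGET_{t}", Family.TARGET) for t in vocabulary]
    return FeatureMatrix([r.id for r in records], metas, rows)


def assemble(parts: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of matrices with identical rows.

    Family tags are preserved; feature-name collisions and row-id mismatches
    raise ``ValueError``.
    """
    if not parts:
        raise ValueError("no parts to assemble")
    first = parts[0]
    for p in parts[1:]:
        if p.ids != first.ids:
            raise ValueError("row ids (or their order) differ between parts")
    if len(parts) == 1:
        return first
    metas = [m for p in parts for m in p.metas]
    values = np.concatenate([p.values for p in parts], axis=1)
    return FeatureMatrix(list(first.ids), metas, values)
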