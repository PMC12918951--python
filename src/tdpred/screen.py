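"""Virtual screening: score an external library and apply the filter cascade.

Candidates are kept when they pass, in order: predicted activity probability
strictly above the threshold (default 0.8), zero violations of Lipinski's Rule
of Five, zero PAINS alerts, at most one Brenk alert, annotated blood–brain-
barrier permeability, and no prior testing against TDP-43 aggregation.  The
last two criteria are consumed as annotation columns (the original analysis
used an external ADME web service; here they are inputs).  Novelty versus the
training actives is reported as the maximum Tanimoto similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from .chemio import CompoundRecord, mol_from_standardized
from .fingerprints import bulk_tanimoto
from .model import ModelBundle


# ---------------------------------------------------------------------------
# rule-of-five

def lipinski_violations(smiles_std: str) -> int:
    """Count of violated Rule-of-Five conditions (0-4).

    Conditions: MW > 500, logP > 5 (atom-contribution estimate), H-bond
    donors > 5 (N-H/O-H count), H-bond acceptors > 10 (N+O count) — the
    classic N/O heuristic.
    """
    mol = mol_from_standardized(smiles_std)
    violations = 0
    if Descriptors.MolWt(mol) > 500:
        violations += 1
    if Crippen.MolLogP(mol) > 5:
        violations += 1
    if Lipinski.NHOHCount(mol) > 5:
        violations += 1
    if Lipinski.NOCount(mol) > 10:
        violations += 1
    return violations


# ---------------------------------------------------------------------------
# structural alerts

class SmartsCatalog:
    """A named set of SMARTS patterns for structural alerts."""

    def __init__(self, name: str, patterns: Sequence[tuple[str, str]]):
        self.name = name
        self.patterns: list[tuple[str, Chem.Mol]] = []
        for pname, smarts in patterns:
            q = Chem.MolFromSmarts(smarts)
            if q is None:
                raise ValueError(f"malformed SMARTS for pattern {pname!r} in catalog {name!r}")
            self.patterns.append((pname, q))

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "SmartsCatalog":
        """Load a plain-text catalog: one ``name<TAB>smarts`` pair per line
        (lines starting with ``#`` are comments)."""
        path = Path(path)
        patterns = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",", 1)
            if len(parts) != 2:
                raise ValueError(f"malformed catalog line in {path}: {line!r}")
            patterns.append((parts[0].strip(), parts[1].strip()))
        return cls(name or path.stem, patterns)

    def match(self, smiles_std: str) -> list[str]:
        """Names of catalog patterns with at least one substructure match."""
        mol = mol_from_standardized(smiles_std)
        return [pname for pname, q in self.patterns if mol.HasSubstructMatch(q)]

    def count(self, smiles_std: str) -> int:
        return len(self.match(smiles_std))


class _FilterCatalogAlerts:
    """Structural alerts backed by the toolkit's curated catalogs (PAINS, Brenk)."""

    _CATALOGS = {
        "pains": FilterCatalogParams.FilterCatalogs.PAINS,
        "brenk": FilterCatalogParams.FilterCatalogs.BRENK,
    }

    def __init__(self, name: str):
        params = FilterCatalogParams()
        params.AddCatalog(self._CATALOGS[name.lower()])
        self.name = name.lower()
        self._catalog = FilterCatalog(params)

    def match(self, smiles_std: str) -> list[str]:
        mol = mol_from_standardized(smiles_std)
        return [e.GetDescription() for e in self._catalog.GetMatches(mol)]

    def count(self, smiles_std: str) -> int:
        return len(self.match(smiles_std))


def builtin_catalog(name: str):
    """The curated PAINS or Brenk alert catalog."""
    return _FilterCatalogAlerts(name)


def structural_alerts(smiles_std: str, catalog) -> tuple[int, list[str]]:
    """Number of catalog patterns matching the molecule, with their names."""
    names = catalog.match(smiles_std)
    return len(names), names


# ---------------------------------------------------------------------------
# novelty

def novelty(candidate_fp: np.ndarray, training_active_fps: np.ndarray) -> float:
    """Maximum Tanimoto similarity of a candidate to the training actives."""
    mat = np.asarray(training_active_fps)
    if mat.size == 0:
        raise ValueError("empty reference set of training actives")
    return float(bulk_tanimoto(candidate_fp, mat).max())


# ---------------------------------------------------------------------------
# cascade

@dataclass
class ScreenConfig:
    threshold: float = 0.8
    max_brenk: int = 1
    bbb_column: str = "bbb_permeable"
    prior_column: str = "prior_tdp43"


@dataclass
class ScreenReport:
    """Per-compound filter outcomes plus per-stage survivor counts."""

    table: pd.DataFrame
    stage_counts: list[tuple[str, int]] = field(default_factory=list)

    def survivors(self) -> list[str]:
        return self.table.loc[self.table["verdict"], "id"].tolist()

    def save(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def predict_library(bundle: ModelBundle, library: Sequence[CompoundRecord],
                    ) -> tuple[np.ndarray, list[CompoundRecord], list[dict]]:
    """Score a standardized, deduplicated library with the trained bundle.

    Compounds that fail featurization are routed to the rejects list, not
    scored.  Returns (probabilities, scored records, rejects).
    """
    scored, rejects = [], []
    for r in library:
        try:
            bundle.pipeline.transform([r])
            scored.append(r)
        except Exception as exc:
            rejects.append({"id": r.id, "smiles": r.smiles_std, "reason": str(exc)})
    probs = bundle.predict_proba(scored) if scored else np.zeros(0)
    return probs, scored, rejects


def filter_cascade(probabilities: Sequence[float], records: Sequence[CompoundRecord],
                   annotations: pd.DataFrame | None = None,
                   config: ScreenConfig | None = None,
                   pains=None, brenk=None) -> ScreenReport:
    """Apply the sequential screening filters and report per-stage survivors.

    ``annotations`` is indexed by compound id and may carry the BBB
    permeability and prior-testing columns; a missing column skips that
    criterion with a prominent warning.  Catalogs default to the curated
    PAINS/Brenk sets.
    """
    config = config or ScreenConfig()
    pains = pains or builtin_catalog("pains")
    brenk = brenk or builtin_catalog("brenk")
    probs = np.asarray(probabilities, dtype=float)
    if len(probs) != len(records):
        raise ValueError("probabilities and records differ in length")

    ann = annotations if annotations is not None else pd.DataFrame(index=[r.id for r in records])
    have_bbb = config.bbb_column in ann.columns
    have_prior = config.prior_column in ann.columns
    if not have_bbb:
        warnings.warn(f"annotation column {config.bbb_column!r} missing: "
                      "the blood-brain-barrier criterion is SKIPPED")
    if not have_prior:
        warnings.warn(f"annotation column {config.prior_column!r} missing: "
                      "the prior-testing criterion is SKIPPED")

    rows = []
    for p, r in zip(probs, records):
        lip = lipinski_violations(r.smiles_std)
        n_pains, pains_names = structural_alerts(r.smiles_std, pains)
        n_brenk, brenk_names = structural_alerts(r.smiles_std, brenk)
        pass_prob = bool(p > config.threshold)
        pass_lip = lip == 0
        pass_pains = n_pains == 0
        pass_brenk = n_brenk <= config.max_brenk
        pass_bbb = bool(ann.loc[r.id, config.bbb_column]) if have_bbb else True
        pass_prior = (not bool(ann.loc[r.id, config.prior_column])) if have_prior else True
        rows.append({
            "id": r.id, "smiles": r.smiles_std, "probability": float(p),
            "pass_probability": pass_prob,
            "lipinski_violations": lip, "pass_lipinski": pass_lip,
            "pains_alerts": n_pains, "pass_pains": pass_pains,
            "pains_names": ";".join(pains_names),
            "brenk_alerts": n_brenk, "pass_brenk": pass_brenk,
            "brenk_names": ";".join(brenk_names),
            "pass_bbb": pass_bbb, "pass_prior": pass_prior,
            "verdict": (pass_prob and pass_lip and pass_pains and pass_brenk
                        and pass_bbb and pass_prior),
        })
    table = pd.DataFrame(rows)
    stages = [("probability", "pass_probability"), ("lipinski", "pass_lipinski"),
              ("pains", "pass_pains"), ("brenk", "pass_brenk"),
              ("bbb", "pass_bbb"), ("prior_testing", "pass_prior")]
    counts = []
    alive = pd.Series(True, index=table.index)
    for name, col in stages:
        alive = alive & table[col]
        counts.append((name, int(alive.sum())))
    return ScreenReport(table=table, stage_counts=counts)
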