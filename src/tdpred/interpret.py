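"""Post-hoc interpretability for the hybrid model.

Three complementary views:

* exact tree-conditional Shapley attributions of the gradient-boosted
  classifier (:mod:`tdpred.treeshap`), ranked by mean |value| and exported in
  a beeswarm-ready long format;
* Pearson correlation between top-ranked target annotations and descriptors,
  to check that the two families carry complementary information;
* Monte-Carlo-tree-search "rationales": connected substructures of a molecule
  that keep the trained message-passing network's predicted activity high,
  found by deleting peripheral atoms or pendant rings from the full molecule.

Plus a 2-D t-SNE chemical-space map of circular fingerprints for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.manifold import TSNE

from .chemio import standardize, to_graph
from .dmpnn import MPNNModel, build_directed_graph
from .featurize import Family, FeatureMatrix
from .model import FittedModel
from .treeshap import TreeEnsemble, shapley_values

# ---------------------------------------------------------------------------
# Shapley attributions

@dataclass
class Attribution:
    """Per-compound, per-feature Shapley values in margin space."""

    ids: list[str]
    feature_names: list[str]
    families: list[Family]
    values: np.ndarray          # (n_rows, n_features)
    base_value: float
    feature_values: np.ndarray  # the underlying feature matrix, for beeswarms

    def margin(self, row: int) -> float:
        return self.base_value + float(self.values[row].sum())


def shapley_attributions(fitted: FittedModel, matrix: FeatureMatrix) -> Attribution:
    """Exact path-dependent Shapley values for every row of ``matrix``.

    Columns must match the fitted model's training columns.
    """
    if matrix.names != fitted.feature_names:
        raise ValueError("feature columns do not match the fitted model")
    ens = TreeEnsemble.from_xgboost(fitted.estimator)
    phi, base = shapley_values(ens, matrix.values)
    return Attribution(ids=list(matrix.ids), feature_names=list(matrix.names),
                       families=list(matrix.families), values=phi, base_value=base,
                       feature_values=matrix.values.copy())


def rank_features(attr: Attribution, top_k: int = 30) -> pd.DataFrame:
    """Features ordered by mean |Shapley value| with family tags.

    Returns one row per feature: name, family, mean_abs_shap, rank.
    """
    mean_abs = np.abs(attr.values).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")[:top_k]
    return pd.DataFrame({
        "feature": [attr.feature_names[j] for j in order],
        "family": [attr.families[j].value for j in order],
        "mean_abs_shap": mean_abs[order],
        "rank": np.arange(1, len(order) + 1),
    })


def beeswarm_table(attr: Attribution, features: Sequence[str]) -> pd.DataFrame:
    """Long table (compound, feature, shap_value, feature_value) for plotting."""
    idx = [attr.feature_names.index(f) for f in features]
    rows = []
    for r, rid in enumerate(attr.ids):
        for j in idx:
            rows.append((rid, attr.feature_names[j], attr.values[r, j],
                         attr.feature_values[r, j]))
    return pd.DataFrame(rows, columns=["id", "feature", "shap_value", "feature_value"])


def target_descriptor_correlation(matrix: FeatureMatrix,
                                  target_names: Sequence[str] | None = None,
                                  descriptor_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Pearson r for each (target, descriptor) pair among the supplied lists.

    Constant columns yield r = 0 and are flagged in the ``constant`` columns.
    """
    targets = list(target_names) if target_names is not None else matrix.family_columns(Family.TARGET)
    descs = list(descriptor_names) if descriptor_names is not None else matrix.family_columns(Family.DESCRIPTOR)
    if not targets or not descs:
        raise ValueError("matrix must contain both TARGET and DESCRIPTOR families")
    X = matrix.values
    pos = {n: j for j, n in enumerate(matrix.names)}
    rows = []
    for t in targets:
        xt = X[:, pos[t]]
        for d in descs:
            xd = X[:, pos[d]]
            const = xt.std() == 0 or xd.std() == 0
            r = 0.0 if const else float(np.corrcoef(xt, xd)[0, 1])
            rows.append((t, d, r, const))
    return pd.DataFrame(rows, columns=["target", "descriptor", "pearson_r", "constant"])


# ---------------------------------------------------------------------------
# MCTS rationales

@dataclass
class Rationale:
    """A connected substructure associated with high predicted activity."""

    parent_id: str
    atom_indices: tuple[int, ...]
    smiles: str
    score: float      # predicted activity probability of the fragment
    visits: int


def _connected(atoms: frozenset[int], adjacency: dict[int, set[int]]) -> bool:
    if not atoms:
        return False
    start = next(iter(atoms))
    seen = {start}
    stack = [start]
    while stack:
        a = stack.pop()
        for b in adjacency[a] & atoms:
            if b not in seen:
                seen.add(b)
                stack.append(b)
    return len(seen) == len(atoms)


def _fragment_smiles(mol: Chem.Mol, atoms: frozenset[int]) -> str | None:
    """Induced-subgraph molecule with valences patched by implicit hydrogens."""
    rw = Chem.RWMol(mol)
    for idx in sorted(set(range(mol.GetNumAtoms())) - atoms, reverse=True):
        rw.RemoveAtom(idx)
    try:
        frag = rw.GetMol()
        Chem.SanitizeMol(frag)
        return standardize(Chem.MolToSmiles(frag))
    except Exception:
        return None


def _actions(mol: Chem.Mol, atoms: frozenset[int],
             adjacency: dict[int, set[int]]) -> list[frozenset[int]]:
    """Child states: delete one peripheral (non-ring) atom or one pendant ring."""
    rings = [frozenset(r) for r in mol.GetRingInfo().AtomRings()]
    in_ring_here = set()
    for ring in rings:
        if ring <= atoms:
            in_ring_here |= ring
    children = []
    for a in sorted(atoms):
        if a in in_ring_here:
            continue
        cand = atoms - {a}
        if cand and _connected(cand, adjacency):
            children.append(cand)
    for ring in rings:
        if not ring <= atoms:
            continue
        shared = {a for a in ring
                  for other in rings
                  if other is not ring and other <= atoms and a in other}
        removable = ring - shared
        if not removable:
            continue
        cand = atoms - removable
        if cand and _connected(cand, adjacency):
            children.append(cand)
    # de-duplicate while preserving order
    seen, uniq = set(), []
    for c in children:
        if c not in seen:
            seen.add(c)
            uniq.append(c)
    return uniq


class _MCTSNode:
    __slots__ = ("atoms", "children", "visits", "total", "prior")

    def __init__(self, atoms: frozenset[int], prior: float):
        self.atoms = atoms
        self.children: list["_MCTSNode"] | None = None
        self.visits = 0
        self.total = 0.0
        self.prior = prior


def mcts_rationale(model: MPNNModel, smiles_std: str, parent_id: str = "",
                   min_atoms: int = 8, max_atoms: int = 20, n_rollouts: int = 500,
                   c_explore: float = 10.0, seed: int = 0, top_k: int = 3,
                   ) -> list[Rationale]:
    """Search connected subgraphs that keep the encoder's activity score high.

    The root is the whole molecule; actions delete a peripheral atom or a
    pendant ring while preserving connectivity.  Leaf reward is the predicted
    activity probability of the fragment (valences patched with implicit
    hydrogens, fragment re-standardized before scoring).  Selection follows a
    prior-weighted upper-confidence rule with exploration constant
    ``c_explore``.  Returns the highest-scoring visited states within
    [min_atoms, max_atoms]; empty (with a warning) for molecules smaller than
    ``min_atoms``.
    """
    mol = Chem.MolFromSmiles(smiles_std)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles_std!r}")
    n = mol.GetNumAtoms()
    if n < min_atoms:
        warnings.warn(f"molecule {parent_id or smiles_std} has fewer than "
                      f"{min_atoms} heavy atoms; no rationale extracted")
        return []
    if n_rollouts <= 0:
        return []
    adjacency = {a.GetIdx(): {b.GetIdx() for b in a.GetNeighbors()} for a in mol.GetAtoms()}

    score_cache: dict[frozenset[int], float] = {}
    smiles_cache: dict[frozenset[int], str | None] = {}

    def score(atoms: frozenset[int]) -> float:
        if atoms in score_cache:
            return score_cache[atoms]
        smi = _fragment_smiles(mol, atoms)
        smiles_cache[atoms] = smi
        val = 0.0
        if smi is not None:
            g = build_directed_graph([to_graph(smi)])
            val = float(model.predict_proba(g)[0])
        score_cache[atoms] = val
        return val

    root = _MCTSNode(frozenset(range(n)), prior=score(frozenset(range(n))))
    node_index: dict[frozenset[int], _MCTSNode] = {root.atoms: root}

    def expand(node: _MCTSNode) -> None:
        if node.children is not None:
            return
        kids = []
        if len(node.atoms) > min_atoms:
            for cand in _actions(mol, node.atoms, adjacency):
                if len(cand) < min_atoms:
                    continue
                child = node_index.get(cand)
                if child is None:
                    child = _MCTSNode(cand, prior=score(cand))
                    node_index[cand] = child
                kids.append(child)
        node.children = kids

    for _ in range(n_rollouts):
        path = [root]
        node = root
        while True:
            expand(node)
            if not node.children:
                break
            nv = node.visits
            best, best_u = None, -np.inf
            for ch in node.children:
                q = ch.total / ch.visits if ch.visits else 0.0
                u = q + c_explore * ch.prior * np.sqrt(nv + 1e-9) / (1 + ch.visits)
                if u > best_u + 1e-12:
                    best, best_u = ch, u
            node = best
            path.append(node)
            if node.visits == 0:
                break
        reward = score(node.atoms)
        for nd in path:
            nd.visits += 1
            nd.total += reward

    candidates = [nd for nd in node_index.values()
                  if min_atoms <= len(nd.atoms) <= max_atoms
                  and smiles_cache.get(nd.atoms)]
    candidates.sort(key=lambda nd: (-score_cache[nd.atoms], sorted(nd.atoms)))
    out = []
    for nd in candidates[:top_k]:
        out.append(Rationale(parent_id=parent_id, atom_indices=tuple(sorted(nd.atoms)),
                             smiles=smiles_cache[nd.atoms], score=score_cache[nd.atoms],
                             visits=nd.visits))
    return out


# ---------------------------------------------------------------------------
# chemical-space map

def chemical_space_map(fingerprints: np.ndarray, ids: Sequence[str],
                       tags: Sequence[str] | None = None, perplexity: float = 50,
                       max_iter: int = 1200, learning_rate: float = 200,
                       init: str = "pca", seed: int = 0) -> pd.DataFrame:
    """2-D t-SNE embedding of fingerprint rows; returns (id, x, y, tag).

    Perplexity is auto-reduced with a warning when there are fewer than
    3 x perplexity rows.
    """
    X = np.asarray(fingerprints, dtype=float)
    n = len(X)
    if n < 3 * perplexity:
        new_p = max(2.0, (n - 1) / 3)
        warnings.warn(f"perplexity reduced from {perplexity} to {new_p:.1f} for n={n}")
        perplexity = new_p
    ts = TSNE(n_components=2, perplexity=perplexity, max_iter=max_iter,
              learning_rate=learning_rate, init=init, random_state=seed)
    coords = ts.fit_transform(X)
    return pd.DataFrame({
        "id": list(ids), "x": coords[:, 0], "y": coords[:, 1],
        "tag": list(tags) if tags is not None else [""] * n,
    })
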