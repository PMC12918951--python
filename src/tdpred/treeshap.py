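"""Exact tree-conditional Shapley attributions for gradient-boosted trees.

Implements the polynomial-time path-dependent tree-traversal algorithm: for
each decision path the proportions of training mass (node covers recorded by
the booster) falling left/right weight the conditional expectations, and the
Shapley weights over feature subsets are maintained incrementally along the
path (EXTEND/UNWIND recursions).  Attributions satisfy local accuracy,

    base_value + sum_i phi_i = margin(x),

for every scored row, which the test suite checks at 1e-6 together with
equivalence against a brute-force subset-enumeration oracle on small
ensembles.  The booster's trees are read from its JSON dump with cover
statistics, so no third-party explainer is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["TreeEnsemble", "shapley_values", "expected_value"]


@dataclass
class _Node:
    feature: int          # -1 for leaves
    threshold: float
    yes: "_Node | None"   # taken when x[feature] < threshold
    no: "_Node | None"
    value: float          # leaf value
    cover: float


def _parse_node(d: dict) -> _Node:
    if "leaf" in d:
        return _Node(-1, 0.0, None, None, float(d["leaf"]), float(d.get("cover", 1.0)))
    feat = d["split"]
    idx = int(feat[1:]) if isinstance(feat, str) and feat.startswith("f") else int(feat)
    kids = {c["nodeid"]: c for c in d["children"]}
    # the booster compares in single precision; keep thresholds float32
    return _Node(idx, float(np.float32(d["split_condition"])),
                 _parse_node(kids[d["yes"]]), _parse_node(kids[d["no"]]),
                 0.0, float(d.get("cover", 1.0)))


class TreeEnsemble:
    """Parsed additive tree ensemble (binary-logistic margin space)."""

    def __init__(self, trees: list[_Node], base_margin: float = 0.0):
        self.trees = trees
        self.base_margin = base_margin

    @classmethod
    def from_xgboost(cls, clf) -> "TreeEnsemble":
        booster = clf.get_booster() if hasattr(clf, "get_booster") else clf
        dump = booster.get_dump(with_stats=True, dump_format="json")
        trees = [_parse_node(json.loads(t)) for t in dump]
        cfg = json.loads(booster.save_config())
        base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
        base_margin = float(np.log(base_score / (1.0 - base_score)))
        return cls(trees, base_margin)

    def margin(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=np.float32)
        total = self.base_margin
        for t in self.trees:
            node = t
            while node.feature >= 0:
                node = node.yes if x[node.feature] < node.threshold else node.no
            total += node.value
        return total

    def n_features(self) -> int:
        mx = -1
        stack = list(self.trees)
        while stack:
            n = stack.pop()
            if n.feature >= 0:
                mx = max(mx, n.feature)
                stack.extend([n.yes, n.no])
        return mx + 1

    def used_features(self) -> set[int]:
        used: set[int] = set()
        stack = list(self.trees)
        while stack:
            n = stack.pop()
            if n.feature >= 0:
                used.add(n.feature)
                stack.extend([n.yes, n.no])
        return used


def expected_value(ensemble: TreeEnsemble) -> float:
    """Cover-weighted expectation of the ensemble margin (the SHAP base value)."""

    def rec(node: _Node) -> float:
        if node.feature < 0:
            return node.value
        wl = node.yes.cover / node.cover
        return wl * rec(node.yes) + (1 - wl) * rec(node.no)

    return ensemble.base_margin + sum(rec(t) for t in ensemble.trees)


# ---------------------------------------------------------------------------
# path-dependent algorithm

class _Path:
    """Decision-path state: per-depth feature, zero/one fractions, subset weights."""

    __slots__ = ("d", "z", "o", "w", "length")

    def __init__(self, capacity: int):
        self.d = np.empty(capacity, dtype=np.int64)
        self.z = np.empty(capacity)
        self.o = np.empty(capacity)
        self.w = np.empty(capacity)
        self.length = 0

    def copy(self) -> "_Path":
        p = _Path(len(self.d))
        l = self.length
        p.d[:l] = self.d[:l]
        p.z[:l] = self.z[:l]
        p.o[:l] = self.o[:l]
        p.w[:l] = self.w[:l]
        p.length = l
        return p

    def extend(self, pz: float, po: float, pi: int) -> None:
        l = self.length
        self.d[l], self.z[l], self.o[l] = pi, pz, po
        self.w[l] = 1.0 if l == 0 else 0.0
        for i in range(l - 1, -1, -1):
            self.w[i + 1] += po * self.w[i] * (i + 1) / (l + 1)
            self.w[i] = pz * self.w[i] * (l - i) / (l + 1)
        self.length = l + 1

    def unwind(self, i: int) -> None:
        l = self.length - 1
        po, pz = self.o[i], self.z[i]
        n = self.w[l]
        if po != 0:
            for j in range(l - 1, -1, -1):
                t = self.w[j]
                self.w[j] = n * (l + 1) / ((j + 1) * po)
                n = t - self.w[j] * pz * (l - j) / (l + 1)
        else:
            for j in range(l - 1, -1, -1):
                self.w[j] = self.w[j] * (l + 1) / (pz * (l - j))
        for j in range(i, l):
            self.d[j], self.z[j], self.o[j] = self.d[j + 1], self.z[j + 1], self.o[j + 1]
        self.length = l

    def unwound_sum(self, i: int) -> float:
        """Sum of path weights if element i were unwound (non-mutating)."""
        l = self.length - 1
        po, pz = self.o[i], self.z[i]
        total = 0.0
        if po != 0:
            n = self.w[l]
            for j in range(l - 1, -1, -1):
                tmp = n * (l + 1) / ((j + 1) * po)
                total += tmp
                n = self.w[j] - tmp * pz * (l - j) / (l + 1)
        else:
            for j in range(l - 1, -1, -1):
                total += self.w[j] * (l + 1) / (pz * (l - j))
        return total


def _tree_shap(node: _Node, x: np.ndarray, phi: np.ndarray, path: _Path,
               pz: float, po: float, pi: int, max_depth: int) -> None:
    path = path.copy()
    path.extend(pz, po, pi)
    if node.feature < 0:
        for i in range(1, path.length):
            w = path.unwound_sum(i)
            phi[path.d[i]] += w * (path.o[i] - path.z[i]) * node.value
        return
    hot, cold = (node.yes, node.no) if x[node.feature] < node.threshold else (node.no, node.yes)
    iz, io = 1.0, 1.0
    for k in range(1, path.length):
        if path.d[k] == node.feature:
            iz, io = path.z[k], path.o[k]
            path.unwind(k)
            break
    _tree_shap(hot, x, phi, path, iz * hot.cover / node.cover, io, node.feature, max_depth)
    _tree_shap(cold, x, phi, path, iz * cold.cover / node.cover, 0.0, node.feature, max_depth)


def _depth(node: _Node) -> int:
    if node.feature < 0:
        return 1
    return 1 + max(_depth(node.yes), _depth(node.no))


def shapley_values(ensemble: TreeEnsemble, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-row, per-feature Shapley values and the shared base value.

    Returns ``(phi, base)`` with ``phi`` of shape (n_rows, n_features);
    ``base + phi[i].sum()`` equals the model margin of row i.
    """
    # single precision mirrors the booster's split comparisons
    X = np.atleast_2d(np.asarray(X, dtype=np.float32))
    n_feat = X.shape[1]
    phi = np.zeros((X.shape[0], n_feat))
    base = expected_value(ensemble)
    for t in ensemble.trees:
        cap = _depth(t) + 2
        for r in range(X.shape[0]):
            path = _Path(cap)
            _tree_shap(t, X[r], phi[r], path, 1.0, 1.0, -1, cap)
    return phi, base
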