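"""Structure-aware data partitioning.

Generalisation to novel chemotypes is estimated by keeping structurally
related compounds on one side of every boundary: compounds are clustered with
the Butina sphere-exclusion algorithm on Tanimoto distances between circular
fingerprints, the 80/20 train/test split and the outer cross-validation folds
then operate on whole clusters, and the encoder's internal 80/10/10 split
operates on Bemis–Murcko scaffolds.  Every split is deterministic given its
seed, and helper audits assert the zero-leakage invariant programmatically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold


class InfeasibleSplitError(ValueError):
    """The requested split cannot be realised (e.g. one cluster covers everything)."""


@dataclass
class ClusterAssignment:
    """Partition of a dataset into sphere-exclusion clusters."""

    cluster_of: list[int]            # per-compound cluster id
    members: list[list[int]]         # per-cluster member indices
    distance_cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.members)


@dataclass
class SplitPlan:
    """Cluster-respecting train/test membership plus outer CV folds."""

    train_ids: list[str]
    test_ids: list[str]
    outer_folds: list[tuple[list[str], list[str]]] = field(default_factory=list)
    seed: int = 0
    distance_cutoff: float = 0.4

    def to_json(self) -> str:
        return json.dumps({
            "train_ids": self.train_ids,
            "test_ids": self.test_ids,
            "outer_folds": [[list(tr), list(va)] for tr, va in self.outer_folds],
            "seed": self.seed,
            "distance_cutoff": self.distance_cutoff,
        })

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, payload: str) -> "SplitPlan":
        d = json.loads(payload)
        return cls(train_ids=list(d["train_ids"]), test_ids=list(d["test_ids"]),
                   outer_folds=[(list(tr), list(va)) for tr, va in d["outer_folds"]],
                   seed=int(d["seed"]), distance_cutoff=float(d["distance_cutoff"]))

    @classmethod
    def load(cls, path: str | Path) -> "SplitPlan":
        return cls.from_json(Path(path).read_text())


def butina_cluster(fps: Sequence[np.ndarray], distance_cutoff: float) -> ClusterAssignment:
    """Sphere-exclusion (Butina) clustering on Tanimoto distance (1 - similarity).

    Neighbor lists are computed within ``distance_cutoff``; the unassigned
    compound with the most unassigned neighbors becomes the next centroid
    (ties broken by lowest input index) and absorbs its unassigned neighbors.
    Singletons are allowed.
    """
    if not 0 < distance_cutoff < 1:
        raise ValueError("distance_cutoff must lie in (0, 1)")
    n = len(fps)
    if n == 0:
        return ClusterAssignment([], [], distance_cutoff)
    mat = np.asarray(fps, dtype=bool)
    neighbors: list[set[int]] = []
    for i in range(n):
        inter = (mat & mat[i]).sum(axis=1).astype(float)
        union = (mat | mat[i]).sum(axis=1).astype(float)
        sim = np.ones(n)
        nz = union > 0
        sim[nz] = inter[nz] / union[nz]
        dist = 1.0 - sim
        nbr = set(np.nonzero(dist <= distance_cutoff)[0].tolist())
        nbr.discard(i)
        neighbors.append(nbr)

    unassigned = set(range(n))
    cluster_of = [-1] * n
    members: list[list[int]] = []
    while unassigned:
        # centroid: maximal count of unassigned neighbors, ties -> lowest index
        best, best_count = None, -1
        for i in sorted(unassigned):
            c = len(neighbors[i] & unassigned)
            if c > best_count:
                best, best_count = i, c
        cluster = sorted({best} | (neighbors[best] & unassigned))
        cid = len(members)
        for m in cluster:
            cluster_of[m] = cid
            unassigned.discard(m)
        members.append(cluster)
    return ClusterAssignment(cluster_of, members, distance_cutoff)


def _ordered_clusters(assignment: ClusterAssignment, rng: np.random.Generator) -> list[int]:
    """Cluster ids largest-first with seeded shuffling among equal sizes."""
    sizes = np.array([len(m) for m in assignment.members])
    jitter = rng.permutation(len(sizes))
    order = sorted(range(len(sizes)), key=lambda c: (-sizes[c], jitter[c]))
    return order


def cluster_train_test_split(assignment: ClusterAssignment, labels: Sequence[int],
                             ids: Sequence[str], test_fraction: float = 0.2,
                             seed: int = 0) -> SplitPlan:
    """Assign whole clusters to the test side until it holds ~``test_fraction``.

    Greedy, largest clusters first (seeded shuffling among equal sizes); a
    cluster goes to test while the test side is below target and adding it
    keeps the test size within +2% of the dataset and does not push the test
    active fraction more than 3 percentage points from the global rate unless
    no balanced choice exists.  Deterministic given the seed.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if assignment.n_clusters <= 1:
        raise InfeasibleSplitError("a single cluster covers the whole dataset")
    target = test_fraction * n
    size_tol = max(1.0, 0.02 * n)
    global_frac = labels.mean()
    rng = np.random.default_rng(seed)
    order = _ordered_clusters(assignment, rng)

    test_clusters: set[int] = set()
    test_n = 0
    test_actives = 0
    for cid in order:
        if test_n >= target:
            break
        mem = assignment.members[cid]
        size = len(mem)
        if test_n + size > target + size_tol:
            continue
        acts = int(labels[mem].sum())
        new_frac = (test_actives + acts) / (test_n + size)
        cur_dev = abs(test_actives / test_n - global_frac) if test_n else 1.0
        if abs(new_frac - global_frac) <= 0.03 or abs(new_frac - global_frac) < cur_dev:
            test_clusters.add(cid)
            test_n += size
            test_actives += acts
    # top up with any remaining clusters if still short of the size window
    # (relaxes the balance preference, never the no-straddling invariant)
    if test_n < target - size_tol:
        for cid in order:
            if test_n >= target - size_tol:
                break
            if cid in test_clusters:
                continue
            size = len(assignment.members[cid])
            if test_n + size <= target + size_tol:
                test_clusters.add(cid)
                test_n += size
                test_actives += int(labels[assignment.members[cid]].sum())
    # improvement pass: swap test/train clusters of similar size while the
    # test active fraction sits more than 3 points from the global rate
    cluster_stats = {cid: (len(m), int(labels[m].sum()))
                     for cid, m in enumerate(assignment.members)}
    for _ in range(200):
        frac = test_actives / test_n
        if abs(frac - global_frac) <= 0.03:
            break
        best_swap, best_dev = None, abs(frac - global_frac)
        for cid_out in sorted(test_clusters):
            n_out, a_out = cluster_stats[cid_out]
            for cid_in in order:
                if cid_in in test_clusters:
                    continue
                n_in, a_in = cluster_stats[cid_in]
                new_n = test_n - n_out + n_in
                if abs(new_n - target) > size_tol:
                    continue
                new_dev = abs((test_actives - a_out + a_in) / new_n - global_frac)
                if new_dev < best_dev - 1e-12:
                    best_swap, best_dev = (cid_out, cid_in), new_dev
        if best_swap is None:
            break
        cid_out, cid_in = best_swap
        test_clusters.remove(cid_out)
        test_clusters.add(cid_in)
        test_n += cluster_stats[cid_in][0] - cluster_stats[cid_out][0]
        test_actives += cluster_stats[cid_in][1] - cluster_stats[cid_out][1]

    test_idx = sorted(i for cid in test_clusters for i in assignment.members[cid])
    train_idx = sorted(set(range(n)) - set(test_idx))
    if not train_idx or not test_idx:
        raise InfeasibleSplitError("split produced an empty partition")
    ids = list(ids)
    return SplitPlan(train_ids=[ids[i] for i in train_idx],
                     test_ids=[ids[i] for i in test_idx],
                     seed=seed, distance_cutoff=assignment.distance_cutoff)


def stratified_group_kfold(ids: Sequence[str], labels: Sequence[int],
                           groups: Sequence[int], k: int,
                           seed: int = 0) -> list[tuple[list[str], list[str]]]:
    """Grouped, class-balanced k-fold: each group lies wholly inside one fold.

    Groups are assigned greedily (largest first, seeded tie shuffling) to the
    fold that minimises the deviation of per-fold class counts, so every id
    appears in exactly one validation fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels)
    ids = list(ids)
    group_ids = {}
    for i, g in enumerate(groups):
        group_ids.setdefault(g, []).append(i)
    if len(group_ids) < k:
        raise InfeasibleSplitError(f"{len(group_ids)} groups < k={k}")
    rng = np.random.default_rng(seed)
    keys = list(group_ids)
    jitter = dict(zip(keys, rng.permutation(len(keys))))
    keys.sort(key=lambda g: (-len(group_ids[g]), jitter[g]))

    fold_counts = np.zeros((k, 2))           # per fold: [inactives, actives]
    fold_members: list[list[int]] = [[] for _ in range(k)]
    for g in keys:
        mem = group_ids[g]
        acts = int(labels[mem].sum())
        add = np.array([len(mem) - acts, acts], dtype=float)
        best_fold, best_cost = 0, None
        for f in range(k):
            trial = fold_counts.copy()
            trial[f] += add
            # cost: spread of class counts across folds (sklearn-style heuristic)
            cost = trial.std(axis=0).sum()
            if best_cost is None or cost < best_cost - 1e-12:
                best_fold, best_cost = f, cost
        fold_counts[best_fold] += add
        fold_members[best_fold].extend(mem)

    folds = []
    all_idx = set(range(len(ids)))
    for f in range(k):
        val = sorted(fold_members[f])
        tr = sorted(all_idx - set(val))
        folds.append(([ids[i] for i in tr], [ids[i] for i in val]))
    return folds


def murcko_scaffold(smiles: str) -> str:
    """Bemis–Murcko scaffold SMILES; empty string for acyclic molecules."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def murcko_scaffold_split(smiles_list: Sequence[str], ids: Sequence[str],
                          fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                          seed: int = 0) -> tuple[list[str], list[str], list[str]]:
    """Scaffold-balanced 3-way split: no scaffold spans partitions.

    Scaffold bins are assigned largest-first to the partition with the lowest
    fill relative to its quota.  Acyclic molecules share one "empty scaffold"
    bin so the no-straddling invariant stays meaningful.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = list(ids)
    bins: dict[str, list[int]] = {}
    for i, smi in enumerate(smiles_list):
        bins.setdefault(murcko_scaffold(smi), []).append(i)
    rng = np.random.default_rng(seed)
    keys = list(bins)
    jitter = dict(zip(keys, rng.permutation(len(keys))))
    keys.sort(key=lambda s: (-len(bins[s]), jitter[s]))

    n = len(ids)
    quotas = np.array(fractions) * n
    filled = np.zeros(3)
    parts: list[list[int]] = [[], [], []]
    for sc in keys:
        mem = bins[sc]
        ratios = np.where(quotas > 0, filled / np.where(quotas > 0, quotas, 1.0), np.inf)
        p = int(np.argmin(ratios))
        parts[p].extend(mem)
        filled[p] += len(mem)
    if any(len(p) == 0 for p in parts):
        warnings.warn("scaffold split produced an empty partition "
                      "(too few scaffolds for the requested fractions)")
    return tuple([ids[i] for i in sorted(p)] for p in parts)  # type: ignore[return-value]


def add_outer_folds(plan: SplitPlan, assignment: ClusterAssignment,
                    labels_by_id: dict[str, int], ids: Sequence[str],
                    k: int = 5, seed: int = 0) -> SplitPlan:
    """Attach cluster-grouped outer CV folds over the plan's training ids."""
    pos = {rid: i for i, rid in enumerate(ids)}
    train_ids = plan.train_ids
    groups = [assignment.cluster_of[pos[rid]] for rid in train_ids]
    labels = [labels_by_id[rid] for rid in train_ids]
    plan.outer_folds = stratified_group_kfold(train_ids, labels, groups, k=k, seed=seed)
    return plan


def assert_no_cluster_leakage(plan: SplitPlan, assignment: ClusterAssignment,
                              ids: Sequence[str]) -> None:
    """Raise if any cluster spans train/test or two outer folds."""
    pos = {rid: i for i, rid in enumerate(ids)}
    train_clusters = {assignment.cluster_of[pos[r]] for r in plan.train_ids}
    test_clusters = {assignment.cluster_of[pos[r]] for r in plan.test_ids}
    overlap = train_clusters & test_clusters
    if overlap:
        raise AssertionError(f"clusters straddle the train/test boundary: {sorted(overlap)[:5]}")
    val_clusters_seen: set[int] = set()
    for _tr, val in plan.outer_folds:
        vc = {assignment.cluster_of[pos[r]] for r in val}
        dup = vc & val_clusters_seen
        if dup:
            raise AssertionError(f"clusters appear in two outer validation folds: {sorted(dup)[:5]}")
        val_clusters_seen |= vc
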