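"""Extended-connectivity (Morgan) fingerprints and Tanimoto similarity.

The circular-fingerprint algorithm is implemented here from first principles:
initial atom invariants are hashed from local atom properties, then iteratively
combined with the sorted (bond-order, neighbor-identifier) pairs for radii
1..R, and all environment identifiers are folded modulo the bit length into a
binary vector.  The hashing pipeline reproduces the de-facto reference
implementation bit for bit (32-bit Fibonacci-style hash combining, round
hashes seeded with the 0-based layer index, and de-duplication of environments
that cover an already-seen bond set), which the test suite asserts against an
independent toolkit on randomly generated molecules.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem

__all__ = ["morgan_environment_ids", "compute_ecfp", "tanimoto", "bulk_tanimoto"]

_M32 = 0xFFFFFFFF
_GOLDEN = 0x9E3779B9


def _hash_combine(seed: int, value: int) -> int:
    # classic boost-style 32-bit combine; all arithmetic mod 2**32
    return (seed ^ ((value + _GOLDEN + ((seed << 6) & _M32) + (seed >> 2)) & _M32)) & _M32


def _hash_range(values, seed: int = 0) -> int:
    s = seed
    for v in values:
        s = _hash_combine(s, v & _M32)
    return s


def _initial_invariant(atom: Chem.Atom) -> int:
    """Hash of the standard Morgan atom invariants.

    Components: atomic number, total degree (incl. H), attached-H count,
    formal charge, isotope mass delta (always 0 here: isotopes are not
    distinguished), plus a trailing 1 for ring atoms.
    """
    comps = [atom.GetAtomicNum(), atom.GetTotalDegree(), atom.GetTotalNumHs(),
             atom.GetFormalCharge() & _M32, 0]
    if atom.IsInRing():
        comps.append(1)
    return _hash_range(comps)


def morgan_environment_ids(mol: Chem.Mol, radius: int) -> set[int]:
    """All distinct 32-bit environment identifiers for radii 0..radius.

    Two environments covering the same set of bonds are counted once (the one
    with the lexicographically smallest (bond-envelope, identifier, atom)
    triple survives); an atom whose environment stops growing is retired from
    further rounds.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    n = mol.GetNumAtoms()
    invariants = [_initial_invariant(a) for a in mol.GetAtoms()]
    ids = set(invariants)

    neighbors: list[list[tuple[int, int, int]]] = [[] for _ in range(n)]  # (bt, other, bond idx)
    for b in mol.GetBonds():
        i, j, bt = b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondType())
        neighbors[i].append((bt, j, b.GetIdx()))
        neighbors[j].append((bt, i, b.GetIdx()))

    atom_env: list[frozenset[int]] = [frozenset() for _ in range(n)]  # bond envelope per atom
    seen_envelopes: set[frozenset[int]] = set()
    dead = [False] * n

    for layer in range(radius):
        round_inv = list(invariants)
        round_env = list(atom_env)
        this_round = []
        for a in range(n):
            if dead[a] or not neighbors[a]:
                continue
            pairs = sorted((bt, invariants[o]) for bt, o, _ in neighbors[a])
            inv = _hash_range(
                [invariants[a]] + [_hash_range(p) for p in pairs], seed=layer)
            env = set(atom_env[a])
            for bt, o, bidx in neighbors[a]:
                env.add(bidx)
                env |= atom_env[o]
            envf = frozenset(env)
            round_inv[a] = inv
            if envf == atom_env[a]:   # environment exhausted: retire the atom
                dead[a] = True
                continue
            round_env[a] = envf
            this_round.append((sorted(envf), inv, a))
        for env_sorted, inv, _a in sorted(this_round):
            envf = frozenset(env_sorted)
            if envf not in seen_envelopes:
                ids.add(inv)
                seen_envelopes.add(envf)
        invariants = round_inv
        atom_env = round_env
    return ids


def compute_ecfp(mol_or_smiles: Chem.Mol | str, radius: int = 2, nbits: int = 2048) -> np.ndarray:
    """Folded binary circular fingerprint (default: 2,048 bits, radius 2).

    ``nbits`` must be a power of two; environment identifiers are folded
    modulo ``nbits``.
    """
    if nbits <= 0 or (nbits & (nbits - 1)) != 0:
        raise ValueError("nbits must be a power of two")
    mol = Chem.MolFromSmiles(mol_or_smiles) if isinstance(mol_or_smiles, str) else mol_or_smiles
    if mol is None:
        raise ValueError("unparseable SMILES")
    fp = np.zeros(nbits, dtype=np.uint8)
    for ident in morgan_environment_ids(mol, radius):
        fp[ident % nbits] = 1
    return fp


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b|; 1.0 when both vectors are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def bulk_tanimoto(query: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Tanimoto of one fingerprint against the rows of a fingerprint matrix."""
    q = np.asarray(query, dtype=bool)
    m = np.asarray(matrix, dtype=bool)
    if m.ndim != 2 or m.shape[1] != q.shape[0]:
        raise ValueError("fingerprint length mismatch")
    inter = (m & q).sum(axis=1).astype(float)
    union = (m | q).sum(axis=1).astype(float)
    out = np.ones(len(m))
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out
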