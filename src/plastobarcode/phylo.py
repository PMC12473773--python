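"""Distance-based tree building (NJ, BIONJ) and species discrimination.

Both builders agglomerate with the Saitou-Nei Q criterion and deterministic
tie-breaking (lowest index pair). BIONJ differs only in its distance
reduction, which weights the two merged rows to minimise the variance of the
new distances (variances are tracked alongside the distances, initialised to
the distances themselves). Negative branch-length estimates are clamped to
zero with the deficit transferred to the sister edge.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .trees import Node, Tree


def _as_matrix(D) -> tuple[list[str], np.ndarray]:
    """Accept a barcode_eval.DistanceMatrix or (ids, ndarray)-like input."""
    if hasattr(D, "sample_ids") and hasattr(D, "d"):
        defined = getattr(D, "defined", None)
        n = len(D.sample_ids)
        if defined is not None:
            off = ~np.eye(n, dtype=bool)
            if not defined[off].all():
                raise ValueError(
                    "distance matrix has undefined entries; impute them or drop "
                    "the affected samples before tree building"
                )
        return list(D.sample_ids), np.array(D.d, dtype=float)
    ids, mat = D
    return list(ids), np.array(mat, dtype=float)


def _clamped(b_i: float, b_j: float) -> tuple[float, float]:
    if b_i < 0:
        b_j += b_i
        b_i = 0.0
    if b_j < 0:
        b_i += b_j
        b_j = 0.0
    return max(b_i, 0.0), max(b_j, 0.0)


def _agglomerate(ids: list[str], d: np.ndarray, bionj_update: bool) -> Tree:
    n = len(ids)
    if n < 3:
        raise ValueError("tree building needs at least 3 samples")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    nodes: list[Node] = [Node(name) for name in ids]
    cur = d.copy()
    var = d.copy()  # BIONJ variance estimates; unused by plain NJ
    while len(nodes) > 3:
        r = len(nodes)
        R = cur.sum(axis=1)
        Q = (r - 2) * cur - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # first minimum in row-major order: lowest (i, j)
        i, j = divmod(flat, r)
        if i > j:
            i, j = j, i
        dij = cur[i, j]
        b_i = 0.5 * dij + (R[i] - R[j]) / (2.0 * (r - 2))
        b_j = dij - b_i
        b_i, b_j = _clamped(b_i, b_j)
        parent = Node()
        nodes[i].length = b_i
        nodes[j].length = b_j
        parent.add(nodes[i])
        parent.add(nodes[j])
        if bionj_update and var[i, j] > 0:
            others = [k for k in range(r) if k not in (i, j)]
            lam = 0.5 + float(np.sum(var[j, others] - var[i, others])) / (
                2.0 * (r - 2) * var[i, j]
            )
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        new_d = lam * (cur[i] - b_i) + (1.0 - lam) * (cur[j] - b_j)
        new_v = lam * var[i] + (1.0 - lam) * var[j] - lam * (1.0 - lam) * var[i, j]
        keep = [k for k in range(r) if k not in (i, j)]
        cur = np.pad(cur[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        var = np.pad(var[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        cur[-1, :-1] = cur[:-1, -1] = new_d[keep]
        var[-1, :-1] = var[:-1, -1] = new_v[keep]
        nodes = [nodes[k] for k in keep] + [parent]
    # resolve the final three nodes with the three-point formulas
    d01, d02, d12 = cur[0, 1], cur[0, 2], cur[1, 2]
    root = Node()
    lengths = [
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    ]
    for node, length in zip(nodes, lengths):
        node.length = max(length, 0.0)
        root.add(node)
    return Tree(root)


def nj(D) -> Tree:
    """Classical Saitou-Nei neighbour joining; consistent on additive matrices."""
    ids, d = _as_matrix(D)
    return _agglomerate(ids, d, bionj_update=False)


def bionj(D) -> Tree:
    """Neighbour joining with the variance-weighted (BIONJ) distance update."""
    ids, d = _as_matrix(D)
    off = ~np.eye(len(ids), dtype=bool)
    if (d[off] >= 1.0).any():
        warnings.warn("distances >= 1 strain the BIONJ variance model")
    return _agglomerate(ids, d, bionj_update=True)


def is_monophyletic(tree: Tree, leafset: Iterable[str]) -> bool:
    """True iff some edge bipartition separates exactly ``leafset``.

    Singletons and the full leaf set are trivially monophyletic.
    """
    target = frozenset(leafset)
    if not target:
        raise ValueError("empty leaf set")
    all_leaves = frozenset(tree.leaf_names())
    unknown = target - all_leaves
    if unknown:
        raise KeyError(f"leaves not in tree: {sorted(unknown)}")
    if len(target) == 1 or target == all_leaves:
        return True
    complement = all_leaves - target
    for below in tree.bipartitions():
        if below == target or below == complement:
            return True
    return False


@dataclass(frozen=True)
class DiscriminationResult:
    n_discriminated: int
    per_species: dict
    singletons: frozenset


def species_discrimination(tree: Tree, partition: Mapping[str, str]) -> DiscriminationResult:
    """Count species whose full leaf set is monophyletic; singletons flagged."""
    leaves = tree.leaf_names()
    missing = [s for s in leaves if s not in partition]
    if missing:
        raise ValueError(f"leaves without species assignment: {missing}")
    by_species: dict[str, set[str]] = {}
    for sid in leaves:
        by_species.setdefault(partition[sid], set()).add(sid)
    per_species = {
        sp: is_monophyletic(tree, members) for sp, members in sorted(by_species.items())
    }
    singletons = frozenset(sp for sp, members in by_species.items() if len(members) == 1)
    return DiscriminationResult(
        n_discriminated=sum(per_species.values()),
        per_species=per_species,
        singletons=singletons,
    )


def root_with_outgroup(tree: Tree, leaf_label: str) -> Tree:
    """Root on the midpoint of the outgroup's pendant edge."""
    return tree.root_with_outgroup(leaf_label)
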