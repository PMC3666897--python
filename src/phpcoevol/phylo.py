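"""Distance-based phylogenetics: p-distances, neighbor joining, bootstrap.

Trees are dendropy ``Tree`` objects throughout (unrooted; the seed node of
an NJ tree is the trifurcating central node).  Neighbor joining follows
the Saitou-Nei agglomeration with the Q criterion; ties in Q are broken
by the lexicographically smallest (label, label) pair, and negative
branch lengths are clamped to zero with the count recorded on the tree
as ``tree.n_clamped_branches``.

The default distance model is the p-distance (mismatch fraction over
mutually ungapped columns); a Poisson correction ``-ln(1 - p)`` is
available as ``model="poisson"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import dendropy
import numpy as np

from .errors import PhpCoevolError, UndefinedDistanceError, ValidationError
from .seq_io import Alignment

DistanceModel = Literal["p", "poisson"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with ordered labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.all(np.isfinite(v)):
            raise ValidationError("non-finite distances")
        if np.any(v < 0):
            raise ValidationError("negative distances")
        if not np.allclose(v, v.T):
            raise ValidationError("asymmetric distance matrix")
        if not np.allclose(np.diag(v), 0):
            raise ValidationError("nonzero diagonal")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def _char_matrix(alignment: Alignment) -> np.ndarray:
    return np.array([list(r.residues) for r in alignment.records])


def p_distance(alignment: Alignment, id_i: str, id_j: str) -> float:
    """Mismatch fraction over columns where both sequences are ungapped."""
    a = alignment.record(id_i).residues
    b = alignment.record(id_j).residues
    shared = mismatch = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            shared += 1
            if x != y:
                mismatch += 1
    if shared == 0:
        raise UndefinedDistanceError(f"{id_i} and {id_j} share no ungapped columns")
    return mismatch / shared


def distance_matrix(alignment: Alignment, model: DistanceModel = "p") -> DistanceMatrix:
    """All pairwise distances under the chosen model."""
    chars = _char_matrix(alignment)
    return _distance_matrix_from_chars(chars, tuple(alignment.ids), model)


def _distance_matrix_from_chars(
    chars: np.ndarray, labels: tuple[str, ...], model: DistanceModel
) -> DistanceMatrix:
    n = chars.shape[0]
    gaps = chars == "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gaps[i] & ~gaps[j]
            shared = int(ok.sum())
            if shared == 0:
                raise UndefinedDistanceError(
                    f"{labels[i]} and {labels[j]} share no ungapped columns"
                )
            p = float((chars[i, ok] != chars[j, ok]).mean())
            if model == "poisson":
                if p >= 1.0:
                    raise UndefinedDistanceError(
                        f"Poisson correction undefined at p=1 for {labels[i]},{labels[j]}"
                    )
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=labels, values=d)


def neighbor_joining(matrix: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    Returns an unrooted dendropy tree whose seed node is the final
    trifurcation (for >= 4 taxa) or the central node (3 taxa).
    """
    labels = list(matrix.labels)
    if len(labels) < 3:
        raise ValidationError("neighbor joining requires at least 3 taxa")
    tns = dendropy.TaxonNamespace(labels)
    nodes: dict[str, dendropy.Node] = {
        lab: dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels
    }
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            d[_key(a, b)] = float(matrix.values[i, j])
    active = sorted(labels)
    n_clamped = 0

    def dist(a: str, b: str) -> float:
        return d[_key(a, b)]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, k) for k in active if k != a) for a in active}
        best = None
        best_pair = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                a, b = active[ai], active[bi]
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                pair = _key(a, b)
                if best is None or q < best - 1e-12 or (abs(q - best) <= 1e-12 and pair < best_pair):
                    best, best_pair = q, pair
        a, b = best_pair
        la = 0.5 * dist(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        lb = dist(a, b) - la
        la, lb, clamped = _clamp(la, lb)
        n_clamped += clamped
        u = dendropy.Node()
        u.add_child(nodes[a])
        u.add_child(nodes[b])
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        new_label = min(a, b)
        dab = dist(a, b)
        for k in active:
            if k in (a, b):
                continue
            d[_key(new_label, k)] = 0.5 * (dist(a, k) + dist(b, k) - dab)
        active = sorted(set(active) - {a, b} | {new_label})
        nodes[new_label] = u

    # resolve the final three clusters around a central node
    x, y, z = active
    center = dendropy.Node()
    lx = 0.5 * (dist(x, y) + dist(x, z) - dist(y, z))
    ly = 0.5 * (dist(x, y) + dist(y, z) - dist(x, z))
    lz = 0.5 * (dist(x, z) + dist(y, z) - dist(x, y))
    for lab, ln in ((x, lx), (y, ly), (z, lz)):
        if ln < 0:
            ln = 0.0
            n_clamped += 1
        center.add_child(nodes[lab])
        nodes[lab].edge.length = ln
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    tree.n_clamped_branches = n_clamped
    return tree


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def _clamp(la: float, lb: float) -> tuple[float, float, int]:
    clamped = 0
    if la < 0:
        la, clamped = 0.0, clamped + 1
    if lb < 0:
        lb, clamped = 0.0, clamped + 1
    return la, lb, clamped


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions as normalized leaf-label sets.

    Each internal edge splits the leaves in two; the side *not* containing
    the lexicographically smallest leaf label is reported, so bipartitions
    compare across trees with the same taxon set.
    """
    all_leaves = frozenset(leaf_labels(tree))
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = all_leaves - below if anchor in below else below
        if len(side) >= 2 and len(all_leaves) - len(side) >= 2:
            out.add(side)
    return out


def bootstrap_support(
    alignment: Alignment,
    n_reps: int = 100,
    seed: int = 0,
    model: DistanceModel = "p",
) -> dendropy.Tree:
    """NJ tree with bootstrap supports from column resampling.

    Support of an internal edge is the fraction of replicate NJ trees (on
    alignments with columns resampled with replacement) containing the
    same bipartition.  Deterministic given ``seed``; with ``n_reps=0`` the
    plain NJ tree is returned without supports.
    """
    chars = _char_matrix(alignment)
    ids = tuple(alignment.ids)
    tree = neighbor_joining(_distance_matrix_from_chars(chars, ids, model))
    if n_reps == 0:
        return tree
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, chars.shape[1], size=chars.shape[1])
        rep_tree = neighbor_joining(
            _distance_matrix_from_chars(chars[:, cols], ids, model)
        )
        for bp in bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    all_leaves = frozenset(ids)
    anchor = min(all_leaves)
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = all_leaves - below if anchor in below else below
        support = counts.get(side, 0) / n_reps
        node.support = support
        node.label = f"{support:.3f}"
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    """Newick string with branch lengths and any support labels."""
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip() + "\n"


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; malformed input raises a package error."""
    try:
        return dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise PhpCoevolError(f"Newick parse error: {exc}") from exc


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree))


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-rooted copy for display; analysis stays unrooted."""
    clone = tree.clone(depth=1)
    clone.reroot_at_midpoint(update_bipartitions=False)
    clone.is_rooted = True
    return clone
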