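import random

import numpy as np
import pytest

from phpcoevol.errors import UndefinedDistanceError, ValidationError
from phpcoevol.phylo import (
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    distance_matrix,
    neighbor_joining,
    p_distance,
    read_newick,
    to_newick,
)
from phpcoevol.seq_io import Alignment, SequenceRecord


def _aln(rows: dict[str, str]) -> Alignment:
    return Alignment(
        records=tuple(SequenceRecord(id=k, residues=v) for k, v in rows.items())
    )


def test_p_distance_basics():
    aln = _aln({"a": "AAAA", "b": "AAAV", "c": "AAAA"})
    assert p_distance(aln, "a", "c") == 0.0
    assert p_distance(aln, "a", "b") == 0.25


def test_p_distance_ignores_gapped_columns_and_errors():
    aln = _aln({"a": "A-AA", "b": "AV-A"})
    # only columns 1 and 4 are mutually ungapped
    assert p_distance(aln, "a", "b") == 0.0
    disjoint = _aln({"a": "AA--", "b": "--AA"})
    with pytest.raises(UndefinedDistanceError):
        p_distance(disjoint, "a", "b")


def test_p_distance_matches_naive_loop():
    rng = random.Random(5)
    rows = {
        f"s{i}": "".join(rng.choice("ACDE-") for _ in range(60)) for i in range(5)
    }
    rows["anchor"] = "A" * 60  # guarantee no all-gap rows / empty overlaps
    aln = _aln(rows)
    dm = distance_matrix(aln)
    for i, a in enumerate(dm.labels):
        for j, b in enumerate(dm.labels):
            if i >= j:
                continue
            ra, rb = aln.record(a).residues, aln.record(b).residues
            pairs = [(x, y) for x, y in zip(ra, rb) if x != "-" and y != "-"]
            expected = sum(x != y for x, y in pairs) / len(pairs)
            assert dm.values[i, j] == pytest.approx(expected)


def test_nj_exact_on_additive_four_taxa():
    """The additive matrix of ((A:1,B:2):1,(C:3,D:4)) is recovered exactly."""
    labels = ("A", "B", "C", "D")
    d = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    )
    tree = neighbor_joining(DistanceMatrix(labels, d))
    assert bipartitions(tree) == {frozenset({"C", "D"})}
    # exact branch lengths: patristic distances reproduce the input matrix
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(d[i, j])


def test_nj_three_taxa_closed_form():
    labels = ("A", "B", "C")
    d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
    tree = neighbor_joining(DistanceMatrix(labels, d))
    lengths = {
        lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
    }
    assert lengths["A"] == pytest.approx(0.0)  # (2+3-5)/2
    assert lengths["B"] == pytest.approx(2.0)
    assert lengths["C"] == pytest.approx(3.0)


def test_nj_invariant_under_label_permutation():
    rng = np.random.default_rng(7)
    n = 7
    base = rng.uniform(1, 5, size=(n, n))
    d = (base + base.T) / 2
    np.fill_diagonal(d, 0)
    labels = tuple(f"L{i}" for i in range(n))
    t1 = neighbor_joining(DistanceMatrix(labels, d))
    perm = rng.permutation(n)
    t2 = neighbor_joining(
        DistanceMatrix(tuple(labels[i] for i in perm), d[np.ix_(perm, perm)])
    )
    assert bipartitions(t1) == bipartitions(t2)


def test_nj_rejects_invalid_matrices():
    with pytest.raises(ValidationError):
        DistanceMatrix(("a", "b"), np.array([[0, 1], [2, 0]], dtype=float))
    with pytest.raises(ValidationError):
        neighbor_joining(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


def test_nj_agrees_with_independent_implementation():
    """Cross-check topology against scikit-bio's NJ on a random matrix."""
    skbio_tree_mod = pytest.importorskip("skbio.tree")
    from skbio import DistanceMatrix as SkbioDM

    rng = np.random.default_rng(13)
    n = 8
    labels = tuple(f"t{i}" for i in range(n))
    # near-additive: distances from random points on a line plus jitter
    coords = np.sort(rng.uniform(0, 10, size=n))
    d = np.abs(coords[:, None] - coords[None, :]) + 0.5
    np.fill_diagonal(d, 0)
    d *= rng.uniform(0.99, 1.01, size=d.shape)
    d = (d + d.T) / 2
    ours = neighbor_joining(DistanceMatrix(labels, d))
    theirs = skbio_tree_mod.nj(SkbioDM(d, ids=list(labels)))
    their_bps = set()
    all_leaves = frozenset(labels)
    anchor = min(all_leaves)
    for node in theirs.non_tips():
        below = frozenset(t.name for t in node.tips())
        side = all_leaves - below if anchor in below else below
        if len(side) >= 2 and len(all_leaves) - len(side) >= 2:
            their_bps.add(side)
    assert bipartitions(ours) == their_bps


def test_newick_round_trip():
    tree = read_newick("(A:1,B:2);")
    assert sorted(lf.taxon.label for lf in tree.leaf_node_iter()) == ["A", "B"]
    quoted = read_newick("('sp one':1,'sp two':2,'sp three':3);")
    assert "sp one" in {lf.taxon.label for lf in quoted.leaf_node_iter()}
    rng = np.random.default_rng(3)
    n = 6
    base = rng.uniform(1, 4, size=(n, n))
    d = (base + base.T) / 2
    np.fill_diagonal(d, 0)
    t = neighbor_joining(DistanceMatrix(tuple(f"x{i}" for i in range(n)), d))
    back = read_newick(to_newick(t))
    assert bipartitions(back) == bipartitions(t)


def test_newick_malformed_raises():
    from phpcoevol.errors import PhpCoevolError

    with pytest.raises(PhpCoevolError):
        read_newick("(A:1,B:2")


def _two_clade_alignment() -> Alignment:
    # two groups separated by 15 diagnostic columns (so every bootstrap
    # replicate contains group signal), each member with a private column
    g1 = "AAAAAAAAAA" + "C" * 15
    g2 = "AAAAAAAAAA" + "G" * 15
    rows = {}
    names = [f"p{i}" for i in range(3)] + [f"q{i}" for i in range(3)]
    for idx, name in enumerate(names):
        extra = ["A"] * 6
        extra[idx] = "V"  # private marker distinguishing this member
        prefix = g1 if name.startswith("p") else g2
        rows[name] = prefix + "".join(extra)
    return _aln(rows)


def test_bootstrap_supports():
    aln = _two_clade_alignment()
    plain = bootstrap_support(aln, n_reps=0, seed=1)
    assert all(not hasattr(n, "support") for n in plain.preorder_node_iter())
    t1 = bootstrap_support(aln, n_reps=50, seed=42)
    t2 = bootstrap_support(aln, n_reps=50, seed=42)
    assert to_newick(t1) == to_newick(t2)  # determinism contract
    supports = {
        frozenset(lf.taxon.label for lf in n.leaf_iter()): n.support
        for n in t1.preorder_node_iter()
        if n.parent_node is not None and not n.is_leaf()
    }
    # the clean two-clade split must have full support
    clade_supports = [
        s for k, s in supports.items()
        if k in (frozenset({"p0", "p1", "p2"}), frozenset({"q0", "q1", "q2"}))
    ]
    assert clade_supports and all(s == 1.0 for s in clade_supports)
    assert all(0.0 <= n.support <= 1.0 for n in t1.preorder_node_iter() if hasattr(n, "support"))
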