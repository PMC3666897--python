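"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the study conditions of the analysis: a clock-like
Yule species tree; an indel-free protein alignment carrying the
nine-position metal-site panel, with panel residues substituted
(preferentially to arginine) in one monophyletic clade; loop deletions
around the site-7 cysteine in a fraction of the variant sequences;
epsilon-like DEDDh sequences (plus optional DEDDy decoys) whose presence
tracks the variant clade at a configurable concordance level; two-state
melt/denaturation and first-order kinetic traces with known parameters;
and coordinate sets under known rigid transforms with constructed metal
sites.

Everything is deterministic given (config, seed), and each generator
returns a machine-readable ground-truth ledger alongside its data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .biophys import (
    Spectrum,
    Trace,
    first_order_signal,
    two_state_denat_signal,
    two_state_melt_signal,
)
from .errors import ValidationError
from .php_sites import DEFAULT_CONSENSUS, ECO_REF_POSITIONS
from .seq_io import Alignment, SequenceRecord
from .struct_geom import Atom, CoordSet

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: epsilon background alphabet: no D/E/H/W/Y, so implanted motifs are unique
EPS_BACKGROUND = "ACFGIKLMNPQRSTV"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults encode the scenario the analysis is built around: 30 taxa, a
    variant clade of ~40% of taxa with histidine sites 1, 4 and 9 replaced
    (arginine preferred 4:1), the loop around site 7 deleted in 20% of
    taxa (drawn from the variant clade), perfect clade/epsilon
    concordance, melt temperatures spanning 46.0 to 39.4 °C across the
    wild-type-to-quintuple-mutant series, ΔG_H2O 20 kJ/mol with
    m = 10 kJ/mol/M, and kinetic rates halving with PHP-site mutation.
    """

    seed: int
    n_taxa: int = 30
    birth_rate: float = 1.0
    seq_length: int = 250
    subst_rate: float = 0.05          # per site per unit branch length
    clade_fraction: float = 0.4
    n_clade_markers: int = 20         # shared derived columns marking the clade
    implant_sites: tuple[int, ...] = (1, 4, 9)
    replacement_dist: tuple[tuple[str, float], ...] = (("R", 0.8), ("Q", 0.2))
    loop_deletion_fraction: float = 0.2
    loop_window: int = 5
    epsilon_concordance: float = 1.0
    decoy_fraction: float = 0.5       # DEDDy decoys among non-clade taxa
    melt_tm_c: tuple[tuple[str, float], ...] = (
        ("WT", 46.0), ("3mPHP", 44.0), ("4mPHP", 42.0), ("5mPHP", 39.4),
    )
    dh_vh_kj: float = 300.0
    dg_h2o_kj: tuple[tuple[str, float], ...] = (("WT", 20.0), ("3mPHP", 16.0))
    m_value_kj_per_m: float = 10.0
    k_rates: tuple[tuple[str, float], ...] = (
        ("WT", 0.010), ("3mPHP", 0.005), ("4mPHP", 0.005), ("5mPHP", 0.0025),
    )
    noise_sigma: float = 0.02         # fraction of signal range

    def __post_init__(self) -> None:
        for name, p in (
            ("clade_fraction", self.clade_fraction),
            ("loop_deletion_fraction", self.loop_deletion_fraction),
            ("epsilon_concordance", self.epsilon_concordance),
            ("decoy_fraction", self.decoy_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {p}")
        if abs(sum(w for _, w in self.replacement_dist) - 1.0) > 1e-9:
            raise ValidationError("replacement distribution weights must sum to 1")


# ---------------------------------------------------------------------------
# species tree

def simulate_tree(config: SimConfig) -> dendropy.Tree:
    """Clock-like Yule tree: exponential waiting times, tips extended to now.

    Deterministic given the config seed.  Leaf labels are T01..Tnn in
    preorder of the final topology.
    """
    if config.n_taxa < 3:
        raise ValidationError("need >= 3 taxa")
    rng = random.Random(config.seed)
    root = dendropy.Node()
    a, b = dendropy.Node(), dendropy.Node()
    root.add_child(a)
    root.add_child(b)
    start: dict[int, float] = {id(a): 0.0, id(b): 0.0}
    active = [a, b]
    t = 0.0
    while len(active) < config.n_taxa:
        t += rng.expovariate(config.birth_rate * len(active))
        node = active.pop(rng.randrange(len(active)))
        node.edge.length = t - start[id(node)]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            start[id(child)] = t
            active.append(child)
    t_end = t + rng.expovariate(config.birth_rate * config.n_taxa)
    for node in active:
        node.edge.length = t_end - start[id(node)]
    width = max(2, len(str(config.n_taxa)))
    labels = [f"T{i:0{width}d}" for i in range(1, config.n_taxa + 1)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.taxon = tns.get_taxon(labels[i])
            i += 1
    tree.is_rooted = True
    return tree


def _pick_clade(tree: dendropy.Tree, target_size: int) -> list[str]:
    """Leaf set of the internal edge whose size is closest to target.

    Deterministic: ties go to the clade found first in preorder.
    """
    n = len(tree.leaf_nodes())
    best: tuple[int, int, list[str]] | None = None
    for idx, node in enumerate(tree.preorder_node_iter()):
        if node.parent_node is None or node.is_leaf():
            continue
        leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
        if len(leaves) >= n - 1:
            continue
        key = (abs(len(leaves) - target_size), idx)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], leaves)
    if best is None:
        raise ValidationError("tree has no usable internal edge")
    return best[2]


# ---------------------------------------------------------------------------
# sequence cohort

def evolve_alignment(
    tree: dendropy.Tree, config: SimConfig
) -> tuple[Alignment, dict]:
    """Evolve an indel-free alignment on the tree and implant the variant clade.

    Panel sites are held at the consensus primary residues in all taxa and
    then substituted per the replacement distribution in the target clade,
    so the classifier's ground truth is exact.  Loop deletions (gap blocks
    around the site-7 column) are applied to a fraction of taxa drawn from
    the clade, never to the reference taxon.  Returns the alignment and a
    ground-truth ledger.
    """
    rng = random.Random(config.seed + 1)
    if config.seq_length < max(ECO_REF_POSITIONS):
        raise ValidationError("seq_length must cover the panel span")
    panel_cols = ECO_REF_POSITIONS        # 1-based; indel-free, columns == positions
    primary = [s[0] for s in DEFAULT_CONSENSUS]
    root_seq = [rng.choice(AA20) for _ in range(config.seq_length)]
    for col, res in zip(panel_cols, primary):
        root_seq[col - 1] = res

    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    clade = _pick_clade(tree, round(config.clade_fraction * len(leaves)))
    ref_candidates = [lf for lf in leaves if lf not in clade]
    ref_id = ref_candidates[0] if ref_candidates else leaves[0]

    panel_idx = {c - 1 for c in panel_cols}
    marker_pool = [i for i in range(config.seq_length) if i not in panel_idx]
    marker_cols = sorted(rng.sample(marker_pool, min(config.n_clade_markers, len(marker_pool))))

    seqs: dict[str, list[str]] = {}

    def evolve(node: dendropy.Node, seq: list[str]) -> None:
        blen = node.edge.length or 0.0
        p = 1.0 - np.exp(-config.subst_rate * blen)
        child_seq = list(seq)
        for i in range(config.seq_length):
            if i in panel_idx or i in marker_cols:
                continue
            if rng.random() < p:
                child_seq[i] = rng.choice([x for x in AA20 if x != child_seq[i]])
        if node.is_leaf():
            seqs[node.taxon.label] = child_seq
        else:
            for child in node.child_nodes():
                evolve(child, child_seq)

    for child in tree.seed_node.child_nodes():
        evolve(child, root_seq)

    # clade markers: one shared derived state per marker column
    marker_states = {}
    for i in marker_cols:
        derived = rng.choice([x for x in AA20 if x != root_seq[i]])
        marker_states[i] = derived
        for taxon in clade:
            seqs[taxon][i] = derived

    # panel implants in the clade
    residues, weights = zip(*config.replacement_dist)
    implants: dict[str, dict[int, str]] = {}
    for taxon in sorted(clade):
        implants[taxon] = {}
        for site in config.implant_sites:
            repl = rng.choices(residues, weights=weights)[0]
            seqs[taxon][panel_cols[site - 1] - 1] = repl
            implants[taxon][site] = repl

    # loop deletions around the site-7 column, within the clade, never the ref
    n_del = round(config.loop_deletion_fraction * len(leaves))
    del_pool = sorted(x for x in clade if x != ref_id)
    loop_deleted = sorted(rng.sample(del_pool, min(n_del, len(del_pool))))
    site7_col = panel_cols[6]
    lo = max(1, site7_col - config.loop_window)
    hi = min(config.seq_length, site7_col + config.loop_window)
    for taxon in loop_deleted:
        for c in range(lo, hi + 1):
            seqs[taxon][c - 1] = "-"

    records = tuple(
        SequenceRecord(id=lf, residues="".join(seqs[lf]), species=lf) for lf in leaves
    )
    ledger = {
        "panel_columns": list(panel_cols),
        "ref_id": ref_id,
        "clade": sorted(clade),
        "implants": implants,
        "implant_sites": list(config.implant_sites),
        "loop_deleted": loop_deleted,
        "loop_window_columns": [lo, hi],
        "marker_columns": [c + 1 for c in marker_cols],
        "marker_states": {c + 1: s for c, s in marker_states.items()},
    }
    return Alignment(records=records), ledger


# ---------------------------------------------------------------------------
# epsilon cohort

#: 1-based implant positions of the epsilon-like sequence (DnaQ-style anchors)
EPS_LAYOUT = {12: "D", 14: "E", 103: "D", 162: "H", 167: "D", 225: "H", 241: "W"}
EPS_LENGTH = 250


def _epsilon_sequence(rng: random.Random, deddy: bool = False, tail: bool = True) -> str:
    s = [rng.choice(EPS_BACKGROUND) for _ in range(EPS_LENGTH)]
    for pos, res in EPS_LAYOUT.items():
        if not tail and pos in (225, 241):
            continue
        s[pos - 1] = res
    if deddy:
        s[162 - 1] = "Y"
    return "".join(s)


def generate_epsilon_cohort(
    clade: Sequence[str], all_taxa: Sequence[str], config: SimConfig
) -> tuple[list[SequenceRecord], dict]:
    """Epsilon-like sequences tracking the variant clade.

    Each clade taxon receives a DEDDh + tail sequence with probability
    ``epsilon_concordance``; non-clade taxa receive a DEDDy decoy (never
    a bona fide epsilon) with probability ``decoy_fraction``.  Returns the
    sequences and a truth table of expected bona fide calls per species.
    """
    rng = random.Random(config.seed + 2)
    clade_set = set(clade)
    records: list[SequenceRecord] = []
    truth: dict[str, bool] = {}
    for taxon in sorted(all_taxa):
        if taxon in clade_set:
            if rng.random() < config.epsilon_concordance:
                records.append(
                    SequenceRecord(
                        id=f"{taxon}_eps", residues=_epsilon_sequence(rng), species=taxon
                    )
                )
                truth[taxon] = True
            else:
                truth[taxon] = False
        else:
            if rng.random() < config.decoy_fraction:
                records.append(
                    SequenceRecord(
                        id=f"{taxon}_exoY",
                        residues=_epsilon_sequence(rng, deddy=True),
                        species=taxon,
                    )
                )
            truth[taxon] = False
    return records, {"expected_bona_fide": truth}


# ---------------------------------------------------------------------------
# biophysics traces

MELT_GRID_C = tuple(float(t) for t in range(20, 71))          # 1 °C steps
DENAT_GRID_M = tuple(round(0.2 * i, 10) for i in range(16))   # 0..3.0 M
KINETIC_GRID_S = tuple(float(t) for t in range(0, 610, 10))
SPECTRUM_GRID_NM = tuple(float(w) for w in range(295, 398, 2))


def melt_trace(
    tm_c: float,
    dh_kj: float = 300.0,
    baselines: tuple[float, float, float, float] = (335.0, 0.0, 350.0, 0.0),
    grid_c: Sequence[float] = MELT_GRID_C,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Trace:
    """A two-state melt evaluated on the acquisition grid, optionally noisy.

    ``noise_sigma`` is a fraction of the clean signal range.
    """
    x = np.asarray(grid_c, dtype=float)
    y = two_state_melt_signal(x, tm_c, dh_kj, *baselines)
    if noise_sigma > 0:
        rng = rng or np.random.default_rng(0)
        y = y + rng.normal(0.0, noise_sigma * float(np.ptp(y)), size=y.shape)
    return Trace(x=tuple(x), y=tuple(y))


def denat_trace(
    dg_kj: float,
    m_kj: float,
    baselines: tuple[float, float, float, float] = (-10000.0, 150.0, -2000.0, 50.0),
    grid_m: Sequence[float] = DENAT_GRID_M,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    temperature_c: float = 25.0,
) -> Trace:
    x = np.asarray(grid_m, dtype=float)
    y = two_state_denat_signal(x, dg_kj, m_kj, *baselines,
                               temperature_k=temperature_c + 273.15)
    if noise_sigma > 0:
        rng = rng or np.random.default_rng(0)
        y = y + rng.normal(0.0, noise_sigma * float(np.ptp(y)), size=y.shape)
    return Trace(x=tuple(x), y=tuple(y))


def kinetic_trace(
    k: float,
    a0: float = 0.25,
    a_inf: float = 0.05,
    grid_s: Sequence[float] = KINETIC_GRID_S,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Trace:
    x = np.asarray(grid_s, dtype=float)
    y = first_order_signal(x, k, a0, a_inf)
    if noise_sigma > 0:
        rng = rng or np.random.default_rng(0)
        span = float(np.ptp(y)) or abs(a0) or 1.0
        y = y + rng.normal(0.0, noise_sigma * span, size=y.shape)
    return Trace(x=tuple(x), y=tuple(y))


def melt_spectra(
    tm_c: float,
    dh_kj: float = 300.0,
    native_nm: float = 330.0,
    unfolded_nm: float = 350.0,
    width_nm: float = 15.0,
    grid_c: Sequence[float] = MELT_GRID_C,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, Spectrum]]:
    """Emission scans whose centre of mass shifts with the unfolded fraction.

    Each scan is an equal-area mixture of a native and an unfolded
    Gaussian on the 295-397 nm / 2 nm acquisition grid, so the scan centre
    of mass is linear in the unfolded fraction and the centre-of-mass
    reduction feeds the melt fit end to end.
    """
    lam = np.asarray(SPECTRUM_GRID_NM)
    rng = rng or np.random.default_rng(0)
    out = []
    for t in grid_c:
        frac = two_state_melt_signal(np.array([t]), tm_c, dh_kj, 0.0, 0.0, 1.0, 0.0)[0]
        shape = (1 - frac) * np.exp(-0.5 * ((lam - native_nm) / width_nm) ** 2)
        shape = shape + frac * np.exp(-0.5 * ((lam - unfolded_nm) / width_nm) ** 2)
        if noise_sigma > 0:
            shape = np.clip(
                shape + rng.normal(0.0, noise_sigma * float(shape.max()), lam.shape),
                0.0, None,
            )
        out.append((float(t), Spectrum(wavelengths=tuple(lam), intensities=tuple(shape))))
    return out


def generate_curves(config: SimConfig) -> dict[str, dict]:
    """Per-construct melt / denaturation / kinetic traces with ground truth."""
    rng = np.random.default_rng(config.seed + 3)
    sigma = config.noise_sigma
    dg_map = dict(config.dg_h2o_kj)
    k_map = dict(config.k_rates)
    out: dict[str, dict] = {}
    for name, tm in config.melt_tm_c:
        entry: dict = {"truth": {"tm_c": tm, "dh_vh_kj": config.dh_vh_kj}}
        entry["melt"] = melt_trace(tm, config.dh_vh_kj, noise_sigma=sigma, rng=rng)
        if name in dg_map:
            entry["truth"]["dg_h2o_kj"] = dg_map[name]
            entry["truth"]["m_value_kj_per_m"] = config.m_value_kj_per_m
            entry["denat"] = denat_trace(
                dg_map[name], config.m_value_kj_per_m, noise_sigma=sigma, rng=rng
            )
        if name in k_map:
            entry["truth"]["k"] = k_map[name]
            entry["kinetic"] = kinetic_trace(k_map[name], noise_sigma=sigma, rng=rng)
        out[name] = entry
    return out


# ---------------------------------------------------------------------------
# coordinates

def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR with sign fix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def generate_coordinates(
    n_points: int = 10,
    noise_sigma: float = 0.0,
    zn_ligand_distances: Sequence[float] = (),
    seed: int = 0,
) -> dict:
    """A Cα cloud, a rigid-transformed (optionally noised) copy, and PDB text.

    When ``zn_ligand_distances`` is given, the base structure also gains a
    Zn ion with one nitrogen ligand per requested distance.  Returns the
    two CoordSets, the true transform, and synthetic PDB text for each.
    """
    if n_points < 3:
        raise ValidationError("need >= 3 points")
    rng = np.random.default_rng(seed)
    xyz = rng.uniform(-10, 10, size=(n_points, 3))
    rot = random_rotation(rng)
    shift = rng.uniform(-20, 20, size=3)
    moved = xyz @ rot.T + shift
    if noise_sigma > 0:
        moved = moved + rng.normal(0.0, noise_sigma, size=moved.shape)

    def build(points: np.ndarray, with_metal: bool) -> CoordSet:
        atoms = [
            Atom(chain="A", res_number=i + 1, res_name="GLY", atom_name="CA",
                 xyz=tuple(float(v) for v in points[i]), element="C")
            for i in range(len(points))
        ]
        if with_metal and len(zn_ligand_distances) > 0:
            zn_pos = points.mean(axis=0) + np.array([30.0, 0.0, 0.0])
            atoms.append(Atom(chain="M", res_number=900, res_name="ZN",
                              atom_name="ZN", xyz=tuple(zn_pos), element="ZN"))
            for j, dist in enumerate(zn_ligand_distances):
                direction = np.zeros(3)
                direction[j % 3] = 1.0
                lig = zn_pos + dist * direction
                atoms.append(Atom(chain="M", res_number=901 + j, res_name="LIG",
                                  atom_name=f"N{j+1}", xyz=tuple(float(v) for v in lig),
                                  element="N"))
        return CoordSet(atoms=tuple(atoms))

    base = build(xyz, with_metal=True)
    transformed = build(moved, with_metal=False)
    return {
        "base": base,
        "transformed": transformed,
        "rotation": rot,
        "translation": shift,
        "noise_sigma": noise_sigma,
        "pdb_base": to_pdb_text(base),
        "pdb_transformed": to_pdb_text(transformed),
    }


def to_pdb_text(c: CoordSet) -> str:
    """Minimal PDB-format text (ATOM/HETATM records) for a CoordSet."""
    lines = []
    standard = {"GLY", "ALA", "SER", "CYS", "HIS", "ASP", "GLU", "LYS", "ARG"}
    for serial, a in enumerate(c.atoms, start=1):
        record = "ATOM  " if a.res_name in standard else "HETATM"
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        x, y, z = a.xyz
        lines.append(
            f"{record}{serial:5d} {name:<4.4s} {a.res_name:<3.3s} {a.chain:1.1s}"
            f"{a.res_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {a.element:>2.2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
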