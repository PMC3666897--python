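"""Metal-coordination consensus panel for Pol III/Pol C PHP domains.

Canonical PHP domains coordinate up to three catalytic metal ions through
nine conserved residues.  This module encodes that nine-position panel
(consensus residue sets H, H, D/H, H, E, H, C/H, D/N, H anchored to
E. coli Pol III residue numbers 10, 12, 19, 44, 69, 83, 134, 201, 203),
classifies individual PHP domains as canonical or variant, summarizes the
substitution spectrum of a cohort, detects absence of the loop carrying
the site-7 cysteine, and computes per-column conservation.

Two classification modes are provided:

``permissive``
    a residue matches if it is in the full consensus set of its site
    (e.g. N matches the D/N site);
``strict``
    only the primary (first-listed) consensus residue matches, so the
    D->N substitution seen in G. kaustophilus Pol C counts as a deviation.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .errors import AnchorError, RangeError, ValidationError
from .seq_io import Alignment, anchor_positions

Mode = Literal["permissive", "strict"]

#: ordered consensus residues per site; first entry of each tuple is primary
DEFAULT_CONSENSUS: tuple[tuple[str, ...], ...] = (
    ("H",),
    ("H",),
    ("D", "H"),
    ("H",),
    ("E",),
    ("H",),
    ("C", "H"),
    ("D", "N"),
    ("H",),
)

#: E. coli Pol III residue numbers of the nine panel positions
ECO_REF_POSITIONS: tuple[int, ...] = (10, 12, 19, 44, 69, 83, 134, 201, 203)

ECO_REF_ID = "Eco_PolIII"


@dataclass(frozen=True)
class SitePanel:
    """The ordered metal-coordinating positions and their consensus sets."""

    consensus: tuple[tuple[str, ...], ...] = DEFAULT_CONSENSUS
    ref_id: str = ECO_REF_ID
    ref_positions: tuple[int, ...] = ECO_REF_POSITIONS

    def __post_init__(self) -> None:
        if len(self.consensus) != len(self.ref_positions):
            raise ValidationError("panel consensus and ref_positions length mismatch")
        if any(not s for s in self.consensus):
            raise ValidationError("empty consensus set")
        if list(self.ref_positions) != sorted(set(self.ref_positions)):
            raise ValidationError("ref_positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.consensus)

    @property
    def consensus_sets(self) -> tuple[frozenset[str], ...]:
        return tuple(frozenset(s) for s in self.consensus)

    @property
    def primary(self) -> tuple[str, ...]:
        return tuple(s[0] for s in self.consensus)


def default_panel() -> SitePanel:
    """The nine-position panel with E. coli Pol III reference numbering."""
    return SitePanel()


@dataclass(frozen=True)
class PHPClassification:
    """Per-site match record and canonical/variant verdict for one sequence."""

    seq_id: str
    observed: tuple[str, ...]
    matches: tuple[bool, ...]
    mode: Mode

    @property
    def n_deviations(self) -> int:
        return sum(not m for m in self.matches)

    @property
    def label(self) -> str:
        return "canonical" if self.n_deviations == 0 else "variant"

    @property
    def deviating_sites(self) -> tuple[int, ...]:
        """1-based panel site indices at which the sequence deviates."""
        return tuple(i + 1 for i, m in enumerate(self.matches) if not m)


def classify_row(
    observed: Sequence[str], panel: SitePanel | None = None, mode: Mode = "permissive"
) -> PHPClassification:
    """Classify a row of observed panel residues against the consensus.

    ``observed`` holds one symbol per panel site; ``'-'`` marks an absent
    position and never matches (an absent residue cannot coordinate metal).
    """
    panel = panel or default_panel()
    obs = tuple(str(r).upper() for r in observed)
    if len(obs) != panel.n_sites:
        raise ValidationError(
            f"expected {panel.n_sites} residues, got {len(obs)}"
        )
    if mode not in ("permissive", "strict"):
        raise ValidationError(f"unknown mode {mode!r}")
    matches = []
    for site, residue in enumerate(obs):
        allowed = panel.consensus[site] if mode == "permissive" else panel.consensus[site][:1]
        matches.append(residue in allowed)
    return PHPClassification(seq_id="", observed=obs, matches=tuple(matches), mode=mode)


def classify_sequence(
    alignment: Alignment,
    seq_id: str,
    panel: SitePanel | None = None,
    mode: Mode = "permissive",
) -> PHPClassification:
    """Classify one aligned sequence at the panel columns of the reference."""
    panel = panel or default_panel()
    anchor = anchor_positions(alignment, panel.ref_id, panel.ref_positions)
    row = alignment.record(seq_id)
    observed = tuple(row.residues[c - 1] for c in anchor.columns)
    cls = classify_row(observed, panel, mode)
    return PHPClassification(
        seq_id=seq_id, observed=cls.observed, matches=cls.matches, mode=mode
    )


@dataclass(frozen=True)
class SubstitutionSpectrum:
    """Per-site residue counts and modal replacements across a cohort."""

    site_counts: tuple[Mapping[str, int], ...]
    modal_replacements: tuple[frozenset[str], ...]  # tied sets, empty if no deviants
    n_sequences: int
    loop_absent_fraction: float | None = None


def substitution_spectrum(
    classifications: Iterable[PHPClassification],
    loop_absent: Sequence[bool] | None = None,
) -> SubstitutionSpectrum:
    """Summarize observed residues and modal replacements per panel site.

    Modal replacements are computed over deviating sequences only; ties are
    reported as an unordered set, never broken silently.
    """
    cls = list(classifications)
    if not cls:
        raise ValidationError("no classifications supplied")
    n_sites = len(cls[0].observed)
    counts: list[Counter[str]] = [Counter() for _ in range(n_sites)]
    deviant_counts: list[Counter[str]] = [Counter() for _ in range(n_sites)]
    for c in cls:
        for site, (residue, ok) in enumerate(zip(c.observed, c.matches)):
            counts[site][residue] += 1
            if not ok:
                deviant_counts[site][residue] += 1
    modal = []
    for dc in deviant_counts:
        if not dc:
            modal.append(frozenset())
        else:
            top = max(dc.values())
            modal.append(frozenset(r for r, n in dc.items() if n == top))
    frac = None
    if loop_absent is not None:
        flags = list(loop_absent)
        frac = sum(flags) / len(flags) if flags else 0.0
    return SubstitutionSpectrum(
        site_counts=tuple(dict(c) for c in counts),
        modal_replacements=tuple(modal),
        n_sequences=len(cls),
        loop_absent_fraction=frac,
    )


def detect_loop_absence(
    alignment: Alignment,
    seq_id: str,
    panel: SitePanel | None = None,
    window: int = 5,
    gap_threshold: float = 0.8,
) -> bool:
    """True when the loop around the site-7 position is gapped out.

    Looks at ``window`` alignment columns on each side of the anchored
    site-7 column (11 columns by default) and reports absence when the
    gap fraction of the sequence over that window exceeds ``gap_threshold``.
    """
    panel = panel or default_panel()
    anchor = anchor_positions(alignment, panel.ref_id, panel.ref_positions)
    site7_col = anchor.columns[6]
    lo, hi = site7_col - window, site7_col + window
    if lo < 1 or hi > alignment.length:
        raise RangeError(
            f"loop window [{lo},{hi}] outside alignment of length {alignment.length}"
        )
    segment = alignment.record(seq_id).residues[lo - 1 : hi]
    gap_fraction = segment.count("-") / len(segment)
    return gap_fraction > gap_threshold


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation scores in [0, 1] with high-gap flags."""

    scores: tuple[float, ...]
    gappy: tuple[bool, ...]


def conservation_profile(
    alignment: Alignment, gap_flag_threshold: float = 0.5
) -> ConservationProfile:
    """Entropy-based conservation: 1 - H_col / log2(20) over non-gap residues.

    An invariant column scores 1; a column uniform over all twenty residues
    scores 0.  Columns whose gap fraction exceeds ``gap_flag_threshold`` are
    flagged; an all-gap column scores 0 and is flagged.
    """
    if len(alignment.records) < 2:
        raise ValidationError("conservation requires at least two sequences")
    max_entropy = math.log2(20)
    scores, gappy = [], []
    n_rows = len(alignment.records)
    for col in range(alignment.length):
        residues = [r.residues[col] for r in alignment.records]
        non_gap = [x for x in residues if x != "-"]
        gap_fraction = 1 - len(non_gap) / n_rows
        gappy.append(gap_fraction > gap_flag_threshold)
        if not non_gap:
            scores.append(0.0)
            continue
        freqs = Counter(non_gap)
        total = len(non_gap)
        entropy = -sum((n / total) * math.log2(n / total) for n in freqs.values())
        scores.append(max(0.0, 1.0 - entropy / max_entropy))
    return ConservationProfile(scores=tuple(scores), gappy=tuple(gappy))


def load_panel(path) -> SitePanel:
    """Read a panel definition from a YAML file.

    Expected keys: ``ref_id``, ``sites`` — a list of mappings with
    ``position`` (reference residue number) and ``consensus`` (ordered
    residue string, primary first, e.g. "DN").
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        sites = sorted(doc["sites"], key=lambda s: int(s["position"]))
        consensus = tuple(tuple(str(s["consensus"]).upper()) for s in sites)
        positions = tuple(int(s["position"]) for s in sites)
        return SitePanel(consensus=consensus, ref_id=str(doc["ref_id"]),
                         ref_positions=positions)
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: malformed panel definition: {exc}") from exc


def classification_table(classifications: Iterable[PHPClassification]) -> str:
    """Tab-delimited report: seq_id, nine observed residues, n_deviations, label."""
    lines = ["seq_id\t" + "\t".join(f"site{i}" for i in range(1, 10)) + "\tn_deviations\tlabel"]
    for c in classifications:
        lines.append(
            "\t".join([c.seq_id, *c.observed, str(c.n_deviations), c.label])
        )
    return "\n".join(lines) + "\n"
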