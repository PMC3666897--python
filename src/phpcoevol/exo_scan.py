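"""DEDD-superfamily exonuclease motif scanning and epsilon-subunit calls.

DEDD exonucleases carry four strictly conserved acidic residues (D, E, D,
D) spread over three sequence motifs (ExoI, ExoII, ExoIII) that together
coordinate two catalytic metal ions.  A fifth conserved residue near the
last motif splits the superfamily into DEDDh (histidine) and DEDDy
(tyrosine).  A "bona fide" epsilon proofreading subunit is defined as a
DEDDh exonuclease that also carries the C-terminal tail used to bind the
polymerase alpha subunit, recognized here through its conserved His/Trp
pair (His 225 and Trp 241 in E. coli, 16 residues apart).

The motif patterns are deliberately simple and fully configurable: the
family definition is four acidic anchors plus the fifth H/Y, so the
defaults encode the classical arrangement (ExoI = D-x-E; ExoII = D;
ExoIII = H/Y followed by D five residues later, matching the E. coli
DnaQ anchors D12/E14/D103/D167 with catalytic H162) with permissive
spacing bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .errors import ValidationError
from .seq_io import SequenceRecord

Subtype = Literal["DEDDh", "DEDDy", "undetermined"]


@dataclass(frozen=True)
class ExoMotifConfig:
    """Spacing and pattern parameters of the DEDD/tail scanner.

    Positions are 1-based.  ``exo1_gap`` is the offset from the ExoI D to
    its E (2 = one intervening residue, D-x-E).  Spacing bounds are gaps
    between consecutive anchor positions, inclusive.
    """

    exo1_gap: int = 2
    exo12_spacing: tuple[int, int] = (20, 150)   # ExoI E -> ExoII D
    exo23_spacing: tuple[int, int] = (20, 150)   # ExoII D -> fifth residue
    fifth_to_acid: int = 5                       # fifth residue -> ExoIII D
    min_length: int = 50
    tail_window: int = 60                        # C-terminal segment searched
    tail_spacing: tuple[int, int] = (10, 25)     # His -> Trp gap, brackets Eco 16

    def __post_init__(self) -> None:
        for lo, hi in (self.exo12_spacing, self.exo23_spacing, self.tail_spacing):
            if lo > hi or lo < 1:
                raise ValidationError("spacing bounds must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class ExoAnnotation:
    """Motif hits, subtype, tail detection and the epsilon verdict."""

    seq_id: str
    dedd_found: bool
    anchor_positions: tuple[int, int, int, int] | None = None
    fifth_position: int | None = None
    subtype: Subtype = "undetermined"
    tail_found: bool = False
    tail_positions: tuple[int, int] | None = None
    candidates: tuple[tuple[int, int, int, int], ...] = ()

    @property
    def bona_fide_epsilon(self) -> bool:
        return self.dedd_found and self.subtype == "DEDDh" and self.tail_found


def _check_unaligned(seq: SequenceRecord) -> str:
    if "-" in seq.residues:
        raise ValidationError(
            f"{seq.id}: motif scan operates on unaligned sequence (contains gaps)"
        )
    return seq.residues


def _dedd_arrangements(s: str, cfg: ExoMotifConfig):
    """All complete DEDD arrangements, ordered by (exo1, exo2, fifth) position.

    Yields tuples (d1, e1, d2, d3, fifth_pos, fifth_residue), 1-based.
    """
    n = len(s)
    exo1 = [
        i for i in range(n - cfg.exo1_gap)
        if s[i] == "D" and s[i + cfg.exo1_gap] == "E"
    ]
    for i in exo1:
        e1 = i + cfg.exo1_gap
        lo2, hi2 = e1 + cfg.exo12_spacing[0], e1 + cfg.exo12_spacing[1]
        for j in range(lo2, min(hi2 + 1, n)):
            if s[j] != "D":
                continue
            lo3, hi3 = j + cfg.exo23_spacing[0], j + cfg.exo23_spacing[1]
            for q in range(lo3, min(hi3 + 1, n - cfg.fifth_to_acid)):
                if s[q] in "HY" and s[q + cfg.fifth_to_acid] == "D":
                    yield (i + 1, e1 + 1, j + 1, q + cfg.fifth_to_acid + 1, q + 1, s[q])


def scan_dedd(seq: SequenceRecord, config: ExoMotifConfig | None = None) -> ExoAnnotation:
    """Locate the leftmost complete DEDD arrangement and its subtype.

    The leftmost complete arrangement (lexicographic on anchor positions)
    wins; all candidate anchor quadruples are retained in ``candidates``.
    """
    cfg = config or ExoMotifConfig()
    s = _check_unaligned(seq)
    if len(s) < cfg.min_length:
        raise ValidationError(
            f"{seq.id}: sequence shorter than minimum scan length {cfg.min_length}"
        )
    hits = list(_dedd_arrangements(s, cfg))
    if not hits:
        return ExoAnnotation(seq_id=seq.id, dedd_found=False)
    d1, e1, d2, d3, fifth_pos, fifth = hits[0]
    subtype: Subtype = "DEDDh" if fifth == "H" else "DEDDy"
    return ExoAnnotation(
        seq_id=seq.id,
        dedd_found=True,
        anchor_positions=(d1, e1, d2, d3),
        fifth_position=fifth_pos,
        subtype=subtype,
        candidates=tuple(h[:4] for h in hits),
    )


def detect_tail(
    seq: SequenceRecord, config: ExoMotifConfig | None = None
) -> tuple[bool, tuple[int, int] | None]:
    """Find the alpha-binding-tail His/Trp pair in the C-terminal segment.

    Searches the last ``tail_window`` residues for a His followed by a Trp
    whose gap lies within ``tail_spacing`` (inclusive); the first such pair
    (leftmost His, then leftmost Trp) is reported with 1-based positions.
    """
    cfg = config or ExoMotifConfig()
    s = _check_unaligned(seq)
    start = max(0, len(s) - cfg.tail_window)
    lo, hi = cfg.tail_spacing
    for h in range(start, len(s)):
        if s[h] != "H":
            continue
        for w in range(h + lo, min(h + hi + 1, len(s))):
            if s[w] == "W":
                return True, (h + 1, w + 1)
    return False, None


def annotate(seq: SequenceRecord, config: ExoMotifConfig | None = None) -> ExoAnnotation:
    """Full annotation: DEDD scan plus tail detection."""
    ann = scan_dedd(seq, config)
    tail_found, tail_positions = detect_tail(seq, config)
    return ExoAnnotation(
        seq_id=ann.seq_id,
        dedd_found=ann.dedd_found,
        anchor_positions=ann.anchor_positions,
        fifth_position=ann.fifth_position,
        subtype=ann.subtype,
        tail_found=tail_found,
        tail_positions=tail_positions,
        candidates=ann.candidates,
    )


def call_epsilon(annotation: ExoAnnotation) -> bool:
    """Bona fide epsilon: DEDDh exonuclease with the alpha-binding tail."""
    return annotation.bona_fide_epsilon


def load_motif_config(path) -> ExoMotifConfig:
    """Read scanner parameters from a YAML file; absent keys keep defaults."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f for f in ExoMotifConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValidationError(f"{path}: unknown motif config keys {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in doc.items()
    }
    return ExoMotifConfig(**kwargs)


def annotation_table(annotations: Iterable[ExoAnnotation]) -> str:
    """Tab-delimited report of motif hits and epsilon verdicts."""
    lines = [
        "seq_id\tdedd_found\tanchors\tsubtype\ttail_found\ttail_positions\tbona_fide_epsilon"
    ]
    for a in annotations:
        anchors = ",".join(map(str, a.anchor_positions)) if a.anchor_positions else "-"
        tail = ",".join(map(str, a.tail_positions)) if a.tail_positions else "-"
        lines.append(
            "\t".join(
                [
                    a.seq_id,
                    str(a.dedd_found),
                    anchors,
                    a.subtype,
                    str(a.tail_found),
                    tail,
                    str(a.bona_fide_epsilon),
                ]
            )
        )
    return "\n".join(lines) + "\n"
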