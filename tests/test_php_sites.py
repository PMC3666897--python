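import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import TABLE_ROWS
from phpcoevol.errors import RangeError, ValidationError
from phpcoevol.php_sites import (
    classify_row,
    classify_sequence,
    conservation_profile,
    default_panel,
    detect_loop_absence,
    substitution_spectrum,
)
from phpcoevol.seq_io import Alignment, SequenceRecord


def test_default_panel_shape():
    panel = default_panel()
    assert panel.n_sites == 9
    assert panel.ref_positions[0] == 10
    assert panel.consensus_sets[7] == frozenset({"D", "N"})
    assert panel.primary == ("H", "H", "D", "H", "E", "H", "C", "D", "H")


@pytest.mark.parametrize(
    "name,permissive,strict,sites",
    [
        ("Eco", 5, 5, (1, 4, 5, 7, 9)),
        ("Taq", 0, 0, ()),
        ("Gka", 0, 1, ()),
        ("3mPHP", 2, 2, (5, 7)),
        ("4mPHP", 1, 1, (5,)),
        ("5mPHP", 0, 0, ()),
    ],
)
def test_characterized_polymerases(name, permissive, strict, sites):
    row = list(TABLE_ROWS[name])
    perm = classify_row(row, mode="permissive")
    assert perm.n_deviations == permissive
    assert perm.deviating_sites == sites
    assert perm.label == ("canonical" if permissive == 0 else "variant")
    assert classify_row(row, mode="strict").n_deviations == strict


def test_restoration_path_is_monotone():
    """The engineered revertant series repairs deviations one at a time."""
    devs = [classify_row(list(TABLE_ROWS[n])).n_deviations for n in ("3mPHP", "4mPHP", "5mPHP")]
    assert devs == [2, 1, 0]
    assert classify_row(list(TABLE_ROWS["5mPHP"])).label == "canonical"


@given(st.lists(st.sampled_from("ACDEFGHIKLMNPQRSTVWY-"), min_size=9, max_size=9))
@settings(max_examples=200, deadline=None)
def test_permissive_never_exceeds_strict(row):
    perm = classify_row(row, mode="permissive").n_deviations
    strict = classify_row(row, mode="strict").n_deviations
    assert perm <= strict


def test_gap_counts_as_deviation():
    row = list(TABLE_ROWS["Taq"])
    row[6] = "-"
    cls = classify_row(row)
    assert cls.n_deviations == 1 and cls.deviating_sites == (7,)


def test_wrong_arity_rejected():
    with pytest.raises(ValidationError):
        classify_row(list("HHDH"))


def _panel_alignment(rows: dict[str, str]) -> Alignment:
    """Build an alignment whose reference carries the panel at its own numbering."""
    panel = default_panel()
    length = max(panel.ref_positions) + 5
    records = []
    base = ["A"] * length
    for col, res in zip(panel.ref_positions, panel.primary):
        base[col - 1] = res
    records.append(SequenceRecord(id=panel.ref_id, residues="".join(base)))
    for name, panel_row in rows.items():
        seq = list(base)
        for col, res in zip(panel.ref_positions, panel_row):
            seq[col - 1] = res
        records.append(SequenceRecord(id=name, residues="".join(seq)))
    return Alignment(records=tuple(records))


def test_classify_sequence_extracts_anchored_columns():
    aln = _panel_alignment(TABLE_ROWS)
    ref_cls = classify_sequence(aln, default_panel().ref_id)
    assert ref_cls.n_deviations == 0  # reference carries the primary consensus
    for name, expected in [("Eco", 5), ("Taq", 0), ("3mPHP", 2)]:
        assert classify_sequence(aln, name).n_deviations == expected
    eco = classify_sequence(aln, "Eco")
    assert "".join(eco.observed) == TABLE_ROWS["Eco"]


def test_substitution_spectrum_modal_and_ties():
    single = [classify_row(list(TABLE_ROWS["Eco"]))]
    spec = substitution_spectrum(single)
    assert spec.modal_replacements[0] == frozenset({"R"})
    assert spec.site_counts[0] == {"R": 1}
    canon = [classify_row(list(TABLE_ROWS["Taq"]))] * 3
    assert all(m == frozenset() for m in substitution_spectrum(canon).modal_replacements)
    tied = [classify_row(list("RHDHEHCDH")), classify_row(list("QHDHEHCDH"))]
    assert substitution_spectrum(tied).modal_replacements[0] == frozenset({"R", "Q"})


def test_substitution_spectrum_counts_sum():
    rows = [TABLE_ROWS[n] for n in TABLE_ROWS]
    spec = substitution_spectrum([classify_row(list(r)) for r in rows])
    for counts in spec.site_counts:
        assert sum(counts.values()) == len(rows)


def test_loop_absence():
    aln = _panel_alignment({"full": TABLE_ROWS["Taq"]})
    panel = default_panel()
    assert detect_loop_absence(aln, "full") is False
    # gap out 11 columns around site 7
    site7 = panel.ref_positions[6]
    rec = aln.record("full")
    gapped = list(rec.residues)
    for c in range(site7 - 5, site7 + 6):
        gapped[c - 1] = "-"
    aln2 = Alignment(records=(aln.records[0], SequenceRecord(id="full", residues="".join(gapped))))
    assert detect_loop_absence(aln2, "full") is True
    with pytest.raises(RangeError):
        detect_loop_absence(aln, "full", window=10**6)


def test_conservation_closed_forms():
    rows = ["AC", "AD"]
    aln = Alignment(records=tuple(SequenceRecord(id=f"s{i}", residues=r) for i, r in enumerate(rows)))
    prof = conservation_profile(aln)
    assert prof.scores[0] == pytest.approx(1.0)
    assert prof.scores[1] == pytest.approx(1 - 1 / math.log2(20))
    # uniform over all twenty residues -> score 0
    aln20 = Alignment(
        records=tuple(SequenceRecord(id=f"u{i}", residues=c) for i, c in enumerate("ACDEFGHIKLMNPQRSTVWY"))
    )
    assert conservation_profile(aln20).scores[0] == pytest.approx(0.0)


def test_conservation_order_invariant_and_degenerate():
    rows = ["ACD", "AVD", "AVE"]
    fwd = Alignment(records=tuple(SequenceRecord(id=f"a{i}", residues=r) for i, r in enumerate(rows)))
    rev = Alignment(records=tuple(SequenceRecord(id=f"b{i}", residues=r) for i, r in enumerate(rows[::-1])))
    assert conservation_profile(fwd).scores == conservation_profile(rev).scores
    with pytest.raises(ValidationError):
        conservation_profile(Alignment(records=(SequenceRecord(id="x", residues="MK"),)))


def test_load_panel_from_yaml(tmp_path):
    p = tmp_path / "panel.yaml"
    p.write_text(
        "ref_id: myref\n"
        "sites:\n"
        "  - {position: 10, consensus: H}\n"
        "  - {position: 19, consensus: DH}\n"
        "  - {position: 201, consensus: DN}\n"
    )
    from phpcoevol.php_sites import load_panel

    panel = load_panel(p)
    assert panel.ref_id == "myref"
    assert panel.ref_positions == (10, 19, 201)
    assert panel.consensus_sets[1] == frozenset({"D", "H"})
    assert panel.primary == ("H", "D", "D")
    p.write_text("sites: nope\n")
    with pytest.raises(ValidationError):
        load_panel(p)
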