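"""Splice-aware frame annotation, minimal region, cohort summaries."""

import itertools

import pytest

from ubtftd.annotate import (
    TDAnnotation,
    minimal_duplicated_region,
    splice_aware_frame,
    summarize_cohort,
)
from ubtftd.errors import CoordinateError
from ubtftd.synthetic import CohortSpec, TDSpec, sample_cohort


def test_exonic_48_in_frame(gm):
    ann = splice_aware_frame(TDSpec(700, 748), gm)
    assert ann.in_frame and ann.spliced_inserted_length == 48
    assert ann.contains_core and ann.category == "core"
    assert "ELLTRLA" in ann.peptide
    assert ann.leucine_rich
    assert ann.exon_span == ["exon13"]


def test_intron_spanning_598_exon13_exon13_product(gm):
    """A 598-bp duplication spanning exons 12-14 splices to an in-frame
    product carrying exon 13 twice, although 598 is not a multiple of 3."""
    ann = splice_aware_frame(TDSpec(460, 1058), gm)
    assert 598 % 3 != 0
    assert ann.in_frame
    assert ann.spliced_inserted_length % 3 == 0
    assert ann.exon13_duplicated
    assert ann.exon_span == ["exon12", "exon13", "exon14"]


def test_out_of_frame_47(gm):
    ann = splice_aware_frame(TDSpec(700, 747), gm)
    assert ann.in_frame is False
    assert ann.spliced_inserted_length == 47


def test_non_core_42_leucine_rich(gm):
    ann = splice_aware_frame(TDSpec(753, 795), gm)
    assert not ann.contains_core
    assert ann.in_frame and ann.peptide == "GLCLRFNQLDLDQA"
    assert ann.category == "non-core leucine-rich"


def test_splice_disrupting_breakpoint(gm):
    donor_mid = gm.exons[0][1] + 1  # between G and T of the exon-12 donor
    ann = splice_aware_frame(TDSpec(460, donor_mid), gm)
    assert ann.splice_disrupting and ann.in_frame is None
    assert ann.category == "splice-disrupting"


def test_insert_spliced_out_when_junction_intronic(gm):
    # junction (dup_end) in intron 12: the non-templated insert is intronic
    td_intronic = TDSpec(550, 900)  # wholly intronic ends around exon 13
    ann = splice_aware_frame(td_intronic, gm)
    assert ann.spliced_inserted_length == 189  # exactly the exon-13 content
    assert ann.in_frame


def _ann(iv):
    return TDAnnotation(True, None, "", True, True, [], iv, False, False, "core")


def test_minimal_region_interval_intersection():
    annotated = [
        ("a", _ann((1300, 1351))),
        ("b", _ann((1306, 1340))),
        ("c", _ann((1290, 1327))),
    ]
    region, excluded, _ = minimal_duplicated_region(annotated)
    assert region == (1306, 1327)
    assert excluded == []


def test_minimal_region_order_invariant_and_idempotent():
    base = [("a", _ann((1300, 1351))), ("b", _ann((1306, 1340))), ("c", _ann((1290, 1327)))]
    results = {
        minimal_duplicated_region(list(perm))[0] for perm in itertools.permutations(base)
    }
    assert results == {(1306, 1327)}
    region, _, _ = minimal_duplicated_region([("r", _ann((1306, 1327)))])
    assert region == (1306, 1327)


def test_minimal_region_single_call_identity():
    region, _, _ = minimal_duplicated_region([("only", _ann((1290, 1400)))])
    assert region == (1290, 1400)


def test_minimal_region_disjoint_reports_none():
    region, _, diags = minimal_duplicated_region(
        [("a", _ann((1300, 1310))), ("b", _ann((1320, 1330)))]
    )
    assert region is None and diags


def test_minimal_region_requires_core_call():
    ann = _ann((1300, 1310))
    ann.contains_core = False
    with pytest.raises(CoordinateError):
        minimal_duplicated_region([("a", ann)])


def test_cohort_summary_printed_fractions(gm):
    """A cohort with the printed 18/10/6-of-59 size counts gives 58%."""
    tds = []
    sizes = [48] * 18 + [51] * 10 + [54] * 6 + [63] * 25
    for i, size in enumerate(sizes):
        td = TDSpec(717 - (size - 21) // 2, 717 - (size - 21) // 2 + size)
        tds.append((f"P{i}", td))
    # plant deletions in 15 of 59 (25%)
    for i in range(15):
        pid, td = tds[i]
        tds[i] = (pid, TDSpec(td.dup_start, td.dup_end + 3, "", ((744, 747),)))
    summary = summarize_cohort(tds, gm)
    assert summary.fraction_sizes_48_51_54 == pytest.approx(34 / 59)
    assert round(100 * summary.fraction_sizes_48_51_54) == 58
    assert summary.fraction_with_deletion == pytest.approx(15 / 59)


def test_cohort_summary_no_deletions(gm):
    tds = [(f"P{i}", TDSpec(700, 748)) for i in range(5)]
    s = summarize_cohort(tds, gm)
    assert s.fraction_with_deletion == 0.0
    assert s.size_histogram == {48: 5}


def test_sampled_cohort_all_in_frame_with_planted_core(gm):
    patients = sample_cohort(CohortSpec(n_patients=400, seed=21), gm)
    summary = summarize_cohort([(p.patient_id, p.td) for p in patients], gm)
    assert summary.fraction_in_frame == 1.0
    assert summary.minimal_region == (1306, 1327)  # c.1306-c.1326
    assert summary.minimal_region_length == 21
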