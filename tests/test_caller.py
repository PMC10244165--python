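"""TD caller: suspicion scan, clip clustering, reconstruction, VAF."""

import numpy as np
import pytest

from ubtftd.caller import (
    CallerConfig,
    call_tds,
    cluster_softclips,
    collect_cigar_insertions,
    suspicion_scan,
)
from ubtftd.errors import ConfigError
from ubtftd.synthetic import ReadSimConfig, TDSpec, mutate_locus, simulate_reads

WINDOW = (0, 1521)


def test_suspicion_scan_negative_on_wild_type(gm):
    sim = simulate_reads(gm, [(gm.sequence, 1.0, None)], ReadSimConfig(seed=20, depth=300))
    suspicious, summary = suspicion_scan(sim.reads, gm, WINDOW)
    assert not suspicious
    assert summary["clip_reads"] == 0


@pytest.mark.parametrize("td", [TDSpec(700, 748), TDSpec(460, 1058)])
def test_suspicion_scan_positive_on_td(gm, td):
    mut = mutate_locus(gm, td)
    sim = simulate_reads(
        gm, [(gm.sequence, 0.55, None), (mut, 0.45, td)], ReadSimConfig(seed=21)
    )
    suspicious, _ = suspicion_scan(sim.reads, gm, WINDOW)
    assert suspicious


def test_suspicion_scan_empty_window_errors(gm):
    with pytest.raises(ConfigError):
        suspicion_scan([], gm, (500, 500))


def test_cluster_softclips_wild_type_empty(gm):
    sim = simulate_reads(gm, [(gm.sequence, 1.0, None)], ReadSimConfig(seed=22, depth=300))
    assert cluster_softclips(sim.reads) == []


def test_small_td_evidence_right_clips_and_insertions(gm):
    """For a 48-bp TD with 150-bp reads the junction shows right-clips at
    the 3' breakpoint plus CIGAR insertions; reads whose anchor on the 5'
    side is too short never clear the clip-length threshold."""
    td = TDSpec(700, 748, allele_fraction=0.45)
    mut = mutate_locus(gm, td)
    sim = simulate_reads(
        gm, [(gm.sequence, 0.55, None), (mut, 0.45, td)], ReadSimConfig(seed=23)
    )
    clusters = cluster_softclips(sim.reads)
    assert [(c.side, c.breakpoint) for c in clusters] == [("right", 748)]
    ins = collect_cigar_insertions(sim.reads)
    assert len(ins) == 1 and ins[0].breakpoint == 748
    assert len(ins[0].clip_consensus) == 48


def test_large_td_clip_pair_at_both_junctions(gm):
    td = TDSpec(460, 1058, allele_fraction=0.45)
    mut = mutate_locus(gm, td)
    sim = simulate_reads(
        gm, [(gm.sequence, 0.55, None), (mut, 0.45, td)], ReadSimConfig(seed=24)
    )
    clusters = cluster_softclips(sim.reads)
    assert {(c.side, c.breakpoint) for c in clusters} == {("left", 460), ("right", 1058)}


def test_call_perfect_48(gm, simulate_and_call):
    _, calls = simulate_and_call(TDSpec(700, 748, allele_fraction=0.45), 0.45, 25)
    assert len(calls) == 1
    td = calls[0].reconstructed
    assert (td.dup_start, td.dup_end) == (700, 748)
    assert td.insert == "" and td.deletions == ()
    assert td.total_inserted_length == 48
    assert calls[0].suspicion_flag


def test_call_composite_recovers_insert_and_deletion(gm, simulate_and_call):
    truth = TDSpec(700, 751, "ACG", ((744, 750),), allele_fraction=0.45)
    _, calls = simulate_and_call(truth, 0.45, 26)
    assert len(calls) == 1
    td = calls[0].reconstructed
    assert td.total_inserted_length == 48
    assert td.insert == "ACG"
    assert len(td.deletions) == 1 and td.deletions[0][1] - td.deletions[0][0] == 6
    # the reconstructed haplotype is sequence-identical to the planted one
    assert mutate_locus(gm, td) == mutate_locus(gm, truth)


def test_call_large_598(gm, simulate_and_call):
    _, calls = simulate_and_call(TDSpec(460, 1058, allele_fraction=0.45), 0.45, 27)
    assert len(calls) == 1
    call = calls[0]
    assert call.evidence == "clip_pair"
    assert abs(call.reconstructed.total_inserted_length - 598) <= 5
    assert abs(call.vaf - 0.45) <= 0.07


def test_two_co_occurring_tds_resolved(gm):
    td_a = TDSpec(700, 748)
    td_b = TDSpec(690, 792)  # second haplotype with a distinct 102-bp TD
    mut_a, mut_b = mutate_locus(gm, td_a), mutate_locus(gm, td_b)
    sim = simulate_reads(
        gm,
        [(gm.sequence, 0.4, None), (mut_a, 0.3, td_a), (mut_b, 0.3, td_b)],
        ReadSimConfig(seed=28),
    )
    clusters = cluster_softclips(sim.reads)
    assert len(clusters) + len(collect_cigar_insertions(sim.reads)) >= 3
    calls = call_tds(sim.reads, gm)
    intervals = {(c.reconstructed.dup_start, c.reconstructed.dup_end) for c in calls}
    assert intervals == {(700, 748), (690, 792)}


def test_vaf_estimates_in_band(gm, simulate_and_call):
    _, calls = simulate_and_call(TDSpec(700, 748, allele_fraction=0.45), 0.45, 29)
    assert 0.40 <= calls[0].vaf_breakpoint <= 0.50
    assert calls[0].vaf_method == "breakpoint"


def test_vaf_homozygous_near_one(gm, simulate_and_call):
    _, calls = simulate_and_call(TDSpec(460, 1058), 1.0, 30)
    call = calls[0]
    assert call.vaf_breakpoint == pytest.approx(1.0, abs=0.05)
    assert call.vaf_coverage == pytest.approx(1.0, abs=0.15)


def test_vaf_grid_mean_absolute_error(gm, simulate_and_call):
    """Junction VAF is unbiased over f in 0.1..0.9 at 2000x (MC check)."""
    errs = []
    for f in (0.1, 0.3, 0.5, 0.7, 0.9):
        for rep in range(3):
            _, calls = simulate_and_call(
                TDSpec(700, 748, allele_fraction=f), f, 1000 + int(f * 100) + rep, depth=2000
            )
            errs.append(abs(calls[0].vaf_breakpoint - f))
    assert float(np.mean(errs)) <= 0.03


def test_breakpoint_and_coverage_vaf_agree_for_large_td(gm, simulate_and_call):
    _, calls = simulate_and_call(TDSpec(460, 1058, allele_fraction=0.45), 0.45, 31, depth=1000)
    call = calls[0]
    assert abs(call.vaf_breakpoint - call.vaf_coverage) <= 0.08


def test_no_false_calls_on_wild_type(gm):
    for seed in range(100):
        sim = simulate_reads(
            gm, [(gm.sequence, 1.0, None)], ReadSimConfig(seed=5000 + seed, depth=300)
        )
        assert call_tds(sim.reads, gm) == []


def test_recall_small_tds(gm, simulate_and_call):
    """Recall and exact size on 60 seeded draws of 39-120-bp TDs, f >= 0.2."""
    rng = np.random.default_rng(77)
    hits = 0
    n = 60
    for rep in range(n):
        size = int(rng.integers(13, 41)) * 3  # 39..120, in frame
        f = float(rng.uniform(0.2, 0.9))
        p1 = int(rng.integers(738 - size, 718)) if size >= 21 else 700
        td = TDSpec(p1, p1 + size, allele_fraction=f)
        _, calls = simulate_and_call(td, f, 40_000 + rep, depth=300)
        if calls and calls[0].reconstructed is not None:
            hits += calls[0].reconstructed.total_inserted_length == size
    assert hits / n >= 0.98


def test_recall_large_tds(gm, simulate_and_call):
    """TDs longer than the read length: recall >= 0.9, size within 5 bp."""
    rng = np.random.default_rng(78)
    hits = 0
    n = 20
    for rep in range(n):
        size = int(rng.integers(200, 800))
        p1 = int(rng.integers(max(0, 738 - size), min(718, 1521 - size)))
        td = TDSpec(p1, p1 + size, allele_fraction=0.45)
        _, calls = simulate_and_call(td, 0.45, 50_000 + rep, depth=300)
        if calls and calls[0].reconstructed is not None:
            hits += abs(calls[0].reconstructed.total_inserted_length - size) <= 5
    assert hits / n >= 0.9


def test_calls_below_reporting_floor_suppressed(gm):
    td = TDSpec(700, 748, allele_fraction=0.005)
    mut = mutate_locus(gm, td)
    sim = simulate_reads(
        gm, [(gm.sequence, 0.995, None), (mut, 0.005, td)], ReadSimConfig(seed=32, depth=300)
    )
    calls = call_tds(sim.reads, gm)
    assert all(c.vaf is None or c.vaf >= 0.01 for c in calls)
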