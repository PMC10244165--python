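"""Synthetic-data generator: TD construction, cohort statistics, reads."""

import numpy as np
import pytest

from ubtftd.caller import _coverage
from ubtftd.clonal import CNState
from ubtftd.errors import ArchitectureError, ConfigError, TDSpecError
from ubtftd.synthetic import (
    CohortSpec,
    PlantedClone,
    ReadSimConfig,
    TDSpec,
    cohort_to_frame,
    mutate_locus,
    sample_cohort,
    simulate_paired_timepoints,
    simulate_reads,
    simulate_trace,
)


# ---------------------------------------------------------------------------
# TDSpec and mutate_locus
# ---------------------------------------------------------------------------

def test_tdspec_length_arithmetic():
    td = TDSpec(700, 751, "ACG", ((744, 750),))
    assert td.dup_length == 51
    assert td.total_inserted_length == 51 + 3 - 6
    assert td.kept_copy_intervals() == [(700, 744), (750, 751)]


def test_tdspec_validation():
    with pytest.raises(TDSpecError):
        TDSpec(700, 748, deletions=((690, 700),))  # deletion outside duplication
    with pytest.raises(TDSpecError):
        TDSpec(700, 690)
    with pytest.raises(TDSpecError):
        TDSpec(700, 748, allele_fraction=0.0)
    with pytest.raises(TDSpecError):
        TDSpec(700, 748, insert="ACGX")


def test_mutate_locus_perfect_48(gm):
    mut = mutate_locus(gm, TDSpec(700, 748))
    assert len(mut) == gm.sequence_length + 48
    # the duplicated segment appears twice in tandem
    assert mut[700:748] == mut[748:796] == gm.sequence[700:748]
    # the screening amplicon grows to the Fig-style 665 bp
    assert (gm.reverse_primer_pos + 48) - gm.forward_primer_pos == 665


def test_mutate_locus_empty_td_is_identity(gm):
    assert mutate_locus(gm, TDSpec(700, 700)) == gm.sequence


def test_mutate_locus_composite(gm):
    td = TDSpec(700, 751, "ACG", ((744, 750),))
    mut = mutate_locus(gm, td)
    assert len(mut) == gm.sequence_length + 48
    copy = gm.sequence[700:744] + gm.sequence[750:751]
    assert mut[751 : 751 + 3 + len(copy)] == "ACG" + copy


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

def test_degenerate_size_weights_all_48(gm):
    spec = CohortSpec(n_patients=10, td_size_weights={48: 1.0}, p_non_core=0.0, seed=1)
    patients = sample_cohort(spec, gm)
    assert len(patients) == 10
    assert all(p.td.total_inserted_length == 48 for p in patients)


def test_cohort_spec_validation():
    with pytest.raises(ConfigError):
        CohortSpec(n_patients=0)
    with pytest.raises(ConfigError):
        CohortSpec(td_size_weights={48: 1.5})
    with pytest.raises(ConfigError):
        CohortSpec(p_internal_deletion_small=-0.1)


def test_cohort_distributions_at_n5000(gm):
    patients = sample_cohort(CohortSpec(n_patients=5000, seed=11), gm)
    df = cohort_to_frame(patients, gm)
    sizes = df.total_inserted_length.to_numpy()
    assert abs(np.isin(sizes, (48, 51, 54)).mean() - 0.58) < 0.02
    has_del = (df.deletions.str.len() > 0).to_numpy()
    assert abs(has_del[sizes > 100].mean() - 0.64) < 0.03
    assert abs(has_del[sizes <= 100].mean() - 0.13) < 0.03
    assert abs(df.allele_fraction.median() - 0.45) < 0.02
    assert sizes.min() >= 39 and sizes.max() <= 950
    # all but the rare non-core class contain the ELLTRLA core
    assert df.contains_core[~df.non_core].all()


def test_cohort_deterministic(gm):
    a = cohort_to_frame(sample_cohort(CohortSpec(n_patients=50, seed=3), gm), gm)
    b = cohort_to_frame(sample_cohort(CohortSpec(n_patients=50, seed=3), gm), gm)
    assert a.equals(b)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def test_wild_type_sample_has_no_clips_or_insertions(gm):
    sim = simulate_reads(gm, [(gm.sequence, 1.0, None)], ReadSimConfig(seed=5, depth=300))
    for read in sim.reads:
        assert all(op in (0,) for op, _ in read.cigartuples)


def test_junction_reads_recorded_in_truth(gm):
    td = TDSpec(700, 748, allele_fraction=0.45)
    mut = mutate_locus(gm, td)
    sim = simulate_reads(
        gm, [(gm.sequence, 0.55, None), (mut, 0.45, td)], ReadSimConfig(seed=6)
    )
    truth = sim.truth
    assert truth.junction_overlap.sum() > 0
    # junction reads only originate from the mutant haplotype
    assert (truth.loc[truth.junction_overlap, "haplotype"] == 1).all()


def test_large_td_evidence_is_clips_only(gm):
    """A 598-bp TD exceeds the read length: no read contains it as a CIGAR I."""
    td = TDSpec(460, 1058, allele_fraction=0.45)
    mut = mutate_locus(gm, td)
    sim = simulate_reads(
        gm, [(gm.sequence, 0.55, None), (mut, 0.45, td)], ReadSimConfig(seed=7)
    )
    n_clips = 0
    for read in sim.reads:
        assert not any(op == 1 for op, _ in read.cigartuples)
        n_clips += any(op == 4 for op, _ in read.cigartuples)
    assert n_clips > 0


def test_depth_ratio_converges_to_allele_fraction(gm):
    """Coverage excess over the duplicated interval's interior approaches f.

    The interior excludes one read length at each end of the interval, where
    soft-clipping shaves aligned bases off junction-crossing reads.
    """
    f, R = 0.4, 150
    td = TDSpec(460, 1058, allele_fraction=f)
    mut = mutate_locus(gm, td)
    sim = simulate_reads(
        gm, [(gm.sequence, 1 - f, None), (mut, f, td)], ReadSimConfig(seed=8, depth=2000)
    )
    depth = _coverage(sim.reads, gm.sequence_length)
    inner = depth[460 + R : 1058 - R].mean()
    flank = np.concatenate([depth[460 - 60 : 460], depth[1058 : 1058 + 60]]).mean()
    assert abs(inner / flank - 1 - f) < 0.03


def test_simulated_sam_is_byte_identical_under_fixed_seed(gm, tmp_path):
    td = TDSpec(700, 748, allele_fraction=0.45)
    mut = mutate_locus(gm, td)
    haps = [(gm.sequence, 0.55, None), (mut, 0.45, td)]
    paths = []
    for i in range(2):
        sim = simulate_reads(gm, haps, ReadSimConfig(seed=42, depth=100))
        p = tmp_path / f"run{i}.sam"
        sim.write_sam(str(p))
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_haplotype_fraction_validation(gm):
    with pytest.raises(ConfigError):
        simulate_reads(gm, [], ReadSimConfig(seed=0))
    with pytest.raises(ConfigError):
        simulate_reads(gm, [(gm.sequence, 0.7, None)], ReadSimConfig(seed=0))


# ---------------------------------------------------------------------------
# Traces and paired timepoints
# ---------------------------------------------------------------------------

def test_trace_deterministic_and_peaked():
    a = simulate_trace(617, 48, 0.45, seed=9)
    b = simulate_trace(617, 48, 0.45, seed=9)
    assert np.array_equal(a.heights, b.heights)
    assert a.sizes[np.argmax(a.heights)] == pytest.approx(617, abs=0.5)


def test_single_clone_het_vaf_half_prevalence():
    clones = [
        PlantedClone("c0", None, [("V1", "UBTF-TD", CNState.diploid_het())],
                     {"diagnosis": 0.9, "progression": 0.9})
    ]
    variants, truth = simulate_paired_timepoints(clones, depth=20000, seed=10)
    for v in variants:
        assert v.vaf == pytest.approx(0.45, abs=0.02)
    assert (truth.true_vaf == 0.45).all()


def test_upd_homozygous_vaf_equals_prevalence():
    clones = [
        PlantedClone("c0", None, [("W1", "WT1", CNState.upd_hom())],
                     {"diagnosis": 0.8, "progression": 0.8})
    ]
    variants, _ = simulate_paired_timepoints(clones, depth=20000, seed=11)
    for v in variants:
        assert v.vaf == pytest.approx(0.8, abs=0.02)


def test_biallelic_expansion_shows_high_relapse_vafs():
    het = CNState.diploid_het()
    clones = [
        PlantedClone("c0", None, [("UBTF-TD.1", "UBTF-TD", het)],
                     {"diagnosis": 0.9, "progression": 0.95}),
        PlantedClone("c1", "c0", [("WT1.1", "WT1", het), ("WT1.2", "WT1", het)],
                     {"diagnosis": 0.05, "progression": 0.9}),
    ]
    variants, _ = simulate_paired_timepoints(clones, depth=500, seed=12)
    relapse_wt1 = [v.vaf for v in variants if v.gene == "WT1" and v.timepoint == "progression"]
    assert len(relapse_wt1) == 2 and all(v > 0.35 for v in relapse_wt1)


def test_architecture_validation():
    het = CNState.diploid_het()
    with pytest.raises(ArchitectureError):
        simulate_paired_timepoints(
            [
                PlantedClone("a", None, [("V1", "WT1", het)], {"diagnosis": 0.5, "progression": 0.5}),
                PlantedClone("b", "a", [("V1", "WT1", het)], {"diagnosis": 0.2, "progression": 0.2}),
            ],
            seed=0,
        )
    with pytest.raises(ArchitectureError):
        simulate_paired_timepoints(
            [
                PlantedClone("a", None, [("V1", "WT1", het)], {"diagnosis": 0.5, "progression": 0.5}),
                PlantedClone("b", "a", [("V2", "WT1", het)], {"diagnosis": 0.9, "progression": 0.2}),
            ],
            seed=0,
        )
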