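"""CCF arithmetic, clone-tree building, WT1 status and relapse patterns."""

import numpy as np
import pytest

from conftest import recovery_run

from ubtftd.clonal import (
    CNState,
    TIMEPOINTS,
    TimepointVariant,
    analyze_patient,
    build_clone_tree,
    ccf,
    classify_wt1,
)
from ubtftd.errors import ArchitectureError, ConfigError
from ubtftd.synthetic import PlantedClone, simulate_paired_timepoints


def tv(vid, gene, tp, vaf, cn=None, depth=500):
    return TimepointVariant(vid, gene, tp, vaf, depth, cn or CNState.diploid_het())


def both(vid, gene, vdx, vrel, cn=None, depth=500):
    return [tv(vid, gene, "diagnosis", vdx, cn, depth), tv(vid, gene, "progression", vrel, cn, depth)]


# ---------------------------------------------------------------------------
# CCF
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "vaf,cn,expected",
    [
        (0.45, CNState.diploid_het(), 0.90),
        (0.80, CNState.upd_hom(), 0.80),
        (0.45, CNState.mut_plus_del(), 0.45),
        (0.30, CNState(3, 2), 0.45),
    ],
)
def test_ccf_copy_number_correction(vaf, cn, expected):
    assert ccf(tv("v", "WT1", "diagnosis", vaf, cn)) == pytest.approx(expected)


def test_ccf_linear_in_vaf_and_depth_invariant():
    for f in np.linspace(0.01, 0.5, 7):
        assert ccf(tv("v", "X", "diagnosis", f)) == pytest.approx(2 * f)
    assert ccf(tv("v", "X", "diagnosis", 0.3, depth=100)) == ccf(
        tv("v", "X", "diagnosis", 0.3, depth=100000)
    )


def test_ccf_capped_at_one():
    assert ccf(tv("v", "X", "diagnosis", 0.8)) == 1.0


def test_ccf_upd_binomial_sampling_oracle():
    """Planted UPD-homozygous clone at 0.8: mean CCF of binomial draws -> 0.8."""
    clones = [
        PlantedClone("c", None, [("W", "WT1", CNState.upd_hom())],
                     {"diagnosis": 0.8, "progression": 0.8})
    ]
    vals = []
    for seed in range(30):
        variants, _ = simulate_paired_timepoints(clones, depth=500, seed=seed)
        vals += [ccf(v) for v in variants]
    assert np.mean(vals) == pytest.approx(0.8, abs=0.01)


def test_cn_state_validation_and_parse():
    with pytest.raises(ConfigError):
        CNState(1, 2)
    assert CNState.parse("UPD-hom").mutated_copies == 2
    assert CNState.parse("custom:3:2") == CNState(3, 2)


# ---------------------------------------------------------------------------
# Clone tree
# ---------------------------------------------------------------------------

def test_wt1_nests_inside_ubtf_founder():
    variants = both("UBTF-TD.1", "UBTF-TD", 0.45, 0.45) + both("WT1.1", "WT1", 0.25, 0.45)
    tree = build_clone_tree(variants)
    founder = next(n for n in tree.nodes if "UBTF-TD.1" in n.variant_ids)
    wt1 = next(n for n in tree.nodes if "WT1.1" in n.variant_ids)
    assert founder.parent is None
    assert wt1.parent == founder.clone_id


def test_single_variant_tree():
    tree = build_clone_tree(both("V", "UBTF-TD", 0.45, 0.4))
    assert len(tree.nodes) == 1
    assert tree.nodes[0].ccf["diagnosis"] == pytest.approx(0.9)


def test_empty_variant_list_rejected():
    with pytest.raises(ArchitectureError):
        build_clone_tree([])


def test_unresolvable_configuration_reported_not_raised():
    # forced onto one lineage at diagnosis (CCFs 1.4 + 1.1 exceed the budget)
    # yet neither variant can contain the other at relapse
    variants = both("A", "X", 0.35, 0.05) + both("B", "Y", 0.275, 0.225)
    tree = build_clone_tree(variants)
    assert tree.unresolvable
    assert any("forced into lineage" in v for v in tree.violations)


def test_fishplot_frame_shape():
    variants = both("UBTF-TD.1", "UBTF-TD", 0.45, 0.45) + both("WT1.1", "WT1", 0.25, 0.4)
    df = build_clone_tree(variants).fishplot_frame()
    assert list(df.columns) == ["clone", "parent", "diagnosis", "progression", "variants"]
    assert df.parent.iloc[0] == 0  # founder hangs off the virtual root


# ---------------------------------------------------------------------------
# WT1 allelic status
# ---------------------------------------------------------------------------

def test_wt1_bi_alt_by_pigeonhole():
    """Two WT1 mutants whose CCFs cannot occupy disjoint subclones."""
    variants = (
        both("UBTF-TD.1", "UBTF-TD", 0.46, 0.46)
        + both("WT1.1", "WT1", 0.44, 0.44)
        + both("WT1.2", "WT1", 0.43, 0.43)
    )
    tree = build_clone_tree(variants)
    assert classify_wt1(variants, tree, "progression") == "bi_alt"


def test_wt1_mono_alt_single_het():
    variants = both("UBTF-TD.1", "UBTF-TD", 0.45, 0.45) + both("WT1.1", "WT1", 0.20, 0.2)
    tree = build_clone_tree(variants)
    assert classify_wt1(variants, tree, "diagnosis") == "mono_alt"


def test_wt1_bi_alt_by_upd():
    variants = both("UBTF-TD.1", "UBTF-TD", 0.45, 0.45) + both(
        "WT1.1", "WT1", 0.2, 0.80, CNState.upd_hom()
    )
    tree = build_clone_tree(variants)
    assert classify_wt1(variants, tree, "progression") == "bi_alt"


def test_wt1_none_below_detection():
    variants = both("UBTF-TD.1", "UBTF-TD", 0.45, 0.45) + both("WT1.1", "WT1", 0.005, 0.004)
    tree = build_clone_tree(variants)
    assert classify_wt1(variants, tree, "diagnosis") == "none"


# ---------------------------------------------------------------------------
# Relapse patterns and variant status
# ---------------------------------------------------------------------------

def _report_for(clones, seed=1):
    variants, _ = simulate_paired_timepoints(clones, depth=500, seed=seed)
    return analyze_patient(variants), variants


def test_e_type_biallelic_preexisting():
    het = CNState.diploid_het()
    clones = [
        PlantedClone("f", None, [("UBTF-TD.1", "UBTF-TD", het)], {"diagnosis": 0.9, "progression": 0.95}),
        PlantedClone("w", "f", [("WT1.1", "WT1", CNState.upd_hom())], {"diagnosis": 0.05, "progression": 0.9}),
    ]
    report, _ = _report_for(clones)
    assert report.wt1_class["progression"] == "bi_alt"
    assert report.relapse_pattern == "bi_alt_preexisting"


def test_f_type_biallelic_from_mono():
    het = CNState.diploid_het()
    clones = [
        PlantedClone("f", None, [("UBTF-TD.1", "UBTF-TD", het)], {"diagnosis": 0.9, "progression": 0.95}),
        PlantedClone("m", "f", [("WT1.1", "WT1", het)], {"diagnosis": 0.5, "progression": 0.9}),
        PlantedClone("b", "m", [("WT1.2", "WT1", het)], {"diagnosis": 0.0, "progression": 0.85}),
    ]
    report, _ = _report_for(clones)
    assert report.wt1_class["diagnosis"] == "mono_alt"
    assert report.relapse_pattern == "bi_alt_from_mono"


def test_g_type_biallelic_emergent():
    het = CNState.diploid_het()
    clones = [
        PlantedClone("f", None, [("UBTF-TD.1", "UBTF-TD", het)], {"diagnosis": 0.9, "progression": 0.95}),
        PlantedClone("b", "f", [("WT1.1", "WT1", het), ("WT1.2", "WT1", het)],
                     {"diagnosis": 0.0, "progression": 0.85}),
    ]
    report, _ = _report_for(clones)
    assert report.relapse_pattern == "bi_alt_emergent"


def test_a_type_mono_on_persistent_flt3():
    het = CNState.diploid_het()
    clones = [
        PlantedClone("f", None, [("UBTF-TD.1", "UBTF-TD", het)], {"diagnosis": 0.9, "progression": 0.95}),
        PlantedClone("flt", "f", [("FLT3-ITD.1", "FLT3-ITD", het)], {"diagnosis": 0.6, "progression": 0.9}),
        PlantedClone("w", "flt", [("WT1.1", "WT1", het)], {"diagnosis": 0.0, "progression": 0.8}),
    ]
    report, _ = _report_for(clones)
    assert report.relapse_pattern == "mono_on_flt3"


def test_variant_loss_detected():
    """A FLT3-ITD clone swept away at relapse is reported as lost."""
    het = CNState.diploid_het()
    clones = [
        PlantedClone("f", None, [("UBTF-TD.1", "UBTF-TD", het)], {"diagnosis": 0.9, "progression": 0.95}),
        PlantedClone("flt", "f", [("FLT3-ITD.1", "FLT3-ITD", het)], {"diagnosis": 0.6, "progression": 0.0}),
        PlantedClone("w", "f", [("WT1.1", "WT1", het)], {"diagnosis": 0.05, "progression": 0.9}),
    ]
    report, _ = _report_for(clones)
    assert report.variant_status["FLT3-ITD.1"] == "lost"
    assert report.variant_status["WT1.1"] == "persistent"
    assert report.variant_status["UBTF-TD.1"] == "persistent"


# ---------------------------------------------------------------------------
# Parameter recovery and pigeonhole consistency
# ---------------------------------------------------------------------------

def test_planted_architecture_recovery_50_seeds():
    """>= 90% exact topology and prevalence MAE <= 0.05 at depth 500."""
    results = [recovery_run(seed) for seed in range(50)]
    topo = np.mean([r[0] for r in results])
    mae = np.mean([r[1] for r in results])
    assert topo >= 0.9
    assert mae <= 0.05


def test_accepted_trees_satisfy_pigeonhole():
    """Sibling CCFs sum to at most the container CCF + tolerance."""
    for seed in range(50):
        _, _, tree = recovery_run(seed)
        if tree.unresolvable:
            continue
        for parent_id in {n.parent for n in tree.nodes}:
            sibs = [n for n in tree.nodes if n.parent == parent_id]
            cap = (
                {t: 1.0 for t in TIMEPOINTS}
                if parent_id is None
                else next(n for n in tree.nodes if n.clone_id == parent_id).ccf
            )
            for t in TIMEPOINTS:
                assert sum(n.ccf[t] for n in sibs) <= cap[t] + 0.1 + 1e-9
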