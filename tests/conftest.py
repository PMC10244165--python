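import numpy as np
import pytest

from ubtftd.clonal import TIMEPOINTS, build_clone_tree
from ubtftd.genemodel import fixture_gene_model
from ubtftd.synthetic import ReadSimConfig, TDSpec, mutate_locus, simulate_reads


@pytest.fixture(scope="session")
def gm():
    return fixture_gene_model()


@pytest.fixture(scope="session")
def simulate_and_call(gm):
    """Run the read simulator and TD caller on a planted duplication."""
    from ubtftd.caller import call_tds

    def _run(td: TDSpec, fraction: float, seed: int, depth: float = 500.0, read_length: int = 150):
        mut = mutate_locus(gm, td)
        if fraction >= 1.0:
            haps = [(mut, 1.0, td)]
        else:
            haps = [(gm.sequence, 1 - fraction, None), (mut, fraction, td)]
        sim = simulate_reads(
            gm, haps, ReadSimConfig(depth=depth, read_length=read_length, seed=seed)
        )
        return sim, call_tds(sim.reads, gm)

    return _run


def assert_tree_matches(clones, tree) -> bool:
    """Exact topology match between a planted architecture and a clone tree."""
    cvars = {c.clone_id: frozenset(v for v, _, _ in c.variants) for c in clones}
    cparent = {c.clone_id: c.parent for c in clones}
    if len(tree.nodes) != len(clones):
        return False
    inf_by_set = {frozenset(n.variant_ids): n for n in tree.nodes}
    if set(inf_by_set) != set(cvars.values()):
        return False
    for cid, vs in cvars.items():
        node = inf_by_set[vs]
        if cparent[cid] is None:
            if node.parent is not None:
                return False
        else:
            if node.parent is None:
                return False
            pnode = next(x for x in tree.nodes if x.clone_id == node.parent)
            if frozenset(pnode.variant_ids) != cvars[cparent[cid]]:
                return False
    return True


def recovery_run(seed: int, depth: int = 500):
    """Plant a random 2-5-clone architecture, add noise, rebuild the tree."""
    from ubtftd.synthetic import sample_architecture, simulate_paired_timepoints

    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 6))
    clones = sample_architecture(n, seed + 10_000)
    variants, _truth = simulate_paired_timepoints(clones, depth=depth, seed=seed + 20_000)
    tree = build_clone_tree(variants)
    ok = assert_tree_matches(clones, tree)
    vclone = {v: c.clone_id for c in clones for v, _, _ in c.variants}
    prev = {c.clone_id: c.prevalence for c in clones}
    errors = [
        abs(node.ccf[t] - prev[vclone[v]][t])
        for node in tree.nodes
        for v in node.variant_ids
        for t in TIMEPOINTS
    ]
    return ok, float(np.mean(errors)), tree
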