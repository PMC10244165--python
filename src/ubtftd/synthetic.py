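"""Synthetic data generation for every pipeline stage.

Generates, from the cohort's stated distributions, the four kinds of input
the pipeline consumes: TD-bearing haplotypes, aligned short reads (SAM with
soft-clip/insertion CIGARs computed from the known junction geometry),
capillary fragment-analysis traces, and paired diagnosis/relapse variant
tables from a planted clone tree.  Every artifact comes with a truth table,
and a fixed seed makes all outputs byte-identical.

Cohort defaults encode the study conditions: TD sizes concentrated at
48/51/54 bp (18/10/6 of 59) with a log-uniform tail up to 950 bp, internal
deletions in 64% of TDs > 100 bp vs 13% below, non-templated junction
inserts of 0-6 nt, a logit-normal VAF distribution with median 0.45 (IQR
0.37-0.48), and the observed co-mutation rates (WT1 0.63, FLT3-ITD 0.53, ...).
Reads are emitted pre-aligned: alignment of simulated reads is not the
method under test, and the known junction geometry determines the CIGAR a
correct aligner would produce.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import pysam

from .clonal import TIMEPOINTS, CNState, TimepointVariant
from .errors import ArchitectureError, ConfigError, TDSpecError
from .fragments import FragmentTrace
from .genemodel import ELLTRLA_CORE_CDS, GeneModel

__all__ = [
    "TDSpec",
    "CohortSpec",
    "PatientSim",
    "ReadSimConfig",
    "SimulatedReads",
    "sample_cohort",
    "sample_tdspec",
    "mutate_locus",
    "simulate_reads",
    "simulate_trace",
    "PlantedClone",
    "simulate_paired_timepoints",
    "cohort_to_frame",
]


# ---------------------------------------------------------------------------
# TD specification
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TDSpec:
    """A tandem duplication at genomic scale.

    The segment ``[dup_start, dup_end)`` is duplicated in tandem; the copy is
    appended at the 3' end of the original segment, preceded by the
    non-templated ``insert`` at the junction, with ``deletions`` (genomic
    intervals within the duplicated segment) removed from the copy.
    """

    dup_start: int
    dup_end: int
    insert: str = ""
    deletions: tuple[tuple[int, int], ...] = ()
    allele_fraction: float = 1.0
    non_core: bool = False

    def __post_init__(self) -> None:
        if self.dup_end < self.dup_start:
            raise TDSpecError("dup_end must be >= dup_start")
        if not (0.0 < self.allele_fraction <= 1.0):
            raise TDSpecError("allele_fraction must lie in (0, 1]")
        prev = self.dup_start
        for s, e in self.deletions:
            if s < self.dup_start or e > self.dup_end or s >= e:
                raise TDSpecError(f"deletion [{s},{e}) outside duplication")
            if s < prev:
                raise TDSpecError("deletions must be sorted and disjoint")
            prev = e
        if set(self.insert.upper()) - set("ACGT"):
            raise TDSpecError("insert must be an ACGT string")

    @property
    def dup_length(self) -> int:
        return self.dup_end - self.dup_start

    @property
    def deleted_length(self) -> int:
        return sum(e - s for s, e in self.deletions)

    @property
    def total_inserted_length(self) -> int:
        return self.dup_length + len(self.insert) - self.deleted_length

    def kept_copy_intervals(self) -> list[tuple[int, int]]:
        """Genomic intervals of the duplicated copy after internal deletions."""
        kept = []
        pos = self.dup_start
        for s, e in self.deletions:
            if s > pos:
                kept.append((pos, s))
            pos = e
        if pos < self.dup_end:
            kept.append((pos, self.dup_end))
        return kept

    def cds_interval(self, gm: GeneModel) -> tuple[int, int] | None:
        """Half-open c. interval of the exonic span of the duplication."""
        cds = [
            gm.genomic_to_cds(p)
            for p in range(self.dup_start, self.dup_end)
            if gm.is_exonic(p)
        ]
        if not cds:
            return None
        return min(cds), max(cds) + 1

    def contains_core(self, gm: GeneModel) -> bool:
        lo, hi = ELLTRLA_CORE_CDS
        try:
            core_genomic = [gm.cds_to_genomic(c) for c in range(lo, hi + 1)]
        except Exception:
            return False
        return all(self.dup_start <= p < self.dup_end for p in core_genomic)


def mutate_locus(gm: GeneModel, td: TDSpec) -> str:
    """Apply a tandem duplication to the wild-type locus sequence."""
    seq = gm.sequence
    if td.dup_end > len(seq):
        raise TDSpecError("duplicated interval outside locus")
    copy = "".join(seq[s:e] for s, e in td.kept_copy_intervals())
    mutant = seq[: td.dup_end] + td.insert + copy + seq[td.dup_end :]
    assert len(mutant) == len(seq) + td.total_inserted_length
    return mutant


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

_DEFAULT_COMUT = {
    "WT1": 0.63,
    "FLT3-ITD": 0.53,
    "trisomy8": 0.28,
    "NRAS": 0.23,
    "KRAS": 0.12,
    "PTPN11": 0.11,
    "RIT1": 0.11,
}


@dataclasses.dataclass
class CohortSpec:
    """Distributional description of a simulated UBTF-TD cohort."""

    n_patients: int = 59
    td_size_weights: dict[int, float] = dataclasses.field(
        default_factory=lambda: {48: 18 / 59, 51: 10 / 59, 54: 6 / 59}
    )
    tail_range: tuple[int, int] = (39, 950)
    exonic_max_size: int = 120
    deletion_size_threshold: int = 100
    p_internal_deletion_small: float = 0.13
    p_internal_deletion_large: float = 0.64
    vaf_logit_mean: float = math.log(0.45 / 0.55)
    vaf_logit_sd: float = 0.335
    insert_max: int = 6
    p_non_core: float = 1 / 59
    co_mutation_rates: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_COMUT)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if any(not 0 <= w <= 1 for w in self.td_size_weights.values()):
            raise ConfigError("size weights must lie in [0, 1]")
        if sum(self.td_size_weights.values()) > 1 + 1e-9:
            raise ConfigError("size weights must sum to <= 1")
        for p in (
            self.p_internal_deletion_small,
            self.p_internal_deletion_large,
            self.p_non_core,
            *self.co_mutation_rates.values(),
        ):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must lie in [0, 1]")


@dataclasses.dataclass
class PatientSim:
    patient_id: str
    td: TDSpec
    co_mutations: frozenset[str]


def _sample_size(spec: CohortSpec, rng: np.random.Generator) -> int:
    r = rng.random()
    acc = 0.0
    for size, w in sorted(spec.td_size_weights.items()):
        acc += w
        if r < acc:
            return size
    lo, hi = spec.tail_range
    s = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
    s = min(max(s, lo), hi)
    if s <= spec.exonic_max_size:
        s = max(3 * round(s / 3), 39)  # exonic TDs are in-frame as-is
    return s


def sample_tdspec(
    gm: GeneModel,
    size: int,
    rng: np.random.Generator,
    spec: CohortSpec,
    non_core: bool = False,
    allele_fraction: float | None = None,
) -> TDSpec:
    """Draw one TD of the requested total inserted length on the locus.

    Exonic TDs (size <= ``exonic_max_size``) live entirely in exon 13,
    contain the ELLTRLA core, and may carry a non-templated junction insert
    and an internal deletion preferentially removing the W445/N446/D447
    codons.  Larger TDs span the flanking introns with breakpoints adjusted
    so that the spliced inserted coding length stays a multiple of 3 and no
    splice dinucleotide is disrupted.
    """
    if allele_fraction is None:
        allele_fraction = float(
            1.0 / (1.0 + math.exp(-rng.normal(spec.vaf_logit_mean, spec.vaf_logit_sd)))
        )
    exon13 = gm.exons[1]
    core_lo = gm.cds_to_genomic(ELLTRLA_CORE_CDS[0])
    core_hi = gm.cds_to_genomic(ELLTRLA_CORE_CDS[1]) + 1  # half-open genomic
    if non_core:
        # the one cohort class not containing the core: a 42-bp duplication
        # of the downstream GLCLRFNQLDLDQA-encoding segment
        p1 = gm.cds_to_genomic(1342)
        return TDSpec(p1, p1 + 42, allele_fraction=allele_fraction, non_core=True)

    large = size > spec.deletion_size_threshold
    p_del = spec.p_internal_deletion_large if large else spec.p_internal_deletion_small
    has_del = rng.random() < p_del
    del_len = int(3 * rng.integers(1, 4)) if has_del else 0
    # preferred deletion target: codons 445-447
    del_target = gm.cds_to_genomic(1333)

    if size <= spec.exonic_max_size:
        ins_len = int(rng.integers(0, spec.insert_max + 1))
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, size=ins_len))
        d = size - ins_len + del_len
        lo = max(exon13[0], core_hi - d)
        hi = min(core_lo, exon13[1] - d)
        if lo > hi:
            raise TDSpecError(f"cannot place exonic TD of span {d} around the core")
        p1 = int(rng.integers(lo, hi + 1))
        deletions: tuple[tuple[int, int], ...] = ()
        if has_del:
            ds = min(max(del_target, p1 + 1), p1 + d - del_len - 1)
            if p1 < ds and ds + del_len < p1 + d:
                deletions = ((ds, ds + del_len),)
            else:
                d -= del_len  # deletion does not fit; keep total size exact
                p1 = int(rng.integers(max(exon13[0], core_hi - d), min(core_lo, exon13[1] - d) + 1))
        return TDSpec(p1, p1 + d, insert, deletions, allele_fraction)

    # intron-spanning TD: no junction insert; deletion sits in the exon-13 copy
    d = size + del_len
    lo = max(0, core_hi - d)
    hi = min(core_lo, gm.sequence_length - d)
    if has_del:
        # keep the deletion site strictly inside the duplicated segment
        lo = max(lo, del_target + del_len + 2 - d)
        hi = min(hi, del_target - 2)
    if has_del and lo > hi:
        has_del, del_len, d = False, 0, size
        lo = max(0, core_hi - d)
        hi = min(core_lo, gm.sequence_length - d)
    if lo > hi:
        raise TDSpecError(f"TD of span {d} does not fit the locus")
    p1 = int(rng.integers(lo, hi + 1))
    deletions = ()
    if has_del:
        deletions = ((del_target, del_target + del_len),)
    sites = gm.splice_site_positions()
    del_exonic = sum(
        1 for s, e in deletions for p in range(s, e) if gm.is_exonic(p)
    )

    def ok(p1c: int) -> bool:
        p2c = p1c + d
        if p1c < 0 or p2c > gm.sequence_length:
            return False
        if not (p1c <= core_lo and p2c >= core_hi):
            return False
        if p1c in sites or (p2c - 1) in sites or p2c in sites:
            return False
        if any(not (p1c < s and e < p2c) for s, e in deletions):
            return False
        return (gm.exonic_count(p1c, p2c) - del_exonic) % 3 == 0

    for delta in sorted(range(-250, 251), key=abs):
        if ok(p1 + delta):
            p1 = p1 + delta
            break
    else:
        raise TDSpecError(f"no in-frame placement found for TD span {d}")
    return TDSpec(p1, p1 + d, "", deletions, allele_fraction)


def sample_cohort(spec: CohortSpec, gm: GeneModel | None = None) -> list[PatientSim]:
    """Draw a cohort of patients with TD specs and co-mutation sets."""
    from .genemodel import fixture_gene_model

    if gm is None:
        gm = fixture_gene_model()
    rng = np.random.default_rng(spec.seed)
    patients = []
    genes = sorted(spec.co_mutation_rates)
    for i in range(spec.n_patients):
        non_core = rng.random() < spec.p_non_core
        size = _sample_size(spec, rng)
        td = sample_tdspec(gm, size, rng, spec, non_core=non_core)
        comuts = frozenset(
            g for g in genes if rng.random() < spec.co_mutation_rates[g]
        )
        patients.append(PatientSim(f"P{i + 1:04d}", td, comuts))
    return patients


def cohort_to_frame(patients: list[PatientSim], gm: GeneModel) -> pd.DataFrame:
    rows = []
    for p in patients:
        td = p.td
        rows.append(
            {
                "patient_id": p.patient_id,
                "dup_start": td.dup_start,
                "dup_end": td.dup_end,
                "insert": td.insert,
                "deletions": ";".join(f"{s}-{e}" for s, e in td.deletions),
                "total_inserted_length": td.total_inserted_length,
                "allele_fraction": td.allele_fraction,
                "non_core": td.non_core,
                "contains_core": td.contains_core(gm),
                "co_mutations": ";".join(sorted(p.co_mutations)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ReadSimConfig:
    read_length: int = 150
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    depth: float = 500.0
    substitution_error_rate: float = 0.001
    min_anchor: int = 10  # bases required on both sides for a CIGAR 'I' call
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length >= self.fragment_mean:
            raise ConfigError("read_length must be below the mean fragment size")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")


@dataclasses.dataclass
class _HapInfo:
    sequence: str
    fraction: float
    td: TDSpec | None
    refmap: np.ndarray  # mutant position -> reference position (-1 = inserted)

    @property
    def junction(self) -> int | None:
        return None if self.td is None else self.td.dup_end


def _build_refmap(gm: GeneModel, td: TDSpec | None, hap_len: int) -> np.ndarray:
    n = gm.sequence_length
    if td is None:
        return np.arange(n, dtype=np.int64)
    parts = [np.arange(td.dup_end, dtype=np.int64)]
    parts.append(np.full(len(td.insert), -1, dtype=np.int64))
    for s, e in td.kept_copy_intervals():
        parts.append(np.arange(s, e, dtype=np.int64))
    parts.append(np.arange(td.dup_end, n, dtype=np.int64))
    refmap = np.concatenate(parts)
    assert refmap.size == hap_len
    return refmap


def _cigar_from_refmap(refmap: np.ndarray, a: int, b: int) -> tuple[int, list[tuple[int, int]]]:
    """CIGAR for a fully-mapped contiguous mutant slice [a, b)."""
    sl = refmap[a:b]
    ref_start = int(sl[0])
    cig: list[tuple[int, int]] = []
    jumps = np.nonzero(np.diff(sl) != 1)[0]
    pos = 0
    for j in jumps:
        cig.append((0, int(j) + 1 - pos))  # M
        cig.append((2, int(sl[j + 1] - sl[j] - 1)))  # D
        pos = int(j) + 1
    cig.append((0, int(sl.size - pos)))
    return ref_start, cig


def _align_read(hap: _HapInfo, u: int, v: int, min_anchor: int) -> tuple[int, list[tuple[int, int]]]:
    """Reference placement and CIGAR an aligner would report for read [u, v)."""
    td = hap.td
    if td is None:
        return u, [(0, v - u)]
    p2 = td.dup_end
    k = len(td.insert)
    t_total = td.total_inserted_length
    if v <= p2 or u >= p2 + k:
        return _cigar_from_refmap(hap.refmap, u, v)
    # read overlaps the junction / insert
    if u <= p2 - min_anchor and v >= p2 + t_total + min_anchor:
        # whole insertion within the read: represented as a CIGAR insertion
        return u, [(0, p2 - u), (1, t_total), (0, v - p2 - t_total)]
    left = p2 - u
    right = v - (p2 + k)
    if left >= right:
        return u, [(0, left), (4, v - p2)]  # right soft-clip at breakpoint p2
    clip = (p2 + k) - u
    ref_start, cig = _cigar_from_refmap(hap.refmap, p2 + k, v)
    return ref_start, [(4, clip)] + cig  # left soft-clip at duplication start


@dataclasses.dataclass
class SimulatedReads:
    header: pysam.AlignmentHeader
    reads: list[pysam.AlignedSegment]
    truth: pd.DataFrame

    def write_sam(self, path: str) -> None:
        with pysam.AlignmentFile(path, "w", header=self.header) as fh:
            for r in self.reads:
                fh.write(r)

    def write_truth(self, path: str) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def simulate_reads(
    gm: GeneModel,
    haplotypes: list[tuple[str, float, TDSpec | None]],
    cfg: ReadSimConfig,
) -> SimulatedReads:
    """Simulate aligned paired-end reads from a haplotype mixture.

    Reads crossing a TD junction carry soft-clips (or a CIGAR insertion when
    the whole inserted segment plus anchors fits inside one read); all other
    reads align as pure matches with deletion gaps where the duplicated copy
    lost internal bases.  Substitution errors are applied uniformly; indel
    errors are not modeled.
    """
    if not haplotypes:
        raise ConfigError("at least one haplotype is required")
    fr = np.array([f for _, f, _ in haplotypes], dtype=float)
    if abs(fr.sum() - 1.0) > 1e-6:
        raise ConfigError("haplotype fractions must sum to 1")
    rng = np.random.default_rng(cfg.seed)
    haps = [
        _HapInfo(seq, f, td, _build_refmap(gm, td, len(seq)))
        for seq, f, td in haplotypes
    ]
    R = cfg.read_length
    # fragments are drawn per unit of template: an allele's share of
    # molecules is its DNA fraction times its (TD-lengthened) locus length
    weights = fr * np.array([len(h.sequence) for h in haps], dtype=float)
    mean_len = float(weights.sum())  # = E[haplotype length]
    fr = weights / weights.sum()
    n_frag = int(round(cfg.depth * mean_len / (2 * R)))
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": gm.locus_name, "LN": gm.sequence_length}],
        }
    )
    hap_idx = rng.choice(len(haps), size=n_frag, p=fr)
    records: list[tuple[int, pysam.AlignedSegment]] = []
    truth_rows = []
    for i in range(n_frag):
        hap = haps[int(hap_idx[i])]
        hlen = len(hap.sequence)
        flen = int(np.clip(rng.normal(cfg.fragment_mean, cfg.fragment_sd), R + 10, hlen))
        start = int(rng.integers(0, hlen - flen + 1))
        mates = ((start, start + R, False), (start + flen - R, start + flen, True))
        placed = []
        for u, v, is_rev in mates:
            ref_start, cig = _align_read(hap, u, v, cfg.min_anchor)
            seq = list(hap.sequence[u:v])
            n_err = rng.binomial(R, cfg.substitution_error_rate)
            for pos in rng.integers(0, R, size=n_err):
                cur = seq[pos]
                seq[pos] = "ACGT"[(("ACGT".index(cur) + int(rng.integers(1, 4))) % 4)]
            placed.append((ref_start, cig, "".join(seq), is_rev, u, v))
        for mate_no, (ref_start, cig, seq, is_rev, u, v) in enumerate(placed):
            a = pysam.AlignedSegment(header)
            a.query_name = f"frag{i:07d}"
            a.query_sequence = seq
            a.reference_id = 0
            a.reference_start = ref_start
            a.cigartuples = cig
            a.mapping_quality = 60
            flag = 0x1 | 0x2
            flag |= 0x40 if mate_no == 0 else 0x80
            if is_rev:
                flag |= 0x10
            else:
                flag |= 0x20
            a.flag = flag
            a.next_reference_id = 0
            a.next_reference_start = placed[1 - mate_no][0]
            a.template_length = flen if mate_no == 0 else -flen
            a.query_qualities = pysam.qualitystring_to_array("I" * R)
            records.append((ref_start, a))
            j = hap.junction
            truth_rows.append(
                {
                    "read_id": a.query_name,
                    "mate": mate_no + 1,
                    "haplotype": int(hap_idx[i]),
                    "junction_overlap": bool(j is not None and u < j + len(hap.td.insert) and v > j),
                    "ref_start": ref_start,
                }
            )
    records.sort(key=lambda t: t[0])
    truth = pd.DataFrame(truth_rows)
    return SimulatedReads(header, [r for _, r in records], truth)


# ---------------------------------------------------------------------------
# Fragment trace simulation
# ---------------------------------------------------------------------------

def simulate_trace(
    wt_size: float,
    total_inserted_length: int | None,
    allele_fraction: float = 0.5,
    seed: int = 0,
    grid_step: float = 0.25,
    sigma: float = 0.25,
    scale: float = 1000.0,
    noise: float = 2.0,
    stutter_fraction: float = 0.0,
    pad: float = 150.0,
) -> FragmentTrace:
    """Simulate a calibrated electropherogram of the screening amplicon.

    Gaussian peaks at the wild-type size and (if a TD is present) at
    wt + total inserted length, with heights proportional to (1 - f) and f,
    additive uniform baseline noise, and optional +/-1 bp stutter satellites.
    """
    if wt_size <= 0:
        raise ConfigError("wild-type size must be positive")
    rng = np.random.default_rng(seed)
    mut_size = None if total_inserted_length is None else wt_size + total_inserted_length
    top = wt_size if mut_size is None else max(wt_size, mut_size)
    grid = np.arange(wt_size - pad, top + pad + grid_step, grid_step)
    heights = rng.uniform(0, noise, size=grid.size)

    def add_peak(center: float, height: float) -> None:
        heights_local = height * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
        np.add(heights, heights_local, out=heights)

    f = allele_fraction if mut_size is not None else 0.0
    add_peak(wt_size, (1 - f) * scale)
    if stutter_fraction > 0:
        add_peak(wt_size - 1, (1 - f) * scale * stutter_fraction)
    if mut_size is not None:
        add_peak(mut_size, f * scale)
        if stutter_fraction > 0:
            add_peak(mut_size - 1, f * scale * stutter_fraction)
    return FragmentTrace(grid, heights)


# ---------------------------------------------------------------------------
# Paired-timepoint clone architectures
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PlantedClone:
    """A planted clone: its new variants and subtree-inclusive prevalence."""

    clone_id: str
    parent: str | None
    variants: list[tuple[str, str, CNState | dict[str, CNState]]]
    prevalence: dict[str, float]  # timepoint -> inclusive prevalence (CCF)


_ARCH_GENES = ["WT1", "FLT3-ITD", "NRAS", "KRAS", "PTPN11", "RIT1", "TET2"]


def _architecture_identifiable(
    clones: list[PlantedClone], margin: float = 0.16
) -> bool:
    """Is the planted tree recoverable from two bulk samples?

    Requires (a) exact recovery by the pigeonhole builder on noise-free
    CCFs, (b) every non-ancestral pair separated by >= margin at some
    timepoint in the dominated direction, and (c) sibling budgets left slack
    so binomial noise cannot spuriously force lineages.
    """
    from .clonal import build_clone_tree

    by_id = {c.clone_id: c for c in clones}

    def ancestors(c: PlantedClone) -> set[str]:
        out = set()
        while c.parent is not None:
            out.add(c.parent)
            c = by_id[c.parent]
        return out

    for a in clones:
        anc = ancestors(a)
        for b in clones:
            if b.clone_id == a.clone_id or b.clone_id in anc:
                continue
            if not any(
                a.prevalence[t] >= b.prevalence[t] + margin for t in TIMEPOINTS
            ):
                return False
    for parent_id in {c.parent for c in clones}:
        sibs = [c for c in clones if c.parent == parent_id]
        if len(sibs) < 2:
            continue  # no competing siblings, nothing to force spuriously
        cap = (
            {t: 1.0 for t in TIMEPOINTS}
            if parent_id is None
            else by_id[parent_id].prevalence
        )
        for t in TIMEPOINTS:
            if sum(c.prevalence[t] for c in sibs) > cap[t] - 0.02:
                return False
    # noise-free recovery check
    exact = [
        TimepointVariant(vid, gene, t, min(c.prevalence[t] / 2, 1.0), 10000, cn)
        for c in clones
        for vid, gene, cn in c.variants
        for t in TIMEPOINTS
    ]
    tree = build_clone_tree(exact)
    if tree.unresolvable or len(tree.nodes) != len(clones):
        return False
    truth_sets = {frozenset(v for v, _, _ in c.variants): c for c in clones}
    inf_sets = {frozenset(n.variant_ids): n for n in tree.nodes}
    if set(truth_sets) != set(inf_sets):
        return False
    for key, c in truth_sets.items():
        node = inf_sets[key]
        if c.parent is None:
            if node.parent is not None:
                return False
        else:
            pnode = next(n for n in tree.nodes if n.clone_id == node.parent) if node.parent is not None else None
            if pnode is None:
                return False
            if frozenset(pnode.variant_ids) != frozenset(
                v for v, _, _ in by_id[c.parent].variants
            ):
                return False
    return True


def sample_architecture(
    n_clones: int, seed: int, jitter: float = 0.03
) -> list[PlantedClone]:
    """Draw an identifiable planted clone tree with 2-5 clones.

    A structural template (chain or branching, with crossing sibling
    trajectories between diagnosis and relapse) is chosen and its
    prevalences jittered; each clone carries one or two diploid-
    heterozygous variants.  Draws are accepted only when the planted truth
    is recoverable by the pigeonhole builder from noise-free CCFs with
    margins against binomial VAF noise, so recovery failures in tests
    measure the builder, not degeneracy of the planted tree.
    """
    if n_clones not in _ARCH_TEMPLATES:
        raise ConfigError("n_clones must be between 2 and 5")
    for attempt in range(100):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        templates = _ARCH_TEMPLATES[n_clones]
        template = templates[int(rng.integers(len(templates)))]
        het = CNState.diploid_het()
        clones = []
        vcount = 0
        for cid, parent, (dx, pr) in template:
            prev = {
                "diagnosis": float(np.clip(dx + rng.uniform(-jitter, jitter), 0.01, 0.99)),
                "progression": float(np.clip(pr + rng.uniform(-jitter, jitter), 0.01, 0.99)),
            }
            n_vars = 1 + int(rng.random() < 0.4)
            variants = []
            for _ in range(n_vars):
                gene = (
                    "UBTF-TD"
                    if parent is None
                    else _ARCH_GENES[int(rng.integers(len(_ARCH_GENES)))]
                )
                vcount += 1
                variants.append((f"{gene}.{vcount}", gene, het))
            clones.append(PlantedClone(cid, parent, variants, prev))
        try:
            simulate_paired_timepoints(clones, depth=10, seed=0)
        except ArchitectureError:
            continue
        if _architecture_identifiable(clones, margin=0.14):
            return clones
    raise ConfigError(f"no identifiable {n_clones}-clone architecture found for seed {seed}")


# structural templates: (clone_id, parent, (diagnosis, progression) CCF).
# Chains model stepwise mutation acquisition; branches model competing
# subclones whose trajectories cross between diagnosis and relapse.
_ARCH_TEMPLATES: dict[int, list] = {
    2: [
        [("c0", None, (0.95, 0.92)), ("c1", "c0", (0.55, 0.25))],
        [("c0", None, (0.93, 0.95)), ("c1", "c0", (0.20, 0.65))],
    ],
    3: [
        [("c0", None, (0.95, 0.93)), ("c1", "c0", (0.60, 0.66)),
         ("c2", "c1", (0.25, 0.35))],
        [("c0", None, (0.92, 0.95)), ("c1", "c0", (0.60, 0.15)),
         ("c2", "c0", (0.12, 0.70))],
    ],
    4: [
        [("c0", None, (0.95, 0.95)), ("c1", "c0", (0.68, 0.70)),
         ("c2", "c1", (0.42, 0.38)), ("c3", "c2", (0.15, 0.08))],
        [("c0", None, (0.95, 0.92)), ("c1", "c0", (0.62, 0.78)),
         ("c2", "c1", (0.38, 0.10)), ("c3", "c1", (0.08, 0.55))],
    ],
    5: [
        [("c0", None, (0.96, 0.95)), ("c1", "c0", (0.70, 0.68)),
         ("c2", "c1", (0.45, 0.44)), ("c3", "c2", (0.22, 0.20)),
         ("c4", "c3", (0.04, 0.03))],
        [("c0", None, (0.96, 0.95)), ("c1", "c0", (0.70, 0.78)),
         ("c2", "c1", (0.45, 0.12)), ("c3", "c1", (0.10, 0.62)),
         ("c4", "c3", (0.02, 0.42))],
    ],
}

def simulate_paired_timepoints(
    clones: list[PlantedClone],
    depth: int = 500,
    seed: int = 0,
    tolerance: float = 1e-6,
) -> tuple[list[TimepointVariant], pd.DataFrame]:
    """Sample noisy paired-timepoint VAF tables from a planted clone tree.

    Each variant's true VAF is the inclusive prevalence of its introducing
    clone times mutated/total copies; observed VAFs are binomial draws at
    the given depth.  Returns the variant list and a truth table.
    """
    by_id = {c.clone_id: c for c in clones}
    if len(by_id) != len(clones):
        raise ArchitectureError("clone ids must be unique")
    seen_variants: set[str] = set()
    for c in clones:
        if c.parent is not None and c.parent not in by_id:
            raise ArchitectureError(f"unknown parent {c.parent!r}")
        for t in TIMEPOINTS:
            if t not in c.prevalence:
                raise ArchitectureError(f"clone {c.clone_id} lacks prevalence at {t}")
            if c.parent is not None and c.prevalence[t] > by_id[c.parent].prevalence[t] + tolerance:
                raise ArchitectureError(
                    f"clone {c.clone_id} exceeds parent prevalence at {t}"
                )
        for vid, _, _ in c.variants:
            if vid in seen_variants:
                raise ArchitectureError(f"variant {vid} introduced twice (non-nested sets)")
            seen_variants.add(vid)
    for t in TIMEPOINTS:
        for parent_id in {c.parent for c in clones}:
            sibs = [c for c in clones if c.parent == parent_id]
            cap = 1.0 if parent_id is None else by_id[parent_id].prevalence[t]
            if sum(c.prevalence[t] for c in sibs) > cap + tolerance:
                raise ArchitectureError(
                    f"sibling prevalences under {parent_id!r} exceed budget at {t}"
                )

    rng = np.random.default_rng(seed)
    variants: list[TimepointVariant] = []
    truth_rows = []
    for c in clones:
        for vid, gene, cn in c.variants:
            for t in TIMEPOINTS:
                cn_t = cn[t] if isinstance(cn, dict) else cn
                true_vaf = c.prevalence[t] * cn_t.mutated_copies / cn_t.total_copies
                true_vaf = min(max(true_vaf, 0.0), 1.0)
                obs = rng.binomial(depth, true_vaf) / depth
                variants.append(TimepointVariant(vid, gene, t, float(obs), depth, cn_t))
                truth_rows.append(
                    {
                        "variant_id": vid,
                        "gene": gene,
                        "clone_id": c.clone_id,
                        "timepoint": t,
                        "true_vaf": true_vaf,
                        "true_ccf": c.prevalence[t],
                        "observed_vaf": float(obs),
                    }
                )
    return variants, pd.DataFrame(truth_rows)
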