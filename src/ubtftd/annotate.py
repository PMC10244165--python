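"""Interpretation of TD calls: frame, peptide, core membership, cohort view.

Frame status is splice-aware: the mutant haplotype is projected through the
exon model (duplicated exonic bases are retained, duplicated intronic bases
are spliced out, canonical splice sites assumed intact), and the frame and
encoded peptide are computed on the spliced product.  This is how a genomic
duplication whose raw length is not a multiple of 3 — e.g. one spanning
whole introns — can still yield an in-frame insertion, including the
exon13-exon13 fused transcript produced by duplications spanning both
introns around exon 13.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import CoordinateError
from .genemodel import ELLTRLA_CORE_CDS, GeneModel, translate
from .synthetic import TDSpec

__all__ = [
    "TDAnnotation",
    "CohortSummary",
    "splice_aware_frame",
    "minimal_duplicated_region",
    "summarize_cohort",
]


@dataclasses.dataclass
class TDAnnotation:
    in_frame: bool | None
    spliced_inserted_length: int | None
    peptide: str
    contains_core: bool
    leucine_rich: bool
    exon_span: list[str]
    cds_interval: tuple[int, int] | None
    exon13_duplicated: bool
    splice_disrupting: bool
    category: str  # core | non-core leucine-rich | non-core | splice-disrupting


def _splice_disrupting(td: TDSpec, gm: GeneModel) -> bool:
    # a breakpoint separating the two bases of a GT donor or AG acceptor,
    # or a deletion removing either base, breaks the canonical site
    mids = set()
    for i, (s, e) in enumerate(gm.exons):
        if i < len(gm.exons) - 1:
            mids.add(e + 1)  # between G and T of the donor
        if i > 0:
            mids.add(s - 1)  # between A and G of the acceptor
    if td.dup_start in mids or td.dup_end in mids:
        return True
    sites = gm.splice_site_positions()
    for s, e in td.deletions:
        if any(s <= p < e for p in sites):
            return True
    return False


def splice_aware_frame(td: TDSpec, gm: GeneModel) -> TDAnnotation:
    """Annotate a TD with spliced frame status and encoded peptide."""
    if td.dup_end > gm.sequence_length:
        raise CoordinateError("duplication outside locus")
    contains_core = td.contains_core(gm)
    cds_iv = td.cds_interval(gm)
    exon_span = [
        name
        for (s, e), name in zip(gm.exons, gm.exon_names)
        if s < td.dup_end and e > td.dup_start
    ]
    if _splice_disrupting(td, gm):
        return TDAnnotation(
            None, None, "", contains_core, False, exon_span, cds_iv,
            False, True, "splice-disrupting",
        )
    # inserted coding content after projection through the exon model
    kept = td.kept_copy_intervals()
    copy_cds = "".join(
        gm.sequence[p] for s, e in kept for p in range(s, e) if gm.is_exonic(p)
    )
    insert_retained = (
        len(td.insert) > 0
        and td.dup_end > 0
        and gm.is_exonic(td.dup_end - 1)
        and gm.is_exonic(td.dup_start)
    )
    ins_cds = (td.insert if insert_retained else "") + copy_cds
    e_len = len(ins_cds)
    in_frame = e_len % 3 == 0
    exon13_duplicated = all(
        any(s <= p < e for s, e in kept) for p in range(*gm.exons[1])
    ) if td.dup_start < gm.exons[1][1] and td.dup_end > gm.exons[1][0] else False

    peptide = ""
    if in_frame and e_len > 0:
        wt_cds = gm.spliced_cds()
        # number of coding bases before the insertion point (ref < dup_end)
        j = sum(min(e, td.dup_end) - s for s, e in gm.exons if s < td.dup_end)
        mutant_cds = wt_cds[:j] + ins_cds + wt_cds[j:]
        off = (gm.cds_start - 1 + j) % 3
        a = j - off
        b = j + e_len
        b += (3 - (gm.cds_start - 1 + b) % 3) % 3
        peptide = translate(mutant_cds[a:b])
    leucine_rich = peptide.count("L") >= 3
    if contains_core:
        category = "core"
    elif leucine_rich:
        category = "non-core leucine-rich"
    else:
        category = "non-core"
    return TDAnnotation(
        in_frame, e_len, peptide, contains_core, leucine_rich, exon_span,
        cds_iv, exon13_duplicated, False, category,
    )


def minimal_duplicated_region(
    annotated: list[tuple[str, TDAnnotation]]
) -> tuple[tuple[int, int] | None, list[str], list[str]]:
    """Intersect duplicated CDS intervals over core-containing calls.

    Returns (interval, excluded_ids, diagnostics).  Non-core calls are
    excluded and listed; an empty intersection is reported as None together
    with pairwise-overlap diagnostics rather than raised.
    """
    core = [(pid, a.cds_interval) for pid, a in annotated if a.contains_core and a.cds_interval]
    excluded = [pid for pid, a in annotated if not a.contains_core]
    if not core:
        raise CoordinateError("at least one core-containing call is required")
    lo = max(iv[0] for _, iv in core)
    hi = min(iv[1] for _, iv in core)
    if lo >= hi:
        diags = [
            f"{a_id} [{a_iv[0]},{a_iv[1]}) vs {b_id} [{b_iv[0]},{b_iv[1]}): disjoint"
            for i, (a_id, a_iv) in enumerate(core)
            for b_id, b_iv in core[i + 1 :]
            if min(a_iv[1], b_iv[1]) <= max(a_iv[0], b_iv[0])
        ]
        return None, excluded, diags
    return (lo, hi), excluded, []


@dataclasses.dataclass
class CohortSummary:
    size_histogram: dict[int, int]
    minimal_region: tuple[int, int] | None
    minimal_region_length: int | None
    fraction_with_deletion: float
    fraction_deletion_large: float  # among TDs > threshold
    fraction_deletion_small: float
    fraction_sizes_48_51_54: float
    fraction_in_frame: float
    n: int
    excluded_non_core: list[str]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["size_histogram"] = {int(k): int(v) for k, v in self.size_histogram.items()}
        return d


def summarize_cohort(
    tds: list[tuple[str, TDSpec]],
    gm: GeneModel,
    deletion_size_threshold: int = 100,
) -> CohortSummary:
    """Cohort-level structure statistics over annotated TD calls."""
    if not tds:
        raise CoordinateError("empty cohort")
    annotated = [(pid, splice_aware_frame(td, gm)) for pid, td in tds]
    sizes = np.array([td.total_inserted_length for _, td in tds])
    has_del = np.array([len(td.deletions) > 0 for _, td in tds])
    large = sizes > deletion_size_threshold
    hist = pd.Series(sizes).value_counts().sort_index()
    region, excluded, _diags = minimal_duplicated_region(annotated)
    in_frame = np.array([a.in_frame is True for _, a in annotated])
    return CohortSummary(
        size_histogram={int(k): int(v) for k, v in hist.items()},
        minimal_region=region,
        minimal_region_length=None if region is None else region[1] - region[0],
        fraction_with_deletion=float(has_del.mean()),
        fraction_deletion_large=float(has_del[large].mean()) if large.any() else 0.0,
        fraction_deletion_small=float(has_del[~large].mean()) if (~large).any() else 0.0,
        fraction_sizes_48_51_54=float(np.isin(sizes, (48, 51, 54)).mean()),
        fraction_in_frame=float(in_frame.mean()),
        n=len(tds),
        excluded_non_core=excluded,
    )
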