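"""Detection and reconstruction of UBTF exon-13 tandem duplications.

Evidence model, mirroring what the IGV signature of these lesions shows:

* soft-clipped read clusters at the two duplication junctions (the 3'
  breakpoint collects right-clips whose clipped tail re-aligns upstream;
  the duplication start collects left-clips),
* CIGAR insertion strings when the whole inserted segment fits in a read,
* excess coverage over the duplicated interval relative to its flanks,
* a cheap mismatch-based suspicion scan (TD-positive samples always leave
  at least a small-variant footprint in standard callers).

Breakpoint consensus sequences are re-aligned to the local reference
(semi-global, match +1 / mismatch -1 / gap -2, leftmost placement on ties)
to recover the duplicated interval, the non-templated junction insert and
internal deletions in the copy.  VAF is estimated from junction-supporting
versus breakpoint-spanning reads and, independently, from the coverage
excess; the junction estimator subtracts the expected contribution of reads
wholly contained in the duplicated copy, which otherwise align as pure
matches across the 3' breakpoint and deflate the estimate.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict

import numpy as np
import pysam

from .errors import ConfigError
from .genemodel import GeneModel
from .synthetic import TDSpec

__all__ = [
    "CallerConfig",
    "SoftClipCluster",
    "TDCall",
    "suspicion_scan",
    "cluster_softclips",
    "collect_cigar_insertions",
    "reconstruct_td",
    "estimate_vaf",
    "call_tds",
]


@dataclasses.dataclass
class CallerConfig:
    min_clip_length: int = 10
    cluster_tolerance: int = 3
    min_support: int = 3
    search_window: int = 1500
    min_vaf_report: float = 0.01
    min_insertion_length: int = 10
    max_insert_scan: int = 8  # longest non-templated insert tried during re-alignment
    max_internal_deletion: int = 60
    mismatch_min_fraction: float = 0.02
    flank_margin: int = 400  # stay this far from locus ends when sampling
    # flank depth: coverage ramps up over roughly one fragment length

    def __post_init__(self) -> None:
        for name in (
            "min_clip_length",
            "cluster_tolerance",
            "min_support",
            "search_window",
            "min_insertion_length",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclasses.dataclass
class SoftClipCluster:
    breakpoint: int
    side: str  # "left" (clip precedes alignment) or "right"
    read_count: int
    clip_consensus: str
    mean_clip_length: float


@dataclasses.dataclass
class TDCall:
    reconstructed: TDSpec | None
    support_junction_reads: int
    spanning_ref_reads: int
    vaf_breakpoint: float | None
    vaf_coverage: float | None
    depth_dup_interval: float
    depth_flank: float
    suspicion_flag: bool
    vaf: float | None = None
    vaf_method: str = ""
    evidence: str = ""
    flags: list[str] = dataclasses.field(default_factory=list)


# ---------------------------------------------------------------------------
# Evidence collection
# ---------------------------------------------------------------------------

def _coverage(alignments: list[pysam.AlignedSegment], length: int) -> np.ndarray:
    cov = np.zeros(length + 1)
    for read in alignments:
        rpos = read.reference_start
        for op, n in read.cigartuples or ():
            if op == 0:  # M
                cov[rpos] += 1
                cov[min(rpos + n, length)] -= 1
                rpos += n
            elif op == 2:  # D
                rpos += n
    return np.cumsum(cov)[:length]


def suspicion_scan(
    alignments: list[pysam.AlignedSegment],
    gm: GeneModel,
    window: tuple[int, int],
    cfg: CallerConfig | None = None,
) -> tuple[bool, dict]:
    """Cheap pre-filter: does the window contain any non-reference signal?

    True iff a mismatch pileup rises above the sequencing-error model (same
    alternate base in >= min_support reads and >= mismatch_min_fraction of
    the local depth) or any read carries a CIGAR indel or long clip inside
    the window.
    """
    cfg = cfg or CallerConfig()
    lo, hi = window
    if hi <= lo:
        raise ConfigError("empty suspicion window")
    ref = np.frombuffer(gm.sequence.encode(), dtype="S1")
    mismatches: Counter = Counter()
    indel_reads = 0
    clip_reads = 0
    for read in alignments:
        if read.reference_end is None or read.reference_end <= lo or read.reference_start >= hi:
            continue
        seq = np.frombuffer(read.query_sequence.encode(), dtype="S1")
        qpos, rpos = 0, read.reference_start
        for op, n in read.cigartuples or ():
            if op == 0:
                a, b = max(rpos, lo), min(rpos + n, hi)
                if b > a:
                    qa = qpos + (a - rpos)
                    diff = np.nonzero(seq[qa : qa + (b - a)] != ref[a:b])[0]
                    for off in diff:
                        pos = a + int(off)
                        mismatches[(pos, seq[qa + int(off)].decode())] += 1
                qpos += n
                rpos += n
            elif op == 1:
                if n >= cfg.min_insertion_length and lo <= rpos < hi:
                    indel_reads += 1
                qpos += n
            elif op == 2:
                if lo <= rpos < hi:
                    indel_reads += 1
                rpos += n
            elif op == 4:
                if n >= cfg.min_clip_length and lo <= rpos < hi:
                    clip_reads += 1
                qpos += n
    depth = _coverage(alignments, gm.sequence_length)
    mm_hits = {
        key: cnt
        for key, cnt in mismatches.items()
        if cnt >= cfg.min_support and cnt >= cfg.mismatch_min_fraction * max(depth[key[0]], 1)
    }
    suspicious = bool(mm_hits) or indel_reads >= cfg.min_support or clip_reads >= cfg.min_support
    return suspicious, {
        "mismatch_sites": len(mm_hits),
        "indel_reads": indel_reads,
        "clip_reads": clip_reads,
    }


def _majority_consensus(strings: list[str], right_align: bool, min_cov: int) -> str:
    if right_align:
        strings = [s[::-1] for s in strings]
    length = max(len(s) for s in strings)
    out = []
    for col in range(length):
        bases = [s[col] for s in strings if len(s) > col]
        if len(bases) < min_cov:
            break
        counts = Counter(bases)
        top = max(counts.values())
        out.append(min(b for b, c in counts.items() if c == top))
    cons = "".join(out)
    return cons[::-1] if right_align else cons


def cluster_softclips(
    alignments: list[pysam.AlignedSegment], cfg: CallerConfig | None = None
) -> list[SoftClipCluster]:
    """Group soft-clips >= min_clip_length by (side, breakpoint +/- tolerance).

    Consensus is per-column majority (ties toward the lexicographically
    smallest base); columns supported by fewer than two reads are dropped
    for clusters with at least three reads.  Clusters below min_support are
    discarded.
    """
    cfg = cfg or CallerConfig()
    raw: dict[str, list[tuple[int, str]]] = {"left": [], "right": []}
    for read in alignments:
        cig = read.cigartuples or ()
        if not cig:
            continue
        seq = read.query_sequence
        if cig[0][0] == 4 and cig[0][1] >= cfg.min_clip_length:
            raw["left"].append((read.reference_start, seq[: cig[0][1]]))
        if cig[-1][0] == 4 and cig[-1][1] >= cfg.min_clip_length:
            raw["right"].append((read.reference_end, seq[len(seq) - cig[-1][1] :]))
    clusters: list[SoftClipCluster] = []
    for side, items in raw.items():
        items.sort(key=lambda t: (t[0], t[1]))
        group: list[tuple[int, str]] = []
        for pos, clip in items + [(10**12, "")]:
            if group and pos - group[0][0] > cfg.cluster_tolerance:
                if len(group) >= cfg.min_support:
                    positions = [p for p, _ in group]
                    bp = Counter(positions).most_common(1)[0][0]
                    clips = [c for _, c in group]
                    min_cov = 2 if len(clips) >= 3 else 1
                    cons = _majority_consensus(clips, side == "left", min_cov)
                    clusters.append(
                        SoftClipCluster(
                            bp,
                            side,
                            len(group),
                            cons,
                            float(np.mean([len(c) for c in clips])),
                        )
                    )
                group = []
            if clip:
                group.append((pos, clip))
    clusters.sort(key=lambda c: (c.breakpoint, c.side))
    return clusters


def collect_cigar_insertions(
    alignments: list[pysam.AlignedSegment], cfg: CallerConfig | None = None
) -> list[SoftClipCluster]:
    """Cluster long CIGAR insertions; returned as pseudo-clusters (side='ins')."""
    cfg = cfg or CallerConfig()
    events: list[tuple[int, str]] = []
    for read in alignments:
        qpos, rpos = 0, read.reference_start
        for op, n in read.cigartuples or ():
            if op == 0:
                qpos += n
                rpos += n
            elif op == 1:
                if n >= cfg.min_insertion_length:
                    events.append((rpos, read.query_sequence[qpos : qpos + n]))
                qpos += n
            elif op == 2:
                rpos += n
            elif op == 4:
                qpos += n
    events.sort(key=lambda t: (t[0], t[1]))
    clusters = []
    group: list[tuple[int, str]] = []
    for pos, ins in events + [(10**12, "")]:
        if group and pos - group[0][0] > cfg.cluster_tolerance:
            if len(group) >= cfg.min_support:
                bp = Counter(p for p, _ in group).most_common(1)[0][0]
                # consensus among the modal insertion length
                lengths = Counter(len(s) for _, s in group)
                modal = lengths.most_common(1)[0][0]
                strs = [s for _, s in group if len(s) == modal]
                cons = _majority_consensus(strs, right_align=False, min_cov=1)
                clusters.append(
                    SoftClipCluster(bp, "ins", len(group), cons, float(modal))
                )
            group = []
        if ins:
            group.append((pos, ins))
    return clusters


# ---------------------------------------------------------------------------
# Consensus re-alignment
# ---------------------------------------------------------------------------

_MATCH, _MISMATCH = 1, -1
_GAP_OPEN, _GAP_EXT = 4, 1  # affine penalties (subtracted)


def _dp_semiglobal(
    query: str, ref: str, anchor_end: bool = False
) -> tuple[int, int, int, list[tuple[int, int]], int]:
    """Gotoh semi-global alignment: query global, reference end gaps free.

    Returns (score, ref_start, ref_end, deletions, matched_bases) where
    deletions are reference intervals skipped by gaps in the query.  With
    ``anchor_end`` the alignment must consume the reference up to its last
    base.  Leftmost reference start is preferred on score ties.
    """
    nq, nr = len(query), len(ref)
    NEG = -(10**9)
    # state matrices: M diagonal, D gap-in-query (consumes ref), I gap-in-ref
    M = [[NEG] * (nr + 1) for _ in range(nq + 1)]
    D = [[NEG] * (nr + 1) for _ in range(nq + 1)]
    Ins = [[NEG] * (nr + 1) for _ in range(nq + 1)]
    for j in range(nr + 1):
        M[0][j] = 0  # free leading reference gap
    for i in range(1, nq + 1):
        Ins[i][0] = -_GAP_OPEN - (i - 1) * _GAP_EXT
    for i in range(1, nq + 1):
        qc = query[i - 1]
        Mi, Di, Ii = M[i], D[i], Ins[i]
        Mp, Dp, Ip = M[i - 1], D[i - 1], Ins[i - 1]
        for j in range(1, nr + 1):
            s = _MATCH if qc == ref[j - 1] else _MISMATCH
            Mi[j] = max(Mp[j - 1], Dp[j - 1], Ip[j - 1]) + s
            Di[j] = max(Mi[j - 1] - _GAP_OPEN, Di[j - 1] - _GAP_EXT)
            Ii[j] = max(Mp[j] - _GAP_OPEN, Ip[j] - _GAP_EXT)
    if anchor_end:
        end_j = nr
    else:
        end_j = max(range(nr + 1), key=lambda j: (max(M[nq][j], Ins[nq][j]), -j))
    # traceback
    state = "M" if M[nq][end_j] >= Ins[nq][end_j] else "I"
    i, j = nq, end_j
    deletions: list[tuple[int, int]] = []
    del_end = None
    n_match = 0
    while i > 0:
        if state == "M":
            if del_end is not None:
                deletions.append((j, del_end))
                del_end = None
            if query[i - 1] == ref[j - 1]:
                n_match += 1
            s = _MATCH if query[i - 1] == ref[j - 1] else _MISMATCH
            prev_val = M[i][j] - s
            i, j = i - 1, j - 1
            if M[i][j] == prev_val:
                state = "M"
            elif D[i][j] == prev_val:
                state = "D"
            else:
                state = "I"
        elif state == "D":
            if del_end is None:
                del_end = j
            if D[i][j] == M[i][j - 1] - _GAP_OPEN:
                state = "M"
            j -= 1
        else:  # I: gap in reference, consumes query
            if del_end is not None:
                deletions.append((j, del_end))
                del_end = None
            if Ins[i][j] == M[i - 1][j] - _GAP_OPEN:
                state = "M"
            i -= 1
    if del_end is not None:
        deletions.append((j, del_end))
    deletions.reverse()
    return max(M[nq][end_j], Ins[nq][end_j]), j, end_j, deletions, n_match


def _realign_consensus(
    consensus: str, window: str, cfg: CallerConfig, anchored_end: int | None = None
) -> tuple[int, int, int, list[tuple[int, int]]] | None:
    """Locate consensus[k:] in a reference window, trying non-templated
    insert lengths k = 0..max_insert_scan.

    Returns (k, start, end, deletions) in window coordinates or None.  When
    ``anchored_end`` is given the alignment must end there (used for CIGAR
    insertion strings, whose duplicated copy ends at the breakpoint).
    """
    n = len(consensus)
    min_probe = max(cfg.min_clip_length, 12)
    for k in range(0, min(cfg.max_insert_scan, max(n - min_probe, 0)) + 1):
        probe = consensus[k:]
        if anchored_end is not None:
            start = anchored_end - len(probe)
            if start >= 0 and window[start:anchored_end] == probe:
                return k, start, anchored_end, []
        else:
            idx = window.find(probe)
            if idx >= 0:
                return k, idx, idx + len(probe), []
    # imperfect consensus or internal deletions: seeded dynamic programming;
    # all insert lengths are scored and the best alignment wins (smallest k
    # on ties, so junction inserts are not silently absorbed as mismatches)
    best = None
    for k in range(0, min(cfg.max_insert_scan, max(n - min_probe, 0)) + 1):
        probe = consensus[k:]
        if len(probe) < min_probe:
            break
        if anchored_end is not None:
            lo = max(0, anchored_end - len(probe) - cfg.max_internal_deletion - 10)
            sub = (lo, anchored_end)
        else:
            seed = probe[: min(16, len(probe))]
            idx = window.find(seed)
            if idx < 0:
                continue
            lo = max(0, idx - 5)
            hi = min(len(window), idx + len(probe) + cfg.max_internal_deletion + 10)
            sub = (lo, hi)
        score, s, e, dels, n_match = _dp_semiglobal(
            probe, window[sub[0] : sub[1]], anchor_end=anchored_end is not None
        )
        if n_match < 0.85 * len(probe):
            continue
        if best is None or score > best[0]:
            best = (score, k, sub[0] + s, sub[0] + e, [(sub[0] + a, sub[0] + b) for a, b in dels])
    if best is None:
        return None
    _score, k, s, e, dels = best
    return k, s, e, dels


# ---------------------------------------------------------------------------
# Reconstruction
# ---------------------------------------------------------------------------

def _candidate_from_cluster(
    cluster: SoftClipCluster, gm: GeneModel, cfg: CallerConfig
) -> dict | None:
    wlo = max(0, cluster.breakpoint - cfg.search_window)
    whi = min(gm.sequence_length, cluster.breakpoint + cfg.search_window)
    cons = cluster.clip_consensus
    if len(cons) < cfg.min_clip_length:
        return None
    if cluster.side == "right":
        # clip = insert + start of the duplicated copy; re-align after p1.
        # The window overhangs the breakpoint: a clip can run past p2 into
        # reference sequence that continues contiguously after the copy.
        whi_r = min(gm.sequence_length, cluster.breakpoint + len(cons) + 10)
        window = gm.sequence[wlo:whi_r]
        hit = _realign_consensus(cons, window, cfg)
        if hit is None:
            return None
        k, s, _e, dels = hit
        p1 = wlo + s
        if p1 >= cluster.breakpoint:
            return None
        return {
            "p1": p1,
            "p2": cluster.breakpoint,
            "insert": cons[:k],
            "deletions": [
                (wlo + a, wlo + b)
                for a, b in dels
                if wlo + b <= cluster.breakpoint
            ],
            "complete_deletions": False,
            "support": cluster.read_count,
            "evidence": "right_clip",
        }
    if cluster.side == "left":
        # clip = reference tail ending at p2, followed by the insert; the
        # tail may begin before p1, so the window extends left of it
        rev = cons[::-1]
        wlo_l = max(0, cluster.breakpoint - len(cons) - 10)
        window = gm.sequence[wlo_l:whi][::-1]
        hit = _realign_consensus(rev, window, cfg)
        if hit is None:
            return None
        k, s, _e, _dels = hit
        # reversed-window index s maps to reference position whi - 1 - s;
        # the probe starts at the junction-proximal base p2 - 1
        p2 = whi - s
        if p2 <= cluster.breakpoint:
            return None
        return {
            "p1": cluster.breakpoint,
            "p2": p2,
            "insert": cons[len(cons) - k :],
            "deletions": [],
            "complete_deletions": False,
            "support": cluster.read_count,
            "evidence": "left_clip",
        }
    # CIGAR insertion: insert + full copy, copy ends at the breakpoint
    window = gm.sequence[wlo : cluster.breakpoint]
    hit = _realign_consensus(cons, window, cfg, anchored_end=len(window))
    if hit is None:
        return None
    k, s, _e, dels = hit
    return {
        "p1": wlo + s,
        "p2": cluster.breakpoint,
        "insert": cons[:k],
        "deletions": [(wlo + a, wlo + b) for a, b in dels],
        "complete_deletions": True,
        "support": cluster.read_count,
        "evidence": "cigar_insertion",
    }


def reconstruct_td(
    clusters: list[SoftClipCluster],
    insertions: list[SoftClipCluster],
    gm: GeneModel,
    cfg: CallerConfig | None = None,
) -> list[dict]:
    """Merge per-cluster candidates into duplication reconstructions.

    Returns candidate dicts with keys p1, p2, insert, deletions, support,
    evidence (clip_pair / cigar_insertion / one-sided), partial (bool) and
    no_duplication (True when a consensus re-aligned nowhere in the search
    window, i.e. the insertion is not a local tandem duplication).
    """
    cfg = cfg or CallerConfig()
    cands = []
    unplaced = []
    for cl in clusters + insertions:
        c = _candidate_from_cluster(cl, gm, cfg)
        if c is None:
            unplaced.append(cl)
            continue
        cands.append(c)
    merged: list[dict] = []
    cands.sort(key=lambda c: (c["p1"], c["p2"]))
    for c in cands:
        home = None
        for m in merged:
            if (
                abs(c["p1"] - m["p1"]) <= cfg.cluster_tolerance
                and abs(c["p2"] - m["p2"]) <= cfg.cluster_tolerance
            ):
                home = m
                break
        if home is None:
            c["members"] = [c["evidence"]]
            merged.append(c)
            continue
        home["support"] += c["support"]
        home["members"].append(c["evidence"])
        # prefer the most complete reconstruction: CIGAR insertions see the
        # whole copy, right clips see its start, left clips only imply it
        rank = {"left_clip": 0, "right_clip": 1, "cigar_insertion": 2}
        if rank[c["evidence"]] > max(rank[e] for e in home["members"][:-1]):
            for key in ("p1", "p2", "insert", "deletions", "complete_deletions"):
                home[key] = c[key]
    out = []
    for m in merged:
        kinds = set(m["members"])
        if "cigar_insertion" in kinds:
            evidence = "cigar_insertion"
        elif {"left_clip", "right_clip"} <= kinds:
            evidence = "clip_pair"
        else:
            evidence = m["members"][0]
        m["evidence"] = evidence
        m["partial"] = evidence in ("left_clip", "right_clip")
        m["no_duplication"] = False
        out.append(m)
    for cl in unplaced:
        # a cluster whose consensus could not be re-aligned still supports a
        # reconstructed call if its breakpoint matches one of the junctions
        key = "p1" if cl.side == "left" else "p2"
        home = next(
            (m for m in out if abs(cl.breakpoint - m[key]) <= cfg.cluster_tolerance),
            None,
        )
        if home is not None:
            home["support"] += cl.read_count
            continue
        if len(cl.clip_consensus) < cfg.min_clip_length + 4:
            continue  # too short to say anything about the inserted sequence
        out.append(
            {
                "p1": None,
                "p2": cl.breakpoint,
                "insert": "",
                "deletions": [],
                "support": cl.read_count,
                "evidence": cl.side,
                "partial": True,
                "no_duplication": True,
                "members": [cl.side],
            }
        )
    return out


# ---------------------------------------------------------------------------
# VAF estimation and top-level calling
# ---------------------------------------------------------------------------

def _spanning_reads(
    alignments: list[pysam.AlignedSegment], breakpoint: int, min_anchor: int
) -> int:
    n = 0
    for read in alignments:
        if read.reference_end is None:
            continue
        if read.reference_start > breakpoint - min_anchor:
            continue
        if read.reference_end < breakpoint + min_anchor:
            continue
        cig = read.cigartuples or ()
        # any clip disqualifies: junction reads with sub-threshold clips
        # otherwise masquerade as reference-spanning matches
        if any(op == 4 for op, _ in cig):
            continue
        if any(op == 1 and ln >= 3 for op, ln in cig):
            continue
        n += 1
    return n


def estimate_vaf(
    candidate: dict,
    alignments: list[pysam.AlignedSegment],
    gm: GeneModel,
    cfg: CallerConfig | None = None,
    suspicion: bool = True,
) -> TDCall:
    """Attach junction-based and coverage-based VAF estimates to a candidate.

    The junction estimator counts supporting reads against breakpoint-
    spanning reference-like reads; the observed spanning count is corrected
    downward by the expected number of reads wholly contained in the
    duplicated copy (which cross the 3' breakpoint as pure matches).  The
    coverage estimator is depth(duplicated interval) / depth(flanks) - 1.
    The reported VAF is the junction estimate when support >= min_support,
    otherwise the coverage estimate.
    """
    cfg = cfg or CallerConfig()
    p1, p2 = candidate["p1"], candidate["p2"]
    flags = []
    if candidate.get("no_duplication"):
        flags.append("no-duplication")
    if candidate.get("partial"):
        flags.append("partial evidence")
    support = candidate["support"]
    depth = _coverage(alignments, gm.sequence_length)
    read_lengths = [a.query_length for a in alignments[:200] if a.query_length]
    R = int(np.median(read_lengths)) if read_lengths else 150
    a0 = cfg.min_clip_length
    if p1 is None:
        return TDCall(
            None, support, 0, None, None, 0.0, 0.0, suspicion,
            vaf=None, vaf_method="undefined", evidence=candidate["evidence"], flags=flags,
        )
    m = p2 - p1
    td = TDSpec(
        p1,
        p2,
        candidate["insert"],
        tuple(candidate["deletions"]),
        allele_fraction=1.0,
    )
    s_obs = _spanning_reads(alignments, p2, a0)
    w_c = max(0, min(m, R - a0) - a0 + 1)
    denom_w = max(R - 2 * a0 + 1, 1)
    contamination = support * w_c / denom_w
    s_corr = max(0.0, s_obs - contamination)
    spanning = int(round(s_corr))
    if support + s_corr > 0:
        vaf_bp = support / (support + s_corr)
    else:
        vaf_bp = None
        flags.append("zero depth at breakpoint")
    # coverage over duplicated interval vs two equal-width flanks; flanks
    # stay clear of the locus edges where coverage ramps down
    margin = cfg.flank_margin
    w = min(m, 300)
    lo_a, lo_b = max(p1 - w, margin), p1
    hi_a, hi_b = p2, min(p2 + w, gm.sequence_length - margin)
    depth_dup = float(depth[p1:p2].mean()) if p2 > p1 else 0.0
    flank_parts = [depth[a:b] for a, b in ((lo_a, lo_b), (hi_a, hi_b)) if b > a]
    depth_flank = float(np.concatenate(flank_parts).mean()) if flank_parts else 0.0
    vaf_cov = None
    if depth_flank > 0:
        vaf_cov = float(min(max(depth_dup / depth_flank - 1.0, 0.0), 1.05))
    if support >= cfg.min_support and vaf_bp is not None:
        vaf, method = min(vaf_bp, 1.05), "breakpoint"
    else:
        vaf, method = vaf_cov, "coverage"
    return TDCall(
        td,
        support,
        spanning,
        None if vaf_bp is None else float(min(vaf_bp, 1.05)),
        vaf_cov,
        depth_dup,
        depth_flank,
        suspicion,
        vaf=vaf,
        vaf_method=method,
        evidence=candidate["evidence"],
        flags=flags,
    )


def call_tds(
    alignments: list[pysam.AlignedSegment],
    gm: GeneModel,
    cfg: CallerConfig | None = None,
) -> list[TDCall]:
    """Full caller: suspicion scan, clip clustering, reconstruction, VAF.

    Calls below min_vaf_report (the screen's 1% sensitivity floor) are
    suppressed; no call is emitted without the mismatch suspicion flag.
    """
    cfg = cfg or CallerConfig()
    alignments = list(alignments)
    exon13 = gm.exons[1]
    window = (
        max(0, exon13[0] - cfg.search_window),
        min(gm.sequence_length, exon13[1] + cfg.search_window),
    )
    suspicious, _summary = suspicion_scan(alignments, gm, window, cfg)
    if not suspicious:
        return []
    clusters = cluster_softclips(alignments, cfg)
    insertions = collect_cigar_insertions(alignments, cfg)
    candidates = reconstruct_td(clusters, insertions, gm, cfg)
    calls = []
    for cand in candidates:
        call = estimate_vaf(cand, alignments, gm, cfg, suspicion=suspicious)
        if call.reconstructed is None:
            calls.append(call)
            continue
        if call.vaf is not None and call.vaf < cfg.min_vaf_report:
            continue
        calls.append(call)
    calls.sort(key=lambda c: (-(c.vaf or 0.0), c.support_junction_reads))
    return calls
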