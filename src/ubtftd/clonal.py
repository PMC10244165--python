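"""Clonal architecture and diagnosis -> relapse evolution from bulk VAFs.

Bulk variant allele fractions are converted to cancer-cell fractions (CCF)
by correcting for the copy-number state of each variant (a heterozygous
variant on two copies has CCF = 2 x VAF; a UPD-homozygous variant or a
mutation retained after loss of the other allele has CCF = VAF).  Variants
are then nested into a clone tree by a greedy pigeonhole argument: a variant
fits inside the smallest clone whose CCF dominates its own at every
timepoint, and two variants whose CCFs cannot coexist in disjoint subclones
of their container must lie on one lineage.  Tumor purity is assumed to be 1
(blast-enriched samples); the 1% VAF detection floor is the presence/absence
threshold for evolution calls.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ArchitectureError, ConfigError

__all__ = [
    "CNState",
    "TimepointVariant",
    "ccf",
    "CloneNode",
    "CloneTree",
    "build_clone_tree",
    "classify_wt1",
    "classify_relapse_pattern",
    "EvolutionReport",
    "analyze_patient",
    "TIMEPOINTS",
    "DETECTION_VAF",
]

TIMEPOINTS = ("diagnosis", "progression")
#: presence/absence sensitivity floor on VAF
DETECTION_VAF = 0.01


@dataclasses.dataclass(frozen=True)
class CNState:
    """Copy-number state of a variant locus: total and mutated copy counts."""

    total_copies: int
    mutated_copies: int
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.mutated_copies < 1:
            raise ConfigError("mutated_copies must be >= 1")
        if self.mutated_copies > self.total_copies:
            raise ConfigError("mutated_copies cannot exceed total_copies")

    @classmethod
    def diploid_het(cls) -> "CNState":
        return cls(2, 1, "diploid-het")

    @classmethod
    def upd_hom(cls) -> "CNState":
        return cls(2, 2, "UPD-hom")

    @classmethod
    def mut_plus_del(cls) -> "CNState":
        return cls(1, 1, "mut-plus-del")

    @classmethod
    def parse(cls, text: str) -> "CNState":
        text = text.strip()
        named = {
            "diploid-het": cls.diploid_het,
            "UPD-hom": cls.upd_hom,
            "mut-plus-del": cls.mut_plus_del,
        }
        if text in named:
            return named[text]()
        if text.startswith("custom"):
            _, cn, m = text.split(":")
            return cls(int(cn), int(m))
        raise ConfigError(f"unknown copy-number state {text!r}")


@dataclasses.dataclass
class TimepointVariant:
    """A variant observed at one timepoint with its VAF and CN context."""

    variant_id: str
    gene: str
    timepoint: str
    vaf: float
    depth: int
    cn_state: CNState

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ConfigError(f"timepoint must be one of {TIMEPOINTS}")
        if not (0.0 <= self.vaf <= 1.0):
            raise ConfigError("vaf must lie in [0, 1]")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")


def ccf(v: TimepointVariant, cap: float = 1.0) -> float:
    """Cancer-cell fraction: VAF x total copies / mutated copies, capped."""
    raw = v.vaf * v.cn_state.total_copies / v.cn_state.mutated_copies
    return min(raw, cap)


def ccf_raw(v: TimepointVariant) -> float:
    return v.vaf * v.cn_state.total_copies / v.cn_state.mutated_copies


# ---------------------------------------------------------------------------
# Clone tree
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CloneNode:
    clone_id: int
    parent: int | None  # None for top-level clones
    variant_ids: list[str]
    ccf: dict[str, float]  # timepoint -> subtree-inclusive CCF
    ccf_sd: dict[str, float] = dataclasses.field(default_factory=dict)

    def exclusive_prevalence(self, tree: "CloneTree", timepoint: str) -> float:
        child_sum = sum(
            c.ccf[timepoint] for c in tree.nodes if c.parent == self.clone_id
        )
        return max(0.0, self.ccf[timepoint] - child_sum)


@dataclasses.dataclass
class CloneTree:
    nodes: list[CloneNode]
    violations: list[str] = dataclasses.field(default_factory=list)

    @property
    def unresolvable(self) -> bool:
        return bool(self.violations)

    def node_of_variant(self, variant_id: str) -> CloneNode | None:
        for n in self.nodes:
            if variant_id in n.variant_ids:
                return n
        return None

    def ancestors(self, clone_id: int) -> list[int]:
        out = []
        node = next(n for n in self.nodes if n.clone_id == clone_id)
        while node.parent is not None:
            out.append(node.parent)
            node = next(n for n in self.nodes if n.clone_id == node.parent)
        return out

    def same_lineage(self, vid_a: str, vid_b: str) -> bool:
        """True if the clones of two variants are identical or nested."""
        na, nb = self.node_of_variant(vid_a), self.node_of_variant(vid_b)
        if na is None or nb is None:
            return False
        if na.clone_id == nb.clone_id:
            return True
        return na.clone_id in self.ancestors(nb.clone_id) or nb.clone_id in self.ancestors(
            na.clone_id
        )

    def fishplot_frame(self) -> pd.DataFrame:
        """Fishplot-ready matrix: inclusive prevalences per timepoint + parent."""
        rows = []
        for n in self.nodes:
            row = {"clone": n.clone_id, "parent": 0 if n.parent is None else n.parent + 1}
            for t in TIMEPOINTS:
                row[t] = round(n.ccf[t], 6)
            row["variants"] = ";".join(n.variant_ids)
            rows.append(row)
        df = pd.DataFrame(rows)
        df["clone"] = df["clone"] + 1  # fishplot uses 1-based ids, 0 = root
        return df

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "nodes": [
                {
                    "clone_id": n.clone_id,
                    "parent": n.parent,
                    "variants": n.variant_ids,
                    "ccf": n.ccf,
                }
                for n in self.nodes
            ],
            "violations": self.violations,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _collect_ccfs(
    variants: list[TimepointVariant],
) -> tuple[dict[str, dict[str, float]], dict[str, dict[str, float]]]:
    """Per-variant CCF and its binomial standard deviation per timepoint."""
    out: dict[str, dict[str, float]] = {}
    sds: dict[str, dict[str, float]] = {}
    for v in variants:
        out.setdefault(v.variant_id, {t: 0.0 for t in TIMEPOINTS})[v.timepoint] = ccf(v)
        factor = v.cn_state.total_copies / v.cn_state.mutated_copies
        sd = factor * math.sqrt(max(v.vaf * (1 - v.vaf), 1.0 / v.depth) / v.depth)
        sds.setdefault(v.variant_id, {t: 0.0 for t in TIMEPOINTS})[v.timepoint] = sd
    return out, sds


#: chi-square critical value (2 df, alpha ~ 0.004) for the same-clone test
_MERGE_CHI2 = 11.0
#: absolute cap: never merge CCFs further apart than this at any timepoint
_MERGE_CAP = 0.25


def _same_clone(
    cv: dict[str, float],
    sv: dict[str, float],
    node: CloneNode,
) -> bool:
    """Can a variant's CCF trajectory belong to an existing clone?

    Pools the squared z-scores of the per-timepoint CCF differences into a
    chi-square statistic, so depth decides how much separation is noise.
    """
    chi2 = 0.0
    for t in TIMEPOINTS:
        diff = cv[t] - node.ccf[t]
        if abs(diff) > _MERGE_CAP:
            return False
        var = sv[t] ** 2 + node.ccf_sd.get(t, 0.0) ** 2
        chi2 += diff * diff / max(var, 1e-12)
    return chi2 <= _MERGE_CHI2


def build_clone_tree(
    variants: list[TimepointVariant],
    tolerance: float = 0.1,
    cluster_tolerance: float = 0.1,
) -> CloneTree:
    """Greedy pigeonhole nesting of variants into a clone tree.

    Variants are inserted in order of decreasing CCF (founding-clone ties
    broken in favour of UBTF-TD-class variants, then diagnosis CCF, then
    variant id).  Each variant descends from the root into the smallest
    already-placed clone that dominates it at every timepoint; when its CCF
    and a sibling's cannot both fit in their container (sum exceeds the
    container CCF plus tolerance at some timepoint) the two are forced onto
    one lineage.  Variants whose CCFs match an existing clone within the
    cluster tolerance at every timepoint join that clone.  Inconsistencies
    are reported in ``CloneTree.violations``, never silently resolved.
    """
    if not variants:
        raise ArchitectureError("at least one variant is required")
    ccfs, sds = _collect_ccfs(variants)
    genes = {v.variant_id: v.gene for v in variants}

    def sort_key(vid: str):
        c = ccfs[vid]
        is_ubtf = genes[vid].upper().startswith("UBTF")
        return (
            -sum(c[t] for t in TIMEPOINTS),
            0 if is_ubtf else 1,
            -c["diagnosis"],
            vid,
        )

    order = sorted(ccfs, key=sort_key)
    nodes: list[CloneNode] = []
    violations: list[str] = []
    root_ccf = {t: 1.0 for t in TIMEPOINTS}

    def children_of(parent: int | None) -> list[CloneNode]:
        return [n for n in nodes if n.parent == parent]

    for vid in order:
        cv = ccfs[vid]
        parent: int | None = None
        parent_ccf = root_ccf
        while True:
            kids = children_of(parent)
            forced = [
                k
                for k in kids
                if any(cv[t] + k.ccf[t] > parent_ccf[t] + tolerance for t in TIMEPOINTS)
            ]
            eligible = [
                k for k in kids if all(k.ccf[t] >= cv[t] - tolerance for t in TIMEPOINTS)
            ]
            if forced:
                # must share a lineage with the forced sibling(s)
                target = max(forced, key=lambda k: sum(k.ccf[t] for t in TIMEPOINTS))
                if target not in eligible:
                    violations.append(
                        f"variant {vid} (CCF {cv}) forced into lineage of clone "
                        f"{target.clone_id} (CCF {target.ccf}) that does not contain it"
                    )
                # merge if CCFs are indistinguishable, else descend
                if _same_clone(cv, sds[vid], target):
                    _merge(target, vid, cv, sds[vid])
                    break
                parent, parent_ccf = target.clone_id, target.ccf
                continue
            merge_cands = [k for k in eligible if _same_clone(cv, sds[vid], k)]
            if merge_cands:
                target = min(
                    merge_cands,
                    key=lambda k: sum(abs(cv[t] - k.ccf[t]) for t in TIMEPOINTS),
                )
                _merge(target, vid, cv, sds[vid])
                break
            if eligible:
                # descend into the tightest dominating clone; clones that
                # dominate without needing the tolerance take precedence
                strict = [
                    k for k in eligible if all(k.ccf[t] >= cv[t] for t in TIMEPOINTS)
                ]
                pool = strict or eligible
                target = min(pool, key=lambda k: sum(k.ccf[t] for t in TIMEPOINTS))
                parent, parent_ccf = target.clone_id, target.ccf
                continue
            # new child of the current container
            node = CloneNode(len(nodes), parent, [vid], dict(cv), dict(sds[vid]))
            nodes.append(node)
            sib_sum = {
                t: sum(k.ccf[t] for k in children_of(parent)) for t in TIMEPOINTS
            }
            for t in TIMEPOINTS:
                if sib_sum[t] > parent_ccf[t] + tolerance:
                    violations.append(
                        f"sibling CCFs sum to {sib_sum[t]:.3f} > container "
                        f"{parent_ccf[t]:.3f} + {tolerance} at {t} after placing {vid}"
                    )
            break

    return CloneTree(nodes, violations)


def _merge(node: CloneNode, vid: str, cv: dict[str, float], sv: dict[str, float]) -> None:
    n = len(node.variant_ids)
    node.variant_ids.append(vid)
    for t in node.ccf:
        node.ccf[t] = (node.ccf[t] * n + cv[t]) / (n + 1)
        pooled = math.sqrt((node.ccf_sd.get(t, 0.0) * n) ** 2 + sv[t] ** 2)
        node.ccf_sd[t] = pooled / (n + 1)


# ---------------------------------------------------------------------------
# WT1 allelic status and relapse patterns
# ---------------------------------------------------------------------------

def classify_wt1(
    variants: list[TimepointVariant],
    tree: CloneTree,
    timepoint: str,
    detection_vaf: float = DETECTION_VAF,
) -> str:
    """WT1 allelic status at one timepoint: none, mono_alt or bi_alt.

    Biallelic status arises from (a) two WT1 variants on one lineage, (b) a
    UPD-homozygous WT1 variant, or (c) a WT1 mutation combined with loss of
    the other allele (mut-plus-del).
    """
    present = [
        v
        for v in variants
        if v.gene == "WT1" and v.timepoint == timepoint and v.vaf >= detection_vaf
    ]
    if not present:
        return "none"
    for v in present:
        if v.cn_state.label in ("UPD-hom", "mut-plus-del"):
            return "bi_alt"
        if v.cn_state.mutated_copies == v.cn_state.total_copies and v.cn_state.total_copies > 1:
            return "bi_alt"
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            if tree.same_lineage(present[i].variant_id, present[j].variant_id):
                return "bi_alt"
    return "mono_alt"


@dataclasses.dataclass
class EvolutionReport:
    variant_status: dict[str, str]  # variant_id -> gained | lost | persistent
    wt1_class: dict[str, str]  # timepoint -> none | mono_alt | bi_alt
    relapse_pattern: str
    tree: CloneTree

    def to_frame(self, variants: list[TimepointVariant]) -> pd.DataFrame:
        by_id: dict[str, dict] = {}
        for v in variants:
            rec = by_id.setdefault(
                v.variant_id, {"variant_id": v.variant_id, "gene": v.gene}
            )
            rec[f"vaf_{v.timepoint}"] = v.vaf
        rows = []
        for vid, rec in sorted(by_id.items()):
            rec["status"] = self.variant_status.get(vid, "absent")
            node = self.tree.node_of_variant(vid)
            rec["clone"] = None if node is None else node.clone_id
            rows.append(rec)
        df = pd.DataFrame(rows)
        df["wt1_diagnosis"] = self.wt1_class["diagnosis"]
        df["wt1_progression"] = self.wt1_class["progression"]
        df["relapse_pattern"] = self.relapse_pattern
        return df


def _vaf_at(variants: list[TimepointVariant], vid: str, timepoint: str) -> float:
    for v in variants:
        if v.variant_id == vid and v.timepoint == timepoint:
            return v.vaf
    return 0.0


def classify_relapse_pattern(
    variants: list[TimepointVariant],
    tree: CloneTree,
    wt1_dx: str,
    wt1_rel: str,
    detection_vaf: float = DETECTION_VAF,
) -> str:
    """Classify the diagnosis -> relapse trajectory of the WT1 lineage.

    ``bi_alt_preexisting``: the relapse-driving biallelic WT1 configuration
    is already detectable (VAF >= 1%) at diagnosis; ``bi_alt_from_mono``:
    only its monoallelic component is; ``bi_alt_emergent``: neither is;
    ``mono_on_flt3``: relapse carries a monoallelic WT1 hit arising within a
    persistent FLT3-ITD clone; ``other`` otherwise.
    """
    if wt1_rel == "bi_alt":
        if wt1_dx == "bi_alt":
            return "bi_alt_preexisting"
        if wt1_dx == "mono_alt":
            return "bi_alt_from_mono"
        return "bi_alt_emergent"
    if wt1_rel == "mono_alt":
        flt3 = [
            v.variant_id
            for v in variants
            if v.gene == "FLT3-ITD" and v.timepoint == "diagnosis" and v.vaf >= detection_vaf
        ]
        flt3_persistent = [
            vid for vid in flt3 if _vaf_at(variants, vid, "progression") >= detection_vaf
        ]
        wt1_rel_ids = [
            v.variant_id
            for v in variants
            if v.gene == "WT1" and v.timepoint == "progression" and v.vaf >= detection_vaf
        ]
        for f in flt3_persistent:
            for w in wt1_rel_ids:
                if tree.same_lineage(f, w):
                    return "mono_on_flt3"
    return "other"


def analyze_patient(
    variants: list[TimepointVariant],
    tolerance: float = 0.1,
    detection_vaf: float = DETECTION_VAF,
) -> EvolutionReport:
    """Full per-patient evolution analysis from a paired-timepoint table."""
    tree = build_clone_tree(variants, tolerance=tolerance)
    status: dict[str, str] = {}
    for vid in {v.variant_id for v in variants}:
        dx = _vaf_at(variants, vid, "diagnosis") >= detection_vaf
        rel = _vaf_at(variants, vid, "progression") >= detection_vaf
        if dx and rel:
            status[vid] = "persistent"
        elif rel:
            status[vid] = "gained"
        elif dx:
            status[vid] = "lost"
        else:
            status[vid] = "absent"
    wt1 = {
        t: classify_wt1(variants, tree, t, detection_vaf) for t in TIMEPOINTS
    }
    pattern = classify_relapse_pattern(
        variants, tree, wt1["diagnosis"], wt1["progression"], detection_vaf
    )
    return EvolutionReport(status, wt1, pattern, tree)


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def variants_to_frame(variants: list[TimepointVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "gene": [v.gene for v in variants],
            "timepoint": [v.timepoint for v in variants],
            "vaf": [v.vaf for v in variants],
            "depth": [v.depth for v in variants],
            "cn_state": [
                v.cn_state.label
                if v.cn_state.label != "custom"
                else f"custom:{v.cn_state.total_copies}:{v.cn_state.mutated_copies}"
                for v in variants
            ],
        }
    )


def variants_from_frame(df: pd.DataFrame) -> list[TimepointVariant]:
    return [
        TimepointVariant(
            str(r.variant_id),
            str(r.gene),
            str(r.timepoint),
            float(r.vaf),
            int(r.depth),
            CNState.parse(str(r.cn_state)),
        )
        for r in df.itertuples()
    ]
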