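"""End-to-end orchestration: synth -> screen -> call -> annotate -> clonal -> stats.

A single root seed feeds named substreams (one per stage) so reruns with the
same configuration are byte-identical.  Each stage writes its outputs under
the configured directory and records itself in a JSON manifest; a stage
failure is recorded and downstream stages are skipped.
"""

from __future__ import annotations

import dataclasses
import json
import traceback
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import summarize_cohort
from .caller import CallerConfig, call_tds
from .clonal import CNState, analyze_patient, variants_to_frame
from .errors import ConfigError
from .fragments import call_peaks, peak_calls_to_frame
from .genemodel import fixture_gene_model, write_gene_model
from .io import write_call_report, write_vcf
from .stats import ContingencyTable, benjamini_hochberg, fisher_exact_two_sided
from .synthetic import (
    CohortSpec,
    PlantedClone,
    ReadSimConfig,
    cohort_to_frame,
    mutate_locus,
    sample_cohort,
    simulate_paired_timepoints,
    simulate_reads,
    simulate_trace,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

#: the in-study CR/CRp contingency comparisons (group x outcome yes/no)
STUDY_TABLES = {
    "wt1_mutated_vs_wt_in_td": (4, 6, 10, 1),
    "td_vs_wt_in_wt1_mutated": (4, 6, 38, 10),
}


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 7
    outdir: str = "ubtftd_run"
    n_patients: int = 20
    n_sequenced: int = 5
    depth: float = 500.0
    read_length: int = 150
    trace_stutter: float = 0.0
    clonal_depth: int = 500
    stages: tuple[str, ...] = ("synth", "screen", "call", "annotate", "clonal", "stats")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        if "stages" in d:
            d = {**d, "stages": tuple(d["stages"])}
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def _substreams(root_seed: int, names: tuple[str, ...]) -> dict[str, int]:
    ss = np.random.SeedSequence(root_seed)
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the requested stages; returns (and writes) the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _substreams(cfg.seed, ("synth", "screen", "call", "clonal"))
    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "seeds": seeds,
        "stages": {},
    }
    state: dict = {}
    failed = False
    for stage in cfg.stages:
        entry: dict = {"status": "skipped (upstream failure)"} if failed else {}
        if not failed:
            try:
                outputs = _STAGES[stage](cfg, seeds, out, state)
                entry = {"status": "ok", "outputs": outputs}
            except Exception as exc:  # recorded, not raised: manifest is the record
                entry = {
                    "status": "failed",
                    "error": f"{type(exc).__name__}: {exc}",
                    "traceback": traceback.format_exc(),
                }
                failed = True
        manifest["stages"][stage] = entry
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    _write_report(manifest, state, out / "report.md")
    if failed:
        raise RuntimeError(f"pipeline failed; see {out / 'manifest.json'}")
    return manifest


def _stage_synth(cfg: PipelineConfig, seeds, out: Path, state: dict) -> list[str]:
    gm = fixture_gene_model()
    cohort_spec = CohortSpec(n_patients=cfg.n_patients, seed=seeds["synth"])
    patients = sample_cohort(cohort_spec, gm)
    state["gm"], state["patients"] = gm, patients
    df = cohort_to_frame(patients, gm)
    write_gene_model(gm, out / "locus.fa", out / "exons.tsv")
    df.to_csv(out / "cohort_truth.tsv", sep="\t", index=False)
    return ["locus.fa", "exons.tsv", "cohort_truth.tsv"]


def _stage_screen(cfg: PipelineConfig, seeds, out: Path, state: dict) -> list[str]:
    gm, patients = state["gm"], state["patients"]
    wt = gm.amplicon_length()
    rows = []
    rng = np.random.default_rng(seeds["screen"])
    for p in patients:
        trace = simulate_trace(
            wt,
            p.td.total_inserted_length,
            p.td.allele_fraction,
            seed=int(rng.integers(2**31)),
            stutter_fraction=cfg.trace_stutter,
        )
        calls, no_wt = call_peaks(trace, wt)
        mut = [c for c in calls if c.classification == "mutant"]
        rows.append(
            {
                "patient_id": p.patient_id,
                "screen_positive": bool(mut),
                "td_size_estimate": mut[0].td_size if mut else None,
                "true_size": p.td.total_inserted_length,
                "no_wt_peak": no_wt,
                "beyond_size_standard": any(c.beyond_size_standard for c in mut),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "screen.tsv", sep="\t", index=False)
    state["screen"] = df
    return ["screen.tsv"]


def _stage_call(cfg: PipelineConfig, seeds, out: Path, state: dict) -> list[str]:
    gm, patients = state["gm"], state["patients"]
    caller_cfg = CallerConfig()
    outputs = []
    rows = []
    rng = np.random.default_rng(seeds["call"])
    for p in patients[: cfg.n_sequenced]:
        mut = mutate_locus(gm, p.td)
        f = p.td.allele_fraction
        sim = simulate_reads(
            gm,
            [(gm.sequence, 1 - f, None), (mut, f, p.td)],
            ReadSimConfig(
                read_length=cfg.read_length,
                depth=cfg.depth,
                seed=int(rng.integers(2**31)),
            ),
        )
        sam = out / f"{p.patient_id}.sam"
        sim.write_sam(str(sam))
        calls = call_tds(sim.reads, gm, caller_cfg)
        write_vcf(calls, gm, out / f"{p.patient_id}.vcf", sample=p.patient_id)
        write_call_report(calls, out / f"{p.patient_id}.calls.json")
        outputs += [sam.name, f"{p.patient_id}.vcf", f"{p.patient_id}.calls.json"]
        top = calls[0] if calls else None
        rows.append(
            {
                "patient_id": p.patient_id,
                "called": top is not None and top.reconstructed is not None,
                "called_size": None
                if top is None or top.reconstructed is None
                else top.reconstructed.total_inserted_length,
                "true_size": p.td.total_inserted_length,
                "called_vaf": None if top is None else top.vaf,
                "true_vaf": f,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "calls_summary.tsv", sep="\t", index=False)
    state["calls"] = df
    return outputs + ["calls_summary.tsv"]


def _stage_annotate(cfg: PipelineConfig, seeds, out: Path, state: dict) -> list[str]:
    gm, patients = state["gm"], state["patients"]
    summary = summarize_cohort([(p.patient_id, p.td) for p in patients], gm)
    (out / "cohort_summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
    state["summary"] = summary
    return ["cohort_summary.json"]


def demo_relapse_architectures() -> dict[str, list[PlantedClone]]:
    """Three planted diagnosis->relapse architectures of the observed types.

    E-type: a biallelic (UPD-homozygous) WT1 subclone present at low level at
    diagnosis expands at relapse.  F-type: a monoallelic WT1 clone acquires a
    second WT1 hit at relapse.  A-type: relapse is driven by a monoallelic
    WT1 hit arising inside a persistent FLT3-ITD clone.
    """
    het = CNState.diploid_het()
    return {
        "E_type": [
            PlantedClone("founder", None, [("UBTF-TD.1", "UBTF-TD", het)],
                         {"diagnosis": 0.9, "progression": 0.95}),
            PlantedClone("wt1_hom", "founder", [("WT1.1", "WT1", CNState.upd_hom())],
                         {"diagnosis": 0.05, "progression": 0.9}),
        ],
        "F_type": [
            PlantedClone("founder", None, [("UBTF-TD.1", "UBTF-TD", het)],
                         {"diagnosis": 0.9, "progression": 0.95}),
            PlantedClone("wt1_mono", "founder", [("WT1.1", "WT1", het)],
                         {"diagnosis": 0.5, "progression": 0.9}),
            PlantedClone("wt1_second", "wt1_mono", [("WT1.2", "WT1", het)],
                         {"diagnosis": 0.0, "progression": 0.85}),
        ],
        "A_type": [
            PlantedClone("founder", None, [("UBTF-TD.1", "UBTF-TD", het)],
                         {"diagnosis": 0.9, "progression": 0.95}),
            PlantedClone("flt3", "founder", [("FLT3-ITD.1", "FLT3-ITD", het)],
                         {"diagnosis": 0.6, "progression": 0.9}),
            PlantedClone("wt1_mono", "flt3", [("WT1.1", "WT1", het)],
                         {"diagnosis": 0.0, "progression": 0.8}),
        ],
    }


def _stage_clonal(cfg: PipelineConfig, seeds, out: Path, state: dict) -> list[str]:
    outputs = []
    results = {}
    for i, (name, clones) in enumerate(demo_relapse_architectures().items()):
        variants, truth = simulate_paired_timepoints(
            clones, depth=cfg.clonal_depth, seed=seeds["clonal"] + i
        )
        report = analyze_patient(variants)
        frame = report.to_frame(variants)
        frame.to_csv(out / f"evolution_{name}.tsv", sep="\t", index=False)
        report.tree.fishplot_frame().to_csv(out / f"fishplot_{name}.csv", index=False)
        variants_to_frame(variants).to_csv(out / f"variants_{name}.tsv", sep="\t", index=False)
        outputs += [f"evolution_{name}.tsv", f"fishplot_{name}.csv", f"variants_{name}.tsv"]
        results[name] = report.relapse_pattern
    state["clonal"] = results
    return outputs


def _stage_stats(cfg: PipelineConfig, seeds, out: Path, state: dict) -> list[str]:
    pvals = {
        name: fisher_exact_two_sided(ContingencyTable(*counts))
        for name, counts in STUDY_TABLES.items()
    }
    qvals = benjamini_hochberg(list(pvals.values()))
    payload = {
        name: {"table": list(STUDY_TABLES[name]), "p": p, "q": q}
        for (name, p), q in zip(pvals.items(), qvals)
    }
    (out / "stats.json").write_text(json.dumps(payload, indent=2))
    state["stats"] = payload
    return ["stats.json"]


_STAGES = {
    "synth": _stage_synth,
    "screen": _stage_screen,
    "call": _stage_call,
    "annotate": _stage_annotate,
    "clonal": _stage_clonal,
    "stats": _stage_stats,
}


def _write_report(manifest: dict, state: dict, path: Path) -> None:
    lines = ["# UBTF-TD pipeline report", ""]
    lines.append(f"Root seed: {manifest['config']['seed']}")
    lines.append("")
    for stage, entry in manifest["stages"].items():
        lines.append(f"## {stage}: {entry.get('status', '?')}")
    if "summary" in state:
        s = state["summary"]
        lines += [
            "",
            "## Cohort structure",
            f"- patients: {s.n}",
            f"- minimal duplicated region: c.{s.minimal_region[0]}-c.{s.minimal_region[1] - 1}"
            if s.minimal_region
            else "- minimal duplicated region: empty",
            f"- fraction of sizes 48/51/54: {s.fraction_sizes_48_51_54:.2f}",
            f"- fraction with internal deletion: {s.fraction_with_deletion:.2f}",
            f"- fraction in-frame after splicing: {s.fraction_in_frame:.2f}",
        ]
    if "screen" in state:
        df = state["screen"]
        exact = (df.dropna(subset=["td_size_estimate"]).td_size_estimate
                 == df.dropna(subset=["td_size_estimate"]).true_size).mean()
        lines += ["", "## Fragment screen",
                  f"- screen-positive: {int(df.screen_positive.sum())}/{len(df)}",
                  f"- exact size recovery among positives: {exact:.2f}"]
    if "clonal" in state:
        lines += ["", "## Relapse patterns"] + [
            f"- {k}: {v}" for k, v in state["clonal"].items()
        ]
    if "stats" in state:
        lines += ["", "## Contingency statistics"] + [
            f"- {k}: p = {v['p']:.3f}, q = {v['q']:.3f}" for k, v in state["stats"].items()
        ]
    path.write_text("\n".join(lines) + "\n")
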