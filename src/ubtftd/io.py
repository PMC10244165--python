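"""Writers for caller output: VCF (symbolic tandem-duplication ALT) + JSON."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pysam

from .caller import TDCall
from .genemodel import GeneModel

__all__ = ["write_vcf", "calls_to_json", "write_call_report"]


def write_vcf(calls: list[TDCall], gm: GeneModel, path: str | Path, sample: str = "SAMPLE") -> None:
    """Write TD calls as VCF with a symbolic <DUP:TANDEM> ALT.

    The full inserted sequence (non-templated insert + duplicated copy after
    internal deletions) is carried in INFO/INSSEQ; INFO/END and INFO/SVLEN
    describe the duplicated interval and the net inserted length.
    """
    header = pysam.VariantHeader()
    header.add_line('##ALT=<ID=DUP:TANDEM,Description="Tandem duplication">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End of duplicated interval">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Net inserted length">')
    header.add_line('##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Full inserted sequence">')
    header.add_line('##INFO=<ID=NTINS,Number=1,Type=String,Description="Non-templated junction insert">')
    header.add_line('##INFO=<ID=DELS,Number=1,Type=String,Description="Internal deletions start-end;...">')
    header.add_line('##INFO=<ID=EVIDENCE,Number=1,Type=String,Description="Evidence class">')
    header.add_line('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Junction-supporting reads">')
    header.add_line('##FORMAT=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">')
    header.add_line('##FORMAT=<ID=VAFBP,Number=1,Type=Float,Description="Junction-read VAF">')
    header.add_line('##FORMAT=<ID=VAFCOV,Number=1,Type=Float,Description="Coverage-excess VAF">')
    header.contigs.add(gm.locus_name, gm.sequence_length)
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in calls:
            td = call.reconstructed
            if td is None:
                continue
            rec = vcf.new_record(
                contig=gm.locus_name,
                start=td.dup_start,
                stop=td.dup_end,
                alleles=(gm.sequence[td.dup_start], "<DUP:TANDEM>"),
            )
            insseq = td.insert + "".join(
                gm.sequence[s:e] for s, e in td.kept_copy_intervals()
            )
            rec.info["SVLEN"] = td.total_inserted_length
            rec.info["INSSEQ"] = insseq or "."
            rec.info["NTINS"] = td.insert or "."
            rec.info["DELS"] = ";".join(f"{s}-{e}" for s, e in td.deletions) or "."
            rec.info["EVIDENCE"] = call.evidence
            rec.info["SUPPORT"] = call.support_junction_reads
            rec.samples[sample]["VAF"] = None if call.vaf is None else round(call.vaf, 4)
            rec.samples[sample]["VAFBP"] = (
                None if call.vaf_breakpoint is None else round(call.vaf_breakpoint, 4)
            )
            rec.samples[sample]["VAFCOV"] = (
                None if call.vaf_coverage is None else round(call.vaf_coverage, 4)
            )
            vcf.write(rec)


def calls_to_json(calls: list[TDCall]) -> list[dict]:
    out = []
    for call in calls:
        d = dataclasses.asdict(call)
        td = call.reconstructed
        d["reconstructed"] = None if td is None else {
            "dup_start": td.dup_start,
            "dup_end": td.dup_end,
            "insert": td.insert,
            "deletions": list(map(list, td.deletions)),
            "total_inserted_length": td.total_inserted_length,
        }
        out.append(d)
    return out


def write_call_report(calls: list[TDCall], path: str | Path) -> None:
    Path(path).write_text(json.dumps(calls_to_json(calls), indent=2))
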