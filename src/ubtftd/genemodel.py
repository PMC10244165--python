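"""Gene model, coordinate arithmetic and translation.

Genomic intervals are 0-based half-open throughout the package; coding (CDS)
positions are 1-based c. numbers (HGVS convention).  Conversions happen only
through :class:`GeneModel`, which owns the exon structure of the modeled locus.

The packaged fixture locus (:func:`fixture_gene_model`) is a synthetic,
seeded, forward-strand stand-in for the UBTF exon 12-14 region: exon 13
carries a 21-nt core encoding the leucine-rich ELLTRLA motif at codons
436-442 (c.1306-c.1326), the Trp445/Asn446/Asp447 codons that internal
deletions preferentially remove, and a downstream 42-nt segment encoding
GLCLRFNQLDLDQA (codons 448-461).  The exon 12 -> exon 14 screening amplicon
is exactly 617 bp, matching the wild-type fragment-analysis peak.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .errors import CoordinateError, FrameError

__all__ = [
    "GeneModel",
    "CodingCoordinate",
    "codon_of",
    "position_in_codon",
    "translate",
    "fixture_gene_model",
    "load_gene_model",
    "write_gene_model",
    "ELLTRLA_CORE_CDS",
]

#: CDS interval (1-based, inclusive) of the minimal duplicated core encoding
#: ELLTRLA (codons 436-442).
ELLTRLA_CORE_CDS = (1306, 1326)


def codon_of(cds_position: int) -> int:
    """Return the 1-based codon index containing a 1-based CDS position."""
    if cds_position < 1:
        raise CoordinateError(f"CDS position must be >= 1, got {cds_position}")
    return (cds_position - 1) // 3 + 1


def position_in_codon(cds_position: int) -> int:
    """Return the 1..3 offset of a CDS position within its codon."""
    if cds_position < 1:
        raise CoordinateError(f"CDS position must be >= 1, got {cds_position}")
    return (cds_position - 1) % 3 + 1


@dataclasses.dataclass(frozen=True)
class CodingCoordinate:
    """A 1-based coding position with its codon decomposition."""

    cds_position: int
    codon_index: int
    position_in_codon: int

    @classmethod
    def from_cds(cls, cds_position: int) -> "CodingCoordinate":
        return cls(cds_position, codon_of(cds_position), position_in_codon(cds_position))


def translate(cds_subsequence: str) -> str:
    """Translate an in-frame nucleotide string with the standard code.

    Stop codons are rendered as ``*`` (a peptide containing ``*`` before its
    last residue is truncated).  Raises :class:`FrameError` if the length is
    not a multiple of 3 and :class:`CoordinateError` on non-ACGT characters.
    """
    seq = cds_subsequence.upper()
    if len(seq) % 3 != 0:
        raise FrameError(f"length {len(seq)} is not a multiple of 3")
    if set(seq) - set("ACGT"):
        raise CoordinateError(f"non-ACGT characters in {seq!r}")
    return str(Seq(seq).translate())


@dataclasses.dataclass
class GeneModel:
    """Exon structure and coordinate system of a single-gene locus.

    Parameters
    ----------
    locus_name : str
        Name used as the SAM/VCF reference name.
    sequence : str
        Forward-strand genomic sequence of the locus.
    exons : list of (start, end)
        Sorted, disjoint 0-based half-open genomic intervals.  Every exonic
        base is treated as coding (the locus models an internal slice of the
        CDS, not the UTRs).
    cds_start : int
        1-based c. position assigned to the first exonic base of the locus.
    forward_primer_pos, reverse_primer_pos : int
        Genomic positions of the screening-amplicon ends; the wild-type
        amplicon length is their difference.
    """

    locus_name: str
    sequence: str
    exons: list[tuple[int, int]]
    cds_start: int
    forward_primer_pos: int
    reverse_primer_pos: int
    exon_names: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exon_names:
            self.exon_names = [f"exon{i + 1}" for i in range(len(self.exons))]
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end <= len(self.sequence)):
                raise CoordinateError(f"exon [{start},{end}) outside locus")
            if start <= prev_end:
                raise CoordinateError("exons must be sorted and disjoint")
            prev_end = end
        if self.cds_start < 1:
            raise CoordinateError("cds_start must be a 1-based c. position")
        # cumulative exonic length before each exon, for O(1)-ish mapping
        self._cum = np.cumsum([0] + [e - s for s, e in self.exons])
        mask = np.zeros(len(self.sequence), dtype=np.int32)
        for s, e in self.exons:
            mask[s:e] = 1
        self._exonic_prefix = np.concatenate([[0], np.cumsum(mask)])

    # -- basic properties -------------------------------------------------
    @property
    def sequence_length(self) -> int:
        return len(self.sequence)

    @property
    def coding_length(self) -> int:
        return int(self._cum[-1])

    @property
    def cds_end(self) -> int:
        """Last modeled c. position (inclusive)."""
        return self.cds_start + self.coding_length - 1

    def amplicon_length(self) -> int:
        return self.reverse_primer_pos - self.forward_primer_pos

    # -- coordinate conversion --------------------------------------------
    def is_exonic(self, genomic_pos: int) -> bool:
        return any(s <= genomic_pos < e for s, e in self.exons)

    def exonic_count(self, start: int, end: int) -> int:
        """Number of exonic bases in the genomic interval [start, end)."""
        start = max(start, 0)
        end = min(end, self.sequence_length)
        if end <= start:
            return 0
        return int(self._exonic_prefix[end] - self._exonic_prefix[start])

    def exon_index_of(self, genomic_pos: int) -> int | None:
        for i, (s, e) in enumerate(self.exons):
            if s <= genomic_pos < e:
                return i
        return None

    def genomic_to_cds(self, genomic_pos: int) -> int | None:
        """Map a genomic position to its 1-based c. position.

        Returns ``None`` for intronic/flanking positions ("non-coding").
        """
        if not (0 <= genomic_pos < self.sequence_length):
            raise CoordinateError(f"position {genomic_pos} outside locus")
        for i, (s, e) in enumerate(self.exons):
            if s <= genomic_pos < e:
                return self.cds_start + int(self._cum[i]) + (genomic_pos - s)
        return None

    def cds_to_genomic(self, cds_position: int) -> int:
        offset = cds_position - self.cds_start
        if not (0 <= offset < self.coding_length):
            raise CoordinateError(f"c.{cds_position} not in modeled CDS")
        for i, (s, e) in enumerate(self.exons):
            if offset < self._cum[i + 1]:
                return s + (offset - int(self._cum[i]))
        raise AssertionError("unreachable")

    # -- sequence access ---------------------------------------------------
    def spliced_cds(self) -> str:
        """Concatenated exonic sequence (the modeled CDS slice)."""
        return "".join(self.sequence[s:e] for s, e in self.exons)

    def cds_sequence(self, cds_from: int, cds_to: int) -> str:
        """Spliced sequence for the inclusive c. interval [cds_from, cds_to]."""
        if cds_to < cds_from:
            raise CoordinateError("empty CDS interval")
        spliced = self.spliced_cds()
        a = cds_from - self.cds_start
        b = cds_to - self.cds_start + 1
        if a < 0 or b > len(spliced):
            raise CoordinateError(f"c.{cds_from}-{cds_to} not in modeled CDS")
        return spliced[a:b]

    def splice_site_positions(self) -> set[int]:
        """Genomic positions of donor/acceptor dinucleotides flanking exons."""
        sites: set[int] = set()
        for i, (s, e) in enumerate(self.exons):
            if i > 0:  # acceptor AG just before exon start
                sites.update((s - 2, s - 1))
            if i < len(self.exons) - 1:  # donor GT just after exon end
                sites.update((e, e + 1))
        return sites

    def wild_type_amplicon(self) -> str:
        return self.sequence[self.forward_primer_pos : self.reverse_primer_pos]


# ---------------------------------------------------------------------------
# Fixture construction
# ---------------------------------------------------------------------------

_FIXED_CODONS = {
    # codon index -> codon; ELLTRLA core at 436-442 (c.1306-1326)
    436: "GAA", 437: "CTG", 438: "CTG", 439: "ACC", 440: "CGT", 441: "CTT",
    442: "GCT",
    # deletion-prone residues Trp445 Asn446 Asp447 (c.1333-1341)
    445: "TGG", 446: "AAT", 447: "GAT",
    # GLCLRFNQLDLDQA at 448-461 (c.1342-1383), the one non-core motif class
    448: "GGT", 449: "CTG", 450: "TGT", 451: "CTC", 452: "CGC", 453: "TTT",
    454: "AAC", 455: "CAA", 456: "CTT", 457: "GAT", 458: "CTA", 459: "GAC",
    460: "CAG", 461: "GCC",
}

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in _STOPS]

# fixture geometry (0-based half-open genomic coordinates)
_FLANK5 = 400
_EXON12 = (400, 520)     # c.1141-1260
_INTRON12_LEN = 152
_EXON13 = (672, 861)     # c.1261-1449
_INTRON13_LEN = 140
_EXON14 = (1001, 1121)   # c.1450-1569
_FLANK3 = 400
_FWD_PRIMER = 450
_REV_PRIMER = 1067       # amplicon 1067 - 450 = 617 bp


def fixture_gene_model(seed: int = 20130217) -> GeneModel:
    """Build the deterministic synthetic UBTF-like exon 12-14 locus.

    The sequence is random under a fixed seed except for the biologically
    anchored codons (ELLTRLA core, W445/N446/D447, GLCLRFNQLDLDQA) and the
    canonical GT..AG splice dinucleotides.
    """
    rng = np.random.default_rng(seed)
    first_codon = codon_of(1141)  # == 381; c.1141 starts a codon
    n_codons = (1569 - 1141 + 1) // 3
    codons = []
    for k in range(n_codons):
        idx = first_codon + k
        codons.append(_FIXED_CODONS.get(idx, _CODONS[rng.integers(len(_CODONS))]))
    cds = "".join(codons)
    assert len(cds) == 429

    def random_seq(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

    intron12 = "GT" + random_seq(_INTRON12_LEN - 4) + "AG"
    intron13 = "GT" + random_seq(_INTRON13_LEN - 4) + "AG"
    seq = (
        random_seq(_FLANK5)
        + cds[0:120]          # exon 12
        + intron12
        + cds[120:309]        # exon 13
        + intron13
        + cds[309:429]        # exon 14
        + random_seq(_FLANK3)
    )
    gm = GeneModel(
        locus_name="UBTF_synthetic_locus",
        sequence=seq,
        exons=[_EXON12, _EXON13, _EXON14],
        cds_start=1141,
        forward_primer_pos=_FWD_PRIMER,
        reverse_primer_pos=_REV_PRIMER,
        exon_names=["exon12", "exon13", "exon14"],
    )
    return gm


# ---------------------------------------------------------------------------
# Loaders (real-data entry point): FASTA + 4-column exon TSV
# ---------------------------------------------------------------------------

def load_gene_model(
    fasta_path: str | Path,
    exon_table_path: str | Path,
    cds_start: int = 1,
    forward_primer_pos: int | None = None,
    reverse_primer_pos: int | None = None,
) -> GeneModel:
    """Load a gene model from a FASTA locus and an exon TSV.

    The exon table has four tab-separated columns: name, start, end (0-based
    half-open) and frame anchor.  The frame anchor of the FIRST exon row is
    interpreted as the 1-based c. position of that exon's first base and
    overrides ``cds_start`` when positive.
    """
    from Bio import SeqIO

    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    exons: list[tuple[int, int]] = []
    names: list[str] = []
    anchor = cds_start
    with open(exon_table_path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, start, end, frame = line.split("\t")[:4]
            names.append(name)
            exons.append((int(start), int(end)))
            if i == 0 and int(frame) > 0:
                anchor = int(frame)
    seq = str(record.seq).upper()
    n = len(seq)
    return GeneModel(
        locus_name=record.id,
        sequence=seq,
        exons=exons,
        cds_start=anchor,
        forward_primer_pos=0 if forward_primer_pos is None else forward_primer_pos,
        reverse_primer_pos=n if reverse_primer_pos is None else reverse_primer_pos,
        exon_names=names,
    )


def write_gene_model(gm: GeneModel, fasta_path: str | Path, exon_table_path: str | Path) -> None:
    """Write a gene model as FASTA + exon TSV (inverse of :func:`load_gene_model`)."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{gm.locus_name}\n")
        for i in range(0, len(gm.sequence), 70):
            fh.write(gm.sequence[i : i + 70] + "\n")
    with open(exon_table_path, "w") as fh:
        for i, ((s, e), name) in enumerate(zip(gm.exons, gm.exon_names)):
            frame = gm.cds_start if i == 0 else 0
            fh.write(f"{name}\t{s}\t{e}\t{frame}\n")
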