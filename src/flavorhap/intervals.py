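"""Genomic intervals and gene models.

All internal coordinates are 0-based half-open. External formats (VCF, GFF3,
locus strings such as ``SL4.0ch09:3508156-3512282``) are 1-based inclusive and
are converted at the I/O boundary, never inside the analysis code.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @classmethod
    def from_1based(cls, chrom: str, start1: int, end1: int, strand: str = "+") -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (GFF/VCF convention)."""
        return cls(chrom, start1 - 1, end1, strand)

    def to_1based(self) -> tuple[int, int]:
        return self.start + 1, self.end

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


# intron positions this close to an exon boundary are splice-relevant
SPLICE_WINDOW_BP = 2


@dataclass
class GeneModel:
    """Strand-aware exon/CDS structure for one gene plus flank conventions.

    The default flanks (3 kb upstream of the transcription start, 1 kb
    downstream of the termination site) define the haplotype-analysis region.
    """

    gene_id: str
    locus: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    upstream_flank_bp: int = 3000
    downstream_flank_bp: int = 1000

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.gene_id}: overlapping exons {a} and {b}")
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValueError(f"{self.gene_id}: CDS {c} not contained in any exon")
        if self.cds and self.cds_length == 0:
            raise ValueError(f"{self.gene_id}: zero-length CDS")

    # ------------------------------------------------------------------ geometry

    @property
    def strand(self) -> str:
        return self.locus.strand

    @property
    def chrom(self) -> str:
        return self.locus.chrom

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    @property
    def flanked_region(self) -> GenomicInterval:
        """Locus plus strand-aware upstream/downstream flanks."""
        if self.strand == "+":
            start = self.locus.start - self.upstream_flank_bp
            end = self.locus.end + self.downstream_flank_bp
        else:
            start = self.locus.start - self.downstream_flank_bp
            end = self.locus.end + self.upstream_flank_bp
        return GenomicInterval(self.chrom, max(0, start), end, self.strand)

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def splice_positions(self) -> set[int]:
        """Intronic positions within SPLICE_WINDOW_BP of an exon junction."""
        pos: set[int] = set()
        for intron in self.introns:
            w = min(SPLICE_WINDOW_BP, len(intron))
            pos.update(range(intron.start, intron.start + w))
            pos.update(range(intron.end - w, intron.end))
        return pos

    def in_cds(self, pos: int) -> bool:
        return any(c.contains(pos) for c in self.cds)

    def in_exon(self, pos: int) -> bool:
        return any(e.contains(pos) for e in self.exons)

    # --------------------------------------------------------------- CDS mapping

    def cds_genomic_positions(self) -> list[int]:
        """Genomic positions of CDS bases in plus-strand order."""
        out: list[int] = []
        for c in self.cds:
            out.extend(range(c.start, c.end))
        return out

    def genomic_to_cds_offset(self, pos: int) -> int | None:
        """Offset of a genomic position within the coding sequence (coding-strand
        orientation: 0 is the A of the initiator ATG). None if not in CDS."""
        off = 0
        plus_off = None
        for c in self.cds:
            if c.contains(pos):
                plus_off = off + (pos - c.start)
                break
            off += len(c)
        if plus_off is None:
            return None
        if self.strand == "+":
            return plus_off
        return self.cds_length - 1 - plus_off

    def cds_sequence(self, chrom_seq: str) -> str:
        """Coding-strand CDS sequence extracted from the chromosome sequence."""
        seq = "".join(chrom_seq[c.start : c.end] for c in self.cds)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
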