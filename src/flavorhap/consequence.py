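"""Functional consequence annotation of variants against a gene model.

Region classes are assigned by containment (strand-aware flanks, exon minus
CDS as UTR, introns, a 2-bp splice window at each exon-intron junction); CDS
SNPs are translated with the standard genetic code on the coding strand; CDS
indels are frameshift unless their net length change is a multiple of three.
When a variant touches several features the most severe class wins.

For nucleotide-diversity partitioning, SNP classes fold into
non_synonymous / synonymous / non_coding; for haplotype heatmaps the display
class folds splice-site variants into the frameshift class.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .intervals import GeneModel, GenomicInterval, reverse_complement
from .variants import VariantRecord

#: most severe first
SEVERITY_ORDER = (
    "start_lost",
    "stop_gained",
    "frameshift",
    "splice_site",
    "inframe_indel",
    "missense",
    "synonymous",
    "utr5",
    "utr3",
    "intronic",
    "upstream",
    "downstream",
)

_SEVERITY_RANK = {cls: i for i, cls in enumerate(SEVERITY_ORDER)}

#: heatmap display convention: splicing-site variants count as frameshift
DISPLAY_FOLD = {"splice_site": "frameshift"}

_AA_CHANGE_CLASSES = {"missense", "synonymous", "start_lost", "stop_gained"}


@dataclass(frozen=True)
class Consequence:
    variant_id: str
    cls: str
    aa_change: tuple[str, int, str] | None = None

    def __post_init__(self) -> None:
        if self.cls not in _SEVERITY_RANK:
            raise ValueError(f"unknown consequence class {self.cls!r}")
        if (self.aa_change is not None) != (self.cls in _AA_CHANGE_CLASSES):
            raise ValueError(
                f"{self.variant_id}: aa_change must be present iff cls is one of "
                f"{sorted(_AA_CHANGE_CLASSES)} (got cls={self.cls})"
            )

    @property
    def display_cls(self) -> str:
        return DISPLAY_FOLD.get(self.cls, self.cls)


def _classify_cds_snp(rec: VariantRecord, gene: GeneModel, chrom_seq: str) -> Consequence:
    cds_seq = gene.cds_sequence(chrom_seq)
    if len(cds_seq) % 3 != 0:
        raise ValueError(f"{gene.gene_id}: CDS length {len(cds_seq)} not divisible by 3")
    off = gene.genomic_to_cds_offset(rec.start)
    assert off is not None
    alt_base = rec.alt if gene.strand == "+" else reverse_complement(rec.alt)
    if cds_seq[off] != (rec.ref if gene.strand == "+" else reverse_complement(rec.ref)):
        raise ValueError(
            f"{rec.variant_id}: REF does not match reference CDS base {cds_seq[off]!r}"
        )
    codon_idx = off // 3
    within = off % 3
    ref_codon = cds_seq[3 * codon_idx : 3 * codon_idx + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    aa_pos = codon_idx + 1
    change = (ref_aa, aa_pos, alt_aa)
    if codon_idx == 0 and ref_aa == "M" and alt_aa != "M":
        return Consequence(rec.variant_id, "start_lost", change)
    if alt_aa == "*" and ref_aa != "*":
        return Consequence(rec.variant_id, "stop_gained", change)
    if ref_aa == alt_aa:
        return Consequence(rec.variant_id, "synonymous", change)
    # includes loss of the stop codon: protein-changing either way
    return Consequence(rec.variant_id, "missense", change)


def _region_classes(rec: VariantRecord, gene: GeneModel) -> set[str]:
    """All non-CDS region classes the variant's footprint touches."""
    classes: set[str] = set()
    # an insertion's footprint is the single anchor base
    span = GenomicInterval(rec.chrom, rec.start, max(rec.end, rec.start + 1))
    positions = range(span.start, span.end)
    splice = gene.splice_positions()
    cds_span = (
        (gene.cds[0].start, gene.cds[-1].end) if gene.cds else (gene.locus.start, gene.locus.end)
    )
    for pos in positions:
        if pos in splice:
            classes.add("splice_site")
        if gene.locus.contains(pos):
            if gene.in_cds(pos):
                continue  # handled by the CDS branch
            if gene.in_exon(pos):
                if pos < cds_span[0]:
                    classes.add("utr5" if gene.strand == "+" else "utr3")
                elif pos >= cds_span[1]:
                    classes.add("utr3" if gene.strand == "+" else "utr5")
            elif pos not in splice:
                classes.add("intronic")
        elif pos < gene.locus.start:
            classes.add("upstream" if gene.strand == "+" else "downstream")
        else:
            classes.add("downstream" if gene.strand == "+" else "upstream")
    return classes


def classify(rec: VariantRecord, gene: GeneModel, reference) -> Consequence:
    """Consequence of one variant; ``reference`` maps chrom -> sequence."""
    region = gene.flanked_region
    span = GenomicInterval(rec.chrom, rec.start, max(rec.end, rec.start + 1))
    if not region.overlaps(span):
        raise ValueError(f"{rec.variant_id} outside {gene.gene_id} locus +/- flanks")
    chrom_seq = reference[gene.chrom]

    candidates: list[Consequence] = []
    overlaps_cds = any(span.overlaps(c) for c in gene.cds)
    if overlaps_cds:
        if rec.is_snp:
            candidates.append(_classify_cds_snp(rec, gene, chrom_seq))
        else:
            net = len(rec.alt) - len(rec.ref)
            cls = "inframe_indel" if net % 3 == 0 else "frameshift"
            candidates.append(Consequence(rec.variant_id, cls))
    for cls in _region_classes(rec, gene):
        candidates.append(Consequence(rec.variant_id, cls))
    if not candidates:
        # footprint strictly inside CDS already covered; fall back defensively
        raise ValueError(f"{rec.variant_id}: no feature overlap in {gene.gene_id}")
    return min(candidates, key=lambda c: _SEVERITY_RANK[c.cls])


_NON_SYN = {"missense", "start_lost", "stop_gained", "splice_site"}
_NON_CODING = {"utr5", "utr3", "intronic", "upstream", "downstream"}


def diversity_class(cons: Consequence) -> str:
    """Fold a SNP consequence into the three diversity partitions."""
    if cons.cls in ("frameshift", "inframe_indel"):
        raise ValueError(f"{cons.variant_id}: diversity classes are defined for SNPs only")
    if cons.cls in _NON_SYN:
        return "non_synonymous"
    if cons.cls == "synonymous":
        return "synonymous"
    if cons.cls in _NON_CODING:
        return "non_coding"
    raise ValueError(f"unhandled class {cons.cls}")


def annotate_all(records, gene: GeneModel, reference) -> dict[str, Consequence]:
    """Annotate every record overlapping the flanked region; keyed by variant id."""
    out: dict[str, Consequence] = {}
    region = gene.flanked_region
    for rec in records:
        span_end = max(rec.end, rec.start + 1)
        if rec.chrom != gene.chrom or span_end <= region.start or rec.start >= region.end:
            continue
        out[rec.variant_id] = classify(rec, gene, reference)
    return out


def consequences_to_frame(cons: dict[str, Consequence]):
    """Tabular (TSV-ready) view of an annotation set."""
    import pandas as pd

    rows = []
    for vid, c in cons.items():
        aa = "" if c.aa_change is None else f"{c.aa_change[0]}{c.aa_change[1]}{c.aa_change[2]}"
        rows.append({"variant_id": vid, "cls": c.cls, "display_cls": c.display_cls, "aa_change": aa})
    return pd.DataFrame(rows, columns=["variant_id", "cls", "display_cls", "aa_change"])
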