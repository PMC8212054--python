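"""Readers and writers for the external formats the pipeline touches.

VCF reading goes through pysam (htslib); multiallelic rows are split into
biallelic records and indels are left-aligned against the reference when one
is supplied. VCF writing is a deliberately small text writer so that outputs
are byte-reproducible; the round-trip test reads its output back through
htslib, which keeps the writer honest.

Gene models are accepted as GFF3 (via gffutils, in-memory db) or as a simple
5-column TSV. Phenotype, accession and duplication-evidence tables are plain
TSV with a header row, read into pandas.
"""

from __future__ import annotations

import io
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GeneModel, GenomicInterval
from .variants import HET, HOM_ALT, HOM_REF, KNOWN_INFO_KEYS, MISSING, VariantRecord

log = logging.getLogger("flavorhap")

# ----------------------------------------------------------------------- alleles


def trim_and_left_align(
    start: int, ref: str, alt: str, chrom_seq: str | None = None
) -> tuple[int, str, str]:
    """Normalize an allele pair: strip shared suffix/prefix, then shift indels
    left while the flanking reference base allows it (bcftools norm semantics).

    ``chrom_seq`` is the full sequence of the variant's chromosome; without it
    only trimming is performed.
    """
    ref, alt = ref.upper(), alt.upper()
    # shared suffix (always keep at least one base of each allele)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        start += 1
    if chrom_seq is not None and len(ref) != len(alt):
        # left-shift: representable iff the trailing base matches the base
        # entering from the left
        while start > 0 and ref[-1] == alt[-1]:
            prev = chrom_seq[start - 1].upper()
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            start -= 1
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
    return start, ref, alt


def _gt_code(alleles: tuple, alt_index: int) -> int:
    """Map a raw genotype tuple to a code for the biallelic row of ``alt_index``.

    Alleles pointing at a *different* alt are not representable in this row and
    make the genotype missing.
    """
    if alleles is None or any(a is None for a in alleles):
        return MISSING
    if len(alleles) != 2:
        raise ValueError(f"non-diploid genotype {alleles}")
    coded = []
    for a in alleles:
        if a == 0:
            coded.append(0)
        elif a == alt_index:
            coded.append(1)
        else:
            return MISSING
    s = sum(coded)
    return (HOM_REF, HET, HOM_ALT)[s]


def read_vcf(
    path: str | Path,
    accession_filter: Sequence[str] | None = None,
    reference: Mapping[str, str] | None = None,
) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF 4.x file into VariantRecords plus the accession ordering.

    Multiallelic rows are split into biallelic records; alleles are trimmed and
    (given ``reference``) left-aligned. Phased separators are treated as
    unphased; coordinates become 0-based half-open.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if accession_filter is not None:
        unknown = [a for a in accession_filter if a not in samples]
        if unknown:
            raise ValueError(f"unknown accessions in filter: {', '.join(sorted(unknown))}")
        keep_idx = [samples.index(a) for a in accession_filter]
        samples_out = list(accession_filter)
    else:
        keep_idx = list(range(len(samples)))
        samples_out = samples

    records: list[VariantRecord] = []
    for line_no, rec in enumerate(vf, start=1):
        alts = rec.alts or ()
        try:
            raw_gts = [rec.samples[samples[i]].get("GT") for i in keep_idx]
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed genotype field at record {line_no}") from exc
        for alt_index, alt in enumerate(alts, start=1):
            try:
                codes = np.array(
                    [_gt_code(gt, alt_index) for gt in raw_gts], dtype=np.int8
                )
            except ValueError as exc:
                raise ValueError(f"record {line_no} ({rec.chrom}:{rec.pos}): {exc}") from exc
            info = {}
            for key in KNOWN_INFO_KEYS:
                if key in rec.info:
                    val = rec.info[key]
                    if isinstance(val, tuple):
                        val = val[0]
                    info[key] = val
            start = rec.start
            ref = rec.ref
            if alt.startswith("<"):  # symbolic SV allele, no sequence to normalize
                norm_start, norm_ref, norm_alt = start, ref, alt
            else:
                chrom_seq = reference.get(rec.chrom) if reference else None
                norm_start, norm_ref, norm_alt = trim_and_left_align(
                    start, ref, alt, chrom_seq
                )
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    start=norm_start,
                    ref=norm_ref,
                    alt=norm_alt,
                    qual=float(rec.qual) if rec.qual is not None else float("nan"),
                    info=info,
                    genotypes=codes,
                )
            )
    vf.close()
    records.sort(key=lambda r: (r.chrom, r.start, r.ref, r.alt))
    return records, samples_out


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}

_INFO_INT_KEYS = {"PE", "SR", "SU", "SVLEN"}


def _fmt_info_value(key: str, val) -> str:
    if key == "SVTYPE":
        return str(val)
    if key in _INFO_INT_KEYS:
        return str(int(val))
    return f"{float(val):.6g}"


def write_vcf(
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write biallelic records as VCF 4.2 text (deterministic byte layout)."""
    lines = ["##fileformat=VCFv4.2", "##source=flavorhap"]
    if contig_lengths:
        for chrom, length in contig_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
    meta = {
        "MQ": ("1", "Float", "RMS mapping quality"),
        "QD": ("1", "Float", "Quality by depth"),
        "FS": ("1", "Float", "FisherStrand phred-scaled p-value"),
        "MQRankSum": ("1", "Float", "Mapping quality rank sum"),
        "ReadPosRankSum": ("1", "Float", "Read position rank sum"),
        "PE": ("1", "Integer", "Paired-end supporting reads"),
        "SR": ("1", "Integer", "Split-read supporting reads"),
        "SU": ("1", "Integer", "Total supporting reads"),
        "SVTYPE": ("1", "String", "Structural variant type"),
        "SVLEN": ("1", "Integer", "Structural variant length"),
    }
    for key, (num, typ, desc) in meta.items():
        lines.append(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for rec in records:
        if rec.n_accessions != len(samples):
            raise ValueError(
                f"{rec.variant_id}: {rec.n_accessions} genotypes for {len(samples)} samples"
            )
        info_items = [
            f"{k}={_fmt_info_value(k, rec.info[k])}" for k in KNOWN_INFO_KEYS if k in rec.info
        ]
        info_str = ";".join(info_items) if info_items else "."
        qual_str = "." if np.isnan(rec.qual) else f"{rec.qual:.6g}"
        gts = "\t".join(_GT_STR[int(g)] for g in rec.genotypes)
        lines.append(
            f"{rec.chrom}\t{rec.pos1}\t.\t{rec.ref}\t{rec.alt}\t{qual_str}\tPASS\t"
            f"{info_str}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def write_region_fasta(
    reference: Mapping[str, str],
    gene: GeneModel,
    per_accession_substitutions: Mapping[str, Sequence[tuple[int, str, str]]],
    path: str | Path | None = None,
) -> dict[str, str]:
    """Per-accession sequences of the gene's flanked region with alternate
    alleles substituted into the reference.

    Substitutions are (start, ref, alt) in chromosome coordinates, must be
    sorted and non-overlapping. Returns {accession: sequence}; writes FASTA when
    ``path`` is given (headers carry accession and gene id).
    """
    region = gene.flanked_region
    chrom_seq = reference[gene.chrom]
    base = chrom_seq[region.start : region.end]
    out: dict[str, str] = {}
    for acc, subs in per_accession_substitutions.items():
        prev_end = -1
        prev_label = None
        parts: list[str] = []
        cursor = 0
        for start, ref, alt in subs:
            label = f"{gene.chrom}:{start + 1}:{ref}>{alt}"
            if start < prev_end:
                raise ValueError(f"overlapping substitutions {prev_label} and {label}")
            off = start - region.start
            if off < 0 or start + len(ref) > region.end:
                raise ValueError(f"substitution {label} outside region {region}")
            if base[off : off + len(ref)] != ref.upper():
                raise ValueError(
                    f"substitution {label} does not match reference "
                    f"{base[off:off + len(ref)]!r}"
                )
            parts.append(base[cursor:off])
            parts.append(alt.upper())
            cursor = off + len(ref)
            prev_end = start + len(ref)
            prev_label = label
        parts.append(base[cursor:])
        out[acc] = "".join(parts)
    if path is not None:
        write_fasta({f"{acc} {gene.gene_id}": s for acc, s in out.items()}, path)
    return out


# -------------------------------------------------------------------- gene model


def read_gene_model_tsv(path: str | Path) -> GeneModel:
    """Gene model from a TSV with columns gene_id, chrom, strand, feature,
    start, end (1-based inclusive); features gene/exon/CDS."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "feature", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene model TSV missing columns: {sorted(missing)}")
    gene_rows = df[df["feature"].str.lower() == "gene"]
    if len(gene_rows) != 1:
        raise ValueError("gene model TSV must contain exactly one 'gene' row")
    g = gene_rows.iloc[0]
    strand = str(g["strand"])
    locus = GenomicInterval.from_1based(str(g["chrom"]), int(g["start"]), int(g["end"]), strand)

    def ivals(feature: str) -> list[GenomicInterval]:
        sub = df[df["feature"].str.lower() == feature.lower()]
        return [
            GenomicInterval.from_1based(str(r["chrom"]), int(r["start"]), int(r["end"]), strand)
            for _, r in sub.iterrows()
        ]

    return GeneModel(str(g["gene_id"]), locus, exons=ivals("exon"), cds=ivals("CDS"))


def read_gene_model_gff3(path: str | Path, gene_id: str | None = None) -> GeneModel:
    """Gene model from GFF3; only gene/exon/CDS features are read."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = list(db.features_of_type("gene"))
    if gene_id is not None:
        genes = [g for g in genes if g.id == gene_id]
    if len(genes) != 1:
        raise ValueError(f"expected exactly one gene, found {len(genes)}")
    g = genes[0]
    locus = GenomicInterval.from_1based(g.seqid, g.start, g.end, g.strand)
    exons = [
        GenomicInterval.from_1based(f.seqid, f.start, f.end, g.strand)
        for f in db.children(g, featuretype="exon")
    ]
    cds = [
        GenomicInterval.from_1based(f.seqid, f.start, f.end, g.strand)
        for f in db.children(g, featuretype="CDS")
    ]
    return GeneModel(g.id, locus, exons=exons, cds=cds)


def read_gene_model(path: str | Path, gene_id: str | None = None) -> GeneModel:
    p = Path(path)
    if p.suffix.lower() in (".gff", ".gff3"):
        return read_gene_model_gff3(p, gene_id)
    return read_gene_model_tsv(p)


def write_gene_model_gff3(gene: GeneModel, path: str | Path) -> None:
    start1, end1 = gene.locus.to_1based()
    rows = [
        "##gff-version 3",
        "\t".join(
            [gene.chrom, "flavorhap", "gene", str(start1), str(end1), ".",
             gene.strand, ".", f"ID={gene.gene_id}"]
        ),
    ]
    for i, e in enumerate(gene.exons, 1):
        s, t = e.to_1based()
        rows.append(
            "\t".join(
                [gene.chrom, "flavorhap", "exon", str(s), str(t), ".", gene.strand,
                 ".", f"ID={gene.gene_id}.exon{i};Parent={gene.gene_id}"]
            )
        )
    for i, c in enumerate(gene.cds, 1):
        s, t = c.to_1based()
        rows.append(
            "\t".join(
                [gene.chrom, "flavorhap", "CDS", str(s), str(t), ".", gene.strand,
                 ".", f"ID={gene.gene_id}.cds{i};Parent={gene.gene_id}"]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")


# ------------------------------------------------------------------------ tables


def read_accession_table(path: str | Path) -> pd.DataFrame:
    """Accession metadata: columns accession_id, subpopulation."""
    df = pd.read_csv(path, sep="\t", dtype={"accession_id": str})
    if df["accession_id"].duplicated().any():
        dup = df.loc[df["accession_id"].duplicated(), "accession_id"].tolist()
        raise ValueError(f"duplicate accession ids: {dup}")
    return df


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Phenotypes: accession_id index, one column per metabolite."""
    df = pd.read_csv(path, sep="\t", dtype={"accession_id": str})
    return df.set_index("accession_id")


def read_evidence_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"accession_id": str})
    df["deletion_present"] = df["deletion_present"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Deterministic TSV output shared by all stages."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
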