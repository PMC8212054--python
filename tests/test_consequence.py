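"""Consequence annotation against an independent translate-and-diff oracle,
including the exhaustive scan over every single-base substitution of the toy
gene and the strand-mirror property."""

import numpy as np
import pytest
from Bio.Seq import Seq

from flavorhap.consequence import Consequence, classify, diversity_class
from flavorhap.intervals import GeneModel, GenomicInterval, reverse_complement

from conftest import make_record, make_toy_gene, make_toy_reference

BASES = "ACGT"


# --------------------------------------------------------------------- oracle


def oracle_snp_class(pos: int, alt: str, gene: GeneModel, chrom_seq: str) -> str:
    """Independent classification: full-transcript extraction, whole-protein
    translate-and-diff for CDS positions, explicit interval logic elsewhere.
    Written for plus-strand genes only (the toy gene)."""
    assert gene.strand == "+"

    def extract_cds(seq: str) -> str:
        return "".join(seq[c.start : c.end] for c in gene.cds)

    in_cds = any(c.start <= pos < c.end for c in gene.cds)
    if in_cds:
        mutated = chrom_seq[:pos] + alt + chrom_seq[pos + 1 :]
        ref_prot = str(Seq(extract_cds(chrom_seq)).translate())
        alt_prot = str(Seq(extract_cds(mutated)).translate())
        off = 0
        for c in gene.cds:
            if c.start <= pos < c.end:
                off += pos - c.start
                break
            off += len(c)
        ci = off // 3
        if ci == 0 and not extract_cds(mutated).startswith("ATG"):
            return "start_lost"
        if alt_prot[ci] == "*" and ref_prot[ci] != "*":
            return "stop_gained"
        if ref_prot == alt_prot:
            return "synonymous"
        return "missense"
    splice = set()
    for a, b in zip(gene.exons, gene.exons[1:]):
        splice |= {a.end, a.end + 1, b.start - 2, b.start - 1}
    if pos in splice:
        return "splice_site"
    if gene.locus.start <= pos < gene.locus.end:
        if any(e.start <= pos < e.end for e in gene.exons):
            return "utr5" if pos < gene.cds[0].start else "utr3"
        return "intronic"
    return "upstream" if pos < gene.locus.start else "downstream"


# ---------------------------------------------------------------------- tests


class TestSnpExamples:
    def test_missense_asn_to_asp(self, toy_gene, toy_reference):
        # plant an AAT codon, mutate first base A->G: AAT -> GAT is Asn -> Asp
        seq = toy_reference["toy"]
        cds_pos = toy_gene.cds_genomic_positions()
        codon_start = cds_pos[3 * 10]
        seq = seq[:codon_start] + "AAT" + seq[codon_start + 3 :]
        rec = make_record(start=codon_start, ref="A", alt="G")
        cons = classify(rec, toy_gene, {"toy": seq})
        assert cons.cls == "missense"
        assert cons.aa_change == ("N", 11, "D")

    def test_synonymous_third_position(self, toy_gene, toy_reference):
        seq = toy_reference["toy"]
        cds_pos = toy_gene.cds_genomic_positions()
        codon_start = cds_pos[3 * 20]
        seq = seq[:codon_start] + "GGT" + seq[codon_start + 3 :]
        rec = make_record(start=codon_start + 2, ref="T", alt="C")  # GGT -> GGC, both Gly
        cons = classify(rec, toy_gene, {"toy": seq})
        assert cons.cls == "synonymous"
        assert cons.aa_change[0] == cons.aa_change[2] == "G"

    def test_splice_site_displays_as_frameshift(self, toy_gene, toy_reference):
        pos = toy_gene.exons[0].end  # first intronic base
        ref = toy_reference["toy"][pos]
        alt = "A" if ref != "A" else "G"
        cons = classify(make_record(start=pos, ref=ref, alt=alt), toy_gene, toy_reference)
        assert cons.cls == "splice_site"
        assert cons.display_cls == "frameshift"

    def test_variant_outside_flanks_errors(self, toy_gene, toy_reference):
        rec = make_record(start=50, ref=toy_reference["toy"][50], alt="A")
        with pytest.raises(ValueError, match="outside"):
            classify(rec, toy_gene, toy_reference)


class TestIndels:
    @pytest.mark.parametrize(
        "length,expected",
        [(13, "frameshift"), (1, "frameshift"), (3, "inframe_indel"), (15, "inframe_indel")],
    )
    def test_cds_duplication_insertions(self, toy_gene, toy_reference, length, expected):
        seq = toy_reference["toy"]
        p = toy_gene.cds[1].start + 10
        dup = seq[p + 1 : p + 1 + length]
        rec = make_record(start=p, ref=seq[p], alt=seq[p] + dup)
        assert classify(rec, toy_gene, toy_reference).cls == expected

    @pytest.mark.parametrize(
        "length,expected",
        [(15, "inframe_indel"), (13, "frameshift"), (3, "inframe_indel"), (1, "frameshift")],
    )
    def test_cds_deletions(self, toy_gene, toy_reference, length, expected):
        seq = toy_reference["toy"]
        p = toy_gene.cds[1].start + 30
        rec = make_record(start=p, ref=seq[p : p + length + 1], alt=seq[p])
        assert classify(rec, toy_gene, toy_reference).cls == expected

    def test_intronic_indel_is_not_frameshift(self, toy_gene, toy_reference):
        intron = toy_gene.introns[1]
        p = intron.start + 40
        seq = toy_reference["toy"]
        rec = make_record(start=p, ref=seq[p : p + 5], alt=seq[p])
        assert classify(rec, toy_gene, toy_reference).cls == "intronic"


class TestExhaustiveOracle:
    def test_all_single_base_substitutions_match_oracle(self, toy_gene, toy_reference):
        """100% agreement across every position of the flanked region and
        every alternate base (the acceptance-grade exhaustive scan)."""
        seq = toy_reference["toy"]
        region = toy_gene.flanked_region
        mismatches = []
        for pos in range(region.start, region.end):
            ref = seq[pos]
            for alt in BASES:
                if alt == ref:
                    continue
                got = classify(make_record(start=pos, ref=ref, alt=alt), toy_gene, toy_reference)
                want = oracle_snp_class(pos, alt, toy_gene, seq)
                if got.cls != want:
                    mismatches.append((pos, ref, alt, got.cls, want))
        assert mismatches == []


class TestStrandMirror:
    def test_minus_strand_equals_reverse_complement_mirror(self, toy_gene, toy_reference):
        """Classifying a variant on a minus-strand gene must equal classifying
        its reverse complement on the plus-strand mirror gene."""
        L = len(toy_reference["toy"])
        plus_seq = toy_reference["toy"]
        minus_seq = reverse_complement(plus_seq)

        def mirror_iv(iv):
            return GenomicInterval(iv.chrom, L - iv.end, L - iv.start, "-")

        minus_gene = GeneModel(
            toy_gene.gene_id,
            mirror_iv(toy_gene.locus),
            exons=[mirror_iv(e) for e in toy_gene.exons],
            cds=[mirror_iv(c) for c in toy_gene.cds],
            upstream_flank_bp=toy_gene.upstream_flank_bp,
            downstream_flank_bp=toy_gene.downstream_flank_bp,
        )
        rng = np.random.default_rng(0)
        region = toy_gene.flanked_region
        for pos in rng.integers(region.start, region.end, size=300):
            pos = int(pos)
            ref = plus_seq[pos]
            alt = BASES[(BASES.index(ref) + 1) % 4]
            plus_cons = classify(make_record(start=pos, ref=ref, alt=alt), toy_gene, toy_reference)
            mpos = L - 1 - pos
            mrec = make_record(
                start=mpos, ref=reverse_complement(ref), alt=reverse_complement(alt)
            )
            minus_cons = classify(mrec, minus_gene, {"toy": minus_seq})
            assert minus_cons.cls == plus_cons.cls, (pos, plus_cons.cls, minus_cons.cls)
            assert minus_cons.aa_change == plus_cons.aa_change


class TestDiversityClass:
    @pytest.mark.parametrize(
        "cls,expected",
        [
            ("missense", "non_synonymous"),
            ("start_lost", "non_synonymous"),
            ("stop_gained", "non_synonymous"),
            ("splice_site", "non_synonymous"),
            ("synonymous", "synonymous"),
            ("utr3", "non_coding"),
            ("utr5", "non_coding"),
            ("intronic", "non_coding"),
            ("upstream", "non_coding"),
            ("downstream", "non_coding"),
        ],
    )
    def test_fold(self, cls, expected):
        aa = ("N", 1, "D") if cls in ("missense", "start_lost", "stop_gained") else None
        if cls == "synonymous":
            aa = ("G", 1, "G")
        assert diversity_class(Consequence("v", cls, aa)) == expected

    def test_indel_classes_rejected(self):
        with pytest.raises(ValueError, match="SNP"):
            diversity_class(Consequence("v", "frameshift"))

    def test_aa_change_presence_invariant(self):
        with pytest.raises(ValueError):
            Consequence("v", "missense", None)
        with pytest.raises(ValueError):
            Consequence("v", "intronic", ("A", 1, "B"))


def test_planted_bundle_truth_labels_recovered(bundle):
    """Every consequence class the generator plants is classified correctly."""
    from flavorhap.consequence import annotate_all

    cons = annotate_all(bundle.records, bundle.gene, bundle.reference)
    planted = bundle.truth.planted_consequences
    assert len(planted) >= 9
    for vid, truth_cls in planted.items():
        assert cons[vid].cls == truth_cls, vid
    assert {c for c in planted.values()} >= {
        "synonymous", "missense", "frameshift", "inframe_indel", "splice_site",
        "utr5", "utr3", "intronic", "upstream", "downstream",
    }
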