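"""Synthetic study bundles emulating a resequenced tomato diversity panel.

The generator produces everything the downstream stages consume — a reference
region, a gene model, a multi-sample VCF, accession/phenotype tables, a
duplication-evidence table — plus a ground-truth record, from a
founder-haplotype mosaic model:

- 166 accessions in the panel's nine subpopulations (three wild SP, five
  semi-domesticated SLC, one SLL landrace group);
- six founder haplotypes (one equal to the reference) derived from a shared
  ancestor by sprinkled mutations; each subpopulation draws predominantly from
  one founder, so within-subpopulation diversity is below between-founder
  divergence and the planted clusters are recoverable;
- a mostly-selfing diploid model (two haplotype draws per accession, usually
  identical), plus rare private mutations and random missing genotypes;
- planted variants covering every consequence class (including a 13-bp
  coding duplication -> frameshift and a 15-bp in-frame deletion);
- additive phenotype effects with betas solved so each causal variant's
  theoretical PVE matches the configured fraction; sugar/acid phenotypes are
  Gaussian, the two volatiles log-normal (so the normality gate in the
  association stage has work to do);
- a duplication-evidence table planting 28 carriers (~2x coverage, inflated
  apparent heterozygosity, no deletion against the two-copy assembly) among
  the wild and Ecuadorian subpopulations.

One RNG stream per component (reference, founders, genotypes, phenotypes,
missingness, evidence, QC decoys) so changing one leaves the others untouched.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval
from .io_formats import write_fasta, write_gene_model_gff3, write_table, write_vcf
from .variants import HET, HOM_ALT, HOM_REF, MISSING, VariantRecord

BASES = "ACGT"
_NEXT_BASE = {"A": "G", "C": "T", "G": "A", "T": "C"}  # transition-biased, deterministic

DEFAULT_SUBPOPS = (
    ("SP-SECU", 14),
    ("SP-NECU", 14),
    ("SP-PER", 20),
    ("SLC-ECU", 30),
    ("SLC-PER", 18),
    ("SLC-SM", 13),
    ("SLC-CA", 22),
    ("SLC-MEX", 18),
    ("SLL", 17),
)
# which founder haplotype dominates each subpopulation (6 founders, 9 subpops);
# founder 5 spans the three largest SLC groups so its sites segregate near the
# default causal-variant frequency target of 0.30
DEFAULT_FOUNDER_OF_SUBPOP = {
    "SP-SECU": 1,
    "SP-NECU": 1,
    "SP-PER": 2,
    "SLC-ECU": 3,
    "SLC-PER": 4,
    "SLC-SM": 5,
    "SLC-CA": 5,
    "SLC-MEX": 5,
    "SLL": 0,  # founder 0 == reference haplotype
}


@dataclass(frozen=True)
class MetaboliteSpec:
    name: str
    unit: str
    baseline_mean: float  # log-scale mean when log_scale
    noise_sd: float  # log-scale sd when log_scale
    pve: float
    log_scale: bool = False
    causal: str | None = None  # variant id, or None for automatic selection

    def __post_init__(self) -> None:
        if not (0.0 < self.pve < 1.0):
            raise ValueError(f"{self.name}: PVE must be in (0, 1)")


DEFAULT_METABOLITES = (
    MetaboliteSpec("SSC", "Bx", 5.0, 1.0, 0.15),
    MetaboliteSpec("malate", "mg/g", 2.5, 0.6, 0.15),
    MetaboliteSpec("isobutyl_acetate", "ng/g", 2.5, 0.8, 0.15, log_scale=True),
    MetaboliteSpec("Z3_hexenol", "ng/g", 2.8, 0.9, 0.15, log_scale=True),
)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    subpop_spec: tuple[tuple[str, int], ...] = DEFAULT_SUBPOPS
    upstream_bp: int = 3000
    downstream_bp: int = 1000
    n_clusters_planted: int = 6
    founder_mutation_rate: float = 0.0045  # per site, per non-reference founder
    private_mutation_rate: float = 4e-5  # per site, per accession
    admixture_prob: float = 0.12  # accession draws a random founder instead
    selfing_prob: float = 0.92  # second haplotype equals the first
    missing_rate: float = 0.02
    metabolites: tuple[MetaboliteSpec, ...] = DEFAULT_METABOLITES
    causal_maf_target: float = 0.30
    n_duplication_carriers: int = 28
    coverage_multiplier: float = 2.0
    carrier_het_mean: float = 0.55
    noncarrier_het_mean: float = 0.08
    evidence_cov_sd: float = 0.08
    evidence_het_sd: float = 0.05
    mean_depth: float = 20.0
    n_qc_decoys: int = 3  # records planted to fail the hard/missingness filters
    chrom: str = "chrSim"

    def __post_init__(self) -> None:
        for p in (
            self.founder_mutation_rate,
            self.private_mutation_rate,
            self.admixture_prob,
            self.selfing_prob,
            self.missing_rate,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if sum(n for _, n in self.subpop_spec) <= 0:
            raise ValueError("subpopulation sizes must sum to a positive count")

    @property
    def n_accessions(self) -> int:
        return sum(n for _, n in self.subpop_spec)


@dataclass
class SimTruth:
    founder_of_accession: dict[str, int]
    causal: dict[str, dict]  # metabolite -> {variant_id, beta, pve, maf}
    duplication_carriers: list[str]
    founder_sites: dict[int, list[str]]  # founder -> variant ids carried
    planted_consequences: dict[str, str]  # variant id -> truth class

    def to_json(self, path: str | Path) -> None:
        payload = {
            "founder_of_accession": self.founder_of_accession,
            "causal": self.causal,
            "duplication_carriers": self.duplication_carriers,
            "founder_sites": {str(k): v for k, v in self.founder_sites.items()},
            "planted_consequences": self.planted_consequences,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


@dataclass
class Bundle:
    config: SimConfig
    reference: dict[str, str]
    gene: GeneModel
    records: list[VariantRecord]
    accessions: list[str]
    accession_table: pd.DataFrame
    phenotypes: pd.DataFrame
    evidence: pd.DataFrame
    truth: SimTruth

    @property
    def subpop_of(self) -> dict[str, str]:
        return dict(
            zip(self.accession_table["accession_id"], self.accession_table["subpopulation"])
        )


# ------------------------------------------------------------- gene construction

_MARGIN = 500
_UTR5, _CDS1, _INTRON1, _CDS2, _INTRON2, _CDS3, _UTR3 = 120, 498, 700, 900, 600, 300, 180


def _default_gene(config: SimConfig) -> GeneModel:
    g0 = _MARGIN + config.upstream_bp
    e1s, e1e = g0, g0 + _UTR5 + _CDS1
    i1e = e1e + _INTRON1
    e2s, e2e = i1e, i1e + _CDS2
    i2e = e2e + _INTRON2
    e3s, e3e = i2e, i2e + _CDS3 + _UTR3
    c = config.chrom
    return GeneModel(
        gene_id="GeneA",
        locus=GenomicInterval(c, g0, e3e, "+"),
        exons=[
            GenomicInterval(c, e1s, e1e, "+"),
            GenomicInterval(c, e2s, e2e, "+"),
            GenomicInterval(c, e3s, e3e, "+"),
        ],
        cds=[
            GenomicInterval(c, e1s + _UTR5, e1e, "+"),
            GenomicInterval(c, e2s, e2e, "+"),
            GenomicInterval(c, e3s, e3s + _CDS3, "+"),
        ],
        upstream_flank_bp=config.upstream_bp,
        downstream_flank_bp=config.downstream_bp,
    )


_STOP_CODONS = {"TAA", "TAG", "TGA"}
_MISSENSE_CODON_INDEX = 365  # carries AAT so its first-base transition is Asn->Asp


def _make_reference(config: SimConfig, gene: GeneModel, rng: np.random.Generator) -> str:
    length = gene.flanked_region.end + _MARGIN
    seq = list(rng.choice(list(BASES), size=length))
    # overwrite the CDS with a clean ORF: ATG ... internal non-stop codons ... TAA
    n_codons = gene.cds_length // 3
    codons = ["ATG"]
    safe = [c for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
            if c not in _STOP_CODONS and c != "ATG"]
    idx = rng.integers(0, len(safe), size=n_codons - 2)
    codons.extend(safe[i] for i in idx)
    codons.append("TAA")
    codons[_MISSENSE_CODON_INDEX] = "AAT"
    cds_seq = "".join(codons)
    for pos, base in zip(gene.cds_genomic_positions(), cds_seq):
        seq[pos] = base
    return "".join(seq)


# --------------------------------------------------------- planted consequences


def plant_consequences(
    gene: GeneModel, chrom_seq: str
) -> list[tuple[int, str, str, str]]:
    """Deterministic planted variants, one per consequence class:
    (start, ref, alt, truth class)."""
    if gene.cds_length % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if len(gene.cds) < 3 or len(gene.cds[1]) < 400 or len(gene.introns) < 2:
        raise ValueError(f"{gene.gene_id}: gene too short to host all variant classes")
    cds2 = gene.cds[1]
    out: list[tuple[int, str, str, str]] = []
    cds_pos = gene.cds_genomic_positions()

    # synonymous: third position of an internal codon whose AA survives the swap
    from Bio.Seq import Seq

    cds_seq = gene.cds_sequence(chrom_seq)
    syn = None
    for ci in range(1, len(cds_seq) // 3 - 1):
        codon = cds_seq[3 * ci : 3 * ci + 3]
        for b in BASES:
            if b == codon[2]:
                continue
            alt_codon = codon[:2] + b
            if str(Seq(codon).translate()) == str(Seq(alt_codon).translate()):
                syn = (cds_pos[3 * ci + 2], codon[2], b)
                break
        if syn:
            break
    if syn is None:  # pragma: no cover - dense codon table makes this unreachable
        raise ValueError("no synonymous site available")
    out.append((syn[0], syn[1], syn[2], "synonymous"))

    # missense: AAT -> GAT (Asn -> Asp) at the dedicated codon
    mpos = cds_pos[3 * _MISSENSE_CODON_INDEX]
    assert chrom_seq[mpos] == "A"
    out.append((mpos, "A", "G", "missense"))

    # frameshift: 13-bp duplication inside the second exon
    p = cds2.start + 100
    dup = chrom_seq[p + 1 : p + 14]
    out.append((p, chrom_seq[p], chrom_seq[p] + dup, "frameshift"))

    # in-frame deletion of five codons (15 bp) inside the second exon
    q = cds2.start + 300
    out.append((q, chrom_seq[q : q + 16], chrom_seq[q], "inframe_indel"))

    introns = gene.introns
    sp = introns[0].start  # first intronic base: canonical donor site
    out.append((sp, chrom_seq[sp], _NEXT_BASE[chrom_seq[sp]], "splice_site"))

    exon1 = gene.exons[0]
    u5 = exon1.start + 50
    out.append((u5, chrom_seq[u5], _NEXT_BASE[chrom_seq[u5]], "utr5"))
    exon3 = gene.exons[-1]
    u3 = exon3.end - 50
    out.append((u3, chrom_seq[u3], _NEXT_BASE[chrom_seq[u3]], "utr3"))

    mid2 = introns[1].start + len(introns[1]) // 2
    out.append((mid2, chrom_seq[mid2], _NEXT_BASE[chrom_seq[mid2]], "intronic"))

    up = gene.locus.start - 1000
    out.append((up, chrom_seq[up], _NEXT_BASE[chrom_seq[up]], "upstream"))
    down = gene.locus.end + 500
    out.append((down, chrom_seq[down], _NEXT_BASE[chrom_seq[down]], "downstream"))
    return out


# ----------------------------------------------------------------- main generator


def _passing_info(rng: np.random.Generator) -> dict:
    return {
        "MQ": 60.0,
        "QD": float(np.round(20.0 + 10.0 * rng.random(), 3)),
        "FS": float(np.round(3.0 * rng.random(), 3)),
        "MQRankSum": float(np.round(rng.normal(0.0, 0.5), 3)),
        "ReadPosRankSum": float(np.round(rng.normal(0.0, 0.5), 3)),
    }


def simulate_bundle(config: SimConfig) -> Bundle:
    """Generate a full study bundle; deterministic given ``config.seed``."""
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_ref, rng_founder, rng_geno, rng_pheno, rng_miss, rng_evid, rng_qc = (
        np.random.default_rng(s) for s in streams
    )

    gene = _default_gene(config)
    chrom_seq = _make_reference(config, gene, rng_ref)
    chrom = config.chrom
    region = gene.flanked_region

    accessions: list[str] = []
    subpop_rows = []
    for name, size in config.subpop_spec:
        for _ in range(size):
            acc = f"ACC{len(accessions) + 1:04d}"
            accessions.append(acc)
            subpop_rows.append({"accession_id": acc, "subpopulation": name})
    n_acc = len(accessions)
    accession_table = pd.DataFrame(subpop_rows)

    planted = plant_consequences(gene, chrom_seq)
    blocked: set[int] = set()
    for start, ref, _alt, _cls in planted:
        blocked.update(range(start - 1, start + len(ref) + 1))

    # founder haplotypes: sprinkled mutations on the shared ancestor (founder 0
    # stays identical to the reference)
    k = config.n_clusters_planted
    founder_sites: dict[int, set[int]] = {0: set()}
    candidates = np.array(
        [p for p in range(region.start, region.end) if p not in blocked]
    )
    for f in range(1, k):
        draw = rng_founder.random(candidates.size) < config.founder_mutation_rate
        founder_sites[f] = set(int(p) for p in candidates[draw])

    # planted consequence variants ride on one or two non-reference founders
    planted_founders: dict[int, list[int]] = {}
    for start, _ref, _alt, _cls in planted:
        n_f = 1 + int(rng_founder.random() < 0.5)
        fs = sorted(rng_founder.choice(np.arange(1, k), size=n_f, replace=False))
        planted_founders[start] = [int(f) for f in fs]

    founder_of_subpop = {
        name: DEFAULT_FOUNDER_OF_SUBPOP.get(name, i % k)
        for i, (name, _) in enumerate(config.subpop_spec)
    }

    # accession haplotype draws (mosaic + mostly selfing)
    hap1 = np.empty(n_acc, dtype=int)
    hap2 = np.empty(n_acc, dtype=int)
    for j, row in enumerate(subpop_rows):
        primary = founder_of_subpop[row["subpopulation"]]
        if rng_geno.random() < config.admixture_prob:
            primary = int(rng_geno.integers(0, k))
        hap1[j] = primary
        hap2[j] = primary if rng_geno.random() < config.selfing_prob else int(
            rng_geno.integers(0, k)
        )

    # private mutations (mostly homozygous: selfers)
    private: dict[int, list[tuple[int, int]]] = {}  # pos -> [(accession, code)]
    chrom_len = len(chrom_seq)
    for j in range(n_acc):
        n_mut = rng_geno.binomial(chrom_len, config.private_mutation_rate)
        for _ in range(n_mut):
            pos = int(rng_geno.integers(0, chrom_len))
            if pos in blocked:
                continue
            code = HOM_ALT if rng_geno.random() < 0.6 else HET
            private.setdefault(pos, []).append((j, code))

    # assemble site list
    site_defs: dict[int, tuple[str, str, str | None]] = {}  # pos -> (ref, alt, cls)
    for start, ref, alt, cls in planted:
        site_defs[start] = (ref, alt, cls)
    founder_union = sorted(set().union(*founder_sites.values()))
    for pos in founder_union:
        base = chrom_seq[pos]
        site_defs.setdefault(pos, (base, _NEXT_BASE[base], None))
    for pos in private:
        base = chrom_seq[pos]
        site_defs.setdefault(pos, (base, _NEXT_BASE[base], None))

    carries: dict[int, np.ndarray] = {}
    for pos in site_defs:
        in_f = np.array(
            [
                pos in founder_sites.get(f, set())
                or f in planted_founders.get(pos, [])
                and f != 0
                for f in range(k)
            ]
        )
        dosage = in_f[hap1].astype(np.int8) + in_f[hap2].astype(np.int8)
        carries[pos] = dosage

    records: list[VariantRecord] = []
    truth_planted: dict[str, str] = {}
    for pos in sorted(site_defs):
        ref, alt, cls = site_defs[pos]
        codes = carries[pos].copy()
        for j, code in private.get(pos, []):
            if codes[j] == HOM_REF:
                codes[j] = code
            elif codes[j] == HET:
                codes[j] = HOM_ALT
        if np.all(codes == HOM_REF):
            continue  # monomorphic in this draw
        miss = rng_miss.random(n_acc) < config.missing_rate
        codes = codes.astype(np.int8)
        codes[miss] = MISSING
        rec = VariantRecord(
            chrom=chrom,
            start=pos,
            ref=ref,
            alt=alt,
            qual=float(np.round(200.0 + 800.0 * rng_qc.random(), 2)),
            info=_passing_info(rng_qc),
            genotypes=codes,
        )
        records.append(rec)
        if cls is not None:
            truth_planted[rec.variant_id] = cls

    # one SV (intronic deletion) carried by founder-(k-1) accessions, passing
    # the read-support filter at the configured mean depth
    sv_start = gene.introns[0].start + 150
    sv_len = 300
    sv_codes = np.where(
        (hap1 == k - 1) & (hap2 == k - 1), HOM_ALT,
        np.where((hap1 == k - 1) | (hap2 == k - 1), HET, HOM_REF),
    ).astype(np.int8)
    records.append(
        VariantRecord(
            chrom=chrom,
            start=sv_start,
            ref=chrom_seq[sv_start],
            alt="<DEL>",
            qual=300.0,
            info={"SVTYPE": "DEL", "SVLEN": -sv_len, "PE": 6, "SR": 4,
                  "SU": int(config.mean_depth)},
            genotypes=sv_codes,
        )
    )
    # decoy SV failing the support filter (SR > PE)
    records.append(
        VariantRecord(
            chrom=chrom,
            start=sv_start + 2000,
            ref=chrom_seq[sv_start + 2000],
            alt="<DEL>",
            qual=150.0,
            info={"SVTYPE": "DEL", "SVLEN": -250, "PE": 2, "SR": 5, "SU": 7},
            genotypes=np.where(rng_qc.random(n_acc) < 0.05, HET, HOM_REF).astype(np.int8),
        )
    )

    # QC decoys: records built to fail the hard filters / missingness threshold
    used = set(site_defs)
    decoy_pos = [p for p in range(region.start + 10, region.end, 37) if p not in used]
    fail_infos = [
        {"MQ": 30.0, "QD": 25.0, "FS": 1.0, "MQRankSum": 0.0, "ReadPosRankSum": 0.0},
        {"MQ": 60.0, "QD": 1.0, "FS": 1.0, "MQRankSum": 0.0, "ReadPosRankSum": 0.0},
        {"MQ": 60.0, "QD": 25.0, "FS": 90.0, "MQRankSum": 0.0, "ReadPosRankSum": 0.0},
    ]
    for i in range(min(config.n_qc_decoys, len(fail_infos))):
        pos = decoy_pos[i]
        base = chrom_seq[pos]
        codes = np.where(rng_qc.random(n_acc) < 0.2, HET, HOM_REF).astype(np.int8)
        records.append(
            VariantRecord(
                chrom=chrom, start=pos, ref=base, alt=_NEXT_BASE[base],
                qual=500.0, info=fail_infos[i], genotypes=codes,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.start, r.ref, r.alt))

    # ----------------------------------------------------------- phenotypes
    snp_records = {
        r.variant_id: r for r in records if r.is_snp and r.variant_id not in truth_planted
    }
    causal_pool = []
    for vid, rec in snp_records.items():
        maf = rec.maf
        if 0.15 <= maf <= 0.45 and rec.missing_fraction < 0.05:
            causal_pool.append((abs(maf - config.causal_maf_target), vid))
    causal_pool.sort()
    if len(causal_pool) < len(config.metabolites):
        raise ValueError("not enough intermediate-frequency variants to plant effects")

    phenotypes = pd.DataFrame(index=pd.Index(accessions, name="accession_id"))
    causal_truth: dict[str, dict] = {}
    rec_by_id = {r.variant_id: r for r in records}
    for i, met in enumerate(config.metabolites):
        vid = met.causal or causal_pool[i][1]
        rec = rec_by_id[vid]
        d = rec.dosage()
        d = np.where(np.isnan(d), np.nanmean(d), d)
        sd_d = float(np.std(d))
        if sd_d == 0:
            raise ValueError(
                f"{met.name}: requested PVE {met.pve} unattainable at a monomorphic "
                "causal variant (attainable maximum is 0)"
            )
        beta = met.noise_sd * np.sqrt(met.pve / (1.0 - met.pve)) / sd_d
        latent = (
            met.baseline_mean
            + beta * (d - d.mean())
            + rng_pheno.normal(0.0, met.noise_sd, size=n_acc)
        )
        values = np.exp(latent) if met.log_scale else np.maximum(latent, 0.0)
        phenotypes[met.name] = np.round(values, 6)
        causal_truth[met.name] = {
            "variant_id": vid,
            "beta": float(beta),
            "pve": met.pve,
            "maf": float(rec.maf),
            "log_scale": met.log_scale,
        }

    # ------------------------------------------------------ duplication evidence
    sp_like = [
        j
        for j, row in enumerate(subpop_rows)
        if row["subpopulation"].startswith("SP") or row["subpopulation"] == "SLC-ECU"
    ]
    n_carriers = min(config.n_duplication_carriers, len(sp_like))
    carrier_idx = sorted(
        int(i) for i in rng_evid.choice(sp_like, size=n_carriers, replace=False)
    )
    carrier_set = set(carrier_idx)
    ev_rows = []
    for j, acc in enumerate(accessions):
        if j in carrier_set:
            cov = config.coverage_multiplier + rng_evid.normal(0.0, config.evidence_cov_sd)
            het = config.carrier_het_mean + rng_evid.normal(0.0, config.evidence_het_sd)
            deletion = False
        else:
            cov = 1.0 + rng_evid.normal(0.0, config.evidence_cov_sd)
            het = config.noncarrier_het_mean + rng_evid.normal(0.0, config.evidence_het_sd)
            deletion = True
        ev_rows.append(
            {
                "accession_id": acc,
                "norm_coverage": round(max(cov, 0.0), 6),
                "het_fraction": round(min(max(het, 0.0), 1.0), 6),
                "deletion_present": deletion,
            }
        )
    evidence = pd.DataFrame(ev_rows)

    truth = SimTruth(
        founder_of_accession={acc: int(hap1[j]) for j, acc in enumerate(accessions)},
        causal=causal_truth,
        duplication_carriers=[accessions[j] for j in carrier_idx],
        founder_sites={
            f: sorted(
                vid
                for vid, rec in rec_by_id.items()
                if rec.start in founder_sites[f]
                or f in planted_founders.get(rec.start, [])
            )
            for f in range(k)
        },
        planted_consequences=truth_planted,
    )
    return Bundle(
        config=config,
        reference={chrom: chrom_seq},
        gene=gene,
        records=records,
        accessions=accessions,
        accession_table=accession_table,
        phenotypes=phenotypes,
        evidence=evidence,
        truth=truth,
    )


def write_bundle(bundle: Bundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as the plain-text formats the readers consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.fa",
        "gene_model": out / "gene_model.gff3",
        "vcf": out / "variants.vcf",
        "accessions": out / "accessions.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "evidence": out / "evidence.tsv",
        "truth": out / "truth.json",
    }
    write_fasta(bundle.reference, paths["reference"])
    write_gene_model_gff3(bundle.gene, paths["gene_model"])
    write_vcf(
        bundle.records,
        bundle.accessions,
        paths["vcf"],
        contig_lengths={c: len(s) for c, s in bundle.reference.items()},
    )
    write_table(bundle.accession_table, paths["accessions"])
    write_table(bundle.phenotypes.reset_index(), paths["phenotypes"])
    write_table(bundle.evidence, paths["evidence"])
    bundle.truth.to_json(paths["truth"])
    return paths
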