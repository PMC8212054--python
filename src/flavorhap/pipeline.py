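"""Per-gene pipeline orchestration: chain QC, duplication genotyping,
consequence annotation, haplotype clustering, networks, diversity and the
association scan into one run with a single config and one output directory.

Every stage writes a deterministic TSV; a JSON manifest records parameters,
stage completion and a content hash per output so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import normalize_phenotype, scan, subpopulation_covariates
from .consequence import annotate_all, consequences_to_frame
from .diversity import diversity_table, gene_pi_summary
from .duplication import genotype_collection
from .haplotype_clusters import (
    HaplotypeMatrix,
    build_matrix,
    compare_clusters,
    decile_classes,
    ward_cluster,
)
from .haplotype_network import build_network, collapse_haplotypes
from .io_formats import write_table, write_vcf
from .synthetic_data import Bundle
from .variant_qc import apply_qc, profile_spec

STAGES = ("qc", "dupcall", "annotate", "cluster", "network", "diversity", "assoc")


@dataclass
class RunConfig:
    """Configuration for one gene x phenotype analysis."""

    phenotype: str  # metabolite column paired with the gene
    filter_profile: str = "varitome"  # 10% missingness; "cultivated" = 50%
    k: int = 6
    alpha: float = 0.05
    maf_min: float = 0.02
    shapiro_alpha: float = 0.01
    cluster_metric: str = "manhattan"
    network_method: str = "msn"
    use_subpop_covariates: bool = False
    exclude_duplication_carriers: bool = False
    dup_cov_min: float = 1.5
    dup_het_min: float = 0.4
    mean_depth: float | None = None
    outgroup: str | None = "reference"  # root the network at the reference CDS
    seed: int = 0

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class GeneReport:
    outdir: Path
    manifest: dict
    cluster_assignment: pd.Series | None = None
    association: pd.DataFrame | None = None
    n_carriers: int | None = None
    haplotype_matrix: HaplotypeMatrix | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_gene(bundle: Bundle, config: RunConfig, outdir: str | Path) -> GeneReport:
    """Execute the full per-gene analysis on a study bundle.

    Stage order: qc -> dupcall (optional carrier exclusion) -> annotate ->
    cluster -> network -> diversity -> assoc. Any stage error aborts with the
    stage name attached.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gene = bundle.gene
    if config.phenotype not in bundle.phenotypes.columns:
        raise ValueError(
            f"phenotype {config.phenotype!r} not in phenotype table "
            f"(has {list(bundle.phenotypes.columns)})"
        )
    manifest: dict = {
        "gene": gene.gene_id,
        "config": config.to_dict(),
        "version": __version__,
        "stages_completed": [],
        "outputs": {},
    }
    stage = "init"
    try:
        # ------------------------------------------------------------------ qc
        stage = "qc"
        spec = profile_spec(config.filter_profile)
        mean_depth = config.mean_depth or getattr(bundle.config, "mean_depth", None)
        records, audit = apply_qc(bundle.records, spec, mean_depth)
        audit_df = pd.DataFrame(audit, columns=["variant_id", "kept", "reason"])
        write_table(audit_df, out / "qc_audit.tsv")
        write_vcf(
            records,
            bundle.accessions,
            out / "filtered.vcf",
            contig_lengths={c: len(s) for c, s in bundle.reference.items()},
        )
        manifest["n_variants_pass_qc"] = len(records)
        manifest["stages_completed"].append(stage)

        # ------------------------------------------------------------- dupcall
        stage = "dupcall"
        accessions = list(bundle.accessions)
        subpop_of = bundle.subpop_of
        genotyping = genotype_collection(
            bundle.evidence,
            cov_min=config.dup_cov_min,
            het_min=config.dup_het_min,
            subpop_of=subpop_of,
        )
        write_table(genotyping.calls, out / "duplication_calls.tsv")
        manifest["n_duplication_carriers"] = genotyping.n_carriers
        carriers = set(
            genotyping.calls.loc[genotyping.calls["call"] == "carrier", "accession_id"]
        )
        if config.exclude_duplication_carriers:
            keep_idx = [i for i, a in enumerate(accessions) if a not in carriers]
            accessions = [accessions[i] for i in keep_idx]
            idx = np.array(keep_idx)
            from dataclasses import replace as _replace

            records = [_replace(r, genotypes=r.genotypes[idx]) for r in records]
        manifest["n_accessions_analyzed"] = len(accessions)
        manifest["stages_completed"].append(stage)

        # ------------------------------------------------------------ annotate
        stage = "annotate"
        consequences = annotate_all(records, gene, bundle.reference)
        write_table(consequences_to_frame(consequences), out / "consequences.tsv")
        manifest["stages_completed"].append(stage)

        # ------------------------------------------------------------- cluster
        stage = "cluster"
        matrix = build_matrix(records, gene, accessions)
        assignment = ward_cluster(matrix, k=config.k, metric=config.cluster_metric)
        phen = bundle.phenotypes[config.phenotype].reindex(accessions)
        classes = decile_classes(phen)
        cluster_df = pd.DataFrame(
            {
                "accession_id": accessions,
                "cluster": assignment.labels.values,
                "subpopulation": [subpop_of.get(a, "NA") for a in accessions],
                "phenotype": phen.values,
                "phenotype_class": classes.values,
            }
        )
        write_table(cluster_df, out / "clusters.tsv")
        comparison = compare_clusters(assignment, phen, alpha=config.alpha)
        write_table(comparison.summary, out / "cluster_comparison.tsv")
        write_table(comparison.pairwise, out / "cluster_pairwise.tsv")
        manifest["stages_completed"].append(stage)

        # ------------------------------------------------------------- network
        stage = "network"
        haplotypes = collapse_haplotypes(
            records,
            gene,
            bundle.reference,
            accessions,
            subpopulations=subpop_of,
            phenotype_classes=dict(zip(accessions, classes.values)),
        )
        outgroup_seq = (
            gene.cds_sequence(bundle.reference[gene.chrom])
            if config.outgroup == "reference"
            else config.outgroup
        )
        network = build_network(haplotypes, outgroup_seq, method=config.network_method)
        write_table(network.edge_table(), out / "network_edges.tsv")
        write_table(network.node_table(), out / "network_nodes.tsv")
        network.to_graphml(out / "network.graphml")
        manifest["n_haplotypes"] = len(haplotypes)
        manifest["stages_completed"].append(stage)

        # ----------------------------------------------------------- diversity
        stage = "diversity"
        div = diversity_table(records, consequences, gene, accessions, subpop_of)
        write_table(div, out / "diversity_windows.tsv")
        write_table(gene_pi_summary(div), out / "diversity_gene.tsv")
        manifest["stages_completed"].append(stage)

        # --------------------------------------------------------------- assoc
        stage = "assoc"
        norm = normalize_phenotype(phen, shapiro_alpha=config.shapiro_alpha)
        covariates = None
        if config.use_subpop_covariates:
            covariates = subpopulation_covariates(
                pd.Series([subpop_of.get(a, "NA") for a in accessions], index=accessions)
            )
        vclasses = {
            r.variant_id: r.vclass for r in records
        }
        assoc = scan(
            matrix.data,
            norm,
            maf_min=config.maf_min,
            covariates=covariates,
            variant_classes=vclasses,
        )
        write_table(assoc, out / "association.tsv")
        manifest["phenotype_transformed"] = norm.was_transformed
        manifest["shapiro_p"] = norm.shapiro_p
        manifest["stages_completed"].append(stage)
    except Exception as exc:
        raise RuntimeError(
            f"stage {stage!r} failed for gene {gene.gene_id}: {exc} "
            f"(rerun: flavorhap run --gene {gene.gene_id} --phenotype "
            f"{config.phenotype} --seed {config.seed})"
        ) from exc

    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return GeneReport(
        outdir=out,
        manifest=manifest,
        cluster_assignment=assignment.labels,
        association=assoc,
        n_carriers=genotyping.n_carriers,
        haplotype_matrix=matrix,
    )
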