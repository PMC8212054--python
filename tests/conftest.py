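import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from flavorhap.intervals import GeneModel, GenomicInterval
from flavorhap.synthetic_data import SimConfig, simulate_bundle
from flavorhap.variants import VariantRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_toy_gene(strand: str = "+") -> GeneModel:
    """Three-exon toy gene with a 300-bp CDS: exon1 = 20 bp UTR5 + 100 bp CDS,
    exon2 = 100 bp CDS, exon3 = 100 bp CDS + 20 bp UTR3; introns of 100 bp."""
    c = "toy"
    return GeneModel(
        gene_id="toyGene",
        locus=GenomicInterval(c, 400, 940, strand),
        exons=[
            GenomicInterval(c, 400, 520, strand),
            GenomicInterval(c, 620, 720, strand),
            GenomicInterval(c, 820, 940, strand),
        ],
        cds=[
            GenomicInterval(c, 420, 520, strand),
            GenomicInterval(c, 620, 720, strand),
            GenomicInterval(c, 820, 920, strand),
        ],
        upstream_flank_bp=300,
        downstream_flank_bp=200,
    )


def make_toy_reference(gene: GeneModel, seed: int = 123) -> dict[str, str]:
    """Random chromosome carrying a clean ORF in the toy gene's CDS."""
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=1600))
    stop = {"TAA", "TAG", "TGA"}
    import itertools

    safe = [
        "".join(t)
        for t in itertools.product("ACGT", repeat=3)
        if "".join(t) not in stop and "".join(t) != "ATG"
    ]
    n_codons = gene.cds_length // 3
    codons = ["ATG"] + [safe[int(i)] for i in rng.integers(0, len(safe), n_codons - 2)] + ["TAA"]
    for pos, base in zip(gene.cds_genomic_positions(), "".join(codons)):
        seq[pos] = base
    return {gene.chrom: "".join(seq)}


@pytest.fixture(scope="session")
def toy_gene() -> GeneModel:
    return make_toy_gene()


@pytest.fixture(scope="session")
def toy_reference(toy_gene) -> dict[str, str]:
    return make_toy_reference(toy_gene)


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study bundle (166 accessions, nine subpopulations)."""
    return simulate_bundle(SimConfig(seed=11))


@pytest.fixture(scope="session")
def qc_bundle(bundle):
    """Bundle records after the default QC profile."""
    from flavorhap.variant_qc import apply_qc, profile_spec

    records, audit = apply_qc(bundle.records, profile_spec(), bundle.config.mean_depth)
    return bundle, records


def make_record(
    start: int = 100,
    ref: str = "A",
    alt: str = "G",
    qual: float = 500.0,
    info: dict | None = None,
    genotypes=None,
    chrom: str = "toy",
) -> VariantRecord:
    if genotypes is None:
        genotypes = [0, 1, 2, 0, 0, 1, 2, 0]
    return VariantRecord(
        chrom=chrom,
        start=start,
        ref=ref,
        alt=alt,
        qual=qual,
        info=info or {},
        genotypes=np.array(genotypes, dtype=np.int8),
    )
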