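"""Variant records: one (split, normalized) VCF row with per-accession genotypes.

Genotypes are stored as small integer codes; phase is discarded (none of the
analyses use it). A variant is an SV when it is declared via SVTYPE or when
either allele is >= 100 bp, a SNP when both alleles are single bases, and an
INDEL otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

SV_MIN_ALLELE_LEN = 100  # SVs (> 100 bp)

#: INFO keys the pipeline understands; anything else is dropped on read.
KNOWN_INFO_KEYS = (
    "MQ",
    "QD",
    "FS",
    "MQRankSum",
    "ReadPosRankSum",
    "PE",
    "SR",
    "SU",
    "SVTYPE",
    "SVLEN",
)


@dataclass
class VariantRecord:
    """One biallelic variant with genotype codes over a fixed accession order."""

    chrom: str
    start: int  # 0-based
    ref: str
    alt: str
    qual: float = float("nan")
    info: dict = field(default_factory=dict)
    genotypes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if not self.ref or not self.alt:
            raise ValueError(f"{self.variant_id}: empty allele")

    # ------------------------------------------------------------------ identity

    @property
    def end(self) -> int:
        """End of the REF footprint (half-open)."""
        return self.start + len(self.ref)

    @property
    def pos1(self) -> int:
        """1-based POS as printed in VCF."""
        return self.start + 1

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos1}:{self.ref}>{self.alt}"

    @property
    def vclass(self) -> str:
        if "SVTYPE" in self.info or max(len(self.ref), len(self.alt)) >= SV_MIN_ALLELE_LEN:
            return "SV"
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNP"
        return "INDEL"

    @property
    def is_snp(self) -> bool:
        return self.vclass == "SNP"

    # ----------------------------------------------------------------- genotypes

    @property
    def n_accessions(self) -> int:
        return self.genotypes.size

    @property
    def missing_fraction(self) -> float:
        if self.genotypes.size == 0:
            return 0.0
        return float(np.mean(self.genotypes == MISSING))

    def allele_counts(self, subset: np.ndarray | None = None) -> tuple[int, int]:
        """(ref_count, alt_count) over non-missing diploid genotypes.

        het contributes one of each allele; ``subset`` is an optional index
        array restricting to a subpopulation.
        """
        g = self.genotypes if subset is None else self.genotypes[subset]
        g = g[g != MISSING]
        alt = int(np.sum(g))  # dosage coding makes this the alt allele count
        ref = int(2 * g.size - alt)
        return ref, alt

    @property
    def minor_allele_count(self) -> int:
        ref, alt = self.allele_counts()
        return min(ref, alt)

    @property
    def maf(self) -> float:
        ref, alt = self.allele_counts()
        n = ref + alt
        if n == 0:
            return float("nan")
        return min(ref, alt) / n

    def dosage(self) -> np.ndarray:
        """Additive dosage {0, 1, 2} with NaN for missing genotypes."""
        d = self.genotypes.astype(float)
        d[self.genotypes == MISSING] = np.nan
        return d
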