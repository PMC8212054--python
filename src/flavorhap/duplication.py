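"""Gene-duplication genotyping from three evidence channels.

A tandem duplication that is absent from the reference assembly leaves three
summary-level footprints in short-read data: (i) roughly doubled normalized
read depth over the gene, (ii) inflated apparent heterozygosity where
paralogous reads are mismapped onto the single-copy locus, and (iii) — when
calls are made against an alternate assembly that carries both copies — the
*absence* of the deletion allele that single-copy accessions show. An
accession is called a carrier when at least two of the three criteria are met.

The numeric thresholds (coverage >= 1.5x baseline, het fraction >= 0.4) are
configurable: the evidence channels are strongly separated in practice and the
defaults sit midway between the one-copy and two-copy expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .variants import HET, MISSING

DEFAULT_COV_MIN = 1.5
DEFAULT_HET_MIN = 0.4
MIN_VARIANT_SITES = 5
DELETION_OVERLAP_FRACTION = 0.5  # reciprocal


@dataclass(frozen=True)
class DuplicationEvidence:
    accession_id: str
    norm_coverage: float
    het_fraction: float
    deletion_present: bool

    def __post_init__(self) -> None:
        if self.norm_coverage < 0:
            raise ValueError(f"{self.accession_id}: norm_coverage must be >= 0")
        if not (0.0 <= self.het_fraction <= 1.0):
            raise ValueError(f"{self.accession_id}: het_fraction must be in [0, 1]")


@dataclass(frozen=True)
class DuplicationCall:
    accession_id: str
    criteria_met: frozenset  # subset of {coverage, heterozygosity, deletion_absence}
    call: str  # carrier | non_carrier

    def __post_init__(self) -> None:
        expected = "carrier" if len(self.criteria_met) >= 2 else "non_carrier"
        if self.call != expected:
            raise ValueError("call inconsistent with 2-of-3 criteria rule")


def evidence_from_data(
    accession_id: str,
    site_depths: np.ndarray,
    baseline_depth: float,
    gene_genotypes: np.ndarray,
    deletion_calls: Sequence[GenomicInterval],
    duplicated_segment: GenomicInterval,
) -> DuplicationEvidence:
    """Summarize per-site data into the three evidence channels.

    ``site_depths``: read depths over the gene; ``baseline_depth``: genome-wide
    or flank mean depth; ``gene_genotypes``: genotype codes at variant sites
    within the gene; ``deletion_calls``: deletion intervals called against the
    alternate (two-copy) assembly.
    """
    if baseline_depth <= 0:
        raise ValueError("baseline depth must be positive")
    gts = np.asarray(gene_genotypes)
    observed = gts[gts != MISSING]
    if observed.size < MIN_VARIANT_SITES:
        raise ValueError(
            f"{accession_id}: need >= {MIN_VARIANT_SITES} genotyped variant sites "
            f"within the gene, got {observed.size}"
        )
    norm_cov = float(np.mean(site_depths)) / baseline_depth
    het_fraction = float(np.mean(observed == HET))
    seg_len = len(duplicated_segment)
    deletion_present = False
    for dele in deletion_calls:
        ov = dele.overlap_length(duplicated_segment)
        if ov >= DELETION_OVERLAP_FRACTION * seg_len and ov >= DELETION_OVERLAP_FRACTION * len(dele):
            deletion_present = True
            break
    return DuplicationEvidence(accession_id, norm_cov, het_fraction, deletion_present)


def call_duplication(
    ev: DuplicationEvidence,
    cov_min: float = DEFAULT_COV_MIN,
    het_min: float = DEFAULT_HET_MIN,
) -> DuplicationCall:
    """Apply the 2-of-3 decision rule to one accession's evidence."""
    met = set()
    if ev.norm_coverage >= cov_min:
        met.add("coverage")
    if ev.het_fraction >= het_min:
        met.add("heterozygosity")
    if not ev.deletion_present:
        met.add("deletion_absence")
    call = "carrier" if len(met) >= 2 else "non_carrier"
    return DuplicationCall(ev.accession_id, frozenset(met), call)


@dataclass
class CollectionGenotyping:
    calls: pd.DataFrame  # accession_id, criteria, n_criteria, call
    n_carriers: int
    by_subpopulation: pd.DataFrame | None = None
    thresholds: dict = field(default_factory=dict)


def genotype_collection(
    evidence: pd.DataFrame,
    cov_min: float = DEFAULT_COV_MIN,
    het_min: float = DEFAULT_HET_MIN,
    subpop_of: dict | None = None,
) -> CollectionGenotyping:
    """Call every accession in an evidence table (columns accession_id,
    norm_coverage, het_fraction, deletion_present) and summarize carriers."""
    if len(evidence) == 0:
        raise ValueError("empty evidence table")
    if evidence["accession_id"].duplicated().any():
        dup = evidence.loc[evidence["accession_id"].duplicated(), "accession_id"].tolist()
        raise ValueError(f"duplicate accession rows: {dup}")
    rows = []
    for r in evidence.itertuples():
        ev = DuplicationEvidence(
            str(r.accession_id),
            float(r.norm_coverage),
            float(r.het_fraction),
            bool(r.deletion_present),
        )
        c = call_duplication(ev, cov_min, het_min)
        rows.append(
            {
                "accession_id": c.accession_id,
                "criteria": ",".join(sorted(c.criteria_met)),
                "n_criteria": len(c.criteria_met),
                "call": c.call,
            }
        )
    calls = pd.DataFrame(rows)
    n_carriers = int((calls["call"] == "carrier").sum())
    by_subpop = None
    if subpop_of is not None:
        calls["subpopulation"] = calls["accession_id"].map(subpop_of)
        by_subpop = (
            calls[calls["call"] == "carrier"]
            .groupby("subpopulation")
            .size()
            .rename("carriers")
            .reset_index()
        )
    return CollectionGenotyping(
        calls=calls,
        n_carriers=n_carriers,
        by_subpopulation=by_subpop,
        thresholds={"cov_min": cov_min, "het_min": het_min},
    )
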