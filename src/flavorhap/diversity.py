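"""Nucleotide diversity (pi) per subpopulation, partitioned by functional
variant class, in fixed non-overlapping windows.

Per-site pi is the standard pairwise-difference estimator
ref_count * alt_count / C(n, 2) over the 2N chromosomes sampled in the
subpopulation (heterozygotes contribute one of each allele; missing genotypes
are excluded). Window pi divides the summed site values by the *window length*
(the convention of the usual command-line tool), not by the number of
genotyped sites — which deflates pi where data are sparse, and is documented
for that reason.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consequence import Consequence, diversity_class
from .intervals import GeneModel
from .variants import VariantRecord

DIVERSITY_CLASSES = ("non_synonymous", "synonymous", "non_coding", "all")


def site_pi(ref_count: int, alt_count: int) -> float:
    """Pairwise-difference pi at one biallelic site with known allele counts."""
    n = ref_count + alt_count
    if n < 2:
        raise ValueError(f"need >= 2 chromosomes, got {n}")
    return ref_count * alt_count / (n * (n - 1) / 2)


def windowed_pi(
    records: Sequence[VariantRecord],
    consequences: Mapping[str, Consequence],
    gene: GeneModel,
    accessions: Sequence[str],
    subpop_of: Mapping[str, str],
    subpopulation: str,
    cls: str = "all",
    window_bp: int = 1000,
) -> pd.DataFrame:
    """Per-window pi for one subpopulation and one variant class.

    Windows tile the flanked region starting at its left boundary. Only SNPs
    are used; ``cls`` is one of non_synonymous / synonymous / non_coding / all.
    """
    if cls not in DIVERSITY_CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    members = [i for i, a in enumerate(accessions) if subpop_of.get(a) == subpopulation]
    if not members:
        raise ValueError(f"unknown or empty subpopulation {subpopulation!r}")
    subset = np.array(members)

    region = gene.flanked_region
    n_windows = int(np.ceil(len(region) / window_bp))
    sums = np.zeros(n_windows)
    for rec in records:
        if not rec.is_snp or rec.chrom != gene.chrom:
            continue
        if not region.contains(rec.start):
            continue
        if cls != "all":
            cons = consequences.get(rec.variant_id)
            if cons is None or diversity_class(cons) != cls:
                continue
        ref, alt = rec.allele_counts(subset)
        if ref + alt < 2:
            continue
        w = (rec.start - region.start) // window_bp
        sums[w] += site_pi(ref, alt)

    rows = []
    for w in range(n_windows):
        start = region.start + w * window_bp
        end = min(start + window_bp, region.end)
        rows.append(
            {
                "subpopulation": subpopulation,
                "class": cls,
                "chrom": gene.chrom,
                "window_start": start,
                "window_end": end,
                "pi": sums[w] / window_bp,
            }
        )
    return pd.DataFrame(rows)


def diversity_table(
    records: Sequence[VariantRecord],
    consequences: Mapping[str, Consequence],
    gene: GeneModel,
    accessions: Sequence[str],
    subpop_of: Mapping[str, str],
    window_bp: int = 1000,
) -> pd.DataFrame:
    """All subpopulations x all classes, plus a per-gene mean-over-windows
    summary column for plotting."""
    subpops = sorted(set(subpop_of.values()))
    frames = [
        windowed_pi(records, consequences, gene, accessions, subpop_of, sp, cls, window_bp)
        for sp in subpops
        for cls in DIVERSITY_CLASSES
    ]
    return pd.concat(frames, ignore_index=True)


def gene_pi_summary(window_table: pd.DataFrame) -> pd.DataFrame:
    """Gene-level pi = mean over windows, per subpopulation and class."""
    return (
        window_table.groupby(["subpopulation", "class"], as_index=False)["pi"]
        .mean()
        .rename(columns={"pi": "mean_pi"})
    )
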