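"""Hard filters, missingness/MAC/quality thresholds, SV support filtering,
SV merging and 1-per-kb thinning.

SNP filters are KEEP conditions (MQ > 40, QD > 2, FS < 60, MQRankSum > -12.5,
ReadPosRankSum > -8); INDEL filters are REMOVE conditions (QD <= 2, FS > 200,
ReadPosRankSum < -20). Both predicate directions are explicit in FilterSpec
because upstream tooling prints them in opposite conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .variants import HET, HOM_ALT, HOM_REF, MISSING, VariantRecord


@dataclass(frozen=True)
class FilterSpec:
    # SNP keep predicates: (info key, strict lower bound?) etc., encoded directly
    snp_mq_gt: float = 40.0
    snp_qd_gt: float = 2.0
    snp_fs_lt: float = 60.0
    snp_mqranksum_gt: float = -12.5
    snp_readposranksum_gt: float = -8.0
    # INDEL remove predicates
    indel_qd_le: float = 2.0
    indel_fs_gt: float = 200.0
    indel_readposranksum_lt: float = -20.0
    # genotype-level filters
    max_missing_fraction: float = 0.10  # alternate profile: 0.50
    mac_min: int = 4
    qual_min: float = 100.0
    # SV read-support filter
    sv_pe_min: int = 1
    sv_sr_min: int = 1
    sv_sr_le_pe: bool = True
    sv_support_lo_factor: float = 0.5
    sv_support_hi_factor: float = 3.0
    # SV merging and thinning
    merge_max_dist_bp: int = 500
    thin_bp: int = 1000
    # what to do when an INFO field a class requires is absent
    missing_info_action: str = "drop"  # or "pass"

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_missing_fraction <= 1.0):
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if self.sv_support_lo_factor <= 0 or self.sv_support_hi_factor <= 0:
            raise ValueError("SV support factors must be positive")
        if self.missing_info_action not in ("drop", "pass"):
            raise ValueError("missing_info_action must be 'drop' or 'pass'")


#: the two missingness profiles the study uses
def profile_spec(profile: str = "varitome") -> FilterSpec:
    if profile == "varitome":
        return FilterSpec(max_missing_fraction=0.10)
    if profile == "cultivated":
        return FilterSpec(max_missing_fraction=0.50)
    raise ValueError(f"unknown profile {profile!r}")


_SNP_REQUIRED = ("MQ", "QD", "FS", "MQRankSum", "ReadPosRankSum")
_INDEL_REQUIRED = ("QD", "FS", "ReadPosRankSum")


def hard_filter(rec: VariantRecord, spec: FilterSpec = FilterSpec()) -> tuple[bool, str | None]:
    """(keep, reason) for one record. SVs pass through (they have their own
    read-support filter); reason names the first failing predicate."""
    info = rec.info
    if rec.vclass == "SV":
        return True, None
    if rec.vclass == "SNP":
        missing = [k for k in _SNP_REQUIRED if k not in info]
        if missing:
            if spec.missing_info_action == "drop":
                return False, "missing_info"
            return True, None
        checks = (
            (info["MQ"] > spec.snp_mq_gt, "MQ"),
            (info["QD"] > spec.snp_qd_gt, "QD"),
            (info["FS"] < spec.snp_fs_lt, "FS"),
            (info["MQRankSum"] > spec.snp_mqranksum_gt, "MQRankSum"),
            (info["ReadPosRankSum"] > spec.snp_readposranksum_gt, "ReadPosRankSum"),
        )
        for ok, name in checks:
            if not ok:
                return False, name
        return True, None
    # INDEL: drop when any remove predicate is true
    missing = [k for k in _INDEL_REQUIRED if k not in info]
    if missing:
        if spec.missing_info_action == "drop":
            return False, "missing_info"
        return True, None
    if info["QD"] <= spec.indel_qd_le:
        return False, "QD"
    if info["FS"] > spec.indel_fs_gt:
        return False, "FS"
    if info["ReadPosRankSum"] < spec.indel_readposranksum_lt:
        return False, "ReadPosRankSum"
    return True, None


def missingness_mac_qual_filter(
    records: Iterable[VariantRecord],
    spec: FilterSpec = FilterSpec(),
    audit: list | None = None,
) -> list[VariantRecord]:
    """Drop records by missing fraction, minor allele count and site quality."""
    kept = []
    for rec in records:
        if rec.missing_fraction > spec.max_missing_fraction:
            reason = "missingness"
        elif rec.minor_allele_count < spec.mac_min:
            reason = "mac"
        elif not np.isnan(rec.qual) and rec.qual < spec.qual_min:
            reason = "qual"
        else:
            kept.append(rec)
            continue
        if audit is not None:
            audit.append((rec.variant_id, False, reason))
    return kept


def sv_support_filter(
    rec: VariantRecord, mean_depth: float, spec: FilterSpec = FilterSpec()
) -> tuple[bool, str | None]:
    """Read-support filter for one SV record."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    info = rec.info
    missing = [k for k in ("PE", "SR", "SU") if k not in info]
    if missing:
        return False, "missing_info"
    pe, sr, su = info["PE"], info["SR"], info["SU"]
    if pe < spec.sv_pe_min:
        return False, "PE"
    if sr < spec.sv_sr_min:
        return False, "SR"
    if spec.sv_sr_le_pe and sr > pe:
        return False, "SR>PE"
    lo = spec.sv_support_lo_factor * mean_depth
    hi = spec.sv_support_hi_factor * mean_depth
    if not (lo <= su <= hi):
        return False, "SU"
    return True, None


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def _merge_genotypes(gts: np.ndarray) -> np.ndarray:
    """Per-accession union of genotype calls across merged records: het if any
    het (or a mix of hom calls), hom_alt only when every non-missing call is."""
    out = np.full(gts.shape[1], MISSING, dtype=np.int8)
    for j in range(gts.shape[1]):
        col = gts[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            continue
        if np.any(obs == HET):
            out[j] = HET
        elif np.all(obs == HOM_ALT):
            out[j] = HOM_ALT
        elif np.any(obs == HOM_ALT):
            out[j] = HET
        else:
            out[j] = HOM_REF
    return out


def merge_svs(
    records: Sequence[VariantRecord], merge_max_dist_bp: int = 500
) -> list[VariantRecord]:
    """Transitively merge same-type SVs whose breakpoints are within
    ``merge_max_dist_bp``; merged records take median breakpoints and the
    union of carrier genotypes. Non-SV records pass through untouched."""
    svs = [r for r in records if r.vclass == "SV"]
    others = [r for r in records if r.vclass != "SV"]
    groups: dict[tuple[str, str], list[VariantRecord]] = {}
    for r in svs:
        key = (r.chrom, str(r.info.get("SVTYPE", f"LEN{len(r.ref)}x{len(r.alt)}")))
        groups.setdefault(key, []).append(r)

    merged: list[VariantRecord] = []
    for group in groups.values():
        group.sort(key=lambda r: (r.start, r.end))
        dsu = _DSU(len(group))
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if (
                    abs(group[i].start - group[j].start) <= merge_max_dist_bp
                    and abs(group[i].end - group[j].end) <= merge_max_dist_bp
                ):
                    dsu.union(i, j)
        comps: dict[int, list[VariantRecord]] = {}
        for i, rec in enumerate(group):
            comps.setdefault(dsu.find(i), []).append(rec)
        for comp in comps.values():
            if len(comp) == 1:
                merged.append(comp[0])
                continue
            starts = sorted(r.start for r in comp)
            med_start = starts[(len(starts) - 1) // 2]  # lower median, deterministic
            rep = min(comp, key=lambda r: (abs(r.start - med_start), r.start))
            gts = np.stack([r.genotypes for r in comp])
            merged.append(
                replace(
                    rep,
                    start=med_start,
                    qual=float(np.nanmax([r.qual for r in comp])),
                    genotypes=_merge_genotypes(gts),
                )
            )
    out = others + merged
    out.sort(key=lambda r: (r.chrom, r.start, r.ref, r.alt))
    return out


def thin_variants(records: Sequence[VariantRecord], thin_bp: int = 1000) -> list[VariantRecord]:
    """Greedy left-to-right thinning: keep a record iff its start is at least
    ``thin_bp`` from the last kept record's start (per chromosome)."""
    kept: list[VariantRecord] = []
    last_start: dict[str, int] = {}
    for rec in records:
        prev = last_start.get(rec.chrom)
        if prev is None or rec.start - prev >= thin_bp:
            kept.append(rec)
            last_start[rec.chrom] = rec.start
    return kept


def apply_qc(
    records: Sequence[VariantRecord],
    spec: FilterSpec = FilterSpec(),
    mean_depth: float | None = None,
) -> tuple[list[VariantRecord], list[tuple[str, bool, str | None]]]:
    """Full QC pass: hard filters (SNP/INDEL), SV support filter, SV merge,
    then missingness/MAC/quality. Returns surviving records and an audit log
    of (variant_id, kept, reason)."""
    audit: list[tuple[str, bool, str | None]] = []
    surviving: list[VariantRecord] = []
    for rec in records:
        if rec.vclass == "SV":
            if mean_depth is not None:
                keep, reason = sv_support_filter(rec, mean_depth, spec)
            else:
                keep, reason = True, None
        else:
            keep, reason = hard_filter(rec, spec)
        audit.append((rec.variant_id, keep, reason))
        if keep:
            surviving.append(rec)
    surviving = merge_svs(surviving, spec.merge_max_dist_bp)
    surviving = missingness_mac_qual_filter(surviving, spec, audit)
    return surviving, audit
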