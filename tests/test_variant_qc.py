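"""Every printed QC threshold gets a pass-boundary and a fail-boundary case;
SV merging and thinning are checked against independent rule oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flavorhap.variant_qc import (
    FilterSpec,
    apply_qc,
    hard_filter,
    merge_svs,
    missingness_mac_qual_filter,
    profile_spec,
    sv_support_filter,
    thin_variants,
)

from conftest import make_record

PASSING_SNP_INFO = {"MQ": 50.0, "QD": 5.0, "FS": 10.0, "MQRankSum": 0.0, "ReadPosRankSum": 0.0}
PASSING_INDEL_INFO = {"QD": 5.0, "FS": 10.0, "ReadPosRankSum": 0.0}


def snp(info):
    return make_record(ref="A", alt="G", info=info)


def indel(info):
    return make_record(ref="AC", alt="A", info=info)


class TestHardFilterSnp:
    def test_all_predicates_pass(self):
        assert hard_filter(snp(PASSING_SNP_INFO)) == (True, None)

    @pytest.mark.parametrize(
        "key,passing,failing",
        [
            ("MQ", 40.01, 40.0),  # strictly > 40
            ("QD", 2.01, 2.0),  # strictly > 2
            ("FS", 59.99, 60.0),  # strictly < 60
            ("MQRankSum", -12.49, -12.5),  # strictly > -12.5
            ("ReadPosRankSum", -7.99, -8.0),  # strictly > -8
        ],
    )
    def test_boundaries(self, key, passing, failing):
        ok = dict(PASSING_SNP_INFO, **{key: passing})
        bad = dict(PASSING_SNP_INFO, **{key: failing})
        assert hard_filter(snp(ok)) == (True, None)
        assert hard_filter(snp(bad)) == (False, key)

    def test_missing_info_policies(self):
        rec = snp({"MQ": 50.0})  # other fields absent
        assert hard_filter(rec) == (False, "missing_info")
        assert hard_filter(rec, FilterSpec(missing_info_action="pass")) == (True, None)

    def test_idempotent(self):
        rec = snp(PASSING_SNP_INFO)
        assert hard_filter(rec) == hard_filter(rec)


class TestHardFilterIndel:
    @pytest.mark.parametrize(
        "key,passing,failing",
        [
            ("QD", 2.01, 2.0),  # removed when QD <= 2
            ("FS", 200.0, 250.0),  # removed when FS > 200
            ("ReadPosRankSum", -20.0, -20.01),  # removed when < -20
        ],
    )
    def test_boundaries(self, key, passing, failing):
        ok = dict(PASSING_INDEL_INFO, **{key: passing})
        bad = dict(PASSING_INDEL_INFO, **{key: failing})
        assert hard_filter(indel(ok)) == (True, None)
        assert hard_filter(indel(bad)) == (False, key)

    def test_sv_passes_through(self):
        rec = make_record(ref="T", alt="<DEL>", info={"SVTYPE": "DEL"})
        assert hard_filter(rec) == (True, None)


class TestMissingnessMacQual:
    def _rec_with_genotypes(self, codes, qual=500.0):
        return make_record(genotypes=codes, qual=qual, info=PASSING_SNP_INFO)

    def test_missingness_boundary_10pct(self):
        # 100 accessions: 10 missing passes (not "more than 10%"), 11 drops
        ok = self._rec_with_genotypes([2] * 5 + [1] * 5 + [0] * 80 + [-1] * 10)
        bad = self._rec_with_genotypes([2] * 5 + [1] * 5 + [0] * 79 + [-1] * 11)
        spec = FilterSpec(mac_min=1)
        assert missingness_mac_qual_filter([ok], spec) == [ok]
        assert missingness_mac_qual_filter([bad], spec) == []

    def test_cultivated_profile_50pct(self):
        codes = [-1] * 50 + [2] * 25 + [0] * 25
        rec = self._rec_with_genotypes(codes)
        assert missingness_mac_qual_filter([rec], profile_spec("cultivated")) == [rec]
        assert missingness_mac_qual_filter([rec], profile_spec("varitome")) == []

    def test_mac_boundary(self):
        # het counts 1, hom_alt counts 2 over non-missing accessions
        mac4 = self._rec_with_genotypes([2, 1, 1] + [0] * 97)
        mac3 = self._rec_with_genotypes([2, 1] + [0] * 98)
        assert missingness_mac_qual_filter([mac4]) == [mac4]
        assert missingness_mac_qual_filter([mac3]) == []

    def test_all_hom_ref_dropped(self):
        rec = self._rec_with_genotypes([0] * 100)
        assert missingness_mac_qual_filter([rec]) == []

    def test_qual_boundary_100(self):
        good = self._rec_with_genotypes([2] * 50 + [0] * 50, qual=100.0)
        bad = self._rec_with_genotypes([2] * 50 + [0] * 50, qual=99.99)
        assert missingness_mac_qual_filter([good]) == [good]
        assert missingness_mac_qual_filter([bad]) == []


class TestSvSupport:
    def sv(self, pe, sr, su):
        return make_record(ref="T", alt="<DEL>", info={"SVTYPE": "DEL", "PE": pe, "SR": sr, "SU": su})

    def test_sr_greater_than_pe_dropped(self):
        assert sv_support_filter(self.sv(3, 5, 8), 10.0) == (False, "SR>PE")

    def test_su_boundaries_at_half_and_triple_depth(self):
        assert sv_support_filter(self.sv(6, 4, 10), 20.0) == (True, None)  # SU = depth/2
        assert sv_support_filter(self.sv(6, 4, 60), 20.0) == (True, None)  # SU = 3*depth
        assert sv_support_filter(self.sv(6, 4, 9), 20.0) == (False, "SU")
        assert sv_support_filter(self.sv(6, 4, 61), 20.0) == (False, "SU")

    def test_min_read_support(self):
        assert sv_support_filter(self.sv(0, 0, 0), 10.0)[0] is False
        assert sv_support_filter(self.sv(1, 0, 6), 10.0) == (False, "SR")
        assert sv_support_filter(self.sv(0, 1, 6), 10.0) == (False, "PE")
        assert sv_support_filter(self.sv(1, 1, 6), 10.0) == (True, None)

    def test_nonpositive_depth_errors(self):
        with pytest.raises(ValueError):
            sv_support_filter(self.sv(1, 1, 5), 0.0)


def sv_at(start, length=300, svtype="DEL", genotypes=None):
    return make_record(
        start=start,
        ref="T",
        alt=f"<{svtype}>",
        info={"SVTYPE": svtype, "SVLEN": -length, "PE": 5, "SR": 3, "SU": 15},
        genotypes=genotypes if genotypes is not None else [0, 1, 2, 0, 0, 1, 2, 0],
    )


class TestMergeSvs:
    def test_two_close_dels_merge(self):
        out = merge_svs([sv_at(1000), sv_at(1400)], 500)
        assert len(out) == 1

    def test_distance_boundary(self):
        assert len(merge_svs([sv_at(1000), sv_at(1500)], 500)) == 1
        assert len(merge_svs([sv_at(1000), sv_at(1501)], 500)) == 2

    def test_type_mismatch_not_merged(self):
        out = merge_svs([sv_at(1000, svtype="DEL"), sv_at(1000, svtype="DUP")], 500)
        assert len(out) == 2

    def test_transitive_chain(self):
        out = merge_svs([sv_at(0), sv_at(400), sv_at(800)], 500)
        assert len(out) == 1
        assert out[0].start == 400  # median breakpoint

    def test_genotype_union_rule(self):
        a = sv_at(0, genotypes=[0, 1, 2, 2, -1, 0, 0, 0])
        b = sv_at(100, genotypes=[0, 0, 2, 1, -1, 2, -1, 0])
        (merged,) = merge_svs([a, b], 500)
        #            het if any het; hom_alt iff all hom_alt; mixed hom -> het
        expected = [0, 1, 2, 1, -1, 1, 0, 0]
        assert list(merged.genotypes) == expected

    def test_against_union_find_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            starts = sorted(int(s) for s in rng.integers(0, 5000, size=8))
            records = [sv_at(s) for s in starts]
            out = merge_svs(records, 500)
            # oracle: connected components of the pairwise-within-500 graph
            comp = list(range(len(starts)))

            def find(i):
                while comp[i] != i:
                    i = comp[i]
                return i

            for i in range(len(starts)):
                for j in range(i + 1, len(starts)):
                    if abs(starts[i] - starts[j]) <= 500:
                        comp[find(i)] = find(j)
            assert len(out) == len({find(i) for i in range(len(starts))})

    def test_postcondition_no_close_same_type_pairs(self):
        rng = np.random.default_rng(7)
        starts = sorted(int(s) for s in rng.integers(0, 20000, size=20))
        out = merge_svs([sv_at(s) for s in starts], 500)
        positions = sorted(r.start for r in out)
        assert all(b - a > 500 for a, b in zip(positions, positions[1:]))


class TestThinning:
    def test_greedy_example(self):
        recs = [make_record(start=s, info=PASSING_SNP_INFO) for s in (100, 500, 1500)]
        assert [r.start for r in thin_variants(recs, 1000)] == [100, 1500]

    def test_exact_spacing_kept(self):
        recs = [make_record(start=s) for s in (0, 1000, 2000)]
        assert [r.start for r in thin_variants(recs, 1000)] == [0, 1000, 2000]

    def test_single_record_kept(self):
        recs = [make_record(start=5)]
        assert thin_variants(recs, 1000) == recs

    @given(st.lists(st.integers(0, 50000), min_size=1, max_size=40), st.integers(1, 5000))
    def test_spacing_and_subset_properties(self, starts, thin_bp):
        starts = sorted(starts)
        recs = [make_record(start=s) for s in starts]
        out = thin_variants(recs, thin_bp)
        kept = [r.start for r in out]
        assert all(b - a >= thin_bp for a, b in zip(kept, kept[1:]))
        assert kept[0] == starts[0]  # greedy keeps the first
        it = iter(recs)
        assert all(any(r is o for r in it) for o in out)  # order-preserving subset
        assert thin_variants(out, thin_bp) == out  # idempotent


def test_apply_qc_drops_planted_decoys(qc_bundle):
    bundle, records = qc_bundle
    kept_ids = {r.variant_id for r in records}
    # the generator plants one MQ-fail, one QD-fail, one FS-fail SNP and one
    # SR>PE SV decoy; all must be gone
    _, audit = apply_qc(bundle.records, profile_spec(), bundle.config.mean_depth)
    dropped_reasons = {reason for _, kept, reason in audit if not kept}
    assert {"MQ", "QD", "FS", "SR>PE"} <= dropped_reasons
    # no surviving SNP carries a failing hard-filter annotation
    assert all(r.info.get("MQ", 60.0) > 40.0 for r in records if r.vclass == "SNP")
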