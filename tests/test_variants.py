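"""VCF ingestion and the two filter regimes against predicate oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmbpair.variants import (
    FilterConfig,
    VariantCall,
    annotate_known,
    germline_filter,
    panel_filter,
    read_vcf,
    wgs_quality_filter,
    write_vcf,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##INFO=<ID=CONSEQUENCE,Number=1,Type=String,Description="Class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def _write(tmp_path, body, name="t.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


class TestReadVcf:
    def test_vaf_from_format_ad_dp(self, tmp_path):
        path = _write(tmp_path, "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP:AD\t0/1:50:40,10\n")
        calls, report = read_vcf(path)
        (c,) = calls
        assert (c.chrom, c.pos, c.ref, c.alt) == ("chr1", 100, "A", "T")
        assert c.depth == 50 and c.alt_depth == 10 and c.vaf == pytest.approx(0.2)
        assert c.var_class == "SNV"
        assert report.depth_source == "format"

    def test_multiallelic_split(self, tmp_path):
        path = _write(
            tmp_path, "chr1\t100\t.\tA\tT,G\t.\tPASS\t.\tGT:DP:AD\t0/1:60:30,20,10\n"
        )
        calls, report = read_vcf(path)
        assert len(calls) == 2 and report.n_multiallelic == 1
        assert [c.alt for c in calls] == ["T", "G"]
        assert [c.vaf for c in calls] == [pytest.approx(1 / 3), pytest.approx(1 / 6)]
        assert all(c.pos == 100 for c in calls)

    def test_nonpass_dropped_by_default(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tT\t.\tq10\t.\tGT:DP:AD\t0/1:50:40,10\n"
            "chr1\t200\t.\tC\tG\t.\tPASS\t.\tGT:DP:AD\t0/1:50:40,10\n"
        )
        path = _write(tmp_path, body)
        calls, report = read_vcf(path)
        assert len(calls) == 1 and report.n_nonpass_dropped == 1
        calls, _ = read_vcf(path, keep_nonpass=True)
        assert len(calls) == 2

    def test_missing_depth_yields_zero_depth_call(self, tmp_path):
        path = _write(tmp_path, "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\n")
        calls, report = read_vcf(path)
        assert calls[0].depth == 0 and report.n_missing_depth == 1
        kept, _ = wgs_quality_filter(calls)
        assert kept == []

    def test_indel_classification(self, tmp_path):
        body = (
            "chr1\t10\t.\tA\tAT\t.\tPASS\t.\tGT:DP:AD\t0/1:50:40,10\n"
            "chr1\t20\t.\tAG\tA\t.\tPASS\t.\tGT:DP:AD\t0/1:50:40,10\n"
            "chr1\t30\t.\tAG\tTC\t.\tPASS\t.\tGT:DP:AD\t0/1:50:40,10\n"
        )
        calls, _ = read_vcf(_write(tmp_path, body))
        assert [c.var_class for c in calls] == ["indel", "indel", "MNV"]

    def test_consequence_tag_parsed(self, tmp_path):
        path = _write(
            tmp_path,
            "chr1\t10\t.\tA\tT\t.\tPASS\tCONSEQUENCE=intronic\tGT:DP:AD\t0/1:50:40,10\n",
        )
        calls, _ = read_vcf(path)
        assert calls[0].consequence == "intronic"

    def test_write_read_round_trip(self, tmp_path):
        calls = [
            VariantCall("chr1", 50, "A", "T", 80, 20, consequence="splice_site"),
            VariantCall("chr1", 10, "C", "CA", 44, 11, var_class="indel"),
        ]
        path = tmp_path / "rt.vcf"
        write_vcf(calls, path, contigs={"chr1": 100000})
        back, report = read_vcf(path)
        assert report.n_missing_depth == 0
        assert sorted(c.key for c in back) == sorted(c.key for c in calls)
        by_key = {c.key: c for c in back}
        for c in calls:
            assert by_key[c.key].depth == c.depth
            assert by_key[c.key].alt_depth == c.alt_depth
            assert by_key[c.key].consequence == c.consequence


def _call(depth, alt_depth, var_class="SNV", consequence="exonic",
          known=False, pop_af=None, pos=100):
    ref, alt = ("A", "T") if var_class == "SNV" else ("A", "AT")
    return VariantCall("chr1", pos, ref, alt, depth, alt_depth,
                       var_class=var_class, consequence=consequence,
                       known_snp=known, pop_af=pop_af)


class TestWgsQualityFilter:
    @pytest.mark.parametrize(
        "depth,alt,kept,reason",
        [
            (14, 7, False, "low_depth"),     # depth < 15 removed
            (15, 1, True, None),             # exactly at threshold kept
            (100, 4, False, "low_vaf"),      # vaf 0.04 < 0.05 removed
            (100, 5, True, None),            # vaf exactly 0.05 kept
            (1000, 49, False, "low_vaf"),    # vaf 0.049
        ],
    )
    def test_threshold_edges(self, depth, alt, kept, reason):
        out, report = wgs_quality_filter([_call(depth, alt)])
        assert (len(out) == 1) is kept
        if reason:
            assert report.removed == {reason: 1}

    def test_snv_only_by_default_with_switch(self):
        indel = _call(100, 40, var_class="indel")
        out, report = wgs_quality_filter([indel])
        assert out == [] and report.removed == {"not_snv": 1}
        out, _ = wgs_quality_filter([indel], FilterConfig(include_indels=True))
        assert len(out) == 1

    def test_matches_predicate_oracle_and_conserves(self, rng):
        calls = _random_calls(rng, 500)
        cfg = FilterConfig()
        kept, report = wgs_quality_filter(calls, cfg)
        oracle = [
            c
            for c in calls
            if c.var_class == "SNV" and c.depth >= 15 and c.vaf >= 0.05
        ]
        assert [c.key for c in kept] == [c.key for c in oracle]
        assert report.conserved and report.n_input == 500


class TestGermlineFilter:
    def test_pop_af_above_cutoff_removed(self):
        out, report = germline_filter([_call(100, 30, pop_af=0.001, known=False)])
        assert out == [] and report.removed == {"pop_af": 1}

    def test_pop_af_exactly_at_cutoff_kept(self):
        out, _ = germline_filter([_call(100, 30, pop_af=0.0001)])
        assert len(out) == 1

    def test_unannotated_kept(self):
        out, _ = germline_filter([_call(100, 30)])
        assert len(out) == 1

    def test_known_snp_membership(self):
        out, report = germline_filter([_call(100, 30, known=True)])
        assert out == [] and report.removed == {"known_snp": 1}
        out, _ = germline_filter(
            [_call(100, 30, known=True)], FilterConfig(filter_known_snp=False)
        )
        assert len(out) == 1

    def test_commutes_with_quality_filter(self, rng):
        calls = _random_calls(rng, 300)
        a, _ = germline_filter(wgs_quality_filter(calls)[0])
        b, _ = wgs_quality_filter(germline_filter(calls)[0])
        assert {c.key for c in a} == {c.key for c in b}


class TestPanelFilter:
    @pytest.mark.parametrize(
        "call,reason",
        [
            (_call(500, 200, var_class="indel"), "not_snv"),
            (_call(500, 200, consequence="other"), "consequence"),
            (_call(59, 30), "low_coverage"),
            (_call(100, 4), "low_af"),
            (_call(100, 30, known=True), "known_snp"),
            (_call(100, 30, pop_af=0.01), "pop_af"),
        ],
    )
    def test_first_failing_predicate(self, call, reason):
        out, report = panel_filter([call])
        assert out == [] and report.removed == {reason: 1}

    def test_at_thresholds_kept(self):
        assert len(panel_filter([_call(60, 3)])[0]) == 1  # 60x, vaf 0.05

    def test_matches_conjunction_oracle(self, rng):
        calls = _random_calls(rng, 300)
        cfg = FilterConfig()
        kept, report = panel_filter(calls, cfg)
        oracle = [
            c
            for c in calls
            if c.var_class == "SNV"
            and c.consequence in cfg.allowed_consequences
            and c.depth >= 60
            and c.vaf >= 0.05
            and not c.known_snp
            and (c.pop_af or 0) <= 0.0001
        ]
        assert [c.key for c in kept] == [c.key for c in oracle]
        assert report.conserved


def _random_calls(rng, n):
    calls = []
    for i in range(n):
        depth = int(rng.integers(0, 200))
        alt = int(rng.integers(0, depth + 1))
        calls.append(
            _call(
                depth,
                alt,
                var_class=["SNV", "indel", "MNV"][int(rng.integers(3))],
                consequence=["exonic", "splice_site", "intronic", "other"][
                    int(rng.integers(4))
                ],
                known=bool(rng.random() < 0.15),
                pop_af=float(rng.choice([0.0, 1e-5, 1e-4, 1e-3, 0.3]))
                if rng.random() < 0.5
                else None,
                pos=i + 1,
            )
        )
    return calls


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    st.integers(min_value=0, max_value=100),
    st.integers(min_value=0, max_value=100),
    st.floats(min_value=0, max_value=0.5),
    st.floats(min_value=0, max_value=0.5),
)
def test_filter_monotone_in_thresholds(d1, d2, v1, v2):
    """Raising any threshold never increases the number of retained calls."""
    rng = np.random.default_rng(7)
    calls = _random_calls(rng, 200)
    lo = FilterConfig(min_depth=min(d1, d2), min_vaf=min(v1, v2),
                      panel_min_coverage=min(d1, d2), panel_min_af=min(v1, v2))
    hi = FilterConfig(min_depth=max(d1, d2), min_vaf=max(v1, v2),
                      panel_min_coverage=max(d1, d2), panel_min_af=max(v1, v2))
    assert len(wgs_quality_filter(calls, hi)[0]) <= len(
        wgs_quality_filter(calls, lo)[0]
    )
    assert len(panel_filter(calls, hi)[0]) <= len(panel_filter(calls, lo)[0])


class TestAnnotateKnown:
    def test_membership_requires_allele_identity(self, tmp_path):
        resource = tmp_path / "res.vcf"
        resource.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=100000>\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tA\tT\t.\t.\tAF=0.3\n"
            "chr1\t200\t.\tC\tG\t.\t.\tAF=0.01\n"
        )
        calls = [
            VariantCall("chr1", 100, "A", "T", 50, 20),   # exact match
            VariantCall("chr1", 100, "A", "G", 50, 20),   # same pos, other allele
            VariantCall("chr1", 300, "A", "T", 50, 20),   # absent
        ]
        out = annotate_known(calls, resource)
        assert [c.known_snp for c in out] == [True, False, False]
        assert out[0].pop_af == pytest.approx(0.3)

    def test_planted_germline_annotated_somatic_untouched(
        self, small_cohort, small_cohort_dir
    ):
        from tmbpair.variants import read_vcf

        p = small_cohort.patients[0]
        calls, _ = read_vcf(small_cohort_dir / f"{p.patient_id}_site1.vcf")
        annotated = annotate_known(
            calls, small_cohort_dir / "germline_resource.vcf"
        )
        truth = p.truth_variants
        t1 = truth[truth.site == "site1"]
        germ_keys = {
            (r.chrom, r.pos, r.ref, r.alt)
            for r in t1[t1.origin == "germline"].itertuples()
        }
        somatic_keys = {
            (r.chrom, r.pos, r.ref, r.alt)
            for r in t1[t1.origin.isin(["trunk", "private"])].itertuples()
        }
        for c in annotated:
            if c.key in germ_keys:
                assert c.known_snp and c.pop_af is not None
            if c.key in somatic_keys:
                assert not c.known_snp
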