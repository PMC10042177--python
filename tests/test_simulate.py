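"""Ground-truth bookkeeping, determinism and round-trips of the simulator."""

import filecmp

import numpy as np
import pytest

from tmbpair.regions import load_bed
from tmbpair.simulate import (
    CohortConfig,
    generate_cohort,
    generate_patient,
    generate_regions,
    sample_positions,
)
from tmbpair.variants import read_vcf


def _small_cfg(**kw):
    base = dict(n_patients=3, seed=42)
    base.update(kw)
    return CohortConfig(**base)


class TestRegions:
    def test_nested_definitions_and_sizes(self):
        cfg = _small_cfg()
        rb = generate_regions(cfg)
        sizes = rb.sizes_mb()
        genome_mb = sum(cfg.contigs.values()) / 1e6
        assert sizes["canonical"] == pytest.approx(
            genome_mb * cfg.exome_fraction, rel=0.01
        )
        assert sizes["panel"] == pytest.approx(cfg.panel_mb, rel=0.01)
        # strict nesting: tcga < crev2 < canonical, panel < canonical
        assert rb.crev2.subtract(rb.canonical).total_length_bp == 0
        assert rb.tcga.subtract(rb.crev2).total_length_bp == 0
        assert rb.panel.subtract(rb.canonical).total_length_bp == 0

    def test_gap_subtraction_reduces_by_planted_overlap_exactly(self):
        rb = generate_regions(_small_cfg())
        overlap = rb.canonical.intersect(rb.gaps).total_length_bp
        assert overlap > 0  # gaps overlap the canonical set by construction
        assert (
            rb.callable.total_length_bp
            == rb.canonical.total_length_bp - overlap
        )

    def test_same_seed_same_regions(self):
        a = generate_regions(_small_cfg())
        b = generate_regions(_small_cfg())
        assert a.canonical == b.canonical and a.gaps == b.gaps

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(exome_fraction=0.0).validate()
        with pytest.raises(ValueError):
            CohortConfig(panel_mb=100.0).validate()
        with pytest.raises(ValueError):
            CohortConfig(trunk_rate=-1).validate()


class TestSamplePositions:
    def test_positions_distinct_and_inside(self, rng):
        rb = generate_regions(_small_cfg())
        rs = rb.callable
        pos = sample_positions(rs, 500, rng)
        assert len(set(pos)) == 500
        assert all(rs.contains(c, p) for c, p in pos)


class TestPatient:
    def test_trunk_shared_between_sites(self):
        cfg = _small_cfg()
        rb = generate_regions(cfg)
        p = generate_patient(cfg, rb, "P01")
        t = p.truth_variants
        trunk1 = t[(t.site == "site1") & (t.origin == "trunk")]
        trunk2 = t[(t.site == "site2") & (t.origin == "trunk")]
        key = ["chrom", "pos", "ref", "alt", "true_vaf"]
        assert trunk1[key].reset_index(drop=True).equals(
            trunk2[key].reset_index(drop=True)
        )
        priv1 = set(map(tuple, t[(t.site == "site1") & (t.origin == "private")][
            ["chrom", "pos"]].itertuples(index=False)))
        priv2 = set(map(tuple, t[(t.site == "site2") & (t.origin == "private")][
            ["chrom", "pos"]].itertuples(index=False)))
        trunk = set(map(tuple, trunk1[["chrom", "pos"]].itertuples(index=False)))
        assert priv1.isdisjoint(priv2)
        assert priv1.isdisjoint(trunk) and priv2.isdisjoint(trunk)

    def test_no_private_no_artefact_sites_identical(self):
        cfg = _small_cfg(
            private_rate_site1=0.0,
            private_rate_site2=0.0,
            artefact_rate=0.0,
            germline_rate=0.0,
            mean_depth=500.0,
            vaf_alpha=20.0,
            vaf_beta=30.0,
        )
        rb = generate_regions(cfg)
        p = generate_patient(cfg, rb, "P01")
        keys1 = [c.key for c in p.calls["site1"]]
        keys2 = [c.key for c in p.calls["site2"]]
        assert keys1 == keys2 and len(keys1) == p.trunk_count

    def test_planted_trunk_count_unbiased(self):
        cfg = _small_cfg(germline_rate=0.0, artefact_rate=0.0)
        rb = generate_regions(cfg)
        mb = rb.callable.total_length_mb()
        counts = [
            generate_patient(cfg, rb, f"R{i}", build_truth=False).trunk_count
            for i in range(300)
        ]
        lam = cfg.trunk_rate * mb
        se = np.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_artefacts_violate_thresholds(self):
        cfg = _small_cfg(artefact_rate=5.0)
        rb = generate_regions(cfg)
        p = generate_patient(cfg, rb, "P01")
        t = p.truth_variants
        art = t[t.origin == "artefact"]
        assert len(art) > 0
        vaf = art.alt_depth / art.depth
        assert ((art.depth < 15) | (vaf < 0.05)).all()

    def test_build_truth_false_same_calls(self):
        cfg = _small_cfg()
        rb = generate_regions(cfg)
        a = generate_patient(cfg, rb, "P02")
        b = generate_patient(cfg, rb, "P02", build_truth=False)
        assert [c.key for c in a.calls["site1"]] == [c.key for c in b.calls["site1"]]


class TestCohort:
    def test_exact_kras_positive_count(self):
        cohort = generate_cohort(CohortConfig(n_patients=10, seed=3))
        assert sum(p.kras_positive for p in cohort.patients) == 3

    def test_truth_vcf_consistency(self, small_cohort, small_cohort_dir):
        """Every emitted record is in the truth table and vice versa."""
        for p in small_cohort.patients[:2]:
            for site in ("site1", "site2"):
                calls, report = read_vcf(
                    small_cohort_dir / f"{p.patient_id}_{site}.vcf"
                )
                assert report.n_missing_depth == 0  # pipeline closure
                t = p.truth_variants
                t = t[(t.site == site) & t.emitted]
                truth_keys = {
                    (r.chrom, r.pos, r.ref, r.alt) for r in t.itertuples()
                }
                assert {c.key for c in calls} == truth_keys

    def test_deterministic_byte_identical_outputs(self, tmp_path):
        cfg = _small_cfg()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1 = generate_cohort(cfg).write(d1)
        m2 = generate_cohort(_small_cfg()).write(d2)
        assert m1["files"] == m2["files"]
        for name in m1["files"]:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_adding_patient_preserves_earlier_patients(self):
        a = generate_cohort(_small_cfg(n_patients=3, kras_positive_fraction=0.0))
        b = generate_cohort(_small_cfg(n_patients=4, kras_positive_fraction=0.0))
        for pa, pb in zip(a.patients[:3], b.patients[:3]):
            assert [c.key for c in pa.calls["site1"]] == [
                c.key for c in pb.calls["site1"]
            ]

    def test_refuses_nonempty_dir_without_overwrite(self, tmp_path):
        d = tmp_path / "c"
        d.mkdir()
        (d / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            generate_cohort(_small_cfg()).write(d)

    def test_beds_round_trip(self, small_cohort, small_cohort_dir):
        for name in ("canonical", "crev2", "tcga", "panel", "gaps"):
            rs = load_bed(small_cohort_dir / f"{name}.bed")
            assert rs.intervals == getattr(small_cohort.regions, name).intervals
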