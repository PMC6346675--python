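"""File formats and the shared data model."""

import numpy as np
import pandas as pd
import pytest

from restogen.formats import (
    CohortGL,
    DosageMatrix,
    canonical_unit,
    read_cohort_vcf,
    read_dosage_matrix,
    write_dosage_matrix,
    read_herd_table,
    read_ledger,
    read_unit_map,
    write_cohort_vcf,
    write_unit_map,
)

from conftest import write_test_vcf

UNIT_MAP = {"s1": "U1", "s2": "U1", "s3": "U2"}


class TestVcfInput:
    def test_shape_contract(self, tmp_path):
        vcf = write_test_vcf(tmp_path / "c.vcf", [
            (("chr1", 100, "G"), [(0, 30, 60)] * 3, [8, 9, 7]),
            (("chr2", 5, "T"), [(60, 30, 0)] * 3, [4, 5, 6]),
        ])
        cohort = read_cohort_vcf(vcf, UNIT_MAP)
        assert cohort.gl.shape == (3, 2, 3)
        assert cohort.depth.shape == (3, 2)
        assert cohort.locus_ids == ["chr1:100", "chr2:5"]

    def test_phred_conversion(self, tmp_path):
        # PL (0, 30, 60) is likelihood ratio 1 : 1e-3 : 1e-6
        vcf = write_test_vcf(tmp_path / "c.vcf",
                             [(("chr1", 1, "G"), [(0, 30, 60)] * 3, [5, 5, 5])])
        cohort = read_cohort_vcf(vcf, UNIT_MAP)
        triple = cohort.gl[0, 0] / cohort.gl[0, 0].max()
        np.testing.assert_allclose(triple, [1.0, 1e-3, 1e-6], rtol=1e-9)

    def test_conversion_preserves_ordering(self, tmp_path):
        pls = [(40, 0, 55), (3, 17, 0), (0, 11, 90)]
        vcf = write_test_vcf(tmp_path / "c.vcf", [(("chr1", 1, "G"), pls, [5, 5, 5])])
        cohort = read_cohort_vcf(vcf, UNIT_MAP)
        for i, pl in enumerate(pls):
            assert np.argmax(cohort.gl[i, 0]) == int(np.argmin(pl))

    def test_unknown_sample_rejected(self, tmp_path):
        vcf = write_test_vcf(tmp_path / "c.vcf",
                             [(("chr1", 1, "G"), [(0, 1, 2)] * 3, [5, 5, 5])])
        with pytest.raises(ValueError, match="s3"):
            read_cohort_vcf(vcf, {"s1": "U1", "s2": "U1"})

    def test_multiallelic_rejected(self, tmp_path):
        vcf = write_test_vcf(tmp_path / "c.vcf",
                             [(("chr1", 77, "G,T"), [(0, 1, 2)] * 3, [5, 5, 5])])
        with pytest.raises(ValueError, match="chr1:77"):
            read_cohort_vcf(vcf, UNIT_MAP)

    def test_zero_depth_gets_flat_triple(self, tmp_path):
        vcf = write_test_vcf(tmp_path / "c.vcf",
                             [(("chr1", 1, "G"), [(0, 30, 60)] * 3, [0, 5, 5])])
        cohort = read_cohort_vcf(vcf, UNIT_MAP)
        assert np.ptp(cohort.gl[0, 0]) == 0

    def test_round_trip_through_writer(self, tmp_path, tiny_cohort):
        path = tmp_path / "rt.vcf"
        write_cohort_vcf(tiny_cohort, path)
        back = read_cohort_vcf(path, tiny_cohort.unit_of)
        assert back.locus_ids == tiny_cohort.locus_ids
        np.testing.assert_array_equal(back.depth, tiny_cohort.depth)
        np.testing.assert_allclose(back.normalized_gl(),
                                   tiny_cohort.normalized_gl(), atol=2e-4)


class TestDosageMatrix:
    def test_round_trip_exact(self, tmp_path):
        m = DosageMatrix(["a", "b"], ["l1", "l2"], {"a": "U", "b": "U"},
                         [[0.0, 1.0], [2.0, 1.0]])
        write_dosage_matrix(m, tmp_path / "d.tsv")
        back = read_dosage_matrix(tmp_path / "d.tsv", {"a": "U", "b": "U"})
        np.testing.assert_array_equal(back.dosage, m.dosage)
        assert back.individual_ids == m.individual_ids

    def test_round_trip_six_decimals(self, tmp_path):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 2, size=(5, 7))
        d[1, 2] = np.nan
        m = DosageMatrix([f"i{i}" for i in range(5)], [f"l{j}" for j in range(7)],
                         {f"i{i}": "U" for i in range(5)}, d)
        write_dosage_matrix(m, tmp_path / "d.tsv")
        back = read_dosage_matrix(tmp_path / "d.tsv")
        np.testing.assert_allclose(back.dosage, np.round(d, 6), atol=1e-12)
        # writing the read-back matrix reproduces the file byte for byte
        write_dosage_matrix(back, tmp_path / "d2.tsv")
        assert (tmp_path / "d.tsv").read_bytes() == (tmp_path / "d2.tsv").read_bytes()

    def test_out_of_range_rejected(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("individual\tl1\na\t2.3\n")
        with pytest.raises(ValueError, match="l1"):
            read_dosage_matrix(tmp_path / "bad.tsv")

    def test_constructor_bounds(self):
        with pytest.raises(ValueError, match="out of"):
            DosageMatrix(["a"], ["l1"], {"a": "U"}, [[2.5]])

    def test_posterior_collapse(self):
        # a perfectly known heterozygote collapses to dosage exactly 1
        post = np.array([[[0.0, 1.0, 0.0], [0.25, 0.5, 0.25]]])
        m = DosageMatrix.from_posterior(post, ["a"], ["l1", "l2"], {"a": "U"})
        np.testing.assert_allclose(m.dosage, [[1.0, 1.0]])


class TestTables:
    def test_herd_table_normalizes_status(self, tmp_path):
        (tmp_path / "h.tsv").write_text(
            "unit\tdesert\tstatus\tn_sources\tlat\tlon\n"
            "161\tGB\tReintroduced\t1\t39.0\t-117.0\n"
            "212\tGB\tREMNANT\t0\t38.0\t-117.5\n"
        )
        df = read_herd_table(tmp_path / "h.tsv")
        assert list(df["status"]) == ["reintroduced", "remnant"]

    def test_unknown_status_rejected(self, tmp_path):
        (tmp_path / "h.tsv").write_text(
            "unit\tdesert\tstatus\tn_sources\tlat\tlon\n161\tGB\textinct\t1\t39\t-117\n")
        with pytest.raises(ValueError, match="extinct"):
            read_herd_table(tmp_path / "h.tsv")

    def test_latitude_bound(self, tmp_path):
        (tmp_path / "h.tsv").write_text(
            "unit\tdesert\tstatus\tn_sources\tlat\tlon\n161\tGB\tremnant\t1\t95\t-117\n")
        with pytest.raises(ValueError, match="lat"):
            read_herd_table(tmp_path / "h.tsv")

    def test_empty_ledger_ok(self, tmp_path):
        (tmp_path / "l.tsv").write_text("source\tdestination\tyear\tcount\n")
        assert len(read_ledger(tmp_path / "l.tsv")) == 0

    def test_ledger_self_move_rejected(self, tmp_path):
        (tmp_path / "l.tsv").write_text(
            "source\tdestination\tyear\tcount\n268\t268\t1970\t5\n")
        with pytest.raises(ValueError, match="differ"):
            read_ledger(tmp_path / "l.tsv")

    def test_bundled_herd_table_round_trips(self, tmp_path):
        from restogen.datasets import load_nevada_herds
        from restogen.formats import write_herd_table

        herds = load_nevada_herds()
        assert len(herds) == 28
        assert (herds["status"] == "remnant").sum() == 16
        assert (herds["status"] == "reintroduced").sum() == 12
        write_herd_table(herds, tmp_path / "h.tsv")
        back = read_herd_table(tmp_path / "h.tsv")
        assert list(back["unit"]) == list(herds["unit"])
        assert list(back["n_sources"]) == list(herds["n_sources"])

    def test_merged_units_share_label(self, tmp_path):
        # Black (267) and Muddy (268) Mountains are one population
        assert canonical_unit("267") == "268"
        write_unit_map({"x": "267", "y": "268"}, tmp_path / "u.tsv")
        assert set(read_unit_map(tmp_path / "u.tsv").values()) == {"268"}


class TestCohortGL:
    def test_dimension_validation(self):
        with pytest.raises(ValueError, match="shape"):
            CohortGL(["a"], ["l1", "l2"], {"a": "U"},
                     np.ones((1, 1, 3)), np.ones((1, 2)))

    def test_best_genotype_tie_goes_het(self, tiny_cohort):
        g = tiny_cohort.best_genotypes()
        assert g[0, 1] == -1          # depth 0 is missing
        assert g[1, 0] == 1
        gl = np.array([[[0.5, 0.5, 0.1]]])
        c = CohortGL(["a"], ["l:1"], {"a": "U"}, gl, np.array([[4]]))
        assert c.best_genotypes()[0, 0] == 1

    def test_point_dosage_range(self, two_herd_cohort):
        cohort, _ = two_herd_cohort
        d = cohort.point_dosage()
        assert d.min() >= 0 and d.max() <= 2
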