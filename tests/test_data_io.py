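import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from triocausal.data_io import (
    ExpressionMatrix,
    GenotypeMatrix,
    PhenotypeTable,
    align_samples,
    load_expression,
    load_genotypes,
    load_phenotypes,
    snp_qc,
)
from triocausal.synthetic import CohortSpec, simulate_cohort

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
)


def write_vcf(path, records):
    path.write_text(VCF_HEADER + "".join(records))


class TestVcfLoading:
    def test_gt_calls_map_to_alt_allele_counts(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        write_vcf(vcf, ["1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"])
        g = load_genotypes(vcf, "vcf")
        assert g.sample_ids == ["A", "B", "C"]
        np.testing.assert_array_equal(g.dosages[:, 0], [0.0, 1.0, 2.0])

    def test_missing_call_becomes_missing_entry(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        write_vcf(vcf, ["1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t./.\t1/1\n"])
        g = load_genotypes(vcf, "vcf")
        assert np.isnan(g.dosages[1, 0])
        assert g.dosages[0, 0] == 0.0 and g.dosages[2, 0] == 2.0

    def test_non_biallelic_record_skipped(self, tmp_path, caplog):
        vcf = tmp_path / "t.vcf"
        write_vcf(
            vcf,
            [
                "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n",
                "1\t200\trs2\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n",
            ],
        )
        with caplog.at_level("WARNING"):
            g = load_genotypes(vcf, "vcf")
        assert g.snp_ids == ["rs1"]
        assert any("non-biallelic" in r.message for r in caplog.records)


class TestRoundTrips:
    def test_genotype_tsv_roundtrip_preserves_missing(self, tmp_path, rng):
        dosages = rng.binomial(2, 0.3, (6, 4)).astype(float)
        dosages[2, 1] = np.nan
        meta = pd.DataFrame({"id": [f"rs{j}" for j in range(4)], "chrom": "1",
                             "pos": [10, 20, 30, 40]})
        g = GenotypeMatrix(dosages, meta, [f"i{k}" for k in range(6)])
        g.save(tmp_path / "g.tsv")
        g2 = load_genotypes(tmp_path / "g.tsv", "dosage_tsv")
        np.testing.assert_array_equal(g.dosages, g2.dosages)
        assert g.sample_ids == g2.sample_ids
        assert list(g2.snp_meta["pos"]) == [10, 20, 30, 40]

    def test_expression_and_phenotype_roundtrip(self, tmp_path):
        _, e, p, _ = simulate_cohort(CohortSpec(n=20, n_snps=4, n_probes=10,
                                                module_sizes=(5,), seed=3))
        e.save(tmp_path / "e.tsv")
        p.save(tmp_path / "p.tsv")
        e2 = load_expression(tmp_path / "e.tsv")
        p2 = load_phenotypes(tmp_path / "p.tsv")
        np.testing.assert_allclose(e.values, e2.values, rtol=0, atol=1e-12)
        assert e.probe_ids == e2.probe_ids
        pd.testing.assert_frame_equal(
            p.data.reset_index(drop=True), p2.data.reset_index(drop=True),
            check_dtype=False, atol=1e-12,
        )

    def test_expression_missing_rejected_unless_imputed(self, tmp_path):
        df = pd.DataFrame({"p1": [1.0, np.nan, 3.0], "p2": [0.0, 1.0, 2.0]},
                          index=["a", "b", "c"])
        df.index.name = "individual_id"
        df.to_csv(tmp_path / "e.tsv", sep="\t", na_rep="NA")
        with pytest.raises(ValueError, match="missing"):
            load_expression(tmp_path / "e.tsv")
        e = load_expression(tmp_path / "e.tsv", impute_missing=True)
        assert e.values[1, 0] == pytest.approx(2.0)  # probe mean


class TestSnpQc:
    def test_low_maf_removed_and_counted(self):
        col_keep = np.array([0] * 9 + [1], dtype=float)  # MAF 0.05
        col_mono = np.zeros(10)
        g = GenotypeMatrix(
            np.column_stack([col_keep, col_mono]),
            pd.DataFrame({"id": ["keep", "mono"], "chrom": "1", "pos": [1, 2]}),
            [f"i{k}" for k in range(10)],
        )
        g2, report = snp_qc(g, maf_min=0.01, miss_max=0.05)
        assert g2.snp_ids == ["keep"]
        assert report["removed_maf"] == 1 and report["removed_missingness"] == 0

    def test_planted_filter_counts(self, rng):
        n, m = 200, 50
        dosages = rng.binomial(2, 0.3, (n, m)).astype(float)
        dosages[:, :5] = 0.0  # 5 monomorphic
        for j in range(5, 8):  # 3 SNPs at 10% missingness
            dosages[rng.choice(n, 20, replace=False), j] = np.nan
        meta = pd.DataFrame({"id": [f"rs{j}" for j in range(m)], "chrom": "1",
                             "pos": np.arange(m)})
        g = GenotypeMatrix(dosages, meta, [f"i{k}" for k in range(n)])
        _, report = snp_qc(g, maf_min=0.01, miss_max=0.05)
        assert (report["removed_maf"], report["removed_missingness"]) == (5, 3)

    def test_qc_idempotent(self, rng):
        dosages = rng.binomial(2, rng.uniform(0.0, 0.5, 30), (100, 30)).astype(float)
        g = GenotypeMatrix(
            dosages,
            pd.DataFrame({"id": [f"rs{j}" for j in range(30)], "chrom": "1",
                          "pos": np.arange(30)}),
            [f"i{k}" for k in range(100)],
        )
        g1, _ = snp_qc(g, 0.05, 0.05)
        g2, report2 = snp_qc(g1, 0.05, 0.05)
        assert report2["removed_maf"] == 0 and report2["removed_missingness"] == 0
        np.testing.assert_array_equal(g1.dosages, g2.dosages)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_allele_swap_leaves_maf_and_qc_fate_unchanged(self, seed):
        r = np.random.default_rng(seed)
        dosages = r.binomial(2, r.uniform(0.0, 1.0, 10), (40, 10)).astype(float)
        meta = pd.DataFrame({"id": [f"rs{j}" for j in range(10)], "chrom": "1",
                             "pos": np.arange(10)})
        g = GenotypeMatrix(dosages, meta, [f"i{k}" for k in range(40)])
        g_swap = GenotypeMatrix(2.0 - dosages, meta, g.sample_ids)
        np.testing.assert_allclose(g.maf(), g_swap.maf(), atol=1e-12)
        try:
            _, rep = snp_qc(g, 0.05, 0.05)
            _, rep_swap = snp_qc(g_swap, 0.05, 0.05)
            assert rep["removed_maf"] == rep_swap["removed_maf"]
        except ValueError:
            with pytest.raises(ValueError):
                snp_qc(g_swap, 0.05, 0.05)

    def test_all_removed_raises_empty_panel(self):
        g = GenotypeMatrix(
            np.zeros((10, 2)),
            pd.DataFrame({"id": ["a", "b"], "chrom": "1", "pos": [1, 2]}),
            [f"i{k}" for k in range(10)],
        )
        with pytest.raises(ValueError, match="empty panel"):
            snp_qc(g, 0.01, 0.05)


class TestAlignSamples:
    @staticmethod
    def _inputs(g_ids, e_ids, p_ids, rng):
        g = GenotypeMatrix(
            rng.binomial(2, 0.3, (len(g_ids), 2)).astype(float),
            pd.DataFrame({"id": ["rs1", "rs2"], "chrom": "1", "pos": [1, 2]}),
            list(g_ids),
        )
        e = ExpressionMatrix(rng.normal(size=(len(e_ids), 3)),
                             pd.DataFrame({"probe_id": ["p1", "p2", "p3"]}),
                             list(e_ids))
        y = pd.Series(rng.normal(size=len(p_ids)), index=list(p_ids))
        return g, e, y

    def test_identical_sets_any_order_align(self, rng):
        g, e, y = self._inputs(["a", "b", "c"], ["c", "a", "b"], ["b", "c", "a"], rng)
        g2, e2, y2 = align_samples(g, e, y)
        assert g2.sample_ids == e2.sample_ids == list(y2.index) == ["a", "b", "c"]

    def test_intersection_cardinality_matches_set_oracle(self, rng):
        universe = [f"i{k}" for k in range(700)]
        g_ids = list(rng.choice(universe, 600, replace=False))
        e_ids = list(rng.choice(universe, 638, replace=False))
        p_ids = list(rng.choice(universe, 620, replace=False))
        expected = len(set(g_ids) & set(e_ids) & set(p_ids))
        g, e, y = self._inputs(g_ids, e_ids, p_ids, rng)
        g2, e2, y2 = align_samples(g, e, y)
        assert g2.n_samples == len(y2) == expected

    def test_too_small_intersection_errors(self, rng):
        g, e, y = self._inputs(["a", "b", "c"], ["b", "c", "d"], ["b", "c", "d"], rng)
        with pytest.raises(ValueError, match="shared"):
            align_samples(g, e, y)


def test_phenotype_table_rejects_inconsistent_sex():
    df = pd.DataFrame(
        {
            "individual_id": ["a", "a"],
            "time_point": [0, 1],
            "trait": ["SBP", "SBP"],
            "value": [120.0, 121.0],
            "age": [50.0, 50.0],
            "sex": [0, 1],
            "medication": [0, 0],
            "smoking": [0, 0],
        }
    )
    with pytest.raises(ValueError, match="sex"):
        PhenotypeTable(df)
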