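"""Data model and preprocessing: gene assignment, transforms, filters,
EAF, variant sets and file round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import setrvat as sv
from setrvat import data as d


def _exon_frame():
    return pd.DataFrame({
        "gene_id": ["gA", "gA", "gB"],
        "chrom": ["1", "1", "1"],
        "start": [1000, 2000, 10_000],
        "end": [1199, 2199, 10_499],
        "strand": ["+", "+", "+"],
    })


def _variant_frame(positions, chrom="1"):
    return pd.DataFrame({
        "chrom": [chrom] * len(positions),
        "pos": positions,
        "ref": ["A"] * len(positions),
        "alt": ["T"] * len(positions),
    })


class TestAssignVariantsToGenes:
    @pytest.mark.parametrize(
        "pos,expected_genes",
        [
            (1100, {"gA"}),          # inside an exon, distance 0
            (2199 + 300, {"gA"}),    # exactly at the window boundary: assigned
            (2199 + 301, set()),     # one base past the window: not assigned
            (1000 - 300, {"gA"}),    # boundary on the upstream side
            (1400, {"gA"}),          # intronic, within 300 bp of an exon end
            (10_000, {"gB"}),
            (5000, set()),           # intergenic
        ],
    )
    def test_window_rule(self, pos, expected_genes):
        res = d.assign_variants_to_genes(_variant_frame([pos]), _exon_frame())
        assert set(res["gene_id"]) == expected_genes

    def test_variant_can_map_to_multiple_genes(self):
        exons = _exon_frame()
        exons.loc[2, ["start", "end"]] = [2300, 2500]  # gB exon near gA's
        res = d.assign_variants_to_genes(_variant_frame([2250]), exons)
        assert set(res["gene_id"]) == {"gA", "gB"}

    def test_malformed_interval_raises(self):
        exons = _exon_frame()
        exons.loc[0, ["start", "end"]] = [2000, 1000]
        with pytest.raises(d.DataError):
            d.assign_variants_to_genes(_variant_frame([1500]), exons)


class TestTransformMaf:
    def test_half_gives_two(self):
        assert d.transform_maf(0.5) == pytest.approx(2.0)

    def test_rare_value(self):
        # independent arithmetic: 1/sqrt(0.001 * 0.999)
        assert d.transform_maf(0.001) == pytest.approx(31.63865, abs=1e-4)

    def test_strictly_decreasing_on_half_open_interval(self):
        p = np.linspace(0.001, 0.5, 200)
        t = d.transform_maf(p)
        assert np.all(np.diff(t) < 0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_domain_error(self, bad):
        with pytest.raises(d.DataError):
            d.transform_maf(bad)


class TestQualifyingFilter:
    def _table(self):
        return pd.DataFrame({
            "maf": [0.0005, 0.001, 0.002, 0.01, 0.2],
            "cadd_phred": [10.0] * 5,
        })

    def test_strict_maf_boundary(self):
        kept = d.filter_qualifying_variants(self._table(), maf_cutoff=0.001)
        assert len(kept) == 1  # 0.001 itself is excluded

    def test_count_at_looser_cutoff(self):
        assert len(d.filter_qualifying_variants(self._table(), maf_cutoff=0.01)) == 3

    def test_strict_cadd_boundary(self):
        tab = self._table()
        tab["cadd_phred"] = 5.0
        assert len(d.filter_qualifying_variants(tab, maf_cutoff=0.5)) == 0

    def test_idempotent(self):
        tab = self._table()
        kept = d.filter_qualifying_variants(tab, maf_cutoff=0.01)
        again = d.filter_qualifying_variants(tab.iloc[kept].reset_index(drop=True),
                                             maf_cutoff=0.01)
        assert len(again) == len(kept)


class TestQuantileTransform:
    def test_median_maps_to_zero(self):
        y = np.array([3.0, 1.0, 2.0, 5.0, 4.0])
        out = d.quantile_transform_phenotype(y)
        assert out[np.argsort(y)[2]] == pytest.approx(0.0)

    def test_monotone(self, rng):
        y = rng.gamma(2.0, size=501)
        out = d.quantile_transform_phenotype(y)
        assert np.all(np.diff(out[np.argsort(y)]) >= 0)

    def test_mean_near_zero_untied(self, rng):
        out = d.quantile_transform_phenotype(rng.normal(size=1001))
        assert abs(out.mean()) < 1e-6

    def test_missing_stay_missing(self):
        y = np.array([1.0, np.nan, 2.0, 3.0])
        out = d.quantile_transform_phenotype(y)
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3]]).all()

    def test_ties_get_average_ranks(self):
        out = d.quantile_transform_phenotype(np.array([1.0, 1.0, 2.0, 3.0]))
        assert out[0] == pytest.approx(out[1])
        assert out[0] == pytest.approx(stats.norm.ppf(1.0 / 4.0))

    def test_constant_input_raises(self):
        with pytest.raises(d.DataError):
            d.quantile_transform_phenotype(np.ones(10))


class TestEAF:
    def test_inclusive_boundary(self):
        caf, eaf, ok = d.compute_eaf(np.array([0.001]), 50_000)
        assert (caf, eaf, ok) == (pytest.approx(0.001), pytest.approx(50.0), True)

    def test_additive_fails_below_threshold(self):
        caf, eaf, ok = d.compute_eaf(np.array([0.0004, 0.0006]), 40_000)
        assert caf == pytest.approx(0.001) and eaf == pytest.approx(40.0) and not ok

    def test_binary_uses_case_count(self):
        _, eaf, ok = d.compute_eaf(np.array([0.05]), 900)
        assert eaf == pytest.approx(45.0) and not ok

    def test_empty_gene_fails(self):
        caf, eaf, ok = d.compute_eaf(np.array([]), 1000)
        assert caf == 0.0 and not ok

    def test_linear_in_n(self, rng):
        mafs = rng.uniform(1e-4, 1e-3, size=5)
        _, e1, _ = d.compute_eaf(mafs, 1000)
        _, e2, _ = d.compute_eaf(mafs, 3000)
        assert e2 == pytest.approx(3 * e1)


class TestVariantSets:
    def test_bookkeeping_identity(self, small_cohort):
        _, dataset, truth = small_cohort
        qual = d.filter_qualifying_variants(dataset.variants, 0.01)
        gene = dataset.gene_ids[0]
        sets = d.build_variant_sets(dataset, gene, truth.assignment, qual)
        gene_rows = truth.assignment.loc[
            truth.assignment["gene_id"] == gene, "variant_row"].to_numpy()
        rows = np.intersect1d(gene_rows, qual)
        nnz = (dataset.genotypes.matrix.tocsc()[:, rows] != 0).sum()
        assert sum(len(s) for s in sets) == nnz

    def test_homozygous_carrier_not_duplicated(self, small_cohort):
        _, dataset, truth = small_cohort
        qual = np.arange(len(dataset.variants))
        gene = dataset.gene_ids[0]
        for s in d.build_variant_sets(dataset, gene, truth.assignment, qual):
            assert len(np.unique(s.variant_rows)) == len(s.variant_rows)

    def test_unknown_gene_raises(self, small_cohort):
        _, dataset, truth = small_cohort
        with pytest.raises(d.DataError):
            d.build_variant_sets(dataset, "no_such_gene", truth.assignment,
                                 np.arange(10))


class TestRoundTrips:
    def test_sparse_container(self, small_cohort, tmp_path):
        _, dataset, _ = small_cohort
        path = str(tmp_path / "geno.h5")
        d.write_sparse_genotypes(path, dataset.genotypes)
        back = d.read_sparse_genotypes(path)
        assert (back.matrix != dataset.genotypes.matrix).nnz == 0
        assert np.allclose(back.maf, dataset.genotypes.maf)
        assert np.array_equal(back.individual_ids, dataset.genotypes.individual_ids)

    def test_vcf(self, small_cohort, tmp_path):
        _, dataset, _ = small_cohort
        path = str(tmp_path / "geno.vcf")
        d.write_vcf(path, dataset.genotypes, dataset.variants)
        back, table = d.read_vcf(path, maf=dataset.genotypes.maf)
        assert (back.matrix != dataset.genotypes.matrix).nnz == 0
        assert list(table["pos"]) == list(dataset.variants["pos"])

    def test_cohort_directory(self, small_cohort, tmp_path):
        cfg, dataset, truth = small_cohort
        sv.write_cohort(str(tmp_path / "c"), dataset, truth, cfg)
        back = sv.read_cohort(str(tmp_path / "c"))
        assert (back.genotypes.matrix != dataset.genotypes.matrix).nnz == 0
        pd.testing.assert_frame_equal(back.phenotypes, dataset.phenotypes)
        assert back.annotation_cols == dataset.annotation_cols
        assert back.binary_traits == dataset.binary_traits
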