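"""Hudson F_ST: per-SNP components, gene aggregation, VCF filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from conftest import brute_force_gene_fst
from pbs4.fst import (
    assign_snps_to_genes,
    corrected_gene_fst,
    filter_variants,
    gene_fst,
    gene_pair_fst,
    hudson_fst_snp,
    summaries_to_frame,
)
from pbs4.simulate import (
    QuartetModel,
    allele_summaries_from_dosages,
    genotype_dosages,
    simulate_site_frequencies,
)


class TestHudsonSnp:
    def test_fixed_difference(self):
        num, den = hudson_fst_snp(1.0, 10, 0.0, 10)
        assert num == pytest.approx(1.0) and den == pytest.approx(1.0)

    def test_identical_intermediate_frequencies_negative(self):
        num, den = hudson_fst_snp(0.5, 10, 0.5, 10)
        assert num == pytest.approx(-2 * 0.25 / 9)
        assert den == pytest.approx(0.5)
        assert num / den == pytest.approx(-0.111111, abs=1e-6)

    def test_differentiated_site(self):
        num, den = hudson_fst_snp(0.8, 100, 0.2, 100)
        assert num == pytest.approx(0.36 - 2 * 0.16 / 99)
        assert den == pytest.approx(0.68)

    def test_symmetric_in_populations(self):
        assert hudson_fst_snp(0.8, 40, 0.2, 60) == pytest.approx(
            hudson_fst_snp(0.2, 60, 0.8, 40)
        )

    def test_numerator_never_exceeds_denominator(self):
        rng = np.random.default_rng(0)
        p1, p2 = rng.uniform(0, 1, 500), rng.uniform(0, 1, 500)
        num, den = hudson_fst_snp(p1, 50, p2, 50)
        assert np.all(num <= den + 1e-12)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            hudson_fst_snp(0.5, 1, 0.5, 10)


class TestGeneFst:
    def test_fixed_difference_gene(self):
        assert gene_fst(*hudson_fst_snp(1.0, 10, 0.0, 10)) == 1.0

    def test_negative_ratio_clamped_to_zero(self):
        num, den = hudson_fst_snp(0.5, 10, 0.5, 10)
        assert gene_fst(num, den) == 0.0

    def test_ratio_of_averages_two_snps(self):
        n1, d1 = hudson_fst_snp(0.8, 100, 0.2, 100)
        n2, d2 = hudson_fst_snp(0.5, 10, 0.5, 10)
        # clamping happens only after aggregation, so the negative SNP
        # contributes its raw components
        assert gene_fst(n1 + n2, d1 + d2) == pytest.approx(0.25526, abs=1e-5)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            gene_fst(0.1, 0.0)

    def test_matches_brute_force_on_small_genotypes(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_snps = rng.integers(1, 11)
            da = rng.binomial(2, 0.4, size=(n_snps, rng.integers(5, 21)))
            db = rng.binomial(2, 0.7, size=(n_snps, rng.integers(5, 21)))
            n1, n2 = 2 * da.shape[1], 2 * db.shape[1]
            p1, p2 = da.sum(axis=1) / n1, db.sum(axis=1) / n2
            num, den = hudson_fst_snp(p1, n1, p2, n2)
            keep = den > 0
            if not keep.any():
                continue
            ours = gene_fst(num[keep].sum(), den[keep].sum())
            assert ours == pytest.approx(brute_force_gene_fst(da, db), abs=1e-12)


class TestFilterVariants:
    def write_vcf(self, tmp_path, records):
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4",
        ]
        lines += records
        path = tmp_path / "toy.vcf"
        path.write_text("\n".join(lines) + "\n")
        return str(path)

    @pytest.fixture
    def sample_map(self):
        return {"s1": "P1", "s2": "P1", "s3": "P2", "s4": "P2"}

    def test_filters_indels_monomorphic_keeps_snps(self, tmp_path, sample_map):
        path = self.write_vcf(
            tmp_path,
            [
                "1\t100\t.\tA\tAT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0",  # indel
                "1\t200\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0",  # monomorphic
                "1\t300\t.\tA\tG\t.\tPASS\t.\tGT\t1/1\t1/1\t1/1\t1/1",  # monomorphic alt
                "1\t400\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/1\t0/0\t0/0",  # polymorphic in P1 only
            ],
        )
        out = list(filter_variants(path, sample_map))
        assert [s.pos for s in out] == [400]
        assert out[0].p == {"P1": 0.5, "P2": 0.0}
        assert out[0].n == {"P1": 4, "P2": 4}

    def test_missing_genotypes_shrink_allele_counts(self, tmp_path, sample_map):
        path = self.write_vcf(
            tmp_path,
            ["1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t0/0\t0/1"],
        )
        (s,) = filter_variants(path, sample_map)
        assert s.n == {"P1": 2, "P2": 4}
        assert s.p == {"P1": 0.5, "P2": 0.25}

    def test_maf_filter(self, tmp_path, sample_map):
        path = self.write_vcf(
            tmp_path,
            [
                "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0",  # maf 1/8
                "1\t200\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/1\t0/1\t0/1",  # maf 1/2
            ],
        )
        assert [s.pos for s in filter_variants(path, sample_map, maf=0.2)] == [200]

    def test_unknown_samples_rejected_by_name(self, tmp_path, sample_map):
        path = self.write_vcf(
            tmp_path, ["1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0"]
        )
        with pytest.raises(ValueError, match="s9"):
            list(filter_variants(path, {**sample_map, "s9": "P2"}))


class TestAssignSnpsToGenes:
    ann = pd.DataFrame(
        {
            "chrom": ["1", "1", "1"],
            "start": [100, 150, 500],
            "end": [200, 250, 600],
            "gene": ["gA", "gB", "gC"],
        }
    )

    def snps(self, positions):
        return pd.DataFrame({"chrom": "1", "pos": positions})

    def test_one_based_position_inside_interval(self):
        idx = assign_snps_to_genes(self.snps([150]), self.ann)
        assert list(idx["gA"]) == [0]

    def test_boundary_position_excluded(self):
        # VCF pos 100 (1-based) is 0-based coordinate 99, before start 100
        idx = assign_snps_to_genes(self.snps([100]), self.ann)
        assert "gA" not in idx
        # pos 101 -> coordinate 100 is the first base of the interval
        idx = assign_snps_to_genes(self.snps([101]), self.ann)
        assert list(idx["gA"]) == [0]

    def test_overlapping_genes_both_assigned(self):
        idx = assign_snps_to_genes(self.snps([180]), self.ann)
        assert list(idx["gA"]) == [0] and list(idx["gB"]) == [0]

    def test_intergenic_snp_dropped(self):
        idx = assign_snps_to_genes(self.snps([400]), self.ann)
        assert idx == {}

    def test_degenerate_interval_rejected(self):
        bad = self.ann.copy()
        bad.loc[0, "end"] = 100
        with pytest.raises(ValueError):
            assign_snps_to_genes(self.snps([150]), bad)


class TestGenePairFst:
    def test_drift_ranking_concordant_with_separating_drift(self):
        # mean gene F_ST should rank population pairs by total path drift
        model = QuartetModel(
            branch_F={"W": 0.02, "X": 0.05, "Y": 0.10, "Z": 0.15, "internal": 0.05},
            sample_sizes={p: 30 for p in "WXYZ"},
        )
        rng = np.random.default_rng(42)
        n_genes, spg = 500, 5
        freqs = simulate_site_frequencies(model, n_genes * spg, rng)
        dosages = genotype_dosages(freqs, model.sample_sizes, rng)
        snps = allele_summaries_from_dosages(dosages)
        pos = snps["pos"].to_numpy()
        gene_index = {
            f"g{i}": np.flatnonzero((pos > i * spg) & (pos <= (i + 1) * spg))
            for i in range(n_genes)
        }
        gene_index = {g: ix for g, ix in gene_index.items() if ix.size}
        table = gene_pair_fst(snps, gene_index, list("WXYZ"))
        mean_fst = table.groupby(["pop_a", "pop_b"])["fst"].mean()

        f = model.branch_F
        path = {
            ("W", "X"): f["W"] + f["X"],
            ("W", "Y"): f["W"] + f["internal"] + f["Y"],
            ("W", "Z"): f["W"] + f["internal"] + f["Z"],
            ("X", "Y"): f["X"] + f["internal"] + f["Y"],
            ("X", "Z"): f["X"] + f["internal"] + f["Z"],
            ("Y", "Z"): f["Y"] + f["Z"],
        }
        rho = spearmanr(
            [path[p] for p in mean_fst.index], mean_fst.to_numpy()
        ).statistic
        assert rho > 0.9

    def test_symmetry_of_estimator(self):
        # same data, swapped population roles -> identical gene F_ST
        rng = np.random.default_rng(1)
        da = rng.binomial(2, 0.3, size=(8, 10))
        db = rng.binomial(2, 0.6, size=(8, 10))
        assert brute_force_gene_fst(da, db) == brute_force_gene_fst(db, da)


class TestCorrectedGeneFst:
    def test_neutral_when_b_equals_reference(self):
        assert corrected_gene_fst(0.3, 0.8, 0.8) == pytest.approx(0.3)

    def test_zero_fst_stays_zero(self):
        assert corrected_gene_fst(0.0, 0.4, 0.8) == 0.0

    def test_monotone_in_b(self):
        vals = [corrected_gene_fst(0.3, b, 0.8) for b in (0.2, 0.4, 0.6, 0.8)]
        assert vals == sorted(vals)
        assert vals[-1] == pytest.approx(0.3)

    def test_invalid_b_rejected(self):
        with pytest.raises(ValueError):
            corrected_gene_fst(0.3, 0.0, 0.8)

    def test_pluggable_correction(self):
        assert corrected_gene_fst(0.3, 0.5, 0.8, correction=lambda f, b, r: f) == 0.3
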