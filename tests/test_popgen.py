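import numpy as np
import pandas as pd
import pytest

from oracles import (
    hudson_fst_site_oracle,
    site_pi_oracle,
    wc_fst_site_oracle,
)
from silknet import io, popgen, simulate


def make_panel(population, pos, alt_count, n_alleles, het_count=None, chrom_len=1000):
    pos = np.asarray(pos, dtype=np.int64)
    n = np.asarray(n_alleles, dtype=np.int64)
    ac = np.asarray(alt_count, dtype=np.int64)
    het = np.zeros_like(ac) if het_count is None else np.asarray(het_count)
    return popgen.GenotypePanel(
        population=population,
        samples=[],
        chrom=np.array(["chr1"] * len(pos), dtype=object),
        pos=pos,
        n_alleles=n,
        alt_count=ac,
        het_count=het,
        chrom_lengths={"chr1": chrom_len},
    )


def random_panels(seed, n_sites=60, n1=10, n2=8, chrom_len=3000):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(chrom_len, n_sites, replace=False)) + 1
    g1 = rng.binomial(2, rng.uniform(0.05, 0.95, n_sites)[:, None], (n_sites, n1))
    g2 = rng.binomial(2, rng.uniform(0.05, 0.95, n_sites)[:, None], (n_sites, n2))

    def panel(name, g):
        return popgen.GenotypePanel(
            population=name,
            samples=[],
            chrom=np.array(["chr1"] * n_sites, dtype=object),
            pos=pos,
            n_alleles=np.full(n_sites, 2 * g.shape[1]),
            alt_count=g.sum(axis=1),
            het_count=(g == 1).sum(axis=1),
            chrom_lengths={"chr1": chrom_len},
        )

    return panel("domestic", g1), panel("wild", g2), (g1, g2)


class TestVCFReading:
    def write_fixture(self, tmp_path, extra_lines=()):
        ds = simulate.generate_genotype_panels(
            simulate.GenotypeSimConfig(
                n_pop1=3, n_pop2=2, chrom_length=5000, snp_density=0.01, rng_seed=3
            )
        )
        path = tmp_path / "v.vcf"
        ds.write(tmp_path)
        if extra_lines:
            with open(tmp_path / "variants.vcf", "a") as fh:
                for line in extra_lines:
                    fh.write(line + "\n")
        return ds

    def test_roundtrip_matches_in_memory_panels(self, tmp_path):
        ds = self.write_fixture(tmp_path)
        p1, p2, report = popgen.read_vcf_panels(
            str(tmp_path / "variants.vcf"), ds.popmap
        )
        m1, m2 = ds.panels()
        for got, want in ((p1, m1), (p2, m2)):
            assert np.array_equal(got.pos, want.pos)
            assert np.array_equal(got.alt_count, want.alt_count)
            assert np.array_equal(got.het_count, want.het_count)
            assert np.array_equal(got.n_alleles, want.n_alleles)
        assert report["n_dropped_non_biallelic_snp"] == 0

    def test_allele_counts_match_scripted_text_parse(self, tmp_path):
        ds = self.write_fixture(tmp_path)
        p1, _, _ = popgen.read_vcf_panels(str(tmp_path / "variants.vcf"), ds.popmap)
        # independent line-by-line parse
        alt = []
        with open(tmp_path / "variants.vcf") as fh:
            for line in fh:
                if line.startswith("#"):
                    if line.startswith("#CHROM"):
                        header = line.rstrip("\n").split("\t")
                    continue
                fields = line.rstrip("\n").split("\t")
                count = 0
                for name, val in zip(header[9:], fields[9:]):
                    if ds.popmap[name] == "domestic":
                        count += val.count("1")
                alt.append(count)
        assert np.array_equal(p1.alt_count, np.array(alt))

    def test_triallelic_site_dropped_and_reported(self, tmp_path):
        ds = self.write_fixture(
            tmp_path, ["chr1\t4999\t.\tA\tT,G\t.\tPASS\t.\tGT\t0/1\t0/2\t0/0\t1/1\t0/0"]
        )
        _, _, report = popgen.read_vcf_panels(str(tmp_path / "variants.vcf"), ds.popmap)
        assert report["n_dropped_non_biallelic_snp"] == 1

    def test_all_missing_site_retained_without_alleles(self, tmp_path):
        ds = self.write_fixture(
            tmp_path, ["chr1\t4998\t.\tA\tT\t.\tPASS\t.\tGT\t./.\t./.\t./.\t./.\t./."]
        )
        p1, _, _ = popgen.read_vcf_panels(str(tmp_path / "variants.vcf"), ds.popmap)
        at = np.where(p1.pos == 4998)[0]
        assert len(at) == 1 and p1.n_alleles[at[0]] == 0

    def test_unknown_sample_in_map_raises(self, tmp_path):
        ds = self.write_fixture(tmp_path)
        popmap = dict(ds.popmap)
        popmap["GHOST"] = "domestic"
        with pytest.raises(ValueError, match="GHOST"):
            popgen.read_vcf_panels(str(tmp_path / "variants.vcf"), popmap)


class TestWindowPi:
    def test_empty_window_pi_zero(self):
        panel = make_panel("p", [500], [2], [4], chrom_len=1000)
        out = popgen.window_pi(panel, 100, 100)
        assert out.loc[0, "pi"] == 0.0

    def test_single_snp_two_of_four(self):
        panel = make_panel("p", [50], [2], [4], chrom_len=100)
        out = popgen.window_pi(panel, 100, 100)
        assert out.loc[0, "pi"] == pytest.approx((4 / 6) / 100)
        assert out.loc[0, "pi"] == pytest.approx(site_pi_oracle(2, 4) / 100)

    def test_doubling_window_halves_pi(self):
        panel = make_panel("p", [10, 20], [3, 1], [8, 8], chrom_len=200)
        small = popgen.window_pi(panel, 100, 100)
        big = popgen.window_pi(panel, 200, 200)
        assert big.loc[0, "pi"] == pytest.approx(small.loc[0, "pi"] / 2)

    def test_invariant_to_individual_relabeling(self):
        p1, _, (g1, _) = random_panels(2)
        shuffled = g1[:, ::-1]
        p_shuf = make_panel(
            "p", p1.pos, shuffled.sum(axis=1), np.full(len(p1.pos), 2 * g1.shape[1]),
            (shuffled == 1).sum(axis=1), chrom_len=3000,
        )
        a = popgen.window_pi(p1, 500, 250)
        b = popgen.window_pi(p_shuf, 500, 250)
        assert np.allclose(a["pi"], b["pi"])

    def test_bad_window_step_raises(self):
        panel = make_panel("p", [1], [1], [4])
        with pytest.raises(ValueError):
            popgen.window_pi(panel, 10, 20)

    def test_matches_pairwise_oracle(self):
        p1, _, _ = random_panels(6)
        out = popgen.window_pi(p1, 500, 500)
        expected = np.zeros(len(out))
        for i in range(p1.n_sites):
            w = (p1.pos[i] - 1) // 500
            expected[w] += site_pi_oracle(p1.alt_count[i], p1.n_alleles[i])
        assert np.allclose(out["pi"], expected / 500, atol=1e-10)


class TestWindowFst:
    def test_fixed_difference_gives_one(self):
        p1 = make_panel("d", [50], [10], [10], [0], chrom_len=100)
        p2 = make_panel("w", [50], [0], [10], [0], chrom_len=100)
        out = popgen.window_fst(p1, p2, 100, 100)
        assert out.loc[0, "fst"] == pytest.approx(1.0)

    def test_hudson_negative_not_clamped(self):
        p1 = make_panel("d", [50], [5], [10], chrom_len=100)
        p2 = make_panel("w", [50], [5], [10], chrom_len=100)
        out = popgen.window_fst(p1, p2, 100, 100, estimator="hudson")
        num, den = hudson_fst_site_oracle(10, 0.5, 10, 0.5)
        assert out.loc[0, "fst"] == pytest.approx(num / den)
        assert out.loc[0, "fst"] <= 0

    def test_weir_cockerham_matches_component_oracle_seed13(self):
        p1, p2, _ = random_panels(13)
        out = popgen.window_fst(p1, p2, 500, 250)
        for rec in out.itertuples(index=False):
            num = den = 0.0
            for i in range(p1.n_sites):
                pos0 = p1.pos[i] - 1
                if not (rec.start <= pos0 < rec.start + 500):
                    continue
                n1 = p1.n_alleles[i] / 2
                n2 = p2.n_alleles[i] / 2
                a, b, c = wc_fst_site_oracle(
                    n1, p1.alt_count[i] / p1.n_alleles[i], p1.het_count[i] / n1,
                    n2, p2.alt_count[i] / p2.n_alleles[i], p2.het_count[i] / n2,
                )
                num += a
                den += a + b + c
            if den != 0:
                assert rec.fst == pytest.approx(num / den, abs=1e-10)

    def test_symmetric_under_population_swap(self):
        p1, p2, _ = random_panels(21)
        for est in ("weir_cockerham", "hudson"):
            a = popgen.window_fst(p1, p2, 500, 250, estimator=est)
            b = popgen.window_fst(p2, p1, 500, 250, estimator=est)
            assert np.allclose(a["fst"], b["fst"], equal_nan=True)

    def test_empty_window_is_nan(self):
        p1 = make_panel("d", [50], [3], [10], chrom_len=1000)
        p2 = make_panel("w", [50], [4], [10], chrom_len=1000)
        out = popgen.window_fst(p1, p2, 100, 100)
        assert np.isnan(out.loc[5, "fst"])


class TestSelectionRegions:
    def null_stats(self, n=100):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n) * 100,
                "end": np.arange(n) * 100 + 100,
                "n_snps": 5,
                "pi_d": 0.01,
                "pi_w": 0.01,
                "pi_ratio": 1.0,
                "pi_diff": 0.0,
                "fst": 0.05,
            }
        )

    def test_identical_windows_give_no_outliers(self):
        regions, _ = popgen.call_selection_regions(self.null_stats())
        assert len(regions) == 0

    def test_single_planted_outlier_called_exactly(self):
        stats = self.null_stats(101)
        rng = np.random.default_rng(0)
        stats["pi_ratio"] = 1.0 + rng.normal(0, 0.01, len(stats))
        stats["fst"] = 0.05 + rng.normal(0, 0.005, len(stats))
        stats.loc[50, ["pi_ratio", "fst"]] = [0.01, 0.9]
        regions, _ = popgen.call_selection_regions(stats)
        assert len(regions) == 1
        assert regions.loc[0, "start"] == 5000 and regions.loc[0, "end"] == 5100

    def test_compound_rule_requires_both_tails(self):
        stats = self.null_stats(101)
        rng = np.random.default_rng(1)
        stats["pi_ratio"] = 1.0 + rng.normal(0, 0.01, len(stats))
        stats["fst"] = 0.05 + rng.normal(0, 0.005, len(stats))
        stats.loc[50, "pi_ratio"] = 0.01  # extreme pi only, median Fst
        regions, _ = popgen.call_selection_regions(stats)
        assert not (
            (regions.get("start", pd.Series(dtype=int)) == 5000)
        ).any()

    def test_too_few_windows_raises(self):
        with pytest.raises(ValueError):
            popgen.call_selection_regions(self.null_stats(10))

    def test_quantile_monotonicity(self):
        stats = self.null_stats(100)
        rng = np.random.default_rng(2)
        stats["pi_ratio"] = rng.random(100)
        stats["fst"] = rng.random(100)

        def called(lq, uq):
            regions, _ = popgen.call_selection_regions(stats, lower_q=lq, upper_q=uq)
            return {(r.chrom, r.start, r.end) for r in regions.itertuples()}

        def outliers(lq, uq):
            lo = np.quantile(stats["pi_ratio"], lq)
            hi = np.quantile(stats["fst"], uq)
            return set(stats.index[(stats["pi_ratio"] < lo) & (stats["fst"] > hi)])

        assert outliers(0.05, 0.95) <= outliers(0.20, 0.95)
        assert outliers(0.05, 0.95) <= outliers(0.05, 0.80)

    def test_adjacent_outliers_merged(self):
        stats = self.null_stats(100)
        rng = np.random.default_rng(3)
        stats["pi_ratio"] = 1.0 + rng.normal(0, 0.01, 100)
        stats["fst"] = 0.05 + rng.normal(0, 0.005, 100)
        stats.loc[[40, 41], "pi_ratio"] = 0.01
        stats.loc[[40, 41], "fst"] = 0.9
        regions, _ = popgen.call_selection_regions(stats)
        assert len(regions) == 1
        assert regions.loc[0, "start"] == 4000 and regions.loc[0, "end"] == 4200


class TestOverlapGenes:
    def models(self):
        return pd.DataFrame(
            {
                "gene": ["inside", "abut", "outside"],
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [150, 50, 500],
                "end": [180, 100, 600],
            }
        )

    def regions(self):
        return pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})

    def test_gene_inside_selected(self):
        assert "inside" in popgen.overlap_genes(self.regions(), self.models())

    def test_half_open_abutment_not_selected(self):
        selected = popgen.overlap_genes(self.regions(), self.models())
        assert "abut" not in selected and "outside" not in selected

    def test_planted_subset_selected_exactly(self):
        genes = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(20)],
                "chrom": "chr1",
                "start": np.arange(20) * 100,
                "end": np.arange(20) * 100 + 80,
            }
        )
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [400], "end": [800]})
        assert popgen.overlap_genes(regions, genes) == {"g4", "g5", "g6", "g7"}


class TestWindowStats:
    def test_combined_table_consistent(self):
        p1, p2, _ = random_panels(17)
        stats = popgen.window_stats(p1, p2, 500, 250)
        assert {"pi_d", "pi_w", "pi_ratio", "pi_diff", "fst"} <= set(stats.columns)
        ok = stats["pi_w"] > 0
        assert np.allclose(
            stats.loc[ok, "pi_ratio"], stats.loc[ok, "pi_d"] / stats.loc[ok, "pi_w"]
        )
        assert np.allclose(stats["pi_diff"], stats["pi_d"] - stats["pi_w"])
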