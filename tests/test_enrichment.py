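import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonmeth import enrichment as en


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


class TestAnnotateSites:
    def test_site_inside_interval_gets_its_state(self):
        bed = _bed([("chr1", 0, 100, "Quies"), ("chr1", 100, 200, "EnhA")])
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [150]}, index=["cg1"])
        out = en.annotate_sites(sites, bed)
        assert out.loc["cg1", "state"] == "EnhA"

    def test_boundary_belongs_to_half_open_container(self):
        bed = _bed([("chr1", 0, 100, "A"), ("chr1", 100, 200, "B")])
        # 1-based position 100 -> 0-based 99 -> interval [0, 100)
        sites = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [100, 101]}, index=["x", "y"]
        )
        out = en.annotate_sites(sites, bed)
        assert out.loc["x", "state"] == "A"
        assert out.loc["y", "state"] == "B"

    def test_matches_linear_scan_oracle(self, small_annotation):
        ann, beds, _ = small_annotation
        bed = beds["monocyte"]
        rng = np.random.default_rng(0)
        idx = rng.choice(len(ann), 100, replace=False)
        sites = ann.iloc[idx][["chrom", "pos"]]
        out = en.annotate_sites(sites, bed)
        arr = bed.to_numpy()
        for probe, row in sites.iterrows():
            state = None
            for chrom, start, end, name in arr:
                if chrom == row["chrom"] and start <= row["pos"] - 1 < end:
                    state = name
                    break
            assert out.loc[probe, "state"] == state

    def test_overlapping_segments_warn_first_wins(self):
        bed = _bed([("chr1", 0, 150, "A"), ("chr1", 100, 200, "B")])
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [120]}, index=["cg1"])
        with pytest.warns(UserWarning, match="first interval wins"):
            out = en.annotate_sites(sites, bed)
        assert out.loc["cg1", "state"] == "A"

    def test_orphan_sites_warn_and_get_missing_state(self):
        bed = _bed([("chr1", 0, 100, "A")])
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [500]}, index=["cg1"])
        with pytest.warns(UserWarning, match="outside the segmentation"):
            out = en.annotate_sites(sites, bed)
        assert out.loc["cg1", "state"] is None


class TestComposition:
    def _sites(self, rng, n=2000):
        cats = rng.choice(["EnhA", "Quies", "Tx"], size=n, p=[0.1, 0.6, 0.3])
        return pd.DataFrame(
            {"state": cats}, index=pd.Index([f"cg{i}" for i in range(n)])
        )

    def test_uniform_draw_has_unit_ratios(self):
        rng = np.random.default_rng(1)
        sites = self._sites(rng)
        chosen = sites.index[rng.choice(len(sites), 400, replace=False)]
        out = en.composition_enrichment(chosen, sites, "state")
        assert np.allclose(out["ratio"], 1.0, atol=0.35)
        assert (out["p"] > 0.001).all()

    def test_pure_enhancer_set_fold_is_reciprocal_background(self):
        rng = np.random.default_rng(2)
        sites = self._sites(rng)
        enh = sites.index[sites["state"] == "EnhA"][:50]
        out = en.composition_enrichment(enh, sites, "state").set_index("category")
        assert out.loc["EnhA", "prop_set"] == 1.0
        assert out.loc["EnhA", "ratio"] == pytest.approx(
            1.0 / out.loc["EnhA", "prop_background"]
        )

    def test_proportions_sum_to_one_within_each_group(self):
        rng = np.random.default_rng(3)
        sites = self._sites(rng)
        chosen = sites.index[:300]
        out = en.composition_enrichment(chosen, sites, "state")
        assert out["prop_set"].sum() == pytest.approx(1.0)
        assert out["prop_background"].sum() == pytest.approx(1.0)


class TestRegulatoryDomains:
    CHROMS = {"chr1": 1_000_000}

    def _tss(self, rows):
        return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])

    def test_single_gene_basal_plus_clipped_extension(self):
        tss = self._tss([("g1", "chr1", 500_001, "+")])
        dom = en.build_regulatory_domains(tss, self.CHROMS, max_extension=100_000)
        assert dom.loc["g1", "basal_start"] == 500_000 - 5000
        assert dom.loc["g1", "basal_end"] == 500_000 + 1000
        assert dom.loc["g1", "domain_start"] == 400_000
        assert dom.loc["g1", "domain_end"] == 600_000

    def test_adjacent_genes_stop_at_each_others_basal(self):
        tss = self._tss(
            [("g1", "chr1", 100_001, "+"), ("g2", "chr1", 200_001, "+")]
        )
        dom = en.build_regulatory_domains(tss, self.CHROMS)
        # g1 extends right until g2's basal start; g2 extends left to g1's basal end
        assert dom.loc["g1", "domain_end"] == dom.loc["g2", "basal_start"]
        assert dom.loc["g2", "domain_start"] == dom.loc["g1", "basal_end"]

    def test_gene_near_origin_clipped_at_zero(self):
        tss = self._tss([("g1", "chr1", 2000, "+")])
        dom = en.build_regulatory_domains(tss, self.CHROMS)
        assert dom.loc["g1", "basal_start"] == 0
        assert dom.loc["g1", "domain_start"] == 0

    def test_minus_strand_basal_is_mirrored(self):
        plus = en.build_regulatory_domains(
            self._tss([("g", "chr1", 500_001, "+")]), self.CHROMS
        )
        minus = en.build_regulatory_domains(
            self._tss([("g", "chr1", 500_001, "-")]), self.CHROMS
        )
        # upstream window flips around the TSS
        assert plus.loc["g", "basal_start"] == 495_000
        assert minus.loc["g", "basal_end"] == 505_001
        assert minus.loc["g", "basal_end"] - minus.loc["g", "basal_start"] == (
            plus.loc["g", "basal_end"] - plus.loc["g", "basal_start"]
        )

    def test_coverage_fraction_matches_base_pair_counting(self):
        rng = np.random.default_rng(4)
        chroms = {"chr1": 100_000}
        tss = self._tss(
            [
                (f"g{i}", "chr1", int(p), rng.choice(["+", "-"]))
                for i, p in enumerate(
                    np.sort(rng.choice(np.arange(1000, 99_000), 8, replace=False))
                )
            ]
        )
        dom = en.build_regulatory_domains(tss, chroms, max_extension=10_000)
        frac = en.domain_coverage_fraction(dom, list(dom.index[:4]), chroms)
        # brute-force base-pair union
        covered = np.zeros(100_000, dtype=bool)
        for g in dom.index[:4]:
            covered[dom.loc[g, "domain_start"] : dom.loc[g, "domain_end"]] = True
        assert frac == pytest.approx(covered.mean(), abs=1e-12)
        assert 0.0 <= frac <= 1.0


class TestGreatTests:
    def _setup(self):
        chroms = {"chr1": 100_000}
        tss = pd.DataFrame(
            {
                "gene": ["g1", "g2", "g3", "g4"],
                "chrom": "chr1",
                "tss": [10_001, 40_001, 70_001, 90_001],
                "strand": ["+", "-", "+", "+"],
            }
        )
        domains = en.build_regulatory_domains(tss, chroms, max_extension=5_000)
        return chroms, domains

    def test_whole_genome_term_is_never_significant(self):
        chroms = {"chr1": 100_000}
        tss = pd.DataFrame(
            {"gene": ["g1"], "chrom": "chr1", "tss": [50_001], "strand": ["+"]}
        )
        domains = en.build_regulatory_domains(tss, chroms, max_extension=10**9)
        sites = pd.DataFrame({"chrom": ["chr1"] * 10, "pos": np.arange(1, 11) * 9000})
        out = en.great_binomial(sites, {"t": ["g1"]}, domains, chroms)
        assert out["n_hits"].iloc[0] == 10
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_binomial_tail_matches_direct_summation(self):
        # p_t = 0.5, n = 10, k = 5 -> direct upper-tail summation
        expect = sum(
            stats.binom.pmf(i, 10, 0.5) for i in range(5, 11)
        )
        assert stats.binom.sf(4, 10, 0.5) == pytest.approx(expect, rel=1e-12)
        chroms, domains = self._setup()
        sites = pd.DataFrame(
            {"chrom": ["chr1"] * 6, "pos": [10_500, 10_600, 40_500, 99_000, 99_100, 99_200]}
        )
        out = en.great_binomial(sites, {"t": ["g1", "g2"]}, domains, chroms).iloc[0]
        p_t = en.domain_coverage_fraction(domains, ["g1", "g2"], chroms)
        manual = sum(stats.binom.pmf(i, 6, p_t) for i in range(int(out["n_hits"]), 7))
        assert out["p"] == pytest.approx(manual, rel=1e-9)

    def test_hypergeometric_matches_brute_force_summation(self):
        chroms, domains = self._setup()
        sites = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [10_500, 40_500]})
        out = en.gene_hypergeometric(sites, {"t": ["g1", "g2"]}, domains).iloc[0]
        # hits: g1 and g2 -> N=4, K=2, n=2, k=2
        def hyper_pmf(k, N, K, n):
            from math import comb

            return comb(K, k) * comb(N - K, n - k) / comb(N, n)

        manual = hyper_pmf(2, 4, 2, 2)
        assert out["p"] == pytest.approx(manual, rel=1e-12)

    def test_term_without_hits_is_nonsignificant(self):
        chroms, domains = self._setup()
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [10_500]})  # hits g1 only
        out = en.gene_hypergeometric(sites, {"t": ["g3", "g4"]}, domains).iloc[0]
        assert out["p"] >= 0.5

    def test_planted_term_bias_passes_both_tests(self):
        # a larger gene universe so the gene-level hypergeometric can reach
        # significance when only the planted term's gene is hit
        chroms = {"chr1": 1_250_000}
        rng = np.random.default_rng(5)
        n_genes = 60
        tss = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n_genes)],
                "chrom": "chr1",
                "tss": np.arange(1, n_genes + 1) * 20_000 + 1,
                "strand": "+",
            }
        )
        domains = en.build_regulatory_domains(tss, chroms, max_extension=5_000)
        span = domains.loc["g0"]
        pos = rng.integers(span["domain_start"] + 1, span["domain_end"], 40)
        sites = pd.DataFrame({"chrom": ["chr1"] * 40, "pos": pos})
        terms = {"planted": ["g0"], "other": [f"g{i}" for i in range(30, 40)]}
        out = en.great_enrichment(sites, terms, domains, chroms)
        planted = out[out["term"] == "planted"].iloc[0]
        assert planted["enriched"]
        assert not out[out["term"] == "other"].iloc[0]["enriched"]

    def test_bonferroni_is_min_one_p_times_terms(self):
        chroms, domains = self._setup()
        sites = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [10_500, 10_600, 10_700]})
        terms = {f"t{i}": ["g1"] for i in range(4)}
        out = en.great_binomial(sites, terms, domains, chroms)
        assert np.allclose(
            out["p_bonferroni"], np.minimum(1.0, out["p"] * len(out))
        )


class TestEnhancerSpecificity:
    def _tables(self, shift=0.0, n=200, seed=0):
        rng = np.random.default_rng(seed)
        n_tot = 3 * n
        probes = pd.Index([f"cg{i}" for i in range(n_tot)])
        est = rng.normal(size=n_tot)
        est[:n] += shift * est.std()
        ann = pd.DataFrame(
            {
                "state_hsc": ["EnhA"] * n + ["Quies"] * n + ["Quies"] * n,
                "state_monocyte": ["Quies"] * n + ["EnhA"] * n + ["Quies"] * n,
            },
            index=probes,
        )
        tab = pd.DataFrame({"estimate": est}, index=probes)
        return tab, ann

    def test_identical_groups_show_no_difference(self):
        tab, ann = self._tables(seed=1)
        # same estimates in both groups: copy group A into group B
        tab.iloc[200:400] = tab.iloc[:200].to_numpy()
        out = en.enhancer_specificity_compare(tab, ann, "hsc", "monocyte")
        assert out["mean_a"] == pytest.approx(out["mean_b"])
        assert out["p"] == pytest.approx(1.0)

    def test_one_sd_shift_detected(self):
        tab, ann = self._tables(shift=1.0, seed=2)
        out = en.enhancer_specificity_compare(tab, ann, "hsc", "monocyte")
        assert out["p"] < 1e-10
        assert out["mean_a"] > out["mean_b"]
        lo, hi = out["ci_a"]
        assert lo < out["mean_a"] < hi

    def test_singleton_groups_rejected(self):
        tab, ann = self._tables(seed=3)
        ann.iloc[1:200, 0] = "Quies"  # leave one A-specific probe
        with pytest.raises(ValueError, match="at least two probes"):
            en.enhancer_specificity_compare(tab, ann, "hsc", "monocyte")
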