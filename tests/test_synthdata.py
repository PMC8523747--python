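import numpy as np
import pandas as pd
import pytest

from clonmeth import motifs as mf
from clonmeth import preprocess as pp
from clonmeth import synthdata as sd
from clonmeth.io import write_bed


class TestMakeAnnotation:
    def test_uniform_states_split_evenly(self):
        props = {s: 1 / 15 for s in sd.CHROMHMM_STATES}
        ann, _, _ = sd.make_annotation(3000, state_proportions=props, seed=1)
        counts = ann["state_monocyte"].value_counts(normalize=True)
        for s in sd.CHROMHMM_STATES:
            assert counts.get(s, 0.0) == pytest.approx(1 / 15, abs=0.02)

    def test_zero_enhancer_proportion_gives_zero_enhancer_probes(self):
        props = dict(sd.DEFAULT_STATE_PROPORTIONS)
        props["Quies"] += props.pop("EnhA")
        props["EnhA"] = 0.0
        ann, _, _ = sd.make_annotation(2000, state_proportions=props, seed=2)
        for col in ann.columns:
            if col.startswith("state_"):
                assert (ann[col] != "EnhA").all()

    def test_fixed_seed_gives_byte_identical_bed(self, tmp_path):
        out = []
        for run in range(2):
            _, beds, _ = sd.make_annotation(800, seed=5)
            path = tmp_path / f"run{run}.bed"
            write_bed(beds["monocyte"], path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_bed_tiles_genome_without_overlap(self):
        ann, beds, _ = sd.make_annotation(1000, genome_length=500_000, seed=3)
        for bed in beds.values():
            assert bed["start"].iloc[0] == 0
            assert (bed["start"].iloc[1:].to_numpy() == bed["end"].iloc[:-1].to_numpy()).all()
            assert bed["end"].iloc[-1] == 500_000

    def test_probes_inside_genome_and_consistent_with_bed(self):
        ann, beds, tss = sd.make_annotation(1000, genome_length=400_000, seed=4)
        assert ann["pos"].between(1, 400_000).all()
        assert ann.index.is_unique
        assert set(ann["island_relation"]) <= set(sd.ISLAND_RELATIONS)
        assert tss["tss"].between(1, 400_000).all()
        # manifest state equals the BED interval covering each probe
        bed = beds["B"]
        bounds = bed["start"].to_numpy()
        seg = np.searchsorted(bounds, ann["pos"].to_numpy() - 1, side="right") - 1
        assert (bed["name"].to_numpy()[seg] == ann["state_B"].to_numpy()).all()

    def test_too_many_probes_rejected(self):
        with pytest.raises(ValueError, match="genome capacity"):
            sd.make_annotation(1000, genome_length=500, seed=0)


class TestReferenceProfiles:
    def test_marker_blocks_are_pairwise_discriminative(self, small_annotation):
        ann, _, _ = small_annotation
        refs, markers = sd.make_reference_profiles(ann, seed=6, n_markers_per_type=10)
        assert len(markers) == 10 * len(refs)
        sub = refs.loc[:, markers].to_numpy()
        for i in range(len(refs)):
            for j in range(i + 1, len(refs)):
                assert np.max(np.abs(sub[i] - sub[j])) >= 0.5

    def test_all_betas_in_open_unit_interval(self, small_references):
        refs, _ = small_references
        vals = refs.to_numpy()
        assert (vals > 0).all() and (vals < 1).all()

    def test_duplicate_cell_types_refused(self, small_annotation):
        ann, _, _ = small_annotation
        with pytest.raises(ValueError, match="duplicate cell types"):
            sd.make_reference_profiles(ann, cell_types=("a", "a"), seed=0)

    def test_seeded_reproducibility(self, small_annotation):
        ann, _, _ = small_annotation
        a, _ = sd.make_reference_profiles(ann, seed=11)
        b, _ = sd.make_reference_profiles(ann, seed=11)
        assert np.array_equal(a.to_numpy(), b.to_numpy())


class TestSimulateCohort:
    def test_noise_free_unmutated_equal_mixture(self, small_annotation, small_references):
        ann, _, _ = small_annotation
        refs, _ = small_references
        design = sd.SimDesign(
            seed=20,
            n_pairs=5,
            n_singletons=4,
            n_probes=len(ann),
            mutation_rates={},
            noise_sd=0.0,
            twin_sd=0.0,
            batch_sd=0.0,
        )
        cohort, truth = sd.simulate_cohort(design, ann, refs)
        expected = cohort.cell_fractions.to_numpy() @ refs.to_numpy()
        assert np.allclose(cohort.beta.to_numpy(), expected, atol=1e-9)

    def test_effect_model_shift_is_slope_times_vaf(self, small_annotation, small_references):
        ann, _, _ = small_annotation
        refs, _ = small_references
        design = sd.SimDesign(
            seed=21,
            n_pairs=0,
            n_singletons=40,
            n_probes=len(ann),
            mutation_rates={"TET2": 0.5},
            vaf_distribution=(0.5, 0.5000001),
            effect_model={"TET2": 1.0},
            affected_fraction_by_state={"TET2": {"default": 0.05}},
            noise_sd=0.0,
            twin_sd=0.0,
            batch_sd=0.0,
            monocyte_bump=0.0,
            cell_fraction_concentration=1e9,
        )
        cohort, truth = sd.simulate_cohort(design, ann, refs)
        carriers = cohort.samples["mut_TET2"].astype(bool)
        aff = truth["affected_TET2"].to_numpy()
        m = cohort.m
        shift = m.loc[carriers, aff].mean(axis=0) - m.loc[~carriers, aff].mean(axis=0)
        # effect 1.0 M-units at VAF 0.5 -> expected shift 0.5
        assert np.allclose(shift, 0.5, atol=0.02)
        null_shift = m.loc[carriers, ~aff].mean(axis=0) - m.loc[~carriers, ~aff].mean(axis=0)
        assert np.abs(null_shift).max() < 0.02

    def test_truth_table_flags_exactly_shifted_probes(self, small_cohort):
        cohort, truth, design = small_cohort
        assert (truth.loc[truth["affected_TET2"], "effect_TET2"] != 0).all()
        assert (truth.loc[~truth["affected_TET2"], "effect_TET2"] == 0).all()

    def test_betas_in_open_unit_interval(self, small_cohort):
        cohort, _, _ = small_cohort
        vals = cohort.beta.to_numpy()
        assert (vals > 0).all() and (vals < 1).all()

    def test_twin_pairs_share_metadata_and_correlate(self, small_cohort):
        cohort, _, _ = small_cohort
        meta = cohort.samples
        paired = meta.dropna(subset=["pair"])
        for _, grp in paired.groupby("pair"):
            assert len(grp) == 2
            assert grp["age"].nunique() == 1
            assert grp["sex"].nunique() == 1
        # co-twin residual correlation (pair intercepts) is positive
        m = cohort.m.loc[paired.index].to_numpy()
        m = m - m.mean(axis=0)
        a, b = m[0::2], m[1::2]
        r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert r > 0.05

    def test_monocyte_bump_raises_carrier_fractions(self, small_annotation, small_references):
        ann, _, _ = small_annotation
        refs, _ = small_references
        design = sd.SimDesign(seed=22, n_pairs=60, n_singletons=30, n_probes=len(ann))
        cohort, _ = sd.simulate_cohort(design, ann, refs)
        carriers = cohort.samples["mut_TET2"].astype(bool)
        mono = cohort.cell_fractions["monocyte"]
        assert mono[carriers].mean() - mono[~carriers].mean() > 0.01

    def test_seeded_determinism(self, small_annotation, small_references):
        ann, _, _ = small_annotation
        refs, _ = small_references
        design = sd.SimDesign(seed=23, n_pairs=6, n_singletons=2, n_probes=len(ann))
        c1, t1 = sd.simulate_cohort(design, ann, refs)
        c2, t2 = sd.simulate_cohort(design, ann, refs)
        assert np.array_equal(c1.beta.to_numpy(), c2.beta.to_numpy())
        assert t1.equals(t2)

    def test_invalid_design_parameters_rejected(self):
        with pytest.raises(ValueError, match="VAF support"):
            sd.SimDesign(seed=0, vaf_distribution=(0.0, 0.5))
        with pytest.raises(ValueError, match="mutation rate"):
            sd.SimDesign(seed=0, mutation_rates={"TET2": 1.5})
        with pytest.raises(ValueError, match="affected fraction"):
            sd.SimDesign(
                seed=0, affected_fraction_by_state={"TET2": {"EnhA": 2.0}}
            )

    def test_reference_probe_mismatch_rejected(self, small_annotation, small_references):
        ann, _, _ = small_annotation
        refs, _ = small_references
        design = sd.SimDesign(seed=24, n_pairs=3, n_singletons=0, n_probes=len(ann))
        with pytest.raises(ValueError, match="do not cover"):
            sd.simulate_cohort(design, ann, refs.iloc[:, :100])


class TestCompanionFixtures:
    def test_variant_calls_cover_rules_and_true_mutations(self, small_cohort):
        cohort, _, _ = small_cohort
        calls = sd.simulate_variant_calls(cohort, seed=30)
        kept = pp.filter_variant_calls(calls)
        n_true = int(
            cohort.samples[["mut_TET2", "mut_DNMT3A"]].to_numpy().sum()
        )
        assert (kept["gene"] != "ARTIFACT").sum() == n_true
        assert (calls["gene"] == "ARTIFACT").sum() > 0
        # the germline-band and low-VAF artifacts are filtered out
        dropped = calls.loc[calls.index.difference(kept.index)]
        assert (dropped["gene"] == "ARTIFACT").all()

    def test_raw_array_channels_align(self, small_cohort):
        cohort, _, _ = small_cohort
        raw = sd.simulate_raw_array(cohort, seed=31)
        assert raw.detection_p.shape == cohort.beta.shape
        assert raw.bead_count.to_numpy().min() >= 0


class TestMotifRegions:
    def test_full_planting_gives_exact_consensus_in_every_region(self):
        pwm = mf.pwm_from_consensus("m", "ACGTACGTAC", p=1.0)
        regions, truth = sd.simulate_motif_regions(
            pwm, 50, planted_top_fraction=1.0, consensus_mutation_rate=0.0, seed=40
        )
        assert truth.all()
        assert all("ACGTACGTAC" in s for s in regions.sequences)

    def test_zero_planting_leaves_background_rate(self):
        pwm = mf.pwm_from_consensus("m", "ACGTACGTACGT", p=1.0)
        regions, truth = sd.simulate_motif_regions(
            pwm, 200, planted_top_fraction=0.0, seed=41
        )
        assert not truth.any()
        hits = sum("ACGTACGTACGT" in s for s in regions.sequences)
        # 12-mer exact match by chance: ~200 * 189 / 4^12 (both strands) << 1
        assert hits <= 2

    def test_scores_sorted_descending_and_truth_on_top(self):
        pwm = mf.pwm_from_consensus("m", "ACGTACGT")
        regions, truth = sd.simulate_motif_regions(
            pwm, 100, planted_top_fraction=0.3, seed=42
        )
        assert (np.diff(regions.scores) <= 0).all()
        assert truth[:30].all() and not truth[30:].any()

    def test_planted_fraction_above_one_rejected(self):
        pwm = mf.pwm_from_consensus("m", "ACGT")
        with pytest.raises(ValueError, match="planted_top_fraction"):
            sd.simulate_motif_regions(pwm, 10, planted_top_fraction=1.5, seed=0)

    def test_region_shorter_than_motif_rejected(self):
        pwm = mf.pwm_from_consensus("m", "ACGTACGTACGT")
        with pytest.raises(ValueError, match="shorter than the motif"):
            sd.simulate_motif_regions(pwm, 10, region_length=5, seed=0)
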