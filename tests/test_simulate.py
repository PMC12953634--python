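"""Ground-truth contracts of the synthetic-data generator."""

import numpy as np
import pytest

from resistkit.simulate import (
    FourPLParams,
    ResistanceEventSet,
    SimConfig,
    derive_resistant,
    dilution_series,
    four_pl_poc,
    make_panel_sites,
    sample_sequencing,
    simulate_combination,
    simulate_drug_screen,
    simulate_parental,
    simulate_phospho,
)


class TestParentalClone:
    def test_single_segment_at_base_ploidy_with_requested_snvs(self):
        cfg = SimConfig(seed=1, chromosomes=(("chr1", 10_000_000),), n_somatic_snvs=100)
        clone = simulate_parental(cfg)
        assert clone.segments == [("chr1", 0, 10_000_000, 2)]
        assert len(clone.snvs) == 100
        assert all(v.site_total_copies == 2 for v in clone.snvs)
        assert all(1 <= v.alt_copies <= 2 for v in clone.snvs)

    def test_same_seed_reproduces_identical_clone(self):
        cfg = SimConfig(seed=5, chromosomes=(("chr1", 1_000_000),), n_somatic_snvs=30)
        a, b = simulate_parental(cfg), simulate_parental(cfg)
        assert a.segments == b.segments
        assert [(v.chrom, v.pos, v.alt_copies) for v in a.snvs] == [
            (v.chrom, v.pos, v.alt_copies) for v in b.snvs
        ]

    def test_zero_snvs_gives_empty_list(self):
        cfg = SimConfig(seed=1, chromosomes=(("chr1", 1_000_000),), n_somatic_snvs=0)
        assert simulate_parental(cfg).snvs == []

    def test_invalid_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, chromosomes=())
        with pytest.raises(ValueError):
            SimConfig(seed=1, chromosomes=(("chr1", 0),))


class TestResistantDerivation:
    def test_wgd_doubles_copies_and_preserves_allele_fraction(self):
        cfg = SimConfig(seed=2, chromosomes=(("chr1", 1_000_000),), n_somatic_snvs=40)
        parental = simulate_parental(cfg)
        resistant = derive_resistant(
            parental, ResistanceEventSet(whole_genome_duplication=True), seed=2
        )
        assert all(cn == 4 for _, _, _, cn in resistant.segments)
        for before, after in zip(parental.snvs, resistant.snvs):
            assert after.alt_copies == 2 * before.alt_copies
            assert after.site_total_copies == 2 * before.site_total_copies

    def test_fixation_sets_alt_to_total(self):
        cfg = SimConfig(seed=3, chromosomes=(("chr1", 1_000_000),), n_somatic_snvs=10)
        parental = simulate_parental(cfg)
        resistant = derive_resistant(
            parental, ResistanceEventSet(snv_fixations=10), seed=3
        )
        assert all(v.alt_copies == v.site_total_copies for v in resistant.snvs)

    def test_wgd_then_segmental_loss_hand_trace(self):
        # diploid -> WGD (4 copies) -> delta -1 on the first half => 3 copies there
        cfg = SimConfig(seed=4, chromosomes=(("chr1", 1_000_000),), n_somatic_snvs=200)
        parental = simulate_parental(cfg)
        events = ResistanceEventSet(
            whole_genome_duplication=True,
            segmental_events=(("chr1", 0, 500_000, -1),),
        )
        resistant = derive_resistant(parental, events, seed=4)
        seg = {(s, e): cn for _, s, e, cn in resistant.segments}
        assert seg == {(0, 500_000): 3, (500_000, 1_000_000): 4}
        for v in resistant.snvs:
            assert v.site_total_copies == (3 if v.pos < 500_000 else 4)

    def test_event_to_negative_copies_rejected(self):
        cfg = SimConfig(seed=4, chromosomes=(("chr1", 1_000_000),), n_somatic_snvs=0)
        parental = simulate_parental(cfg)
        with pytest.raises(ValueError):
            derive_resistant(
                parental,
                ResistanceEventSet(segmental_events=(("chr1", 0, 500_000, -3),)),
                seed=0,
            )


class TestSequencingSampler:
    def test_deterministic_given_seed_and_sample_name(self, small_config):
        clone = simulate_parental(small_config)
        panel = make_panel_sites(small_config)
        v1, w1 = sample_sequencing(clone, panel, small_config, "sampleA")
        v2, w2 = sample_sequencing(clone, panel, small_config, "sampleA")
        assert v1.data.equals(v2.data)
        assert w1.data.equals(w2.data)
        v3, _ = sample_sequencing(clone, panel, small_config, "sampleB")
        assert not v3.data.equals(
            v1.data.rename(columns=lambda c: c.replace("sampleA", "sampleB"))
        )

    def test_mean_af_matches_allele_copy_fraction(self):
        # 10,000 sites at alt 1/4, depth 100: empirical mean AF within 0.25 +/- 0.005
        rng_cfg = SimConfig(
            seed=9,
            chromosomes=(("chr1", 50_000_000),),
            base_ploidy=4,
            mean_depth=100.0,
            depth_dispersion=0.0,
            n_het_sites_per_chrom=0,
            n_somatic_snvs=10_000,
        )
        clone = simulate_parental(rng_cfg)
        for v in clone.snvs:
            v.alt_copies = 1
        var, _ = sample_sequencing(clone, [], rng_cfg, "s")
        af = var.data["s.ad_alt"] / var.data["s.dp"]
        assert abs(af.mean() - 0.25) < 0.005

    def test_window_counts_proportional_to_copy_number(self):
        # 1,000 windows; regression of count on local CN recovers slope within 5%
        cfg = SimConfig(
            seed=10,
            chromosomes=(("chr1", 50_000_000),),
            n_het_sites_per_chrom=0,
            n_somatic_snvs=0,
            mean_depth=30.0,
        )
        clone = simulate_parental(cfg)
        events = ResistanceEventSet(
            segmental_events=(("chr1", 0, 25_000_000, 2),)  # CN 4 left, CN 2 right
        )
        altered = derive_resistant(clone, events, seed=10)
        _, win = sample_sequencing(altered, [], cfg, "s")
        df = win.data
        left = df[df["end"] <= 25_000_000]["count"].mean()
        right = df[df["start"] >= 25_000_000]["count"].mean()
        assert left / right == pytest.approx(2.0, rel=0.05)

    def test_tetraploid_af_spectrum_peaks_at_quarter_lattice(self):
        cfg = SimConfig(
            seed=11,
            chromosomes=(("chr1", 20_000_000),),
            base_ploidy=4,
            mean_depth=60.0,
            n_het_sites_per_chrom=6000,
            n_somatic_snvs=0,
        )
        clone = simulate_parental(cfg)
        panel = make_panel_sites(cfg)
        var, _ = sample_sequencing(clone, panel, cfg, "s")
        dp = var.data["s.dp"].to_numpy()
        af = var.data["s.ad_alt"].to_numpy()[dp > 0] / dp[dp > 0]
        hist, edges = np.histogram(af, bins=100, range=(0, 1))
        centers = (edges[:-1] + edges[1:]) / 2
        for peak in (0.25, 0.5, 0.75):
            window = (centers > peak - 0.1) & (centers < peak + 0.1)
            mode = centers[window][np.argmax(hist[window])]
            assert abs(mode - peak) <= 0.02

    def test_zero_copy_region_yields_zero_alt_reads(self):
        cfg = SimConfig(
            seed=12, chromosomes=(("chr1", 1_000_000),), n_het_sites_per_chrom=0,
            n_somatic_snvs=20,
        )
        clone = simulate_parental(cfg)
        wiped = derive_resistant(
            clone,
            ResistanceEventSet(segmental_events=(("chr1", 0, 1_000_000, -2),)),
            seed=0,
        )
        var, _ = sample_sequencing(wiped, [], cfg, "s")
        assert (var.data["s.ad_alt"] == 0).all()


class TestPhosphoSimulator:
    def test_null_matrix_has_no_true_shifts(self):
        _, _, truth = simulate_phospho(100, 3, 0.0, 3.0, seed=0)
        assert truth.sum() == 0

    def test_exact_differential_count(self):
        _, _, truth = simulate_phospho(1000, 3, 0.1, 3.0, seed=0)
        assert truth.sum() == 100

    def test_true_shift_gives_large_t(self, rng):
        from scipy.stats import ttest_ind

        matrix, groups, truth = simulate_phospho(200, 6, 0.5, 3.0, seed=3)
        vals = matrix.to_numpy()
        t = ttest_ind(vals[:, 6:], vals[:, :6], axis=1).statistic
        assert np.mean(np.abs(t[truth]) > 2) > 0.9

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_phospho(10, 3, 1.5, 1.0, seed=0)


class TestDrugSimulators:
    def test_default_dilution_series(self):
        np.testing.assert_allclose(
            dilution_series(100.0, 5.0, 7),
            [100, 20, 4, 0.8, 0.16, 0.032, 0.0064],
        )

    def test_steep_curve_full_viability_below_ic50(self):
        doses = dilution_series(100.0, 5.0, 7)
        poc = four_pl_poc(doses, FourPLParams(ic50_uM=100.0, hill=8.0))
        assert np.all(poc[1:] > 99)  # every dose below the top

    def test_midpoint_exact_on_grid(self):
        tables = simulate_drug_screen(
            {"L": 4.0}, noise_cv=0.0, seed=0
        )  # 4 uM is on the 1:5 series
        row = tables["L"].loc[np.isclose(tables["L"].index.to_numpy(), 4.0)]
        assert np.allclose(row.to_numpy(), 50.0)

    def test_combination_null_and_signal_surfaces(self):
        from resistkit.pharm import bliss_excess

        doses = np.concatenate([[0.0], dilution_series(100, 5, 7)[::-1]])
        a = FourPLParams(ic50_uM=100.0)
        b = FourPLParams(ic50_uM=100.0)
        g0 = simulate_combination(a, b, doses, doses, 0.0, 0.0, 0)
        assert np.abs(bliss_excess(g0)).max() < 1e-9
        g10 = simulate_combination(a, b, doses, doses, 10.0, 0.0, 0)
        excess = bliss_excess(g10)
        assert np.allclose(excess[1:, 1:], 10.0)

    def test_monotherapy_rows_embed_single_agent_curves(self):
        doses = np.concatenate([[0.0], dilution_series(100, 5, 7)[::-1]])
        a = FourPLParams(ic50_uM=2.0)
        b = FourPLParams(ic50_uM=50.0)
        g = simulate_combination(a, b, doses, doses, 0.0, 0.0, 0)
        np.testing.assert_allclose(
            g.iloc[:, 0].to_numpy(), four_pl_poc(doses, a), atol=1e-9
        )
        np.testing.assert_allclose(
            g.iloc[0, :].to_numpy(), four_pl_poc(doses, b), atol=1e-9
        )

    def test_grid_without_zero_dose_rejected(self):
        doses = dilution_series(100, 5, 4)
        with pytest.raises(ValueError):
            simulate_combination(
                FourPLParams(), FourPLParams(), doses, doses, 0.0, 0.0, 0
            )
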