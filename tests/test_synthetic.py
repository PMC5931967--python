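import numpy as np
import pandas as pd
import pytest

from phagelight import architecture as arch
from phagelight.expression import Assay, splicing_ratio
from phagelight.photophysiology import fvfm_series
from phagelight.synthetic import (
    SimulationConfig,
    SyntheticGenomeSpec,
    infection_mean_model,
    simulate_expression_ct,
    simulate_fluorescence,
    simulate_genome,
    simulate_infection,
    simulate_qpcr_plate,
)


class TestConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(eclipse_h=8.0)  # exceeds the HL latent period
        with pytest.raises(ValueError):
            SimulationConfig(qpcr_efficiency=2.5)
        with pytest.raises(ValueError):
            SimulationConfig(noise_cv=-0.1)

    def test_poisson_infected_fraction(self):
        cfg = SimulationConfig()
        expected = 1e8 * (1 - np.exp(-cfg.vbr * cfg.adsorbed_fraction))
        assert cfg.n_infected == pytest.approx(expected, rel=1e-12)


class TestInfection:
    def test_extracellular_conservation_sharp_lysis(self):
        # zero noise, instantaneous lysis: total release = burst * N_inf
        cfg = SimulationConfig(seed=1, noise_cv=0.0, lysis_sd_h=0.0, burst_size=10.0)
        _, extr = infection_mean_model([0.0, 1e6], cfg, "LL")
        assert extr[1] - extr[0] == pytest.approx(10.0 * cfg.n_infected, rel=1e-9)

    def test_one_genome_per_cell_before_eclipse(self, quiet_config):
        intr, _ = infection_mean_model([0.0, 1.0, 2.0], quiet_config, "LL")
        np.testing.assert_allclose(intr, quiet_config.n_infected, rtol=1e-12)

    def test_hl_rise_precedes_ll_by_at_least_4h(self, quiet_config):
        # threshold crossing of the mean extracellular curve at 2x baseline
        t = np.linspace(0, 18, 3601)
        crossings = {}
        for cond in ("HL", "LL"):
            _, extr = infection_mean_model(t, quiet_config, cond)
            threshold = 2 * extr[0]
            crossings[cond] = t[np.argmax(extr >= threshold)]
        assert crossings["LL"] - crossings["HL"] >= 4.0

    def test_burst_size_monotone_in_plateau(self):
        plateaus = []
        for burst in (5.0, 10.0, 20.0):
            cfg = SimulationConfig(seed=1, noise_cv=0.0, burst_size=burst)
            _, extr = infection_mean_model([30.0], cfg, "LL")
            plateaus.append(extr[0])
        assert plateaus[0] < plateaus[1] < plateaus[2]

    def test_dna_kinetics_shared_between_conditions(self, quiet_config):
        # DNA synthesis is condition-independent: intracellular per-cell
        # copies match between HL and LL before HL lysis begins (t << 7.5 h)
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        ll, _ = infection_mean_model(t, quiet_config, "LL")
        hl, _ = infection_mean_model(t, quiet_config, "HL")
        np.testing.assert_allclose(hl, ll, rtol=1e-3)

    def test_seed_reproducibility(self, config):
        a = simulate_infection(config, "HL", 3)
        b = simulate_infection(config, "HL", 3)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_conditions_distinct_noise_streams(self, config):
        a = simulate_infection(config, "HL", 1)
        b = simulate_infection(config, "LL", 1)
        assert not np.allclose(
            a.df["copies_per_ml"].to_numpy() / b.df["copies_per_ml"].to_numpy(), 1.0
        )

    def test_invalid_inputs(self, config):
        with pytest.raises(ValueError):
            simulate_infection(config, "HL", 0)
        with pytest.raises(ValueError):
            simulate_infection(config, "dark", 3)


class TestQpcrPlate:
    def test_ct_closed_form(self):
        cfg = SimulationConfig(seed=1, ct_sd=0.0, qpcr_efficiency=2.0, qpcr_intercept=40.0)
        plate = simulate_qpcr_plate([1e3], cfg)
        ct = plate.unknowns()["ct"].iloc[0]
        assert ct == pytest.approx(40 - 3.321928 * 3, abs=1e-5)

    def test_doubling_copies_drops_ct_by_one(self):
        cfg = SimulationConfig(seed=1, ct_sd=0.0, qpcr_efficiency=2.0)
        plate = simulate_qpcr_plate([1e5, 2e5], cfg)
        cts = plate.unknowns()["ct"].to_numpy()
        assert cts[0] - cts[1] == pytest.approx(1.0, abs=1e-9)

    def test_standard_ladder_structure(self, config):
        plate = simulate_qpcr_plate([1e6], config, n_standards=9)
        std = plate.standards()
        levels = sorted(std["known_copies"].unique(), reverse=True)
        assert levels[0] == pytest.approx(2.5e10)
        assert levels[-1] == pytest.approx(2.5e2)
        np.testing.assert_allclose(np.diff(np.log10(levels)), -1.0, atol=1e-12)
        assert (std.groupby("known_copies").size() == 3).all()

    def test_seeded_plates_identical(self, config):
        a = simulate_qpcr_plate([1e4, 1e6], config)
        b = simulate_qpcr_plate([1e4, 1e6], config)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_nonpositive_copies_rejected(self, config):
        with pytest.raises(ValueError):
            simulate_qpcr_plate([0.0], config)


class TestGenome:
    def test_planted_gap_statistics(self, planted_genome):
        genome, features, _ = planted_genome
        gaps = arch.intergenic_gaps(features, len(genome))
        assert arch.median_intergenic(gaps) == 6
        assert max(g.length for g in gaps) == 232

    def test_planted_inverted_repeat_recovered(self, planted_genome):
        genome, _, plan = planted_genome
        region = genome.sequence[
            plan.long_gap_genome_start - 1 : plan.long_gap_genome_end
        ]
        repeats = arch.find_inverted_repeats(region, min_arm=10)
        assert repeats, "planted repeat not found"
        top = repeats[0]
        assert top.total_paired_length == 36
        assert top.arm_length == 18
        assert top.loop_length == 8
        assert top.mismatches == 0

    def test_unspliced_gene_hits_premature_stop(self, planted_genome):
        genome, features, plan = planted_genome
        row = features.get(plan.designated_gene_id)
        gene = genome.sequence[row["start"] - 1 : row["end"]]
        stops = arch.find_inframe_stops(gene[:-3], frame=0)
        assert stops, "no premature stop in the unspliced transcript"
        assert min(stops) < len(gene) - 3
        intron = gene[plan.intron_start_in_gene - 1 : plan.intron_end_in_gene]
        gene_frame_stops = arch.find_inframe_stops(intron, frame=0)
        assert len(gene_frame_stops) >= 2

    def test_spliced_isoform_is_clean_orf(self, planted_genome):
        genome, features, plan = planted_genome
        row = features.get(plan.designated_gene_id)
        gene = genome.sequence[row["start"] - 1 : row["end"]]
        pair = arch.splice_isoforms(gene, plan.intron_start_in_gene, plan.intron_end_in_gene)
        assert arch.find_inframe_stops(pair.spliced[:-3], frame=0) == []
        assert pair.spliced.endswith("TAA")

    def test_reproducible_and_infeasible_specs(self):
        a = simulate_genome(SyntheticGenomeSpec(), seed=9)
        b = simulate_genome(SyntheticGenomeSpec(), seed=9)
        assert a[0].sequence == b[0].sequence
        pd.testing.assert_frame_equal(a[1].df, b[1].df)
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(long_gap_bp=30)  # cannot host the repeat


class TestExpressionCt:
    def test_inverse_construction_recovers_ratios_exactly(self):
        cfg = SimulationConfig(seed=2, ct_sd=0.0)
        plate = simulate_expression_ct(cfg)
        E = cfg.qpcr_efficiency
        assays = {k: Assay(k, E) for k in ("spliced", "unspliced", "ref16S")}
        spliced = splicing_ratio(
            plate, assays, "vs_reference_16S", target="spliced",
            control_group="LL:late", treated_group="HL:late",
        )
        assert spliced.ratio == pytest.approx(10.6, rel=1e-9)
        unspliced = splicing_ratio(
            plate, assays, "vs_reference_16S", target="unspliced",
            control_group="LL:late", treated_group="HL:late",
        )
        assert unspliced.ratio == pytest.approx(3.37, rel=1e-9)
        early = splicing_ratio(
            plate, assays, "spliced_vs_unspliced", control_group="LL:early"
        )
        assert early.ratio == pytest.approx(2.0, rel=1e-9)

    def test_unit_ratio_gives_equal_cts(self):
        cfg = SimulationConfig(seed=2, ct_sd=0.0)
        plate = simulate_expression_ct(
            cfg,
            true_ratio_spliced_HL_LL=1.0,
            true_ratio_unspliced_HL_LL=1.0,
            true_spliced_to_unspliced_early=1.0,
        )
        df = plate.df
        for assay in ("spliced", "unspliced"):
            hl = df[(df.assay_id == assay) & df.sample_id.str.startswith("HL:late")]["ct"]
            ll = df[(df.assay_id == assay) & df.sample_id.str.startswith("LL:late")]["ct"]
            assert hl.mean() == pytest.approx(ll.mean(), abs=1e-12)

    def test_efficiency_two_three_cycles_is_eightfold(self):
        cfg = SimulationConfig(seed=2, ct_sd=0.0, qpcr_efficiency=2.0)
        plate = simulate_expression_ct(cfg, true_ratio_spliced_HL_LL=8.0)
        df = plate.df
        hl = df[(df.assay_id == "spliced") & df.sample_id.str.startswith("HL:late")]["ct"]
        ll = df[(df.assay_id == "spliced") & df.sample_id.str.startswith("LL:late")]["ct"]
        assert ll.mean() - hl.mean() == pytest.approx(3.0, abs=1e-12)

    def test_nonpositive_ratio_rejected(self, config):
        with pytest.raises(ValueError):
            simulate_expression_ct(config, true_ratio_spliced_HL_LL=0.0)


class TestFluorescence:
    def test_ll_constant_without_noise(self):
        cfg = SimulationConfig(seed=1, fvfm_noise_cv=0.0)
        series = fvfm_series(simulate_fluorescence(cfg, "LL", False, 1))
        assert series["fvfm"].nunique() == 1

    @pytest.mark.parametrize("infected,fraction", [(False, 0.65), (True, 0.90)])
    def test_hl_plateaus_relative_to_ll(self, infected, fraction):
        cfg = SimulationConfig(seed=1, fvfm_noise_cv=0.0)
        hl = fvfm_series(simulate_fluorescence(cfg, "HL", infected, 1))
        ll = fvfm_series(simulate_fluorescence(cfg, "LL", infected, 1))
        late_hl = hl[hl["time_h"] == 18]["fvfm"].iloc[0]
        late_ll = ll[ll["time_h"] == 18]["fvfm"].iloc[0]
        assert late_hl / late_ll == pytest.approx(fraction, abs=0.005)

    def test_infected_recovery_starts_after_delay(self):
        cfg = SimulationConfig(seed=1, fvfm_noise_cv=0.0)
        inf = fvfm_series(simulate_fluorescence(cfg, "HL", True, 1))
        uninf = fvfm_series(simulate_fluorescence(cfg, "HL", False, 1))
        early = inf[inf["time_h"] <= 2]["fvfm"].to_numpy()
        early_u = uninf[uninf["time_h"] <= 2]["fvfm"].to_numpy()
        np.testing.assert_allclose(early, early_u, rtol=1e-9)
        late = inf[inf["time_h"] == 18]["fvfm"].iloc[0]
        assert late > uninf[uninf["time_h"] == 18]["fvfm"].iloc[0]

    def test_seed_reproducibility(self, config):
        a = simulate_fluorescence(config, "HL", True)
        b = simulate_fluorescence(config, "HL", True)
        pd.testing.assert_frame_equal(a.df, b.df)
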