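"""Culture-simulator behaviour: growth mutagenesis, resting-phase LOH, plating."""

import numpy as np
import pytest
from scipy import stats

from lohsim.model import ModelParams
from lohsim.simulate import (
    SimConfig,
    materialize_clone,
    plate_assay,
    record_load_summary,
    run_experiment,
    simulate_growth_phase,
    stationary_day_step,
)
from lohsim._rng import stage_rng


def quiet_config(**kw) -> SimConfig:
    """Small population, no background/leak unless overridden."""
    defaults = dict(
        n_initial=100_000,
        background_freq=0.0,
        leak_reporter_prob=0.0,
        n_plated_selective=10_000_000,
        n_plated_permissive=1_000,
        archive_per_day=5,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestGrowthPhase:
    def test_no_mutagenesis_leaves_everyone_wildtype(self):
        cfg = quiet_config(
            hyper_fraction=0.0,
            model=ModelParams(mu_base=1e-12, mu_hyper=1e-12, r_loh=0.0),
            genome_rate_base=0.0,
            genome_rate_hyper=0.0,
        )
        # per-copy hit probability ~1e-12 over 1e5 cells: effectively zero
        state = simulate_growth_phase(cfg, stage_rng(0, "t"))
        assert state.day == 1
        assert all(c.genotype == "++" for c in state.cohorts)
        assert state.mean_genome_load() == 0.0

    def test_population_doubles_each_division(self):
        cfg = quiet_config(doublings_growth=5, model=ModelParams(r_loh=0.0))
        state = simulate_growth_phase(cfg, stage_rng(0, "t"))
        assert state.total == cfg.n_initial * 2**5

    def test_coincident_mutant_frequency_matches_binomial_oracle(self):
        """With f=0 the double-mutant frequency equals (per-copy hit prob)**2.

        Per-copy per-assay rate is mu; with independent copies the expected
        m/m fraction is mu**2 — checked against pooled Monte-Carlo counts
        within 3 SE of the binomial expectation.  Rates are scaled up so the
        expectation is measurable at desk scale.
        """
        mu = 0.02
        d = 8
        cfg = quiet_config(
            n_initial=200_000,
            hyper_fraction=0.0,
            model=ModelParams(mu_base=mu, mu_hyper=mu, r_loh=0.0),
            doublings_growth=d,
        )
        q = mu / d
        p_copy = 1.0 - (1.0 - q) ** d
        expected_frac = p_copy**2
        total_mm = 0
        total_cells = 0
        for seed in range(5):
            state = simulate_growth_phase(cfg, stage_rng(seed, "growth-oracle"))
            total_mm += sum(c.count for c in state.cohorts if c.genotype == "mm")
            total_cells += state.total
        se = np.sqrt(expected_frac * (1 - expected_frac) * total_cells)
        assert abs(total_mm - expected_frac * total_cells) < 3 * se

    def test_hypermutable_genome_load_accumulates_poisson_means(self):
        cfg = quiet_config(doublings_growth=5, genome_rate_hyper=40.0, hyper_fraction=0.2)
        state = simulate_growth_phase(cfg, stage_rng(0, "t"))
        hyper = [c for c in state.cohorts if c.subpop == "hyper"]
        assert hyper and all(c.het_load == pytest.approx(5 * 40.0) for c in hyper)


class TestStationaryPhase:
    def test_rejects_day_zero_state(self):
        cfg = quiet_config()
        from lohsim.simulate import _initial_state

        state = _initial_state(cfg, stage_rng(0, "t"))
        with pytest.raises(ValueError):
            stationary_day_step(state, cfg, stage_rng(0, "t"))

    def test_no_hazards_nothing_changes(self):
        cfg = quiet_config(loh_hazard=(0.0,) * 5, meiosis_hazard=(0.0,) * 5)
        state = simulate_growth_phase(cfg, stage_rng(1, "t"))
        before = sorted((c.genotype, c.count) for c in state.cohorts)
        for _ in range(5):
            state = stationary_day_step(state, cfg, stage_rng(1, "t"))
        after = sorted((c.genotype, c.count) for c in state.cohorts)
        assert before == after and state.day == 6

    def test_cell_count_conserved_under_loh_and_meiosis(self):
        cfg = quiet_config(hyper_fraction=0.3, loh_hazard=(0.05,) * 5, meiosis_hazard=(0.01,) * 5)
        rng = stage_rng(2, "t")
        state = simulate_growth_phase(cfg, rng)
        n1 = state.total
        for _ in range(5):
            state = stationary_day_step(state, cfg, rng)
        assert state.total == n1

    def test_mean_load_unchanged_by_resting_loh(self):
        """LOH rezygoses but neither adds nor removes expected mutations."""
        cfg = quiet_config(hyper_fraction=0.3, loh_hazard=(0.05,) * 5, meiosis_hazard=(0.0,) * 5)
        rng = stage_rng(2, "t")
        state = simulate_growth_phase(cfg, rng)
        load1 = state.mean_genome_load()
        for _ in range(5):
            state = stationary_day_step(state, cfg, rng)
        assert state.mean_genome_load() == pytest.approx(load1, rel=1e-9)

    def test_loh_converts_heterozygotes_at_the_scheduled_hazard(self):
        cfg = quiet_config(
            n_initial=500_000,
            hyper_fraction=0.0,
            model=ModelParams(mu_base=0.05, mu_hyper=0.05, r_loh=0.0),
            loh_hazard=(0.5, 0.0, 0.0, 0.0, 0.0),
            meiosis_hazard=(0.0,) * 5,
        )
        rng = stage_rng(3, "t")
        state = simulate_growth_phase(cfg, rng)
        het_before = sum(c.count for c in state.cohorts if c.genotype == "+m")
        state = stationary_day_step(state, cfg, rng)
        mm_loh = sum(c.count for c in state.cohorts if c.genotype == "mm" and c.tag == "loh")
        se = np.sqrt(het_before * 0.25)
        assert abs(mm_loh - 0.5 * het_before) < 4 * se


class TestPlating:
    def test_no_resistant_cells_scores_zero(self):
        cfg = quiet_config(
            hyper_fraction=0.0,
            model=ModelParams(mu_base=1e-12, mu_hyper=1e-12, r_loh=0.0),
        )
        state = simulate_growth_phase(cfg, stage_rng(0, "t"))
        res = plate_assay(state, cfg, stage_rng(0, "p"))
        assert res.n_resistant == 0
        assert res.n_viable > 0

    def test_heterozygote_is_not_resistant(self):
        """Recessive reporter: +/m diploids never score on canavanine."""
        cfg = quiet_config(
            hyper_fraction=0.0,
            model=ModelParams(mu_base=0.2, mu_hyper=0.2, r_loh=0.0),
            doublings_growth=1,
        )
        rng = stage_rng(5, "t")
        state = simulate_growth_phase(cfg, rng)
        # keep only the heterozygous cohorts
        state.cohorts = [c for c in state.cohorts if c.genotype == "+m"]
        res = plate_assay(state, cfg, rng)
        assert res.n_resistant == 0

    def test_overloaded_haploids_score_dead_on_both_media(self):
        cfg = quiet_config(
            ploidy=1,
            hyper_fraction=1.0,
            model=ModelParams(mu_base=0.05, mu_hyper=0.05, r_loh=0.0, haploid_tolerance=100),
            genome_rate_hyper=200.0,  # load far beyond tolerance after 8 doublings
        )
        rng = stage_rng(6, "t")
        state = simulate_growth_phase(cfg, rng)
        res = plate_assay(state, cfg, rng, n_permissive=10_000)
        assert res.n_resistant == 0
        assert res.n_viable == 0

    def test_invalid_plated_count_rejected(self):
        cfg = quiet_config()
        state = simulate_growth_phase(cfg, stage_rng(0, "t"))
        with pytest.raises(ValueError):
            plate_assay(state, cfg, stage_rng(0, "p"), n_selective=0)


class TestRunExperiment:
    def test_identical_seeds_identical_counts(self):
        cfg = SimConfig(n_initial=200_000, seed=42)
        t1 = run_experiment(cfg).table
        t2 = run_experiment(SimConfig(n_initial=200_000, seed=42)).table
        assert t1.equals(t2)

    def test_different_seeds_differ(self):
        t1 = run_experiment(SimConfig(seed=1)).table
        t2 = run_experiment(SimConfig(seed=2)).table
        assert not t1["n_resistant"].equals(t2["n_resistant"])

    def test_haploid_frequency_rises_then_stays_flat(self):
        """Across 20 seeds: clear day-0 to day-1 rise, zero slope on days 1-6."""
        day0, day1, rest = [], [], []
        for seed in range(20):
            table = run_experiment(SimConfig(ploidy=1, seed=seed)).table.set_index("day")
            f = table["frequency"]
            day0.append(f[0])
            day1.append(f[1])
            rest.append(f.loc[1:6].values)
        t, p = stats.ttest_rel(day1, day0)
        assert t > 0 and p < 1e-4
        # regression of frequency on day over the resting phase, pooled
        days = np.tile(np.arange(1, 7), len(rest))
        vals = np.concatenate(rest)
        slope = stats.linregress(days, vals)
        assert slope.pvalue > 0.05

    def test_diploid_frequency_keeps_rising_while_resting(self):
        table = run_experiment(SimConfig(seed=7)).table.set_index("day")
        assert table.loc[6, "frequency"] > 10 * table.loc[1, "frequency"]

    def test_resting_diploid_archive_loads_match_growth_only_mutagenesis(self):
        """Archived resistant clones from any day carry the same expected
        load — mutations are acquired only during growth."""
        result = run_experiment(SimConfig(seed=11))
        hyper_loads = {
            day: [r.total_load for r in result.archive if r.day == day and r.subpop == "hyper"]
            for day in (1, 6)
        }
        expected = 8 * 300.0
        for day, loads in hyper_loads.items():
            assert loads, f"no hypermutable clones archived on day {day}"
            assert np.mean(loads) == pytest.approx(expected, rel=0.1)

    def test_meiotic_hazard_puts_haploids_into_the_late_archive(self):
        cfg = SimConfig(
            seed=3,
            model=ModelParams(mu_base=1e-4, mu_hyper=1e-3),
            meiosis_hazard=(0.0, 0.0, 0.0, 0.2, 0.2),
            archive_per_day=40,
        )
        result = run_experiment(cfg)
        haploids = [r for r in result.archive if r.ploidy == 1]
        assert haploids
        assert all(r.day >= 5 for r in haploids)

    def test_day1_diploid_frequency_exceeds_squared_haploid(self):
        """The hypermutable fraction makes diploid recovery far exceed the
        square of the observed haploid frequency."""
        dip = run_experiment(SimConfig(seed=5)).table.set_index("day")
        hap = run_experiment(SimConfig(ploidy=1, seed=5)).table.set_index("day")
        assert dip.loc[1, "frequency"] > 10 * hap.loc[1, "frequency"] ** 2


class TestMaterialisation:
    def test_record_load_summary_reflects_record(self):
        result = run_experiment(SimConfig(seed=1))
        rec = result.archive[0]
        summ = record_load_summary(rec)
        assert summ.total == rec.total_load
        assert summ.day == rec.day

    def test_loh_clone_round_trips_through_the_caller(self, chrv_reference, marker_map):
        """A materialised LOH clone is called positive with the true
        breakpoint inside the reported interval."""
        from lohsim import pipeline

        cfg = SimConfig(seed=9, genome_rate_base=0.1, genome_rate_hyper=60.0)
        result = run_experiment(cfg)
        loh_recs = [r for r in result.archive if r.tag in ("loh", "loh_growth")][:5]
        assert loh_recs
        rng = stage_rng(9, "mat")
        for rec in loh_recs:
            clone = materialize_clone(rec, chrv_reference, cfg, rng)
            is_loh, call = pipeline.call_loh(clone, marker_map)
            assert is_loh
            if call.breakpoint_interval is not None:
                lo, hi = call.breakpoint_interval
                assert lo < rec.breakpoint <= hi

    def test_meiotic_haploid_recovered_as_haploid(self, chrv_reference):
        from lohsim import pipeline

        cfg = SimConfig(
            seed=3,
            model=ModelParams(mu_base=1e-4, mu_hyper=1e-3),
            meiosis_hazard=(0.0, 0.0, 0.0, 0.2, 0.2),
            genome_rate_base=60.0,
            genome_rate_hyper=600.0,
            archive_per_day=40,
        )
        result = run_experiment(cfg)
        rec = next(r for r in result.archive if r.ploidy == 1)
        clone = materialize_clone(rec, chrv_reference, cfg, stage_rng(3, "mat"))
        assert clone.ploidy == 1
        assert pipeline.infer_ploidy(clone) == 1


class TestConfigValidation:
    def test_schedule_length_must_match_days(self):
        with pytest.raises(ValueError):
            SimConfig(loh_hazard=(0.1, 0.1))

    def test_hazards_must_be_probabilities(self):
        with pytest.raises(ValueError):
            SimConfig(loh_hazard=(0.1, 0.1, 0.1, 0.1, 1.5))

    def test_event_split_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(growth_event_split={"gene_conversion": 0.5, "crossover": 0.1, "chrom_loss": 0.05})
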