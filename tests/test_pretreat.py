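"""Pretreatment metrics: residue, recovery, partition, reagent tables."""

import numpy as np
import pytest

import spicpms as sp
from spicpms.errors import UndefinedPartitionError, ValidationError
from spicpms.pretreat import REAGENT_SCENARIOS


def _quant(particulate, dissolved, mean_d=float("nan"), sd_d=float("nan")):
    return sp.QuantResult(
        n_events=0, number_concentration=0.0,
        particulate_mass_concentration=particulate,
        dissolved_concentration=dissolved,
        mean_diameter=mean_d, median_diameter=mean_d, sd_diameter=sd_d,
        size_lod=1.0, diameters=np.array([]))


def _run_scenario(reagent, seed, settings, calib):
    pop = sp.ParticlePopulation.from_mass_concentration(100.0, 100.0)
    pops, dissolved = sp.apply_scenario(pop, 0.0, REAGENT_SCENARIOS[reagent])
    tr = sp.simulate_trace(pops, dissolved, settings, seed=seed)
    return sp.quantify_sample(sp.detect_events(tr), calib,
                              settings.transport_efficiency, settings)


class TestResidueRate:
    def test_no_residue(self):
        assert sp.residue_rate(1.0, 0.0) == 0.0

    def test_alkaline_style_five_percent_residue(self):
        assert sp.residue_rate(1.0, 0.05) == pytest.approx(5.0)

    def test_acid_style_quarter_residue(self):
        assert sp.residue_rate(1.0, 0.25) == pytest.approx(25.0)

    def test_residue_exceeding_initial_mass_rejected(self):
        with pytest.raises(ValidationError):
            sp.residue_rate(1.0, 1.5)


class TestRecoveryRates:
    def test_back_calculation_through_500_fold_dilution(self):
        """0.2 ng/mL measured at 500x against a 100 ng/mL spike -> 100%."""
        rep = sp.recovery_rates(_quant(0.2, 0.0), sp.SamplePrep())
        assert rep.particle_recovery == pytest.approx(100.0)
        assert rep.ion_recovery == 0.0
        assert rep.fda_pass

    def test_fda_interval_is_closed_and_boundary_strict(self):
        prep = sp.SamplePrep()
        assert not sp.recovery_rates(_quant(0.1598, 0.0), prep).fda_pass  # 79.9%
        assert sp.recovery_rates(_quant(0.16, 0.0), prep).fda_pass        # 80.0%
        assert sp.recovery_rates(_quant(0.24, 0.0), prep).fda_pass        # 120.0%
        assert not sp.recovery_rates(_quant(0.2402, 0.0), prep).fda_pass

    def test_zero_spike_rejected(self):
        with pytest.raises(ValidationError):
            sp.SamplePrep(spike_concentration=0.0)

    def test_acid_scenario_is_all_ionic(self, settings, calib):
        q = _run_scenario("HNO3", 3, settings, calib)
        rep = sp.recovery_rates(q, sp.SamplePrep())
        assert rep.particle_recovery < 2.0
        assert rep.ion_recovery == pytest.approx(100.0, rel=0.05)

    def test_recovery_invariant_to_matched_measurement_dilution(self, settings, calib):
        """Same sample at 250x vs 500x dilution: same recovery percentages."""
        pop = sp.ParticlePopulation.from_mass_concentration(100.0, 100.0)
        recs = []
        for f in (500.0, 1000.0):
            vals = []
            for seed in range(6):
                pops, dis = sp.apply_scenario(pop, 0.0,
                                              sp.ScenarioTransform(dilution_factor=f))
                tr = sp.simulate_trace(pops, dis, settings, seed=seed)
                q = sp.quantify_sample(sp.detect_events(tr), calib,
                                       settings.transport_efficiency, settings)
                vals.append(sp.recovery_rates(
                    q, sp.SamplePrep(measurement_dilution=f)).particle_recovery)
            recs.append(np.mean(vals))
        assert recs[0] == pytest.approx(recs[1], rel=0.06)


class TestPartition:
    def test_liver_like_partition(self):
        p = sp.partition(_quant(80.0, 20.0))
        assert p.particle_fraction == pytest.approx(80.0)
        assert p.ion_fraction == pytest.approx(20.0)

    def test_all_ionic_partition(self):
        p = sp.partition(_quant(0.0, 5.0))
        assert (p.particle_fraction, p.ion_fraction) == (0.0, 100.0)

    def test_zero_total_is_undefined(self):
        with pytest.raises(UndefinedPartitionError):
            sp.partition(_quant(0.0, 0.0))

    @pytest.mark.parametrize("particulate,dissolved", [(1e-9, 3.0), (7.7, 0.1),
                                                       (2.5, 2.5)])
    def test_fractions_close_to_100(self, particulate, dissolved):
        p = sp.partition(_quant(particulate, dissolved))
        assert p.particle_fraction + p.ion_fraction == pytest.approx(100.0, abs=1e-9)

    @pytest.mark.parametrize("p_ion", [0.0, 0.2, 0.5, 0.95, 1.0])
    def test_pipeline_recovers_configured_ionized_fraction(self, p_ion, settings, calib):
        """Blood/liver-style partition: end-to-end recovery of the split."""
        pop = sp.ParticlePopulation.from_mass_concentration(100.0, 100.0)
        tf = sp.ScenarioTransform(ionized_fraction=p_ion, dilution_factor=500.0)
        fracs = []
        for seed in range(6):
            pops, dis = sp.apply_scenario(pop, 0.0, tf)
            tr = sp.simulate_trace(pops, dis, settings, seed=seed)
            q = sp.quantify_sample(sp.detect_events(tr), calib,
                                   settings.transport_efficiency, settings)
            fracs.append(sp.partition(q).ion_fraction)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs)) if p_ion not in (0, 1) else 0.3
        assert np.mean(fracs) == pytest.approx(100.0 * p_ion, abs=3 * se + 1.0)


class TestCompareReagents:
    def _report(self, particle=100.0, ion=0.0, d=100.0):
        return sp.RecoveryReport(particle_recovery=particle, ion_recovery=ion,
                                 total_recovery=particle + ion,
                                 fda_pass=80 <= particle + ion <= 120,
                                 mean_diameter=d, sd_diameter=5.0, residue_rate=5.0)

    def test_single_replicate_has_nan_sd(self):
        df = sp.compare_reagents({"NaOH": [self._report()]})
        assert df.loc["NaOH", ("particle_recovery", "mean")] == 100.0
        assert np.isnan(df.loc["NaOH", ("particle_recovery", "sd")])
        assert df.loc["NaOH", ("n", "")] == 1

    def test_identical_replicates_have_zero_sd(self):
        df = sp.compare_reagents({"TMAH": [self._report()] * 3})
        assert df.loc["TMAH", ("particle_recovery", "sd")] == 0.0

    def test_rows_sorted_by_reagent_name(self):
        df = sp.compare_reagents({"HCl": [self._report()], "NaOH": [self._report()]})
        assert list(df.index) == ["HCl", "NaOH"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            sp.compare_reagents({})

    def test_simulated_alkaline_replicates_recover_spike_and_size(self, settings, calib):
        """Triplicate no-transform scenario: ~100% particulate, ~100 nm."""
        reports = []
        for seed in (11, 12, 13):
            q = _run_scenario("NaOH", seed, settings, calib)
            reports.append(sp.recovery_rates(q, sp.SamplePrep(), 5.0))
        df = sp.compare_reagents({"NaOH": reports})
        assert df.loc["NaOH", ("particle_recovery", "mean")] == pytest.approx(100, rel=0.1)
        assert df.loc["NaOH", ("mean_diameter", "mean")] == pytest.approx(100, rel=0.05)

    def test_aggregating_scenario_broadens_and_grows_diameters(self, settings, calib):
        """Dimer-forming scenario: bigger mean diameter, inflated SD."""
        q_agg = _run_scenario("TMAH", 7, settings, calib)
        q_ref = _run_scenario("NaOH", 7, settings, calib)
        assert q_agg.mean_diameter > q_ref.mean_diameter
        assert q_agg.mean_diameter == pytest.approx(120.0, rel=0.05)
        assert q_agg.sd_diameter > 1.5 * q_ref.sd_diameter
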