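"""Simulator: trace shape, Poisson occupancy, scenario transforms."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

import spicpms as sp
from spicpms.errors import ValidationError

from conftest import population_for_events


class TestSimulateTrace:
    def test_trace_has_floor_duration_over_dwell_windows(self, settings):
        pop = sp.ParticlePopulation(mean_diameter=100.0, number_concentration=0.0)
        trace = sp.simulate_trace(pop, 0.0, settings, seed=0)
        assert len(trace) == 3000

    def test_nothing_to_detect_gives_all_zero_trace(self, settings):
        pop = sp.ParticlePopulation(mean_diameter=100.0, number_concentration=0.0)
        trace = sp.simulate_trace(pop, 0.0, settings, seed=3)
        assert np.all(trace.intensities == 0)

    def test_identical_seed_gives_bit_identical_trace(self, settings, make_population):
        pop = make_population(n_events=200)
        t1 = sp.simulate_trace(pop, 1.0, settings, seed=42)
        t2 = sp.simulate_trace(pop, 1.0, settings, seed=42)
        assert np.array_equal(t1.intensities, t2.intensities)
        t3 = sp.simulate_trace(pop, 1.0, settings, seed=43)
        assert not np.array_equal(t1.intensities, t3.intensities)

    def test_background_mean_matches_calibration_line(self):
        s = sp.AcquisitionSettings(calib_intercept=2.0)
        pop = sp.ParticlePopulation(mean_diameter=100.0, number_concentration=0.0)
        trace = sp.simulate_trace(pop, 5.0, s, seed=5)
        expected = s.calib_intercept + s.calib_slope * 5.0
        # Poisson mean over 3000 windows: SE = sqrt(mu/3000)
        assert trace.intensities.mean() == pytest.approx(
            expected, abs=4 * np.sqrt(expected / 3000))

    def test_unphysical_arrival_rate_rejected(self, settings):
        pop = population_for_events(settings, 100.0, n_events=3000 * 11)
        with pytest.raises(ValidationError):
            sp.simulate_trace(pop, 0.0, settings, seed=0)

    def test_negative_dissolved_rejected(self, settings, make_population):
        with pytest.raises(ValidationError):
            sp.simulate_trace(make_population(), -1.0, settings, seed=0)

    def test_occupancy_matches_poisson_closed_form(self, settings):
        """Fraction of occupied windows ~= 1 - exp(-lambda) across lambdas."""
        for lam in (0.01, 0.1, 0.5, 1.0):
            pop = population_for_events(settings, 100.0, n_events=lam * 3000)
            occ = []
            for seed in range(30):
                tr = sp.simulate_trace(pop, 0.0, settings, seed=seed)
                occ.append(tr.truth.n_occupied_windows)
            expected = sp.expected_detected(lam * 3000, 3000)
            se = np.std(occ, ddof=1) / np.sqrt(len(occ))
            assert np.mean(occ) == pytest.approx(expected, abs=3.5 * max(se, 1.0))

    def test_occupied_windows_547_true_events_near_500(self, settings):
        """3000 windows, 547 true arrivals -> ~500 occupied on average."""
        pop = population_for_events(settings, 100.0, n_events=547)
        occ = [sp.simulate_trace(pop, 0.0, settings, seed=s).truth.n_occupied_windows
               for s in range(200)]
        # closed form: 3000*(1 - exp(-547/3000)) = 500.2
        assert np.mean(occ) == pytest.approx(500.2, rel=0.02)

    def test_low_rate_arrivals_are_linear_in_concentration(self, settings):
        pop = population_for_events(settings, 100.0, n_events=40)
        n = [sp.simulate_trace(pop, 0.0, settings, seed=s).truth.n_particles
             for s in range(50)]
        se = np.sqrt(40 / 50)
        assert np.mean(n) == pytest.approx(40, abs=3 * se)


class TestApplyScenario:
    def test_full_ionization_dissolves_everything(self):
        pop = sp.ParticlePopulation.from_mass_concentration(100.0, 100.0)
        pops, dissolved = sp.apply_scenario(pop, 0.0,
                                            sp.ScenarioTransform(ionized_fraction=1.0))
        assert pops == ()
        assert dissolved == pytest.approx(100.0, rel=1e-9)

    def test_identity_transform_is_identity(self):
        pop = sp.ParticlePopulation.from_mass_concentration(50.0, 70.0)
        pops, dissolved = sp.apply_scenario(pop, 2.0, sp.ScenarioTransform())
        assert len(pops) == 1
        assert pops[0] == pop
        assert dissolved == 2.0

    def test_dimer_mixture_number_weighted_mean_diameter(self):
        """50% of 100 nm monomers dimerize: mean = (0.5*100+0.25*126)/0.75."""
        pop = sp.ParticlePopulation(mean_diameter=100.0, number_concentration=1e5,
                                    cv_diameter=0.0)
        pops, _ = sp.apply_scenario(
            pop, 0.0, sp.ScenarioTransform(aggregated_fraction=0.5, aggregate_order=2))
        n = np.array([p.number_concentration for p in pops])
        d = np.array([p.mean_diameter for p in pops])
        assert d[1] == pytest.approx(100.0 * 2 ** (1 / 3), rel=1e-12)
        mean_d = np.sum(n * d) / np.sum(n)
        assert mean_d == pytest.approx(108.66, abs=0.01)

    @given(ion=st.floats(0, 1), agg=st.floats(0, 1), k=st.integers(2, 5),
           dil=st.floats(1, 1000))
    @hsettings(max_examples=60, deadline=None)
    def test_mass_conservation_before_dilution(self, ion, agg, k, dil):
        if ion + agg > 1:
            agg = 1 - ion
        pop = sp.ParticlePopulation.from_mass_concentration(80.0, 100.0)
        tf = sp.ScenarioTransform(ionized_fraction=ion, aggregated_fraction=agg,
                                  aggregate_order=k, dilution_factor=dil)
        pops, dissolved = sp.apply_scenario(pop, 5.0, tf)
        total_after = (sum(p.mass_concentration for p in pops) + dissolved) * dil
        assert total_after == pytest.approx(85.0, rel=1e-9)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValidationError):
            sp.ScenarioTransform(ionized_fraction=0.7, aggregated_fraction=0.7)
        with pytest.raises(ValidationError):
            sp.ScenarioTransform(aggregate_order=1)


class TestDilutionSeries:
    def test_ladder_shape_and_concentration_grid(self, settings):
        stock = sp.ParticlePopulation(mean_diameter=100.0, number_concentration=0.0)
        traces = sp.simulate_dilution_series(
            stock, [2000, 800, 700, 600], n_steps=10, step_factor=10 ** (1 / 3),
            settings=settings, seed=1)
        assert len(traces) == 40
        # trace (i, j) concentration = start / factor^(j-1)
        c0 = traces[0].truth.particulate_mass_concentration
        c1 = traces[1].truth.particulate_mass_concentration
        assert c0 / c1 == pytest.approx(10 ** (1 / 3), rel=1e-9)
        # last series bottoms out 3 decades below 600 pg/mL ~= 600 fg/mL
        assert traces[-1].truth.particulate_mass_concentration * 1e3 == pytest.approx(
            0.6, rel=1e-9)

    def test_single_step_keeps_start_concentrations(self, settings):
        stock = sp.ParticlePopulation(mean_diameter=100.0, number_concentration=0.0)
        traces = sp.simulate_dilution_series(stock, [100.0, 50.0], 1, 2.0,
                                             settings, seed=2)
        concs = [t.truth.particulate_mass_concentration * 1e3 for t in traces]
        assert concs == pytest.approx([100.0, 50.0], rel=1e-9)

    def test_mass_to_number_conversion_for_100nm_silver(self, settings):
        """2000 pg/mL of ~100 nm Ag -> ~3.64e5 particles/mL."""
        stock = sp.ParticlePopulation(mean_diameter=100.0, number_concentration=0.0,
                                      cv_diameter=0.0)
        pop = sp.ParticlePopulation.from_mass_concentration(2.0e-3 * 1e3, 100.0,
                                                            cv_diameter=0.0)
        # 100 nm Ag sphere: (pi/6)*10.49*(1e-5 cm)^3 = 5.493e-15 g = 5.493 fg
        assert pop.number_concentration == pytest.approx(3.64e5, rel=0.01)
        del stock

    def test_empty_start_list_rejected(self, settings):
        stock = sp.ParticlePopulation(mean_diameter=100.0, number_concentration=0.0)
        with pytest.raises(ValidationError):
            sp.simulate_dilution_series(stock, [], 10, 2.0, settings, seed=0)
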