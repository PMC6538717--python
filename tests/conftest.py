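import numpy as np
import pytest

import spicpms as sp


@pytest.fixture
def settings():
    """Default acquisition: 10 ms dwell, 30 s, 3000 windows."""
    return sp.AcquisitionSettings()


@pytest.fixture
def calib(settings):
    """Ionic calibration consistent with the simulator settings."""
    return sp.IonicCalibration(slope=settings.calib_slope,
                               intercept=settings.calib_intercept, r_squared=1.0)


@pytest.fixture
def eta(settings):
    return sp.TransportEfficiency(eta=settings.transport_efficiency,
                                  method="configured")


def population_for_events(settings, mean_diameter, n_events, cv=0.05):
    """Population whose expected event count per acquisition is n_events."""
    n_conc = n_events / (settings.transport_efficiency * settings.sample_flow
                         * settings.duration)
    return sp.ParticlePopulation(mean_diameter=mean_diameter,
                                 number_concentration=n_conc, cv_diameter=cv)


@pytest.fixture
def make_population(settings):
    def _make(mean_diameter=100.0, n_events=300, cv=0.05):
        return population_for_events(settings, mean_diameter, n_events, cv)
    return _make


def run_pipeline(trace, calib, settings):
    """simulate -> detect -> quantify convenience for tests."""
    detection = sp.detect_events(trace)
    return sp.quantify_sample(detection, calib, settings.transport_efficiency,
                              settings)
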