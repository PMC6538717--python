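"""Particle/ion partition of silver in blood- and liver-like samples.

Emulates the physical state of intravenously administered 100 nm
silver nanoparticles: a liver-like scenario where ~20% of the silver
has ionized, and a blood-like scenario where ~95% has. The pipeline
measures each sample and reports the particle/ion split of the total
silver.
"""

import spicpms as sp

settings = sp.AcquisitionSettings()
calib = sp.IonicCalibration(slope=settings.calib_slope,
                            intercept=settings.calib_intercept, r_squared=1.0)

scenarios = {
    "liver-like (20% ionized)": sp.ScenarioTransform(ionized_fraction=0.20,
                                                     dilution_factor=500.0),
    "blood-like (95% ionized)": sp.ScenarioTransform(ionized_fraction=0.95,
                                                     dilution_factor=500.0),
}
sample = sp.ParticlePopulation.from_mass_concentration(100.0, 100.0)

for name, transform in scenarios.items():
    pops, dissolved = sp.apply_scenario(sample, 0.0, transform)
    trace = sp.simulate_trace(pops, dissolved, settings, seed=5)
    q = sp.quantify_sample(sp.detect_events(trace), calib,
                           settings.transport_efficiency, settings)
    p = sp.partition(q)
    print(f"{name}: particle {p.particle_fraction:5.1f}%  "
          f"ion {p.ion_fraction:5.1f}%  total {p.total_ag * 500:6.1f} ng/mL")

# The measured splits recover the configured ionized fractions: ~80%
# particulate in the liver-like sample, ~95% ionic in the blood-like
# sample. Plain (non-single-particle) ICP-MS would report only the
# totals and could not distinguish the two states.
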