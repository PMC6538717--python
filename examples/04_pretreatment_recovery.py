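"""Spike-recovery comparison of tissue-solubilization reagents.

A liver-homogenate surrogate spiked with 100 ng/mL of 100 nm silver
particles is run through phenomenological pretreatment scenarios
(alkaline reagents preserve particles, acids ionize them, proteinase K
partially ionizes, TMAH aggregates), diluted 500-fold, measured, and
back-calculated against the spike. Triplicates, mean +/- SD.
"""

import numpy as np

import spicpms as sp
from spicpms.pretreat import REAGENT_SCENARIOS, TYPICAL_RESIDUE_RATES

settings = sp.AcquisitionSettings()
calib = sp.IonicCalibration(slope=settings.calib_slope,
                            intercept=settings.calib_intercept, r_squared=1.0)
spiked = sp.ParticlePopulation.from_mass_concentration(100.0, 100.0)
prep = sp.SamplePrep()  # 100 ng/mL spike, 500-fold measurement dilution

reports: dict[str, list[sp.RecoveryReport]] = {}
rng = np.random.default_rng(2)
for reagent, transform in REAGENT_SCENARIOS.items():
    reps = []
    for _ in range(3):
        pops, dissolved = sp.apply_scenario(spiked, 0.0, transform)
        trace = sp.simulate_trace(pops, dissolved, settings,
                                  seed=int(rng.integers(2**31 - 1)))
        q = sp.quantify_sample(sp.detect_events(trace), calib,
                               settings.transport_efficiency, settings)
        reps.append(sp.recovery_rates(q, prep, TYPICAL_RESIDUE_RATES[reagent]))
    reports[reagent] = reps

table = sp.compare_reagents(reports)
with np.printoptions(precision=1):
    print(table.round(1).to_string())

# Alkaline scenarios recover ~100% of the spike as particles with the
# original ~100 nm mean diameter (TMAH with an aggregation-shifted,
# broadened distribution); acids recover it as ions. Together with the
# residue rate (tissue solubility) this reproduces the reasoning that
# ranks NaOH as the optimal pretreatment.
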