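# spicpms

Single-particle ICP-MS (sp-ICP-MS) signal processing for nanoparticle
analysis in liquids and solubilized tissues: trace simulation with
known ground truth, particle-event detection over an ionic background,
calibration, size/concentration quantification, counting-linearity
analysis, and pretreatment-evaluation metrics.

**Who it is for.** Analysts and method developers who need to (a)
process time-resolved sp-ICP-MS traces into particle size
distributions, number/mass concentrations and dissolved fractions,
(b) determine the coincidence-limited maximum particle count of an
acquisition, and (c) evaluate tissue-pretreatment protocols by spike
recovery and particle/ion partition — plus a simulator to validate all
of it against known truth.

## The model in brief

sp-ICP-MS reads one intensity per dwell window (10 ms here; 30 s →
3000 windows). Dissolved analyte gives a steady Poisson background
`b + s·C` (s: counts/dwell per ng/mL); each particle reaching the
plasma in a window adds `m·s/(η·Q·τ)` counts on average (m: analyte
mass, η: transport efficiency, Q: sample flow, τ: dwell). Detection is
iterative mean + kσ thresholding; event mass inverts the flux
equivalence `m = I_net·(η·Q·τ)/s`, and the spherical-equivalent
diameter follows from `m = (π/6)·ρ·d³`. With Poisson arrivals at rate
λ per window, detected events track the occupied-window count
`n·(1 − e^(−λ))`; above λ ≈ 0.18 (≈500 events per 30 s) coincidence
breaks counting linearity and inflates sizes — the critical count that
the dilution-series procedure (`spicpms.linearity`) measures.

## Worked example

```python
import spicpms as sp

settings = sp.AcquisitionSettings()          # 10 ms dwell, 30 s, eta=0.05
calib = sp.IonicCalibration(slope=settings.calib_slope,
                            intercept=settings.calib_intercept, r_squared=1.0)

# 100 nm silver suspension, ~300 expected events per acquisition
n_conc = 300 / (settings.transport_efficiency * settings.sample_flow
                * settings.duration)
pop = sp.ParticlePopulation(mean_diameter=100.0, number_concentration=n_conc)

trace = sp.simulate_trace(pop, dissolved_conc=0.5, settings=settings, seed=1)
q = sp.quantify_sample(sp.detect_events(trace), calib,
                       settings.transport_efficiency, settings)
print(f"{q.n_events} events, mean {q.mean_diameter:.1f} nm, "
      f"particulate {q.particulate_mass_concentration:.3f} ng/mL, "
      f"dissolved {q.dissolved_concentration:.3f} ng/mL")
```

prints

```
296 events, mean 100.9 nm, particulate 0.200 ng/mL, dissolved 0.499 ng/mL
```

— 296 of the 312 delivered particles were detected (a few windows
held two particles), the recovered mean diameter matches the 100 nm
truth to ~1%, and the 0.5 ng/mL dissolved spike is returned by the
background mean through the ionic calibration.

The `examples/` directory has one narrative script per capability:
simulation + detection, calibration + sizing, the critical-count
procedure, pretreatment spike recovery, and in-vivo-like particle/ion
partition. A thin CLI wraps the same pipeline
(`spicpms simulate|detect|quantify|linearity|pretreat|calibrate`).

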