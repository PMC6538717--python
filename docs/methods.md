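# Methods

## Scope and model

`spicpms` implements the data-processing chain of single-particle
ICP-MS (sp-ICP-MS) for nanoparticle suspensions and solubilized tissue
samples, together with a synthetic-signal generator that stands in for
the instrument (and for animal-derived samples) with known ground
truth. The physical picture is the standard one: the nebulized sample
reaches the plasma with transport efficiency η; dissolved analyte
produces a steady ionic background; each nanoparticle that arrives
within one dwell window produces a burst of counts proportional to its
analyte mass. Particle detection is a window-occupancy problem — with
Poisson arrivals at per-window rate

    λ = N · Q · η · τ            (N: particles/mL, Q: mL/s flow, τ: dwell)

the expected number of occupied (hence detectable) windows out of n is

    E[detected] = n · (1 − e^(−λ)),

and windows holding two or more particles are read as one
correspondingly larger particle (coincidence), which undercounts
particles and overestimates sizes as concentration rises.

## Signal simulation

Per dwell window the simulator draws

* background counts ~ Poisson(b + s·C_diss), where s is the ionic
  sensitivity (counts per dwell per ng/mL), b the blank level
  (default 0, i.e. blank-corrected counts) and C_diss the dissolved
  concentration;
* particle arrivals ~ Poisson(λ); each particle draws a lognormal
  diameter (arithmetic mean d̄, coefficient of variation cv), converts
  to analyte mass m = (π/6)·ρ·d³·f (ρ density, f analyte mass
  fraction), and contributes Poisson(m·s/(η·Q·τ)) counts, so that a
  given mass flux yields the same counts whether it arrives dissolved
  or particulate. Contributions within a window sum.

All randomness flows through one `numpy` Generator per trace; identical
inputs and seed give bit-identical traces. Events are contained in a
single window (at 10 ms dwell an ion-cloud transit of ~0.5 ms never
straddles two windows in practice); a `merge_adjacent` detection toggle
exists for short-dwell users but is off by default. Counts are pure
shot noise; flicker/electronic noise is not modeled.

Key defaults (all explicit configuration):

| parameter | default | note |
|---|---|---|
| dwell time τ | 10 ms | 30 s acquisition → 3000 windows |
| sample flow Q | 0.346 mL/min | illustrative; instrument-specific |
| transport efficiency η | 0.05 | illustrative; calibrate per run |
| ionic sensitivity s | 1000 counts/dwell/(ng/mL) | illustrative |
| blank b | 0 counts/dwell | blank-corrected counts |
| Ag density ρ | 10.49 g/cm³ | pure-element particles, f = 1 |
| diameter cv | 0.05 | monodisperse commercial stocks |

Results that depend only on the product η·Q (masses, concentrations)
are invariant to the split between the two.

### Pretreatment scenarios

Reagent action is modeled phenomenologically on the (population,
dissolved) pair, not chemically: an ionized fraction p of the particles
moves its mass to the dissolved pool (implemented as removal of a
number fraction p, which conserves mass exactly); an aggregated
fraction a is replaced by a/k k-mers of diameter d·k^(1/3) (mass
conservation); everything is then diluted. Presets: alkaline reagents
(NaOH) = identity; acids (HNO₃, HCl) = full ionization; proteinase K =
50% ionization; TMAH = dimer formation with a = 0.87, chosen so the
number-weighted mean detected diameter of a 100 nm stock shifts to
~120 nm with a visibly broadened distribution. The generator emulates
the *physical state* of a pretreated sample, not matrix effects,
incomplete nebulization of residues, or size-dependent dissolution —
so passing tests demonstrate the correctness of the processing chain,
not the chemistry of any real reagent.

## Event detection

Iterative outlier thresholding: compute mean μ and sample (n−1)
standard deviation σ of the current background set (initially all
windows), set t = μ + kσ (k = 3 default), move windows with intensity
strictly above t out of the background, repeat until stable. Events
are the windows above the final threshold; the surviving background
mean is the ionic signal. Conventions: strict inequality at the
threshold (a constant trace yields no events); background-only
re-detection is idempotent; raising k never increases the event count.
k = 5 is recommended for near-zero backgrounds, where the discrete
Poisson tail above 3σ is non-negligible.

Two genuine failure modes are surfaced rather than hidden: (i) if
fewer than `min_background_windows` survive, a degenerate-trace error
names the trace; (ii) at high occupancy (above roughly 15–20% of
windows, depending on the intensity contrast) the mixture's standard
deviation is so inflated that the threshold converges *above* the
single-particle intensity and only multi-particle windows are
reported. The second is a faithful property of mean+kσ thresholding on
event-dense traces; it sharpens the apparent loss of counting
linearity at high concentration and is one more reason to work below
the critical count.

## Calibration and quantification

The ionic line is ordinary least squares on (concentration, mean
counts/dwell) standards (`scipy.stats.linregress`); a non-positive
slope is a calibration error. Transport efficiency uses the
particle-frequency method: η = n_events/(N_ref · Q · T) for a reference
particle standard of known number concentration N_ref over acquisition
time T; η outside (0, 1] is rejected, and a warning is raised when the
reference measurement itself exceeds a supplied critical count (the
frequency method then undercounts).

Event mass inverts the mass-flux equivalence:

    m = I_net · (η · Q · τ) / s / f        [ng → reported as fg]

with I_net = raw − background mean (not raw − threshold: unbiased mass
at the cost of a soft size floor; the floor is reported as `size_lod`,
the diameter at net intensity t − μ). Diameter is the
spherical-equivalent d = (6m/(π·ρ·f))^(1/3). Per sample:
number concentration = n_events/(η·Q·T); particulate mass
concentration = Σm/(η·Q·T); dissolved concentration = (μ − b)/s,
clipped at 0 (the negative raw value is logged). Zero events is a
valid result (size statistics reported as NaN), so background-only
samples still quantify their dissolved fraction. Internally one unit
system is used throughout (s, mL, ng, nm, fg); ng/mL and µg/L are the
same unit.

## Counting linearity and the critical count

The dilution-series procedure mirrors the graphical method: fit a
zero-intercept theoretical count line on the low-concentration region,
plot theoretical − detected, and report the largest detected count
whose relative shortfall (theoretical − detected)/theoretical stays
within a tolerance (default 0.085). Under the noiseless occupancy
model the shortfall 1 − (1 − e^(−λ))/λ reaches 0.085 at λ ≈ 0.180,
i.e. ~495 detected events in 3000 windows — the "keep detected counts
below ~500 per 30 s" rule. The tolerance is configuration and is
echoed in every result.

Counting noise makes the literal procedure ill-defined on a real
serial-dilution ladder (the bottom decade holds a handful of events),
so two documented guards operationalize it:

* **Fit region.** The lowest quartile by concentration rank, united
  with the contiguous low-concentration prefix of samples whose
  *observed* occupancy is ≤ 8% of windows — the occupancy at which the
  expected coincidence shortfall is half the default tolerance. The
  criterion is slope-free and observable; the prefix restriction
  matters because detected counts are non-monotone in concentration
  once thresholding breaks down, so a global cap could pull collapsed
  high-concentration samples into the "linear" fit. The cap value was
  selected by minimizing the slope error (bias and RMSE) against
  simulator truth. A residual check warns when the region's top point
  falls > 3 Poisson SE below the fitted line.
* **Breach significance.** A sample only counts toward the sustained
  breach (two consecutive samples above tolerance) when its deficit
  also exceeds `breach_sigma`·√(theoretical/n_replicates) counts
  (default 3σ). Without it, Poisson noise at the sparse ladder bottom
  false-triggers the two-consecutive rule in a substantial fraction of
  runs. `breach_sigma = 0` recovers the literal rule for noiseless
  series.

Replicate ladders can be pooled (`pool_series`); the per-seed estimate
is robust to occasional single-replicate threshold collapse, so the
headline statistic averages per-ladder critical counts over seeds.
Measured under the default study conditions (60 seeds), per-ladder
critical counts are ~480 ± 50 around the ~500 noiseless value.

The simulated ladder follows the four-start serial dilution (2000,
800, 700, 600 pg/mL); the step factor defaults to 10^(1/3), spanning
three decades per 10-member series (≈0.6 pg/mL to 2000 pg/mL overall).
Mass-to-number conversion uses the population's mean particle mass
including the lognormal moment factor (1 + cv²)³.

## Pretreatment evaluation metrics

* residue rate = 100 · residue mass / initial tissue mass;
* spike recovery: measured concentrations are multiplied by the
  measurement dilution (default 500×) and referenced to the
  homogenate-level spike (default 100 ng/mL). The 1:1 v/v reagent
  addition is treated as already reflected in the quoted spike level —
  this bookkeeping choice is deliberate and prominent, since recovery
  percentages shift twofold if the spike is defined before the reagent
  addition;
* the total-recovery acceptance gate is the closed interval
  [80%, 120%]; values above 100% are legal and reported as-is;
* particle/ion partition = each pool's share of the total analyte mass
  concentration (closes to 100% by construction);
* reagent comparison tables report mean ± sample SD (n−1) over
  replicates (SD is NaN for n = 1); no hypothesis testing is
  performed.

## Numerical choices and degenerate inputs

Validation errors are raised for non-finite or sign-violating inputs;
λ > 10 particles per window is rejected as unphysical. Mass↔diameter
conversion round-trips to 1e-12 relative. Serial-dilution traces use
child seeds drawn from a single parent generator (all < 2³¹). Trace
CSV round-trips are bit-exact (floats written with `repr`). Mean + kσ
iteration caps at 100 passes (convergence is typically ≤ 5).

## Known limitations

* The simulator's noise model is Poisson-only; real detectors add
  flicker and dead-time effects, so real size distributions are
  broader than simulated ones at equal cv.
* Split events, matrix-dependent sensitivity drift, internal-standard
  correction, and vendor file formats are out of scope.
* Ionization is modeled as particle removal; a partially dissolving
  sample whose particles *shrink* (smaller mean diameter at the same
  number) is not distinguished from one whose particles vanish.
* The critical count is a property of (window count, tolerance,
  detection settings), not a universal constant; the ~500 value holds
  for 3000 windows at the default tolerance.
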