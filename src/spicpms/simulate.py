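"""Synthetic sp-ICP-MS trace generator with known ground truth.

Single-particle ICP-MS records one intensity reading per dwell window.
Dissolved (ionic) analyte contributes a steady Poisson background; each
nanoparticle that reaches the plasma during a window contributes a burst
of counts proportional to its mass. When two or more particles arrive in
the same window their counts sum and the event is read as one larger
particle — the coincidence failure mode that limits counting linearity.

The generator models:

* particle arrivals per window as Poisson with rate
  ``lambda = number_concentration * sample_flow * transport_efficiency * dwell_time``;
* lognormal particle diameters, converted to analyte mass via the
  sphere-volume formula;
* per-particle counts as a Poisson draw with mean
  ``mass * calib_slope / (transport_efficiency * sample_flow * dwell_time)``,
  so that a given mass flux produces the same counts whether it arrives
  dissolved or particulate (the mass-flux equivalence the downstream
  quantification inverts);
* ionic background counts as Poisson with mean
  ``calib_intercept + calib_slope * dissolved_conc`` per window.

Pretreatment scenarios (ionization, aggregation, dilution) are
phenomenological transforms of the (population, dissolved) pair applied
before simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .conversions import FG_PER_NG, sphere_analyte_mass_fg
from .errors import ValidationError

__all__ = [
    "AcquisitionSettings",
    "ParticlePopulation",
    "ScenarioTransform",
    "TraceTruth",
    "TimeTrace",
    "simulate_trace",
    "apply_scenario",
    "simulate_dilution_series",
    "DEFAULT_LADDER_STARTS_PG",
    "DEFAULT_LADDER_STEP_FACTOR",
    "DEFAULT_LADDER_STEPS",
]

#: Serial-dilution ladder defaults: four start concentrations (pg/mL),
#: each diluted in 10^(1/3)-fold steps to a 10-member series (3 decades),
#: i.e. 40 solutions spanning roughly 600 fg/mL to 2000 pg/mL.
DEFAULT_LADDER_STARTS_PG: tuple[float, ...] = (2000.0, 800.0, 700.0, 600.0)
DEFAULT_LADDER_STEP_FACTOR: float = 10.0 ** (1.0 / 3.0)
DEFAULT_LADDER_STEPS: int = 10


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def _finite(x: float) -> bool:
    return math.isfinite(float(x))


@dataclass(frozen=True)
class AcquisitionSettings:
    """Instrument acquisition settings and ionic calibration.

    Defaults follow a 10 ms dwell / 30 s acquisition (3000 windows) with
    an illustrative sample flow of 0.346 mL/min and transport efficiency
    of 0.05; flow and efficiency are instrument-specific and must be set
    explicitly for real data. ``calib_slope`` is the ionic sensitivity in
    counts per dwell per (ng/mL); ``calib_intercept`` is the blank
    background in counts per dwell (0 = blank-corrected counts).
    """

    dwell_time: float = 0.010           # s
    duration: float = 30.0              # s
    sample_flow: float = 0.346 / 60.0   # mL/s
    transport_efficiency: float = 0.05  # dimensionless
    calib_slope: float = 1000.0         # counts/dwell per (ng/mL)
    calib_intercept: float = 0.0        # counts/dwell

    def __post_init__(self) -> None:
        _require(_finite(self.dwell_time) and self.dwell_time > 0, "dwell_time must be > 0")
        _require(_finite(self.duration) and self.duration >= self.dwell_time,
                 "duration must be >= dwell_time")
        _require(_finite(self.sample_flow) and self.sample_flow > 0, "sample_flow must be > 0")
        _require(_finite(self.transport_efficiency) and 0 < self.transport_efficiency <= 1,
                 "transport_efficiency must be in (0, 1]")
        _require(_finite(self.calib_slope) and self.calib_slope > 0, "calib_slope must be > 0")
        _require(_finite(self.calib_intercept) and self.calib_intercept >= 0,
                 "calib_intercept must be >= 0")

    @property
    def n_windows(self) -> int:
        """Number of dwell windows in one acquisition."""
        # small epsilon guards floor(30 / 0.010) against binary rounding
        return int(math.floor(self.duration / self.dwell_time + 1e-9))

    @property
    def effective_volume(self) -> float:
        """Sample volume (mL) effectively reaching the plasma per dwell."""
        return self.transport_efficiency * self.sample_flow * self.dwell_time


@dataclass(frozen=True)
class ParticlePopulation:
    """A lognormal nanoparticle population.

    ``mean_diameter`` is the arithmetic-mean diameter in nm and
    ``cv_diameter`` the coefficient of variation of the lognormal
    diameter distribution (0.05 default for monodisperse commercial
    stocks). ``density`` defaults to silver (10.49 g/cm^3) and
    ``mass_fraction`` to 1.0 (pure-element particles).
    """

    mean_diameter: float                   # nm
    number_concentration: float            # particles/mL
    cv_diameter: float = 0.05
    density: float = 10.49                 # g/cm^3
    mass_fraction: float = 1.0

    def __post_init__(self) -> None:
        _require(_finite(self.mean_diameter) and self.mean_diameter > 0,
                 "mean_diameter must be > 0")
        _require(_finite(self.cv_diameter) and self.cv_diameter >= 0,
                 "cv_diameter must be >= 0")
        _require(_finite(self.number_concentration) and self.number_concentration >= 0,
                 "number_concentration must be >= 0")
        _require(_finite(self.density) and self.density > 0, "density must be > 0")
        _require(_finite(self.mass_fraction) and 0 < self.mass_fraction <= 1,
                 "mass_fraction must be in (0, 1]")

    @property
    def mean_mass_fg(self) -> float:
        """Mean analyte mass per particle (fg), including the lognormal
        diameter spread: E[d^3] = mean^3 (1 + cv^2)^3."""
        e_d3 = self.mean_diameter**3 * (1.0 + self.cv_diameter**2) ** 3
        return float(sphere_analyte_mass_fg(1.0, self.density, self.mass_fraction) * e_d3)

    @property
    def mass_concentration(self) -> float:
        """Particulate analyte mass concentration (ng/mL)."""
        return self.number_concentration * self.mean_mass_fg / FG_PER_NG

    @classmethod
    def from_mass_concentration(cls, mass_conc_ng_ml: float, mean_diameter: float,
                                **kwargs) -> "ParticlePopulation":
        """Build a population from a particulate mass concentration (ng/mL)."""
        _require(_finite(mass_conc_ng_ml) and mass_conc_ng_ml >= 0,
                 "mass concentration must be >= 0")
        probe = cls(mean_diameter=mean_diameter, number_concentration=0.0, **kwargs)
        n = mass_conc_ng_ml * FG_PER_NG / probe.mean_mass_fg
        return replace(probe, number_concentration=n)


@dataclass(frozen=True)
class ScenarioTransform:
    """Phenomenological pretreatment transform.

    ``ionized_fraction`` of the particles dissolve (their mass moves to
    the ionic pool); ``aggregated_fraction`` of the particles merge into
    k-mers of ``aggregate_order`` monomers (diameter scales as k^(1/3),
    conserving mass); everything is then diluted ``dilution_factor``-fold
    before measurement.
    """

    ionized_fraction: float = 0.0
    aggregated_fraction: float = 0.0
    aggregate_order: int = 2
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        _require(0.0 <= self.ionized_fraction <= 1.0, "ionized_fraction must be in [0, 1]")
        _require(0.0 <= self.aggregated_fraction <= 1.0, "aggregated_fraction must be in [0, 1]")
        _require(self.ionized_fraction + self.aggregated_fraction <= 1.0 + 1e-12,
                 "ionized_fraction + aggregated_fraction must be <= 1")
        _require(int(self.aggregate_order) == self.aggregate_order and self.aggregate_order >= 2,
                 "aggregate_order must be an integer >= 2")
        _require(_finite(self.dilution_factor) and self.dilution_factor >= 1.0,
                 "dilution_factor must be >= 1")


@dataclass(frozen=True)
class TraceTruth:
    """Ground-truth record attached to a simulated trace."""

    populations: tuple[ParticlePopulation, ...]
    dissolved_conc: float          # ng/mL
    seed: int
    n_particles: int               # particles actually delivered
    n_occupied_windows: int        # windows with >= 1 particle

    @property
    def particulate_mass_concentration(self) -> float:
        """True particulate mass concentration (ng/mL)."""
        return sum(p.mass_concentration for p in self.populations)

    @property
    def total_mass_concentration(self) -> float:
        return self.particulate_mass_concentration + self.dissolved_conc


@dataclass(frozen=True)
class TimeTrace:
    """One acquisition: integer counts per dwell window plus settings."""

    intensities: np.ndarray
    settings: AcquisitionSettings
    truth: TraceTruth | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 1:
            raise ValidationError("intensities must be one-dimensional")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.asarray(arr, float) == np.floor(np.asarray(arr, float))):
                raise ValidationError("intensities must be integral counts")
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ValidationError("intensities must be non-negative")
        if arr.size != self.settings.n_windows:
            raise ValidationError(
                f"trace has {arr.size} windows, settings imply {self.settings.n_windows}")
        object.__setattr__(self, "intensities", arr.astype(np.int64))

    def __len__(self) -> int:
        return int(self.intensities.size)


def _as_populations(population) -> tuple[ParticlePopulation, ...]:
    if isinstance(population, ParticlePopulation):
        return (population,)
    pops = tuple(population)
    for p in pops:
        if not isinstance(p, ParticlePopulation):
            raise ValidationError("population must be ParticlePopulation or a sequence of them")
    return pops


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def simulate_trace(population, dissolved_conc: float, settings: AcquisitionSettings,
                   seed: int) -> TimeTrace:
    """Simulate one acquisition.

    ``population`` may be a single :class:`ParticlePopulation` or a
    sequence of them (a mixture, e.g. from :func:`apply_scenario`);
    ``dissolved_conc`` is the ionic analyte concentration in ng/mL.
    Identical inputs and seed produce a bit-identical trace.
    """
    pops = _as_populations(population)
    _require(_finite(dissolved_conc) and dissolved_conc >= 0, "dissolved_conc must be >= 0")
    n = settings.n_windows
    eff_vol = settings.effective_volume  # mL per dwell

    lam_total = sum(p.number_concentration * eff_vol for p in pops)
    if lam_total > 10.0:
        raise ValidationError(
            f"expected {lam_total:.3g} particles per dwell window (> 10): "
            "unphysical configuration, dilute the sample")

    rng = np.random.default_rng(seed)
    bg_rate = settings.calib_intercept + settings.calib_slope * dissolved_conc
    counts = rng.poisson(bg_rate, n).astype(np.int64)

    occupied = np.zeros(n, dtype=bool)
    n_particles = 0
    for pop in pops:
        lam = pop.number_concentration * eff_vol
        arrivals = rng.poisson(lam, n)
        k = int(arrivals.sum())
        if k == 0:
            continue
        idx = np.repeat(np.arange(n), arrivals)
        if pop.cv_diameter > 0:
            mu, sig = _lognormal_params(pop.mean_diameter, pop.cv_diameter)
            diam = rng.lognormal(mean=mu, sigma=sig, size=k)
        else:
            diam = np.full(k, pop.mean_diameter)
        mass_fg = sphere_analyte_mass_fg(diam, pop.density, pop.mass_fraction)
        # counts per particle: mass expressed as the dissolved-equivalent
        # concentration it represents inside one effective dwell volume
        expected_counts = mass_fg / FG_PER_NG * settings.calib_slope / eff_vol
        burst = rng.poisson(expected_counts)
        np.add.at(counts, idx, burst)
        occupied[idx] = True
        n_particles += k

    truth = TraceTruth(populations=pops, dissolved_conc=float(dissolved_conc),
                       seed=int(seed), n_particles=n_particles,
                       n_occupied_windows=int(occupied.sum()))
    return TimeTrace(intensities=counts, settings=settings, truth=truth)


def apply_scenario(population, dissolved_conc: float,
                   transform: ScenarioTransform) -> tuple[tuple[ParticlePopulation, ...], float]:
    """Apply a pretreatment scenario to (population, dissolved) inputs.

    Returns a mixture of populations (monomers plus k-mers, zero-number
    components dropped) and the new dissolved concentration. Total
    analyte mass is conserved exactly before the dilution step.
    """
    pops = _as_populations(population)
    _require(_finite(dissolved_conc) and dissolved_conc >= 0, "dissolved_conc must be >= 0")
    i, a, k = transform.ionized_fraction, transform.aggregated_fraction, transform.aggregate_order
    out: list[ParticlePopulation] = []
    dissolved = float(dissolved_conc)
    for p in pops:
        dissolved += i * p.mass_concentration
        n_mono = p.number_concentration * (1.0 - i - a)
        if n_mono > 0:
            out.append(replace(p, number_concentration=n_mono))
        n_kmer = p.number_concentration * a / k
        if n_kmer > 0:
            out.append(replace(p, number_concentration=n_kmer,
                               mean_diameter=p.mean_diameter * k ** (1.0 / 3.0)))
    f = transform.dilution_factor
    out = [replace(p, number_concentration=p.number_concentration / f) for p in out]
    return tuple(out), dissolved / f


def simulate_dilution_series(stock: ParticlePopulation, start_concs: Sequence[float],
                             n_steps: int, step_factor: float,
                             settings: AcquisitionSettings, seed: int,
                             dissolved_conc: float = 0.0) -> list[TimeTrace]:
    """Simulate a serial-dilution ladder.

    ``start_concs`` are particulate mass concentrations in pg/mL; trace
    (i, j) is simulated at ``start_concs[i] / step_factor**(j-1)`` for
    j = 1..n_steps, converting mass to number concentration through the
    stock population's mean particle mass. Per-trace seeds are derived
    deterministically from ``seed``.
    """
    start_concs = list(start_concs)
    _require(len(start_concs) > 0, "start_concs must be non-empty")
    _require(all(_finite(c) and c > 0 for c in start_concs),
             "start concentrations must be positive")
    _require(int(n_steps) == n_steps and n_steps >= 1, "n_steps must be an integer >= 1")
    _require(_finite(step_factor) and step_factor > 1, "step_factor must be > 1")

    seeder = np.random.default_rng(seed)
    child_seeds = seeder.integers(0, 2**31 - 1, size=len(start_concs) * n_steps)
    traces: list[TimeTrace] = []
    pos = 0
    for c0 in start_concs:
        for j in range(n_steps):
            mass_ng = c0 / step_factor**j * 1e-3  # pg/mL -> ng/mL
            pop = replace(stock,
                          number_concentration=mass_ng * FG_PER_NG / stock.mean_mass_fg)
            traces.append(simulate_trace(pop, dissolved_conc, settings,
                                         int(child_seeds[pos])))
            pos += 1
    return traces
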