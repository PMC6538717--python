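"""Event-to-size conversion and per-sample quantification.

A detected event's net intensity (raw counts minus the background mean)
is converted to analyte mass by inverting the mass-flux equivalence: a
dissolved concentration C yields ``slope * C`` counts per dwell, and the
sample volume effectively reaching the plasma per dwell is
``eta * flow * dwell``, so

    mass = net_counts * (eta * flow * dwell) / slope / mass_fraction

Mass converts to a spherical-equivalent diameter through the particle
density. Per-sample concentrations follow from the event rate (number),
the summed event masses (particulate mass) and the background mean
(dissolved), all normalized by the effectively analyzed volume
``eta * flow * duration``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .calibrate import IonicCalibration, TransportEfficiency
from .conversions import FG_PER_NG, mass_to_diameter_nm, sphere_analyte_mass_fg
from .detect import DetectionResult
from .errors import ValidationError
from .simulate import AcquisitionSettings

__all__ = ["ElementProperties", "ParticleEvent", "QuantResult", "SILVER",
           "event_mass", "mass_to_diameter", "diameter_to_mass", "quantify_sample"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElementProperties:
    """Analyte element: bulk density (g/cm^3) and analyte mass fraction."""

    density: float
    mass_fraction: float = 1.0
    symbol: str = ""

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValidationError("density must be > 0")
        if not 0 < self.mass_fraction <= 1:
            raise ValidationError("mass_fraction must be in (0, 1]")


#: Elemental silver
SILVER = ElementProperties(density=10.49, mass_fraction=1.0, symbol="Ag")


@dataclass(frozen=True)
class ParticleEvent:
    """One detected particle: net counts, analyte mass (fg), diameter (nm)."""

    window_index: int
    net_intensity: float
    mass: float
    diameter: float
    raw_intensity: float = float("nan")


@dataclass(frozen=True)
class QuantResult:
    """Per-sample summary of a quantified acquisition.

    Concentrations are ng/mL; diameters nm. ``size_lod`` is the
    spherical-equivalent diameter corresponding to the detection
    threshold above background — the soft size floor of the
    measurement. Size statistics are NaN when no events were detected.
    """

    n_events: int
    number_concentration: float
    particulate_mass_concentration: float
    dissolved_concentration: float
    mean_diameter: float
    median_diameter: float
    sd_diameter: float
    size_lod: float
    diameters: np.ndarray
    events: tuple[ParticleEvent, ...] = field(default=(), repr=False)

    @property
    def total_concentration(self) -> float:
        """Particulate + dissolved analyte concentration (ng/mL)."""
        return self.particulate_mass_concentration + self.dissolved_concentration


def _eta_value(eta) -> float:
    e = eta.eta if isinstance(eta, TransportEfficiency) else float(eta)
    if not 0 < e <= 1:
        raise ValidationError("eta must be in (0, 1]")
    return e


def event_mass(net_intensity: float, calib: IonicCalibration, eta,
               sample_flow: float, dwell_time: float,
               element: ElementProperties = SILVER) -> float:
    """Analyte mass (fg) of one event from its net intensity (counts).

    ``eta`` may be a :class:`TransportEfficiency` or a plain fraction;
    ``sample_flow`` is mL/s and ``dwell_time`` s.
    """
    net = np.asarray(net_intensity, dtype=float)
    if np.any(net <= 0):
        raise ValidationError("net_intensity must be > 0")
    e = _eta_value(eta)
    mass_ng = net * (e * sample_flow * dwell_time) / calib.slope / element.mass_fraction
    out = mass_ng * FG_PER_NG
    return float(out) if np.isscalar(net_intensity) else out


def mass_to_diameter(mass: float, element: ElementProperties = SILVER) -> float:
    """Spherical-equivalent diameter (nm) from an analyte mass (fg)."""
    out = mass_to_diameter_nm(mass, element.density, element.mass_fraction)
    return float(out) if np.isscalar(mass) else out


def diameter_to_mass(diameter: float, element: ElementProperties = SILVER) -> float:
    """Analyte mass (fg) of a sphere of the given diameter (nm)."""
    out = sphere_analyte_mass_fg(diameter, element.density, element.mass_fraction)
    return float(out) if np.isscalar(diameter) else out


def quantify_sample(detection: DetectionResult, calib: IonicCalibration, eta,
                    settings: AcquisitionSettings,
                    element: ElementProperties = SILVER) -> QuantResult:
    """Convert a detection result into per-sample concentrations and sizes.

    Zero detected events is a valid outcome (size statistics reported as
    NaN), so background-only samples quantify their dissolved fraction.
    """
    e = _eta_value(eta)
    analyzed_volume = e * settings.sample_flow * settings.duration  # mL

    net = detection.event_raw_intensities - detection.background_mean
    keep = net > 0
    if not np.all(keep):
        logger.info("dropping %d event(s) with non-positive net intensity",
                    int((~keep).sum()))
    net = net[keep]
    idx = detection.event_indices[keep]

    if net.size:
        masses = event_mass(net, calib, e, settings.sample_flow,
                            settings.dwell_time, element)
        diams = mass_to_diameter(masses, element)
        events = tuple(
            ParticleEvent(window_index=int(i), net_intensity=float(s),
                          mass=float(m), diameter=float(d),
                          raw_intensity=float(s) + detection.background_mean)
            for i, s, m, d in zip(idx, net, masses, diams))
        mean_d = float(np.mean(diams))
        median_d = float(np.median(diams))
        sd_d = float(np.std(diams, ddof=1)) if diams.size > 1 else float("nan")
        total_mass_fg = float(np.sum(masses))
    else:
        diams = np.array([])
        events = ()
        mean_d = median_d = sd_d = float("nan")
        total_mass_fg = 0.0

    raw_dissolved = (detection.background_mean - calib.intercept) / calib.slope
    if raw_dissolved < 0:
        logger.info("background below calibration intercept: dissolved estimate "
                    "%.4g ng/mL clipped to 0", raw_dissolved)
    dissolved = max(0.0, raw_dissolved)

    net_lod = detection.threshold - detection.background_mean
    if net_lod > 0:
        size_lod = mass_to_diameter(
            event_mass(net_lod, calib, e, settings.sample_flow,
                       settings.dwell_time, element), element)
    else:
        size_lod = 0.0

    return QuantResult(
        n_events=len(events),
        number_concentration=len(events) / analyzed_volume,
        particulate_mass_concentration=total_mass_fg / FG_PER_NG / analyzed_volume,
        dissolved_concentration=dissolved,
        mean_diameter=mean_d,
        median_diameter=median_d,
        sd_diameter=sd_d,
        size_lod=float(size_lod),
        diameters=diams,
        events=events,
    )
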