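"""Ionic sensitivity calibration and transport-efficiency determination.

The ionic calibration is an ordinary least-squares line through a ladder
of dissolved standards (concentration in ng/mL vs mean counts per
dwell). Transport efficiency — the fraction of nebulized sample that
actually reaches the plasma — is determined by the particle-frequency
method: count events from a reference particle standard of known number
concentration (the role RM8013 plays) and divide by the number of
particles delivered to the nebulizer during the acquisition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .detect import DetectionResult
from .errors import (CalibrationError, InconsistentReferenceError,
                     InsufficientSignalError, ValidationError)

__all__ = ["IonicCalibration", "TransportEfficiency", "fit_ionic_calibration",
           "transport_efficiency_particle_frequency", "CoincidenceWarning"]


class CoincidenceWarning(UserWarning):
    """The reference measurement itself may be coincidence-limited."""


@dataclass(frozen=True)
class IonicCalibration:
    """Linear ionic response: counts/dwell = slope * C(ng/mL) + intercept."""

    slope: float        # counts/dwell per (ng/mL)
    intercept: float    # counts/dwell
    r_squared: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise CalibrationError("calibration slope must be > 0")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValidationError("r_squared must be in [0, 1]")


@dataclass(frozen=True)
class TransportEfficiency:
    """Nebulization transport efficiency eta in (0, 1]."""

    eta: float
    method: str = "particle-frequency"
    reference_number_conc: float | None = None  # particles/mL

    def __post_init__(self) -> None:
        if not 0.0 < self.eta <= 1.0:
            raise ValidationError("eta must be in (0, 1]")


def fit_ionic_calibration(
        standards: Sequence[tuple[float, float]]) -> IonicCalibration:
    """Least-squares fit of the ionic standard ladder.

    ``standards`` are (concentration ng/mL, mean counts/dwell) pairs;
    at least two distinct concentrations are required and the fitted
    slope must be strictly positive.
    """
    pts = [(float(c), float(y)) for c, y in standards]
    if len(pts) < 2:
        raise ValidationError("at least two calibration standards are required")
    conc = np.array([p[0] for p in pts])
    intens = np.array([p[1] for p in pts])
    if not (np.all(np.isfinite(conc)) and np.all(np.isfinite(intens))):
        raise ValidationError("calibration standards must be finite")
    if np.unique(conc).size < 2:
        raise ValidationError("calibration standards need >= 2 distinct concentrations")

    fit = stats.linregress(conc, intens)
    if not fit.slope > 0:
        raise CalibrationError(
            f"fitted slope {fit.slope:.4g} is not positive; instrument response is flat "
            "or inverted")
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0
    return IonicCalibration(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=min(max(r2, 0.0), 1.0))


def transport_efficiency_particle_frequency(
        detection: DetectionResult, reference_number_conc: float,
        sample_flow: float, duration: float,
        critical_count: int | None = None) -> TransportEfficiency:
    """Transport efficiency from a reference particle standard.

    ``eta = n_events / (reference_number_conc * sample_flow * duration)``
    with flow in mL/s and duration in s. If ``critical_count`` is given
    and the reference measurement exceeds it, a
    :class:`CoincidenceWarning` is issued (the frequency method then
    undercounts and eta is biased low).
    """
    if not reference_number_conc > 0:
        raise ValidationError("reference_number_conc must be > 0")
    if not (sample_flow > 0 and duration > 0):
        raise ValidationError("sample_flow and duration must be > 0")
    n = detection.n_events
    if n == 0:
        raise InsufficientSignalError("no particle events detected in the reference standard")
    if critical_count is not None and n > critical_count:
        warnings.warn(
            f"reference standard produced {n} events, above the critical count "
            f"{critical_count}; eta will be biased low by coincidence",
            CoincidenceWarning, stacklevel=2)
    delivered = reference_number_conc * sample_flow * duration
    eta = n / delivered
    if eta > 1.0:
        raise InconsistentReferenceError(
            f"eta = {eta:.3g} > 1: detected events exceed particles delivered; "
            "check the reference number concentration and flow")
    return TransportEfficiency(eta=float(eta),
                               reference_number_conc=float(reference_number_conc))
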