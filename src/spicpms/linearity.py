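"""Counting-linearity analysis and the critical particle count.

At low particle concentration the number of detected events per
acquisition grows linearly with concentration. As the arrival rate per
dwell window (lambda) rises, two or more particles increasingly share a
window (coincidence) and are read as one event, so detected counts fall
below the theoretical line and sizes are simultaneously overestimated
(the masses of coincident particles sum). For Poisson arrivals the
expected detected (occupied-window) count is the closed form

    detected = n_windows * (1 - exp(-lambda)),   lambda = true_count / n_windows

This module operationalizes the graphical dilution-series procedure:
fit a zero-intercept theoretical count line on the low-concentration
(linear) region, form the difference curve (theoretical - detected),
and report the largest detected count whose relative shortfall stays
within a tolerance — the critical count above which counting departs
from linearity. With 3000 windows and the default tolerance 0.085 the
noiseless closed form puts the critical count near 500 events per
acquisition (lambda ~= 0.18).

Two noise guards make the procedure well-defined on real (Poisson-
noisy) ladders; both are reported configuration, not hidden state:

* the fit region is the rank-based low fraction of the ladder united
  with the contiguous low-concentration prefix of samples whose
  *observed* occupancy (detected counts / windows) stays at or below
  ``occupancy_cap`` — an observable, slope-free criterion that pulls
  all linear-regime samples into the fit; the default cap of 8% is the
  occupancy at which the expected coincidence shortfall reaches half
  the default tolerance (shortfall ~ lambda/2 = 0.0425 at occupancy
  1 - e^-0.085);
* a sample only counts toward a breach of linearity when its deficit is
  also statistically significant (``breach_sigma`` Poisson standard
  errors of the theoretical count, scaled by the number of pooled
  replicate ladders), so counting noise at the sparse bottom of a
  serial-dilution ladder cannot fake a saturation breakpoint.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detect import DetectionParams, detect_events
from .errors import NoLinearRegionError, ValidationError
from .simulate import TimeTrace

__all__ = ["DilutionSeries", "LinearityResult", "expected_detected",
           "fit_theoretical_line", "critical_count", "series_from_traces",
           "pool_series", "analyze_series", "LinearityWarning",
           "DEFAULT_TOLERANCE", "DEFAULT_LOW_REGION_FRACTION",
           "DEFAULT_OCCUPANCY_CAP"]

#: Relative-shortfall tolerance that reproduces the ~500-event rule for a
#: 3000-window acquisition under the noiseless occupancy model.
DEFAULT_TOLERANCE = 0.085
DEFAULT_LOW_REGION_FRACTION = 0.25
#: Occupied-window fraction below which counting is treated as linear
#: for the theoretical-line fit: at 8% occupancy the expected
#: coincidence shortfall is ~ tolerance/2 for the default tolerance.
DEFAULT_OCCUPANCY_CAP = 0.08
#: Poisson significance (in SE of the theoretical count) a deficit must
#: reach before a sample can breach the linearity tolerance.
DEFAULT_BREACH_SIGMA = 3.0


class LinearityWarning(UserWarning):
    """The theoretical-line fit or the series shape looks suspect."""


@dataclass(frozen=True)
class DilutionSeries:
    """A concentration ladder with the detected event count per trace."""

    concentrations: np.ndarray   # pg/mL
    detected_counts: np.ndarray  # events per acquisition
    n_windows: int

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        cnt = np.asarray(self.detected_counts)
        if conc.size != cnt.size or conc.size < 4:
            raise ValidationError("series needs equal-length arrays of >= 4 samples")
        if np.any(conc <= 0) or not np.all(np.isfinite(conc)):
            raise ValidationError("concentrations must be positive and finite")
        if np.any(cnt < 0) or np.any(cnt > self.n_windows):
            raise ValidationError("counts must lie in [0, n_windows]")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "detected_counts", cnt.astype(np.int64))

    def __len__(self) -> int:
        return int(self.concentrations.size)


@dataclass(frozen=True)
class LinearityResult:
    """Outcome of the difference procedure on one dilution series.

    ``differences`` (theoretical - detected) are aligned with the input
    series order. ``saturated`` is False when no sustained departure
    from linearity was observed, in which case ``critical_count`` is
    simply the largest detected count in the series.
    """

    theoretical_slope: float      # counts per (pg/mL)
    low_region_max_conc: float    # pg/mL
    differences: np.ndarray
    critical_count: int
    tolerance: float
    saturated: bool
    n_windows: int


def expected_detected(true_count: float, n_windows: int) -> float:
    """Expected detected (occupied-window) count for Poisson arrivals."""
    if true_count < 0 or n_windows < 1:
        raise ValidationError("true_count must be >= 0 and n_windows >= 1")
    lam = true_count / n_windows
    return n_windows * -math.expm1(-lam)


def _low_region_mask(series: DilutionSeries, low_region_fraction: float,
                     occupancy_cap: float | None) -> np.ndarray:
    n_low = max(3, int(math.floor(low_region_fraction * len(series) + 1e-9)))
    order = np.argsort(series.concentrations, kind="stable")
    mask = np.zeros(len(series), dtype=bool)
    mask[order[:n_low]] = True
    if occupancy_cap is not None:
        # contiguous low-concentration prefix only: detected counts are
        # not monotone in concentration once thresholding breaks down at
        # high occupancy, so a global cap could pull saturated samples in
        cap = occupancy_cap * series.n_windows
        for idx in order:
            if series.detected_counts[idx] > cap:
                break
            mask[idx] = True
    return mask


def fit_theoretical_line(series: DilutionSeries,
                         low_region_fraction: float = DEFAULT_LOW_REGION_FRACTION,
                         occupancy_cap: float | None = DEFAULT_OCCUPANCY_CAP) -> float:
    """Zero-intercept least-squares slope over the linear (low) region.

    The fit region is the lowest ``low_region_fraction`` of the samples
    by concentration rank, united with every sample whose observed
    occupancy is at or below ``occupancy_cap`` (set it to None for the
    purely rank-based region). A :class:`LinearityWarning` is raised
    when the region's highest point already falls more than 3 Poisson
    SE below the fitted line, i.e. the region reaches into the
    saturating regime.
    """
    if not 0 < low_region_fraction <= 1:
        raise ValidationError("low_region_fraction must be in (0, 1]")
    mask = _low_region_mask(series, low_region_fraction, occupancy_cap)
    c = series.concentrations[mask]
    y = series.detected_counts[mask].astype(float)
    slope = float(np.sum(c * y) / np.sum(c * c))

    top = int(np.argmax(c))
    theo_top = slope * c[top]
    if theo_top > 0 and (theo_top - y[top]) > 3.0 * math.sqrt(theo_top):
        warnings.warn(
            "low-region fit shows curvature: its highest point already falls "
            ">3 Poisson SE below the line; consider a smaller low region",
            LinearityWarning, stacklevel=2)
    return slope


def critical_count(series: DilutionSeries, slope: float,
                   tolerance: float = DEFAULT_TOLERANCE,
                   low_region_max_conc: float = float("nan"),
                   breach_sigma: float = DEFAULT_BREACH_SIGMA,
                   n_replicates: int = 1) -> LinearityResult:
    """Find the coincidence-limited critical detected-particle count.

    For each sample the relative shortfall ``(theoretical - detected) /
    theoretical`` is computed with ``theoretical = slope * conc``.
    Samples are scanned in increasing concentration order up to the
    first sustained breach — two consecutive samples whose shortfall
    exceeds the tolerance *and* whose deficit is statistically
    significant (more than ``breach_sigma * sqrt(theoretical /
    n_replicates)`` counts) — and the critical count is the largest
    detected count among the within-tolerance samples seen before it.
    Set ``breach_sigma = 0`` for noiseless series. ``n_replicates``
    states over how many replicate ladders the counts were averaged
    (see :func:`pool_series`); it only rescales the significance guard.
    """
    if not slope > 0:
        raise ValidationError("slope must be > 0")
    if not 0 < tolerance < 0.5:
        raise ValidationError("tolerance must be in (0, 0.5)")
    if breach_sigma < 0 or n_replicates < 1:
        raise ValidationError("breach_sigma must be >= 0 and n_replicates >= 1")

    theo = slope * series.concentrations
    detected = series.detected_counts.astype(float)
    differences = theo - detected
    shortfall = differences / theo

    order = np.argsort(series.concentrations, kind="stable")
    sf = shortfall[order]
    det = detected[order]
    deficit = differences[order]
    significant = deficit > breach_sigma * np.sqrt(theo[order] / n_replicates)
    breach = (sf > tolerance) & significant

    stop = len(series)
    for i in range(len(series) - 1):
        if breach[i] and breach[i + 1]:
            stop = i + 1  # the first sample of the pair is still scanned
            break
    saturated = stop < len(series)

    within = det[:stop][sf[:stop] <= tolerance]
    if within.size == 0:
        raise NoLinearRegionError(
            "every sample breaches the linearity tolerance; no linear region found")
    return LinearityResult(
        theoretical_slope=float(slope),
        low_region_max_conc=float(low_region_max_conc),
        differences=differences,
        critical_count=int(round(float(within.max()))),
        tolerance=float(tolerance),
        saturated=saturated,
        n_windows=series.n_windows,
    )


def series_from_traces(traces: Sequence[TimeTrace],
                       params: DetectionParams | None = None) -> DilutionSeries:
    """Detect events in simulated ladder traces and assemble the series.

    Concentrations are taken from each trace's ground-truth record
    (particulate mass concentration, converted to pg/mL).
    """
    if not traces:
        raise ValidationError("no traces supplied")
    conc = []
    counts = []
    for t in traces:
        if t.truth is None:
            raise ValidationError("traces must carry ground-truth records")
        conc.append(t.truth.particulate_mass_concentration * 1e3)  # ng/mL -> pg/mL
        counts.append(detect_events(t, params).n_events)
    return DilutionSeries(concentrations=np.array(conc),
                          detected_counts=np.array(counts),
                          n_windows=traces[0].settings.n_windows)


def pool_series(series_seq: Sequence[DilutionSeries]) -> DilutionSeries:
    """Average detected counts over replicate ladders (same concentrations).

    Counts are rounded to the nearest integer; pass the replicate count
    to :func:`critical_count` / :func:`analyze_series` so the breach
    significance guard uses the pooled standard error.
    """
    series_seq = list(series_seq)
    if not series_seq:
        raise ValidationError("no series supplied")
    first = series_seq[0]
    for s in series_seq[1:]:
        if (s.n_windows != first.n_windows
                or not np.allclose(s.concentrations, first.concentrations)):
            raise ValidationError("replicate series must share concentrations and windows")
    mean_counts = np.mean([s.detected_counts for s in series_seq], axis=0)
    return DilutionSeries(concentrations=first.concentrations.copy(),
                          detected_counts=np.round(mean_counts).astype(np.int64),
                          n_windows=first.n_windows)


def analyze_series(series: DilutionSeries | Sequence[DilutionSeries],
                   low_region_fraction: float = DEFAULT_LOW_REGION_FRACTION,
                   tolerance: float = DEFAULT_TOLERANCE,
                   occupancy_cap: float | None = DEFAULT_OCCUPANCY_CAP,
                   breach_sigma: float = DEFAULT_BREACH_SIGMA) -> LinearityResult:
    """Fit the theoretical line and locate the critical count in one call.

    Accepts a single series or a sequence of replicate series (pooled
    with :func:`pool_series`).
    """
    n_replicates = 1
    if not isinstance(series, DilutionSeries):
        reps = list(series)
        n_replicates = len(reps)
        series = pool_series(reps)
    slope = fit_theoretical_line(series, low_region_fraction, occupancy_cap)
    mask = _low_region_mask(series, low_region_fraction, occupancy_cap)
    low_max = float(series.concentrations[mask].max())
    return critical_count(series, slope, tolerance, low_region_max_conc=low_max,
                          breach_sigma=breach_sigma, n_replicates=n_replicates)
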