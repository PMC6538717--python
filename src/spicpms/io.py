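"""Trace files, reports and run configuration.

Traces are plain CSV with ``#key=value`` header lines carrying the
acquisition settings (units are spelled out in the key names), a
``index,counts`` column header, and one integer count per dwell window.
Reports serialize the result dataclasses to JSON (with a config echo,
config hash and package version) or to CSV event tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .detect import DetectionParams
from .errors import ConfigError, ParseError, ValidationError
from .quantify import ElementProperties, QuantResult, SILVER
from .simulate import (AcquisitionSettings, ParticlePopulation, ScenarioTransform,
                       TimeTrace)

__all__ = ["read_trace", "write_trace", "write_report", "read_report",
           "write_event_table", "RunConfig", "load_config", "config_hash"]

_HEADER_KEYS = {
    "dwell_time_s": ("dwell_time", 1.0),
    "duration_s": ("duration", 1.0),
    "sample_flow_ml_min": ("sample_flow", 1.0 / 60.0),
    "transport_efficiency": ("transport_efficiency", 1.0),
    "calib_slope_counts_per_dwell_per_ng_ml": ("calib_slope", 1.0),
    "calib_intercept_counts_per_dwell": ("calib_intercept", 1.0),
}


def write_trace(trace: TimeTrace, path, isotope: str = "107Ag") -> Path:
    """Write a trace to the documented CSV dialect; round-trips bit-exactly."""
    path = Path(path)
    s = trace.settings
    lines = [
        f"#dwell_time_s={s.dwell_time!r}",
        f"#duration_s={s.duration!r}",
        f"#sample_flow_ml_min={s.sample_flow * 60.0!r}",
        f"#transport_efficiency={s.transport_efficiency!r}",
        f"#calib_slope_counts_per_dwell_per_ng_ml={s.calib_slope!r}",
        f"#calib_intercept_counts_per_dwell={s.calib_intercept!r}",
        f"#isotope={isotope}",
        "index,counts",
    ]
    lines.extend(f"{i},{c}" for i, c in enumerate(trace.intensities))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trace(path) -> TimeTrace:
    """Read a trace written by :func:`write_trace`.

    Parse failures raise :class:`ParseError` naming the offending line.
    Missing header keys (units are part of the key name and therefore
    mandatory) and record-count mismatches are rejected.
    """
    path = Path(path)
    header: dict[str, float] = {}
    counts: list[int] = []
    expected_index = 0
    saw_columns = False
    with path.open() as fh:
        for lineno, rawline in enumerate(fh, start=1):
            line = rawline.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise ParseError(f"{path}:{lineno}: malformed header line {line!r}")
                key, _, value = line[1:].partition("=")
                if key in _HEADER_KEYS:
                    attr, scale = _HEADER_KEYS[key]
                    try:
                        header[attr] = float(value) * scale
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: non-numeric value for {key}") from None
                continue
            if not saw_columns:
                if line != "index,counts":
                    raise ParseError(
                        f"{path}:{lineno}: expected column header 'index,counts', "
                        f"got {line!r}")
                saw_columns = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'index,counts' record")
            try:
                idx, c = int(parts[0]), int(parts[1])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer index or count") from None
            if idx != expected_index:
                raise ParseError(
                    f"{path}:{lineno}: window index {idx}, expected {expected_index}")
            if c < 0:
                raise ParseError(f"{path}:{lineno}: negative count {c}")
            counts.append(c)
            expected_index += 1

    missing = [k for k, (attr, _) in _HEADER_KEYS.items() if attr not in header]
    if missing:
        raise ParseError(f"{path}: missing header keys: {', '.join(missing)}")
    try:
        settings = AcquisitionSettings(**header)
    except ValidationError as exc:
        raise ParseError(f"{path}: invalid header: {exc}") from exc
    if len(counts) != settings.n_windows:
        raise ParseError(
            f"{path}: {len(counts)} records but header implies "
            f"{settings.n_windows} dwell windows")
    return TimeTrace(intensities=np.array(counts, dtype=np.int64), settings=settings)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and (obj != obj):  # NaN -> null for valid JSON
        return None
    return obj


def config_hash(config: Any) -> str:
    """Deterministic sha256 over the canonical JSON form of a config."""
    payload = json.dumps(_jsonable(config), sort_keys=True, allow_nan=False)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_report(results: Any, path, format: str = "json",
                 config: Any = None) -> Path:
    """Serialize results (dataclasses, dicts, arrays) to a report file.

    JSON reports carry every result field plus a config echo, its hash
    and the package version. ``format='csv'`` writes the event table of
    a :class:`QuantResult` instead.
    """
    path = Path(path)
    if format == "csv":
        if not isinstance(results, QuantResult):
            raise ValidationError("CSV reports are event tables of a QuantResult")
        return write_event_table(results, path)
    if format != "json":
        raise ValidationError(f"unknown report format {format!r}")
    doc = {
        "package": "spicpms",
        "version": __version__,
        "results": _jsonable(results),
        "config": _jsonable(config) if config is not None else None,
        "config_hash": config_hash(config) if config is not None else None,
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def read_report(path) -> dict:
    """Load a JSON report back into a plain dictionary."""
    return json.loads(Path(path).read_text())


def write_event_table(quant: QuantResult, path) -> Path:
    """CSV event table: window_index, raw, net, mass_fg, diameter_nm."""
    path = Path(path)
    lines = ["window_index,raw,net,mass_fg,diameter_nm"]
    for ev in quant.events:
        lines.append(f"{ev.window_index},{ev.raw_intensity:.6g},"
                     f"{ev.net_intensity:.6g},{ev.mass:.6g},{ev.diameter:.6g}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Run configuration

@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated run configuration for the CLI and scripted pipelines."""

    settings: AcquisitionSettings
    detection: DetectionParams
    element: ElementProperties
    population: ParticlePopulation | None
    dissolved_conc: float
    scenario: ScenarioTransform | None
    seed: int
    tolerance: float
    low_region_fraction: float
    ladder_start_concs_pg: tuple[float, ...]
    ladder_n_steps: int
    ladder_step_factor: float


def _build(cls, mapping: Mapping[str, Any], section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {section!r}: {', '.join(sorted(unknown))}")
    try:
        return cls(**mapping)
    except (ValidationError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc


_TOP_LEVEL = {"settings", "detection", "element", "population", "dissolved_conc",
              "scenario", "seed", "tolerance", "low_region_fraction", "ladder"}
_LADDER_KEYS = {"start_concs_pg", "n_steps", "step_factor"}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    from .linearity import DEFAULT_LOW_REGION_FRACTION, DEFAULT_TOLERANCE
    from .simulate import (DEFAULT_LADDER_STARTS_PG, DEFAULT_LADDER_STEP_FACTOR,
                           DEFAULT_LADDER_STEPS)

    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration document must be a mapping")
    unknown = set(raw) - _TOP_LEVEL
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")

    settings = _build(AcquisitionSettings, raw.get("settings", {}), "settings")
    detection = _build(DetectionParams, raw.get("detection", {}), "detection")
    element = (_build(ElementProperties, raw["element"], "element")
               if "element" in raw else SILVER)
    population = (_build(ParticlePopulation, raw["population"], "population")
                  if raw.get("population") else None)
    scenario = (_build(ScenarioTransform, raw["scenario"], "scenario")
                if raw.get("scenario") else None)

    ladder = raw.get("ladder", {})
    unknown = set(ladder) - _LADDER_KEYS
    if unknown:
        raise ConfigError(f"unknown key(s) in section 'ladder': {', '.join(sorted(unknown))}")

    return RunConfig(
        settings=settings,
        detection=detection,
        element=element,
        population=population,
        dissolved_conc=float(raw.get("dissolved_conc", 0.0)),
        scenario=scenario,
        seed=int(raw.get("seed", 0)),
        tolerance=float(raw.get("tolerance", DEFAULT_TOLERANCE)),
        low_region_fraction=float(raw.get("low_region_fraction",
                                          DEFAULT_LOW_REGION_FRACTION)),
        ladder_start_concs_pg=tuple(ladder.get("start_concs_pg",
                                               DEFAULT_LADDER_STARTS_PG)),
        ladder_n_steps=int(ladder.get("n_steps", DEFAULT_LADDER_STEPS)),
        ladder_step_factor=float(ladder.get("step_factor",
                                            DEFAULT_LADDER_STEP_FACTOR)),
    )
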