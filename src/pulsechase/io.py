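"""Pattern tables, JSON reports, and validation.

A pattern table is a delimited text file (comma- or tab-separated,
auto-detected) with a header row ``time_min,value`` and metadata in leading
comment lines::

    # pulse_min: 30
    # design: chase
    # label: p30
    time_min,value
    0,1.0
    40,0.64

``pulse_min`` accepts the token ``inf`` for the synthesis-shutoff limit
case.  Reports are JSON with explicit units and the full configuration that
produced them.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import DecayPattern, FitResult
from .model import (
    PulseProtocol,
    RateSet,
    derived_quantities,
)

__all__ = [
    "PatternFormatError",
    "read_pattern",
    "write_pattern",
    "fit_report",
    "derived_report",
    "save_report",
]


class PatternFormatError(ValueError):
    """A pattern table failed validation; the message cites the row."""


_COLUMNS = ("time_min", "value")


def _parse_pulse(token: str) -> float:
    token = token.strip().lower()
    if token in ("inf", "infinite", "infinity"):
        return math.inf
    try:
        return float(token)
    except ValueError as exc:
        raise PatternFormatError(f"cannot parse pulse_min value {token!r}") from exc


def read_pattern(path) -> DecayPattern:
    """Read and validate a pattern table; errors cite the offending row."""
    path = Path(path)
    meta: dict[str, str] = {}
    header = None
    with path.open() as fh:
        lines = fh.readlines()
    data_start = 0
    for i, line in enumerate(lines):
        s = line.strip()
        if not s:
            data_start = i + 1
            continue
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            data_start = i + 1
            continue
        header = s
        break
    if header is None:
        raise PatternFormatError(f"{path}: no header row found")
    delimiter = "\t" if "\t" in header else ","
    cols = [c.strip() for c in header.split(delimiter)]
    for c in _COLUMNS:
        if c not in cols:
            raise PatternFormatError(f"{path}: missing required column {c!r}")

    df = pd.read_csv(path, comment="#", sep=delimiter, skip_blank_lines=True)
    df.columns = [c.strip() for c in df.columns]
    for c in _COLUMNS:
        numeric = pd.to_numeric(df[c], errors="coerce")
        bad = numeric.isna() & df[c].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise PatternFormatError(
                f"{path}: non-numeric {c} value {df[c][bad.idxmax()]!r} at data row {row}"
            )
        df[c] = numeric
    if df[_COLUMNS[0]].isna().any() or df[_COLUMNS[1]].isna().any():
        row = int(df[list(_COLUMNS)].isna().any(axis=1).idxmax()) + 1
        raise PatternFormatError(f"{path}: missing value at data row {row}")

    if "pulse_min" not in meta:
        raise PatternFormatError(
            f"{path}: missing '# pulse_min:' metadata (number of minutes or 'inf')"
        )
    design = meta.get("design", "chase")
    try:
        return DecayPattern(
            pulse_length=_parse_pulse(meta["pulse_min"]),
            times=df["time_min"].to_numpy(dtype=float),
            values=df["value"].to_numpy(dtype=float),
            design=design,
            label=meta.get("label", path.stem),
            metadata={k: v for k, v in meta.items()
                      if k not in ("pulse_min", "design", "label")},
        )
    except ValueError as exc:
        raise PatternFormatError(f"{path}: {exc}") from exc


def write_pattern(pattern: DecayPattern, path, delimiter: str = ",") -> Path:
    """Write a pattern table; round-trips bit-exactly through read_pattern."""
    path = Path(path)
    pulse = "inf" if math.isinf(pattern.pulse_length) else repr(pattern.pulse_length)
    with path.open("w") as fh:
        fh.write(f"# pulse_min: {pulse}\n")
        fh.write(f"# design: {pattern.design}\n")
        if pattern.label:
            fh.write(f"# label: {pattern.label}\n")
        fh.write(delimiter.join(_COLUMNS) + "\n")
        for t, v in zip(pattern.times, pattern.values):
            fh.write(f"{float(t)!r}{delimiter}{float(v)!r}\n")
    return path


def fit_report(result: FitResult, config: dict | None = None) -> dict:
    """JSON-ready report of a FitResult, with units and provenance."""
    report = result.to_dict()
    report["units"] = {"rates": "1/min", "objective": "squared log ratio"}
    if config:
        report["config"] = config
    if isinstance(result.rates, RateSet):
        report["derived"] = _derived_dict(result.rates, PulseProtocol())
    return report


def _derived_dict(rates: RateSet, protocol: PulseProtocol) -> dict:
    d = derived_quantities(rates, protocol)
    return {
        "mean_lifetime_min": d.mean_lifetime,
        "mean_lifetime_hours": d.mean_lifetime / 60.0,
        "half_time_min": d.half_time,
        "pulse_length_min": ("inf" if math.isinf(protocol.pulse_length)
                             else protocol.pulse_length),
        "pi1": d.pi1,
        "pi2": d.pi2,
        "tau1_min": rates.tau1,
        "tau2_min": rates.tau2,
        "p10": rates.p10,
        "p12": rates.p12,
        "synthesis_rate_per_min": protocol.synthesis_rate,
        "steady_state_abundance": d.steady_state_abundance,
    }


def derived_report(rates: RateSet, protocol: PulseProtocol | None = None) -> dict:
    """Stability summary (mean lifetime, half-time, occupancies, ...) as JSON."""
    if protocol is None:
        protocol = PulseProtocol()
    return {
        "rates_per_min": {"kappa10": rates.kappa10, "kappa12": rates.kappa12,
                          "kappa20": rates.kappa20},
        **_derived_dict(rates, protocol),
    }


def save_report(report: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
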