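"""Delimited-text and JSON readers/writers plus config loading.

Series travel as delimited text (CSV/TSV, ``.`` decimal, UTF-8),
structured results as JSON, configurations as YAML or JSON with keys
mirroring the dataclass field names exactly; unknown keys are rejected
so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .beats import BeatSeries
from .brs import BRSResult, OnsetResult
from .classify import FeaturePoint, Hyperplane
from .cohort import CohortSpec
from .oscillator import BPdSchedule, OscillatorParams, SimTrace, StimulusProfile

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "write_trace",
    "read_trace",
    "write_beats",
    "read_beats",
    "write_features",
    "read_features",
    "save_hyperplane",
    "load_hyperplane",
    "result_to_json",
    "load_config",
    "params_from_config",
]

_TRACE_COLUMNS = ("t", "x1", "x2", "x2p", "z2", "bpd", "v0")
_BEAT_COLUMNS = ("peak_time_s", "sbp_mmHg", "dbp_mmHg", "isi_s", "hr_bpm")


def read_timeseries(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (time s, value) delimited text file.

    Delimiter (comma/tab/whitespace) and an optional single header row
    are auto-detected; time must be strictly increasing.
    """
    path = Path(path)
    first_line = ""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                first_line = line
                break
    sep = "\t" if "\t" in first_line else ("," if "," in first_line else r"\s+")
    df = pd.read_csv(
        path,
        sep=sep,
        header=None,
        comment="#",
        float_precision="round_trip",
        engine="python" if sep == r"\s+" else "c",
    )
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns, got {df.shape[1]}")
    first = df.iloc[0]
    try:
        float(first.iloc[0]), float(first.iloc[1])
        has_header = False
    except (TypeError, ValueError):
        has_header = True
    if has_header:
        df = df.iloc[1:]
    if len(df) < 2:
        raise ValueError(f"{path}: need at least 2 data rows")
    try:
        t = df.iloc[:, 0].astype(float).to_numpy()
        v = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        row = int(bad[0]) + 1 + (1 if has_header else 0)
        raise ValueError(f"{path}: time not strictly increasing at data row {row + 1}")
    return t, v


def write_timeseries(path, t, values, header: tuple = ("t_s", "bp_mmHg")) -> None:
    pd.DataFrame({header[0]: t, header[1]: values}).to_csv(path, index=False)


def write_trace(trace: SimTrace, path) -> None:
    """Write a full simulation trace as CSV (t,x1,x2,x2p,z2,bpd,v0)."""
    trace.to_frame().to_csv(path, index=False)


def read_trace(path) -> SimTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trace columns {sorted(missing)}")
    return SimTrace(**{c: df[c].to_numpy(dtype=float) for c in _TRACE_COLUMNS})


def write_beats(beats: BeatSeries, path) -> None:
    """Beat series as CSV; interval/HR of the last beat are empty."""
    n = len(beats)
    isi = np.append(beats.isi, np.nan)
    hr = np.append(beats.hr_bpm, np.nan)
    pd.DataFrame(
        {
            "peak_time_s": beats.peak_times,
            "sbp_mmHg": beats.sbp,
            "dbp_mmHg": beats.dbp,
            "isi_s": isi[:n],
            "hr_bpm": hr[:n],
        }
    ).to_csv(path, index=False)


def read_beats(path) -> BeatSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_BEAT_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing beat columns {sorted(missing)}")
    return BeatSeries(
        peak_times=df["peak_time_s"].to_numpy(dtype=float),
        sbp=df["sbp_mmHg"].to_numpy(dtype=float),
        dbp=df["dbp_mmHg"].to_numpy(dtype=float),
    )


def write_features(points, path) -> None:
    pd.DataFrame(
        {
            "episode_id": [p.episode_id for p in points],
            "bp_max_drop_mmHg": [p.bp_max_drop for p in points],
            "delta_brs_max": [p.delta_brs_max for p in points],
            "label": [p.label for p in points],
        }
    ).to_csv(path, index=False)


def read_features(path) -> list[FeaturePoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        FeaturePoint(
            episode_id=str(r.episode_id),
            bp_max_drop=float(r.bp_max_drop_mmHg),
            delta_brs_max=float(r.delta_brs_max),
            label=str(r.label),
        )
        for r in df.itertuples()
    ]


def save_hyperplane(plane: Hyperplane, path) -> None:
    payload = {
        "w": list(map(float, plane.w)),
        "b": plane.b,
        "center": list(map(float, plane.center)),
        "scale": list(map(float, plane.scale)),
        "train_error": plane.train_error,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_hyperplane(path) -> Hyperplane:
    d = json.loads(Path(path).read_text())
    return Hyperplane(
        w=np.array(d["w"], dtype=float),
        b=float(d["b"]),
        center=np.array(d["center"], dtype=float),
        scale=np.array(d["scale"], dtype=float),
        train_error=float(d["train_error"]),
    )


def result_to_json(result: BRSResult | OnsetResult) -> str:
    """Serialize a BRS or onset result dataclass as JSON text."""
    return json.dumps(dataclasses.asdict(result), indent=2)


def load_config(path) -> dict:
    """Load a YAML or JSON config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _build(cls, block: dict, what: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise ValueError(f"unknown {what} keys: {sorted(unknown)}")
    return cls(**block)


def params_from_config(config: dict):
    """Build (params, schedule, stimulus) from a config mapping.

    Recognized blocks: ``oscillator`` (OscillatorParams fields), ``bpd``
    (list of [time, level] events), ``stimulus`` (StimulusProfile
    fields), ``cohort`` (CohortSpec fields, optional).  Unknown keys in
    any block are rejected.
    """
    known = {"oscillator", "bpd", "stimulus", "cohort"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    params = _build(OscillatorParams, config.get("oscillator", {}), "oscillator")
    bpd_events = config.get("bpd")
    schedule = (
        BPdSchedule(tuple((float(t), float(v)) for t, v in bpd_events))
        if bpd_events
        else BPdSchedule.constant()
    )
    stim = _build(StimulusProfile, config.get("stimulus", {}), "stimulus")
    out = (params, schedule, stim)
    if "cohort" in config:
        block = dict(config["cohort"])
        if "stimulus" in block:
            block["stimulus"] = _build(StimulusProfile, block["stimulus"], "stimulus")
        if "params" in block:
            block["params"] = _build(OscillatorParams, block["params"], "oscillator")
        out = out + (_build(CohortSpec, block, "cohort"),)
    return out
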