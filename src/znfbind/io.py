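"""Readers and writers for the package's plain-text dialects.

Trace, lane and titration tables are CSV with fixed headers; sequences are
FASTA; fit results and reports are JSON carrying explicit units and a schema
version; generator/scenario configuration is YAML.  Reads are strict --
missing columns, non-numeric cells or duplicate lane ids raise a
:class:`ParseError` naming the offending field and row -- and write/read
round-trips are lossless on the canonical in-memory form.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import NM, RateConstants
from .competition import DoseEvent, DosingSchedule, Ligand
from .emsa import LaneQuantification, TitrationSeries
from .tracefit import SwitchTrace

__all__ = [
    "ParseError",
    "SCHEMA_VERSION",
    "read_traces",
    "write_traces",
    "read_lanes",
    "write_lanes",
    "read_titration",
    "write_titration",
    "read_fasta",
    "write_fasta",
    "write_json_result",
    "write_config_sidecar",
    "read_scenario",
    "parse_duration",
]

SCHEMA_VERSION = "1.0"

TRACE_COLUMNS = ["experiment_id", "spot_id", "phase", "concentration_nM", "time_s", "response"]
LANE_COLUMNS = ["lane_id", "condition", "shifted_intensity", "free_intensity"]
TITRATION_COLUMNS = ["concentration_nM", "replicate", "fraction_bound_pct"]


class ParseError(ValueError):
    """Malformed input file (missing column, bad cell, duplicate key)."""


def _read_csv(path: str | Path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several flavors
        raise ParseError(f"{path}: cannot read CSV ({exc})") from exc
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at row {int(bad[0]) + 2}"
            )
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 2
            raise ParseError(f"{path}: empty cell in column {col!r} at row {row}")
        df[col] = converted
    return df


def read_traces(path: str | Path) -> list[SwitchTrace]:
    """Read the trace CSV dialect into SwitchTrace objects."""
    df = _read_csv(path, TRACE_COLUMNS, ["concentration_nM", "time_s", "response"])
    traces = []
    keys = ["experiment_id", "spot_id", "phase", "concentration_nM"]
    for (exp, spot, phase, c_nM), grp in df.groupby(keys, sort=False):
        if phase not in ("association", "dissociation"):
            raise ParseError(f"{path}: unknown phase {phase!r}")
        grp = grp.sort_values("time_s")
        traces.append(
            SwitchTrace(
                times=grp["time_s"].to_numpy(),
                responses=grp["response"].to_numpy(),
                concentration=float(c_nM) * NM,
                spot_id=str(spot),
                phase=phase,
                experiment_id=str(exp),
            )
        )
    return traces


def write_traces(traces: Sequence[SwitchTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for t, y in zip(tr.times, tr.responses):
            rows.append(
                {
                    "experiment_id": tr.experiment_id,
                    "spot_id": tr.spot_id,
                    "phase": tr.phase,
                    "concentration_nM": tr.concentration / NM,
                    "time_s": t,
                    "response": y,
                }
            )
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False, lineterminator="\n")


def read_lanes(path: str | Path) -> list[LaneQuantification]:
    df = _read_csv(path, LANE_COLUMNS, ["shifted_intensity", "free_intensity"])
    ids = df["lane_id"].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        row = int(dup.index[0]) + 2
        raise ParseError(f"{path}: duplicate lane id {dup.iloc[0]!r} at row {row}")
    return [
        LaneQuantification(
            lane_id=str(r.lane_id),
            condition="" if pd.isna(r.condition) else str(r.condition),
            shifted_intensity=float(r.shifted_intensity),
            free_intensity=float(r.free_intensity),
        )
        for r in df.itertuples()
    ]


def write_lanes(lanes: Sequence[LaneQuantification], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "lane_id": l.lane_id,
                "condition": l.condition,
                "shifted_intensity": l.shifted_intensity,
                "free_intensity": l.free_intensity,
            }
            for l in lanes
        ],
        columns=LANE_COLUMNS,
    ).to_csv(path, index=False, lineterminator="\n")


def read_titration(path: str | Path, L_total_nM: float = 3.0) -> TitrationSeries:
    """Read the titration CSV dialect.

    The labeled-DNA concentration is experiment metadata, not a column, so
    it is supplied by the caller (default 3 nM).
    """
    df = _read_csv(path, TITRATION_COLUMNS, ["concentration_nM", "fraction_bound_pct"])
    concs, fractions = [], []
    for c_nM, grp in df.groupby("concentration_nM", sort=True):
        concs.append(float(c_nM) * NM)
        fractions.append(grp["fraction_bound_pct"].to_numpy(dtype=float))
    return TitrationSeries(
        L_total=L_total_nM * NM, concentrations=np.array(concs), fractions=fractions
    )


def write_titration(series: TitrationSeries, path: str | Path) -> None:
    rows = []
    for c, reps in zip(series.concentrations, series.fractions):
        for i, f in enumerate(reps, start=1):
            rows.append(
                {"concentration_nM": c / NM, "replicate": i, "fraction_bound_pct": f}
            )
    pd.DataFrame(rows, columns=TITRATION_COLUMNS).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA; bases are upper-cased (a lowercase input is flagged in
    the record's annotations under 'normalized')."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        upper = raw.upper()
        rec = SeqRecord(Seq(upper), id=rec.id, description=rec.description)
        rec.annotations["normalized"] = raw != upper
        records.append(rec)
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | Path) -> None:
    SeqIO.write(records, str(path), "fasta")


def write_json_result(result: dict, path: str | Path, units: dict | None = None) -> None:
    """Write a result JSON with schema version and per-field units."""
    payload = {"schema_version": SCHEMA_VERSION, **result}
    if units:
        payload["units"] = units
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")


def write_config_sidecar(config: dict, path: str | Path) -> None:
    """Persist the exact run configuration next to an output artifact."""
    payload = {"schema_version": SCHEMA_VERSION, **config}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


_DURATION_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(h|min|s)?\s*$")


def parse_duration(value: str | float | int) -> float:
    """Parse '14h', '30min', '90s' or a bare number (seconds) to seconds."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _DURATION_RE.match(value)
    if not m:
        raise ParseError(f"cannot parse duration {value!r}")
    mag = float(m.group(1))
    unit = m.group(2) or "s"
    return mag * {"s": 1.0, "min": 60.0, "h": 3600.0}[unit]


def read_scenario(path: str | Path) -> tuple[float, list[Ligand], DosingSchedule]:
    """Read a competition scenario YAML.

    Expected layout::

        protein_total_nM: 2284
        horizon: 15h
        ligands:
          - {name: hot, total_nM: 10, k_on: 725, k_off: 1.1e-5, labeled: true}
          - {name: cold, total_nM: 1000, k_on: 725, k_off: 1.1e-5}
        schedule:                    # optional; default: everything at t=0
          - {time: 0, protein_nM: 2284, ligands: {hot: 10}}
          - {time: 1h, ligands: {cold: 1000}}
    """
    data = yaml.safe_load(Path(path).read_text())
    try:
        protein_total = float(data["protein_total_nM"]) * NM
        horizon = parse_duration(data["horizon"])
        ligands = [
            Ligand(
                name=str(l["name"]),
                total=float(l["total_nM"]) * NM,
                rates=RateConstants(k_on=float(l["k_on"]), k_off=float(l["k_off"])),
                labeled=bool(l.get("labeled", False)),
            )
            for l in data["ligands"]
        ]
    except KeyError as exc:
        raise ParseError(f"{path}: missing scenario field {exc}") from exc
    if "schedule" in data:
        events = [
            DoseEvent(
                time=parse_duration(ev.get("time", 0)),
                protein=float(ev.get("protein_nM", 0.0)) * NM,
                ligands={
                    str(k): float(v) * NM for k, v in ev.get("ligands", {}).items()
                },
            )
            for ev in data["schedule"]
        ]
        schedule = DosingSchedule(events=events, horizon=horizon)
    else:
        schedule = DosingSchedule(
            events=[
                DoseEvent(
                    0.0,
                    protein=protein_total,
                    ligands={l.name: l.total for l in ligands},
                )
            ],
            horizon=horizon,
        )
    return protein_total, ligands, schedule
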