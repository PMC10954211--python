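"""Trace / sequence / config file plumbing.

Traces travel as CSV with the documented header (``time_min``,
``signal_au``, ``replicate``, ``condition``); written files carry the
tool version and the run seed as ``#``-comment lines, which the reader
skips.  Sequences go through FASTA (via biopython, 60-column wrap),
schedules and kinetic parameters through JSON.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import metadata

import pandas as pd

from .kinetics import KineticParams, Schedule

__all__ = [
    "read_traces",
    "write_traces",
    "read_fasta",
    "write_fasta",
    "schedule_from_json",
    "schedule_to_json",
    "params_from_json",
    "params_to_json",
    "tool_version",
]

TRACE_COLUMNS = ["time_min", "signal_au", "replicate", "condition"]


def tool_version() -> str:
    try:
        return metadata.version("traptamer")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def write_traces(df: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write traces as CSV with a version/seed comment header."""
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table is missing columns {missing}")
    with open(path, "w", newline="") as fh:
        fh.write(f"# traptamer {tool_version()}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df[TRACE_COLUMNS].to_csv(fh, index=False)


def read_traces(path) -> pd.DataFrame:
    """Read a trace CSV (order-normalised; empty file -> empty table)."""
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} is missing column(s) {missing}")
    df = df[TRACE_COLUMNS].sort_values(
        ["condition", "replicate", "time_min"], kind="mergesort")
    return df.reset_index(drop=True)


def write_fasta(records: dict[str, str], path) -> None:
    """Write name -> sequence records as FASTA (60-column lines)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    seqio_write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq) for rec in parse(str(path), "fasta")}


def schedule_to_json(schedule: Schedule, path) -> None:
    payload = {
        "events": [{"time": t, "species": sp, "concentration": c}
                   for t, sp, c in schedule.events],
        "horizon": schedule.horizon,
        "output_grid": schedule.output_grid,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def schedule_from_json(path) -> Schedule:
    with open(path) as fh:
        payload = json.load(fh)
    try:
        events = tuple((float(e["time"]), str(e["species"]), float(e["concentration"]))
                       for e in payload["events"])
        return Schedule(events, horizon=float(payload.get("horizon", 200.0)),
                        output_grid=float(payload.get("output_grid", 1.0)))
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed schedule JSON {path}: {exc}") from exc


def params_to_json(params: KineticParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(params), fh, indent=2)


def params_from_json(path) -> KineticParams:
    with open(path) as fh:
        payload = json.load(fh)
    valid = {f.name for f in dataclasses.fields(KineticParams)}
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(f"unknown kinetic parameter(s) {sorted(unknown)} in {path}")
    return KineticParams(**payload)
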