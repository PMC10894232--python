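"""Plain-text I/O for traces and stage tables.

Traces are stored as a delimited text file with a two-line comment header
carrying the sampling interval and units; stage hand-offs (events,
annotations, sized events, ground truth) are TSV tables so intermediates
stay inspectable.  Spike calls are nested into a single column as
``time:depth:width:kind`` tuples joined by ``;``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .events import Trace
from .spikes import EventAnnotation, SpikeCall

__all__ = [
    "write_trace",
    "read_trace",
    "write_table",
    "read_table",
    "annotations_to_df",
    "df_to_annotations",
]


def write_trace(trace: Trace, path: str | Path) -> None:
    path = Path(path)
    header = f"# sample_interval_ms={trace.sample_interval_ms!r}\n# units=pA\n"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, trace.samples, fmt="%.4f")


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    sample_interval = None
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            if "sample_interval_ms=" in line:
                sample_interval = float(line.split("=", 1)[1])
            pos = fh.tell()
        samples = np.loadtxt(fh, ndmin=1) if line else np.empty(0)
    if sample_interval is None:
        raise ValueError(f"{path}: missing '# sample_interval_ms=' header line")
    return Trace(samples, sample_interval)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _spikes_to_str(spikes) -> str:
    return ";".join(
        f"{s.time_ms:.6f}:{s.depth_pA:.4f}:{s.width_ms:.6f}:{s.kind}" for s in spikes
    )


def _str_to_spikes(text) -> tuple[SpikeCall, ...]:
    if not isinstance(text, str) or not text:
        return ()
    out = []
    for tok in text.split(";"):
        t, d, w, k = tok.split(":")
        out.append(SpikeCall(time_ms=float(t), depth_pA=float(d), width_ms=float(w), kind=k))
    return tuple(out)


def annotations_to_df(annotations: list[EventAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [a.event_id for a in annotations],
            "duration_ms": [a.duration_ms for a in annotations],
            "plateau_drop_pA": [a.plateau_drop_pA for a in annotations],
            "folded": [a.folded for a in annotations],
            "orientation": [a.orientation for a in annotations],
            "n_cycles": [a.n_cycles for a in annotations],
            "spikes": [_spikes_to_str(a.spikes) for a in annotations],
        }
    )


def df_to_annotations(df: pd.DataFrame) -> list[EventAnnotation]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            EventAnnotation(
                event_id=int(row.event_id),
                plateau_drop_pA=float(row.plateau_drop_pA),
                spikes=_str_to_spikes(row.spikes),
                folded=bool(row.folded),
                orientation=str(row.orientation),
                n_cycles=int(row.n_cycles),
                duration_ms=float(row.duration_ms),
            )
        )
    return out
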