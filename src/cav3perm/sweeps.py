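"""The SweepSet container: one whole-cell recording and its provenance.

A recording is a family of current traces, one per step voltage, sharing a
single time base, plus metadata describing the protocol, the solutions and
every transform that has been applied.  On disk a SweepSet is a plain CSV
(column ``time_ms`` plus one ``I_pA@<step_mV>`` column per sweep) with a JSON
sidecar carrying the metadata.  UTF-8, '.' decimal, no thousands separators.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["SweepSet", "load_sweepset"]


def _fmt_mv(v: float) -> str:
    """Canonical string for a step voltage (no trailing zeros)."""
    return f"{float(v):g}"


@dataclass
class SweepSet:
    """A voltage-clamp recording: time base, per-step traces, metadata.

    ``traces`` maps step voltage (mV) to a current trace in pA sampled on
    ``time_ms``.  ``metadata`` must stay JSON-serializable; every transform
    appends an entry to ``metadata['history']``.
    """

    time_ms: np.ndarray
    step_voltages_mV: np.ndarray
    traces: dict[float, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.step_voltages_mV = np.asarray(self.step_voltages_mV, dtype=float)
        self.traces = {float(v): np.asarray(tr, dtype=float) for v, tr in self.traces.items()}
        n = self.time_ms.size
        for v, tr in self.traces.items():
            if tr.size != n:
                raise ValueError(f"trace at {v} mV has {tr.size} samples, time base has {n}")
        if set(self.traces) != set(float(v) for v in self.step_voltages_mV):
            raise ValueError("traces and step_voltages_mV disagree")
        self.metadata.setdefault("history", [])

    @property
    def n_sweeps(self) -> int:
        return len(self.traces)

    def trace(self, step_mV: float) -> np.ndarray:
        return self.traces[float(step_mV)]

    def with_traces(self, new_traces: Mapping[float, np.ndarray], history_entry: dict) -> "SweepSet":
        """Copy with replaced traces and one appended history record."""
        md = copy.deepcopy(self.metadata)
        md.setdefault("history", []).append(history_entry)
        return SweepSet(
            time_ms=self.time_ms.copy(),
            step_voltages_mV=self.step_voltages_mV.copy(),
            traces={float(v): np.asarray(tr, dtype=float) for v, tr in new_traces.items()},
            metadata=md,
        )

    # ---------------------------------------------------------------- I/O

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_ms": self.time_ms}
        for v in sorted(self.traces):
            cols[f"I_pA@{_fmt_mv(v)}"] = self.traces[v]
        return pd.DataFrame(cols)

    def save(self, path: str | Path) -> Path:
        """Write ``<stem>.csv`` and ``<stem>.json``; returns the CSV path."""
        path = Path(path)
        stem = path.with_suffix("") if path.suffix == ".csv" else path
        csv_path = stem.with_suffix(".csv")
        json_path = stem.with_suffix(".json")
        csv_path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(csv_path, index=False)
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(self.metadata, fh, indent=1, sort_keys=True)
        return csv_path


def load_sweepset(path: str | Path) -> SweepSet:
    """Read a SweepSet written by :meth:`SweepSet.save`."""
    path = Path(path)
    stem = path.with_suffix("") if path.suffix == ".csv" else path
    df = pd.read_csv(stem.with_suffix(".csv"))
    json_path = stem.with_suffix(".json")
    metadata: dict = {}
    if json_path.exists():
        with open(json_path, encoding="utf-8") as fh:
            metadata = json.load(fh)
    voltages, traces = [], {}
    for col in df.columns:
        if col.startswith("I_pA@"):
            v = float(col.split("@", 1)[1])
            voltages.append(v)
            traces[v] = df[col].to_numpy()
    return SweepSet(
        time_ms=df["time_ms"].to_numpy(),
        step_voltages_mV=np.array(sorted(voltages)),
        traces=traces,
        metadata=metadata,
    )
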