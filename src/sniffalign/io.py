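"""File interfaces: pressure traces (HDF5 / long CSV), event and trial tables.

Pressure traces live either in an HDF5 file with one dataset per trial
(attributes ``sample_rate`` and ``t0``) or in a long-format CSV with columns
``trial_id, t_ms, pressure``.  Sniff events, behavior trials and results
tables are plain CSVs read and written through pandas.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .psychometrics import BehaviorTrial
from .sniff import PressureTrace, SniffCycle

__all__ = [
    "save_traces_hdf5",
    "load_traces_hdf5",
    "save_traces_csv",
    "load_traces_csv",
    "save_sniff_events",
    "load_sniff_events",
    "save_behavior_table",
    "load_behavior_table",
]


def save_traces_hdf5(path, traces: dict[str, PressureTrace]) -> None:
    with h5py.File(path, "w") as f:
        for trial_id, tr in traces.items():
            d = f.create_dataset(str(trial_id), data=tr.samples)
            d.attrs["sample_rate"] = tr.sample_rate
            d.attrs["t0"] = tr.t0


def load_traces_hdf5(path) -> dict[str, PressureTrace]:
    out = {}
    with h5py.File(path, "r") as f:
        for trial_id in f:
            d = f[trial_id]
            out[trial_id] = PressureTrace(
                samples=d[...],
                sample_rate=float(d.attrs["sample_rate"]),
                t0=float(d.attrs.get("t0", 0.0)),
            )
    return out


def save_traces_csv(path, traces: dict[str, PressureTrace]) -> None:
    frames = [
        pd.DataFrame({"trial_id": tid, "t_ms": tr.times, "pressure": tr.samples})
        for tid, tr in traces.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_traces_csv(path) -> dict[str, PressureTrace]:
    df = pd.read_csv(path)
    out = {}
    for tid, grp in df.groupby("trial_id", sort=False):
        t = grp["t_ms"].to_numpy()
        dt = np.diff(t)
        if dt.size == 0 or not np.allclose(dt, dt[0]):
            raise ValueError(f"trial {tid!r}: non-uniform sampling in CSV")
        out[str(tid)] = PressureTrace(
            samples=grp["pressure"].to_numpy(), sample_rate=1000.0 / dt[0],
            t0=float(t[0]),
        )
    return out


def save_sniff_events(path, cycles: list[SniffCycle]) -> None:
    pd.DataFrame(
        {
            "trial_id": [c.trial_id for c in cycles],
            "onset_ms": [c.onset for c in cycles],
            "inhalation_offset_ms": [c.inhalation_offset for c in cycles],
            "cycle_end_ms": [c.cycle_end for c in cycles],
            "flagged": [c.flagged for c in cycles],
        }
    ).to_csv(path, index=False)


def load_sniff_events(path) -> list[SniffCycle]:
    df = pd.read_csv(path)
    return [
        SniffCycle(
            onset=row.onset_ms,
            inhalation_offset=row.inhalation_offset_ms,
            cycle_end=row.cycle_end_ms,
            trial_id=row.trial_id,
            flagged=bool(row.flagged),
        )
        for row in df.itertuples()
    ]


def save_behavior_table(path, trials: list[BehaviorTrial]) -> None:
    pd.DataFrame(
        {
            "session_id": [t.session_id for t in trials],
            "trial_id": [t.trial_id for t in trials],
            "concentration_log10": [t.concentration for t in trials],
            "choice": [t.choice for t in trials],
            "first_sniff_ms": [t.first_sniff_ms for t in trials],
        }
    ).to_csv(path, index=False)


def load_behavior_table(path) -> list[BehaviorTrial]:
    df = pd.read_csv(path)
    return [
        BehaviorTrial(
            concentration=row.concentration_log10,
            choice=row.choice,
            first_sniff_ms=row.first_sniff_ms,
            session_id=row.session_id,
            trial_id=row.trial_id,
        )
        for row in df.itertuples()
    ]
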