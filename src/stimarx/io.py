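"""Container formats: HDF5 recordings (with a plain-text CSV fallback),
JSON ground-truth sidecars, tidy results tables and run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import (
    ElectrodeGeometry,
    GroundTruthSystem,
    InvalidArgumentError,
    Recording,
    StimEvent,
    StimSchedule,
)

EVENT_COLUMNS = ("onset_sample", "duration_ms", "freq_hz", "amp_ma")


def _events_frame(schedule: StimSchedule) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.onset, e.duration_ms, e.freq_hz, e.amp_ma) for e in schedule.events],
        columns=list(EVENT_COLUMNS),
    )


def _events_from_frame(df: pd.DataFrame, a_safe: float, gap_ms: int) -> StimSchedule:
    events = tuple(
        StimEvent(
            onset=int(r.onset_sample), duration_ms=int(r.duration_ms),
            freq_hz=float(r.freq_hz), amp_ma=float(r.amp_ma),
        )
        for r in df.itertuples()
    )
    return StimSchedule(events=events, a_safe=a_safe, gap_ms=gap_ms)


def save_recording(recording: Recording, path: str | Path,
                   a_safe: float | None = None) -> Path:
    """Write a recording container.

    ``.h5``/``.hdf5`` paths use HDF5 (datasets ``/signal``, ``/coords``,
    ``/events``); any other path is treated as a directory holding
    ``signal.csv`` (wide, one column per channel), ``coords.csv``,
    ``events.csv`` and ``meta.json``.
    """
    path = Path(path)
    sched = recording.schedule
    meta = {
        "fs": recording.fs,
        "anode_index": recording.geometry.anode_index,
        "session_id": recording.session_id,
        "a_safe": a_safe if a_safe is not None else sched.a_safe,
        "gap_ms": sched.gap_ms,
    }
    ev = _events_frame(sched)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=recording.signal, dtype="f8")
            f.create_dataset("coords", data=recording.geometry.coords, dtype="f8")
            grp = f.create_group("events")
            grp.create_dataset("onset_sample", data=ev.onset_sample.to_numpy("i8"))
            grp.create_dataset("duration_ms", data=ev.duration_ms.to_numpy("i8"))
            grp.create_dataset("freq_hz", data=ev.freq_hz.to_numpy("f8"))
            grp.create_dataset("amp_ma", data=ev.amp_ma.to_numpy("f8"))
            for key, val in meta.items():
                f.attrs[key] = val
        return path
    path.mkdir(parents=True, exist_ok=True)
    cols = [f"ch{k}" for k in range(recording.n_channels)]
    pd.DataFrame(recording.signal.T, columns=cols).to_csv(
        path / "signal.csv", index=False, float_format="%.17g")
    pd.DataFrame(recording.geometry.coords, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
        path / "coords.csv", index=False, float_format="%.17g")
    ev.to_csv(path / "events.csv", index=False, float_format="%.17g")
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            signal = f["signal"][...]
            coords = f["coords"][...]
            ev = pd.DataFrame({k: f["events"][k][...] for k in EVENT_COLUMNS})
            meta = dict(f.attrs)
    elif path.is_dir():
        signal = pd.read_csv(path / "signal.csv").to_numpy().T
        coords = pd.read_csv(path / "coords.csv").to_numpy()
        ev = pd.read_csv(path / "events.csv")
        meta = json.loads((path / "meta.json").read_text())
    else:
        raise InvalidArgumentError(f"no recording container at {path}")
    geometry = ElectrodeGeometry(coords=coords, anode_index=int(meta["anode_index"]))
    schedule = _events_from_frame(ev, float(meta["a_safe"]), int(meta["gap_ms"]))
    return Recording(
        signal=signal, geometry=geometry, schedule=schedule,
        fs=int(meta["fs"]), session_id=str(meta["session_id"]),
    )


def write_ground_truth(
    system: GroundTruthSystem,
    geometry: ElectrodeGeometry,
    schedule: StimSchedule,
    path: str | Path,
) -> Path:
    """JSON sidecar with the full generating system; round-trips exactly."""
    path = Path(path)
    payload = {
        "system": {
            "a": system.a.tolist(),
            "b": system.b.tolist(),
            "c": system.c.tolist(),
            "d": system.d.tolist(),
            "gating": system.gating,
            "noise_sd": system.noise_sd,
            "margin": system.margin,
            "seed": system.seed,
        },
        "geometry": {
            "coords": geometry.coords.tolist(),
            "anode_index": geometry.anode_index,
        },
        "schedule": {
            "a_safe": schedule.a_safe,
            "gap_ms": schedule.gap_ms,
            "events": [
                {"onset": e.onset, "duration_ms": e.duration_ms,
                 "freq_hz": e.freq_hz, "amp_ma": e.amp_ma}
                for e in schedule.events
            ],
        },
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth(
    path: str | Path,
) -> tuple[GroundTruthSystem, ElectrodeGeometry, StimSchedule]:
    data = json.loads(Path(path).read_text())
    s = data["system"]
    system = GroundTruthSystem(
        a=np.array(s["a"], dtype=float),
        b=np.array(s["b"], dtype=float),
        c=np.array(s["c"], dtype=float),
        d=np.array(s["d"], dtype=float),
        gating=s["gating"], noise_sd=s["noise_sd"], margin=s["margin"],
        seed=s["seed"],
    )
    g = data["geometry"]
    geometry = ElectrodeGeometry(
        coords=np.array(g["coords"], dtype=float), anode_index=g["anode_index"]
    )
    sc = data["schedule"]
    schedule = StimSchedule(
        events=tuple(
            StimEvent(onset=e["onset"], duration_ms=e["duration_ms"],
                      freq_hz=e["freq_hz"], amp_ma=e["amp_ma"])
            for e in sc["events"]
        ),
        a_safe=sc["a_safe"], gap_ms=sc["gap_ms"],
    )
    return system, geometry, schedule


def write_results_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return path
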