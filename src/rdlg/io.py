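"""On-disk session layout.

A session directory contains::

    session.json            {"phase": "pre_sleep" | "task" | "post_sleep"}
    <label>.f32             raw little-endian float32 samples
    <label>.json            sidecar {"rate_hz": ..., "t0_s": ..., "units": "uV"}
    spikes.tsv              unit_id  region  time_s   (one row per spike)
    waveforms.tsv           unit_id  channel  dt_ms  trough_index  s0 .. s{n-1}
    trajectory.tsv          time_s  x_cm  y_cm                     (optional)
    trials.tsv              trial table                            (optional)
    hypnogram.tsv           start_s  end_s  state                  (optional)
    events/<kind>.tsv       start_s  peak_s  end_s  peak_score     (optional)

Floats are written with ``repr`` precision so times and counts round-trip
bit-exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (FormatError, Interval, IntervalSet, SampledSignal, Session,
                   SpikeTrain, UnitWaveform, ValidationError)

log = logging.getLogger("rdlg.io")

_KNOWN_FILES = {"session.json", "spikes.tsv", "waveforms.tsv",
                "trajectory.tsv", "trials.tsv", "hypnogram.tsv",
                "ground_truth.json"}


def _fmt(x: float) -> str:
    return repr(float(x))


def write_session(session: Session, dir_path) -> Path:
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    (d / "session.json").write_text(json.dumps({"phase": session.phase}) + "\n")

    for label, sig in sorted(session.signals.items()):
        sig.samples.astype("<f4").tofile(d / f"{label}.f32")
        sidecar = {"rate_hz": sig.rate_hz, "t0_s": sig.t0_s, "units": "uV",
                   "label": label}
        (d / f"{label}.json").write_text(json.dumps(sidecar, sort_keys=True) + "\n")

    with open(d / "spikes.tsv", "w") as fh:
        fh.write("unit_id\tregion\ttime_s\n")
        for tr in session.trains:
            for t in tr.times_s:
                fh.write(f"{tr.unit_id}\t{tr.region}\t{_fmt(t)}\n")

    if session.waveforms:
        n = session.waveforms[0].mean_waveform.size
        cols = "\t".join(f"s{i}" for i in range(n))
        with open(d / "waveforms.tsv", "w") as fh:
            fh.write(f"unit_id\tchannel\tdt_ms\ttrough_index\t{cols}\n")
            for wf in session.waveforms:
                vals = "\t".join(_fmt(v) for v in wf.mean_waveform)
                fh.write(f"{wf.unit_id}\t{wf.channel}\t{_fmt(wf.dt_ms)}\t"
                         f"{wf.trough_index}\t{vals}\n")

    if session.trajectory is not None:
        session.trajectory.to_csv(d / "trajectory.tsv", sep="\t", index=False,
                                  float_format="%.17g")
    if session.trials is not None:
        session.trials.to_csv(d / "trials.tsv", sep="\t", index=False,
                              float_format="%.17g")
    if session.hypnogram is not None:
        write_hypnogram(session.hypnogram, d / "hypnogram.tsv")
    if session.events:
        (d / "events").mkdir(exist_ok=True)
        for kind, ivs in sorted(session.events.items()):
            write_events(ivs, d / "events" / f"{kind}.tsv")
    return d


def write_events(ivs: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("start_s\tpeak_s\tend_s\tpeak_score\n")
        for iv in ivs:
            p = "" if iv.peak_s is None else _fmt(iv.peak_s)
            q = "" if iv.peak_score is None else _fmt(iv.peak_score)
            fh.write(f"{_fmt(iv.start_s)}\t{p}\t{_fmt(iv.end_s)}\t{q}\n")


def read_events(path, kind: str) -> IntervalSet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    need = {"start_s", "peak_s", "end_s", "peak_score"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    return IntervalSet.from_arrays(df["start_s"], df["end_s"], kind,
                                   peaks=[None if pd.isna(v) else float(v)
                                          for v in df["peak_s"]],
                                   scores=[None if pd.isna(v) else float(v)
                                           for v in df["peak_score"]])


def write_hypnogram(hyp: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("start_s\tend_s\tstate\n")
        for iv in hyp:
            fh.write(f"{_fmt(iv.start_s)}\t{_fmt(iv.end_s)}\t{iv.kind}\n")


def read_hypnogram(path) -> IntervalSet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    ivs = [Interval(float(r.start_s), float(r.end_s), str(r.state))
           for r in df.itertuples()]
    return IntervalSet(ivs, "other")


def read_session(dir_path) -> Session:
    """Read a session directory; unknown files are ignored with a warning."""
    d = Path(dir_path)
    meta_path = d / "session.json"
    if not meta_path.exists():
        raise FormatError(f"{d}: missing session.json")
    phase = json.loads(meta_path.read_text())["phase"]
    session = Session(phase=phase)

    for f32 in sorted(d.glob("*.f32")):
        sidecar = f32.with_suffix(".json")
        if not sidecar.exists():
            raise FormatError(f"{f32}: missing JSON sidecar")
        meta = json.loads(sidecar.read_text())
        samples = np.fromfile(f32, dtype="<f4").astype(np.float64)
        session.signals[f32.stem] = SampledSignal(
            samples, float(meta["rate_hz"]), float(meta.get("t0_s", 0.0)),
            f32.stem)

    spikes_path = d / "spikes.tsv"
    if spikes_path.exists():
        df = pd.read_csv(spikes_path, sep="\t", float_precision="round_trip",
                         dtype={"unit_id": str, "region": str})
        for (uid, region), grp in df.groupby(["unit_id", "region"], sort=True):
            times = grp["time_s"].to_numpy()
            if np.any(np.diff(times) < 0):
                raise ValidationError(
                    f"spikes.tsv: times out of order for unit {uid}")
            session.trains.append(SpikeTrain(uid, region, times))

    wf_path = d / "waveforms.tsv"
    if wf_path.exists():
        df = pd.read_csv(wf_path, sep="\t", float_precision="round_trip",
                         dtype={"unit_id": str})
        scols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
        scols.sort(key=lambda c: int(c[1:]))
        for r in df.itertuples():
            wave = np.array([getattr(r, c) for c in scols], dtype=np.float64)
            session.waveforms.append(
                UnitWaveform(str(r.unit_id), wave, float(r.dt_ms),
                             int(r.trough_index), int(r.channel)))

    if (d / "trajectory.tsv").exists():
        session.trajectory = pd.read_csv(d / "trajectory.tsv", sep="\t",
                                         float_precision="round_trip")
    if (d / "trials.tsv").exists():
        session.trials = pd.read_csv(d / "trials.tsv", sep="\t",
                                     float_precision="round_trip")
    if (d / "hypnogram.tsv").exists():
        session.hypnogram = read_hypnogram(d / "hypnogram.tsv")

    ev_dir = d / "events"
    if ev_dir.is_dir():
        for f in sorted(ev_dir.glob("*.tsv")):
            session.events[f.stem] = read_events(f, f.stem)

    known = set(_KNOWN_FILES)
    for f in sorted(d.iterdir()):
        if f.is_dir() and f.name == "events":
            continue
        if f.suffix in {".f32"} or (f.suffix == ".json"
                                    and (d / f"{f.stem}.f32").exists()):
            continue
        if f.name not in known:
            log.warning("ignoring unknown file %s", f)
    return session


def write_psth_h5(pm, path) -> None:
    """PSTH matrix as HDF5 with /lags, /unit_ids, /z."""
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("lags", data=pm.lags_s)
        f.create_dataset("unit_ids", data=np.array(pm.unit_ids, dtype="S"))
        f.create_dataset("z", data=pm.z)
        f.attrs["n_events"] = pm.n_events


def write_tfmap_h5(tfmap, path) -> None:
    """Time-frequency map as HDF5 with /times, /freqs, /power."""
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=tfmap.times_s)
        f.create_dataset("freqs", data=tfmap.freqs_hz)
        f.create_dataset("power", data=tfmap.power)
        f.attrs["normalization"] = tfmap.normalization
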