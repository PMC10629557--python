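"""File layouts: HDF5 trace containers, CSV tables, TIFF image stacks.

HDF5 layout (one file per run/condition)::

    /config                  YAML dump of the SimConfig (attrs)
    /traces/<loc>/<channel>  1-D intensity array; attrs: frame_interval, t0,
                             excitation
    /timeline                flat event table (same columns as the CSV)

Interval tables and event tables round-trip through plain CSV with
documented column names.  Image stacks are multi-page TIFF plus a JSON
sidecar carrying excitation labels, frame times, and ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import SimConfig
from .intervals import Interval
from .render import ImageStack, Trace, TraceSet
from .simulate import BindingEvent, EventTimeline, LocationTimeline

__all__ = ["timeline_to_frame", "write_timeline_csv", "intervals_to_frame",
           "write_intervals_csv", "read_intervals_csv", "save_run_h5",
           "load_traces_h5", "save_image_stack", "load_image_stack"]

INTERVAL_COLUMNS = ["location_id", "channel", "episode_id", "start_frame",
                    "end_frame", "start_time_s", "end_time_s", "stoichiometry",
                    "censored_start", "censored_end"]


def timeline_to_frame(timeline: EventTimeline) -> pd.DataFrame:
    """Flat per-event table of a ground-truth timeline."""
    rows = []
    for loc in timeline:
        for ev in loc.events:
            rows.append({
                "location_id": loc.location_id, "is_dna": loc.is_dna,
                "is_active": loc.is_active, "species": ev.species,
                "arrival_s": ev.arrival, "departure_s": ev.departure,
                "censored": ev.censored, "specific": ev.specific,
                "ordinal": ev.ordinal,
                "release_class": ev.tags.get("release_class", ""),
                "mo": bool(ev.tags.get("mo", False)),
                "salt_stable": loc.salt_stable,
            })
    return pd.DataFrame(rows)


def write_timeline_csv(timeline: EventTimeline, path) -> None:
    timeline_to_frame(timeline).to_csv(path, index=False)


def intervals_to_frame(intervals: List[Interval]) -> pd.DataFrame:
    rows = [{
        "location_id": iv.location_id, "channel": iv.channel,
        "episode_id": iv.episode_id, "start_frame": iv.start_frame,
        "end_frame": iv.end_frame, "start_time_s": iv.start_time,
        "end_time_s": iv.end_time, "stoichiometry": iv.stoichiometry,
        "censored_start": iv.censored_start, "censored_end": iv.censored_end,
    } for iv in intervals]
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def write_intervals_csv(intervals: List[Interval], path) -> None:
    intervals_to_frame(intervals).to_csv(path, index=False)


def read_intervals_csv(path) -> List[Interval]:
    df = pd.read_csv(path)
    out: List[Interval] = []
    for _, r in df.iterrows():
        nf = int(r.end_frame) - int(r.start_frame)
        dt = ((r.end_time_s - r.start_time_s) / nf) if nf else 1.0
        out.append(Interval(int(r.location_id), str(r.channel),
                            int(r.start_frame), int(r.end_frame), float(dt),
                            t0=float(r.start_time_s) - int(r.start_frame) * float(dt),
                            stoichiometry=int(r.stoichiometry),
                            censored_start=bool(r.censored_start),
                            censored_end=bool(r.censored_end),
                            episode_id=int(r.episode_id)))
    return out


def save_run_h5(path, traces: TraceSet, config: SimConfig,
                timeline: Optional[EventTimeline] = None) -> None:
    """Write traces (and optionally the ground-truth timeline) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["config_yaml"] = yaml.safe_dump(config.to_dict())
        g = f.create_group("traces")
        for loc_id, chans in traces.items():
            gl = g.create_group(str(loc_id))
            for name, tr in chans.items():
                d = gl.create_dataset(name, data=tr.values)
                d.attrs["frame_interval"] = tr.frame_interval
                d.attrs["t0"] = tr.t0
                d.attrs["excitation"] = tr.excitation
        if timeline is not None:
            df = timeline_to_frame(timeline)
            rec = df.to_records(index=False)
            # h5py needs fixed-width strings
            dt = [(n, "S32" if rec.dtype[n].kind in "OU" else rec.dtype[n])
                  for n in rec.dtype.names]
            f.create_dataset("timeline", data=rec.astype(dt))


def load_traces_h5(path) -> tuple[TraceSet, SimConfig]:
    with h5py.File(path, "r") as f:
        cfg = SimConfig.from_dict(yaml.safe_load(f.attrs["config_yaml"]))
        out = TraceSet()
        for loc_id, gl in f["traces"].items():
            chans: Dict[str, Trace] = {}
            for name, d in gl.items():
                chans[name] = Trace(int(loc_id), name, d[...],
                                    float(d.attrs["frame_interval"]),
                                    excitation=str(d.attrs["excitation"]),
                                    t0=float(d.attrs["t0"]))
            out[int(loc_id)] = chans
    return out, cfg


def save_image_stack(path, stack: ImageStack) -> None:
    """Multi-page TIFF plus a JSON sidecar with labels, times, and truth."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    truth = stack.truth
    sidecar = {
        "excitation": list(stack.excitation),
        "times_s": stack.times.tolist(),
        "pixel_size": stack.pixel_size,
        "truth": {
            "dna": np.asarray(truth.get("dna", [])).tolist(),
            "fiducial": np.asarray(truth.get("fiducial", [])).tolist(),
            "impurity": np.asarray(truth.get("impurity", [])).tolist(),
            "drift": np.asarray(truth.get("drift", [])).tolist(),
            "n_ref": int(truth.get("n_ref", 0)),
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_image_stack(path) -> ImageStack:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    side = json.loads(path.with_suffix(".json").read_text())
    truth = {k: np.asarray(v) for k, v in side["truth"].items()
             if k != "n_ref"}
    truth["n_ref"] = side["truth"]["n_ref"]
    return ImageStack(frames=frames, excitation=side["excitation"],
                      times=np.asarray(side["times_s"]),
                      pixel_size=side["pixel_size"], truth=truth)
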