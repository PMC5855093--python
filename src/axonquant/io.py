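"""Readers and writers for the plain-text and TIFF formats of the pipeline.

Tracks:        CSV with columns granule_id, t_s, pos_um
Domain counts: CSV with columns t_bin_s, n_central, n_peripheral
Traces:        CSV with columns filopodium_id, frame, t_s, length_um
Puncta/dots:   CSV with columns id, x_um, y_um [, intensity]
Events:        JSON {gc_trajectory: [[t,x,y],...], target_path: [[x,y],...],
               contact_time, contacts: [{id,start,end},...]}
ROI lines:     JSON {x1,y1,x2,y2} in pixels
Polygons:      JSON list of [x, y] um pairs
Images:        single- or two-channel TIFF via tifffile
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .colocalization import PunctumSet
from .encounters import EncounterEvent, FilopodialContact
from .granule_transport import DomainCounts, Track
from .growth_cone import FilopodiumTrace
from .tract_sorting import ReferenceLine, TractImage


def read_tracks_csv(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    return [
        Track(str(gid), g["t_s"].to_numpy(), g["pos_um"].to_numpy())
        for gid, g in df.sort_values(["granule_id", "t_s"]).groupby("granule_id")
    ]


def write_tracks_csv(tracks: list[Track], path: str | Path) -> None:
    rows = [
        (t.granule_id, ts, ps) for t in tracks for ts, ps in zip(t.times, t.positions)
    ]
    pd.DataFrame(rows, columns=["granule_id", "t_s", "pos_um"]).to_csv(path, index=False)


def read_domain_counts_csv(path: str | Path) -> list[DomainCounts]:
    df = pd.read_csv(path)
    return [
        DomainCounts(float(r.t_bin_s), int(r.n_central), int(r.n_peripheral))
        for r in df.itertuples()
    ]


def write_domain_counts_csv(counts: list[DomainCounts], path: str | Path) -> None:
    pd.DataFrame(
        [(c.time_bin, c.n_central, c.n_peripheral) for c in counts],
        columns=["t_bin_s", "n_central", "n_peripheral"],
    ).to_csv(path, index=False)


def read_traces_csv(path: str | Path, frame_interval: float = 5.0) -> list[FilopodiumTrace]:
    df = pd.read_csv(path)
    traces = []
    for fid, g in df.sort_values(["filopodium_id", "frame"]).groupby("filopodium_id"):
        traces.append(FilopodiumTrace(str(fid), g["length_um"].to_numpy(), frame_interval))
    return traces


def read_event_json(path: str | Path) -> EncounterEvent:
    with open(path) as fh:
        d = json.load(fh)
    traj = np.asarray(d["gc_trajectory"], dtype=float)
    return EncounterEvent(
        times=traj[:, 0],
        points=traj[:, 1:3],
        target_path=np.asarray(d["target_path"], dtype=float),
        contact_time=float(d["contact_time"]),
        contacts=[
            FilopodialContact(str(c["id"]), float(c["start"]), float(c["end"]))
            for c in d.get("contacts", [])
        ],
        observation_end=d.get("observation_end"),
        origin=tuple(d["origin"]) if d.get("origin") else None,
        event_id=str(d.get("event_id", Path(path).stem)),
    )


def write_event_json(event: EncounterEvent, path: str | Path) -> None:
    d = {
        "gc_trajectory": [[t, *map(float, p)] for t, p in zip(event.times, event.points)],
        "target_path": event.target_path.tolist(),
        "contact_time": event.contact_time,
        "contacts": [
            {"id": c.filopodium_id, "start": c.start, "end": c.end} for c in event.contacts
        ],
        "observation_end": event.observation_end,
        "origin": list(event.origin) if event.origin else None,
        "event_id": event.event_id,
    }
    Path(path).write_text(json.dumps(d, indent=1))


def read_puncta_csv(path: str | Path, channel: str = "") -> PunctumSet:
    df = pd.read_csv(path)
    inten = df["intensity"].to_numpy() if "intensity" in df.columns else None
    return PunctumSet(channel or Path(path).stem, df[["x_um", "y_um"]].to_numpy(), inten)


def read_line_json(path: str | Path) -> ReferenceLine:
    with open(path) as fh:
        d = json.load(fh)
    return ReferenceLine((d["y1"], d["x1"]), (d["y2"], d["x2"]))


def read_tract_tiff(
    path: str | Path, pixel_size: float, orientation: str = "high", channel_axis: int = 0
) -> TractImage:
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[channel_axis] != 2:
        raise ValueError("expected a two-channel TIFF")
    arr = np.moveaxis(arr, channel_axis, 0).astype(float)
    return TractImage(arr[0], arr[1], pixel_size, orientation)


def write_tract_tiff(image: TractImage, path: str | Path) -> None:
    tifffile.imwrite(path, np.stack([image.dorsal, image.ventral]).astype(np.float32))


def read_polygon_json(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        return np.asarray(json.load(fh), dtype=float)
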