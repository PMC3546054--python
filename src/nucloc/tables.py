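"""Tabular and image I/O.

The native table format is UTF-8 tab-separated text with a commented metadata
header (``# key: value`` lines), one row per cell: cell_id followed by one
localization value per frame, columns labelled with the frame time in seconds
(``t0``, ``t4``, ...).  This mirrors the per-cell trajectory sheets that
single-cell shuttling studies ship as supplementary data.  Spreadsheets
(.xlsx) are accepted read-only; row/column orientation is auto-detected from
the header.  Values are written with shortest round-tripping repr, so a
write/read cycle is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .dynamics import CellMetrics, StateTrack, AnalysisParams
from .quantify import CellRegion, ImageStack, LocalizationTrajectory

__all__ = [
    "write_trajectories",
    "read_trajectories",
    "write_state_tracks",
    "read_state_tracks",
    "write_metrics",
    "read_metrics",
    "write_stack",
    "read_stack",
    "write_masks",
    "read_masks",
]


def _fmt(x: float) -> str:
    return repr(float(x))


def write_trajectories(
    path: str | Path,
    trajs: list[LocalizationTrajectory],
    metadata: dict | None = None,
) -> None:
    """Write localization trajectories as a TSV trajectory table."""
    if not trajs:
        raise ValueError("nothing to write")
    base = trajs[0].times
    for t in trajs[1:]:
        if not np.array_equal(t.times, base):
            raise ValueError("trajectories must share a time base")
    path = Path(path)
    meta = dict(metadata or {})
    meta.setdefault("frame_interval", float(base[1] - base[0]) if len(base) > 1 else 0.0)
    with path.open("w", encoding="utf-8") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        header = ["cell_id"] + [f"t{v:g}" for v in base]
        fh.write("\t".join(header) + "\n")
        for traj in trajs:
            row = [traj.cell_id] + [_fmt(v) for v in traj.loc_value]
            fh.write("\t".join(row) + "\n")


def _parse_meta(lines: list[str]) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    return meta


def _times_from_labels(labels: list[str], meta: dict) -> np.ndarray:
    vals = []
    for lab in labels:
        s = str(lab).strip()
        if s.startswith(("t", "T")):
            s = s[1:].lstrip("=")
        try:
            vals.append(float(s))
        except ValueError:
            vals.append(np.nan)
    times = np.array(vals)
    if np.any(np.isnan(times)) or (len(times) > 1 and not np.all(np.diff(times) > 0)):
        dt = float(meta.get("frame_interval", 4.0))
        times = np.arange(len(labels)) * dt
    return times


def read_trajectories(
    path: str | Path,
) -> tuple[list[LocalizationTrajectory], dict]:
    """Read a trajectory table (TSV or spreadsheet). Returns (trajectories, metadata).

    Orientation is auto-detected: rows are cells when the first header cell is
    ``cell_id``; if instead the first column is labelled ``time`` the table is
    transposed (columns are cells).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, header=0)
        meta: dict = {}
    else:
        meta_lines = []
        with path.open("r", encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#"):
                    meta_lines.append(line)
                else:
                    break
        meta = _parse_meta(meta_lines)
        df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    if df.shape[1] < 2 or df.shape[0] < 1:
        raise ValueError(f"{path}: table must have a label column and data")

    first_col = str(df.columns[0]).strip().lower()
    if first_col in ("time", "t", "times", "time_s"):
        # columns are cells: first column holds times
        times = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
        if np.any(np.isnan(times)):
            raise ValueError(f"{path}: non-numeric time column")
        cell_ids = [str(c) for c in df.columns[1:]]
        payload = df.iloc[:, 1:].T
        payload.index = cell_ids
    else:
        labels = [str(c) for c in df.columns[1:]]
        times = _times_from_labels(labels, meta)
        payload = df.iloc[:, 1:]
        payload.index = df.iloc[:, 0].astype(str).tolist()

    trajs = []
    for i, (cid, row) in enumerate(payload.iterrows()):
        vals = np.empty(len(row))
        for j, raw in enumerate(row):
            try:
                vals[j] = float(raw)  # exact round trip of repr-formatted values
            except (TypeError, ValueError):
                vals[j] = np.nan
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise ValueError(
                f"{path}: row {i + 1} (cell {cid!r}), column {bad[0] + 2}: "
                "non-numeric or non-finite localization value"
            )
        if vals.size != times.size:
            raise ValueError(f"{path}: row {i + 1} (cell {cid!r}) is not rectangular")
        trajs.append(LocalizationTrajectory(str(cid), times.copy(), vals))
    return trajs, meta


def write_state_tracks(
    path: str | Path, tracks: list[StateTrack], metadata: dict | None = None
) -> None:
    if not tracks:
        raise ValueError("nothing to write")
    base = tracks[0].times
    path = Path(path)
    prov = tracks[0].provenance
    meta = dict(metadata or {})
    meta.update(
        window=prov.window,
        threshold=prov.threshold,
        min_run=prov.min_run,
        observation_window=prov.observation_window,
        permanence_tail=prov.permanence_tail,
    )
    with path.open("w", encoding="utf-8") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("\t".join(["cell_id"] + [f"t{v:g}" for v in base]) + "\n")
        for track in tracks:
            fh.write("\t".join([track.cell_id] + [str(int(s)) for s in track.state]) + "\n")


def read_state_tracks(path: str | Path) -> tuple[list[StateTrack], dict]:
    path = Path(path)
    meta_lines = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                meta_lines.append(line)
            else:
                break
    meta = _parse_meta(meta_lines)
    params = AnalysisParams(
        window=int(meta.get("window", 5)),
        threshold=float(meta.get("threshold", 0.28)),
        min_run=int(meta.get("min_run", 5)),
        observation_window=float(meta.get("observation_window", 3600.0)),
        permanence_tail=float(meta.get("permanence_tail", 600.0)),
    )
    df = pd.read_csv(path, sep="\t", comment="#", header=0)
    times = _times_from_labels([str(c) for c in df.columns[1:]], meta)
    tracks = []
    for _, row in df.iterrows():
        state = row.iloc[1:].to_numpy(dtype=np.int8)
        tracks.append(StateTrack(str(row.iloc[0]), times.copy(), state, params))
    return tracks, meta


_METRIC_COLS = [
    "cell_id",
    "responded",
    "first_localization_time",
    "total_nuclear_time",
    "n_events",
    "classification",
]


def write_metrics(path: str | Path, metrics: list[CellMetrics]) -> None:
    rows = []
    for m in metrics:
        rows.append(
            {
                "cell_id": m.cell_id,
                "responded": int(m.responded),
                "first_localization_time": (
                    "" if m.first_localization_time is None
                    else _fmt(m.first_localization_time)
                ),
                "total_nuclear_time": _fmt(m.total_nuclear_time),
                "n_events": m.n_events,
                "classification": m.classification,
            }
        )
    pd.DataFrame(rows, columns=_METRIC_COLS).to_csv(path, sep="\t", index=False)


def read_metrics(path: str | Path) -> list[CellMetrics]:
    df = pd.read_csv(path, sep="\t", header=0, dtype={"cell_id": str})
    out = []
    for _, row in df.iterrows():
        first = row["first_localization_time"]
        out.append(
            CellMetrics(
                cell_id=str(row["cell_id"]),
                responded=bool(int(row["responded"])),
                first_localization_time=None if pd.isna(first) else float(first),
                total_nuclear_time=float(row["total_nuclear_time"]),
                n_events=int(row["n_events"]),
                classification=str(row["classification"]),
            )
        )
    return out


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Multi-frame grayscale TIFF; timestamps stored as JSON metadata."""
    tifffile.imwrite(
        Path(path),
        stack.frames.astype(np.float32),
        photometric="minisblack",
        metadata={"timestamps": stack.timestamps.tolist()},
    )


def read_stack(path: str | Path, frame_interval: float = 4.0) -> ImageStack:
    with tifffile.TiffFile(Path(path)) as tif:
        frames = tif.asarray()
        meta = tif.shaped_metadata
    ts = None
    if meta:
        ts = meta[0].get("timestamps")
    if frames.ndim == 2:
        frames = frames[None]
    if ts is None:
        ts = np.arange(frames.shape[0]) * frame_interval
    return ImageStack(np.asarray(frames, dtype=float), np.asarray(ts, dtype=float))


def write_masks(path: str | Path, regions: list[CellRegion], shape: tuple[int, int]) -> None:
    """Labelled integer mask TIFF: 0 = background, k = k-th cell (1-based)."""
    mask = np.zeros(shape, dtype=np.uint16)
    ids = {}
    for k, region in enumerate(regions, start=1):
        mask[region.rows, region.cols] = k
        ids[str(k)] = region.cell_id
    tifffile.imwrite(Path(path), mask, metadata={"cell_ids": json.dumps(ids)})


def read_masks(path: str | Path) -> list[CellRegion]:
    with tifffile.TiffFile(Path(path)) as tif:
        mask = tif.asarray()
        meta = tif.shaped_metadata
    ids = {}
    if meta and "cell_ids" in meta[0]:
        ids = json.loads(meta[0]["cell_ids"])
    regions = []
    for k in np.unique(mask):
        if k == 0:
            continue
        rows, cols = np.nonzero(mask == k)
        cid = ids.get(str(int(k)), f"cell_{int(k)}")
        regions.append(CellRegion(cid, rows, cols))
    return regions
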