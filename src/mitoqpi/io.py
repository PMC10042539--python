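"""TIFF stack and CSV readers/writers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .classify import CHANNELS, CellClassRecord, FluorImage
from .errors import InputError
from .qpi import PhaseImage
from .tracking import CellTrack, LineageRecord

__all__ = [
    "read_stack",
    "write_stack",
    "write_tracks",
    "read_tracks",
    "write_lineages",
]


def read_stack(
    path: str | Path,
    channel: str = "phase",
    frame_interval: float = 0.25,
) -> list:
    """Read a multi-frame TIFF as a list of PhaseImage or FluorImage.

    ``channel`` is ``"phase"`` or one of the fluorescence channel names;
    frame times are ``i * frame_interval`` in acquisition order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image stack not found: {path}")
    data = np.asarray(tifffile.imread(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise InputError(f"{path}: expected a 2-D or 3-D TIFF, got ndim={data.ndim}")
    frames = []
    for i, plane in enumerate(data):
        t = i * frame_interval
        if channel == "phase":
            frames.append(PhaseImage(plane.astype(float), frame_time=t))
        elif channel in CHANNELS:
            frames.append(FluorImage(plane.astype(float), channel=channel, frame_time=t))
        else:
            raise InputError(f"unknown channel {channel!r}")
    return frames


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a (T, H, W) float stack as a multi-frame float32 TIFF."""
    arr = np.asarray(stack, dtype=np.float32)
    if arr.ndim != 3:
        raise InputError(f"expected a (T, H, W) stack, got shape {arr.shape}")
    tifffile.imwrite(Path(path), arr)


TRACK_COLUMNS = [
    "track_id", "frame", "time_h", "x_px", "y_px", "mass_pg",
    "recipient_marker", "donor_mito", "cell_class", "fate",
]


def write_tracks(
    tracks: list[CellTrack],
    classes: list[CellClassRecord] | None,
    path: str | Path,
) -> pd.DataFrame:
    """Write one CSV row per (track, frame); returns the table written.

    Numeric fields are written at full precision, so a read-back reproduces
    them bit-exactly.
    """
    cls_by_id = {c.track_id: c.cell_class for c in (classes or [])}
    rows = []
    for tr in tracks:
        for i in range(tr.n_frames):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": tr.frame_indices[i],
                    "time_h": tr.times[i],
                    "x_px": tr.centroids[i][1],
                    "y_px": tr.centroids[i][0],
                    "mass_pg": tr.masses[i],
                    "recipient_marker": _at(tr.intensities.get("recipient_marker"), i),
                    "donor_mito": _at(tr.intensities.get("donor_mito"), i),
                    "cell_class": cls_by_id.get(tr.track_id, ""),
                    "fate": tr.fate,
                }
            )
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    # %.17g guarantees bit-exact float round trips through the CSV
    df.to_csv(Path(path), index=False, float_format="%.17g")
    return df


def _at(series: list[float] | None, i: int) -> float:
    if series is None or i >= len(series):
        return float("nan")
    return series[i]


def read_tracks(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"track table not found: {path}")
    return pd.read_csv(path, float_precision="round_trip")


def write_lineages(lineages: list[LineageRecord], path: str | Path) -> pd.DataFrame:
    """One CSV row per lineage: parent/daughter ids and inheritance flags."""
    rows = [
        {
            "parent_id": lin.parent.track_id,
            "division_time_h": lin.parent.division_time,
            "daughter1_id": lin.daughters[0].track_id,
            "daughter2_id": lin.daughters[1].track_id,
            "daughter1_inherits": lin.inheritance[0],
            "daughter2_inherits": lin.inheritance[1],
        }
        for lin in lineages
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "parent_id", "division_time_h", "daughter1_id", "daughter2_id",
            "daughter1_inherits", "daughter2_inherits",
        ],
    )
    df.to_csv(Path(path), index=False)
    return df
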