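"""On-disk interchange: 8-bit PNG frames with CSV sidecars, table and
gridded-field CSV round-trips."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from imageio import v3 as iio

from .conc import GriddedField
from .segment import Frame

__all__ = ["write_frames", "read_frames", "write_gridded", "read_gridded"]

_SIDECAR = "frames.csv"


def write_frames(frames: list[np.ndarray] | list[Frame], out_dir: str | Path,
                 metadata: pd.DataFrame | None = None) -> Path:
    """Write frames as 8-bit PNGs plus a sidecar CSV of per-frame metadata.

    ``metadata`` needs one row per frame (columns ``depth_m, along_track_m,
    time_s``); if frames are :class:`Frame` objects it is derived from them.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, fr in enumerate(frames):
        if isinstance(fr, Frame):
            px, meta = fr.pixels, (fr.depth_m, fr.along_track_m, fr.time_s)
        else:
            px = np.asarray(fr, float)
            if metadata is not None:
                m = metadata.iloc[i]
                meta = (m["depth_m"], m["along_track_m"], m["time_s"])
            else:
                meta = (0.0, 0.0, 0.0)
        iio.imwrite(out / f"frame_{i:06d}.png",
                    np.clip(px * 255.0, 0, 255).astype(np.uint8))
        rows.append(dict(frame=i, file=f"frame_{i:06d}.png",
                         depth_m=meta[0], along_track_m=meta[1], time_s=meta[2]))
    pd.DataFrame(rows).to_csv(out / _SIDECAR, index=False)
    return out


def read_frames(in_dir: str | Path) -> list[Frame]:
    """Read PNG frames + sidecar back into :class:`Frame` objects
    (intensities rescaled to [0, 1])."""
    in_dir = Path(in_dir)
    sidecar = pd.read_csv(in_dir / _SIDECAR)
    frames = []
    for _, row in sidecar.iterrows():
        px = iio.imread(in_dir / row["file"]).astype(float) / 255.0
        frames.append(Frame(px, row["depth_m"], row["along_track_m"], row["time_s"]))
    return frames


def write_gridded(field: GriddedField, path: str | Path) -> Path:
    """Gridded field as a CSV matrix: first column depth_m, header along_track_m."""
    path = Path(path)
    df = pd.DataFrame(field.values, index=pd.Index(field.z_m, name="depth_m"),
                      columns=field.x_m)
    df.attrs["units"] = field.units
    df.to_csv(path)
    return path


def read_gridded(path: str | Path, units: str = "") -> GriddedField:
    df = pd.read_csv(path, index_col=0)
    return GriddedField(df.columns.to_numpy(float), df.index.to_numpy(float),
                        df.to_numpy(float), units=units)
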