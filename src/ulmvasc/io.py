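"""File I/O: TIFF frame stacks, NIfTI volumes, CSV tables, YAML descriptors.

Tabular conventions: header rows, fixed column order, floats with 6
significant digits; in-plane coordinates in mm, radii in µm, densities in
percent in the summary tables.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import Detection, FrameStack, RadiusMap, Track, Volume3D

__all__ = [
    "read_frame_stack",
    "write_frame_stack",
    "read_volume",
    "write_volume",
    "write_radius_map",
    "detections_to_frame",
    "detections_from_frame",
    "tracks_to_frame",
    "tracks_from_frame",
    "write_csv",
    "read_yaml",
    "write_yaml",
]

_FLOAT_FMT = "%.6g"


def read_frame_stack(
    path: str | Path, pixel_size: float, frame_rate: float, kind: str = "contrast"
) -> FrameStack:
    """Load a multi-page TIFF or a NIfTI stack as a FrameStack.

    NIfTI stacks are expected (nz, nx, n_frames) and are transposed to the
    internal (n_frames, nz, nx) layout.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
        arr = np.asanyarray(nib.load(str(path)).dataobj)
        if arr.ndim != 3:
            raise ValueError("expected a 3D (nz, nx, time) NIfTI")
        frames = np.moveaxis(arr, 2, 0)
    else:
        frames = tifffile.imread(str(path))
        if frames.ndim == 2:
            frames = frames[None]
    return FrameStack(frames=frames, pixel_size=pixel_size, frame_rate=frame_rate, kind=kind)


def write_frame_stack(stack: FrameStack, path: str | Path) -> None:
    """Write the frames as a multi-page float32 TIFF with resolution tags."""
    tifffile.imwrite(
        str(path),
        stack.frames.astype(np.float32),
        photometric="minisblack",
        resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
        metadata={
            "pixel_size_mm": stack.pixel_size,
            "frame_rate_hz": stack.frame_rate,
            "kind": stack.kind,
        },
    )


def read_volume(path: str | Path, voxel_size_um: float | None = None) -> Volume3D:
    """Load a NIfTI volume; voxel size from the header unless overridden."""
    img = nib.load(str(path))
    if voxel_size_um is None:
        voxel_size_um = float(img.header.get_zooms()[0]) * 1000.0  # header in mm
    return Volume3D(data=np.asanyarray(img.dataobj).astype(float), voxel_size_um=voxel_size_um)


def write_volume(vol: Volume3D | np.ndarray, path: str | Path, voxel_size_um: float = 26.5) -> None:
    if isinstance(vol, Volume3D):
        data, vs = vol.data, vol.voxel_size_um
    else:
        data, vs = np.asarray(vol, dtype=float), voxel_size_um
    affine = np.diag([vs / 1000.0, vs / 1000.0, vs / 1000.0, 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def write_radius_map(rmap: RadiusMap, path: str | Path) -> None:
    write_volume(rmap.radius_vox, path, voxel_size_um=rmap.voxel_size_um)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def detections_to_frame(detections: list[list[Detection]]) -> pd.DataFrame:
    rows = [
        (d.frame_index, d.x_mm, d.z_mm, d.amplitude)
        for per_frame in detections
        for d in per_frame
    ]
    return pd.DataFrame(rows, columns=["frame", "x_mm", "z_mm", "amplitude"])


def detections_from_frame(df: pd.DataFrame) -> list[list[Detection]]:
    n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    out: list[list[Detection]] = [[] for _ in range(n_frames)]
    for row in df.itertuples(index=False):
        out[int(row.frame)].append(
            Detection(
                frame_index=int(row.frame),
                x_mm=float(row.x_mm),
                z_mm=float(row.z_mm),
                amplitude=float(getattr(row, "amplitude", 1.0)),
            )
        )
    return out


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = [
        (t.track_id, int(f), float(p[0]), float(p[1]))
        for t in tracks
        for f, p in zip(t.frame_indices, t.positions_mm)
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_mm", "z_mm"])


def tracks_from_frame(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                track_id=int(tid),
                frame_indices=grp["frame"].to_numpy(dtype=int),
                positions_mm=grp[["x_mm", "z_mm"]].to_numpy(dtype=float),
            )
        )
    return tracks


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# YAML
# ---------------------------------------------------------------------------


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
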