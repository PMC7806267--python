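"""File I/O: track tables (CSV), image stacks (TIFF), count matrices (MTX).

Track CSV schema (one row per frame × cell):

====================  =======================================================
column                meaning
====================  =======================================================
``frame``             0-based frame index
``time_min``          acquisition time in minutes (0 = end of division)
``cell_id``           ``a`` / ``b`` for the siblings, ``ref0`` … for
                      mature-cell references
``x``, ``y``          centroid coordinates (pixels unless noted); an optional
                      ``z`` column is carried through but ignored by the
                      2-D angle analysis
``role``              ``sibling`` or ``reference``
``reporter``          1/0/empty — emx2-reporter status of sibling cells
====================  =======================================================
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from .track_geometry import PairTrajectory

__all__ = [
    "trajectory_to_frame",
    "frame_to_trajectory",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_count_matrix",
    "read_count_matrix",
    "write_json",
]


def trajectory_to_frame(trajectory: PairTrajectory, pair_id: str = "pair0") -> pd.DataFrame:
    """Flatten a :class:`PairTrajectory` into the track CSV schema."""
    rows = []
    rep = trajectory.reporter or {}

    def _status(cell: str):
        v = rep.get(cell)
        if isinstance(v, dict):
            v = v.get("status")
        return "" if v is None else int(bool(v))

    for k, t in enumerate(trajectory.times):
        for cell, arr in (("a", trajectory.cell_a_xy), ("b", trajectory.cell_b_xy)):
            rows.append({
                "pair_id": pair_id, "frame": k, "time_min": float(t), "cell_id": cell,
                "x": float(arr[k, 0]), "y": float(arr[k, 1]),
                "role": "sibling", "reporter": _status(cell),
            })
        if trajectory.reference_points is not None:
            for j in range(trajectory.reference_points.shape[1]):
                rows.append({
                    "pair_id": pair_id, "frame": k, "time_min": float(t),
                    "cell_id": f"ref{j}",
                    "x": float(trajectory.reference_points[k, j, 0]),
                    "y": float(trajectory.reference_points[k, j, 1]),
                    "role": "reference", "reporter": "",
                })
    df = pd.DataFrame(rows)
    df.attrs["neuromast_axis"] = trajectory.neuromast_axis
    return df


def frame_to_trajectory(df: pd.DataFrame, neuromast_axis: Optional[str] = None) -> PairTrajectory:
    """Rebuild a :class:`PairTrajectory` from the track CSV schema."""
    if neuromast_axis is None:
        neuromast_axis = df.attrs.get("neuromast_axis", df.get("neuromast_axis", pd.Series(["AP"])).iloc[0]
                                      if "neuromast_axis" in df.columns else "AP")
    sib = df[df["role"] == "sibling"].sort_values(["frame", "cell_id"])
    frames = np.sort(sib["frame"].unique())
    times = (
        sib.drop_duplicates("frame").sort_values("frame")["time_min"].to_numpy(dtype=float)
    )

    def _cells(cell: str) -> np.ndarray:
        part = sib[sib["cell_id"] == cell].set_index("frame").reindex(frames)
        return part[["x", "y"]].to_numpy(dtype=float)

    reporter = {}
    for cell in ("a", "b"):
        vals = sib.loc[sib["cell_id"] == cell, "reporter"]
        vals = vals[vals.astype(str).str.len() > 0]
        if len(vals):
            reporter[cell] = bool(int(float(vals.iloc[0])))
    refs = None
    ref_rows = df[df["role"] == "reference"]
    if len(ref_rows):
        ids = sorted(ref_rows["cell_id"].unique())
        refs = np.stack(
            [
                ref_rows[ref_rows["cell_id"] == rid]
                .set_index("frame").reindex(frames)[["x", "y"]]
                .to_numpy(dtype=float)
                for rid in ids
            ],
            axis=1,
        )
    return PairTrajectory(
        times=times,
        cell_a_xy=_cells("a"),
        cell_b_xy=_cells("b"),
        reference_points=refs,
        neuromast_axis=neuromast_axis,
        reporter=reporter or None,
    )


def write_tracks_csv(path, trajectories: Sequence[PairTrajectory]) -> None:
    """Write one or more trajectories to a single track CSV."""
    frames = []
    axis = None
    for k, tr in enumerate(trajectories):
        df = trajectory_to_frame(tr, pair_id=f"pair{k:04d}")
        df["neuromast_axis"] = tr.neuromast_axis
        axis = tr.neuromast_axis
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks_csv(path) -> List[PairTrajectory]:
    """Read all pairs from a track CSV written by :func:`write_tracks_csv`."""
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _pid, part in df.groupby("pair_id", sort=True):
        axis = part["neuromast_axis"].iloc[0] if "neuromast_axis" in part.columns else "AP"
        out.append(frame_to_trajectory(part, neuromast_axis=axis))
    return out


def write_stack_tiff(path, stack: np.ndarray, frame_interval_min: float = 3.0,
                     voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a TZYX uint16 stack with axis and interval metadata."""
    tifffile.imwrite(
        path,
        np.asarray(stack, dtype=np.uint16),
        photometric="minisblack",
        metadata={
            "axes": "TZYX",
            "frame_interval_min": frame_interval_min,
            "voxel_size_zyx": list(voxel_size),
        },
    )


def read_stack_tiff(path) -> Tuple[np.ndarray, dict]:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    return data, dict(meta)


def write_count_matrix(prefix, matrix: sparse.spmatrix, gene_names: Sequence[str],
                       cell_ids: Sequence[str]) -> None:
    """Write an MTX matrix plus genes/barcodes text files next to ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.coo_matrix(matrix))
    prefix.with_name(prefix.name + "_genes.txt").write_text("\n".join(gene_names) + "\n")
    prefix.with_name(prefix.name + "_barcodes.txt").write_text("\n".join(cell_ids) + "\n")


def read_count_matrix(prefix) -> Tuple[sparse.csr_matrix, List[str], List[str]]:
    prefix = Path(prefix)
    matrix = sparse.csr_matrix(spio.mmread(str(prefix.with_suffix(".mtx"))))
    genes = prefix.with_name(prefix.name + "_genes.txt").read_text().splitlines()
    cells = prefix.with_name(prefix.name + "_barcodes.txt").read_text().splitlines()
    return matrix, genes, cells


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
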