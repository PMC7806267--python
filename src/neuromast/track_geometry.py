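"""Drift correction and division-axis-referenced angles for sibling hair-cell tracks.

After a hair-cell precursor divides, the two nascent cells are tracked as 2-D
centroids over time.  The line through the two centroids at the end of the
division (frame 0) defines the reference ("horizontal") axis; everything
downstream — Rock/Roll phase segmentation and outcome classification — is a
function of the signed angle between the current inter-cell axis and that
reference axis.

Conventions
-----------
* Angles are in degrees, counterclockwise positive, with the image y-axis
  pointing down.  Classification uses ``|theta|`` so the sign convention is
  cosmetic.
* Frame 0 is the end of precursor division; callers trim earlier frames.
* 3-D centroids are accepted but only the (x, y) imaging-plane coordinates
  enter the angle computation, matching a projected-image workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "PairTrajectory",
    "AngleSeries",
    "correct_drift",
    "compute_angles",
    "fill_gaps",
]

#: maximum run of missing frames bridged by linear interpolation
MAX_GAP_FRAMES = 2


@dataclass
class PairTrajectory:
    """Timestamped centroids of two sibling hair cells.

    Parameters
    ----------
    times
        Strictly increasing sample times in minutes; ``times[0]`` corresponds
        to the end of the precursor division.
    cell_a_xy, cell_b_xy
        ``(n_frames, 2)`` centroid arrays (pixels or micrometers; see
        ``unit``).  NaN rows mark missing frames and must be filled with
        :func:`fill_gaps` before angle computation.
    reference_points
        Optional ``(n_frames, n_ref, 2)`` array of mature-cell centroids used
        for drift correction.
    neuromast_axis
        ``"AP"`` (x = anterior→posterior) or ``"DV"`` (y = dorsal→ventral).
    reporter
        Optional map ``{"a": bool, "b": bool}`` of emx2-reporter status, or
        per-cell dicts ``{"status": bool, "onset_frame": int}``.
    """

    times: np.ndarray
    cell_a_xy: np.ndarray
    cell_b_xy: np.ndarray
    reference_points: Optional[np.ndarray] = None
    neuromast_axis: str = "AP"
    reporter: Optional[dict] = None
    unit: str = "px"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cell_a_xy = np.asarray(self.cell_a_xy, dtype=float)
        self.cell_b_xy = np.asarray(self.cell_b_xy, dtype=float)
        if self.times.ndim != 1 or self.times.size < 3:
            raise ValueError("a trajectory needs at least 3 frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, arr in (("cell_a_xy", self.cell_a_xy), ("cell_b_xy", self.cell_b_xy)):
            if arr.shape != (self.times.size, 2):
                raise ValueError(f"{name} must have shape (n_frames, 2)")
        if self.reference_points is not None:
            self.reference_points = np.asarray(self.reference_points, dtype=float)
            if self.reference_points.ndim != 3 or self.reference_points.shape[0] != self.times.size:
                raise ValueError("reference_points must have shape (n_frames, n_ref, 2)")
        if self.neuromast_axis not in ("AP", "DV"):
            raise ValueError("neuromast_axis must be 'AP' or 'DV'")
        v0 = self.cell_b_xy[0] - self.cell_a_xy[0]
        if np.all(np.isfinite(v0)) and np.hypot(*v0) == 0.0:
            raise ValueError("cells coincide at frame 0: division axis undefined")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def frame_interval_min(self) -> float:
        """Median sampling interval in minutes."""
        return float(np.median(np.diff(self.times)))


@dataclass
class AngleSeries:
    """Signed angular displacement of the inter-cell axis vs the division axis.

    ``theta_deg`` is wrapped to (−180, 180]; ``theta_unwrapped_deg`` is the
    continuous accumulation of minimal-magnitude frame-to-frame changes and
    may exceed ±180 (a full exchange-and-return reaches ±360).
    """

    times: np.ndarray
    theta_deg: np.ndarray
    theta_unwrapped_deg: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self.theta_unwrapped_deg = np.asarray(self.theta_unwrapped_deg, dtype=float)
        if not (self.times.shape == self.theta_deg.shape == self.theta_unwrapped_deg.shape):
            raise ValueError("times and angle arrays must share one shape")
        if abs(self.theta_unwrapped_deg[0]) > 1e-9:
            raise ValueError("unwrapped angle must start at 0")
        if np.any(np.abs(np.diff(self.theta_unwrapped_deg)) >= 180.0):
            raise ValueError("frame-to-frame angle change >= 180 deg: aliased sampling")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def frame_interval_min(self) -> float:
        return float(np.median(np.diff(self.times)))


def fill_gaps(trajectory: PairTrajectory, max_gap: int = MAX_GAP_FRAMES) -> PairTrajectory:
    """Linearly interpolate missing (NaN) centroids across gaps of <= ``max_gap`` frames."""

    def _fill(arr: np.ndarray, label: str) -> np.ndarray:
        out = arr.copy()
        missing = ~np.isfinite(out).all(axis=1)
        if not missing.any():
            return out
        if missing[0] or missing[-1]:
            raise ValueError(f"{label}: first/last frame missing, cannot interpolate")
        # find runs of consecutive missing frames
        idx = np.flatnonzero(missing)
        run_start = idx[np.r_[True, np.diff(idx) > 1]]
        run_end = idx[np.r_[np.diff(idx) > 1, True]]
        for s, e in zip(run_start, run_end):
            if e - s + 1 > max_gap:
                raise ValueError(f"{label}: gap of {e - s + 1} frames at frame {s} exceeds {max_gap}")
            t0, t1 = s - 1, e + 1
            for k in range(s, e + 1):
                w = (trajectory.times[k] - trajectory.times[t0]) / (
                    trajectory.times[t1] - trajectory.times[t0]
                )
                out[k] = (1 - w) * out[t0] + w * out[t1]
        return out

    return replace(
        trajectory,
        cell_a_xy=_fill(trajectory.cell_a_xy, "cell_a"),
        cell_b_xy=_fill(trajectory.cell_b_xy, "cell_b"),
    )


def correct_drift(trajectory: PairTrajectory) -> PairTrajectory:
    """Remove rigid sample drift using mature-cell reference centroids.

    The mean of the reference centroids at each frame, relative to frame 0,
    estimates the per-frame stage/sample translation; it is subtracted from
    both sibling cells and from the references themselves (which therefore
    become stationary in the mean).
    """
    refs = trajectory.reference_points
    if refs is None or refs.shape[1] == 0:
        raise ValueError("drift correction requires reference_points")
    bad = np.flatnonzero(~np.isfinite(refs).all(axis=(1, 2)))
    if bad.size:
        raise ValueError(f"reference centroid missing at frame {int(bad[0])}")
    ref_mean = refs.mean(axis=1)            # (n_frames, 2)
    drift = ref_mean - ref_mean[0]
    return replace(
        trajectory,
        cell_a_xy=trajectory.cell_a_xy - drift,
        cell_b_xy=trajectory.cell_b_xy - drift,
        reference_points=refs - drift[:, None, :],
    )


def compute_angles(trajectory: PairTrajectory) -> AngleSeries:
    """Signed angle of the inter-cell axis relative to its frame-0 direction.

    The reference axis is the unit vector from cell *a* to cell *b* at frame
    0.  ``theta_deg[k]`` is the signed (CCW-positive) angle from that axis to
    the frame-``k`` inter-cell vector; the unwrapped series accumulates the
    minimal-magnitude change between consecutive frames.  Swapping the two
    cell labels flips both the reference and the current vector, so the
    angles are label-invariant.
    """
    v = trajectory.cell_b_xy - trajectory.cell_a_xy
    norms = np.hypot(v[:, 0], v[:, 1])
    if np.any(~np.isfinite(norms)):
        raise ValueError("trajectory contains missing centroids; run fill_gaps first")
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise ValueError(f"coincident centroids at frame {int(zero[0])}: angle undefined")
    u = v[0] / norms[0]
    # signed angle from u to v_k
    cross = u[0] * v[:, 1] - u[1] * v[:, 0]
    dot = v @ u
    theta = np.degrees(np.arctan2(cross, dot))
    # map -180 -> +180 so wrapped angles live in (-180, 180]
    theta[np.isclose(theta, -180.0)] = 180.0
    unwrapped = np.degrees(np.unwrap(np.radians(theta)))
    unwrapped -= unwrapped[0]  # exact zero at frame 0
    return AngleSeries(times=trajectory.times, theta_deg=theta, theta_unwrapped_deg=unwrapped)
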