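"""Rock/Roll phase segmentation, pair classification, and positional scoring.

After division, sibling hair cells first *rock* — the inter-cell axis
oscillates within ±30° of the division axis — and a majority then *roll*:
the angular displacement exceeds 30°, keeps increasing, and the pair rotates
through 180° to exchange positions.  A minority completes the exchange but
continues rotating back to the original configuration (*roll back*).

The segmentation rules operate on the unwrapped angle series:

* **Roll onset** — first frame whose absolute unwrapped angle exceeds the
  rock band (default 30°) *and* keeps increasing (non-decreasing within a
  tolerance) over a short look-ahead window.
* **Roll end** — the frame at which the inter-cell axis crosses the
  reference line in the exchanged sense, i.e. the unwrapped angle reaches a
  multiple of 180°; for pairs that keep rotating (roll-back, repeated rolls)
  the *last* such crossing ends the Roll phase.

Durations are quantized to the sampling interval and reported in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .track_geometry import AngleSeries, PairTrajectory

__all__ = [
    "ClassifierConfig",
    "PhaseSegmentation",
    "PairOutcome",
    "CohortSummary",
    "segment_phases",
    "classify_pair",
    "score_position",
    "summarize_cohort",
    "round_half_up",
]

#: numerical slack (degrees) when testing whether a 180° multiple was reached
CROSSING_EPS_DEG = 1e-9


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the phase segmentation and outcome rules.

    rock_band_deg
        Half-width of the Rock band about the division axis (degrees).
    roll_monotone_window
        Look-ahead (frames) over which the excursion must keep increasing for
        a Roll onset to be accepted.
    monotone_tolerance_deg
        Allowed per-frame decrease (degrees) within the look-ahead window.
    exchange_threshold_deg
        Final configurations with ``|theta mod 360 - 180| <=
        180 - exchange_threshold_deg`` count as exchanged.
    return_threshold_deg
        Final unwrapped angles within this of 0 (mod 360) count as returned.
    """

    rock_band_deg: float = 30.0
    roll_monotone_window: int = 2
    monotone_tolerance_deg: float = 5.0
    exchange_threshold_deg: float = 165.0
    return_threshold_deg: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.rock_band_deg < self.exchange_threshold_deg <= 180):
            raise ValueError("require 0 < rock_band_deg < exchange_threshold_deg <= 180")
        if self.roll_monotone_window < 0 or self.monotone_tolerance_deg < 0:
            raise ValueError("window and tolerance must be non-negative")
        if self.return_threshold_deg < 0:
            raise ValueError("return_threshold_deg must be non-negative")


@dataclass
class PhaseSegmentation:
    """Per-frame phase labels with onset/end indices and durations (minutes)."""

    per_frame_label: np.ndarray  # array of {"rock","roll","post","indeterminate"}
    rock_start_idx: int
    roll_onset_idx: Optional[int]
    roll_end_idx: Optional[int]
    rock_duration_min: float
    roll_duration_min: Optional[float]

    @property
    def rocknroll_duration_min(self) -> Optional[float]:
        if self.roll_duration_min is None:
            return None
        return self.rock_duration_min + self.roll_duration_min

    @property
    def n_frames(self) -> int:
        return len(self.per_frame_label)


@dataclass
class PairOutcome:
    """Classification and positional outcome of one sibling pair."""

    outcome_class: str  # roll | no_roll | roll_back | incomplete
    exchanged: bool
    n_roll_events: int
    final_positions: Optional[dict] = None  # {"a": "anterior", "b": "posterior"} etc.
    emx2_cell: Optional[str] = None
    mislocated: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.outcome_class not in ("roll", "no_roll", "roll_back", "incomplete"):
            raise ValueError(f"unknown outcome_class {self.outcome_class!r}")


@dataclass
class CohortSummary:
    """Frequency and duration summary of a classified cohort."""

    counts: dict
    percentages: dict
    n_classified: int
    n_incomplete: int
    durations: pd.DataFrame  # columns: phase, mean_min, sem_min, n

    def frequency_row(self) -> List[int]:
        return [self.counts["roll"], self.counts["no_roll"], self.counts["roll_back"]]


def round_half_up(x) -> np.ndarray:
    """Round half away from zero (display convention for percentages)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def _crossing_frames(abs_unwrapped: np.ndarray, start: int) -> List[int]:
    """Frames (>= start) at which |unwrapped| first reaches each new multiple of 180."""
    m_prev = 0
    frames = []
    for k in range(start, abs_unwrapped.size):
        m = int((abs_unwrapped[k] + CROSSING_EPS_DEG) // 180.0)
        if m > m_prev:
            frames.extend([k] * (m - m_prev))  # one event per half-turn completed
            m_prev = m
    return frames


def segment_phases(angles: AngleSeries, config: ClassifierConfig = ClassifierConfig()) -> PhaseSegmentation:
    """Segment an angle series into Rock, Roll, and post-Roll frames.

    Implements the onset rule (band exceedance that keeps increasing) and the
    end rule (reference-line crossing of the exchanged pair); see the module
    docstring.  A sub-exchange excursion that returns into the rock band by
    the end of the recording is treated as rocking, not rolling.
    """
    if angles.n_frames == 0:
        raise ValueError("empty angle series")
    a = np.abs(angles.theta_unwrapped_deg)
    n = a.size
    band = config.rock_band_deg

    onset: Optional[int] = None
    for k in range(n):
        if a[k] <= band:
            continue
        stop = min(k + config.roll_monotone_window, n - 1)
        seg = a[k : stop + 1]
        if np.all(np.diff(seg) >= -config.monotone_tolerance_deg):
            onset = k
            break

    labels = np.array(["rock"] * n, dtype=object)
    times = angles.times
    if onset is None:
        return PhaseSegmentation(
            per_frame_label=labels,
            rock_start_idx=0,
            roll_onset_idx=None,
            roll_end_idx=None,
            rock_duration_min=float(times[-1] - times[0]),
            roll_duration_min=None,
        )

    crossings = _crossing_frames(a, onset)
    end: Optional[int] = crossings[-1] if crossings else None

    if end is None:
        if a[-1] <= config.return_threshold_deg:
            # excursion beyond the band that came back without exchanging:
            # the pair only rocked
            return PhaseSegmentation(
                per_frame_label=labels,
                rock_start_idx=0,
                roll_onset_idx=None,
                roll_end_idx=None,
                rock_duration_min=float(times[-1] - times[0]),
                roll_duration_min=None,
            )
        labels[onset:] = "indeterminate"
        return PhaseSegmentation(
            per_frame_label=labels,
            rock_start_idx=0,
            roll_onset_idx=onset,
            roll_end_idx=None,
            rock_duration_min=float(times[onset] - times[0]),
            roll_duration_min=None,
        )

    labels[onset : end + 1] = "roll"
    if end + 1 < n:
        labels[end + 1 :] = "post"
    return PhaseSegmentation(
        per_frame_label=labels,
        rock_start_idx=0,
        roll_onset_idx=onset,
        roll_end_idx=end,
        rock_duration_min=float(times[onset] - times[0]),
        roll_duration_min=float(times[end] - times[onset]),
    )


def classify_pair(
    segmentation: PhaseSegmentation,
    angles: AngleSeries,
    config: ClassifierConfig = ClassifierConfig(),
) -> PairOutcome:
    """Classify a segmented pair as roll, no_roll, roll_back, or incomplete.

    * ``no_roll`` — the excursion never left the rock band (or returned to it
      without exchanging).
    * ``roll`` — a completed exchange and the final configuration is
      exchanged (final wrapped angle within ``180 - exchange_threshold_deg``
      of 180, i.e. an odd number of half-turns).
    * ``roll_back`` — at least one completed exchange but the final unwrapped
      angle is back within ``return_threshold_deg`` of 0 (mod 360).
    * ``incomplete`` — a Roll onset whose motion was still in progress when
      the recording ended.

    ``n_roll_events`` counts completed half-turn crossings (a plain roll has
    1, a roll-back 2, repeated rolls more).
    """
    if segmentation.n_frames != angles.n_frames:
        raise ValueError("segmentation and angle series have different lengths")
    a = np.abs(angles.theta_unwrapped_deg)

    if segmentation.roll_onset_idx is None:
        return PairOutcome(outcome_class="no_roll", exchanged=False, n_roll_events=0)

    n_events = len(_crossing_frames(a, segmentation.roll_onset_idx))
    final_mod = float(a[-1] % 360.0)
    exch_tol = 180.0 - config.exchange_threshold_deg
    exchanged = abs(final_mod - 180.0) <= exch_tol
    returned = min(final_mod, 360.0 - final_mod) <= config.return_threshold_deg

    if segmentation.roll_end_idx is None or n_events == 0:
        return PairOutcome(outcome_class="incomplete", exchanged=exchanged, n_roll_events=n_events)
    if exchanged:
        return PairOutcome(outcome_class="roll", exchanged=True, n_roll_events=n_events)
    if returned:
        return PairOutcome(outcome_class="roll_back", exchanged=False, n_roll_events=n_events)
    return PairOutcome(outcome_class="incomplete", exchanged=False, n_roll_events=n_events)


_AXIS_LABELS = {"AP": ("anterior", "posterior"), "DV": ("dorsal", "ventral")}


def score_position(outcome: PairOutcome, trajectory: PairTrajectory) -> PairOutcome:
    """Assign final positional identities and the mislocation flag.

    Along the declared neuromast axis the cell with the smaller final
    coordinate is anterior (AP) or dorsal (DV).  The emx2-positive cell is
    *mislocated* when it ends posterior/ventral — the reverse of its normal
    location.  With no reporter annotation the flag is left undefined.
    """
    lo_label, hi_label = _AXIS_LABELS[trajectory.neuromast_axis]
    coord = 0 if trajectory.neuromast_axis == "AP" else 1
    a_val = trajectory.cell_a_xy[-1, coord]
    b_val = trajectory.cell_b_xy[-1, coord]
    if a_val <= b_val:
        positions = {"a": lo_label, "b": hi_label}
    else:
        positions = {"a": hi_label, "b": lo_label}
    outcome.final_positions = positions

    reporter = trajectory.reporter or {}

    def _status(cell: str):
        val = reporter.get(cell)
        if isinstance(val, dict):
            return bool(val.get("status", False))
        return None if val is None else bool(val)

    pos = [c for c in ("a", "b") if _status(c)]
    if not pos:
        outcome.emx2_cell = None
        outcome.mislocated = None
        return outcome
    outcome.emx2_cell = pos[0]
    outcome.mislocated = positions[pos[0]] == hi_label
    return outcome


def summarize_cohort(
    outcomes: Sequence[PairOutcome],
    segmentations: Sequence[PhaseSegmentation],
) -> CohortSummary:
    """Frequency and duration summary in the style of the cohort figures.

    Percentages (rounded half-up to integers) are computed over classified
    pairs; incomplete pairs are reported separately.  Duration means and SEM
    are restricted to pairs whose Roll onset occurred, matching the
    convention of summarizing only pairs that underwent Rock and Roll.
    """
    if len(outcomes) == 0 or len(outcomes) != len(segmentations):
        raise ValueError("need non-empty outcome/segmentation lists of equal length")

    counts = {"roll": 0, "no_roll": 0, "roll_back": 0}
    n_incomplete = 0
    for o in outcomes:
        if o.outcome_class == "incomplete":
            n_incomplete += 1
        else:
            counts[o.outcome_class] += 1
    n_classified = sum(counts.values())
    if n_classified == 0:
        percentages = {k: 0 for k in counts}
    else:
        percentages = {
            k: int(round_half_up(100.0 * v / n_classified)) for k, v in counts.items()
        }

    rows = []
    rolled = [
        s
        for o, s in zip(outcomes, segmentations)
        if o.outcome_class != "incomplete" and s.roll_onset_idx is not None
    ]
    for phase, getter in (
        ("rock", lambda s: s.rock_duration_min),
        ("roll", lambda s: s.roll_duration_min),
        ("rocknroll", lambda s: s.rocknroll_duration_min),
    ):
        vals = np.array([getter(s) for s in rolled if getter(s) is not None], dtype=float)
        if vals.size:
            sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            rows.append({"phase": phase, "mean_min": float(vals.mean()), "sem_min": sem, "n": vals.size})
    durations = pd.DataFrame(rows, columns=["phase", "mean_min", "sem_min", "n"])
    return CohortSummary(
        counts=counts,
        percentages=percentages,
        n_classified=n_classified,
        n_incomplete=n_incomplete,
        durations=durations,
    )
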