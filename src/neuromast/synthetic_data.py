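"""Ground-truthed synthetic inputs for the rearrangement pipeline.

Four generators emulate the study's data modalities:

* :func:`generate_pair_trajectory` — two-cell post-division tracks sampled at
  3–6 min intervals, with a sinusoidal rocking oscillation about the division
  axis followed (for rolling pairs) by a rotation through one or more
  half-turns.  Ground truth records the generating phase boundaries and
  outcome class exactly.
* :func:`generate_cohort` — multinomial Roll / No Roll / Roll-back cohorts
  with per-class log-normal duration draws.  Presets encode the wild-type,
  emx2 loss-of-function, emx2 gain-of-function, and vangl2 study conditions.
* :func:`generate_protrusion_stack` — tubulin-reporter-like TZYX stacks: two
  nascent cell bodies rendered as 3-D Gaussian blobs, a mature-cell apical
  band, and an elongating apical protrusion (bright cylinder growing toward
  the apical surface, i.e. smaller y).
* :func:`generate_count_matrix` — toy sparse gene-count matrices with
  controllable per-cell unique-gene counts, UMI totals, mitochondrial
  fractions, and emx2 detection probability.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse

from .track_geometry import PairTrajectory
from .rocknroll import PairOutcome, PhaseSegmentation

__all__ = [
    "TrajectoryParams",
    "DurationModel",
    "CohortParams",
    "StackParams",
    "CountMatrixParams",
    "generate_pair_trajectory",
    "generate_cohort",
    "generate_protrusion_stack",
    "generate_count_matrix",
    "COHORT_PRESETS",
    "cohort_preset",
]

_OUTCOMES = ("roll", "no_roll", "roll_back")


@dataclass(frozen=True)
class TrajectoryParams:
    """Generating parameters of one sibling-pair trajectory.

    Durations are in minutes and are quantized to ``frame_interval_min`` so
    the scheduled phase boundaries fall exactly on frames.  The rock
    amplitude must stay below 30° so that ground-truth Rock frames satisfy
    the Rock criterion.  ``n_extra_rolls`` adds half-turns beyond the minimum
    for the outcome class (vangl2-style repeated rolls); its parity must keep
    the final configuration consistent with the outcome.
    """

    frame_interval_min: float = 3.0
    rock_duration_min: float = 90.0
    roll_duration_min: float = 75.0
    outcome_class: str = "roll"
    rock_amplitude_deg: float = 20.0
    angle_noise_deg: float = 0.0
    n_extra_rolls: int = 0
    neuromast_axis: str = "AP"
    emx2_positive_cell: Optional[str] = None  # "first" | "second" | None (auto)
    emx2_initial_position: Optional[str] = None  # anterior/posterior/dorsal/ventral
    rock_period_min: float = 12.0
    post_duration_min: float = 15.0
    cell_separation: float = 8.0  # px between sibling centroids
    n_reference_cells: int = 2
    drift_rw_sigma: float = 0.0  # px/frame random-walk drift added to all points
    partial_rollback: bool = False  # alternative sub-360 roll-back mode
    direction: int = 0  # +1 CCW, -1 CW, 0 = draw from seed
    seed: int = 0

    def __post_init__(self) -> None:
        if not (3.0 <= self.frame_interval_min <= 6.0):
            raise ValueError("frame_interval_min must lie in [3, 6] minutes")
        if self.outcome_class not in _OUTCOMES:
            raise ValueError(f"outcome_class must be one of {_OUTCOMES}")
        if not (0.0 < self.rock_amplitude_deg < 30.0):
            raise ValueError("rock_amplitude_deg must lie in (0, 30): ground-truth Rock "
                             "frames must satisfy the 30-degree Rock criterion")
        if self.angle_noise_deg < 0 or self.rock_duration_min < 0 or self.roll_duration_min < 0:
            raise ValueError("durations and noise must be non-negative")
        if (self.roll_duration_min == 0) != (self.outcome_class == "no_roll"):
            raise ValueError("roll_duration_min == 0 iff outcome_class == 'no_roll'")
        if self.n_extra_rolls < 0:
            raise ValueError("n_extra_rolls must be non-negative")
        if self.outcome_class == "roll" and self.n_extra_rolls % 2 != 0:
            raise ValueError("a rolling pair must end exchanged: n_extra_rolls must be even")
        if self.outcome_class == "roll_back" and not self.partial_rollback and self.n_extra_rolls % 2 != 0:
            raise ValueError("a roll-back pair must end returned: n_extra_rolls must be even")
        if self.neuromast_axis not in ("AP", "DV"):
            raise ValueError("neuromast_axis must be 'AP' or 'DV'")

    @property
    def total_half_turns(self) -> int:
        if self.outcome_class == "no_roll":
            return 0
        if self.outcome_class == "roll":
            return 1 + self.n_extra_rolls
        return 2 + self.n_extra_rolls  # roll_back


def _quantize_frames(duration_min: float, dt: float, minimum: int = 0) -> int:
    return max(minimum, int(round(duration_min / dt)))


def _schedule_angles(params: TrajectoryParams, rng: np.random.Generator) -> Tuple[np.ndarray, dict]:
    """Noise-free unwrapped angle schedule plus ground-truth frame indices."""
    dt = params.frame_interval_min
    f_rock = _quantize_frames(params.rock_duration_min, dt, minimum=1)
    amp = params.rock_amplitude_deg
    omega = 2.0 * np.pi / params.rock_period_min

    if params.outcome_class == "no_roll":
        n_frames = f_rock + _quantize_frames(params.post_duration_min, dt) + 1
        t = np.arange(n_frames) * dt
        theta = amp * np.sin(omega * t)
        return theta, {"onset": None, "end": None, "n_frames": n_frames}

    n_roll = _quantize_frames(params.roll_duration_min, dt, minimum=1)
    onset = f_rock
    end = f_rock + n_roll
    n_post = _quantize_frames(params.post_duration_min, dt)
    n_frames = end + n_post + 1
    t = np.arange(n_frames) * dt
    theta = np.empty(n_frames)
    theta[:onset] = amp * np.sin(omega * t[:onset])

    if params.outcome_class == "roll_back" and params.partial_rollback:
        # alternative mode: excursion past the exchange point and back,
        # peaking at 200 deg mid-roll rather than continuing through 360
        s = np.arange(1, n_roll + 2) / (n_roll + 1)
        theta[onset:end + 1] = 200.0 * np.sin(np.pi * s)
        theta[end] = 0.0
    else:
        target = 180.0 * params.total_half_turns
        # the Roll excursion leaves the rock band at the onset frame and
        # reaches the target multiple of 180 exactly at the end frame
        s = np.arange(1, n_roll + 2) / (n_roll + 1)
        theta[onset:end + 1] = 30.0 + (target - 30.0) * s
    theta[end + 1:] = theta[end]
    direction = params.direction or (1 if rng.random() < 0.5 else -1)
    return direction * theta, {"onset": onset, "end": end, "n_frames": n_frames}


def generate_pair_trajectory(
    params: TrajectoryParams,
) -> Tuple[PairTrajectory, PhaseSegmentation, PairOutcome]:
    """Generate one sibling-pair trajectory with exact ground truth.

    The two cells start diametrically opposed about the division midpoint;
    the inter-cell axis follows the scheduled angle (rock oscillation, then
    the Roll ramp for rolling outcomes) with optional per-frame Gaussian
    angle noise (frame 0 is noise-free: it defines the reference axis).
    Returns the trajectory, the generating :class:`PhaseSegmentation`, and
    the generating :class:`PairOutcome`.
    """
    rng = np.random.default_rng(params.seed)
    theta, gt = _schedule_angles(params, rng)
    n = gt["n_frames"]
    dt = params.frame_interval_min
    if params.angle_noise_deg > 0:
        noise = rng.normal(0.0, params.angle_noise_deg, size=n)
        noise[0] = 0.0
        theta = theta + noise

    times = np.arange(n) * dt
    axis0 = np.array([1.0, 0.0]) if params.neuromast_axis == "AP" else np.array([0.0, 1.0])
    ang0 = np.arctan2(axis0[1], axis0[0])
    phi = ang0 + np.radians(theta)
    r = params.cell_separation / 2.0
    center = np.array([50.0, 50.0])
    u = np.column_stack([np.cos(phi), np.sin(phi)])
    cell_a = center - r * u
    cell_b = center + r * u

    refs = None
    if params.n_reference_cells > 0:
        base = center + rng.normal(0.0, 15.0, size=(params.n_reference_cells, 2))
        refs = np.broadcast_to(base, (n,) + base.shape).copy()

    if params.drift_rw_sigma > 0:
        steps = rng.normal(0.0, params.drift_rw_sigma, size=(n, 2))
        steps[0] = 0.0
        drift = np.cumsum(steps, axis=0)
        cell_a = cell_a + drift
        cell_b = cell_b + drift
        if refs is not None:
            refs = refs + drift[:, None, :]

    # --- reporter assignment ---------------------------------------------
    # cell_a starts at the smaller-coordinate (anterior/dorsal) pole.
    exchanged = params.total_half_turns % 2 == 1
    lo, hi = ("anterior", "posterior") if params.neuromast_axis == "AP" else ("dorsal", "ventral")
    start_pos = {"a": lo, "b": hi}
    final_pos = {"a": hi, "b": lo} if exchanged else dict(start_pos)

    emx2_cell = None
    if params.emx2_positive_cell in ("first", "second"):
        emx2_cell = "a" if params.emx2_positive_cell == "first" else "b"
    elif params.emx2_initial_position is not None:
        emx2_cell = next(c for c, p in start_pos.items() if p == params.emx2_initial_position)
    reporter = None
    mislocated = None
    if emx2_cell is not None:
        onset_frame = gt["end"] if gt["end"] is not None else n - 1
        reporter = {emx2_cell: {"status": True, "onset_frame": int(onset_frame)},
                    ("b" if emx2_cell == "a" else "a"): {"status": False}}
        mislocated = final_pos[emx2_cell] == hi

    trajectory = PairTrajectory(
        times=times,
        cell_a_xy=cell_a,
        cell_b_xy=cell_b,
        reference_points=refs,
        neuromast_axis=params.neuromast_axis,
        reporter=reporter,
        meta={"params": params},
    )

    labels = np.array(["rock"] * n, dtype=object)
    onset, end = gt["onset"], gt["end"]
    if onset is not None:
        labels[onset : end + 1] = "roll"
        if end + 1 < n:
            labels[end + 1 :] = "post"
    segmentation = PhaseSegmentation(
        per_frame_label=labels,
        rock_start_idx=0,
        roll_onset_idx=onset,
        roll_end_idx=end,
        rock_duration_min=float(times[onset] - times[0]) if onset is not None else float(times[-1]),
        roll_duration_min=float(times[end] - times[onset]) if onset is not None else None,
    )
    n_events = params.total_half_turns if not (params.outcome_class == "roll_back" and params.partial_rollback) else 1
    outcome = PairOutcome(
        outcome_class=params.outcome_class if not (params.outcome_class == "roll_back" and params.partial_rollback) else "roll_back",
        exchanged=exchanged,
        n_roll_events=n_events,
        final_positions=final_pos,
        emx2_cell=emx2_cell,
        mislocated=mislocated,
    )
    return trajectory, segmentation, outcome


@dataclass(frozen=True)
class DurationModel:
    """Log-normal duration model parameterized by its mean (minutes)."""

    mean_min: float
    sigma_log: float = 0.25

    def draw(self, rng: np.random.Generator) -> float:
        mu = np.log(self.mean_min) - self.sigma_log**2 / 2.0
        return float(rng.lognormal(mu, self.sigma_log))


@dataclass(frozen=True)
class CohortParams:
    """Parameters of a multinomial Roll / No Roll / Roll-back cohort."""

    n_pairs: int
    class_probs: Tuple[float, float, float]  # (roll, no_roll, roll_back)
    rock_duration: DurationModel = DurationModel(90.0)
    roll_duration: DurationModel = DurationModel(75.0)
    rock_amplitude_deg: float = 20.0
    angle_noise_deg: float = 0.0
    n_extra_rolls: int = 0
    frame_interval_min: float = 3.0
    neuromast_axis: str = "AP"
    mislocation_prob: float = 0.0
    emx2_fraction: float = 1.0  # fraction of pairs carrying a reporter-positive cell
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        p = np.asarray(self.class_probs, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("class_probs must be 3 non-negative probabilities summing to 1")
        if not (0.0 <= self.mislocation_prob <= 1.0 and 0.0 <= self.emx2_fraction <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")


#: cohort presets for the study conditions: Roll/No-Roll/Roll-back frequencies
#: and mean Rock durations follow the reported cohort summaries (WT 57/40/3,
#: rock 90 min, roll 75 min; LOF 59/24/17, rock 67 min; GOF 32/68/0 with a
#: prolonged Roll phase; vangl2 with reduced Roll frequency, a prolonged Roll
#: phase, and repeated rolls).
COHORT_PRESETS: Dict[str, dict] = {
    "WT": dict(class_probs=(0.57, 0.40, 0.03),
               rock_duration=DurationModel(90.0), roll_duration=DurationModel(75.0)),
    "LOF": dict(class_probs=(0.59, 0.24, 0.17),
                rock_duration=DurationModel(67.0), roll_duration=DurationModel(75.0)),
    "GOF": dict(class_probs=(0.32, 0.68, 0.0),
                rock_duration=DurationModel(90.0), roll_duration=DurationModel(105.0)),
    "vangl2": dict(class_probs=(0.33, 0.67, 0.0),
                   rock_duration=DurationModel(90.0), roll_duration=DurationModel(120.0),
                   n_extra_rolls=2),
}


def cohort_preset(name: str, n_pairs: int, seed: int = 0, **overrides) -> CohortParams:
    """Build :class:`CohortParams` for a named study condition."""
    if name not in COHORT_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(COHORT_PRESETS)}")
    kwargs = dict(COHORT_PRESETS[name])
    kwargs.update(overrides)
    return CohortParams(n_pairs=n_pairs, seed=seed, **kwargs)


def generate_cohort(
    params: CohortParams,
) -> List[Tuple[PairTrajectory, PhaseSegmentation, PairOutcome]]:
    """Generate a cohort of pairs with multinomially drawn outcome classes."""
    rng = np.random.default_rng(params.seed)
    classes = rng.choice(3, size=params.n_pairs, p=np.asarray(params.class_probs))
    child_seeds = rng.integers(0, 2**31 - 1, size=params.n_pairs)
    out = []
    for k in range(params.n_pairs):
        outcome_class = _OUTCOMES[classes[k]]
        rock = params.rock_duration.draw(rng)
        roll = 0.0 if outcome_class == "no_roll" else max(
            params.frame_interval_min, params.roll_duration.draw(rng)
        )
        has_reporter = rng.random() < params.emx2_fraction
        mislocate = has_reporter and rng.random() < params.mislocation_prob
        emx2_initial = None
        if has_reporter:
            lo, hi = ("anterior", "posterior") if params.neuromast_axis == "AP" else ("dorsal", "ventral")
            final_exchanged = outcome_class == "roll"  # extra rolls keep parity
            # normally the emx2-positive cell ends at the lo pole; mislocated ends hi
            want_final = hi if mislocate else lo
            emx2_initial = (
                ({lo: hi, hi: lo}[want_final]) if final_exchanged else want_final
            )
        tp = TrajectoryParams(
            frame_interval_min=params.frame_interval_min,
            rock_duration_min=rock,
            roll_duration_min=roll,
            outcome_class=outcome_class,
            rock_amplitude_deg=params.rock_amplitude_deg,
            angle_noise_deg=params.angle_noise_deg,
            n_extra_rolls=params.n_extra_rolls if outcome_class != "no_roll" else 0,
            neuromast_axis=params.neuromast_axis,
            emx2_initial_position=emx2_initial,
            seed=int(child_seeds[k]),
        )
        out.append(generate_pair_trajectory(tp))
    return out


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StackParams:
    """Parameters of a synthetic tubulin-reporter TZYX stack.

    The apical surface is rendered as a thin bright band at ``apical_surface_y``
    (apical = smaller y, matching the measurement convention); the protrusion
    is a cylinder of radius ``protrusion_radius_vox`` growing from the top of
    the first cell toward the apical band following ``protrusion_lengths``
    (one target length in voxels per frame).
    """

    shape_tzyx: Tuple[int, int, int, int] = (10, 12, 96, 64)
    cell_centers: Tuple[Tuple[float, float, float], ...] = ((6.0, 60.0, 24.0), (6.0, 60.0, 40.0))  # (z, y, x)
    cell_radius_vox: float = 6.0
    apical_surface_y: int = 12
    protrusion_lengths: Tuple[float, ...] = tuple(float(2 * k) for k in range(10))
    protrusion_intensity: float = 400.0
    protrusion_radius_vox: float = 2.0
    cell_intensity: float = 250.0
    background_level: float = 40.0
    noise_model: str = "gaussian"  # gaussian | poisson | none
    noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t, z, y, x = self.shape_tzyx
        if min(t, z, y, x) < 1:
            raise ValueError("all stack dimensions must be >= 1")
        if len(self.protrusion_lengths) != t:
            raise ValueError("protrusion_lengths must give one target length per frame")
        if any(l < 0 for l in self.protrusion_lengths):
            raise ValueError("protrusion lengths must be non-negative")
        for cz, cy, cx in self.cell_centers:
            if not (0 <= cz < z and 0 <= cy < y and 0 <= cx < x):
                raise ValueError("cell centers must lie inside the volume")
        cz, cy, cx = self.cell_centers[0]
        apex_y = cy - self.cell_radius_vox
        max_len = apex_y - self.apical_surface_y
        if max(self.protrusion_lengths) > max_len:
            raise ValueError(
                f"protrusion target {max(self.protrusion_lengths)} exceeds the geometric bound "
                f"{max_len} (cell apex to apical surface)"
            )
        if self.noise_model not in ("gaussian", "poisson", "none"):
            raise ValueError("noise_model must be gaussian, poisson, or none")
        if self.background_level < 0 or self.noise_scale < 0:
            raise ValueError("background and noise scale must be non-negative")


def generate_protrusion_stack(params: StackParams) -> Tuple[np.ndarray, pd.DataFrame]:
    """Render a synthetic apical-protrusion stack with per-frame ground truth.

    Returns the uint16 TZYX stack and a ground-truth table with the noise-free
    protrusion length (voxels) and mean cylinder intensity per frame.
    """
    rng = np.random.default_rng(params.seed)
    t_dim, z_dim, y_dim, x_dim = params.shape_tzyx
    zz, yy, xx = np.meshgrid(
        np.arange(z_dim), np.arange(y_dim), np.arange(x_dim), indexing="ij"
    )

    base = np.full((z_dim, y_dim, x_dim), params.background_level, dtype=float)
    for cz, cy, cx in params.cell_centers:
        d2 = ((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (params.cell_radius_vox / 2.0) ** 2)
        base += params.cell_intensity * np.exp(-d2)
    # mature-cell apical signal: a thin bright band at the apical surface
    band = np.exp(-((yy - params.apical_surface_y) ** 2) / 2.0)
    base += 0.5 * params.cell_intensity * band * np.exp(
        -((zz - params.cell_centers[0][0]) ** 2) / (2 * (z_dim / 3.0) ** 2)
    )

    cz0, cy0, cx0 = params.cell_centers[0]
    apex_y = cy0 - params.cell_radius_vox
    truth_rows = []
    frames = np.empty((t_dim, z_dim, y_dim, x_dim), dtype=float)
    for f in range(t_dim):
        vol = base.copy()
        length = params.protrusion_lengths[f]
        if length > 0:
            in_cyl = (
                (np.hypot(xx - cx0, zz - cz0) <= params.protrusion_radius_vox)
                & (yy <= apex_y)
                & (yy >= apex_y - length)
            )
            vol[in_cyl] += params.protrusion_intensity
            mean_int = params.protrusion_intensity + params.background_level
        else:
            mean_int = np.nan
        truth_rows.append({"frame": f, "length_vox": float(length), "mean_intensity": mean_int})
        frames[f] = vol

    if params.noise_model == "gaussian" and params.noise_scale > 0:
        frames = frames + rng.normal(0.0, params.noise_scale, size=frames.shape)
    elif params.noise_model == "poisson" and params.noise_scale > 0:
        frames = rng.poisson(np.clip(frames, 0, None) / params.noise_scale) * params.noise_scale

    stack = np.clip(frames, 0, 65535).astype(np.uint16)
    return stack, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupRates:
    """Per-group rate parameters of the toy count-matrix generator."""

    n_unique_genes: int
    n_umi: int
    mito_fraction: float
    emx2_prob: float

    def __post_init__(self) -> None:
        if self.n_unique_genes < 1 or self.n_umi < self.n_unique_genes:
            raise ValueError("need n_umi >= n_unique_genes >= 1")
        if not (0.0 <= self.mito_fraction <= 1.0 and 0.0 <= self.emx2_prob <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class CountMatrixParams:
    """Parameters of the synthetic sparse gene-count matrix."""

    n_cells_per_group: Tuple[int, ...]
    group_rates: Tuple[GroupRates, ...]
    group_names: Optional[Tuple[str, ...]] = None
    n_genes: int = 3000
    n_mito_genes: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_cells_per_group) != len(self.group_rates):
            raise ValueError("need one GroupRates per group")
        if any(n < 1 for n in self.n_cells_per_group):
            raise ValueError("group sizes must be >= 1")
        if self.n_mito_genes < 1:
            raise ValueError("the mitochondrial gene subset must be non-empty")
        if self.n_genes < self.n_mito_genes + 2:
            raise ValueError("n_genes too small for the mito subset plus emx2")
        if self.group_names is not None and len(self.group_names) != len(self.n_cells_per_group):
            raise ValueError("group_names length mismatch")

    def gene_names(self) -> List[str]:
        mito = [f"mt-gene{i}" for i in range(self.n_mito_genes)]
        n_other = self.n_genes - self.n_mito_genes - 1
        other = [f"gene{i:05d}" for i in range(n_other)]
        return ["emx2"] + mito + other


def generate_count_matrix(params: CountMatrixParams) -> Tuple[sparse.csr_matrix, pd.DataFrame, List[str]]:
    """Generate a cells × genes sparse count matrix plus a per-cell truth table.

    Truth columns record each cell's realized unique-gene count, UMI total,
    mitochondrial fraction, emx2 positivity, group label, and whether the
    cell violates the canonical QC rules (``should_fail_qc``).
    """
    rng = np.random.default_rng(params.seed)
    genes = params.gene_names()
    emx2_idx = 0
    mito_idx = np.arange(1, 1 + params.n_mito_genes)
    other_idx = np.arange(1 + params.n_mito_genes, params.n_genes)

    names = params.group_names or tuple(f"group{i}" for i in range(len(params.n_cells_per_group)))
    rows, cols, vals = [], [], []
    records = []
    cell = 0
    for gi, (n_cells, rates) in enumerate(zip(params.n_cells_per_group, params.group_rates)):
        for _ in range(n_cells):
            k = max(1, int(rng.poisson(rates.n_unique_genes)))
            emx2_pos = bool(rng.random() < rates.emx2_prob)
            n_mito_used = 0
            if rates.mito_fraction > 0:
                n_mito_used = int(rng.integers(1, params.n_mito_genes + 1))
            k_special = n_mito_used + int(emx2_pos)
            k_other = max(1, k - k_special)
            k = k_other + k_special
            chosen_other = rng.choice(other_idx, size=min(k_other, other_idx.size), replace=False)
            k_other = chosen_other.size
            k = k_other + k_special

            umi = max(k, int(rng.poisson(rates.n_umi)))
            mito_umi = int(round(rates.mito_fraction * umi))
            mito_umi = min(max(mito_umi, n_mito_used), umi - (k - n_mito_used))
            rest = umi - mito_umi

            gene_ids = []
            counts = []
            if n_mito_used:
                m_choice = rng.choice(mito_idx, size=n_mito_used, replace=False)
                alloc = rng.multinomial(mito_umi - n_mito_used, np.full(n_mito_used, 1.0 / n_mito_used)) + 1
                gene_ids.extend(m_choice.tolist())
                counts.extend(alloc.tolist())
            else:
                mito_umi = 0
                rest = umi
            non_mito_ids = chosen_other.tolist() + ([emx2_idx] if emx2_pos else [])
            n_nm = len(non_mito_ids)
            alloc = rng.multinomial(rest - n_nm, np.full(n_nm, 1.0 / n_nm)) + 1
            gene_ids.extend(non_mito_ids)
            counts.extend(alloc.tolist())

            rows.extend([cell] * len(gene_ids))
            cols.extend(gene_ids)
            vals.extend(counts)

            umi_real = int(sum(counts))
            mito_frac = float(sum(c for g, c in zip(gene_ids, counts) if g in set(mito_idx.tolist())) / umi_real)
            n_unique = len(gene_ids)
            should_fail = (
                n_unique < 400 or n_unique > 2500 or umi_real > 10000 or mito_frac > 0.05
            )
            records.append({
                "cell_id": f"cell{cell:05d}",
                "group": names[gi],
                "n_unique_genes": n_unique,
                "n_umi": umi_real,
                "mito_fraction": mito_frac,
                "emx2_positive": emx2_pos,
                "should_fail_qc": should_fail,
            })
            cell += 1

    matrix = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(cell, params.n_genes), dtype=np.int64
    )
    return matrix, pd.DataFrame(records), genes
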