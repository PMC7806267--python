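"""Summary tables mirroring the study's reporting layouts.

Three layouts are produced:

* a frequency table of Roll / No Roll / Roll-back percentages per cohort
  (Fig-4D style),
* a reporter-position table per cohort: total HCs, reporter-positive cells,
  anterior vs posterior reporter-positive cells, mislocated cells
  (Table-1 style),
* positions of reporter-positive cells split by Roll vs No Roll
  (Table-2 style).

Each writer emits a display CSV with integer-rounded percentages plus a
machine-readable JSON with unrounded values.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .rocknroll import CohortSummary, PairOutcome, round_half_up
from .io import write_json

__all__ = [
    "frequency_table",
    "position_table",
    "position_by_roll_table",
    "write_report",
]


def frequency_table(summaries: Dict[str, CohortSummary]) -> pd.DataFrame:
    """Roll / No-Roll / Roll-back counts and percentages per cohort."""
    rows = []
    for name, s in summaries.items():
        row = {"cohort": name, "n": s.n_classified, "n_incomplete": s.n_incomplete}
        for cls in ("roll", "no_roll", "roll_back"):
            row[f"{cls}_count"] = s.counts[cls]
            row[f"{cls}_pct"] = s.percentages[cls]
        rows.append(row)
    return pd.DataFrame(rows)


def _position_counts(outcomes: Sequence[PairOutcome]) -> dict:
    scored = [o for o in outcomes if o.mislocated is not None]
    n_lo = sum(1 for o in scored if not o.mislocated)
    n_hi = sum(1 for o in scored if o.mislocated)
    return {"n_scored": len(scored), "normal": n_lo, "mislocated": n_hi}


def position_table(cohorts: Dict[str, Sequence[PairOutcome]]) -> pd.DataFrame:
    """Reporter-positive cell positions per cohort (Table-1 style).

    Each classified pair contributes two hair cells, at most one of them
    reporter-positive; the normal location of the reporter-positive cell is
    anterior (AP) or dorsal (DV).
    """
    rows = []
    for name, outcomes in cohorts.items():
        outcomes = [o for o in outcomes if o.outcome_class != "incomplete"]
        counts = _position_counts(outcomes)
        total_hcs = 2 * len(outcomes)
        gfp = counts["n_scored"]
        rows.append({
            "cohort": name,
            "total_hcs": total_hcs,
            "gfp_positive": gfp,
            "gfp_positive_pct": int(round_half_up(100.0 * gfp / total_hcs)) if total_hcs else 0,
            "anterior_gfp": counts["normal"],
            "posterior_gfp": counts["mislocated"],
            "mislocated": counts["mislocated"],
            "mislocated_pct": int(round_half_up(100.0 * counts["mislocated"] / gfp)) if gfp else 0,
        })
    return pd.DataFrame(rows)


def position_by_roll_table(cohorts: Dict[str, Sequence[PairOutcome]]) -> pd.DataFrame:
    """Positions of reporter-positive cells by Roll vs No Roll (Table-2 style)."""
    rows = []
    for name, outcomes in cohorts.items():
        row = {"cohort": name}
        for label, keep in (("roll", ("roll", "roll_back")), ("no_roll", ("no_roll",))):
            sub = [o for o in outcomes if o.outcome_class in keep and o.mislocated is not None]
            n = len(sub)
            normal = sum(1 for o in sub if not o.mislocated)
            row[f"{label}_n"] = n
            row[f"{label}_normal"] = normal
            row[f"{label}_mislocated"] = n - normal
            row[f"{label}_normal_pct"] = (
                float(np.round(100.0 * normal / n, 1)) if n else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(
    out_dir,
    summaries: Dict[str, CohortSummary],
    cohorts: Dict[str, Sequence[PairOutcome]],
) -> List[Path]:
    """Write the three display CSVs plus an unrounded JSON; returns the paths."""
    if not summaries or not cohorts:
        raise ValueError("empty cohort: nothing to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    freq = frequency_table(summaries)
    pos = position_table(cohorts)
    pos_roll = position_by_roll_table(cohorts)
    paths = []
    for name, df in (("frequencies", freq), ("positions", pos), ("positions_by_roll", pos_roll)):
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)

    payload = {
        "frequencies": {
            name: {
                "counts": s.counts,
                "n_classified": s.n_classified,
                "n_incomplete": s.n_incomplete,
                "percent_unrounded": {
                    k: 100.0 * v / s.n_classified if s.n_classified else 0.0
                    for k, v in s.counts.items()
                },
                "durations": s.durations.to_dict(orient="records"),
            }
            for name, s in summaries.items()
        },
        "positions": pos.to_dict(orient="records"),
        "positions_by_roll": pos_roll.to_dict(orient="records"),
    }
    p = out_dir / "report.json"
    write_json(p, payload)
    paths.append(p)
    return paths
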