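"""Acoustic-startle scoring from per-frame xy trajectories.

A trial counts as a startle when the larva moves strictly more than
``displacement_threshold`` pixels (default 4 px, about 1.9 mm at the
tracker's 0.475 mm/px scale) between any two frames within the two-frame
window after stimulus onset.  Animals with no assessable trial (missing
tracking) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StartleParams", "StartleResult", "detect_startle", "aggregate_startle", "score_animals"]


@dataclass(frozen=True)
class StartleParams:
    displacement_threshold_px: float = 4.0  # strictly greater than
    window_frames: int = 2
    px_to_mm: float = 0.475
    frame_rate: float = 30.0
    n_trials: int = 5

    def __post_init__(self) -> None:
        if self.displacement_threshold_px <= 0:
            raise ValueError("displacement_threshold_px must be positive")
        if self.window_frames < 1:
            raise ValueError("window_frames must be >= 1")


def detect_startle(
    track: pd.DataFrame,
    stim_frame: int,
    params: StartleParams = StartleParams(),
) -> bool | None:
    """Score one trial; ``None`` marks an unassessable trial.

    ``track`` has columns ``frame``, ``x``, ``y`` for a single animal and
    trial.  All pairwise straight-line displacements among the positions at
    onset, onset+1, ..., onset+window are checked; any missing position in
    that span makes the trial unassessable.
    """
    frames = range(stim_frame, stim_frame + params.window_frames + 1)
    positions = []
    indexed = track.set_index("frame")
    for f in frames:
        if f not in indexed.index:
            return None
        row = indexed.loc[f]
        if np.isnan(row["x"]) or np.isnan(row["y"]):
            return None
        positions.append((float(row["x"]), float(row["y"])))
    pts = np.asarray(positions)
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if np.hypot(*(pts[j] - pts[i])) > params.displacement_threshold_px:
                return True
    return False


@dataclass
class StartleResult:
    flags: list[bool | None]
    proportion: float  # NaN when excluded
    n_assessable: int
    excluded: bool


def aggregate_startle(
    flags: list[bool | None],
    params: StartleParams = StartleParams(),
) -> StartleResult:
    """Per-animal response proportion over assessable trials."""
    assessable = [f for f in flags if f is not None]
    if not assessable:
        return StartleResult(flags=flags, proportion=float("nan"), n_assessable=0, excluded=True)
    prop = sum(assessable) / len(assessable)
    return StartleResult(
        flags=flags, proportion=prop, n_assessable=len(assessable), excluded=False
    )


def score_animals(
    tracks: pd.DataFrame,
    stim_schedule: pd.DataFrame,
    params: StartleParams = StartleParams(),
) -> pd.DataFrame:
    """Score every animal in a tidy track table.

    ``tracks`` columns: ``animal``, ``trial``, ``frame``, ``x``, ``y``;
    ``stim_schedule`` columns: ``trial``, ``stim_frame``.  Returns one row
    per animal with its startle proportion and exclusion flag.
    """
    stim_by_trial = dict(zip(stim_schedule["trial"], stim_schedule["stim_frame"]))
    rows = []
    for animal, grp in tracks.groupby("animal", sort=True):
        flags: list[bool | None] = []
        for trial, stim_frame in sorted(stim_by_trial.items()):
            trial_track = grp[grp["trial"] == trial]
            if trial_track.empty:
                flags.append(None)
            else:
                flags.append(detect_startle(trial_track, int(stim_frame), params))
        res = aggregate_startle(flags, params)
        rows.append(
            {
                "animal": animal,
                "proportion": res.proportion,
                "n_assessable": res.n_assessable,
                "excluded": res.excluded,
            }
        )
    return pd.DataFrame(rows)
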