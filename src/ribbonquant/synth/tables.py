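"""Synthetic innervation tables and startle trajectories.

These generators emulate the two tabular data streams of the study: single
afferent-terminal innervation maps (which hair cells of each orientation a
terminal contacts, and how many complete synapses it forms there) and
per-frame xy tracks of larvae in a startle assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ..selectivity import ORIENTATIONS

__all__ = [
    "InnervationSpec",
    "generate_innervation",
    "sample_innervation_cohort",
    "TrajectorySpec",
    "generate_trajectories",
]


@dataclass(frozen=True)
class InnervationSpec:
    """Deterministic per-terminal contact counts.

    ``preferred``/``nonpreferred`` give, per terminal, how many innervated
    hair cells share / oppose the terminal's preferred orientation.  A
    single integer applies to every terminal.
    """

    n_terminals: int
    preferred: int | Sequence[int]
    nonpreferred: int | Sequence[int] = 0
    synapses_per_cell: int = 2
    terminal_type: str = "P-to-A"
    seed: int = 0

    def _per_terminal(self, value) -> list[int]:
        if np.isscalar(value):
            return [int(value)] * self.n_terminals
        value = [int(v) for v in value]
        if len(value) != self.n_terminals:
            raise ValueError("per-terminal counts must have n_terminals entries")
        return value

    def __post_init__(self) -> None:
        if self.n_terminals < 1:
            raise ValueError("n_terminals must be >= 1")
        if self.terminal_type not in ORIENTATIONS:
            raise ValueError(f"terminal_type must be one of {ORIENTATIONS}")
        pref = self._per_terminal(self.preferred)
        nonp = self._per_terminal(self.nonpreferred)
        if min(pref) < 0 or min(nonp) < 0:
            raise ValueError("contact counts must be non-negative")
        if any(p + n == 0 for p, n in zip(pref, nonp)):
            raise ValueError("every terminal must innervate at least one hair cell")


def generate_innervation(spec: InnervationSpec) -> pd.DataFrame:
    """Tidy contact table: one row per innervated terminal-hair-cell contact."""
    rng = np.random.default_rng(spec.seed)
    other = ORIENTATIONS[1 - ORIENTATIONS.index(spec.terminal_type)]
    pref = spec._per_terminal(spec.preferred)
    nonp = spec._per_terminal(spec.nonpreferred)
    rows = []
    for tid in range(spec.n_terminals):
        cell = 0
        for orientation, count in ((spec.terminal_type, pref[tid]), (other, nonp[tid])):
            for _ in range(count):
                rows.append(
                    {
                        "terminal_id": tid,
                        "terminal_type": spec.terminal_type,
                        "hair_cell_id": cell,
                        "orientation": orientation,
                        "innervated": True,
                        "n_synapses": int(
                            max(1, rng.poisson(spec.synapses_per_cell))
                        ),
                    }
                )
                cell += 1
    return pd.DataFrame(rows)


def sample_innervation_cohort(
    n_terminals: int,
    selectivity_mean: float,
    selectivity_sd: float,
    n_innervated_range: tuple[int, int] = (4, 7),
    synapses_per_cell: int = 2,
    terminal_type: str = "P-to-A",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a terminal cohort around a planted selectivity distribution.

    Each terminal gets a target index from a clipped normal distribution
    and an innervated-cell count from ``n_innervated_range``; the preferred
    count is the nearest integer realizing the target.  Returns
    ``(contacts, planted)`` where ``planted`` lists each terminal's
    realized planted index (the recovery target for the metrics pipeline).
    """
    rng = np.random.default_rng(seed)
    lo, hi = n_innervated_range
    pref_counts, nonp_counts, planted_idx = [], [], []
    for _ in range(n_terminals):
        n = int(rng.integers(lo, hi + 1))
        target = float(np.clip(rng.normal(selectivity_mean, selectivity_sd), 50.0, 100.0))
        pref = int(np.clip(round(target / 100.0 * n), int(np.ceil(n / 2)), n))
        pref_counts.append(pref)
        nonp_counts.append(n - pref)
        planted_idx.append(100.0 * pref / n)
    spec = InnervationSpec(
        n_terminals=n_terminals,
        preferred=pref_counts,
        nonpreferred=nonp_counts,
        synapses_per_cell=synapses_per_cell,
        terminal_type=terminal_type,
        seed=int(rng.integers(2**31)),
    )
    planted = pd.DataFrame(
        {"terminal_id": np.arange(n_terminals), "planted_index": planted_idx}
    )
    return generate_innervation(spec), planted


@dataclass(frozen=True)
class TrajectorySpec:
    """Startle-assay track recipe.

    Responder trials contain one straight-line jump drawn from
    ``responder_displacement_px`` within the scoring window after the
    stimulus frame; non-responder trials only jitter.  With probability
    ``dropout_prob`` a trial has no tracking rows at all.
    """

    n_larvae: int
    n_trials: int = 5
    n_frames: int = 60
    stim_frame: int = 30
    frame_rate: float = 30.0
    respond_prob: float = 1.0
    responder_displacement_px: tuple[float, float] = (6.0, 12.0)
    jitter_sd_px: float = 0.3
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if min(self.responder_displacement_px) < 0:
            raise ValueError("displacements must be non-negative")
        if not 0 <= self.stim_frame < self.n_frames - 2:
            raise ValueError("stim_frame must leave a two-frame scoring window")


def generate_trajectories(spec: TrajectorySpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame xy tracks plus the planted per-trial outcome table."""
    rng = np.random.default_rng(spec.seed)
    track_rows, planted_rows = [], []
    for animal in range(spec.n_larvae):
        for trial in range(spec.n_trials):
            dropped = bool(rng.uniform() < spec.dropout_prob)
            responded = bool(rng.uniform() < spec.respond_prob) and not dropped
            planted_rows.append(
                {"animal": animal, "trial": trial, "responded": responded, "dropped": dropped}
            )
            if dropped:
                continue
            pos = np.array([30.0 + 40.0 * animal, 30.0 + 40.0 * trial])
            jump_frame = spec.stim_frame + int(rng.integers(1, 3))
            jump_dir = rng.uniform(0, 2 * np.pi)
            jump_mag = rng.uniform(*spec.responder_displacement_px)
            for f in range(spec.n_frames):
                pos = pos + rng.normal(0, spec.jitter_sd_px, 2)
                if responded and f == jump_frame:
                    pos = pos + jump_mag * np.array([np.cos(jump_dir), np.sin(jump_dir)])
                track_rows.append(
                    {"animal": animal, "trial": trial, "frame": f,
                     "x": float(pos[0]), "y": float(pos[1])}
                )
    tracks = pd.DataFrame(track_rows)
    planted = pd.DataFrame(planted_rows)
    return tracks, planted
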