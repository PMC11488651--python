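"""Cohort-level recovery experiments shared by the analysis scripts and tests.

Each function generates a seeded synthetic cohort, runs the corresponding
quantification pipeline end to end, and returns tidy per-organ results.
Seeds are spawned deterministically from a single base seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calcium import (
    CLASS_PARAMS,
    classify_response,
    extract_dff,
    flag_square_wave,
    preprocess_movie,
    summarize_responses,
)
from .pairing import pair_puncta, percent_reduction, summarize_neuromast
from .puncta import PRESETS, detect_puncta
from .synth import generate_calcium_movie, generate_neuromast_stack, movie_spec, stack_spec

__all__ = [
    "spawn_seeds",
    "run_synapse_cohort",
    "synapse_reduction",
    "run_calcium_cohort",
    "calcium_reduction",
]


def spawn_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def run_synapse_cohort(
    preset: str,
    seeds: list[int],
    detection_preset: str = "zf_lateral_line",
    n_hair_cells: int = 15,
) -> pd.DataFrame:
    """Generate stacks for one genotype and push them through the pipeline.

    Returns one row per organ (stack) with the pipeline-reported per-cell
    rates alongside the planted ground-truth rates.
    """
    params = PRESETS[detection_preset]
    rows = []
    for seed in seeds:
        spec = stack_spec(preset, seed=seed, n_hair_cells=n_hair_cells)
        stack, truth = generate_neuromast_stack(spec)
        pre = detect_puncta(stack["pre"], truth.mask, params["ctbp"], spec.pixel_size_xy)
        post = detect_puncta(stack["post"], truth.mask, params["maguk"], spec.pixel_size_xy)
        records = pair_puncta(pre, post)
        summary = summarize_neuromast(records, pre, post, spec.n_hair_cells)
        planted = truth.per_cell
        rows.append(
            {
                "preset": preset,
                "seed": seed,
                "complete_per_cell": summary.complete_per_cell,
                "unpaired_pre_per_cell": summary.unpaired_pre_per_cell,
                "unpaired_post_per_cell": summary.unpaired_post_per_cell,
                "total_pre_per_cell": summary.total_pre_per_cell,
                "total_post_per_cell": summary.total_post_per_cell,
                "planted_complete_per_cell": planted["complete"].mean(),
                "planted_unpaired_pre_per_cell": planted["unpaired_pre"].mean(),
                "planted_unpaired_post_per_cell": planted["unpaired_post"].mean(),
            }
        )
    return pd.DataFrame(rows)


def synapse_reduction(
    control_preset: str,
    mutant_preset: str,
    base_seed: int,
    n_per_group: int = 12,
    n_hair_cells: int = 15,
) -> tuple[float, pd.DataFrame]:
    """Percent reduction in pipeline-reported complete synapses per cell."""
    seeds = spawn_seeds(base_seed, 2 * n_per_group)
    control = run_synapse_cohort(control_preset, seeds[:n_per_group], n_hair_cells=n_hair_cells)
    mutant = run_synapse_cohort(mutant_preset, seeds[n_per_group:], n_hair_cells=n_hair_cells)
    table = pd.concat([control, mutant], ignore_index=True)
    reduction = percent_reduction(
        control["complete_per_cell"].mean(), mutant["complete_per_cell"].mean()
    )
    return reduction, table


def process_movie(spec, movie: np.ndarray, roi_table: pd.DataFrame):
    """Full single-movie calcium pipeline; returns (traces, organ summary)."""
    params = CLASS_PARAMS[spec.signal_class]
    frames, _shifts = preprocess_movie(movie, params)
    onset = spec.stim_onset_timepoint - 1 - params.n_trim
    traces = []
    for _, row in roi_table.iterrows():
        trace = extract_dff(frames, (int(row["y"]), int(row["x"])), params)
        trace.artifact = flag_square_wave(trace.dff)
        trace.responsive = classify_response(
            trace, params, onset, spec.stim_duration_s, spec.frame_interval_s
        )
        trace.direction = str(row["direction"])
        traces.append(trace)
    return traces, summarize_responses(traces)


def run_calcium_cohort(preset: str, amplitude: float, seeds: list[int]) -> pd.DataFrame:
    """Generate movies for one genotype and run the calcium pipeline."""
    rows = []
    for seed in seeds:
        spec = movie_spec(preset, seed=seed, amplitude=amplitude)
        movie, table = generate_calcium_movie(spec)
        _traces, organ = process_movie(spec, movie, table)
        rows.append(
            {
                "preset": preset,
                "seed": seed,
                "planted_amplitude": amplitude,
                "max_dff": organ.max_dff,
                "n_active": organ.n_active,
            }
        )
    return pd.DataFrame(rows)


def calcium_reduction(
    preset: str,
    control_amplitude: float,
    mutant_amplitude: float,
    base_seed: int,
    n_per_group: int = 12,
) -> tuple[float, pd.DataFrame]:
    """Percent reduction of the group-mean organ max dF/F0."""
    seeds = spawn_seeds(base_seed, 2 * n_per_group)
    control = run_calcium_cohort(preset, control_amplitude, seeds[:n_per_group])
    mutant = run_calcium_cohort(preset, mutant_amplitude, seeds[n_per_group:])
    table = pd.concat([control, mutant], ignore_index=True)
    reduction = percent_reduction(control["max_dff"].mean(), mutant["max_dff"].mean())
    return reduction, table
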