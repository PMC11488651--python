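"""Cohort presets: the study conditions each recovery experiment assumes.

Stack presets plant the per-cell pairing structure of the two genotype
comparisons: mature neuromasts (wild type 10 complete + 1 lone pre + 1 lone
post per cell; mutant 4 complete + 6 lone pre + 2 lone post, so the total
presynapse count is unchanged while total postsynapses fall) and developing
neuromasts (mutant cells alternate 6 and 7 complete synapses with lone
counts chosen so each cell's total pre and post puncta match the wild
type).  Movie presets plant the evoked-response amplitudes of the
presynaptic (110 timepoints) and postsynaptic (80 timepoints) recordings.
"""

from __future__ import annotations

from .movies import MovieSpec
from .stacks import StackSpec

__all__ = ["stack_spec", "movie_spec", "STACK_PRESETS", "MOVIE_PRESETS"]

_DEV_TOTAL = 11  # per-cell total pre (and post) puncta in both genotypes


def _dev_mut_counts(n_cells: int) -> tuple[list[int], list[int], list[int]]:
    complete = [6 if i % 2 == 0 else 7 for i in range(n_cells)]
    lone = [_DEV_TOTAL - c for c in complete]
    return complete, lone, lone


STACK_PRESETS = ("mature_wt", "mature_mut", "dev3dpf_wt", "dev3dpf_mut")
MOVIE_PRESETS = ("presyn_movie", "postsyn_movie")


def stack_spec(preset: str, seed: int, n_hair_cells: int = 15, **overrides) -> StackSpec:
    """Build the StackSpec for a named cohort preset."""
    if preset in ("mature_wt", "dev3dpf_wt"):
        kw = dict(complete_per_cell=10, unpaired_pre_per_cell=1, unpaired_post_per_cell=1)
    elif preset == "mature_mut":
        kw = dict(complete_per_cell=4, unpaired_pre_per_cell=6, unpaired_post_per_cell=2)
    elif preset == "dev3dpf_mut":
        complete, lone_pre, lone_post = _dev_mut_counts(n_hair_cells)
        kw = dict(
            complete_per_cell=complete,
            unpaired_pre_per_cell=lone_pre,
            unpaired_post_per_cell=lone_post,
        )
    else:
        raise ValueError(f"unknown stack preset {preset!r}; choose from {STACK_PRESETS}")
    kw.update(overrides)
    return StackSpec(n_hair_cells=n_hair_cells, seed=seed, **kw)


def movie_spec(preset: str, seed: int, amplitude: float, **overrides) -> MovieSpec:
    """Build the MovieSpec for a named signal-class preset."""
    if preset == "presyn_movie":
        kw = dict(signal_class="presynaptic", n_timepoints=110, n_zslices=3)
    elif preset == "postsyn_movie":
        kw = dict(signal_class="postsynaptic", n_timepoints=80, n_zslices=5)
    else:
        raise ValueError(f"unknown movie preset {preset!r}; choose from {MOVIE_PRESETS}")
    kw.update(overrides)
    return MovieSpec(planted_amplitudes=amplitude, seed=seed, **kw)
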