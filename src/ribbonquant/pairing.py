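"""Cross-channel pairing of puncta and neuromast-level accounting.

A presynaptic punctum and a postsynaptic punctum are partners ("complete
synapse") when their pixel sets overlap or lie within ``max_gap`` pixels of
each other, edge to edge.  Candidate pairs are resolved into a one-to-one
matching greedily by ascending gap distance, with (pre id, post id) as the
deterministic tie-break; leftover puncta are reported as unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import pixel_set_distance
from .puncta import Punctum

__all__ = [
    "SynapseRecord",
    "NeuromastSummary",
    "ChannelPairCounts",
    "pair_puncta",
    "summarize_neuromast",
    "pair_channel_counts",
    "percent_reduction",
]


@dataclass(frozen=True)
class SynapseRecord:
    """Outcome of pairing: a complete synapse or a lone punctum."""

    pre_id: int | None
    post_id: int | None
    status: str  # complete | unpaired_pre | unpaired_post
    pair_distance: float  # px edge-to-edge, 0 for overlapping partners

    def __post_init__(self) -> None:
        if self.status == "complete":
            if self.pre_id is None or self.post_id is None:
                raise ValueError("complete record needs both ids")
        elif self.status == "unpaired_pre":
            if self.pre_id is None or self.post_id is not None:
                raise ValueError("unpaired_pre record must carry only pre_id")
        elif self.status == "unpaired_post":
            if self.post_id is None or self.pre_id is not None:
                raise ValueError("unpaired_post record must carry only post_id")
        else:
            raise ValueError(f"unknown status {self.status!r}")


def _candidate_pairs(
    pre: list[Punctum], post: list[Punctum], max_gap: float
) -> list[tuple[float, int, int]]:
    """All (gap, pre_id, post_id) with edge-to-edge gap <= max_gap."""
    if not pre or not post:
        return []
    post_pixels = np.concatenate([p.coords for p in post]).astype(float)
    post_owner = np.concatenate([np.full(len(p.coords), i) for i, p in enumerate(post)])
    tree = cKDTree(post_pixels)
    out: list[tuple[float, int, int]] = []
    for i, pp in enumerate(pre):
        hits = tree.query_ball_point(pp.coords.astype(float), r=max_gap)
        near = {int(post_owner[k]) for lst in hits for k in lst}
        for j in sorted(near):
            d = pixel_set_distance(pp.coords, post[j].coords)
            if d <= max_gap:
                out.append((d, pp.id, post[j].id))
    return out


def pair_puncta(
    pre: list[Punctum], post: list[Punctum], max_gap: float = 2.0
) -> list[SynapseRecord]:
    """Match pre- and postsynaptic puncta into synapse records.

    The matching is symmetric: swapping the argument order swaps the
    unpaired statuses but yields the same set of matched (pre, post) pairs.
    """
    by_pre = {p.id: p for p in pre}
    by_post = {p.id: p for p in post}
    if len(by_pre) != len(pre) or len(by_post) != len(post):
        raise ValueError("puncta ids must be unique within a channel")

    candidates = sorted(_candidate_pairs(pre, post, max_gap))
    used_pre: set[int] = set()
    used_post: set[int] = set()
    records: list[SynapseRecord] = []
    for d, i, j in candidates:
        if i in used_pre or j in used_post:
            continue
        used_pre.add(i)
        used_post.add(j)
        records.append(SynapseRecord(pre_id=i, post_id=j, status="complete", pair_distance=d))
    for p in pre:
        if p.id not in used_pre:
            records.append(
                SynapseRecord(pre_id=p.id, post_id=None, status="unpaired_pre", pair_distance=np.inf)
            )
    for p in post:
        if p.id not in used_post:
            records.append(
                SynapseRecord(pre_id=None, post_id=p.id, status="unpaired_post", pair_distance=np.inf)
            )
    return records


@dataclass
class NeuromastSummary:
    """Whole-organ synapse counts expressed per hair cell.

    Area and intensity means are split by pairing status; entries are NaN
    when a category is empty.
    """

    n_hair_cells: int
    complete_per_cell: float
    unpaired_pre_per_cell: float
    unpaired_post_per_cell: float
    total_pre_per_cell: float
    total_post_per_cell: float
    mean_area_paired_pre: float
    mean_area_unpaired_pre: float
    mean_area_paired_post: float
    mean_area_unpaired_post: float
    mean_intensity_paired_pre: float
    mean_intensity_unpaired_pre: float
    mean_intensity_paired_post: float
    mean_intensity_unpaired_post: float


def _mean(values: list[float]) -> float:
    return float(np.mean(values)) if values else float("nan")


def summarize_neuromast(
    records: list[SynapseRecord],
    pre: list[Punctum],
    post: list[Punctum],
    n_hair_cells: int,
) -> NeuromastSummary:
    """Organ totals divided by the (manually supplied) hair-cell count."""
    if n_hair_cells < 1:
        raise ValueError("n_hair_cells must be >= 1")
    by_pre = {p.id: p for p in pre}
    by_post = {p.id: p for p in post}

    n_complete = sum(r.status == "complete" for r in records)
    n_up_pre = sum(r.status == "unpaired_pre" for r in records)
    n_up_post = sum(r.status == "unpaired_post" for r in records)

    paired_pre = [by_pre[r.pre_id] for r in records if r.status == "complete"]
    paired_post = [by_post[r.post_id] for r in records if r.status == "complete"]
    lone_pre = [by_pre[r.pre_id] for r in records if r.status == "unpaired_pre"]
    lone_post = [by_post[r.post_id] for r in records if r.status == "unpaired_post"]

    n = float(n_hair_cells)
    return NeuromastSummary(
        n_hair_cells=n_hair_cells,
        complete_per_cell=n_complete / n,
        unpaired_pre_per_cell=n_up_pre / n,
        unpaired_post_per_cell=n_up_post / n,
        total_pre_per_cell=(n_complete + n_up_pre) / n,
        total_post_per_cell=(n_complete + n_up_post) / n,
        mean_area_paired_pre=_mean([p.area_um2 for p in paired_pre]),
        mean_area_unpaired_pre=_mean([p.area_um2 for p in lone_pre]),
        mean_area_paired_post=_mean([p.area_um2 for p in paired_post]),
        mean_area_unpaired_post=_mean([p.area_um2 for p in lone_post]),
        mean_intensity_paired_pre=_mean([p.mean_intensity for p in paired_pre]),
        mean_intensity_unpaired_pre=_mean([p.mean_intensity for p in lone_pre]),
        mean_intensity_paired_post=_mean([p.mean_intensity for p in paired_post]),
        mean_intensity_unpaired_post=_mean([p.mean_intensity for p in lone_post]),
    )


@dataclass
class ChannelPairCounts:
    """Pairing of an arbitrary channel pair, e.g. CTBP-CaV1.3 or MAGUK-CaV1.3.

    Reports the paired count per hair cell plus the area and mean intensity
    of the B-channel member of each pair (the calcium-channel punctum when B
    is CaV1.3).
    """

    channel_a: str
    channel_b: str
    n_pairs: int
    pairs_per_cell: float
    mean_area_b: float
    mean_intensity_b: float


def pair_channel_counts(
    channel_a: list[Punctum],
    channel_b: list[Punctum],
    n_hair_cells: int,
    max_gap: float = 2.0,
) -> ChannelPairCounts:
    """Count A-B paired puncta with the same rule as pre/post pairing."""
    if n_hair_cells < 1:
        raise ValueError("n_hair_cells must be >= 1")
    records = pair_puncta(channel_a, channel_b, max_gap=max_gap)
    by_b = {p.id: p for p in channel_b}
    paired_b = [by_b[r.post_id] for r in records if r.status == "complete"]
    return ChannelPairCounts(
        channel_a=channel_a[0].channel if channel_a else "",
        channel_b=channel_b[0].channel if channel_b else "",
        n_pairs=len(paired_b),
        pairs_per_cell=len(paired_b) / float(n_hair_cells),
        mean_area_b=_mean([p.area_um2 for p in paired_b]),
        mean_intensity_b=_mean([p.mean_intensity for p in paired_b]),
    )


def percent_reduction(control_mean: float, mutant_mean: float) -> float:
    """``100 * (1 - mutant/control)``; requires a positive control mean."""
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    return 100.0 * (1.0 - mutant_mean / control_mean)
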