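"""Pairing rule, matching properties and neuromast accounting."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribbonquant.geometry import pixel_set_distance
from ribbonquant.pairing import (
    SynapseRecord,
    pair_channel_counts,
    pair_puncta,
    percent_reduction,
    summarize_neuromast,
)
from ribbonquant.puncta import Punctum


def make_punctum(pid, channel, coords, area=0.03, intensity=100.0):
    coords = np.asarray(coords)
    return Punctum(
        id=pid,
        channel=channel,
        coords=coords,
        centroid=tuple(coords.mean(axis=0)),
        area_um2=area,
        mean_intensity=intensity,
        circularity=0.3,
    )


def square(pid, channel, r0, c0, size=3, **kw):
    coords = [(r, c) for r in range(r0, r0 + size) for c in range(c0, c0 + size)]
    return make_punctum(pid, channel, coords, **kw)


def test_overlapping_puncta_pair_at_distance_zero():
    pre = [square(0, "pre", 10, 10)]
    post = [square(0, "post", 11, 11)]
    records = pair_puncta(pre, post)
    assert [r.status for r in records] == ["complete"]
    assert records[0].pair_distance == 0.0


def test_three_pixel_gap_does_not_pair():
    pre = [square(0, "pre", 10, 10)]  # rows 10-12
    post = [square(0, "post", 15, 10)]  # rows 15-17: nearest pixels 3 px apart
    statuses = sorted(r.status for r in pair_puncta(pre, post))
    assert statuses == ["unpaired_post", "unpaired_pre"]


def test_two_pixel_gap_pairs():
    pre = [square(0, "pre", 10, 10)]  # rows 10-12
    post = [square(0, "post", 14, 10)]  # rows 14-16: nearest pixels 2 px apart
    records = pair_puncta(pre, post)
    assert [r.status for r in records] == ["complete"]
    assert records[0].pair_distance == pytest.approx(2.0)


def test_empty_inputs_allowed():
    assert pair_puncta([], []) == []


def test_closest_candidate_wins():
    pre = [square(0, "pre", 10, 10)]
    post = [square(0, "post", 10, 10), square(1, "post", 10, 14)]  # gaps 0 and 1
    records = pair_puncta(pre, post)
    complete = [r for r in records if r.status == "complete"]
    assert len(complete) == 1 and complete[0].post_id == 0
    assert any(r.status == "unpaired_post" and r.post_id == 1 for r in records)


def _random_puncta(rng, channel, n, spread=60):
    """Single-pixel puncta at well-separated random positions."""
    out = []
    taken = []
    for i in range(n):
        for _ in range(100):
            p = rng.integers(0, spread, 2)
            if all(abs(p - q).max() > 4 for q in taken):
                taken.append(p)
                break
        out.append(make_punctum(i, channel, [tuple(taken[-1])]))
    return out


def _brute_force_matching(pre, post, max_gap=2.0):
    """Exhaustive minimum-total-distance one-to-one matching oracle."""
    dist = {
        (a.id, b.id): pixel_set_distance(a.coords, b.coords) for a in pre for b in post
    }
    candidates = {k for k, d in dist.items() if d <= max_gap}
    best, best_cost = set(), (0, 0.0)  # maximize pairs, then minimize cost
    ids_post = [b.id for b in post]
    for perm in permutations(ids_post):
        matched = set()
        used = set()
        cost = 0.0
        for a, b in zip([p.id for p in pre], perm):
            if (a, b) in candidates and b not in used:
                matched.add((a, b))
                used.add(b)
                cost += dist[(a, b)]
        key = (len(matched), -cost)
        if key > (best_cost[0], -best_cost[1]):
            best, best_cost = matched, (len(matched), cost)
    return best, best_cost[0]


@pytest.mark.parametrize("seed", range(8))
def test_greedy_equals_exhaustive_on_separated_configurations(seed):
    """On stack-like geometry the greedy matching is the optimal matching."""
    rng = np.random.default_rng(seed)
    n_pre, n_post = rng.integers(1, 6, 2)
    pre = _random_puncta(rng, "pre", int(n_pre))
    post = _random_puncta(rng, "post", int(n_post))
    records = pair_puncta(pre, post)
    greedy = {(r.pre_id, r.post_id) for r in records if r.status == "complete"}
    _best, best_n = _brute_force_matching(pre, post)
    assert len(greedy) == best_n


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_matching_invariants(seed):
    """Accounting identity, uniqueness, and swap symmetry on random inputs."""
    rng = np.random.default_rng(seed)
    pre = _random_puncta(rng, "pre", int(rng.integers(0, 8)), spread=30)
    post = _random_puncta(rng, "post", int(rng.integers(0, 8)), spread=30)
    records = pair_puncta(pre, post)

    n_complete = sum(r.status == "complete" for r in records)
    n_up_pre = sum(r.status == "unpaired_pre" for r in records)
    n_up_post = sum(r.status == "unpaired_post" for r in records)
    assert n_complete + n_up_pre == len(pre)
    assert n_complete + n_up_post == len(post)

    pre_ids = [r.pre_id for r in records if r.pre_id is not None]
    post_ids = [r.post_id for r in records if r.post_id is not None]
    assert len(pre_ids) == len(set(pre_ids))
    assert len(post_ids) == len(set(post_ids))

    swapped = pair_puncta(post, pre)
    forward = {(r.pre_id, r.post_id) for r in records if r.status == "complete"}
    backward = {(r.post_id, r.pre_id) for r in swapped if r.status == "complete"}
    assert forward == backward


def test_record_validation():
    with pytest.raises(ValueError):
        SynapseRecord(pre_id=None, post_id=None, status="complete", pair_distance=0)
    with pytest.raises(ValueError):
        SynapseRecord(pre_id=1, post_id=2, status="unpaired_pre", pair_distance=0)
    with pytest.raises(ValueError):
        SynapseRecord(pre_id=1, post_id=2, status="nonsense", pair_distance=0)


class TestSummarize:
    def test_rate_arithmetic(self):
        pre = [square(i, "pre", 10 * i, 0) for i in range(25)]
        post = [square(i, "post", 10 * i, 0) for i in range(20)] + [
            square(20 + i, "post", 10 * i, 30) for i in range(5)
        ]
        records = pair_puncta(pre, post)
        s = summarize_neuromast(records, pre, post, n_hair_cells=2)
        assert s.complete_per_cell == 10.0
        assert s.unpaired_pre_per_cell == 2.5
        assert s.unpaired_post_per_cell == 2.5
        assert s.total_pre_per_cell == 12.5
        assert s.total_post_per_cell == 12.5

    def test_empty_records_give_zero_rates(self):
        s = summarize_neuromast([], [], [], n_hair_cells=4)
        assert s.complete_per_cell == 0.0
        assert np.isnan(s.mean_area_paired_pre)

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            summarize_neuromast([], [], [], n_hair_cells=0)


def test_channel_pair_counts_reports_b_member():
    a = [square(0, "ctbp", 10, 10)]
    b = [square(0, "cav", 11, 10, area=0.05, intensity=80.0)]
    out = pair_channel_counts(a, b, n_hair_cells=2)
    assert out.n_pairs == 1 and out.pairs_per_cell == 0.5
    assert out.mean_area_b == pytest.approx(0.05)
    assert out.mean_intensity_b == pytest.approx(80.0)
    empty = pair_channel_counts(a, [], n_hair_cells=2)
    assert empty.n_pairs == 0


@pytest.mark.parametrize(
    "control, mutant, expected",
    [(10.0, 4.0, 60.0), (10.0, 10.0, 0.0), (8.0, 10.0, -25.0)],
)
def test_percent_reduction(control, mutant, expected):
    assert percent_reduction(control, mutant) == pytest.approx(expected)


def test_percent_reduction_needs_positive_control():
    with pytest.raises(ValueError):
        percent_reduction(0.0, 1.0)
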