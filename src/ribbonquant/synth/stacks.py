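"""Ground-truthed synthetic neuromast image stacks.

The generator plants pre/postsynaptic (and optionally calcium-channel)
puncta inside elliptical hair-cell footprints, with exact control over how
many puncta per cell are paired across channels ("complete synapses") and
how many are lone.  Geometry is enforced on the rendered pixel sets, not on
nominal radii: every planted pair has half-maximum edge gap <= 2 px, every
planted lone punctum keeps at least ``min_unpaired_gap_px`` from all
opposite-channel puncta, and same-channel puncta never touch.  Imaging
emulates acquisition at 0.043 um/px with a constant background, a shading
gradient, signal-dependent photon noise and additive read noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .blobs import BlobRender, PlacementError, render_punctum

__all__ = ["StackSpec", "GroundTruthSynapses", "generate_neuromast_stack", "PlacementError"]

_DEFAULT_MIN_AREAS = MappingProxyType({"pre": 0.025, "post": 0.04, "cav": 0.025})

# gap (px) below which two same-channel support footprints may merge into
# one detected particle; candidate placements closer than this are rejected
_SAME_CHANNEL_GAP = 2.5
# minimum support-level gap between opposite-channel puncta of different sites
_CROSS_SUPPORT_GAP = 2.5


@dataclass(frozen=True)
class StackSpec:
    """Recipe for one synthetic neuromast stack.

    Per-cell counts may be a single integer (same for every hair cell) or a
    sequence with one entry per cell.  ``min_area_um2`` carries the
    detection size floors the planted puncta must clear; ``area_margin``
    sets how far above the floor the smallest planted punctum sits.
    """

    n_hair_cells: int
    complete_per_cell: int | Sequence[int]
    unpaired_pre_per_cell: int | Sequence[int] = 0
    unpaired_post_per_cell: int | Sequence[int] = 0
    include_cav: bool = False
    pixel_size_xy: float = 0.043  # um/px
    z_step: float = 0.15  # um
    n_zslices: int = 3
    punctum_radius_um: tuple[float, float] = (0.10, 0.16)
    pair_offset_um: float = 0.2  # centroid gap between pair members
    min_unpaired_gap_px: float = 5.0
    amplitude: float = 150.0
    amplitude_jitter: float = 0.1
    background: float = 20.0
    background_gradient: float = 10.0
    photon_gain: float = 0.6  # noise variance = read^2 + gain * intensity
    read_noise_sd: float = 3.0
    min_area_um2: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIN_AREAS)
    )
    area_margin: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hair_cells < 1:
            raise ValueError("n_hair_cells must be >= 1")
        for name in ("complete_per_cell", "unpaired_pre_per_cell", "unpaired_post_per_cell"):
            if min(self._per_cell(name)) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.min_unpaired_gap_px <= 2:
            raise ValueError("min_unpaired_gap_px must exceed the 2-px pairing gap")
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be positive")
        lo, hi = self.punctum_radius_um
        if not 0 < lo <= hi:
            raise ValueError("punctum_radius_um must be an increasing positive range")

    def _per_cell(self, name: str) -> list[int]:
        value = getattr(self, name)
        if np.isscalar(value):
            return [int(value)] * self.n_hair_cells
        value = [int(v) for v in value]
        if len(value) != self.n_hair_cells:
            raise ValueError(f"{name} list must have n_hair_cells entries")
        return value

    @property
    def complete_counts(self) -> list[int]:
        return self._per_cell("complete_per_cell")

    @property
    def unpaired_pre_counts(self) -> list[int]:
        return self._per_cell("unpaired_pre_per_cell")

    @property
    def unpaired_post_counts(self) -> list[int]:
        return self._per_cell("unpaired_post_per_cell")


@dataclass
class GroundTruthSynapses:
    """Planted geometry and counts emitted alongside a synthetic stack."""

    puncta: pd.DataFrame  # punctum, channel, cell, y, x, area_px, area_um2, pair_id
    per_cell: pd.DataFrame  # cell, complete, unpaired_pre, unpaired_post
    mask_labels: np.ndarray  # uint16 label image of hair-cell footprints
    pixel_sets: list[np.ndarray]  # half-max (row, col) sets, row-aligned with puncta

    @property
    def mask(self) -> np.ndarray:
        return self.mask_labels > 0


class _Occupancy:
    """Per-channel pixel bookkeeping with cached minimum-gap queries."""

    def __init__(self) -> None:
        self.support: dict[str, list[np.ndarray]] = {}
        self.halfmax: dict[str, list[np.ndarray]] = {}
        self._trees: dict[tuple[str, str], cKDTree | None] = {}

    def add(self, channel: str, support: np.ndarray, halfmax: np.ndarray) -> None:
        self.support.setdefault(channel, []).append(support)
        self.halfmax.setdefault(channel, []).append(halfmax)
        self._trees.pop(("support", channel), None)
        self._trees.pop(("halfmax", channel), None)

    def _gap(self, kind: str, channel: str, coords: np.ndarray, exclude: int | None) -> float:
        sets = getattr(self, kind).get(channel, [])
        if not sets:
            return np.inf
        if exclude is not None:
            pts = [s for i, s in enumerate(sets) if i != exclude]
            if not pts:
                return np.inf
            tree = cKDTree(np.concatenate(pts).astype(float))
        else:
            tree = self._trees.get((kind, channel))
            if tree is None:
                tree = cKDTree(np.concatenate(sets).astype(float))
                self._trees[(kind, channel)] = tree
        d, _ = tree.query(coords.astype(float), k=1)
        return float(d.min())

    def support_gap(self, channel: str, coords: np.ndarray, exclude: int | None = None) -> float:
        return self._gap("support", channel, coords, exclude)

    def halfmax_gap(self, channel: str, coords: np.ndarray, exclude: int | None = None) -> float:
        return self._gap("halfmax", channel, coords, exclude)

    def n(self, channel: str) -> int:
        return len(self.support.get(channel, []))


def _cell_layout(spec: StackSpec) -> tuple[np.ndarray, list[tuple[float, float]], tuple[float, float]]:
    """Label image of elliptical hair-cell footprints on a grid."""
    max_sites = max(
        c + up + upo
        for c, up, upo in zip(
            spec.complete_counts, spec.unpaired_pre_counts, spec.unpaired_post_counts
        )
    )
    max_sites = max(max_sites, 1)
    # room for max_sites puncta at a conservative ~20 px site pitch, with
    # random-sequential packing efficiency ~0.5
    area_needed = max_sites * 20.0**2 * 0.866 / 0.5
    semi_b = float(np.sqrt(area_needed / (np.pi * 1.25)))
    semi_a = 1.25 * semi_b

    n_cols = min(5, spec.n_hair_cells)
    n_rows = int(np.ceil(spec.n_hair_cells / n_cols))
    pitch_x = 2 * semi_a + 10
    pitch_y = 2 * semi_b + 10
    shape = (int(n_rows * pitch_y + 20), int(n_cols * pitch_x + 20))

    labels = np.zeros(shape, dtype=np.uint16)
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    centers: list[tuple[float, float]] = []
    for i in range(spec.n_hair_cells):
        r, c = divmod(i, n_cols)
        cy = 10 + pitch_y * (r + 0.5)
        cx = 10 + pitch_x * (c + 0.5)
        inside = ((yy - cy) / semi_b) ** 2 + ((xx - cx) / semi_a) ** 2 <= 1.0
        labels[inside] = i + 1
        centers.append((cy, cx))
    return labels, centers, (semi_b, semi_a)


def _sample_center(
    rng: np.random.Generator, center: tuple[float, float], semi: tuple[float, float]
) -> tuple[int, int]:
    t = rng.uniform(0, 2 * np.pi)
    u = np.sqrt(rng.uniform())
    return (
        int(round(center[0] + 0.92 * semi[0] * u * np.sin(t))),
        int(round(center[1] + 0.92 * semi[1] * u * np.cos(t))),
    )


def _shifted(blob: BlobRender, at: tuple[int, int], shape: tuple[int, int]):
    """Absolute (half-max, support) coordinate sets, or None if out of frame."""
    off = np.array(at) - (blob.window - 1) // 2
    support = blob.support + off
    if support.min() < 0 or (support[:, 0] >= shape[0]).any() or (support[:, 1] >= shape[1]).any():
        return None
    return blob.halfmax + off, support


def _min_gap(a: np.ndarray, b: np.ndarray) -> float:
    d, _ = cKDTree(a.astype(float)).query(b.astype(float), k=1)
    return float(d.min())


def generate_neuromast_stack(
    spec: StackSpec,
) -> tuple[dict[str, np.ndarray], GroundTruthSynapses]:
    """Render a multi-channel stack with exactly the requested pairing structure.

    Returns ``(stack, ground_truth)`` where ``stack`` maps channel name
    ("pre", "post" and optionally "cav") to a ``(z, y, x)`` float32 array.
    Raises :class:`PlacementError` when the requested puncta cannot be
    placed at the required gaps.
    """
    rng = np.random.default_rng(spec.seed)
    labels, centers, semi = _cell_layout(spec)
    shape = labels.shape
    px = spec.pixel_size_xy
    min_area_px = {k: v / px**2 for k, v in spec.min_area_um2.items()}
    pair_offset_px = spec.pair_offset_um / px

    channels = ("pre", "post", "cav") if spec.include_cav else ("pre", "post")
    occ = _Occupancy()
    signal = {ch: np.zeros(shape) for ch in channels}
    rows: list[dict] = []
    pixel_sets: list[np.ndarray] = []
    pair_counter = 0

    def _draw_blob(channel: str) -> BlobRender:
        r_um = rng.uniform(*spec.punctum_radius_um)
        target = np.pi * (r_um / px) ** 2
        floor = min_area_px[channel] * spec.area_margin
        return render_punctum(rng, max(target, floor), floor)

    def _stamp(channel: str, blob: BlobRender, at: tuple[int, int], scale: float) -> None:
        w = blob.window
        off = (at[0] - (w - 1) // 2, at[1] - (w - 1) // 2)
        y0, y1 = max(off[0], 0), min(off[0] + w, shape[0])
        x0, x1 = max(off[1], 0), min(off[1] + w, shape[1])
        signal[channel][y0:y1, x0:x1] += (
            scale * blob.image[y0 - off[0] : y1 - off[0], x0 - off[1] : x1 - off[1]]
        )

    def _record(channel: str, cell: int, blob: BlobRender, halfmax: np.ndarray,
                pair_id: int | None) -> None:
        rows.append(
            {
                "punctum": len(rows),
                "channel": channel,
                "cell": cell,
                "y": float(halfmax[:, 0].mean()),
                "x": float(halfmax[:, 1].mean()),
                "area_px": blob.area_px,
                "area_um2": blob.area_px * px**2,
                "pair_id": -1 if pair_id is None else pair_id,
            }
        )
        pixel_sets.append(halfmax)

    def _amp() -> float:
        return spec.amplitude * (1 + rng.uniform(-spec.amplitude_jitter, spec.amplitude_jitter))

    def _fits(channel: str, halfmax: np.ndarray, support: np.ndarray, cell_label: int,
              opposite: Sequence[str], exclude: Mapping[str, int] | None = None) -> bool:
        exclude = exclude or {}
        if not (labels[support[:, 0], support[:, 1]] == cell_label).all():
            return False
        if occ.support_gap(channel, support, exclude.get(channel)) < _SAME_CHANNEL_GAP:
            return False
        for och in opposite:
            if occ.halfmax_gap(och, halfmax, exclude.get(och)) < spec.min_unpaired_gap_px:
                return False
            if occ.support_gap(och, support, exclude.get(och)) < _CROSS_SUPPORT_GAP:
                return False
        return True

    def _plant_cav(pre_at: tuple[int, int], cell: int, partner_post: np.ndarray | None) -> None:
        """Calcium-channel punctum almost concentric with its presynapse."""
        cell_label = cell + 1
        post_exclude = occ.n("post") - 1 if partner_post is not None else None
        for _ in range(60):
            blob = _draw_blob("cav")
            at = (
                pre_at[0] + int(rng.integers(-1, 2)),
                pre_at[1] + int(rng.integers(-1, 2)),
            )
            shifted = _shifted(blob, at, shape)
            if shifted is None:
                continue
            hm, sup = shifted
            if not (labels[sup[:, 0], sup[:, 1]] == cell_label).all():
                continue
            if occ.support_gap("cav", sup) < _SAME_CHANNEL_GAP:
                continue
            # must pair with its own post at complete sites ...
            if partner_post is not None and _min_gap(partner_post, hm) > 2.0:
                continue
            # ... and must stay clear of every other postsynapse
            if occ.halfmax_gap("post", hm, exclude=post_exclude) < 2.5:
                continue
            occ.add("cav", sup, hm)
            _stamp("cav", blob, at, _amp())
            _record("cav", cell, blob, hm, None)
            return
        raise PlacementError("could not place a CaV punctum next to its presynapse")

    for cell in range(spec.n_hair_cells):
        cell_label = cell + 1
        center = centers[cell]
        jobs = (
            [("pair", None)] * spec.complete_counts[cell]
            + [("lone", "pre")] * spec.unpaired_pre_counts[cell]
            + [("lone", "post")] * spec.unpaired_post_counts[cell]
        )
        rng.shuffle(jobs)
        for kind, channel in jobs:
            placed = False
            for _ in range(400):
                at = _sample_center(rng, center, semi)
                if kind == "lone":
                    blob = _draw_blob(channel)
                    shifted = _shifted(blob, at, shape)
                    if shifted is None:
                        continue
                    hm, sup = shifted
                    opposite = ["post"] if channel == "pre" else ["pre"]
                    if channel == "post" and spec.include_cav:
                        opposite.append("cav")
                    if not _fits(channel, hm, sup, cell_label, opposite):
                        continue
                    occ.add(channel, sup, hm)
                    _stamp(channel, blob, at, _amp())
                    _record(channel, cell, blob, hm, None)
                    if channel == "pre" and spec.include_cav:
                        _plant_cav(at, cell, None)
                    placed = True
                    break
                # complete pair: place the pre member, then its post partner
                pre_blob = _draw_blob("pre")
                pre_shift = _shifted(pre_blob, at, shape)
                if pre_shift is None:
                    continue
                pre_hm, pre_sup = pre_shift
                if not _fits("pre", pre_hm, pre_sup, cell_label, ["post"]):
                    continue
                partner = None
                for _ in range(25):
                    ang = rng.uniform(0, 2 * np.pi)
                    post_at = (
                        int(round(at[0] + pair_offset_px * np.sin(ang))),
                        int(round(at[1] + pair_offset_px * np.cos(ang))),
                    )
                    post_blob = _draw_blob("post")
                    post_shift = _shifted(post_blob, post_at, shape)
                    if post_shift is None:
                        continue
                    post_hm, post_sup = post_shift
                    # the partner must satisfy the pairing rule against its pre
                    # (its pre is not yet in the occupancy, so _fits sees only
                    # foreign presynapses, which it must stay clear of)
                    if _min_gap(pre_hm, post_hm) > 2.0:
                        continue
                    if not _fits("post", post_hm, post_sup, cell_label, ["pre"]):
                        continue
                    partner = (post_blob, post_at, post_hm, post_sup)
                    break
                if partner is None:
                    continue
                post_blob, post_at, post_hm, post_sup = partner
                occ.add("pre", pre_sup, pre_hm)
                occ.add("post", post_sup, post_hm)
                _stamp("pre", pre_blob, at, _amp())
                _stamp("post", post_blob, post_at, _amp())
                _record("pre", cell, pre_blob, pre_hm, pair_counter)
                _record("post", cell, post_blob, post_hm, pair_counter)
                if spec.include_cav:
                    _plant_cav(at, cell, post_hm)
                pair_counter += 1
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"cell {cell}: could not place a {kind} punctum under the gap "
                    "constraints; reduce counts or enlarge the cells"
                )

    puncta = pd.DataFrame(
        rows,
        columns=["punctum", "channel", "cell", "y", "x", "area_px", "area_um2", "pair_id"],
    )
    per_cell = pd.DataFrame(
        {
            "cell": np.arange(spec.n_hair_cells),
            "complete": spec.complete_counts,
            "unpaired_pre": spec.unpaired_pre_counts,
            "unpaired_post": spec.unpaired_post_counts,
        }
    )
    truth = GroundTruthSynapses(
        puncta=puncta, per_cell=per_cell, mask_labels=labels, pixel_sets=pixel_sets
    )

    # --- imaging: z-profiles, background, shading and noise -----------------
    nz = spec.n_zslices
    stack: dict[str, np.ndarray] = {}
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    grad_dir = rng.uniform(0, 2 * np.pi)
    shading = spec.background_gradient * (
        (yy / shape[0]) * np.sin(grad_dir) + (xx / shape[1]) * np.cos(grad_dir)
    )
    for ch in channels:
        planes = np.empty((nz,) + shape, dtype=np.float32)
        z_center = int(rng.integers(0, nz))
        z_weights = np.exp(-0.5 * ((np.arange(nz) - z_center) / 0.8) ** 2)
        z_weights /= z_weights.max()
        for z in range(nz):
            ideal = spec.background + shading + signal[ch] * z_weights[z]
            if spec.read_noise_sd > 0 or spec.photon_gain > 0:
                var = spec.read_noise_sd**2 + spec.photon_gain * np.clip(ideal, 0, None)
                ideal = ideal + rng.normal(0, 1, shape) * np.sqrt(var)
            planes[z] = ideal
        stack[ch] = planes
    return stack, truth
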