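"""Renderer for single synthetic puncta.

A punctum is drawn as a short chain of overlapping Gaussian lobes with
perpendicular jitter and per-lobe size/brightness variation.  The lumpy,
elongated outline this produces is what keeps digitized particles inside
the detector's circularity acceptance window (a clean disk or smooth
ellipse would score far too circular under the staircase-perimeter
convention).  Each rendered blob is measured and resampled until its
half-maximum area and circularity fall inside the requested acceptance
band, so planted ground truth is detectable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as sk_label

from ..geometry import circularity, halfmax_mask

__all__ = ["BlobRender", "render_punctum", "PlacementError"]

#: empirical half-max area of the 4-lobe chain, in units of sigma^2
_AREA_PER_SIGMA2 = 13.5
_N_LOBES = 4
_LOBE_SPREAD = 1.8  # lobe spacing along the chain, in sigma
_PERP_JITTER = 0.6  # perpendicular lobe jitter, in sigma
#: fraction of the peak below which a pixel no longer counts as blob support
SUPPORT_FRACTION = 0.15


class PlacementError(RuntimeError):
    """Raised when puncta cannot be rendered or placed under the constraints."""


@dataclass
class BlobRender:
    """A rendered punctum in its local window (intensity normalized to 1)."""

    image: np.ndarray  # (w, w) float, peak 1.0
    halfmax: np.ndarray  # (n, 2) local pixel coords at >= 50% peak
    support: np.ndarray  # (n, 2) local pixel coords at >= SUPPORT_FRACTION peak
    area_px: int
    circularity: float

    @property
    def window(self) -> int:
        return self.image.shape[0]


def _render_once(rng: np.random.Generator, sigma: float, window: int) -> np.ndarray:
    yy, xx = np.mgrid[:window, :window].astype(float)
    c = (window - 1) / 2
    ang = rng.uniform(0, np.pi)
    d = np.array([np.cos(ang), np.sin(ang)])
    p = np.array([-d[1], d[0]])
    img = np.zeros((window, window))
    offsets = (np.arange(_N_LOBES) - (_N_LOBES - 1) / 2) * _LOBE_SPREAD * sigma
    for o in offsets:
        jit = rng.normal(0, _PERP_JITTER * sigma)
        cy = c + o * d[0] + jit * p[0]
        cx = c + o * d[1] + jit * p[1]
        s = sigma * rng.uniform(0.7, 1.1)
        amp = rng.uniform(0.7, 1.0)
        img += amp * np.exp(-0.5 * (((yy - cy) / s) ** 2 + ((xx - cx) / s) ** 2))
    return img / img.max()


def render_punctum(
    rng: np.random.Generator,
    target_area_px: float,
    min_area_px: float,
    circ_range: tuple[float, float] = (0.15, 0.47),
    max_tries: int = 80,
) -> BlobRender:
    """Render a punctum whose half-max footprint passes the particle filter.

    ``target_area_px`` sets the expected half-maximum area; the blob is
    resampled until the measured area is at least ``min_area_px`` and the
    circularity (checked at both the half-max and a lower, detection-like
    threshold) lies within ``circ_range``.
    """
    from ..puncta import _watershed_split  # detector's own splitting step

    sigma = float(np.sqrt(max(target_area_px, min_area_px) / _AREA_PER_SIGMA2))
    window = int(np.ceil(10 * sigma)) | 1  # odd
    # the adaptive threshold lands somewhere in this band of the peak,
    # depending on amplitude jitter and the local mean under the blob
    check_fractions = (0.3, 0.35, 0.45, 0.5, 0.55)
    for _ in range(max_tries):
        img = _render_once(rng, sigma, window)
        hm = halfmax_mask(img)
        area = int(hm.sum())
        if area < min_area_px:
            continue
        ok = True
        for frac in check_fractions:
            m = img >= frac * img.max()
            if m.sum() < min_area_px / (1.1 if frac > 0.5 else 1.0):
                ok = False
                break
            if sk_label(m, connectivity=2).max() != 1:
                ok = False  # must stay one connected particle
                break
            if not (circ_range[0] <= circularity(m) <= circ_range[1]):
                ok = False
                break
            # the detector's watershed must leave the particle whole
            if _watershed_split(m).max() > 1:
                ok = False
                break
        if not ok:
            continue
        support = img >= SUPPORT_FRACTION * img.max()
        return BlobRender(
            image=img,
            halfmax=np.argwhere(hm),
            support=np.argwhere(support),
            area_px=area,
            circularity=circularity(hm),
        )
    raise PlacementError(
        f"could not render an acceptable punctum (target area {target_area_px:.1f} px, "
        f"min {min_area_px:.1f} px, circularity {circ_range}) in {max_tries} tries"
    )
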