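"""Synthetic GCaMP6s-like evoked-response movies with planted amplitudes.

Each ROI receives a stimulus-locked transient whose sampled peak dF/F0
equals its planted amplitude exactly in the noiseless limit: the response
kernel (saturating rise during the 500 ms stimulus, exponential decay
after) is normalized to unit maximum on the movie's own time grid.  A slow
exponential photobleaching term and Gaussian noise are layered on top;
designated ROIs receive an instantaneous sustained step, the signature of
a movement artifact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MovieSpec", "generate_calcium_movie"]


@dataclass(frozen=True)
class MovieSpec:
    """Recipe for one synthetic calcium movie.

    ``stim_onset_timepoint`` is the 1-based acquisition timepoint at which
    the stimulus starts (31 means the stimulus begins with the 31st
    recorded volume).  ``planted_amplitudes`` is either one peak dF/F0 for
    every ROI or a per-ROI sequence.
    """

    signal_class: str = "presynaptic"
    n_rois: int = 8
    n_timepoints: int = 110
    n_zslices: int = 3
    stim_onset_timepoint: int = 31
    stim_duration_s: float = 0.5
    frame_interval_s: float = 0.1
    planted_amplitudes: float | Sequence[float] = 0.40
    rise_tau_s: float = 0.18
    decay_tau_s: float = 1.2
    bleach_tau_s: float = 200.0
    bleach_fast_frac: float = 0.05
    bleach_fast_tau_s: float = 0.5
    baseline_f: float = 150.0
    background: float = 3.0
    texture_frac: float = 0.05  # static tissue texture, fraction of baseline_f
    noise_sd: float = 1.5  # pixel noise, absolute intensity (1% of baseline)
    artifact_rois: tuple[int, ...] = ()
    artifact_step: float = 0.5
    direction: str = "P-to-A"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.stim_onset_timepoint <= self.n_timepoints:
            raise ValueError("stim_onset_timepoint must fall inside the movie")
        if np.any(np.asarray(self.amplitudes) < 0):
            raise ValueError("planted amplitudes must be non-negative")
        if any(not 0 <= r < self.n_rois for r in self.artifact_rois):
            raise ValueError("artifact_rois indices out of range")

    @property
    def amplitudes(self) -> np.ndarray:
        a = self.planted_amplitudes
        if np.isscalar(a):
            return np.full(self.n_rois, float(a))
        a = np.asarray(a, dtype=float)
        if len(a) != self.n_rois:
            raise ValueError("planted_amplitudes must have n_rois entries")
        return a


#: ROI grid spacing margin around the class ROI size, px
_ROI_MARGIN = 14


def _response_kernel(spec: MovieSpec) -> np.ndarray:
    """Unit-peak transient on the movie's sample grid (0 before onset)."""
    t = np.arange(spec.n_timepoints) * spec.frame_interval_s
    onset = (spec.stim_onset_timepoint - 1) * spec.frame_interval_s
    rel = t - onset
    kernel = np.zeros_like(rel)
    during = (rel >= 0) & (rel <= spec.stim_duration_s)
    after = rel > spec.stim_duration_s
    kernel[during] = 1.0 - np.exp(-rel[during] / spec.rise_tau_s)
    peak = 1.0 - np.exp(-spec.stim_duration_s / spec.rise_tau_s)
    kernel[after] = peak * np.exp(-(rel[after] - spec.stim_duration_s) / spec.decay_tau_s)
    m = kernel.max()
    return kernel / m if m > 0 else kernel


def generate_calcium_movie(spec: MovieSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a ``(t, z, y, x)`` float32 movie and its planted-amplitude table.

    The table has one row per ROI: center (y, x) in the frame, planted peak
    dF/F0, artifact flag and stimulus direction.  ROI centers are laid out
    on a grid sized from the signal class's ROI side length.
    """
    from ..calcium import CLASS_PARAMS

    if spec.signal_class not in CLASS_PARAMS:
        raise ValueError(f"unknown signal class {spec.signal_class!r}")
    roi_size = CLASS_PARAMS[spec.signal_class].roi_size
    rng = np.random.default_rng(spec.seed)

    pitch = roi_size + _ROI_MARGIN
    n_cols = min(4, spec.n_rois)
    n_rows = int(np.ceil(spec.n_rois / n_cols))
    shape = (n_rows * pitch + _ROI_MARGIN, n_cols * pitch + _ROI_MARGIN)
    # jittered, individually sized cells: a strictly periodic layout would
    # make translation registration ambiguous (every lattice displacement is
    # an equally good phase-correlation peak)
    centers = []
    for i in range(spec.n_rois):
        r, c = divmod(i, n_cols)
        centers.append(
            (_ROI_MARGIN // 2 + pitch * r + pitch // 2 + int(rng.integers(-3, 4)),
             _ROI_MARGIN // 2 + pitch * c + pitch // 2 + int(rng.integers(-3, 4)))
        )

    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    footprints = []
    roi_gain = []
    for cy, cx in centers:
        # flat-top (super-Gaussian) cell body filling most of the ROI, so
        # the square-ROI mean tracks the planted amplitude closely
        sigma = roi_size * 0.55 * rng.uniform(0.9, 1.1)
        r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / sigma**2
        footprints.append(np.exp(-0.5 * r2**2))
        roi_gain.append(rng.uniform(0.9, 1.1))

    # static tissue texture (bleaches with everything else); anchors the
    # registration the way out-of-focus structure does in real recordings
    from scipy import ndimage as ndi

    texture = ndi.gaussian_filter(rng.normal(0, 1, shape), 3)
    texture = spec.texture_frac * spec.baseline_f * (texture - texture.min()) / np.ptp(texture)

    kernel = _response_kernel(spec)
    t = np.arange(spec.n_timepoints) * spec.frame_interval_s
    # slow monoexponential bleaching plus a fast initial component (the
    # reason the first ~1 s of every recording is discarded)
    bleach = np.exp(-t / spec.bleach_tau_s) * (
        1.0 - spec.bleach_fast_frac * np.exp(-t / spec.bleach_fast_tau_s)
    )
    onset0 = spec.stim_onset_timepoint - 1
    amplitudes = spec.amplitudes

    movie = np.empty((spec.n_timepoints, spec.n_zslices) + shape, dtype=np.float32)
    for ti in range(spec.n_timepoints):
        frame = spec.background + texture.copy()
        for i, fp in enumerate(footprints):
            if i in spec.artifact_rois:
                gain = 1.0 + (spec.artifact_step if ti >= onset0 else 0.0)
            else:
                gain = 1.0 + amplitudes[i] * kernel[ti]
            frame = frame + spec.baseline_f * roi_gain[i] * fp * gain
        frame = frame * bleach[ti]
        for z in range(spec.n_zslices):
            plane = frame
            if spec.noise_sd > 0:
                plane = plane + rng.normal(0, spec.noise_sd, shape)
            movie[ti, z] = plane

    table = pd.DataFrame(
        {
            "roi": np.arange(spec.n_rois),
            "y": [c[0] for c in centers],
            "x": [c[1] for c in centers],
            "planted_amplitude": amplitudes,
            "artifact": [i in spec.artifact_rois for i in range(spec.n_rois)],
            "direction": spec.direction,
        }
    )
    return movie, table
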