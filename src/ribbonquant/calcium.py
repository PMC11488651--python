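"""GCaMP movie processing: projection, registration, dF/F0, classification.

The pipeline mirrors a standard evoked-response workflow for volumetric
time-lapse recordings of lateral-line hair cells and their afferents:
average z-projection, translation registration by phase correlation,
spatial Gaussian smoothing (3x3 kernel, sigma 2), removal of the first ten
timepoints (initial photobleaching), F0 from the next twenty retained
timepoints, and per-class response thresholds on dF/F0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

__all__ = [
    "CalciumParams",
    "CLASS_PARAMS",
    "RoiTrace",
    "NeuromastResponse",
    "preprocess_movie",
    "extract_dff",
    "classify_response",
    "flag_square_wave",
    "summarize_responses",
    "baseline_intensity",
]


@dataclass(frozen=True)
class CalciumParams:
    """Per-signal-class processing settings.

    Thresholds are fractions of F0 (0.10 means ">10% dF/F0").  The square
    ROI side length is class specific; the nominal "circular" ROI of the
    acquisition software is implemented as a square with an optional
    inscribed-disk mask.
    """

    signal_class: str
    roi_size: int
    gaussian_size: int = 3
    gaussian_sigma: float = 2.0
    n_trim: int = 10
    n_baseline: int = 20
    # class thresholds; unused entries are None
    stim_threshold: float | None = None  # within the stimulus window
    onset_threshold: float | None = None  # within 1 s of onset (presynaptic OR)
    post_stim_threshold: float | None = None  # 500 ms after stimulus (bundle AND)
    min_duration_s: float | None = None  # sustained-above requirement (postsynaptic)
    circular_roi: bool = False


CLASS_PARAMS: dict[str, CalciumParams] = {
    "presynaptic": CalciumParams(
        signal_class="presynaptic",
        roi_size=18,
        stim_threshold=0.10,
        onset_threshold=0.20,
    ),
    "hair_bundle": CalciumParams(
        signal_class="hair_bundle",
        roi_size=8,
        stim_threshold=0.15,
        post_stim_threshold=0.15,
    ),
    "postsynaptic": CalciumParams(
        signal_class="postsynaptic",
        roi_size=12,
        stim_threshold=0.05,
        min_duration_s=0.5,
    ),
}


def preprocess_movie(
    movie: np.ndarray,
    params: CalciumParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Project, register, smooth and trim a ``(t, z, y, x)`` movie.

    Every frame is registered (translation only, subpixel phase
    correlation) to the mean of the first five projected frames.  Returns
    ``(frames, shifts)`` where ``frames`` is ``(t - n_trim, y, x)`` and
    ``shifts`` logs the estimated (dy, dx) per original frame.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 4:
        raise ValueError(f"expected (t, z, y, x), got shape {movie.shape}")
    n_t = movie.shape[0]
    if n_t < params.n_trim + params.n_baseline + 1:
        raise ValueError(
            f"movie too short: {n_t} timepoints < trim {params.n_trim} "
            f"+ baseline {params.n_baseline} + 1"
        )
    proj = movie.mean(axis=1)

    reference = proj[:5].mean(axis=0)
    shifts = np.zeros((n_t, 2))
    registered = np.empty_like(proj)
    for t in range(n_t):
        shift, _, _ = phase_cross_correlation(
            reference, proj[t], upsample_factor=20, normalization=None
        )
        shifts[t] = shift
        registered[t] = ndi.shift(proj[t], shift, order=1, mode="nearest")

    # "size=3, sigma=2": a 3x3 Gaussian kernel, i.e. radius-1 truncation
    radius = (params.gaussian_size - 1) // 2
    smoothed = np.empty_like(registered)
    for t in range(n_t):
        smoothed[t] = ndi.gaussian_filter(registered[t], params.gaussian_sigma, radius=radius)

    return smoothed[params.n_trim :], shifts


@dataclass
class RoiTrace:
    """One ROI's intensity time series and derived dF/F0."""

    center: tuple[int, int]
    raw: np.ndarray
    f0: float
    dff: np.ndarray
    max_dff: float
    responsive: bool = False
    artifact: bool = False
    direction: str = ""  # A-to-P | P-to-A | ""


def _roi_mask(size: int, circular: bool) -> np.ndarray:
    if not circular:
        return np.ones((size, size), dtype=bool)
    yy, xx = np.mgrid[:size, :size]
    c = (size - 1) / 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= (size / 2) ** 2


def extract_dff(
    frames: np.ndarray,
    roi_center: tuple[int, int],
    params: CalciumParams,
) -> RoiTrace:
    """Mean-intensity trace of a square ROI and its dF/F0 normalization."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be (t, y, x); run preprocess_movie first")
    if frames.shape[0] < params.n_baseline:
        raise ValueError("trace shorter than the baseline window")
    half = params.roi_size // 2
    r, c = roi_center
    r0, r1 = r - half, r - half + params.roi_size
    c0, c1 = c - half, c - half + params.roi_size
    if r0 < 0 or c0 < 0 or r1 > frames.shape[1] or c1 > frames.shape[2]:
        raise ValueError(f"ROI at {roi_center} extends outside the frame")
    mask = _roi_mask(params.roi_size, params.circular_roi)
    raw = frames[:, r0:r1, c0:c1][:, mask].mean(axis=1)
    f0 = float(raw[: params.n_baseline].mean())
    if f0 <= 0:
        raise ValueError("non-positive F0; check ROI placement and baseline window")
    dff = (raw - f0) / f0
    return RoiTrace(
        center=(r, c),
        raw=raw,
        f0=f0,
        dff=dff,
        max_dff=float(dff.max()),
    )


def _window(onset: int, t_from_s: float, t_to_s: float, dt_s: float, n: int) -> slice:
    """Frame slice covering [onset + t_from, onset + t_to] seconds, inclusive."""
    lo = onset + int(np.ceil(t_from_s / dt_s - 1e-9))
    hi = onset + int(np.floor(t_to_s / dt_s + 1e-9))
    return slice(max(lo, 0), min(hi + 1, n))


def classify_response(
    trace: RoiTrace,
    params: CalciumParams,
    stim_onset: int,
    stim_duration_s: float = 0.5,
    frame_interval_s: float = 0.1,
    *,
    responds_both_directions: bool = False,
) -> bool:
    """Apply the class-specific responsiveness rule to a dF/F0 trace.

    ``stim_onset`` is the frame index of stimulus onset within the trimmed
    trace.  Presynaptic: >10% dF/F0 during the 500 ms stimulus, or >20%
    within 1 s of onset (the onset window includes the stimulus itself).
    Hair bundle: >15% during the stimulus and >15% in the 500 ms after;
    bundles responding to both stimulus directions are excluded.
    Postsynaptic: >5% sustained continuously for at least 500 ms.
    Artifact-flagged traces are never responsive.
    """
    if params.signal_class not in CLASS_PARAMS:
        raise ValueError(f"unknown signal class {params.signal_class!r}")
    if trace.artifact:
        return False
    dff = trace.dff
    n = len(dff)
    dt = frame_interval_s

    if params.signal_class == "presynaptic":
        stim = dff[_window(stim_onset, 0.0, stim_duration_s, dt, n)]
        onset1s = dff[_window(stim_onset, 0.0, 1.0, dt, n)]
        return bool(
            (stim.size and stim.max() > params.stim_threshold)
            or (onset1s.size and onset1s.max() > params.onset_threshold)
        )
    if params.signal_class == "hair_bundle":
        if responds_both_directions:
            return False
        stim = dff[_window(stim_onset, 0.0, stim_duration_s, dt, n)]
        # the post-stimulus window starts strictly after the stimulus ends
        after = dff[_window(stim_onset, stim_duration_s + dt, stim_duration_s + 0.5, dt, n)]
        return bool(
            stim.size
            and after.size
            and stim.max() > params.stim_threshold
            and after.max() > params.post_stim_threshold
        )
    # postsynaptic: continuously above threshold for >= min_duration
    min_frames = int(np.ceil(params.min_duration_s / dt - 1e-9))
    above = dff > params.stim_threshold
    run = 0
    for flag in above:
        run = run + 1 if flag else 0
        if run >= min_frames:
            return True
    return False


def flag_square_wave(
    dff: np.ndarray,
    jump_low: float = 0.2,
    jump_high: float = 0.8,
    plateau_cv: float = 0.05,
    min_plateau_frac: float = 0.5,
) -> bool:
    """Movement-artifact heuristic: an instantaneous, flat, sustained step.

    Flags traces whose excursion jumps from below ``jump_low`` to above
    ``jump_high`` of their own range within one frame and then *stays* high:
    at least ``min_plateau_frac`` of the post-jump samples remain above
    ``jump_high`` with a coefficient of variation below ``plateau_cv``.
    Physiological transients rise over several frames and decay away from
    the peak, so they fail the jump or the persistence condition; slow
    photobleaching across a genuine step is absorbed by the CV allowance.
    """
    dff = np.asarray(dff, dtype=float)
    rng = np.ptp(dff)
    if rng == 0 or len(dff) < 4:
        return False
    norm = (dff - dff.min()) / rng
    jumps = np.flatnonzero((norm[:-1] < jump_low) & (norm[1:] > jump_high))
    for i in jumps:
        tail = norm[i + 1 :]
        plateau = tail[tail > jump_high]
        if len(plateau) < 3 or len(plateau) < min_plateau_frac * len(tail):
            continue
        mean = plateau.mean()
        if mean > 0 and plateau.std() / mean < plateau_cv:
            return True
    return False


@dataclass
class NeuromastResponse:
    """Organ-level summary over responsive, artifact-free ROIs."""

    mean_trace: np.ndarray | None
    max_dff: float  # NaN when no ROI is responsive
    n_active: int
    n_active_by_direction: dict[str, int] = field(default_factory=dict)
    baseline: float = float("nan")


def summarize_responses(traces: list[RoiTrace]) -> NeuromastResponse:
    """Average the responsive, non-artifact traces and take the peak.

    The organ's response magnitude is the maximum of the *mean* trace, not
    the mean of per-ROI maxima.  Active-site counts are tallied per
    stimulus direction label where provided.
    """
    if not traces:
        raise ValueError("need at least one trace")
    active = [t for t in traces if t.responsive and not t.artifact]
    by_dir: dict[str, int] = {}
    for t in active:
        if t.direction:
            by_dir[t.direction] = by_dir.get(t.direction, 0) + 1
    if not active:
        return NeuromastResponse(
            mean_trace=None, max_dff=float("nan"), n_active=0, n_active_by_direction=by_dir
        )
    mean_trace = np.mean([t.dff for t in active], axis=0)
    return NeuromastResponse(
        mean_trace=mean_trace,
        max_dff=float(mean_trace.max()),
        n_active=len(active),
        n_active_by_direction=by_dir,
    )


def baseline_intensity(
    frames: np.ndarray,
    prestim: slice,
) -> tuple[float, bool]:
    """Mean Otsu-foreground intensity over the prestimulus window.

    Each frame in ``prestim`` is autothresholded (Otsu) and the mean
    foreground intensity taken; the per-frame means are then averaged.
    Returns ``(value, degenerate)`` where ``degenerate`` marks windows with
    at least one contrast-free frame.
    """
    from skimage.filters import threshold_otsu

    frames = np.asarray(frames, dtype=float)[prestim]
    if frames.size == 0:
        raise ValueError("empty prestimulus window")
    means = []
    degenerate = False
    for frame in frames:
        if np.ptp(frame) == 0:
            degenerate = True
            means.append(float(frame.mean()))
            continue
        thr = threshold_otsu(frame)
        fg = frame > thr
        means.append(float(frame[fg].mean()) if fg.any() else float(frame.mean()))
    return float(np.mean(means)), degenerate
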