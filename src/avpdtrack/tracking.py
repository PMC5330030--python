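"""Template tracking of annulus landmarks by normalized cross-correlation.

Each landmark is tracked twice through the cycle — forward from end
diastole to the last timeframe and backward through the wrap — by
matching a square template (region of interest, ROI) around the last
tracked position against a larger square search window (region of
search, ROS) centered on the *predicted* position in the next
timeframe.  The prediction comes from the statistical curve prior, so
the search window always sits where a physiological AV-plane would be.
The two displacement curves are merged as a convex, linearly weighted
sum and finally smoothed by projecting onto the prior's leading
principal components.

The correlation surface is the classic normalized cross-correlation

    gamma(u, v) = sum_xy [S(x,y) - Sbar_uv] [I(x-u, y-v) - Ibar]
                  / sqrt( sum_xy [S(x,y) - Sbar_uv]^2
                          * sum_xy [I(x-u, y-v) - Ibar]^2 )

with the ROS-window mean ``Sbar_uv`` recomputed under every placement
(u, v) of the template and ``Ibar`` the template mean; gamma lies in
[-1, 1] and is invariant to affine intensity changes of either patch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from avpdtrack.geometry import AVPlane, Landmark, signed_displacement
from avpdtrack.io import CineSeries
from avpdtrack.prior import CurvePriorModel, DisplacementCurve, resample_curve

#: fallback template/search sizes (mm) when no optimized table is supplied;
#: wide enough to cover +-2 SD of per-frame AVPD steps at 30 frames/cycle
DEFAULT_ROI_MM = 13.0
DEFAULT_ROS_MM = 27.0


@dataclass(frozen=True)
class TrackingParams:
    """Square template (ROI) and search (ROS) side lengths for one landmark."""

    roi_size_mm: float = DEFAULT_ROI_MM
    ros_size_mm: float = DEFAULT_ROS_MM
    subpixel: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.roi_size_mm < self.ros_size_mm:
            raise ValueError("need ros_size_mm > roi_size_mm > 0")


@dataclass
class TrackResult:
    """Per-frame tracked positions and signed displacement of one landmark."""

    positions: np.ndarray  # (n_frames, 2) pixel (row, col)
    displacement: np.ndarray  # (n_frames,) mm, 0 at the ED frame
    peak_gamma: np.ndarray  # (n_frames,) best correlation per frame (1 at ED)
    direction: Literal["forward", "backward", "merged"]
    ed_frame: int = 0


def patch_size_px(size_mm: float, spacing_mm: float) -> int:
    """Convert a patch side length in mm to the nearest odd pixel count (>= 3)."""
    if size_mm <= 0 or spacing_mm <= 0:
        raise ValueError("size and spacing must be positive")
    n_exact = size_mm / spacing_mm
    n = int(np.floor((n_exact - 1.0) / 2.0 + 0.5)) * 2 + 1  # nearest odd, ties up
    if n < 3:
        raise ValueError(f"{size_mm} mm at {spacing_mm} mm/px gives a patch below 3 px")
    return n


def extract_patch(
    image: np.ndarray,
    center: tuple[float, float],
    size_px: tuple[int, int],
    clip: bool = False,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Extract a square (or clipped rectangular) patch centered on ``center``.

    Returns ``(patch, top_left)``.  With ``clip=False`` (template
    extraction) a patch that would leave the image raises; with
    ``clip=True`` (search-window extraction) the patch is restricted to
    the image bounds.
    """
    h, w = size_px
    if h % 2 == 0 or w % 2 == 0:
        raise ValueError("patch sizes must be odd")
    r = int(round(center[0]))
    c = int(round(center[1]))
    r0, r1 = r - h // 2, r + h // 2 + 1
    c0, c1 = c - w // 2, c + w // 2 + 1
    if clip:
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, image.shape[0]), min(c1, image.shape[1])
        if r1 <= r0 or c1 <= c0:
            raise ValueError("search window lies entirely outside the image")
    elif r0 < 0 or c0 < 0 or r1 > image.shape[0] or c1 > image.shape[1]:
        raise ValueError(
            f"template around ({r}, {c}) with size {size_px} extends outside the image"
        )
    return image[r0:r1, c0:c1], (r0, c0)


def ncc_map(
    roi: np.ndarray, ros: np.ndarray, return_degenerate: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation of template ``roi`` over search window ``ros``.

    Evaluates gamma(u, v) for every full placement of the template
    inside the search window; the returned map has shape
    ``(Hs - Hr + 1, Ws - Wr + 1)`` and entries in [-1, 1].  Placements
    where either the template or the local window has zero variance are
    undefined; they are reported as 0 (and flagged when
    ``return_degenerate`` is set).
    """
    roi = np.asarray(roi, dtype=float)
    ros = np.asarray(ros, dtype=float)
    if roi.ndim != 2 or ros.ndim != 2:
        raise ValueError("patches must be 2-D")
    if ros.shape[0] < roi.shape[0] or ros.shape[1] < roi.shape[1]:
        raise ValueError("search window must be at least as large as the template")

    n = roi.size
    roi_c = roi - roi.mean()
    roi_ss = float(np.sum(roi_c**2))

    windows = sliding_window_view(ros, roi.shape)  # (U, V, h, w)
    win_sum = windows.sum(axis=(2, 3))
    # numerator: sum (S - Sbar)(I - Ibar) = sum S * (I - Ibar), since sum(I - Ibar) = 0
    num = np.einsum("uvxy,xy->uv", windows, roi_c)
    win_ss = np.einsum("uvxy,uvxy->uv", windows, windows) - win_sum**2 / n

    denom_sq = np.clip(win_ss, 0.0, None) * roi_ss
    degenerate = denom_sq <= 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(degenerate, 0.0, num / np.sqrt(np.where(degenerate, 1.0, denom_sq)))
    gamma = np.clip(gamma, -1.0, 1.0)
    if return_degenerate:
        return gamma, degenerate
    return gamma


def best_match(
    gamma: np.ndarray,
    prediction_index: tuple[int, int] | None = None,
    degenerate: np.ndarray | None = None,
) -> tuple[int, int]:
    """Placement index of the correlation maximum.

    Exact ties are broken by the smallest Euclidean distance to the
    prediction-centered placement (the map center by default), then by
    row-major order.  If every placement is degenerate the prediction
    placement is returned with a warning.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.size == 0:
        raise ValueError("empty correlation map")
    if prediction_index is None:
        prediction_index = (gamma.shape[0] // 2, gamma.shape[1] // 2)
    if degenerate is not None and bool(np.all(degenerate)):
        warnings.warn("all correlation placements degenerate; falling back to prediction",
                      stacklevel=2)
        return prediction_index
    peak = gamma.max()
    cand = np.argwhere(gamma == peak)
    d2 = ((cand - np.asarray(prediction_index)) ** 2).sum(axis=1)
    best = cand[np.lexsort((cand[:, 1], cand[:, 0], d2))][0]
    return int(best[0]), int(best[1])


def _parabolic_offset(g_m: float, g_0: float, g_p: float) -> float:
    denom = g_m - 2.0 * g_0 + g_p
    if denom >= 0.0:  # not a proper maximum
        return 0.0
    return float(np.clip(0.5 * (g_m - g_p) / denom, -0.5, 0.5))


def track_direction(
    series: CineSeries,
    ed_point: tuple[float, float],
    predictions: np.ndarray,
    params: TrackingParams,
    plane: AVPlane,
    direction: Literal["forward", "backward"],
    ed_frame: int = 0,
) -> TrackResult:
    """Track one landmark through the whole cycle in one direction.

    Starting at the end-diastolic point, each step extracts the template
    around the current position and searches the window centered on the
    next frame's predicted position; frames are traversed cyclically
    (retrospective gating makes the cycle periodic), visiting
    ED+1 ... ED+T-1 forward or ED-1 ... ED-T+1 backward.
    """
    frames = series.frames
    T = series.n_frames
    if predictions.shape != (T, 2):
        raise ValueError("predictions must cover every frame")
    spacing = series.pixel_spacing
    roi_px = (patch_size_px(params.roi_size_mm, spacing[0]),
              patch_size_px(params.roi_size_mm, spacing[1]))
    ros_px = (patch_size_px(params.ros_size_mm, spacing[0]),
              patch_size_px(params.ros_size_mm, spacing[1]))
    if ros_px[0] <= roi_px[0] or ros_px[1] <= roi_px[1]:
        raise ValueError("search window must be strictly larger than the template")

    step = 1 if direction == "forward" else -1
    positions = np.zeros((T, 2))
    peak_gamma = np.zeros(T)
    positions[ed_frame] = ed_point
    peak_gamma[ed_frame] = 1.0

    cur = np.asarray(ed_point, dtype=float)
    cur_frame = ed_frame
    for _ in range(T - 1):
        nxt_frame = (cur_frame + step) % T
        roi, _ = extract_patch(frames[cur_frame], tuple(cur), roi_px, clip=False)
        ros, ros_tl = extract_patch(frames[nxt_frame], tuple(predictions[nxt_frame]),
                                    ros_px, clip=True)
        if ros.shape[0] < roi.shape[0] or ros.shape[1] < roi.shape[1]:
            raise ValueError("search window clipped below the template size at the image border")
        gamma, degenerate = ncc_map(roi, ros, return_degenerate=True)
        pred_center = (int(round(predictions[nxt_frame][0])) - ros_tl[0] - roi_px[0] // 2,
                       int(round(predictions[nxt_frame][1])) - ros_tl[1] - roi_px[1] // 2)
        pred_center = (int(np.clip(pred_center[0], 0, gamma.shape[0] - 1)),
                       int(np.clip(pred_center[1], 0, gamma.shape[1] - 1)))
        u, v = best_match(gamma, pred_center, degenerate)
        pos = np.array([ros_tl[0] + u + roi_px[0] // 2, ros_tl[1] + v + roi_px[1] // 2],
                       dtype=float)
        if params.subpixel:
            if 0 < u < gamma.shape[0] - 1:
                pos[0] += _parabolic_offset(gamma[u - 1, v], gamma[u, v], gamma[u + 1, v])
            if 0 < v < gamma.shape[1] - 1:
                pos[1] += _parabolic_offset(gamma[u, v - 1], gamma[u, v], gamma[u, v + 1])
        positions[nxt_frame] = pos
        peak_gamma[nxt_frame] = gamma[u, v]
        cur, cur_frame = pos, nxt_frame

    displacement = np.array(
        [signed_displacement(positions[t], positions[ed_frame], plane) for t in range(T)]
    )
    displacement[ed_frame] = 0.0
    return TrackResult(positions, displacement, peak_gamma, direction, ed_frame)


def merge_weights(n_frames: int) -> np.ndarray:
    """Forward-track weights in cycle order from end diastole: 1 linearly down to 0."""
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    return np.linspace(1.0, 0.0, n_frames)


def merge_tracks(fwd: TrackResult, bwd: TrackResult) -> np.ndarray:
    """Convex merge of the forward and backward displacement curves.

    Each run is weighted linearly from 1 at its first tracked frame to 0
    at its last, which makes the two weights complementary at every
    cycle frame: the forward weight falls from 1 at end diastole to 0 at
    the last frame of the cycle and the backward weight rises
    accordingly, so the merged curve lies pointwise between the two.
    """
    if fwd.displacement.shape != bwd.displacement.shape:
        raise ValueError("forward/backward curves differ in length")
    if fwd.ed_frame != bwd.ed_frame:
        raise ValueError("forward/backward tracks disagree on the end-diastolic frame")
    T = fwd.displacement.size
    w = merge_weights(T)
    order = (fwd.ed_frame + np.arange(T)) % T
    merged = np.empty(T)
    merged[order] = w * fwd.displacement[order] + (1.0 - w) * bwd.displacement[order]
    return merged


def track_landmark(
    series: CineSeries,
    landmark: Landmark,
    plane: AVPlane,
    model: CurvePriorModel,
    params: TrackingParams | None = None,
    reconstruct: bool = True,
) -> DisplacementCurve:
    """Full per-landmark pipeline: predict, track both ways, merge, smooth.

    Returns the landmark's displacement curve at the series' native
    frame count, anchored to 0 at the end-diastolic frame.  With
    ``reconstruct`` the merged curve is resampled to the prior's
    30-frame grid, projected onto the leading principal components
    (physiological smoothing) and resampled back.
    """
    params = params or TrackingParams()
    prior = model[landmark.key]
    predictions = prior.prediction_positions(
        plane, landmark.position, series.n_frames, series.cycle_duration
    )
    fwd = track_direction(series, landmark.position, predictions, params, plane,
                          "forward", landmark.frame)
    bwd = track_direction(series, landmark.position, predictions, params, plane,
                          "backward", landmark.frame)
    merged = merge_tracks(fwd, bwd)
    values = merged
    if reconstruct:
        on_grid = (merged if series.n_frames == prior.n_frames
                   else resample_curve(merged, prior.n_frames))
        recon = prior.reconstruct(on_grid)
        values = (recon if series.n_frames == prior.n_frames
                  else resample_curve(recon, series.n_frames))
        values = values - values[landmark.frame]
    return DisplacementCurve(values=values, cycle_duration=series.cycle_duration,
                             label=landmark.label, view=landmark.view)


def track_all(
    series_by_view: Mapping[str, CineSeries],
    landmarks: list[Landmark],
    planes: Mapping[str, AVPlane],
    model: CurvePriorModel,
    params: Mapping[str, TrackingParams] | None = None,
) -> dict[str, DisplacementCurve]:
    """Track every provided landmark; returns ``{view/label: DisplacementCurve}``."""
    out: dict[str, DisplacementCurve] = {}
    for lm in landmarks:
        p = (params or {}).get(lm.key) if params else None
        out[lm.key] = track_landmark(series_by_view[lm.view], lm, planes[lm.view], model, p)
    return out
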