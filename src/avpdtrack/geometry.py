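"""AV-plane definition and perpendicular displacement projection.

Each long-axis view gets its own atrioventricular (AV) plane: a line
through the end-diastolic annulus landmarks plus a unit vector
perpendicular to that line pointing toward the apex.  All displacement
throughout the cycle is measured as the perpendicular excursion of a
tracked point relative to this end-diastolic plane, with motion toward
the apex counted as *negative* millimetres (so a normal left-ventricular
AVPD curve dips to roughly -13 mm at end systole).

Coordinates are (row, col), 0-based and pixel-centered.  Geometry is
done in millimetre space so that anisotropic pixel spacing cannot skew
the fitted line or the projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: anatomical labels expected per view (2 + 3 + 3 = 8 landmarks)
VIEW_LABELS: dict[str, frozenset[str]] = {
    "2ch": frozenset({"lv_a", "lv_b"}),
    "3ch": frozenset({"lv_lateral", "septum", "rv_outflow"}),
    "4ch": frozenset({"lv_lateral", "septum", "rv_lateral"}),
}

#: the six landmarks entering the left-ventricular AVPD mean
LV_LANDMARKS: tuple[tuple[str, str], ...] = (
    ("2ch", "lv_a"),
    ("2ch", "lv_b"),
    ("3ch", "lv_lateral"),
    ("3ch", "septum"),
    ("4ch", "lv_lateral"),
    ("4ch", "septum"),
)

#: landmarks entering the right-ventricular AVPD combination
RV_LANDMARKS: tuple[tuple[str, str], ...] = (
    ("4ch", "rv_lateral"),
    ("3ch", "rv_outflow"),
    ("3ch", "septum"),
    ("4ch", "septum"),
)

ALL_LANDMARKS: tuple[tuple[str, str], ...] = (
    ("2ch", "lv_a"),
    ("2ch", "lv_b"),
    ("3ch", "lv_lateral"),
    ("3ch", "septum"),
    ("3ch", "rv_outflow"),
    ("4ch", "lv_lateral"),
    ("4ch", "septum"),
    ("4ch", "rv_lateral"),
)


def landmark_key(view: str, label: str) -> str:
    """Canonical string key ``view/label`` for one of the 8 landmarks."""
    return f"{view}/{label}"


@dataclass(frozen=True)
class Landmark:
    """One anatomically labelled annulus point.

    Parameters
    ----------
    view : {"2ch", "3ch", "4ch"}
    label : str
        Anatomical role; must belong to the view's label set
        (see :data:`VIEW_LABELS`).
    position : (float, float)
        (row, col) in pixel units.
    frame : int
        Timeframe index; end-diastolic index for user input points.
    """

    view: str
    label: str
    position: tuple[float, float]
    frame: int = 0

    def __post_init__(self) -> None:
        if self.view not in VIEW_LABELS:
            raise ValueError(f"unknown view {self.view!r}; expected one of {sorted(VIEW_LABELS)}")
        if self.label not in VIEW_LABELS[self.view]:
            raise ValueError(
                f"label {self.label!r} not valid for view {self.view!r}; "
                f"expected one of {sorted(VIEW_LABELS[self.view])}"
            )

    @property
    def key(self) -> str:
        return landmark_key(self.view, self.label)


@dataclass(frozen=True)
class AVPlane:
    """AV-plane of one long-axis view: a line plus the apex direction.

    ``anchor`` is a point on the line in pixel coordinates;
    ``line_direction`` and ``apex_direction`` are orthonormal unit
    vectors *in millimetre space*, with ``apex_direction`` pointing from
    the plane toward the apex.
    """

    view: str
    anchor: tuple[float, float]
    line_direction: tuple[float, float]
    apex_direction: tuple[float, float]
    pixel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.line_direction, dtype=float)
        a = np.asarray(self.apex_direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9 or abs(np.linalg.norm(a) - 1.0) > 1e-9:
            raise ValueError("line_direction and apex_direction must be unit vectors")
        if abs(float(d @ a)) > 1e-9:
            raise ValueError("apex_direction must be perpendicular to line_direction")


def _to_mm(points: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    return np.asarray(points, dtype=float) * np.asarray(spacing, dtype=float)


def fit_av_plane(
    points: Iterable[Landmark],
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
    apex_hint: tuple[float, float] | None = None,
    image_shape: tuple[int, int] | None = None,
) -> AVPlane:
    """Fit the AV-plane line of one view from its end-diastolic landmarks.

    The line is fitted per view: through the two points (2-chamber),
    as the total-least-squares line minimizing perpendicular residuals
    over the three points (4-chamber), or through the LV lateral point
    and the septum/RV-outflow midpoint (3-chamber).  The apex side of
    the perpendicular is resolved by ``apex_hint`` (a pixel point on the
    apex side) or, failing that, by the image centroid given
    ``image_shape`` — in standard long-axis acquisitions the ventricles
    occupy the image center below the annulus.

    Parameters
    ----------
    points : iterable of Landmark
        All landmarks of one view (2 or 3 points).
    pixel_spacing : (float, float)
        mm per pixel along (row, col).  The fit is carried out in mm
        space so anisotropic spacing cannot bias the line.
    apex_hint : (row, col), optional
        Any pixel point on the apex side of the plane.
    image_shape : (n_rows, n_cols), optional
        Used to orient the apex direction toward the image centroid when
        no hint is given.

    Returns
    -------
    AVPlane
    """
    pts = list(points)
    if not pts:
        raise ValueError("no landmarks given")
    view = pts[0].view
    if any(p.view != view for p in pts):
        raise ValueError("all landmarks must share one view")
    labels = {p.label for p in pts}
    if labels != VIEW_LABELS[view]:
        missing = VIEW_LABELS[view] - labels
        raise ValueError(f"view {view!r} landmark set incomplete or wrong; missing {sorted(missing)}")
    by_label = {p.label: np.asarray(p.position, dtype=float) for p in pts}
    spacing = np.asarray(pixel_spacing, dtype=float)

    if view == "2ch":
        p0, p1 = by_label["lv_a"], by_label["lv_b"]
        d_mm = (p1 - p0) * spacing
        anchor = p0
    elif view == "3ch":
        mid = 0.5 * (by_label["septum"] + by_label["rv_outflow"])
        p0 = by_label["lv_lateral"]
        d_mm = (mid - p0) * spacing
        anchor = p0
    else:  # 4ch: total least squares on the 3 points
        arr = np.array([by_label[lb] for lb in ("lv_lateral", "septum", "rv_lateral")])
        arr_mm = _to_mm(arr, spacing)
        centroid_mm = arr_mm.mean(axis=0)
        # first right-singular vector = direction minimizing orthogonal residuals
        _, _, vt = np.linalg.svd(arr_mm - centroid_mm)
        d_mm = vt[0]
        anchor = centroid_mm / spacing

    nrm = float(np.linalg.norm(d_mm))
    if nrm < 1e-12:
        raise ValueError("degenerate AV-plane: landmarks coincide")
    line_dir = d_mm / nrm
    perp = np.array([-line_dir[1], line_dir[0]])

    anchor_mm = np.asarray(anchor, dtype=float) * spacing
    if apex_hint is not None:
        target_mm = np.asarray(apex_hint, dtype=float) * spacing
    elif image_shape is not None:
        target_mm = (np.asarray(image_shape, dtype=float) - 1.0) / 2.0 * spacing
    else:
        raise ValueError("need apex_hint or image_shape to orient the apex direction")
    side = float((target_mm - anchor_mm) @ perp)
    if abs(side) < 1e-12:
        raise ValueError("apex reference point lies on the AV-plane; cannot orient")
    apex_dir = perp if side > 0 else -perp

    return AVPlane(
        view=view,
        anchor=(float(anchor[0]), float(anchor[1])),
        line_direction=(float(line_dir[0]), float(line_dir[1])),
        apex_direction=(float(apex_dir[0]), float(apex_dir[1])),
        pixel_spacing=(float(spacing[0]), float(spacing[1])),
    )


def signed_displacement(
    p_t: Sequence[float], p_0: Sequence[float], plane: AVPlane
) -> float:
    """Perpendicular displacement of ``p_t`` relative to ``p_0`` in mm.

    Only motion perpendicular to the end-diastolic AV-plane counts;
    the component along the plane is projected away.  Motion toward the
    apex yields a *negative* value, so a larger systolic excursion is a
    more negative AVPD.
    """
    delta_mm = (np.asarray(p_t, dtype=float) - np.asarray(p_0, dtype=float)) * np.asarray(
        plane.pixel_spacing, dtype=float
    )
    return -float(delta_mm @ np.asarray(plane.apex_direction, dtype=float))
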