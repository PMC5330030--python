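"""Statistical curve-shape prior for AVPD tracking.

The prior is a per-landmark principal-component model of AVPD curve
shape.  Training curves (signed perpendicular displacement in mm, one
cardiac cycle each) are interpolated to a common 30-timeframe grid,
normalized by their amplitude, and stacked into an ``n_subjects x 30``
matrix; eigen-decomposition of its covariance yields the shape basis.
Five components suffice to capture essentially all (>= 99%) of the
variance of physiological AVPD curves, so tracked curves are smoothed
by projecting onto the five leading eigenvectors ("curve shape
reconstruction"), and the reconstructed population mean — rescaled by
the mean training amplitude — serves as the position *prediction curve*
that tells the tracker where to search in each timeframe.

:class:`CurvePrior` is the single-landmark model, a scikit-learn style
transformer (``fit`` on an ``(n_subjects, n_frames)`` matrix of mm
curves, ``transform`` = shape reconstruction).  :class:`CurvePriorModel`
bundles one fitted prior per landmark and (de)serializes to JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from avpdtrack.geometry import AVPlane

N_MODEL_FRAMES = 30  #: common timeframe grid all training curves are resampled to

MODEL_FORMAT_VERSION = 1


@dataclass
class DisplacementCurve:
    """Signed per-frame perpendicular displacement of one landmark.

    ``values[0]`` is 0 by construction (end-diastolic reference frame);
    values are mm, negative toward the apex.
    """

    values: np.ndarray
    cycle_duration: float
    label: str = ""
    view: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("curve values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.size


def resample_curve(values: np.ndarray, n_target: int) -> np.ndarray:
    """Linearly interpolate a per-frame curve to ``n_target`` frames.

    Frames are mapped to normalized cycle time ``t_i = i/(n-1)`` so the
    end-diastolic start and the final frame are preserved exactly.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D curve with at least 2 frames")
    if n_target < 2:
        raise ValueError("n_target must be >= 2")
    t_src = np.linspace(0.0, 1.0, values.size)
    t_dst = np.linspace(0.0, 1.0, n_target)
    return np.interp(t_dst, t_src, values)


def normalize_amplitude(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale a curve to unit amplitude; returns ``(unit_values, amplitude)``.

    Amplitude is the maximum absolute displacement over the cycle.  An
    all-zero curve is degenerate: it is returned unchanged with
    amplitude 0 and a warning.
    """
    values = np.asarray(values, dtype=float)
    amplitude = float(np.max(np.abs(values))) if values.size else 0.0
    if amplitude == 0.0:
        warnings.warn("zero-amplitude curve: normalization is degenerate", stacklevel=2)
        return values.copy(), 0.0
    return values / amplitude, amplitude


class CurvePrior(BaseEstimator, TransformerMixin):
    """PCA shape model of one landmark's AVPD curve.

    Parameters
    ----------
    n_components : int, default 5
        Number of leading eigenvectors retained for reconstruction and
        sampling.  Five capture >= 99% of physiological curve variance.
    n_frames : int, default 30
        Common timeframe grid; training curves of other lengths are
        resampled to it.

    Attributes (after :meth:`fit`)
    ------------------------------
    mean_curve_ : (n_frames,) ndarray
        Column mean of the amplitude-normalized training matrix.
    eigenvectors_ : (n_frames, n_frames) ndarray
        Orthonormal columns ordered by descending eigenvalue.
    eigenvalues_ : (n_frames,) ndarray
        Non-negative, descending.
    weight_sd_ : (n_components,) ndarray
        SD of the training-curve weights on each retained component.
    amplitude_mean_, amplitude_sd_ : float
        Training amplitude statistics in mm.
    prediction_curve_ : (n_frames,) ndarray
        Mean curve reconstructed through the retained components and
        rescaled by ``amplitude_mean_`` — the tracker's per-frame
        position prediction, in mm.
    """

    def __init__(self, n_components: int = 5, n_frames: int = N_MODEL_FRAMES):
        self.n_components = n_components
        self.n_frames = n_frames

    def fit(self, X: np.ndarray, y: None = None) -> "CurvePrior":
        """Fit the shape model on an ``(n_subjects, n_frames)`` matrix of mm curves."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("training input must be a 2-D (n_subjects, n_frames) matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("training matrix contains non-finite entries")
        if X.shape[0] < self.n_components + 1:
            raise ValueError(
                f"need at least {self.n_components + 1} training curves, got {X.shape[0]}"
            )
        if X.shape[1] != self.n_frames:
            X = np.vstack([resample_curve(row, self.n_frames) for row in X])

        amplitudes = np.max(np.abs(X), axis=1)
        if np.any(amplitudes == 0):
            raise ValueError("training matrix contains an all-zero curve")
        normed = X / amplitudes[:, None]

        self.mean_curve_ = normed.mean(axis=0)
        centered = normed - self.mean_curve_
        cov = centered.T @ centered / (normed.shape[0] - 1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        self.eigenvalues_ = np.clip(eigvals[order], 0.0, None)
        self.eigenvectors_ = eigvecs[:, order]

        weights = centered @ self.eigenvectors_[:, : self.n_components]
        self.weight_sd_ = weights.std(axis=0, ddof=1)
        self.amplitude_mean_ = float(amplitudes.mean())
        self.amplitude_sd_ = float(amplitudes.std(ddof=1))

        # The centered mean is the zero vector, so projecting the mean through
        # any number of components reproduces it; reconstruct explicitly anyway
        # to keep the definition operational.
        mean_recon = self._reconstruct_normalized(self.mean_curve_, self.n_components)
        pred = mean_recon * self.amplitude_mean_
        self.prediction_curve_ = pred - pred[0]
        return self

    # -- internals ---------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "eigenvectors_"):
            raise RuntimeError("CurvePrior is not fitted")

    def _reconstruct_normalized(self, unit_values: np.ndarray, k: int) -> np.ndarray:
        V = self.eigenvectors_[:, :k]
        centered = unit_values - self.mean_curve_
        return self.mean_curve_ + V @ (V.T @ centered)

    # -- public API --------------------------------------------------------

    def variance_fraction(self, k: int) -> float:
        """Fraction of the eigenvalue sum carried by the ``k`` largest eigenvalues."""
        self._check_fitted()
        if not 1 <= k <= self.eigenvalues_.size:
            raise ValueError(f"k must be in [1, {self.eigenvalues_.size}]")
        total = float(self.eigenvalues_.sum())
        if total == 0.0:
            return 1.0
        return float(self.eigenvalues_[:k].sum()) / total

    def reconstruct(self, values: np.ndarray, k: int | None = None) -> np.ndarray:
        """Physiological smoothing: project a mm curve onto the leading components.

        The curve is normalized by its own amplitude, mean-subtracted,
        projected onto the first ``k`` eigenvectors, back-projected,
        re-meaned and rescaled by the same amplitude; frame 0 is then
        re-pinned to exactly 0 (the end-diastolic reference).
        """
        self._check_fitted()
        k = self.n_components if k is None else k
        values = np.asarray(values, dtype=float)
        if values.size != self.n_frames:
            raise ValueError(f"expected a {self.n_frames}-frame curve; resample first")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            unit, amplitude = normalize_amplitude(values)
        if amplitude == 0.0:
            return np.zeros_like(values)
        recon = self._reconstruct_normalized(unit, k) * amplitude
        return recon - recon[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Reconstruct each row of an ``(n, n_frames)`` matrix (sklearn API)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([self.reconstruct(row) for row in X])

    def sample_curves(self, n: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
        """Draw ``n`` plausible mm curves from the shape span.

        Component weights are drawn uniformly within +-2 SD of the
        prediction curve's weights (which are zero: the prediction curve
        is the reconstructed mean), the curves reconstructed through the
        retained eigenvectors and rescaled by the mean amplitude.
        """
        self._check_fitted()
        rng = np.random.default_rng(rng)
        if n == 0:
            return np.empty((0, self.n_frames))
        w = rng.uniform(-2.0 * self.weight_sd_, 2.0 * self.weight_sd_, size=(n, self.n_components))
        normed = self.mean_curve_ + w @ self.eigenvectors_[:, : self.n_components].T
        curves = normed * self.amplitude_mean_
        return curves - curves[:, [0]]

    def prediction_positions(
        self,
        plane: AVPlane,
        ed_point: tuple[float, float],
        n_frames: int,
        cycle_duration: float | None = None,
    ) -> np.ndarray:
        """Per-frame predicted pixel positions of a landmark.

        The mm prediction curve is resampled to the series' frame count
        and each displacement converted to a pixel offset from the
        end-diastolic point along the apex axis (negative displacement
        moves the point toward the apex).
        """
        self._check_fitted()
        if n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        curve = (
            self.prediction_curve_
            if n_frames == self.n_frames
            else resample_curve(self.prediction_curve_, n_frames)
        )
        apex = np.asarray(plane.apex_direction, dtype=float)
        spacing = np.asarray(plane.pixel_spacing, dtype=float)
        ed = np.asarray(ed_point, dtype=float)
        # displacement s is -(delta_mm . apex): a point at displacement s sits
        # at ed_mm + (-s) * apex; convert back to pixels per axis
        offsets_px = (-curve[:, None]) * apex[None, :] / spacing[None, :]
        return ed[None, :] + offsets_px

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "n_components": self.n_components,
            "n_frames": self.n_frames,
            "mean_curve": self.mean_curve_.tolist(),
            "eigenvectors": self.eigenvectors_.tolist(),
            "eigenvalues": self.eigenvalues_.tolist(),
            "weight_sd": self.weight_sd_.tolist(),
            "amplitude_mean": self.amplitude_mean_,
            "amplitude_sd": self.amplitude_sd_,
            "prediction_curve": self.prediction_curve_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CurvePrior":
        prior = cls(n_components=int(d["n_components"]), n_frames=int(d["n_frames"]))
        prior.mean_curve_ = np.asarray(d["mean_curve"], dtype=float)
        prior.eigenvectors_ = np.asarray(d["eigenvectors"], dtype=float)
        prior.eigenvalues_ = np.asarray(d["eigenvalues"], dtype=float)
        prior.weight_sd_ = np.asarray(d["weight_sd"], dtype=float)
        prior.amplitude_mean_ = float(d["amplitude_mean"])
        prior.amplitude_sd_ = float(d["amplitude_sd"])
        prior.prediction_curve_ = np.asarray(d["prediction_curve"], dtype=float)
        return prior


@dataclass
class CurvePriorModel:
    """One fitted :class:`CurvePrior` per landmark, JSON-persistable."""

    priors: dict[str, CurvePrior] = field(default_factory=dict)

    def __getitem__(self, key: str) -> CurvePrior:
        return self.priors[key]

    def __contains__(self, key: str) -> bool:
        return key in self.priors

    @classmethod
    def train(
        cls,
        matrices: Mapping[str, np.ndarray],
        n_components: int = 5,
        n_frames: int = N_MODEL_FRAMES,
    ) -> "CurvePriorModel":
        """Fit a prior per landmark from ``{landmark_key: (n, n_frames) mm matrix}``."""
        priors = {
            key: CurvePrior(n_components=n_components, n_frames=n_frames).fit(mat)
            for key, mat in matrices.items()
        }
        return cls(priors)

    def save(self, path: str | Path) -> None:
        doc = {
            "format": "avpdtrack-curve-prior",
            "version": MODEL_FORMAT_VERSION,
            "landmarks": {key: prior.to_dict() for key, prior in self.priors.items()},
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "CurvePriorModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "avpdtrack-curve-prior":
            raise ValueError(f"{path}: not a curve-prior model file")
        if doc.get("version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported model version {doc.get('version')}")
        return cls({key: CurvePrior.from_dict(d) for key, d in doc["landmarks"].items()})
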