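"""Qualitative analysis: PCA of DCT features with per-class confidence ellipses.

The feature vectors of replicate measurements of single-analyte stocks are
mean-centered (no autoscaling by default: all DCT coefficients share μA units)
and decomposed by SVD. Scores on the first two principal components are
summarized per class by a confidence ellipse derived from the class mean and
2×2 covariance: semi-axes sqrt(λ_i·q) with q the χ²₂ quantile at the chosen
confidence level. Well-separated ellipses indicate that the sensor array
discriminates the analyte classes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass
class PcaModel:
    mean: np.ndarray  # feature-space mean (n_features,)
    loadings: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_fraction: np.ndarray  # (n_components,), non-increasing
    scale: np.ndarray | None = None  # per-feature divisor if autoscaled

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


@dataclass(frozen=True)
class ClassEllipse:
    center: tuple[float, float]
    axes: tuple[float, float]  # semi-axis lengths, major first
    angle: float  # radians, orientation of the major axis
    level: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which 2-D points fall inside the ellipse."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.center)
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[ca, sa], [-sa, ca]])  # rotate into ellipse frame
        q = p @ rot.T
        return (q[:, 0] / self.axes[0]) ** 2 + (q[:, 1] / self.axes[1]) ** 2 <= 1.0

    def boundary(self, n: int = 360) -> np.ndarray:
        t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        xy = np.column_stack([self.axes[0] * np.cos(t), self.axes[1] * np.sin(t)])
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[ca, -sa], [sa, ca]])
        return xy @ rot.T + np.asarray(self.center)


def fit_pca(features: np.ndarray, n_components: int = 2,
            autoscale: bool = False) -> PcaModel:
    """Mean-centered SVD; components ordered by decreasing explained variance.

    Sign convention: each loading vector is flipped so that its element of
    largest magnitude is positive, making score plots reproducible.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("need a 2-D feature matrix with >= 2 rows")
    n, p = x.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValidationError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
        )
    mean = x.mean(axis=0)
    xc = x - mean
    scale = None
    if autoscale:
        scale = xc.std(axis=0, ddof=1)
        if np.any(scale == 0):
            raise ValidationError("autoscaling impossible: constant feature column")
        xc = xc / scale
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float(np.sum(s**2))
    frac = (s**2 / total) if total > 0 else np.zeros_like(s)
    loadings = vt[:n_components]
    # fix signs: largest-|.| element of each loading positive
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    return PcaModel(mean=mean, loadings=loadings,
                    explained_fraction=frac[:n_components], scale=scale)


def project(model: PcaModel, features: np.ndarray) -> np.ndarray:
    """Scores of (rows of) ``features`` on the model's components."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.mean.size:
        raise ValidationError(
            f"feature length {x.shape[1]} != model dimension {model.mean.size}"
        )
    xc = x - model.mean
    if model.scale is not None:
        xc = xc / model.scale
    return xc @ model.loadings.T


def reconstruct(model: PcaModel, scores: np.ndarray) -> np.ndarray:
    """Back-project scores into feature space (inverse of :func:`project`)."""
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    xc = s @ model.loadings
    if model.scale is not None:
        xc = xc * model.scale
    return xc + model.mean


def confidence_ellipse(scores_2d: np.ndarray, level: float = 0.95) -> ClassEllipse:
    """Confidence ellipse of one class from its 2-D score cloud.

    Uses the known-covariance (χ²₂) form: semi-axes sqrt(eigenvalue · q) with
    q = χ²₂ quantile at ``level``.
    """
    pts = np.asarray(scores_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError("need >= 3 points of dimension 2")
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval[0] <= 0 or not np.all(np.isfinite(eigval)):
        raise ValidationError("singular score covariance: degenerate ellipse")
    q = stats.chi2.ppf(level, df=2)
    # eigh returns ascending order; major axis last
    axes = np.sqrt(eigval[::-1] * q)
    major = eigvec[:, -1]
    angle = float(np.arctan2(major[1], major[0]))
    return ClassEllipse(center=(float(center[0]), float(center[1])),
                        axes=(float(axes[0]), float(axes[1])),
                        angle=angle, level=level)


def ellipses_overlap(a: ClassEllipse, b: ClassEllipse, n: int = 720) -> bool:
    """Numerical overlap test: boundary/center containment either way."""
    if a.contains(np.asarray([b.center]))[0] or b.contains(np.asarray([a.center]))[0]:
        return True
    return bool(b.contains(a.boundary(n)).any() or a.contains(b.boundary(n)).any())
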