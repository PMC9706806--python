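"""Single-analyte sensor characterization.

Each sensor's peak-height response h(C) to one analyte saturates following the
one-site Langmuir isotherm h = B_max·C/(k_D + C); fitting it yields the
saturation response B_max (μA) and dissociation constant k_D (μM). At low
concentration (C ≲ k_D/5) the response is close to linear in log10 C, which
supports a logarithmic low-range calibration and a limit of detection of the
conventional 3·σ_blank/sensitivity form, with the initial-slope sensitivity
B_max/k_D (μA/μM). Repeatability is summarized as the percent relative
standard deviation of replicate peak heights.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import FitError, ValidationError


@dataclass(frozen=True)
class LangmuirFit:
    b_max: float  # μA
    k_d: float  # μM
    r2: float

    def height(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.b_max * conc / (self.k_d + conc)


@dataclass(frozen=True)
class LogLinearFit:
    slope: float  # μA per decade of concentration
    intercept: float  # μA at 1 μM
    r2: float


@dataclass(frozen=True)
class CalibrationFit:
    """Full single-analyte characterization of one sensor."""

    b_max: float
    k_d: float
    r2_langmuir: float
    log_slope: float
    log_intercept: float
    r2_log: float
    lod: float  # μM
    linear_range: tuple[float, float]  # μM, [LOD, C at 90% of B_max]


def _langmuir(c: np.ndarray, b_max: float, k_d: float) -> np.ndarray:
    return b_max * c / (k_d + c)


def fit_langmuir(concs: np.ndarray, heights: np.ndarray) -> LangmuirFit:
    """Least-squares Langmuir fit with deterministic initialization.

    Initialization: B_max0 = 1.1·max(h); k_D0 = concentration at which the
    (monotonized) response crosses B_max0/2, by linear interpolation.
    """
    c = np.asarray(concs, dtype=float)
    h = np.asarray(heights, dtype=float)
    if c.shape != h.shape or c.ndim != 1:
        raise ValidationError("concs and heights must be equal-length 1-D vectors")
    if np.unique(c[c > 0]).size < 3:
        raise ValidationError("need >= 3 distinct positive concentrations")
    if np.any(h < 0):
        raise ValidationError("heights must be nonnegative")
    if h.max() <= 0:
        raise FitError("all heights are zero: nothing to fit")

    order = np.argsort(c)
    c_s, h_s = c[order], h[order]
    b0 = 1.1 * h.max()
    h_mono = np.maximum.accumulate(h_s)  # monotone envelope for interpolation
    kd0 = float(np.interp(b0 / 2.0, h_mono, c_s))
    kd0 = max(kd0, 1e-6)

    try:
        popt, _ = optimize.curve_fit(
            _langmuir, c, h, p0=[b0, kd0],
            bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Langmuir fit failed: {exc}") from exc
    b_max, k_d = float(popt[0]), float(popt[1])
    resid = h - _langmuir(c, b_max, k_d)
    ss_tot = float(np.sum((h - h.mean()) ** 2))
    if ss_tot == 0.0:
        raise FitError("degenerate (constant) response: saturation not identifiable")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    if not np.isfinite(b_max) or not np.isfinite(k_d) or b_max <= 0:
        raise FitError("Langmuir fit did not converge to finite positive parameters")
    return LangmuirFit(b_max=b_max, k_d=k_d, r2=max(0.0, min(1.0, r2)))


def fit_loglinear(concs: np.ndarray, heights: np.ndarray) -> LogLinearFit:
    """Ordinary least squares of height on log10(concentration)."""
    c = np.asarray(concs, dtype=float)
    h = np.asarray(heights, dtype=float)
    if c.shape != h.shape or c.size < 3:
        raise ValidationError("need >= 3 (conc, height) pairs of equal length")
    if np.any(c <= 0):
        raise ValidationError("all concentrations must be > 0 for a log fit")
    res = stats.linregress(np.log10(c), h)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return LogLinearFit(slope=float(res.slope), intercept=float(res.intercept), r2=r2)


def compute_lod(blank_sd: float, slope: float, factor: float = 3.0) -> float:
    """LOD = factor·σ_blank / sensitivity (default 3σ; 3.3σ also conventional)."""
    if slope <= 0:
        raise ValidationError(f"slope must be > 0, got {slope}")
    if blank_sd < 0:
        raise ValidationError(f"blank_sd must be >= 0, got {blank_sd}")
    return factor * blank_sd / slope


def compute_rsd(replicate_heights: np.ndarray) -> float:
    """Percent relative standard deviation, sample (n−1) convention."""
    h = np.asarray(replicate_heights, dtype=float)
    if h.size < 2:
        raise ValidationError("need >= 2 replicates")
    mean = h.mean()
    if mean == 0:
        raise ValidationError("replicate mean is zero; %RSD undefined")
    return 100.0 * float(np.std(h, ddof=1)) / float(mean)


def characterize(
    concs: np.ndarray,
    heights: np.ndarray,
    blank_sd: float,
    low_range_fraction: float = 0.2,
    lod_factor: float = 3.0,
) -> CalibrationFit:
    """Assemble the full calibration report for one sensor–analyte pair.

    The log-linear segment is fitted on points with C <= low_range_fraction·k_D
    (falling back to the three lowest concentrations if fewer than three
    qualify); the linear range is reported as [LOD, C at 90% of B_max] = [LOD,
    9·k_D], capped at the largest measured concentration.
    """
    c = np.asarray(concs, dtype=float)
    h = np.asarray(heights, dtype=float)
    lang = fit_langmuir(c, h)
    low = c <= low_range_fraction * lang.k_d
    if low.sum() < 3:
        low = np.argsort(c)[:3]
    loglin = fit_loglinear(c[low], h[low])
    sensitivity = lang.b_max / lang.k_d  # initial Langmuir slope, μA/μM
    lod = compute_lod(blank_sd, sensitivity, lod_factor)
    upper = min(9.0 * lang.k_d, float(c.max()))
    return CalibrationFit(
        b_max=lang.b_max,
        k_d=lang.k_d,
        r2_langmuir=lang.r2,
        log_slope=loglin.slope,
        log_intercept=loglin.intercept,
        r2_log=loglin.r2,
        lod=lod,
        linear_range=(lod, upper),
    )
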