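"""Voltammogram preprocessing and DCT feature compression.

Smooth DPV traces concentrate almost all of their energy in the lowest
cosine-frequency coefficients, so an orthonormal type-II DCT truncated to the
first ``k`` coefficients compresses each trace (114 points → 12 by default)
while keeping the peak information that PCA/ANN need. The per-sensor
coefficient blocks are concatenated in a canonical sensor order (sorted
sensor_id) into one fixed-length feature vector — 4 sensors × 12 coefficients
= 48 features for the default array.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.fft import dct, idct

from .errors import ValidationError
from .simulate import ArrayMeasurement, Voltammogram

DEFAULT_K = 12
DEFAULT_N_EDGE = 10


@dataclass
class FeatureVector:
    """Concatenated per-sensor DCT coefficients, sensor-major."""

    values: np.ndarray
    sensor_order: tuple[str, ...]
    k: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.sensor_order) * self.k:
            raise ValidationError(
                f"feature length {self.values.size} != "
                f"{len(self.sensor_order)} sensors x {self.k} coefficients"
            )

    def __len__(self) -> int:
        return self.values.size

    def block(self, sensor_id: str) -> np.ndarray:
        """The k coefficients belonging to one sensor."""
        i = self.sensor_order.index(sensor_id)
        return self.values[i * self.k : (i + 1) * self.k]


def correct_baseline(v: Voltammogram, n_edge: int = DEFAULT_N_EDGE) -> Voltammogram:
    """Subtract the straight line fitted to the first and last ``n_edge`` points."""
    n = len(v)
    if n_edge < 2 or 2 * n_edge >= n:
        raise ValidationError(
            f"need 2 <= n_edge and 2*n_edge < {n}, got n_edge={n_edge}"
        )
    idx = np.r_[0:n_edge, n - n_edge : n]
    coef = np.polyfit(v.potentials[idx], v.currents[idx], 1)
    line = np.polyval(coef, v.potentials)
    return Voltammogram(v.potentials, v.currents - line, sensor_id=v.sensor_id)


def dct_compress(currents: np.ndarray, k: int) -> np.ndarray:
    """First ``k`` orthonormal type-II DCT coefficients, lowest frequency first."""
    x = np.asarray(currents, dtype=float)
    if not 1 <= k <= x.size:
        raise ValidationError(f"k must be in [1, {x.size}], got {k}")
    return dct(x, type=2, norm="ortho")[:k]


def dct_reconstruct(coeffs: np.ndarray, n: int) -> np.ndarray:
    """Inverse orthonormal type-II DCT of ``coeffs`` zero-padded to length ``n``."""
    c = np.asarray(coeffs, dtype=float)
    if n < c.size:
        raise ValidationError(f"n={n} smaller than number of coefficients {c.size}")
    padded = np.zeros(n)
    padded[: c.size] = c
    return idct(padded, type=2, norm="ortho")


def _reconstruction_r2(trace: np.ndarray, k: int) -> float:
    rec = dct_reconstruct(dct_compress(trace, k), trace.size)
    ss_res = float(np.sum((trace - rec) ** 2))
    ss_tot = float(np.sum((trace - trace.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-18 else 0.0
    return 1.0 - ss_res / ss_tot


def choose_k(traces: Iterable[np.ndarray], fidelity: float = 0.999) -> int:
    """Smallest k whose truncated-DCT reconstruction reaches R² >= ``fidelity``
    on every trace."""
    if not 0.0 < fidelity < 1.0:
        raise ValidationError(f"fidelity must be in (0, 1), got {fidelity}")
    traces = [np.asarray(t, dtype=float) for t in traces]
    if not traces:
        raise ValidationError("empty trace set")
    n_max = max(t.size for t in traces)
    for k in range(1, n_max + 1):
        if all(_reconstruction_r2(t, min(k, t.size)) >= fidelity for t in traces):
            return k
    return n_max  # full length always reconstructs exactly


def assemble_features(
    m: ArrayMeasurement,
    k: int = DEFAULT_K,
    baseline_n_edge: int = DEFAULT_N_EDGE,
    baseline_correct: bool = True,
) -> FeatureVector:
    """Baseline-correct, compress and concatenate one array measurement.

    Traces are taken in canonical order (sorted by sensor_id) regardless of
    their storage order, so the feature layout is stable across measurements.
    """
    traces = sorted(m.traces, key=lambda t: t.sensor_id)
    ids = tuple(t.sensor_id for t in traces)
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate sensor_id in measurement: {ids}")
    blocks = []
    for t in traces:
        if len(t) < k:
            raise ValidationError(
                f"trace {t.sensor_id}: length {len(t)} < k={k}"
            )
        if baseline_correct:
            t = correct_baseline(t, baseline_n_edge)
        blocks.append(dct_compress(t.currents, k))
    return FeatureVector(np.concatenate(blocks), sensor_order=ids, k=k)


def feature_matrix(
    measurements: Sequence[ArrayMeasurement],
    k: int = DEFAULT_K,
    baseline_n_edge: int = DEFAULT_N_EDGE,
    baseline_correct: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Stack feature vectors of many measurements: (n_samples, n_sensors*k)."""
    rows, ids = [], []
    for m in measurements:
        fv = assemble_features(m, k, baseline_n_edge, baseline_correct)
        rows.append(fv.values)
        ids.append(m.sample.sample_id)
    return np.vstack(rows), ids
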