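"""Simultaneous multi-analyte quantification with a feed-forward ANN.

A single-hidden-layer network maps the 48 DCT features of one array
measurement to the three analyte concentrations: logistic-sigmoid ("logsig")
hidden units and hyperbolic-tangent ("tansig") output units. Because tansig is
bounded in (−1, 1), inputs and targets are affinely scaled into [−1, 1] before
training (inputs through one shared map with a 10% margin, targets per analyte
with a wide margin that keeps them in tanh's quasi-linear zone); predictions
are inverse-scaled back to μM. Training minimizes full-batch mean squared error in scaled space
with L-BFGS from a seed-determined initialization, which makes runs exactly
reproducible. Topology (hidden-layer width) is selected by seeded k-fold
cross-validation inside the training subset only; the external testing subset
is reserved for the final obtained-vs-expected assessment.

Performance is summarized per analyte by the ordinary-least-squares slope,
intercept and R² (squared Pearson correlation) of predicted vs expected
concentration — the ideal comparison line being y = x — and globally by the
total normalized root mean square error

    NRMSE = sqrt( Σ_{samples, analytes} (ĉ − c)² / Σ c² ).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from sklearn.model_selection import KFold

from .errors import ValidationError

log = logging.getLogger(__name__)

DEFAULT_HIDDEN = 7
DEFAULT_MARGIN = 0.1


@dataclass(frozen=True)
class AffineScaler:
    """Per-dimension affine map sending [lo, hi] to [−1, 1]."""

    lo: np.ndarray
    hi: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(x, dtype=float) - self.lo) / (self.hi - self.lo) - 1.0

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return (np.asarray(z, dtype=float) + 1.0) * (self.hi - self.lo) / 2.0 + self.lo


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Inputs are scaled with one shared affine map over all feature dimensions
    (DCT coefficients share μA units, and per-dimension scaling would blow
    noise-dominated high-order coefficients up to O(1) amplitude); targets are
    scaled per analyte with a wide margin so they occupy tanh's quasi-linear
    zone (|scaled| <= 1/3 at ``output_margin=1.0``).
    """

    seed: int = 0
    max_epochs: int = 2000
    tol: float = 1e-9  # L-BFGS relative decrease threshold on the scaled MSE
    optimizer: str = "l-bfgs"
    input_margin: float = DEFAULT_MARGIN
    output_margin: float = 1.0


@dataclass
class AnnModel:
    """Trained (n_in, n_hidden, n_out) logsig/tansig network plus its scalers."""

    w1: np.ndarray  # (n_hidden, n_in)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_out, n_hidden)
    b2: np.ndarray  # (n_out,)
    input_scaler: AffineScaler
    output_scaler: AffineScaler
    train_config: TrainConfig
    converged: bool = True
    final_loss: float = np.nan
    hidden_transfer: str = "logsig"
    output_transfer: str = "tansig"

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return (self.w1.shape[1], self.w1.shape[0], self.w2.shape[0])


def fit_scalers(
    train_features: np.ndarray,
    train_targets: np.ndarray,
    margin: float = DEFAULT_MARGIN,
) -> tuple[AffineScaler, AffineScaler]:
    """Scalers mapping [min−m, max+m] → [−1, 1], m = margin·(max−min)."""
    out = []
    for name, arr in (("feature", train_features), ("target", train_targets)):
        a = np.atleast_2d(np.asarray(arr, dtype=float))
        lo, hi = a.min(axis=0), a.max(axis=0)
        degenerate = np.nonzero(hi <= lo)[0]
        if degenerate.size:
            raise ValidationError(
                f"constant {name} dimension(s) {degenerate.tolist()}: "
                "range is degenerate, cannot scale"
            )
        m = margin * (hi - lo)
        out.append(AffineScaler(lo=lo - m, hi=hi + m))
    return out[0], out[1]


def shared_range_scaler(features: np.ndarray, margin: float = DEFAULT_MARGIN) -> AffineScaler:
    """One affine map for every feature dimension, from the global min/max."""
    a = np.atleast_2d(np.asarray(features, dtype=float))
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        raise ValidationError("all feature values identical: degenerate range")
    m = margin * (hi - lo)
    n = a.shape[1]
    return AffineScaler(lo=np.full(n, lo - m), hi=np.full(n, hi + m))


def _logsig(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(params, shapes, xs):
    w1, b1, w2, b2 = _unpack(params, shapes)
    a1 = _logsig(xs @ w1.T + b1)
    y = np.tanh(a1 @ w2.T + b2)
    return y, a1


def _pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def _unpack(params, shapes):
    (h, n_in), n_out = shapes
    i = 0
    w1 = params[i : i + h * n_in].reshape(h, n_in); i += h * n_in
    b1 = params[i : i + h]; i += h
    w2 = params[i : i + n_out * h].reshape(n_out, h); i += n_out * h
    b2 = params[i : i + n_out]
    return w1, b1, w2, b2


def _loss_grad(params, shapes, xs, ts):
    w1, b1, w2, b2 = _unpack(params, shapes)
    a1 = _logsig(xs @ w1.T + b1)
    y = np.tanh(a1 @ w2.T + b2)
    err = y - ts
    n_terms = err.size
    loss = float(np.sum(err**2)) / n_terms
    dz2 = (2.0 / n_terms) * err * (1.0 - y**2)
    gw2 = dz2.T @ a1
    gb2 = dz2.sum(axis=0)
    dz1 = (dz2 @ w2) * a1 * (1.0 - a1)
    gw1 = dz1.T @ xs
    gb1 = dz1.sum(axis=0)
    return loss, _pack(gw1, gb1, gw2, gb2)


def train_ann(
    features: np.ndarray,
    targets: np.ndarray,
    n_hidden: int = DEFAULT_HIDDEN,
    config: TrainConfig = TrainConfig(),
) -> AnnModel:
    """Train the logsig/tansig network by full-batch L-BFGS on scaled MSE.

    Deterministic for a fixed seed and config; the returned model's training
    loss never exceeds the loss at initialization. Non-convergence within
    ``max_epochs`` returns the best parameters found with ``converged=False``
    and a logged warning.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    t = np.atleast_2d(np.asarray(targets, dtype=float))
    if x.shape[0] != t.shape[0]:
        raise ValidationError("features and targets must have the same row count")
    if x.shape[0] < 10:
        raise ValidationError(f"need >= 10 training rows, got {x.shape[0]}")
    if not (np.isfinite(x).all() and np.isfinite(t).all()):
        raise ValidationError("features/targets contain NaN or Inf")

    in_scaler = shared_range_scaler(x, config.input_margin)
    _, out_scaler = fit_scalers(x, t, config.output_margin)
    xs, ts = in_scaler.transform(x), out_scaler.transform(t)
    n_in, n_out = x.shape[1], t.shape[1]
    shapes = ((n_hidden, n_in), n_out)

    # Nguyen-Widrow hidden-layer initialization (inputs in [-1, 1]): weight
    # rows of norm beta with biases spread over [-beta, beta], so the sigmoid
    # active regions tile the input range. Output layer: small uniform.
    rng = np.random.default_rng(config.seed)
    beta = 0.7 * n_hidden ** (1.0 / n_in)
    w1 = rng.uniform(-1.0, 1.0, size=(n_hidden, n_in))
    w1 *= beta / np.linalg.norm(w1, axis=1, keepdims=True)
    b1 = beta * np.linspace(-1.0, 1.0, n_hidden) * np.sign(rng.uniform(-1, 1, n_hidden))
    r2 = np.sqrt(6.0 / (n_hidden + n_out))
    p0 = _pack(w1, b1, rng.uniform(-r2, r2, size=(n_out, n_hidden)), np.zeros(n_out))
    f0, _ = _loss_grad(p0, shapes, xs, ts)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # L-BFGS line-search chatter
        res = optimize.minimize(
            _loss_grad, p0, args=(shapes, xs, ts), jac=True, method="L-BFGS-B",
            options={"maxiter": config.max_epochs, "ftol": config.tol,
                     "gtol": 1e-12, "maxfun": 10 * config.max_epochs},
        )
    params, final = (res.x, float(res.fun)) if res.fun <= f0 else (p0, f0)
    converged = bool(res.success) or final <= f0
    if not res.success and res.status == 1:  # hit maxiter
        converged = False
        log.warning("ANN training stopped at max_epochs=%d (loss %.3e)",
                    config.max_epochs, final)
    w1, b1, w2, b2 = _unpack(params, shapes)
    return AnnModel(
        w1=w1.copy(), b1=b1.copy(), w2=w2.copy(), b2=b2.copy(),
        input_scaler=in_scaler, output_scaler=out_scaler,
        train_config=config, converged=converged, final_loss=final,
    )


def predict(model: AnnModel, features: np.ndarray) -> np.ndarray:
    """Concentration predictions (μM) for rows of ``features``."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.layer_sizes[0]:
        raise ValidationError(
            f"feature dimension {x.shape[1]} != model input {model.layer_sizes[0]}"
        )
    xs = model.input_scaler.transform(x)
    a1 = _logsig(xs @ model.w1.T + model.b1)
    ys = np.tanh(a1 @ model.w2.T + model.b2)
    out = model.output_scaler.inverse(ys)
    if not np.isfinite(out).all():
        raise ValidationError("non-finite prediction")
    return out


def total_nrmse(predicted: np.ndarray, expected: np.ndarray) -> float:
    """sqrt(Σ(ĉ−c)² / Σc²) over all samples and analytes."""
    p = np.asarray(predicted, dtype=float)
    e = np.asarray(expected, dtype=float)
    if p.shape != e.shape:
        raise ValidationError("predicted and expected must have equal shapes")
    denom = float(np.sum(e**2))
    if denom == 0:
        raise ValidationError("expected values are all zero; NRMSE undefined")
    return float(np.sqrt(np.sum((p - e) ** 2) / denom))


@dataclass(frozen=True)
class AnalyteRegression:
    analyte: str
    slope: float
    intercept: float
    r2: float


@dataclass
class RegressionReport:
    """Obtained-vs-expected assessment of one subset."""

    subset: str
    analytes: list[AnalyteRegression] = field(default_factory=list)
    total_nrmse: float = np.nan

    @property
    def min_r2(self) -> float:
        return min(a.r2 for a in self.analytes)


def evaluate(
    predicted: np.ndarray,
    expected: np.ndarray,
    subset: str = "testing",
    analyte_names: tuple[str, ...] | None = None,
) -> RegressionReport:
    """Per-analyte OLS of predicted on expected (slope/intercept/R²) + NRMSE."""
    p = np.atleast_2d(np.asarray(predicted, dtype=float))
    e = np.atleast_2d(np.asarray(expected, dtype=float))
    if p.shape != e.shape:
        raise ValidationError("predicted and expected must have equal shapes")
    if p.shape[0] < 3:
        raise ValidationError("need >= 3 samples to evaluate")
    if analyte_names is None:
        analyte_names = tuple(f"analyte_{j}" for j in range(p.shape[1]))
    rows = []
    for j, name in enumerate(analyte_names):
        if np.ptp(e[:, j]) == 0:
            raise ValidationError(
                f"expected column {name!r} is constant; R² undefined"
            )
        res = stats.linregress(e[:, j], p[:, j])
        rows.append(AnalyteRegression(
            analyte=name, slope=float(res.slope),
            intercept=float(res.intercept), r2=float(res.rvalue**2),
        ))
    return RegressionReport(subset=subset, analytes=rows,
                            total_nrmse=total_nrmse(p, e))


def topology_search(
    features: np.ndarray,
    targets: np.ndarray,
    candidate_hidden: list[int],
    cv_folds: int = 3,
    seed: int = 0,
    config: TrainConfig = TrainConfig(),
) -> tuple[int, dict[int, float]]:
    """Pick the hidden-layer width by seeded k-fold CV on total NRMSE.

    Returns the candidate with the lowest mean fold NRMSE; ties go to the
    smaller network. A candidate that fails to train on any fold scores inf.
    """
    if not candidate_hidden:
        raise ValidationError("candidate_hidden must be non-empty")
    if cv_folds < 2:
        raise ValidationError(f"cv_folds must be >= 2, got {cv_folds}")
    x = np.atleast_2d(np.asarray(features, dtype=float))
    t = np.atleast_2d(np.asarray(targets, dtype=float))
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(x))
    scores: dict[int, float] = {}
    for h in candidate_hidden:
        fold_scores = []
        for i, (tr, va) in enumerate(splits):
            try:
                model = train_ann(x[tr], t[tr], n_hidden=h,
                                  config=replace(config, seed=config.seed + i))
                fold_scores.append(total_nrmse(predict(model, x[va]), t[va]))
            except (ValidationError, FloatingPointError) as exc:
                log.warning("candidate h=%d failed on fold %d: %s", h, i, exc)
                fold_scores.append(np.inf)
        scores[h] = float(np.mean(fold_scores))
    best = min(sorted(candidate_hidden), key=lambda h: (scores[h], h))
    return best, scores
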