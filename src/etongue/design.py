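"""Calibration mixture designs.

The training set for multivariate calibration is a full-factorial design whose
per-factor concentration levels are slightly "tilted" (offset between factors)
so that no two analytes share identical level sets — this decorrelates the
design matrix. The external-validation set is drawn uniformly at random from
the same concentration domain.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Default per-factor tilt fractions (of each factor's range), cycled if there
#: are more factors than entries. Chosen small enough that level order is kept.
DEFAULT_TILT_CYCLE = (0.0, 0.03, -0.03)

#: Concentration domain used throughout the default study, in μM.
DEFAULT_RANGE = (2.0, 300.0)


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of a tilted full-factorial mixture design.

    Parameters
    ----------
    factors : number of analytes varied.
    levels : concentration levels per factor (>= 2).
    ranges : per-factor (low, high) concentration interval in μM, low > 0.
    tilt_offsets : per-factor additive level shifts as fractions of the
        factor's range; ``None`` selects the default 0/+0.03/−0.03 cycle.
    seed : seed for any randomized companion design.
    """

    factors: int = 3
    levels: int = 3
    ranges: tuple[tuple[float, float], ...] = field(default=None)  # type: ignore[assignment]
    tilt_offsets: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ranges is None:
            object.__setattr__(self, "ranges", (DEFAULT_RANGE,) * self.factors)
        self.validate()

    def validate(self) -> None:
        if self.factors < 1:
            raise ValidationError(f"factors must be >= 1, got {self.factors}")
        if self.levels < 2:
            raise ValidationError(f"levels must be >= 2, got {self.levels}")
        if len(self.ranges) != self.factors:
            raise ValidationError(
                f"ranges: expected {self.factors} intervals, got {len(self.ranges)}"
            )
        for i, (low, high) in enumerate(self.ranges):
            if not (low > 0 and high > low):
                raise ValidationError(
                    f"ranges[{i}]: need 0 < low < high, got ({low}, {high})"
                )
        tilts = self.resolved_tilts()
        half_spacing = 0.5 / (self.levels - 1)
        for i, t in enumerate(tilts):
            if abs(t) >= half_spacing:
                raise ValidationError(
                    f"tilt_offsets[{i}]: |{t}| must be < {half_spacing} "
                    "(half the inter-level spacing fraction)"
                )

    def resolved_tilts(self) -> tuple[float, ...]:
        if self.tilt_offsets is not None:
            if len(self.tilt_offsets) != self.factors:
                raise ValidationError(
                    f"tilt_offsets: expected {self.factors} entries, "
                    f"got {len(self.tilt_offsets)}"
                )
            return tuple(float(t) for t in self.tilt_offsets)
        cycle = itertools.cycle(DEFAULT_TILT_CYCLE)
        return tuple(next(cycle) for _ in range(self.factors))


@dataclass
class MixtureSample:
    """One mixture: per-analyte concentrations (μM) plus bookkeeping tags."""

    concentrations: np.ndarray
    label: str | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.ndim != 1:
            raise ValidationError("concentrations must be a 1-D vector")
        if np.any(self.concentrations < 0):
            raise ValidationError("concentrations must be nonnegative")

    @property
    def n_analytes(self) -> int:
        return self.concentrations.size


def factor_levels(spec: DesignSpec, factor: int) -> np.ndarray:
    """Tilted arithmetic level set for one factor, clipped to its range."""
    low, high = spec.ranges[factor]
    span = high - low
    grid = np.linspace(low, high, spec.levels)
    shifted = grid + spec.resolved_tilts()[factor] * span
    return np.clip(shifted, low, high)


def make_factorial_design(spec: DesignSpec) -> list[MixtureSample]:
    """Full crossing of the per-factor tilted level sets.

    Returns ``levels**factors`` samples in lexicographic level order (first
    factor slowest). Measurement-order randomization is the caller's concern.
    """
    spec.validate()
    level_sets = [factor_levels(spec, i) for i in range(spec.factors)]
    samples = []
    width = len(str(spec.levels**spec.factors))
    for i, combo in enumerate(itertools.product(*level_sets)):
        samples.append(
            MixtureSample(
                concentrations=np.array(combo, dtype=float),
                label="train",
                sample_id=f"train-{i + 1:0{width}d}",
            )
        )
    return samples


def make_random_test_set(
    n: int,
    ranges: tuple[tuple[float, float], ...] | None = None,
    seed: int = 0,
    factors: int = 3,
) -> list[MixtureSample]:
    """``n`` mixtures drawn uniformly from the per-analyte ranges (seeded)."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if ranges is None:
        ranges = (DEFAULT_RANGE,) * factors
    for i, (low, high) in enumerate(ranges):
        if not (low > 0 and high > low):
            raise ValidationError(f"ranges[{i}]: need 0 < low < high, got ({low}, {high})")
    rng = np.random.default_rng(seed)
    lows = np.array([r[0] for r in ranges])
    highs = np.array([r[1] for r in ranges])
    conc = rng.uniform(lows, highs, size=(n, len(ranges)))
    width = len(str(n))
    return [
        MixtureSample(conc[i], label="test", sample_id=f"test-{i + 1:0{width}d}")
        for i in range(n)
    ]
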