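"""Synthetic differential-pulse voltammetry (DPV) for an MIP sensor array.

Emulates the measurement stage of a voltammetric electronic tongue: four
working electrodes — three molecularly imprinted polymer (MIP) sensors, each
templated on one fluoroquinolone, plus a nonimprinted (NIP) control — scanned
over +0.6..+1.5 V. Each analyte contributes a Gaussian oxidation peak at its
characteristic potential whose height saturates with concentration following a
one-site Langmuir isotherm h = B_max·C/(k_D + C). Cross-sensitivity is encoded
by giving every sensor a (smaller) B_max for the non-template analytes; the
NIP has the weakest response to everything. Peaks superpose additively on a
slowly varying baseline (linear by default, with an optional exponential rise
at the anodic end emulating the solvent-oxidation wall), and measurement noise
is additive + relative Gaussian with an optional per-trace drift offset.

This is a behavioral stand-in for the instrument, not an electrochemical
mechanism model: no electron-transfer kinetics, diffusion or competitive
binding are simulated.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import MixtureSample
from .errors import ValidationError

#: Canonical analyte tags: the three quantification targets plus the two
#: extra fluoroquinolones used in the 5-class discrimination study.
ANALYTES = ("CFX", "LFX", "MFX", "FLQ", "NA")

#: Canonical sensor order of the default array (also lexicographic).
SENSOR_ORDER = ("MIP-CFX", "MIP-LFX", "MIP-MFX", "NIP")

POTENTIAL_WINDOW = (0.6, 1.5)


@dataclass(frozen=True)
class GridSpec:
    """Uniform potential grid: ``n_points`` over ``window`` (V)."""

    n_points: int = 114
    window: tuple[float, float] = POTENTIAL_WINDOW

    def potentials(self) -> np.ndarray:
        if self.n_points < 16:
            raise ValidationError(f"n_points must be >= 16, got {self.n_points}")
        return np.linspace(self.window[0], self.window[1], self.n_points)


@dataclass(frozen=True)
class AnalyteResponse:
    """One sensor's response parameters for one analyte."""

    b_max: float  # μA, peak current at saturation
    k_d: float  # μM, dissociation constant (half-saturation)
    e_peak: float  # V, peak potential
    width: float = 0.07  # V, Gaussian peak standard deviation (FWHM ≈ 165 mV)

    def validate(self, window: tuple[float, float] = POTENTIAL_WINDOW) -> None:
        if self.b_max < 0:
            raise ValidationError(f"b_max must be >= 0, got {self.b_max}")
        if self.k_d <= 0:
            raise ValidationError(f"k_d must be > 0, got {self.k_d}")
        if not (window[0] < self.e_peak < window[1]):
            raise ValidationError(
                f"e_peak {self.e_peak} V outside window {window}"
            )
        if self.width <= 0:
            raise ValidationError(f"width must be > 0, got {self.width}")


@dataclass(frozen=True)
class Baseline:
    """Slowly varying background current: line + optional anodic exponential
    rise (solvent-oxidation wall). The default array uses purely linear
    baselines — the two-edge correction then removes them exactly, which keeps
    even near-blank corrected traces compressible to 12 DCT coefficients; the
    exponential term is available for harder, wall-contaminated scenarios."""

    intercept: float = 0.0  # μA at the cathodic end of the window
    slope: float = 0.0  # μA/V
    exp_amplitude: float = 0.0  # μA at the onset potential
    onset: float = 1.6  # V
    rise_scale: float = 0.25  # V, e-folding of the anodic rise

    def currents(self, potentials: np.ndarray) -> np.ndarray:
        e0 = potentials[0]
        return (
            self.intercept
            + self.slope * (potentials - e0)
            + self.exp_amplitude * np.exp((potentials - self.onset) / self.rise_scale)
        )


@dataclass(frozen=True)
class SensorSpec:
    """Per-analyte binding/peak parameters and baseline of one sensor."""

    sensor_id: str
    responses: dict[str, AnalyteResponse] = field(default_factory=dict)
    baseline: Baseline = field(default_factory=Baseline)

    def validate(self, window: tuple[float, float] = POTENTIAL_WINDOW) -> None:
        for tag, resp in self.responses.items():
            try:
                resp.validate(window)
            except ValidationError as exc:
                raise ValidationError(f"{self.sensor_id}/{tag}: {exc}") from exc


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: per-point additive and relative Gaussian
    components plus a per-trace constant drift offset. The defaults emulate,
    conservatively, the high-single-digit %RSD repeatability regime of real
    MIP sensor arrays."""

    additive_sd: float = 0.06  # μA (0.5% of the largest default B_max)
    relative_sd: float = 0.01  # fraction of the clean current
    drift_per_trace: float = 0.0  # μA
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.additive_sd, self.relative_sd, self.drift_per_trace) < 0:
            raise ValidationError("noise magnitudes must be nonnegative")


ZERO_NOISE = NoiseSpec(additive_sd=0.0, relative_sd=0.0, drift_per_trace=0.0)


@dataclass
class Voltammogram:
    """One sensor's current trace on a uniform ascending potential grid."""

    potentials: np.ndarray
    currents: np.ndarray
    sensor_id: str = ""

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.potentials.shape != self.currents.shape or self.potentials.ndim != 1:
            raise ValidationError("potentials and currents must be equal-length 1-D")
        d = np.diff(self.potentials)
        if d.size and (np.any(d <= 0) or np.ptp(d) > 1e-9 * abs(d[0])):
            raise ValidationError("potential grid must be uniform and increasing")

    def __len__(self) -> int:
        return self.potentials.size


@dataclass
class ArrayMeasurement:
    """A mixture sample with one voltammogram per sensor of the array."""

    sample: MixtureSample
    traces: list[Voltammogram]

    def __post_init__(self) -> None:
        grids = [t.potentials for t in self.traces]
        for g in grids[1:]:
            if g.shape != grids[0].shape or not np.allclose(g, grids[0], rtol=1e-12):
                raise ValidationError("all traces must share one potential grid")

    def trace(self, sensor_id: str) -> Voltammogram:
        for t in self.traces:
            if t.sensor_id == sensor_id:
                return t
        raise KeyError(sensor_id)


def peak_height(sensor: SensorSpec, analyte: str, conc: float) -> float:
    """Langmuir one-site peak height h = B_max·C/(k_D + C), in μA."""
    if conc < 0:
        raise ValidationError(f"conc must be >= 0, got {conc}")
    try:
        resp = sensor.responses[analyte]
    except KeyError:
        raise KeyError(
            f"sensor {sensor.sensor_id!r} has no response entry for {analyte!r}"
        ) from None
    return resp.b_max * conc / (resp.k_d + conc)


def _gauss(potentials: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((potentials - center) / width) ** 2)


def simulate_voltammogram(
    sensor: SensorSpec,
    sample: MixtureSample,
    analytes: tuple[str, ...] | None = None,
    grid: GridSpec = GridSpec(),
    noise: NoiseSpec = ZERO_NOISE,
    rng: np.random.Generator | None = None,
) -> Voltammogram:
    """Simulate one DPV trace: baseline + Σ Langmuir-height Gaussian peaks + noise.

    ``analytes`` names the entries of ``sample.concentrations`` by position and
    defaults to the canonical tags. A fresh generator is derived from
    ``noise.seed`` unless ``rng`` is supplied (as :func:`simulate_array` does to
    give each sensor an independent substream).
    """
    if analytes is None:
        analytes = ANALYTES[: sample.n_analytes]
    if len(analytes) != sample.n_analytes:
        raise ValidationError(
            f"sample has {sample.n_analytes} concentrations but "
            f"{len(analytes)} analyte tags were given"
        )
    sensor.validate(grid.window)
    potentials = grid.potentials()
    currents = sensor.baseline.currents(potentials)
    for tag, conc in zip(analytes, sample.concentrations):
        h = peak_height(sensor, tag, float(conc))
        resp = sensor.responses[tag]
        currents = currents + h * _gauss(potentials, resp.e_peak, resp.width)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    n = potentials.size
    currents = (
        currents
        + noise.additive_sd * rng.standard_normal(n)
        + noise.relative_sd * currents * rng.standard_normal(n)
        + noise.drift_per_trace * rng.standard_normal()
    )
    return Voltammogram(potentials, currents, sensor_id=sensor.sensor_id)


def simulate_array(
    sensors: list[SensorSpec],
    sample: MixtureSample,
    analytes: tuple[str, ...] | None = None,
    grid: GridSpec = GridSpec(),
    noise: NoiseSpec = ZERO_NOISE,
) -> ArrayMeasurement:
    """Simulate the whole array for one sample, one noise substream per sensor."""
    ids = [s.sensor_id for s in sensors]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate sensor_id in array: {ids}")
    streams = np.random.SeedSequence(noise.seed).spawn(len(sensors))
    traces = [
        simulate_voltammogram(s, sample, analytes, grid, noise, np.random.default_rng(ss))
        for s, ss in zip(sensors, streams)
    ]
    return ArrayMeasurement(sample=sample, traces=traces)


def simulate_dataset(
    sensors: list[SensorSpec],
    samples: list[MixtureSample],
    analytes: tuple[str, ...] | None = None,
    grid: GridSpec = GridSpec(),
    noise: NoiseSpec = ZERO_NOISE,
) -> list[ArrayMeasurement]:
    """Measure a list of samples; sample ``i`` uses noise seed ``seed + i``."""
    out = []
    for i, sample in enumerate(samples):
        per_sample = NoiseSpec(
            noise.additive_sd, noise.relative_sd, noise.drift_per_trace,
            seed=noise.seed + i,
        )
        out.append(simulate_array(sensors, sample, analytes, grid, per_sample))
    return out


# Default response tables. B_max (μA) encodes class selectivity: each of the
# CFX/LFX imprints responds most to its own template, the NIP responds least to
# every analyte, and MFX draws intrinsically smaller currents than CFX/LFX on
# every electrode. k_D (μM) sits well above the 2–300 μM working domain top
# (weak-saturation regime, own template = highest affinity): the response is
# visibly hyperbolic over the domain (~30–40% saturated at 300 μM) yet the
# whole range up to 300 μM stays analytically usable, which is what a wide
# detection range requires. Peak potentials/widths are plausible placements in
# the +0.6..+1.5 V window so current maxima fall at distinct potentials.
_E_PEAK = {"CFX": 1.00, "LFX": 0.94, "MFX": 1.08, "FLQ": 1.20, "NA": 1.25}

_BANK_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    # sensor -> analyte -> (b_max μA, k_d μM)
    "MIP-CFX": {"CFX": (12.0, 480.0), "LFX": (6.0, 600.0), "MFX": (3.5, 560.0),
                "FLQ": (4.0, 640.0), "NA": (3.0, 700.0)},
    "MIP-LFX": {"CFX": (7.0, 560.0), "LFX": (11.0, 440.0), "MFX": (3.0, 600.0),
                "FLQ": (3.5, 620.0), "NA": (2.5, 660.0)},
    "MIP-MFX": {"CFX": (6.5, 580.0), "LFX": (6.0, 620.0), "MFX": (4.5, 400.0),
                "FLQ": (3.0, 600.0), "NA": (2.8, 640.0)},
    "NIP": {"CFX": (2.5, 660.0), "LFX": (2.2, 680.0), "MFX": (1.2, 720.0),
            "FLQ": (1.5, 760.0), "NA": (1.0, 800.0)},
}

_BANK_BASELINES = {
    "MIP-CFX": Baseline(0.60, 0.40),
    "MIP-LFX": Baseline(0.55, 0.35),
    "MIP-MFX": Baseline(0.50, 0.30),
    "NIP": Baseline(0.40, 0.25),
}


def default_sensor_bank() -> list[SensorSpec]:
    """The default 4-sensor array (3 MIPs + NIP) with 5-analyte cross-response."""
    bank = []
    for sensor_id in SENSOR_ORDER:
        responses = {
            tag: AnalyteResponse(b_max=b, k_d=kd, e_peak=_E_PEAK[tag])
            for tag, (b, kd) in _BANK_TABLE[sensor_id].items()
        }
        bank.append(
            SensorSpec(sensor_id, responses, baseline=_BANK_BASELINES[sensor_id])
        )
    return bank
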