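"""End-to-end orchestration of the electronic-tongue workflows.

Stages (``simulate → calibrate / pca / train → evaluate``) communicate only
through files in the output directory plus the run configuration, so any stage
can be re-run in isolation. One global seed is split deterministically into
named per-stage substreams; a run log records the config echo, derived seeds
and library versions, which is enough to reproduce any stage bit-for-bit.
"""
from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import characterize, CalibrationFit
from .design import DesignSpec, MixtureSample, make_factorial_design, make_random_test_set
from .discrimination import confidence_ellipse, fit_pca, project
from .errors import ValidationError
from .quantify import (
    RegressionReport,
    TrainConfig,
    evaluate,
    predict,
    topology_search,
    train_ann,
)
from .signals import DEFAULT_K, DEFAULT_N_EDGE, feature_matrix
from .simulate import (
    ANALYTES,
    GridSpec,
    NoiseSpec,
    SensorSpec,
    default_sensor_bank,
    simulate_dataset,
)
from . import storage

log = logging.getLogger(__name__)

COMMANDS = ("simulate", "calibrate", "pca", "train", "evaluate", "all")

QUANT_ANALYTES = ("CFX", "LFX", "MFX")

#: Substream labels, in spawn order, for splitting the global seed.
_STREAMS = ("test_design", "train_noise", "test_noise", "ann_init",
            "calib_noise", "pca_noise", "cv_split")


@dataclass
class RunConfig:
    """Everything needed to reproduce a full synthetic study."""

    levels: int = 3
    factors: int = 3
    ranges: tuple[tuple[float, float], ...] = ((2.0, 300.0),) * 3
    tilt_offsets: tuple[float, ...] | None = None
    n_test: int = 10
    bank: str = "default"  # or path to a YAML sensor-bank file
    additive_sd: float = 0.06
    relative_sd: float = 0.01
    drift_per_trace: float = 0.0
    n_points: int = 114
    window: tuple[float, float] = (0.6, 1.5)
    k: int = DEFAULT_K
    n_edge: int = DEFAULT_N_EDGE
    n_hidden: int = 7
    candidate_hidden: list[int] | None = None  # enables topology search
    cv_folds: int = 3
    max_epochs: int = 2000
    tol: float = 1e-9
    pca_replicates: int = 8
    pca_stock_uM: float = 100.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        self.ranges = tuple(tuple(r) for r in self.ranges)
        self.window = tuple(self.window)

    # -- derived pieces -------------------------------------------------
    def stream_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {
            name: int(ss.generate_state(1, np.uint32)[0] % 2**31)
            for name, ss in zip(_STREAMS, children)
        }

    def grid(self) -> GridSpec:
        return GridSpec(n_points=self.n_points, window=self.window)

    def noise(self, seed: int) -> NoiseSpec:
        return NoiseSpec(self.additive_sd, self.relative_sd,
                         self.drift_per_trace, seed=seed)

    def load_bank(self) -> list[SensorSpec]:
        if self.bank == "default":
            return default_sensor_bank()
        p = Path(self.bank)
        if not p.exists():
            raise ValidationError(f"sensor bank file not found: {p}")
        return storage.read_bank(p)

    def train_config(self) -> TrainConfig:
        return TrainConfig(seed=self.stream_seeds()["ann_init"],
                           max_epochs=self.max_epochs, tol=self.tol)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Path) -> None:
        d = dataclasses.asdict(self)
        d["ranges"] = [list(r) for r in self.ranges]
        d["window"] = list(self.window)
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def _setup_logging(out_dir: Path) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    handlers.append(logging.FileHandler(out_dir / "run.log"))
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    root = logging.getLogger("etongue")
    root.setLevel(logging.INFO)
    for h in handlers:
        h.setFormatter(fmt)
        root.addHandler(h)


def _teardown_logging() -> None:
    root = logging.getLogger("etongue")
    for h in list(root.handlers):
        h.close()
        root.removeHandler(h)


# ---------------------------------------------------------------- stages

def stage_simulate(config: RunConfig, out: Path) -> None:
    seeds = config.stream_seeds()
    spec = DesignSpec(factors=config.factors, levels=config.levels,
                      ranges=config.ranges, tilt_offsets=config.tilt_offsets)
    train = make_factorial_design(spec)
    test = make_random_test_set(config.n_test, config.ranges,
                                seed=seeds["test_design"])
    storage.write_design(train, out / "design_train.csv",
                         analytes=ANALYTES[: config.factors])
    storage.write_design(test, out / "design_test.csv",
                         analytes=ANALYTES[: config.factors])
    bank = config.load_bank()
    storage.write_bank(bank, out / "sensor_bank.yaml")
    for name, samples, noise_seed in (
        ("train", train, seeds["train_noise"]),
        ("test", test, seeds["test_noise"]),
    ):
        meas = simulate_dataset(bank, samples, grid=config.grid(),
                                noise=config.noise(noise_seed))
        storage.write_voltammograms(meas, out / f"voltammograms_{name}.csv")
    log.info("simulate: %d train + %d test samples", len(train), len(test))


def _measurements(config: RunConfig, out: Path, name: str):
    design = storage.read_design(out / f"design_{name}.csv")
    conc = {s.sample_id: s.concentrations for s in design}
    return storage.read_voltammograms(out / f"voltammograms_{name}.csv", conc)


def _features(config: RunConfig, out: Path, name: str):
    meas = _measurements(config, out, name)
    x, ids = feature_matrix(meas, k=config.k, baseline_n_edge=config.n_edge)
    y = np.vstack([m.sample.concentrations for m in meas])
    storage.write_features(
        x, ids, out / f"features_{name}.csv",
        sidecar={"k": config.k, "n_edge": config.n_edge,
                 "sensor_order": sorted(t.sensor_id for t in meas[0].traces)},
    )
    return x, y, ids


def stage_calibrate(config: RunConfig, out: Path) -> dict[tuple[str, str], CalibrationFit]:
    """Single-analyte calibration of every sensor–analyte pair.

    Simulates a concentration series plus blank replicates under the
    configured noise, reads peak heights at each analyte's peak potential on
    baseline-corrected traces, and fits Langmuir + log-linear models.
    """
    from .signals import correct_baseline

    seeds = config.stream_seeds()
    bank = config.load_bank()
    grid = config.grid()
    series = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 300.0])
    fits: dict[tuple[str, str], CalibrationFit] = {}
    analytes = tuple(sorted(bank[0].responses))
    rng_seed = seeds["calib_noise"]
    for sensor in bank:
        for analyte in analytes:
            e_peak = sensor.responses[analyte].e_peak
            j = int(np.argmin(np.abs(grid.potentials() - e_peak)))
            heights, blanks = [], []
            for rep, conc in enumerate(np.r_[series, np.zeros(10)]):
                sample = MixtureSample(np.array([conc]), sample_id="cal")
                meas = simulate_dataset(
                    [sensor], [sample], analytes=(analyte,), grid=grid,
                    noise=config.noise(rng_seed))[0]
                rng_seed += 1
                corrected = correct_baseline(meas.traces[0], config.n_edge)
                (heights if conc > 0 else blanks).append(corrected.currents[j])
            blank_sd = float(np.std(blanks, ddof=1))
            # blank subtraction removes the deterministic residual the edge-line
            # correction leaves under the anodic exponential rise; noise can
            # still push near-blank reads slightly negative, so clip at zero
            heights = np.clip(np.array(heights) - np.mean(blanks), 0.0, None)
            fits[(sensor.sensor_id, analyte)] = characterize(
                series, heights, blank_sd)
    storage.write_calibration(fits, out / "calibration.csv")
    log.info("calibrate: %d sensor-analyte fits", len(fits))
    return fits


def stage_pca(config: RunConfig, out: Path) -> None:
    """Five-class stock discrimination: DCT features → 2-component PCA."""
    seeds = config.stream_seeds()
    bank = config.load_bank()
    analytes = tuple(sorted(bank[0].responses))
    samples, labels = [], []
    for a_idx, analyte in enumerate(analytes):
        conc = np.zeros(len(analytes))
        conc[a_idx] = config.pca_stock_uM
        for r in range(config.pca_replicates):
            samples.append(MixtureSample(conc, label=analyte,
                                         sample_id=f"{analyte}-{r + 1}"))
            labels.append(analyte)
    meas = simulate_dataset(bank, samples, analytes=analytes, grid=config.grid(),
                            noise=config.noise(seeds["pca_noise"]))
    x, ids = feature_matrix(meas, k=config.k, baseline_n_edge=config.n_edge)
    model = fit_pca(x, n_components=2)
    scores = project(model, x)
    pd.DataFrame({
        "sample_id": ids, "label": labels,
        "pc1": [storage._f(v) for v in scores[:, 0]],
        "pc2": [storage._f(v) for v in scores[:, 1]],
    }).to_csv(out / "pca_scores.csv", index=False)
    rows = []
    for analyte in analytes:
        mask = np.array(labels) == analyte
        ell = confidence_ellipse(scores[mask], level=0.95)
        rows.append({
            "label": analyte,
            "center_x": storage._f(ell.center[0]), "center_y": storage._f(ell.center[1]),
            "semi_major": storage._f(ell.axes[0]), "semi_minor": storage._f(ell.axes[1]),
            "angle_rad": storage._f(ell.angle), "level": ell.level,
        })
    pd.DataFrame(rows).to_csv(out / "pca_ellipses.csv", index=False)
    log.info("pca: explained fractions %s",
             np.array2string(model.explained_fraction, precision=4))


def stage_train(config: RunConfig, out: Path) -> None:
    x, y, _ = _features(config, out, "train")
    tc = config.train_config()
    n_hidden = config.n_hidden
    if config.candidate_hidden:
        n_hidden, scores = topology_search(
            x, y, config.candidate_hidden, cv_folds=config.cv_folds,
            seed=config.stream_seeds()["cv_split"], config=tc)
        log.info("topology search: %s -> %d hidden", scores, n_hidden)
    model = train_ann(x, y, n_hidden=n_hidden, config=tc)
    storage.write_model(model, out / "ann_model.json")
    log.info("train: layers %s, final scaled MSE %.3e, converged=%s",
             model.layer_sizes, model.final_loss, model.converged)


def stage_evaluate(config: RunConfig, out: Path) -> list[RegressionReport]:
    model = storage.read_model(out / "ann_model.json")
    reports = []
    for name in ("train", "test"):
        x, y, _ = _features(config, out, name)
        rep = evaluate(predict(model, x), y,
                       subset="training" if name == "train" else "testing",
                       analyte_names=QUANT_ANALYTES[: y.shape[1]])
        reports.append(rep)
        log.info("evaluate(%s): min R2 %.4f, NRMSE %.4f",
                 rep.subset, rep.min_r2, rep.total_nrmse)
    storage.write_report(reports, out / "report.csv")
    return reports


def run_pipeline(config: RunConfig, command: str, out_dir: Path) -> int:
    """Execute one stage (or ``all``); returns a process exit status."""
    if command not in COMMANDS:
        raise ValidationError(f"unknown command {command!r}; choose from {COMMANDS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    try:
        config.to_yaml(out / "config_echo.yaml")
        log.info("etongue %s | command=%s seed=%d streams=%s",
                 __version__, command, config.seed, config.stream_seeds())
        log.info("versions: numpy %s", np.__version__)
        stages = {
            "simulate": [stage_simulate],
            "calibrate": [stage_calibrate],
            "pca": [stage_pca],
            "train": [stage_train],
            "evaluate": [stage_evaluate],
            "all": [stage_simulate, stage_calibrate, stage_pca,
                    stage_train, stage_evaluate],
        }[command]
        for stage in stages:
            log.info("stage: %s", stage.__name__)
            stage(config, out)
    except Exception:
        log.exception("pipeline failed in command %r", command)
        return 1
    finally:
        _teardown_logging()
    return 0
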