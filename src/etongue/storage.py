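"""Serialization of designs, voltammograms, features, models and reports.

All numeric CSV output is formatted at 9 significant digits so that
write→read round trips and byte-identity checks between reruns are exact on
the textual representation.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationFit
from .design import MixtureSample
from .errors import ParseError
from .quantify import AffineScaler, AnnModel, RegressionReport, TrainConfig
from .simulate import (
    AnalyteResponse,
    ArrayMeasurement,
    Baseline,
    NoiseSpec,
    SensorSpec,
    Voltammogram,
)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.9g"
MODEL_FORMAT_VERSION = 1


def _f(x: float) -> str:
    return FLOAT_FMT % x


# ---------------------------------------------------------------- designs

def write_design(samples: list[MixtureSample], path: Path,
                 analytes: tuple[str, ...] = ("CFX", "LFX", "MFX")) -> None:
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id}
        row.update({f"conc_{a}_uM": _f(c) for a, c in zip(analytes, s.concentrations)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_design(path: Path) -> list[MixtureSample]:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    conc_cols = [c for c in df.columns if c.startswith("conc_")]
    if not conc_cols:
        raise ParseError(f"{path}: no conc_* columns")
    return [
        MixtureSample(row[conc_cols].to_numpy(dtype=float),
                      sample_id=str(row["sample_id"]))
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------- voltammograms

VOLT_COLUMNS = ["sample_id", "sensor_id", "potential_V", "current_uA"]


def write_voltammograms(measurements: list[ArrayMeasurement], path: Path) -> None:
    """Long-format CSV: one row per (sample, sensor, potential)."""
    frames = []
    for m in measurements:
        for t in m.traces:
            frames.append(pd.DataFrame({
                "sample_id": m.sample.sample_id,
                "sensor_id": t.sensor_id,
                "potential_V": [_f(p) for p in t.potentials],
                "current_uA": [_f(c) for c in t.currents],
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_voltammograms(
    path: Path,
    concentrations: dict[str, np.ndarray] | None = None,
) -> list[ArrayMeasurement]:
    """Parse the long-format CSV back into measurements.

    ``concentrations`` optionally maps sample_id → concentration vector (e.g.
    loaded from the design CSV); absent entries get zero vectors, since the
    trace file itself carries no targets. Grids are validated per sample, and
    every sample must expose the same sensor set.
    """
    df = pd.read_csv(path)
    if df.empty:
        log.warning("%s: empty voltammogram file", path)
        return []
    missing = [c for c in VOLT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    dup = df.duplicated(subset=["sample_id", "sensor_id", "potential_V"])
    if dup.any():
        raise ParseError(f"{path}: duplicate (sample, sensor, potential) at "
                         f"row {int(np.nonzero(dup.to_numpy())[0][0]) + 2}")
    sensor_sets = df.groupby("sample_id")["sensor_id"].agg(lambda s: frozenset(s))
    expected = sensor_sets.iloc[0]
    for sid, got in sensor_sets.items():
        if got != expected:
            raise ParseError(
                f"{path}: sample {sid!r} has sensors {sorted(got)}, "
                f"expected {sorted(expected)}"
            )
    measurements = []
    grid_len = None
    for sid, g in df.groupby("sample_id", sort=False):
        traces = []
        for sensor_id, gs in g.groupby("sensor_id", sort=True):
            pot = gs["potential_V"].to_numpy(dtype=float)
            cur = gs["current_uA"].to_numpy(dtype=float)
            order = np.argsort(pot)
            pot, cur = pot[order], cur[order]
            # snap text-rounded grids back to exactly uniform spacing
            d = np.diff(pot)
            if d.size and np.all(d > 0) and np.ptp(d) < 1e-4 * d.mean():
                pot = np.linspace(pot[0], pot[-1], pot.size)
            try:
                traces.append(Voltammogram(pot, cur, str(sensor_id)))
            except Exception as exc:
                raise ParseError(f"{path}: sample {sid!r}/{sensor_id}: {exc}") from exc
            if grid_len is None:
                grid_len = len(pot)
            elif len(pot) != grid_len:
                raise ParseError(f"{path}: ragged grid for sample {sid!r}")
        conc = (concentrations or {}).get(
            str(sid), np.zeros(3)
        )
        measurements.append(ArrayMeasurement(
            sample=MixtureSample(conc, sample_id=str(sid)), traces=traces))
    return measurements


# --------------------------------------------------------------- features

def write_features(matrix: np.ndarray, sample_ids: list[str], path: Path,
                   sidecar: dict | None = None) -> None:
    cols = {f"f_{j + 1:03d}": [_f(v) for v in matrix[:, j]]
            for j in range(matrix.shape[1])}
    pd.DataFrame({"sample_id": sample_ids, **cols}).to_csv(path, index=False)
    if sidecar is not None:
        Path(str(path) + ".meta.yaml").write_text(
            yaml.safe_dump(sidecar, sort_keys=True))


def read_features(path: Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    fcols = [c for c in df.columns if c.startswith("f_")]
    if "sample_id" not in df.columns or not fcols:
        raise ParseError(f"{path}: expected sample_id and f_* columns")
    return df[fcols].to_numpy(dtype=float), df["sample_id"].astype(str).tolist()


# ------------------------------------------------------- bank/noise config

def bank_to_dict(bank: list[SensorSpec]) -> dict:
    return {
        s.sensor_id: {
            "baseline": asdict(s.baseline),
            "responses": {tag: asdict(r) for tag, r in s.responses.items()},
        }
        for s in bank
    }


def bank_from_dict(d: dict) -> list[SensorSpec]:
    bank = []
    for sensor_id in sorted(d):
        entry = d[sensor_id]
        bank.append(SensorSpec(
            sensor_id=sensor_id,
            responses={tag: AnalyteResponse(**r)
                       for tag, r in entry["responses"].items()},
            baseline=Baseline(**entry.get("baseline", {})),
        ))
    return bank


def write_bank(bank: list[SensorSpec], path: Path) -> None:
    path.write_text(yaml.safe_dump(bank_to_dict(bank), sort_keys=True))


def read_bank(path: Path) -> list[SensorSpec]:
    return bank_from_dict(yaml.safe_load(Path(path).read_text()))


def noise_to_dict(noise: NoiseSpec) -> dict:
    return asdict(noise)


# ------------------------------------------------------------------ model

def write_model(model: AnnModel, path: Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "layer_sizes": list(model.layer_sizes),
        "hidden_transfer": model.hidden_transfer,
        "output_transfer": model.output_transfer,
        "weights": {
            "w1": model.w1.ravel().tolist(), "b1": model.b1.tolist(),
            "w2": model.w2.ravel().tolist(), "b2": model.b2.tolist(),
        },
        "input_scaler": {"lo": model.input_scaler.lo.tolist(),
                         "hi": model.input_scaler.hi.tolist()},
        "output_scaler": {"lo": model.output_scaler.lo.tolist(),
                          "hi": model.output_scaler.hi.tolist()},
        "train_config": asdict(model.train_config),
        "converged": model.converged,
        "final_loss": model.final_loss,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_model(path: Path) -> AnnModel:
    d = json.loads(Path(path).read_text())
    if d.get("format_version") != MODEL_FORMAT_VERSION:
        raise ParseError(f"{path}: unsupported model format {d.get('format_version')}")
    n_in, h, n_out = d["layer_sizes"]
    return AnnModel(
        w1=np.array(d["weights"]["w1"]).reshape(h, n_in),
        b1=np.array(d["weights"]["b1"]),
        w2=np.array(d["weights"]["w2"]).reshape(n_out, h),
        b2=np.array(d["weights"]["b2"]),
        input_scaler=AffineScaler(np.array(d["input_scaler"]["lo"]),
                                  np.array(d["input_scaler"]["hi"])),
        output_scaler=AffineScaler(np.array(d["output_scaler"]["lo"]),
                                   np.array(d["output_scaler"]["hi"])),
        train_config=TrainConfig(**d["train_config"]),
        converged=d["converged"],
        final_loss=d["final_loss"],
        hidden_transfer=d["hidden_transfer"],
        output_transfer=d["output_transfer"],
    )


# ----------------------------------------------------------------- reports

def write_report(reports: list[RegressionReport], path: Path) -> None:
    rows = []
    for rep in reports:
        for a in rep.analytes:
            rows.append({
                "subset": rep.subset, "analyte": a.analyte,
                "slope": _f(a.slope), "intercept": _f(a.intercept),
                "r2": _f(a.r2), "total_nrmse": _f(rep.total_nrmse),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_calibration(fits: dict[tuple[str, str], CalibrationFit], path: Path) -> None:
    rows = []
    for (sensor_id, analyte), fit in sorted(fits.items()):
        rows.append({
            "sensor_id": sensor_id, "analyte": analyte,
            "B_max_uA": _f(fit.b_max), "k_D_uM": _f(fit.k_d),
            "r2_langmuir": _f(fit.r2_langmuir),
            "log_slope": _f(fit.log_slope), "log_intercept": _f(fit.log_intercept),
            "r2_log": _f(fit.r2_log), "lod_uM": _f(fit.lod),
            "linear_low_uM": _f(fit.linear_range[0]),
            "linear_high_uM": _f(fit.linear_range[1]),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
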