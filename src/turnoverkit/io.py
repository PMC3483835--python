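"""Configuration loading and the simulate/fit pipeline entry points.

Interchange is plain delimited text with explicit headers:

- time courses: ``time_h,mrna,protein_total,protein_labeled,protein_unlabeled``
- measurements: ``time_h,replicate,signal``

Parameter sets come from flat key-value config (YAML), with
``doubling_time_h: none`` marking non-dividing cells; a run config adds a
scenario (preset reference or explicit perturbation list), sampling
times, an optional noise block and a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import yaml

from . import __version__
from .estimation import HalfLifeEstimate, fit_half_life
from .kinetics import ParameterError, TurnoverParams, rate_constants
from .measurement import MeasurementSet, NoiseModel, read_measurements, sample_measurements
from .scenarios import Perturbation, Scenario, TimeCourse, preset, simulate

log = logging.getLogger("turnoverkit")

__all__ = [
    "RunConfig",
    "params_from_dict",
    "load_params",
    "scenario_from_dict",
    "load_run_config",
    "run_simulate",
    "run_fit",
]

_PARAM_KEYS = {
    "mrna_copies",
    "translation_rate_per_h",
    "mrna_half_life_h",
    "protein_half_life_h",
    "doubling_time_h",
}


def params_from_dict(d: dict) -> TurnoverParams:
    """Build TurnoverParams from the flat key-value convention."""
    missing = _PARAM_KEYS - {"doubling_time_h"} - set(d)
    if missing:
        raise ParameterError(f"parameter config missing keys: {sorted(missing)}")
    unknown = set(d) - _PARAM_KEYS
    if unknown:
        raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
    doubling = d.get("doubling_time_h")
    if isinstance(doubling, str):
        if doubling.lower() in {"none", "non-dividing", "nondividing"}:
            doubling = None
        else:
            raise ParameterError(f"doubling_time_h must be a number or 'none', got {doubling!r}")
    return TurnoverParams(
        mrna_copies=float(d["mrna_copies"]),
        translation_rate=float(d["translation_rate_per_h"]),
        mrna_half_life=float(d["mrna_half_life_h"]),
        protein_half_life=float(d["protein_half_life_h"]),
        doubling_time=None if doubling is None else float(doubling),
    )


def load_params(path) -> TurnoverParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ParameterError(f"{path}: parameter config must be a mapping")
    return params_from_dict(d)


def scenario_from_dict(d: dict, sampling_times) -> Scenario:
    """Build a Scenario from a preset reference or explicit perturbation list."""
    if "preset" in d:
        options = dict(d.get("options") or {})
        return preset(d["preset"], sampling_times, **options)
    perts = []
    for row in d.get("perturbations", []):
        perts.append(
            Perturbation(
                onset=float(row["onset_h"]),
                kind=str(row["kind"]),
                magnitude=float(row.get("magnitude", 1.0)),
            )
        )
    return Scenario(perturbations=tuple(perts), sampling_times=tuple(sampling_times))


@dataclass(frozen=True)
class RunConfig:
    """Everything one simulate run needs: parameters, scenario, noise, seed."""

    params: TurnoverParams
    scenario: Scenario
    noise: Optional[NoiseModel] = None
    seed: Optional[int] = None
    channel: str = "total"

    def __post_init__(self) -> None:
        if self.noise is not None and self.seed is None:
            raise ParameterError("seed is mandatory when a noise model is present")


def load_run_config(path, seed: Optional[int] = None) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: run config must be a mapping")
    params = params_from_dict(raw.get("params") or {})
    times = raw.get("sampling_times_h")
    if not times:
        raise ParameterError("run config must list sampling_times_h")
    scenario = scenario_from_dict(raw.get("scenario") or {}, times)
    cfg_seed = seed if seed is not None else raw.get("seed")
    noise = None
    if raw.get("noise"):
        nd = dict(raw["noise"])
        if cfg_seed is None:
            raise ParameterError("seed is mandatory when a noise model is present")
        noise = NoiseModel(
            cv=float(nd.get("cv", 0.10)),
            replicates=int(nd.get("replicates", 3)),
            seed=int(cfg_seed),
            detection_floor=float(nd.get("detection_floor", 0.0)),
        )
    return RunConfig(
        params=params,
        scenario=scenario,
        noise=noise,
        seed=cfg_seed,
        channel=str(raw.get("channel", "total")),
    )


def run_simulate(config: RunConfig, outdir) -> Tuple[TimeCourse, Optional[MeasurementSet]]:
    """Simulate a run config and write its tables under ``outdir``.

    Writes ``timecourse.csv`` always and ``measurements.csv`` when a
    noise model is configured; logs the parameters, the derived rate
    constants and the tool version for provenance.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ParameterError(f"cannot create output directory {outdir}: {exc}") from exc

    rc = rate_constants(config.params)
    log.info(
        "turnoverkit %s simulate: params=%s rates k_M=%.6g D=%.6g V=%.6g k_P=%.6g /h "
        "(effective half-life %.6g h)",
        __version__,
        config.params,
        rc.k_m,
        rc.d,
        rc.v,
        rc.k_p,
        rc.effective_half_life,
    )
    tc = simulate(config.scenario, config.params)
    tc_path = outdir / "timecourse.csv"
    try:
        tc.write_csv(tc_path)
    except OSError as exc:
        raise ParameterError(f"cannot write {tc_path}: {exc}") from exc

    ms = None
    if config.noise is not None:
        ms = sample_measurements(tc, config.channel, config.noise)
        ms_path = outdir / "measurements.csv"
        try:
            ms.write_csv(ms_path)
        except OSError as exc:
            raise ParameterError(f"cannot write {ms_path}: {exc}") from exc
    return tc, ms


def run_fit(table_path, method: str = "nonlinear_1exp", concept: str = "apparent") -> HalfLifeEstimate:
    """Fit a half-life to a measurement table (or a noiseless time course).

    Accepts the ``time_h,replicate,signal`` measurement format; if the
    table instead carries time-course columns, the total-protein channel
    is converted to a single noiseless replicate first.
    """
    import pandas as pd

    try:
        df = pd.read_csv(table_path)
    except OSError as exc:
        raise ParameterError(f"cannot read {table_path}: {exc}") from exc
    if {"time_h", "replicate", "signal"} <= set(df.columns):
        ms = read_measurements(table_path)
    elif "protein_total" in df.columns:
        tc = TimeCourse.from_frame(df)
        ms = sample_measurements(tc, "total", NoiseModel(cv=0.0, replicates=1, seed=0))
    else:
        raise ParameterError(
            f"{table_path}: expected columns (time_h, replicate, signal) or a time-course table"
        )
    est = fit_half_life(ms, method=method, concept=concept)
    log.info(
        "turnoverkit %s fit: method=%s concept=%s half_life=%.6g h rate=%.6g /h stderr=%s",
        __version__,
        est.method,
        est.concept,
        est.half_life,
        est.rate,
        est.stderr,
    )
    return est
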