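"""Readers, writers, bundled reference tables, configuration and pipeline.

Units are fixed pipeline-wide: seconds, mol/L, kJ/mol, L mol^-1 s^-1.  Time
columns must be named ``time_s``; a differently unit-annotated time header is
rejected rather than converted silently.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .correlation import BDERecord
from .model import TimeCourse

REPORT_SCHEMA_VERSION = "1.0"

#: Negative concentrations beyond this magnitude fail validation, mol/L.
NEGATIVE_TOLERANCE = 1e-9


# ---------------------------------------------------------------------------
# time-course serialization


def write_timecourse(tc: TimeCourse, path: str | Path) -> None:
    """Write a time course as CSV, lossless to 12 significant digits."""
    tc.frame.to_csv(path, index=False, float_format="%.12e")


def read_timecourse(path: str | Path, provenance: str = "measured") -> TimeCourse:
    """Read a ``time_s, <species>...`` CSV into a :class:`TimeCourse`.

    Unknown columns are preserved as additional species columns.  Errors on
    a missing/misnamed time column, non-monotone times (naming the offending
    rows), and negative concentrations beyond tolerance.
    """
    frame = pd.read_csv(path)
    time_like = [c for c in frame.columns if c.lower().startswith("time")]
    if "time_s" not in frame.columns:
        if time_like:
            raise ValueError(
                f"time column must be named 'time_s' (seconds); found {time_like!r} — "
                "convert units explicitly instead of relying on the reader"
            )
        raise ValueError("CSV lacks the mandatory 'time_s' column")
    if len(time_like) > 1:
        raise ValueError(f"multiple time-like columns {time_like!r}; keep only 'time_s'")
    if len(frame.columns) < 2:
        raise ValueError("CSV needs at least one species column")
    for col in frame.columns:
        if col == "time_s":
            continue
        vals = frame[col].to_numpy(dtype=float)
        if np.any(vals < -NEGATIVE_TOLERANCE):
            bad = np.where(vals < -NEGATIVE_TOLERANCE)[0]
            raise ValueError(
                f"column {col!r} has negative concentrations at rows {bad.tolist()}"
            )
        frame[col] = np.clip(vals, 0.0, None)
    return TimeCourse(frame, provenance=provenance, meta={"source": str(path)})


# ---------------------------------------------------------------------------
# bundled reference tables


def _data_path(name: str):
    return resources.files("oxcascade.data").joinpath(name)


def load_rate_constant_table() -> pd.DataFrame:
    """Measured second-order rate constants k with standard deviations dk.

    Columns: base, cascade, step, measurement (direct/indirect), k, dk
    (L mol^-1 s^-1).
    """
    with resources.as_file(_data_path("table2_rate_constants.csv")) as p:
        return pd.read_csv(p)


def load_bde_table() -> pd.DataFrame:
    """Calculated BDE(C-H) values with measured/inferred rate constants."""
    with resources.as_file(_data_path("table3_bde_records.csv")) as p:
        return pd.read_csv(p)


def load_bde_records() -> list[BDERecord]:
    """The BDE table as :class:`BDERecord` objects (ln k recomputed from k)."""
    df = load_bde_table()
    return [
        BDERecord(
            base=row.base,
            bde=float(row.bde_kj_mol),
            k=float(row.k),
            series=row.series,
            inferred=bool(row.inferred),
        )
        for row in df.itertuples()
    ]


def load_constants() -> dict:
    """Reference experimental constants (k_TM, concentrations, K values)."""
    with resources.as_file(_data_path("constants.json")) as p:
        return json.loads(p.read_text())


# ---------------------------------------------------------------------------
# configuration


class DesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    substrate_init: float = 2.0e-4
    oxidant_init: float = 1.0e-3
    n_times: int = 12
    t_min: float = 60.0
    t_max: float = 86_400.0
    standard_conc: float = 2.0e-4
    start_species: Literal["5hm", "5f"] = "5hm"


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    integral_cv: float = 0.02
    loss_rate: Optional[float] = None  # None -> default (~70% recovery at 1 day)
    acid_extra_loss_rate: float = 0.0
    detection_limit: float = 2.0e-6


class SynthConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    variant: Literal["direct", "hydrate_route", "dual"] = "direct"
    k_TM: float = 1.75e-5
    k_hm: float = 0.0
    k_f: float = 0.0
    k_dhm: float = 0.0
    k_for: float = 1000.0
    K: Optional[float] = None
    design: DesignConfig = Field(default_factory=DesignConfig)
    noise: Optional[NoiseConfig] = None


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    variant: Literal["direct", "hydrate_route", "dual"] = "direct"
    k_TM: float = 1.75e-5
    K: Optional[float] = None
    start: Literal["hm", "f"] = "hm"
    exclude_acid: bool = True
    t_cut: Optional[float] = 86_400.0
    oxidant_init: Optional[float] = None


class CompareConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_hm: float
    k_TM: float = 1.75e-5
    K: float
    oxidant_init: Optional[float] = None
    exclude_acid: bool = True
    t_cut: Optional[float] = 86_400.0


class CorrelateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    series: list[str] = Field(default_factory=lambda: ["hm"])
    records_csv: Optional[str] = None  # default: bundled BDE table
    include_inferred: bool = True


class PipelineConfig(BaseModel):
    """Declarative pipeline configuration (YAML on disk)."""

    model_config = ConfigDict(extra="forbid")
    stages: list[Literal["synth", "fit", "compare", "correlate"]] = Field(
        default_factory=list
    )
    seed: int = 0
    input_timecourse: Optional[str] = None
    synth: Optional[SynthConfig] = None
    fit: Optional[FitConfig] = None
    compare: Optional[CompareConfig] = None
    correlate: Optional[CorrelateConfig] = None

    @model_validator(mode="after")
    def _check_consistency(self) -> "PipelineConfig":
        if self.input_timecourse is not None and self.synth is not None:
            raise ValueError(
                "config names both a measured input_timecourse and synth settings; "
                "choose one data source"
            )
        for stage in self.stages:
            if getattr(self, stage) is None and stage != "synth":
                raise ValueError(f"stage {stage!r} listed but not configured")
        if "synth" in self.stages and self.synth is None:
            raise ValueError("stage 'synth' listed but not configured")
        if ("fit" in self.stages or "compare" in self.stages) and (
            self.input_timecourse is None and "synth" not in self.stages
        ):
            raise ValueError("fit/compare stages need input_timecourse or a synth stage")
        return self


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline


def _synth_stage(cfg: SynthConfig, seed: int, out_dir: Path) -> tuple[TimeCourse, dict]:
    from .model import RateParameters, build_cascade
    from .synthdata import (
        ExperimentDesign,
        NoiseLossModel,
        default_sample_times,
        generate_timecourse,
        DEFAULT_LOSS_RATE,
    )

    params = RateParameters(
        k_TM=cfg.k_TM, k_hm=cfg.k_hm, k_f=cfg.k_f, k_dhm=cfg.k_dhm, k_for=cfg.k_for
    )
    model = build_cascade(cfg.variant, params, cfg.K)
    design = ExperimentDesign(
        substrate_init=cfg.design.substrate_init,
        oxidant_init=cfg.design.oxidant_init,
        sample_times=default_sample_times(cfg.design.n_times, cfg.design.t_min, cfg.design.t_max),
        standard_conc=cfg.design.standard_conc,
        start_species=cfg.design.start_species,
    )
    noise = None
    if cfg.noise is not None:
        noise = NoiseLossModel(
            integral_cv=cfg.noise.integral_cv,
            loss_rate=cfg.noise.loss_rate if cfg.noise.loss_rate is not None else DEFAULT_LOSS_RATE,
            acid_extra_loss_rate=cfg.noise.acid_extra_loss_rate,
            detection_limit=cfg.noise.detection_limit,
        )
    tc, integrals = generate_timecourse(model, design, noise, seed=seed)
    write_timecourse(tc, out_dir / "timecourse.csv")
    integrals.to_csv(out_dir / "integrals.csv", index=False, float_format="%.12e")
    truth = {
        "variant": cfg.variant,
        "params": params.as_dict(),
        "K": cfg.K,
        "seed": seed,
        "design": cfg.design.model_dump(),
        "noise": cfg.noise.model_dump() if cfg.noise else None,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return tc, {"files": ["timecourse.csv", "integrals.csv", "truth.json"], "truth": truth}


def _fit_stage(cfg: FitConfig, tc: TimeCourse, out_dir: Path) -> dict:
    from .fitting import fit_direct_start, fit_staged
    from .model import RateParameters, build_cascade
    from .fitting import rmsd_tot as rmsd_tot_fn

    if cfg.start == "f":
        fit = fit_direct_start(
            tc, cfg.variant, cfg.k_TM, cfg.K,
            oxidant_init=cfg.oxidant_init, exclude_acid=cfg.exclude_acid, t_cut=cfg.t_cut,
        )
        report = {"direct_start": fit.to_dict()}
    else:
        f1, f2 = fit_staged(
            tc, cfg.variant, cfg.k_TM, cfg.K,
            oxidant_init=cfg.oxidant_init, exclude_acid=cfg.exclude_acid, t_cut=cfg.t_cut,
        )
        report = {"step1": f1.to_dict(), "step2": f2.to_dict()}
    return report


def _compare_stage(cfg: CompareConfig, tc: TimeCourse) -> dict:
    from .fitting import compare_pathways

    ranked = compare_pathways(
        tc, cfg.k_hm, cfg.k_TM, cfg.K,
        oxidant_init=cfg.oxidant_init, exclude_acid=cfg.exclude_acid, t_cut=cfg.t_cut,
    )
    return {"ranking": [r.to_dict() for r in ranked]}


def _correlate_stage(cfg: CorrelateConfig) -> dict:
    from .correlation import lnk_bde_regression, select_series

    if cfg.records_csv is not None:
        df = pd.read_csv(cfg.records_csv)
        records = [
            BDERecord(
                base=row.base, bde=float(row.bde_kj_mol), k=float(row.k),
                series=row.series, inferred=bool(getattr(row, "inferred", False)),
            )
            for row in df.itertuples()
        ]
    else:
        records = load_bde_records()
    chosen = select_series(records, *cfg.series)
    if not cfg.include_inferred:
        chosen = [r for r in chosen if not r.inferred]
    corr = lnk_bde_regression(chosen)
    return {
        "series": cfg.series,
        "slope_per_kj_mol": corr.slope,
        "intercept": corr.intercept,
        "r_squared": corr.r_squared,
        "n": corr.n,
        "members": list(corr.members),
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages and write ``report.json``.

    Per-stage failures are recorded in the report (``success: false``)
    without aborting later stages; callers should exit nonzero when the
    overall ``success`` flag is false.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software_version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "stages": {},
        "success": True,
    }
    tc: TimeCourse | None = None
    if config.input_timecourse is not None:
        tc = read_timecourse(config.input_timecourse)
    for stage in config.stages:
        try:
            if stage == "synth":
                tc, info = _synth_stage(config.synth, config.seed, out_dir)
                report["stages"]["synth"] = {"success": True, **info}
            elif stage == "fit":
                if tc is None:
                    raise ValueError("fit stage has no input time course")
                report["stages"]["fit"] = {"success": True, **_fit_stage(config.fit, tc, out_dir)}
            elif stage == "compare":
                if tc is None:
                    raise ValueError("compare stage has no input time course")
                report["stages"]["compare"] = {"success": True, **_compare_stage(config.compare, tc)}
            elif stage == "correlate":
                report["stages"]["correlate"] = {"success": True, **_correlate_stage(config.correlate)}
        except Exception as exc:  # noqa: BLE001 - failures belong in the report
            report["stages"][stage] = {"success": False, "error": str(exc)}
            report["success"] = False
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
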