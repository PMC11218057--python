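"""End-to-end orchestration: design → simulate/ingest → metrics → fit → optimize.

The pipeline is a sequence of pure library calls with stable on-disk formats
(CSV for tables, JSON for models/setpoints, YAML config, Markdown report).
Every run writes a manifest naming the seeds, package version and input
checksums so a rerun with identical inputs is bit-identical apart from
timestamps.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import DesignTable, FactorSpec, interaction_model
from .kinetics import (
    GeometryConstants,
    ReactorSeries,
    diameter_stats,
    fit_growth_rate,
    qpcr_normalize,
    series_from_frame,
    stability_from_series,
)
from .modeling import (
    DEFAULT_TRANSFORMS,
    correlation_matrix,
    fit_campaign,
    normalize_to_center_points,
)
from .optimize import Criterion, optimize_setpoint

__all__ = [
    "PipelineConfig",
    "assemble_responses",
    "default_normalized_columns",
    "run_pipeline",
    "validate_tables",
    "read_factors",
    "read_criteria",
]

# signed, near-zero responses are excluded from multiplicative batch
# normalization by default (dividing by a near-zero center mean is unstable)
UNNORMALIZED_RESPONSES = {"aggregate_pct_error"}


def assemble_responses(
    design: DesignTable,
    series: list[ReactorSeries],
    endpoints: pd.DataFrame | None = None,
    geom: GeometryConstants = GeometryConstants(),
    day_initial: int = 1,
    day_final: int = 3,
) -> pd.DataFrame:
    """Build the per-run response table from time series and endpoint assays.

    Kinetics-derived columns: growth_rate (K), doubling_time, day3_diameter,
    diameter_sd, diameter_slope, aggregate_pct_error, cell_concentration
    (last-day mean count).  Endpoint columns are passed through, with qPCR Ct
    pairs decoded to expression units (1000/2^ΔCt).
    """
    rows = {}
    for s in series:
        growth = fit_growth_rate(s)
        stats_df, slope = diameter_stats(s)
        stab = stability_from_series(s, geom, day_initial, day_final)
        last_day = max(s.counts)
        d3 = float(
            stats_df.loc[stats_df["day"] == day_final, "mean"].iloc[0]
        )
        rows[s.run_id] = {
            "growth_rate": growth.K,
            "doubling_time": growth.doubling_time,
            "day3_diameter": d3,
            "diameter_sd": stab.diameter_sd,
            "diameter_slope": stab.diameter_slope,
            "aggregate_pct_error": stab.pct_error,
            "cell_concentration": float(s.counts[last_day].mean()),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "run_id"
    df = df.loc[[r for r in design.run_ids if r in df.index]]
    if endpoints is not None:
        ep = endpoints.copy()
        ct_cols = [c for c in ep.columns if c.startswith("ct_") and c != "ct_housekeeping"]
        if ct_cols and "ct_housekeeping" in ep.columns:
            for c in ct_cols:
                gene = c[len("ct_") :]
                ep[f"{gene}_qpcr"] = qpcr_normalize(ep[c], ep["ct_housekeeping"])
            ep = ep.drop(columns=ct_cols + ["ct_housekeeping"])
        df = df.join(ep, how="left")
    return df


def default_normalized_columns(responses: pd.DataFrame) -> list[str]:
    return [
        c
        for c in responses.columns
        if pd.api.types.is_numeric_dtype(responses[c]) and c not in UNNORMALIZED_RESPONSES
    ]


@dataclass
class PipelineConfig:
    """Paths, constants and options for a full pipeline run."""

    outdir: Path = Path("pipeline_out")
    factors_csv: Path | None = None
    design_csv: Path | None = None
    series_csv: Path | None = None
    endpoints_csv: Path | None = None
    criteria_yaml: Path | None = None
    geometry: GeometryConstants = field(default_factory=GeometryConstants)
    transforms: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    normalize: bool = True
    n_runs: int = 16
    n_center: int = 3
    n_batches: int = 2
    seed: int = 0
    simulate: bool = False  # generate synthetic series when no series_csv
    verbose: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        geom = GeometryConstants(**raw.pop("geometry", {}))
        kwargs = {}
        for key in (
            "outdir", "factors_csv", "design_csv", "series_csv",
            "endpoints_csv", "criteria_yaml",
        ):
            if key in raw and raw[key] is not None:
                kwargs[key] = Path(raw.pop(key))
            else:
                raw.pop(key, None)
        for key in (
            "transforms", "normalize", "n_runs", "n_center",
            "n_batches", "seed", "simulate", "verbose",
        ):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(geometry=geom, **kwargs)


def read_factors(path: str | Path) -> list[FactorSpec]:
    df = pd.read_csv(path)
    required = {"name", "low", "high"}
    if not required <= set(df.columns):
        raise ValueError(f"factors file needs columns {sorted(required)}")
    return [
        FactorSpec(
            str(r["name"]), float(r["low"]), float(r["high"]),
            str(r.get("units", "")) if "units" in df.columns else "",
        )
        for _, r in df.iterrows()
    ]


def read_criteria(path: str | Path) -> list[Criterion]:
    raw = yaml.safe_load(Path(path).read_text())
    out = []
    for name, spec in raw.items():
        out.append(
            Criterion(
                response=name,
                goal=spec["goal"],
                lower=float(spec["lower"]),
                upper=float(spec["upper"]),
                target=float(spec["target"]) if "target" in spec else None,
                weight=float(spec.get("weight", 1.0)),
            )
        )
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(cfg: PipelineConfig, msg: str) -> None:
    if cfg.verbose:
        print(f"[aggdoe] {msg}", file=sys.stderr)


def validate_tables(
    design: DesignTable | None = None,
    series_df: pd.DataFrame | None = None,
    responses: pd.DataFrame | None = None,
) -> list[str]:
    """Schema and invariant checks; returns a list of diagnostics (empty = ok)."""
    diags: list[str] = []
    if design is not None:
        if len(set(design.run_ids)) != len(design.run_ids):
            diags.append("design: duplicate run_id")
        if np.any(np.abs(design.coded) > 1 + 1e-9):
            diags.append("design: coded levels outside [-1, +1]")
        center = design.coded[design.is_center]
        if center.size and np.any(np.abs(center) > 1e-9):
            diags.append("design: center rows with nonzero coded levels")
    if series_df is not None:
        need = {"run_id", "day", "measurement_type", "replicate", "value"}
        if not need <= set(series_df.columns):
            diags.append(f"series: missing columns {sorted(need - set(series_df.columns))}")
        else:
            bad = series_df[
                series_df["measurement_type"].isin(["count", "diameter"])
                & (series_df["value"] <= 0)
            ]
            for _, r in bad.iterrows():
                diags.append(
                    f"series: nonpositive {r['measurement_type']} for run "
                    f"{r['run_id']} day {int(r['day'])}"
                )
            if design is not None:
                for run_id in pd.unique(series_df["run_id"]):
                    if str(run_id) not in design.run_ids:
                        diags.append(f"series: unknown run_id {run_id!r}")
                per_run = series_df[series_df["measurement_type"] == "diameter"]
                for run_id in design.run_ids:
                    days = set(per_run.loc[per_run["run_id"] == run_id, "day"])
                    for needed in (1, 3):
                        if days and needed not in days:
                            diags.append(
                                f"series: run {run_id} missing diameter day {needed}"
                                " (stability metric will be undefined)"
                            )
    if responses is not None:
        pct_cols = [c for c in responses.columns if c.endswith("_flow") or c == "viability"]
        for c in pct_cols:
            vals = responses[c].dropna()
            if ((vals < 0) | (vals > 100)).any():
                diags.append(f"responses: {c} outside [0, 100]")
    return diags


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "aggdoe_version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
    }

    # --- stage 1: design -------------------------------------------------
    from .simulate import paper_shape_design  # deferred: optional stage deps

    if config.factors_csv:
        factors = read_factors(config.factors_csv)
        manifest["inputs"]["factors_csv"] = _sha256(Path(config.factors_csv))
    else:
        from .design import default_factors

        factors = default_factors()
    model = interaction_model(factors)
    if config.design_csv:
        design = DesignTable.read_csv(config.design_csv, factors)
        manifest["inputs"]["design_csv"] = _sha256(Path(config.design_csv))
    else:
        design = paper_shape_design(
            n_runs=config.n_runs, n_center=config.n_center,
            n_batches=config.n_batches, seed=config.seed, factors=factors,
        )
    design.write_csv(out / "design.csv")
    manifest["stages"]["design"] = "design.csv"
    _log(config, f"design: {design.n_runs} runs ({int(design.is_center.sum())} center)")

    # --- stage 2: series (measured or simulated) -------------------------
    endpoints = None
    if config.series_csv:
        series_df = pd.read_csv(config.series_csv)
        manifest["inputs"]["series_csv"] = _sha256(Path(config.series_csv))
    elif config.simulate:
        from .kinetics import series_to_frame
        from .simulate import simulate_campaign

        campaign = simulate_campaign(design, seed=config.seed)
        series_df = series_to_frame(campaign.series)
        endpoints = campaign.endpoints
    else:
        raise ValueError("no series_csv given and simulate=False")
    diags = validate_tables(design, series_df)
    hard = [d for d in diags if "nonpositive" in d or "unknown run_id" in d]
    if hard:
        raise ValueError("; ".join(hard))
    series_df.to_csv(out / "series.csv", index=False)
    manifest["stages"]["series"] = "series.csv"

    if config.endpoints_csv:
        endpoints = pd.read_csv(config.endpoints_csv).set_index("run_id")
        manifest["inputs"]["endpoints_csv"] = _sha256(Path(config.endpoints_csv))

    # --- stage 3: metrics -> responses -----------------------------------
    series = series_from_frame(series_df)
    responses = assemble_responses(design, series, endpoints, config.geometry)
    if config.normalize:
        responses = normalize_to_center_points(
            responses, design, columns=default_normalized_columns(responses)
        )
    responses.to_csv(out / "responses.csv")
    manifest["stages"]["responses"] = "responses.csv"
    _log(config, f"responses: {responses.shape[1]} variables x {responses.shape[0]} runs")

    # --- stage 4: fit -----------------------------------------------------
    fits = fit_campaign(design, responses, model, transforms=config.transforms)
    models_json = {name: fm.to_dict() for name, fm in fits.items()}
    (out / "models.json").write_text(json.dumps(models_json, indent=1, sort_keys=True))
    manifest["stages"]["models"] = "models.json"
    metric_rows = [
        {
            "response": name,
            "r2": fm.r2, "q2": fm.q2,
            "validity": fm.validity, "reproducibility": fm.reproducibility,
        }
        for name, fm in fits.items()
    ]
    metrics = pd.DataFrame(metric_rows).set_index("response")
    r, p = correlation_matrix(responses.dropna(axis=1, how="any"))
    r.to_csv(out / "corr.csv")
    manifest["stages"]["corr"] = "corr.csv"

    # --- stage 5: optimize ------------------------------------------------
    setpoint = None
    if config.criteria_yaml:
        criteria = read_criteria(config.criteria_yaml)
        manifest["inputs"]["criteria_yaml"] = _sha256(Path(config.criteria_yaml))
        setpoint = optimize_setpoint(fits, criteria, seed=config.seed, factors=factors)
        (out / "setpoint.json").write_text(
            json.dumps(setpoint.to_dict(), indent=1, sort_keys=True)
        )
        manifest["stages"]["setpoint"] = "setpoint.json"
        _log(config, f"setpoint D = {setpoint.desirability:.3f}")

    # --- report -----------------------------------------------------------
    lines = ["# aggdoe pipeline report", ""]
    lines += [f"- package version: {__version__}", f"- seed: {config.seed}", ""]
    lines += ["## Model quality", "", "```", metrics.round(4).to_string(), "```", ""]
    lines += ["## Coefficients (coded units)", ""]
    for name, fm in fits.items():
        lines += [f"### {name} ({fm.transform})", "", "```",
                  fm.coef_table().round(4).to_string(), "```", ""]
    if setpoint is not None:
        lines += ["## Optimizer setpoint", "", "```json",
                  json.dumps(setpoint.to_dict(), indent=1, sort_keys=True), "```", ""]
    if diags:
        lines += ["## Diagnostics", ""] + [f"- {d}" for d in diags] + [""]
    (out / "report.md").write_text("\n".join(lines))
    manifest["stages"]["report"] = "report.md"
    manifest["runtime_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    _log(config, f"done in {manifest['runtime_s']} s -> {out}")
    return manifest
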