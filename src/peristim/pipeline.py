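"""Pipeline orchestration: dosimetry → field simulation → adverse events.

:func:`run_pipeline` executes the analysis stages described by a
:class:`~peristim.config.RunConfig` and writes four CSV outputs mirroring the
customary reporting tables, plus a run log:

* ``dose_table.csv`` — electrode-level dose metrics per session, with the
  published safety-limit rows on top;
* ``margins.csv`` — safety margins (ratio and orders of magnitude) of the
  electrode metrics and of the published benchmark field summary against the
  published limits;
* ``field_summary.csv`` — per-region field statistics of the solved phantom
  (skipped when the config has no phantom section);
* ``ae_results.csv`` — incidence percentages, frequency categories and
  exact-test p-values per adverse event.

Any stage failure aborts the run with a stage-labelled error; the log records
which outputs were completed so partial results are identifiable.
"""

from __future__ import annotations

import logging
import math
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__, reference
from .adverse_events import (ContingencyTable2x2, PairedRatings,
                             compare_conditions, incidence_summary)
from .config import RunConfig, sessions_from_config
from .dosimetry import build_dose_table, round_to_printed, safety_margin
from .phantom import PhantomParameters, build_synthetic_head, phantom_conductivities
from .volume_conductor import (assemble_system, field_maps, margin_report,
                               solve_potential, summarize_fields)

__all__ = ["PipelineError", "ReportBundle", "run_pipeline"]

logger = logging.getLogger("peristim")

#: dose-table column -> metric name understood by the safety limits
_DOSE_METRICS = {
    "current_density_mA_cm2": "current_density",
    "charge_density_C_cm2": "charge_density",
    "charge_density_per_phase_C_cm2ph": "charge_density_per_phase",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ReportBundle:
    """Everything one pipeline run produced."""

    dose_table: pd.DataFrame
    margins: pd.DataFrame
    ae_results: pd.DataFrame
    field_summary: Optional[pd.DataFrame] = None
    outputs: Dict[str, Path] = field(default_factory=dict)
    solver_info: Dict[str, float] = field(default_factory=dict)


def _rounded(df: pd.DataFrame, precision: Dict[str, int]) -> pd.DataFrame:
    out = df.copy()
    for column, decimals in precision.items():
        if column in out.columns:
            out[column] = out[column].map(
                lambda v: round_to_printed(v, decimals)
                if isinstance(v, (int, float)) and not (
                    isinstance(v, float) and math.isnan(v)) else v)
    return out


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, na_rep="–", lineterminator="\n")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-labelled and re-raised
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("dosimetry")
def _run_dosimetry(cfg: RunConfig):
    sessions = sessions_from_config(cfg)
    table = build_dose_table(sessions,
                             duty_cycle_corrected=cfg.duty_cycle_corrected)
    if cfg.sessions is None:
        # packaged comparison: published limit rows verbatim on top
        limit_rows = pd.DataFrame(reference.SAFETY_LIMIT_TABLE_ROWS)
        for column in limit_rows.columns:
            if column != "label":
                limit_rows[column] = limit_rows[column].astype(float)
        table = pd.concat([limit_rows, table], ignore_index=True)

    limits = cfg.safety_limits()
    margin_rows = []
    for _, row in table.iterrows():
        if str(row["label"]).startswith("Safety limits"):
            continue
        for column, metric in _DOSE_METRICS.items():
            value = row[column]
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue
            for limit in limits:
                if limit.metric != metric:
                    continue
                rep = safety_margin(float(value), limit, metric=metric)
                margin_rows.append({
                    "region": row["label"], "metric": metric,
                    "statistic": "electrode-level", "value": rep.value,
                    "unit": limit.unit, "limit_value": limit.value,
                    "limit_source": limit.source, "ratio": rep.ratio,
                    "orders_of_magnitude": rep.orders_of_magnitude,
                    "within_limit": rep.within_limit,
                })
    return table, pd.DataFrame(margin_rows), limits


@_stage("field-simulation")
def _run_field_stage(cfg: RunConfig, out_dir: Path):
    opts = dict(cfg.phantom or {})
    total_current = float(opts.pop("total_current_ua", 350.0)) * 1e-6
    rtol = float(opts.pop("rtol", 1e-6))
    export_nifti = bool(opts.pop("export_nifti", False))
    export_vtk = bool(opts.pop("export_vtk", False))
    params = PhantomParameters(**opts)
    volume, source = build_synthetic_head(params)
    source = source.scaled(total_current)
    table = phantom_conductivities()
    system = assemble_system(volume, table, source)
    t0 = time.perf_counter()
    solution = solve_potential(system, rtol=rtol)
    elapsed = time.perf_counter() - t0
    fields = field_maps(solution, volume, table)
    summary = summarize_fields(fields, volume)
    info = {"iterations": solution.iterations,
            "residual": solution.residual,
            "unknowns": int(system.matrix.shape[0]),
            "solve_seconds": elapsed}
    if export_nifti or export_vtk:
        from . import gridio
        if export_nifti:
            gridio.save_labels_nifti(volume, out_dir / "phantom_labels.nii")
            gridio.save_map_nifti(fields.j_magnitude, volume,
                                  out_dir / "j_magnitude_A_per_m2.nii")
            gridio.save_map_nifti(fields.e_magnitude, volume,
                                  out_dir / "e_magnitude_V_per_m.nii")
        if export_vtk:
            gridio.write_vtk_structured_points(
                out_dir / "fields.vtk", volume,
                {"j_magnitude": fields.j_magnitude,
                 "e_magnitude": fields.e_magnitude})
    return summary, info


@_stage("adverse-events")
def _run_ae_stage(cfg: RunConfig):
    section = cfg.adverse_events or {}
    if "counts_csv" in section:
        counts = pd.read_csv(section["counts_csv"])
        required = {"event", "phase", "condition", "k", "n"}
        if not required.issubset(counts.columns):
            raise ValueError(f"counts table must have columns {sorted(required)}")
    else:
        rows = []
        for event, phase, k_racs, k_ps in reference.ADVERSE_EVENT_COUNTS:
            rows.append(("rACS", event, phase, k_racs, reference.GROUP_SIZE))
            rows.append(("PS", event, phase, k_ps, reference.GROUP_SIZE))
        counts = pd.DataFrame(
            rows, columns=["condition", "event", "phase", "k", "n"])

    tables: List[ContingencyTable2x2] = []
    for (event, phase), grp in counts.groupby(["event", "phase"], sort=False):
        by_cond = {str(r.condition): (int(r.k), int(r.n))
                   for r in grp.itertuples()}
        if set(by_cond) != {"rACS", "PS"}:
            raise ValueError(f"event {event!r}/{phase!r} needs both conditions")
        (k1, n1), (k2, n2) = by_cond["rACS"], by_cond["PS"]
        tables.append(ContingencyTable2x2(k1, n1 - k1, k2, n2 - k2,
                                          ("rACS", "PS"), event, phase))

    ratings = None
    if section.get("ratings_csv"):
        frame = pd.read_csv(section["ratings_csv"])
        ratings = {}
        for phase in ("during", "after"):
            a, b = f"rACS_{phase}", f"PS_{phase}"
            if a in frame.columns and b in frame.columns:
                ratings[f"pain (overall)/{phase}"] = PairedRatings(
                    tuple(int(v) for v in frame[a].fillna(0)),
                    tuple(int(v) for v in frame[b].fillna(0)))

    results = compare_conditions(tables, ratings,
                                 bonferroni=bool(section.get("bonferroni")))
    incid = incidence_summary(
        [(f"{r.event} [{r.condition}]", r.phase, int(r.k), int(r.n))
         for r in counts.itertuples()])
    return results, incid


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute all configured stages and write the CSV report bundle."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, cfg.verbosity.upper(), logging.INFO))
    outputs: Dict[str, Path] = {}
    try:
        logger.info("peristim %s | python %s | numpy %s | seed %d",
                    __version__, sys.version.split()[0],
                    np.__version__, cfg.seed)

        dose_table, dose_margins, limits = _run_dosimetry(cfg)
        path = out_dir / "dose_table.csv"
        _write_csv(_rounded(dose_table, cfg.precision), path)
        outputs["dose_table"] = path
        logger.info("dose stage complete: %d rows", len(dose_table))

        field_summary, solver_info = None, {}
        if cfg.phantom is not None:
            summary, solver_info = _run_field_stage(cfg, out_dir)
            field_summary = summary.table
            path = out_dir / "field_summary.csv"
            _write_csv(field_summary, path)
            outputs["field_summary"] = path
            logger.info("field stage complete: %d unknowns, %d CG iterations, "
                        "residual %.2e (%.1f s)", solver_info["unknowns"],
                        solver_info["iterations"], solver_info["residual"],
                        solver_info["solve_seconds"])
        else:
            logger.info("field stage skipped (no phantom section)")

        # margins: electrode-level + published FEM benchmark fields
        benchmark = margin_report(reference.published_field_summary(),
                                  [l for l in limits
                                   if l.metric in ("current_density",
                                                   "electric_field")])
        if len(benchmark):
            benchmark["statistic"] = "published benchmark max"
        margins = pd.concat([dose_margins, benchmark], ignore_index=True)
        path = out_dir / "margins.csv"
        _write_csv(margins, path)
        outputs["margins"] = path

        ae_results, incid = _run_ae_stage(cfg)
        merged = pd.concat([ae_results,
                            incid.rename(columns={"percent": "percent_incidence"})],
                           axis=0, ignore_index=True)
        path = out_dir / "ae_results.csv"
        _write_csv(merged, path)
        outputs["ae_results"] = path
        logger.info("adverse-event stage complete: %d tests", len(ae_results))

        logger.info("run complete; outputs: %s",
                    ", ".join(str(p) for p in outputs.values()))
        return ReportBundle(dose_table=dose_table, margins=margins,
                            ae_results=merged, field_summary=field_summary,
                            outputs=outputs, solver_info=solver_info)
    except PipelineError as exc:
        logger.error("%s; completed outputs: %s", exc,
                     ", ".join(outputs) or "none")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
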