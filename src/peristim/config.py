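"""Run configuration: one structured YAML document for the whole pipeline.

A config document has up to five sections:

``sessions``
    List of stimulation-session descriptors (label, amplitude_ua_pp,
    frequency_hz, area_cm2, duration_min, block_on_s, block_off_s, basis,
    omit).  When omitted, the packaged montage comparison set is used.
``limits``
    List of safety limits (source, metric, value, unit).  Defaults to the
    packaged published limits.
``phantom``
    Volume-conductor stage parameters (voxel_mm, total_current_ua, rtol,
    export_nifti, export_vtk, plus any :class:`~peristim.phantom.
    PhantomParameters` field).  Omit the section to skip the field stage.
``adverse_events``
    ``counts_csv`` (columns event, phase, condition, k, n) and optional
    ``ratings_csv`` (per-subject NRS-11 columns "<cond>_<phase>").  When the
    section is omitted the packaged published counts are used.
``output``
    ``directory`` and per-column rounding ``precision`` applied only at CSV
    serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import reference
from .dosimetry import ElectrodeSpec, SafetyLimit, StimulusWaveform

__all__ = ["RunConfig", "load_config", "default_config", "sessions_from_config"]

#: decimals per dose-table column at serialization, matching the customary
#: printed precision of dose-comparison tables
DEFAULT_PRECISION: Dict[str, int] = {
    "amplitude_mA": 2,
    "area_cm2": 3,
    "duration_min": 1,
    "frequency_Hz": 1,
    "current_density_mA_cm2": 2,
    "charge_density_C_cm2": 3,
    "charge_per_phase_C": 6,
    "charge_density_per_phase_C_cm2ph": 6,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    sessions: Optional[List[dict]] = None       # None -> packaged montages
    limits: Optional[List[dict]] = None         # None -> packaged limits
    phantom: Optional[dict] = None              # None -> skip field stage
    adverse_events: Optional[dict] = None       # None -> packaged counts
    output_dir: str = "peristim_out"
    precision: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PRECISION))
    duty_cycle_corrected: bool = False
    seed: int = 0
    verbosity: str = "INFO"

    def safety_limits(self) -> Tuple[SafetyLimit, ...]:
        if self.limits is None:
            return tuple(reference.SAFETY_LIMITS)
        return tuple(SafetyLimit(source=e["source"], metric=e["metric"],
                                 value=float(e["value"]),
                                 unit=e.get("unit", ""))
                     for e in self.limits)


def default_config() -> RunConfig:
    """The packaged study conditions: nominal periorbital AC session plus the
    literature comparison montages, published limits and counts, and the
    default 2 mm phantom."""
    return RunConfig(phantom={"voxel_mm": 2.0, "total_current_ua": 350.0,
                              "rtol": 1e-6})


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config document into a :class:`RunConfig`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**doc)
    if "precision" in doc:
        merged = dict(DEFAULT_PRECISION)
        merged.update(doc["precision"])
        cfg.precision = merged
    return cfg


def sessions_from_config(
    cfg: RunConfig,
) -> List[tuple]:
    """Materialize (label, waveform, electrode, options) session tuples."""
    if cfg.sessions is None:
        return list(reference.COMPARISON_MONTAGES)
    out = []
    for entry in cfg.sessions:
        frequency = entry.get("frequency_hz")
        waveform = StimulusWaveform(
            shape=entry.get("shape", "sine" if frequency else "dc"),
            peak_to_peak_amplitude=float(entry["amplitude_ua_pp"]),
            frequency=frequency,
            block_on=float(entry.get("block_on_s", 0.0)),
            block_off=float(entry.get("block_off_s", 0.0)),
            session_duration=float(entry.get("duration_min", 0.0)) * 60.0,
        )
        electrode = ElectrodeSpec(contact_area=float(entry["area_cm2"]))
        opts = {"basis": entry.get("basis", "peak")}
        if entry.get("omit"):
            opts["omit"] = tuple(entry["omit"])
        out.append((entry["label"], waveform, electrode, opts))
    return out
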