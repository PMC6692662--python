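"""Electrode-level dose metrics for weak-current electrical stimulation.

The quantities computed here are the standard predictors of stimulation-induced
tissue damage: current density at the electrode (mA/cm²), charge density
integrated over the session (C/cm²), charge per phase (C) and charge density
per phase (C/(cm²·phase)) for charge-balanced alternating-current protocols.
Each metric can be compared against published animal-model damage limits
(e.g. Agnew & McCreery 1987; Liebetanz et al. 2009) to obtain a safety margin
expressed in orders of magnitude.

Conventions
-----------
* Waveform amplitudes are peak-to-peak, in μA, matching how clinical
  low-voltage stimulators report them; dose metrics are in mA-based units.
* The effective (RMS-equivalent) amplitude of a sine stimulus is
  ``a_pp / sqrt(2)``: the peak-to-peak value is treated as the driving
  amplitude and its RMS equivalent is reported.
* Charge uses the conservative rectangular estimate Q = I·t over the whole
  session (pauses included), deliberately over- rather than under-estimating
  the injected charge.  A duty-cycle-corrected charge is available but off by
  default.
* Charge per phase is the charge delivered over one full stimulus cycle,
  ``I / f``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DosimetryError",
    "MetricUndefinedError",
    "StimulusWaveform",
    "ElectrodeSpec",
    "DoseSummary",
    "SafetyLimit",
    "MarginReport",
    "effective_amplitude",
    "current_density",
    "charge_density",
    "charge_per_phase",
    "charge_density_per_phase",
    "safety_margin",
    "summarize_session",
    "build_dose_table",
    "round_to_printed",
]

WAVEFORM_SHAPES = ("sine", "sampled", "dc")

#: dose metric identifiers, shared with SafetyLimit
METRICS = (
    "current_density",          # mA/cm²
    "charge_density",           # C/cm²
    "charge_density_per_phase", # C/(cm²·phase)
    "electric_field",           # V/m
)


class DosimetryError(ValueError):
    """Invalid dosimetry input."""


class MetricUndefinedError(DosimetryError):
    """The requested metric is undefined for this waveform (e.g. charge per
    phase for a direct-current stimulus); callers report it as absent."""


@dataclass(frozen=True)
class StimulusWaveform:
    """Parametric or sampled AC/DC stimulus with block timing.

    Parameters
    ----------
    shape : {"sine", "sampled", "dc"}
    peak_to_peak_amplitude : float
        Peak-to-peak current in μA (for "dc", the constant current).
    frequency : float, optional
        Stimulation frequency in Hz; required for shape="sine".
    samples, sample_rate : optional
        For shape="sampled": current samples in μA and their rate in Hz.
    block_on, block_off, session_duration : float
        Block timing in seconds; e.g. 30 s on / 30 s off over a 600 s session.
    """

    shape: str
    peak_to_peak_amplitude: float
    frequency: Optional[float] = None
    samples: Optional[Sequence[float]] = None
    sample_rate: Optional[float] = None
    block_on: float = 0.0
    block_off: float = 0.0
    session_duration: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in WAVEFORM_SHAPES:
            raise DosimetryError(f"unknown waveform shape {self.shape!r}")
        if self.peak_to_peak_amplitude < 0:
            raise DosimetryError("peak_to_peak_amplitude must be >= 0")
        if self.shape == "sine" and (self.frequency is None or self.frequency <= 0):
            raise DosimetryError("sine waveform requires frequency > 0")
        if self.shape == "sampled":
            if self.samples is None or len(self.samples) == 0:
                raise DosimetryError("sampled waveform requires non-empty samples")
        for name in ("block_on", "block_off", "session_duration"):
            if getattr(self, name) < 0:
                raise DosimetryError(f"{name} must be >= 0")

    @property
    def duty_cycle(self) -> float:
        """Fraction of the session with current flowing (1.0 if no pauses)."""
        total = self.block_on + self.block_off
        return self.block_on / total if total > 0 else 1.0


@dataclass(frozen=True)
class ElectrodeSpec:
    """Physical electrode contact: area per contact (cm²), count, role."""

    contact_area: float
    n_contacts: int = 1
    role: str = "active"
    material: str = ""

    def __post_init__(self) -> None:
        if self.contact_area <= 0:
            raise DosimetryError("contact_area must be > 0")
        if self.n_contacts < 1:
            raise DosimetryError("n_contacts must be >= 1")


@dataclass(frozen=True)
class SafetyLimit:
    """A published tissue-damage limit for one dose metric."""

    source: str
    metric: str
    value: float
    unit: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise DosimetryError("safety limit value must be > 0")


@dataclass(frozen=True)
class MarginReport:
    """How far a measured dose metric sits below a safety limit."""

    metric: str
    value: float
    limit: SafetyLimit
    ratio: float
    orders_of_magnitude: float
    within_limit: bool


@dataclass(frozen=True)
class DoseSummary:
    """One row of a dose-comparison table (amplitudes in mA, area cm²,
    duration min; None marks a metric that is undefined or not reported)."""

    label: str
    amplitude: float
    area: float
    duration: Optional[float]
    frequency: Optional[float]
    effective_amplitude: Optional[float]
    current_density: float
    charge_density: Optional[float]
    charge_per_phase: Optional[float]
    charge_density_per_phase: Optional[float]


def effective_amplitude(waveform: StimulusWaveform) -> float:
    """RMS-equivalent amplitude of a stimulus, in μA.

    For a pure sine the closed form ``a_pp / sqrt(2)`` is used; sampled
    stimuli use the numerical RMS of their samples; a DC stimulus is its own
    effective amplitude.
    """
    if waveform.shape == "sine":
        return waveform.peak_to_peak_amplitude / math.sqrt(2.0)
    if waveform.shape == "sampled":
        samples = np.asarray(waveform.samples, dtype=float)
        return float(np.sqrt(np.mean(samples * samples)))
    return waveform.peak_to_peak_amplitude


def current_density(amplitude: float, area: float) -> float:
    """Current density in mA/cm² from amplitude (mA) and contact area (cm²)."""
    if area <= 0:
        raise DosimetryError("electrode area must be > 0")
    return amplitude / area


def charge_density(current_density: float, duration: float) -> float:
    """Session charge density in C/cm² from J (mA/cm²) and duration (s).

    Uses the rectangular estimate Q = I·t over the full duration; pass a
    duty-cycle-scaled duration for the less conservative variant.
    """
    if duration < 0:
        raise DosimetryError("duration must be >= 0")
    return current_density * 1e-3 * duration


def charge_per_phase(amplitude: float, frequency: Optional[float]) -> float:
    """Charge per stimulus cycle in C from amplitude (mA) and frequency (Hz)."""
    if frequency is None:
        raise MetricUndefinedError("charge per phase is undefined for DC stimuli")
    if frequency <= 0:
        raise DosimetryError("frequency must be > 0")
    return amplitude * 1e-3 / frequency


def charge_density_per_phase(charge_per_phase: float, area: float) -> float:
    """Per-phase charge density in C/(cm²·phase)."""
    if area <= 0:
        raise DosimetryError("electrode area must be > 0")
    return charge_per_phase / area


def safety_margin(
    value: float,
    limit: SafetyLimit,
    metric: Optional[str] = None,
) -> MarginReport:
    """Compare a dose metric against a safety limit.

    The margin is expressed as ``ratio = limit / value`` and as whole orders
    of magnitude ``floor(log10(ratio))`` — "two orders of magnitude below the
    limit" means the limit exceeds the value at least 100-fold.  A zero value
    yields an infinite ratio and is trivially within the limit.
    """
    if value < 0:
        raise DosimetryError("metric value must be >= 0")
    if metric is not None and metric != limit.metric:
        raise DosimetryError(
            f"metric mismatch: value is {metric!r}, limit is {limit.metric!r}"
        )
    if value == 0:
        return MarginReport(limit.metric, 0.0, limit, math.inf, math.inf, True)
    ratio = limit.value / value
    oom = math.floor(math.log10(ratio)) if ratio > 1 else 0
    return MarginReport(limit.metric, value, limit, ratio, oom, value < limit.value)


def summarize_session(
    label: str,
    waveform: StimulusWaveform,
    electrode: ElectrodeSpec,
    basis: str = "peak",
    duty_cycle_corrected: bool = False,
    omit: Sequence[str] = (),
) -> DoseSummary:
    """Compute the dose-table row for one stimulation session.

    Parameters
    ----------
    basis : {"peak", "effective"}
        Whether densities are computed from the peak-to-peak or the
        RMS-equivalent amplitude.  Peak-to-peak is the conservative default.
    duty_cycle_corrected : bool
        If True, charge accumulates only during on-blocks.  Off by default:
        the full-session estimate deliberately over-states injected charge.
    omit : sequence of str
        Metric names to blank (reported as absent); used when mirroring
        literature rows whose sources did not report a quantity.
    """
    if basis not in ("peak", "effective"):
        raise DosimetryError(f"unknown amplitude basis {basis!r}")
    a_eff_ua = effective_amplitude(waveform)
    a_ua = a_eff_ua if basis == "effective" else waveform.peak_to_peak_amplitude
    a_ma = a_ua * 1e-3
    area = electrode.contact_area
    duration_s = waveform.session_duration
    if duty_cycle_corrected:
        duration_s = duration_s * waveform.duty_cycle

    j = current_density(a_ma, area)
    q = charge_density(j, duration_s)
    try:
        q_ph: Optional[float] = charge_per_phase(a_ma, waveform.frequency)
        cd_ph: Optional[float] = charge_density_per_phase(q_ph, area)
    except MetricUndefinedError:
        q_ph = cd_ph = None

    row = DoseSummary(
        label=label,
        amplitude=a_ma,
        area=area,
        duration=waveform.session_duration / 60.0,
        frequency=waveform.frequency,
        effective_amplitude=a_eff_ua * 1e-3,
        current_density=j,
        charge_density=q,
        charge_per_phase=q_ph,
        charge_density_per_phase=cd_ph,
    )
    if omit:
        row = replace(row, **{name: None for name in omit})
    return row


#: column order of the emitted dose table
DOSE_TABLE_COLUMNS = [
    "label",
    "amplitude_mA",
    "area_cm2",
    "duration_min",
    "frequency_Hz",
    "current_density_mA_cm2",
    "charge_density_C_cm2",
    "charge_per_phase_C",
    "charge_density_per_phase_C_cm2ph",
]


def build_dose_table(
    sessions: Sequence[tuple],
    duty_cycle_corrected: bool = False,
) -> pd.DataFrame:
    """Build a dose-comparison table, one row per session.

    ``sessions`` is a non-empty sequence of ``(label, waveform, electrode)``
    or ``(label, waveform, electrode, options)`` tuples, where ``options`` is
    a dict understood by :func:`summarize_session` (``basis``, ``omit``).
    Rows appear in input order; undefined metrics (per-phase charge for DC)
    are NaN and serialize as "–".
    """
    if len(sessions) == 0:
        raise DosimetryError("sessions list must be non-empty")
    rows = []
    for entry in sessions:
        label, waveform, electrode, *rest = entry
        opts = dict(rest[0]) if rest else {}
        summary = summarize_session(
            label, waveform, electrode,
            duty_cycle_corrected=duty_cycle_corrected, **opts,
        )
        nan = float("nan")

        def _num(value):
            return nan if value is None else value

        rows.append(
            {
                "label": summary.label,
                "amplitude_mA": summary.amplitude,
                "area_cm2": summary.area,
                "duration_min": summary.duration,
                "frequency_Hz": _num(summary.frequency),
                "current_density_mA_cm2": summary.current_density,
                "charge_density_C_cm2": _num(summary.charge_density),
                "charge_per_phase_C": _num(summary.charge_per_phase),
                "charge_density_per_phase_C_cm2ph": _num(
                    summary.charge_density_per_phase),
            }
        )
    return pd.DataFrame(rows, columns=DOSE_TABLE_COLUMNS)


def round_to_printed(value: float, decimals: int) -> float:
    """Round half away from zero to a fixed number of decimals.

    Matches how printed tables round (0.025 → 0.03), unlike banker's
    rounding.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return value
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))
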