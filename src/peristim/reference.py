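"""Published reference values used for comparison and as generator defaults.

This module collects, as plain data:

* tissue-damage safety limits from the animal literature
  (Agnew & McCreery 1987; Liebetanz et al. 2009);
* dose parameters of related low-voltage stimulation protocols
  (Electrosleep, transcorneal electrical stimulation, tACS, tSDCS, tDCS)
  as printed in their sources, for side-by-side comparison;
* the nominal periorbital AC (rACS) session: 0.35 mA peak-to-peak sine at
  10 Hz over 0.35 cm² felt contacts, 30 s on / 30 s off for 10 min, with a
  9 cm² stainless-steel return at the neck;
* isotropic tissue conductivities (S/m) for the volume-conductor model;
* a published high-resolution FEM benchmark field summary for the periorbital
  montage (per-region max/mean/median current density and electric field),
  used as input to the order-of-magnitude margin report;
* adverse-event counts and pain-rating moments from a 20-subject periorbital
  stimulation vs. photic stimulation tolerability cohort, used as defaults
  for the synthetic cohort generator.

Literature limit rows are stored exactly as printed in their sources and are
never recomputed here.
"""

from __future__ import annotations

import pandas as pd

from .dosimetry import ElectrodeSpec, SafetyLimit, StimulusWaveform

# --------------------------------------------------------------------------
# Safety limits
# --------------------------------------------------------------------------

#: charge-density-per-phase and current-density limits for neural damage
AGNEW_MCCREERY_LIMITS = (
    SafetyLimit("Agnew & McCreery (1987)", "current_density", 25.0, "mA/cm^2"),
    SafetyLimit("Agnew & McCreery (1987)", "charge_density_per_phase",
                0.000400, "C/(cm^2*ph)"),
)

#: brain-lesion thresholds from a rat tDCS model; the electric-field limit
#: (42 V/m) and the current-density limit (14.29 mA/cm² == 14.9 A/m² at the
#: printed precision of the source table) apply to distributed tissue metrics
LIEBETANZ_LIMITS = (
    SafetyLimit("Liebetanz et al. (2009)", "current_density", 14.29, "mA/cm^2"),
    SafetyLimit("Liebetanz et al. (2009)", "electric_field", 42.0, "V/m"),
    SafetyLimit("Liebetanz et al. (2009)", "charge_density", 85.714, "C/cm^2",
                note="printed as 85.714 (52.400) in the source comparison"),
)

SAFETY_LIMITS = AGNEW_MCCREERY_LIMITS + LIEBETANZ_LIMITS

#: the two limit rows of the dose-comparison table, verbatim as printed
SAFETY_LIMIT_TABLE_ROWS = [
    {
        "label": "Safety limits (Agnew & McCreery 1987)",
        "amplitude_mA": None, "area_cm2": None, "duration_min": None,
        "frequency_Hz": None, "current_density_mA_cm2": 25.0,
        "charge_density_C_cm2": None, "charge_per_phase_C": None,
        "charge_density_per_phase_C_cm2ph": 0.000400,
    },
    {
        "label": "Safety limits (Liebetanz et al. 2009)",
        "amplitude_mA": 0.5, "area_cm2": 0.035, "duration_min": 10.0,
        "frequency_Hz": None, "current_density_mA_cm2": 14.29,
        "charge_density_C_cm2": 85.714, "charge_per_phase_C": None,
        "charge_density_per_phase_C_cm2ph": None,
    },
]

# --------------------------------------------------------------------------
# The periorbital AC session and literature comparison montages
# --------------------------------------------------------------------------

#: nominal periorbital AC stimulus: 0.35 mA pp sine, 10 Hz, 30 s blocks with
#: 30 s pauses over 10 min
RACS_WAVEFORM = StimulusWaveform(
    shape="sine", peak_to_peak_amplitude=350.0, frequency=10.0,
    block_on=30.0, block_off=30.0, session_duration=600.0,
)

#: one periorbital felt contact (four are placed around the eyes)
RACS_ELECTRODE = ElectrodeSpec(contact_area=0.35, n_contacts=4,
                               role="active", material="gold / felt buffer")

RACS_RETURN_ELECTRODE = ElectrodeSpec(contact_area=9.0, n_contacts=1,
                                      role="return", material="stainless steel")


def _montage(label, amplitude_ma, area_cm2, duration_min, frequency_hz,
             omit=(), basis="peak"):
    wf = StimulusWaveform(
        shape="sine" if frequency_hz else "dc",
        peak_to_peak_amplitude=amplitude_ma * 1e3,
        frequency=frequency_hz,
        session_duration=duration_min * 60.0,
    )
    opts = {"basis": basis}
    if omit:
        opts["omit"] = tuple(omit)
    return (label, wf, ElectrodeSpec(contact_area=area_cm2), opts)


#: dose-comparison montages (label, waveform, electrode, options), in the
#: customary comparison order; "omit" blanks metrics the source did not report
COMPARISON_MONTAGES = [
    _montage("rACS", 0.35, 0.35, 10, 10.0),
    _montage("rACS (effective amplitude)", 0.35, 0.35, 10, 10.0,
             basis="effective"),
    _montage("Electrosleep", 25.0, 1.25, 60, 100.0),
    _montage("TCES (Ma)", 1.2, 1.0, 5, 20.0),
    _montage("TCES (low amplitude)", 0.28, 1.25, 7, 10.0),
    _montage("TCES (Gekeler, max)", 3.0, 0.35, 7, None,
             omit=("charge_density",)),
    _montage("TCES (Gekeler, optimal)", 0.08, 0.35, 7, None,
             omit=("charge_density",)),
    _montage("tACS", 0.4, 16.0, 5, 10.0),
    _montage("tSDCS", 0.25, 16.0, 4, 10.0),
    _montage("tDCS", 1.0, 35.0, 9, None, omit=("charge_density",)),
]

# --------------------------------------------------------------------------
# Tissue conductivities (S/m), isotropic averages
# --------------------------------------------------------------------------

CONDUCTIVITY_S_PER_M = {
    "scalp": 0.465,
    "muscle": 0.35,
    "skull": 0.01,
    "csf": 1.65,
    "gray_matter": 0.276,
    "white_matter": 0.126,
    "fat": 0.04,
    "blood_vessels": 0.7,
    "eye_lens": 0.32,
    "eye_retina_choroid_sclera": 0.623,
    "eye_vitreous": 1.55,
    "eye_cornea": 0.5,
    "eye_aqueous": 1.5,
    "optic_nerve": 0.126,   # optic tract / chiasm / cranial nerve II
    "air": 1.00e-7,
    "sponge_felt": 1.84,
    "electrode_gold": 4.10e7,
    "electrode_steel": 1.45e6,
}

# --------------------------------------------------------------------------
# Published FEM benchmark field summary (periorbital montage, 350 μA)
# --------------------------------------------------------------------------

_PUBLISHED_FIELDS = [
    # region, J max/mean/median (mA/cm²), E max/mean/median (V/m)
    ("retina",      0.124, 0.007, 0.005, 1.99, 0.11, 0.08),
    ("optic nerve", 0.033, 0.003, 0.002, 2.60, 0.20, 0.14),
    ("cortex",      0.013, 0.001, 0.001, 0.47, 0.05, 0.04),
    ("V1",          0.003, 0.001, 0.001, 0.12, 0.03, 0.03),
]


def published_field_summary() -> pd.DataFrame:
    """Benchmark per-region field summary in tidy form.

    Columns: region, quantity ("current_density" | "electric_field"),
    unit, max, mean, median.  Values come from a published >10M-element
    anatomical FEM solution of the same montage and are used as inputs to
    the order-of-magnitude margin report, not recomputed here.
    """
    rows = []
    for region, jmax, jmean, jmed, emax, emean, emed in _PUBLISHED_FIELDS:
        rows.append({"region": region, "quantity": "current_density",
                     "unit": "mA/cm^2", "max": jmax, "mean": jmean,
                     "median": jmed})
        rows.append({"region": region, "quantity": "electric_field",
                     "unit": "V/m", "max": emax, "mean": emean,
                     "median": emed})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Adverse-event counts (20 subjects per arm) and pain-rating moments
# --------------------------------------------------------------------------

GROUP_SIZE = 20

#: subjects reporting each event, by phase, for active stimulation (rACS)
#: versus photic stimulation (PS)
ADVERSE_EVENT_COUNTS = [
    # event, phase, rACS k, PS k
    ("pain (overall)",                "during", 8, 4),
    ("pain (overall)",                "after",  0, 2),
    ("fatigue",                       "during", 7, 4),
    ("fatigue",                       "after",  7, 4),
    ("tingling",                      "during", 14, 0),
    ("tingling",                      "after",  0, 0),
    ("headache",                      "during", 0, 3),
    ("headache",                      "after",  1, 1),
    ("itching",                       "during", 6, 0),
    ("itching",                       "after",  5, 0),
    ("burning",                       "during", 6, 0),
    ("burning",                       "after",  0, 0),
    ("difficulties in concentrating", "during", 0, 0),
    ("difficulties in concentrating", "after",  0, 2),
    ("metallic taste",                "during", 3, 0),
    ("metallic taste",                "after",  0, 0),
    ("muscle twitches",               "during", 3, 0),
    ("muscle twitches",               "after",  0, 0),
    ("acute mood changes",            "during", 0, 0),
    ("acute mood changes",            "after",  0, 0),
    ("nausea",                        "during", 0, 0),
    ("nausea",                        "after",  0, 0),
]

#: NRS-11 pain moments in affected subjects, (mean, SD) per (condition, phase)
PAIN_RATING_MOMENTS = {
    ("rACS", "during"): (2.5, 1.73),
    ("PS", "during"): (2.75, 0.83),
    ("PS", "after"): (1.5, 0.5),
}

#: cohort moments: 10 Hz phosphene threshold and electrode impedance.  The
#: threshold unit is printed as μV in the source but is stored here as μA,
#: consistent with the amplitudes it determines (120% rule); the ambiguity is
#: carried in THRESHOLD_UNIT.
PHOSPHENE_THRESHOLD_MEAN = 290.50
PHOSPHENE_THRESHOLD_SD = 45.36
THRESHOLD_UNIT = "uA (printed as uV in the source)"
IMPEDANCE_MEAN_KOHM = 12.05
IMPEDANCE_SD_KOHM = 2.89
AMPLITUDE_FACTOR = 1.2  # stimulation amplitude = 120% of phosphene threshold

#: photic-stimulation luminance threshold, recorded as metadata only
PHOTIC_THRESHOLD_CD = 1.24
PHOTIC_THRESHOLD_SD_CD = 0.44
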