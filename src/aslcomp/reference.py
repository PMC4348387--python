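"""Reference physiology and protocol values for the modeled acquisition.

These summarize the five-subject healthy-volunteer study whose short-TI
pulsed-ASL protocol this package implements: per-subject brachial pressures,
heart rates, and the slice just above the circle of Willis, plus the group
median arterial compliance per flow territory.  They serve as realistic
defaults for the synthetic generator and as inputs to worked examples
(e.g. converting compliance to percent aBV change over the cardiac cycle).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "REFERENCE_SUBJECTS",
    "GROUP_AC",
    "GROUP_PULSE_PRESSURE",
    "subjects_frame",
    "mean_heart_rate",
]

#: per-subject summaries: brachial pressures (mm Hg), heart rate (bpm,
#: averaged over the seven scans), and the axial slice index just above the
#: circle of Willis.
REFERENCE_SUBJECTS = (
    {"subject": "I", "age": 28, "sex": "M", "bp_sys": 122.0, "bp_dia": 56.0,
     "heart_rate_bpm": 59.8, "cow_slice": 4},
    {"subject": "II", "age": 24, "sex": "M", "bp_sys": 119.0, "bp_dia": 62.0,
     "heart_rate_bpm": 50.6, "cow_slice": 4},
    {"subject": "III", "age": 25, "sex": "F", "bp_sys": 108.0, "bp_dia": 66.0,
     "heart_rate_bpm": 71.7, "cow_slice": 3},
    {"subject": "IV", "age": 25, "sex": "F", "bp_sys": 110.0, "bp_dia": 64.0,
     "heart_rate_bpm": 69.5, "cow_slice": 3},
    {"subject": "V", "age": 25, "sex": "M", "bp_sys": 119.0, "bp_dia": 66.0,
     "heart_rate_bpm": 75.2, "cow_slice": 4},
)

#: group median arterial compliance per flow territory, %/mm Hg
GROUP_AC = {"RMCA": 0.57, "LMCA": 0.50, "ACA": 0.43, "RPCA": 1.1, "LPCA": 1.1}

#: group mean brachial pulse pressure, mm Hg
GROUP_PULSE_PRESSURE = 52.7


def subjects_frame() -> pd.DataFrame:
    """Reference subjects as a DataFrame with a derived pulse-pressure column."""
    df = pd.DataFrame(REFERENCE_SUBJECTS)
    df["pp"] = df["bp_sys"] - df["bp_dia"]
    return df


def mean_heart_rate() -> float:
    """Group mean heart rate (bpm) over the reference subjects."""
    return float(subjects_frame()["heart_rate_bpm"].mean())
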