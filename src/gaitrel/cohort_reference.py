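"""Published reference cohort values for markerless gait reliability.

Cycle-average variation (degrees) per joint/plane channel from a published
two-session, two-clothing-condition markerless gait study of 22 healthy
adults (5 trials per condition per session, 101-point right-sided gait
cycles), together with the corresponding published variability ratios.
These serve as inputs for table reconstruction and as cross-checks for the
package's summary arithmetic; they are *data*, not computed here.
"""

from __future__ import annotations

import numpy as np

from .constants import CHANNELS

#: cycle-average inter-trial variation (deg), loose clothing
INTER_TRIAL_LOOSE = {
    ("pelvis", "sagittal"): 0.84, ("pelvis", "frontal"): 0.55, ("pelvis", "transverse"): 1.64,
    ("hip", "sagittal"): 1.48, ("hip", "frontal"): 0.92, ("hip", "transverse"): 1.86,
    ("knee", "sagittal"): 1.79, ("knee", "frontal"): 1.04, ("knee", "transverse"): 1.89,
    ("ankle", "sagittal"): 1.49, ("ankle", "frontal"): 1.44, ("ankle", "transverse"): 1.31,
}

#: cycle-average inter-trial variation (deg), tight clothing
INTER_TRIAL_TIGHT = {
    ("pelvis", "sagittal"): 0.85, ("pelvis", "frontal"): 0.50, ("pelvis", "transverse"): 1.55,
    ("hip", "sagittal"): 1.48, ("hip", "frontal"): 0.83, ("hip", "transverse"): 1.74,
    ("knee", "sagittal"): 1.90, ("knee", "frontal"): 0.97, ("knee", "transverse"): 1.96,
    ("ankle", "sagittal"): 1.52, ("ankle", "frontal"): 1.35, ("ankle", "transverse"): 0.88,
}

#: cycle-average inter-session variation (deg), loose clothing
INTER_SESSION_LOOSE = {
    ("pelvis", "sagittal"): 1.52, ("pelvis", "frontal"): 0.93, ("pelvis", "transverse"): 2.41,
    ("hip", "sagittal"): 2.22, ("hip", "frontal"): 1.45, ("hip", "transverse"): 2.65,
    ("knee", "sagittal"): 2.45, ("knee", "frontal"): 1.53, ("knee", "transverse"): 2.80,
    ("ankle", "sagittal"): 2.07, ("ankle", "frontal"): 2.11, ("ankle", "transverse"): 1.83,
}

#: cycle-average inter-session variation (deg), tight clothing
INTER_SESSION_TIGHT = {
    ("pelvis", "sagittal"): 1.47, ("pelvis", "frontal"): 0.70, ("pelvis", "transverse"): 2.27,
    ("hip", "sagittal"): 2.22, ("hip", "frontal"): 1.14, ("hip", "transverse"): 2.72,
    ("knee", "sagittal"): 2.40, ("knee", "frontal"): 1.44, ("knee", "transverse"): 2.84,
    ("ankle", "sagittal"): 1.84, ("ankle", "frontal"): 2.00, ("ankle", "transverse"): 1.50,
}

#: cycle-average inter-session-clothing variation (deg), both conditions pooled
INTER_SESSION_CLOTHING = {
    ("pelvis", "sagittal"): 1.88, ("pelvis", "frontal"): 1.36, ("pelvis", "transverse"): 2.72,
    ("hip", "sagittal"): 2.83, ("hip", "frontal"): 1.77, ("hip", "transverse"): 2.98,
    ("knee", "sagittal"): 2.82, ("knee", "frontal"): 1.75, ("knee", "transverse"): 3.41,
    ("ankle", "sagittal"): 2.26, ("ankle", "frontal"): 2.45, ("ankle", "transverse"): 1.98,
}

#: published variability ratios (inter-session / inter-trial), loose clothing
RATIOS_LOOSE = {
    ("pelvis", "sagittal"): 1.81, ("pelvis", "frontal"): 1.72, ("pelvis", "transverse"): 1.47,
    ("hip", "sagittal"): 1.51, ("hip", "frontal"): 1.59, ("hip", "transverse"): 1.42,
    ("knee", "sagittal"): 1.37, ("knee", "frontal"): 1.54, ("knee", "transverse"): 1.50,
    ("ankle", "sagittal"): 1.41, ("ankle", "frontal"): 1.48, ("ankle", "transverse"): 1.41,
}

#: published variability ratios, tight clothing
RATIOS_TIGHT = {
    ("pelvis", "sagittal"): 1.73, ("pelvis", "frontal"): 1.43, ("pelvis", "transverse"): 1.48,
    ("hip", "sagittal"): 1.54, ("hip", "frontal"): 1.38, ("hip", "transverse"): 1.57,
    ("knee", "sagittal"): 1.33, ("knee", "frontal"): 1.54, ("knee", "transverse"): 1.45,
    ("ankle", "sagittal"): 1.21, ("ankle", "frontal"): 1.52, ("ankle", "transverse"): 1.71,
}

TABLES = {
    ("inter_trial", "loose"): INTER_TRIAL_LOOSE,
    ("inter_trial", "tight"): INTER_TRIAL_TIGHT,
    ("inter_session", "loose"): INTER_SESSION_LOOSE,
    ("inter_session", "tight"): INTER_SESSION_TIGHT,
    ("inter_session_clothing", None): INTER_SESSION_CLOTHING,
}


def cells(table: dict[tuple[str, str], float]) -> np.ndarray:
    """The 12 per-channel values of a reference table in channel order."""
    return np.array([table[ch] for ch in CHANNELS])
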