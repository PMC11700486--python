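"""Joint/plane channel layout shared across the package.

A lower-limb gait analysis reports angles for the pelvis (relative to the
lab) and the hip, knee and ankle (distal segment relative to proximal), each
decomposed into sagittal (flexion-extension), frontal (ab-adduction) and
transverse (internal-external rotation) components.  The 4 x 3 = 12
joint/plane combinations are stored as a fixed channel order everywhere.
"""

from __future__ import annotations

JOINTS: tuple[str, ...] = ("pelvis", "hip", "knee", "ankle")
PLANES: tuple[str, ...] = ("sagittal", "frontal", "transverse")

#: Fixed (joint, plane) ordering of the 12 angle channels.
CHANNELS: tuple[tuple[str, str], ...] = tuple(
    (joint, plane) for joint in JOINTS for plane in PLANES
)

#: Number of samples a time-normalized gait cycle carries (0..100 % inclusive).
N_CYCLE_POINTS: int = 101

#: Canonical clothing-condition labels for a two-condition study.
CONDITIONS: tuple[str, str] = ("tight", "loose")

#: Session labels for a two-session study.
SESSIONS: tuple[int, int] = (1, 2)


def channel_index(joint: str, plane: str) -> int:
    """Return the row index of ``(joint, plane)`` in the channel layout."""
    try:
        return CHANNELS.index((joint, plane))
    except ValueError:
        raise KeyError(f"unknown joint/plane combination: {joint}/{plane}") from None
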