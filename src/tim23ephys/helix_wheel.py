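"""Helical-wheel projection of transmembrane helix windows.

Projects a residue window onto the plane perpendicular to an ideal
alpha-helix axis (3.6 residues/turn, 100 deg/residue), tags each position as
polar or apolar, and computes the mean polar direction and the Eisenberg
hydrophobic moment.  Used to document the geometry of pore-lining candidate
faces of channel transmembrane helices (e.g. residues 150-163 of the second
transmembrane helix of Tim23, whose mutated positions N150, G153, L155,
A156, Y159, N160 cluster on one face).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Tuple

import numpy as np

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Default polar classification. Glycine is deliberately *not* polar here
#: (neutral, excluded); the classification is a config knob, not a constant
#: of nature.
DEFAULT_POLAR_SET = frozenset("DEKRHNQSTYC")

#: Eisenberg consensus hydrophobicity scale.
EISENBERG_SCALE: Dict[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}


@dataclasses.dataclass(frozen=True)
class HelixWindow:
    """A contiguous residue window of a helix.

    ``start_position`` is the residue number of the first letter;
    ``angle_step_deg`` is the wheel rotation per residue (100 deg for an
    ideal alpha-helix).
    """

    sequence: str
    start_position: int
    angle_step_deg: float = 100.0

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("sequence must be non-empty")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid residue letters: {sorted(bad)}")
        if not (0 < self.angle_step_deg < 360):
            raise ValueError("angle_step_deg must be in the open interval (0, 360)")

    @property
    def positions(self) -> List[int]:
        return list(range(self.start_position, self.start_position + len(self.sequence)))


def wheel_angles(window: HelixWindow) -> List[Tuple[int, str, float]]:
    """(position, residue, wheel angle in [0, 360)) for each residue.

    angle(i) = ((i - start_position) * angle_step) mod 360.
    """
    return [
        (pos, res, ((pos - window.start_position) * window.angle_step_deg) % 360.0)
        for pos, res in zip(window.positions, window.sequence)
    ]


@dataclasses.dataclass(frozen=True)
class FaceAssignment:
    """Polar/apolar tag per residue plus the mean polar direction."""

    tags: Tuple[Tuple[int, str, str], ...]  # (position, residue, 'polar'|'apolar')
    mean_polar_angle_deg: Optional[float]   # None when the polar vectors cancel


def face_assignment(
    window: HelixWindow, polar_set=DEFAULT_POLAR_SET
) -> FaceAssignment:
    """Tag residues by polarity and locate the polar face.

    The polar face direction is the argument of the vector sum of unit
    vectors at the polar residues' wheel angles; when the resultant is ~0
    (symmetrically placed polar residues) the direction is undefined and
    reported as ``None``.
    """
    angles = wheel_angles(window)
    tags = []
    vx = vy = 0.0
    for pos, res, ang in angles:
        polar = res in polar_set
        tags.append((pos, res, "polar" if polar else "apolar"))
        if polar:
            vx += math.cos(math.radians(ang))
            vy += math.sin(math.radians(ang))
    resultant = math.hypot(vx, vy)
    if resultant < 1e-9:
        mean_angle = None
    else:
        mean_angle = math.degrees(math.atan2(vy, vx)) % 360.0
    return FaceAssignment(tags=tuple(tags), mean_polar_angle_deg=mean_angle)


def hydrophobic_moment(
    window: HelixWindow, scale: Dict[str, float] = EISENBERG_SCALE
) -> Tuple[float, Optional[float]]:
    """Helical hydrophobic moment: magnitude and direction (deg).

    Vector sum of per-residue hydrophobicity times the unit vector at the
    residue's wheel angle.  The magnitude is invariant under global rotation
    of the wheel; the direction is ``None`` for zero magnitude.

    Raises ``KeyError`` if a residue is missing from the scale.
    """
    vx = vy = 0.0
    for _, res, ang in wheel_angles(window):
        h = scale[res]
        vx += h * math.cos(math.radians(ang))
        vy += h * math.sin(math.radians(ang))
    mag = math.hypot(vx, vy)
    direction = math.degrees(math.atan2(vy, vx)) % 360.0 if mag > 1e-12 else None
    return mag, direction
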