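"""Helical wheel projection of a pore-lining transmembrane helix window.

Projects a 14-residue window (numbered from residue 150, the second
transmembrane helix of the channel) onto an ideal alpha-helical wheel
(100 deg/residue), tags polar vs apolar faces and computes the Eisenberg
hydrophobic moment.  The sequence here is a synthetic stand-in carrying the
six pore-lining positions mutated in selectivity studies of this channel
(N150, G153, L155, A156, Y159, N160) at their correct offsets.
"""

from tim23ephys import HelixWindow, face_assignment, hydrophobic_moment, wheel_angles

window = HelixWindow(sequence="NVVGSLAIFYNVMI", start_position=150)

faces = face_assignment(window)
print("pos  res  angle    face")
for (pos, res, ang), (_, _, face) in zip(wheel_angles(window), faces.tags):
    print(f"{pos}   {res}   {ang:5.0f}   {face}")

mag, direction = hydrophobic_moment(window)
print(f"\nmean polar direction: {faces.mean_polar_angle_deg:.0f} deg")
print(f"hydrophobic moment: {mag:.2f} (direction {direction:.0f} deg)")
# Polar residues clustering around one wheel direction mark the face that
# lines the aqueous pore; the hydrophobic moment points toward the
# lipid-facing side.
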