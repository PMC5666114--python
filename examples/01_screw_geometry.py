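"""Rigid-transform algebra: screw parameters and the twist-swing split.

Builds the generator of an open ring (55 deg about z, 2 A rise), reads off
its helical parameters, and decomposes a combined rotation into its shear
(about the ring axis) and hinge (perpendicular) components -- the same
decomposition used to compare a dimer's orientation between two assemblies.
"""

import numpy as np

from openring import (RigidTransform, decompose_rotation, screw_parameters,
                      screw_transform)

gen = screw_transform(axis=[0, 0, 1], angle_deg=55.0, rise=2.0)
par = screw_parameters(gen)
print(f"generator: {par.angle_per_unit:.2f} deg/unit, "
      f"rise {par.rise_per_unit:.2f} A/unit")
print(f"  -> {par.units_per_turn:.3f} units per turn, pitch {par.pitch:.1f} A")
print("  6 units cover", 6 * par.angle_per_unit, "deg: an open single turn "
      "with a 30 deg end gap\n")

# a rotation combining 20 deg of shear about z with 25 deg of hinge about x
combined = (RigidTransform.from_rotvec([1, 0, 0], 25.0)
            @ RigidTransform.from_rotvec([0, 0, 1], 20.0))
dec = decompose_rotation(combined, main_axis=[0, 0, 1])
print(f"combined rotation: total {dec.total_angle:.1f} deg")
print(f"  twist (shear, about the main axis):      {dec.twist_angle:.1f} deg")
print(f"  swing (hinge, about a perpendicular):    {dec.swing_angle:.1f} deg")
print("the two components recompose the rotation exactly:",
      np.allclose(dec.swing.rotation @ dec.twist.rotation, combined.rotation))
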