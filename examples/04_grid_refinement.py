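"""Grid-search refinement: recovering a helix generator from noisy SAXS data.

Simulates a 2%-noise scattering profile of an open 6-unit ring with a known
step transform, then starts the grid search from a deliberately wrong center
(2 deg / 2 A off) and shows that the best-first lattice search recovers the
true generator.  A continuous Powell polish then refines off-lattice.
"""

import numpy as np

from openring import (GridSpec, RigidTransform, default_q_grid, local_refine,
                      make_bead_dimer, make_ground_truth_assembly,
                      refine_against_saxs, simulate_profile)

TILT = RigidTransform.from_euler(20, 35, 10)  # generic, gimbal-lock-free

dimer = make_bead_dimer(n_beads=40, seed=1)
truth = make_ground_truth_assembly(dimer, 55.0, 2.0, 40.0, 6,
                                   seed=1).transformed(TILT)
tp = truth.generator.params()
print("true step parameters (alpha beta gamma, deg; tx ty tz, A):")
print(" ", np.round(tp, 3))

q = default_q_grid()
profile = simulate_profile(truth.assembly, q, rel_noise=0.02, seed=42)

center = RigidTransform.from_params(tp + np.array([2, -2, 1, -1, 2, -2.0]))
spec = GridSpec.around(center, angle_half=5, angle_step=1,
                       trans_half=3, trans_step=1, n_units=6)
print(f"\nscanning around a perturbed center, grid of {spec.grid_size} "
      "lattice points (searched best-first, not exhaustively)")
result = refine_against_saxs(truth.unit, spec, profile, mode="frontier")
print(f"evaluated {result.n_evaluated} models "
      f"({result.n_clashing} clashing, excluded)")
print("best grid model: ", np.round(result.best_params, 3),
      f" chi2 = {result.best_fit.chi2:.3f}")
print("offset from truth (grid steps):",
      np.round(np.abs(result.best_params - tp), 2))

refined, fit = local_refine(result.best_transform, truth.unit, profile, 6)
print(f"\nafter continuous local refinement: chi2 = {fit.chi2:.3f} "
      "(at 2% matched noise the optimum sits at chi2 ~ 1)")
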