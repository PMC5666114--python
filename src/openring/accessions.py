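"""Geometric analyses of deposited crystal structures.

These routines reproduce the rigid-body analyses reported for the Anbu
crystal structures when the deposited coordinate files (PDB entries 5LOX,
5LOY, and the proteasome 1PMA for comparison) are available locally — they
are not bundled with the package.  Place the files under a directory of your
choice (tests look in ``data/accessions/`` at the repository root) and pass
paths explicitly.

All published-figure comparisons use CA atoms of matched residues; the
selection is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import pair_dimers
from .geometry import decompose_rotation, extract_step_transform, \
    kabsch_superpose, screw_parameters
from .structure_io import AtomSet, concat_atom_sets, select_atoms


def chain_count(atoms: AtomSet) -> int:
    """Number of distinct protein chains (34 for the Pa-Anbu asymmetric unit)."""
    return len(atoms.chains)


def _chain_pair_set(atoms: AtomSet, pair) -> AtomSet:
    return select_atoms(atoms, chains=list(pair))


def _common_ca(a: AtomSet, b: AtomSet):
    """CA coordinate arrays over the residue numbers the two sets share,
    chain-position by chain-position."""
    ca_a = select_atoms(a, atom_names=["CA"])
    ca_b = select_atoms(b, atom_names=["CA"])
    pa, pb = [], []
    for c_a, c_b in zip(ca_a.chains, ca_b.chains):
        sub_a = select_atoms(ca_a, chains=[c_a])
        sub_b = select_atoms(ca_b, chains=[c_b])
        map_a = {int(r): i for i, r in enumerate(sub_a.residue_numbers)}
        map_b = {int(r): i for i, r in enumerate(sub_b.residue_numbers)}
        common = sorted(set(map_a) & set(map_b))
        pa.append(sub_a.coords[[map_a[r] for r in common]])
        pb.append(sub_b.coords[[map_b[r] for r in common]])
    return np.concatenate(pa), np.concatenate(pb)


def dimer_superposition_rmsds(atoms: AtomSet,
                              contact_cutoff: float = 5.0) -> np.ndarray:
    """CA RMSD of every contact-paired dimer onto the first one.

    For the Pa-Anbu helix (17 dimers) the maximum stays below 0.4 Å — the
    intra-dimer interface is virtually invariant.
    """
    pairs = pair_dimers(atoms, contact_cutoff=contact_cutoff)
    ref = _chain_pair_set(atoms, pairs[0])
    out = []
    for pair in pairs[1:]:
        mob = _chain_pair_set(atoms, pair)
        P, Q = _common_ca(mob, ref)
        out.append(kabsch_superpose(P, Q).rmsd)
    return np.array(out)


def neighbor_subunit_rmsds(atoms: AtomSet, chain_order=None) -> np.ndarray:
    """RMSD of each neighboring-subunit pair onto the next pair along the helix.

    Variability in the lateral (inter-dimer) interface shows up here: for the
    Pa-Anbu helix these reach ≈ 1.6 Å, an order of magnitude above the
    intra-dimer spread.
    """
    chains = chain_order or atoms.chains
    rmsds = []
    for i in range(len(chains) - 2):
        pair_i = select_atoms(atoms, chains=chains[i:i + 2])
        pair_j = select_atoms(atoms, chains=chains[i + 1:i + 3])
        P, Q = _common_ca(pair_i, pair_j)
        rmsds.append(kabsch_superpose(P, Q).rmsd)
    return np.array(rmsds)


def cross_structure_dimer_rmsd(dimer_a: AtomSet, dimer_b: AtomSet) -> float:
    """CA RMSD between corresponding dimers of two structures (≈1.0 Å for
    the consensus protein vs Pa-Anbu)."""
    P, Q = _common_ca(dimer_a, dimer_b)
    return kabsch_superpose(P, Q).rmsd


@dataclass(frozen=True)
class DimerOrientation:
    """Orientation difference of the upper protomers after aligning the lower."""

    total_angle: float
    hinge_angle: float  # about an axis ⊥ main axis ("closing")
    shear_angle: float  # about the main axis


def compare_dimer_orientation(dimer_a: AtomSet, dimer_b: AtomSet,
                              main_axis=(0.0, 0.0, 1.0)) -> DimerOrientation:
    """Rotation relating the upper protomers once the lower ones are aligned.

    Chains are taken in order (lower, upper).  The rotation is decomposed
    into a hinge component about an axis perpendicular to ``main_axis`` (the
    ring/helix axis) and a shear component about it.  For an Anbu dimer vs a
    proteasome opposing-β pair, the total is ≈ 30°.
    """
    la, ua = (select_atoms(dimer_a, chains=[c]) for c in dimer_a.chains[:2])
    lb, ub = (select_atoms(dimer_b, chains=[c]) for c in dimer_b.chains[:2])
    # align the lower protomers: map structure b onto a
    P, Q = _common_ca(lb, la)
    lower_fit = kabsch_superpose(P, Q)
    ub_aligned = ub.with_coords(lower_fit.transform.apply(ub.coords))
    # the residual rotation between the upper protomers
    P2, Q2 = _common_ca(ub_aligned, ua)
    upper_fit = kabsch_superpose(P2, Q2)
    dec = decompose_rotation(upper_fit.transform, main_axis)
    return DimerOrientation(total_angle=dec.total_angle,
                            hinge_angle=dec.swing_angle,
                            shear_angle=dec.twist_angle)


def lattice_helix_units_per_turn(unit_i: AtomSet, unit_j: AtomSet) -> float:
    """Units per turn of a crystal-lattice helix from two consecutive units
    (8 dimers per turn for the consensus-protein lattice)."""
    P, Q = _common_ca(unit_i, unit_j)
    step = kabsch_superpose(P, Q).transform
    return screw_parameters(step).units_per_turn
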