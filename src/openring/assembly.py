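"""Helical segments and closed rings from a rigid seed unit.

An :class:`Assembly` is a seed :class:`~openring.structure_io.AtomSet` plus an
ordered list of rigid placements (``placements[0]`` is always the identity).
Symmetric assemblies additionally record the generator step, so that
``placements[k] = generator^k``.  Also here: steric-clash counting, the
"can a further unit associate?" termination test, dimer pairing by contact
matching, and Shrake–Rupley buried interface area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidTransform
from .structure_io import AtomSet, concat_atom_sets

# Clash cutoffs, Å.  Chosen at the short end of nonbonded contact distances
# so only genuine overlap counts: 2.5 Å between heavy atoms, 3.5 Å between
# one-per-residue CA beads.
CLASH_CUTOFF_ATOM = 2.5
CLASH_CUTOFF_BEAD = 3.5

#: van der Waals radii for surface-area calculations, Å
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "SE": 1.90, "P": 1.80,
    # residue-level bead: effective radius of an average residue
    "RES": 3.50,
}
VDW_DEFAULT = 1.70


def default_clash_cutoff(atoms: AtomSet) -> float:
    return CLASH_CUTOFF_BEAD if atoms.is_bead else CLASH_CUTOFF_ATOM


@dataclass
class Assembly:
    """Seed unit plus the rigid placements of its copies."""

    seed: AtomSet
    placements: list[RigidTransform]
    generator: RigidTransform | None = None

    def __post_init__(self) -> None:
        if not self.placements:
            raise ValueError("assembly needs at least one placement")
        if not self.placements[0].is_close(RigidTransform.identity(), atol=1e-9):
            raise ValueError("placements[0] must be the identity")

    @property
    def n_units(self) -> int:
        return len(self.placements)

    def unit_coords(self, k: int) -> np.ndarray:
        return self.placements[k].apply(self.seed.coords)

    def all_coords(self) -> np.ndarray:
        return np.concatenate([self.unit_coords(k) for k in range(self.n_units)])

    def to_atomset(self) -> AtomSet:
        """Expand to a flat AtomSet; copy k's chains are renamed '<id>.<k>'
        (copy 0 keeps the seed's chain ids)."""
        parts = []
        for k in range(self.n_units):
            part = self.seed.with_coords(self.unit_coords(k))
            if k > 0:
                part = part.with_chain_ids(np.array(
                    [f"{c}.{k}" for c in part.chain_ids], dtype=object))
            parts.append(part)
        return concat_atom_sets(parts)

    def transformed(self, t: RigidTransform) -> "Assembly":
        """Apply a global rigid motion: conjugates placements and generator."""
        inv = t.inverse()
        new_seed = self.seed.with_coords(t.apply(self.seed.coords))
        new_pl = [t @ p @ inv for p in self.placements]
        new_gen = (t @ self.generator @ inv) if self.generator else None
        return Assembly(new_seed, new_pl, new_gen)

    def to_dict(self) -> dict:
        return {
            "n_units": self.n_units,
            "generator": self.generator.to_dict() if self.generator else None,
            "placements": [p.to_dict() for p in self.placements],
        }


@dataclass(frozen=True)
class RingSpec:
    """Closed C_n ring: n units, seed displaced by ``radius`` from the axis."""

    n_units: int
    radius: float

    def __post_init__(self) -> None:
        if self.n_units < 3:
            raise ValueError("a closed ring needs n_units >= 3")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")

    @property
    def rotation_per_unit(self) -> float:
        """360/n degrees: 60° for a hexamer, 51.43° for a heptamer."""
        return 360.0 / self.n_units


def build_helix(seed: AtomSet, step: RigidTransform, n_units: int) -> Assembly:
    """n_units copies of ``seed`` generated by repeated application of ``step``."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    placements = [RigidTransform.identity()]
    for _ in range(n_units - 1):
        placements.append(step @ placements[-1])
    return Assembly(seed=seed, placements=placements, generator=step)


def build_closed_ring(seed: AtomSet, spec: RingSpec) -> Assembly:
    """Closed C_n ring about the z-axis.

    The seed is first translated by ``radius`` along +x, then replicated by
    successive rotations of 360/n about z; the ring closes exactly
    (generator^n = identity).
    """
    shifted = seed.with_coords(seed.coords + np.array([spec.radius, 0.0, 0.0]))
    gen = RigidTransform.from_rotvec([0, 0, 1], spec.rotation_per_unit)
    return build_helix(shifted, gen, spec.n_units)


# ---------------------------------------------------------------------------
# clashes


def clash_count(assembly: Assembly, cutoff: float | None = None) -> int:
    """Number of inter-unit atom pairs within ``cutoff`` Å (intra-unit ignored).

    Uses k-d trees per unit; exact (verified against the O(N²) brute force in
    the test suite).
    """
    if cutoff is None:
        cutoff = default_clash_cutoff(assembly.seed)
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    trees = [cKDTree(assembly.unit_coords(k)) for k in range(assembly.n_units)]
    total = 0
    for i in range(assembly.n_units):
        for j in range(i + 1, assembly.n_units):
            total += int(trees[i].count_neighbors(trees[j], cutoff))
    return total


def can_extend(assembly: Assembly, step: RigidTransform | None = None,
               cutoff: float | None = None) -> tuple[bool, int]:
    """Can one more unit be added without steric clash?

    The candidate copy n+1 is placed by one further application of ``step``
    (default: the assembly's generator) and tested against every existing
    copy.  Returns (extendable, clash count of the candidate).
    """
    step = step or assembly.generator
    if step is None:
        raise ValueError("assembly has no generator; pass the step explicitly")
    if cutoff is None:
        cutoff = default_clash_cutoff(assembly.seed)
    next_placement = step @ assembly.placements[-1]
    new_tree = cKDTree(next_placement.apply(assembly.seed.coords))
    clashes = 0
    for k in range(assembly.n_units):
        clashes += int(new_tree.count_neighbors(
            cKDTree(assembly.unit_coords(k)), cutoff))
    return clashes == 0, clashes


# ---------------------------------------------------------------------------
# dimer pairing


def contact_count(coords_a: np.ndarray, coords_b: np.ndarray,
                  cutoff: float = 5.0) -> int:
    """Number of inter-set atom pairs within ``cutoff`` Å."""
    return int(cKDTree(coords_a).count_neighbors(cKDTree(coords_b), cutoff))


def pair_dimers(atoms: AtomSet, contact_cutoff: float = 5.0):
    """Pair chains into dimers by maximum-weight contact matching.

    Weight between two chains = number of inter-chain atom pairs within
    ``contact_cutoff`` Å.  A maximum-weight matching over the chain contact
    graph recovers dimers of opposing protomers without any sequence
    annotation.  Returns a list of (chain_i, chain_j) pairs; unpaired chains
    trigger a warning.
    """
    import networkx as nx

    chains = atoms.chains
    if len(chains) < 2:
        raise ValueError("pair_dimers needs at least 2 chains")
    by_chain = {c: atoms.coords[atoms.chain_ids == c] for c in chains}
    g = nx.Graph()
    g.add_nodes_from(chains)
    for i, ci in enumerate(chains):
        for cj in chains[i + 1:]:
            w = contact_count(by_chain[ci], by_chain[cj], contact_cutoff)
            if w > 0:
                g.add_edge(ci, cj, weight=w)
    matching = nx.max_weight_matching(g, maxcardinality=True)
    order = {c: i for i, c in enumerate(chains)}
    pairs = sorted((tuple(sorted(p, key=order.get)) for p in matching),
                   key=lambda p: order[p[0]])
    paired = {c for p in pairs for c in p}
    unpaired = [c for c in chains if c not in paired]
    if unpaired:
        warnings.warn(f"pair_dimers: unpaired chain(s) {unpaired}")
    return pairs


# ---------------------------------------------------------------------------
# surface area


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _radii(atoms: AtomSet) -> np.ndarray:
    return np.array([VDW_RADII.get(str(e).upper(), VDW_DEFAULT)
                     for e in atoms.elements])


def sasa(atoms: AtomSet, probe: float = 1.4, n_points: int = 960,
         radii: np.ndarray | None = None) -> float:
    """Shrake–Rupley solvent-accessible surface area, Å².

    Each atom's sphere of radius r_vdw + probe is sampled at ``n_points``
    golden-spiral points; a point is accessible if it lies outside every
    other atom's expanded sphere.
    """
    if probe <= 0:
        raise ValueError("probe must be > 0")
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a stable estimate")
    r = (radii if radii is not None else _radii(atoms)) + probe
    xyz = atoms.coords
    pts = _sphere_points(n_points)
    tree = cKDTree(xyz)
    rmax = r.max()
    total = 0.0
    for i in range(len(xyz)):
        nb = [j for j in tree.query_ball_point(xyz[i], r[i] + rmax) if j != i]
        surface = xyz[i] + r[i] * pts
        if nb:
            d2 = ((surface[:, None, :] - xyz[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (r[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        total += frac * 4.0 * np.pi * r[i] ** 2
    return float(total)


def interface_area(a: AtomSet, b: AtomSet, probe: float = 1.4,
                   n_points: int = 960) -> float:
    """Buried interface area SASA(a) + SASA(b) − SASA(a∪b), Å² (not halved)."""
    ra, rb = _radii(a), _radii(b)
    sa = sasa(a, probe, n_points, radii=ra)
    sb = sasa(b, probe, n_points, radii=rb)
    ab = concat_atom_sets([a, b])
    sab = sasa(ab, probe, n_points, radii=np.concatenate([ra, rb]))
    return sa + sb - sab
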