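"""Synthetic ground-truth inputs for every pipeline stage.

The experimental scattering profile behind the original study is not publicly
deposited, so the pipeline is exercised end-to-end on synthetic data with
known ground truth instead: bead protomers and two-chain dimers standing in
for the rigid dimeric unit, helical/ring assemblies generated by a known
screw transform, noisy scattering profiles with a declared noise model, and
alignments mutated from a known consensus.

Everything is deterministic given (parameters, seed): ``numpy.random
.default_rng(seed)`` is the only randomness source.

Noise model: Gaussian with σ(q) = a·I(q) + b.  This matches how the
third-column uncertainties of standard SAXS text files behave and keeps the
χ² calibration analytic (E[χ²] = 1 at the generating model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import Assembly, build_helix, clash_count, default_clash_cutoff
from .consensus import AMINO_ACIDS, GAP, MSA
from .geometry import RigidTransform, screw_transform
from .saxs import DEFAULT_FF, FormFactorTable, SAXSProfile, debye_profile
from .structure_io import AtomSet, concat_atom_sets

# Default toy scale, mirroring the dodecamer: ~230 residues per protomer,
# two protomers per dimeric unit, six units per assembly.
DEFAULT_N_BEADS = 230
DEFAULT_EXTENT = 40.0  # Å, protomer long dimension
DEFAULT_ANGLE = 55.0  # degrees per unit: open single-turn ring regime
DEFAULT_RISE = 2.0  # Å per unit, too low to continue into a second turn
DEFAULT_RADIUS = 40.0  # Å, unit centroid distance from the helix axis

# protomer ellipsoid semi-axes as fractions of `extent`; distinct values make
# the cloud anisotropic, the long axis lies along z (the eventual ring axis)
_AXIS_FRACS = np.array([0.40, 0.30, 0.55])


def _bead_set(coords: np.ndarray, chain: str, label: str) -> AtomSet:
    n = len(coords)
    return AtomSet(
        coords=coords,
        elements=np.array(["RES"] * n, dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        chain_ids=np.array([chain] * n, dtype=object),
        residue_numbers=np.arange(1, n + 1),
        insertion_codes=np.array([""] * n, dtype=object),
        residue_names=np.array(["ALA"] * n, dtype=object),
        is_bead=True,
        source_label=label,
    )


def make_bead_protomer(n_beads: int = DEFAULT_N_BEADS, shape: str = "blob",
                       extent: float = DEFAULT_EXTENT, seed: int = 0,
                       chain: str = "A") -> AtomSet:
    """Asymmetric bead cloud standing in for one protomer.

    ``blob``: beads uniform in a triaxial ellipsoid (semi-axes 0.40/0.30/0.55
    of ``extent``), giving Rg ≈ 0.33·extent.  ``helix-bundle``: beads along
    four jittered rods.  Both are chirality-bearing: the mirror image has the
    same Debye profile but nonzero superposition RMSD to the original.
    """
    if n_beads < 10:
        raise ValueError("n_beads must be >= 10")
    rng = np.random.default_rng(seed)
    semi = _AXIS_FRACS * extent
    if shape == "blob":
        pts = []
        while len(pts) < n_beads:
            cand = rng.uniform(-1.0, 1.0, size=(4 * n_beads, 3))
            inside = (cand ** 2).sum(axis=1) <= 1.0
            pts.extend(cand[inside])
        coords = np.array(pts[:n_beads]) * semi
    elif shape == "helix-bundle":
        n_rods = 4
        per = int(np.ceil(n_beads / n_rods))
        offsets = np.array([[0.6, 0.0], [-0.6, 0.2], [0.1, 0.7], [-0.2, -0.6]])
        coords = []
        for r in range(n_rods):
            z = np.linspace(-semi[2], semi[2], per)
            x = np.full(per, offsets[r, 0] * semi[0])
            y = np.full(per, offsets[r, 1] * semi[1])
            coords.append(np.column_stack([x, y, z]))
        coords = np.concatenate(coords)[:n_beads]
        coords += rng.normal(scale=0.15 * semi[0], size=coords.shape)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    coords -= coords.mean(axis=0)
    return _bead_set(coords, chain, f"synthetic protomer ({shape}, seed={seed})")


def make_bead_dimer(n_beads: int = DEFAULT_N_BEADS, shape: str = "blob",
                    extent: float = DEFAULT_EXTENT, seed: int = 0,
                    min_gap: float = 4.0) -> AtomSet:
    """Two-chain dimer of opposing protomers.

    Chain B is chain A rotated 180° about x (antiparallel, as in a dimer
    paired across a coiled-coil-like interface) and displaced along z until
    the closest inter-chain bead distance is ≈ ``min_gap`` Å, producing a
    realistic contact patch for contact-based dimer pairing.
    """
    prot = make_bead_protomer(n_beads, shape, extent, seed, chain="A")
    flip = RigidTransform.from_rotvec([1, 0, 0], 180.0)
    b_coords = flip.apply(prot.coords)

    from scipy.spatial import cKDTree
    tree = cKDTree(prot.coords)

    def min_dist(dz: float) -> float:
        return float(tree.query(b_coords + np.array([0, 0, dz]))[0].min())

    lo, hi = 0.0, 4.0 * extent
    while min_dist(hi) < min_gap:
        hi *= 1.5
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < min_gap:
            lo = mid
        else:
            hi = mid
    dz = hi
    other = _bead_set(b_coords + np.array([0, 0, dz]), "B",
                      prot.source_label)
    dimer = concat_atom_sets([prot, other])
    dimer.source_label = f"synthetic dimer (seed={seed})"
    return dimer.with_coords(dimer.coords - dimer.coords.mean(axis=0))


@dataclass
class SyntheticTruth:
    """A ground-truth assembly with its exact generator and provenance."""

    seed: int
    unit: AtomSet  # the placed seed unit (copy 0)
    generator: RigidTransform
    n_units: int
    assembly: Assembly
    noise_rel: float = 0.0
    noise_baseline: float = 0.0
    params: dict = field(default_factory=dict)

    def transformed(self, t: RigidTransform) -> "SyntheticTruth":
        """Apply a global rigid motion; the generator conjugates accordingly."""
        asm = self.assembly.transformed(t)
        return SyntheticTruth(
            seed=self.seed, unit=asm.seed, generator=asm.generator,
            n_units=self.n_units, assembly=asm,
            noise_rel=self.noise_rel, noise_baseline=self.noise_baseline,
            params=dict(self.params))


def make_ground_truth_assembly(unit: AtomSet,
                               angle_per_unit: float = DEFAULT_ANGLE,
                               rise: float = DEFAULT_RISE,
                               radius: float = DEFAULT_RADIUS,
                               n_units: int = 6, seed: int = 0,
                               clash_cutoff: float | None = None
                               ) -> SyntheticTruth:
    """Open-ring / helical assembly with a known screw generator.

    The unit is centered, displaced by ``radius`` along +x, then replicated
    ``n_units`` times by the screw (``angle_per_unit`` about z, ``rise``
    along z).  The defaults (6 units, 55°, 2 Å rise) sit in the open
    single-turn-ring regime: clash-free, but terminated — a seventh unit
    would clash with the first.  Construction fails loudly if any existing
    pair of units clashes.
    """
    centered = unit.with_coords(unit.coords - unit.coords.mean(axis=0))
    shifted = centered.with_coords(centered.coords + np.array([radius, 0.0, 0.0]))
    gen = screw_transform([0, 0, 1], angle_per_unit, rise)
    asm = build_helix(shifted, gen, n_units)
    cutoff = (clash_cutoff if clash_cutoff is not None
              else default_clash_cutoff(unit))
    if clash_count(asm, cutoff) > 0:
        pair = _first_clashing_pair(asm, cutoff)
        raise ValueError(
            f"ground-truth assembly clashes (units {pair[0]} and {pair[1]} "
            f"at cutoff {cutoff} Å); adjust angle/rise/radius")
    return SyntheticTruth(
        seed=seed, unit=shifted, generator=gen, n_units=n_units, assembly=asm,
        params={"angle_per_unit": angle_per_unit, "rise": rise,
                "radius": radius, "n_units": n_units})


def _first_clashing_pair(asm: Assembly, cutoff: float):
    from scipy.spatial import cKDTree
    trees = [cKDTree(asm.unit_coords(k)) for k in range(asm.n_units)]
    for i in range(asm.n_units):
        for j in range(i + 1, asm.n_units):
            if trees[i].count_neighbors(trees[j], cutoff) > 0:
                return i, j
    return None


def simulate_profile(assembly: Assembly, q_grid, rel_noise: float = 0.02,
                     baseline: float = 0.0, seed: int = 0,
                     ff: FormFactorTable = DEFAULT_FF,
                     bin_width: float = 0.1) -> SAXSProfile:
    """Noisy observation of an assembly's Debye profile.

    σ(q) = rel_noise·I_true(q) + baseline;  I_obs = I_true + Normal(0, σ).
    With ``rel_noise = baseline = 0`` the exact Debye profile is returned
    (no σ column).
    """
    if rel_noise < 0 or baseline < 0:
        raise ValueError("noise parameters must be >= 0")
    truth = debye_profile(assembly, q_grid, ff=ff, bin_width=bin_width,
                          label="synthetic truth")
    if rel_noise == 0.0 and baseline == 0.0:
        return truth
    sigma = rel_noise * truth.I + baseline
    rng = np.random.default_rng(seed)
    I_obs = truth.I + rng.normal(0.0, sigma)
    return SAXSProfile(truth.q, I_obs, sigma,
                       label=f"synthetic data (a={rel_noise}, b={baseline}, "
                             f"seed={seed})")


def default_q_grid(q_max: float = 0.50, n_q: int = 201) -> np.ndarray:
    """Typical experimental momentum-transfer grid, Å⁻¹ (starts above 0)."""
    return np.linspace(q_max / n_q, q_max, n_q)


# ---------------------------------------------------------------------------
# sequence data


def random_consensus(length: int = 240, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def make_synthetic_msa(true_consensus: str, n_seqs: int = 50,
                       sub_rate: float = 0.1, gap_rate: float = 0.0,
                       seed: int = 0) -> MSA:
    """Alignment of sequences mutated i.i.d. per column from a consensus.

    Each position is replaced by a gap with probability ``gap_rate``, else
    substituted (uniformly over the 19 other residues) with probability
    ``sub_rate``.
    """
    for name, rate in (("sub_rate", sub_rate), ("gap_rate", gap_rate)):
        if not (0.0 <= rate < 0.5):
            raise ValueError(f"{name} must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    aas = list(AMINO_ACIDS)
    ids, seqs = [], []
    for s in range(n_seqs):
        chars = []
        for c in true_consensus:
            u = rng.random()
            if u < gap_rate:
                chars.append(GAP)
            elif u < gap_rate + sub_rate:
                others = [a for a in aas if a != c]
                chars.append(others[rng.integers(len(others))])
            else:
                chars.append(c)
        ids.append(f"synth_{s:03d}")
        seqs.append("".join(chars))
    return MSA(ids, seqs)
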