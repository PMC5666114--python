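"""Rigid-transform algebra, superposition, screw parameters, twist–swing split.

Euler convention
----------------
All Euler angles in this package are intrinsic Z–Y–Z, in degrees.  The
convention is fixed here as :data:`EULER_CONVENTION` and stated in every
serialized transform.  At gimbal lock (β ≈ 0 or 180°) the degeneracy is
resolved by reporting γ = 0 and folding the rotation into α.

A :class:`RigidTransform` maps points by ``x ↦ R·x + t``.  Composition
``a.compose(b)`` applies *b first*, then *a* (function composition a∘b).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

EULER_CONVENTION = "ZYZ-intrinsic-degrees"

_ORTHO_TOL = 1e-9


def _check_rotation(rot: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    rot = np.asarray(rot, dtype=float).reshape(3, 3)
    if not np.allclose(rot.T @ rot, np.eye(3), atol=tol):
        raise ValueError("rotation matrix is not orthonormal")
    if np.linalg.det(rot) < 0:
        raise ValueError("rotation matrix is improper (det = -1)")
    return rot


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: rotation (3×3 orthonormal, det +1) + translation (Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler(cls, alpha: float, beta: float, gamma: float,
                   translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from intrinsic Z–Y–Z Euler angles in degrees."""
        rot = Rotation.from_euler("ZYZ", [alpha, beta, gamma], degrees=True)
        return cls(rot.as_matrix(), np.asarray(translation, dtype=float))

    @classmethod
    def from_rotvec(cls, axis, angle_deg: float,
                    translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis)
        return cls(rot.as_matrix(), np.asarray(translation, dtype=float))

    @classmethod
    def from_params(cls, params) -> "RigidTransform":
        """(α, β, γ, tx, ty, tz) — the grid-search parameterization."""
        a, b, g, tx, ty, tz = params
        return cls.from_euler(a, b, g, (tx, ty, tz))

    # -- views -------------------------------------------------------------
    def euler_angles(self) -> tuple[float, float, float]:
        """Intrinsic Z–Y–Z angles in degrees; γ = 0 at gimbal lock."""
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # scipy warns at gimbal lock
            a, b, g = Rotation.from_matrix(self.rotation).as_euler(
                "ZYZ", degrees=True)
        if abs(b) < 1e-6 or abs(abs(b) - 180.0) < 1e-6:
            # fold degenerate γ into α
            if abs(b) < 1e-6:
                a, g = a + g, 0.0
            else:
                a, g = a - g, 0.0
            a = (a + 180.0) % 360.0 - 180.0
        return float(a), float(b), float(g)

    def params(self) -> np.ndarray:
        """(α, β, γ, tx, ty, tz) vector, degrees and Å."""
        a, b, g = self.euler_angles()
        return np.array([a, b, g, *self.translation], dtype=float)

    # -- algebra -----------------------------------------------------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first, then ``self``)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def power(self, k: int) -> "RigidTransform":
        """k-fold self-composition (k ≥ 0)."""
        out = RigidTransform.identity()
        for _ in range(int(k)):
            out = self.compose(out)
        return out

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def rotation_angle(self) -> float:
        """Total rotation angle in degrees, in [0, 180]."""
        cos = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))

    def is_close(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return (np.allclose(self.rotation, other.rotation, atol=atol)
                and np.allclose(self.translation, other.translation, atol=atol))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation": [float(v) for v in self.rotation.ravel()],
            "translation": [float(v) for v in self.translation],
            "convention": EULER_CONVENTION,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"], dtype=float).reshape(3, 3),
                   np.array(d["translation"], dtype=float))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# superposition


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares fit of a mobile atom set onto a target."""

    transform: RigidTransform  # maps mobile onto target
    rmsd: float  # Å, over the matched atoms
    n_atoms: int


def _matched_coords(mobile, target, selection):
    """Pair coordinates between two AtomSets under a matching rule.

    ``selection`` is ``"all"``, an atom-name string (e.g. ``"CA"``), or a
    list of atom names.  Atoms are paired in order after the selection; a
    count mismatch raises with the residue bookkeeping needed to debug it.
    """
    from .structure_io import AtomSet, select_atoms

    def pick(s):
        if isinstance(s, AtomSet):
            if selection in (None, "all"):
                return s
            names = [selection] if isinstance(selection, str) else list(selection)
            return select_atoms(s, atom_names=names)
        return None

    ma, ta = pick(mobile), pick(target)
    if ma is None:  # raw coordinate arrays
        return (np.asarray(mobile, dtype=float),
                np.asarray(target, dtype=float))
    if len(ma) != len(ta):
        res_m = {r for r in ma.residues()}
        res_t = {r for r in ta.residues()}
        raise ValueError(
            f"atom count mismatch after selection ({len(ma)} vs {len(ta)}); "
            f"residues only in mobile: {sorted(res_m - res_t)[:5]}, "
            f"only in target: {sorted(res_t - res_m)[:5]}")
    return ma.coords, ta.coords


def kabsch_superpose(mobile, target, selection="all") -> SuperpositionResult:
    """Optimal proper-rotation least-squares superposition (Kabsch, via SVD).

    Accepts AtomSets (paired in order after applying ``selection``) or raw
    (n, 3) arrays.  Returns the transform mapping mobile onto target and the
    RMSD at the optimum.
    """
    P, Q = _matched_coords(mobile, target, selection)
    if len(P) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) atom configuration: "
                         "rotation is not determined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(RigidTransform(R, t), rmsd, len(P))


def extract_step_transform(unit_i, unit_j, selection="all",
                           rigid_rmsd_warn: float = 2.0) -> RigidTransform:
    """Transform superposing unit_i onto unit_j — the helix step generator.

    Units must be copies of the same chain composition; residues are paired
    in order.  A residual RMSD above ``rigid_rmsd_warn`` logs a warning that
    the units are not rigid copies of each other.
    """
    import logging
    res = kabsch_superpose(unit_i, unit_j, selection=selection)
    if res.rmsd > rigid_rmsd_warn:
        logging.getLogger(__name__).warning(
            "extract_step_transform: residual rmsd %.2f Å exceeds %.2f Å — "
            "units are not rigid copies", res.rmsd, rigid_rmsd_warn)
    return res.transform


# ---------------------------------------------------------------------------
# screw parameters


@dataclass(frozen=True)
class HelicalParams:
    """Screw description of a helix generator."""

    axis: np.ndarray  # unit 3-vector
    angle_per_unit: float  # degrees in (0, 180]
    rise_per_unit: float  # Å, signed along axis
    axis_point: np.ndarray = None  # a point the screw axis passes through

    @property
    def units_per_turn(self) -> float:
        return 360.0 / self.angle_per_unit

    @property
    def pitch(self) -> float:
        """Rise per full turn, Å."""
        return self.rise_per_unit * self.units_per_turn

    def radius_of(self, point) -> float:
        """Distance of a point from the screw axis line, Å."""
        p = np.asarray(point, dtype=float) - self.axis_point
        perp = p - np.dot(p, self.axis) * self.axis
        return float(np.linalg.norm(perp))


def screw_parameters(t: RigidTransform,
                     min_angle_deg: float = 0.1) -> HelicalParams:
    """Axis, per-unit rotation angle and rise of a screw transformation.

    The axis is the rotation's fixed direction (eigenvector for eigenvalue 1),
    with sign chosen so the angle lies in (0, 180]; the rise is the
    translation component along that axis and carries the sign.  Near-pure
    translations (angle < ``min_angle_deg``) are rejected: their axis is
    degenerate.
    """
    rv = Rotation.from_matrix(t.rotation).as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rv)))
    if angle < min_angle_deg:
        raise ValueError(
            f"rotation angle {angle:.4f}° below {min_angle_deg}°: "
            "screw axis is degenerate for a near-pure translation")
    axis = rv / np.linalg.norm(rv)
    rise = float(np.dot(t.translation, axis))
    # a point on the axis: solve (I - R) x = t_perp in the plane ⊥ axis
    t_perp = t.translation - rise * axis
    anchor = np.linalg.pinv(np.eye(3) - t.rotation) @ t_perp
    return HelicalParams(axis=axis, angle_per_unit=angle, rise_per_unit=rise,
                         axis_point=anchor)


def screw_discrepancy(step: RigidTransform, reference: RigidTransform,
                      anchor_point) -> dict:
    """Conjugation-invariant distance between two screw generators.

    A helix generator acting on a *fixed* seed unit is identifiable from the
    assembly shape only up to near-exact conjugations (rotating the whole
    assembly about its own axis, or shifting the axis tangentially, leaves
    the model nearly congruent).  This compares the invariant description
    instead: rotation angle, signed rise, axis direction, and the distance
    of ``anchor_point`` (typically the seed-unit centroid) from the screw
    axis.  Returns deltas as a dict with keys ``d_angle_deg``, ``d_rise``,
    ``axis_tilt_deg`` and ``d_radius``.
    """
    a = screw_parameters(step)
    b = screw_parameters(reference)
    sign = np.sign(np.dot(a.axis, b.axis)) or 1.0
    tilt = float(np.degrees(np.arccos(
        np.clip(abs(np.dot(a.axis, b.axis)), -1.0, 1.0))))
    return {
        "d_angle_deg": a.angle_per_unit - b.angle_per_unit,
        "d_rise": sign * a.rise_per_unit - b.rise_per_unit,
        "axis_tilt_deg": tilt,
        "d_radius": a.radius_of(anchor_point) - b.radius_of(anchor_point),
    }


def screw_transform(axis, angle_deg: float, rise: float) -> RigidTransform:
    """Build the screw with given axis, rotation angle and axial rise.

    Inverse of :func:`screw_parameters` for screws whose axis passes through
    the origin.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return RigidTransform.from_rotvec(axis, angle_deg, translation=rise * axis)


# ---------------------------------------------------------------------------
# twist–swing (hinge–shear) decomposition


@dataclass(frozen=True)
class RotationDecomposition:
    """Split of a rotation into twist about a main axis and a ⊥ swing.

    ``R = R_swing ∘ R_twist`` with the twist ("shear") about ``main_axis``
    and the swing ("hinge") about an axis perpendicular to it.  All angles
    in degrees, in [0, 180].
    """

    total_angle: float
    twist_angle: float
    swing_angle: float
    main_axis: np.ndarray
    twist: RigidTransform = field(repr=False, default=None)
    swing: RigidTransform = field(repr=False, default=None)


def decompose_rotation(t: RigidTransform, main_axis) -> RotationDecomposition:
    """Twist–swing decomposition of the rotational part of ``t``.

    Quaternion construction: the twist is the projection of the rotation
    quaternion onto the (1, main_axis) plane, the swing is what remains;
    the swing axis is perpendicular to ``main_axis`` by construction.
    """
    a = np.asarray(main_axis, dtype=float)
    norm = np.linalg.norm(a)
    if norm < 1e-12:
        raise ValueError("main_axis is not normalizable")
    a = a / norm

    q = Rotation.from_matrix(t.rotation).as_quat()  # (x, y, z, w)
    v, w = q[:3], q[3]
    proj = float(np.dot(v, a))
    tq = np.array([*(proj * a), w])
    n = np.linalg.norm(tq)
    if n < 1e-12:
        # 180° rotation about an axis ⊥ main_axis: pure swing
        twist_rot = Rotation.identity()
    else:
        twist_rot = Rotation.from_quat(tq / n)
    total = t.rotation_angle()
    twist_angle = float(np.degrees(twist_rot.magnitude()))
    swing_rot = Rotation.from_matrix(t.rotation) * twist_rot.inv()
    swing_angle = float(np.degrees(swing_rot.magnitude()))
    return RotationDecomposition(
        total_angle=total,
        twist_angle=twist_angle,
        swing_angle=swing_angle,
        main_axis=a,
        twist=RigidTransform(twist_rot.as_matrix(), np.zeros(3)),
        swing=RigidTransform(swing_rot.as_matrix(), np.zeros(3)),
    )
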