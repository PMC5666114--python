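"""Grid-search refinement of symmetric assemblies against a SAXS profile.

The core procedure: parameterize the inter-unit step transform by intrinsic
Z–Y–Z Euler angles (degrees) and a translation (Å), enumerate candidate steps
on a grid around a starting transform, build the n-unit symmetric assembly
for each, discard sterically clashing models, score the rest by Debye-profile
χ² against the data, and rank.  Model classes (open helical segments vs
closed rings of six or seven units at scanned radii) are compared by their
best χ².  A derivative-free coordinate descent refines the best grid model
off-lattice.

Two enumeration modes are provided.  ``product`` is the full Cartesian grid
over all six parameters (capped).  ``sweep`` scans axis-aligned 1-D series —
varying one parameter at a time, as the original modelling of helical series
varied individual angles and translation components — and iterates the sweeps
from the running best point until no parameter changes, which keeps large
searches tractable while remaining fully deterministic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .assembly import Assembly, RingSpec, build_closed_ring, build_helix, \
    clash_count, default_clash_cutoff
from .geometry import RigidTransform
from .saxs import DEFAULT_FF, FitResult, FormFactorTable, SAXSProfile, \
    chi_square_fit, debye_intensity_from_pairs
from .structure_io import AtomSet

logger = logging.getLogger(__name__)

PARAM_NAMES = ("alpha", "beta", "gamma", "tx", "ty", "tz")


@dataclass(frozen=True)
class GridSpec:
    """Per-parameter (center, half-range, step) for (α, β, γ, tx, ty, tz).

    Angles in degrees, translations in Å.  Axis k runs over
    ``center[k] + j·step[k]`` for integer j with ``|j·step[k]| ≤ half_range[k]``.
    """

    centers: tuple
    half_ranges: tuple
    steps: tuple
    n_units: int = 6

    def __post_init__(self) -> None:
        for name in ("centers", "half_ranges", "steps"):
            v = tuple(float(x) for x in getattr(self, name))
            if len(v) != 6:
                raise ValueError(f"{name} must have 6 entries (α β γ tx ty tz)")
            object.__setattr__(self, name, v)
        if any(s <= 0 for s in self.steps):
            raise ValueError("steps must be > 0")
        if any(h < 0 for h in self.half_ranges):
            raise ValueError("half_ranges must be >= 0")

    @classmethod
    def around(cls, center: RigidTransform, angle_half: float = 5.0,
               angle_step: float = 1.0, trans_half: float = 3.0,
               trans_step: float = 1.0, n_units: int = 6) -> "GridSpec":
        """Symmetric grid around a transform: ±angle_half at angle_step on all
        three Euler angles, ±trans_half at trans_step on the translation."""
        return cls(
            centers=tuple(center.params()),
            half_ranges=(angle_half,) * 3 + (trans_half,) * 3,
            steps=(angle_step,) * 3 + (trans_step,) * 3,
            n_units=n_units,
        )

    def axis(self, k: int) -> np.ndarray:
        n = int(np.floor(self.half_ranges[k] / self.steps[k] + 1e-9))
        return self.centers[k] + self.steps[k] * np.arange(-n, n + 1)

    @property
    def grid_size(self) -> int:
        size = 1
        for k in range(6):
            size *= len(self.axis(k))
        return size

    @property
    def center_transform(self) -> RigidTransform:
        return RigidTransform.from_params(self.centers)


def enumerate_grid(spec: GridSpec, cap: int = 10 ** 6):
    """Full product grid in deterministic lexicographic order.

    Yields (params 6-vector, RigidTransform); the center is always included.
    Raises if the predicted grid size exceeds ``cap``.
    """
    size = spec.grid_size
    if size > cap:
        raise ValueError(
            f"grid size {size} exceeds cap {cap}; narrow the ranges or "
            "raise the cap explicitly")
    logger.info("enumerating product grid of %d transforms", size)
    axes = [spec.axis(k) for k in range(6)]
    for combo in itertools.product(*axes):
        p = np.array(combo, dtype=float)
        yield p, RigidTransform.from_params(p)


def enumerate_sweeps(spec: GridSpec, at: np.ndarray | None = None):
    """Axis-aligned 1-D sweeps: vary one parameter at a time around ``at``
    (default: the grid centers).  The center point appears exactly once."""
    base = np.array(spec.centers if at is None else at, dtype=float)
    seen = set()
    for k in range(6):
        for v in spec.axis(k):
            p = base.copy()
            p[k] = v
            key = tuple(np.round(p, 9))
            if key in seen:
                continue
            seen.add(key)
            yield p, RigidTransform.from_params(p)


# ---------------------------------------------------------------------------
# scoring


class ModelScorer:
    """Scores candidate step transforms: build, clash-filter, Debye, χ².

    Exploits the assembly's symmetry: for placements g^k of a rigid unit the
    pair-distance multiset decomposes into the intra-unit distances (identical
    in every copy, multiplicity n) and, for each separation k = 1..n−1, the
    unit-0-to-unit-k cross distances with multiplicity n−k.  Each candidate
    then costs n−1 small cdist blocks instead of one large pdist, and the
    clash filter reads off the same blocks.  Identical results to scoring the
    expanded assembly (asserted in the test suite).
    """

    def __init__(self, seed_unit: AtomSet, n_units: int,
                 experiment: SAXSProfile, ff: FormFactorTable = DEFAULT_FF,
                 bin_width: float = 0.5, clash_cutoff: float | None = None):
        if experiment.sigma is None:
            raise ValueError("experiment must carry uncertainties")
        self.seed = seed_unit
        self.n_units = int(n_units)
        self.experiment = experiment
        self.bin_width = float(bin_width)
        self.clash_cutoff = (clash_cutoff if clash_cutoff is not None
                             else default_clash_cutoff(seed_unit))
        f_unit = ff.lookup(seed_unit.elements)
        self._f_unit = f_unit
        self._X = seed_unit.coords
        n = self.n_units
        # intra-unit part, multiplicity n
        self._d_intra = pdist(self._X)
        iu, ju = np.triu_indices(len(f_unit), k=1)
        self._w_intra = n * (f_unit[iu] * f_unit[ju])
        # cross-pair weights f_a f_b for one (unit0, unitk) block, row-major
        self._w_cross = np.outer(f_unit, f_unit).ravel()
        self.self_term = float(n * (f_unit ** 2).sum())
        self.n_evaluated = 0
        self.n_clashing = 0

    def assembly_for(self, step: RigidTransform) -> Assembly:
        return build_helix(self.seed, step, self.n_units)

    def score(self, step: RigidTransform, model_id: str = ""):
        """Return (FitResult | None, clash_count); None when the model clashes."""
        from scipy.spatial.distance import cdist

        self.n_evaluated += 1
        n = self.n_units
        ds = [self._d_intra]
        ws = [self._w_intra]
        g_k = step
        for k in range(1, n):
            D = cdist(self._X, g_k.apply(self._X)).ravel()
            n_close = int((D <= self.clash_cutoff).sum())
            if n_close > 0:
                self.n_clashing += 1
                return None, (n - k) * n_close
            ds.append(D)
            ws.append((n - k) * self._w_cross)
            if k < n - 1:
                g_k = step @ g_k
        I = debye_intensity_from_pairs(
            self.experiment.q, np.concatenate(ds), np.concatenate(ws),
            self.self_term, self.bin_width)
        fit = chi_square_fit(SAXSProfile(self.experiment.q, I),
                             self.experiment, model_id=model_id)
        return fit, 0


@dataclass
class RefinementResult:
    """Ranked outcome of a grid scan."""

    ranked: list  # [(params 6-vector, FitResult)], ascending χ²
    n_evaluated: int
    n_clashing: int
    spec: GridSpec
    mode: str
    seed_unit: AtomSet = field(repr=False, default=None)

    @property
    def best_params(self) -> np.ndarray:
        return self.ranked[0][0]

    @property
    def best_fit(self) -> FitResult:
        return self.ranked[0][1]

    @property
    def best_transform(self) -> RigidTransform:
        return RigidTransform.from_params(self.best_params)

    @property
    def best_assembly(self) -> Assembly:
        return build_helix(self.seed_unit, self.best_transform,
                           self.spec.n_units)

    def to_table(self) -> list[dict]:
        rows = []
        for rank, (p, fit) in enumerate(self.ranked, start=1):
            row = {"rank": rank, **{n: float(v) for n, v in zip(PARAM_NAMES, p)},
                   "chi2": fit.chi2, "scale": fit.scale}
            rows.append(row)
        return rows


def _frontier_moves() -> np.ndarray:
    """Lattice moves for the best-first search: single-axis ±1 steps, all
    two-axis ±1 diagonals, and the ±1 diagonals of the angle and translation
    triples — enough to follow the curved, coupled valleys of the χ² surface."""
    moves = []
    for k in range(6):
        for s in (1, -1):
            m = [0] * 6
            m[k] = s
            moves.append(m)
    for k1 in range(6):
        for k2 in range(k1 + 1, 6):
            for s1 in (1, -1):
                for s2 in (1, -1):
                    m = [0] * 6
                    m[k1], m[k2] = s1, s2
                    moves.append(m)
    for dims in ((0, 1, 2), (3, 4, 5)):
        for signs in itertools.product((1, -1), repeat=3):
            m = [0] * 6
            for k, s in zip(dims, signs):
                m[k] = s
            moves.append(m)
    return np.array(moves, dtype=float)


_FRONTIER_MOVES = _frontier_moves()


def refine_against_saxs(seed_unit: AtomSet, spec: GridSpec,
                        experiment: SAXSProfile,
                        clash_cutoff: float | None = None,
                        mode: str = "frontier",
                        ff: FormFactorTable = DEFAULT_FF,
                        bin_width: float = 0.5,
                        max_rounds: int = 10,
                        patience: int = 40,
                        max_expansions: int = 150,
                        grid_cap: int = 10 ** 6) -> RefinementResult:
    """Enumerate step transforms, filter clashes, score by χ², rank.

    Modes (all deterministic for fixed inputs; clashing models are excluded
    from the ranking but counted):

    ``product``
        The full 6-D Cartesian grid (size-capped).
    ``sweep``
        Axis-aligned 1-D sweeps iterated from the running best point until
        no parameter changes (at most ``max_rounds`` rounds).  Cheap, but can
        stall on the strongly coupled angle/translation valleys.
    ``frontier`` (default)
        Best-first lattice search: repeatedly expand the lowest-χ² evaluated
        grid point by its neighborhood moves (single-axis, two-axis and
        angle/translation-triple ±1 steps), allowing temporarily uphill
        intermediates to be traversed in χ² order.  Stops after ``patience``
        expansions without improvement or ``max_expansions`` total.
    """
    scorer = ModelScorer(seed_unit, spec.n_units, experiment, ff=ff,
                         bin_width=bin_width, clash_cutoff=clash_cutoff)
    results: dict[tuple, tuple[np.ndarray, FitResult]] = {}

    def eval_point(p, t=None):
        key = tuple(np.round(p, 9))
        if key in results:
            return results[key][1]
        fit, _ = scorer.score(t if t is not None
                              else RigidTransform.from_params(p))
        if fit is not None:
            results[key] = (p, fit)
        return fit

    if mode == "product":
        for p, t in enumerate_grid(spec, cap=grid_cap):
            eval_point(p, t)
    elif mode == "sweep":
        current = np.array(spec.centers, dtype=float)
        for _ in range(max_rounds):
            best_chi2 = np.inf
            best_p = None
            for p, t in enumerate_sweeps(spec, at=current):
                fit = eval_point(p, t)
                if fit is not None and fit.chi2 < best_chi2:
                    best_chi2, best_p = fit.chi2, p
            if best_p is None:
                break
            if np.allclose(best_p, current):
                break
            current = best_p
    elif mode == "frontier":
        import heapq

        centers = np.array(spec.centers, dtype=float)
        halves = np.array(spec.half_ranges, dtype=float)
        steps = np.array(spec.steps, dtype=float)
        # warm start: iterated axis sweeps position the search near the
        # basin cheaply; every swept point seeds the frontier heap
        current = centers.copy()
        for _ in range(6):
            moved = False
            best_chi2 = np.inf
            best_p = None
            for p, t in enumerate_sweeps(spec, at=current):
                fit = eval_point(p, t)
                if fit is not None and fit.chi2 < best_chi2:
                    best_chi2, best_p = fit.chi2, p
            if best_p is None or np.allclose(best_p, current):
                break
            current = best_p
        frontier = [(fit.chi2, tuple(np.round(p, 9)))
                    for p, fit in results.values()]
        if not frontier:
            frontier = [(np.inf, tuple(np.round(centers, 9)))]
        heapq.heapify(frontier)
        expanded: set = set()
        best_chi2 = min(c for c, _ in frontier)
        since_improved = 0
        n_expanded = 0
        while (frontier and n_expanded < max_expansions
               and since_improved < patience):
            chi2, pt = heapq.heappop(frontier)
            if pt in expanded:
                continue
            expanded.add(pt)
            n_expanded += 1
            improved = False
            for mv in _FRONTIER_MOVES:
                p = np.array(pt) + mv * steps
                if np.any(np.abs(p - centers) > halves + 1e-9):
                    continue
                key = tuple(np.round(p, 9))
                if key in expanded:
                    continue
                fit = eval_point(p)
                if fit is None:
                    continue
                heapq.heappush(frontier, (fit.chi2, key))
                if fit.chi2 < best_chi2 - 1e-12:
                    best_chi2 = fit.chi2
                    improved = True
            since_improved = 0 if improved else since_improved + 1
    else:
        raise ValueError(
            f"unknown mode {mode!r} (use 'product', 'sweep' or 'frontier')")

    if not results:
        raise RuntimeError(
            "every candidate model clashes at the given cutoff; widen the "
            "grid or revisit the starting transform")
    ranked = sorted(results.values(), key=lambda item: item[1].chi2)
    logger.info("refinement: %d evaluated, %d clashing, best chi2 %.4g",
                scorer.n_evaluated, scorer.n_clashing, ranked[0][1].chi2)
    return RefinementResult(ranked=ranked, n_evaluated=scorer.n_evaluated,
                            n_clashing=scorer.n_clashing, spec=spec,
                            mode=mode, seed_unit=seed_unit)


def rescore_all_atom(result: RefinementResult, seed_atoms: AtomSet,
                     experiment: SAXSProfile, top: int = 10,
                     ff: FormFactorTable = DEFAULT_FF,
                     bin_width: float = 0.1) -> RefinementResult:
    """Re-rank the top models of a coarse-grained scan with all-atom profiles.

    ``seed_atoms`` is the atomic seed unit the coarse-grained scan stood in
    for; only the ``top`` ranked models are rescored (grid scans are run on
    beads for speed, the leaders re-checked at full resolution).
    """
    scorer = ModelScorer(seed_atoms, result.spec.n_units, experiment,
                         ff=ff, bin_width=bin_width)
    rescored = []
    for p, _ in result.ranked[:top]:
        fit, _ = scorer.score(RigidTransform.from_params(p))
        if fit is not None:
            rescored.append((p, fit))
    rescored.sort(key=lambda item: item[1].chi2)
    return RefinementResult(ranked=rescored, n_evaluated=result.n_evaluated,
                            n_clashing=result.n_clashing, spec=result.spec,
                            mode=result.mode + "+all-atom", seed_unit=seed_atoms)


# ---------------------------------------------------------------------------
# model-class comparison


@dataclass(frozen=True)
class ClassResult:
    """Best model of one geometry class (e.g. 'ring6', 'helix')."""

    name: str
    fit: FitResult
    params: dict
    n_scored: int
    n_clashing: int


def _centered(seed: AtomSet) -> AtomSet:
    return seed.with_coords(seed.coords - seed.centroid())


def ring_radius_scan(seed_unit: AtomSet, n_ring: int, radii,
                     experiment: SAXSProfile,
                     ff: FormFactorTable = DEFAULT_FF,
                     bin_width: float = 0.1,
                     clash_cutoff: float | None = None) -> ClassResult:
    """Closed C_n rings at each radius (1 Å scan by convention); best χ².

    The seed is centered at the origin first, so ``radius`` is the distance
    of the unit centroid from the symmetry axis.  A heptamer scan uses the
    per-unit rotation 360/7 = 51.43°.
    """
    seed0 = _centered(seed_unit)
    cutoff = (clash_cutoff if clash_cutoff is not None
              else default_clash_cutoff(seed_unit))
    best = None
    n_scored = n_clash = 0
    for radius in radii:
        asm = build_closed_ring(seed0, RingSpec(n_ring, float(radius)))
        if clash_count(asm, cutoff) > 0:
            n_clash += 1
            continue
        from .saxs import debye_profile
        model = debye_profile(asm, experiment.q, ff=ff, bin_width=bin_width)
        fit = chi_square_fit(model, experiment,
                             model_id=f"ring{n_ring}_r{float(radius):g}")
        n_scored += 1
        if best is None or fit.chi2 < best[0].chi2:
            best = (fit, float(radius))
    if best is None:
        raise RuntimeError(
            f"all ring-{n_ring} radii clash; extend the radius scan")
    fit, radius = best
    return ClassResult(name=f"ring{n_ring}", fit=fit,
                       params={"n_units": n_ring, "radius": radius,
                               "rotation_per_unit": 360.0 / n_ring},
                       n_scored=n_scored, n_clashing=n_clash)


def model_selection(seed_unit: AtomSet, experiment: SAXSProfile,
                    helix_spec: GridSpec, radii=None,
                    ring_ns=(6, 7), mode: str = "frontier",
                    ff: FormFactorTable = DEFAULT_FF,
                    bin_width: float = 0.5,
                    clash_cutoff: float | None = None) -> list[ClassResult]:
    """Compare model classes: open helical segments vs closed 6- and 7-rings.

    Rings are scanned over ``radii`` (default 10–80 Å at the conventional
    1 Å interval); the helix class is refined over ``helix_spec``.  Returns
    per-class best fits ranked by χ² (ascending).
    """
    if radii is None:
        radii = np.arange(10.0, 81.0, 1.0)
    out = []
    for n_ring in ring_ns:
        out.append(ring_radius_scan(seed_unit, n_ring, radii, experiment,
                                    ff=ff, bin_width=bin_width,
                                    clash_cutoff=clash_cutoff))
    ref = refine_against_saxs(seed_unit, helix_spec, experiment,
                              clash_cutoff=clash_cutoff, mode=mode,
                              ff=ff, bin_width=bin_width)
    out.append(ClassResult(
        name=f"helix{helix_spec.n_units}",
        fit=ref.best_fit,
        params={n: float(v) for n, v in zip(PARAM_NAMES, ref.best_params)},
        n_scored=ref.n_evaluated - ref.n_clashing,
        n_clashing=ref.n_clashing))
    return sorted(out, key=lambda c: c.fit.chi2)


# ---------------------------------------------------------------------------
# continuous local refinement


def local_refine(start: RigidTransform, seed_unit: AtomSet,
                 experiment: SAXSProfile, n_units: int,
                 step_init: float = 0.5, step_min: float = 0.01,
                 ff: FormFactorTable = DEFAULT_FF, bin_width: float = 0.5,
                 clash_cutoff: float | None = None,
                 max_iter: int = 2000,
                 polish: str | None = "powell") -> tuple[RigidTransform,
                                                         FitResult]:
    """Derivative-free continuous descent on the six step parameters.

    Two stages.  First, coordinate descent: moves of ``step_init`` (degrees /
    Å, half a typical grid step) along one parameter at a time, halving the
    move size whenever a full pass yields no improvement, down to
    ``step_min``.  Axis-aligned moves zigzag on the curved, strongly coupled
    valleys of the χ² surface, so a Powell direction-set polish (scipy)
    follows by default and handles the correlated directions.  Clashing trial
    points are rejected; the returned χ² never exceeds the starting χ².
    """
    scorer = ModelScorer(seed_unit, n_units, experiment, ff=ff,
                         bin_width=bin_width, clash_cutoff=clash_cutoff)

    def chi2_of(p):
        fit, _ = scorer.score(RigidTransform.from_params(p))
        return (np.inf, None) if fit is None else (fit.chi2, fit)

    current = start.params()
    best_chi2, best_fit = chi2_of(current)
    if best_fit is None:
        raise ValueError("starting model clashes; cannot refine locally")
    step = float(step_init)
    it = 0
    while step >= step_min and it < max_iter:
        improved = False
        for k in range(6):
            for sign in (+1.0, -1.0):
                trial = current.copy()
                trial[k] += sign * step
                chi2, fit = chi2_of(trial)
                it += 1
                if chi2 < best_chi2 - 1e-15:
                    current, best_chi2, best_fit = trial, chi2, fit
                    improved = True
                    break
        if not improved:
            step *= 0.5

    if polish == "powell":
        from scipy.optimize import minimize

        def objective(p):
            chi2, _ = chi2_of(p)
            return 1e12 if not np.isfinite(chi2) else chi2

        res = minimize(objective, current, method="Powell",
                       options={"xtol": 1e-4, "ftol": 1e-10,
                                "maxfev": max_iter})
        chi2, fit = chi2_of(res.x)
        if fit is not None and chi2 < best_chi2:
            current, best_chi2, best_fit = np.asarray(res.x), chi2, fit
    elif polish is not None:
        raise ValueError(f"unknown polish {polish!r}")
    return RigidTransform.from_params(current), best_fit
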