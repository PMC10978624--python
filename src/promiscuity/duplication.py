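"""Selection, duplication and specialisation over constrained feasible spaces.

Two evolutionary scenarios are solved per feasible space:

* **Ancestor** — a single-copy generalist under selection for all ``n``
  reactions.  Selection is modelled as maximisation of a diminishing-returns
  fitness F(x) = sum_i x_i / (x_i + K) (strictly increasing and strictly
  concave per coordinate, default K = 0.5) over the feasible polytope.
* **Duplicate** — after duplication, each copy is under positive selection
  for exactly one reaction ``r``: a linear program maximises x_r.  The other
  ("neutral") activities drift; a variability analysis (two LPs per neutral
  reaction, with x_r fixed at its optimum) yields the attainable range of
  each, and loss-of-function erosion is modelled by reporting each neutral
  activity at its variability *minimum*.

*Frustration* of a variant is the mean shortfall 1 - x_i over the reactions
under selection; an ancestor is frustrated when the constraint structure
makes the all-ones vector unreachable.  The study table across all
enumerated spaces links the mean antagonism score Â and the dissimilarity of
a space to the gain from duplication, residual frustration, and the
promiscuity of the specialised duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog, minimize

from .constraints import (
    FeasibleSpace,
    antagonism_mean,
    dissimilarity_score,
    enumerate_feasible_spaces,
)
from .kinetics import promiscuity_index

FEASIBILITY_TOL = 1e-6
FRUSTRATION_TOL = 1e-6
FIX_SLACK = 1e-9


class SolverError(RuntimeError):
    """An optimisation did not converge; carries the solver status message."""


@dataclass(frozen=True)
class FitnessModel:
    """Diminishing-returns fitness F(x) = sum_{i in S} x_i / (x_i + K)."""

    n: int
    selected: tuple[int, ...]
    saturation_constant: float = 0.5

    def __post_init__(self) -> None:
        if not self.selected:
            raise ValueError("at least one reaction must be under selection")
        if self.saturation_constant <= 0:
            raise ValueError("saturation_constant must be > 0")

    def value(self, x: np.ndarray) -> float:
        xs = np.asarray(x, dtype=float)[list(self.selected)]
        return float((xs / (xs + self.saturation_constant)).sum())

    def gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros(self.n)
        xs = np.asarray(x, dtype=float)[list(self.selected)]
        g[list(self.selected)] = self.saturation_constant / (xs + self.saturation_constant) ** 2
        return g


@dataclass(frozen=True)
class VariantResult:
    """An optimised efficiency vector with its fitness and frustration."""

    x: np.ndarray
    role: str  # "ancestor" or "duplicate(r)"
    fitness: float
    frustration: float
    promiscuity: float


@dataclass(frozen=True)
class DuplicationOutcome:
    """A specialised duplicate: LP optimum plus post-drift reported vector."""

    space_id: str
    reaction: int
    x_selected_star: float
    neutral_ranges: dict[int, tuple[float, float]]
    reported_vector: np.ndarray
    gain: float
    duplicate_promiscuity: float
    duplicate_frustration: float


def _linear_args(space: FeasibleSpace):
    A, b = space.halfspaces
    if A.size == 0:
        return None, None
    return A, b


def _chebyshev_centre(space: FeasibleSpace) -> np.ndarray:
    """Deterministic strictly interior start point (Chebyshev centre LP)."""
    n = space.n
    A, b = space.halfspaces
    # Variables (x, r): maximise r s.t. a.x + ||a|| r <= b, r <= x_i <= 1 - r.
    rows, rhs = [], []
    for a, bi in zip(A, b):
        rows.append(np.append(a, np.linalg.norm(a)))
        rhs.append(bi)
    for i in range(n):
        e = np.zeros(n)
        e[i] = -1.0
        rows.append(np.append(e, 1.0))  # -x_i + r <= 0
        rhs.append(0.0)
        e = np.zeros(n)
        e[i] = 1.0
        rows.append(np.append(e, 1.0))  # x_i + r <= 1
        rhs.append(1.0)
    c = np.zeros(n + 1)
    c[-1] = -1.0
    res = linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs),
                  bounds=[(None, None)] * n + [(0, None)], method="highs")
    if not res.success:
        raise SolverError(f"Chebyshev centre LP failed for {space.space_id}: {res.message}")
    return np.clip(res.x[:-1], 0.0, 1.0)


def _check_feasible(space: FeasibleSpace, x: np.ndarray, label: str) -> None:
    if not space.contains(x, tol=FEASIBILITY_TOL):
        raise SolverError(f"{label} returned an infeasible point for {space.space_id}: {x}")


def optimize_ancestor(
    space: FeasibleSpace, fitness: FitnessModel | None = None
) -> VariantResult:
    """Fitness-maximising generalist ancestor of a feasible space.

    Maximises the concave fitness over the polytope with a deterministic
    SLSQP configuration started from the Chebyshev centre.  The optimum is
    unique (strictly concave objective); among numerically tied candidate
    solutions the lexicographically largest is kept.
    """
    n = space.n
    if fitness is None:
        fitness = FitnessModel(n=n, selected=tuple(range(n)))
    A, b = _linear_args(space)
    constraints = []
    if A is not None:
        constraints.append({"type": "ineq", "fun": lambda x: b - A @ x, "jac": lambda x: -A})

    def objective(x: np.ndarray) -> float:
        return -fitness.value(x)

    def grad(x: np.ndarray) -> np.ndarray:
        return -fitness.gradient(x)

    candidates = []
    for x0 in (_chebyshev_centre(space), np.full(n, 0.25)):
        res = minimize(
            objective, x0, jac=grad, bounds=[(0.0, 1.0)] * n,
            constraints=constraints, method="SLSQP",
            options={"ftol": 1e-12, "maxiter": 500},
        )
        if not res.success:
            raise SolverError(
                f"ancestor optimisation failed for {space.space_id}: {res.message}"
            )
        candidates.append(np.clip(res.x, 0.0, 1.0))

    best_value = max(fitness.value(x) for x in candidates)
    tied = [x for x in candidates if fitness.value(x) >= best_value - 1e-8]
    x_star = max(tied, key=tuple)  # lexicographically largest among ties
    _check_feasible(space, x_star, "ancestor optimisation")
    frustration = float(np.mean(1.0 - x_star[list(fitness.selected)]))
    result = VariantResult(
        x=x_star,
        role="ancestor",
        fitness=fitness.value(x_star),
        frustration=frustration,
        promiscuity=promiscuity_index(x_star) if x_star.sum() > 0 else 0.0,
    )
    space._ancestor = result
    return result


def ancestor_of(space: FeasibleSpace) -> VariantResult:
    """The cached ancestor of a space, computed on first use."""
    if space._ancestor is None:
        optimize_ancestor(space)
    return space._ancestor  # type: ignore[return-value]


def _solve_lp(space: FeasibleSpace, c: np.ndarray, bounds) -> np.ndarray:
    A, b = _linear_args(space)
    res = linprog(c, A_ub=A, b_ub=b, bounds=bounds, method="highs")
    if not res.success:
        raise SolverError(f"LP failed for {space.space_id}: {res.message}")
    return res.x


def neutral_variability(
    space: FeasibleSpace, r: int, x_r_star: float
) -> dict[int, tuple[float, float]]:
    """Attainable (min, max) of each neutral activity with x_r fixed at its optimum.

    Two LPs per neutral reaction over the polytope intersected with
    x_r = x_r_star (a slack of 1e-9 absorbs LP round-off).
    """
    n = space.n
    lo = max(x_r_star - FIX_SLACK, 0.0)
    hi = min(x_r_star + FIX_SLACK, 1.0)
    ranges: dict[int, tuple[float, float]] = {}
    for q in range(n):
        if q == r:
            continue
        bounds = [(0.0, 1.0)] * n
        bounds[r] = (lo, hi)
        c = np.zeros(n)
        c[q] = 1.0
        q_min = _solve_lp(space, c, bounds)[q]
        q_max = _solve_lp(space, -c, bounds)[q]
        ranges[q] = (float(np.clip(q_min, 0.0, 1.0)), float(np.clip(q_max, 0.0, 1.0)))
    return ranges


def optimize_duplicate(
    space: FeasibleSpace,
    r: int,
    ancestor: VariantResult | None = None,
    joint_neutral_minimum: bool = False,
) -> DuplicationOutcome:
    """A duplicate under positive selection for reaction ``r`` alone.

    Maximises x_r by linear programming, runs the neutral variability
    analysis at the optimum, and reports the duplicate as x_r at its maximum
    with every neutral activity eroded to its variability minimum.  With
    ``joint_neutral_minimum=True`` the neutral activities are instead taken
    from a single LP minimising their sum at fixed x_r (the per-neutral
    minima need not be jointly attainable).  Gain is measured against the
    space's generalist ancestor and is non-negative by construction.
    """
    n = space.n
    if not 0 <= r < n:
        raise ValueError(f"reaction index {r} out of range for n={n}")
    if ancestor is None:
        ancestor = ancestor_of(space)

    c = np.zeros(n)
    c[r] = -1.0
    x_opt = _solve_lp(space, c, [(0.0, 1.0)] * n)
    _check_feasible(space, x_opt, "duplicate LP")
    x_r_star = float(np.clip(x_opt[r], 0.0, 1.0))

    ranges = neutral_variability(space, r, x_r_star)

    reported = np.empty(n)
    reported[r] = x_r_star
    if joint_neutral_minimum:
        bounds = [(0.0, 1.0)] * n
        bounds[r] = (max(x_r_star - FIX_SLACK, 0.0), min(x_r_star + FIX_SLACK, 1.0))
        c_sum = np.ones(n)
        c_sum[r] = 0.0
        x_joint = _solve_lp(space, c_sum, bounds)
        for q in range(n):
            if q != r:
                reported[q] = float(np.clip(x_joint[q], 0.0, 1.0))
    else:
        for q, (q_min, _) in ranges.items():
            reported[q] = q_min

    gain = x_r_star - float(ancestor.x[r])
    if gain < -1e-7:
        raise SolverError(
            f"negative duplication gain {gain} for {space.space_id}, reaction {r}"
        )
    return DuplicationOutcome(
        space_id=space.space_id,
        reaction=r,
        x_selected_star=x_r_star,
        neutral_ranges=ranges,
        reported_vector=reported,
        gain=max(gain, 0.0),
        duplicate_promiscuity=promiscuity_index(reported) if reported.sum() > 0 else 0.0,
        duplicate_frustration=1.0 - x_r_star,
    )


def duplication_study(
    n: int,
    saturation_constant: float = 0.5,
    spaces: Sequence[FeasibleSpace] | None = None,
) -> pd.DataFrame:
    """Ancestor plus all ``n`` specialised duplicates for every feasible space.

    Returns one row per (space, duplicated reaction) — n * C(k + 4, k) rows
    — with the space descriptors (Â, relative dissimilarity), the ancestor's
    frustration, and the duplicate's gain, frustration, promiscuity and best
    efficiency.  Deterministic.
    """
    if spaces is None:
        spaces = enumerate_feasible_spaces(n)
    rows = []
    for space in spaces:
        fitness = FitnessModel(n=space.n, selected=tuple(range(space.n)),
                               saturation_constant=saturation_constant)
        ancestor = optimize_ancestor(space, fitness)
        a_hat = antagonism_mean(space)
        d_rel = dissimilarity_score(space)
        for r in range(space.n):
            outcome = optimize_duplicate(space, r, ancestor=ancestor)
            rows.append(
                {
                    "space_id": space.space_id,
                    "classes": "".join(c.letter for c in space.classes),
                    "A_hat": a_hat,
                    "D_rel": d_rel,
                    "ancestor_frustration": ancestor.frustration,
                    "reaction": r,
                    "gain": outcome.gain,
                    "duplicate_frustration": outcome.duplicate_frustration,
                    "duplicate_promiscuity": outcome.duplicate_promiscuity,
                    "duplicate_best_efficiency": float(outcome.reported_vector.max()),
                }
            )
    return pd.DataFrame(rows)


def frustrated_fraction(n: int, as_percentage: bool = True) -> float:
    """Share of feasible spaces whose generalist ancestor is frustrated.

    A space counts as frustrated when the ancestor's frustration exceeds
    1e-6, i.e. the all-ones efficiency vector is infeasible.  Returned as a
    percentage rounded to the nearest integer by default.
    """
    spaces = enumerate_feasible_spaces(n)
    frustrated = sum(
        1 for space in spaces if ancestor_of(space).frustration > FRUSTRATION_TOL
    )
    fraction = frustrated / len(spaces)
    if as_percentage:
        return float(round(100.0 * fraction))
    return fraction


def model_promiscuity_distribution(n: int) -> np.ndarray:
    """Promiscuity indices of every specialised duplicate at reaction count ``n``."""
    return duplication_study(n)["duplicate_promiscuity"].to_numpy()
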