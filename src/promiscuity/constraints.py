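"""Pairwise catalytic constraints and the feasible spaces they induce.

An enzyme catalysing ``n`` reactions is a point in the unit cube of scaled
catalytic efficiencies (0 = inactive, 1 = maximum attainable, e.g. the
diffusion limit).  Mutational accessibility is modelled by a *feasible
space*: the subset of the cube satisfying one linear constraint set per
unordered reaction pair.  Each pair falls into one of five symmetric
relationship classes, graded by an antagonism score A:

=====================  =====  ==============================
class                  A      constraints on (x_i, x_j)
=====================  =====  ==============================
strong antagonism      1.00   x_i + x_j <= 1
weak antagonism        0.75   x_i + x_j <= c_B   (default 1.5)
unconstrained          0.50   none beyond the unit box
weak synergism         0.25   |x_i - x_j| <= w_D (default 0.5)
strong synergism       0.00   |x_i - x_j| <= eps_E (default 0.1)
=====================  =====  ==============================

A feasible space for ``n`` reactions assigns one class to each of the
k = n(n-1)/2 pairs.  Spaces are enumerated one per *multiset* of classes
(order over pairs does not matter), giving C(k + 4, k) spaces; the
canonical representative assigns the multiset, sorted by descending
antagonism score, to pairs in lexicographic order.  Two scalar descriptors
summarise a space: the mean antagonism score Â of its pairs, and a
dissimilarity score D = sum_{i<j} |A_i - A_j| reported relative to the
maximum over all spaces with the same ``n``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Iterator, Mapping, Sequence

import numpy as np


class RelationClass(Enum):
    """The five pairwise relationship classes, in order of decreasing antagonism."""

    STRONG_ANTAGONISM = ("A", 1.0)
    WEAK_ANTAGONISM = ("B", 0.75)
    UNCONSTRAINED = ("C", 0.5)
    WEAK_SYNERGISM = ("D", 0.25)
    STRONG_SYNERGISM = ("E", 0.0)

    def __init__(self, letter: str, antagonism_score: float) -> None:
        self.letter = letter
        self.antagonism_score = antagonism_score

    @classmethod
    def from_letter(cls, letter: str) -> "RelationClass":
        for member in cls:
            if member.letter == letter:
                return member
        raise ValueError(f"unknown relationship class {letter!r}")


#: Classes ordered by descending antagonism score (A, B, C, D, E).
CLASS_ORDER: tuple[RelationClass, ...] = tuple(RelationClass)


@dataclass(frozen=True)
class ConstraintGeometry:
    """Tunable coordinates of the canonical constraint geometry.

    ``c_B`` is the weak-antagonism budget (x_i + x_j <= c_B), ``w_D`` the
    weak-synergy band half-width and ``eps_E`` the strong-synergy band
    half-width (|x_i - x_j| bounded).  Defaults keep the class-level corner
    semantics: the origin is always feasible, (1,1) is feasible exactly for
    the unconstrained and synergistic classes, (1,0) exactly for the
    antagonistic and unconstrained classes.
    """

    c_B: float = 1.5
    w_D: float = 0.5
    eps_E: float = 0.1

    def __post_init__(self) -> None:
        if not (1.0 < self.c_B < 2.0):
            raise ValueError("c_B must lie in (1, 2)")
        if not (0.0 < self.eps_E < self.w_D < 1.0):
            raise ValueError("need 0 < eps_E < w_D < 1")


DEFAULT_GEOMETRY = ConstraintGeometry()


def build_pairwise_constraints(
    cls: RelationClass,
    i: int,
    j: int,
    n: int,
    geometry: ConstraintGeometry = DEFAULT_GEOMETRY,
) -> list[tuple[np.ndarray, float]]:
    """Halfspaces (a, b), meaning a . x <= b, for one reaction pair.

    Constraints are symmetric in (i, j); the unit box is implicit and not
    returned.
    """
    if i == j:
        raise ValueError("a pairwise relationship needs two distinct reactions")
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError("reaction indices out of range")

    def row(ci: float, cj: float) -> np.ndarray:
        a = np.zeros(n)
        a[i], a[j] = ci, cj
        return a

    if cls is RelationClass.STRONG_ANTAGONISM:
        return [(row(1.0, 1.0), 1.0)]
    if cls is RelationClass.WEAK_ANTAGONISM:
        return [(row(1.0, 1.0), geometry.c_B)]
    if cls is RelationClass.UNCONSTRAINED:
        return []
    band = geometry.w_D if cls is RelationClass.WEAK_SYNERGISM else geometry.eps_E
    return [(row(1.0, -1.0), band), (row(-1.0, 1.0), band)]


def reaction_pairs(n: int) -> list[tuple[int, int]]:
    """Unordered reaction pairs in lexicographic order."""
    return list(itertools.combinations(range(n), 2))


@dataclass
class FeasibleSpace:
    """A feasible space: one relationship class per reaction pair.

    Halfspaces are built lazily (enumeration at large ``n`` only needs the
    combinatorics).  The ancestor optimum is cached by the duplication
    routines.
    """

    n: int
    assignment: dict[tuple[int, int], RelationClass]
    geometry: ConstraintGeometry = DEFAULT_GEOMETRY
    _halfspaces: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )
    _ancestor: "object | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two reactions")
        expected = set(reaction_pairs(self.n))
        if set(self.assignment) != expected:
            raise ValueError("assignment must cover every unordered reaction pair exactly once")

    @property
    def space_id(self) -> str:
        letters = "".join(self.assignment[p].letter for p in reaction_pairs(self.n))
        return f"n{self.n}-{letters}"

    @property
    def classes(self) -> tuple[RelationClass, ...]:
        return tuple(self.assignment[p] for p in reaction_pairs(self.n))

    @property
    def scores(self) -> np.ndarray:
        return np.array([c.antagonism_score for c in self.classes])

    @property
    def halfspaces(self) -> tuple[np.ndarray, np.ndarray]:
        """(A, b) with A x <= b over the unit box, possibly with zero rows."""
        if self._halfspaces is None:
            rows: list[np.ndarray] = []
            bs: list[float] = []
            for (i, j), cls in sorted(self.assignment.items()):
                for a, b in build_pairwise_constraints(cls, i, j, self.n, self.geometry):
                    rows.append(a)
                    bs.append(b)
            A = np.array(rows) if rows else np.zeros((0, self.n))
            self._halfspaces = (A, np.array(bs))
        return self._halfspaces

    def contains(self, x: np.ndarray, tol: float = 1e-9) -> bool:
        x = np.asarray(x, dtype=float)
        if (x < -tol).any() or (x > 1 + tol).any():
            return False
        A, b = self.halfspaces
        return bool(A.size == 0 or (A @ x <= b + tol).all())

    def feasible_mask(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Vectorised feasibility over an (m, n) array of points in the box."""
        A, b = self.halfspaces
        if A.size == 0:
            return np.ones(len(points), dtype=bool)
        return (points @ A.T <= b + tol).all(axis=1)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "geometry": {"c_B": self.geometry.c_B, "w_D": self.geometry.w_D,
                         "eps_E": self.geometry.eps_E},
            "pairs": {f"{i},{j}": cls.letter for (i, j), cls in sorted(self.assignment.items())},
        }


def space_from_letters(
    letters: str | Sequence[str],
    n: int,
    geometry: ConstraintGeometry = DEFAULT_GEOMETRY,
) -> FeasibleSpace:
    """Build a space from class letters in lexicographic pair order."""
    pairs = reaction_pairs(n)
    if len(letters) != len(pairs):
        raise ValueError(f"need {len(pairs)} class letters for n={n}")
    assignment = {
        pair: RelationClass.from_letter(letter) for pair, letter in zip(pairs, letters)
    }
    return FeasibleSpace(n, assignment, geometry)


def count_feasible_spaces(n: int) -> int:
    """Number of feasible spaces for ``n`` reactions: C(k + 4, k), k = n(n-1)/2."""
    if not 2 <= n <= 8:
        raise ValueError("n must be between 2 and 8")
    k = n * (n - 1) // 2
    return math.comb(k + 4, k)


def enumerate_feasible_spaces(
    n: int, geometry: ConstraintGeometry = DEFAULT_GEOMETRY
) -> list[FeasibleSpace]:
    """All feasible spaces for ``n`` reactions, one per class multiset.

    The canonical representative assigns the multiset sorted by descending
    antagonism score to pairs in lexicographic order; the output list is in
    lexicographic order of that canonical class sequence (most antagonistic
    space first).
    """
    if not 2 <= n <= 8:
        raise ValueError("n must be between 2 and 8")
    pairs = reaction_pairs(n)
    spaces = []
    for multiset in itertools.combinations_with_replacement(CLASS_ORDER, len(pairs)):
        assignment = dict(zip(pairs, multiset))
        spaces.append(FeasibleSpace(n, assignment, geometry))
    return spaces


def antagonism_mean(space: FeasibleSpace) -> float:
    """Mean antagonism score Â of the space's pairwise relationships."""
    return float(space.scores.mean())


def _raw_dissimilarity(scores: np.ndarray) -> float:
    diff = np.abs(scores[:, None] - scores[None, :])
    return float(diff[np.triu_indices(len(scores), k=1)].sum())


@lru_cache(maxsize=None)
def max_dissimilarity(n: int) -> float:
    """Maximum raw dissimilarity over all class multisets with ``n`` reactions.

    Computed by enumerating score multisets (the dissimilarity depends only
    on the multiset of antagonism scores) and cached.
    """
    if not 2 <= n <= 8:
        raise ValueError("n must be between 2 and 8")
    k = n * (n - 1) // 2
    score_values = [c.antagonism_score for c in CLASS_ORDER]
    best = 0.0
    for multiset in itertools.combinations_with_replacement(score_values, k):
        best = max(best, _raw_dissimilarity(np.array(multiset)))
    return best


def dissimilarity_score(space: FeasibleSpace) -> float:
    """Dissimilarity of the pairwise antagonism scores, scaled to [0, 1].

    The raw score D = sum_{i<j} |A_i - A_j| is divided by the maximum raw
    score among spaces with the same number of reactions, so 0 means all
    pairwise relationships are identical and 1 means they are as different
    as the class palette allows.
    """
    d_max = max_dissimilarity(space.n)
    if space.n == 2:
        return 0.0  # a single pair is always self-similar
    return _raw_dissimilarity(space.scores) / d_max
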