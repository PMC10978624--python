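"""Shared fixtures and the exhaustive grid oracle for the constraint model."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from promiscuity import EnzymeProfile, KineticRecord


def grid_points(n: int, step: float = 0.05) -> np.ndarray:
    """All points of the regular grid with the given step over [0, 1]^n."""
    axis = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    return np.array(list(itertools.product(axis, repeat=n)))


def grid_oracle(space, step: float = 0.05, saturation_constant: float = 0.5) -> dict:
    """Brute-force reference for ancestor, duplicate maxima and variability.

    Enumerates the feasibility of every grid point and optimises by direct
    search; independent of the LP/NLP route it is used to check.
    """
    pts = grid_points(space.n, step)
    feasible = pts[space.feasible_mask(pts)]
    fitness = (feasible / (feasible + saturation_constant)).sum(axis=1)
    ancestor = feasible[np.argmax(fitness)]
    result = {"ancestor": ancestor, "duplicates": {}}
    for r in range(space.n):
        x_r_star = feasible[:, r].max()
        at_opt = feasible[np.abs(feasible[:, r] - x_r_star) < step / 2]
        ranges = {
            q: (at_opt[:, q].min(), at_opt[:, q].max())
            for q in range(space.n) if q != r
        }
        result["duplicates"][r] = {"x_r_star": x_r_star, "ranges": ranges}
    return result


@pytest.fixture
def simple_records() -> list[KineticRecord]:
    """One enzyme, substrate A once and substrate B in duplicate."""
    return [
        KineticRecord("enz1", "E. coli", "A", kcat=2.0, km=0.5),
        KineticRecord("enz1", "E. coli", "B", kcat=1.0, km=1.0),
        KineticRecord("enz1", "E. coli", "B", kcat=3.0, km=1.0),
    ]


@pytest.fixture
def hand_profiles() -> list[EnzymeProfile]:
    """Five hand-built profiles with spreadsheet-checked summary statistics."""
    return [
        EnzymeProfile("e1", {"a": 4.0, "b": 4.0}),            # index 1.0, best 4
        EnzymeProfile("e2", {"a": 10.0, "b": 0.0}),           # index 0.0, best 10
        EnzymeProfile("e3", {"a": 3.0, "b": 1.0}),            # index 0.8113, best 3
        EnzymeProfile("e4", {"a": 0.6, "b": 0.4, "c": 0.5}),  # index 0.9878, best 0.6
        EnzymeProfile("e5", {"a": 100.0, "b": 100.0, "c": 100.0, "d": 100.0}),  # 1.0
    ]
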