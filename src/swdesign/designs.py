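"""Canonical stepped wedge designs and the time-and-condition reversal.

The correlation model is unchanged by running time backwards, and reversing
time *and* swapping the control/intervention labels maps any valid design to
another valid design with identical precision.  The search therefore works in
the space of designs invariant under this reversal: schedules are chosen for
clusters ``1..K/2`` only and mirrored into clusters ``K..K/2+1``.

Constructors provided here: the complete design with a straight diagonal
cross-over boundary, staircase designs (recruitment windows of width ``j``
either side of each cluster's cross-over) and reversal-symmetric random
designs used as a performance baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidDesignError
from .model import Design, Scenario

__all__ = [
    "HalfSchedule",
    "reverse_design",
    "symmetrize",
    "half_of",
    "is_symmetric",
    "complete_diagonal_design",
    "staircase_design",
    "staircase_width",
    "random_symmetric_design",
    "validate_design",
]


@dataclass
class HalfSchedule:
    """Cross-over and recruitment schedules for clusters ``1..K/2`` only."""

    crossover: np.ndarray  # shape (K/2,)
    recruit: np.ndarray  # shape (K/2, M)

    def __post_init__(self) -> None:
        self.crossover = np.asarray(self.crossover, dtype=int)
        self.recruit = np.asarray(self.recruit).astype(bool)
        if self.crossover.ndim != 1 or self.recruit.ndim != 2:
            raise InvalidDesignError("crossover must be 1-D and recruit 2-D")
        if self.recruit.shape[0] != self.crossover.shape[0]:
            raise InvalidDesignError("crossover and recruit disagree on cluster count")


def _round_half_up(x: np.ndarray | float) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def reverse_design(design: Design) -> Design:
    """Reverse the time scale and swap the control/intervention conditions.

    Cluster ``k`` maps to cluster ``K+1-k``, slot ``s`` to ``M+1-s`` (index
    reversal preserves the slot grid and all inter-arrival gaps, which is all
    the correlation model sees), and the cross-over to ``M+2-c``.  The result
    is a valid design with exactly the same treatment-effect precision; the
    map is an involution.
    """
    M = design.M
    crossover = (M + 2 - design.crossover)[::-1].copy()
    recruit = design.recruit[::-1, ::-1].copy()
    return Design(crossover, recruit)


def symmetrize(half: HalfSchedule, K: int, M: int) -> Design:
    """Expand a half schedule into a full reversal-invariant design.

    Clusters ``K..K/2+1`` receive the time-reversed, condition-swapped images
    of clusters ``1..K/2``.
    """
    if K % 2 != 0 or K < 2:
        raise InvalidDesignError(f"K must be a positive even integer, got {K}")
    if half.crossover.shape[0] != K // 2 or half.recruit.shape != (K // 2, M):
        raise InvalidDesignError(
            f"half schedule has shape {half.recruit.shape}, expected {(K // 2, M)}"
        )
    crossover = np.concatenate([half.crossover, (M + 2 - half.crossover)[::-1]])
    recruit = np.vstack([half.recruit, half.recruit[::-1, ::-1]])
    return Design(crossover, recruit)


def half_of(design: Design) -> HalfSchedule:
    """The first ``K/2`` clusters of a design, as a half schedule."""
    if design.K % 2 != 0:
        raise InvalidDesignError("design must have an even number of clusters")
    h = design.K // 2
    return HalfSchedule(design.crossover[:h].copy(), design.recruit[:h].copy())


def is_symmetric(design: Design) -> bool:
    """True iff the design is invariant under time-and-condition reversal."""
    return design == reverse_design(design)


def _diagonal_crossovers(K: int, M: int) -> np.ndarray:
    k = np.arange(1, K + 1)
    last_control = _round_half_up(M * (k - 1) / (K - 1))
    return last_control + 1


def complete_diagonal_design(K: int, M: int) -> Design:
    """Complete design (n = M*K) with a straight diagonal cross-over boundary.

    Cluster ``k``'s last control slot is the nearest integer (half up) to
    ``M*(k-1)/(K-1)``; every slot is recruited.
    """
    if not K >= 2:
        raise InvalidDesignError(f"K must be at least 2, got {K}")
    return Design(_diagonal_crossovers(K, M), np.ones((K, M), dtype=bool))


def staircase_design(K: int, M: int, j: int) -> Design:
    """Staircase design: recruit ``j`` slots either side of each cross-over.

    Same cross-over boundary as :func:`complete_diagonal_design`; cluster
    ``k`` recruits slots ``max(1, c_k - j) .. c_k - 1`` (control) and
    ``c_k .. min(M, c_k + j - 1)`` (intervention), windows truncated at the
    trial boundaries, so ``n <= 2*j*K``.
    """
    if not j >= 1:
        raise InvalidDesignError(f"staircase width j must be at least 1, got {j}")
    crossover = _diagonal_crossovers(K, M)
    recruit = np.zeros((K, M), dtype=bool)
    for k in range(K):
        c = int(crossover[k])
        lo = max(1, c - j)
        recruit[k, lo - 1 : c - 1] = True
        hi = min(M, c + j - 1)
        if c <= M:
            recruit[k, c - 1 : hi] = True
    return Design(crossover, recruit)


def staircase_width(K: int, M: int) -> int:
    """Default recruitment-window width: nearest integer to ``M/(K-1)``, minimum 1."""
    return max(1, int(_round_half_up(M / (K - 1))))


def random_symmetric_design(
    K: int, M: int, seed: int | np.random.SeedSequence | np.random.Generator
) -> Design:
    """A reversal-invariant design drawn at random (reproducible from the seed).

    For each of the first ``K/2`` clusters the cross-over slot is uniform on
    ``{1, ..., M+1}`` (including the two degenerate always-control /
    always-intervention schedules); a recruitment probability ``p`` is drawn
    once per design uniformly on [0, 1] and each slot is recruited
    independently with probability ``p``.  The other half mirrors the first.
    """
    if K % 2 != 0 or K < 2:
        raise InvalidDesignError(f"K must be a positive even integer, got {K}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    crossover = rng.integers(1, M + 2, size=K // 2)
    p = rng.uniform()
    recruit = rng.random((K // 2, M)) < p
    return symmetrize(HalfSchedule(crossover, recruit), K, M)


def validate_design(
    design: Design, scenario: Scenario | None = None, check_symmetry: bool = False
) -> list[str]:
    """Check a design's structural invariants; returns a list of violations.

    Never raises: an empty list means the design is valid.  With
    ``check_symmetry`` the design must also equal its own reversal.
    """
    violations: list[str] = []
    if scenario is not None and (design.K != scenario.K or design.M != scenario.M):
        violations.append(
            f"dimensions {design.K} x {design.M} do not match scenario "
            f"{scenario.K} x {scenario.M}"
        )
    M = design.M
    bad = (design.crossover < 1) | (design.crossover > M + 1)
    for k in np.flatnonzero(bad):
        violations.append(f"crossover out of range in cluster {k + 1}: {design.crossover[k]}")
    if design.recruit.dtype != bool:
        violations.append("recruitment indicators are not binary")
    if check_symmetry:
        if design.K % 2 != 0:
            violations.append("symmetric designs need an even number of clusters")
        elif not is_symmetric(design):
            violations.append("not reversal-invariant")
    return violations
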