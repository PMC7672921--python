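"""Shared fixtures and independent oracles.

The dense-GLS oracle here deliberately ignores all the package's shortcuts:
it stacks raw-monomial design columns into one matrix, builds the full
block-diagonal covariance and solves a single n x n system, so any error in
the block-wise/rank-one machinery shows up as a mismatch.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.linalg import block_diag

import swdesign as sw


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def dense_treatment_variance(
    scenario: sw.Scenario, design: sw.Design, poly_mix: np.ndarray | None = None
) -> float:
    """Treatment variance via one dense GLS solve with raw powers of t.

    ``poly_mix`` optionally replaces the monomial block with an arbitrary
    invertible reparameterisation of the same polynomial space.
    """
    deg = scenario.degree
    Zs, Vs = [], []
    for k in range(design.K):
        slots = np.flatnonzero(design.recruit[k]) + 1
        if slots.size == 0:
            continue
        t = slots / design.M
        P = np.column_stack([t**j for j in range(deg + 1)])
        if poly_mix is not None:
            P = P @ poly_mix
        Z = np.column_stack([P, (slots >= design.crossover[k]).astype(float)])
        R = scenario.rho * scenario.tau ** np.abs(t[:, None] - t[None, :])
        np.fill_diagonal(R, 1.0)
        Zs.append(Z)
        Vs.append(scenario.sigma2 * R)
    Z = np.vstack(Zs)
    V = block_diag(*Vs)
    info = Z.T @ np.linalg.solve(V, Z)
    return float(np.linalg.inv(info)[-1, -1])


def exchangeable_cluster_information(
    scenario: sw.Scenario, design: sw.Design, k: int
) -> np.ndarray:
    """Cluster information at tau = 1 via the closed-form inverse of (1-rho)I + rho*J."""
    assert scenario.tau == 1.0
    slots = np.flatnonzero(design.recruit[k]) + 1
    m = slots.size
    rho = scenario.rho
    Vinv = (np.eye(m) - rho * np.ones((m, m)) / (1 - rho + m * rho)) / (
        (1 - rho) * scenario.sigma2
    )
    Z = sw.design_matrix(scenario, design)[k]
    return Z.T @ Vinv @ Z


def random_general_design(rng: np.random.Generator, K: int, M: int) -> sw.Design:
    """A random design with no symmetry constraint (may be non-identifiable)."""
    crossover = rng.integers(1, M + 2, size=K)
    recruit = rng.random((K, M)) < rng.uniform(0.3, 1.0)
    return sw.Design(crossover, recruit)


def random_identifiable_design(
    rng: np.random.Generator, scenario: sw.Scenario, symmetric: bool = False
) -> sw.Design:
    """Rejection-sample a design whose treatment effect is estimable."""
    for _ in range(1000):
        if symmetric:
            design = sw.random_symmetric_design(
                scenario.K, scenario.M, int(rng.integers(2**31 - 1))
            )
        else:
            design = random_general_design(rng, scenario.K, scenario.M)
        try:
            sw.treatment_variance(scenario, design)
        except (sw.IdentifiabilityError, sw.InvalidDesignError):
            continue
        return design
    raise RuntimeError("could not draw an identifiable design")


def enumerate_symmetric_designs(K: int, M: int):
    """All reversal-invariant designs (non-empty) for small K, M."""
    h = K // 2
    for crossovers in itertools.product(range(1, M + 2), repeat=h):
        for bits in itertools.product([0, 1], repeat=h * M):
            recruit = np.array(bits, dtype=bool).reshape(h, M)
            if not recruit.any():
                continue
            yield sw.symmetrize(
                sw.HalfSchedule(np.array(crossovers), recruit), K, M
            )


def best_symmetric_by_n(scenario: sw.Scenario) -> dict[int, float]:
    """Exhaustive optimum precision per sample size over the symmetric space."""
    best: dict[int, float] = {}
    for design in enumerate_symmetric_designs(scenario.K, scenario.M):
        try:
            prec = sw.treatment_precision(scenario, design)
        except (sw.IdentifiabilityError, sw.InvalidDesignError):
            continue
        n = design.n
        if n not in best or prec > best[n]:
            best[n] = prec
    return best
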