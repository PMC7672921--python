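"""GLS precision machinery for stepped wedge trials with continuous recruitment.

Outcome model
-------------
Participant ``i`` in cluster ``k`` presents at time ``t_ik`` on the unit
interval (slot ``s`` of ``M`` maps to time ``s/M``) and contributes

    Y_ik = T(t_ik) + theta * H(t_ik - t*_k) + eps_ik,

where ``T`` is a degree-``d`` polynomial time effect shared by all clusters,
``H`` is the unit step (``H(0) = 1``: a participant presenting exactly at the
cross-over is treated), ``theta`` is the treatment effect, and the residuals
have variance ``sigma2`` with within-cluster correlation

    Corr(eps_i1k, eps_i2k) = rho * tau ** |t_i1k - t_i2k|

and zero correlation across clusters.  Outcomes are never simulated: only the
covariance structure enters, through the GLS variance

    Var(theta_hat) = [(Z' V^-1 Z)^-1]_(treatment, treatment),

computed block by block over clusters.  "Precision" is the inverse of this
variance on the sigma2 = 1 scale.

Internally the polynomial columns of ``Z`` use Legendre polynomials on the
recruitment interval rather than raw powers of ``t``; the treatment variance
is invariant to this reparameterisation and the conditioning is far better at
high degree.

:class:`ClusterState` caches per-cluster inverse-covariance products so that
removing or adding a single observation is a rank-one update rather than a
fresh matrix inversion — the workhorse of the design search.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from numpy.polynomial import legendre
from scipy.linalg import cho_factor, cho_solve

from .errors import (
    IdentifiabilityError,
    InvalidDesignError,
    NumericError,
)

__all__ = [
    "Scenario",
    "Design",
    "ClusterState",
    "correlation_block",
    "design_matrix",
    "information_matrix",
    "treatment_variance",
    "treatment_precision",
    "adjust_information",
    "precision_after_changes",
    "time_basis",
    "reversal_matrix",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """Trial and model constants.

    Parameters
    ----------
    K : even number of clusters (evenness is required by the symmetric
        design space used throughout the search).
    M : recruitment slots per cluster; one eligible participant presents at
        each of the regularly spaced times ``1/M, 2/M, ..., M/M``.
    rho : intracluster correlation of two same-cluster participants sampled
        at the same time, ``0 <= rho < 1``.
    tau : decay of that correlation over the whole (unit) trial duration,
        ``0 < tau <= 1``; correlation at separation ``dt`` is ``rho*tau**dt``.
    sigma2 : residual outcome variance (> 0).
    degree : polynomial degree of the time effect ``T(t)``.
    """

    K: int
    M: int
    rho: float
    tau: float
    sigma2: float = 1.0
    degree: int = 6

    def __post_init__(self) -> None:
        if not (isinstance(self.K, (int, np.integer)) and self.K >= 2 and self.K % 2 == 0):
            raise InvalidDesignError(f"K must be a positive even integer, got {self.K}")
        if not (isinstance(self.M, (int, np.integer)) and self.M >= 1):
            raise InvalidDesignError(f"M must be a positive integer, got {self.M}")
        if not (0.0 <= self.rho < 1.0):
            raise InvalidDesignError(f"rho must satisfy 0 <= rho < 1, got {self.rho}")
        if not (0.0 < self.tau <= 1.0):
            raise InvalidDesignError(f"tau must satisfy 0 < tau <= 1, got {self.tau}")
        if not self.sigma2 > 0:
            raise InvalidDesignError(f"sigma2 must be positive, got {self.sigma2}")
        if not (isinstance(self.degree, (int, np.integer)) and self.degree >= 0):
            raise InvalidDesignError(f"degree must be a non-negative integer, got {self.degree}")

    @property
    def p(self) -> int:
        """Number of fixed-effect parameters: intercept + degree + treatment."""
        return int(self.degree) + 2

    @property
    def times(self) -> np.ndarray:
        """Arrival times ``s/M`` for slots ``s = 1..M``."""
        return np.arange(1, self.M + 1, dtype=float) / self.M

    def with_degree(self, degree: int) -> "Scenario":
        """Same trial constants with a different analysis polynomial degree."""
        return replace(self, degree=int(degree))


@dataclass
class Design:
    """A recruitment and cross-over schedule.

    ``crossover[k]`` is the first slot recruited under the intervention in
    cluster ``k`` (1-based; ``M + 1`` means the cluster never crosses over,
    ``1`` means intervention throughout).  ``recruit[k, s-1]`` says whether
    the participant presenting at slot ``s`` of cluster ``k`` is recruited.
    A recruited slot ``s`` is under intervention iff ``s >= crossover[k]``.
    """

    crossover: np.ndarray  # shape (K,), int, values in 1..M+1
    recruit: np.ndarray  # shape (K, M), bool

    def __post_init__(self) -> None:
        self.crossover = np.asarray(self.crossover, dtype=int)
        self.recruit = np.asarray(self.recruit).astype(bool)
        if self.crossover.ndim != 1 or self.recruit.ndim != 2:
            raise InvalidDesignError("crossover must be 1-D and recruit 2-D")
        if self.recruit.shape[0] != self.crossover.shape[0]:
            raise InvalidDesignError(
                "crossover and recruit disagree on the number of clusters"
            )
        # Range of crossover values is checked by validate_design (which
        # reports rather than raises) and by every consumer that builds Z.

    @property
    def K(self) -> int:
        return self.recruit.shape[0]

    @property
    def M(self) -> int:
        return self.recruit.shape[1]

    @property
    def n(self) -> int:
        """Total sample size (number of recruited participants)."""
        return int(self.recruit.sum())

    @property
    def cluster_sizes(self) -> np.ndarray:
        return self.recruit.sum(axis=1).astype(int)

    def copy(self) -> "Design":
        return Design(self.crossover.copy(), self.recruit.copy())

    def __eq__(self, other: object) -> bool:  # type: ignore[override]
        if not isinstance(other, Design):
            return NotImplemented
        return bool(
            np.array_equal(self.crossover, other.crossover)
            and np.array_equal(self.recruit, other.recruit)
        )


# ---------------------------------------------------------------------------
# Basis and covariance building blocks
# ---------------------------------------------------------------------------


def time_basis(scenario: Scenario, times: np.ndarray) -> np.ndarray:
    """Evaluate the polynomial time-effect basis at the given times.

    Legendre polynomials in ``u = 2t - 1`` span the same space as raw powers
    ``1, t, ..., t^degree``; the treatment variance is invariant to the choice.
    """
    t = np.asarray(times, dtype=float)
    return legendre.legvander(2.0 * t - 1.0, int(scenario.degree))


def reversal_matrix(scenario: Scenario) -> np.ndarray:
    """Linear map ``S`` with ``z_reversed = S z`` for design-matrix rows.

    Reversing a cluster maps slot ``s`` to slot ``M + 1 - s`` (time
    ``t -> 1 + 1/M - t``, an affine map preserving the slot grid and all
    inter-arrival gaps) and swaps conditions (``x -> 1 - x``).  Both are
    linear on the model columns, so the mirrored cluster's information
    contribution is ``S W S'``.  Exploited by the symmetric search.
    """
    d = int(scenario.degree)
    p = scenario.p
    # Affine time map in Legendre coordinates: u -> 2/M - u.
    nodes = np.linspace(-1.0, 1.0, d + 1)
    B0 = legendre.legvander(nodes, d)
    B1 = legendre.legvander(2.0 / scenario.M - nodes, d)
    A = np.linalg.solve(B0, B1).T  # phi(r(t)) = A @ phi(t)
    S = np.zeros((p, p))
    S[: d + 1, : d + 1] = A
    # 1 - x = phi_0(t) * 1 - x  (phi_0 is identically 1).
    S[p - 1, 0] = 1.0
    S[p - 1, p - 1] = -1.0
    return S


def correlation_block(scenario: Scenario, times: Sequence[float]) -> np.ndarray:
    """Within-cluster correlation matrix ``rho * tau**|t_i - t_j|`` (unit diagonal).

    Times must be strictly increasing (one arrival per slot; ties forbidden).
    Positive definite for ``rho < 1`` and ``tau > 0``.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise InvalidDesignError("times must be a 1-D sequence")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise InvalidDesignError("times must be strictly increasing")
    R = scenario.rho * scenario.tau ** np.abs(t[:, None] - t[None, :])
    np.fill_diagonal(R, 1.0)
    return R


def _cov_block(scenario: Scenario, times: np.ndarray) -> np.ndarray:
    return scenario.sigma2 * correlation_block(scenario, times)


def _cluster_slots(design: Design, k: int) -> np.ndarray:
    """1-based recruited slot numbers of cluster ``k`` (0-based index)."""
    return np.flatnonzero(design.recruit[k]) + 1


def _cluster_design_matrix(
    scenario: Scenario, slots: np.ndarray, crossover: int
) -> np.ndarray:
    times = slots.astype(float) / scenario.M
    Zt = time_basis(scenario, times)
    treat = (slots >= crossover).astype(float)
    return np.column_stack([Zt, treat])


def design_matrix(scenario: Scenario, design: Design) -> list[np.ndarray]:
    """Per-cluster fixed-effect blocks ``Z_k``.

    One row per recruited slot (ordered by slot): the polynomial basis at
    ``t = s/M`` followed by the treatment indicator ``1{s >= crossover[k]}``.
    """
    _check_dims(scenario, design)
    return [
        _cluster_design_matrix(scenario, _cluster_slots(design, k), int(design.crossover[k]))
        for k in range(design.K)
    ]


def _check_dims(scenario: Scenario, design: Design) -> None:
    if design.K != scenario.K or design.M != scenario.M:
        raise InvalidDesignError(
            f"design is {design.K} x {design.M} but scenario expects "
            f"{scenario.K} x {scenario.M}"
        )


# ---------------------------------------------------------------------------
# Information and variance
# ---------------------------------------------------------------------------


def _cluster_information(scenario: Scenario, slots: np.ndarray, crossover: int) -> np.ndarray:
    """``Z_k' V_k^-1 Z_k`` for one cluster, from scratch."""
    if slots.size == 0:
        return np.zeros((scenario.p, scenario.p))
    Z = _cluster_design_matrix(scenario, slots, crossover)
    V = _cov_block(scenario, slots.astype(float) / scenario.M)
    c, low = cho_factor(V, lower=True)
    G = cho_solve((c, low), Z)
    return Z.T @ G


def information_matrix(scenario: Scenario, design: Design) -> np.ndarray:
    """Total GLS information ``Z' V^-1 Z`` summed over cluster blocks."""
    _check_dims(scenario, design)
    n = design.n
    if n == 0:
        raise InvalidDesignError("design recruits no participants")
    if n < scenario.p:
        raise IdentifiabilityError(
            f"design recruits n={n} participants but the model has p={scenario.p} parameters"
        )
    W = np.zeros((scenario.p, scenario.p))
    for k in range(design.K):
        slots = _cluster_slots(design, k)
        if slots.size:
            W += _cluster_information(scenario, slots, int(design.crossover[k]))
    return W


def _diagnose_singular(scenario: Scenario, design: Design) -> str:
    treat_vals = []
    all_times: set[int] = set()
    for k in range(design.K):
        slots = _cluster_slots(design, k)
        all_times.update(slots.tolist())
        treat_vals.extend((slots >= int(design.crossover[k])).tolist())
    if len(set(treat_vals)) <= 1:
        cond = "intervention" if (treat_vals and treat_vals[0]) else "control"
        return (
            "treatment effect is confounded: every recruited participant is "
            f"under the {cond} condition"
        )
    if len(all_times) < scenario.degree + 1:
        return (
            f"only {len(all_times)} distinct recruitment times but the degree-"
            f"{scenario.degree} time effect needs at least {scenario.degree + 1}"
        )
    return "information matrix is singular (treatment confounded with the time effect)"


def _variance_from_information(
    scenario: Scenario, info: np.ndarray, design: Design | None = None
) -> float:
    p = info.shape[0]
    e = np.zeros(p)
    e[p - 1] = 1.0
    try:
        c, low = cho_factor(info, lower=True)
        var = float(cho_solve((c, low), e)[p - 1])
    except np.linalg.LinAlgError:
        msg = (
            _diagnose_singular(scenario, design)
            if design is not None
            else "information matrix is singular"
        )
        raise IdentifiabilityError(msg) from None
    if not np.isfinite(var) or var <= 0:
        msg = (
            _diagnose_singular(scenario, design)
            if design is not None
            else "information matrix is numerically singular"
        )
        raise IdentifiabilityError(msg)
    return var


def treatment_variance(scenario: Scenario, design: Design) -> float:
    """``Var(theta_hat)``: treatment-effect diagonal entry of ``(Z'V^-1 Z)^-1``.

    Includes the ``sigma2`` scale.  Raises :class:`IdentifiabilityError`
    (naming the defect) if the treatment effect is not estimable.
    """
    info = information_matrix(scenario, design)
    return _variance_from_information(scenario, info, design)


def treatment_precision(scenario: Scenario, design: Design) -> float:
    """Inverse variance of the treatment effect estimator on the sigma2 = 1 scale."""
    return scenario.sigma2 / treatment_variance(scenario, design)


# ---------------------------------------------------------------------------
# ClusterState: cached inverse-covariance products, rank-one add/remove
# ---------------------------------------------------------------------------


class ClusterState:
    """Cached GLS quantities for a single cluster.

    Holds the recruited slots, ``Vinv = V_k^-1``, ``G = V_k^-1 Z_k`` and the
    information contribution ``W = Z_k' V_k^-1 Z_k``, and updates them under
    observation removal (standard deletion downdate ``W - g g'/u`` with
    ``g`` the observation's row of ``G`` and ``u`` its diagonal entry of
    ``Vinv``), observation addition (the reverse, via the block-inverse
    update) and cross-over shifts.  Rows follow insertion order, which the
    correlation model is indifferent to.
    """

    def __init__(self, scenario: Scenario, crossover: int, recruit_row: np.ndarray):
        self.scenario = scenario
        self.crossover = int(crossover)
        if not 1 <= self.crossover <= scenario.M + 1:
            raise InvalidDesignError(f"crossover {crossover} out of range 1..{scenario.M + 1}")
        slots = np.flatnonzero(np.asarray(recruit_row).astype(bool)) + 1
        self.slots: list[int] = [int(s) for s in slots]
        self._rebuild()

    # -- construction ------------------------------------------------------

    def _rebuild(self) -> None:
        sc = self.scenario
        m = len(self.slots)
        slot_arr = np.asarray(sorted(self.slots), dtype=int)
        # Rebuild in sorted order; insertion order is only a bookkeeping detail.
        self.slots = [int(s) for s in slot_arr]
        self.times = slot_arr.astype(float) / sc.M
        if m == 0:
            self.Vinv = np.zeros((0, 0))
            self.Z = np.zeros((0, sc.p))
            self.G = np.zeros((0, sc.p))
            self.W = np.zeros((sc.p, sc.p))
            return
        V = _cov_block(sc, self.times)
        self.Vinv = np.linalg.inv(V)
        self.Z = _cluster_design_matrix(sc, slot_arr, self.crossover)
        self.G = self.Vinv @ self.Z
        self.W = self.Z.T @ self.G

    @property
    def m(self) -> int:
        return len(self.slots)

    @property
    def recruit_row(self) -> np.ndarray:
        row = np.zeros(self.scenario.M, dtype=bool)
        if self.slots:
            row[np.asarray(self.slots) - 1] = True
        return row

    def position_of(self, slot: int) -> int:
        try:
            return self.slots.index(int(slot))
        except ValueError:
            raise InvalidDesignError(f"slot {slot} is not recruited in this cluster") from None

    # -- covariance helpers ------------------------------------------------

    def _cov_vector(self, slot: int) -> np.ndarray:
        """Covariance of a prospective observation at ``slot`` with current ones."""
        sc = self.scenario
        t_new = slot / sc.M
        return sc.sigma2 * sc.rho * sc.tau ** np.abs(t_new - self.times)

    def _row(self, slot: int) -> np.ndarray:
        sc = self.scenario
        z = np.empty(sc.p)
        z[: sc.p - 1] = time_basis(sc, np.array([slot / sc.M]))[0]
        z[sc.p - 1] = 1.0 if slot >= self.crossover else 0.0
        return z

    # -- candidate (non-mutating) updates ----------------------------------

    def info_without(self, slot: int) -> np.ndarray:
        """Information contribution after deleting the observation at ``slot``."""
        pos = self.position_of(slot)
        u = self.Vinv[pos, pos]
        if u <= 0:
            raise NumericError(f"non-positive V^-1 diagonal entry {u}: stale cluster cache")
        g = self.G[pos]
        return self.W - np.outer(g, g) / u

    def info_with(self, slot: int) -> np.ndarray:
        """Information contribution after adding an observation at ``slot``."""
        slot = int(slot)
        if slot in self.slots:
            raise InvalidDesignError(f"slot {slot} is already recruited")
        if not 1 <= slot <= self.scenario.M:
            raise InvalidDesignError(f"slot {slot} out of range 1..{self.scenario.M}")
        v = self._cov_vector(slot)
        z = self._row(slot)
        a = self.Vinv @ v
        d = self.scenario.sigma2 - float(v @ a)
        if d <= 0:
            raise NumericError(f"non-positive conditional variance {d}: stale cluster cache")
        g = self.G.T @ v - z
        return self.W + np.outer(g, g) / d

    # -- mutating updates ---------------------------------------------------

    def apply_remove(self, slot: int) -> None:
        pos = self.position_of(slot)
        u = self.Vinv[pos, pos]
        if u <= 0:
            raise NumericError(f"non-positive V^-1 diagonal entry {u}: stale cluster cache")
        q = self.Vinv[:, pos].copy()
        g = self.G[pos].copy()
        self.W = self.W - np.outer(g, g) / u
        Vinv = self.Vinv - np.outer(q, q) / u
        G = self.G - np.outer(q, g) / u
        keep = np.arange(self.m) != pos
        self.Vinv = Vinv[np.ix_(keep, keep)]
        self.G = G[keep]
        self.Z = self.Z[keep]
        self.times = self.times[keep]
        del self.slots[pos]

    def apply_add(self, slot: int) -> None:
        slot = int(slot)
        if slot in self.slots:
            raise InvalidDesignError(f"slot {slot} is already recruited")
        if not 1 <= slot <= self.scenario.M:
            raise InvalidDesignError(f"slot {slot} out of range 1..{self.scenario.M}")
        v = self._cov_vector(slot)
        z = self._row(slot)
        a = self.Vinv @ v
        d = self.scenario.sigma2 - float(v @ a)
        if d <= 0:
            raise NumericError(f"non-positive conditional variance {d}: stale cluster cache")
        g = self.G.T @ v - z
        self.W = self.W + np.outer(g, g) / d
        m = self.m
        Vinv = np.empty((m + 1, m + 1))
        Vinv[:m, :m] = self.Vinv + np.outer(a, a) / d
        Vinv[:m, m] = -a / d
        Vinv[m, :m] = -a / d
        Vinv[m, m] = 1.0 / d
        self.Vinv = Vinv
        self.G = np.vstack([self.G + np.outer(a, g) / d, -g / d])
        self.Z = np.vstack([self.Z, z])
        self.times = np.append(self.times, slot / self.scenario.M)
        self.slots.append(slot)

    def set_crossover(self, crossover: int) -> None:
        """Move the cross-over boundary; refreshes the treatment column."""
        crossover = int(crossover)
        if not 1 <= crossover <= self.scenario.M + 1:
            raise InvalidDesignError(
                f"crossover {crossover} out of range 1..{self.scenario.M + 1}"
            )
        self.crossover = crossover
        if self.m:
            self.Z[:, -1] = (np.asarray(self.slots) >= crossover).astype(float)
            self.G = self.Vinv @ self.Z
            self.W = self.Z.T @ self.G


def adjust_information(state: ClusterState, slot: int, mode: str) -> np.ndarray:
    """Cluster information after adding/removing one observation (no mutation).

    ``mode`` is ``"remove"`` (the slot must currently be recruited) or
    ``"add"`` (it must not be).  Equals rebuilding ``W_k`` from scratch.
    """
    if mode == "remove":
        return state.info_without(slot)
    if mode == "add":
        return state.info_with(slot)
    raise ValueError(f"mode must be 'add' or 'remove', got {mode!r}")


def precision_after_changes(
    scenario: Scenario,
    design: Design,
    changes: Iterable[tuple[int, int, str]],
) -> float:
    """Precision of the design after a batch of slot additions/removals.

    ``changes`` is an iterable of ``(cluster, slot, mode)`` with 1-based
    cluster and slot indices and ``mode`` in {"add", "remove"}.  The input
    design is not mutated; affected clusters are re-evaluated through
    :class:`ClusterState` updates, so the result equals a full recomputation.
    """
    _check_dims(scenario, design)
    changes = list(changes)
    seen: set[tuple[int, int]] = set()
    for k, s, mode in changes:
        if mode not in ("add", "remove"):
            raise ValueError(f"mode must be 'add' or 'remove', got {mode!r}")
        if (k, s) in seen:
            raise InvalidDesignError(f"conflicting changes for cluster {k}, slot {s}")
        seen.add((k, s))
        if not 1 <= k <= design.K:
            raise InvalidDesignError(f"cluster {k} out of range 1..{design.K}")
        if not 1 <= s <= design.M:
            raise InvalidDesignError(f"slot {s} out of range 1..{design.M}")

    info = information_matrix(scenario, design)
    by_cluster: dict[int, list[tuple[int, str]]] = {}
    for k, s, mode in changes:
        by_cluster.setdefault(k, []).append((s, mode))
    for k, ops in by_cluster.items():
        state = ClusterState(scenario, int(design.crossover[k - 1]), design.recruit[k - 1])
        info -= state.W
        for s, mode in ops:
            if mode == "remove":
                state.apply_remove(s)
            else:
                state.apply_add(s)
        info += state.W
    var = _variance_from_information(scenario, info)
    return scenario.sigma2 / var
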