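"""Iterative greedy search for efficient incomplete stepped wedge designs.

The search walks the space of reversal-invariant designs (see
:mod:`swdesign.designs`).  A *forward* search starts from the complete
diagonal design and repeats: hill-climb with sample-size-preserving moves
until no improvement, then remove the recruited participant (together with
its mirror image) whose deletion costs the least precision.  A *backward*
search starts from a narrow staircase design and greedily adds the most
informative participant pair instead.  :func:`hunt` runs both and keeps the
smaller design that meets a target precision.

Sample-size-preserving move families (all applied simultaneously to a
half-cluster and its mirror, so the design stays symmetric):

* crossover shift — move one cluster's cross-over boundary by one slot;
* within-cluster relocation — move one recruited slot of a cluster to any
  currently unrecruited slot of the same cluster;
* cross-cluster relocation (off by default) — move a recruited slot to an
  unrecruited slot of a different cluster; the greedy remove/add steps
  already transfer recruitment across clusters over iterations.

Every candidate is scored through rank-one updates of the cached per-cluster
information contributions (:class:`~swdesign.model.ClusterState`), batched
into stacked ``p x p`` solves, so a full sweep costs far less than one fresh
``n x n`` GLS evaluation per candidate.  Mirror-image contributions come for
free through the reversal map ``W_mirror = S W S'``.  All moves and
tie-breaks are deterministic: candidates are scanned in (family, cluster,
slot) order and only a strictly better precision displaces the incumbent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import (
    HalfSchedule,
    complete_diagonal_design,
    is_symmetric,
    staircase_design,
    staircase_width,
    symmetrize,
)
from .errors import (
    IdentifiabilityError,
    InvalidDesignError,
    SearchExhaustedError,
)
from .model import (
    ClusterState,
    Design,
    Scenario,
    _variance_from_information,
    reversal_matrix,
    time_basis,
)
from .power import PowerSpec, required_precision

__all__ = [
    "MoveConfig",
    "TrajectoryRecord",
    "SearchTrajectory",
    "HuntResult",
    "improvement_sweep",
    "greedy_remove_pair",
    "greedy_add_pair",
    "forward_search",
    "backward_search",
    "hunt",
    "best_complete",
]

_REBUILD_EVERY = 64  # rank-one updates per cluster before a from-scratch refresh


@dataclass(frozen=True)
class MoveConfig:
    """Which sample-size-preserving move families the sweeps may use."""

    crossover_shift: bool = True
    within_cluster: bool = True
    cross_cluster: bool = False
    tol: float = 1e-10  # relative precision gain below which a move is noise
    sweep_limit: int | None = None  # max moves per sweep; default 10*K*M

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise InvalidDesignError(f"improvement tolerance must be positive, got {self.tol}")
        if self.sweep_limit is not None and self.sweep_limit < 1:
            raise InvalidDesignError(f"sweep limit must be >= 1, got {self.sweep_limit}")


@dataclass
class TrajectoryRecord:
    iteration: int
    step_type: str  # 'sweep' (initial), 'remove' or 'add'; designs are post-sweep
    n: int
    variance: float
    precision: float
    design: Design | None = None


@dataclass
class SearchTrajectory:
    """Ordered (n, design, variance, precision) iterates of one search run."""

    direction: str  # 'forward' or 'backward'
    target: float | None
    records: list[TrajectoryRecord] = field(default_factory=list)
    achieved: bool = False
    unachievable: bool = False
    exhausted: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [r.iteration for r in self.records],
                "step_type": [r.step_type for r in self.records],
                "n": [r.n for r in self.records],
                "variance": [r.variance for r in self.records],
                "precision": [r.precision for r in self.records],
            }
        )

    def precision_by_n(self) -> dict[int, float]:
        return {r.n: r.precision for r in self.records}

    def last_meeting_target(self) -> TrajectoryRecord | None:
        if self.target is None:
            return None
        ok = [r for r in self.records if r.precision >= self.target]
        return ok[-1] if ok else None


@dataclass
class HuntResult:
    """Outcome of a two-direction hunt for a target precision."""

    design: Design
    n: int
    variance: float
    precision: float
    achieved: bool
    target: float
    forward: SearchTrajectory | None = None
    backward: SearchTrajectory | None = None


# ---------------------------------------------------------------------------
# Symmetric working state
# ---------------------------------------------------------------------------


class _SymState:
    """Half-cluster states plus the total information of the symmetric design."""

    def __init__(self, scenario: Scenario, design: Design, check: bool = True):
        if design.K != scenario.K or design.M != scenario.M:
            raise InvalidDesignError("design dimensions do not match the scenario")
        if check and not is_symmetric(design):
            raise InvalidDesignError("search operations require a reversal-invariant design")
        self.sc = scenario
        self.h = scenario.K // 2
        self.S = reversal_matrix(scenario)
        self.states = [
            ClusterState(scenario, int(design.crossover[k]), design.recruit[k])
            for k in range(self.h)
        ]
        self._mut = [0] * self.h
        self._unit_basis = time_basis(scenario, scenario.times)  # (M, d+1)
        self._refresh_info()

    def _refresh_info(self) -> None:
        S = self.S
        I = np.zeros((self.sc.p, self.sc.p))
        for st in self.states:
            I += st.W + S @ st.W @ S.T
        self.I = I

    @property
    def n(self) -> int:
        return 2 * sum(st.m for st in self.states)

    def variance(self) -> float:
        return _variance_from_information(self.sc, self.I)

    def precision(self) -> float:
        return self.sc.sigma2 / self.variance()

    def design(self) -> Design:
        half = HalfSchedule(
            np.array([st.crossover for st in self.states]),
            np.vstack([st.recruit_row for st in self.states]),
        )
        return symmetrize(half, self.sc.K, self.sc.M)

    # -- helpers -------------------------------------------------------------

    def _row(self, k: int, slot: int) -> np.ndarray:
        st = self.states[k]
        z = np.empty(self.sc.p)
        z[:-1] = self._unit_basis[slot - 1]
        z[-1] = 1.0 if slot >= st.crossover else 0.0
        return z

    def _add_ingredients(self, k: int):
        """Per-cluster quantities shared by all addition-type candidates.

        Returns ``(targets, Vc, Zadd)``: unrecruited slots in ascending
        order, their covariance with the cluster's current observations
        (n_add x m) and their design rows (n_add x p).
        """
        st = self.states[k]
        sc = self.sc
        mask = np.ones(sc.M, dtype=bool)
        if st.slots:
            mask[np.asarray(st.slots) - 1] = False
        targets = np.flatnonzero(mask) + 1
        if targets.size == 0:
            return targets, None, None
        t_new = targets.astype(float) / sc.M
        Vc = sc.sigma2 * sc.rho * sc.tau ** np.abs(t_new[:, None] - st.times[None, :])
        Zadd = np.column_stack(
            [self._unit_basis[targets - 1], (targets >= st.crossover).astype(float)]
        )
        return targets, Vc, Zadd

    def _batch_precisions(self, dW: np.ndarray) -> np.ndarray:
        """Precision after adding ``dW`` (and its mirror image) to the information.

        ``dW`` is a stack of per-candidate changes to first-half cluster
        information; the mirrored half contributes ``S dW S'``.  Candidates
        yielding a non-identifiable design score ``-inf``.
        """
        if dW.shape[0] == 0:
            return np.empty(0)
        S = self.S
        X = self.I + dW + S @ dW @ S.T
        p = self.sc.p
        e = np.zeros(p)
        e[-1] = 1.0
        b = np.broadcast_to(e[:, None], (X.shape[0], p, 1))
        try:
            var = np.linalg.solve(X, b)[:, -1, 0]
        except np.linalg.LinAlgError:
            var = np.full(X.shape[0], np.nan)
            for i in range(X.shape[0]):
                try:
                    var[i] = np.linalg.solve(X[i], e)[-1]
                except np.linalg.LinAlgError:
                    pass
        prec = np.where(np.isfinite(var) & (var > 0), self.sc.sigma2 / var, -np.inf)
        return prec

    # -- candidate generation --------------------------------------------------

    def shift_candidates(self, k: int):
        """Cross-over shifts by one slot; yields (move, dW) pairs."""
        st = self.states[k]
        sc = self.sc
        out = []
        for delta in (-1, 1):
            c_new = st.crossover + delta
            if not 1 <= c_new <= sc.M + 1:
                continue
            flip_slot = st.crossover - 1 if delta == -1 else st.crossover
            if flip_slot not in st.slots:
                continue  # boundary moves through an unrecruited slot: no effect
            pos = st.slots.index(flip_slot)
            sign = 1.0 if delta == -1 else -1.0
            dz = np.zeros(sc.p)
            dz[-1] = sign
            gi = st.G[pos]
            dW = np.outer(gi, dz) + np.outer(dz, gi) + st.Vinv[pos, pos] * np.outer(dz, dz)
            out.append((("shift", k, delta), dW))
        return out

    def removal_batch(self, k: int):
        """All single-slot removals in cluster ``k`` (slot-ascending order)."""
        st = self.states[k]
        if st.m == 0:
            return [], np.zeros((0, self.sc.p, self.sc.p))
        order = np.argsort(st.slots)
        slots = [st.slots[i] for i in order]
        g = st.G[order]
        u = np.diag(st.Vinv)[order]
        dW = -(g[:, :, None] * g[:, None, :]) / u[:, None, None]
        return slots, dW

    def addition_batch(self, k: int):
        """All single-slot additions in cluster ``k`` (slot-ascending order)."""
        targets, Vc, Zadd = self._add_ingredients(k)
        if targets.size == 0:
            return targets, np.zeros((0, self.sc.p, self.sc.p))
        st = self.states[k]
        A = st.Vinv @ Vc.T  # (m, n_add)
        d = self.sc.sigma2 - np.einsum("nm,mn->n", Vc, A)
        g = (st.G.T @ Vc.T).T - Zadd  # (n_add, p)
        bad = d <= 0
        d = np.where(bad, 1.0, d)
        dW = (g[:, :, None] * g[:, None, :]) / d[:, None, None]
        if bad.any():
            dW[bad] = np.nan  # poisons the solve -> -inf precision
        return targets, dW

    def relocation_batches(self, k: int):
        """Within-cluster relocations: for each recruited slot (ascending), the
        batch of moves to every unrecruited slot (ascending).

        Yields ``(slot_from, targets, dW)``.  The removal downdate and the
        conditional add are chained exactly, so each ``dW`` equals the true
        change in the cluster's information contribution.
        """
        st = self.states[k]
        if st.m == 0:
            return
        targets, Vc, Zadd = self._add_ingredients(k)
        if targets.size == 0:
            return
        sc = self.sc
        A0 = st.Vinv @ Vc.T  # (m, n_add)
        d0 = sc.sigma2 - np.einsum("nm,mn->n", Vc, A0)
        B0 = st.G.T @ Vc.T  # (p, n_add)
        order = np.argsort(st.slots)
        for pos in order:
            u = st.Vinv[pos, pos]
            q = st.Vinv[:, pos]
            g_rem = st.G[pos]
            qV = q @ Vc.T  # (n_add,)
            d = d0 + qV * qV / u
            gT = B0 - np.outer(g_rem, qV) / u - Zadd.T  # (p, n_add)
            g = gT.T
            bad = d <= 0
            d = np.where(bad, 1.0, d)
            dW = (g[:, :, None] * g[:, None, :]) / d[:, None, None] - np.outer(
                g_rem, g_rem
            ) / u
            if bad.any():
                dW[bad] = np.nan
            yield st.slots[pos], targets, dW

    # -- mutation ----------------------------------------------------------------

    def apply_move(self, move: tuple) -> None:
        kind = move[0]
        if kind == "shift":
            _, k, delta = move
            st = self.states[k]
            st.set_crossover(st.crossover + delta)
            self._touch(k)
        elif kind == "reloc":
            _, k, s_from, s_to = move
            st = self.states[k]
            st.apply_remove(s_from)
            st.apply_add(s_to)
            self._touch(k)
        elif kind == "xreloc":
            _, k_from, s_from, k_to, s_to = move
            self.states[k_from].apply_remove(s_from)
            self.states[k_to].apply_add(s_to)
            self._touch(k_from)
            self._touch(k_to)
        elif kind == "remove":
            _, k, s = move
            self.states[k].apply_remove(s)
            self._touch(k)
        elif kind == "add":
            _, k, s = move
            self.states[k].apply_add(s)
            self._touch(k)
        else:  # pragma: no cover - internal contract
            raise ValueError(f"unknown move {move!r}")

    def _touch(self, k: int) -> None:
        self._mut[k] += 1
        if self._mut[k] >= _REBUILD_EVERY:
            self.states[k]._rebuild()
            self._mut[k] = 0
        self._refresh_info()


# ---------------------------------------------------------------------------
# Sweeps and greedy steps
# ---------------------------------------------------------------------------


_TIE_REL = 1e-12  # float noise level at which two candidate precisions tie


def _argbest(prec: np.ndarray) -> int:
    """First index whose precision ties the maximum (lowest-slot tie-break)."""
    i = int(np.argmax(prec))
    top = prec[i]
    if not np.isfinite(top):
        return i
    return int(np.flatnonzero(prec >= top - abs(top) * _TIE_REL)[0])


def _beats(new: float, best: float) -> bool:
    """Strictly better beyond float noise (earlier candidates win ties)."""
    if not np.isfinite(best):
        return bool(np.isfinite(new))
    return bool(new > best + abs(best) * _TIE_REL)


def _best_move(state: _SymState, moves: MoveConfig, cur_prec: float):
    """The single best improving move, or None if no move beats the tolerance.

    Candidates are scanned in (family, cluster, slot) order with a strictly-
    greater comparison, so ties resolve to the lowest-ordered move.
    """
    best_prec = cur_prec * (1.0 + moves.tol)
    best = None
    if moves.crossover_shift:
        for k in range(state.h):
            for move, dW in state.shift_candidates(k):
                prec = state._batch_precisions(dW[None, :, :])[0]
                if _beats(prec, best_prec):
                    best_prec, best = prec, move
    if moves.within_cluster:
        for k in range(state.h):
            labels, mats = [], []
            for s_from, targets, dW in state.relocation_batches(k):
                labels.append((s_from, targets))
                mats.append(dW)
            if not mats:
                continue
            # one stacked solve per cluster: the p x p systems are tiny, so
            # per-call overhead, not flops, dominates the sweep
            prec_all = state._batch_precisions(np.concatenate(mats, axis=0))
            off = 0
            for s_from, targets in labels:
                prec = prec_all[off : off + targets.size]
                off += targets.size
                i = _argbest(prec)
                if _beats(prec[i], best_prec):
                    best_prec, best = prec[i], ("reloc", k, s_from, int(targets[i]))
    if moves.cross_cluster:
        add_cache = {k: state.addition_batch(k) for k in range(state.h)}
        for k_from in range(state.h):
            slots, dW_rem = state.removal_batch(k_from)
            for s_idx, s_from in enumerate(slots):
                for k_to in range(state.h):
                    if k_to == k_from:
                        continue
                    targets, dW_add = add_cache[k_to]
                    if targets.size == 0:
                        continue
                    prec = state._batch_precisions(dW_add + dW_rem[s_idx])
                    i = _argbest(prec)
                    if _beats(prec[i], best_prec):
                        best_prec, best = (
                            prec[i],
                            ("xreloc", k_from, s_from, k_to, int(targets[i])),
                        )
    return best, best_prec


def _sweep(state: _SymState, moves: MoveConfig) -> float:
    """Hill-climb with the enabled move families until no move improves."""
    limit = moves.sweep_limit or 10 * state.sc.K * state.sc.M
    cur = state.precision()
    for _ in range(limit):
        move, prec = _best_move(state, moves, cur)
        if move is None:
            break
        state.apply_move(move)
        cur = state.precision()
    return cur


def _greedy_remove(state: _SymState) -> tuple[int, int]:
    """Remove the mirror pair costing the least precision; returns (cluster, slot)."""
    if state.n - 2 < state.sc.p:
        raise SearchExhaustedError(
            f"cannot remove below p={state.sc.p} recruited participants"
        )
    best_prec = -np.inf
    best = None
    for k in range(state.h):
        slots, dW = state.removal_batch(k)
        if not slots:
            continue
        prec = state._batch_precisions(dW)
        i = _argbest(prec)
        if _beats(prec[i], best_prec):
            best_prec, best = prec[i], (k, slots[i])
    if best is None or not np.isfinite(best_prec):
        raise SearchExhaustedError("every candidate removal destroys identifiability")
    k, s = best
    state.apply_move(("remove", k, s))
    return k + 1, s


def _greedy_add(state: _SymState) -> tuple[int, int]:
    """Add the mirror pair gaining the most precision; returns (cluster, slot)."""
    best_prec = -np.inf
    best = None
    for k in range(state.h):
        targets, dW = state.addition_batch(k)
        if targets.size == 0:
            continue
        prec = state._batch_precisions(dW)
        i = _argbest(prec)
        if _beats(prec[i], best_prec):
            best_prec, best = prec[i], (k, int(targets[i]))
    if best is None:
        raise SearchExhaustedError("design is already complete")
    k, s = best
    state.apply_move(("add", k, s))
    return k + 1, s


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def improvement_sweep(
    design: Design, scenario: Scenario, moves: MoveConfig | None = None
) -> Design:
    """Hill-climb a symmetric design with sample-size-preserving moves.

    Applies the best improving move (move + its mirror image) repeatedly
    until a full pass over all enabled families finds none whose relative
    precision gain exceeds the tolerance.  The output is symmetric, has the
    same sample size, and its precision is never below the input's.
    """
    moves = moves or MoveConfig()
    state = _SymState(scenario, design)
    _sweep(state, moves)
    return state.design()


def greedy_remove_pair(
    design: Design, scenario: Scenario
) -> tuple[Design, tuple[int, int]]:
    """Remove the recruited mirror pair that costs the least precision.

    Every recruited slot in clusters ``1..K/2`` is evaluated together with
    its mirror image (an exhaustive scan, accelerated by rank-one
    downdates); ties break to the lowest (cluster, slot).  Returns the new
    design and the (1-based) half-cluster slot that was removed.
    """
    state = _SymState(scenario, design)
    pair = _greedy_remove(state)
    return state.design(), pair


def greedy_add_pair(
    design: Design, scenario: Scenario
) -> tuple[Design, tuple[int, int]]:
    """Add the unrecruited mirror pair that gains the most precision."""
    state = _SymState(scenario, design)
    pair = _greedy_add(state)
    return state.design(), pair


def _record(
    state: _SymState, iteration: int, step_type: str, keep_designs: bool
) -> TrajectoryRecord:
    var = state.variance()
    return TrajectoryRecord(
        iteration=iteration,
        step_type=step_type,
        n=state.n,
        variance=var,
        precision=state.sc.sigma2 / var,
        design=state.design() if keep_designs else None,
    )


def forward_search(
    scenario: Scenario,
    target: float | None = None,
    min_n: int | None = None,
    moves: MoveConfig | None = None,
    callback=None,
    start_design: Design | None = None,
    keep_designs: bool = True,
) -> SearchTrajectory:
    """Search from the complete diagonal design downwards in sample size.

    Alternates improvement sweeps with greedy mirror-pair removals,
    recording one iterate per sample size (the post-sweep design).  Stops
    when the precision first falls below ``target`` (that iterate is
    recorded too), when ``n`` reaches the floor ``min_n`` (default ``p + 2``)
    or when no removal keeps the design identifiable.  If even the complete
    design misses the target the trajectory is flagged ``unachievable``.
    Deterministic given the scenario and move configuration.
    """
    moves = moves or MoveConfig()
    design0 = start_design if start_design is not None else complete_diagonal_design(
        scenario.K, scenario.M
    )
    state = _SymState(scenario, design0)
    prec = _sweep(state, moves)
    traj = SearchTrajectory(direction="forward", target=target)
    rec = _record(state, 0, "sweep", keep_designs)
    traj.records.append(rec)
    if callback is not None:
        callback(rec)
    if target is not None and prec < target:
        traj.unachievable = True
        return traj
    if target is not None:
        traj.achieved = True
    floor = scenario.p + 2 if min_n is None else max(min_n, scenario.p)
    iteration = 0
    while state.n - 2 >= floor:
        try:
            _greedy_remove(state)
        except SearchExhaustedError:
            traj.exhausted = True
            break
        prec = _sweep(state, moves)
        iteration += 1
        rec = _record(state, iteration, "remove", keep_designs)
        traj.records.append(rec)
        if callback is not None:
            callback(rec)
        if target is not None and prec < target:
            break
    return traj


def backward_search(
    scenario: Scenario,
    target: float,
    moves: MoveConfig | None = None,
    callback=None,
    start_design: Design | None = None,
    keep_designs: bool = True,
) -> SearchTrajectory:
    """Search upwards from a narrow staircase design until the target is met.

    The starting staircase has window width ``round(M/(K-1))`` (minimum 1),
    widened if necessary until the model is identifiable.  Alternates
    improvement sweeps with greedy mirror-pair additions; stops once the
    target precision is reached, or flags the trajectory ``unachievable`` if
    the design completes first.
    """
    moves = moves or MoveConfig()
    if start_design is not None:
        state = _SymState(scenario, start_design)
    else:
        j = staircase_width(scenario.K, scenario.M)
        while True:
            design0 = staircase_design(scenario.K, scenario.M, j)
            try:
                state = _SymState(scenario, design0)
                state.variance()
                break
            except IdentifiabilityError:
                j += 1
                if j > scenario.M:
                    raise
    prec = _sweep(state, moves)
    traj = SearchTrajectory(direction="backward", target=target)
    rec = _record(state, 0, "sweep", keep_designs)
    traj.records.append(rec)
    if callback is not None:
        callback(rec)
    if prec >= target:
        traj.achieved = True
        return traj
    iteration = 0
    while True:
        try:
            _greedy_add(state)
        except SearchExhaustedError:
            traj.unachievable = True
            break
        prec = _sweep(state, moves)
        iteration += 1
        rec = _record(state, iteration, "add", keep_designs)
        traj.records.append(rec)
        if callback is not None:
            callback(rec)
        if prec >= target:
            traj.achieved = True
            break
    return traj


def hunt(
    scenario: Scenario,
    power_spec: PowerSpec,
    moves: MoveConfig | None = None,
    forward_callback=None,
    backward_callback=None,
    keep_designs: bool = True,
) -> HuntResult:
    """Find the smallest design meeting a power target, searching both ways.

    Converts the power specification to a target precision, runs the forward
    and backward searches and returns whichever candidate achieves the target
    with the smaller sample size (ties: higher precision).  If even the best
    complete design is underpowered, that complete design is returned with
    ``achieved=False``.
    """
    target = required_precision(power_spec)
    fwd = forward_search(
        scenario,
        target=target,
        moves=moves,
        callback=forward_callback,
        keep_designs=keep_designs,
    )
    start = fwd.records[0]
    if fwd.unachievable:
        return HuntResult(
            design=start.design,
            n=start.n,
            variance=start.variance,
            precision=start.precision,
            achieved=False,
            target=target,
            forward=fwd,
            backward=None,
        )
    bwd = backward_search(
        scenario, target, moves=moves, callback=backward_callback, keep_designs=keep_designs
    )
    candidates = []
    f_rec = fwd.last_meeting_target()
    if f_rec is not None:
        candidates.append(f_rec)
    if bwd.achieved:
        b_rec = bwd.records[-1]
        if b_rec.precision >= target:
            candidates.append(b_rec)
    best = min(candidates, key=lambda r: (r.n, -r.precision))
    return HuntResult(
        design=best.design,
        n=best.n,
        variance=best.variance,
        precision=best.precision,
        achieved=True,
        target=target,
        forward=fwd,
        backward=bwd,
    )


def best_complete(scenario: Scenario, moves: MoveConfig | None = None) -> Design:
    """The most powerful complete design the hill-climb can find.

    Full recruitment everywhere; starting from the diagonal boundary, only
    mirror-symmetric cross-over shifts are feasible (there are no unrecruited
    slots), and they are applied until no shift improves precision.
    """
    moves = moves or MoveConfig()
    state = _SymState(scenario, complete_diagonal_design(scenario.K, scenario.M))
    _sweep(state, moves)
    return state.design()
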