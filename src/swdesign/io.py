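"""Design file format, baseline experiment runners and fixture scenarios.

Design files are plain CSV with the bit-exact header

    cluster,crossover_slot,s1,...,sM

one row per cluster, ``crossover_slot`` in ``1..M+1`` and the ``s`` columns
binary recruitment indicators.  Which condition a recruited slot falls under
is *not* stored: it is always recomputed from ``crossover_slot`` (a slot is
under intervention iff ``s >= crossover_slot``), so files cannot contradict
themselves.  Reading and writing round-trip losslessly.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .designs import random_symmetric_design, staircase_design
from .errors import DesignFileError, IdentifiabilityError, InvalidDesignError
from .model import Design, Scenario, treatment_variance

__all__ = [
    "read_design",
    "write_design",
    "random_baseline",
    "staircase_sweep",
    "fixture_scenarios",
    "FULL_SCALE_CORRELATIONS",
]

logger = logging.getLogger("swdesign")

# The five full-scale (rho, tau) pairs studied at K=30, M=100, degree 6.
FULL_SCALE_CORRELATIONS: tuple[tuple[float, float], ...] = (
    (0.01, 1.0),
    (0.05, 0.2),
    (0.05, 1.0),
    (0.25, 0.2),
    (0.25, 1.0),
)

# Mentioned only alongside the main results: clusters arrange in four
# macro-steps under this very fast decay.
EXTRA_CORRELATION: tuple[float, float] = (0.25, 0.04)


def write_design(design: Design, path) -> None:
    """Write a design as CSV with header ``cluster,crossover_slot,s1,...,sM``."""
    M = design.M
    data = {"cluster": np.arange(1, design.K + 1), "crossover_slot": design.crossover}
    for s in range(1, M + 1):
        data[f"s{s}"] = design.recruit[:, s - 1].astype(int)
    pd.DataFrame(data).to_csv(path, index=False)


def read_design(path) -> Design:
    """Read a design CSV; raises :class:`DesignFileError` naming the bad cell."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DesignFileError(f"cannot parse design file {path}: {exc}") from exc
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "cluster" or cols[1] != "crossover_slot":
        raise DesignFileError(
            f"malformed header in {path}: expected cluster,crossover_slot,s1,...,sM"
        )
    M = len(cols) - 2
    if cols[2:] != [f"s{s}" for s in range(1, M + 1)]:
        raise DesignFileError(
            f"malformed header in {path}: recruitment columns must be s1..s{M}"
        )
    if df.isna().any().any():
        row = int(np.argwhere(df.isna().any(axis=1).to_numpy())[0][0])
        raise DesignFileError(f"missing value in {path} at data row {row + 1}")
    for col in cols:
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise DesignFileError(f"non-integer values in column {col!r} of {path}")
    crossover = df["crossover_slot"].to_numpy()
    bad = np.flatnonzero((crossover < 1) | (crossover > M + 1))
    if bad.size:
        raise DesignFileError(
            f"crossover_slot out of range 1..{M + 1} in {path} at data row "
            f"{bad[0] + 1}: {crossover[bad[0]]}"
        )
    recruit = df[[f"s{s}" for s in range(1, M + 1)]].to_numpy()
    bad_rc = np.argwhere((recruit != 0) & (recruit != 1))
    if bad_rc.size:
        r, c = bad_rc[0]
        raise DesignFileError(
            f"non-binary recruitment value in {path} at data row {r + 1}, "
            f"column s{c + 1}: {recruit[r, c]}"
        )
    return Design(crossover, recruit.astype(bool))


def _evaluate(scenario: Scenario, design: Design) -> tuple[float, float]:
    var = treatment_variance(scenario, design)
    return var, scenario.sigma2 / var


def random_baseline(
    scenario: Scenario,
    n_designs: int,
    seed: int,
    log_every: int = 10_000,
) -> pd.DataFrame:
    """Evaluate ``n_designs`` random reversal-invariant designs.

    Each design is drawn from its own seed stream ``(seed, design_id)`` so
    tables are reproducible under partial re-runs.  Non-identifiable draws
    are skipped; their count is in ``df.attrs["n_skipped"]``.  Columns:
    ``design_id, n, variance, precision, generator``.
    """
    if n_designs < 1:
        raise ValueError(f"n_designs must be >= 1, got {n_designs}")
    rows = []
    skipped = 0
    for i in range(n_designs):
        design = random_symmetric_design(
            scenario.K, scenario.M, np.random.SeedSequence([int(seed), i])
        )
        try:
            var, prec = _evaluate(scenario, design)
        except (IdentifiabilityError, InvalidDesignError):
            # empty or confounded draw: counted, not evaluated
            skipped += 1
            continue
        rows.append((i, design.n, var, prec))
        if log_every and (i + 1) % log_every == 0:
            logger.info("random baseline: %d/%d designs evaluated", i + 1, n_designs)
    df = pd.DataFrame(rows, columns=["design_id", "n", "variance", "precision"])
    df["generator"] = "random"
    df.attrs["n_skipped"] = skipped
    return df


def staircase_sweep(scenario: Scenario, j_values: Iterable[int]) -> pd.DataFrame:
    """Evaluate staircase designs for each recruitment-window width ``j``."""
    j_values = list(j_values)
    if not j_values:
        raise ValueError("j_values must be non-empty")
    rows = []
    for j in j_values:
        design = staircase_design(scenario.K, scenario.M, int(j))
        var, prec = _evaluate(scenario, design)
        rows.append((int(j), design.n, var, prec, f"staircase-{int(j)}"))
    return pd.DataFrame(rows, columns=["design_id", "n", "variance", "precision", "generator"])


def fixture_scenarios(include_extra: bool = False) -> list[Scenario]:
    """The five full-scale study scenarios plus small test-size scenarios.

    Full scale: ``K=30, M=100``, sixth-degree time effect, with the five
    (rho, tau) pairs in :data:`FULL_SCALE_CORRELATIONS`.  With
    ``include_extra`` the results-only (0.25, 0.04) pair is appended.  The
    scaled-down scenarios (K in {2, 4, 8}, M in {3, 6, 12}, degree 2) keep
    the test suite fast while exercising the same machinery.
    """
    scenarios = [
        Scenario(K=30, M=100, rho=rho, tau=tau, degree=6)
        for rho, tau in FULL_SCALE_CORRELATIONS
    ]
    if include_extra:
        rho, tau = EXTRA_CORRELATION
        scenarios.append(Scenario(K=30, M=100, rho=rho, tau=tau, degree=6))
    for K in (2, 4, 8):
        for M in (3, 6, 12):
            scenarios.append(Scenario(K=K, M=M, rho=0.05, tau=0.2, degree=2))
    return scenarios
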