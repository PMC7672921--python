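# Methods

## The design problem

A stepped wedge cluster-randomised trial recruits from `K` clusters that each
cross over from the control to the intervention condition at a scheduled time.
Here recruitment is (near-)continuous: one eligible participant presents at
each cluster at the regularly spaced times `1/M, 2/M, ..., M/M` over a trial
of unit duration, and the investigator may choose, slot by slot, whether to
recruit.  A *design* is therefore a per-cluster cross-over slot
`c_k ∈ {1, ..., M+1}` (slot `c_k` is the first recruited under intervention;
`M+1` means never crosses, `1` means intervention throughout) together with a
binary recruitment sequence of length `M` per cluster.  A *complete* design
recruits everyone (`n = MK`); an *incomplete* design suspends recruitment at
some cluster/slot combinations to save sample size.

## Statistical model

The outcome of participant `i` in cluster `k`, recruited at `t_ik`, is

    Y_ik = T(t_ik) + θ · H(t_ik − t*_k) + ε_ik,

with `T` a degree-`d` polynomial time effect common to all clusters (default
`d = 6`), `H` the unit step (`H(0) = 1`), `θ` the treatment effect, and
residuals of variance `σ²` correlated within clusters as

    Corr(ε_i1k, ε_i2k) = ρ · τ^|t_i1k − t_i2k|,

zero between clusters.  `ρ` is the intracluster correlation of two
same-cluster participants sampled at the same time; `τ` is the factor by
which it decays over the whole trial duration (`τ = 1` recovers the
exchangeable, Hussey–Hughes-type structure in continuous time).  No outcomes
are simulated anywhere: design quality is the GLS precision

    precision = 1 / [(Z′V⁻¹Z)⁻¹]_(θ,θ)   evaluated at σ² = 1,

computed cluster-block by cluster-block since `V` is block diagonal.
Variance components are treated as known, so no degrees-of-freedom correction
is applied anywhere.

Power uses the standard normal approximation with the far tail ignored:
`power = Φ(|δ|·√precision − z_{1−α/2})` for a standardized effect `δ = Δ/σ`,
inverted as `precision ≥ ((z_{1−α/2} + z_power)/δ)²` to convert a power target
into a precision target (e.g. 116.75 for δ = 0.30, α = 0.05, power = 0.90).

### Numerical choices

* The polynomial columns of `Z` are Legendre polynomials in `2t − 1` rather
  than raw powers; the treatment variance is invariant to any invertible
  reparameterisation of the polynomial block (tested), and conditioning at
  degree 6–8 is far better.
* `(Z′V⁻¹Z)` is factorised by Cholesky; failure, a non-finite result or a
  non-positive variance raises an identifiability error that names the defect
  (treatment confounded with a condition, or fewer distinct recruitment times
  than the polynomial needs).
* Designs with `n < p = d + 2` parameters are rejected up front.

## Reversal symmetry

Reversing the time scale *and* swapping the condition labels maps a valid
design to a valid design with exactly the same precision, because the
correlation model depends only on time gaps.  On the slot grid the reversal is
the index map `s ↦ M + 1 − s` (time `t ↦ 1 + 1/M − t`, which preserves the
grid and all gaps; the naive `t ↦ 1 − t` maps the grid off itself), cluster
`k ↦ K + 1 − k`, and `c ↦ M + 2 − c`.  The search is restricted to designs
invariant under this reversal (`K` must be even): schedules are free in
clusters `1..K/2` and mirrored in the rest.  Both map directions are affine
on the model columns, so a mirrored cluster's information contribution is
`S W S′` for a fixed `p × p` matrix `S` — the searches therefore maintain
state for half the clusters only.

## The search

Forward: start from the complete design whose cross-over boundary is the
straight diagonal (`c_k − 1` = nearest integer, half up, to `M(k−1)/(K−1)`),
then alternate

1. an *improvement sweep*: repeatedly apply the single best
   sample-size-preserving move until none improves the precision by more than
   a relative `1e−10` (moves: ±1 cross-over shifts; relocation of a recruited
   slot to an unrecruited slot of the same cluster; optionally cross-cluster
   relocation, off by default since the greedy steps already migrate
   recruitment between clusters over iterations); and
2. a *greedy removal*: exhaustively score every recruited slot in the first
   half-clusters and delete the one (with its mirror image) whose loss costs
   the least precision.

Backward: the same loop from a narrow staircase design (window width
`round(M/(K−1))`, minimum 1, widened if not identifiable), greedily *adding*
the most informative pair instead.  `hunt` runs both against a target
precision and keeps the smaller design that meets it; if even the best
complete design misses the target the result is flagged unachievable and that
complete design is returned.

Every operation acts on a participant *pair* (a slot and its reversal image,
always in distinct clusters), so `n` moves in steps of two and the design
space stays symmetric throughout.  Candidate scoring uses exact rank-one
updates of cached per-cluster quantities (`V_k⁻¹`, `G = V_k⁻¹Z_k`,
`W = Z_k′V_k⁻¹Z_k`): deleting observation `i` downdates `W` by `g g′/u`
(`g` the `i`-th row of `G`, `u` the diagonal entry of `V_k⁻¹`), adding uses
the block-inverse identity, and a cross-over shift is a symmetric rank-two
row update.  All candidate `p × p` systems in a cluster are solved in one
stacked LAPACK call.  Per-cluster caches are rebuilt from scratch every 64
rank-one mutations to stop floating-point drift; tests confirm incremental
and from-scratch evaluations agree to `1e−10`.

Determinism: candidates are scanned in a fixed (family, cluster, slot) order
and an incumbent is displaced only by a relative improvement above `1e−12`,
so exact-arithmetic ties (e.g. mirror-equivalent removals that differ only in
rounding) resolve to the lowest-ordered candidate and repeated runs are
bit-identical.

### Known limitations

* Hill climbing with these move families can stall at local optima.  On
  exhaustively enumerable instances (K = 2, M ≤ 4) the search attains the
  global symmetric optimum at every sample size except one case (M = 4,
  degree 0, n = 6) where it is 0.22% below — the tests assert a 1% bound.
* Designs are restricted to the reversal-symmetric space; asymmetric designs
  of odd sample size are out of scope (the evaluation machinery itself
  handles them fine).
* Transition periods, non-polynomial time effects (splines), random arrival
  processes and estimation from data (mixed models / GEE) are out of scope.

## Canonical designs and baselines

* **Staircase**: same diagonal cross-over boundary, recruitment only in
  windows of width `j` immediately before and after each cluster's
  cross-over, truncated at the trial boundaries (the only convention that
  keeps every window inside the trial), so `n ≤ 2jK`.
* **Random symmetric baseline**: per design, cross-over slots uniform on
  `{1, ..., M+1}` (including the two degenerate schedules) in the free half,
  one recruitment probability `p ~ U[0,1]`, slots recruited independently
  with probability `p`, then mirrored.  Each design draws from its own
  `(seed, design_id)` stream, so tables are reproducible under partial
  re-runs; non-identifiable draws are skipped and counted.

These baselines emulate the benchmark experiment at full scale
(K = 30, M = 100, ρ = 0.05, τ = 0.2, degree 6).  What they do not emulate:
real trials have uneven arrival processes, unknown (ρ, τ), non-polynomial
secular trends and cluster-size imbalance — passing tests show the *search
machinery* is exact and effective under the stated model, not that a found
schedule is robust to model misspecification.  The degree-override mechanism
in `design_power` is the tool for probing that robustness.

## Problem sizes used by the test suite and acceptance script

Exact identities (oracle equivalence, closed forms, downdates, reversal
invariance) are checked on randomized small scenarios (K ≤ 6, M ≤ 12,
degree ≤ 3).  Search optimality is checked against exhaustive enumeration of
the whole symmetric design space at K = 2, M ≤ 4 and against 10,000-design
random envelopes.  The full-scale trade-off experiment is run once, exactly
as specified (K = 30, M = 100, ρ = 0.05, τ = 0.2, degree 6): forward search
from n = 3000 down to n = 58, staircase widths 1..100, and a backward search
to the 90%-power target for δ = 0.30.  Its headline outputs — the relative
precision retained at half the maximum sample size and the floor of
staircase-vs-search relative precision — are what `scripts/acceptance.py`
recomputes and writes.
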