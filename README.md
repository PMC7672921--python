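# swdesign

Efficient, incomplete stepped wedge trial designs with continuous recruitment.

## The problem

In a stepped wedge cluster-randomised trial, `K` clusters each cross over from
the control to the intervention condition at a scheduled time.  When eligible
participants present continuously — one per cluster at each of the regularly
spaced times `1/M, ..., M/M` over a unit-duration trial — and every recruited
participant costs money and consent burden, the design question becomes: *when
should each cluster cross over, and which presenting participants should be
recruited, to reach a precision (power) target with the fewest participants?*

`swdesign` is for trial statisticians exploring that trade-off.  It provides:

* **exact GLS precision** of the treatment effect estimator under the
  continuous-time model

      Y_ik = T(t_ik) + θ·H(t_ik − t*_k) + ε_ik,
      Corr(ε_i1k, ε_i2k) = ρ·τ^|t_i1k − t_i2k|,   Var(ε_ik) = σ²,

  with a polynomial time effect `T` (default degree 6), a step intervention
  effect `θ`, intracluster correlation `ρ` decaying by a factor `τ` over the
  trial duration, and `precision = 1/[(Z′V⁻¹Z)⁻¹]_(θ,θ)` at `σ² = 1`,
  computed cluster-block by cluster-block;
* a **deterministic greedy search** over reversal-symmetric designs: from the
  complete design, repeatedly hill-climb with sample-size-preserving moves
  (cross-over shifts, recruitment relocations) and remove the participant pair
  that costs the least precision — and the mirror-image backward search that
  adds the most informative pair starting from a narrow staircase design;
* **power conversions** (`precision ↔ power` for a standardized effect size at
  a two-sided significance level), canonical **staircase** and **random
  symmetric** baseline designs, a bit-exact **CSV design format**, and a CLI.

All of it is evaluation of covariance structure — no outcome data are ever
simulated.  See `docs/methods.md` for the model, the algorithm and its
numerical internals.

## Worked example

Find the smallest design for 8 clusters and 12 recruitment slots per cluster
(`ρ = 0.05`, `τ = 0.2`, quadratic time effect) detecting a standardized effect
of 0.9 with 90% power at the two-sided 5% level:

```python
import swdesign as sw

scenario = sw.Scenario(K=8, M=12, rho=0.05, tau=0.2, degree=2)
spec = sw.PowerSpec(delta=0.9, alpha=0.05, power=0.90)

print(sw.required_precision(spec))        # 12.972127236346443
result = sw.hunt(scenario, spec)
print(result.n, result.precision)         # 56 13.25107636227382
print(sw.design_power(scenario, result.design, 0.9))   # 0.9059496465907799
sw.write_design(result.design, "design.csv")
```

The target precision 12.97 is what 90% power requires; the search finds a
56-participant design (of 96 available) whose precision 13.25 exceeds it, i.e.
90.6% power, saving 40 participants relative to complete recruitment.  The
design file shows the familiar pattern — recruitment concentrated around each
cluster's cross-over, with clusters crossing along a diagonal:

```
cluster,crossover_slot,s1,s2,s3,s4,s5,s6,s7,s8,s9,s10,s11,s12
1,4,1,1,1,1,1,1,1,1,0,0,0,0
2,1,1,1,1,1,1,0,0,0,0,0,0,0
...
8,10,0,0,0,0,1,1,1,1,1,1,1,1
```

The same run from the shell:

```sh
swdesign hunt --k 8 --m 12 --rho 0.05 --tau 0.2 --degree 2 \
         --delta 0.9 --out design.csv --trajectory traj.csv
swdesign evaluate --k 8 --m 12 --rho 0.05 --tau 0.2 --degree 2 --design design.csv
swdesign power --delta 0.3 --alpha 0.05 --power 0.9     # required precision
```

Exit codes: 0 ok, 2 invalid input, 3 treatment effect not estimable under the
design, 4 target unachievable (the best complete design is then written out).

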