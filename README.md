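# trophicmeta

Linear stability analysis of body-size-structured food webs coupled
across habitat-patch networks by allometric dispersal.

## The problem

Large-bodied consumers sit high in food webs and often move farthest and
fastest, so they are widely expected to be the species that knit local
communities into a stable regional whole.  `trophicmeta` is a simulation
library for testing that expectation.  It builds *trophic
metacommunities* — copies of one food web living in `N` discrete habitat
patches with spatially varying ecological rates, coupled by dispersal —
and asks when the coupled system is linearly stable, and whether
stability depends on body-size-ordered dispersal specifically or just on
the overall level of patch coupling.

## Model

* **Topology.** Food webs are drawn from the niche model: each of `S`
  species gets a niche value `n_i ~ U(0,1)` and eats every species in a
  feeding range of width `x·n_i` (with `x ~ Beta(1, 1/(2C) − 1)`, so the
  expected connectance is `C`) centred at or below `n_i`.  Webs without
  a basal producer, without full basal support, or not forming a single
  connected component are discarded and redrawn.
* **Allometry.** A species at trophic position `T_i` (shortest feeding
  path to a producer) has body mass `M_i = R^{T_i}` with `R = 42`, and
  biomass turnover rate `α_i = M_i^{−1/4}`.
* **Local dynamics.** Rather than fixing functional forms, each patch's
  `S×S` Jacobian is parameterized at an assumed steady state with
  generalized-modeling scale (`α`), branching (`ρ, σ, β, χ`) and
  elasticity (`φ, ψ, γ, μ`; `λ = 1`) parameters, drawn uniformly and
  independently per patch from ecologically motivated ranges.  The
  analytic Jacobian is validated against finite differences of an exact
  power-law realisation of the normalised dynamics.
* **Space.** Patches are a random geometric graph: `N = 10` points in
  the unit square, linked below distance `0.32`, rejected unless
  connected.  With per-species dispersal rates `δ_i = d·M_i^z` on the
  diagonal of `D` and the patch Laplacian `L`, the metacommunity
  Jacobian is the `SN×SN` matrix

      J = P − L ⊗ D,

  where `P` is block-diagonal in the local Jacobians.  The system is
  stable when every eigenvalue of `J` has negative real part.
* **Attribution.**  A permutation analysis re-assembles `J` with the
  species' dispersal rates randomly reassigned and compares the sign of
  the leading eigenvalue with the median over permutations; a binomial
  (logit) GLM with all-subsets AIC selection attributes stability to
  `S`, `C`, `d`, `z` and spatial heterogeneity summaries.

## Worked example

```python
import numpy as np, trophicmeta as tm

rng = np.random.default_rng(7)
meta = tm.generate_metacommunity(S=12, C=0.18, rng=rng, d=0.1, z=0.5)
res = meta.stability()
print(res.prop_local_stable, res.lambda1, res.metacommunity_stable)
```

prints `0.6 -0.0389 True`: only 6 of 10 patches would be stable in
isolation (their leading eigenvalues range from −0.054 to +0.041), yet
the coupled metacommunity's leading eigenvalue is −0.039 — dispersal
with positive body-size scaling (`z = 0.5`) has stabilized the whole.
Shuffling which species carries which dispersal rate
(`tm.run_permutation_analysis(meta, 100, rng)`) typically leaves the
sign unchanged ("stability unaffected"), evidence that the coupling
level, not the identity of the fastest disperser, drives the outcome.

The `examples/` scripts walk through each capability: web generation,
single-metacommunity stability, the permutation null model, and the
ensemble sweep + GLM.

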