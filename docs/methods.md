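# Methods

This note records the model as implemented, the defaults and why they
were chosen, what the generators do and do not emulate, and the
numerical conventions.  Nothing here reports results beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Niche-model food webs

Species `i = 1..S` receive niche values `n_i ~ Uniform(0, 1)`.  The
feeding-range fraction is `x_i ~ Beta(1, 1/(2C) − 1)`, whose mean is
`2C`, the range width is `r_i = x_i n_i`, and the range centre is
`c_i ~ Uniform(r_i/2, n_i)`; species `i` eats every `j` with `n_j ∈
[c_i − r_i/2, c_i + r_i/2]` (closed interval; the tie set has measure
zero).  This is the canonical niche-model construction; with a uniform
density of niche values it makes the expected realized connectance
(directed links over `S²`, self-links counted) equal to `C` before any
filtering.

Retention requires (i) at least one basal producer (empty prey set,
counting a cannibalistic self-link as prey), (ii) a single connected
component when links are read as undirected, and (iii) a directed
feeding path from every species to some producer.  Condition (iii) goes
beyond connectivity but is necessary for trophic positions — and hence
body masses — to be defined; webs violating any condition are discarded
and redrawn, with a budget of 10,000 attempts before the `(S, C)` pair
is declared infeasible.  Retention is selective: it removes sparse
disconnected draws and dense producer-free draws at different rates, so
the mean connectance of *retained* webs sits very slightly above the
target (about +0.005 at `S = 25, C = 0.2`, where roughly half of raw
draws are rejected, mostly for missing basal support).  The generator
itself is calibrated exactly; the small retained-ensemble elevation is
an unavoidable property of conditioning on ecological sanity.

Cannibalistic self-links are kept as generated (a config flag strips
them) but ignored when computing trophic positions.  Trophic position
`T_i` is the *shortest* directed path to any producer ("any" read as
minimum), computed by multi-source BFS and cross-checked in the tests
against a networkx shortest-path oracle.  Species with identical diets
are not merged.  Body mass is `M_i = R^{T_i}` with `R = 42` — a
representative empirical predator–prey mass ratio — and turnover is
`α_i = M_i^{−1/4}`, the quarter-power metabolic scaling.  Producers
have mass exactly 1 for any `R` because `T = 0`.

## Landscapes

`N = 10` patch coordinates are uniform in the unit square (the
two-dimensional reading of "positions on [0, 1]"); patches are linked
when their Euclidean distance is strictly below the radius `0.32`.
Draws that are not one connected component are rejected, which
conditions the RGG ensemble on connectivity but changes nothing else.
The Laplacian `L = diag(degree) − A` has exact zero row sums by
construction (integer arithmetic before the float cast), is positive
semidefinite, and has a simple zero eigenvalue iff the graph is
connected; `laplacian_spectrum` exposes the eigenvalues `μ_0 ≤ … ≤
μ_{N−1}` used by the homogeneous-limit decomposition test.

## Generalized-model Jacobians

Each patch gets an independent draw of the spatially varying
parameters; the scale parameters `α_i` are spatially homogeneous.

| parameter | meaning | range |
|---|---|---|
| `ρ_i` | fraction of gains from predation | 0 (producer) or 1 (consumer) |
| `σ_i^k` | fraction of losses to predation | U(0, 1); forced 0 without predators |
| `β_ij^k` | share of i's predation loss to predator j | uniform, normalised to Σ_j = 1 |
| `χ_ji^k` | share of j's gains from prey i | uniform, normalised to Σ_i = 1 |
| `φ_i^k` | producer growth elasticity (nutrient availability) | U(0, 1) |
| `ψ_i^k` | predator self-density elasticity (interference) | U(0.5, 1) |
| `γ_i^k` | total-prey elasticity (functional-response saturation) | U(0.5, 1.5) |
| `μ_i^k` | mortality self-density elasticity | U(1, 1.5) |
| `λ` | prey-contribution elasticity (preference adaptivity) | fixed at 1 |

The raw share ranges are [0, 1], but the normalised steady state only
exists when each consumer's gain shares and each prey's loss shares sum
to one, and when apex species put no loss into predation; the sum-to-one
normalisation and the `σ = 0` forcing implement exactly that.  Interior
`ρ` (mixotrophy) is not supported.

With densities normalised by their steady states, the per-capita loss
of prey `n` to predator `j` is realised as `e_jn = f_j(c_j, b_j) b_n^λ
/ c_j`, which equals one at the steady state `b = 1`.  Its elasticities
give

    ∂e_jn/∂b_m |_{b=1} = δ_nm + (γ_j − 1) χ_jm + ψ_j δ_jm   (λ = 1),

and the local Jacobian entry

    J_k[n, m] = α_n [ (1 − ρ_n) φ_n δ_nm
                      + ρ_n (γ_n χ_nm + ψ_n δ_nm)
                      − (1 − σ_n) μ_n δ_nm
                      − σ_n Σ_j β_nj ∂e_jn/∂b_m ].

Entries are exactly zero outside the structural mask (self, prey,
predator, shared-predator).  Correctness is arbitrated by an
independent oracle: `normalized_rhs` evaluates the normalised dynamics
under concrete power-law realisations (`g = b^φ`, `x = b^μ`,
`f = b^ψ c^γ`, `c_j = Σ_i χ_ji b_i`) whose elasticities at `b = 1`
equal the sampled parameters exactly and for which `b = 1` is a steady
state by construction; central finite differences (step `1e−5`) of this
function must match the analytic Jacobian to `1e−6` max-abs, and do so
to ~`1e−10` in practice (truncation error of central differences at
this step size).  Cannibalistic links enter both gain and loss terms
with the species as its own predator/prey; the oracle covers this case.

## Metacommunity assembly and stability

`J = P − L ⊗ D` with patch-major ordering (block `(k, l)` is
`L[k,l]·D`), `P` block-diagonal in the `J_k`, and `D =
diag(d·M_i^z)`.  Dispersal is linear in local density, identical in and
out of every patch (no cross-diffusion, no patch dependence), so the
Laplacian captures all spatial structure.  `d ∈ [1e−4, 1]` is the
global link strength; `z ∈ [−0.75, 0.75]` is the allometric exponent;
producers always disperse at rate `d`.

Stability is classified by the leading real part `λ₁` of the dense
nonsymmetric eigenproblem (LAPACK via `scipy.linalg.eigvals`), with the
strict convention `stable ⇔ λ₁ < 0` and no tolerance band: the
heterogeneous ensemble has no structural zero eigenvalues, so boundary
cases are measure-zero and are reported as unstable.  At study scale
(`SN ≤ 300`) dense solves take tens of milliseconds; no sparse path is
needed.  Two exact limits anchor the implementation: at `d = 0` the
spectrum of `J` is the multiset union of the local spectra, and with
identical patches it is `∪_m spec(J_k − μ_m D)` over Laplacian
eigenvalues — both verified to `1e−8` using optimal bipartite pairing
of eigenvalues (lexicographic sorting mis-pairs near-degenerate complex
pairs).

Although coupling locally stable patches is usually stabilizing,
`−L ⊗ D` is only positive semidefinite in the symmetric sense, so
dispersal-driven (Turing-type) instability of a metacommunity whose
patches are all locally stable is possible and does occur, rarely, in
this ensemble (observed at roughly the 0.1% level per evaluation,
preferentially at intermediate `d` with strongly positive `z`).  The
"all locally stable ⇒ metacommunity stable" observation is therefore
an empirical regularity, not a theorem, and the corresponding test
reports any counterexample with its seed.

## Permutation null model

`permute_dispersal` applies a uniform random permutation to the
dispersal-rate vector; the identity is allowed (a derangement mode
excluding it exists for sensitivity analysis, since the looser reading
"reassigned to a different species" is ambiguous).  Only `D` changes;
local Jacobians are fixed.  The outcome category compares
`sign(λ₁ original)` with `sign(median λ₁ permuted)` — gained, lost, or
unaffected — with the even-length median taken as the midpoint of the
central pair and a median of exactly zero counting as unstable.  When
all rates are equal (`z = 0`, since `M^0 = 1` exactly) every permuted
Jacobian is bit-identical, so the permuted eigenvalues are filled in
without re-solving.

## Ensembles, aggregation, GLM

`run_ensemble` generates `webs_per_cell` independent (web, landscape,
parameters) triples per `(S, C)` cell and scores each at every
`(d, z)`; local Jacobians are dispersal-independent, so per-patch
eigenvalues are computed once per triple.  Per-run seeds come from
`SeedSequence(master_seed, spawn_key=(counter,))`, making any single
triple reproducible in isolation; failed generations are recorded and
skipped, never silently dropped.  Default grids follow the study
design: `S ∈ {10, 12, …, 30}`, `C ∈ {0.12, …, 0.24}`, `d` log-spaced
`{1e−4 … 1}`, `z ∈ {−0.75, …, 0.75}` — all configurable, including from
a YAML file.

`stability_by_local_proportion` bins records by the exact realised
multiples of `1/N` and reports the stable fraction with binomial
standard error `sqrt(p(1−p)/n)`; empty bins are absent rather than
zero.

`fit_stability_glm` fits `stable ~ terms` with binomial errors and a
logit link for **every** subset of the candidate terms (intercept
always included; at most 12 terms, i.e. 4096 submodels) and selects the
minimum-AIC fit.  Predictors are standardized so coefficient magnitudes
are comparable.  Candidate heterogeneity covariates are
per-metacommunity spatial summaries: the overall mean and the mean
across-patch variance of consumer satiation `γ` (over consumers),
nutrient availability `φ` (over producers) and interaction strength
(the `χ` diet shares over realised links; switchable to `β` or `ψ`).
Because diet shares sum to one per consumer, the `χ` summaries are
partially confounded with topology (mean share shrinks with diet
breadth and hence with `S·C`); they are retained as the most direct
reading of "interaction strengths", and the selection criterion of
interest concerns the `S, C, d, z` terms.  Submodels that fail to
converge or separate are excluded from selection with a warning.

## Problem sizes

The package's own reference scales, chosen to make the statistics
sharp at interactive runtimes on a single core:

* acceptance script: 102 base metacommunities reused across all 35
  `(d, z)` combinations, 20 permutations each; replicates per richness
  class decrease with `S` (51/34/17 for `S` = 10/20/30) because the
  dense eigensolve cost grows as `(SN)³`.
* test suite: the same analysis with 10 permutations; a 4,800-member
  ensemble for the `z`-ordering comparison (evaluating the full
  Jacobian only for members in the half-locally-stable bin); 200
  all-locally-stable metacommunities spread over the `(d, z)` grid; a
  1,575-record ensemble for the GLM; 100 random instances for the
  finite-difference oracle and 50 for the spectral limits.

## What the generators do and do not emulate

The synthetic ensemble reproduces the statistical structure of the
study design: niche-model topology with hierarchical feeding,
quarter-power allometry on a fixed mass ratio, patch-wise independent
uniform parameter heterogeneity, connectivity-conditioned random
geometric landscapes, and power-law dispersal allometry.  It does not
emulate: empirical web topologies or mass distributions (ratios vary
hugely across real webs), correlated or gradient-structured
environmental variation (patches are exchangeable here), density- or
behaviour-dependent dispersal, nonlinear or transient dynamics, or
extinction/colonisation turnover.  Passing tests therefore support the
internal logic of the linear-stability claims, not their transfer to
any particular real ecosystem.

## Known limitations

* Linearisation only: `λ₁` says nothing about basins, transients
  (non-normal amplification can be large precisely in these coupled
  systems), or limit cycles after Hopf crossings.
* The steady state is assumed, never constructed; generalized-model
  parameters describe it implicitly, so infeasible steady states
  (negative densities) cannot be detected by construction.
* Retained-web connectance is biased upward by order `+0.005` relative
  to the target at mid `(S, C)` (more at small, sparse webs where
  retention is most selective).
* The GLM treats the 35 records per base triple as independent, as the
  original design does; standard errors are accordingly optimistic.
* No CLI: the library API plus the `examples/` scripts are the
  intended interface; `EnsembleConfig.from_yaml` covers scripted runs.
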