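"""Generalized-model parameters and local food web Jacobians.

Instead of committing to explicit functional forms for growth, feeding
and mortality, the generalized-modeling approach assumes every
population has a (possibly patch-specific) positive steady state and
parameterizes the Jacobian at that steady state with three families of
quantities:

* scale parameters — the normalised biomass turnover rate ``alpha_i``,
  taken from the web's allometry and identical in every patch;
* branching parameters — fractions allocating gains and losses among
  processes: ``rho`` (gains from predation vs primary production, 0 or
  1), ``sigma`` (losses to predation vs mortality), ``beta[i, j]``
  (share of prey i's predation loss taken by predator j) and
  ``chi[j, i]`` (share of consumer j's intake coming from prey i);
* elasticities — log-log sensitivities of the normalised rate functions
  at the steady state: producer growth ``phi``, predator self-density
  ``psi``, total-prey-density ``gamma``, mortality ``mu``, and the prey
  contribution exponent ``lambda`` which is held at 1 (constant
  foraging preferences).

Spatial heterogeneity enters by drawing the branching and elasticity
parameters independently per patch from the uniform ranges in
:data:`PARAMETER_RANGES`; per-predator and per-prey shares are then
normalised to sum to one, which is what makes ``b = 1`` (all densities
at their steady states) an exact equilibrium of the normalised
dynamics.

The analytic Jacobian produced here is validated against central finite
differences of :func:`normalized_rhs`, a concrete power-law realisation
of the normalised dynamics whose elasticities are constant, so the
finite-difference check is exact up to truncation error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .niche_web import FoodWebTopology

__all__ = [
    "PARAMETER_RANGES",
    "GeneralizedParams",
    "LocalJacobian",
    "sample_patch_params",
    "build_local_jacobian",
    "normalized_rhs",
    "finite_difference_jacobian",
    "params_to_frame",
    "params_from_frame",
]

#: Uniform sampling ranges for the spatially varying parameters.
PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "sigma": (0.0, 1.0),   # fraction of biomass loss to predation
    "phi": (0.0, 1.0),     # nutrient availability (producer growth elasticity)
    "psi": (0.5, 1.0),     # predator self-density elasticity
    "gamma": (0.5, 1.5),   # total-prey-density elasticity (satiation)
    "mu": (1.0, 1.5),      # mortality self-density elasticity
}

#: prey-contribution elasticity, fixed: foraging preferences are constant
LAMBDA = 1.0


@dataclass(frozen=True)
class GeneralizedParams:
    """Per-patch generalized-model parameters for one topology.

    Arrays are indexed ``[patch, species]`` (or ``[patch, i, j]`` for the
    link-valued shares).  ``rho`` is topology-determined (1 for any
    species with prey, else 0) and therefore spatially homogeneous.
    """

    rho: np.ndarray          # (S,) 0./1.
    sigma: np.ndarray        # (N, S), 0 where the species has no predator
    beta: np.ndarray         # (N, S, S); beta[k, i, j]: share of i's loss to j
    chi: np.ndarray          # (N, S, S); chi[k, j, i]: share of j's gain from i
    phi: np.ndarray          # (N, S)
    psi: np.ndarray          # (N, S)
    gamma: np.ndarray        # (N, S)
    mu: np.ndarray           # (N, S)

    @property
    def n_patches(self) -> int:
        return self.sigma.shape[0]

    @property
    def n_species(self) -> int:
        return self.sigma.shape[1]

    def validate(self, web: FoodWebTopology, atol: float = 1e-12) -> None:
        """Check structural consistency against a topology.

        Raises ``ValueError`` when branching shares do not respect the
        feeding matrix or do not satisfy their sum-to-one constraints.
        """
        has_prey = web.feeding.any(axis=1)
        has_pred = web.feeding.any(axis=0)
        if not np.array_equal(self.rho.astype(bool), has_prey):
            raise ValueError("rho inconsistent with the feeding matrix")
        if np.any(np.abs(self.sigma[:, ~has_pred]) > 0):
            raise ValueError("sigma must be 0 for species with no predator")
        pred_links = web.feeding.T  # pred_links[i, j]: j eats i
        if np.any(self.beta[:, ~pred_links] != 0) or np.any(self.chi[:, ~web.feeding] != 0):
            raise ValueError("branching shares present on non-links")
        beta_sums = self.beta.sum(axis=2)
        chi_sums = self.chi.sum(axis=2)
        if np.any(np.abs(beta_sums[:, has_pred] - 1) > atol):
            raise ValueError("beta shares of a preyed-upon species must sum to 1")
        if np.any(np.abs(chi_sums[:, has_prey] - 1) > atol):
            raise ValueError("chi shares of a consumer must sum to 1")
        for name in ("phi", "psi", "gamma", "mu"):
            lo, hi = PARAMETER_RANGES[name]
            vals = getattr(self, name)
            if np.any(vals < lo) or np.any(vals > hi):
                raise ValueError(f"{name} outside its range [{lo}, {hi}]")


@dataclass(frozen=True)
class LocalJacobian:
    """The S x S community Jacobian of one habitat patch."""

    matrix: np.ndarray
    patch: int


def sample_patch_params(
    web: FoodWebTopology,
    N: int,
    rng: np.random.Generator,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> GeneralizedParams:
    """Draw independent per-patch parameters for every patch of a landscape.

    Scalar parameters are uniform in their configured ranges per patch
    and species.  Link shares (``beta``, ``chi``) are uniform draws on
    the realised links, renormalised so each preyed-upon species' loss
    shares and each consumer's gain shares sum to one; ``sigma`` is
    forced to 0 for species with no predator (their biomass loss is pure
    mortality).  Entries that a species' role makes inert (e.g. ``phi``
    of a consumer, ``gamma`` of a producer) are still sampled but never
    enter the Jacobian.
    """
    if ranges is None:
        ranges = PARAMETER_RANGES
    S = web.S
    feeding = web.feeding
    has_prey = feeding.any(axis=1)
    has_pred = feeding.any(axis=0)

    def draw(name: str) -> np.ndarray:
        lo, hi = ranges[name]
        return rng.uniform(lo, hi, size=(N, S))

    sigma = draw("sigma")
    sigma[:, ~has_pred] = 0.0

    pred_links = feeding.T  # (i, j) True when j eats i
    beta = np.zeros((N, S, S))
    raw = rng.uniform(0.0, 1.0, size=(N, S, S))
    beta[:, pred_links] = raw[:, pred_links]
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(has_pred[None, :, None], beta / beta.sum(axis=2, keepdims=True), 0.0)

    chi = np.zeros((N, S, S))
    raw = rng.uniform(0.0, 1.0, size=(N, S, S))
    chi[:, feeding] = raw[:, feeding]
    with np.errstate(invalid="ignore", divide="ignore"):
        chi = np.where(has_prey[None, :, None], chi / chi.sum(axis=2, keepdims=True), 0.0)

    return GeneralizedParams(
        rho=has_prey.astype(float),
        sigma=sigma,
        beta=beta,
        chi=chi,
        phi=draw("phi"),
        psi=draw("psi"),
        gamma=draw("gamma"),
        mu=draw("mu"),
    )


def build_local_jacobian(
    web: FoodWebTopology, params: GeneralizedParams, patch: int
) -> LocalJacobian:
    """Analytic Jacobian of the normalised local dynamics at ``b = 1``.

    With the normalised loss function ``e_jn = f_j(c_j, b_j) * b_n / c_j``
    (equal to 1 at steady state) and constant preferences (lambda = 1),

        d e_jn / d b_m |_(b=1) = delta_nm + (gamma_j - 1) chi_jm
                                 + psi_j delta_jm,

    and the Jacobian entry is

        J[n, m] = alpha_n * [ (1 - rho_n) phi_n delta_nm
                              + rho_n (gamma_n chi_nm + psi_n delta_nm)
                              - (1 - sigma_n) mu_n delta_nm
                              - sigma_n sum_j beta_nj d e_jn / d b_m ].

    Entries outside the structural mask (self, prey, predator, shared
    predator) are exactly zero.
    """
    alpha = web.turnover
    rho = params.rho
    sigma = params.sigma[patch]
    beta = params.beta[patch]
    chi = params.chi[patch]
    phi = params.phi[patch]
    psi = params.psi[patch]
    gamma = params.gamma[patch]
    mu = params.mu[patch]
    has_pred = web.has_predator.astype(float)

    gain = rho[:, None] * gamma[:, None] * chi
    loss = sigma[:, None] * ((beta * (gamma - 1.0)[None, :]) @ chi + beta * psi[None, :])
    diag = (1.0 - rho) * phi + rho * psi - (1.0 - sigma) * mu - sigma * has_pred
    J = gain - loss
    J[np.diag_indices_from(J)] += diag
    J *= alpha[:, None]
    return LocalJacobian(matrix=J, patch=patch)


def normalized_rhs(
    web: FoodWebTopology,
    params: GeneralizedParams,
    patch: int,
    b: np.ndarray,
) -> np.ndarray:
    """Normalised dynamics under concrete power-law rate realisations.

    Growth ``g(b) = b**phi``, mortality ``x(b) = b**mu``, prey
    contribution ``b**lambda = b``, feeding ``f(c, b) = b**psi * c**gamma``
    with available food ``c_j = sum_i chi[j, i] * b_i``, and the
    normalised per-predator loss ``e_jn = f_j * b_n / c_j``.  The
    elasticities of these realisations at ``b = 1`` equal the sampled
    parameters exactly, and ``b = 1`` is a steady state by construction,
    so central finite differences of this function provide an
    independent check of :func:`build_local_jacobian`.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise ValueError("normalised densities must be positive")
    alpha = web.turnover
    rho = params.rho
    cons = rho > 0
    sigma = params.sigma[patch]
    beta = params.beta[patch]
    chi = params.chi[patch]
    phi = params.phi[patch]
    psi = params.psi[patch]
    gamma = params.gamma[patch]
    mu = params.mu[patch]

    c = chi @ b  # zero for producers, positive for consumers
    f = np.zeros_like(b)
    f[cons] = b[cons] ** psi[cons] * c[cons] ** gamma[cons]
    ratio = np.zeros_like(b)
    ratio[cons] = f[cons] / c[cons]
    predation_loss = b * (beta @ ratio)
    return alpha * (
        (1.0 - rho) * b**phi + rho * f - (1.0 - sigma) * b**mu - sigma * predation_loss
    )


def finite_difference_jacobian(
    web: FoodWebTopology,
    params: GeneralizedParams,
    patch: int,
    step: float = 1e-5,
) -> np.ndarray:
    """Central-difference Jacobian of :func:`normalized_rhs` at ``b = 1``."""
    S = web.S
    J = np.empty((S, S))
    for m in range(S):
        bp = np.ones(S)
        bp[m] += step
        bm = np.ones(S)
        bm[m] -= step
        J[:, m] = (
            normalized_rhs(web, params, patch, bp)
            - normalized_rhs(web, params, patch, bm)
        ) / (2.0 * step)
    return J


# ---------------------------------------------------------------------------
# serialisation

def params_to_frame(params: GeneralizedParams) -> pd.DataFrame:
    """Long-form table (patch, species, parameter, value); link shares
    carry the partner species in ``other``."""
    rows = []
    N, S = params.n_patches, params.n_species
    for k in range(N):
        for name in ("sigma", "phi", "psi", "gamma", "mu"):
            vals = getattr(params, name)[k]
            rows += [
                {"patch": k, "species": i, "parameter": name, "other": -1, "value": v}
                for i, v in enumerate(vals.tolist())
            ]
        for name in ("beta", "chi"):
            arr = getattr(params, name)[k]
            ii, jj = np.nonzero(arr)
            rows += [
                {"patch": k, "species": int(i), "parameter": name, "other": int(j),
                 "value": float(arr[i, j])}
                for i, j in zip(ii, jj)
            ]
    rows += [
        {"patch": -1, "species": i, "parameter": "rho", "other": -1, "value": v}
        for i, v in enumerate(params.rho.tolist())
    ]
    return pd.DataFrame(rows)


def params_from_frame(frame: pd.DataFrame) -> GeneralizedParams:
    """Inverse of :func:`params_to_frame`."""
    N = int(frame.loc[frame["patch"] >= 0, "patch"].max()) + 1
    S = int(frame["species"].max()) + 1
    scalars = {name: np.zeros((N, S)) for name in ("sigma", "phi", "psi", "gamma", "mu")}
    beta = np.zeros((N, S, S))
    chi = np.zeros((N, S, S))
    rho = np.zeros(S)
    for row in frame.itertuples(index=False):
        if row.parameter == "rho":
            rho[row.species] = row.value
        elif row.parameter == "beta":
            beta[row.patch, row.species, row.other] = row.value
        elif row.parameter == "chi":
            chi[row.patch, row.species, row.other] = row.value
        else:
            scalars[row.parameter][row.patch, row.species] = row.value
    return GeneralizedParams(rho=rho, beta=beta, chi=chi, **scalars)
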