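"""Metacommunity Jacobian assembly and linear stability.

A metacommunity is N copies of the same food web topology, one per
habitat patch, with patch-specific generalized-model parameters and
diffusive dispersal along the patch graph.  Its Jacobian at the
(normalised) steady state is

    J = P - L (x) D,

where P is the block-diagonal collection of the local Jacobians J_k, L
is the patch-graph Laplacian, D is the diagonal matrix of species
dispersal rates and (x) denotes the Kronecker product with patch-major
ordering (block (k, l) equals L[k, l] * D).  Dispersal is allometric:
delta_i = d * M_i**z, so producers (mass 1) always disperse at the
global link strength d.

Linear (asymptotic) stability holds when every Jacobian eigenvalue has
strictly negative real part; the classification uses strict ``< 0``
with no tolerance band, so boundary cases count as unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .generalized_jacobian import GeneralizedParams, LocalJacobian, build_local_jacobian
from .niche_web import FoodWebTopology
from .spatial_graph import SpatialNetwork

__all__ = [
    "DispersalRule",
    "StabilityResult",
    "Metacommunity",
    "dispersal_rates",
    "dispersal_matrix",
    "assemble_jacobian",
    "stability",
    "leading_real_part",
]


class EigensolverError(RuntimeError):
    """Eigenvalue computation failed; carries the run seed when known."""


def leading_real_part(matrix: np.ndarray, *, seed=None) -> float:
    """Largest real part over the eigenvalues of a dense matrix."""
    try:
        eigs = scipy.linalg.eigvals(matrix, check_finite=False)
    except Exception as exc:  # pragma: no cover - LAPACK failures are rare
        raise EigensolverError(f"eigensolver failed (seed={seed!r})") from exc
    return float(eigs.real.max())


def dispersal_rates(masses: np.ndarray, d: float, z: float) -> np.ndarray:
    """Per-species dispersal rate ``delta_i = d * M_i**z``."""
    if d < 0:
        raise ValueError("global link strength d must be non-negative")
    return d * np.asarray(masses, dtype=float) ** z


def dispersal_matrix(masses: np.ndarray, d: float, z: float) -> np.ndarray:
    """Diagonal S x S dispersal matrix D with ``delta_i`` on the diagonal.

    For ``z = 0`` this is ``d * I`` (uniform dispersal); producers with
    mass 1 get exactly ``d`` for any ``z``.
    """
    return np.diag(dispersal_rates(masses, d, z))


@dataclass(frozen=True)
class DispersalRule:
    """Allometric dispersal: global strength ``d`` and mass exponent ``z``."""

    d: float
    z: float

    def rates(self, masses: np.ndarray) -> np.ndarray:
        return dispersal_rates(masses, self.d, self.z)

    def matrix(self, masses: np.ndarray) -> np.ndarray:
        return dispersal_matrix(masses, self.d, self.z)


@dataclass(frozen=True)
class StabilityResult:
    """Leading eigenvalues and stability flags for one metacommunity."""

    lambda1: float
    local_lambda1: np.ndarray
    local_stable: np.ndarray
    prop_local_stable: float
    metacommunity_stable: bool


def assemble_jacobian(
    local_jacobians, laplacian: np.ndarray, dispersal: np.ndarray
) -> np.ndarray:
    """Build ``J = P - L (x) D`` from per-patch Jacobians.

    ``local_jacobians`` may be LocalJacobian objects or plain S x S
    arrays, in patch order.  ``dispersal`` is the diagonal S x S matrix D.
    """
    mats = [
        j.matrix if isinstance(j, LocalJacobian) else np.asarray(j, dtype=float)
        for j in local_jacobians
    ]
    N = len(mats)
    S = mats[0].shape[0]
    if any(m.shape != (S, S) for m in mats):
        raise ValueError("local Jacobians must share a common S x S shape")
    if laplacian.shape != (N, N):
        raise ValueError("Laplacian size must match the number of patches")
    if dispersal.shape != (S, S):
        raise ValueError("dispersal matrix must be S x S")
    J = -np.kron(laplacian, dispersal)
    for k, m in enumerate(mats):
        J[k * S:(k + 1) * S, k * S:(k + 1) * S] += m
    return J


def stability(J: np.ndarray, local_jacobians, *, seed=None) -> StabilityResult:
    """Classify metacommunity and per-patch local stability.

    ``lambda1`` is the largest real part over the eigenvalues of J; the
    metacommunity is stable iff ``lambda1 < 0`` (strict).  Local flags
    are computed the same way per patch.
    """
    local_lambda1 = np.array(
        [
            leading_real_part(
                j.matrix if isinstance(j, LocalJacobian) else j, seed=seed
            )
            for j in local_jacobians
        ]
    )
    local_stable = local_lambda1 < 0.0
    lambda1 = leading_real_part(J, seed=seed)
    return StabilityResult(
        lambda1=lambda1,
        local_lambda1=local_lambda1,
        local_stable=local_stable,
        prop_local_stable=float(local_stable.mean()),
        metacommunity_stable=bool(lambda1 < 0.0),
    )


@dataclass
class Metacommunity:
    """Topology + landscape + per-patch parameters + dispersal rule.

    Lazily yields the block-diagonal local part ``P``, the dispersal
    matrix ``D`` and the full Jacobian ``J = P - L (x) D``.
    """

    web: FoodWebTopology
    space: SpatialNetwork
    params: GeneralizedParams
    dispersal: DispersalRule
    seed: int | None = None
    _local: list[LocalJacobian] | None = field(default=None, repr=False)

    @property
    def local_jacobians(self) -> list[LocalJacobian]:
        if self._local is None:
            self._local = [
                build_local_jacobian(self.web, self.params, k)
                for k in range(self.space.N)
            ]
        return self._local

    @property
    def P(self) -> np.ndarray:
        return scipy.linalg.block_diag(*(j.matrix for j in self.local_jacobians))

    @property
    def D(self) -> np.ndarray:
        return self.dispersal.matrix(self.web.mass)

    @property
    def delta(self) -> np.ndarray:
        return self.dispersal.rates(self.web.mass)

    @property
    def J(self) -> np.ndarray:
        return assemble_jacobian(self.local_jacobians, self.space.laplacian, self.D)

    def stability(self) -> StabilityResult:
        return stability(self.J, self.local_jacobians, seed=self.seed)

    def with_dispersal(self, d: float, z: float) -> "Metacommunity":
        """Same community and landscape under a different dispersal rule."""
        return Metacommunity(
            web=self.web,
            space=self.space,
            params=self.params,
            dispersal=DispersalRule(d=d, z=z),
            seed=self.seed,
            _local=self._local,
        )
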