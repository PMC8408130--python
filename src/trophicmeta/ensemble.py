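"""Parameter sweeps, stability aggregation and the stability GLM.

This module orchestrates the numerical experiment: generate many
independent metacommunities (niche web + random geometric landscape +
per-patch generalized parameters), evaluate local and metacommunity
stability over a grid of dispersal parameters (d, z), aggregate
stability proportions against the fraction of locally stable patches,
and attribute stability to predictors with a binomial (logit link) GLM
selected by AIC over all candidate submodels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .generalized_jacobian import GeneralizedParams, sample_patch_params
from .metacommunity import DispersalRule, Metacommunity, leading_real_part
from .niche_web import DEFAULT_MASS_RATIO, generate_niche_web
from .permutation import run_permutation_analysis
from .spatial_graph import DEFAULT_N_PATCHES, DEFAULT_RADIUS, generate_rgg

__all__ = [
    "EnsembleConfig",
    "EnsembleResults",
    "GlmFit",
    "generate_metacommunity",
    "run_ensemble",
    "stability_by_local_proportion",
    "permutation_sign_change_analysis",
    "fit_stability_glm",
    "DEFAULT_CANDIDATE_TERMS",
]


def _log_spaced_d() -> tuple[float, ...]:
    return (1e-4, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass(frozen=True)
class EnsembleConfig:
    """Grids and replication counts for one sweep.

    Defaults mirror the study design: richness 10-30, connectance
    0.12-0.24, five log-spaced global link strengths, seven allometric
    exponents from -0.75 to 0.75, N = 10 patches with connection radius
    0.32 and body-mass ratio R = 42.  ``webs_per_cell`` controls how
    many independent (web, landscape, parameters) triples are generated
    per (S, C) cell; every triple is evaluated at every (d, z).
    """

    S_grid: tuple[int, ...] = tuple(range(10, 31, 2))
    C_grid: tuple[float, ...] = (0.12, 0.14, 0.16, 0.18, 0.20, 0.22, 0.24)
    d_grid: tuple[float, ...] = field(default_factory=_log_spaced_d)
    z_grid: tuple[float, ...] = (-0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75)
    webs_per_cell: int = 100
    n_perm: int = 100
    n_patches: int = DEFAULT_N_PATCHES
    radius: float = DEFAULT_RADIUS
    mass_ratio: float = DEFAULT_MASS_RATIO
    master_seed: int = 0

    def __post_init__(self):
        if self.webs_per_cell < 1:
            raise ValueError("webs_per_cell must be at least 1")
        for name in ("S_grid", "C_grid", "d_grid", "z_grid"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")

    @property
    def n_records(self) -> int:
        return (
            len(self.S_grid) * len(self.C_grid) * self.webs_per_cell
            * len(self.d_grid) * len(self.z_grid)
        )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EnsembleConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("S_grid", "C_grid", "d_grid", "z_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class EnsembleResults:
    """Long-form per-metacommunity records plus bookkeeping."""

    records: pd.DataFrame
    failures: list[dict]
    config: EnsembleConfig

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _base_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    # counter-based: any single base triple is reproducible in isolation
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def generate_metacommunity(
    S: int,
    C: float,
    rng: np.random.Generator,
    *,
    d: float = 0.0,
    z: float = 0.0,
    n_patches: int = DEFAULT_N_PATCHES,
    radius: float = DEFAULT_RADIUS,
    mass_ratio: float = DEFAULT_MASS_RATIO,
    seed: int | None = None,
) -> Metacommunity:
    """Draw one full metacommunity: web, landscape and patch parameters."""
    web = generate_niche_web(S, C, rng, R=mass_ratio, seed=seed)
    space = generate_rgg(n_patches, radius, rng, seed=seed)
    params = sample_patch_params(web, n_patches, rng)
    return Metacommunity(
        web=web, space=space, params=params,
        dispersal=DispersalRule(d=d, z=z), seed=seed,
    )


def _spatial_moments(values: np.ndarray) -> tuple[float, float]:
    """Overall mean and mean across-patch variance of an (N, n) slab."""
    if values.size == 0:
        return float("nan"), float("nan")
    return float(values.mean()), float(values.var(axis=0, ddof=1).mean())


def spatial_parameter_summaries(
    meta: Metacommunity, interaction_param: str = "chi"
) -> dict[str, float]:
    """Per-metacommunity spatial means/variances of selected parameters.

    Summaries are the overall mean and the across-patch variance
    (averaged over species or links) of consumer satiation ``gamma``,
    producer nutrient availability ``phi`` and the interaction-strength
    shares (``chi`` by default; ``beta`` or ``psi`` selectable).
    """
    params: GeneralizedParams = meta.params
    web = meta.web
    cons = web.consumers
    prod = web.producers
    out: dict[str, float] = {}
    out["gamma_mean"], out["gamma_var"] = _spatial_moments(params.gamma[:, cons])
    out["phi_mean"], out["phi_var"] = _spatial_moments(params.phi[:, prod])
    if interaction_param in ("chi", "beta"):
        arr = getattr(params, interaction_param)
        mask = arr.any(axis=0)  # realised links
        slab = arr[:, mask]
    elif interaction_param == "psi":
        slab = params.psi[:, cons]
    else:
        raise ValueError("interaction_param must be 'chi', 'beta' or 'psi'")
    out["inter_mean"], out["inter_var"] = _spatial_moments(slab)
    return out


def run_ensemble(
    config: EnsembleConfig,
    *,
    permutations: bool = False,
    interaction_param: str = "chi",
    progress: bool = False,
) -> EnsembleResults:
    """Evaluate stability over the full (S, C) x (d, z) grid.

    One (web, landscape, parameters) triple is generated per replicate
    of each (S, C) cell from a per-triple seed derived from
    ``master_seed``; the same triple is then scored at every (d, z).
    Local Jacobians do not depend on dispersal, so per-patch leading
    eigenvalues are computed once per triple.  With
    ``permutations=True`` each record additionally carries the
    dispersal-permutation category (``n_perm`` permutations).

    Failed generations (infeasible cells) are recorded in ``failures``
    and skipped, never silently dropped.
    """
    rows: list[dict] = []
    failures: list[dict] = []
    cells = list(itertools.product(config.S_grid, config.C_grid))
    index = 0
    for S, C in cells:
        for rep in range(config.webs_per_cell):
            ss = _base_seed(config.master_seed, index)
            run_seed = int(ss.generate_state(1)[0] % 2**31)
            rng = np.random.default_rng(ss)
            index += 1
            try:
                meta = generate_metacommunity(
                    S, C, rng,
                    n_patches=config.n_patches, radius=config.radius,
                    mass_ratio=config.mass_ratio, seed=run_seed,
                )
            except Exception as exc:
                failures.append(
                    {"S": S, "C": C, "rep": rep, "seed": run_seed, "error": str(exc)}
                )
                continue
            covars = spatial_parameter_summaries(meta, interaction_param)
            # local Jacobians are dispersal-independent: score them once
            local_l1 = np.array(
                [leading_real_part(j.matrix, seed=run_seed)
                 for j in meta.local_jacobians]
            )
            prop_local = float((local_l1 < 0.0).mean())
            for d, z in itertools.product(config.d_grid, config.z_grid):
                m = meta.with_dispersal(d, z)
                lambda1 = leading_real_part(m.J, seed=run_seed)
                row = {
                    "S": S, "C": C, "rep": rep, "seed": run_seed,
                    "d": d, "z": z,
                    "prop_local_stable": prop_local,
                    "lambda1": lambda1,
                    "stable": bool(lambda1 < 0.0),
                    **covars,
                }
                if permutations:
                    perm = run_permutation_analysis(
                        m, config.n_perm, rng, lambda1_original=lambda1
                    )
                    row["median_permuted"] = perm.median_permuted
                    row["category"] = perm.category
                rows.append(row)
            if progress:  # pragma: no cover - cosmetic
                print(f"cell S={S} C={C} rep={rep} done", flush=True)
    return EnsembleResults(
        records=pd.DataFrame(rows), failures=failures, config=config
    )


def stability_by_local_proportion(records: pd.DataFrame) -> pd.DataFrame:
    """Fraction of stable metacommunities per (d, z, prop_local_stable) bin.

    Bins are the exact multiples of 1/N realised in the data; empty bins
    are simply absent.  ``sem = sqrt(p (1 - p) / n)`` is the binomial
    standard error of the estimated fraction.
    """
    grouped = records.groupby(["d", "z", "prop_local_stable"])["stable"]
    table = grouped.agg(n="size", frac_stable="mean").reset_index()
    table["sem"] = np.sqrt(table["frac_stable"] * (1 - table["frac_stable"]) / table["n"])
    return table


def permutation_sign_change_analysis(
    metas: list[Metacommunity],
    d_grid,
    z_grid,
    n_perm: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Fraction of metacommunities whose stability sign flips, per (d, z).

    Every metacommunity is evaluated at every grid combination; a flip
    means the sign of the original leading eigenvalue differs from the
    sign of the median leading eigenvalue over ``n_perm`` dispersal
    permutations.
    """
    counts = {(d, z): 0 for d, z in itertools.product(d_grid, z_grid)}
    for meta in metas:
        for d, z in itertools.product(d_grid, z_grid):
            m = meta.with_dispersal(d, z)
            perm = run_permutation_analysis(m, n_perm, rng)
            if perm.sign_changed:
                counts[(d, z)] += 1
    rows = [
        {"d": d, "z": z, "n": len(metas), "n_sign_changed": c,
         "fraction_sign_changed": c / len(metas)}
        for (d, z), c in counts.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GLM

DEFAULT_CANDIDATE_TERMS = (
    "S", "C", "d", "z",
    "gamma_mean", "gamma_var", "phi_mean", "phi_var", "inter_mean", "inter_var",
)


@dataclass
class GlmFit:
    """Minimum-AIC binomial GLM over all candidate submodels."""

    selected_terms: tuple[str, ...]
    coefficients: pd.Series
    std_errors: pd.Series
    aic: float
    aic_table: pd.DataFrame
    result: object  # statsmodels results for the selected model


def fit_stability_glm(
    records: pd.DataFrame,
    candidate_terms=DEFAULT_CANDIDATE_TERMS,
    *,
    response: str = "stable",
    standardize: bool = True,
) -> GlmFit:
    """Binomial (logit link) GLM of stability with all-subsets AIC selection.

    Predictors are standardised (centred, unit variance) by default so
    coefficient magnitudes are comparable across terms.  Every subset of
    ``candidate_terms`` (intercept always included) is fitted; submodels
    that fail to converge or separate perfectly are excluded from
    selection with a warning.  Needs at least 50 records with both
    outcomes present.
    """
    candidate_terms = tuple(candidate_terms)
    if len(candidate_terms) > 12:
        raise ValueError("at most 12 candidate terms (2**k submodels are fitted)")
    y = records[response].astype(float)
    if len(records) < 50 or y.nunique() < 2:
        raise ValueError("need >= 50 records with both stable and unstable outcomes")
    X = records[list(candidate_terms)].astype(float)
    if standardize:
        X = (X - X.mean()) / X.std(ddof=0)

    table_rows = []
    fits: dict[tuple[str, ...], object] = {}
    for k in range(len(candidate_terms) + 1):
        for terms in itertools.combinations(candidate_terms, k):
            design = sm.add_constant(X[list(terms)], has_constant="add")
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.GLM(y, design, family=sm.families.Binomial()).fit()
                ok = bool(getattr(res, "converged", True)) and np.isfinite(res.aic)
            except Exception as exc:
                warnings.warn(f"submodel {terms} failed: {exc}")
                ok, res = False, None
            if ok:
                fits[terms] = res
            table_rows.append(
                {"terms": terms, "k": len(terms),
                 "aic": res.aic if ok else np.nan, "converged": ok}
            )
    if not fits:
        raise RuntimeError("no candidate submodel converged")
    aic_table = pd.DataFrame(table_rows).sort_values("aic").reset_index(drop=True)
    best_terms = min(fits, key=lambda t: fits[t].aic)
    best = fits[best_terms]
    return GlmFit(
        selected_terms=best_terms,
        coefficients=best.params,
        std_errors=best.bse,
        aic=float(best.aic),
        aic_table=aic_table,
        result=best,
    )
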