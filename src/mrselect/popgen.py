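"""Individual-level population simulator for two-sample MR selection studies.

The data-generating process is a linear structural model with J mutually
independent biallelic SNPs, an unmeasured confounder U, exposure X and
outcome Y:

    G_ij ~ Binomial(2, maf)
    U_i  = sum_j phi_j  G_ij + eps_U
    X_i  = sum_j alpha_j G_ij + b U_i + eps_X
    Y_i  = sum_j gamma_j G_ij + theta X_i + c U_i + eps_Y

with independent standard-normal noise terms.  ``alpha_j`` are instrument
strengths, ``gamma_j`` direct (horizontal) pleiotropic effects on Y and
``phi_j`` confounder-mediated effects; valid instruments have
``gamma_j = phi_j = 0``.  Four pleiotropy scenarios control the
distributions of ``gamma`` and ``phi`` on the invalid subset:

1. no pleiotropy (all instruments valid);
2. balanced pleiotropy, InSIDE satisfied (gamma ~ N(0, 0.15), phi = 0);
3. directional pleiotropy, InSIDE satisfied (gamma ~ N(0.1, 0.15), phi = 0);
4. directional pleiotropy, InSIDE violated (gamma ~ N(0.1, 0.15),
   phi ~ U(0, 0.1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ScenarioSpec",
    "ParamDraw",
    "Cohort",
    "calibrate_alpha_scale",
    "draw_params",
    "generate_population",
    "population_association",
]

#: refuse to allocate genotype matrices beyond this many cells
MEMORY_GUARD_CELLS = 500_000_000


class InvalidParameterError(ValueError):
    """A structural-model parameter is outside its admissible range."""


class DegenerateRegressorError(ValueError):
    """A genotype column is constant, so its marginal regression is undefined."""


@dataclass(frozen=True)
class ScenarioSpec:
    """All structural parameters of one simulation scenario.

    Parameters
    ----------
    J : int
        Number of genetic variants (instruments).
    theta : float
        Causal effect of the exposure on the outcome (0 or 0.2 in the
        study grid).
    scenario_id : int
        Pleiotropy scenario 1-4 (see module docstring).
    maf : float
        Minor allele frequency of every SNP.
    invalid_fraction : float
        Fraction of SNPs carrying pleiotropic effects (0 under scenario 1).
    gamma_mean, gamma_sd : float
        Normal distribution of direct effects on Y for invalid SNPs.
    phi_low, phi_high : float
        Uniform bounds of confounder effects for invalid SNPs.
    b, c : float
        Confounder effects on X and Y.  The structural model places unit
        coefficients on U, so both default to 1.
    target_r2 : float
        Variance fraction of X explained by the direct genetic effects;
        used to calibrate the instrument-strength scale.
    alpha_scale : float or None
        Upper bound of the Uniform(0, alpha_scale) draw of alpha_j.  When
        None it is derived from ``target_r2`` at construction time.
    """

    J: int = 50
    theta: float = 0.0
    scenario_id: int = 1
    maf: float = 0.3
    invalid_fraction: float = 0.0
    gamma_mean: float = 0.0
    gamma_sd: float = 0.0
    phi_low: float = 0.0
    phi_high: float = 0.0
    b: float = 1.0
    c: float = 1.0
    target_r2: float = 0.10
    alpha_scale: float | None = None

    def __post_init__(self) -> None:
        if self.J < 2:
            raise InvalidParameterError(f"J must be >= 2, got {self.J}")
        if not 0.0 < self.maf < 0.5:
            raise InvalidParameterError(f"maf must be in (0, 0.5), got {self.maf}")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise InvalidParameterError(
                f"invalid_fraction must be in [0, 1], got {self.invalid_fraction}"
            )
        if self.scenario_id not in (1, 2, 3, 4):
            raise InvalidParameterError(f"scenario_id must be 1-4, got {self.scenario_id}")
        if self.scenario_id == 1 and (
            self.gamma_mean or self.gamma_sd or self.phi_low or self.phi_high
            or self.invalid_fraction
        ):
            raise InvalidParameterError(
                "scenario 1 requires gamma_mean=gamma_sd=phi_low=phi_high=0 "
                "and invalid_fraction=0 (all instruments valid)"
            )
        if self.alpha_scale is None:
            object.__setattr__(
                self,
                "alpha_scale",
                calibrate_alpha_scale(self.J, self.target_r2, self.maf, self.b),
            )
        if not self.alpha_scale > 0:
            raise InvalidParameterError(f"alpha_scale must be > 0, got {self.alpha_scale}")

    @property
    def n_invalid(self) -> int:
        return int(round(self.invalid_fraction * self.J))


def scenario(
    scenario_id: int,
    J: int = 50,
    theta: float = 0.0,
    invalid_fraction: float | None = None,
    **kwargs,
) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` for one of the four canonical scenarios.

    ``invalid_fraction`` defaults to 0 for scenario 1 and 0.3 otherwise.
    """
    presets = {
        1: dict(gamma_mean=0.0, gamma_sd=0.0, phi_low=0.0, phi_high=0.0),
        2: dict(gamma_mean=0.0, gamma_sd=0.15, phi_low=0.0, phi_high=0.0),
        3: dict(gamma_mean=0.1, gamma_sd=0.15, phi_low=0.0, phi_high=0.0),
        4: dict(gamma_mean=0.1, gamma_sd=0.15, phi_low=0.0, phi_high=0.1),
    }
    if scenario_id not in presets:
        raise InvalidParameterError(f"scenario_id must be 1-4, got {scenario_id}")
    if invalid_fraction is None:
        invalid_fraction = 0.0 if scenario_id == 1 else 0.3
    return ScenarioSpec(
        J=J,
        theta=theta,
        scenario_id=scenario_id,
        invalid_fraction=invalid_fraction,
        **presets[scenario_id],
        **kwargs,
    )


@dataclass(frozen=True)
class ParamDraw:
    """One realization of the per-SNP structural coefficients."""

    alpha: np.ndarray
    gamma: np.ndarray
    phi: np.ndarray
    invalid_mask: np.ndarray

    def __post_init__(self) -> None:
        J = self.alpha.shape[0]
        for name in ("gamma", "phi", "invalid_mask"):
            if getattr(self, name).shape != (J,):
                raise InvalidParameterError(f"{name} must have shape ({J},)")
        valid = ~self.invalid_mask
        if np.any(self.gamma[valid] != 0) or np.any(self.phi[valid] != 0):
            raise InvalidParameterError("valid SNPs must have gamma = phi = 0")


@dataclass(frozen=True)
class Cohort:
    """Individual-level arrays for one simulated population (no selection)."""

    genotypes: np.ndarray  # (N, J) int8 dosages in {0, 1, 2}
    U: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    params: ParamDraw
    spec: ScenarioSpec
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def J(self) -> int:
        return self.genotypes.shape[1]

    def subset(self, indices: np.ndarray) -> "Cohort":
        """Row-subset view of the cohort (e.g. a selected sample)."""
        return replace(
            self,
            genotypes=self.genotypes[indices],
            U=self.U[indices],
            X=self.X[indices],
            Y=self.Y[indices],
        )

    def to_frame(self):
        """Debug dump as a pandas DataFrame (id, G_1..G_J, U, X, Y)."""
        import pandas as pd

        cols = {"id": np.arange(self.n)}
        for j in range(self.J):
            cols[f"G_{j + 1}"] = self.genotypes[:, j]
        cols.update(U=self.U, X=self.X, Y=self.Y)
        return pd.DataFrame(cols)


def calibrate_alpha_scale(J: int, target_r2: float, maf: float = 0.3, b: float = 1.0) -> float:
    """Upper bound ``a`` of Uniform(0, a) instrument strengths hitting a target R^2.

    With alpha_j ~ U(0, a), E[sum alpha_j^2] = J a^2 / 3 and each SNP
    contributes variance 2 maf (1-maf) alpha_j^2 to X.  Under scenario 1
    (phi = 0) Var(X) = 2 maf (1-maf) sum alpha_j^2 + b^2 + 1, so the
    expected genetic variance fraction equals ``target_r2`` when

        a = sqrt( 3 r2 (b^2 + 1) / ((1 - r2) J 2 maf (1 - maf)) ).
    """
    if not np.isfinite([J, target_r2, maf, b]).all():
        raise InvalidParameterError("non-finite argument")
    if J < 1 or not 0.0 < target_r2 < 1.0 or not 0.0 < maf < 0.5:
        raise InvalidParameterError(
            f"need J >= 1, 0 < target_r2 < 1, 0 < maf < 0.5; got {J=}, {target_r2=}, {maf=}"
        )
    var_g = 2.0 * maf * (1.0 - maf)
    genetic_var = target_r2 / (1.0 - target_r2) * (b**2 + 1.0)
    return float(np.sqrt(3.0 * genetic_var / (J * var_g)))


def draw_params(spec: ScenarioSpec, rng: np.random.Generator) -> ParamDraw:
    """Draw per-SNP coefficients (alpha, gamma, phi) for one replicate.

    The invalid subset is a uniformly random subset of round(invalid_fraction*J)
    SNPs; gamma and phi are drawn independently per invalid SNP from the
    scenario distributions, and are exactly zero elsewhere.
    """
    J = spec.J
    alpha = rng.uniform(0.0, spec.alpha_scale, size=J)
    invalid_mask = np.zeros(J, dtype=bool)
    n_inv = spec.n_invalid
    if n_inv:
        invalid_mask[rng.choice(J, size=n_inv, replace=False)] = True
    gamma = np.zeros(J)
    phi = np.zeros(J)
    if n_inv:
        if spec.gamma_sd > 0 or spec.gamma_mean != 0:
            gamma[invalid_mask] = rng.normal(spec.gamma_mean, spec.gamma_sd, size=n_inv)
        if spec.phi_high > spec.phi_low:
            phi[invalid_mask] = rng.uniform(spec.phi_low, spec.phi_high, size=n_inv)
    return ParamDraw(alpha=alpha, gamma=gamma, phi=phi, invalid_mask=invalid_mask)


def generate_population(
    spec: ScenarioSpec,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    params: ParamDraw | None = None,
) -> Cohort:
    """Simulate a full population of ``n`` individuals under ``spec``.

    When ``params`` is given the coefficient draw is reused (the two GWAS
    populations of one replicate share a ParamDraw and differ only in the
    random genotypes and noise); otherwise a fresh draw is taken from the
    same stream.  Deterministic given (spec, n, seed, params).
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if n * spec.J > MEMORY_GUARD_CELLS:
        raise MemoryError(
            f"genotype matrix of {n} x {spec.J} cells exceeds the memory guard "
            f"({MEMORY_GUARD_CELLS} cells)"
        )
    rng = np.random.default_rng(seed)
    if params is None:
        params = draw_params(spec, rng)

    G = rng.binomial(2, spec.maf, size=(n, spec.J)).astype(np.int8)
    Gf = G.astype(np.float64)
    U = Gf @ params.phi + rng.standard_normal(n)
    X = Gf @ params.alpha + spec.b * U + rng.standard_normal(n)
    Y = Gf @ params.gamma + spec.theta * X + spec.c * U + rng.standard_normal(n)
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return Cohort(genotypes=G, U=U, X=X, Y=Y, params=params, spec=spec, seed=seed_int)


def _marginal_ols(g: np.ndarray, trait: np.ndarray) -> tuple[float, float]:
    """Slope and classical SE of a simple linear regression of trait on g."""
    n = g.shape[0]
    gc = g - g.mean()
    sxx = float(gc @ gc)
    if sxx == 0.0:
        raise DegenerateRegressorError("constant genotype column")
    tc = trait - trait.mean()
    beta = float(gc @ tc) / sxx
    if n <= 2:
        return beta, float("nan")
    rss = float(tc @ tc) - beta**2 * sxx
    sigma2 = max(rss, 0.0) / (n - 2)
    return beta, float(np.sqrt(sigma2 / sxx))


def population_association(cohort: Cohort, j: int, trait: str) -> tuple[float, float]:
    """Selection-free OLS association (beta, se) of a trait on SNP j.

    ``trait`` is ``"exposure"`` (X) or ``"outcome"`` (Y).  This is the
    population-level quantity whose ratio across traits is the per-SNP
    Wald ratio; it serves as the invariance benchmark that selected
    samples are compared against.
    """
    traits = {"exposure": cohort.X, "outcome": cohort.Y}
    if trait not in traits:
        raise ValueError(f"trait must be 'exposure' or 'outcome', got {trait!r}")
    g = cohort.genotypes[:, j].astype(np.float64)
    return _marginal_ols(g, traits[trait])
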