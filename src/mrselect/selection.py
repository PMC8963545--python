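"""Logistic selection mechanisms acting on a simulated population.

Each individual enters the selected sample with probability

    logit(pi_i) = e0 + e_x X_i + e_y Y_i + e_g sum_j G_ij,

and the mechanism determines which of (e_x, e_y, e_g) equal the shared
selection effect ``e`` and which are zero.  Seven mechanisms (X, Y, G,
X+Y, G+X, G+Y, G+X+Y) plus random selection ("none") are supported; the
per-SNP selection effect is a single scalar shared by all SNPs.  The
intercept e0 is not fixed a priori: it is calibrated so that the expected
selected fraction is comparable across mechanisms and effect sizes, after
which exactly ``n_target`` individuals are subsampled uniformly from the
Bernoulli-selected set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .popgen import Cohort

__all__ = [
    "MECHANISMS",
    "SelectionSpec",
    "selection_probability",
    "calibrate_intercept",
    "draw_sample",
    "select_sample",
]

#: mechanism name -> (x on?, y on?, g on?)
MECHANISMS: dict[str, tuple[bool, bool, bool]] = {
    "none": (False, False, False),
    "X": (True, False, False),
    "Y": (False, True, False),
    "G": (False, False, True),
    "X+Y": (True, True, False),
    "G+X": (True, False, True),
    "G+Y": (False, True, True),
    "G+X+Y": (True, True, True),
}


class CalibrationError(RuntimeError):
    """Intercept calibration failed to converge."""


class InsufficientSelectionError(RuntimeError):
    """Fewer individuals were Bernoulli-selected than the target sample size."""


@dataclass(frozen=True)
class SelectionSpec:
    """One selection mechanism applied to one sample.

    Parameters
    ----------
    mechanism : str
        One of ``"none"``, ``"X"``, ``"Y"``, ``"G"``, ``"X+Y"``, ``"G+X"``,
        ``"G+Y"``, ``"G+X+Y"``.
    effect : float
        The shared selection effect ``e`` (the study grid uses
        -2, -1, -0.5, 0, 0.5, 1, 2).
    intercept : float or None
        e0; usually left None and calibrated against a cohort.
    n_target : int
        Number of individuals in the final selected sample.
    oversample_factor : float
        Calibration targets a mean selection probability of
        ``oversample_factor * n_target / N`` so that the Bernoulli draw
        almost surely yields at least ``n_target`` individuals.
    """

    mechanism: str = "none"
    effect: float = 0.0
    intercept: float | None = None
    n_target: int = 10_000
    oversample_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"unknown mechanism {self.mechanism!r}; expected one of {sorted(MECHANISMS)}"
            )
        if self.n_target < 1:
            raise ValueError(f"n_target must be >= 1, got {self.n_target}")
        if self.oversample_factor < 1.0:
            raise ValueError(f"oversample_factor must be >= 1, got {self.oversample_factor}")

    @property
    def coefficients(self) -> tuple[float, float, float]:
        """(e_x, e_y, e_g) implied by the mechanism and effect."""
        on_x, on_y, on_g = MECHANISMS[self.mechanism]
        e = self.effect
        return (e if on_x else 0.0, e if on_y else 0.0, e if on_g else 0.0)


def _linear_predictor(cohort: Cohort, spec: SelectionSpec) -> np.ndarray:
    e_x, e_y, e_g = spec.coefficients
    lp = np.zeros(cohort.n)
    if e_x:
        lp += e_x * cohort.X
    if e_y:
        lp += e_y * cohort.Y
    if e_g:
        lp += e_g * cohort.genotypes.sum(axis=1, dtype=np.float64)
    return lp


def selection_probability(cohort: Cohort, spec: SelectionSpec) -> np.ndarray:
    """Per-individual inclusion probabilities pi_i under the logistic model."""
    if spec.intercept is None:
        raise ValueError("SelectionSpec.intercept is unset; calibrate it first")
    return expit(spec.intercept + _linear_predictor(cohort, spec))


def calibrate_intercept(
    cohort: Cohort,
    spec: SelectionSpec,
    target_fraction: float,
    tol: float = 1e-10,
) -> float:
    """Find e0 such that the mean selection probability equals ``target_fraction``.

    mean_i expit(e0 + lp_i) is strictly increasing in e0, so the root is
    found by scalar bracketing (Brent).  Returns e0; deterministic given
    the cohort.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError(f"target_fraction must be in (0, 1), got {target_fraction}")
    lp = _linear_predictor(cohort, spec)
    if not np.any(lp):
        return float(logit(target_fraction))

    def gap(e0: float) -> float:
        return float(expit(e0 + lp).mean()) - target_fraction

    lo, hi = -40.0, 40.0
    # widen until the bracket straddles the root (extreme effects shift lp far)
    while gap(lo) > 0:
        lo *= 2
        if lo < -1e6:
            raise CalibrationError("no lower bracket for intercept calibration")
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e6:
            raise CalibrationError("no upper bracket for intercept calibration")
    try:
        e0 = brentq(gap, lo, hi, xtol=tol)
    except RuntimeError as exc:  # pragma: no cover - brentq rarely fails on monotone f
        raise CalibrationError(str(exc)) from exc
    return float(e0)


def draw_sample(
    cohort: Cohort,
    spec: SelectionSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> np.ndarray:
    """Bernoulli selection followed by uniform subsampling to exactly n_target.

    Returns the sorted indices of the selected sample.  Raises
    :class:`InsufficientSelectionError` when fewer than ``n_target``
    individuals are Bernoulli-selected (the caller should re-calibrate
    with a larger oversample factor).
    """
    if spec.n_target > cohort.n:
        raise InsufficientSelectionError(
            f"n_target={spec.n_target} exceeds population size {cohort.n}"
        )
    rng = np.random.default_rng(seed)
    pi = selection_probability(cohort, spec)
    selected = np.flatnonzero(rng.random(cohort.n) < pi)
    if selected.size < spec.n_target:
        raise InsufficientSelectionError(
            f"only {selected.size} individuals selected, need {spec.n_target}; "
            f"mechanism={spec.mechanism}, effect={spec.effect}"
        )
    chosen = rng.choice(selected, size=spec.n_target, replace=False)
    return np.sort(chosen)


def select_sample(
    cohort: Cohort,
    spec: SelectionSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
    max_retries: int = 3,
) -> tuple[Cohort, float]:
    """Calibrate the intercept, draw a selected sample, return (sample, e0).

    Convenience wrapper: calibrates e0 to
    ``oversample_factor * n_target / N``, retries with a doubled oversample
    factor if the Bernoulli draw falls short, and returns the row-subset
    cohort together with the calibrated intercept.
    """
    factor = spec.oversample_factor
    last_exc: Exception | None = None
    for _ in range(max_retries):
        target = min(factor * spec.n_target / cohort.n, 0.99)
        e0 = calibrate_intercept(cohort, spec, target)
        cal = SelectionSpec(
            mechanism=spec.mechanism,
            effect=spec.effect,
            intercept=e0,
            n_target=spec.n_target,
            oversample_factor=factor,
        )
        try:
            idx = draw_sample(cohort, cal, seed)
        except InsufficientSelectionError as exc:
            last_exc = exc
            factor *= 2.0
            continue
        return cohort.subset(idx), e0
    raise InsufficientSelectionError(
        f"selection failed after {max_retries} calibration attempts: {last_exc}"
    )
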