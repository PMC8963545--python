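"""Eight pleiotropy-robust two-sample MR estimators.

All methods consume a :class:`~mrselect.gwas.TwoSampleSummary` of per-SNP
exposure associations (beta_x, se_x) and outcome associations
(beta_y, se_y) and return a common :class:`MREstimate`.  They fall into
four families:

* consensus methods — weighted median, mode-based estimate (MBE);
* regression-based methods — IVW, MR-Egger, MR-Robust;
* likelihood-based methods — contamination mixture, MR-RAPS;
* outlier-removal methods — MR-Lasso.

Conventions shared across methods: first-order ratio standard errors
(se_y_j / |beta_x_j|) and inverse-variance weights beta_x_j^2 / se_y_j^2;
multiplicative random-effects standard errors for the regression methods
with the residual scale floored at 1 (never more precise than the
fixed-effect analysis); two-sided p-values, normal reference except
MR-Egger which uses t with J - 2 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate, optimize, stats

from .gwas import TwoSampleSummary

__all__ = [
    "MREstimate",
    "RatioSet",
    "ratio_estimates",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mbe",
    "mr_robust",
    "conmix",
    "mr_raps",
    "mr_lasso",
    "METHODS",
    "estimate_all",
]


class InsufficientInstrumentsError(ValueError):
    """Too few SNPs for the requested method."""


class DivisionDegeneracyError(ValueError):
    """A zero exposure association makes the ratio estimate undefined."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge."""


class RootBracketingError(RuntimeError):
    """The estimating equation has no sign change on the search interval."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal-effect estimate with its uncertainty."""

    method: str
    theta_hat: float
    se: float
    p_value: float
    n_snps_used: int
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RatioSet:
    """Per-SNP Wald ratios with first-order inverse-variance weights."""

    ratios: np.ndarray
    weights: np.ndarray  # beta_x^2 / se_y^2 = 1 / se_ratio^2

    @property
    def se(self) -> np.ndarray:
        return 1.0 / np.sqrt(self.weights)


def _require(summary: TwoSampleSummary, minimum: int, method: str) -> None:
    if summary.J < minimum:
        raise InsufficientInstrumentsError(
            f"{method} needs at least {minimum} SNPs, got {summary.J}"
        )


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def ratio_estimates(summary: TwoSampleSummary) -> RatioSet:
    """Elementwise Wald ratios beta_y / beta_x and first-order weights."""
    zero = np.flatnonzero(summary.beta_x == 0.0)
    if zero.size:
        raise DivisionDegeneracyError(
            f"beta_x is exactly zero for SNP(s) {summary.snp_ids[zero].tolist()}"
        )
    ratios = summary.beta_y / summary.beta_x
    weights = summary.beta_x**2 / summary.se_y**2
    return RatioSet(ratios=ratios, weights=weights)


# ---------------------------------------------------------------------------
# regression-based methods


def ivw(summary: TwoSampleSummary, random_effects: bool = True) -> MREstimate:
    """Inverse-variance weighted estimate.

    Weighted least squares of beta_y on beta_x through the origin with
    weights se_y^-2; multiplicative random-effects SE with the residual
    scale floored at 1.
    """
    _require(summary, 2, "IVW")
    w = 1.0 / summary.se_y**2
    sxx = float(np.sum(w * summary.beta_x**2))
    theta = float(np.sum(w * summary.beta_x * summary.beta_y)) / sxx
    se_fixed = 1.0 / math.sqrt(sxx)
    scale = 1.0
    if random_effects and summary.J > 1:
        resid2 = w * (summary.beta_y - theta * summary.beta_x) ** 2
        scale = max(float(np.sum(resid2)) / (summary.J - 1), 1.0)
    se = se_fixed * math.sqrt(scale)
    return MREstimate(
        method="ivw",
        theta_hat=theta,
        se=se,
        p_value=_normal_p(theta / se),
        n_snps_used=summary.J,
        extras={"residual_scale": scale, "se_fixed": se_fixed},
    )


def _orient(summary: TwoSampleSummary) -> tuple[np.ndarray, np.ndarray]:
    """Flip each SNP's pair of associations so that beta_x >= 0."""
    sign = np.where(summary.beta_x < 0, -1.0, 1.0)
    return sign * summary.beta_x, sign * summary.beta_y


def mr_egger(summary: TwoSampleSummary) -> MREstimate:
    """MR-Egger regression: weighted fit of beta_y on beta_x with intercept.

    The intercept absorbs the average directional pleiotropic effect
    (valid under InSIDE); the slope is the causal estimate.  Orientation
    makes all beta_x non-negative first.  SE is multiplicative
    random-effects (scale floored at 1) and p-values use t with J - 2 df.
    """
    _require(summary, 3, "MR-Egger")
    bx, by = _orient(summary)
    w = 1.0 / summary.se_y**2
    sw = float(np.sum(w))
    swx = float(np.sum(w * bx))
    swxx = float(np.sum(w * bx**2))
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    det = sw * swxx - swx**2
    if det <= 0:
        raise InsufficientInstrumentsError("degenerate design in MR-Egger")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid2 = w * (by - intercept - slope * bx) ** 2
    scale = max(float(np.sum(resid2)) / (summary.J - 2), 1.0)
    se_slope = math.sqrt(scale * sw / det)
    se_int = math.sqrt(scale * swxx / det)
    df = summary.J - 2
    p = float(2.0 * stats.t.sf(abs(slope / se_slope), df))
    p_int = float(2.0 * stats.t.sf(abs(intercept / se_int), df))
    return MREstimate(
        method="egger",
        theta_hat=float(slope),
        se=float(se_slope),
        p_value=p,
        n_snps_used=summary.J,
        extras={
            "intercept": float(intercept),
            "intercept_se": float(se_int),
            "intercept_p": p_int,
            "residual_scale": scale,
        },
    )


def mr_robust(
    summary: TwoSampleSummary,
    tuning: float = 4.685,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> MREstimate:
    """Robust (MM-type) regression of beta_y on beta_x through the origin.

    Works on the precision-standardized data (division by se_y) and
    iteratively reweights with the Tukey biweight at the 95%-efficiency
    tuning constant 4.685.  The residual scale is a MAD estimate from the
    initial robust fit and is held fixed during the IRLS iterations, as in
    MM-estimation.  SE comes from the M-estimator sandwich with the scale
    floored at 1 (the standardized residuals have unit variance under
    homogeneity).
    """
    _require(summary, 3, "MR-Robust")
    x = summary.beta_x / summary.se_y
    y = summary.beta_y / summary.se_y
    rset = ratio_estimates(summary)
    beta = _weighted_median_point(rset.ratios, rset.weights)  # robust initialization

    resid = y - beta * x
    scale = 1.4826 * float(np.median(np.abs(resid)))
    if scale < 1e-10:
        # exact fit: all points on one line through the origin
        sxx = float(x @ x)
        beta = float(x @ y) / sxx
        se = 1.0 / math.sqrt(sxx)
        return MREstimate(
            method="robust",
            theta_hat=beta,
            se=se,
            p_value=_normal_p(beta / se),
            n_snps_used=summary.J,
            extras={"weights": np.ones(summary.J), "scale": 0.0},
        )

    c = tuning
    w_irls = np.ones_like(x)
    for _ in range(max_iter):
        u = resid / scale
        w_irls = np.where(np.abs(u) < c, (1.0 - (u / c) ** 2) ** 2, 0.0)
        denom = float(np.sum(w_irls * x * x))
        if denom <= 0:
            raise ConvergenceError("all SNPs downweighted to zero in MR-Robust")
        new_beta = float(np.sum(w_irls * x * y)) / denom
        if abs(new_beta - beta) < tol * max(1.0, abs(beta)):
            beta = new_beta
            break
        beta = new_beta
        resid = y - beta * x
    else:
        raise ConvergenceError(f"MR-Robust IRLS did not converge in {max_iter} iterations")

    u = (y - beta * x) / scale
    psi = np.where(np.abs(u) < c, u * (1.0 - (u / c) ** 2) ** 2, 0.0)
    dpsi = np.where(
        np.abs(u) < c, (1.0 - (u / c) ** 2) * (1.0 - 5.0 * (u / c) ** 2), 0.0
    )
    a = float(np.sum(dpsi * x * x))
    b = float(np.sum(psi**2 * x * x))
    if a <= 0:
        raise ConvergenceError("singular sandwich in MR-Robust")
    # the precision-standardized residuals have unit scale under homogeneity,
    # so the SE scale is floored at 1 like the other regression methods
    se = max(scale, 1.0) * math.sqrt(b) / a
    return MREstimate(
        method="robust",
        theta_hat=beta,
        se=se,
        p_value=_normal_p(beta / se),
        n_snps_used=summary.J,
        extras={"weights": w_irls, "scale": scale},
    )


# ---------------------------------------------------------------------------
# consensus methods


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of the ratio estimates.

    Order the ratios; with standardized cumulative weights
    p_j = (S_j - w_j / 2) / S_total the estimate interpolates linearly
    to p = 0.5.
    """
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    cum = np.cumsum(w)
    p = (cum - w / 2.0) / cum[-1]
    return float(np.interp(0.5, p, r))


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise interpolated weighted medians for (B, J) bootstrap arrays."""
    order = np.argsort(ratios, axis=1)
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    cum = np.cumsum(w, axis=1)
    p = (cum - w / 2.0) / cum[:, -1:]
    # vectorized piecewise-linear interpolation of 0.5 into each row of p
    k = np.sum(p < 0.5, axis=1)
    out = np.empty(ratios.shape[0])
    first = k == 0
    last = k == ratios.shape[1]
    out[first] = r[first, 0]
    out[last] = r[last, -1]
    mid = ~(first | last)
    if np.any(mid):
        km = k[mid]
        rows = np.flatnonzero(mid)
        p0 = p[rows, km - 1]
        p1 = p[rows, km]
        r0 = r[rows, km - 1]
        r1 = r[rows, km]
        frac = np.where(p1 > p0, (0.5 - p0) / np.where(p1 > p0, p1 - p0, 1.0), 0.0)
        out[mid] = r0 + frac * (r1 - r0)
    return out


def _parametric_resample(
    summary: TwoSampleSummary, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample (beta_x, beta_y) from normals with their SEs; returns
    bootstrap ratios, weights and ratio SEs, each of shape (n_boot, J)."""
    bx = rng.normal(summary.beta_x, summary.se_x, size=(n_boot, summary.J))
    by = rng.normal(summary.beta_y, summary.se_y, size=(n_boot, summary.J))
    bx = np.where(bx == 0.0, np.finfo(float).tiny, bx)
    ratios = by / bx
    weights = bx**2 / summary.se_y**2
    return ratios, weights, np.abs(summary.se_y / bx)


def weighted_median(
    summary: TwoSampleSummary,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> MREstimate:
    """Weighted median of the Wald ratios; consistent when SNPs carrying at
    least half of the weight are valid instruments.

    SE by parametric bootstrap: beta_x and beta_y are redrawn from normal
    distributions with their reported SEs and the weighted median is
    recomputed ``n_boot`` times.
    """
    _require(summary, 3, "weighted median")
    rset = ratio_estimates(summary)
    theta = _weighted_median_point(rset.ratios, rset.weights)
    rng = np.random.default_rng(seed)
    boot_r, boot_w, _ = _parametric_resample(summary, n_boot, rng)
    boots = _weighted_median_rows(boot_r, boot_w)
    se = float(np.std(boots, ddof=1))
    return MREstimate(
        method="weighted_median",
        theta_hat=theta,
        se=se,
        p_value=_normal_p(theta / se),
        n_snps_used=summary.J,
        extras={"n_boot": n_boot},
    )


def _mbe_bandwidth(ratios: np.ndarray, phi: float) -> float:
    """Modified Silverman bandwidth: 0.9 min(SD, scaled MAD) J^(-1/5), scaled
    by the tuning multiplier phi."""
    s = float(np.std(ratios, ddof=1))
    mad = 1.4826 * float(np.median(np.abs(ratios - np.median(ratios))))
    base = min(s, mad) if mad > 0 else s
    return phi * 0.9 * base * len(ratios) ** (-0.2)


def _mbe_mode(
    ratios: np.ndarray, weights: np.ndarray, h: float, n_grid: int
) -> float:
    """Argmax of the weighted normal-kernel density on a uniform grid; ties
    (flat density) are resolved by the midpoint of the maximizing points."""
    grid = np.linspace(ratios.min() - 3.0 * h, ratios.max() + 3.0 * h, n_grid)
    z = (grid[:, None] - ratios[None, :]) / h
    dens = np.exp(-0.5 * z**2) @ weights
    top = np.flatnonzero(dens == dens.max())
    return float(grid[top].mean())


def _mbe_modes_batch(
    ratios: np.ndarray, weights: np.ndarray, phi: float, n_grid: int, chunk: int = 64
) -> np.ndarray:
    """Kernel-density modes for (B, J) bootstrap arrays, one bandwidth and
    grid per row, evaluated in chunks to bound memory."""
    B, J = ratios.shape
    sd = np.std(ratios, axis=1, ddof=1)
    med = np.median(ratios, axis=1)
    mad = 1.4826 * np.median(np.abs(ratios - med[:, None]), axis=1)
    base = np.where(mad > 0, np.minimum(sd, mad), sd)
    h = phi * 0.9 * base * J ** (-0.2)
    out = np.empty(B)
    degenerate = h <= 0
    out[degenerate] = ratios[degenerate, 0]
    live = np.flatnonzero(~degenerate)
    steps = np.arange(n_grid) / (n_grid - 1)
    # resampled beta_x near zero produces isolated extreme ratios with
    # near-zero weight; trimming the grid to the central ratio range keeps
    # the density resolved where the mode can actually lie
    q_lo, q_hi = np.percentile(ratios, [2.0, 98.0], axis=1)
    for start in range(0, live.size, chunk):
        idx = live[start : start + chunk]
        r = ratios[idx]
        hb = h[idx][:, None]
        lo = q_lo[idx][:, None] - 3.0 * hb
        hi = q_hi[idx][:, None] + 3.0 * hb
        grid = lo + (hi - lo) * steps[None, :]
        z = (grid[:, :, None] - r[:, None, :]) / hb[:, :, None]
        # cap the exponent: far-off ratios contribute nothing, and letting
        # them underflow to subnormals is disproportionately slow
        dens = np.einsum(
            "bgj,bj->bg", np.exp(-0.5 * np.minimum(z * z, 80.0)), weights[idx]
        )
        out[idx] = np.take_along_axis(
            grid, np.argmax(dens, axis=1)[:, None], axis=1
        )[:, 0]
    return out


def mbe(
    summary: TwoSampleSummary,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    weighted: bool = False,
    n_grid: int = 4096,
    boot_grid: int = 512,
) -> MREstimate:
    """Mode-based estimate: the maximum of a kernel-smoothed density of the
    Wald ratios (simple/unweighted variant by default; pass ``weighted=True``
    for inverse-variance kernel weights).

    Bandwidth is ``phi`` times the modified Silverman scale of the ratios.
    SE by the same parametric bootstrap as the weighted median, each
    bootstrap draw recomputing its own bandwidth and mode (on a coarser
    grid of ``boot_grid`` points).
    """
    _require(summary, 3, "MBE")
    rset = ratio_estimates(summary)
    weights = rset.weights if weighted else np.ones(summary.J)
    h = _mbe_bandwidth(rset.ratios, phi)
    if h <= 0:
        theta = float(rset.ratios[0])
    else:
        theta = _mbe_mode(rset.ratios, weights / weights.sum(), h, n_grid)

    rng = np.random.default_rng(seed)
    boot_r, boot_w, _ = _parametric_resample(summary, n_boot, rng)
    if not weighted:
        boot_w = np.ones_like(boot_w)
    boots = _mbe_modes_batch(boot_r, boot_w, phi, boot_grid)
    se = float(np.std(boots, ddof=1))
    return MREstimate(
        method="mbe",
        theta_hat=theta,
        se=se,
        p_value=_normal_p(theta / se),
        n_snps_used=summary.J,
        extras={"bandwidth": h, "phi": phi, "n_boot": n_boot},
    )


# ---------------------------------------------------------------------------
# likelihood-based methods


def conmix(
    summary: TwoSampleSummary,
    psi: float | None = None,
    grid: np.ndarray | None = None,
    n_grid: int = 5001,
    ci_level: float = 0.95,
) -> MREstimate:
    """Contamination mixture: each SNP's ratio is modelled as either valid,
    N(theta, se_ratio^2), or invalid, N(0, se_ratio^2 + psi^2).

    For each candidate theta on a grid every SNP takes the more likely
    label; the profile log-likelihood is maximized over the grid.  The CI
    collects grid points within chi2_1(ci_level)/2 of the maximum; the SE
    is the CI width divided by 2 z.  The p-value is the likelihood-ratio
    test of theta = 0.
    """
    _require(summary, 3, "contamination mixture")
    rset = ratio_estimates(summary)
    r = rset.ratios
    s = rset.se
    if psi is None:
        psi = 1.5 * float(np.std(r, ddof=1))
    if psi <= 0:
        psi = float(np.max(s))
    if grid is None:
        pad = 3.0 * float(np.max(s))
        grid = np.linspace(r.min() - pad, r.max() + pad, n_grid)
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size < 2 or grid.min() > r.min() or grid.max() < r.max():
        raise ValueError("theta grid must be non-empty and cover the ratio range")

    s2 = s**2
    inv_var = s2 + psi**2
    ll_invalid = -0.5 * np.log(2.0 * np.pi * inv_var) - 0.5 * r**2 / inv_var

    def profile_ll(thetas: np.ndarray) -> np.ndarray:
        ll_valid = (
            -0.5 * np.log(2.0 * np.pi * s2)[None, :]
            - 0.5 * (r[None, :] - thetas[:, None]) ** 2 / s2[None, :]
        )
        return np.maximum(ll_valid, ll_invalid[None, :]).sum(axis=1)

    ll = profile_ll(grid)
    imax = int(np.argmax(ll))
    theta = float(grid[imax])
    cutoff = stats.chi2.ppf(ci_level, 1) / 2.0
    inside = grid[ll >= ll[imax] - cutoff]
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    se = float((inside.max() - inside.min()) / (2.0 * z)) if inside.size > 1 else float(
        grid[1] - grid[0]
    )
    ll0 = float(profile_ll(np.array([0.0]))[0])
    lr = max(2.0 * (ll[imax] - ll0), 0.0)
    p = float(stats.chi2.sf(lr, 1))
    valid_ll = -0.5 * np.log(2.0 * np.pi * s2) - 0.5 * (r - theta) ** 2 / s2
    return MREstimate(
        method="conmix",
        theta_hat=theta,
        se=se,
        p_value=p,
        n_snps_used=int(np.sum(valid_ll >= ll_invalid)),
        extras={
            "psi": psi,
            "valid_mask": valid_ll >= ll_invalid,
            "ci_lower": float(inside.min()),
            "ci_upper": float(inside.max()),
        },
    )


_HUBER_K = 1.345


def _psi_fns(loss: str, k: float = _HUBER_K) -> tuple[Callable, Callable]:
    if loss == "quadratic":
        return (lambda t: t), (lambda t: np.ones_like(t))
    if loss == "huber":
        return (
            lambda t: np.clip(t, -k, k),
            lambda t: (np.abs(t) < k).astype(float),
        )
    raise ValueError(f"unknown loss {loss!r}")


from functools import lru_cache


@lru_cache(maxsize=None)
def _psi_moments(loss: str, k: float = _HUBER_K) -> tuple[float, float, float]:
    """(E[psi(Z) Z], E[psi(Z)^2], E[psi'(Z)]) for Z ~ N(0,1): the centering
    constant of the overdispersion moment equation and the two constants of
    the model-expected sandwich variance."""
    psi, dpsi = _psi_fns(loss, k)

    def moment(f):
        val, _ = integrate.quad(
            lambda z: f(np.array([z]))[0] * stats.norm.pdf(z),
            -10, 10, points=[-k, k],  # psi' jumps at the Huber knots
        )
        return float(val)

    return (
        moment(lambda z: psi(z) * z),
        moment(lambda z: psi(z) ** 2),
        moment(dpsi),
    )


def mr_raps(
    summary: TwoSampleSummary,
    loss: str = "huber",
    overdispersion: bool = True,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> MREstimate:
    """Robust adjusted profile score (RAPS).

    Solves the profile-score estimating equation
    sum_j psi(t_j) dt_j/dtheta = 0 with standardized residuals
    t_j = (beta_y_j - theta beta_x_j) / sqrt(se_y_j^2 + theta^2 se_x_j^2 + tau^2),
    accounting for measurement error in both beta_x and beta_y.  With
    ``overdispersion`` the systematic-pleiotropy variance tau^2 is
    jointly estimated from the second moment equation
    sum_j (psi(t_j) t_j - delta) / sigma_j^2 = 0.  SE by the sandwich of
    the theta-equation with the psi moments taken under the standard-normal
    residual model (tau^2 estimation uncertainty is not propagated).
    """
    _require(summary, 3, "MR-RAPS")
    psi, dpsi = _psi_fns(loss)
    delta, delta2, delta3 = _psi_moments(loss)
    bx, sx2 = summary.beta_x, summary.se_x**2
    by, sy2 = summary.beta_y, summary.se_y**2

    def t_and_grad(theta: float, tau2: float) -> tuple[np.ndarray, np.ndarray]:
        sig2 = sy2 + theta**2 * sx2 + tau2
        sig = np.sqrt(sig2)
        t = (by - theta * bx) / sig
        dt = -bx / sig - t * theta * sx2 / sig2
        return t, dt

    def score_theta(theta: float, tau2: float) -> float:
        t, dt = t_and_grad(theta, tau2)
        return float(np.sum(psi(t) * dt))

    def score_tau(theta: float, tau2: float) -> float:
        sig2 = sy2 + theta**2 * sx2 + tau2
        t = (by - theta * bx) / np.sqrt(sig2)
        return float(np.sum((psi(t) * t - delta) / sig2))

    def score_grid(thetas: np.ndarray, tau2: float) -> np.ndarray:
        th = thetas[:, None]
        sig2 = sy2[None, :] + th**2 * sx2[None, :] + tau2
        sig = np.sqrt(sig2)
        t = (by[None, :] - th * bx[None, :]) / sig
        dt = -bx[None, :] / sig - t * th * sx2[None, :] / sig2
        return np.sum(psi(t) * dt, axis=1)

    def solve_theta(tau2: float, guess: float) -> float:
        span = max(1.0, 10.0 * abs(guess))
        for width in (span, 10 * span, 100 * span):
            grid = np.linspace(guess - width, guess + width, 801)
            vals = score_grid(grid, tau2)
            sign = np.sign(vals)
            flips = np.flatnonzero(sign[:-1] * sign[1:] < 0)
            if flips.size:
                roots = [
                    optimize.brentq(score_theta, grid[i], grid[i + 1], args=(tau2,))
                    for i in flips
                ]
                return min(roots, key=lambda th: abs(th - guess))
        raise RootBracketingError(
            "RAPS profile score has no sign change on the search interval"
        )

    guess = ivw(summary).theta_hat
    tau2 = 0.0
    theta = solve_theta(tau2, guess)
    if overdispersion:
        for _ in range(max_iter):
            if score_tau(theta, 0.0) <= 0:
                new_tau2 = 0.0
            else:
                hi = float(np.max(sy2))
                while score_tau(theta, hi) > 0:
                    hi *= 4.0
                    if hi > 1e8:
                        raise ConvergenceError("tau^2 moment equation unbounded")
                new_tau2 = optimize.brentq(lambda t2: score_tau(theta, t2), 0.0, hi)
            new_theta = solve_theta(new_tau2, theta)
            if abs(new_theta - theta) < tol and abs(new_tau2 - tau2) < tol:
                theta, tau2 = new_theta, new_tau2
                break
            theta, tau2 = new_theta, new_tau2

    # sandwich variance of the adjusted profile score: the score terms
    # reduce to t_j (beta_x_j + e_j) / sigma_j with e_j the part of the
    # beta_x error orthogonal to t_j, so Var(score) = delta2 sum (betax^2
    # + sx^2) / sigma^2 — estimated unbiasedly by bx^2 — while the
    # information is delta3 sum (bx^2 - sx^2) / sigma^2
    sig2 = sy2 + theta**2 * sx2 + tau2
    var_score = delta2 * float(np.sum(bx**2 / sig2))
    info = delta3 * float(np.sum((bx**2 - sx2) / sig2))
    if info <= 0:
        raise ConvergenceError("profile-score information non-positive (weak instruments)")
    se = math.sqrt(var_score) / info
    return MREstimate(
        method="raps",
        theta_hat=float(theta),
        se=se,
        p_value=_normal_p(theta / se),
        n_snps_used=summary.J,
        extras={"tau2": float(tau2), "loss": loss},
    )


# ---------------------------------------------------------------------------
# outlier-removal methods


def _lasso_fit(
    bx: np.ndarray,
    by: np.ndarray,
    w: np.ndarray,
    lam: float,
    theta0: float,
    gamma0: np.ndarray,
    max_iter: int = 10_000,
    tol: float = 1e-12,
) -> tuple[float, np.ndarray]:
    """Coordinate descent for 1/2 sum w_j (by_j - theta bx_j - gamma_j)^2
    + lam sum |gamma_j|; returns (theta, gamma)."""
    theta, gamma = theta0, gamma0.copy()
    swxx = float(np.sum(w * bx**2))
    for _ in range(max_iter):
        theta_new = float(np.sum(w * bx * (by - gamma))) / swxx
        resid = by - theta_new * bx
        gamma_new = np.sign(resid) * np.maximum(np.abs(resid) - lam / w, 0.0)
        if abs(theta_new - theta) < tol and np.max(np.abs(gamma_new - gamma)) < tol:
            return theta_new, gamma_new
        theta, gamma = theta_new, gamma_new
    return theta, gamma


def mr_lasso(
    summary: TwoSampleSummary,
    lambda_path: np.ndarray | None = None,
    n_lambda: int = 50,
    alpha: float = 0.05,
) -> MREstimate:
    """MR-Lasso: per-SNP pleiotropy intercepts gamma_j with an L1 penalty.

    Along a descending lambda path, SNPs whose intercept is shrunk exactly
    to zero form the retained (apparently valid) set.  The path stops at
    the largest retained set whose weighted heterogeneity statistic stays
    below the chi-square upper quantile at level ``alpha / J`` (Bonferroni
    over path positions); the causal estimate is IVW on that set.
    """
    _require(summary, 3, "MR-Lasso")
    bx, by = summary.beta_x, summary.beta_y
    w = 1.0 / summary.se_y**2
    J = summary.J
    full = ivw(summary)
    theta_full = full.theta_hat
    if lambda_path is None:
        lam_max = 1.05 * float(np.max(w * np.abs(by - theta_full * bx)))
        if lam_max <= 0:  # perfect homogeneity: nothing to shrink
            return MREstimate(
                method="lasso",
                theta_hat=theta_full,
                se=full.se,
                p_value=full.p_value,
                n_snps_used=J,
                extras={
                    "retained_mask": np.ones(J, dtype=bool),
                    "lambda": float("inf"),
                    "heterogeneity": 0.0,
                },
            )
        lambda_path = np.geomspace(lam_max, lam_max * 1e-3, n_lambda)
    lambda_path = np.sort(np.asarray(lambda_path, dtype=float))[::-1]

    theta, gamma = theta_full, np.zeros(J)
    candidates: list[tuple[int, float, np.ndarray, float]] = []
    best_any: tuple[float, int, np.ndarray] | None = None
    for lam in lambda_path:
        theta, gamma = _lasso_fit(bx, by, w, lam, theta, gamma)
        retained = gamma == 0.0
        k = int(retained.sum())
        if k < 2:
            continue
        th_ret = float(np.sum(w[retained] * bx[retained] * by[retained])) / float(
            np.sum(w[retained] * bx[retained] ** 2)
        )
        q = float(np.sum(w[retained] * (by[retained] - th_ret * bx[retained]) ** 2))
        df = k - 1
        threshold = stats.chi2.ppf(1.0 - alpha / J, df)
        ratio = q / threshold if threshold > 0 else np.inf
        if best_any is None or ratio < best_any[0]:
            best_any = (ratio, k, retained.copy())
        if q <= threshold:
            candidates.append((k, lam, retained.copy(), q))
    if not candidates and best_any is None:
        raise InsufficientInstrumentsError(
            "MR-Lasso retained fewer than 2 SNPs at every lambda"
        )
    if candidates:
        k, lam_sel, retained, q = max(candidates, key=lambda c: (c[0], c[1]))
    else:
        # no set passes the heterogeneity screen; fall back to the least
        # heterogeneous retained set along the path
        _, k, retained = best_any
        lam_sel, q = float("nan"), float("nan")

    sub = TwoSampleSummary(
        snp_ids=summary.snp_ids[retained],
        beta_x=bx[retained],
        se_x=summary.se_x[retained],
        beta_y=by[retained],
        se_y=summary.se_y[retained],
    )
    est = ivw(sub)
    return MREstimate(
        method="lasso",
        theta_hat=est.theta_hat,
        se=est.se,
        p_value=est.p_value,
        n_snps_used=k,
        extras={"retained_mask": retained, "lambda": lam_sel, "heterogeneity": q},
    )


# ---------------------------------------------------------------------------
# registry

METHODS: dict[str, Callable[..., MREstimate]] = {
    "ivw": ivw,
    "egger": mr_egger,
    "weighted_median": weighted_median,
    "mbe": mbe,
    "robust": mr_robust,
    "conmix": conmix,
    "raps": mr_raps,
    "lasso": mr_lasso,
}

_SEEDED = {"weighted_median", "mbe"}


def estimate_all(
    summary: TwoSampleSummary,
    methods: list[str] | None = None,
    seed: int | np.random.SeedSequence = 0,
    n_boot: int = 1000,
) -> dict[str, MREstimate | Exception]:
    """Run the requested estimators on one summary; failures are captured
    per method rather than raised."""
    names = list(METHODS) if methods is None else list(methods)
    ss = np.random.SeedSequence(seed) if isinstance(seed, (int, np.integer)) else seed
    children = iter(ss.spawn(len(names)))
    out: dict[str, MREstimate | Exception] = {}
    for name in names:
        child = next(children)
        fn = METHODS[name]
        try:
            if name in _SEEDED:
                out[name] = fn(summary, seed=child, n_boot=n_boot)
            else:
                out[name] = fn(summary)
        except Exception as exc:  # noqa: BLE001 - per-method failure is data
            out[name] = exc
    return out
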