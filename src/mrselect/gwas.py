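"""Per-SNP GWAS summary statistics and the harmonized two-sample container.

Sample I contributes marginal exposure associations (beta_x, se_x), sample
II marginal outcome associations (beta_y, se_y); the two samples never
share individuals.  Regressions are one-SNP-at-a-time simple linear
regressions with classical normal-theory standard errors (n - 2 residual
degrees of freedom), matching the summary statistics that two-sample MR
methods assume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .popgen import Cohort, DegenerateRegressorError

__all__ = [
    "TwoSampleSummary",
    "per_snp_regressions",
    "assemble_two_sample",
    "write_summary",
    "read_summary",
]

SUMMARY_COLUMNS = ["snp", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome"]


@dataclass(frozen=True)
class TwoSampleSummary:
    """Harmonized per-SNP summary statistics from two non-overlapping samples."""

    snp_ids: np.ndarray
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    n1: int | None = None
    n2: int | None = None

    def __post_init__(self) -> None:
        J = len(self.snp_ids)
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            object.__setattr__(self, name, arr)
            if arr.shape != (J,):
                raise ValueError(f"{name} must have length {J}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("all standard errors must be strictly positive")
        object.__setattr__(self, "snp_ids", np.asarray(self.snp_ids))

    @property
    def J(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "beta_exposure": self.beta_x,
                "se_exposure": self.se_x,
                "beta_outcome": self.beta_y,
                "se_outcome": self.se_y,
            }
        )


def per_snp_regressions(
    genotypes: np.ndarray, trait: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal simple-linear-regression slopes and SEs of a trait on each SNP.

    Vectorized over columns: for SNP j, beta_j = S_gy / S_gg and
    se_j = sqrt(RSS_j / (n - 2) / S_gg) with centered cross-products.
    Raises :class:`DegenerateRegressorError` if any column is constant.
    """
    G = np.asarray(genotypes, dtype=np.float64)
    t = np.asarray(trait, dtype=np.float64)
    n, J = G.shape
    if t.shape != (n,):
        raise ValueError(f"trait must have length {n}")
    if n <= 2:
        raise ValueError("need n > 2 individuals for SE estimation")
    Gc = G - G.mean(axis=0)
    tc = t - t.mean()
    sgg = np.einsum("ij,ij->j", Gc, Gc)
    degenerate = sgg == 0.0
    if degenerate.any():
        raise DegenerateRegressorError(
            f"constant genotype column(s) {np.flatnonzero(degenerate).tolist()} in sample"
        )
    sgy = tc @ Gc
    betas = sgy / sgg
    rss = np.maximum(float(tc @ tc) - betas**2 * sgg, 0.0)
    ses = np.sqrt(rss / (n - 2) / sgg)
    return betas, ses


def assemble_two_sample(sample1: Cohort, sample2: Cohort) -> TwoSampleSummary:
    """Build the two-sample MR input from the two selected samples.

    Sample I is regressed for the exposure, sample II for the outcome;
    SNP order is preserved.
    """
    if sample1.J != sample2.J:
        raise ValueError(
            f"samples disagree on SNP count: {sample1.J} vs {sample2.J}"
        )
    beta_x, se_x = per_snp_regressions(sample1.genotypes, sample1.X)
    beta_y, se_y = per_snp_regressions(sample2.genotypes, sample2.Y)
    snp_ids = np.array([f"snp_{j + 1}" for j in range(sample1.J)])
    return TwoSampleSummary(
        snp_ids=snp_ids,
        beta_x=beta_x,
        se_x=se_x,
        beta_y=beta_y,
        se_y=se_y,
        n1=sample1.n,
        n2=sample2.n,
    )


def write_summary(summary: TwoSampleSummary, path: str | Path, sep: str = ",") -> None:
    """Write the harmonized summary table as delimited text."""
    summary.to_frame().to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_summary(path: str | Path, sep: str | None = None) -> TwoSampleSummary:
    """Read a harmonized summary table (comma- or tab-delimited).

    Validates the header and positivity of the standard errors.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary file {path} lacks columns {missing}")
    return TwoSampleSummary(
        snp_ids=df["snp"].to_numpy(),
        beta_x=df["beta_exposure"].to_numpy(dtype=np.float64),
        se_x=df["se_exposure"].to_numpy(dtype=np.float64),
        beta_y=df["beta_outcome"].to_numpy(dtype=np.float64),
        se_y=df["se_outcome"].to_numpy(dtype=np.float64),
    )
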