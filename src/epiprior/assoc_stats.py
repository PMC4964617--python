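"""Self-contained association statistics for candidate validation.

Covers the population-level checks applied to prioritized genes: allelic
case-control odds ratio with Woolf confidence interval reconstructed from
minor-allele frequencies and sample sizes, sample-size-weighted Z-score
meta-analysis across studies, Cochran's Q / I-squared between-study
heterogeneity, and Benjamini-Hochberg FDR adjustment (re-exported from the
enrichment module).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .enrichment import bh_adjust  # noqa: F401  (shared FDR surface)

__all__ = [
    "AlleleTable",
    "StudyStat",
    "MetaResult",
    "table_from_maf",
    "allelic_or_ci",
    "meta_sample_size_z",
    "heterogeneity",
    "bh_adjust",
]

logger = logging.getLogger(__name__)


@dataclass
class AlleleTable:
    """Allele-count 2x2 table: minor/major allele counts in cases and controls."""

    a: float  # minor alleles, cases
    b: float  # major alleles, cases
    c: float  # minor alleles, controls
    d: float  # major alleles, controls

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative allele count in {self}")


@dataclass
class StudyStat:
    """One study's summary statistic for meta-analysis.

    ``z`` is signed by the direction of the minor-allele effect; ``n`` is
    the effective sample size. ``effect``/``se`` are only needed for
    heterogeneity.
    """

    study_id: str
    z: float
    n: float
    effect: float | None = None
    se: float | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"sample size must be positive: {self.study_id} has n={self.n}")


@dataclass
class MetaResult:
    combined_z: float
    combined_p: float
    q_statistic: float | None = None
    q_p: float | None = None
    i_squared: float | None = None


def table_from_maf(
    maf_cases: float,
    maf_controls: float,
    n_cases: int,
    n_controls: int,
    rounding: str = "integer",
) -> AlleleTable:
    """Reconstruct allele counts from minor-allele frequencies and sample sizes.

    Each individual contributes two alleles, so cases carry
    ``2 * n_cases * maf_cases`` minor alleles; ``rounding='integer'``
    (default) rounds to whole alleles, ``'fractional'`` keeps the exact
    products.
    """
    for name, f in (("maf_cases", maf_cases), ("maf_controls", maf_controls)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {f}")
    if n_cases < 0 or n_controls < 0:
        raise ValueError("sample sizes must be non-negative")
    if rounding not in ("integer", "fractional"):
        raise ValueError(f"rounding must be 'integer' or 'fractional', got {rounding!r}")
    a = 2 * n_cases * maf_cases
    c = 2 * n_controls * maf_controls
    if rounding == "integer":
        a, c = round(a), round(c)
    return AlleleTable(a=a, b=2 * n_cases - a, c=c, d=2 * n_controls - c)


def allelic_or_ci(table: AlleleTable, level: float = 0.95):
    """Allelic odds ratio with Woolf confidence interval and normal-test p.

    OR = (a/b)/(c/d); CI bounds are exp(ln OR +/- z * SE) with
    SE = sqrt(1/a + 1/b + 1/c + 1/d); the two-sided p comes from
    ln OR / SE against the standard normal. Any zero cell triggers the
    Haldane-Anscombe +0.5 correction on all four cells (logged).

    Returns ``(or_, ci_low, ci_high, p)``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == b == c == d == 0:
        raise ValueError("all-zero allele table")
    if min(a, b, c, d) == 0:
        logger.info("zero cell in allele table %s: Haldane-Anscombe +0.5 applied", table)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z_crit = norm.ppf(0.5 + level / 2)
    log_or = math.log(or_)
    ci_low = math.exp(log_or - z_crit * se)
    ci_high = math.exp(log_or + z_crit * se)
    p = 2 * norm.sf(abs(log_or) / se)
    return or_, ci_low, ci_high, float(p)


def meta_sample_size_z(studies: list[StudyStat]) -> MetaResult:
    """Sample-size-weighted Z-score meta-analysis.

    combined Z = sum(z_i * w_i) / sqrt(sum(w_i^2)) with w_i = sqrt(n_i);
    two-sided p from the standard normal. Invariant under uniform scaling
    of the sample sizes.
    """
    if not studies:
        raise ValueError("meta-analysis needs at least one study")
    w = np.sqrt([s.n for s in studies])
    z = np.array([s.z for s in studies])
    combined_z = float(np.sum(z * w) / math.sqrt(float(np.sum(w**2))))
    combined_p = float(2 * norm.sf(abs(combined_z)))
    return MetaResult(combined_z=combined_z, combined_p=combined_p)


def heterogeneity(studies: list[StudyStat]):
    """Cochran's Q and I-squared between-study heterogeneity.

    Fixed-effect weights 1/SE^2; Q = sum w_i (beta_i - beta_bar)^2 with
    beta_bar the weighted mean effect; p from chi-square with k-1 df;
    I^2 = max(0, (Q - df) / Q) * 100 percent.

    Returns ``(Q, q_p, i_squared)``.
    """
    if len(studies) < 2:
        raise ValueError("heterogeneity needs at least two studies")
    for s in studies:
        if s.effect is None or s.se is None or not math.isfinite(s.se) or s.se <= 0:
            raise ValueError(f"study {s.study_id} lacks a finite effect/SE")
    beta = np.array([s.effect for s in studies], dtype=float)
    w = np.array([1 / s.se**2 for s in studies])
    beta_bar = float(np.sum(w * beta) / np.sum(w))
    q = float(np.sum(w * (beta - beta_bar) ** 2))
    df = len(studies) - 1
    q_p = float(chi2.sf(q, df))
    i_squared = max(0.0, (q - df) / q) * 100 if q > 0 else 0.0
    return q, q_p, i_squared


def read_study_tsv(path) -> pd.DataFrame:
    """Read per-study summary rows (snp, study, z or effect+se, n, direction)."""
    return pd.read_csv(path, sep="\t")


def meta_by_snp(df: pd.DataFrame) -> pd.DataFrame:
    """Meta-analyze a study summary table per SNP; BH-adjust the combined p.

    Expects columns ``snp, study, z, n`` and optionally ``effect, se`` for
    heterogeneity. Returns one row per SNP mirroring a meta-analysis report
    (combined Z/p, Q, Q p, I^2, adjusted p).
    """
    rows = []
    for snp, grp in df.groupby("snp", sort=False):
        studies = [
            StudyStat(
                study_id=str(r.study),
                z=float(r.z),
                n=float(r.n),
                effect=float(r.effect) if "effect" in grp.columns else None,
                se=float(r.se) if "se" in grp.columns else None,
            )
            for r in grp.itertuples()
        ]
        meta = meta_sample_size_z(studies)
        q = q_p = i2 = float("nan")
        if len(studies) >= 2 and all(s.effect is not None and s.se is not None for s in studies):
            q, q_p, i2 = heterogeneity(studies)
        rows.append((snp, meta.combined_z, meta.combined_p, q, q_p, i2))
    out = pd.DataFrame(
        rows, columns=["snp", "combined_z", "combined_p", "q", "q_p", "i_squared"]
    )
    out["adjusted_p"] = bh_adjust(out["combined_p"].to_numpy())
    return out
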