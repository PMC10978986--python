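"""Genomic scaling laws and residual-based functional enrichment.

Within prokaryotic genomes the number of genes in a broad functional
category (COG or KEGG BRITE level) scales as a power law of the total
gene count, ``y = c * x**beta``, i.e. a linear law on log10-transformed
variables. Deviations from the pooled fit (residuals in log space) are a
size-corrected measure of functional enrichment or depletion: a group of
genomes whose residuals for a category sit above the pooled trend carries
more genes in that category than expected for its genome size.

Group comparisons use a two-sided Mann-Whitney U test on residual
distributions, with Bonferroni and Benjamini-Hochberg corrections across
the categories that pass the fit-quality gate (R^2 >= 0.3 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScalingFit",
    "EnrichmentResult",
    "fit_scaling_law",
    "residuals",
    "enrichment_scan",
    "R2_MIN",
]

R2_MIN = 0.3


@dataclass(frozen=True)
class ScalingFit:
    """OLS fit of log10(category count) on log10(total count)."""

    category_id: str
    slope: float
    intercept: float
    r_squared: float
    n_genomes: int

    def predict_log10(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.log10(x)


@dataclass(frozen=True)
class EnrichmentResult:
    category_id: str
    tested: bool
    u_statistic: float | None = None
    p_value: float | None = None
    p_bonferroni: float | None = None
    p_bh: float | None = None
    direction: str | None = None  # enriched / depleted (group A vs group B)
    r_squared: float | None = None
    n_a: int = 0
    n_b: int = 0


def _positive_pairs(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = (x > 0) & (y > 0)
    return x[keep], y[keep]


def fit_scaling_law(
    x: Sequence[float], y: Sequence[float], category_id: str = ""
) -> ScalingFit:
    """Fit log10(y) = intercept + slope * log10(x) by ordinary least squares.

    Genomes with a zero count in either variable are excluded (log
    undefined); at least 3 usable points are required.
    """
    xp, yp = _positive_pairs(x, y)
    if xp.size < 3:
        raise ValueError(f"need >= 3 positive (x, y) pairs, got {xp.size}")
    res = stats.linregress(np.log10(xp), np.log10(yp))
    return ScalingFit(
        category_id=category_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_genomes=int(xp.size),
    )


def residuals(fit: ScalingFit, x: Sequence[float], y: Sequence[float]) -> np.ndarray:
    """Per-genome residuals observed - predicted log10 category count.

    Genomes with zero counts get NaN (excluded from any comparison);
    the mean residual over the fitting set is zero by OLS construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.full(x.shape, np.nan)
    keep = (x > 0) & (y > 0)
    out[keep] = np.log10(y[keep]) - fit.predict_log10(x[keep])
    return out


def enrichment_scan(
    annotations: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    totals: pd.Series | None = None,
    r2_min: float = R2_MIN,
    min_group_n: int = 3,
) -> pd.DataFrame:
    """Scan categories for residual enrichment of group A versus group B.

    Parameters
    ----------
    annotations : wide table, genomes x categories, of gene counts.
    group_a, group_b : disjoint genome id collections (rows of the table).
    totals : total gene count per genome; row sums of ``annotations`` when
        omitted.
    r2_min : categories whose pooled fit has R^2 below this are marked
        untested and carry no p-values.

    One pooled fit per category over A union B; residual distributions of
    the two groups are compared with a two-sided Mann-Whitney U test;
    Bonferroni and Benjamini-Hochberg corrections are applied across the
    tested categories. Direction is the sign of the median residual
    difference (A - B).
    """
    a = sorted(set(group_a))
    b = sorted(set(group_b))
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if set(a) & set(b):
        raise ValueError("groups must be disjoint")
    pooled = a + b
    sub = annotations.loc[pooled]
    tot = sub.sum(axis=1) if totals is None else totals.loc[pooled]

    results: list[EnrichmentResult] = []
    for cat in annotations.columns:
        y = sub[cat]
        try:
            fit = fit_scaling_law(tot.values, y.values, category_id=str(cat))
        except ValueError:
            results.append(EnrichmentResult(str(cat), tested=False))
            continue
        if fit.r_squared < r2_min:
            results.append(
                EnrichmentResult(str(cat), tested=False, r_squared=fit.r_squared)
            )
            continue
        res = pd.Series(residuals(fit, tot.values, y.values), index=sub.index)
        ra = res.loc[a].dropna()
        rb = res.loc[b].dropna()
        if len(ra) < min_group_n or len(rb) < min_group_n:
            raise ValueError(
                f"category {cat!r}: a group has fewer than {min_group_n} genomes"
            )
        u, p = stats.mannwhitneyu(ra, rb, alternative="two-sided")
        direction = "enriched" if ra.median() >= rb.median() else "depleted"
        results.append(
            EnrichmentResult(
                str(cat),
                tested=True,
                u_statistic=float(u),
                p_value=float(p),
                direction=direction,
                r_squared=fit.r_squared,
                n_a=len(ra),
                n_b=len(rb),
            )
        )

    table = pd.DataFrame([r.__dict__ for r in results]).set_index("category_id")
    tested = table.index[table["tested"]]
    if len(tested):
        raw = table.loc[tested, "p_value"].astype(float).values
        table.loc[tested, "p_bonferroni"] = multipletests(raw, method="bonferroni")[1]
        table.loc[tested, "p_bh"] = multipletests(raw, method="fdr_bh")[1]
    return table
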