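"""Fixed-effects inverse-variance meta-analysis with Cochran's Q / I^2 filtering."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SUMSTATS_COLUMNS, SummaryStats

DEFAULT_I2_EXCLUDE = 75.0  # percent; strictly greater is excluded
DEFAULT_MAF_FILTER = 0.01


@dataclass
class MetaResult:
    variant_id: str
    pooled_beta: float
    pooled_se: float
    pooled_p: float
    cohort_betas: np.ndarray = field(repr=False)
    cohort_ses: np.ndarray = field(repr=False)
    q: float = 0.0
    df: int = 0
    q_p: float = 1.0
    i2: float = 0.0
    excluded: bool = False

    @property
    def pooled_or(self) -> float:
        return float(np.exp(self.pooled_beta))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf((1.0 + level) / 2.0)
        return (self.pooled_beta - z * self.pooled_se,
                self.pooled_beta + z * self.pooled_se)


def fixed_effect_meta(betas, ses, variant_id: str = "") -> MetaResult:
    """Inverse-variance pooling of per-cohort log odds ratios.

    Weights ``1/se^2``; pooled SE ``1/sqrt(sum w)``; two-sided normal p.
    Heterogeneity (Q, I^2) is computed around the pooled estimate; with a
    single cohort the inputs pass through with Q = 0, I^2 = 0.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("at least one cohort required")
    if betas.shape != ses.shape:
        raise ValueError("betas and ses lengths differ")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    pooled_p = max(float(2.0 * stats.norm.sf(abs(pooled / pooled_se))),
                   float(np.finfo(float).tiny))
    q, df, q_p, i2 = cochran_q(betas, ses, pooled)
    return MetaResult(variant_id, pooled, pooled_se, pooled_p,
                      betas, ses, q, df, q_p, i2)


def cochran_q(betas, ses, pooled_beta: float) -> tuple[float, int, float, float]:
    """Cochran's Q around ``pooled_beta`` with inverse-variance weights.

    Returns (q, df, q_p, i2) where ``i2 = max(0, (q - df) / q) * 100`` when
    q > 0, else 0.  A single study gives (0, 0, 1, 0).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape:
        raise ValueError("betas and ses lengths differ")
    k = betas.size
    if k < 2:
        return 0.0, 0, 1.0, 0.0
    w = 1.0 / ses**2
    q = float(np.sum(w * (betas - pooled_beta) ** 2))
    df = k - 1
    q_p = float(stats.chi2.sf(q, df)) if q > 0 else 1.0
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, q_p, i2


def filter_heterogeneous(results: list[MetaResult], i2_threshold: float = DEFAULT_I2_EXCLUDE
                         ) -> list[MetaResult]:
    """Flag and drop variants with I^2 strictly above the threshold.

    Single-cohort variants (df = 0) are always retained.
    """
    if not (0.0 <= i2_threshold <= 100.0):
        raise ValueError("i2_threshold must be in [0, 100]")
    retained = []
    for r in results:
        r.excluded = r.df >= 1 and r.i2 > i2_threshold
        if not r.excluded:
            retained.append(r)
    return retained


def meta_analyze(
    cohorts: list[SummaryStats],
    i2_threshold: float = DEFAULT_I2_EXCLUDE,
    maf_filter: float | None = None,
) -> tuple[SummaryStats, list[MetaResult]]:
    """Meta-analyze harmonized per-cohort summary statistics variant-wise.

    The first cohort provides the reference allele orientation (cohorts must
    already be allele-aligned; use harmonization first when in doubt).
    Variants in a single cohort pass through unchanged.  ``maf_filter``
    drops variants with cohort MAF below the bound before pooling.
    """
    if not cohorts:
        raise ValueError("at least one cohort required")
    tables = []
    for ss in cohorts:
        t = ss.table
        if maf_filter is not None:
            maf = np.minimum(t["eaf"], 1.0 - t["eaf"])
            t = t.loc[maf >= maf_filter]
        tables.append(t.set_index("variant_id"))

    results: list[MetaResult] = []
    rows = []
    ref = tables[0]
    order: list[str] = []
    seen: set[str] = set()
    for t in tables:
        for vid in t.index:
            if vid not in seen:
                seen.add(vid)
                order.append(vid)
    for vid in order:
        present = [t.loc[vid] for t in tables if vid in t.index]
        betas = [float(r["beta"]) for r in present]
        ses = [float(r["se"]) for r in present]
        res = fixed_effect_meta(betas, ses, variant_id=vid)
        results.append(res)
        first = present[0]
        ns = [float(r["n"]) for r in present]
        eafs = [float(r["eaf"]) for r in present]
        rows.append({
            "variant_id": vid,
            "chromosome": str(first["chromosome"]),
            "position": int(first["position"]),
            "effect_allele": str(first["effect_allele"]),
            "other_allele": str(first["other_allele"]),
            "eaf": float(np.average(eafs, weights=ns)),
            "beta": res.pooled_beta,
            "se": res.pooled_se,
            "p_value": max(res.pooled_p, np.finfo(float).tiny),
            "n": float(sum(ns)),
            "n_case": np.nan,
            "n_control": np.nan,
        })
    retained = filter_heterogeneous(results, i2_threshold)
    keep_ids = {r.variant_id for r in retained}
    table = pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)
    table = table.loc[table["variant_id"].isin(keep_ids)].reset_index(drop=True)
    first = cohorts[0]
    pooled = SummaryStats(first.trait_name, first.trait_type, first.effect_scale, table)
    return pooled, results


def meta_table(results: list[MetaResult]) -> pd.DataFrame:
    """Per-variant report with pooled OR, CI and heterogeneity columns."""
    rows = []
    for r in results:
        lo, hi = r.ci()
        rows.append({
            "variant_id": r.variant_id,
            "pooled_or": r.pooled_or,
            "or_ci_lower": float(np.exp(lo)),
            "or_ci_upper": float(np.exp(hi)),
            "pooled_beta": r.pooled_beta,
            "pooled_se": r.pooled_se,
            "pooled_p": r.pooled_p,
            "q": r.q,
            "df": r.df,
            "q_p": r.q_p,
            "i2": r.i2,
            "excluded": r.excluded,
        })
    return pd.DataFrame(rows)
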