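"""Instrument selection: p-value filtering, greedy LD clumping, strength diagnostics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SummaryStats

logger = logging.getLogger(__name__)

GWAS_P_THRESHOLD = 5e-8
DEFAULT_CLUMP_R2 = 0.01
DEFAULT_CLUMP_WINDOW_BP = 10_000_000
MIN_INSTRUMENTS = 3


@dataclass
class LDMatrix:
    """Square symmetric r^2 matrix over an ordered list of variant ids."""

    variant_ids: list[str]
    r2: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 shape {self.r2.shape} does not match {k} ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be exactly 1")
        if self.r2.min() < 0.0 or self.r2.max() > 1.0 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, a: str, b: str) -> float | None:
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def from_square_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(variant_ids=[str(c) for c in df.columns], r2=df.to_numpy(float))

    @classmethod
    def from_triplets(cls, triplets: pd.DataFrame) -> "LDMatrix":
        """Build from long-form (id_a, id_b, r2) rows; absent pairs are 0."""
        ids = sorted(set(triplets.iloc[:, 0]) | set(triplets.iloc[:, 1]))
        idx = {v: i for i, v in enumerate(ids)}
        r2 = np.zeros((len(ids), len(ids)))
        for a, b, val in triplets.itertuples(index=False):
            r2[idx[str(a)], idx[str(b)]] = val
            r2[idx[str(b)], idx[str(a)]] = val
        np.fill_diagonal(r2, 1.0)
        return cls(variant_ids=[str(v) for v in ids], r2=r2)

    def to_square_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t", float_format="%.10g")


def select_instruments(ss: SummaryStats, p_threshold: float = GWAS_P_THRESHOLD) -> pd.DataFrame:
    """Variants with p strictly below threshold, sorted ascending by p."""
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must be in (0, 1)")
    sel = ss.table.loc[ss.table["p_value"] < p_threshold].copy()
    sel = sel.sort_values(
        ["p_value", "chromosome", "position", "variant_id"]).reset_index(drop=True)
    if len(sel) < MIN_INSTRUMENTS:
        logger.warning(
            "%s: only %d instruments below p<%g (>=%d required downstream)",
            ss.trait_name, len(sel), p_threshold, MIN_INSTRUMENTS)
    return sel


def ld_clump(
    candidates: pd.DataFrame,
    ld: LDMatrix,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
) -> pd.DataFrame:
    """Greedy clumping: repeatedly keep the lowest-p unclaimed SNP and
    discard unclaimed SNPs with r^2 >= threshold to it within the window.

    Candidates absent from the LD matrix are treated as unlinked (logged).
    Ties in p break by (chromosome, position, variant_id).
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in (0, 1]")
    if candidates.empty:
        return candidates.copy()
    df = candidates.sort_values(
        ["p_value", "chromosome", "position", "variant_id"]).reset_index(drop=True)
    missing = [v for v in df["variant_id"] if v not in ld._index]
    if missing:
        logger.info("%d candidate(s) absent from LD matrix, treated as unlinked", len(missing))
    unclaimed = list(df.index)
    kept: list[int] = []
    while unclaimed:
        index = unclaimed.pop(0)
        kept.append(index)
        idx_row = df.loc[index]
        survivors = []
        for j in unclaimed:
            row = df.loc[j]
            same_chrom = str(row["chromosome"]) == str(idx_row["chromosome"])
            within = same_chrom and abs(int(row["position"]) - int(idx_row["position"])) <= window_bp
            r2 = ld.lookup(str(idx_row["variant_id"]), str(row["variant_id"]))
            linked = r2 is not None and r2 >= r2_threshold and within
            if not linked:
                survivors.append(j)
        unclaimed = survivors
    return df.loc[kept].reset_index(drop=True)


@dataclass
class InstrumentStrength:
    r2_snp: np.ndarray
    r2_total: float
    r2_mean: float
    r2_sd: float
    f_stat: float
    n: float
    k: int


def instrument_strength(beta_sd: np.ndarray, maf: np.ndarray, n: float) -> InstrumentStrength:
    """Variance explained and F statistic from SD-unit effects and MAFs.

    Per SNP ``r2 = 2 * beta^2 * MAF * (1 - MAF)``;
    ``F = R2_total * (N - 1 - K) / ((1 - R2_total) * K)``.
    """
    beta_sd = np.asarray(beta_sd, dtype=float)
    maf = np.asarray(maf, dtype=float)
    if beta_sd.shape != maf.shape:
        raise ValueError("beta and maf lengths differ")
    k = beta_sd.size
    if k < 1:
        raise ValueError("need at least one instrument")
    if n <= k + 1:
        raise ValueError(f"sample size {n} must exceed k + 1 = {k + 1}")
    r2_snp = 2.0 * beta_sd**2 * maf * (1.0 - maf)
    r2_total = float(r2_snp.sum())
    if r2_total >= 1.0:
        raise ValueError(f"total R^2 = {r2_total:.3f} >= 1")
    f_stat = r2_total * (n - 1 - k) / ((1.0 - r2_total) * k)
    return InstrumentStrength(
        r2_snp=r2_snp,
        r2_total=r2_total,
        r2_mean=float(r2_snp.mean()),
        r2_sd=float(r2_snp.std(ddof=1)) if k > 1 else 0.0,
        f_stat=float(f_stat),
        n=float(n),
        k=int(k),
    )
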