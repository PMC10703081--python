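"""Univariable MR estimators and sensitivity analyses.

Wald ratio, inverse-variance weighted (IVW) regression through the origin
with multiplicative random-effects SE inflation, MR-Egger, weighted median
with parametric bootstrap, contamination mixture by profile likelihood,
leave-one-out, Steiger directionality filtering and the primary-estimate
selection rule (Egger when its intercept p < 0.05, IVW otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats import HarmonizedInstrumentSet

Z95 = stats.norm.ppf(0.975)
CI_LOGLIK_DROP = 1.92  # chi2_1 / 2 at 95%


class InsufficientInstrumentsError(ValueError):
    pass


@dataclass
class MRResult:
    method: str
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    p: float
    n_snp: int
    q: float = float("nan")
    q_df: int = 0
    q_p: float = float("nan")
    intercept: float = float("nan")
    intercept_se: float = float("nan")
    intercept_p: float = float("nan")
    ci_set: list[tuple[float, float]] | None = None
    exposure: str = ""
    outcome: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_lower) and np.isfinite(self.ci_upper):
            if not (self.ci_lower - 1e-12 <= self.estimate <= self.ci_upper + 1e-12):
                raise ValueError("estimate outside its confidence interval")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))


def _normal_ci(estimate: float, se: float) -> tuple[float, float]:
    return estimate - Z95 * se, estimate + Z95 * se


def _normal_p(estimate: float, se: float) -> float:
    if se == 0:
        return float(np.finfo(float).tiny) if estimate != 0 else 1.0
    p = float(2.0 * stats.norm.sf(abs(estimate / se)))
    return max(p, float(np.finfo(float).tiny))


def _unpack(hset, exposure: str | None = None):
    if isinstance(hset, HarmonizedInstrumentSet):
        bx, sx = hset.exposure_effects(exposure)
        return bx, sx, hset.beta_outcome, hset.se_outcome
    bx, sx, by, sy = (np.asarray(a, dtype=float) for a in hset)
    return bx, sx, by, sy


def _labels(hset) -> dict:
    if isinstance(hset, HarmonizedInstrumentSet):
        return {"exposure": hset.primary_exposure, "outcome": hset.outcome_name}
    return {}


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float,
               second_order: bool = False) -> MRResult:
    """Single-SNP ratio estimate with delta-method SE.

    First order: ``se = se_out / |beta_exp|``; the second-order form adds the
    exposure-uncertainty term.
    """
    if beta_exp == 0:
        raise ZeroDivisionError("beta_exp must be nonzero for a Wald ratio")
    estimate = beta_out / beta_exp
    if second_order:
        se = np.sqrt(se_out**2 / beta_exp**2
                     + beta_out**2 * se_exp**2 / beta_exp**4)
    else:
        se = se_out / abs(beta_exp)
    lo, hi = _normal_ci(estimate, se)
    return MRResult("wald", float(estimate), float(se), lo, hi,
                    _normal_p(estimate, se), 1)


def _ratio_q(bx, sy, by, estimate):
    """Cochran's Q over Wald ratios with first-order weights."""
    ratios = by / bx
    w = (bx / sy) ** 2
    q = float(np.sum(w * (ratios - estimate) ** 2))
    df = bx.size - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return q, df, q_p


def ivw(hset, exposure: str | None = None) -> MRResult:
    """IVW estimate: weighted regression of outcome on exposure effects
    through the origin, weights 1/se_out^2, with multiplicative
    random-effects SE inflation floored at 1."""
    bx, sx, by, sy = _unpack(hset, exposure)
    n = bx.size
    if n < 2:
        raise InsufficientInstrumentsError(f"IVW requires >= 2 SNPs, got {n}")
    w = 1.0 / sy**2
    denom = np.sum(w * bx**2)
    estimate = float(np.sum(w * bx * by) / denom)
    se = float(1.0 / np.sqrt(denom))
    q, df, q_p = _ratio_q(bx, sy, by, estimate)
    se *= max(1.0, np.sqrt(q / df)) if df > 0 else 1.0
    lo, hi = _normal_ci(estimate, se)
    return MRResult("ivw", estimate, se, lo, hi, _normal_p(estimate, se),
                    int(n), q, df, q_p, **_labels(hset))


def egger(hset, exposure: str | None = None) -> MRResult:
    """MR-Egger: weighted regression with intercept after orienting all
    exposure effects non-negative; multiplicative SE inflation floored at 1."""
    bx, sx, by, sy = _unpack(hset, exposure)
    n = bx.size
    if n < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >= 3 SNPs, got {n}")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(n), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    xtwy = WX.T @ by
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    rss = float(np.sum(w * resid**2))
    df = n - 2
    scale = max(1.0, np.sqrt(rss / df)) if df > 0 else 1.0
    cov_unit = np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov_unit)) * scale
    intercept, slope = float(coef[0]), float(coef[1])
    i_se, s_se = float(ses[0]), float(ses[1])
    q_p = float(stats.chi2.sf(rss, df)) if df > 0 else float("nan")
    lo, hi = _normal_ci(slope, s_se)
    return MRResult("egger", slope, s_se, lo, hi, _normal_p(slope, s_se),
                    int(n), rss, df, q_p,
                    intercept=intercept, intercept_se=i_se,
                    intercept_p=_normal_p(intercept, i_se), **_labels(hset))


def _weighted_median_point(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median at cumulative weight 0.5."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(v[0])
    if 0.5 >= s[-1]:
        return float(v[-1])
    return float(np.interp(0.5, s, v))


def weighted_median(hset, n_boot: int = 1000, seed: int = 0,
                    exposure: str | None = None) -> MRResult:
    """Weighted median of Wald ratios (inverse-variance weights) with a
    seeded parametric bootstrap SE."""
    bx, sx, by, sy = _unpack(hset, exposure)
    n = bx.size
    if n < 3:
        raise InsufficientInstrumentsError(f"weighted median requires >= 3 SNPs, got {n}")
    ratios = by / bx
    weights = (bx / sy) ** 2
    estimate = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx_b = bx + rng.normal(0.0, sx)
        by_b = by + rng.normal(0.0, sy)
        bad = bx_b == 0
        if bad.any():
            bx_b[bad] = bx[bad]
        boots[i] = _weighted_median_point(by_b / bx_b, (bx_b / sy) ** 2)
    se = float(boots.std(ddof=1))
    lo, hi = _normal_ci(estimate, se)
    return MRResult("weighted_median", estimate, se, lo, hi,
                    _normal_p(estimate, se), int(n), **_labels(hset))


def contamination_mixture(hset, psi: float | None = None,
                          grid_resolution: int = 1000,
                          exposure: str | None = None) -> MRResult:
    """Contamination-mixture estimate by profile likelihood over a grid.

    Each SNP contributes the larger of its valid-instrument likelihood
    (ratio ~ Normal(theta, se)) and invalid likelihood
    (ratio ~ Normal(0, sqrt(se^2 + psi^2))).  The 95% confidence set is the
    union of grid intervals within 1.92 log-likelihood of the maximum and
    may be disjoint.  ``psi`` defaults to 1.5 x SD of the Wald ratios.
    """
    bx, sx, by, sy = _unpack(hset, exposure)
    n = bx.size
    if n < 3:
        raise InsufficientInstrumentsError(f"contamination mixture requires >= 3 SNPs, got {n}")
    if grid_resolution < 2:
        raise ValueError("grid_resolution must be >= 2")
    ratios = by / bx
    ratio_se = np.abs(sy / bx)
    if psi is None:
        psi = 1.5 * float(ratios.std(ddof=1))
    if not psi > 0:
        raise ValueError("psi must be positive")
    span = ratios.max() - ratios.min()
    if span == 0:
        span = max(ratio_se.max() * 4, 1e-6)
    pad = 0.25 * span
    grid = np.linspace(ratios.min() - pad, ratios.max() + pad, grid_resolution + 1)
    if grid[0] == grid[-1]:
        raise ValueError("degenerate likelihood grid")
    ll_valid = stats.norm.logpdf(ratios[None, :], loc=grid[:, None], scale=ratio_se[None, :])
    ll_invalid = stats.norm.logpdf(ratios, loc=0.0, scale=np.sqrt(ratio_se**2 + psi**2))
    ll = np.maximum(ll_valid, ll_invalid[None, :]).sum(axis=1)
    best = int(np.argmax(ll))
    estimate = float(grid[best])
    inside = ll >= ll[best] - CI_LOGLIK_DROP
    ci_set = _runs_to_intervals(grid, inside)
    lo, hi = ci_set[0][0], ci_set[-1][1]
    se = (hi - lo) / (2 * Z95) if len(ci_set) == 1 else float("nan")
    p = _normal_p(estimate, se) if np.isfinite(se) and se > 0 else float("nan")
    return MRResult("contamination_mixture", estimate, float(se), lo, hi, p,
                    int(n), ci_set=ci_set, **_labels(hset))


def _runs_to_intervals(grid: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    intervals = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(grid[start]), float(grid[-1])))
    return intervals


@dataclass
class LeaveOneOutEntry:
    variant_id: str
    result: MRResult
    delta: float
    flagged: bool


def leave_one_out(hset: HarmonizedInstrumentSet, method=ivw) -> list[LeaveOneOutEntry]:
    """Refit the estimator omitting each SNP in turn.

    A SNP is flagged as a driver when its omission flips the estimate's sign
    or moves it by more than one full-set SE.
    """
    n = len(hset)
    if n < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >= 3 SNPs")
    full = method(hset)
    entries = []
    for i in range(n):
        sub = hset.subset([j for j in range(n) if j != i])
        res = method(sub)
        delta = res.estimate - full.estimate
        sign_flip = np.sign(res.estimate) != np.sign(full.estimate) and full.estimate != 0
        flagged = bool(sign_flip or abs(delta) > full.se)
        entries.append(LeaveOneOutEntry(str(hset.table["variant_id"].iloc[i]),
                                        res, float(delta), flagged))
    return entries


# ---------------------------------------------------------------------------
# Steiger directionality


@dataclass
class SteigerResult:
    variant_ids: list[str]
    r2_exposure: np.ndarray
    r2_outcome: np.ndarray
    direction_correct: np.ndarray
    steiger_p: np.ndarray
    retained: HarmonizedInstrumentSet = field(repr=False, default=None)


def _trait_r2(beta: np.ndarray, se: np.ndarray, maf: np.ndarray, n: float,
              binary: bool) -> np.ndarray:
    if binary:
        z2 = (beta / se) ** 2
        return z2 / (z2 + n)
    return 2.0 * beta**2 * maf * (1.0 - maf)


def steiger(hset: HarmonizedInstrumentSet, n_exp: float, n_out: float,
            exposure_binary: bool = False, outcome_binary: bool = True) -> SteigerResult:
    """Per-SNP directionality test: does the SNP explain more variance in
    the exposure than in the outcome?

    Continuous-trait variance explained uses ``2 beta^2 MAF (1 - MAF)``;
    binary traits use the ``Z^2 / (Z^2 + N)`` approximation.  The p-value
    compares the implied correlations across the two independent samples by
    Fisher z.  ``retained`` drops SNPs with the wrong direction.
    """
    if not (n_exp and n_out):
        raise ValueError("sample sizes for both traits are required")
    bx, sx = hset.exposure_effects()
    by, sy = hset.beta_outcome, hset.se_outcome
    maf = hset.maf
    r2_exp = np.clip(_trait_r2(bx, sx, maf, n_exp, exposure_binary), 0.0, 1.0 - 1e-12)
    r2_out = np.clip(_trait_r2(by, sy, maf, n_out, outcome_binary), 0.0, 1.0 - 1e-12)
    direction = r2_exp > r2_out
    z_exp = np.arctanh(np.sqrt(r2_exp))
    z_out = np.arctanh(np.sqrt(r2_out))
    denom = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (z_exp - z_out) / denom
    p = 2.0 * stats.norm.sf(np.abs(z))
    retained = hset.subset(direction)
    return SteigerResult(list(hset.table["variant_id"]), r2_exp, r2_out,
                         direction, p, retained)


def select_primary_estimate(ivw_result: MRResult, egger_result: MRResult
                            ) -> tuple[MRResult, str]:
    """Pick MR-Egger when its intercept p < 0.05, IVW otherwise."""
    if egger_result.intercept_p < 0.05:
        return egger_result, (
            f"Egger intercept p = {egger_result.intercept_p:.3g} < 0.05 "
            "suggests directional pleiotropy; MR-Egger selected")
    return ivw_result, (
        f"Egger intercept p = {egger_result.intercept_p:.3g} >= 0.05; IVW selected")
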