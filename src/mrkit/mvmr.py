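"""Multivariable MR and mediation decomposition."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MRResult, Z95, _normal_ci, _normal_p
from .sumstats import HarmonizedInstrumentSet


class CollinearityError(ValueError):
    pass


@dataclass
class MVMRExposureEstimate:
    exposure: str
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    p: float


@dataclass
class MVMRResult:
    exposures: dict[str, MVMRExposureEstimate]
    n_snp: int
    q: float
    q_df: int
    q_p: float
    intercept: float = float("nan")
    intercept_se: float = float("nan")
    intercept_p: float = float("nan")
    outcome: str = ""

    def __getitem__(self, exposure: str) -> MVMRExposureEstimate:
        return self.exposures[exposure]

    def as_mr_result(self, exposure: str) -> MRResult:
        e = self.exposures[exposure]
        return MRResult("mvmr_ivw", e.estimate, e.se, e.ci_lower, e.ci_upper,
                        e.p, self.n_snp, self.q, self.q_df, self.q_p,
                        exposure=exposure, outcome=self.outcome)


def _design(hset: HarmonizedInstrumentSet):
    cols = [hset.table[f"beta_exp__{name}"].to_numpy(float)
            for name in hset.exposure_names]
    return np.column_stack(cols)


def mvmr_fit(hset: HarmonizedInstrumentSet, egger: bool = False) -> MVMRResult:
    """Weighted multivariable regression of outcome effects on the exposure
    effect matrix (no intercept), weights 1/se_out^2.

    Per-exposure direct (conditional) effects with SEs from the weighted
    normal equations, multiplicative scale inflation floored at 1, and
    Cochran's Q of the weighted residuals.  ``egger=True`` adds an intercept
    after orienting SNPs so the first exposure's effects are non-negative.
    """
    names = list(hset.exposure_names)
    p = len(names)
    if p < 2:
        raise ValueError("multivariable MR requires >= 2 exposures")
    X = _design(hset)
    by = hset.beta_outcome
    sy = hset.se_outcome
    n = X.shape[0]
    if n <= p:
        raise ValueError(f"need more SNPs ({n}) than exposures ({p})")

    if egger:
        flip = np.sign(X[:, 0])
        flip[flip == 0] = 1.0
        X = X * flip[:, None]
        by = by * flip

    # an exposure with identically-zero effects carries no information:
    # exclude it from the fit (reported with estimate 0) rather than letting
    # it fake a collinearity failure
    zero_cols = [i for i in range(p) if not np.any(X[:, i])]
    fit_cols = [i for i in range(p) if i not in zero_cols]
    Xf = X[:, fit_cols]
    if egger:
        Xf = np.column_stack([np.ones(n), Xf])

    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        corr = np.corrcoef(_design(hset), rowvar=False)
        pairs = [(names[i], names[j]) for i in range(p) for j in range(i + 1, p)
                 if abs(corr[i, j]) > 0.999]
        raise CollinearityError(
            f"exposure effect matrix is rank deficient; near-collinear pairs: {pairs or names}")

    w = 1.0 / sy**2
    xtwx = Xf.T @ (Xf * w[:, None])
    xtwy = Xf.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - Xf @ coef
    q = float(np.sum(w * resid**2))
    q_df = n - Xf.shape[1]
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else float("nan")
    scale = max(1.0, np.sqrt(q / q_df)) if q_df > 0 else 1.0
    cov = np.linalg.inv(xtwx) * scale**2
    ses = np.sqrt(np.diag(cov))

    offset = 1 if egger else 0
    estimates = {}
    for i, name in enumerate(names):
        if i in zero_cols:
            estimates[name] = MVMRExposureEstimate(
                name, 0.0, float("inf"), float("-inf"), float("inf"), 1.0)
            continue
        j = offset + fit_cols.index(i)
        est, se = float(coef[j]), float(ses[j])
        lo, hi = _normal_ci(est, se)
        estimates[name] = MVMRExposureEstimate(name, est, se, lo, hi, _normal_p(est, se))
    result = MVMRResult(estimates, int(n), q, int(q_df), q_p, outcome=hset.outcome_name)
    if egger:
        result.intercept = float(coef[0])
        result.intercept_se = float(ses[0])
        result.intercept_p = _normal_p(result.intercept, result.intercept_se)
    return result


@dataclass
class EffectEstimate:
    """A point estimate with its standard error (any scale)."""
    estimate: float
    se: float = 0.0

    @classmethod
    def from_result(cls, r) -> "EffectEstimate":
        return cls(float(r.estimate), float(r.se))


@dataclass
class MediationResult:
    """Product-method decomposition: indirect = A x B, proportion = (A x B) / c.

    ``direct_effect`` is the difference-method direct effect c - A x B;
    ``mvmr_direct_effect`` carries the MVMR-adjusted c' when supplied.
    """

    total_effect: float
    total_se: float
    a_path: float
    a_se: float
    b_path: float
    b_se: float
    indirect: float = field(init=False)
    indirect_se: float = field(init=False)
    direct_effect: float = field(init=False)
    proportion_mediated: float = field(init=False)
    proportion_se: float = field(init=False)
    mvmr_direct_effect: float = float("nan")
    mvmr_direct_se: float = float("nan")
    proportion_defined: bool = field(init=False, default=True)

    def __post_init__(self) -> None:
        a, b, c = self.a_path, self.b_path, self.total_effect
        va, vb, vc = self.a_se**2, self.b_se**2, self.total_se**2
        self.indirect = a * b
        self.indirect_se = float(np.sqrt(a**2 * vb + b**2 * va))
        self.direct_effect = c - self.indirect
        if c == 0:
            self.proportion_defined = False
            self.proportion_mediated = float("nan")
            self.proportion_se = float("nan")
            return
        self.proportion_mediated = self.indirect / c
        # delta method on indirect / total, treating the two as independent
        self.proportion_se = float(np.sqrt(
            self.indirect_se**2 / c**2 + self.indirect**2 * vc / c**4))

    def proportion_ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf((1.0 + level) / 2.0)
        return (self.proportion_mediated - z * self.proportion_se,
                self.proportion_mediated + z * self.proportion_se)


def mediate(total, a_path, b_path, mvmr_direct=None) -> MediationResult:
    """Mediation decomposition from MR estimates of the total effect (c),
    exposure->mediator path (A) and mediator->outcome path (B, adjusted for
    the exposure).  Accepts MRResult-like objects or (estimate, se) pairs.
    """
    def _coerce(x) -> EffectEstimate:
        if isinstance(x, EffectEstimate):
            return x
        if hasattr(x, "estimate"):
            return EffectEstimate.from_result(x)
        est, se = x
        return EffectEstimate(float(est), float(se))

    c, a, b = _coerce(total), _coerce(a_path), _coerce(b_path)
    res = MediationResult(c.estimate, c.se, a.estimate, a.se, b.estimate, b.se)
    if mvmr_direct is not None:
        d = _coerce(mvmr_direct)
        res.mvmr_direct_effect = d.estimate
        res.mvmr_direct_se = d.se
    return res
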