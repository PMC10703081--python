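"""Synthetic two-sample GWAS summary statistics with known causal structure.

Summary statistics are generated directly under an
exposure -> mediator -> outcome structural model (no individual-level
genotypes): true marginal effects are computed from the model, observed
effects add independent normal noise with the analytic GWAS standard error
for each trait's sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LDMatrix
from .sumstats import SUMSTATS_COLUMNS, SummaryStats

DEFAULT_SEED = 20230885


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the structural model and the GWAS noise layer.

    ``theta_direct`` is the direct exposure->outcome effect (c'), ``a_path``
    the exposure->mediator effect (A) and ``b_path`` the mediator->outcome
    effect (B), so the total exposure effect is ``c' + A*B``.  Instruments
    beyond ``m_instruments`` can be given mediator-specific effects
    (``m_mediator_instruments``, needed for multivariable identification) or
    reverse-causal outcome effects (``m_reverse``).
    """

    m_snps: int = 500
    m_instruments: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    sigma_gamma: float = 0.15
    theta_direct: float = 0.0
    a_path: float = 0.0
    b_path: float = 0.0
    pleiotropy_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_exposure: int = 100_000
    n_mediator: int = 100_000
    n_outcome: int = 100_000
    n_case_fraction: float = 0.5
    n_cohorts: int = 1
    ld_block_size: int = 1
    ld_r2: float = 0.0
    seed: int = DEFAULT_SEED
    # mediator-specific instruments (zero exposure effect)
    m_mediator_instruments: int = 0
    sigma_eta: float = 0.15
    # reverse-causal SNPs: primary effect on the outcome, partially
    # transmitted back to the exposure
    m_reverse: int = 0
    reverse_effect_sd: float = 0.0
    reverse_transmission: float = 0.3

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.m_instruments + self.m_mediator_instruments + self.m_reverse > self.m_snps:
            raise ConfigError("instrument counts exceed m_snps")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            raise ConfigError("pleiotropy_fraction must be in [0, 1]")
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) < 100:
                raise ConfigError(f"{name} must be >= 100")
        if not (0.0 < self.n_case_fraction < 1.0):
            raise ConfigError("n_case_fraction must be in (0, 1)")
        if self.n_cohorts not in (1, 2):
            raise ConfigError("n_cohorts must be 1 or 2")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_r2 <= 1.0):
            raise ConfigError(f"ld_r2 must be in [0, 1], got {self.ld_r2}")


@dataclass
class GroundTruth:
    theta_total: float
    theta_direct: float
    a_path: float
    b_path: float
    proportion_mediated: float
    valid_instrument_ids: list[str] = field(default_factory=list)
    invalid_instrument_ids: list[str] = field(default_factory=list)
    mediator_instrument_ids: list[str] = field(default_factory=list)
    reverse_instrument_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _variant_ids(m: int) -> list[str]:
    return [f"snp{j:05d}" for j in range(m)]


def continuous_se(maf: np.ndarray, n: float) -> np.ndarray:
    """Per-SNP GWAS SE for a standardized continuous trait."""
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def binary_se(maf: np.ndarray, n: float, case_fraction: float) -> np.ndarray:
    """Per-SNP GWAS SE on the log-odds scale for a binary trait."""
    v = case_fraction
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * v * (1.0 - v))


def simulate_sumstats(
    config: SimulationConfig,
) -> tuple[dict[str, list[SummaryStats]], GroundTruth]:
    """Generate per-trait, per-cohort summary statistics and the ground truth.

    Returns a mapping trait name -> list of :class:`SummaryStats`, one per
    cohort, for traits ``exposure`` (continuous), ``mediator`` (continuous)
    and ``outcome`` (binary, log-odds).  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.m_snps
    ids = _variant_ids(m)
    maf = rng.uniform(*config.maf_range, size=m)

    k_exp = config.m_instruments
    k_med = config.m_mediator_instruments
    k_rev = config.m_reverse
    gamma = np.zeros(m)
    gamma[:k_exp] = rng.normal(0.0, config.sigma_gamma, size=k_exp)
    eta = np.zeros(m)
    eta[k_exp:k_exp + k_med] = rng.normal(0.0, config.sigma_eta, size=k_med)
    delta = np.zeros(m)
    delta[k_exp + k_med:k_exp + k_med + k_rev] = rng.normal(
        0.0, config.reverse_effect_sd, size=k_rev)

    n_invalid = int(round(config.pleiotropy_fraction * k_exp))
    alpha = np.zeros(m)
    # directional pleiotropy is defined relative to the exposure-increasing
    # orientation of each SNP (sign of gamma); otherwise estimator-side
    # orientation would scramble its sign and cancel the mean
    draw = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n_invalid)
    alpha[:n_invalid] = np.where(gamma[:n_invalid] >= 0, draw, -draw)

    c_prime, a, b = config.theta_direct, config.a_path, config.b_path
    theta_total = c_prime + a * b
    true_beta = {
        "exposure": gamma + config.reverse_transmission * delta,
        "mediator": a * gamma + eta,
        "outcome": theta_total * gamma + b * eta + alpha + delta,
    }
    n_per_trait = {"exposure": config.n_exposure, "mediator": config.n_mediator,
                   "outcome": config.n_outcome}

    result: dict[str, list[SummaryStats]] = {}
    for trait, truth in true_beta.items():
        n = n_per_trait[trait]
        binary = trait == "outcome"
        se = (binary_se(maf, n, config.n_case_fraction) if binary
              else continuous_se(maf, n))
        cohorts = []
        for _ in range(config.n_cohorts):
            beta_hat = truth + rng.normal(0.0, 1.0, size=m) * se
            z = beta_hat / se
            p = 2.0 * stats.norm.sf(np.abs(z))
            p = np.clip(p, np.finfo(float).tiny, 1.0)
            table = pd.DataFrame({
                "variant_id": ids,
                "chromosome": "1",
                "position": 1 + 50_000 * np.arange(m),
                "effect_allele": "A",
                "other_allele": "G",
                "eaf": maf,
                "beta": beta_hat,
                "se": se,
                "p_value": p,
                "n": float(n),
                "n_case": config.n_case_fraction * n if binary else np.nan,
                "n_control": (1 - config.n_case_fraction) * n if binary else np.nan,
            }, columns=SUMSTATS_COLUMNS)
            if binary:  # keep the count invariant exact
                table["n"] = table["n_case"] + table["n_control"]
            cohorts.append(SummaryStats(
                trait, "binary" if binary else "continuous",
                "log_odds" if binary else "sd_units", table))
        result[trait] = cohorts

    if theta_total != 0:
        prop = a * b / theta_total
    else:
        prop = float("nan") if a * b != 0 else 0.0
    truth = GroundTruth(
        theta_total=theta_total,
        theta_direct=c_prime,
        a_path=a,
        b_path=b,
        proportion_mediated=prop,
        valid_instrument_ids=ids[n_invalid:k_exp],
        invalid_instrument_ids=ids[:n_invalid],
        mediator_instrument_ids=ids[k_exp:k_exp + k_med],
        reverse_instrument_ids=ids[k_exp + k_med:k_exp + k_med + k_rev],
    )
    return result, truth


def simulate_ld(config: SimulationConfig) -> LDMatrix:
    """Block-diagonal LD (r^2) matrix matching the simulated variant ids."""
    config.validate()
    m = config.m_snps
    r2 = np.zeros((m, m))
    size = config.ld_block_size
    for start in range(0, m, size):
        stop = min(start + size, m)
        r2[start:stop, start:stop] = config.ld_r2
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(variant_ids=_variant_ids(m), r2=r2)
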