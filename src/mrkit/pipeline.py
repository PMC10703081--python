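"""End-to-end orchestration: instrument selection -> harmonization ->
univariable screen with FDR -> sensitivity analyses -> bidirectional MR ->
Steiger filtering -> multivariable MR -> mediation."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import __version__
from .estimators import (
    InsufficientInstrumentsError,
    MRResult,
    contamination_mixture,
    egger,
    ivw,
    leave_one_out,
    select_primary_estimate,
    steiger,
    weighted_median,
)
from .instruments import (
    DEFAULT_CLUMP_R2,
    DEFAULT_CLUMP_WINDOW_BP,
    GWAS_P_THRESHOLD,
    MIN_INSTRUMENTS,
    LDMatrix,
    instrument_strength,
    ld_clump,
    select_instruments,
)
from .mvmr import mediate, mvmr_fit
from .sumstats import (
    DEFAULT_PALINDROME_WINDOW,
    SummaryStats,
    harmonize,
    harmonize_many,
    read_sumstats,
)

logger = logging.getLogger(__name__)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    ``adjusted_(i) = min_{j >= rank(i)} p_(j) * m / j`` capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


@dataclass
class Thresholds:
    p_instrument: float = GWAS_P_THRESHOLD
    clump_r2: float = DEFAULT_CLUMP_R2
    clump_window_bp: int = DEFAULT_CLUMP_WINDOW_BP
    i2_exclude: float = 75.0
    fdr_level: float = 0.05
    egger_intercept_alpha: float = 0.05
    palindrome_eaf_window: float = DEFAULT_PALINDROME_WINDOW
    n_boot: int = 1000

    def validate(self) -> None:
        if not (0 < self.p_instrument < 1):
            raise ValueError("p_instrument must be in (0, 1)")
        if not (0 < self.clump_r2 <= 1):
            raise ValueError("clump_r2 must be in (0, 1]")
        if not (0 <= self.i2_exclude <= 100):
            raise ValueError("i2_exclude must be in [0, 100]")
        for name in ("fdr_level", "egger_intercept_alpha"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if not (0 <= self.palindrome_eaf_window < 0.5):
            raise ValueError("palindrome_eaf_window must be in [0, 0.5)")


@dataclass
class TraitSpec:
    name: str
    trait_type: str  # binary | continuous
    path: str | None = None
    schema: dict = field(default_factory=dict)
    sep: str | None = None


@dataclass
class RunConfig:
    traits: dict[str, TraitSpec]
    exposures: list[str]
    mediators: list[str]
    outcomes: list[str]
    thresholds: Thresholds = field(default_factory=Thresholds)
    ld_path: str | None = None
    seed: int = 0
    output_dir: str = "."
    force_sensitivity: bool = False

    def validate(self) -> None:
        self.thresholds.validate()
        roles = set(self.exposures) | set(self.mediators) | set(self.outcomes)
        unknown = roles - set(self.traits)
        if unknown:
            raise ValueError(f"analysis graph references unknown traits: {sorted(unknown)}")
        if set(self.outcomes) & set(self.exposures):
            raise ValueError("a trait cannot be both exposure and outcome (cyclic graph)")
        for spec in self.traits.values():
            if spec.path is not None:
                import os
                if not os.path.exists(spec.path):
                    raise FileNotFoundError(spec.path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        traits = {
            name: TraitSpec(name=name, trait_type=spec["trait_type"],
                            path=spec.get("path"), schema=spec.get("schema", {}),
                            sep=spec.get("sep"))
            for name, spec in raw["traits"].items()
        }
        thresholds = Thresholds(**raw.get("thresholds", {}))
        cfg = cls(
            traits=traits,
            exposures=list(raw.get("exposures", [])),
            mediators=list(raw.get("mediators", [])),
            outcomes=list(raw.get("outcomes", [])),
            thresholds=thresholds,
            ld_path=raw.get("ld_path"),
            seed=int(raw.get("seed", 0)),
            output_dir=raw.get("output_dir", "."),
            force_sensitivity=bool(raw.get("force_sensitivity", False)),
        )
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def load_data(self) -> dict[str, SummaryStats]:
        data = {}
        for name, spec in self.traits.items():
            if spec.path is None:
                raise ValueError(f"trait {name} has no input path")
            data[name] = read_sumstats(spec.path, spec.schema, name,
                                       spec.trait_type, sep=spec.sep)
        return data


@dataclass
class PairResult:
    exposure: str
    outcome: str
    status: str = "ok"  # ok | skipped | error
    reason: str = ""
    n_snp: int = 0
    results: dict[str, MRResult] = field(default_factory=dict)
    primary: MRResult | None = None
    rationale: str = ""
    raw_p: float = float("nan")
    fdr_p: float = float("nan")
    significant: bool = False
    strength: object = None
    leave_one_out: list = field(default_factory=list)
    bidirectional: MRResult | None = None
    bidirectional_error: str = ""
    steiger_refit: MRResult | None = None
    steiger_n_removed: int = 0


@dataclass
class ScreenReport:
    pairs: list[PairResult]
    provenance: dict = field(default_factory=dict)

    def get(self, exposure: str, outcome: str) -> PairResult:
        for pr in self.pairs:
            if pr.exposure == exposure and pr.outcome == outcome:
                return pr
        raise KeyError((exposure, outcome))


def _median_n(ss: SummaryStats) -> float:
    return float(ss.table["n"].median())


def _fit_pair(exposure: SummaryStats, outcome: SummaryStats,
              ld: LDMatrix | None, thr: Thresholds, seed: int) -> PairResult:
    pr = PairResult(exposure.trait_name, outcome.trait_name)
    candidates = select_instruments(exposure, thr.p_instrument)
    if ld is not None and not candidates.empty:
        candidates = ld_clump(candidates, ld, thr.clump_r2, thr.clump_window_bp)
    if len(candidates) < MIN_INSTRUMENTS:
        pr.status = "skipped"
        pr.reason = (f"insufficient instruments: {len(candidates)} < {MIN_INSTRUMENTS}")
        return pr
    instrumented = SummaryStats(
        exposure.trait_name, exposure.trait_type, exposure.effect_scale, candidates)
    try:
        hset = harmonize(instrumented, outcome, thr.palindrome_eaf_window)
    except Exception as exc:  # noqa: BLE001 - recorded per pair
        pr.status = "error"
        pr.reason = f"harmonization failed: {exc}"
        return pr
    if len(hset) < MIN_INSTRUMENTS:
        pr.status = "skipped"
        pr.reason = f"insufficient harmonized instruments: {len(hset)}"
        return pr
    pr.n_snp = len(hset)
    pr._hset = hset  # kept for conditional sensitivity stages
    try:
        pr.results["ivw"] = ivw(hset)
        pr.results["egger"] = egger(hset)
        pr.results["weighted_median"] = weighted_median(hset, thr.n_boot, seed)
        pr.results["contamination_mixture"] = contamination_mixture(hset)
    except Exception as exc:  # noqa: BLE001
        pr.status = "error"
        pr.reason = f"estimation failed: {exc}"
        return pr
    pr.primary, pr.rationale = select_primary_estimate(
        pr.results["ivw"], pr.results["egger"])
    pr.raw_p = pr.results["ivw"].p
    if exposure.trait_type == "continuous":
        try:
            pr.strength = instrument_strength(
                hset.beta_exposure, hset.maf, _median_n(outcome))
        except ValueError as exc:
            logger.warning("%s -> %s: instrument strength unavailable: %s",
                           pr.exposure, pr.outcome, exc)
    return pr


def run_univariable_screen(
    data: dict[str, SummaryStats],
    pairs: list[tuple[str, str]],
    ld: LDMatrix | None = None,
    thresholds: Thresholds | None = None,
    seed: int = 0,
    force_sensitivity: bool = False,
) -> ScreenReport:
    """Screen every (exposure, outcome) pair with IVW + sensitivity
    estimators, BH-FDR per outcome family, bidirectional MR, and conditional
    leave-one-out / Steiger-filtered re-estimates."""
    thr = thresholds or Thresholds()
    thr.validate()
    results = [
        _fit_pair(data[exp], data[out], ld, thr, seed) for exp, out in pairs
    ]

    # FDR family: all IVW p-values sharing an outcome
    by_outcome: dict[str, list[PairResult]] = {}
    for pr in results:
        if pr.status == "ok":
            by_outcome.setdefault(pr.outcome, []).append(pr)
    for family in by_outcome.values():
        adj = bh_fdr([pr.raw_p for pr in family])
        for pr, a in zip(family, adj):
            pr.fdr_p = float(a)
            pr.significant = a < thr.fdr_level

    for pr in results:
        if pr.status != "ok":
            continue
        exposure, outcome = data[pr.exposure], data[pr.outcome]
        # bidirectional (outcome -> exposure)
        try:
            rev = _fit_pair(outcome, exposure, ld, thr, seed)
            if rev.status == "ok":
                pr.bidirectional = rev.results["ivw"]
            else:
                pr.bidirectional_error = rev.reason
        except Exception as exc:  # noqa: BLE001
            pr.bidirectional_error = str(exc)

        hset = pr._hset
        st = steiger(hset, _median_n(exposure), _median_n(outcome),
                     exposure_binary=exposure.trait_type == "binary",
                     outcome_binary=outcome.trait_type == "binary")
        direction_indicates = not bool(st.direction_correct.all())
        if pr.significant or force_sensitivity:
            pr.leave_one_out = leave_one_out(hset)
        if pr.significant or direction_indicates or force_sensitivity:
            pr.steiger_n_removed = int((~st.direction_correct).sum())
            if len(st.retained) >= 2:
                pr.steiger_refit = ivw(st.retained)
    report = ScreenReport(results)
    return report


@dataclass
class AnalysisBundle:
    screen_exposure_outcome: ScreenReport
    screen_mediator_outcome: ScreenReport
    screen_exposure_mediator: ScreenReport | None
    mvmr_results: dict
    mediation_results: dict
    provenance: dict


def run_full_analysis(
    config: RunConfig,
    data: dict[str, SummaryStats] | None = None,
    ld: LDMatrix | None = None,
) -> AnalysisBundle:
    """Exposure->outcome screen, mediator->outcome screen, and — for
    mediators with a significant outcome effect — exposure->mediator MR,
    multivariable MR (exposure + mediator on outcome) and mediation
    decomposition."""
    config.validate()
    if data is None:
        data = config.load_data()
    if ld is None and config.ld_path:
        ld = LDMatrix.from_square_tsv(config.ld_path)
    thr = config.thresholds
    seed = config.seed

    q2_pairs = [(e, o) for e in config.exposures for o in config.outcomes]
    q2 = run_univariable_screen(data, q2_pairs, ld, thr, seed,
                                config.force_sensitivity)
    q3_pairs = [(m, o) for m in config.mediators for o in config.outcomes]
    q3 = run_univariable_screen(data, q3_pairs, ld, thr, seed,
                                config.force_sensitivity) if q3_pairs else ScreenReport([])

    passing_mediators = sorted({pr.exposure for pr in q3.pairs if pr.significant})
    q4 = None
    mvmr_results: dict = {}
    mediation_results: dict = {}
    if passing_mediators:
        q4_pairs = [(e, m) for e in config.exposures for m in passing_mediators]
        q4 = run_univariable_screen(data, q4_pairs, ld, thr, seed,
                                    config.force_sensitivity)
        for exp_name in config.exposures:
            for med_name in passing_mediators:
                for out_name in config.outcomes:
                    key = (exp_name, med_name, out_name)
                    try:
                        mvmr_res, med_res = _mediation_stage(
                            data[exp_name], data[med_name], data[out_name],
                            q2.get(exp_name, out_name),
                            q4.get(exp_name, med_name), ld, thr)
                    except Exception as exc:  # noqa: BLE001
                        logger.warning("mediation %s skipped: %s", key, exc)
                        continue
                    mvmr_results[key] = mvmr_res
                    mediation_results[key] = med_res
    else:
        logger.info("no mediator passed the outcome screen; mediation stage skipped")

    provenance = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": config.config_hash(),
        "n_pairs_q2": len(q2.pairs),
        "n_pairs_q3": len(q3.pairs),
        "mediators_passing_q3": passing_mediators,
    }
    q2.provenance = provenance
    return AnalysisBundle(q2, q3, q4, mvmr_results, mediation_results, provenance)


def _mediation_stage(exposure, mediator, outcome, total_pair: PairResult,
                     a_pair: PairResult, ld, thr: Thresholds):
    """MVMR of exposure + mediator on the outcome over the union of
    instrument sets, then product-method mediation."""
    if total_pair.status != "ok" or a_pair.status != "ok":
        raise ValueError("total-effect or A-path MR unavailable")
    sel_exp = select_instruments(exposure, thr.p_instrument)
    sel_med = select_instruments(mediator, thr.p_instrument)
    union_ids = sorted(set(sel_exp["variant_id"]) | set(sel_med["variant_id"]))
    import pandas as pd
    union = pd.concat([exposure.table, mediator.table])
    union = union.loc[union["variant_id"].isin(union_ids)]
    union = union.drop_duplicates("variant_id")
    if ld is not None:
        # re-clump jointly on the best per-variant p across source traits
        best_p = pd.concat([sel_exp, sel_med]).groupby("variant_id")["p_value"].min()
        union = union.assign(p_value=union["variant_id"].map(best_p))
        union = ld_clump(union, ld, thr.clump_r2, thr.clump_window_bp)
        union_ids = list(union["variant_id"])

    def _restrict(ss):
        sub = ss.table.loc[ss.table["variant_id"].isin(union_ids)]
        return SummaryStats(ss.trait_name, ss.trait_type, ss.effect_scale, sub)

    hset = harmonize_many([_restrict(exposure), _restrict(mediator)],
                          _restrict(outcome), thr.palindrome_eaf_window)
    mv = mvmr_fit(hset)
    b_path = mv[mediator.trait_name]
    c_prime = mv[exposure.trait_name]
    med = mediate(
        total_pair.results["ivw"],
        a_pair.results["ivw"],
        (b_path.estimate, b_path.se),
        mvmr_direct=(c_prime.estimate, c_prime.se),
    )
    return mv, med
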