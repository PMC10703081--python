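"""GWAS summary-statistics containers, I/O and allele harmonization.

Effect sizes are kept on an additive scale throughout: log-odds for binary
traits, standard-deviation units for continuous traits.  Odds-ratio columns
are converted at read time.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: canonical column order for the internal summary-statistics table
SUMSTATS_COLUMNS = [
    "variant_id", "chromosome", "position", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p_value", "n", "n_case", "n_control",
]


class SchemaError(ValueError):
    """A mandatory column is missing from the input table."""


class HarmonizationError(ValueError):
    """No variant can be reconciled between the trait sets."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association record for one trait in one cohort."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p_value: float
    n: float
    n_case: float | None = None
    n_control: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect allele equals other allele")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be positive, got {self.se}")
        if not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.variant_id}: eaf outside [0, 1]: {self.eaf}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"{self.variant_id}: p_value outside (0, 1]: {self.p_value}")
        if self.n_case is not None and self.n_control is not None:
            if self.n_case + self.n_control != self.n:
                raise ValueError(f"{self.variant_id}: n_case + n_control != n")


@dataclass
class SummaryStats:
    """A keyed collection of variant associations for one trait.

    Parameters
    ----------
    trait_name:
        Label used in reports and harmonized column names.
    trait_type:
        ``"binary"`` or ``"continuous"``.
    effect_scale:
        ``"log_odds"`` for binary traits, ``"sd_units"`` for continuous.
    table:
        DataFrame with (at least) the :data:`SUMSTATS_COLUMNS`, one row per
        variant, unique ``variant_id``.
    """

    trait_name: str
    trait_type: str
    effect_scale: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        expected = "log_odds" if self.trait_type == "binary" else "sd_units"
        if self.effect_scale != expected:
            raise ValueError(
                f"{self.trait_name}: trait_type {self.trait_type!r} requires "
                f"effect_scale {expected!r}, got {self.effect_scale!r}"
            )
        if self.table["variant_id"].duplicated().any():
            dups = self.table.loc[self.table["variant_id"].duplicated(), "variant_id"]
            raise ValueError(f"duplicate variant ids: {sorted(set(dups))[:5]}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in set(self.table["variant_id"])

    def get(self, variant_id: str) -> VariantAssociation:
        row = self.table.loc[self.table["variant_id"] == variant_id]
        if row.empty:
            raise KeyError(variant_id)
        return _row_to_record(row.iloc[0])

    @property
    def records(self) -> dict[str, VariantAssociation]:
        return {r.variant_id: r for r in map(_row_to_record, self.table.to_dict("records"))}

    @classmethod
    def from_records(
        cls, trait_name: str, trait_type: str, records: Iterable[VariantAssociation]
    ) -> "SummaryStats":
        scale = "log_odds" if trait_type == "binary" else "sd_units"
        rows = [vars(r) if not isinstance(r, dict) else r for r in records]
        table = pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)
        return cls(trait_name, trait_type, scale, table)


def _row_to_record(row) -> VariantAssociation:
    if isinstance(row, pd.Series):
        row = row.to_dict()
    n_case = row.get("n_case")
    n_control = row.get("n_control")
    return VariantAssociation(
        variant_id=str(row["variant_id"]),
        chromosome=str(row["chromosome"]),
        position=int(row["position"]),
        effect_allele=str(row["effect_allele"]),
        other_allele=str(row["other_allele"]),
        eaf=float(row["eaf"]),
        beta=float(row["beta"]),
        se=float(row["se"]),
        p_value=float(row["p_value"]),
        n=float(row["n"]),
        n_case=None if n_case is None or pd.isna(n_case) else float(n_case),
        n_control=None if n_control is None or pd.isna(n_control) else float(n_control),
    )


# ---------------------------------------------------------------------------
# reading / writing


def se_from_or_ci(
    or_point: float, ci_lower: float, ci_upper: float, level: float = 0.95
) -> tuple[float, float]:
    """Recover (beta, se) on the log-odds scale from an OR and its CI.

    ``beta = ln(OR)``; ``se = (ln U - ln L) / (2 z)`` with ``z`` the
    standard-normal quantile at ``(1 + level) / 2``.
    """
    if min(or_point, ci_lower, ci_upper) <= 0:
        raise ValueError("odds ratios and CI bounds must be positive")
    if not (ci_lower <= or_point <= ci_upper):
        raise ValueError("require ci_lower <= or_point <= ci_upper")
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must be in (0, 1)")
    z = stats.norm.ppf((1.0 + level) / 2.0)
    beta = math.log(or_point)
    se = (math.log(ci_upper) - math.log(ci_lower)) / (2.0 * z)
    return beta, se


def read_sumstats(
    path,
    schema: Mapping[str, str],
    trait_name: str,
    trait_type: str,
    sep: str | None = None,
) -> SummaryStats:
    """Read a delimited summary-statistics table into a :class:`SummaryStats`.

    ``schema`` maps internal field names to column names in the file.
    Mandatory fields: variant_id, chromosome, position, effect_allele,
    other_allele, eaf, se, p_value, n, and one of beta / or.  Rows failing
    record invariants are dropped with a logged count; if more than half of
    the rows are rejected the whole file is refused.
    """
    mandatory = ["variant_id", "chromosome", "position", "effect_allele",
                 "other_allele", "eaf", "se", "p_value", "n"]
    if "beta" not in schema and "or" not in schema:
        raise SchemaError("schema must map either 'beta' or 'or'")
    raw = pd.read_csv(path, sep=sep, engine="python")
    missing = [schema[f] for f in mandatory + [k for k in ("beta", "or", "n_case", "n_control") if k in schema]
               if f in schema and schema[f] not in raw.columns]
    absent = [f for f in mandatory if f not in schema]
    if absent:
        raise SchemaError(f"schema missing mandatory fields: {absent}")
    if missing:
        raise SchemaError(f"mapped columns not found in file: {missing}")

    df = pd.DataFrame({f: raw[schema[f]] for f in schema})
    numeric = ["position", "eaf", "se", "p_value", "n"]
    numeric += ["beta"] if "beta" in df else []
    numeric += ["or"] if "or" in df else []
    numeric += [c for c in ("n_case", "n_control") if c in df]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "or" in df:
        with np.errstate(divide="ignore", invalid="ignore"):
            df["beta"] = np.log(df["or"].where(df["or"] > 0))
        df = df.drop(columns=["or"])
    for col in ("n_case", "n_control"):
        if col not in df:
            df[col] = np.nan

    ok = (
        df[["variant_id", "position", "eaf", "beta", "se", "p_value", "n"]].notna().all(axis=1)
        & (df["effect_allele"].astype(str) != df["other_allele"].astype(str))
        & (df["se"] > 0)
        & df["eaf"].between(0.0, 1.0)
        & (df["p_value"] > 0.0) & (df["p_value"] <= 1.0)
    )
    has_counts = df["n_case"].notna() & df["n_control"].notna()
    ok &= ~has_counts | (df["n_case"] + df["n_control"] == df["n"])

    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("%s: rejected %d/%d rows failing validation", path, n_rejected, len(df))
    if len(df) and n_rejected > 0.5 * len(df):
        raise ValueError(f"{path}: more than 50% of rows rejected ({n_rejected}/{len(df)})")

    clean = df.loc[ok].copy()
    clean["variant_id"] = clean["variant_id"].astype(str)
    clean["chromosome"] = clean["chromosome"].astype(str)
    clean["position"] = clean["position"].astype(int)
    for allele_col in ("effect_allele", "other_allele"):
        clean[allele_col] = clean[allele_col].astype(str).str.upper()
    scale = "log_odds" if trait_type == "binary" else "sd_units"
    ss = SummaryStats(trait_name, trait_type, scale, clean[SUMSTATS_COLUMNS])
    ss.n_rejected = n_rejected  # type: ignore[attr-defined]
    return ss


def write_sumstats(ss: SummaryStats, path, sep: str = "\t") -> None:
    ss.table.to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# harmonization

#: palindrome_eaf_window default; common ambiguous palindromes are dropped
DEFAULT_PALINDROME_WINDOW = 0.08


@dataclass
class HarmonizedInstrumentSet:
    """Per-SNP aligned effects across one or more exposures and an outcome.

    ``table`` columns: ``variant_id``, per-exposure ``beta_exp__<name>`` /
    ``se_exp__<name>`` / ``eaf_exp__<name>``, ``beta_outcome``,
    ``se_outcome``, ``eaf_outcome``, ``maf``, ``action``.
    ``actions`` records every input SNP (including dropped ones).
    """

    exposure_names: list[str]
    outcome_name: str
    table: pd.DataFrame = field(repr=False)
    actions: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.actions is None:
            self.actions = self.table[["variant_id", "action"]].copy()
        dropped = self.table["action"].astype(str).str.startswith("dropped")
        if dropped.any():
            raise ValueError("retained set contains dropped SNPs")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def primary_exposure(self) -> str:
        return self.exposure_names[0]

    def exposure_effects(self, name: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        name = name or self.primary_exposure
        return (
            self.table[f"beta_exp__{name}"].to_numpy(float),
            self.table[f"se_exp__{name}"].to_numpy(float),
        )

    @property
    def beta_exposure(self) -> np.ndarray:
        return self.exposure_effects()[0]

    @property
    def se_exposure(self) -> np.ndarray:
        return self.exposure_effects()[1]

    @property
    def beta_outcome(self) -> np.ndarray:
        return self.table["beta_outcome"].to_numpy(float)

    @property
    def se_outcome(self) -> np.ndarray:
        return self.table["se_outcome"].to_numpy(float)

    @property
    def maf(self) -> np.ndarray:
        return self.table["maf"].to_numpy(float)

    def subset(self, mask) -> "HarmonizedInstrumentSet":
        return HarmonizedInstrumentSet(
            list(self.exposure_names),
            self.outcome_name,
            self.table.loc[mask].reset_index(drop=True),
            self.actions,
        )


def _is_palindromic(ea: str, oa: str) -> bool:
    return (ea, oa) in PALINDROMIC_PAIRS


def _alleles_match(ea1, oa1, ea2, oa2) -> str:
    """Classify allele configuration: same / swapped / strand / strand_swapped / mismatch."""
    if (ea1, oa1) == (ea2, oa2):
        return "same"
    if (ea1, oa1) == (oa2, ea2):
        return "swapped"
    c_ea2 = COMPLEMENT.get(ea2)
    c_oa2 = COMPLEMENT.get(oa2)
    if c_ea2 is None or c_oa2 is None:
        return "mismatch"
    if (ea1, oa1) == (c_ea2, c_oa2):
        return "strand"
    if (ea1, oa1) == (c_oa2, c_ea2):
        return "strand_swapped"
    return "mismatch"


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_WINDOW,
) -> HarmonizedInstrumentSet:
    """Align outcome effect alleles to the exposure's.

    Matching alleles are kept; swapped alleles flip the outcome beta and
    complement its EAF; palindromic SNPs are resolved from allele
    frequencies when both traits' EAFs are farther than
    ``palindrome_eaf_window`` from 0.5, otherwise dropped; irreconcilable
    or indel/multi-allelic records are dropped.
    """
    return harmonize_many([exposure], outcome, palindrome_eaf_window)


def harmonize_many(
    exposures: Sequence[SummaryStats],
    outcome: SummaryStats,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_WINDOW,
) -> HarmonizedInstrumentSet:
    """Harmonize several exposures (and/or mediators) plus an outcome.

    The first exposure provides the reference allele orientation; every
    retained SNP must be present in all trait sets.
    """
    if not exposures or not len(outcome):
        raise HarmonizationError("empty input summary statistics")
    if not (0.0 <= palindrome_eaf_window < 0.5):
        raise ValueError("palindrome_eaf_window must be in [0, 0.5)")
    for ss in exposures:
        if not len(ss):
            raise HarmonizationError("empty input summary statistics")

    ref = exposures[0]
    tables = {ss.trait_name: ss.table.set_index("variant_id") for ss in exposures}
    out_table = outcome.table.set_index("variant_id")
    common = set(ref.table["variant_id"])
    for t in tables.values():
        common &= set(t.index)
    common &= set(out_table.index)
    if not common:
        raise HarmonizationError("no shared variant ids between trait sets")

    order = [v for v in ref.table["variant_id"] if v in common]
    rows, action_rows = [], []
    for vid in order:
        ref_rec = tables[ref.trait_name].loc[vid]
        ea, oa = str(ref_rec["effect_allele"]), str(ref_rec["other_allele"])
        action = "kept"
        if len(ea) != 1 or len(oa) != 1 or ea not in COMPLEMENT or oa not in COMPLEMENT:
            action_rows.append((vid, "dropped_mismatch"))
            logger.info("%s: indel/non-ACGT alleles dropped at harmonization", vid)
            continue

        row = {"variant_id": vid, "chromosome": str(ref_rec["chromosome"]),
               "position": int(ref_rec["position"])}
        palindromic = _is_palindromic(ea, oa)
        ok = True
        for i, ss in enumerate(exposures):
            rec = tables[ss.trait_name].loc[vid]
            aligned = _align_record(rec, ea, oa, palindromic, palindrome_eaf_window,
                                    ref_eaf=float(ref_rec["eaf"]), is_reference=(i == 0))
            if aligned is None:
                ok = False
                break
            beta, se, eaf, act = aligned
            row[f"beta_exp__{ss.trait_name}"] = beta
            row[f"se_exp__{ss.trait_name}"] = se
            row[f"eaf_exp__{ss.trait_name}"] = eaf
            action = _merge_action(action, act)
        if ok:
            aligned = _align_record(out_table.loc[vid], ea, oa, palindromic,
                                    palindrome_eaf_window, ref_eaf=float(ref_rec["eaf"]))
            if aligned is None:
                ok = False
            else:
                beta, se, eaf, act = aligned
                row["beta_outcome"] = beta
                row["se_outcome"] = se
                row["eaf_outcome"] = eaf
                action = _merge_action(action, act)
        if not ok:
            reason = "dropped_palindrome" if palindromic else "dropped_mismatch"
            action_rows.append((vid, reason))
            continue
        ref_eaf = float(ref_rec["eaf"])
        row["maf"] = min(ref_eaf, 1.0 - ref_eaf)
        row["effect_allele"] = ea
        row["other_allele"] = oa
        row["action"] = action
        rows.append(row)
        action_rows.append((vid, action))

    actions = pd.DataFrame(action_rows, columns=["variant_id", "action"])
    if not rows:
        raise HarmonizationError("harmonization retained no SNPs")
    table = pd.DataFrame(rows)
    return HarmonizedInstrumentSet(
        [ss.trait_name for ss in exposures], outcome.trait_name, table, actions
    )


def _merge_action(current: str, new: str) -> str:
    rank = {"kept": 0, "flipped": 1, "palindrome_inferred": 2}
    return current if rank[current] >= rank[new] else new


def _align_record(rec, ref_ea, ref_oa, palindromic, window, ref_eaf, is_reference=False):
    """Return (beta, se, eaf, action) for one record aligned to the reference
    alleles, or None when the SNP must be dropped."""
    ea, oa = str(rec["effect_allele"]), str(rec["other_allele"])
    beta, se, eaf = float(rec["beta"]), float(rec["se"]), float(rec["eaf"])
    config = _alleles_match(ref_ea, ref_oa, ea, oa)
    if config == "mismatch":
        return None
    # nominal alignment; for palindromes "strand"/"strand_swapped" coincide
    # with "swapped"/"same" so the eaf check below is the real arbiter
    if config in ("swapped", "strand_swapped") and not (palindromic and config == "strand_swapped"):
        beta, eaf = -beta, 1.0 - eaf
        action = "flipped"
    elif config == "strand" and not palindromic:
        action = "kept"  # strand flip, same orientation
    else:
        action = "kept"
    if palindromic:
        if config == "swapped":  # nominally swapped: already flipped above
            pass
        if is_reference:
            if abs(ref_eaf - 0.5) <= window:
                return None
            return beta, se, eaf, "palindrome_inferred"
        if abs(eaf - 0.5) <= window or abs(ref_eaf - 0.5) <= window:
            return None
        same_strand = (eaf < 0.5) == (ref_eaf < 0.5)
        if not same_strand:
            beta, eaf = -beta, 1.0 - eaf
        return beta, se, eaf, "palindrome_inferred"
    return beta, se, eaf, action


# ---------------------------------------------------------------------------
# results table


def format_or(value: float) -> str:
    """Format an odds ratio to at most two decimals, trimming zeros."""
    return f"{round(value, 2):g}"


def format_or_ci(or_point: float, lo: float, hi: float) -> str:
    return f"{format_or(or_point)} ({format_or(lo)} to {format_or(hi)})"


def write_results(results: Sequence, path, run_report: dict | None = None) -> None:
    """Write MR results as a TSV plus a JSON run report alongside.

    Each element of ``results`` needs the MRResult interface (estimate, se,
    ci bounds, p, n_snp, heterogeneity and Egger-intercept blocks) plus
    ``exposure`` / ``outcome`` attributes when available.
    """
    if not results:
        raise ValueError("no results to write")
    rows = []
    for r in results:
        est = r.estimate
        rows.append({
            "exposure": getattr(r, "exposure", ""),
            "outcome": getattr(r, "outcome", ""),
            "method": r.method,
            "n_snp": r.n_snp,
            "or_ci": format_or_ci(math.exp(est), math.exp(r.ci_lower), math.exp(r.ci_upper)),
            "estimate": est,
            "se": r.se,
            "ci_lower": r.ci_lower,
            "ci_upper": r.ci_upper,
            "p": r.p,
            "q": r.q,
            "q_df": r.q_df,
            "q_p": r.q_p,
            "intercept": r.intercept,
            "intercept_se": r.intercept_se,
            "intercept_p": r.intercept_p,
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    report_path = str(path) + ".report.json"
    with open(report_path, "w") as fh:
        json.dump({"n_results": len(rows), **(run_report or {})}, fh, indent=2)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
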