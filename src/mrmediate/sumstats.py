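"""GWAS summary-statistic containers, I/O, allele harmonization, genomic control.

Summary statistics are held as pandas DataFrames with one row per variant and
the canonical ten columns (``COLUMNS``).  Effect sizes for binary traits are
log-odds throughout; odds-ratio conversion happens only at reporting time.
Coordinates are 1-based inclusive and missing values serialize as ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, HarmonizationError, RowValidationError

log = logging.getLogger(__name__)

#: Canonical column order of a summary-statistic table.
COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "eaf", "pval", "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Median of the chi-square distribution with one degree of freedom,
#: the null reference for the genomic-control inflation factor.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.45493642311957174


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SummaryStatSet:
    """Per-variant association records for one trait.

    Parameters
    ----------
    trait_id
        Identifier of the trait (e.g. a gene symbol or GWAS accession).
    trait_type
        ``"continuous"`` or ``"binary"``.  For binary traits ``beta`` is a
        log odds ratio.
    records
        DataFrame with the columns in :data:`COLUMNS`, unique by
        ``variant_id``.  ``eaf`` may be NaN (missing); every other field is
        mandatory.
    """

    trait_id: str
    trait_type: str
    records: pd.DataFrame

    def __post_init__(self):
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous/binary, got {self.trait_type!r}")
        missing = [c for c in COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"records missing column(s): {', '.join(missing)}")
        if self.records["variant_id"].duplicated().any():
            dups = self.records.loc[self.records["variant_id"].duplicated(), "variant_id"]
            raise ValueError(f"duplicate variant_id(s): {', '.join(dups.astype(str).head(5))}")
        bad = ~_row_valid_mask(self.records)
        if bad.any():
            ids = self.records.loc[bad, "variant_id"].astype(str).head(5)
            raise ValueError(f"invalid record(s) for variant_id(s): {', '.join(ids)}")
        self.records = self.records.reset_index(drop=True)[COLUMNS]

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, variant_ids) -> "SummaryStatSet":
        """Restrict to the given variants, preserving record order."""
        keep = self.records["variant_id"].isin(set(variant_ids))
        return replace(self, records=self.records.loc[keep].reset_index(drop=True))


def _row_valid_mask(df: pd.DataFrame) -> pd.Series:
    """Row-level invariants: se > 0, alleles valid and distinct, pos >= 1,
    pval in (0, 1], n >= 1, eaf missing or in (0, 1)."""
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    ok = (
        np.isfinite(df["beta"])
        & np.isfinite(df["se"]) & (df["se"] > 0)
        & (df["pos"] >= 1)
        & (df["pval"] > 0) & (df["pval"] <= 1)
        & (df["n"] >= 1)
        & ea.isin(_COMPLEMENT) & oa.isin(_COMPLEMENT) & (ea != oa)
        & (df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)))
    )
    return ok


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_sumstats(path, trait_id: str, trait_type: str,
                  column_map: dict[str, str] | None = None) -> SummaryStatSet:
    """Read a tab-separated summary-statistic file.

    ``column_map`` maps file column names to the canonical names in
    :data:`COLUMNS` (``{"SNP": "variant_id", ...}``).  Rows violating the
    record invariants are dropped with a logged count; non-numeric beta/se
    raise :class:`RowValidationError` listing the offending variants.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    df = df[COLUMNS].copy()

    # beta/se must parse for every row; anything else unparseable is a
    # row-level invariant failure and is filtered below.
    for col in ("beta", "se"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            ids = df.loc[bad, "variant_id"].astype(str).tolist()
            raise RowValidationError(
                f"{path}: non-numeric {col} for variant_id(s): {', '.join(ids[:10])}",
                variant_ids=ids)
        df[col] = converted
    for col in ("pos", "eaf", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    parse_ok = df["pos"].notna() & df["pval"].notna() & df["n"].notna() & df["beta"].notna() & df["se"].notna()
    df = df.loc[parse_ok]
    df["pos"] = df["pos"].astype(int)
    df["n"] = df["n"].astype(int)

    valid = _row_valid_mask(df)
    n_rejected = int((~valid).sum()) + int((~parse_ok).sum())
    df = df.loc[valid]
    dup = df["variant_id"].duplicated()
    if dup.any():
        n_rejected += int(dup.sum())
        df = df.loc[~dup]
    if n_rejected:
        log.warning("%s: rejected %d invalid row(s)", path, n_rejected)
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    return SummaryStatSet(trait_id=trait_id, trait_type=trait_type,
                          records=df.reset_index(drop=True))


def write_sumstats(s: SummaryStatSet, path) -> str:
    """Write a tab-separated summary-statistic file; round-trips exactly.

    Floats are serialized with 17 significant digits so that re-reading
    reproduces them bit for bit; missing ``eaf`` is written as ``NA``.
    """
    out = s.records.copy()
    for col in ("beta", "se", "eaf", "pval"):
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else format(v, ".17g"))
    out.to_csv(path, sep="\t", index=False)
    return str(path)


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedPair:
    """Exposure and outcome effects aligned to a shared effect allele.

    ``rows`` carries one row per shared variant with the recorded ``action``
    (kept, flipped, dropped_palindromic, dropped_missing); dropped rows have
    their outcome effect fields set to NaN so they cannot leak downstream.
    """

    exposure_id: str
    outcome_id: str
    rows: pd.DataFrame

    ROW_COLUMNS = ["variant_id", "beta_exp", "se_exp", "eaf_exp", "pval_exp",
                   "n_exp", "beta_out", "se_out", "eaf_out", "n_out", "action"]

    def kept(self) -> pd.DataFrame:
        """Rows usable for estimation (actions kept/flipped)."""
        return self.rows.loc[self.rows["action"].isin(["kept", "flipped"])].reset_index(drop=True)

    @property
    def nsnp(self) -> int:
        return int(self.rows["action"].isin(["kept", "flipped"]).sum())


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return oa == ea.map(_COMPLEMENT)


def harmonize(exposure: SummaryStatSet, outcome: SummaryStatSet,
              palindromic_eaf_window: float = 0.08) -> HarmonizedPair:
    """Align outcome effects to the exposure effect allele.

    Shared variants with identical allele coding are kept as-is; swapped
    codings have the outcome beta sign-flipped and ``eaf`` complemented;
    strand-complement codings are complemented first and then resolved the
    same way.  Palindromic variants (A/T, G/C) are resolved by allele
    frequency: both frequencies must fall outside the ambiguous zone
    ``0.5 ± palindromic_eaf_window`` and lie on the same side of 0.5 once
    expressed for the exposure effect allele; otherwise the variant is
    dropped as unresolvable.
    """
    m = exposure.records.merge(outcome.records, on="variant_id",
                               suffixes=("_exp", "_out"), how="inner")
    if m.empty:
        raise HarmonizationError(
            f"no shared variants between {exposure.trait_id} and {outcome.trait_id}")

    ea_e, oa_e = m["effect_allele_exp"], m["other_allele_exp"]
    ea_o, oa_o = m["effect_allele_out"], m["other_allele_out"]
    pal = _is_palindromic(ea_e, oa_e)

    same = (ea_o == ea_e) & (oa_o == oa_e)
    swapped = (ea_o == oa_e) & (oa_o == ea_e)
    comp_same = (ea_o.map(_COMPLEMENT) == ea_e) & (oa_o.map(_COMPLEMENT) == oa_e)
    comp_swapped = (ea_o.map(_COMPLEMENT) == oa_e) & (oa_o.map(_COMPLEMENT) == ea_e)

    action = pd.Series("dropped_missing", index=m.index)  # allele-incompatible
    flip = pd.Series(False, index=m.index)

    # non-palindromic: direct or strand-complement match
    np_mask = ~pal
    action[np_mask & (same | comp_same)] = "kept"
    keep_flip = np_mask & ~(same | comp_same) & (swapped | comp_swapped)
    action[keep_flip] = "flipped"
    flip[keep_flip] = True

    # palindromic: the strand flip coincides with the allele swap, so only
    # the allele-frequency comparison is informative.
    pal_sameset = pal & (same | swapped)
    action[pal & ~(same | swapped)] = "dropped_missing"
    e1 = m["eaf_exp"]
    # outcome eaf expressed for the exposure effect allele (by letter)
    e2 = np.where(same, m["eaf_out"], 1.0 - m["eaf_out"])
    e2 = pd.Series(e2, index=m.index)
    lo, hi = 0.5 - palindromic_eaf_window, 0.5 + palindromic_eaf_window
    unambiguous = (
        e1.notna() & e2.notna()
        & ((e1 <= lo) | (e1 >= hi)) & ((e2 <= lo) | (e2 >= hi))
        & (np.sign(e1 - 0.5) == np.sign(e2 - 0.5))
    )
    action[pal_sameset & unambiguous & same] = "kept"
    pal_flip = pal_sameset & unambiguous & swapped
    action[pal_flip] = "flipped"
    flip[pal_flip] = True
    action[pal_sameset & ~unambiguous] = "dropped_palindromic"

    rows = pd.DataFrame({
        "variant_id": m["variant_id"],
        "beta_exp": m["beta_exp"], "se_exp": m["se_exp"],
        "eaf_exp": m["eaf_exp"], "pval_exp": m["pval_exp"], "n_exp": m["n_exp"],
        "beta_out": np.where(flip, -m["beta_out"], m["beta_out"]),
        "se_out": m["se_out"],
        "eaf_out": np.where(flip, 1.0 - m["eaf_out"], m["eaf_out"]),
        "n_out": m["n_out"],
        "action": action,
    })
    dropped = ~rows["action"].isin(["kept", "flipped"])
    rows.loc[dropped, ["beta_out", "se_out", "eaf_out"]] = np.nan
    return HarmonizedPair(exposure_id=exposure.trait_id, outcome_id=outcome.trait_id,
                          rows=rows.reset_index(drop=True))


# ---------------------------------------------------------------------------
# genomic control
# ---------------------------------------------------------------------------

def genomic_control_adjust(s: SummaryStatSet) -> tuple[SummaryStatSet, float]:
    """Apply genomic-control inflation correction to one trait's statistics.

    The inflation factor is lambda_GC = median((beta/se)^2) / 0.4549364,
    the observed median chi-square over its null median.  When lambda_GC > 1
    every standard error is multiplied by sqrt(lambda_GC) and the p-value is
    recomputed from the deflated z-score; genomic control never deflates
    (lambda_GC <= 1 returns the set unchanged).
    """
    df = s.records
    chi2 = (df["beta"] / df["se"]) ** 2
    chi2 = chi2[np.isfinite(chi2)]
    if chi2.empty:
        raise ValueError("genomic_control_adjust: no finite beta/se records")
    lam = float(np.median(chi2)) / CHI2_1_MEDIAN
    if lam <= 1.0:
        return s, lam
    out = df.copy()
    out["se"] = out["se"] * np.sqrt(lam)
    z = out["beta"] / out["se"]
    out["pval"] = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-300)
    return replace(s, records=out), lam
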