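"""Instrument selection: significance/frequency/strength filters, cis windows,
and greedy LD clumping.

Two different r-squared quantities live here and must not be confused: the
per-variant *instrument strength* R^2 = 2*(1-MAF)*MAF*beta^2 (held on the
InstrumentSet rows), and the *pairwise LD* correlation squared used by
clumping (held in the LDMatrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError
from .sumstats import SummaryStatSet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GeneRegion:
    """A gene footprint anchoring the cis window (1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class LDMatrix:
    """Pairwise LD correlations (r, not r^2) for a set of variants."""

    variant_ids: list
    r: np.ndarray

    def __post_init__(self):
        self.variant_ids = list(self.variant_ids)
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise ValueError(f"LD matrix shape {self.r.shape} != ({k}, {k})")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("LD correlations must lie in [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def r_between(self, a: str, b: str) -> float:
        try:
            return float(self.r[self._index[a], self._index[b]])
        except KeyError as exc:
            raise ContractError(f"variant {exc.args[0]} missing from LD matrix") from None

    def covers(self, variant_ids) -> list:
        """Return the subset of ``variant_ids`` absent from the matrix."""
        return [v for v in variant_ids if v not in self._index]


def read_ld_matrix(path) -> LDMatrix:
    """Square tab-separated LD matrix with variant_id header row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: LD matrix row and column variant ids differ")
    return LDMatrix(variant_ids=list(df.columns), r=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> str:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(path, sep="\t")
    return str(path)


def read_regions(path) -> dict[str, GeneRegion]:
    """BED-like 4-column TSV (gene_id, chrom, start, end), 1-based inclusive.

    Note the deliberate divergence from 0-based half-open BED: coordinates
    here match the 1-based convention of the summary-statistic tables.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    need = ["gene_id", "chrom", "start", "end"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    return {r.gene_id: GeneRegion(r.gene_id, str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples()}


def write_regions(regions, path) -> str:
    rows = [{"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end}
            for g in (regions.values() if isinstance(regions, dict) else regions)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return str(path)


@dataclass
class InstrumentSet:
    """Post-QC instruments with per-variant strength annotations.

    ``rows`` carries the summary-statistic columns plus ``r2_variant``
    (variance in the exposure explained by the variant) and ``f_stat``.
    """

    exposure_id: str
    rows: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def variant_ids(self) -> list:
        return self.rows["variant_id"].tolist()

    @property
    def total_r2(self) -> float:
        """Summed variance explained across the retained instruments."""
        return float(self.rows["r2_variant"].sum())


@dataclass
class InstrumentConfig:
    """Thresholds of the instrument-selection and clumping stage."""

    pval_max: float = 5e-8
    maf_min: float = 0.01
    f_min: float = 20.0
    cis_kb: int = 1000
    clump_r2: float = 0.1
    clump_kb: int = 10000


# ---------------------------------------------------------------------------
# per-variant strength
# ---------------------------------------------------------------------------

def variant_r2(eaf: float, beta: float) -> float:
    """Variance in the exposure explained by one variant: 2*(1-MAF)*MAF*beta^2.

    MAF is min(eaf, 1-eaf); for a standardized trait the value is bounded by
    beta^2/2 (attained at MAF = 0.5).
    """
    eaf = np.asarray(eaf, dtype=float)
    if np.any(eaf <= 0) or np.any(eaf >= 1):
        raise ValueError("eaf must lie strictly in (0, 1)")
    maf = np.minimum(eaf, 1.0 - eaf)
    out = 2.0 * (1.0 - maf) * maf * np.asarray(beta, dtype=float) ** 2
    return float(out) if out.ndim == 0 else out


def f_statistic(r2: float, n: int) -> float:
    """Instrument-strength F statistic: F = R^2 * (N - 2) / (1 - R^2)."""
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 < 0) or np.any(r2 >= 1):
        raise ValueError("r2 must lie in [0, 1)")
    n = np.asarray(n)
    if np.any(n < 3):
        raise ValueError("n must be >= 3")
    out = r2 * (n - 2) / (1.0 - r2)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# selection and clumping
# ---------------------------------------------------------------------------

def select_instruments(s: SummaryStatSet, region: GeneRegion | None = None,
                       pval_max: float = 5e-8, maf_min: float = 0.01,
                       f_min: float = 20.0, cis_kb: int = 1000) -> InstrumentSet:
    """Apply the four instrument filters and annotate per-variant strength.

    Retains variants with p < ``pval_max``, MAF > ``maf_min``, F >= ``f_min``
    and, when a ``region`` is given, position within ``cis_kb`` kilobases of
    the gene footprint (window inclusive at exactly +-cis_kb*1000 bp).
    Variants without an allele frequency cannot be strength-annotated and are
    excluded.  An empty result is a warning, not an error.
    """
    df = s.records.copy()
    has_eaf = df["eaf"].notna()
    if (~has_eaf).any():
        log.warning("%s: %d variant(s) without eaf excluded from instrument selection",
                    s.trait_id, int((~has_eaf).sum()))
    df = df.loc[has_eaf].copy()
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    df["r2_variant"] = 2.0 * (1.0 - maf) * maf * df["beta"] ** 2
    df["f_stat"] = df["r2_variant"] * (df["n"] - 2) / (1.0 - df["r2_variant"])
    keep = (df["pval"] < pval_max) & (maf > maf_min) & (df["f_stat"] >= f_min)
    if region is not None:
        pad = cis_kb * 1000
        keep &= (df["chrom"].astype(str) == str(region.chrom)) \
            & (df["pos"] >= region.start - pad) & (df["pos"] <= region.end + pad)
    out = df.loc[keep].reset_index(drop=True)
    if out.empty:
        log.warning("%s: no variants pass instrument selection", s.trait_id)
    return InstrumentSet(exposure_id=s.trait_id, rows=out)


def ld_clump(inst: InstrumentSet, ld: LDMatrix, r2_max: float = 0.1,
             window_kb: int = 10000) -> InstrumentSet:
    """Greedy p-value LD clumping.

    Repeatedly keep the remaining variant with the smallest p-value (ties
    broken by larger F statistic, then lexicographic variant_id) and discard
    every remaining variant on the same chromosome within ``window_kb``
    kilobases whose squared LD correlation with it is >= ``r2_max``.  The
    returned rows follow selection order.
    """
    missing = ld.covers(inst.variant_ids)
    if missing:
        raise ContractError(f"variant(s) missing from LD matrix: {', '.join(missing[:5])}")
    df = inst.rows
    order = df.assign(_neg_f=-df["f_stat"]).sort_values(
        ["pval", "_neg_f", "variant_id"], kind="mergesort").index.tolist()
    window = window_kb * 1000
    alive = set(order)
    kept_idx = []
    for i in order:
        if i not in alive:
            continue
        kept_idx.append(i)
        alive.discard(i)
        vi, ci, pi = df.at[i, "variant_id"], str(df.at[i, "chrom"]), df.at[i, "pos"]
        for j in list(alive):
            if str(df.at[j, "chrom"]) != ci or abs(df.at[j, "pos"] - pi) > window:
                continue
            if ld.r_between(vi, df.at[j, "variant_id"]) ** 2 >= r2_max:
                alive.discard(j)
    return InstrumentSet(exposure_id=inst.exposure_id,
                         rows=df.loc[kept_idx].reset_index(drop=True))
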