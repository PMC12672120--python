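"""Synthetic GWAS summary-statistic generator with known causal truth.

Generates matched exposure / mediator / outcome summary statistics for a
single cis region under the linear structural model

    mediator = beta1 * exposure + ...
    logit outcome = direct * exposure + beta2 * mediator + ...

so each variant's true outcome effect is gamma_j * (direct + beta1*beta2)
plus any planted pleiotropy, and the implied total effect obeys
total = direct + beta1*beta2 exactly (path tracing).  Summary statistics
are generated directly — no individual-level genotypes — with per-variant
standard errors from the standard GWAS approximations:

    se_exp = 1/sqrt(n * 2*maf*(1-maf))                     (continuous)
    se_out = 1/sqrt(n * phi*(1-phi) * 2*maf*(1-maf))       (binary, logistic score)

Observed effects are drawn independently per variant around their truth;
the AR(1) LD matrix feeds clumping only.  Everything is reproducible from
the single config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
import pandas as pd

from .instruments import GeneRegion, LDMatrix
from .sumstats import COLUMNS, SummaryStatSet

#: FinnGen R11 delirium preset as reported in the source cohort's abstract
#: (1,083 cases / 445,828 controls).
FINNGEN_ABSTRACT = {"n_out": 446911, "case_fraction": 1083 / 446911}
#: Alternative preset matching the cohort summary table
#: (3,827 cases / 428,053 controls).
FINNGEN_TABLE = {"n_out": 431880, "case_fraction": 3827 / 431880}

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class PleiotropyConfig:
    """Direct variant->outcome pleiotropy planted on invalid instruments.

    mode: "none" (all instruments valid), "balanced" (zero-mean effects,
    InSIDE holds, IVW unbiased but overdispersed) or "directional"
    (mean-shifted effects biasing IVW; the Egger intercept targets the mean).
    ``invalid_fraction`` of the variants receive a draw.
    """

    mode: str = "none"
    sd: float = 0.0
    mean: float = 0.0
    invalid_fraction: float = 0.0

    def __post_init__(self):
        if self.mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.mode!r}")
        if self.sd < 0 or not (0 <= self.invalid_fraction <= 1):
            raise ValueError("pleiotropy sd must be >= 0 and invalid_fraction in [0, 1]")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic exposure/mediator/outcome triple.

    Sample sizes default to the emulated designs: a blood cis-eQTL exposure
    panel (n = 31,684), a small CSF metabolite GWAS (n = 291), and a large,
    heavily imbalanced binary outcome (n = 431,880, case fraction 0.0025).
    ``strong_fraction`` of the variants receive a guaranteed-strong exposure
    effect of magnitude ``strong_effect`` (plus the N(0, instrument_effect_sd^2)
    background) so that genome-wide-significant instruments always exist.
    A disjoint ``med_strong_fraction`` of the variants are mediator QTLs with
    direct mediator effects of magnitude ``med_strong_effect``; these are the
    mediator's own instruments (their outcome effect flows through beta2),
    without which the mediator -> outcome step would be unidentifiable.  The
    large default magnitude emulates the outsized metabolite-QTL effects that
    let even a 291-sample metabolite GWAS yield significant instruments.
    """

    n_variants: int = 100
    maf_range: tuple = (0.05, 0.5)
    n_exp: int = 31684
    n_med: int = 291
    n_out: int = 431880
    case_fraction: float = 0.0025
    beta1_true: float = 0.3
    beta2_true: float = 0.4
    direct_true: float = 0.08
    instrument_effect_sd: float = 0.02
    strong_fraction: float = 0.5
    strong_effect: float = 0.15
    med_strong_fraction: float = 0.3
    med_strong_effect: float = 0.8
    mediator_pleiotropy_sd: float = 0.0
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.pleiotropy, dict):
            self.pleiotropy = PleiotropyConfig(**self.pleiotropy)
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0, 1)")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.instrument_effect_sd < 0 or self.mediator_pleiotropy_sd < 0:
            raise ValueError("effect sds must be >= 0")
        if min(self.n_exp, self.n_med, self.n_out, self.n_variants) < 1:
            raise ValueError("sizes must be positive")
        if not (0 <= self.strong_fraction <= 1 and 0 <= self.med_strong_fraction <= 1
                and self.strong_fraction + self.med_strong_fraction <= 1):
            raise ValueError("strong_fraction + med_strong_fraction must not exceed 1")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated triple."""

    beta1_true: float
    beta2_true: float
    direct_true: float
    total_true: float
    proportion_true: float | None
    exposure_effects: np.ndarray
    mediator_effects: np.ndarray
    outcome_effects: np.ndarray
    invalid_variant_ids: list

    def to_json(self, path) -> str:
        payload = dataclasses.asdict(self)
        for k in ("exposure_effects", "mediator_effects", "outcome_effects"):
            payload[k] = list(map(float, payload[k]))
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return str(path)


def simulate_ld(n_variants: int, ld_rho: float, positions=None,
                variant_ids=None) -> LDMatrix:
    """AR(1) LD: r between variants i and j is ld_rho^|i-j|.

    Such a matrix is positive semi-definite for any ld_rho in [0, 1);
    ``positions`` is accepted for interface completeness (adjacency is by
    variant order, which the generator keeps collinear with position).
    """
    if not (0 <= ld_rho < 1):
        raise ValueError("ld_rho must lie in [0, 1)")
    idx = np.arange(n_variants)
    r = ld_rho ** np.abs(idx[:, None] - idx[None, :])
    if variant_ids is None:
        variant_ids = [f"rs{i + 1:05d}" for i in idx]
    return LDMatrix(variant_ids=list(variant_ids), r=r)


def _sumstat_frame(ids, chrom, pos, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    z = beta / se
    pval = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-300)
    return pd.DataFrame({
        "variant_id": ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa,
        "beta": beta, "se": se, "eaf": eaf, "pval": pval,
        "n": np.full(len(ids), n, dtype=int),
    })[COLUMNS]


def simulate_triple(cfg: SimulationConfig):
    """Generate one exposure/mediator/outcome triple with shared variants.

    Returns (exposure, mediator, outcome, ld, region, truth).  All three
    SummaryStatSets share variant ids, positions (5 kb spacing on one
    chromosome), allele codes and allele frequencies; the GeneRegion spans
    the variant footprint so every variant is cis to the synthetic gene.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_variants
    ids = [f"rs{i + 1:05d}" for i in range(k)]
    pos = 1_000_000 + 5_000 * np.arange(k)
    chrom = np.full(k, "1")
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=k)
    eaf = np.where(rng.random(k) < 0.5, maf, 1.0 - maf)

    gamma = rng.normal(0.0, cfg.instrument_effect_sd, size=k)
    delta = np.zeros(k)  # direct mediator-QTL effects
    n_strong = int(round(cfg.strong_fraction * k))
    n_med_strong = int(round(cfg.med_strong_fraction * k))
    picked = rng.choice(k, size=n_strong + n_med_strong, replace=False)
    strong, med_strong = picked[:n_strong], picked[n_strong:]
    # strong effects are coded positive: the effect allele is the
    # trait-increasing allele (the usual QTL reporting convention), which
    # makes "directional" pleiotropy directional on the ratio scale too.
    if n_strong:
        gamma[strong] = cfg.strong_effect + np.abs(gamma[strong])
    if n_med_strong:
        delta[med_strong] = cfg.med_strong_effect + np.abs(
            rng.normal(0.0, cfg.instrument_effect_sd, size=n_med_strong))

    pi_out = np.zeros(k)
    pi_med = np.zeros(k)
    n_invalid = int(round(cfg.pleiotropy.invalid_fraction * k))
    invalid = np.array([], dtype=int)
    if n_invalid and cfg.pleiotropy.mode != "none":
        invalid = np.sort(rng.choice(k, size=n_invalid, replace=False))
        mean = cfg.pleiotropy.mean if cfg.pleiotropy.mode == "directional" else 0.0
        pi_out[invalid] = rng.normal(mean, cfg.pleiotropy.sd, size=n_invalid)
        if cfg.mediator_pleiotropy_sd > 0:
            pi_med[invalid] = rng.normal(0.0, cfg.mediator_pleiotropy_sd, size=n_invalid)

    total = cfg.direct_true + cfg.beta1_true * cfg.beta2_true
    b_exp = gamma
    b_med = gamma * cfg.beta1_true + delta + pi_med
    b_out = gamma * total + (delta + pi_med) * cfg.beta2_true + pi_out

    het = 2.0 * maf * (1.0 - maf)
    se_exp = 1.0 / np.sqrt(cfg.n_exp * het)
    se_med = 1.0 / np.sqrt(cfg.n_med * het)
    se_out = 1.0 / np.sqrt(cfg.n_out * cfg.case_fraction * (1 - cfg.case_fraction) * het)
    if not (np.all(np.isfinite(se_exp)) and np.all(se_exp > 0)
            and np.all(np.isfinite(se_out)) and np.all(se_out > 0)):
        raise ValueError("configuration implies zero or non-finite standard errors")

    obs_exp = rng.normal(b_exp, se_exp)
    obs_med = rng.normal(b_med, se_med)
    obs_out = rng.normal(b_out, se_out)

    exposure = SummaryStatSet("EXP", "continuous",
                              _sumstat_frame(ids, chrom, pos, ea, oa, eaf, obs_exp, se_exp, cfg.n_exp))
    mediator = SummaryStatSet("MED", "continuous",
                              _sumstat_frame(ids, chrom, pos, ea, oa, eaf, obs_med, se_med, cfg.n_med))
    outcome = SummaryStatSet("OUT", "binary",
                             _sumstat_frame(ids, chrom, pos, ea, oa, eaf, obs_out, se_out, cfg.n_out))
    ld = simulate_ld(k, cfg.ld_rho, positions=pos, variant_ids=ids)
    region = GeneRegion("GENE", "1", int(pos[0]), int(pos[-1]))
    truth = SimulationTruth(
        beta1_true=cfg.beta1_true, beta2_true=cfg.beta2_true,
        direct_true=cfg.direct_true, total_true=total,
        proportion_true=(cfg.beta1_true * cfg.beta2_true / total) if total != 0 else None,
        exposure_effects=b_exp, mediator_effects=b_med, outcome_effects=b_out,
        invalid_variant_ids=[ids[i] for i in invalid])
    return exposure, mediator, outcome, ld, region, truth


# ---------------------------------------------------------------------------
# recovery reporting
# ---------------------------------------------------------------------------

def recovery_report(truth: SimulationTruth, result) -> pd.DataFrame:
    """Per-parameter (true, estimated, error) table for one mediation run."""
    rows = [
        ("beta1", truth.beta1_true, result.beta1),
        ("beta2", truth.beta2_true, result.beta2),
        ("beta0", truth.total_true, result.beta0),
    ]
    if truth.proportion_true is not None:
        rows.append(("proportion", truth.proportion_true, result.proportion))
    df = pd.DataFrame(rows, columns=["parameter", "true", "estimated"])
    df["error"] = df["estimated"] - df["true"]
    return df


def summarize_recovery(reports) -> pd.DataFrame:
    """Aggregate per-parameter mean and sd of errors across replicates."""
    stacked = pd.concat(reports, ignore_index=True)
    out = stacked.groupby("parameter", sort=False).agg(
        true=("true", "first"),
        mean_estimate=("estimated", "mean"),
        mean_error=("error", "mean"),
        sd_error=("error", "std"),
        n_rep=("error", "size"),
    ).reset_index()
    return out
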