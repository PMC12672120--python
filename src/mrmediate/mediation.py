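"""Two-step mediation on summary-level MR estimates, plus FDR screening.

The three-step decomposition: beta1 is the MR effect of the exposure on the
mediator, beta2 of the mediator on the outcome, beta0 the total effect of
the exposure on the outcome.  The indirect (mediated) effect is the product
beta1*beta2 with the Sobel / first-order delta-method standard error, and
the mediated proportion is indirect/beta0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import MediationStepError
from .instruments import InstrumentConfig, InstrumentSet, LDMatrix, GeneRegion, \
    ld_clump, select_instruments
from .mr import Z95, MREstimate, primary_estimate
from .sumstats import SummaryStatSet, harmonize

log = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """Product-of-coefficients mediation decomposition for one triple."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    beta0: float
    se0: float
    indirect: float
    indirect_se: float
    z: float
    pval: float
    proportion: float
    prop_lo95: float
    prop_hi95: float
    nsnp1: int = 0
    nsnp2: int = 0
    nsnp0: int = 0
    flags: list = field(default_factory=list)


@dataclass
class ScreenResult:
    """One scan of many exposures against a single outcome.

    ``table`` has one row per exposure (primary-method estimate, raw p,
    BH-FDR q, significance flags); exposures without instruments appear as
    NA rows with a reason.  The FDR family is exactly the set of exposures
    with an estimate in this scan (``family_size``).
    """

    outcome_id: str
    table: pd.DataFrame
    family_size: int


# ---------------------------------------------------------------------------
# elementary arithmetic
# ---------------------------------------------------------------------------

def indirect_effect(beta1: float, se1: float, beta2: float, se2: float):
    """Indirect effect beta1*beta2 with the Sobel (delta-method) SE.

    indirect_se = sqrt(beta2^2*se1^2 + beta1^2*se2^2); the z statistic is
    indirect/indirect_se with a two-sided normal p-value.  Returns
    (indirect, indirect_se, z, pval).
    """
    vals = np.array([beta1, se1, beta2, se2], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("indirect_effect: inputs must be finite")
    if se1 <= 0 or se2 <= 0:
        raise ValueError("indirect_effect: standard errors must be positive")
    indirect = beta1 * beta2
    se = float(np.sqrt(beta2 ** 2 * se1 ** 2 + beta1 ** 2 * se2 ** 2))
    if se == 0.0:
        # both coefficients exactly zero: no evidence either way
        return 0.0, 0.0, 0.0, 1.0
    z = indirect / se
    return indirect, se, float(z), float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def mediation_proportion(indirect: float, indirect_se: float, beta0: float,
                         se0: float | None = None):
    """Mediated proportion indirect/beta0 with a symmetric Wald 95% CI.

    By default the total effect is treated as fixed, giving
    se_prop = |indirect_se/beta0|; this is the rule whose interval is
    estimate +- 1.96*estimate/z.  Passing ``se0`` switches to the full
    two-term delta method sqrt(se_ind^2/beta0^2 + indirect^2*se0^2/beta0^4).
    A proportion outside [0, 1] (sign-discordant paths or inconsistent
    mediation) is returned verbatim with a logged warning, never clipped.
    """
    if beta0 == 0:
        raise ValueError("mediation_proportion: beta0 must be nonzero (proportion undefined)")
    prop = indirect / beta0
    if se0 is None:
        se_prop = abs(indirect_se / beta0)
    else:
        se_prop = float(np.sqrt(indirect_se ** 2 / beta0 ** 2
                                + indirect ** 2 * se0 ** 2 / beta0 ** 4))
    if prop < 0 or prop > 1:
        log.warning("mediated proportion %.3f outside [0, 1]: inconsistent mediation", prop)
    return float(prop), float(prop - Z95 * se_prop), float(prop + Z95 * se_prop)


def bh_fdr(pvals) -> list[float]:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("bh_fdr: p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


# ---------------------------------------------------------------------------
# workflows
# ---------------------------------------------------------------------------

def _instruments_for(stats_set: SummaryStatSet, cfg: InstrumentConfig,
                     region: GeneRegion | None, ld: LDMatrix | None) -> InstrumentSet:
    inst = select_instruments(stats_set, region=region, pval_max=cfg.pval_max,
                              maf_min=cfg.maf_min, f_min=cfg.f_min, cis_kb=cfg.cis_kb)
    if len(inst) and ld is not None:
        inst = ld_clump(inst, ld, r2_max=cfg.clump_r2, window_kb=cfg.clump_kb)
    return inst


def _mr_step(exposure: SummaryStatSet, outcome: SummaryStatSet,
             inst: InstrumentSet, ivw_model: str, step: str) -> MREstimate:
    if len(inst) == 0:
        raise MediationStepError(f"{step}: no instruments for {exposure.trait_id}")
    pair = harmonize(exposure.subset(inst.variant_ids), outcome)
    if pair.nsnp == 0:
        raise MediationStepError(
            f"{step}: no instruments survive harmonization for {exposure.trait_id}")
    return primary_estimate(pair, ivw_model=ivw_model)


def run_mediation(exposure_stats: SummaryStatSet, mediator_stats: SummaryStatSet,
                  outcome_stats: SummaryStatSet, inst_cfg: InstrumentConfig,
                  ld: LDMatrix | None = None, region: GeneRegion | None = None,
                  mediator_inst_cfg: InstrumentConfig | None = None,
                  mediator_ld: LDMatrix | None = None,
                  ivw_model: str = "multiplicative_re") -> MediationResult:
    """Three-step product-of-coefficients mediation.

    Step 1 estimates beta1 (exposure -> mediator) from the exposure
    instruments; step 2 estimates beta2 (mediator -> outcome) from the
    mediator's own instruments; step 3 estimates the total effect beta0
    (exposure -> outcome) from the exposure instruments.  Each step uses the
    primary-method policy (IVW for >= 2 instruments, Wald ratio for one).
    """
    med_cfg = mediator_inst_cfg or inst_cfg
    inst_exp = _instruments_for(exposure_stats, inst_cfg, region, ld)
    if len(inst_exp) == 0:
        raise MediationStepError(f"step1: no instruments for {exposure_stats.trait_id}")
    inst_med = _instruments_for(mediator_stats, med_cfg, None,
                                mediator_ld if mediator_ld is not None else ld)

    est1 = _mr_step(exposure_stats, mediator_stats, inst_exp, ivw_model, "step1")
    est2 = _mr_step(mediator_stats, outcome_stats, inst_med, ivw_model, "step2")
    est0 = _mr_step(exposure_stats, outcome_stats, inst_exp, ivw_model, "step3")

    indirect, ind_se, z, pval = indirect_effect(est1.beta, est1.se, est2.beta, est2.se)
    prop, lo, hi = mediation_proportion(indirect, ind_se, est0.beta)
    flags = []
    if prop < 0 or prop > 1:
        flags.append("inconsistent_mediation")
    return MediationResult(
        exposure_id=exposure_stats.trait_id, mediator_id=mediator_stats.trait_id,
        outcome_id=outcome_stats.trait_id,
        beta1=est1.beta, se1=est1.se, beta2=est2.beta, se2=est2.se,
        beta0=est0.beta, se0=est0.se,
        indirect=indirect, indirect_se=ind_se, z=z, pval=pval,
        proportion=prop, prop_lo95=lo, prop_hi95=hi,
        nsnp1=est1.nsnp, nsnp2=est2.nsnp, nsnp0=est0.nsnp, flags=flags)


def screen(exposures, outcome: SummaryStatSet, cfg: InstrumentConfig,
           ld: LDMatrix | None = None, regions: dict | None = None,
           ivw_model: str = "multiplicative_re",
           alpha_raw: float = 0.05, alpha_fdr: float = 0.05) -> ScreenResult:
    """Scan every exposure against one outcome with the primary method.

    Exposures with no instruments (or none surviving harmonization) are
    emitted as NA rows carrying a ``reason``; they do not enter the FDR
    family.  q-values are Benjamini-Hochberg over the scanned family.
    """
    exposures = list(exposures)
    if not exposures:
        raise ValueError("screen: at least one exposure required")
    rows = []
    for exp in exposures:
        region = (regions or {}).get(exp.trait_id)
        row = {"exposure_id": exp.trait_id, "outcome_id": outcome.trait_id,
               "method": None, "nsnp": 0, "beta": np.nan, "se": np.nan,
               "pval": np.nan, "or": np.nan, "or_lo95": np.nan, "or_hi95": np.nan,
               "reason": ""}
        try:
            inst = _instruments_for(exp, cfg, region, ld)
            est = _mr_step(exp, outcome, inst, ivw_model, "scan")
        except MediationStepError:
            row["reason"] = "no_instruments"
            rows.append(row)
            continue
        row.update(method=est.method, nsnp=est.nsnp, beta=est.beta, se=est.se,
                   pval=est.pval)
        row["or"], row["or_lo95"], row["or_hi95"] = est.or_value, est.or_lo, est.or_hi
        rows.append(row)
    table = pd.DataFrame(rows)
    tested = table["pval"].notna()
    table["fdr_q"] = np.nan
    if tested.any():
        table.loc[tested, "fdr_q"] = bh_fdr(table.loc[tested, "pval"])
    table["significant_raw"] = tested & (table["pval"] < alpha_raw)
    table["significant_fdr"] = tested & (table["fdr_q"] < alpha_fdr)
    return ScreenResult(outcome_id=outcome.trait_id, table=table,
                        family_size=int(tested.sum()))


def mediation_to_frame(results) -> pd.DataFrame:
    """Tidy mediation output table; proportions reported in percent."""
    return pd.DataFrame([{
        "exposure": m.exposure_id, "mediator": m.mediator_id, "outcome": m.outcome_id,
        "beta1": m.beta1, "se1": m.se1, "beta2": m.beta2, "se2": m.se2,
        "beta0": m.beta0, "se0": m.se0,
        "indirect": m.indirect, "indirect_se": m.indirect_se,
        "z": m.z, "pval": m.pval,
        "proportion_pct": 100.0 * m.proportion,
        "prop_lo95_pct": 100.0 * m.prop_lo95,
        "prop_hi95_pct": 100.0 * m.prop_hi95,
        "flags": ";".join(m.flags),
    } for m in results])
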