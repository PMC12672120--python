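"""Two-sample MR estimators and the sensitivity suite.

Six estimators over harmonized per-variant effects: Wald ratio (single
instrument), inverse-variance weighting (fixed or multiplicative random
effects), MR-Egger regression, weighted median, and the simple/weighted
mode-based estimates.  Sensitivity diagnostics: Cochran's Q heterogeneity,
the MR-Egger intercept (average directional pleiotropy), MR-PRESSO global /
outlier / distortion tests, leave-one-out influence, the Steiger
directionality test, and an asymptotic power calculator for binary outcomes.

All estimators use first-order weights: the Wald-ratio standard error is
se_out/|beta_exp|, and per-variant weights are beta_exp^2/se_out^2, ignoring
the (second-order) uncertainty in the exposure effects.  This matches the
dominant convention of summary-data MR tooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, EstimationError, InsufficientInstrumentsError
from .instruments import InstrumentSet
from .sumstats import HarmonizedPair, SummaryStatSet

log = logging.getLogger(__name__)

#: Two-sided 95% normal quantile used for all Wald confidence intervals.
Z95 = float(stats.norm.ppf(0.975))  # 1.959963984540054

METHODS = ("wald_ratio", "ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")


@dataclass
class MREstimate:
    """One estimator's causal effect on the log-odds (or unit) scale.

    The odds-ratio fields are the exponentiated point estimate and its
    95% Wald interval; they are derived, never stored independently.
    """

    method: str
    beta: float
    se: float
    pval: float
    nsnp: int
    or_value: float = field(init=False)
    or_lo: float = field(init=False)
    or_hi: float = field(init=False)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not (self.se > 0):
            raise ValueError("se must be positive")
        self.or_value = float(np.exp(self.beta))
        self.or_lo = float(np.exp(self.beta - Z95 * self.se))
        self.or_hi = float(np.exp(self.beta + Z95 * self.se))


@dataclass
class SensitivityReport:
    """Bundle of the sensitivity diagnostics for one exposure/outcome pair."""

    nsnp: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    presso_global_pval: float | None = None
    presso_outliers: list = field(default_factory=list)
    presso_distortion_pval: float | None = None
    steiger_correct_direction: bool | None = None
    steiger_pval: float | None = None
    loo_estimates: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _arrays(pair: HarmonizedPair):
    """Kept-row effect arrays (beta_exp, se_exp, beta_out, se_out, ids)."""
    k = pair.kept()
    return (k["beta_exp"].to_numpy(float), k["se_exp"].to_numpy(float),
            k["beta_out"].to_numpy(float), k["se_out"].to_numpy(float),
            k["variant_id"].to_numpy())


def _require(nsnp: int, minimum: int, what: str):
    if nsnp < minimum:
        raise InsufficientInstrumentsError(
            f"{what} requires >= {minimum} instruments, got {nsnp}")


def _two_sided_normal(z):
    return float(np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z))))


def _ivw_core(be, bo, se_o):
    """Fixed-effect IVW slope, its SE, and Cochran's Q on ratio estimates."""
    w = be ** 2 / se_o ** 2
    r = bo / be
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (r - beta) ** 2))
    return beta, se_fixed, q


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-instrument causal estimate beta_out/beta_exp.

    Uses the first-order standard error se_out/|beta_exp|; ``se_exp`` is
    accepted for interface symmetry but does not enter the first-order SE.
    """
    if beta_exp == 0:
        raise ValueError("wald_ratio: beta_exp must be nonzero")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MREstimate("wald_ratio", beta, se, _two_sided_normal(beta / se), 1)


def ivw(pair: HarmonizedPair, model: str = "multiplicative_re") -> MREstimate:
    """Inverse-variance-weighted estimate, the primary causal estimator.

    The fixed model is weighted least squares of beta_out on beta_exp through
    the origin with weights 1/se_out^2.  The multiplicative random-effects
    model (default) inflates the SE by sqrt(max(1, Q/(k-1))), so
    heterogeneity widens but never narrows the interval.
    """
    if model not in ("fixed", "multiplicative_re"):
        raise ValueError(f"unknown IVW model {model!r}")
    be, se_e, bo, se_o, _ = _arrays(pair)
    if np.any(be == 0):
        raise ValueError("ivw: all exposure betas must be nonzero")
    _require(len(be), 1, "ivw")
    if len(be) < 2:
        return wald_ratio(be[0], se_e[0], bo[0], se_o[0])
    beta, se, q = _ivw_core(be, bo, se_o)
    if model == "multiplicative_re":
        se *= float(np.sqrt(max(1.0, q / (len(be) - 1))))
    est = MREstimate("ivw", beta, se, _two_sided_normal(beta / se), len(be))
    return est


def mr_egger(pair: HarmonizedPair) -> tuple[MREstimate, float, float, float]:
    """MR-Egger regression: slope (causal effect) plus a free intercept.

    Variant rows are oriented so every exposure beta is non-negative, then
    beta_out is regressed on beta_exp with weights 1/se_out^2.  Standard
    errors carry the multiplicative over-dispersion factor
    sqrt(max(1, RSS_w/(k-2))); inference uses Student's t with k-2 degrees
    of freedom.  Returns (slope estimate, intercept, intercept SE,
    intercept p).  The intercept estimates the average directional
    pleiotropy of the instruments.
    """
    be, se_e, bo, se_o, _ = _arrays(pair)
    k = len(be)
    _require(k, 3, "mr_egger")
    sgn = np.where(be < 0, -1.0, 1.0)
    x, y = be * sgn, bo * sgn
    w = 1.0 / se_o ** 2
    sw, swx, swx2 = np.sum(w), np.sum(w * x), np.sum(w * x * x)
    det = sw * swx2 - swx ** 2
    if det <= 0 or np.isclose(det / (sw * swx2), 0.0, atol=1e-12):
        raise EstimationError("mr_egger: rank-deficient design (no spread in exposure betas)")
    swy, swxy = np.sum(w * y), np.sum(w * x * y)
    slope = (sw * swxy - swx * swy) / det
    intercept = (swx2 * swy - swx * swxy) / det
    resid = y - intercept - slope * x
    rss_w = float(np.sum(w * resid ** 2))
    phi = max(1.0, rss_w / (k - 2))
    se_slope = float(np.sqrt(phi * sw / det))
    se_int = float(np.sqrt(phi * swx2 / det))
    p_slope = float(2.0 * stats.t.sf(abs(slope / se_slope), df=k - 2))
    p_int = float(2.0 * stats.t.sf(abs(intercept / se_int), df=k - 2))
    est = MREstimate("egger", float(slope), se_slope, p_slope, k)
    return est, float(intercept), se_int, p_int


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median with the midpoint-CDF convention."""
    order = np.argsort(r, kind="mergesort")
    r_s, p = r[order], w[order] / np.sum(w)
    s_star = np.cumsum(p) - p / 2.0
    return float(np.interp(0.5, s_star, r_s))


def _boot_draws(rng, be, se_e, bo, se_o, n_boot):
    be_b = rng.normal(be, se_e, size=(n_boot, be.size))
    bo_b = rng.normal(bo, se_o, size=(n_boot, be.size))
    return be_b, bo_b


def weighted_median(pair: HarmonizedPair, n_boot: int = 5000,
                    seed: int = 0) -> MREstimate:
    """Weighted-median estimator, consistent when valid instruments carry
    more than half of the total weight.

    Ratio estimates are ordered and the estimate is the linear interpolation
    of the ratio at cumulative normalized weight 0.5 (midpoint convention).
    The SE comes from a seeded parametric bootstrap resampling the exposure
    and outcome betas from normals with their reported SEs.
    """
    be, se_e, bo, se_o, _ = _arrays(pair)
    k = len(be)
    _require(k, 3, "weighted_median")
    w = be ** 2 / se_o ** 2
    beta = _weighted_median_point(bo / be, w)

    rng = np.random.default_rng(seed)
    be_b, bo_b = _boot_draws(rng, be, se_e, bo, se_o, n_boot)
    r_b = bo_b / be_b
    w_b = be_b ** 2 / se_o ** 2
    order = np.argsort(r_b, axis=1, kind="mergesort")
    r_s = np.take_along_axis(r_b, order, axis=1)
    p = np.take_along_axis(w_b, order, axis=1)
    p /= p.sum(axis=1, keepdims=True)
    s_star = np.cumsum(p, axis=1) - p / 2.0
    # vectorized interpolation of each bootstrap row at cumulative weight 0.5
    idx = np.argmax(s_star >= 0.5, axis=1)
    ests = np.empty(n_boot)
    at_edge = (s_star[:, 0] >= 0.5)
    ests[at_edge] = r_s[at_edge, 0]
    rows = np.where(~at_edge)[0]
    i = idx[rows]
    x0, x1 = s_star[rows, i - 1], s_star[rows, i]
    y0, y1 = r_s[rows, i - 1], r_s[rows, i]
    ests[rows] = y0 + (0.5 - x0) / (x1 - x0) * (y1 - y0)
    se = float(np.std(ests, ddof=1))
    se = max(se, 1e-12)
    return MREstimate("weighted_median", beta, se, _two_sided_normal(beta / se), k)


def _mode_point(r: np.ndarray, w: np.ndarray, bandwidth_factor: float,
                n_grid: int = 512) -> float:
    """Argmax of a weighted normal-kernel density over the ratio estimates."""
    sd = float(np.std(r, ddof=1)) if r.size > 1 else 0.0
    iqr = float(stats.iqr(r)) / 1.349
    scales = [s for s in (sd, iqr) if s > 0]
    if not scales:
        return float(r[0])  # all ratios identical: zero bandwidth, point mass
    h = bandwidth_factor * 0.9 * min(scales) * r.size ** (-0.2)
    grid = np.linspace(r.min(), r.max(), n_grid)
    dens = (w[None, :] * stats.norm.pdf((grid[:, None] - r[None, :]) / h)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimate(pair: HarmonizedPair, weighted: bool,
                  bandwidth_factor: float = 1.0, n_boot: int = 5000,
                  seed: int = 0) -> MREstimate:
    """Mode-based estimate: the kernel-density mode of the ratio estimates.

    Bandwidth follows the modified Silverman rule
    h = bandwidth_factor * 0.9 * min(sd, IQR/1.349) * k^(-1/5); the density
    is maximised on a 512-point grid spanning the ratio range.  ``weighted``
    selects inverse-variance weights on the ratios (weighted mode) versus
    uniform weights (simple mode).  SE via seeded parametric bootstrap.
    """
    be, se_e, bo, se_o, _ = _arrays(pair)
    k = len(be)
    _require(k, 3, "mode_estimate")
    r = bo / be

    def weights(be_, se_o_):
        return be_ ** 2 / se_o_ ** 2 if weighted else np.ones(be_.shape[-1])

    beta = _mode_point(r, weights(be, se_o), bandwidth_factor)
    rng = np.random.default_rng(seed)
    be_b, bo_b = _boot_draws(rng, be, se_e, bo, se_o, n_boot)
    ests = np.array([
        _mode_point(bo_b[i] / be_b[i], weights(be_b[i], se_o), bandwidth_factor)
        for i in range(n_boot)
    ])
    se = max(float(np.std(ests, ddof=1)), 1e-12)
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(method, beta, se, _two_sided_normal(beta / se), k)


# ---------------------------------------------------------------------------
# sensitivity suite
# ---------------------------------------------------------------------------

def cochran_q(pair: HarmonizedPair) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity of the per-variant ratio estimates.

    Q = sum_j w_j (r_j - beta_IVW_fixed)^2, chi-square with k-1 df under
    homogeneity; p > 0.05 is read as no excess heterogeneity.
    """
    be, _, bo, se_o, _ = _arrays(pair)
    k = len(be)
    if k < 2:
        raise ValueError("cochran_q requires >= 2 instruments")
    _, _, q = _ivw_core(be, bo, se_o)
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def leave_one_out(pair: HarmonizedPair, model: str = "multiplicative_re"):
    """IVW re-estimated with each instrument excluded in turn.

    Returns a list of (left_out_variant_id, MREstimate); an estimate moving
    far from the full-set estimate marks an influential (possibly
    pleiotropic) instrument.
    """
    kept = pair.kept()
    _require(len(kept), 3, "leave_one_out")
    out = []
    for vid in kept["variant_id"]:
        sub = HarmonizedPair(pair.exposure_id, pair.outcome_id,
                             kept.loc[kept["variant_id"] != vid])
        out.append((vid, ivw(sub, model=model)))
    return out


def mr_presso(pair: HarmonizedPair, n_sim: int = 1000,
              outlier_alpha: float = 0.05, seed: int = 0):
    """MR-PRESSO: pleiotropy residual sum and outlier test.

    The observed residual sum RSS = sum_j w_j (beta_out_j - b_(-j) * beta_exp_j)^2
    uses leave-one-out IVW slopes b_(-j).  Its null distribution is built
    from ``n_sim`` seeded simulations drawing beta_out_j* ~ N(b_(-j) *
    beta_exp_j, se_out_j) and beta_exp_j* ~ N(beta_exp_j, se_exp_j); the
    global p-value uses add-one smoothing (1 + #{RSS* >= RSS_obs})/(n_sim+1).
    Per-variant outlier p-values compare each observed contribution with its
    simulated distribution, Bonferroni-corrected at ``outlier_alpha``/k.
    When outliers are found the IVW estimate is recomputed without them and
    a distortion p-value compares the observed estimate shift against shifts
    from removing equally many random variants.

    Returns (global_pval, outliers, distortion_pval | None, corrected
    MREstimate | None).
    """
    be, se_e, bo, se_o, ids = _arrays(pair)
    k = len(be)
    _require(k, 4, "mr_presso")
    rng = np.random.default_rng(seed)
    w = be ** 2 / se_o ** 2
    r = bo / be
    s_num, s_den = np.sum(w * r), np.sum(w)
    b_loo = (s_num - w * r) / (s_den - w)
    contrib_obs = w * (bo - b_loo * be) ** 2
    rss_obs = float(np.sum(contrib_obs))

    be_s = rng.normal(be, se_e, size=(n_sim, k))
    bo_s = rng.normal(b_loo * be, se_o, size=(n_sim, k))
    w_s = be_s ** 2 / se_o ** 2
    r_s = bo_s / be_s
    s_num_s = np.sum(w_s * r_s, axis=1, keepdims=True)
    s_den_s = np.sum(w_s, axis=1, keepdims=True)
    b_loo_s = (s_num_s - w_s * r_s) / (s_den_s - w_s)
    contrib_s = w_s * (bo_s - b_loo_s * be_s) ** 2
    rss_s = contrib_s.sum(axis=1)

    global_pval = float((1 + np.sum(rss_s >= rss_obs)) / (n_sim + 1))
    p_var = (1 + np.sum(contrib_s >= contrib_obs[None, :], axis=0)) / (n_sim + 1)
    outlier_mask = p_var < outlier_alpha / k
    outliers = [str(v) for v in ids[outlier_mask]]

    distortion_pval = None
    corrected = None
    if outliers and k - len(outliers) >= 2:
        keep = ~outlier_mask
        b_full, _, _ = _ivw_core(be, bo, se_o)
        b_corr, se_corr, q_corr = _ivw_core(be[keep], bo[keep], se_o[keep])
        kk = int(keep.sum())
        se_corr *= float(np.sqrt(max(1.0, q_corr / (kk - 1)))) if kk > 1 else 1.0
        corrected = MREstimate("ivw", b_corr, se_corr,
                               _two_sided_normal(b_corr / se_corr), kk)
        d_obs = abs(b_corr - b_full)
        n_out = len(outliers)
        # estimate shifts from removing equally many random variants
        drop = np.argsort(rng.random((n_sim, k)), axis=1)[:, :n_out]
        wr = w * r
        num = np.sum(wr) - wr[drop].sum(axis=1)
        den = np.sum(w) - w[drop].sum(axis=1)
        d_sim = np.abs(num / den - b_full)
        distortion_pval = float((1 + np.sum(d_sim >= d_obs)) / (n_sim + 1))
    return global_pval, outliers, distortion_pval, corrected


def steiger_test(pair: HarmonizedPair, inst: InstrumentSet,
                 outcome_stats: SummaryStatSet) -> tuple[bool, float]:
    """Steiger directionality test: does the instrument set explain more
    variance in the exposure than in the outcome?

    Exposure variance explained sums the per-variant 2*MAF*(1-MAF)*beta^2
    annotations; the outcome side applies the same formula to the outcome
    effects (for a binary outcome this is a log-odds-scale approximation).
    The p-value compares the two implied correlations sqrt(R^2) by the
    Fisher z-transform with the respective sample sizes.  A tie in explained
    variance reports ``correct_direction = False``.
    """
    ids = inst.variant_ids
    r2_exp = inst.total_r2
    out = outcome_stats.records.set_index("variant_id")
    missing = [v for v in ids if v not in out.index]
    if missing:
        raise ContractError(f"instrument(s) missing from outcome stats: {missing[:5]}")
    sub = out.loc[ids]
    if sub["eaf"].isna().any():
        bad = sub.index[sub["eaf"].isna()].tolist()
        raise ContractError(f"missing eaf for instrument(s): {bad[:5]}")
    maf = np.minimum(sub["eaf"], 1.0 - sub["eaf"])
    r2_out = float(np.sum(2.0 * maf * (1.0 - maf) * sub["beta"] ** 2))
    n_exp = float(inst.rows["n"].mean())
    n_out = float(sub["n"].mean())
    z1 = np.arctanh(min(np.sqrt(min(r2_exp, 1.0)), 1 - 1e-12))
    z2 = np.arctanh(min(np.sqrt(min(r2_out, 1.0)), 1 - 1e-12))
    se = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    pval = _two_sided_normal((z1 - z2) / se)
    return bool(r2_exp > r2_out), pval


def mr_power(n_outcome: int, case_fraction: float, r2_instruments: float,
             or_alt: float, alpha: float = 0.05) -> float:
    """Asymptotic two-sided power for MR on a binary outcome.

    power = Phi(|log OR| * sqrt(N * R^2 * phi * (1 - phi)) - z_{1-alpha/2}),
    with phi the case fraction and R^2 the instrument variance explained in
    the exposure.  At OR = 1 this returns alpha/2, the one-tailed margin of
    the approximation (the neglected lower tail is below machine noise at
    any detectable effect).
    """
    if not (0 < case_fraction < 1):
        raise ValueError("case_fraction must lie in (0, 1)")
    if not (0 < r2_instruments < 1):
        raise ValueError("r2_instruments must lie in (0, 1)")
    if or_alt <= 0:
        raise ValueError("or_alt must be positive")
    if n_outcome < 1:
        raise ValueError("n_outcome must be positive")
    ncp = abs(np.log(or_alt)) * np.sqrt(
        n_outcome * r2_instruments * case_fraction * (1 - case_fraction))
    return float(stats.norm.cdf(ncp - stats.norm.ppf(1 - alpha / 2)))


# ---------------------------------------------------------------------------
# convenience wrappers
# ---------------------------------------------------------------------------

def primary_estimate(pair: HarmonizedPair, ivw_model: str = "multiplicative_re") -> MREstimate:
    """The primary-method policy: IVW for >= 2 instruments, Wald ratio for 1."""
    be, se_e, bo, se_o, _ = _arrays(pair)
    if len(be) == 0:
        raise InsufficientInstrumentsError("no usable instruments after harmonization")
    if len(be) == 1:
        return wald_ratio(be[0], se_e[0], bo[0], se_o[0])
    return ivw(pair, model=ivw_model)


def estimate_all(pair: HarmonizedPair, seed: int = 0, n_boot: int = 5000,
                 ivw_model: str = "multiplicative_re") -> list[MREstimate]:
    """Every estimator applicable at the pair's instrument count."""
    nsnp = pair.nsnp
    if nsnp == 0:
        raise InsufficientInstrumentsError("no usable instruments after harmonization")
    if nsnp == 1:
        be, se_e, bo, se_o, _ = _arrays(pair)
        return [wald_ratio(be[0], se_e[0], bo[0], se_o[0])]
    ests = [ivw(pair, model=ivw_model)]
    if nsnp >= 3:
        try:
            ests.append(mr_egger(pair)[0])
        except EstimationError as exc:
            log.warning("egger skipped for %s->%s: %s", pair.exposure_id,
                        pair.outcome_id, exc)
        ests.append(weighted_median(pair, n_boot=n_boot, seed=seed))
        ests.append(mode_estimate(pair, weighted=False, n_boot=n_boot, seed=seed))
        ests.append(mode_estimate(pair, weighted=True, n_boot=n_boot, seed=seed))
    return ests


def sensitivity_report(pair: HarmonizedPair, inst: InstrumentSet | None = None,
                       outcome_stats: SummaryStatSet | None = None,
                       n_sim: int = 1000, seed: int = 0) -> SensitivityReport:
    """Run every applicable diagnostic; inapplicable entries stay None."""
    rep = SensitivityReport(nsnp=pair.nsnp)
    if rep.nsnp >= 2:
        rep.q_stat, rep.q_df, rep.q_pval = cochran_q(pair)
    if rep.nsnp >= 3:
        try:
            _, rep.egger_intercept, rep.egger_intercept_se, rep.egger_intercept_pval = mr_egger(pair)
        except EstimationError:
            pass
        rep.loo_estimates = leave_one_out(pair)
    if rep.nsnp >= 4:
        rep.presso_global_pval, rep.presso_outliers, rep.presso_distortion_pval, _ = \
            mr_presso(pair, n_sim=n_sim, seed=seed)
    if inst is not None and outcome_stats is not None:
        rep.steiger_correct_direction, rep.steiger_pval = \
            steiger_test(pair, inst, outcome_stats)
    return rep


def estimates_to_frame(estimates, exposure_id: str, outcome_id: str) -> pd.DataFrame:
    """Tidy results table (one row per method), the tabular forest plot."""
    return pd.DataFrame([{
        "exposure_id": exposure_id, "outcome_id": outcome_id,
        "method": e.method, "nsnp": e.nsnp, "beta": e.beta, "se": e.se,
        "pval": e.pval, "or": e.or_value, "or_lo95": e.or_lo, "or_hi95": e.or_hi,
    } for e in estimates])
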