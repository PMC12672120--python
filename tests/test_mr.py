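"""Estimators against independent oracles, plus the sensitivity suite."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

import mrmediate as mm
from mrmediate.errors import (ContractError, EstimationError,
                              InsufficientInstrumentsError)

from conftest import make_pair, make_sumstats, random_pair


class TestWaldRatio:
    def test_direct_division(self):
        est = mm.wald_ratio(0.5, 0.05, 0.1, 0.05)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)
        assert est.or_value == pytest.approx(np.exp(0.2))

    def test_null_outcome(self):
        est = mm.wald_ratio(0.5, 0.05, 0.0, 0.05)
        assert est.beta == 0.0
        assert est.pval == pytest.approx(1.0)

    def test_sign_carried(self):
        assert mm.wald_ratio(-0.5, 0.05, 0.1, 0.05).beta == pytest.approx(-0.2)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            mm.wald_ratio(0.0, 0.05, 0.1, 0.05)


class TestIVW:
    def test_degenerate_consensus(self):
        pair = make_pair([0.5, 0.5], [0.01, 0.01], [0.1, 0.1], [0.05, 0.05])
        assert mm.ivw(pair).beta == pytest.approx(0.2)

    def test_equal_weights_unweighted_mean(self):
        pair = make_pair([0.5, 0.5], [0.01, 0.01], [0.05, 0.15], [0.05, 0.05])
        assert mm.ivw(pair).beta == pytest.approx(0.2)

    def test_three_variant_closed_form(self):
        be = np.array([0.2, 0.5, 0.4])
        bo = np.array([0.05, 0.08, 0.12])
        se_o = np.array([0.02, 0.05, 0.03])
        w = be ** 2 / se_o ** 2
        r = bo / be
        pair = make_pair(be, [0.01] * 3, bo, se_o)
        est = mm.ivw(pair, model="fixed")
        assert est.beta == pytest.approx(np.sum(w * r) / np.sum(w), rel=1e-12)
        assert est.se == pytest.approx(1 / np.sqrt(np.sum(w)), rel=1e-12)

    def test_single_variant_defers_to_wald(self):
        pair = make_pair([0.5], [0.01], [0.1], [0.05])
        est = mm.ivw(pair)
        assert est.method == "wald_ratio"
        assert est.beta == pytest.approx(0.2)

    def test_fixed_equals_origin_wls_oracle(self):
        """IVW(fixed) is weighted least squares through the origin of
        beta_out on beta_exp with weights 1/se_out^2."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            pair = random_pair(rng)
            k = pair.kept()
            est = mm.ivw(pair, model="fixed")
            fit = sm.WLS(k["beta_out"], k["beta_exp"],
                         weights=1.0 / k["se_out"] ** 2).fit()
            assert est.beta == pytest.approx(fit.params.iloc[0], abs=1e-8)
            se_model = float(np.sqrt(fit.cov_params(scale=1.0).iloc[0, 0]))
            assert est.se == pytest.approx(se_model, abs=1e-8)

    def test_re_never_narrower_than_fixed(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            pair = random_pair(rng)
            assert mm.ivw(pair, model="multiplicative_re").se >= \
                mm.ivw(pair, model="fixed").se - 1e-15


class TestEgger:
    def test_line_through_origin(self):
        be = np.array([0.1, 0.2, 0.3, 0.4])
        pair = make_pair(be, [0.01] * 4, 0.5 * be, [0.05] * 4)
        est, intercept, _, _ = mm.mr_egger(pair)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_wls_oracle(self):
        """Slope/intercept equal general weighted least squares; SEs match
        statsmodels after the variance floor at 1."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            pair = random_pair(rng)
            k = pair.kept()
            sgn = np.sign(k["beta_exp"]).replace(0, 1)
            x = (k["beta_exp"] * sgn).to_numpy()
            y = (k["beta_out"] * sgn).to_numpy()
            fit = sm.WLS(y, sm.add_constant(x), weights=1.0 / k["se_out"] ** 2).fit()
            est, intercept, int_se, int_p = mm.mr_egger(pair)
            assert intercept == pytest.approx(fit.params[0], abs=1e-8)
            assert est.beta == pytest.approx(fit.params[1], abs=1e-8)
            floor = np.sqrt(max(1.0, fit.scale) / fit.scale)
            assert int_se == pytest.approx(fit.bse[0] * floor, rel=1e-8)
            assert est.se == pytest.approx(fit.bse[1] * floor, rel=1e-8)

    def test_rank_deficient_design(self):
        pair = make_pair([0.3, 0.3, 0.3], [0.01] * 3, [0.1, 0.2, 0.15], [0.05] * 3)
        with pytest.raises(EstimationError):
            mm.mr_egger(pair)

    def test_too_few_instruments(self):
        pair = make_pair([0.3, 0.4], [0.01] * 2, [0.1, 0.2], [0.05] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            mm.mr_egger(pair)


def _wm_oracle(r, w):
    """Loop-based interpolated weighted percentile at 0.5."""
    pairs = sorted(zip(r, w))
    tot = sum(wi for _, wi in pairs)
    cum = 0.0
    xs, ys = [], []
    for ri, wi in pairs:
        xs.append((cum + wi / 2.0) / tot)
        ys.append(ri)
        cum += wi
    if 0.5 <= xs[0]:
        return ys[0]
    if 0.5 >= xs[-1]:
        return ys[-1]
    for i in range(1, len(xs)):
        if xs[i] >= 0.5:
            f = (0.5 - xs[i - 1]) / (xs[i] - xs[i - 1])
            return ys[i - 1] + f * (ys[i] - ys[i - 1])


class TestWeightedMedian:
    def test_middle_order_statistic(self):
        pair = make_pair([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.2, 0.3], [0.05] * 3)
        est = mm.weighted_median(pair, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_consensus_small_se(self):
        pair = make_pair([0.5] * 4, [0.001] * 4, [0.1] * 4, [0.001] * 4)
        est = mm.weighted_median(pair, n_boot=500, seed=1)
        assert est.beta == pytest.approx(0.2)
        assert est.se < 0.02

    def test_matches_percentile_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            pair = random_pair(rng)
            k = pair.kept()
            r = (k["beta_out"] / k["beta_exp"]).to_numpy()
            w = (k["beta_exp"] ** 2 / k["se_out"] ** 2).to_numpy()
            est = mm.weighted_median(pair, n_boot=50, seed=0)
            assert est.beta == pytest.approx(_wm_oracle(r.tolist(), w.tolist()),
                                             abs=1e-8)

    def test_seeded_bootstrap_deterministic(self):
        rng = np.random.default_rng(3)
        pair = random_pair(rng)
        a = mm.weighted_median(pair, n_boot=300, seed=42)
        b = mm.weighted_median(pair, n_boot=300, seed=42)
        assert (a.beta, a.se) == (b.beta, b.se)


def _mode_oracle(r, w, bf=1.0):
    """Dense-grid (1e5 points) argmax of the same kernel density."""
    r = np.asarray(r, float)
    w = np.asarray(w, float)
    sd = np.std(r, ddof=1)
    iqr = stats.iqr(r) / 1.349
    scales = [s for s in (sd, iqr) if s > 0]
    h = bf * 0.9 * min(scales) * r.size ** (-0.2)
    grid = np.linspace(r.min(), r.max(), 100_000)
    dens = (w[None, :] * stats.norm.pdf((grid[:, None] - r[None, :]) / h)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def _narrow_pair(rng, k=None):
    # keeps the ratio range tight so the 512-point grid resolves below 1e-3
    if k is None:
        k = int(rng.integers(4, 11))
    be = rng.uniform(0.2, 0.4, k)
    se_e = rng.uniform(0.005, 0.02, k)
    bo = 0.2 * be + rng.normal(0, 0.01, k)
    se_o = rng.uniform(0.01, 0.05, k)
    return make_pair(be, se_e, bo, se_o)


class TestModeEstimate:
    def test_point_mass(self):
        pair = make_pair([0.5] * 3, [0.01] * 3, [0.1] * 3, [0.05] * 3)
        est = mm.mode_estimate(pair, weighted=False, n_boot=100, seed=2)
        assert est.beta == pytest.approx(0.2)

    def test_robust_to_single_outlier(self):
        pair = make_pair([1.0] * 4, [0.01] * 4, [0.001, -0.001, 0.0005, 5.0],
                         [0.05] * 4)
        est = mm.mode_estimate(pair, weighted=False, n_boot=100, seed=2)
        assert abs(est.beta) < 0.5   # mode near 0, not the mean 1.25

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_dense_grid_oracle(self, weighted):
        rng = np.random.default_rng(31)
        for _ in range(20):
            pair = _narrow_pair(rng)
            k = pair.kept()
            r = (k["beta_out"] / k["beta_exp"]).to_numpy()
            w = (k["beta_exp"] ** 2 / k["se_out"] ** 2).to_numpy() if weighted \
                else np.ones(len(r))
            est = mm.mode_estimate(pair, weighted=weighted, n_boot=20, seed=0)
            assert est.beta == pytest.approx(_mode_oracle(r, w), abs=1e-3)


class TestCochranQ:
    def test_homogeneity(self):
        be = np.array([0.2, 0.4, 0.3])
        pair = make_pair(be, [0.01] * 3, 0.5 * be, [0.05] * 3)
        q, df, p = mm.cochran_q(pair)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert (df, p) == (2, pytest.approx(1.0))

    def test_two_term_hand_sum(self):
        # ratios 0.1, 0.3 with weights 1 and 3 -> beta 0.25, Q = 0.03
        be = np.array([1.0, 1.0])
        se_o = np.array([1.0, 1.0 / np.sqrt(3.0)])
        pair = make_pair(be, [0.01] * 2, np.array([0.1, 0.3]), se_o)
        q, df, p = mm.cochran_q(pair)
        assert q == pytest.approx(0.03, rel=1e-12)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(0.03, 1), rel=1e-12)

    def test_duplication_doubles_q(self):
        rng = np.random.default_rng(9)
        pair = random_pair(rng, k=5)
        q1, df1, _ = mm.cochran_q(pair)
        k = pair.kept()
        doubled = make_pair(
            np.concatenate([k["beta_exp"], k["beta_exp"]]),
            np.concatenate([k["se_exp"], k["se_exp"]]),
            np.concatenate([k["beta_out"], k["beta_out"]]),
            np.concatenate([k["se_out"], k["se_out"]]))
        q2, df2, _ = mm.cochran_q(doubled)
        assert q2 == pytest.approx(2 * q1, rel=1e-10)
        assert df2 == 2 * 5 - 1


class TestMRPresso:
    def _clean_pair(self, seed, k=10):
        rng = np.random.default_rng(seed)
        be = rng.uniform(0.1, 0.3, k)
        se_e = np.full(k, 0.01)
        se_o = rng.uniform(0.02, 0.05, k)
        bo = 0.2 * be + rng.normal(0, se_o)
        return make_pair(be, se_e, bo, se_o)

    def test_determinism(self):
        pair = self._clean_pair(1)
        a = mm.mr_presso(pair, n_sim=300, seed=5)
        b = mm.mr_presso(pair, n_sim=300, seed=5)
        assert a[:3] == b[:3]

    def test_planted_outlier_recovered(self):
        pair = self._clean_pair(2)
        rows = pair.kept().copy()
        rows.loc[3, "beta_out"] += 10 * rows.loc[3, "se_out"]
        spiked = mm.HarmonizedPair("EXP", "OUT", rows)
        gp, outliers, distortion, corrected = mm.mr_presso(spiked, n_sim=500, seed=7)
        assert rows.loc[3, "variant_id"] in outliers
        assert gp < 0.05
        assert corrected is not None and distortion is not None
        # pruning the outlier restores the pre-spike estimate
        clean_beta = mm.ivw(self._clean_pair(2), "fixed").beta
        assert abs(corrected.beta - clean_beta) < 0.02

    def test_clean_data_rarely_flags(self):
        flagged = 0
        for seed in range(15):
            _, outliers, _, _ = mm.mr_presso(self._clean_pair(100 + seed),
                                             n_sim=300, seed=seed)
            flagged += bool(outliers)
        assert flagged <= 2

    def test_too_few_instruments(self):
        pair = self._clean_pair(3, k=3)
        with pytest.raises(InsufficientInstrumentsError):
            mm.mr_presso(pair)


class TestLeaveOneOut:
    def test_cardinality(self):
        pair = make_pair([0.2, 0.3, 0.4], [0.01] * 3, [0.04, 0.06, 0.08],
                         [0.05] * 3)
        assert len(mm.leave_one_out(pair)) == 3

    def test_exchangeable_variants_agree(self):
        pair = make_pair([0.3] * 4, [0.01] * 4, [0.06] * 4, [0.05] * 4)
        full = mm.ivw(pair).beta
        for _, est in mm.leave_one_out(pair):
            assert est.beta == pytest.approx(full)

    def test_planted_outlier_moves_most(self):
        be = np.array([0.2, 0.3, 0.4, 0.25, 0.35])
        bo = 0.2 * be
        bo[2] += 0.5
        pair = make_pair(be, [0.01] * 5, bo, [0.05] * 5)
        full = mm.ivw(pair).beta
        shifts = {vid: abs(est.beta - full) for vid, est in mm.leave_one_out(pair)}
        assert max(shifts, key=shifts.get) == "rs3"


class TestSteiger:
    def _inst(self, eafs, betas, n):
        k = len(eafs)
        s = make_sumstats(
            variant_id=[f"rs{i + 1}" for i in range(k)], chrom=["1"] * k,
            pos=list(range(1, k + 1)), effect_allele=["A"] * k,
            other_allele=["G"] * k, beta=betas, se=[0.01] * k, eaf=eafs,
            pval=[1e-10] * k, n=[n] * k)
        return mm.select_instruments(s, pval_max=1.1, maf_min=0.0, f_min=0.0)

    def _outcome(self, eafs, betas, n):
        k = len(eafs)
        return make_sumstats(
            trait_id="OUT", trait_type="binary",
            variant_id=[f"rs{i + 1}" for i in range(k)], chrom=["1"] * k,
            pos=list(range(1, k + 1)), effect_allele=["A"] * k,
            other_allele=["G"] * k, beta=betas, se=[0.05] * k, eaf=eafs,
            pval=[0.5] * k, n=[n] * k)

    def test_dominant_exposure_variance(self):
        inst = self._inst([0.3, 0.4], [0.25, 0.2], 30000)
        outcome = self._outcome([0.3, 0.4], [0.01, 0.01], 100000)
        pair = make_pair([0.25, 0.2], [0.01] * 2, [0.01, 0.01], [0.05] * 2)
        correct, p = mm.steiger_test(pair, inst, outcome)
        assert correct is True
        assert p < 0.05

    def test_tie_reports_false(self):
        inst = self._inst([0.3], [0.2], 50000)
        outcome = self._outcome([0.3], [0.2], 50000)
        pair = make_pair([0.2], [0.01], [0.2], [0.05])
        correct, p = mm.steiger_test(pair, inst, outcome)
        assert correct is False
        assert p == pytest.approx(1.0)

    def test_fisher_z_closed_form(self):
        inst = self._inst([0.2, 0.3], [0.3, 0.25], 20000)
        outcome = self._outcome([0.2, 0.3], [0.05, 0.04], 150000)
        pair = make_pair([0.3, 0.25], [0.01] * 2, [0.05, 0.04], [0.05] * 2)
        _, p = mm.steiger_test(pair, inst, outcome)
        r2_exp = sum(mm.variant_r2(e, b) for e, b in [(0.2, 0.3), (0.3, 0.25)])
        r2_out = sum(mm.variant_r2(e, b) for e, b in [(0.2, 0.05), (0.3, 0.04)])
        z = (np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))) \
            / np.sqrt(1 / (20000 - 3) + 1 / (150000 - 3))
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-10)

    def test_missing_eaf_contract_error(self):
        inst = self._inst([0.2], [0.3], 20000)
        outcome = self._outcome([np.nan], [0.05], 150000)
        pair = make_pair([0.3], [0.01], [0.05], [0.05])
        with pytest.raises(ContractError):
            mm.steiger_test(pair, inst, outcome)


class TestPower:
    def test_null_effect_floor(self):
        assert mm.mr_power(431880, 0.0025, 0.01, 1.0) == pytest.approx(0.025)

    def test_limit_to_one(self):
        assert mm.mr_power(10 ** 10, 0.5, 0.1, 1.5) > 0.9999

    def test_closed_form_tuple(self):
        n, cf, r2, orr = 431880, 0.0025, 0.01, 1.5
        ncp = abs(np.log(orr)) * np.sqrt(n * r2 * cf * (1 - cf))
        expected = stats.norm.cdf(ncp - stats.norm.ppf(0.975))
        assert mm.mr_power(n, cf, r2, orr) == pytest.approx(expected, rel=1e-12)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            mm.mr_power(1000, 0.0, 0.01, 1.5)
        with pytest.raises(ValueError):
            mm.mr_power(1000, 0.1, 1.0, 1.5)
        with pytest.raises(ValueError):
            mm.mr_power(1000, 0.1, 0.01, -1.0)


class TestEstimatorProperties:
    @pytest.mark.parametrize("estimator", [
        lambda p: mm.ivw(p),
        lambda p: mm.mr_egger(p)[0],
        lambda p: mm.weighted_median(p, n_boot=100, seed=4),
        lambda p: mm.mode_estimate(p, weighted=True, n_boot=50, seed=4),
        lambda p: mm.mode_estimate(p, weighted=False, n_boot=50, seed=4),
    ])
    def test_units_covariance(self, estimator):
        """Rescaling exposure betas and ses by c rescales the estimate by 1/c."""
        rng = np.random.default_rng(17)
        pair = random_pair(rng, k=8)
        c = 2.5
        k = pair.kept()
        scaled = make_pair(k["beta_exp"] * c, k["se_exp"] * c,
                           k["beta_out"], k["se_out"])
        assert estimator(scaled).beta == pytest.approx(estimator(pair).beta / c,
                                                       rel=1e-9)

    def test_all_estimators_converge_with_precise_instruments(self):
        """With valid instruments and vanishing noise every estimator hits
        the true effect."""
        rng = np.random.default_rng(8)
        be = rng.uniform(0.1, 0.4, 10)
        tiny = 1e-6
        pair = make_pair(be, np.full(10, tiny), 0.3 * be, np.full(10, tiny))
        results = [
            mm.ivw(pair).beta,
            mm.mr_egger(pair)[0].beta,
            mm.weighted_median(pair, n_boot=100, seed=1).beta,
            mm.mode_estimate(pair, weighted=False, n_boot=50, seed=1).beta,
            mm.mode_estimate(pair, weighted=True, n_boot=50, seed=1).beta,
        ]
        assert results == pytest.approx([0.3] * 5, abs=1e-3)

    def test_or_fields_consistent(self):
        est = mm.MREstimate("ivw", 0.25, 0.1, 0.012, 5)
        assert est.or_lo < est.or_value < est.or_hi
        assert np.log(est.or_hi / est.or_value) == pytest.approx(
            np.log(est.or_value / est.or_lo))
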