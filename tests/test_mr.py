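"""MR engine: GWLS worked examples, estimator equivalences, sensitivity
estimators, instrument selection/harmonization, BH, and the gate."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from protmr.mr import (MRConfig, bh_adjust, gwls_estimate,
                       harmonize_and_proxy, ld_matrix, make_instrument_set,
                       mr_egger, select_instruments, sensitivity_gate,
                       wald_ratio, weighted_median)
from protmr.simulate import GenotypeMatrix


class TestGwls:
    def test_worked_example_identity_ld(self):
        inst = make_instrument_set("p", [0.4, 0.2], [0.02, 0.02],
                                   [0.2, 0.12], [0.1, 0.1])
        est = gwls_estimate(inst)
        assert est.theta == pytest.approx(0.52, abs=1e-12)
        assert est.alpha == 1.0
        assert est.se == pytest.approx(np.sqrt(1 / 20), abs=1e-12)

    def test_zero_residual_alpha_one(self):
        bx = np.array([0.3, 0.5, 0.2])
        ld = np.array([[1, 0.4, 0.1], [0.4, 1, 0.3], [0.1, 0.3, 1.0]])
        inst = make_instrument_set("p", bx, 0.02 * np.ones(3),
                                   bx, [0.1, 0.12, 0.08], ld)
        est = gwls_estimate(inst)
        assert est.theta == pytest.approx(1.0, abs=1e-12)
        assert est.mse == pytest.approx(0.0, abs=1e-12)
        assert est.alpha == 1.0

    def test_identity_ld_equals_closed_form_ivw(self, rng):
        for _ in range(100):
            m = int(rng.integers(2, 9))
            bx = rng.normal(0.3, 0.15, m)
            sy = rng.uniform(0.05, 0.2, m)
            by = 0.4 * bx + rng.normal(0, 0.05, m)
            inst = make_instrument_set("p", bx, 0.02 * np.ones(m), by, sy)
            est = gwls_estimate(inst)
            w = 1.0 / sy**2
            ivw = np.sum(w * bx * by) / np.sum(w * bx**2)
            assert est.theta == pytest.approx(ivw, abs=1e-10)

    def test_single_instrument_collapses_to_wald(self):
        inst = make_instrument_set("p", [0.5], [0.02], [0.25], [0.1])
        gw = gwls_estimate(inst)
        wd = wald_ratio(inst.table.iloc[0])
        assert gw.theta == wd.theta
        assert gw.se == wd.se
        assert gw.p == wd.p
        assert gw.alpha == 1.0

    def test_allele_flip_invariance(self, rng):
        m = 5
        bx = rng.normal(0.3, 0.1, m)
        by = 0.5 * bx + rng.normal(0, 0.03, m)
        sy = rng.uniform(0.05, 0.15, m)
        ld = np.corrcoef(rng.standard_normal((60, m)), rowvar=False)
        est1 = gwls_estimate(make_instrument_set("p", bx, 0.02 * np.ones(m),
                                                 by, sy, ld))
        flip = np.array([1, -1, 1, -1, -1.0])
        ld_f = ld * np.outer(flip, flip)
        est2 = gwls_estimate(make_instrument_set("p", bx * flip,
                                                 0.02 * np.ones(m),
                                                 by * flip, sy, ld_f))
        assert est2.theta == pytest.approx(est1.theta, rel=1e-10)
        assert est2.se == pytest.approx(est1.se, rel=1e-10)

    def test_sigma_rescaling_rescales_se(self):
        bx = np.array([0.4, 0.25, 0.3])
        by = np.array([0.22, 0.1, 0.18])
        sy = np.array([0.1, 0.12, 0.09])
        e1 = gwls_estimate(make_instrument_set("p", bx, 0.02 * np.ones(3),
                                               by, sy))
        e2 = gwls_estimate(make_instrument_set("p", bx, 0.02 * np.ones(3),
                                               by, 3.0 * sy))
        if e1.alpha == 1.0 and e2.alpha == 1.0:
            assert e2.se == pytest.approx(3.0 * e1.se, rel=1e-10)
        assert e2.theta == pytest.approx(e1.theta, rel=1e-10)

    def test_t_null_option(self):
        inst = make_instrument_set("p", [0.4, 0.2, 0.3], [0.02] * 3,
                                   [0.2, 0.12, 0.14], [0.1, 0.1, 0.1])
        en = gwls_estimate(inst, MRConfig(null_dist="normal"))
        et = gwls_estimate(inst, MRConfig(null_dist="t"))
        assert en.theta == et.theta
        z = en.theta / en.se
        assert en.p == pytest.approx(2 * stats.norm.sf(abs(z)))
        assert et.p == pytest.approx(2 * stats.t.sf(abs(z), 2))
        assert et.p > en.p

    def test_singular_sigma_rejected(self):
        ld = np.array([[1.0, 1.0], [1.0, 1.0]])  # perfectly collinear
        inst = make_instrument_set("p", [0.4, 0.4], [0.02] * 2,
                                   [0.2, 0.2], [0.1, 0.1], ld)
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            gwls_estimate(inst)


class TestWald:
    def test_worked_example(self):
        rec = pd.Series({"beta_x": 0.5, "beta_y": 0.25, "se_y": 0.1})
        est = wald_ratio(rec)
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        rec = pd.Series({"beta_x": 0.5, "beta_y": 0.0, "se_y": 0.1})
        assert wald_ratio(rec).theta == 0.0

    def test_zero_exposure_effect_rejected(self):
        rec = pd.Series({"beta_x": 0.0, "beta_y": 0.2, "se_y": 0.1})
        with pytest.raises(ValueError, match="beta_X = 0"):
            wald_ratio(rec)


class TestWeightedMedian:
    def test_constant_ratios(self):
        bx = np.array([0.2, 0.4, 0.5])
        inst = make_instrument_set("p", bx, 0.02 * np.ones(3),
                                   0.7 * bx, [0.1, 0.1, 0.1])
        assert weighted_median(inst).theta == pytest.approx(0.7, abs=1e-10)

    def test_equal_weight_interpolation(self):
        # ratios (0.2, 0.5, 0.9) with equal weights -> 0.5
        bx = np.ones(3)
        by = np.array([0.2, 0.5, 0.9])
        inst = make_instrument_set("p", bx, 0.02 * np.ones(3),
                                   by, np.ones(3))
        assert weighted_median(inst).theta == pytest.approx(0.5, abs=1e-10)

    def test_needs_three_instruments(self):
        inst = make_instrument_set("p", [0.3, 0.4], [0.02] * 2,
                                   [0.2, 0.2], [0.1, 0.1])
        with pytest.raises(ValueError, match="3 instruments"):
            weighted_median(inst)

    def test_more_robust_than_ivw_under_40pct_pleiotropy(self, rng):
        # 4 of 10 instruments carry a +0.4 outcome offset
        theta = 0.3
        wm_err, ivw_err = [], []
        for _ in range(100):
            bx = rng.uniform(0.2, 0.5, 10)
            sy = np.full(10, 0.1)
            by = theta * bx + rng.normal(0, sy)
            by[:4] += 0.4
            inst = make_instrument_set("p", bx, 0.02 * np.ones(10), by, sy)
            wm_err.append(weighted_median(inst).theta - theta)
            ivw_err.append(gwls_estimate(inst).theta - theta)
        assert abs(np.mean(wm_err)) < abs(np.mean(ivw_err))


class TestEgger:
    def test_exact_linear_data(self):
        bx = np.array([0.2, 0.4, 0.6])
        by = 0.1 + 0.5 * bx
        inst = make_instrument_set("p", bx, 0.02 * np.ones(3),
                                   by, 0.1 * np.ones(3))
        est = mr_egger(inst)
        assert est.theta == pytest.approx(0.5, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.1, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        m = 5
        bx = rng.uniform(0.1, 0.6, m)
        by = 0.05 + 0.4 * bx + rng.normal(0, 0.03, m)
        sy = rng.uniform(0.05, 0.15, m)
        inst = make_instrument_set("p", bx, 0.02 * np.ones(m), by, sy)
        est = mr_egger(inst)
        # weighted normal equations solved independently
        W = np.diag(1.0 / sy**2)
        X = np.column_stack([np.ones(m), bx])
        coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ by)
        assert est.egger_intercept == pytest.approx(coef[0], abs=1e-10)
        assert est.theta == pytest.approx(coef[1], abs=1e-10)

    def test_null_intercept_calibrated(self, rng):
        # no pleiotropy: intercept P uniform, ~5% rejection at alpha=0.05
        m, reps = 10, 200
        ps = []
        for _ in range(reps):
            bx = rng.uniform(0.1, 0.45, m)
            sy = np.full(m, 0.1)
            by = 0.25 * bx + rng.normal(0, sy)
            inst = make_instrument_set("p", bx, 0.02 * np.ones(m), by, sy)
            ps.append(mr_egger(inst).egger_intercept_p)
        rate = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 <= rate <= 0.10
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_all_equal_bx_rejected(self):
        inst = make_instrument_set("p", [0.3, 0.3, 0.3], [0.02] * 3,
                                   [0.2, 0.25, 0.15], [0.1] * 3)
        with pytest.raises(ValueError, match="unidentifiable"):
            mr_egger(inst)


class TestBh:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.034])[0] == pytest.approx(0.034)

    def test_hand_evaluated_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_equal_inputs_collapse(self):
        np.testing.assert_allclose(bh_adjust([0.04] * 5), [0.04] * 5)

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
    def test_never_below_raw_and_monotone(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_oracle_step_up(self, rng):
        # independent hand-computed step-up with monotone enforcement
        ps = rng.uniform(1e-6, 1, 25)
        m = len(ps)
        order = np.argsort(ps)
        stepped = ps[order] * m / (np.arange(m) + 1)
        stepped = np.minimum.accumulate(stepped[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(bh_adjust(ps), oracle, atol=1e-12)


def _toy_genotypes(rng, n=600):
    """Ten variants in one window with planted LD groups."""
    base = {g: rng.binomial(2, 0.3, n).astype(float) for g in range(4)}
    group = [0, 0, 0, 1, 1, 2, 2, 2, 3, 3]
    cols = {}
    for i, g in enumerate(group):
        x = base[g].copy()
        flip = rng.random(n) < 0.12  # degrade LD within group
        x[flip] = rng.binomial(2, 0.3, flip.sum())
        cols[f"v{i}"] = x
    dosages = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
    variants = pd.DataFrame({
        "chrom": 1, "pos": 1_000_000 + 10_000 * np.arange(10),
        "ea": "A", "oa": "G", "maf": 0.3}, index=dosages.columns)
    variants.index.name = "variant"
    return GenotypeMatrix(dosages, variants)


def _exposure_frame(geno, pvals):
    return pd.DataFrame({
        "chrom": geno.variants["chrom"], "pos": geno.variants["pos"],
        "ea": "A", "oa": "G", "beta": 0.3, "se": 0.05,
        "p": pvals, "n": 600}, index=geno.variants.index)


class TestSelectInstruments:
    gene = {"analyte": "p", "gene": "G", "chrom": 1,
            "start": 1_020_000, "end": 1_040_000}

    def test_window_threshold_rule(self, rng):
        geno = _toy_genotypes(rng)
        exposure = _exposure_frame(geno, np.geomspace(1e-10, 1e-3, 10))
        inst = select_instruments(exposure, self.gene, MRConfig(), geno)
        assert inst.n_window == 10
        assert inst.p_b == pytest.approx(0.05 / 10)

    def test_greedy_clump_matches_exhaustive_oracle(self, rng):
        geno = _toy_genotypes(rng)
        pvals = np.array([1e-8, 1e-6, 1e-9, 1e-7, 1e-10,
                          1e-12, 1e-4, 1e-11, 1e-5, 1e-13])
        exposure = _exposure_frame(geno, pvals)
        cfg = MRConfig()
        inst = select_instruments(exposure, self.gene, cfg, geno)
        # oracle: enumerate subsets; the greedy-consistent subset is the one
        # where a variant is retained iff no lower-P retained variant within
        # 1 Mb has r^2 >= threshold with it
        R = ld_matrix(geno, list(geno.variants.index))
        order = np.argsort(pvals, kind="stable")
        expected = None
        for size in range(1, 11):
            for subset in itertools.combinations(range(10), size):
                s = set(subset)
                consistent = all(
                    (i in s) == all(R[i, j] ** 2 < cfg.clump_r2
                                    for j in s
                                    if pvals[j] < pvals[i])
                    for i in order)
                if consistent:
                    expected = s
                    break
            if expected is not None:
                break
        names = {f"v{i}" for i in expected}
        assert set(inst.table.index) == names
        # every retained pair is below the clumping threshold
        if inst.m > 1:
            r2 = inst.ld**2
            assert r2[np.triu_indices(inst.m, 1)].max() < cfg.clump_r2

    def test_all_correlated_leaves_single_lowest_p(self, rng):
        n = 600
        g = rng.binomial(2, 0.3, n).astype(float)
        cols = {f"v{i}": g for i in range(4)}  # perfect mutual LD
        dosages = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
        variants = pd.DataFrame({
            "chrom": 1, "pos": 1_000_000 + 1000 * np.arange(4),
            "ea": "A", "oa": "G", "maf": 0.3}, index=dosages.columns)
        geno = GenotypeMatrix(dosages, variants)
        pvals = np.array([1e-6, 1e-9, 1e-7, 1e-8])
        exposure = _exposure_frame(geno, pvals).iloc[:4]
        inst = select_instruments(exposure, self.gene, MRConfig(), geno)
        assert list(inst.table.index) == ["v1"]

    def test_empty_survivors_marks_untestable(self, rng):
        geno = _toy_genotypes(rng)
        exposure = _exposure_frame(geno, np.full(10, 0.5))  # nothing passes
        inst = select_instruments(exposure, self.gene, MRConfig(), geno)
        assert inst.untestable
        assert inst.p_b == pytest.approx(0.005)


class TestHarmonize:
    def _outcome_frame(self, inst, flip=None):
        t = inst.window
        out = pd.DataFrame({
            "chrom": t["chrom"], "pos": t["pos"], "ea": t["ea"],
            "oa": t["oa"], "beta": 0.1, "se": 0.05, "p": 0.01, "n": 5000},
            index=t.index)
        if flip:
            for v in flip:
                out.loc[v, ["ea", "oa"]] = ["G", "A"]
                out.loc[v, "beta"] = -0.1
        return out

    def test_matched_alleles_noop(self, rng):
        geno = _toy_genotypes(rng)
        exposure = _exposure_frame(geno, np.geomspace(1e-12, 1e-8, 10))
        inst = select_instruments(exposure, TestSelectInstruments.gene,
                                  MRConfig(), geno)
        out = self._outcome_frame(inst)
        h = harmonize_and_proxy(inst, out, geno, MRConfig())
        assert list(h.table.index) == list(inst.table.index)
        assert (h.table["beta_y"] == 0.1).all()

    def test_allele_swap_negates_outcome_beta(self, rng):
        geno = _toy_genotypes(rng)
        exposure = _exposure_frame(geno, np.geomspace(1e-12, 1e-8, 10))
        inst = select_instruments(exposure, TestSelectInstruments.gene,
                                  MRConfig(), geno)
        vid = inst.table.index[0]
        out = self._outcome_frame(inst, flip=[vid])
        h = harmonize_and_proxy(inst, out, geno, MRConfig())
        # stored beta was negated on the swapped record, so aligned value
        # returns to +0.1
        assert h.table.loc[vid, "beta_y"] == pytest.approx(0.1)
        assert h.table.loc[vid, "se_y"] == pytest.approx(0.05)

    def test_missing_variant_replaced_by_proxy(self, rng):
        geno = _toy_genotypes(rng)
        exposure = _exposure_frame(geno, np.geomspace(1e-12, 1e-8, 10))
        inst = select_instruments(exposure, TestSelectInstruments.gene,
                                  MRConfig(), geno)
        vid = inst.table.index[0]
        out = self._outcome_frame(inst).drop(index=vid)
        h = harmonize_and_proxy(inst, out, geno, MRConfig())
        assert vid not in h.table.index
        assert h.m >= inst.m - 1  # substituted or at worst dropped
        if h.m == inst.m:
            new = set(h.table.index) - set(inst.table.index)
            (proxy,) = new
            g0 = geno.dosages[vid]
            r2 = np.corrcoef(g0, geno.dosages[proxy])[0, 1] ** 2
            assert r2 > MRConfig().proxy_r2
            # exposure effect re-estimated at the proxy's own record
            assert h.table.loc[proxy, "beta_x"] == \
                exposure.loc[proxy, "beta"]

    def test_low_ld_proxy_not_substituted(self, rng):
        n = 500
        g0 = rng.binomial(2, 0.3, n).astype(float)
        g1 = rng.binomial(2, 0.3, n).astype(float)  # independent candidate
        dosages = pd.DataFrame({"v0": g0, "v1": g1},
                               index=[f"s{i}" for i in range(n)])
        variants = pd.DataFrame({
            "chrom": 1, "pos": [1_030_000, 1_031_000],
            "ea": "A", "oa": "G", "maf": 0.3}, index=["v0", "v1"])
        geno = GenotypeMatrix(dosages, variants)
        exposure = pd.DataFrame({
            "chrom": 1, "pos": variants["pos"], "ea": "A", "oa": "G",
            "beta": 0.3, "se": 0.05, "p": [1e-10, 1e-9], "n": 500},
            index=["v0", "v1"])
        inst = select_instruments(exposure, TestSelectInstruments.gene,
                                  MRConfig(), geno)
        out = pd.DataFrame({"chrom": 1, "pos": [1_031_000], "ea": "A",
                            "oa": "G", "beta": 0.1, "se": 0.05,
                            "p": 0.01, "n": 5000}, index=["v1"])
        h = harmonize_and_proxy(inst, out, geno, MRConfig())
        assert "v0" not in h.table.index
        assert any(reason == "no_outcome_record_no_proxy"
                   for _, reason in h.dropped)

    def test_ambiguous_palindromic_dropped(self, rng):
        geno = _toy_genotypes(rng)
        variants = geno.variants.copy()
        variants.loc["v0", ["ea", "oa"]] = ["A", "T"]  # palindromic
        variants.loc["v0", "maf"] = 0.48               # ambiguous frequency
        geno = dataclasses.replace(geno, variants=variants)
        exposure = _exposure_frame(geno, np.geomspace(1e-12, 1e-8, 10))
        exposure.loc["v0", ["ea", "oa"]] = ["A", "T"]
        inst = select_instruments(exposure, TestSelectInstruments.gene,
                                  MRConfig(), geno)
        out = self._outcome_frame(inst)
        out.loc["v0", ["ea", "oa"]] = ["A", "T"]
        h = harmonize_and_proxy(inst, out, geno, MRConfig())
        assert "v0" not in h.table.index
        assert ("v0", "palindromic_ambiguous") in h.dropped


class TestGate:
    def _gwls(self, theta=0.5, fdr=0.01, m=5):
        return dataclasses.replace(
            gwls_estimate(make_instrument_set(
                "p", np.linspace(0.2, 0.5, m), 0.02 * np.ones(m),
                theta * np.linspace(0.2, 0.5, m), 0.1 * np.ones(m))),
            fdr=fdr)

    def _wm(self, theta=0.5, p=0.01):
        return dataclasses.replace(self._gwls(theta), method="weighted_median",
                                   p=p, theta=theta)

    def _egger(self, theta=0.5, int_p=0.5):
        e = dataclasses.replace(self._gwls(theta), method="egger",
                                theta=theta)
        e.egger_intercept = 0.01
        e.egger_intercept_p = int_p
        return e

    def test_high_fdr_not_tested(self):
        gated = sensitivity_gate(self._gwls(fdr=0.2),
                                 self._wm(), self._egger())
        assert gated.gate == "not_tested"

    def test_sign_disagreement_fails_step1(self):
        gated = sensitivity_gate(self._gwls(), self._wm(theta=-0.4),
                                 self._egger())
        assert gated.gate == "failed_step1"

    def test_weak_wm_fails_step1(self):
        gated = sensitivity_gate(self._gwls(), self._wm(p=0.2),
                                 self._egger())
        assert gated.gate == "failed_step1"

    def test_egger_intercept_fails_step2(self):
        gated = sensitivity_gate(self._gwls(), self._wm(),
                                 self._egger(int_p=0.01))
        assert gated.gate == "failed_step2"

    def test_egger_sign_disagreement_fails_step2(self):
        gated = sensitivity_gate(self._gwls(), self._wm(),
                                 self._egger(theta=-0.3))
        assert gated.gate == "failed_step2"

    def test_all_pass_causal_candidate(self):
        gated = sensitivity_gate(self._gwls(), self._wm(), self._egger())
        assert gated.gate == "causal_candidate"

    def test_missing_sensitivity_estimate_rejected(self):
        with pytest.raises(ValueError, match="missing sensitivity"):
            sensitivity_gate(self._gwls(), None, None)

    def test_missing_fdr_rejected(self):
        est = self._gwls()
        est.fdr = None
        with pytest.raises(ValueError, match="FDR"):
            sensitivity_gate(est, self._wm(), self._egger())
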