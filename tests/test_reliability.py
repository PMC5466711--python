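"""Variance components, ICCs, I2C2, summaries, scalar measures, duration."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import connrel as cr
from connrel.reliability import _mom_arrays


def brute_force_anova(values):
    """Independent sums-of-squares computation with explicit loops.

    values: (K, J, I) complete data for one edge.
    """
    K, J, I = values.shape
    gbar = values.mean()
    ss_subj = ss_cell = ss_err = 0.0
    for k in range(K):
        ybar_k = values[k].mean()
        ss_subj += (ybar_k - gbar) ** 2
        for j in range(J):
            ybar_jk = values[k, j].mean()
            ss_cell += (ybar_jk - ybar_k) ** 2
            for i in range(I):
                ss_err += (values[k, j, i] - ybar_jk) ** 2
    ms_subj = J * I * ss_subj / (K - 1)
    ms_cell = I * ss_cell / (K * (J - 1))
    ms_err = ss_err / (K * J * (I - 1))
    return ms_subj, ms_cell, ms_err


class TestAnovaMoments:
    def test_constant_panel_gives_zero_components(self):
        panel = cr.EdgeObservationPanel(np.full((3, 2, 2, 1), 0.7))
        ms_s, ms_c, ms_e, vc = cr.anova_moments(panel, 0)
        assert vc.sigma3_sq == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma2_sq == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma0_sq == pytest.approx(0.0, abs=1e-12)
        assert vc.mu == pytest.approx(0.7)

    def test_tiny_integer_panel_matches_brute_force(self, tiny_integer_panel):
        panel = tiny_integer_panel
        ms_s, ms_c, ms_e, vc = cr.anova_moments(panel, 0)
        bf_s, bf_c, bf_e = brute_force_anova(panel.values[..., 0])
        assert ms_s == pytest.approx(bf_s, abs=1e-12)
        assert ms_c == pytest.approx(bf_c, abs=1e-12)
        assert ms_e == pytest.approx(bf_e, abs=1e-12)
        # moment relations, clamped at zero
        I, J = 2, 2
        assert vc.sigma0_sq == pytest.approx(bf_e, abs=1e-12)
        assert vc.sigma2_sq == pytest.approx(max((bf_c - bf_e) / I, 0),
                                             abs=1e-12)
        assert vc.sigma3_sq == pytest.approx(max((bf_s - bf_c) / (I * J), 0),
                                             abs=1e-12)

    def test_random_panels_match_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            vals = rng.normal(size=(4, 3, 5, 1))
            panel = cr.EdgeObservationPanel(vals)
            ms_s, ms_c, ms_e, _ = cr.anova_moments(panel, 0)
            bf = brute_force_anova(vals[..., 0])
            assert np.allclose([ms_s, ms_c, ms_e], bf, atol=1e-12)

    def test_monte_carlo_recovery(self, default_panel):
        cfg, panel, _ = default_panel
        out = _mom_arrays(panel.values)
        assert out["sigma3_sq"].mean() == pytest.approx(cfg.sigma3_sq,
                                                        rel=0.10)
        assert out["sigma2_sq"].mean() == pytest.approx(cfg.sigma2_sq,
                                                        rel=0.10)
        assert out["sigma0_sq"].mean() == pytest.approx(cfg.sigma0_sq,
                                                        rel=0.10)

    def test_missing_data_directs_to_reml(self):
        cfg = cr.SimulationConfig(n_edges=2, seed=0)
        panel, _ = cr.simulate_edge_panel(cfg)
        panel = cr.inject_missing(panel, [(0, 0, 0)])
        with pytest.raises(ValueError, match="fit_em_reml"):
            cr.anova_moments(panel, 0)

    def test_single_condition_reduced_model(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(5, 1, 6, 1))
        panel = cr.EdgeObservationPanel(vals)
        _, _, ms_e, vc = cr.anova_moments(panel, 0)
        assert vc.sigma2_sq == 0.0
        # reduced two-level moments: one-way ANOVA on subjects
        y = vals[:, 0, :, 0]
        msb = 6 * ((y.mean(axis=1) - y.mean()) ** 2).sum() / 4
        msw = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum() / (5 * 5)
        assert vc.sigma0_sq == pytest.approx(msw)
        assert vc.sigma3_sq == pytest.approx(max((msb - msw) / 6, 0))


class TestEmReml:
    def test_balanced_equivalence_with_moments(self):
        """On complete balanced data with interior moment estimates the
        EM solution of the restricted likelihood coincides with the
        ANOVA estimator."""
        cfg = cr.SimulationConfig(n_subjects=8, n_conditions=3, n_sessions=4,
                                  n_edges=40, sigma3_sq=0.5, sigma2_sq=0.3,
                                  sigma0_sq=0.2, seed=21)
        panel, _ = cr.simulate_edge_panel(cfg)
        mom = cr.EdgeReliabilityModel(panel).fit(method="mom")
        reml = cr.EdgeReliabilityModel(panel).fit(method="reml")
        interior = (mom.sigma3_sq > 1e-3) & (mom.sigma2_sq > 1e-3)
        assert interior.sum() >= 20
        for name in ("sigma3_sq", "sigma2_sq", "sigma0_sq", "mu"):
            a = getattr(mom, name)[interior]
            b = getattr(reml, name)[interior]
            assert np.allclose(a, b, rtol=1e-6, atol=1e-12), name

    def test_single_edge_interface(self):
        cfg = cr.SimulationConfig(n_edges=3, seed=13)
        panel, _ = cr.simulate_edge_panel(cfg)
        panel = cr.inject_missing(panel, [(0, 3, 2)])
        vc = cr.fit_em_reml(panel, 1)
        assert vc.estimator == "em_reml"
        assert vc.converged
        assert vc.n_used == 10 * 4 * 12 - 1
        assert vc.sigma3_sq >= 0 and vc.sigma2_sq >= 0 and vc.sigma0_sq > 0

    def test_missingness_recovery(self):
        cfg = cr.SimulationConfig(n_edges=400, seed=30)
        panel, _ = cr.simulate_edge_panel(cfg)
        panel = cr.inject_missing(panel, cr.default_missing_cells(cfg))
        res = cr.EdgeReliabilityModel(panel).fit()
        assert res.estimator == "em_reml"
        assert res.sigma3_sq.mean() == pytest.approx(0.04, rel=0.15)
        assert res.sigma2_sq.mean() == pytest.approx(0.01, rel=0.15)
        assert res.sigma0_sq.mean() == pytest.approx(0.10, rel=0.05)

    def test_boundary_truth_shrinks_to_zero(self):
        cfg = cr.SimulationConfig(n_edges=200, sigma3_sq=0.0, sigma2_sq=0.0,
                                  sigma0_sq=0.1, seed=31)
        panel, _ = cr.simulate_edge_panel(cfg)
        res = cr.EdgeReliabilityModel(panel).fit(method="reml")
        assert np.median(res.sigma3_sq) < 0.005
        assert np.median(res.sigma2_sq) < 0.005

    def test_non_identifiable_patterns_raise(self):
        cfg = cr.SimulationConfig(n_subjects=2, n_conditions=2, n_sessions=2,
                                  n_edges=1, seed=0)
        panel, _ = cr.simulate_edge_panel(cfg)
        # leave every cell with a single session: residual unidentifiable
        cells = [(k, j, 0) for k in range(2) for j in range(2)]
        panel.missing_mask[[0, 0, 1, 1], [0, 1, 0, 1], 0, :] = True
        with pytest.raises(ValueError, match="residual"):
            cr.fit_em_reml(panel, 0)

    def test_matches_lme4_reml_oracle(self, tmp_path):
        """Cross-check the EM solution against lme4's REML fit of the same
        nested two-random-effect model on one edge with missing sessions."""
        cfg = cr.SimulationConfig(n_subjects=6, n_conditions=3, n_sessions=4,
                                  n_edges=1, sigma3_sq=0.5, sigma2_sq=0.3,
                                  sigma0_sq=0.2, seed=77)
        panel, _ = cr.simulate_edge_panel(cfg)
        panel = cr.inject_missing(panel, [(0, 1, 2), (3, 0, 0)])
        vc = cr.fit_em_reml(panel, 0)

        df = panel.to_long_frame()
        df = df[~df["missing"]]
        data_path = tmp_path / "edge.tsv"
        df.to_csv(data_path, sep="\t", index=False)
        rcode = f"""
        suppressMessages(library(lme4))
        d <- read.delim("{data_path}")
        d$subject <- factor(d$subject)
        d$cell <- interaction(d$subject, d$condition)
        m <- lmer(value ~ 1 + (1|subject) + (1|cell), data = d, REML = TRUE)
        v <- as.data.frame(VarCorr(m))
        s3 <- v$vcov[v$grp == "subject"]
        s2 <- v$vcov[v$grp == "cell"]
        s0 <- v$vcov[v$grp == "Residual"]
        cat(sprintf("%.10f %.10f %.10f %.10f", s3, s2, s0, fixef(m)[1]))
        """
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        s3, s2, s0, mu = map(float, out.stdout.split())
        assert vc.sigma3_sq == pytest.approx(s3, rel=1e-3, abs=1e-5)
        assert vc.sigma2_sq == pytest.approx(s2, rel=1e-3, abs=1e-5)
        assert vc.sigma0_sq == pytest.approx(s0, rel=1e-3, abs=1e-5)
        assert vc.mu == pytest.approx(mu, rel=1e-5)


class TestIccFormulas:
    @pytest.mark.parametrize("s3,s2,expected", [
        (3.0, 1.0, 0.75),
        (0.5, 0.0, 1.0),
        (0.0, 0.2, 0.0),
    ])
    def test_between_condition_closed_form(self, s3, s2, expected):
        assert cr.icc_between_condition(s3, s2) == pytest.approx(expected)

    @pytest.mark.parametrize("s3,s2,s0,expected", [
        (3.0, 1.0, 4.0, 0.5),
        (0.3, 0.2, 0.0, 1.0),
        (0.04, 0.01, 0.10, 1 / 3),
    ])
    def test_between_session_closed_form(self, s3, s2, s0, expected):
        assert cr.icc_between_session(s3, s2, s0) == pytest.approx(expected)

    def test_degenerate_denominators_flagged(self):
        assert np.isnan(cr.icc_between_condition(0.0, 0.0))
        assert np.isnan(cr.icc_between_session(0.0, 0.0, 0.0))

    def test_include_residual_variant(self):
        assert cr.icc_between_condition(3.0, 1.0, 4.0,
                                        include_residual=True) == \
            pytest.approx(3 / 8)

    def test_accepts_variance_components_object(self):
        vc = cr.VarianceComponents(0.0, 3.0, 1.0, 4.0)
        assert cr.icc_between_condition(vc) == pytest.approx(0.75)
        assert cr.icc_between_session(vc) == pytest.approx(0.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(s3=st.floats(0, 10), s2=st.floats(0, 10), s0=st.floats(0, 10))
    def test_iccs_bounded_and_ordered(self, s3, s2, s0):
        if s3 + s2 > 0:
            bc = cr.icc_between_condition(s3, s2)
            assert 0 <= bc <= 1
        if s3 + s2 + s0 > 0:
            bs = cr.icc_between_session(s3, s2, s0)
            assert 0 <= bs <= 1
            # adding residual to the denominator can only shrink the ratio
            if s3 + s2 > 0:
                assert cr.icc_between_condition(
                    s3, s2, s0, include_residual=True) <= \
                    cr.icc_between_condition(s3, s2) + 1e-12


class TestPerConditionIcc:
    def test_identical_sessions_give_one(self):
        vals = np.zeros((3, 1, 4, 1))
        vals[:, 0, :, 0] = np.array([[1.0] * 4, [2.0] * 4, [3.0] * 4])
        panel = cr.EdgeObservationPanel(vals)
        icc = cr.per_condition_icc(panel)
        assert icc[0] == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_hits_zero_boundary(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(6, 1, 8, 30))
        panel = cr.EdgeObservationPanel(vals)
        icc = cr.per_condition_icc(panel)
        assert np.median(icc) < 0.1

    def test_matches_one_way_anova_oracle(self):
        """REML two-level ICC tracks the closed-form one-way ANOVA
        estimator (MSB - MSW) / (MSB + (I-1) MSW) on balanced data."""
        rng = np.random.default_rng(33)
        K, I = 3, 4
        vals = (rng.normal(0, 1.0, size=(K, 1, 1, 1))
                + rng.normal(0, 0.5, size=(K, 1, I, 1)))
        panel = cr.EdgeObservationPanel(vals)
        icc = float(cr.per_condition_icc(panel)[0])
        y = vals[:, 0, :, 0]
        msb = I * ((y.mean(axis=1) - y.mean()) ** 2).sum() / (K - 1)
        msw = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum() / (K * (I - 1))
        oracle = max((msb - msw) / (msb + (I - 1) * msw), 0.0)
        assert icc == pytest.approx(oracle, abs=0.02)

    def test_requires_single_condition(self):
        cfg = cr.SimulationConfig(n_edges=1, seed=0)
        panel, _ = cr.simulate_edge_panel(cfg)
        with pytest.raises(ValueError, match="single-condition"):
            cr.per_condition_icc(panel)


class TestI2C2:
    def test_univariate_equals_trace_ratio(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 1))
        subs = np.repeat(["a", "b", "c"], 4)
        lam = cr.i2c2(x, subs)
        ss_w, df_w = 0.0, 0
        for s in np.unique(subs):
            g = x[subs == s, 0]
            ss_w += ((g - g.mean()) ** 2).sum()
            df_w += g.size - 1
        msw = ss_w / df_w
        mst = ((x[:, 0] - x[:, 0].mean()) ** 2).sum() / (len(x) - 1)
        assert lam == pytest.approx(max(1 - msw / mst, 0.0), abs=1e-12)

    def test_identical_replicates_give_one(self):
        base = np.array([[1.0, 2.0], [5.0, 6.0]])
        W = np.repeat(base, 3, axis=0)
        subs = np.repeat(["a", "b"], 3)
        assert cr.i2c2(W, subs) == pytest.approx(1.0)

    def test_pooled_replicates_recover_between_session_icc(
            self, default_panel):
        cfg, panel, _ = default_panel
        W, subs, _ = cr.panel_to_replicates(panel)
        target = cr.icc_between_session(cfg.sigma3_sq, cfg.sigma2_sq,
                                        cfg.sigma0_sq)
        assert cr.i2c2(W, subs) == pytest.approx(target, abs=0.05)

    def test_network_blocks(self, default_panel):
        _, panel, _ = default_panel
        V = panel.n_edges
        blocks = ([("visual", "visual")] * (V // 2)
                  + [("visual", "default")] * (V - V // 2))
        W, subs, img_blocks = cr.panel_to_replicates(panel)
        panel.edge_blocks = blocks
        out = cr.i2c2_by_network(W, subs, blocks * panel.n_conditions,
                                 mode="incident")
        assert set(out) == {"all", "visual", "default"}
        out_within = cr.i2c2_by_network(W, subs,
                                        blocks * panel.n_conditions,
                                        mode="within")
        assert "default" not in out_within  # no default--default edges
        panel.edge_blocks = None

    def test_degenerate_total_variance(self):
        W = np.zeros((4, 3))
        assert np.isnan(cr.i2c2(W, ["a", "a", "b", "b"]))


class TestSummarize:
    def test_constant_iccs_collapse(self):
        icc = np.full(10, 0.5)
        blocks = [("visual", "visual")] * 5 + [("visual", "default")] * 5
        s = cr.summarize(icc, blocks)
        assert s.percentiles == {50: 0.5, 75: 0.5, 95: 0.5}
        assert s.within_network["mean"] == 0.5
        assert s.within_network["sd"] == 0.0
        assert s.within_network["ci_low"] == s.within_network["ci_high"]

    def test_linear_interpolation_percentile(self):
        icc = np.arange(0.1, 1.05, 0.1)
        blocks = [("a", "a")] * 10
        s = cr.summarize(icc, blocks)
        assert s.percentiles[50] == pytest.approx(0.55)

    def test_within_above_between_for_boosted_blocks(self):
        rng = np.random.default_rng(6)
        icc = np.concatenate([rng.uniform(0.6, 0.9, 50),
                              rng.uniform(0.1, 0.4, 50)])
        blocks = [("visual", "visual")] * 50 + [("visual", "default")] * 50
        s = cr.summarize(icc, blocks)
        assert s.within_network["mean"] > s.between_network["mean"]
        assert s.within_network["n"] == 50


class TestScalarMeasures:
    def test_trait_measure_has_high_icc(self):
        rng = np.random.default_rng(7)
        trait = rng.normal(size=(8, 1, 1, 1))
        vals = np.broadcast_to(trait, (8, 2, 6, 1)).copy()
        vals += rng.normal(0, 1e-3, vals.shape)
        panel = cr.ScalarMeasurePanel(vals)
        icc_table, _ = cr.scalar_measure_reliability(panel)
        assert (icc_table["icc"] > 0.95).all()

    def test_large_condition_shift_detected(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(6, 3, 4, 1))
        vals[:, 1] += 5.0
        panel = cr.ScalarMeasurePanel(vals)
        _, anova = cr.scalar_measure_reliability(panel, compute_icc=False)
        assert anova["p"].iloc[0] < 1e-3
        assert anova["df_between"].iloc[0] == 2
        assert anova["df_within"].iloc[0] == 6 * 3 * 4 - 3

    def test_constant_measure_flagged(self):
        vals = np.ones((4, 2, 3, 1))
        panel = cr.ScalarMeasurePanel(vals)
        icc_table, anova = cr.scalar_measure_reliability(panel)
        assert (icc_table["flag"] == "degenerate").all()
        assert np.isnan(anova["F"].iloc[0])


class TestDuration:
    def test_base_duration_equals_single_sessions(
            self, small_timeseries_collection):
        _, coll, _, _ = small_timeseries_collection
        panel = cr.duration_pseudosessions(coll, minutes=10, seed=1)
        # every pseudo-session vector must equal the vector of one of the
        # original sessions, and the four chosen sessions are distinct
        sub, cond = coll.subject_ids[0], coll.condition_labels[0]
        singles = {}
        for ses in coll.session_indices:
            cm = cr.roi_connectivity(coll[(sub, cond, ses)])
            ev = cr.vectorize_edges(cm, coll.partition, to_fisher_z=True,
                                    clip=0.999999)
            singles[ses] = ev.values
        matches = []
        for ps in range(4):
            vec = panel.values[0, 0, ps]
            hits = [s for s, v in singles.items() if np.allclose(v, vec)]
            assert len(hits) == 1
            matches.append(hits[0])
        assert len(set(matches)) == 4

    def test_thirty_minutes_partitions_all_sessions(
            self, small_timeseries_collection):
        _, coll, _, _ = small_timeseries_collection
        panel = cr.duration_pseudosessions(coll, minutes=30, seed=2)
        assert panel.n_sessions == 4  # 4 pseudo-sessions of 3 sessions each

    def test_insufficient_sessions_errors(self, small_timeseries_collection):
        _, coll, _, _ = small_timeseries_collection
        with pytest.raises(ValueError, match="required"):
            cr.duration_pseudosessions(coll, minutes=40, seed=0)

    def test_deterministic(self, small_timeseries_collection):
        _, coll, _, _ = small_timeseries_collection
        a = cr.duration_pseudosessions(coll, minutes=20, seed=3)
        b = cr.duration_pseudosessions(coll, minutes=20, seed=3)
        assert (a.values == b.values).all()


class TestModelResults:
    def test_auto_dispatch(self):
        cfg = cr.SimulationConfig(n_edges=10, seed=9)
        panel, _ = cr.simulate_edge_panel(cfg)
        res = cr.EdgeReliabilityModel(panel).fit()
        assert res.estimator == "mom"
        panel2 = cr.inject_missing(panel, [(0, 0, 0)])
        res2 = cr.EdgeReliabilityModel(panel2).fit()
        assert res2.estimator == "em_reml"
        with pytest.raises(ValueError, match="complete"):
            cr.EdgeReliabilityModel(panel2).fit(method="mom")

    def test_results_frame_and_summary(self, default_panel):
        _, panel, _ = default_panel
        res = cr.EdgeReliabilityModel(panel).fit()
        df = res.to_frame()
        assert len(df) == panel.n_edges
        assert {"sigma3_sq", "icc_between_condition",
                "icc_between_session"} <= set(df.columns)
        bc = res.icc_between_condition()
        assert np.nanmin(bc) >= 0 and np.nanmax(bc) <= 1
        text = res.summary()
        assert "sigma3^2" in text and "ICC between-session" in text

    def test_components_accessor_round_trip(self, tiny_integer_panel):
        res = cr.EdgeReliabilityModel(tiny_integer_panel).fit()
        vc = res.components(0)
        _, _, _, direct = cr.anova_moments(tiny_integer_panel, 0)
        assert vc.sigma3_sq == pytest.approx(direct.sigma3_sq)
        assert vc.mu == pytest.approx(direct.mu)
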