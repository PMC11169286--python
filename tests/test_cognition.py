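"""Composites, tau x gradient interaction models, gradient bins, and
brain-behavior trends."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm_api
from pingouin import partial_corr

import hubgrad as hg
from hubgrad.errors import InvalidParameterError


class TestComposites:
    def test_single_subscore_equals_standardized(self):
        df = pd.DataFrame({"trailA": [10.0, 20, 30, 40]})
        out = hg.build_composites({"speed": df})
        x = df["trailA"].to_numpy()
        assert np.allclose(out["speed"], (x - x.mean()) / x.std(ddof=1))

    def test_mean_across_subdomains(self):
        df = pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 0.0]})
        out = hg.build_composites({"memory": df}, method="minmax")
        assert np.allclose(out["memory"], [0.5, 0.5])

    def test_control_group_standardization_oracle(self):
        df = pd.DataFrame({"s1": [1.0, 2, 3, 4, 5], "s2": [2.0, 2, 4, 4, 8]})
        ctrl = np.array([True, True, True, False, False])
        out = hg.build_composites({"d": df}, control_mask=ctrl)
        expect = np.mean(
            [(df[c] - df[c][ctrl].mean()) / df[c][ctrl].std() for c in df], axis=0
        )
        assert np.allclose(out["d"], expect, atol=1e-12)

    def test_zero_variance_subscore_named(self):
        df = pd.DataFrame({"flat": [1.0, 1, 1, 1]})
        with pytest.raises(InvalidParameterError, match="flat"):
            hg.build_composites({"d": df})


class TestInteractionMap:
    def test_matches_ols_oracle(self):
        rng = np.random.default_rng(0)
        s, n = 12, 3
        tau = rng.uniform(1, 2, (s, n))
        g = rng.standard_normal((s, n))
        y = rng.standard_normal(s)
        cov = pd.DataFrame({"age": rng.normal(70, 5, s)})
        out = hg.interaction_map(tau, g, y, cov)
        for node in range(n):
            X = np.column_stack(
                [np.ones(s), tau[:, node] * g[:, node], tau[:, node], g[:, node], cov]
            )
            fit = sm_api.OLS(y, X).fit()
            assert out.t[node] == pytest.approx(fit.tvalues[1], abs=1e-10)
            assert out.p[node] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            hg.interaction_map(np.ones((5, 3)), np.ones((5, 2)), np.ones(5))


class TestLongitudinalInteraction:
    def test_reduces_to_pooled_ols_without_subject_variance(self):
        """Balanced two-visit data generated with no subject-level effect:
        the random-intercept variance estimate hits the boundary and the
        fixed effects equal pooled OLS."""
        rng = np.random.default_rng(1)
        s = 40
        tau = rng.uniform(1, 2, (s, 1))
        g = rng.standard_normal((s, 1))
        rows = []
        for i in range(s):
            for t in (0.0, 1.0):
                rows.append({"subject_id": f"s{i}", "time": t, "value": rng.standard_normal()})
        long = pd.DataFrame(rows)
        out = hg.longitudinal_interaction(tau, g, long)
        time = long["time"].to_numpy()
        idx = np.repeat(np.arange(s), 2)
        tv, gv = tau[idx, 0], g[idx, 0]
        X = np.column_stack(
            [np.ones(2 * s), time, tv, gv, time * tv, time * gv, tv * gv, time * tv * gv]
        )
        fit = sm_api.OLS(long["value"].to_numpy(), X).fit()
        assert out.estimate[0] == pytest.approx(fit.params[7], abs=1e-6)

    def test_requires_followup(self):
        long = pd.DataFrame({"subject_id": ["a", "b"], "time": [0.0, 0.0], "value": [1.0, 2.0]})
        with pytest.raises(InvalidParameterError):
            hg.longitudinal_interaction(np.ones((2, 1)), np.ones((2, 1)), long)

    def test_planted_negative_three_way_recovered(self, small_cohort):
        c = small_cohort
        sids = [s.subject_id for s in c.subjects]
        tau = np.vstack([c.pet.baseline[sid] for sid in sids])
        g1 = np.vstack([c.gradients[sid].fc.scores[:, 0] for sid in sids])
        long = c.cognition.longitudinal.query("domain == 'MMSE'")[
            ["subject_id", "time", "value"]
        ]
        nodes = np.flatnonzero(c.cognition.planted_nodes)[:5]
        out = hg.longitudinal_interaction(tau, g1, long, c.covariates(education=True), nodes=nodes)
        assert out.t[nodes].mean() < 0


class TestGradientBins:
    def test_even_split(self):
        b = hg.gradient_bins(np.arange(12.0), 6)
        assert np.bincount(b.bin_label)[1:].tolist() == [2] * 6

    def test_remainder_from_low_end(self):
        b = hg.gradient_bins(np.arange(13.0), 6)
        assert np.bincount(b.bin_label)[1:].tolist() == [3, 2, 2, 2, 2, 2]

    def test_bin_means_increase_for_monotone_map(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(40)
        b = hg.gradient_bins(x, 5)
        means = [x[b.bin_label == i].mean() for i in range(1, 6)]
        assert all(a < c for a, c in zip(means, means[1:]))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30)
        a = hg.gradient_bins(x, 6).bin_label
        b = hg.gradient_bins(np.exp(3 * x), 6).bin_label
        assert np.array_equal(a, b)

    def test_bounds_rejected(self):
        with pytest.raises(InvalidParameterError):
            hg.gradient_bins(np.arange(10.0), 6)


class TestPartialR:
    def test_reduces_to_pearson_without_covariates(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        r, _ = hg.cognition.partial_pearson(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_matches_pingouin_oracle(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(10),
                "y": rng.standard_normal(10),
                "c1": rng.standard_normal(10),
                "c2": rng.standard_normal(10),
            }
        )
        r, p = hg.cognition.partial_pearson(df.x, df.y, df[["c1", "c2"]])
        oracle = partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(oracle["r"].iloc[0], abs=1e-10)
        assert p == pytest.approx(oracle["p_val"].iloc[0], abs=1e-8)

    def test_bin_graded_effect_increases_along_bins(self, small_cohort):
        """A composite loaded on bin tau with weights rising along the
        gradient produces partial correlations (global tau controlled)
        that grade along bin order."""
        c = small_cohort
        sids = [s.subject_id for s in c.subjects]
        tau = np.vstack([c.pet.baseline[sid] for sid in sids])
        binning = hg.gradient_bins(c.fc_template.scores[:, 0], 6)
        rng = np.random.default_rng(6)
        y = np.zeros(len(sids))
        for b in range(1, 7):
            bin_tau = tau[:, binning.bin_label == b].mean(axis=1)
            y += (b / 6.0) * (bin_tau - bin_tau.mean()) / bin_tau.std()
        y += 0.5 * rng.standard_normal(len(sids))
        cov = pd.DataFrame({"global_tau": tau.mean(axis=1)}, index=sids)
        out = hg.bin_brain_behavior(binning, tau, y, cov)
        assert out["abs_r"].iloc[-1] > out["abs_r"].iloc[0]
        slope, p = hg.topology_trend(out["r"].to_numpy())
        assert slope > 0 and p < 0.05


class TestTopologyTrend:
    def test_constant_r_zero_slope(self):
        slope, _ = hg.topology_trend([0.4] * 6)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_hand_ols_on_fisher_z(self):
        r = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        slope, p = hg.topology_trend(r)
        x = np.arange(1.0, 7)
        z = np.arctanh(r)
        X = np.column_stack([np.ones(6), x])
        beta = np.linalg.solve(X.T @ X, X.T @ z)
        assert slope == pytest.approx(beta[1], abs=1e-12)
        assert slope > 0

    def test_reversal_flips_sign(self):
        r = np.array([0.1, 0.3, 0.5, 0.55, 0.6])
        s1, _ = hg.topology_trend(r)
        s2, _ = hg.topology_trend(r[::-1])
        assert s2 == pytest.approx(-s1, abs=1e-12)

    def test_needs_three_bins(self):
        with pytest.raises(InvalidParameterError):
            hg.topology_trend([0.1, 0.2])


class TestBraakComparison:
    def test_relabeling_equivalence(self, small_cohort):
        c = small_cohort
        sids = [s.subject_id for s in c.subjects]
        tau = np.vstack([c.pet.baseline[sid] for sid in sids])
        y = tau.mean(axis=1)
        binning = hg.gradient_bins(c.fc_template.scores[:, 0], 6)
        stage_names = np.array(["I", "II", "III", "IV", "V", "VI"])
        braak_like = stage_names[binning.bin_label - 1]
        a = hg.bin_brain_behavior(binning, tau, y)
        b = hg.braak_meta_roi_comparison(braak_like, tau, y)
        assert np.allclose(a["r"].to_numpy(), b["r"].to_numpy(), atol=1e-12)

    def test_missing_labels_rejected(self):
        with pytest.raises(InvalidParameterError):
            hg.braak_meta_roi_comparison(
                np.array(["none"] * 10), np.ones((5, 10)), np.ones(5)
            )


class TestFdr:
    def test_bh_monotone_in_raw_p(self):
        rng = np.random.default_rng(7)
        p = rng.random(40)
        adj, _ = hg.fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
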