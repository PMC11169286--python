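"""Hub selection, gradient-space nearest neighbors, hub-tau features, and
the accumulation regression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm_api

import hubgrad as hg
from hubgrad.errors import InvalidParameterError
from hubgrad.hubs import select_neighbors_variant


def brute_degree(w, sparsity):
    n = w.shape[0]
    keep = int(np.ceil(sparsity * (n - 1)))
    b = np.zeros((n, n), dtype=bool)
    for i in range(n):
        vals = [(w[i, j], -j) for j in range(n) if j != i]
        cut = sorted(vals, reverse=True)[:keep]
        for v, negj in cut:
            b[i, -negj] = True
    b = b | b.T
    return b.sum(1)


class TestNodeDegree:
    def test_complete_graph(self):
        w = np.ones((6, 6)) - np.eye(6)
        assert np.array_equal(hg.node_degree(w, sparsity=1.0), np.full(6, 5))

    def test_star_graph(self):
        w = np.zeros((6, 6))
        w[0, 1:] = w[1:, 0] = 1.0
        deg = hg.node_degree(w, sparsity=1.0)
        assert deg[0] == 5 and (deg[1:] == 1).all()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(6, 31))
            w = rng.random((n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            assert np.array_equal(hg.node_degree(w, 0.25), brute_degree(w, 0.25))


class TestSelectHubs:
    def test_star_center(self):
        assert hg.select_hubs([5, 1, 1, 1], 1).tolist() == [0]

    def test_tie_rule_lower_index(self):
        assert hg.select_hubs(np.full(8, 3), 3).tolist() == [0, 1, 2]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(5, 31))
            deg = rng.integers(0, 6, n)
            k = int(rng.integers(1, n))
            got = set(hg.select_hubs(deg, k).tolist())
            oracle = set(sorted(range(n), key=lambda i: (-deg[i], i))[:k])
            assert got == oracle

    def test_too_many_hubs_rejected(self):
        with pytest.raises(InvalidParameterError):
            hg.select_hubs([1, 2, 3], 3)


class TestNearestHubs:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(8, 31))
            coords = rng.standard_normal((n, 3))
            hubs = sorted(rng.choice(n, size=int(rng.integers(4, n)), replace=False).tolist())
            k = int(rng.integers(1, len(hubs) - 1 if len(hubs) > 2 else 2))
            got = hg.nearest_hubs_in_gradient_space(coords, hubs, k)
            for roi in range(n):
                cands = [h for h in hubs if h != roi]
                oracle = sorted(cands, key=lambda h: (np.linalg.norm(coords[h] - coords[roi]), h))
                assert got[roi].tolist() == oracle[:k]

    def test_self_exclusion(self):
        coords = np.array([[0.0, 0, 0], [0, 0, 0], [5, 0, 0], [9, 0, 0]])
        got = hg.nearest_hubs_in_gradient_space(coords, [0, 2, 3], 1)
        assert got[0].tolist() == [2]  # node 0 is a hub; next nearest hub wins
        assert got[1].tolist() == [0]  # coincident non-hub node picks hub 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        coords = rng.standard_normal((15, 3))
        a = hg.nearest_hubs_in_gradient_space(coords, list(range(8)), 3)
        b = hg.nearest_hubs_in_gradient_space(coords * 2, list(range(8)), 3)
        assert all(np.array_equal(a[r], b[r]) for r in a)

    def test_too_few_hubs_rejected(self):
        with pytest.raises(InvalidParameterError):
            hg.nearest_hubs_in_gradient_space(np.zeros((5, 3)), [0, 1], 3)


class TestHubFeatures:
    def test_uniform_map_and_hand_average(self):
        sels = {"s": {0: np.array([2, 5]), 1: np.array([2, 5])}}
        tau = {"s": np.array([9.0, 9, 1.2, 9, 9, 1.8])}
        dtau = {"s": np.zeros(6)}
        # only ROIs 0 and 1 in the selection dict: restrict maps to match
        table = hg.build_hub_features(
            ["s"],
            {"s": {i: np.array([2, 5]) for i in range(6)}},
            {"s": {i: np.array([2]) for i in range(6)}},
            tau,
            dtau,
        )
        assert (table["tau_fc_hubs"] == 1.5).all()
        assert (table["tau_sc_hubs"] == 1.2).all()

    def test_missing_map_names_subject(self):
        with pytest.raises(InvalidParameterError, match="s2"):
            hg.build_hub_features(["s2"], {}, {}, {}, {})

    def test_matches_independent_loop_oracle(self, small_cohort):
        c = small_cohort
        sids = [s.subject_id for s in c.subjects][:5]
        dmaps = {
            sid: (c.pet.followup[sid] - c.pet.baseline[sid]) / c.pet.delta_days[sid]
            for sid in sids
        }
        table = hg.build_hub_features(
            sids,
            {sid: c.gradients[sid].fc_hub_rois for sid in sids},
            {sid: c.gradients[sid].sc_hub_rois for sid in sids},
            c.pet.baseline,
            dmaps,
        )
        for _, row in table.sample(30, random_state=0).iterrows():
            sid, roi = row["subject_id"], int(row["roi"])
            tau = c.pet.baseline[sid]
            assert row["tau_fc_hubs"] == pytest.approx(
                np.mean([tau[h] for h in c.gradients[sid].fc_hub_rois[roi]]), abs=1e-12
            )
            assert row["delta_tau_roi"] == pytest.approx(dmaps[sid][roi], abs=1e-15)


def toy_table(rng, n_sub=25, n_roi=3):
    rows = []
    for i in range(n_sub):
        for roi in range(n_roi):
            rows.append(
                {
                    "subject_id": f"s{i}",
                    "roi": roi,
                    "tau_fc_hubs": rng.uniform(1, 2),
                    "tau_sc_hubs": rng.uniform(1, 2),
                    "baseline_tau_roi": rng.uniform(1, 2),
                    "delta_tau_roi": rng.normal(0, 1e-4),
                }
            )
    return pd.DataFrame(rows)


class TestAccumulationModel:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        table = toy_table(rng)
        cov = pd.DataFrame(
            {"age": rng.normal(70, 8, 25), "sex": rng.integers(0, 2, 25)},
            index=[f"s{i}" for i in range(25)],
        )
        fc_map, sc_map = hg.fit_accumulation_model(table, cov)
        for roi in range(3):
            sub = table[table.roi == roi]
            X = np.column_stack(
                [
                    np.ones(25),
                    sub["baseline_tau_roi"],
                    sub["tau_fc_hubs"],
                    sub["tau_sc_hubs"],
                    cov.loc[sub["subject_id"]].to_numpy(),
                ]
            )
            fit = sm_api.OLS(sub["delta_tau_roi"].to_numpy(), X).fit()
            assert fc_map.t[roi] == pytest.approx(fit.tvalues[2], abs=1e-10)
            assert sc_map.t[roi] == pytest.approx(fit.tvalues[3], abs=1e-10)

    def test_single_predictor_mode_differs(self):
        rng = np.random.default_rng(5)
        table = toy_table(rng)
        main = hg.fit_accumulation_model(table, None, mode="main")
        single = hg.fit_accumulation_model(table, None, mode="single")
        assert not np.allclose(main[0].t, single[0].t)

    def test_collinear_features_mask_roi(self):
        rng = np.random.default_rng(6)
        table = toy_table(rng)
        table.loc[table.roi == 1, "tau_sc_hubs"] = table.loc[table.roi == 1, "tau_fc_hubs"]
        fc_map, _ = hg.fit_accumulation_model(table, None)
        assert 1 in fc_map.meta["failed_rois"]
        assert not fc_map.significant[1]

    def test_needs_twenty_subjects(self):
        rng = np.random.default_rng(7)
        with pytest.raises(InvalidParameterError):
            hg.fit_accumulation_model(toy_table(rng, n_sub=10), None)


class TestLoocv:
    def test_noise_free_linear_generation(self):
        rng = np.random.default_rng(8)
        table = toy_table(rng, n_sub=30)
        table["delta_tau_roi"] = (
            1e-4 * table["baseline_tau_roi"] + 5e-5 * table["tau_fc_hubs"]
        )
        _, mean_rel = hg.loocv_relative_rmse(table, None)
        assert mean_rel < 0.01

    def test_pure_noise_matches_intercept_only_predictor(self):
        rng = np.random.default_rng(9)
        table = toy_table(rng, n_sub=120, n_roi=2)  # delta tau is pure noise
        _, mean_rel = hg.loocv_relative_rmse(table, None)
        # intercept-only LOO baseline
        rels = []
        for roi in range(2):
            y = table[table.roi == roi]["delta_tau_roi"].to_numpy()
            n = y.size
            loo = (y - y.mean()) * n / (n - 1)
            rels.append(np.sqrt(np.mean(loo**2)) / (y.max() - y.min()))
        assert mean_rel == pytest.approx(np.mean(rels), rel=0.10)

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        table = toy_table(rng)
        a = hg.loocv_relative_rmse(table, None)[1]
        b = hg.loocv_relative_rmse(table, None)[1]
        assert a == b


class TestSensitivityVariants:
    @pytest.fixture(scope="class")
    def variant_tables(self, small_cohort):
        c = small_cohort
        sids = [s.subject_id for s in c.subjects]
        dmaps = {
            sid: (c.pet.followup[sid] - c.pet.baseline[sid]) / c.pet.delta_days[sid]
            for sid in sids
        }
        cfg = c.config

        def builder(variant):
            if variant == "distance_predictors":
                table = hg.build_hub_features(
                    sids,
                    {sid: c.gradients[sid].fc_hub_rois for sid in sids},
                    {sid: c.gradients[sid].sc_hub_rois for sid in sids},
                    c.pet.baseline,
                    dmaps,
                )
                dist = hg.hubs.build_distance_features(
                    sids,
                    {sid: c.gradients[sid].fc_hub_rois for sid in sids},
                    {sid: c.gradients[sid].sc_hub_rois for sid in sids},
                    {sid: {"FC": c.gradients[sid].fc, "SC": c.gradients[sid].sc} for sid in sids},
                )
                table["fc_hub_dist"] = [
                    dist[r.subject_id]["FC"][int(r.roi)] for r in table.itertuples()
                ]
                table["sc_hub_dist"] = [
                    dist[r.subject_id]["SC"][int(r.roi)] for r in table.itertuples()
                ]
                return table
            sels = {}
            for sid in sids:
                deg = hg.node_degree(c.connectomes[sid]["FC"], 0.2)
                hubs_ = hg.select_hubs(deg, cfg.n_hubs)
                sels[sid] = select_neighbors_variant(
                    c.gradients[sid].fc, hubs_, cfg.k_nearest_hubs, variant
                )
            sels_sc = {}
            for sid in sids:
                deg = hg.node_degree(c.connectomes[sid]["SC"], 0.2)
                hubs_ = hg.select_hubs(deg, cfg.n_hubs)
                sels_sc[sid] = select_neighbors_variant(
                    c.gradients[sid].sc, hubs_, cfg.k_nearest_hubs, variant
                )
            return hg.build_hub_features(sids, sels, sels_sc, c.pet.baseline, dmaps)

        return builder

    def test_variant_changes_only_feature_columns(self, variant_tables):
        a = variant_tables("nearest_any")
        b = variant_tables("furthest_nonhub")
        assert np.array_equal(a["baseline_tau_roi"], b["baseline_tau_roi"])
        assert not np.allclose(a["tau_fc_hubs"], b["tau_fc_hubs"])

    def test_nearest_any_stronger_than_furthest_nonhub(self, variant_tables, small_cohort):
        planted = small_cohort.pet.planted_fc_mask | small_cohort.pet.planted_sc_mask
        cov = small_cohort.covariates()
        near = hg.sensitivity_variant(variant_tables, "nearest_any", covariates=cov)
        far = hg.sensitivity_variant(variant_tables, "furthest_nonhub", covariates=cov)
        t_near = np.nanmean([np.abs(near[0].t[planted]), np.abs(near[1].t[planted])])
        t_far = np.nanmean([np.abs(far[0].t[planted]), np.abs(far[1].t[planted])])
        assert t_near >= t_far

    def test_unknown_variant_rejected(self, variant_tables):
        with pytest.raises(InvalidParameterError):
            hg.sensitivity_variant(variant_tables, "bogus")
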