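"""Trajectory mixture: basis arithmetic, VB recovery, Bayes-rule membership."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import cardiotraj as ct
from cardiotraj.errors import DataError
from cardiotraj.evaluate import map_accuracy
from cardiotraj.trajectory import (AgeBasis, GroupParameters, ObservationSet,
                                   TrajectoryModel, build_design,
                                   model_from_dict, model_to_dict)

from conftest import separated_config


@pytest.mark.parametrize("age, expected", [
    (70.0, (1.0, 0.0, 0.0)),
    (80.0, (1.0, 1.0, 1.0)),
    (65.0, (1.0, -0.5, 0.25)),
])
def test_build_design_arithmetic(age, expected):
    basis = AgeBasis(reference_age=70, scale=10, degree=2)
    assert build_design(age, basis) == pytest.approx(expected)


def _toy_model(weights, lvef_means, lvef_sds, ea_means=None, ea_sds=None):
    k = len(weights)
    ea_means = ea_means or [1.0] * k
    ea_sds = ea_sds or [0.2] * k
    groups = [GroupParameters(
        coefficients={"lvef": np.array([m, 0.0, 0.0]), "ea": np.array([e, 0.0, 0.0])},
        residual_sd={"lvef": s, "ea": es})
        for m, s, e, es in zip(lvef_means, lvef_sds, ea_means, ea_sds)]
    return TrajectoryModel(k_max=k, weights=np.asarray(weights, dtype=float),
                           groups=groups, concentration=1.0, basis=AgeBasis(),
                           priors={})


class TestPosteriorMembership:
    def test_single_nonzero_weight_group(self):
        m = _toy_model([1.0, 0.0], [60, 80], [5, 5])
        post = ct.posterior_membership(m, ObservationSet(
            "p1", [70.0], {"lvef": [65.0]}))
        assert post.probabilities == pytest.approx([1.0, 0.0], abs=1e-12)
        assert post.map_group == 0

    def test_symmetric_two_groups(self):
        m = _toy_model([0.5, 0.5], [60, 80], [5, 5])
        post = ct.posterior_membership(m, ObservationSet(
            "p1", [70.0], {"lvef": [70.0], "ea": [np.nan]}))
        assert post.probabilities == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_matches_hand_normalized_bayes_rule(self):
        """Direct density-product oracle for a full (LVEF + E/A) visit."""
        m = _toy_model([0.7, 0.3], [65, 75], [6, 9], ea_means=[0.9, 1.2],
                       ea_sds=[0.2, 0.3])
        age, lvef, ea = 72.0, 68.0, 1.05
        post = ct.posterior_membership(m, ObservationSet(
            "p1", [age], {"lvef": [lvef], "ea": [ea]}))
        dens = np.array([
            0.7 * norm.pdf(lvef, 65, 6) * norm.pdf(ea, 0.9, 0.2),
            0.3 * norm.pdf(lvef, 75, 9) * norm.pdf(ea, 1.2, 0.3),
        ])
        assert post.probabilities == pytest.approx(dens / dens.sum(), abs=1e-12)

    def test_all_missing_rejected(self):
        m = _toy_model([1.0], [60], [5])
        with pytest.raises(DataError):
            ct.posterior_membership(m, ObservationSet(
                "p1", [70.0], {"lvef": [np.nan], "ea": [np.nan]}))

    def test_probabilities_sum_to_one_random_models(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            w = rng.dirichlet(np.ones(4))
            m = _toy_model(w, rng.uniform(40, 90, 4), rng.uniform(3, 15, 4))
            post = ct.posterior_membership(m, ObservationSet(
                "p", [rng.uniform(50, 95)], {"lvef": [rng.uniform(30, 95)]}))
            assert post.probabilities.sum() == pytest.approx(1.0, abs=1e-10)
            assert post.map_group == int(np.argmax(post.probabilities))

    def test_vanishing_noise_gives_perfect_single_visit_assignment(self):
        m = _toy_model([0.4, 0.3, 0.3], [50, 65, 80], [1e-3] * 3,
                       ea_means=[0.7, 1.0, 1.3], ea_sds=[1e-4] * 3)
        rng = np.random.default_rng(1)
        for _ in range(50):
            k = rng.integers(3)
            age = rng.uniform(55, 90)
            X = m.basis.design([age])
            post = ct.posterior_membership(m, ObservationSet("p", [age], {
                "lvef": [m.groups[k].predict("lvef", X)[0] + rng.normal(0, 1e-4)],
                "ea": [m.groups[k].predict("ea", X)[0] + rng.normal(0, 1e-5)]}))
            assert post.map_group == k


class TestCurvesAndEffectiveGroups:
    def test_constant_polynomial_curve(self):
        m = _toy_model([1.0], [66.3], [5])
        curves = ct.trajectory_curves(m, [50, 70, 90])
        assert curves["lvef"].to_numpy() == pytest.approx([66.3] * 3)

    def test_curve_at_reference_age_equals_intercept(self):
        g = GroupParameters(coefficients={"lvef": np.array([61.0, 4.0, -1.0]),
                                          "ea": np.array([0.9, 0.1, 0.0])},
                            residual_sd={"lvef": 5.0, "ea": 0.2})
        m = TrajectoryModel(k_max=1, weights=[1.0], groups=[g], concentration=1.0,
                            basis=AgeBasis(reference_age=70), priors={})
        curves = ct.trajectory_curves(m, [70.0])
        assert curves["lvef"].iloc[0] == pytest.approx(61.0)
        assert curves["ea"].iloc[0] == pytest.approx(0.9)

    @pytest.mark.parametrize("weights, expected_n", [
        ((0.5, 0.5, 0.0, 0.0), 2),
        ((0.996, 0.004, 0.0, 0.0), 1),
    ])
    def test_effective_group_threshold(self, weights, expected_n):
        m = _toy_model(weights, [50, 60, 70, 80], [5] * 4)
        order, mapping = ct.effective_groups(m, min_weight=0.01)
        assert len(order) == expected_n
        assert mapping[order[0]] == 1


class TestFit:
    def test_single_flat_group_collapses_to_one(self):
        cfg = separated_config(n=300, seed=2, n_groups=1)
        visits, *_ = ct.generate_cohort(cfg)
        model = ct.fit_trajectories(visits, k_max=8, restarts=2, seed=3)
        order, _ = ct.effective_groups(model, min_weight=0.01)
        assert len(order) == 1
        assert model.weights[order[0]] >= 0.99

    def test_three_group_recovery(self, separated_cohort, separated_fit):
        model = separated_fit
        truth = separated_cohort["truth"]
        order, _ = ct.effective_groups(model, min_weight=0.01)
        assert len(order) == 3
        w = np.sort(model.weights[order])[::-1]
        assert np.allclose(w, [0.5, 0.3, 0.2], atol=0.05)
        assigned = ct.assign_memberships(model, separated_cohort["visits"])
        t = truth.set_index("participant_id").loc[
            assigned["participant_id"], "group"]
        assert map_accuracy(t.to_numpy(), assigned["map_group"].to_numpy()) >= 0.98

    def test_participant_order_invariance(self, separated_cohort):
        """Permuting participants leaves curves and weights unchanged up to
        group relabelling (same initial responsibilities, permuted rows)."""
        visits = separated_cohort["visits"]
        pids = visits["participant_id"].unique()
        n, K = len(pids), 6
        rng = np.random.default_rng(5)
        r0 = rng.dirichlet(np.ones(K), size=n)
        m1 = ct.fit_trajectories(visits, k_max=K, initial_responsibilities=r0)

        perm = rng.permutation(n)
        key = {p: i for p, i in zip(pids, perm)}
        shuffled = visits.sort_values("participant_id", key=lambda s: s.map(key),
                                      kind="stable").reset_index(drop=True)
        order_of_appearance = shuffled["participant_id"].unique()
        r0_perm = r0[[np.flatnonzero(pids == p)[0] for p in order_of_appearance]]
        m2 = ct.fit_trajectories(shuffled, k_max=K, initial_responsibilities=r0_perm)

        assert np.allclose(np.sort(m1.weights), np.sort(m2.weights), atol=1e-8)
        c1 = np.sort([g.coefficients["lvef"][0] for g in m1.groups])
        c2 = np.sort([g.coefficients["lvef"][0] for g in m2.groups])
        assert np.allclose(c1, c2, atol=1e-6)

    def test_elbo_monotone_and_deterministic(self, separated_cohort):
        visits = separated_cohort["visits"]
        m1 = ct.fit_trajectories(visits, k_max=6, restarts=2, seed=17)
        m2 = ct.fit_trajectories(visits, k_max=6, restarts=2, seed=17)
        assert m1.fit_meta["elbo"] == m2.fit_meta["elbo"]
        assert np.array_equal(m1.weights, m2.weights)
        trace = np.asarray(m1.fit_meta["elbo_trace"])
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-8 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_training_responsibilities_match_posterior_membership(self, separated_cohort, separated_fit):
        visits = separated_cohort["visits"]
        batch = ct.assign_memberships(separated_fit, visits)
        probs = batch[[f"prob_{k}" for k in range(separated_fit.k_max)]].to_numpy()
        for i, pid in enumerate(batch["participant_id"][:40]):
            sub = visits[visits["participant_id"] == pid]
            post = ct.posterior_membership(separated_fit, ObservationSet(
                pid, sub["age_years"].to_numpy(),
                {"lvef": sub["lvef_pct"].to_numpy(), "ea": sub["ea_ratio"].to_numpy()}))
            assert np.max(np.abs(post.probabilities - probs[i])) < 1e-6

    def test_empty_and_nonfinite_inputs_rejected(self):
        with pytest.raises(DataError):
            ct.fit_trajectories(pd.DataFrame(columns=[
                "participant_id", "age_years", "lvef_pct", "ea_ratio"]))
        bad = pd.DataFrame({"participant_id": ["a", "b"], "age_years": [60.0, np.inf],
                            "lvef_pct": [60.0, 61.0], "ea_ratio": [1.0, 1.0]})
        with pytest.raises(DataError):
            ct.fit_trajectories(bad)


class TestSerialization:
    def test_round_trip_lossless(self, separated_fit, tmp_path):
        path = tmp_path / "model.json"
        ct.save_model(separated_fit, path)
        loaded = ct.load_model(path)
        assert np.max(np.abs(loaded.weights - separated_fit.weights)) <= 1e-12
        for g1, g2 in zip(loaded.groups, separated_fit.groups):
            for t in ("lvef", "ea"):
                assert np.max(np.abs(np.asarray(g1.coefficients[t])
                                     - np.asarray(g2.coefficients[t]))) <= 1e-12
                assert abs(g1.residual_sd[t] - g2.residual_sd[t]) <= 1e-12
        assert loaded.basis == separated_fit.basis

    def test_dict_round_trip_identity(self, separated_fit):
        doc = model_to_dict(separated_fit)
        again = model_to_dict(model_from_dict(doc))
        assert doc == again
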