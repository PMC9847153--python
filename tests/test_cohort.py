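import logging

import numpy as np
import pandas as pd
import pytest

from ppdscore import cohort
from ppdscore.cohort import CultivarTrajectory
from ppdscore.exceptions import ClusteringError, MissingTimepointError


def make_assessments(rows):
    return pd.DataFrame(
        rows, columns=["cultivar", "root_id", "dph", "method", "root_score",
                       "contaminated"]
    )


class TestFiltering:
    def test_one_of_nine_flagged_rounds_to_11pct(self):
        rows = [("cv", f"r{i}", 7, "longitudinal", 0.3, i == 0) for i in range(9)]
        retained, contamination = cohort.filter_contaminated(make_assessments(rows))
        assert len(retained) == 8
        assert contamination.loc[0, "contamination_pct"] == 11

    def test_none_flagged(self):
        rows = [("cv", f"r{i}", 7, "longitudinal", 0.3, False) for i in range(6)]
        retained, contamination = cohort.filter_contaminated(make_assessments(rows))
        assert len(retained) == 6
        assert contamination.loc[0, "contamination_pct"] == 0

    def test_all_flagged_warns_and_empties(self, caplog):
        rows = [("cv", f"r{i}", 7, "longitudinal", 0.3, True) for i in range(4)]
        with caplog.at_level(logging.WARNING, logger="ppdscore.cohort"):
            retained, contamination = cohort.filter_contaminated(
                make_assessments(rows)
            )
        assert retained.empty
        assert contamination.loc[0, "contamination_pct"] == 100
        assert any("contaminated" in rec.message for rec in caplog.records)

    def test_fully_contaminated_timepoint_becomes_missing_mean(self):
        rows = [("cv", f"r{i}", t, "longitudinal", 0.3, t == 7)
                for t in (0, 2, 4, 7) for i in range(4)]
        trajs = cohort.build_trajectories(make_assessments(rows))
        traj = trajs[0]
        assert np.isnan(traj.mean[7])
        with pytest.raises(MissingTimepointError, match="7"):
            cohort.average_ppd_score(traj)


class TestAggregation:
    def test_mean_sd_n(self):
        mean, sd, n = cohort.aggregate_timepoint([0.1, 0.2, 0.3])
        assert mean == pytest.approx(0.2)
        assert sd == pytest.approx(0.1)
        assert n == 3

    def test_single_score_degenerate_sd(self):
        mean, sd, n = cohort.aggregate_timepoint([0.25])
        assert mean == 0.25 and n == 1
        assert np.isnan(sd)

    def test_empty_is_missing_never_zero(self):
        mean, sd, n = cohort.aggregate_timepoint([])
        assert np.isnan(mean) and n == 0

    def test_matches_two_pass_oracle(self, rng):
        scores = rng.uniform(size=50)
        mean, sd, n = cohort.aggregate_timepoint(scores)
        m = sum(scores) / 50
        s = (sum((x - m) ** 2 for x in scores) / 49) ** 0.5
        assert mean == pytest.approx(m, abs=1e-12)
        assert sd == pytest.approx(s, abs=1e-12)

    def test_baseline_dph_0_and_1_pooled(self):
        rows = [("cv", "r1", 0, "longitudinal", 0.1, False),
                ("cv", "r2", 1, "longitudinal", 0.3, False)]
        traj = cohort.build_trajectories(make_assessments(rows))[0]
        assert traj.mean[0] == pytest.approx(0.2)
        assert 1 not in traj.mean


class TestAverageScore:
    def test_reported_averages(self, reference_trajectories, reference_cohort):
        """The published average-score column is the rounded mean of the four
        reported time-point means, for every one of the 28 cultivars."""
        reported = dict(
            zip(reference_cohort["cultivar"], reference_cohort["average_ppd_score"])
        )
        for traj in reference_trajectories:
            avg = cohort.round_half_up(cohort.average_ppd_score(traj))
            assert avg == pytest.approx(reported[traj.cultivar], abs=1e-12)

    def test_constant_trajectory(self):
        traj = CultivarTrajectory("cv", {0: 0.3, 2: 0.3, 4: 0.3, 7: 0.3})
        assert cohort.average_ppd_score(traj) == pytest.approx(0.3)

    def test_missing_timepoint_named_in_error(self):
        traj = CultivarTrajectory("cv", {0: 0.1, 2: 0.2, 7: 0.3})
        with pytest.raises(MissingTimepointError, match=r"\[4\]"):
            cohort.average_ppd_score(traj)

    @pytest.mark.parametrize("value,expected", [(0.285, 0.29), (0.1725, 0.17),
                                                (0.2975, 0.30), (0.315, 0.32)])
    def test_report_rounding_is_half_up(self, value, expected):
        assert cohort.round_half_up(value) == expected


def random_trajectories(rng, n, timepoints=(2, 4, 7)):
    return [
        CultivarTrajectory(f"c{i}", {t: rng.uniform() for t in timepoints})
        for i in range(n)
    ]


class TestKmeans:
    def test_k1_centroid_is_grand_mean(self, rng):
        trajs = random_trajectories(rng, 8)
        model = cohort.kmeans_cluster(trajs, k=1, restarts=5, seed=0)
        X = np.array([[t.mean[tp] for tp in (2, 4, 7)] for t in trajs])
        assert model.centroids[0] == pytest.approx(X.mean(axis=0))
        tss = ((X - X.mean(axis=0)) ** 2).sum()
        assert model.wcss == pytest.approx(tss)

    def test_k_equals_n_zero_wcss(self, rng):
        trajs = random_trajectories(rng, 5)
        model = cohort.kmeans_cluster(trajs, k=5, restarts=10, seed=0)
        assert model.wcss == pytest.approx(0.0, abs=1e-12)
        assert sorted(model.labels) == [1, 2, 3, 4, 5]

    def test_k_exceeding_n_raises(self, rng):
        with pytest.raises(ClusteringError):
            cohort.kmeans_cluster(random_trajectories(rng, 3), k=4)

    def test_duplicate_cultivars_raise(self):
        trajs = [CultivarTrajectory("same", {2: 0.1, 4: 0.2, 7: 0.3})] * 2
        with pytest.raises(ClusteringError):
            cohort.kmeans_cluster(trajs, k=1)

    def test_missing_feature_timepoint_raises(self):
        trajs = [CultivarTrajectory("a", {2: 0.1, 4: 0.2})]
        with pytest.raises(ClusteringError, match="a"):
            cohort.kmeans_cluster(trajs, k=1)

    def test_deterministic_given_seed(self, rng):
        trajs = random_trajectories(rng, 12)
        a = cohort.kmeans_cluster(trajs, k=3, restarts=20, seed=7)
        b = cohort.kmeans_cluster(trajs, k=3, restarts=20, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centroids, b.centroids)
        assert a.wcss == b.wcss

    def test_best_of_restarts_invariant(self, rng):
        trajs = random_trajectories(rng, 15)
        model = cohort.kmeans_cluster(trajs, k=4, restarts=30, seed=3)
        assert model.wcss <= min(model.restart_wcss) + 1e-12
        X = np.array([[t.mean[tp] for tp in (2, 4, 7)] for t in trajs])
        d2 = ((X[:, None, :] - model.centroids[None]) ** 2).sum(axis=2)
        assert model.wcss == pytest.approx(
            d2[np.arange(len(X)), model.labels - 1].sum()
        )

    def test_matches_sklearn_objective(self, rng):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        trajs = random_trajectories(rng, 12)
        X = np.array([[t.mean[tp] for tp in (2, 4, 7)] for t in trajs])
        model = cohort.kmeans_cluster(trajs, k=3, restarts=50, seed=0)
        sk = sklearn_cluster.KMeans(n_clusters=3, n_init=50, random_state=0).fit(X)
        assert model.wcss == pytest.approx(sk.inertia_, rel=1e-9)

    def test_recovers_archetype_partition(self):
        from sklearn.metrics import adjusted_rand_score

        from ppdscore import synthetic

        archetypes = tuple(
            a for a in synthetic.DEFAULT_ARCHETYPES
            if a.label in ("delayed", "intermediate-peak", "early")
        )
        spec = synthetic.CohortSimSpec(
            archetypes=archetypes, cultivars_per_archetype=4,
            score_noise_sd=0.04, seed=5,
        )
        assessments, truth = synthetic.simulate_cohort(spec)
        trajs = cohort.build_trajectories(assessments)
        model = cohort.kmeans_cluster(trajs, k=3, restarts=100, seed=5)
        truth_map = dict(zip(truth["cultivar"], truth["class"]))
        labels_true = [truth_map[c] for c in model.cultivars]
        assert adjusted_rand_score(labels_true, model.labels) == 1.0


class TestStatusAssignment:
    def make_cluster(self, means_by_cultivar, membership):
        trajs = [CultivarTrajectory(c, dict(m)) for c, m in means_by_cultivar.items()]
        return cohort.status_from_membership(trajs, membership)

    def test_high_average_is_early_regardless_of_peak(self):
        calls = self.make_cluster(
            {"a": {0: 0.35, 2: 0.40, 4: 0.42, 7: 0.43}}, {"a": 1}
        )
        assert calls[0].status == "early"

    def test_low_average_low_peak_is_delayed(self):
        calls = self.make_cluster(
            {"a": {0: 0.12, 2: 0.2, 4: 0.25, 7: 0.23}}, {"a": 1}
        )
        assert calls[0].status == "delayed"

    def test_low_average_high_peak_is_intermediate(self):
        calls = self.make_cluster(
            {"a": {0: 0.10, 2: 0.15, 4: 0.40, 7: 0.15}}, {"a": 1}
        )
        assert calls[0].status == "intermediate"

    def test_status_is_cluster_constant(self, reference_trajectories,
                                        reference_cohort):
        membership = dict(zip(reference_cohort["cultivar"],
                              reference_cohort["cluster"]))
        calls = cohort.status_from_membership(reference_trajectories, membership)
        by_cluster = {}
        for c in calls:
            by_cluster.setdefault(c.cluster, set()).add(c.status)
        assert all(len(s) == 1 for s in by_cluster.values())

    def test_reported_statuses_reproduced(self, reference_trajectories,
                                          reference_cohort):
        """The threshold rule applied to the published cluster memberships
        reproduces the published delayed/intermediate/early labels."""
        membership = dict(zip(reference_cohort["cultivar"],
                              reference_cohort["cluster"]))
        calls = cohort.status_from_membership(reference_trajectories, membership)
        reported = dict(zip(reference_cohort["cultivar"],
                            reference_cohort["status"]))
        assert {c.cultivar: c.status for c in calls} == reported

    def test_assign_status_uses_model_membership(self, rng):
        trajs = random_trajectories(rng, 6, timepoints=(0, 2, 4, 7))
        model = cohort.kmeans_cluster(trajs, k=2, restarts=10, seed=0)
        calls = cohort.assign_status(model, trajs)
        assert {c.cultivar for c in calls} == {t.cultivar for t in trajs}
        assert all(c.status in cohort.STATUSES for c in calls)


class TestSummaryTable:
    def test_shape_and_rounding(self, reference_trajectories, reference_cohort):
        membership = dict(zip(reference_cohort["cultivar"],
                              reference_cohort["cluster"]))
        calls = cohort.status_from_membership(reference_trajectories, membership)
        table = cohort.summary_table(reference_trajectories, calls)
        assert len(table) == 28
        assert {"cultivar", "mean_4dph", "average_ppd_score", "cluster",
                "status"} <= set(table.columns)
        # sorted by average score, best storability first
        avgs = table["average_ppd_score"].to_numpy()
        assert (np.diff(avgs) >= 0).all()
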