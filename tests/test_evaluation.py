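"""MCC statistics, threshold scan, rarefaction, and experiment drivers."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from helpers import (
    brute_quality,
    brute_stability,
    components_partition,
    graph_is_transitive,
    random_partition,
    random_sparse_dm,
    random_units,
    threshold_graph,
)
from otubench.denovo import method_cluster_fn
from otubench.distance import DistanceMatrix, distance_matrix
from otubench.evaluation import (
    ConfusionCounts,
    mcc,
    otu_abundances,
    quality_confusion,
    rarefy_otu_count,
    run_quality_experiment,
    run_stability_experiment,
    stability_confusion,
    subsample_reads,
    summarize_experiment,
    threshold_scan,
)
from otubench.seqio import OTUPartition
from otubench.synthetic import CommunitySpec, generate_community


class TestMCC:
    def test_perfect_agreement(self):
        assert mcc(ConfusionCounts(10, 10, 0, 0)).mcc == 1.0

    def test_perfect_disagreement(self):
        assert mcc(ConfusionCounts(0, 0, 5, 5)).mcc == -1.0

    def test_hand_arithmetic(self):
        res = mcc(ConfusionCounts(6, 2, 1, 1))
        assert res.mcc == pytest.approx(11 / 21)
        assert res.sensitivity == pytest.approx(6 / 7)
        assert res.specificity == pytest.approx(2 / 3)

    @pytest.mark.parametrize(
        "counts",
        [(0, 0, 0, 0), (0, 5, 0, 0), (5, 0, 0, 0), (0, 0, 5, 0), (0, 0, 0, 5),
         (0, 2, 0, 1), (1, 0, 2, 0)],
    )
    def test_denominator_zero_returns_zero(self, counts):
        assert mcc(ConfusionCounts(*counts)).mcc == 0.0

    def test_sensitivity_specificity_zero_denominators(self):
        res = mcc(ConfusionCounts(0, 0, 0, 0))
        assert res.sensitivity == 0.0 and res.specificity == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


def triangle_dm():
    dm = DistanceMatrix(["A", "B", "C"], storage_cutoff=0.10)
    dm.set("A", "B", 0.02)
    dm.set("A", "C", 0.05)
    dm.set("B", "C", 0.05)
    return dm


class TestQualityConfusion:
    def test_correct_partition_gives_mcc_one(self):
        part = OTUPartition("0.03", [{"A", "B"}, {"C"}])
        c = quality_confusion(part, triangle_dm(), 0.03)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 2, 0, 0)
        assert mcc(c).mcc == 1.0

    def test_all_singletons(self):
        part = OTUPartition("0.03", [{"A"}, {"B"}, {"C"}])
        c = quality_confusion(part, triangle_dm(), 0.03)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 2, 0, 1)
        assert mcc(c).mcc == 0.0

    def test_one_big_otu(self):
        part = OTUPartition("0.03", [{"A", "B", "C"}])
        c = quality_confusion(part, triangle_dm(), 0.03)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 0, 2, 0)
        assert mcc(c).mcc == 0.0

    def test_boundary_distance_is_tp_side_when_inclusive(self):
        dm = DistanceMatrix(["A", "B"], storage_cutoff=0.10)
        dm.set("A", "B", 0.03)
        part = OTUPartition("x", [{"A", "B"}])
        assert quality_confusion(part, dm, 0.03, inclusive=True).tp == 1
        assert quality_confusion(part, dm, 0.03, inclusive=False).fp == 1

    def test_missing_id_is_error(self):
        part = OTUPartition("x", [{"A", "Z"}])
        with pytest.raises(ValueError, match="Z"):
            quality_confusion(part, triangle_dm(), 0.03)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 30))
            dm = random_sparse_dm(rng, n)
            part = random_partition(rng, dm.ids)
            c = quality_confusion(part, dm, 0.05)
            assert (c.tp, c.tn, c.fp, c.fn) == brute_quality(part, dm, 0.05)
            assert c.total == n * (n - 1) // 2

    def test_invariant_under_relabeling(self, rng):
        dm = random_sparse_dm(rng, 12)
        part = random_partition(rng, dm.ids)
        shuffled = OTUPartition(
            "other",
            list(reversed(part.otus)),
            otu_labels=[f"X{i}" for i in range(part.n_otus)],
        )
        a = quality_confusion(part, dm, 0.05)
        b = quality_confusion(shuffled, dm, 0.05)
        assert (a.tp, a.tn, a.fp, a.fn) == (b.tp, b.tn, b.fp, b.fn)

    def test_mcc_one_iff_components_and_transitive(self, rng):
        # forward: components partition scores 1 iff the threshold graph is
        # transitive; reverse: a random partition scoring 1 must equal the
        # components of a transitive graph
        t = 0.05
        seen_forward = 0
        for _ in range(60):
            dm = random_sparse_dm(rng, int(rng.integers(3, 10)))
            g = threshold_graph(dm, t)
            cc = components_partition(dm, t)
            val = mcc(quality_confusion(cc, dm, t)).mcc
            if graph_is_transitive(g) and g.number_of_edges() > 0 and (
                cc.n_otus > 1
            ):
                assert val == pytest.approx(1.0)
                seen_forward += 1
            part = random_partition(rng, dm.ids)
            if mcc(quality_confusion(part, dm, t)).mcc == pytest.approx(1.0):
                assert graph_is_transitive(g)
                assert part.as_sets() == cc.as_sets()
        assert seen_forward > 0


class TestStabilityConfusion:
    def test_self_agreement(self):
        part = OTUPartition("x", [{"A", "B"}, {"C"}])
        c = stability_confusion(part, part)
        assert c.fp == 0 and c.fn == 0
        assert mcc(c).mcc == 1.0

    def test_hand_enumeration_merge_in_full(self):
        sub = OTUPartition("sub", [{"A", "B"}, {"C"}])
        full = OTUPartition("full", [{"A", "B", "C", "D"}])
        c = stability_confusion(sub, full)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 0, 0, 2)

    def test_zero_denominator_case(self):
        sub = OTUPartition("sub", [{"A"}, {"B"}])
        full = OTUPartition("full", [{"A", "B"}])
        c = stability_confusion(sub, full)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 0, 1)
        assert mcc(c).mcc == 0.0

    def test_sub_id_absent_from_full_is_error(self):
        sub = OTUPartition("sub", [{"A", "Z"}])
        full = OTUPartition("full", [{"A", "B"}])
        with pytest.raises(ValueError, match="Z"):
            stability_confusion(sub, full)

    def test_matches_brute_force_and_pair_conservation(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 30))
            ids = [f"s{i}" for i in range(n)]
            sub = random_partition(rng, ids)
            full = random_partition(rng, ids)
            c = stability_confusion(sub, full)
            assert (c.tp, c.tn, c.fp, c.fn) == brute_stability(sub, full)
            assert c.total == n * (n - 1) // 2

    def test_symmetric_when_universes_coincide(self, rng):
        ids = [f"s{i}" for i in range(15)]
        a = random_partition(rng, ids)
        b = random_partition(rng, ids)
        assert mcc(stability_confusion(a, b)).mcc == pytest.approx(
            mcc(stability_confusion(b, a)).mcc
        )


class TestThresholdScan:
    def test_single_element_grid(self):
        part = OTUPartition("x", [{"A", "B"}, {"C"}])
        best, curve = threshold_scan(part, triangle_dm(), [0.03])
        assert best == 0.03 and set(curve) == {0.03}

    def test_empty_grid_is_error(self):
        part = OTUPartition("x", [{"A"}])
        with pytest.raises(ValueError):
            threshold_scan(part, triangle_dm(), [])

    def test_tie_returns_smallest_threshold(self):
        # all-singleton partition on all-distant data: MCC constant at 0
        dm = DistanceMatrix(["A", "B"], storage_cutoff=0.10)
        part = OTUPartition("x", [{"A"}, {"B"}])
        best, curve = threshold_scan(part, dm)
        assert best == 0.0
        assert all(r.mcc == 0.0 for r in curve.values())

    def test_recovers_generating_structure_threshold(self):
        # community whose within-cluster distances extend into (0.02, 0.03]
        spec = CommunitySpec(
            n_clusters=5, variants_per_cluster=3, intra_divergence=0.03,
            inter_divergence=0.15, seq_length=200, n_reads=400,
            error_rate=0.0, seed=11,
        )
        units, truth = generate_community(spec)
        dm = distance_matrix(units, mode="from_alignment", storage_cutoff=0.10)
        best, curve = threshold_scan(truth.planted_partition, dm)
        assert best == 0.03
        assert curve[0.03].mcc == pytest.approx(1.0)
        assert curve[0.02].mcc < 1.0

    def test_grid_above_cutoff_is_error(self):
        part = OTUPartition("x", [{"A", "B"}])
        with pytest.raises(ValueError):
            threshold_scan(part, triangle_dm(), [0.5])


class TestRarefaction:
    def test_full_depth_returns_observed_count(self):
        sizes = {"o1": 5, "o2": 3, "o3": 9}
        assert rarefy_otu_count(sizes, 17) == pytest.approx(3.0)

    def test_single_read(self):
        assert rarefy_otu_count([4, 6], 1) == pytest.approx(1.0)

    def test_hand_hypergeometric(self):
        assert rarefy_otu_count([2, 1], 2) == pytest.approx(5 / 3)

    def test_errors(self):
        with pytest.raises(ValueError):
            rarefy_otu_count([2, 1], 4)
        with pytest.raises(ValueError):
            rarefy_otu_count([2, 1], 0)
        with pytest.raises(ValueError):
            rarefy_otu_count([], 1)

    def test_analytic_matches_monte_carlo(self, rng):
        for _ in range(5):
            sizes = rng.integers(1, 30, size=int(rng.integers(3, 12)))
            N = int(sizes.sum())
            n = int(rng.integers(1, N + 1))
            reps = 4000
            analytic = rarefy_otu_count(sizes, n)
            draws = rng.multivariate_hypergeometric(sizes, n, size=reps)
            observed = (draws > 0).sum(axis=1)
            se = observed.std(ddof=1) / math.sqrt(reps)
            assert abs(analytic - observed.mean()) <= max(3 * se, 1e-6)

    def test_montecarlo_mode_is_seeded(self):
        a = rarefy_otu_count([5, 3, 2], 4, mode="montecarlo", reps=200, seed=1)
        b = rarefy_otu_count([5, 3, 2], 4, mode="montecarlo", reps=200, seed=1)
        assert a == b


class TestSubsampling:
    def test_subsample_preserves_id_space_and_total(self, planted_community, rng):
        units, _ = planted_community
        sub = subsample_reads(units, 100, rng)
        assert sub.total_reads == 100
        assert set(sub.ids) <= set(units.ids)

    def test_bad_sizes(self, planted_community, rng):
        units, _ = planted_community
        with pytest.raises(ValueError):
            subsample_reads(units, 0, rng)
        with pytest.raises(ValueError):
            subsample_reads(units, units.total_reads + 1, rng)


class TestExperiments:
    def test_stability_fraction_one_deterministic_method_gives_mcc_one(
        self, planted_community
    ):
        units, _ = planted_community
        fn = method_cluster_fn("DGC", 0.03)  # abundance-ordered: order-insensitive
        df = run_stability_experiment(
            units, fn, fractions=[1.0], n_subsample_reps=2, n_full_perms=3, seed=5
        )
        assert len(df) == 6
        assert (df["mcc"] == 1.0).all()

    def test_planted_community_fully_stable_at_every_fraction(
        self, planted_community
    ):
        units, _ = planted_community
        fn = method_cluster_fn("AGC", 0.03)
        df = run_stability_experiment(
            units, fn, fractions=[0.2, 0.6], n_subsample_reps=3, n_full_perms=3,
            seed=2,
        )
        assert (df["mcc"] == 1.0).all()

    def test_comparison_count_shape(self, planted_community):
        units, _ = planted_community
        fn = method_cluster_fn("DGC", 0.03)
        df = run_stability_experiment(
            units, fn, fractions=[0.4], n_subsample_reps=4, n_full_perms=5, seed=0
        )
        assert len(df) == 20
        assert df.groupby("fraction").size().tolist() == [20]

    def test_invalid_fraction(self, planted_community):
        units, _ = planted_community
        fn = method_cluster_fn("DGC", 0.03)
        with pytest.raises(ValueError):
            run_stability_experiment(units, fn, fractions=[1.5])

    def test_quality_experiment_planted_mean_one(self, planted_community):
        units, _ = planted_community
        fn = method_cluster_fn("AL", 0.03)
        df = run_quality_experiment(
            units, fn, fractions=[0.4, 0.8], reps=3, seed=4
        )
        assert np.allclose(df["mcc"], 1.0)
        summary = summarize_experiment(df)
        assert np.allclose(summary["mean"], 1.0)
        assert np.allclose(summary["lo"], 1.0)

    def test_quality_experiment_reps_one_interval_collapses(
        self, planted_community
    ):
        units, _ = planted_community
        fn = method_cluster_fn("DGC", 0.03)
        df = run_quality_experiment(units, fn, fractions=[0.5], reps=1, seed=9)
        s = summarize_experiment(df)
        assert s.loc[0, "lo"] == s.loc[0, "hi"] == s.loc[0, "mean"]

    def test_same_seed_reruns_identical(self, planted_community):
        units, _ = planted_community
        fn = method_cluster_fn("DGC", 0.03)
        a = run_quality_experiment(units, fn, fractions=[0.3], reps=3, seed=12)
        b = run_quality_experiment(units, fn, fractions=[0.3], reps=3, seed=12)
        pd.testing.assert_frame_equal(a, b)


class TestPartitionDegradation:
    def test_planted_partition_beats_degraded_versions(self, planted_community, rng):
        # random merges/splits of the planted partition never improve
        # quality MCC
        units, truth = planted_community
        dm = distance_matrix(units, mode="from_alignment", storage_cutoff=0.10)
        base = mcc(quality_confusion(truth.planted_partition, dm, 0.03)).mcc
        assert base == pytest.approx(1.0)
        for _ in range(100):
            otus = [set(o) for o in truth.planted_partition.otus]
            if rng.random() < 0.5 and len(otus) >= 2:
                i, j = rng.choice(len(otus), size=2, replace=False)
                otus[int(i)] |= otus[int(j)]
                del otus[int(j)]
            else:
                k = int(rng.integers(0, len(otus)))
                members = sorted(otus[k])
                if len(members) < 2:
                    continue
                cut = int(rng.integers(1, len(members)))
                otus[k] = set(members[:cut])
                otus.append(set(members[cut:]))
            degraded = OTUPartition("deg", otus)
            assert mcc(quality_confusion(degraded, dm, 0.03)).mcc <= base + 1e-12


class TestOtuAbundances:
    def test_sums_unit_abundances(self, planted_community):
        units, truth = planted_community
        sizes = otu_abundances(truth.planted_partition, units)
        assert sum(sizes.values()) == units.total_reads
        assert len(sizes) == truth.planted_partition.n_otus
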