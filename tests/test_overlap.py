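import numpy as np
import pytest

from orthoeval.overlap import (
    Partition,
    adjusted_rand,
    fgkcs,
    heatmap_layout,
    load_manual_og_registry,
    overlap_fraction_matrix,
    partition_from_orthology,
    perfect_overlap_groups,
    shuffle_calibration,
    splitting_report,
)
from conftest import make_orthology, pair_agreement_ari


def part(labels: list) -> Partition:
    return Partition({i: lb for i, lb in enumerate(labels)})


class TestAdjustedRand:
    def test_identical_partitions_score_one(self):
        p = part(["x", "x", "y", "y", "z"])
        assert adjusted_rand(p, p).value == 1.0

    def test_single_block_vs_itself_degenerate_one(self):
        p = part(["x"] * 5)
        s = adjusted_rand(p, p)
        assert s.value == 1.0 and s.degenerate

    def test_single_block_vs_singletons_is_zero(self):
        a = part(["x"] * 5)
        b = part(list("abcde"))
        assert adjusted_rand(a, b).value == 0.0

    def test_worked_example_matches_pair_oracle(self):
        a = part(["A", "A", "A", "B", "B"])
        b = part(["C", "C", "D", "D", "D"])
        expected = pair_agreement_ari(
            ["A", "A", "A", "B", "B"], ["C", "C", "D", "D", "D"]
        )
        assert adjusted_rand(a, b).value == pytest.approx(expected, abs=1e-12)

    def test_random_partitions_match_pair_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            la = [f"a{v}" for v in rng.integers(0, max(2, n // 2), n)]
            lb = [f"b{v}" for v in rng.integers(0, max(2, n // 2), n)]
            got = adjusted_rand(part(la), part(lb))
            expected = pair_agreement_ari(la, lb)
            if expected is None:
                assert got.degenerate
            else:
                assert got.value == pytest.approx(expected, abs=1e-10)

    def test_symmetry_and_sklearn_cross_check(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(23)
        for _ in range(50):
            n = int(rng.integers(3, 15))
            la = list(rng.integers(0, 4, n))
            lb = list(rng.integers(0, 4, n))
            ab = adjusted_rand(part(la), part(lb))
            ba = adjusted_rand(part(lb), part(la))
            assert ab.value == pytest.approx(ba.value, abs=1e-12)
            if not ab.degenerate:
                assert ab.value == pytest.approx(
                    adjusted_rand_score(la, lb), abs=1e-10
                )

    def test_restricts_to_shared_universe(self):
        a = Partition({1: "x", 2: "x", 3: "y", 99: "y"})
        b = Partition({1: "u", 2: "u", 3: "v", 42: "w"})
        assert adjusted_rand(a, b).n_genes == 3

    def test_tiny_universe_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            adjusted_rand(Partition({1: "x"}), Partition({1: "y"}))


class TestFgkcs:
    def test_identical_partitions_score_one(self):
        p = part(["x", "x", "y", "y"])
        assert fgkcs(p, p).value == 1.0

    def test_singletons_vs_one_cluster(self):
        n = 6
        ref = part(["r"] * n)
        pred = part([f"s{i}" for i in range(n)])
        assert fgkcs(ref, pred).value == pytest.approx(2 / (n + 1))

    def test_three_one_split(self):
        ref = part(["r", "r", "r", "r"])
        pred = part(["p", "p", "p", "q"])
        # best match: k=3, precision 1, recall 3/4 -> F = 6/7
        assert fgkcs(ref, pred).value == pytest.approx(6 / 7)

    def test_not_symmetric_in_general(self):
        ref = part(["r", "r", "s", "t"])
        pred = part(["p", "p", "p", "p"])
        # forward: mean of best-F over {r},{s},{t} = (2/3 + 2/5 + 2/5)/3
        # reverse: single reference cluster with best F = 2/3
        assert fgkcs(ref, pred).value == pytest.approx((2 / 3 + 0.4 + 0.4) / 3)
        assert fgkcs(pred, ref).value == pytest.approx(2 / 3)


class TestShuffleCalibration:
    ORTH = make_orthology(
        {
            f"OG{i}": [f"S{j}|p{i}_{j}" for j in range(6)]
            for i in range(8)
        }
    )

    def test_zero_fraction_scores_exactly_one(self):
        curve = shuffle_calibration(self.ORTH, [0], n_reps=3, seed=1)
        assert curve.loc[0, "ars_mean"] == 1.0
        assert curve.loc[0, "fgkcs_mean"] == 1.0

    def test_full_shuffle_near_chance_and_monotone(self):
        curve = shuffle_calibration(
            self.ORTH, [0, 25, 50, 100], n_reps=30, seed=2
        )
        means = curve["ars_mean"].to_numpy()
        sds = curve["ars_sd"].to_numpy()
        # chance level at 100% shuffling, within Monte-Carlo error
        assert abs(means[-1]) < 3 * sds[-1] / np.sqrt(30) + 0.05
        # non-increasing within noise tolerance
        for i in range(len(means) - 1):
            assert means[i + 1] <= means[i] + 2 * (sds[i] + sds[i + 1])

    def test_fraction_outside_range_rejected(self):
        with pytest.raises(ValueError):
            shuffle_calibration(self.ORTH, [150], n_reps=1, seed=0)


class TestOverlapMatrix:
    def test_fully_contained_manual_og(self):
        manual = make_orthology({"M1": ["A|p1", "B|p2", "C|p3", "D|p4"]}, "manual")
        inferred = make_orthology(
            {"I1": ["A|p1", "B|p2", "C|p3", "D|p4", "E|x"]}, "m"
        )
        m = overlap_fraction_matrix(manual, inferred)
        assert m.fractions.tolist() == [[1.0]]

    def test_split_manual_og_fractions(self):
        manual = make_orthology(
            {"M1": ["A|p1", "B|p2", "C|p3", "D|p4", "E|p5"]}, "manual"
        )
        inferred = make_orthology(
            {"I1": ["A|p1", "B|p2", "C|p3"], "I2": ["D|p4", "E|p5"]}, "m"
        )
        m = overlap_fraction_matrix(manual, inferred)
        assert sorted(m.fractions[0].tolist()) == [0.4, 0.6]

    def test_unassigned_genes_shrink_row_sum(self):
        manual = make_orthology(
            {"M1": ["A|p1", "B|p2", "C|p3", "D|p4", "E|p5"]}, "manual"
        )
        inferred = make_orthology({"I1": ["A|p1", "B|p2", "C|p3", "D|p4"]}, "m")
        m = overlap_fraction_matrix(manual, inferred)
        assert m.fractions.sum() == pytest.approx(0.8)


class TestSplittingReport:
    def test_perfect_mapping(self):
        manual = make_orthology({"M1": ["A|p1", "B|p2"], "M2": ["C|p3"]}, "manual")
        r = splitting_report(overlap_fraction_matrix(manual, manual))
        assert r.oversplit_pct == 0.0
        assert r.undersplit_pct == 0.0
        assert r.assignment_pct == 100.0

    def test_oversplit_forty_percent(self):
        manual = make_orthology(
            {"M1": ["A|p1", "B|p2", "C|p3", "D|p4", "E|p5"]}, "manual"
        )
        inferred = make_orthology(
            {"I1": ["A|p1", "B|p2", "C|p3"], "I2": ["D|p4", "E|p5"]}, "m"
        )
        r = splitting_report(overlap_fraction_matrix(manual, inferred))
        assert r.oversplit_pct == pytest.approx(40.0)
        assert r.undersplit_pct == 0.0

    def test_undersplit_forty_percent(self):
        manual = make_orthology(
            {
                "M1": [f"S{i}|a{i}" for i in range(4)],
                "M2": [f"S{i}|b{i}" for i in range(6)],
            },
            "manual",
        )
        union = [f"S{i}|a{i}" for i in range(4)] + [f"S{i}|b{i}" for i in range(6)]
        inferred = make_orthology({"I1": union}, "m")
        r = splitting_report(overlap_fraction_matrix(manual, inferred))
        assert r.undersplit_pct == pytest.approx(40.0)
        assert r.oversplit_pct == 0.0


class TestPerfectOverlap:
    def test_identical_orthologies_share_everything(self):
        a = make_orthology({"O1": ["A|p1", "B|p2"], "O2": ["C|p3"]}, "a")
        b = make_orthology({"X9": ["A|p1", "B|p2"], "X8": ["C|p3"]}, "b")
        assert len(perfect_overlap_groups([a, b])) == 2

    def test_split_group_excluded(self):
        a = make_orthology({"O1": ["A|p1", "B|p2"], "O2": ["C|p3", "D|p4"]}, "a")
        b = make_orthology(
            {"X1": ["A|p1", "B|p2"], "X2": ["C|p3"], "X3": ["D|p4"]}, "b"
        )
        shared = perfect_overlap_groups([a, b])
        assert len(shared) == 1 and len(shared[0]) == 2

    def test_three_methods_brute_force(self):
        import random

        rng = random.Random(5)
        base = {
            f"OG{i}": [f"S{j}|g{i}_{j}" for j in range(rng.randrange(2, 5))]
            for i in range(10)
        }
        a = make_orthology(base, "a")
        spoiled = dict(base)
        for og in ["OG0", "OG1", "OG2", "OG3", "OG4", "OG5"]:
            spoiled[og] = base[og][:-1] + [f"ZZ|alt_{og}"]
        b = make_orthology(spoiled, "b")
        shared = perfect_overlap_groups([a, b, a])
        expected = {
            frozenset(a.groups[og]) for og in ["OG6", "OG7", "OG8", "OG9"]
        }
        assert set(shared) == expected


class TestHeatmapLayout:
    def test_rows_sorted_by_max_overlap(self):
        manual = make_orthology(
            {"Mlow": [f"S{i}|a{i}" for i in range(5)], "Mhigh": ["S0|b0", "S1|b1"]},
            "manual",
        )
        inferred = make_orthology(
            {"I1": ["S0|b0", "S1|b1"], "I2": ["S0|a0", "S1|a1"]}, "m"
        )
        rows, cols = heatmap_layout(overlap_fraction_matrix(manual, inferred))
        assert rows == ["Mhigh", "Mlow"]
        assert cols[0] == "I1"

    def test_layout_deterministic(self):
        rng = np.random.default_rng(8)
        manual = make_orthology(
            {f"M{i}": [f"S{j}|m{i}_{j}" for j in range(4)] for i in range(6)},
            "manual",
        )
        groups = {}
        for i in range(8):
            src = rng.integers(0, 6)
            groups[f"I{i}"] = [f"S{j}|m{src}_{j}" for j in range(rng.integers(1, 4))]
        inferred = make_orthology(groups, "m")
        inferred.disjoint = False
        m = overlap_fraction_matrix(manual, inferred)
        assert heatmap_layout(m) == heatmap_layout(m)


class TestManualRegistry:
    def test_packaged_registry_bookkeeping(self):
        df = load_manual_og_registry()
        counts = df.groupby("complex").size().to_dict()
        assert counts == {
            "Intraflagellar transport complex": 26,
            "Kinetochore": 91,
            "TBP-associated factors": 8,
        }
        assert len(df) == 125

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "reg.tsv"
        p.write_text("og_id\tcomplex\nX\tc1\nX\tc2\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_manual_og_registry(p)


class TestPartitionFromOrthology:
    def test_singletons_dropped(self):
        orth = make_orthology({"O1": ["A|p1", "B|p2"], "O2": ["C|p3"]})
        p = partition_from_orthology(orth)
        assert set(p.assignment.values()) == {"O1"}

    def test_non_disjoint_rejected(self):
        orth = make_orthology({"O1": ["A|p1", "B|p2"], "O2": ["A|p1", "C|p3"]})
        orth.disjoint = False
        with pytest.raises(ValueError, match="disjoint"):
            partition_from_orthology(orth)
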