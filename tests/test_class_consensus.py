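"""Category fractions, co-migration matching and consensus summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampaflex import class_consensus as cc
from ampaflex import synthetic_data as sd


def make_run(run_id, assignments, categories, k=None):
    return cc.ClassificationRun(
        run_id=run_id,
        k=k or len(categories),
        labels=dict(assignments),
        class_categories=dict(categories),
    )


def brute_force_matched_fraction(C):
    k = C.shape[0]
    best = max(
        sum(C[i, p[i]] for i in range(k)) for p in itertools.permutations(range(k))
    )
    return best / C.sum()


class TestCategoryFraction:
    def test_counting(self):
        cats = {"c1": "non_swapped", "c2": "swapped", "c3": "swapped"}
        labels = {f"p{i}": "c1" for i in range(3)}
        labels.update({f"q{i}": "c2" if i < 4 else "c3" for i in range(7)})
        run = make_run("r", labels, cats)
        assert cc.category_fraction(run, "non_swapped") == pytest.approx(0.3)
        assert cc.category_fraction(run, "swapped") == pytest.approx(0.7)

    def test_all_junk_is_error(self):
        run = make_run(
            "r",
            {"p1": "c1", "p2": "c2", "p3": "c3"},
            {"c1": "junk", "c2": "junk", "c3": "junk"},
        )
        with pytest.raises(ValueError):
            cc.category_fraction(run, "swapped")

    def test_binomial_recovery(self):
        rng = np.random.default_rng(0)
        n, p = 1000, 0.2
        swapped = rng.uniform(size=n) < p
        labels = {f"p{i}": ("c_ns" if swapped[i] else "c_sw") for i in range(n)}
        run = make_run(
            "r", labels, {"c_ns": "non_swapped", "c_sw": "swapped", "c_j": "junk"}
        )
        frac = cc.category_fraction(run, "non_swapped")
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_invariant_to_class_splitting(self):
        rng = np.random.default_rng(1)
        labels = {f"p{i}": ("cs" if rng.uniform() < 0.3 else "cn") for i in range(500)}
        run = make_run("r", labels, {"cs": "swapped", "cn": "non_swapped"}, k=3)
        split_labels = {
            p: (c if c != "cs" else ("cs1" if rng.uniform() < 0.5 else "cs2"))
            for p, c in labels.items()
        }
        split = make_run(
            "r2",
            split_labels,
            {"cs1": "swapped", "cs2": "swapped", "cn": "non_swapped"},
        )
        assert cc.category_fraction(split, "swapped") == pytest.approx(
            cc.category_fraction(run, "swapped")
        )


class TestComigration:
    def test_permuted_class_ids_match_fully(self):
        rng = np.random.default_rng(2)
        k = 5
        cats = {f"c{j}": "swapped" for j in range(k)}
        labels = {f"p{i}": f"c{rng.integers(k)}" for i in range(1000)}
        run_a = make_run("a", labels, cats)
        perm = dict(zip(cats, rng.permutation(list(cats))))
        run_b = make_run("b", {p: perm[c] for p, c in labels.items()}, cats)
        mf, _ = cc.comigration_matched_fraction(run_a, run_b)
        assert mf == pytest.approx(1.0)

    def test_hand_checked_2x2_contingency(self):
        # contingency [[2,1],[0,3]]: optimal matching keeps 5 of 6 particles
        labels_a = {"p1": "x", "p2": "x", "p3": "x", "p4": "y", "p5": "y", "p6": "y"}
        labels_b = {"p1": "u", "p2": "u", "p3": "v", "p4": "v", "p5": "v", "p6": "v"}
        run_a = make_run("a", labels_a, {"x": "swapped", "y": "swapped"}, k=3)
        run_b = make_run("b", labels_b, {"u": "swapped", "v": "swapped"}, k=3)
        mf, matching = cc.comigration_matched_fraction(run_a, run_b)
        assert mf == pytest.approx(5.0 / 6.0)
        assert matching == [("x", "u"), ("y", "v")]

    def test_independent_labelings_match_near_1_over_k(self):
        rng = np.random.default_rng(3)
        k, n = 5, 10000
        cats = {f"c{j}": "swapped" for j in range(k)}
        run_a = make_run("a", {f"p{i}": f"c{rng.integers(k)}" for i in range(n)}, cats)
        run_b = make_run("b", {f"p{i}": f"c{rng.integers(k)}" for i in range(n)}, cats)
        mf, _ = cc.comigration_matched_fraction(run_a, run_b)
        assert abs(mf - 1.0 / k) < 0.03

    def test_assignment_equals_brute_force_small_k(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            k = int(rng.integers(2, 7))
            C = rng.integers(0, 30, size=(k, k)).astype(float)
            if C.sum() == 0:
                continue
            mf, _ = cc.matched_fraction_from_contingency(C)
            assert mf == pytest.approx(brute_force_matched_fraction(C), abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetry_and_relabel_invariance(self, seed):
        rng = np.random.default_rng(seed)
        k, n = int(rng.integers(3, 7)), 200
        cats = {f"c{j}": "swapped" for j in range(k)}
        la = {f"p{i}": f"c{rng.integers(k)}" for i in range(n)}
        lb = {f"p{i}": f"c{rng.integers(k)}" for i in range(n)}
        ra_ = make_run("a", la, cats)
        rb = make_run("b", lb, cats)
        mf_ab, _ = cc.comigration_matched_fraction(ra_, rb)
        mf_ba, _ = cc.comigration_matched_fraction(rb, ra_)
        assert mf_ab == pytest.approx(mf_ba, abs=1e-12)
        perm = dict(zip(cats, rng.permutation(list(cats))))
        rb2 = make_run("b2", {p: perm[c] for p, c in lb.items()}, cats)
        mf_ab2, _ = cc.comigration_matched_fraction(ra_, rb2)
        assert mf_ab2 == pytest.approx(mf_ab, abs=1e-12)

    def test_different_particle_sets_rejected(self):
        cats = {"c0": "swapped", "c1": "swapped", "c2": "swapped"}
        run_a = make_run("a", {"p1": "c0", "p2": "c1"}, cats)
        run_b = make_run("b", {"p1": "c0", "p3": "c1"}, cats)
        with pytest.raises(ValueError, match="particle sets"):
            cc.comigration_matched_fraction(run_a, run_b)

    def test_different_k_rejected(self):
        run_a = make_run("a", {"p1": "c0"}, {f"c{j}": "swapped" for j in range(3)})
        run_b = make_run("b", {"p1": "c0"}, {f"c{j}": "swapped" for j in range(4)})
        with pytest.raises(ValueError, match="different k"):
            cc.comigration_matched_fraction(run_a, run_b)


def _fraction_runs(fractions, n=20, k=6):
    """Runs over the same particles whose swapped fractions are as given."""
    runs = []
    cats = {"cs": "swapped", "cn": "non_swapped"}
    cats.update({f"c{j}": "non_swapped" for j in range(k - 2)})
    for i, f in enumerate(fractions):
        n_swapped = round(f * n)
        labels = {
            f"p{j:03d}": ("cs" if j < n_swapped else "cn") for j in range(n)
        }
        runs.append(make_run(f"r{i}", labels, cats, k=k))
    return runs


class TestSummarizeConsensus:
    def test_hand_computed_mean_and_sem(self):
        runs = _fraction_runs([0.20, 0.25, 0.30])
        summary = cc.summarize_consensus(runs, category="swapped")
        assert summary.n == 3
        assert summary.mean == pytest.approx(0.25)
        assert summary.sem == pytest.approx(0.05 / np.sqrt(3))
        assert summary.sem == pytest.approx(0.0289, abs=1e-4)

    def test_identical_runs_have_zero_sem(self):
        runs = _fraction_runs([0.25] * 5)
        summary = cc.summarize_consensus(runs, category="swapped")
        assert summary.mean == pytest.approx(0.25)
        assert summary.sem == 0.0
        assert summary.n == 5

    def test_out_of_range_runs_excluded(self):
        runs = _fraction_runs([0.2, 0.2], k=6) + _fraction_runs([0.9], k=25)
        summary = cc.summarize_consensus(runs, category="swapped")
        assert summary.n == 2
        assert summary.mean == pytest.approx(0.2)

    def test_inconsistent_runs_error(self):
        # two runs with disjoint class usage never co-migrate above threshold
        cats = {"c0": "swapped", "c1": "swapped", "c2": "swapped",
                "c3": "swapped", "c4": "swapped", "c5": "swapped"}
        rng = np.random.default_rng(9)
        run_a = make_run(
            "a", {f"p{i}": f"c{rng.integers(6)}" for i in range(600)}, cats
        )
        run_b = make_run(
            "b", {f"p{i}": f"c{rng.integers(6)}" for i in range(600)}, cats
        )
        with pytest.raises(ValueError, match="consistent"):
            cc.summarize_consensus([run_a, run_b], category="swapped")

    def test_planted_fraction_recovered_with_noise(self):
        truth = sd.GroundTruth(swapped_fraction=0.3, label_noise=0.05, seed=5)
        runs = sd.simulate_classifications(8000, truth, range(6, 21, 2), 3)
        summary = cc.summarize_consensus(runs, category="swapped")
        assert abs(summary.mean - 0.3) < 0.03


def test_csv_round_trip(tmp_path):
    import pandas as pd

    truth = sd.GroundTruth(swapped_fraction=0.25, label_noise=0.02, seed=6)
    runs = sd.simulate_classifications(500, truth, [6, 8], 2)
    labels = pd.concat(
        pd.DataFrame(
            {
                "particle_id": list(r.labels),
                "run_id": r.run_id,
                "class_id": list(r.labels.values()),
            }
        )
        for r in runs
    )
    cats = pd.concat(
        pd.DataFrame(
            {
                "run_id": r.run_id,
                "class_id": list(r.class_categories),
                "category": list(r.class_categories.values()),
            }
        )
        for r in runs
    )
    labels.to_csv(tmp_path / "labels.csv", index=False)
    cats.to_csv(tmp_path / "cats.csv", index=False)
    back = cc.read_runs_csv(tmp_path / "labels.csv", tmp_path / "cats.csv")
    assert len(back) == len(runs)
    by_id = {r.run_id: r for r in back}
    for r in runs:
        assert by_id[r.run_id].labels == r.labels
        assert by_id[r.run_id].k == r.k
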