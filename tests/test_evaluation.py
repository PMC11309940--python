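import math

import numpy as np
import pandas as pd
import pytest

from metanets.delineation import Delineation, Metacommunity
from metanets.evaluation import (
    DegenerateEvaluation,
    agreement_metrics,
    beta_distribution_test,
    binarize_beta,
    classify_pairs,
    enumerate_pairs,
    evaluate_all,
)
from metanets.diversity import OccurrenceMatrix

from conftest import square_layer


def delineation_of(groups, singletons=(), unassigned=()):
    mcs = [
        Metacommunity(mc_id=name, members=list(members), source_patches=[],
                      extent=None, singleton=name in singletons)
        for name, members in groups.items()
    ]
    return Delineation(source="test", timestep_label=0, theta=None,
                       metacommunities=mcs, unassigned=list(unassigned))


def matrix_of(ids, species_sets):
    species = sorted({s for ss in species_sets for s in ss})
    df = pd.DataFrame(
        [[1 if s in ss else 0 for s in species] for ss in species_sets],
        index=ids, columns=species,
    )
    return OccurrenceMatrix(presence=df)


def hand_welch(a, b):
    """Independent oracle: Welch statistic from first principles."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


class TestEnumeratePairs:
    def setup_method(self):
        self.layer = square_layer([(0, 0), (100, 0), (0, 100), (25_000, 0)],
                                  size=10.0)
        ids = self.layer.ids
        self.matrix = matrix_of(ids, [{"a"}, {"b"}, {"c"}, {"d"}])

    def test_all_within_limit(self):
        pairs = enumerate_pairs(self.matrix, self.layer, limit=1_000.0)
        assert len(pairs) == 3  # C(3,2); the 25 km patch contributes none

    def test_distant_patch_pairs_dropped(self):
        pairs = enumerate_pairs(self.matrix, self.layer, limit=15_000.0)
        names = set(pairs["patch_i"]) | set(pairs["patch_j"])
        assert "p0003" not in names

    def test_infinite_limit_gives_all_pairs(self):
        pairs = enumerate_pairs(self.matrix, self.layer, limit=float("inf"))
        assert len(pairs) == 6  # C(4,2)


class TestClassifyPairs:
    def test_within_between_enumeration(self):
        pairs = pd.DataFrame(
            [(i, j, 1.0) for k, i in enumerate(["P1", "P2", "P3", "P4"])
             for j in ["P1", "P2", "P3", "P4"][k + 1:]],
            columns=["patch_i", "patch_j", "separation_m"],
        )
        d = delineation_of({"MC1": ["P1", "P2"], "MC2": ["P3", "P4"]})
        classes, n_exc = classify_pairs(pairs, d)
        within = {tuple(r) for r, c in zip(pairs[["patch_i", "patch_j"]].values,
                                           classes) if c == "within"}
        assert within == {("P1", "P2"), ("P3", "P4")}
        assert (classes == "between").sum() == 4
        assert n_exc == 0

    def test_singleton_metacommunity_pairs_excluded(self):
        pairs = pd.DataFrame(
            [("P1", "P5", 1.0), ("P1", "P2", 1.0)],
            columns=["patch_i", "patch_j", "separation_m"],
        )
        d = delineation_of({"MC1": ["P1", "P2"], "MC5": ["P5"]},
                           singletons=("MC5",))
        classes, n_exc = classify_pairs(pairs, d)
        assert n_exc == 1
        assert classes.tolist() == [None, "within"]

    def test_all_in_one_metacommunity_flagged_degenerate(self):
        layer = square_layer([(0, 0), (20, 0), (40, 0)], size=10.0)
        matrix = matrix_of(layer.ids, [{"a"}, {"a", "b"}, {"b"}])
        d = delineation_of({"MC1": list(layer.ids)})
        results, _ = evaluate_all([d], matrix, layer)
        assert bool(results.loc[0, "degenerate"])  # zero between pairs
        assert not results.loc[0, "best"]


class TestBinarize:
    def test_median_split(self):
        classes, thr = binarize_beta([0.2, 0.5, 0.8, 0.9])
        assert thr == pytest.approx(0.65)
        assert classes.tolist() == ["low", "low", "high", "high"]

    def test_value_at_threshold_is_high(self):
        classes, _ = binarize_beta([0.3, 0.8, 0.8], threshold=0.8)
        assert classes.tolist() == ["low", "high", "high"]

    def test_fixed_threshold(self):
        classes, _ = binarize_beta([0.79, 0.80], threshold=0.8)
        assert classes.tolist() == ["low", "high"]

    def test_all_identical_degenerate(self):
        with pytest.raises(DegenerateEvaluation):
            binarize_beta([0.8, 0.8, 0.8])

    def test_at_most_half_below_median(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            vals = rng.choice([0.1, 0.5, 0.8, 0.8, 0.9], size=21)
            if vals.min() == vals.max():
                continue
            classes, _ = binarize_beta(vals)
            assert (classes == "low").sum() <= len(vals) / 2


class TestAgreementMetrics:
    def test_worked_contingency(self):
        acc, prec, kappa = agreement_metrics([[40, 10], [10, 40]])
        assert acc == pytest.approx(0.8)
        assert prec == pytest.approx(0.8)
        assert kappa == pytest.approx(0.6)

    def test_perfect_agreement(self):
        acc, _, kappa = agreement_metrics([[50, 0], [0, 50]])
        assert acc == 1.0
        assert kappa == 1.0

    def test_degenerate_marginals_flag_kappa(self):
        acc, prec, kappa = agreement_metrics([[10, 0], [0, 0]])
        assert math.isnan(kappa)

    def test_matches_sklearn_on_random_tables(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(12)
        for _ in range(100):
            c = rng.integers(1, 40, size=(2, 2))
            acc, _, kappa = agreement_metrics(c)
            y_true = ["w"] * (c[0, 0] + c[0, 1]) + ["b"] * (c[1, 0] + c[1, 1])
            y_pred = (["w"] * c[0, 0] + ["b"] * c[0, 1]
                      + ["w"] * c[1, 0] + ["b"] * c[1, 1])
            ref = sklearn_metrics.cohen_kappa_score(y_true, y_pred)
            assert kappa == pytest.approx(ref, abs=1e-12)
            assert acc == pytest.approx(
                sklearn_metrics.accuracy_score(y_true, y_pred), abs=1e-12
            )

    def test_kappa_invariant_under_simultaneous_label_swap(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            c = rng.integers(1, 30, size=(2, 2))
            _, _, k1 = agreement_metrics(c)
            swapped = c[::-1, ::-1]
            _, _, k2 = agreement_metrics(swapped)
            assert k1 == pytest.approx(k2, abs=1e-12)

    def test_kappa_near_zero_under_shuffled_labels(self):
        rng = np.random.default_rng(14)
        kappas = []
        beta_class = np.array(["low"] * 100 + ["high"] * 100)
        for _ in range(300):
            pair_class = rng.permutation(np.array(["within"] * 90 + ["between"] * 110))
            c = np.array([
                [((pair_class == "within") & (beta_class == "low")).sum(),
                 ((pair_class == "within") & (beta_class == "high")).sum()],
                [((pair_class == "between") & (beta_class == "low")).sum(),
                 ((pair_class == "between") & (beta_class == "high")).sum()],
            ])
            kappas.append(agreement_metrics(c)[2])
        assert abs(np.mean(kappas)) < 0.05


class TestBetaDistributionTest:
    def test_welch_worked_example(self):
        t, p, df, ok = beta_distribution_test([0.2, 0.3, 0.4], [0.8, 0.9, 1.0])
        assert t == pytest.approx(-7.348, abs=5e-4)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.0018, abs=2e-4)
        assert ok is True

    def test_identical_groups(self):
        t, p, _, ok = beta_distribution_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert t == 0.0
        assert p == pytest.approx(1.0)
        assert ok is False

    def test_direction_decoupled_from_significance(self):
        t, p, _, ok = beta_distribution_test([0.8, 0.9, 1.0], [0.1, 0.2, 0.3])
        assert p < 0.01
        assert ok is False

    def test_matches_hand_welch_on_random_inputs(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            a = rng.normal(0.6, 0.15, rng.integers(3, 30))
            b = rng.normal(0.8, 0.1, rng.integers(3, 30))
            t, _, df, _ = beta_distribution_test(a, b)
            t_ref, df_ref = hand_welch(a, b)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert df == pytest.approx(df_ref, abs=1e-10)

    def test_student_variant_available(self):
        a, b = [0.2, 0.3, 0.4], [0.8, 0.9, 1.0]
        t_w, _, df_w, _ = beta_distribution_test(a, b, equal_var=False)
        t_s, _, df_s, _ = beta_distribution_test(a, b, equal_var=True)
        assert df_s == pytest.approx(4.0)
        assert t_s == pytest.approx(t_w, abs=1e-9)  # equal variances here


class TestEvaluateAll:
    def test_single_delineation_best_iff_direction_ok(self):
        layer = square_layer([(0, 0), (20, 0), (2000, 0), (2020, 0)], size=10.0)
        ids = layer.ids
        matrix = matrix_of(ids, [{"a", "b"}, {"a", "b", "c"}, {"x", "y"},
                                 {"x", "z"}])
        d = delineation_of({"MC1": ids[:2], "MC2": ids[2:]})
        results, diag = evaluate_all([d], matrix, layer)
        assert len(results) == 1
        assert bool(results.loc[0, "best"]) == bool(results.loc[0, "direction_ok"])
        assert results.loc[0, "n_within"] == 2
        assert results.loc[0, "n_between"] == 4
        assert set(diag.columns) >= {"patch_i", "patch_j", "beta", "beta_class"}

    def test_metric_ranges_on_synthetic_study(self, small_study):
        from metanets.experiments import score_study

        results = score_study(small_study)
        assert (results["kappa"].dropna().abs() <= 1).all()
        assert results["accuracy"].dropna().between(0, 1).all()
        assert results["precision"].dropna().between(0, 1).all()

    def test_shared_pair_universe_across_delineations(self, small_study):
        from metanets.experiments import score_study

        results = score_study(small_study)
        # eligibility exclusions aside, the pair universe is shared: within +
        # between + excluded is constant across rows
        totals = results["n_within"] + results["n_between"] + results["n_excluded"]
        assert totals.nunique() == 1
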