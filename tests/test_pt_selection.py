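import numpy as np
import pytest

from mrs._exceptions import SelectionError, ValidationError
from mrs.da_tests import DAResult, run_da
from mrs.evaluation import roc_auc
from mrs.feature_io import RELATIVE_ABUNDANCE, FeatureTable, to_relative_abundance
from mrs.mrs_core import SubCommunity, mrs_alpha, mrs_standard
from mrs.pt_selection import (
    TERMINAL_EPS,
    apply_subcommunity,
    candidate_thresholds,
    fold_selected_taxa,
    grid_score_matrix,
    pt_select,
)
from mrs.synthetic_data import default_spec, simulate_microbiome


def _da(p_values, effects=None):
    p = np.asarray(p_values, float)
    eff = np.asarray(effects, float) if effects is not None else np.zeros_like(p)
    return DAResult([f"t{i}" for i in range(p.size)], p, eff, "test", 5, 5)


class TestCandidateThresholds:
    def test_unique_plus_terminal(self):
        grid = candidate_thresholds(_da([0.01, 0.2, 0.2, 0.9]))
        np.testing.assert_allclose(grid, [0.01, 0.2, 0.9, 1.0 + TERMINAL_EPS])

    def test_thinning_to_quantiles(self):
        p = np.random.default_rng(0).uniform(size=500)
        grid = candidate_thresholds(_da(p), max_grid=100)
        assert grid.size == 101
        # nearest-rank thinning keeps observed p-values only
        assert set(grid[:-1]).issubset(set(p))

    def test_single_taxon(self):
        grid = candidate_thresholds(_da([0.37]))
        np.testing.assert_allclose(grid, [0.37, 1.0 + TERMINAL_EPS])

    def test_nestedness_of_threshold_sets(self):
        p = np.random.default_rng(1).uniform(size=40)
        da = _da(p)
        grid = candidate_thresholds(da)
        sets = [frozenset(np.where(p < t)[0]) for t in grid]
        for small, big in zip(sets, sets[1:]):
            assert small <= big


class TestGridScores:
    """The prefix-sum fast path must agree with direct sub-community scoring."""

    @pytest.mark.parametrize("spec", ["shannon", "simpson", "observed", "unweighted_sum"])
    def test_matches_direct_scoring(self, spec):
        rng = np.random.default_rng(7)
        q, n = 12, 9
        values = rng.dirichlet(np.full(q, 0.3), size=n).T
        values[rng.random((q, n)) < 0.3] = 0.0
        values = values / np.where(values.sum(0) == 0, 1, values.sum(0))
        table = FeatureTable([f"t{i}" for i in range(q)], [f"s{j}" for j in range(n)],
                             values, RELATIVE_ABUNDANCE)
        p = rng.uniform(size=q)
        thresholds = candidate_thresholds(_da(p))
        fast = grid_score_matrix(values, p, thresholds, spec)
        for ti, t in enumerate(thresholds):
            idx = np.where(p < t)[0]
            if idx.size == 0:
                continue
            sub = SubCommunity([table.feature_ids[i] for i in idx])
            if spec == "unweighted_sum":
                direct = mrs_standard(table, sub, "unweighted").score
            else:
                direct = mrs_alpha(table, sub, spec).score
            np.testing.assert_allclose(fast[ti], direct, atol=1e-10)

    def test_weighted_sum_matches_dot_product(self):
        rng = np.random.default_rng(8)
        q, n = 6, 5
        values = rng.random((q, n))
        p = rng.uniform(size=q)
        w = rng.normal(size=q)
        thresholds = candidate_thresholds(_da(p))
        fast = grid_score_matrix(values, p, thresholds, "weighted_sum", weights=w)
        for ti, t in enumerate(thresholds):
            mask = p < t
            np.testing.assert_allclose(fast[ti], w[mask] @ values[mask], atol=1e-10)


def _perfect_fixture():
    """One taxon perfectly separating cases and controls among mild noise."""
    rng = np.random.default_rng(5)
    n1 = n0 = 10
    n = n1 + n0
    q = 6
    counts = rng.integers(50, 100, size=(q, n)).astype(float)
    counts[0, :n1] = rng.integers(250, 300, n1)  # cases loaded with the signal taxon
    counts[0, n1:] = rng.integers(1, 10, n0)
    table = FeatureTable([f"t{i}" for i in range(q)], [f"s{j}" for j in range(n)],
                         counts, "counts")
    y = np.repeat([1, 0], [n1, n0])
    return table, y


class TestPTSelect:
    def test_perfect_separator_alone_is_chosen_with_auc_one(self):
        """A single perfectly separating taxon with the smallest p-value is
        selected on its own and yields held-out AUC 1."""
        table, y = _perfect_fixture()
        p = np.array([0.001] + [0.5, 0.6, 0.7, 0.8, 0.9])
        da = DAResult(list(table.feature_ids), p, np.array([1.0, 0, 0, 0, 0, 0]),
                      "external", 10, 10)
        with pytest.warns(UserWarning, match="leakage"):
            pt = pt_select(table, y, da_method=da, score_spec="unweighted_sum", cv="loo")
        assert pt.chosen_taxa.taxa == ["t0"]
        assert pt.cv_auc.max() == pytest.approx(1.0)
        assert roc_auc(pt.per_sample_cv_scores, y).auc == pytest.approx(1.0)

    def test_builtin_da_ranks_separator_first_with_high_auc(self):
        table, y = _perfect_fixture()
        da = run_da(table, y, method="wilcoxon")
        assert np.argmin(da.p_value) == 0
        pt = pt_select(table, y, score_spec="unweighted_sum", cv="loo")
        assert "t0" in pt.chosen_taxa.taxa
        assert pt.cv_auc.max() >= 0.95

    def test_deterministic(self, small_cohort):
        y = small_cohort.metadata.outcome
        a = pt_select(small_cohort.microbiome, y, cv="kfold", k=5, seed=3)
        b = pt_select(small_cohort.microbiome, y, cv="kfold", k=5, seed=3)
        np.testing.assert_array_equal(a.thresholds, b.thresholds)
        np.testing.assert_array_equal(a.cv_auc, b.cv_auc)
        np.testing.assert_array_equal(a.per_sample_cv_scores, b.per_sample_cv_scores)
        assert a.chosen_taxa.taxa == b.chosen_taxa.taxa
        assert a.chosen_threshold == b.chosen_threshold

    def test_grid_refinement_never_decreases_max_cv_auc(self, small_cohort):
        y = small_cohort.metadata.outcome
        coarse = pt_select(small_cohort.microbiome, y, cv="kfold", k=5, seed=3, max_grid=5)
        fine = pt_select(small_cohort.microbiome, y, cv="kfold", k=5, seed=3, max_grid=10_000)
        assert set(coarse.thresholds).issubset(set(fine.thresholds))
        assert fine.cv_auc.max() >= coarse.cv_auc.max() - 1e-12

    def test_leakage_guard_fold_selection_ignores_held_out(self, small_cohort):
        table = small_cohort.microbiome
        y = small_cohort.metadata.outcome
        rng = np.random.default_rng(13)
        n = table.n_samples
        for _ in range(5):
            test_idx = rng.choice(n, size=6, replace=False)
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            before = fold_selected_taxa(table, y, train_idx, threshold=0.2)
            perturbed = table.copy()
            perturbed.values[:, test_idx] = rng.integers(0, 10_000, size=(table.n_features, 6))
            after = fold_selected_taxa(perturbed, y, train_idx, threshold=0.2)
            assert before == after

    def test_null_labels_give_moderate_max_auc(self):
        """With permuted labels the best CV-AUC reflects selection noise only.

        Bounds frozen from the null sampling distribution of this pipeline
        (max over the threshold grid of pooled LOO AUCs, n = 60, Q = 50).
        """
        maxima = []
        for rep in range(10):
            c = simulate_microbiome(default_spec(seed=20_000 + rep, n_cases=30,
                                                 n_controls=30, n_taxa=50,
                                                 log_fold_effect=0.0))
            pt = pt_select(c.microbiome, c.metadata.outcome, cv="loo", seed=rep)
            maxima.append(pt.cv_auc.max())
        assert 0.45 < min(maxima) and max(maxima) < 0.9
        assert np.mean(maxima) < 0.8

    def test_imported_da_used_for_all_folds_with_caveat(self, small_cohort):
        table = small_cohort.microbiome
        y = small_cohort.metadata.outcome
        da = run_da(table, y, method="wilcoxon")
        with pytest.warns(UserWarning, match="leakage"):
            pt = pt_select(table, y, da_method=da, cv="kfold", k=5, seed=1)
        assert pt.chosen_taxa.source == "wilcoxon"

    def test_single_class_errors(self, small_cohort):
        with pytest.raises(ValidationError):
            pt_select(small_cohort.microbiome, np.ones(small_cohort.microbiome.n_samples))

    def test_terminal_threshold_always_offers_full_table(self):
        # with every p equal, the only nonempty candidate is the terminal
        # 1+eps threshold, which selects the whole table
        table, y = _perfect_fixture()
        da_const = DAResult(list(table.feature_ids), np.zeros(table.n_features),
                            np.zeros(table.n_features), "x", 10, 10)
        with pytest.warns(UserWarning, match="leakage"):
            pt = pt_select(table, y, da_method=da_const, score_spec="unweighted_sum")
        assert pt.chosen_taxa.size == table.n_features


class TestApply:
    def test_self_application_matches_direct_scoring(self, small_cohort):
        table = small_cohort.microbiome
        sub = SubCommunity(small_cohort.truth["signal_taxa"])
        applied = apply_subcommunity(table, sub, "shannon")
        direct = mrs_alpha(to_relative_abundance(table), sub, "shannon")
        np.testing.assert_allclose(applied.score, direct.score, atol=1e-12)

    def test_missing_taxon_zero_filled(self, small_cohort):
        table = small_cohort.microbiome
        sub = SubCommunity([table.feature_ids[0], "not_a_taxon"])
        with pytest.warns(UserWarning, match="zero-filled"):
            scores = apply_subcommunity(table, sub, "shannon")
        assert scores.score.shape == (table.n_samples,)

    def test_no_overlap_errors(self, small_cohort):
        with pytest.raises(ValidationError, match="no sub-community taxon"):
            apply_subcommunity(small_cohort.microbiome, SubCommunity(["x", "y"]), "shannon")
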