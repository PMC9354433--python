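import io

import numpy as np
import pytest
import skbio

from mrs._exceptions import ValidationError
from mrs.feature_io import COUNTS, RELATIVE_ABUNDANCE, FeatureTable
from mrs.mrs_core import (
    RiskScoreVector,
    SubCommunity,
    mrs_alpha,
    mrs_standard,
    renormalize_subcommunity,
    signed_logcount_score,
    standardize_scores,
)


def _table(values, kind=RELATIVE_ABUNDANCE, subset=False):
    values = np.asarray(values, float)
    return FeatureTable(
        [f"t{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
        kind,
        subset=subset,
    )


class TestRenormalize:
    def test_renormalizes_within_subcommunity(self):
        table = _table([[0.2], [0.3], [0.5]])
        mt, degenerate = renormalize_subcommunity(table, SubCommunity(["t0", "t1"]))
        np.testing.assert_allclose(mt[:, 0], [0.4, 0.6], atol=1e-12)
        assert not degenerate[0]

    def test_all_zero_selected_flagged(self):
        table = _table([[0.0, 0.2], [0.0, 0.3], [1.0, 0.5]], subset=False)
        mt, degenerate = renormalize_subcommunity(table, SubCommunity(["t0", "t1"]))
        np.testing.assert_array_equal(mt[:, 0], [0.0, 0.0])
        assert degenerate[0] and not degenerate[1]

    def test_full_community_is_identity(self, rel_table):
        mt, _ = renormalize_subcommunity(rel_table, SubCommunity(rel_table.feature_ids))
        np.testing.assert_allclose(mt, rel_table.values, atol=1e-12)


class TestAlphaScores:
    def test_shannon_uniform_and_skewed(self):
        table = _table([[0.5, 0.8, 1.0], [0.5, 0.2, 0.0]])
        s = mrs_alpha(table, SubCommunity(["t0", "t1"]), "shannon")
        assert s.score[0] == pytest.approx(np.log(0.5), abs=1e-12)
        assert s.score[1] == pytest.approx(0.8 * np.log(0.8) + 0.2 * np.log(0.2), abs=1e-12)
        # single present taxon: minimal diversity
        assert s.score[2] == pytest.approx(0.0, abs=1e-12)

    def test_simpson_concentration(self):
        table = _table([[0.8, 1.0], [0.2, 0.0]])
        s = mrs_alpha(table, SubCommunity(["t0", "t1"]), "simpson")
        assert s.score[0] == pytest.approx(0.68, abs=1e-12)
        assert s.score[1] == pytest.approx(1.0, abs=1e-12)

    def test_observed_counts_present_taxa(self):
        table = _table([[0.8, 1.0], [0.2, 0.0]])
        s = mrs_alpha(table, SubCommunity(["t0", "t1"]), "observed")
        np.testing.assert_array_equal(s.score, [-2.0, -1.0])

    def test_all_zero_sample_gets_minimal_limit_and_flag(self):
        table = _table([[0.0], [0.0], [1.0]])
        sub = SubCommunity(["t0", "t1"])
        for index, limit in [("shannon", 0.0), ("simpson", 1.0), ("observed", 0.0)]:
            s = mrs_alpha(table, sub, index)
            assert s.score[0] == limit
            assert s.degenerate[0]

    def test_shannon_range_and_uniform_extreme(self):
        rng = np.random.default_rng(3)
        p = 6
        values = rng.dirichlet(np.ones(p), size=20).T
        table = _table(values)
        s = mrs_alpha(table, SubCommunity(table.feature_ids), "shannon")
        assert np.all(s.score <= 1e-12) and np.all(s.score >= -np.log(p) - 1e-12)

    def test_zero_everywhere_taxon_leaves_scores_unchanged(self, rel_table):
        sub = SubCommunity(["A", "B"])
        sub_plus = SubCommunity(["A", "B", "ghost"])
        for index in ("shannon", "simpson", "observed"):
            with pytest.warns(UserWarning, match="zero-filled"):
                extended = mrs_alpha(rel_table, sub_plus, index)
            base = mrs_alpha(rel_table, sub, index)
            np.testing.assert_allclose(base.score, extended.score, atol=1e-12)

    def test_taxon_order_invariance(self, rel_table):
        a = mrs_alpha(rel_table, SubCommunity(["A", "C"]), "shannon")
        b = mrs_alpha(rel_table, SubCommunity(["C", "A"]), "shannon")
        np.testing.assert_allclose(a.score, b.score, atol=1e-12)

    def test_compositional_invariance(self, small_cohort):
        """Scores act on relative abundances: per-sample count rescaling is a no-op."""
        table = small_cohort.microbiome
        scaled = table.copy()
        rng = np.random.default_rng(0)
        scaled.values = table.values * rng.uniform(0.5, 3.0, table.n_samples)
        sub = SubCommunity(table.feature_ids[:7])
        a = mrs_alpha(table, sub, "shannon")
        b = mrs_alpha(scaled, sub, "shannon")
        np.testing.assert_allclose(a.score, b.score, atol=1e-9)


class TestFaithPD:
    TREE = "((A:1,B:2):0.5,(C:3,D:1):0.25):0;"

    def _tree(self):
        return skbio.TreeNode.read(io.StringIO(self.TREE))

    def test_spanning_lengths_by_hand(self):
        # samples: {A,B} -> 3; {A,C} -> 4.75; {A} -> 0 (minimal limit)
        values = np.array(
            [
                [0.5, 0.5, 1.0],
                [0.5, 0.0, 0.0],
                [0.0, 0.5, 0.0],
                [0.0, 0.0, 0.0],
            ]
        )
        table = _table(values, subset=True)
        table.feature_ids[:] = ["A", "B", "C", "D"]
        sub = SubCommunity(["A", "B", "C", "D"])
        s = mrs_alpha(table, sub, "pd", tree=self._tree())
        np.testing.assert_allclose(s.score, [-3.0, -4.75, 0.0], atol=1e-12)

    def test_root_path_option(self):
        values = np.array([[0.5], [0.5], [0.0], [0.0]])
        table = _table(values, subset=True)
        table.feature_ids[:] = ["A", "B", "C", "D"]
        s = mrs_alpha(table, SubCommunity(["A", "B", "C", "D"]), "pd",
                      tree=self._tree(), include_root_path=True)
        assert s.score[0] == pytest.approx(-3.5, abs=1e-12)

    def test_missing_tree_or_leaf_errors(self, rel_table):
        with pytest.raises(ValidationError, match="tree"):
            mrs_alpha(rel_table, SubCommunity(["A"]), "pd")
        with pytest.raises(ValidationError, match="absent from tree"):
            mrs_alpha(rel_table, SubCommunity(["A"]), "pd", tree=self._tree().shear(["C", "D"]))


class TestStandardScores:
    def test_unweighted_sum(self):
        table = _table([[0.2], [0.3], [0.5]])
        s = mrs_standard(table, SubCommunity(["t0", "t1"]), "unweighted")
        assert s.score[0] == pytest.approx(0.5, abs=1e-12)

    def test_weighted_dot_product(self):
        table = _table([[0.2], [0.3], [0.5]])
        sub = SubCommunity(["t0", "t1"], weights=np.array([2.0, -1.0]))
        s = mrs_standard(table, sub, "weighted")
        assert s.score[0] == pytest.approx(0.1, abs=1e-12)

    def test_weighted_without_weights_errors(self):
        table = _table([[1.0]])
        with pytest.raises(ValidationError, match="weights"):
            mrs_standard(table, SubCommunity(["t0"]), "weighted")

    def test_absent_taxa_contribute_zero(self, rel_table):
        with pytest.warns(UserWarning, match="zero-filled"):
            s = mrs_standard(rel_table, SubCommunity(["nope", "nada"]), "unweighted")
        np.testing.assert_array_equal(s.score, np.zeros(4))

    def test_unweighted_equals_weighted_with_unit_weights(self, rel_table):
        sub1 = SubCommunity(["A", "C"])
        sub2 = SubCommunity(["A", "C"], weights=np.ones(2))
        a = mrs_standard(rel_table, sub1, "unweighted")
        b = mrs_standard(rel_table, sub2, "weighted")
        np.testing.assert_allclose(a.score, b.score, atol=1e-12)


class TestSignedLogCount:
    def test_closed_form(self):
        table = _table([[np.e - 1, 0.0]], kind=COUNTS)
        s = signed_logcount_score(table, ["t0"], [1])
        np.testing.assert_allclose(s.score, [1.0, 0.0], atol=1e-12)

    def test_opposite_signs_cancel(self):
        table = _table([[np.e - 1], [np.e - 1]], kind=COUNTS)
        s = signed_logcount_score(table, ["t0", "t1"], [1, -1])
        assert s.score[0] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_feature_errors(self, counts_table):
        with pytest.raises(ValidationError, match="absent"):
            signed_logcount_score(counts_table, ["A", "nope"], [1, -1])


class TestStandardize:
    def test_z_scoring(self):
        v = RiskScoreVector(["a", "b", "c"], [1.0, 2.0, 3.0], "x", "shannon")
        out = standardize_scores(v)
        np.testing.assert_allclose(out.score, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_idempotent_up_to_noise(self):
        rng = np.random.default_rng(5)
        v = RiskScoreVector([f"s{i}" for i in range(50)], rng.normal(3, 2, 50), "x", "shannon")
        once = standardize_scores(v)
        twice = standardize_scores(once)
        np.testing.assert_allclose(once.score, twice.score, atol=1e-12)

    def test_constant_vector_errors(self):
        v = RiskScoreVector(["a", "b"], [1.0, 1.0], "x", "shannon")
        with pytest.raises(ValidationError, match="constant"):
            standardize_scores(v)
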