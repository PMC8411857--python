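import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vfarch.aa import ArchetypeModel, Decomposition
from vfarch.errors import ValidationError
from vfarch.scoring import (
    SignAssignment,
    assign_signs,
    at_sum,
    cohort_report,
    dominant_archetype,
    match_classification,
    meaningful_archetypes,
)


def _decomp(weights):
    return Decomposition(weights=np.asarray(weights, dtype=float), residual_norm=0.0)


def _model(avg_td):
    avg_td = np.asarray(avg_td, dtype=float)
    k = len(avg_td)
    return ArchetypeModel(
        k=k,
        archetypes=np.tile(avg_td[:, None], (1, 54)),
        relative_weight=np.full(k, 1.0 / k),
        average_td=avg_td,
        rss=0.0,
        n_fit=k,
    )


@st.composite
def simplex_weights(draw):
    k = draw(st.integers(2, 14))
    raw = draw(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=k, max_size=k)
    )
    total = sum(raw)
    if total <= 0:
        raw = [1.0] * k
        total = float(k)
    return [100.0 * r / total for r in raw]


class TestMeaningful:
    def test_boundary_inclusive_at_threshold(self):
        assert meaningful_archetypes(_decomp([91, 9, 0]), 9) == {1, 2}

    def test_all_below_threshold_empty(self):
        assert meaningful_archetypes(_decomp([8.9] * 8 + [28.8]), 30) == set()

    def test_pure_field_singleton(self):
        assert meaningful_archetypes(_decomp([0, 100, 0]), 9) == {2}

    @given(simplex_weights())
    def test_count_bounded_by_floor_100_over_threshold(self, weights):
        ids = meaningful_archetypes(_decomp(weights), 9)
        assert len(ids) <= 11  # floor(100 / 9)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValidationError):
            meaningful_archetypes(_decomp([100.0]), 0)


class TestDominant:
    def test_majority_weight_wins(self):
        assert dominant_archetype(_decomp([57, 30, 13])) == 1

    def test_just_below_half_is_none(self):
        assert dominant_archetype(_decomp([49.9, 30.1, 20.0])) is None

    def test_fifty_fifty_tie_is_none(self):
        assert dominant_archetype(_decomp([50.0, 50.0])) is None


class TestSigns:
    def test_median_split_even_k_is_half_and_half(self):
        model = _model(np.linspace(2.0, -24.0, 14))
        signs = assign_signs(model)
        assert (signs.signs == 1).sum() == 7
        assert (signs.signs == -1).sum() == 7
        # higher average TD -> positive
        assert signs.signs[np.argmax(model.average_td)] == 1
        assert signs.signs[np.argmin(model.average_td)] == -1

    def test_two_archetypes(self):
        signs = assign_signs(_model([1.0, -10.0]))
        assert list(signs.signs) == [1, -1]

    def test_odd_k_median_positive(self):
        signs = assign_signs(_model([0.0, -5.0, -10.0]))
        assert list(signs.signs) == [1, 1, -1]

    def test_explicit_override(self):
        model = _model([0.0, -5.0, -10.0])
        signs = assign_signs(model, rule="explicit", explicit_positive=[3])
        assert list(signs.signs) == [-1, -1, 1]

    def test_explicit_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            assign_signs(_model([0.0, -5.0]), rule="explicit", explicit_positive=[3])


class TestATSum:
    def test_pure_positive_archetype_scores_plus_100(self):
        signs = SignAssignment(signs=np.array([1, -1]))
        assert at_sum(_decomp([100, 0]), signs).value == pytest.approx(100.0)

    def test_balanced_cancellation(self):
        signs = SignAssignment(signs=np.array([1, -1]))
        assert at_sum(_decomp([50, 50]), signs).value == pytest.approx(0.0)

    def test_signed_arithmetic(self):
        signs = SignAssignment(signs=np.array([1, -1, -1]))
        assert at_sum(_decomp([60, 25, 15]), signs).value == pytest.approx(20.0)

    @given(simplex_weights())
    def test_bounded_by_plus_minus_100(self, weights):
        k = len(weights)
        signs = SignAssignment(signs=np.array([1, -1] * (k // 2) + [1] * (k % 2)))
        v = at_sum(_decomp(weights), signs).value
        assert -100.0 - 1e-6 <= v <= 100.0 + 1e-6

    def test_sign_count_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            at_sum(_decomp([100, 0]), SignAssignment(signs=np.array([1, -1, 1])))


class TestMatchClassification:
    LABELS = {1: {"arcuate_inferior", "blind_spot_enlargement"}, 2: {"general_depression_mild"}}

    def test_exact(self):
        out = match_classification(1, self.LABELS, {"arcuate_inferior", "blind_spot_enlargement"})
        assert out == "exact"

    def test_different(self):
        out = match_classification(2, self.LABELS, {"arcuate_superior", "arcuate_inferior"})
        assert out == "different"

    def test_partial(self):
        out = match_classification(1, self.LABELS, {"blind_spot_enlargement"})
        assert out == "partial"

    def test_unlabeled_archetype_rejected(self):
        with pytest.raises(ValidationError, match="3"):
            match_classification(3, self.LABELS, {"normal"})

    @given(
        st.sets(st.sampled_from(["a", "b", "c", "d"]), min_size=1),
        st.sets(st.sampled_from(["a", "b", "c", "d"]), min_size=1),
    )
    def test_symmetric_in_tag_sets(self, s1, s2):
        assert match_classification(1, {1: s1}, s2) == match_classification(1, {1: s2}, s1)


class TestCohortReport:
    def test_constant_weight_correlation_skipped(self):
        decomps = [_decomp([100.0, 0.0]) for _ in range(10)]
        meta = pd.DataFrame({"md": np.linspace(-7, -2, 10)})
        rep = cohort_report(decomps, threshold=9, metadata=meta, covariates=("md",))
        at1 = rep["correlations"].query("variable == 'AT1'").iloc[0]
        assert at1["note"] == "constant weight" and np.isnan(at1["r"])

    def test_monotone_link_gives_strong_spearman(self):
        rng = np.random.default_rng(0)
        w1 = rng.uniform(10, 90, size=60)
        decomps = [_decomp([w, 100 - w]) for w in w1]
        md = -7 + 5 * (w1 / 100) + rng.normal(0, 0.05, size=60)
        rep = cohort_report(
            decomps, threshold=9, metadata=pd.DataFrame({"md": md}), covariates=("md",)
        )
        r = rep["correlations"].query("variable == 'AT1'")["r"].iloc[0]
        assert r >= 0.9

    def test_identical_groups_have_null_tests(self):
        rng = np.random.default_rng(1)
        W = rng.dirichlet([1, 1, 1], size=40) * 100
        decomps = [_decomp(w) for w in np.vstack([W, W])]
        meta = pd.DataFrame({"arm": ["a"] * 40 + ["b"] * 40})
        rep = cohort_report(decomps, threshold=9, metadata=meta, group_col="arm")
        tests = rep["group_tests"]
        chi2 = tests.query("test == 'chi2_frequency_table'")["statistic"].iloc[0]
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        wx = tests.query("test == 'wilcoxon_rank_sum'")
        assert np.allclose(wx["statistic"], 0.0, atol=1e-12)

    def test_frequency_and_count_tables(self):
        decomps = [_decomp([91, 9, 0]), _decomp([100, 0, 0]), _decomp([40, 40, 20])]
        rep = cohort_report(decomps, threshold=9)
        freq = rep["frequencies"].set_index("archetype")["n_meaningful"]
        assert list(freq) == [3, 2, 1]
        counts = rep["meaningful_counts"].set_index("n_archetypes")["n_fields"]
        assert counts.to_dict() == {1: 1, 2: 1, 3: 1}

    def test_holm_adjustment_column(self):
        rng = np.random.default_rng(2)
        W = rng.dirichlet([1, 1], size=30) * 100
        decomps = [_decomp(w) for w in W]
        meta = pd.DataFrame({"md": rng.normal(size=30)})
        rep = cohort_report(decomps, threshold=9, metadata=meta, covariates=("md",), holm=True)
        corr = rep["correlations"]
        assert "p_holm" in corr.columns
        ok = corr["p"].notna()
        assert (corr.loc[ok, "p_holm"] >= corr.loc[ok, "p"] - 1e-12).all()


def test_exact_permutation_p_matches_enumeration_bounds():
    # n = 6 distinct pairs: exact two-sided permutation p for a perfectly
    # monotone pairing is 2/6! (the identity and the full reversal)
    rng = np.random.default_rng(3)
    w = np.sort(rng.uniform(10, 90, size=6))
    decomps = [_decomp([v, 100 - v]) for v in w]
    meta = pd.DataFrame({"md": np.arange(6, dtype=float)})
    rep = cohort_report(
        decomps, threshold=9, metadata=meta, covariates=("md",), exact_small_n=True
    )
    at1 = rep["correlations"].query("variable == 'AT1'").iloc[0]
    assert at1["r"] == pytest.approx(1.0)
    assert at1["p"] == pytest.approx(2 / 720)
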