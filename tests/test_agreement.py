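"""Agreement counts, Jaccard, persistence, and the comorbidity medians."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dxopt import (
    AgreementCounts,
    DiagnosticRule,
    comorbidity_axis1,
    comorbidity_axis2,
    cross_tabulate,
    jaccard,
    persistence,
    profile_lattice,
    validity_profile,
)
from dxopt.agreement import AGREEMENT_MEASURES
from dxopt.core_data import ConfigError, DimensionError
from dxopt.rule_space import apply_rule, enumerate_rules


class TestCrossTabulate:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 1, 0, 0], [1, 0, 1, 0], (1, 1, 1, 1)),
            ([1, 0], [1, 0], (1, 0, 0, 1)),
            ([0, 0, 0], [0, 0, 0], (0, 0, 0, 3)),
        ],
    )
    def test_counts_partition_n(self, x, y, expected):
        counts = cross_tabulate(x, y)
        assert (counts.a, counts.b, counts.c, counts.d) == expected
        assert counts.n == len(x)

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            cross_tabulate([1, 0], [1])


class TestJaccard:
    def test_published_overlap_counts(self):
        # counts from the 2x2 cross-classification of the two competing
        # diagnoses in the survey application: 536/(536+145+189)
        assert jaccard(AgreementCounts(536, 145, 189, 14906)) == pytest.approx(
            0.6161, abs=1e-4
        )

    def test_perfect_and_zero_agreement(self):
        assert jaccard(AgreementCounts(5, 0, 0, 3)) == 1.0
        assert jaccard(AgreementCounts(0, 2, 3, 1)) == 0.0

    def test_undefined_is_marked_not_zero(self):
        assert jaccard(AgreementCounts(0, 0, 0, 7)) is None

    @given(
        a=st.integers(0, 50), b=st.integers(0, 50), c=st.integers(0, 50),
        d1=st.integers(0, 50), d2=st.integers(0, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetric_in_bc_and_invariant_to_d(self, a, b, c, d1, d2):
        j1 = jaccard(AgreementCounts(a, b, c, d1))
        j2 = jaccard(AgreementCounts(a, c, b, d2))
        assert j1 == j2
        if j1 is not None:
            assert 0.0 <= j1 <= 1.0

    def test_alternative_measures_are_pluggable(self):
        counts = AgreementCounts(10, 5, 5, 80)
        for name, fn in AGREEMENT_MEASURES.items():
            v = fn(counts)
            assert v is None or np.isfinite(v)
        assert AGREEMENT_MEASURES["jaccard"] is jaccard


class TestPersistence:
    def test_direct_count(self):
        assert persistence([1, 1, 0, 1], [1, 0, 0, 1]) == pytest.approx(2 / 3)

    def test_identity_gives_one(self):
        assert persistence([1, 0, 1], [1, 0, 1]) == 1.0

    def test_empty_conditioning_set_is_undefined(self):
        assert persistence([0, 0], [1, 0]) is None


class TestComorbidityMedians:
    def test_identical_disorders_give_one(self):
        dx = np.array([1, 1, 0, 0, 1])
        axis1 = np.tile(dx[:, None], (1, 7))
        assert comorbidity_axis1(dx, axis1) == 1.0

    def test_odd_and_even_median_convention(self):
        # medians computed over constituent Jaccards; construct disorder
        # columns whose Jaccards with dx are exactly {1, 0} -> median .5
        dx = np.array([1, 0])
        axis = np.column_stack([dx, 1 - dx])  # J = 1 and J = 0
        assert comorbidity_axis1(dx, axis) == pytest.approx(0.5)

    def test_axis2_weighted_combination(self):
        # cluster medians (0.1, 0.3, 0.2) -> .1*.1 + .7*.3 + .2*.2 = 0.26
        dx = np.zeros(20, dtype=int)
        dx[:10] = 1

        def cluster(n_overlap):
            # single disorder entirely inside the 10 diagnosed subjects:
            # J = n_overlap / 10 exactly
            col = np.zeros(20, dtype=int)
            col[:n_overlap] = 1
            return np.column_stack([col])

        v = comorbidity_axis2(dx, (cluster(1), cluster(3), cluster(2)))
        assert v == pytest.approx(0.26)

        # all cluster medians equal c -> convex combination returns c
        axis = np.column_stack([dx])
        assert comorbidity_axis2(dx, (axis, axis, axis)) == 1.0

    def test_degenerate_weight_vector_selects_one_cluster(self):
        dx = np.array([1, 1, 0, 0])
        a = np.column_stack([dx])  # J = 1
        other = np.column_stack([1 - dx])  # J = 0
        assert comorbidity_axis2(dx, (a, other, other), weights=(1, 0, 0)) == 1.0

    def test_weights_must_sum_to_one(self):
        dx = np.array([1, 0])
        m = np.column_stack([dx])
        with pytest.raises(ConfigError):
            comorbidity_axis2(dx, (m, m, m), weights=(0.5, 0.5, 0.5))

    def test_axis2_convexity(self, tiny_bundle):
        dx = apply_rule(DiagnosticRule(frozenset({0}), 1), tiny_bundle.criteria.wave1)
        com = tiny_bundle.comorbidity
        meds = [
            comorbidity_axis1(dx, m)
            for m in (com.cluster_a, com.cluster_b, com.cluster_c)
        ]
        v = comorbidity_axis2(dx, (com.cluster_a, com.cluster_b, com.cluster_c))
        assert min(meds) <= v <= max(meds)


class TestValidityProfile:
    def test_rule_diagnosing_everyone(self, tiny_bundle):
        panel = tiny_bundle.criteria
        # threshold 1 over all criteria diagnoses anyone endorsing anything;
        # force diagnosis for all by flipping wave matrices to ones
        import dataclasses

        full = dataclasses.replace(
            panel, wave1=np.ones_like(panel.wave1), wave2=np.ones_like(panel.wave2)
        )
        rule = DiagnosticRule(frozenset(range(panel.n_criteria)), 1)
        p = validity_profile(rule, full, tiny_bundle.comorbidity)
        assert p.prevalence_w1 == 1.0
        assert p.persistence == 1.0

    def test_rule_diagnosing_no_one_is_invalid(self, tiny_bundle):
        panel = tiny_bundle.criteria
        rule = DiagnosticRule(frozenset(range(panel.n_criteria)), panel.n_criteria)
        if apply_rule(rule, panel.wave1).sum() == 0:
            p = validity_profile(rule, panel, tiny_bundle.comorbidity)
            assert not p.valid and p.persistence is None

    def test_metrics_match_hand_recount_on_small_fixture(self, tiny_bundle):
        """Brute-force recount of all four metrics on a 20-subject panel."""
        panel, com = tiny_bundle.criteria, tiny_bundle.comorbidity
        rule = DiagnosticRule(frozenset({0, 1}), 1)
        dx1 = [
            int(sum(panel.wave1[i, j] for j in (0, 1)) >= 1)
            for i in range(panel.n_subjects)
        ]
        dx2 = [
            int(sum(panel.wave2[i, j] for j in (0, 1)) >= 1)
            for i in range(panel.n_subjects)
        ]
        n1 = sum(dx1)
        assert n1 > 0

        def jac(col):
            a = sum(1 for i in range(len(dx1)) if dx1[i] and col[i])
            b = sum(1 for i in range(len(dx1)) if dx1[i] and not col[i])
            c = sum(1 for i in range(len(dx1)) if not dx1[i] and col[i])
            return a / (a + b + c)

        expected_pers = sum(1 for i in range(len(dx1)) if dx1[i] and dx2[i]) / n1
        expected_ax1 = float(
            np.median([jac(com.axis1[:, m]) for m in range(com.axis1.shape[1])])
        )
        meds = [
            float(np.median([jac(mat[:, m]) for m in range(mat.shape[1])]))
            for mat in (com.cluster_a, com.cluster_b, com.cluster_c)
        ]
        expected_ax2 = 0.1 * meds[0] + 0.7 * meds[1] + 0.2 * meds[2]

        p = validity_profile(rule, panel, com)
        assert p.prevalence_w1 == pytest.approx(n1 / panel.n_subjects)
        assert p.persistence == pytest.approx(expected_pers)
        assert p.comorbidity_ax1 == pytest.approx(expected_ax1)
        assert p.comorbidity_ax2 == pytest.approx(expected_ax2)


class TestProfileLattice:
    def test_vectorized_profile_matches_per_rule_profile(self, k4_bundle):
        """The bulk profiler agrees with rule-by-rule computation on all 32 rules."""
        lattice = enumerate_rules(4)
        table = profile_lattice(k4_bundle.criteria, k4_bundle.comorbidity, lattice)
        for i, rule in enumerate(lattice.rules()):
            p = validity_profile(rule, k4_bundle.criteria, k4_bundle.comorbidity)
            row = table.iloc[i]
            assert row["valid"] == p.valid
            assert row["prevalence_w1"] == pytest.approx(p.prevalence_w1)
            if p.valid:
                assert row["persistence"] == pytest.approx(p.persistence)
                assert row["comorbidity_ax1"] == pytest.approx(p.comorbidity_ax1)
                assert row["comorbidity_ax2"] == pytest.approx(p.comorbidity_ax2)
            else:
                assert np.isnan(row["persistence"])

    def test_nested_rules_shrink_joint_presence(self, k4_bundle):
        """Raising the threshold (a strictly stricter rule) cannot increase
        the joint-presence count with any disorder."""
        panel, com = k4_bundle.criteria, k4_bundle.comorbidity
        subset = frozenset({0, 1, 2})
        loose = apply_rule(DiagnosticRule(subset, 1), panel.wave1)
        strict = apply_rule(DiagnosticRule(subset, 2), panel.wave1)
        for m in range(com.axis1.shape[1]):
            a_loose = cross_tabulate(loose, com.axis1[:, m]).a
            a_strict = cross_tabulate(strict, com.axis1[:, m]).a
            assert a_strict <= a_loose
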