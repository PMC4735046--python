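"""Inverse-normal scoring, composite S, and the per-dataset optimizer.

The optimizer is checked against an independent brute-force oracle that
re-derives every metric, rank, and composite score with plain Python loops
and ``statistics.NormalDist``.
"""

import itertools
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dxopt import (
    AlphaGrid,
    build_score_table,
    composite_score,
    enumerate_rules,
    optimize_dataset,
    profile_lattice,
    rank_inverse_normal,
)
from dxopt.core_data import ConfigError, DegenerateDataError


class TestRankInverseNormal:
    def test_three_values_against_quantile_table(self):
        z = rank_inverse_normal(np.array([3.0, 1.0, 2.0]))
        # ranks (3,1,2) -> percentiles (.75,.25,.50) -> z (0.6745, -0.6745, 0)
        np.testing.assert_allclose(z, [0.674490, -0.674490, 0.0], atol=1e-5)

    def test_quantile_symmetry_without_ties(self):
        values = np.array([10.0, 4.0, 7.0, 1.0, 12.0])
        z = np.sort(rank_inverse_normal(values))
        np.testing.assert_allclose(z, -z[::-1], atol=1e-12)

    def test_all_tied_collapses_to_zero(self):
        np.testing.assert_allclose(rank_inverse_normal(np.array([5.0, 5.0])), [0.0, 0.0])

    def test_invalid_entries_get_no_score(self):
        z = rank_inverse_normal(np.array([1.0, np.nan, 2.0]))
        assert np.isnan(z[1]) and np.isfinite(z[[0, 2]]).all()

    def test_fewer_than_two_valid_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            rank_inverse_normal(np.array([1.0, np.nan]))

    def test_monotone_transform_of_the_metric(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=50)
        z = rank_inverse_normal(values)
        order = np.argsort(values)
        assert np.all(np.diff(z[order]) >= 0)


class TestCompositeScore:
    def test_alpha_one_is_persistence_only(self):
        assert composite_score(1.3, -5.0, 9.0, alpha1=1.0) == 1.3

    def test_alpha_zero_equal_comorbidity(self):
        assert composite_score(99.0, 0.7, 0.7, alpha1=0.0) == pytest.approx(0.7)

    def test_direct_arithmetic(self):
        # .6*1.0 + .4*(.5*.5 + .5*(-.5)) = 0.6
        assert composite_score(1.0, 0.5, -0.5, alpha1=0.6) == pytest.approx(0.6)

    def test_alpha_out_of_range(self):
        with pytest.raises(ConfigError):
            composite_score(0, 0, 0, alpha1=1.2)

    @given(
        z=st.tuples(*[st.floats(-3, 3) for _ in range(3)]),
        dz=st.floats(0, 2),
        alpha=st.floats(0, 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_z(self, z, dz, alpha):
        base = composite_score(*z, alpha)
        assert composite_score(z[0] + dz, z[1], z[2], alpha) >= base - 1e-12
        assert composite_score(z[0], z[1] + dz, z[2], alpha) >= base - 1e-12
        assert composite_score(z[0], z[1], z[2] + dz, alpha) >= base - 1e-12


# ---------------------------------------------------------------------------
# Independent brute-force oracle


def _brute_force_winners(panel, comorbidity, alphas):
    """Re-derive the optimal rule per alpha with plain Python only."""
    n, k = panel.wave1.shape
    disorders = {
        "ax1": [comorbidity.axis1[:, m] for m in range(comorbidity.axis1.shape[1])],
        "a": [comorbidity.cluster_a[:, m] for m in range(comorbidity.cluster_a.shape[1])],
        "b": [comorbidity.cluster_b[:, m] for m in range(comorbidity.cluster_b.shape[1])],
        "c": [comorbidity.cluster_c[:, m] for m in range(comorbidity.cluster_c.shape[1])],
    }

    def jac(dx, col):
        a = sum(1 for i in range(n) if dx[i] and col[i])
        bc = sum(1 for i in range(n) if dx[i] != col[i])
        return a / (a + bc)

    def med(vals):
        return statistics.median(vals)

    rules = []
    for r in range(1, k + 1):
        for sub in itertools.combinations(range(k), r):
            for t in range(1, r + 1):
                dx1 = [int(sum(panel.wave1[i, j] for j in sub) >= t) for i in range(n)]
                n1 = sum(dx1)
                if n1 == 0:
                    continue
                dx2 = [int(sum(panel.wave2[i, j] for j in sub) >= t) for i in range(n)]
                pers = sum(1 for i in range(n) if dx1[i] and dx2[i]) / n1
                ax1 = med([jac(dx1, col) for col in disorders["ax1"]])
                ax2 = (
                    0.1 * med([jac(dx1, col) for col in disorders["a"]])
                    + 0.7 * med([jac(dx1, col) for col in disorders["b"]])
                    + 0.2 * med([jac(dx1, col) for col in disorders["c"]])
                )
                rules.append({"sub": sub, "t": t, "pers": pers, "ax1": ax1, "ax2": ax2})

    def ranks(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        r = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for idx in order[i : j + 1]:
                r[idx] = avg
            i = j + 1
        return r

    nd = statistics.NormalDist()
    m = len(rules)
    for key in ("pers", "ax1", "ax2"):
        rk = ranks([rule[key] for rule in rules])
        for rule, r in zip(rules, rk):
            rule["z_" + key] = nd.inv_cdf(r / (m + 1))

    winners = {}
    for alpha in alphas:
        def s_of(rule):
            return alpha * rule["z_pers"] + (1 - alpha) * 0.5 * (
                rule["z_ax1"] + rule["z_ax2"]
            )

        smax = max(s_of(rule) for rule in rules)
        candidates = [rule for rule in rules if s_of(rule) == smax]
        # parsimony tie-break mirrors the documented convention
        best = min(
            candidates,
            key=lambda rule: (len(rule["sub"]), rule["t"], sum(1 << j for j in rule["sub"])),
        )
        winners[alpha] = (frozenset(best["sub"]), best["t"])
    return winners


class TestOptimizeDataset:
    def test_winner_matches_brute_force_oracle(self, k4_bundle):
        """At every alpha the optimizer's winner equals an independent
        recomputation of the whole metric -> rank -> z -> S chain (32 rules)."""
        grid = AlphaGrid()
        lattice = enumerate_rules(4)
        winners, _ = optimize_dataset(
            k4_bundle.criteria, k4_bundle.comorbidity, lattice, grid, min_subjects=0
        )
        oracle = _brute_force_winners(
            k4_bundle.criteria, k4_bundle.comorbidity, list(grid)
        )
        for alpha in grid:
            rule, profile = winners[alpha]
            assert (rule.subset, rule.threshold) == oracle[alpha], f"alpha={alpha}"
            assert profile.valid

    def test_dominant_rule_wins_at_every_alpha(self, k4_bundle):
        """A rule strictly dominating all three metrics wins regardless of alpha."""
        lattice = enumerate_rules(4)
        profile = profile_lattice(k4_bundle.criteria, k4_bundle.comorbidity, lattice)
        # plant dominance: overwrite metrics so rule 0 beats everything
        profile.loc[:, ["persistence", "comorbidity_ax1", "comorbidity_ax2"]] = 0.1
        profile.loc[:, "valid"] = True
        profile.loc[:, "prevalence_w1"] = 0.5
        profile.loc[0, ["persistence", "comorbidity_ax1", "comorbidity_ax2"]] = 0.9
        st_table = build_score_table(profile, AlphaGrid())
        for alpha in st_table.grid:
            s = st_table.table[st_table.s_col(alpha)].to_numpy()
            assert int(np.argmax(s)) == 0

    def test_tie_broken_toward_smaller_subset(self, k4_bundle):
        """Rules with identical diagnosis vectors share S; parsimony wins."""
        import pandas as pd

        profile = pd.DataFrame(
            {
                "mask": [0b11, 0b111],
                "size": [2, 3],
                "threshold": [1, 1],
                "prevalence_w1": [0.5, 0.5],
                "persistence": [0.4, 0.4],
                "comorbidity_ax1": [0.2, 0.2],
                "comorbidity_ax2": [0.3, 0.3],
                "valid": [True, True],
            }
        )
        table = build_score_table(profile, AlphaGrid((0.5,)))
        from dxopt.scoring import _argmax_parsimonious

        s = table.table[table.s_col(0.5)].to_numpy()
        assert _argmax_parsimonious(table.table, s) == 0

    def test_winner_percentile_is_the_minimum(self, k4_bundle):
        lattice = enumerate_rules(4)
        winners, table = optimize_dataset(
            k4_bundle.criteria, k4_bundle.comorbidity, lattice, min_subjects=0
        )
        for alpha in table.grid:
            rule, _ = winners[alpha]
            pct = table.table[table.pct_col(alpha)]
            assert table.percentile_of(rule, alpha) == pytest.approx(pct.min())
            assert 0 < pct.min() <= 1

    def test_alpha_extremes_reduce_to_single_metric_ranking(self, k4_bundle):
        """At alpha1=1 the winner maximizes the persistence rank; replacing
        the inverse-normal transform by raw ranks cannot change a
        single-metric argmax (monotone transform)."""
        lattice = enumerate_rules(4)
        winners, table = optimize_dataset(
            k4_bundle.criteria, k4_bundle.comorbidity, lattice, min_subjects=0
        )
        tab = table.table
        valid = tab["valid"].to_numpy()
        rule1, _ = winners[1.0]
        best_pers = tab.loc[valid, "persistence"].max()
        i = tab.index[(tab["mask"] == rule1.mask) & (tab["threshold"] == rule1.threshold)][0]
        assert tab.loc[i, "persistence"] == pytest.approx(best_pers)

    def test_min_subjects_guard(self, tiny_bundle):
        with pytest.raises(DegenerateDataError):
            optimize_dataset(
                tiny_bundle.criteria,
                tiny_bundle.comorbidity,
                enumerate_rules(3),
                min_subjects=100,
            )
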