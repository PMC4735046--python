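"""Rank-based inverse-normal scoring and composite optimization.

Persistence and the two comorbidity measures live on different scales, so
before combining them each metric is replaced by the standard-normal
quantile of its rank percentile across all valid rules (ascending ranks,
average ties, percentile r/(N+1)).  The composite score of a rule is

    S = alpha1 * z_persistence + (1 - alpha1) * (.5 * z_ax1 + .5 * z_ax2)

with alpha1 swept over a grid from 0 to 1 in steps of .10: alpha1 = 1 ranks
on persistence alone, alpha1 = 0 on the equal-weighted comorbidity
composite.  The valid rule maximizing S is the optimal rule at that alpha;
ties (identical diagnosis vectors yield identical S) break parsimony-first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .core_data import (
    ComorbidityPanel,
    ConfigError,
    CriterionPanel,
    DegenerateDataError,
    DiagnosticRule,
    ValidityProfile,
)
from .agreement import AXIS2_CLUSTER_WEIGHTS, profile_lattice
from .rule_space import RuleLattice

__all__ = [
    "AlphaGrid",
    "ScoreTable",
    "rank_inverse_normal",
    "composite_score",
    "build_score_table",
    "optimize_dataset",
]


@dataclass(frozen=True)
class AlphaGrid:
    """The grid of persistence weights alpha1 (alpha2 = 1 - alpha1)."""

    alpha1_values: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))

    def __post_init__(self) -> None:
        for a in self.alpha1_values:
            if not 0.0 <= a <= 1.0:
                raise ConfigError(f"alpha1={a} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.alpha1_values)

    def __iter__(self):
        return iter(self.alpha1_values)


def rank_inverse_normal(values: np.ndarray, valid_mask: np.ndarray | None = None) -> np.ndarray:
    """Rank-based inverse normal transform.

    Ascending ranks with average ties; percentile p_i = r_i / (N_valid + 1);
    z_i = Phi^{-1}(p_i).  Entries outside ``valid_mask`` get NaN.  The
    r/(N+1) convention keeps percentiles strictly inside (0, 1), so the
    quantiles are finite; with all values tied every rank is (N+1)/2, giving
    p = .5 and z = 0.
    """
    values = np.asarray(values, dtype=float)
    if valid_mask is None:
        valid_mask = np.isfinite(values)
    else:
        valid_mask = np.asarray(valid_mask, dtype=bool) & np.isfinite(values)
    n_valid = int(valid_mask.sum())
    if n_valid < 2:
        raise DegenerateDataError(f"need >= 2 valid entries, got {n_valid}")
    z = np.full(values.shape, np.nan)
    ranks = rankdata(values[valid_mask], method="average")
    z[valid_mask] = norm.ppf(ranks / (n_valid + 1))
    return z


def composite_score(z_p: float, z_ax1: float, z_ax2: float, alpha1: float):
    """S = alpha1 * z_p + (1 - alpha1) * (.5 * z_ax1 + .5 * z_ax2)."""
    if not 0.0 <= alpha1 <= 1.0:
        raise ConfigError(f"alpha1={alpha1} outside [0, 1]")
    return alpha1 * np.asarray(z_p) + (1.0 - alpha1) * 0.5 * (
        np.asarray(z_ax1) + np.asarray(z_ax2)
    )


@dataclass
class ScoreTable:
    """Per-rule normal scores, composite S per alpha, and S percentiles.

    ``table`` has one row per rule in lattice order with columns ``mask``,
    ``size``, ``threshold``, the raw metrics, ``z_persistence``, ``z_ax1``,
    ``z_ax2``, plus ``s@{alpha}`` and ``pct@{alpha}`` per grid point.
    Percentiles are fractions in (0, 1]: pct = rank of S (descending, min
    ties) / N_valid, so the winner at an alpha has the smallest percentile.
    """

    table: pd.DataFrame
    grid: AlphaGrid
    n_valid: int
    _index: dict[tuple[int, int], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {
                (int(m), int(t)): i
                for i, (m, t) in enumerate(
                    zip(self.table["mask"].to_numpy(), self.table["threshold"].to_numpy())
                )
            }

    def s_col(self, alpha1: float) -> str:
        return f"s@{alpha1:g}"

    def pct_col(self, alpha1: float) -> str:
        return f"pct@{alpha1:g}"

    def percentile_of(self, rule: DiagnosticRule, alpha1: float) -> float | None:
        """Fractional S percentile of a rule at alpha1; None if absent/invalid."""
        i = self._index.get((rule.mask, rule.threshold))
        if i is None:
            return None
        v = self.table[self.pct_col(alpha1)].iloc[i]
        return None if np.isnan(v) else float(v)


def build_score_table(profile: pd.DataFrame, grid: AlphaGrid) -> ScoreTable:
    """Transform raw per-rule metrics into normal scores and composite S.

    Invalid rules (zero Wave-1 prevalence) are excluded from ranking; they
    carry NaN scores and can never be selected.
    """
    table = profile.copy()
    valid = table["valid"].to_numpy(dtype=bool)
    if valid.sum() < 2:
        raise DegenerateDataError("fewer than 2 valid rules to rank")
    z_p = rank_inverse_normal(table["persistence"].to_numpy(), valid)
    z_1 = rank_inverse_normal(table["comorbidity_ax1"].to_numpy(), valid)
    z_2 = rank_inverse_normal(table["comorbidity_ax2"].to_numpy(), valid)
    table["z_persistence"] = z_p
    table["z_ax1"] = z_1
    table["z_ax2"] = z_2
    st = ScoreTable(table=table, grid=grid, n_valid=int(valid.sum()))
    n_valid = st.n_valid
    for alpha1 in grid:
        s = composite_score(z_p, z_1, z_2, alpha1)
        table[st.s_col(alpha1)] = s
        pct = np.full(len(table), np.nan)
        # descending rank of S among valid rules; ties share the best rank
        pct[valid] = rankdata(-s[valid], method="min") / n_valid
        table[st.pct_col(alpha1)] = pct
    return st


def _argmax_parsimonious(table: pd.DataFrame, s: np.ndarray) -> int:
    """Index of the max-S rule; ties break by size, threshold, then mask."""
    smax = np.nanmax(s)
    cand = np.flatnonzero(s == smax)
    if len(cand) == 1:
        return int(cand[0])
    sizes = table["size"].to_numpy()
    thr = table["threshold"].to_numpy()
    masks = table["mask"].to_numpy()
    return int(min(cand, key=lambda i: (sizes[i], thr[i], masks[i])))


def optimize_dataset(
    panel: CriterionPanel,
    comorbidity: ComorbidityPanel,
    lattice: RuleLattice,
    grid: AlphaGrid | None = None,
    cluster_weights: tuple[float, float, float] = AXIS2_CLUSTER_WEIGHTS,
    min_subjects: int = 100,
) -> tuple[dict[float, tuple[DiagnosticRule, ValidityProfile]], ScoreTable]:
    """Optimal rule per alpha for one dataset.

    Profiles every rule in the lattice, scores the valid ones, and for each
    alpha on the grid returns the S-maximizing rule with its validity
    profile, together with the full :class:`ScoreTable`.

    ``min_subjects`` guards against optimizing on panels too small for the
    metrics to be meaningful; set to 0 to disable (toy fixtures).
    """
    if grid is None:
        grid = AlphaGrid()
    if panel.n_subjects < min_subjects:
        raise DegenerateDataError(
            f"panel has {panel.n_subjects} subjects, below min_subjects={min_subjects}"
        )
    profile = profile_lattice(panel, comorbidity, lattice, cluster_weights)
    if not profile["valid"].any():
        raise DegenerateDataError("no rule diagnoses anyone at Wave 1")
    st = build_score_table(profile, grid)
    winners: dict[float, tuple[DiagnosticRule, ValidityProfile]] = {}
    for alpha1 in grid:
        s = st.table[st.s_col(alpha1)].to_numpy()
        i = _argmax_parsimonious(st.table, s)
        rule = lattice.rule_at(i)
        row = st.table.iloc[i]
        winners[alpha1] = (
            rule,
            ValidityProfile(
                prevalence_w1=float(row["prevalence_w1"]),
                persistence=float(row["persistence"]),
                comorbidity_ax1=float(row["comorbidity_ax1"]),
                comorbidity_ax2=float(row["comorbidity_ax2"]),
                valid=True,
            ),
        )
    return winners, st
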