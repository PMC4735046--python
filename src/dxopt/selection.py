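"""Internal validation: k-fold discovery, min-max cross-validation, consensus.

Exhaustive search capitalizes on chance, so the sample is randomly split
into k folds and the optimization is run independently on each fold at every
alpha on the grid (5 folds x 11 alphas = 55 candidate solutions).  Two
selection strategies are then available:

* **Min-max cross-validation** — every discovered rule is re-scored in each
  of the folds that did not discover it; its score is the *maximum* (worst)
  percentile it attains across those folds, and the rule minimizing this
  maximum ("least worst") wins.
* **Consensus voting** — each criterion's vote is the proportion of the 55
  solutions whose rule contains it; criteria voted at or above a cutoff
  (default 60%) form the final set, diagnosed at a configured minimum
  threshold (default 2, guarding against single-criterion diagnosis).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import (
    ComorbidityPanel,
    ConfigError,
    CriterionPanel,
    DegenerateDataError,
    DiagnosticRule,
    SelectionError,
    ValidityProfile,
)
from .rule_space import RuleLattice, enumerate_rules
from .scoring import AlphaGrid, ScoreTable, optimize_dataset

__all__ = [
    "SolutionEntry",
    "SolutionSet",
    "CrossValMatrix",
    "ConsensusResult",
    "kfold_split",
    "discover_solutions",
    "cross_validate",
    "minmax_select",
    "consensus",
    "consensus_from_votes",
]

logger = logging.getLogger(__name__)


def kfold_split(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded uniform random partition into k folds of near-equal size.

    Returns a length-n vector of fold labels 0..k-1.  Sizes differ by at
    most one; when n % k = r, the last r folds carry the extra subject.
    """
    if k < 2:
        raise ConfigError(f"k must be >= 2, got {k}")
    if n < k:
        raise ConfigError(f"cannot split n={n} subjects into k={k} folds")
    base, rem = divmod(n, k)
    sizes = [base] * (k - rem) + [base + 1] * rem
    labels = np.repeat(np.arange(k), sizes)
    rng = np.random.default_rng(seed)
    return labels[rng.permutation(n)]


@dataclass(frozen=True)
class SolutionEntry:
    """One discovered optimum: (fold, alpha1) -> rule + validity profile."""

    fold: int
    alpha1: float
    rule: DiagnosticRule
    profile: ValidityProfile


@dataclass
class SolutionSet:
    """All per-fold, per-alpha optima plus the artifacts needed downstream.

    ``score_tables`` (fold -> ScoreTable) and ``fold_assignment`` are kept
    in memory for cross-validation but excluded from JSON serialization.
    """

    entries: list[SolutionEntry]
    k: int
    grid: AlphaGrid
    seed: int
    criterion_names: tuple[str, ...]
    score_tables: dict[int, ScoreTable] = field(default_factory=dict, repr=False)
    fold_assignment: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "alpha1_grid": list(self.grid.alpha1_values),
            "criterion_names": list(self.criterion_names),
            "entries": [
                {
                    "fold": e.fold,
                    "alpha1": e.alpha1,
                    "criteria": list(e.rule.criteria(self.criterion_names)),
                    "indices": list(e.rule.indices()),
                    "threshold": e.rule.threshold,
                    "profile": e.profile.to_dict(),
                }
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "SolutionSet":
        entries = [
            SolutionEntry(
                fold=int(e["fold"]),
                alpha1=float(e["alpha1"]),
                rule=DiagnosticRule(frozenset(e["indices"]), int(e["threshold"])),
                profile=ValidityProfile(**e["profile"]),
            )
            for e in obj["entries"]
        ]
        return cls(
            entries=entries,
            k=int(obj["k"]),
            grid=AlphaGrid(tuple(obj["alpha1_grid"])),
            seed=int(obj["seed"]),
            criterion_names=tuple(obj["criterion_names"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SolutionSet":
        return cls.from_dict(json.loads(text))


def discover_solutions(
    panel: CriterionPanel,
    comorbidity: ComorbidityPanel,
    k: int,
    grid: AlphaGrid | None = None,
    seed: int = 0,
    lattice: RuleLattice | None = None,
    min_subjects: int = 0,
) -> SolutionSet:
    """Run the optimization on each of k random folds at every alpha.

    Yields k x |grid| solution entries (55 for the default 5-fold, 11-point
    setup).  A fold too degenerate to rank rules is flagged with a warning
    and contributes no entries.
    """
    if grid is None:
        grid = AlphaGrid()
    if lattice is None:
        lattice = enumerate_rules(panel.n_criteria)
    assignment = kfold_split(panel.n_subjects, k, seed)
    entries: list[SolutionEntry] = []
    tables: dict[int, ScoreTable] = {}
    for fold in range(k):
        idx = np.flatnonzero(assignment == fold)
        sub_panel = panel.take(idx)
        sub_com = comorbidity.take(idx)
        try:
            winners, table = optimize_dataset(
                sub_panel, sub_com, lattice, grid, min_subjects=min_subjects
            )
        except DegenerateDataError as exc:
            logger.warning("fold %d skipped: %s", fold, exc)
            continue
        tables[fold] = table
        for alpha1, (rule, profile) in winners.items():
            entries.append(SolutionEntry(fold, alpha1, rule, profile))
        logger.info(
            "fold %d (n=%d): %d optima across %d alphas",
            fold,
            len(idx),
            len({(r.mask, r.threshold) for r, _ in winners.values()}),
            len(grid),
        )
    return SolutionSet(
        entries=entries,
        k=k,
        grid=grid,
        seed=seed,
        criterion_names=panel.criterion_names,
        score_tables=tables,
        fold_assignment=assignment,
    )


@dataclass
class CrossValMatrix:
    """Rule-by-fold percentile matrix with the min-max ("least worst") winner.

    ``table`` has one row per unique (discovery fold, alpha range, rule):
    columns ``fold``, ``alpha_range``, ``criteria``, ``threshold``, one
    percentile column per evaluation fold (NaN on the discovery fold;
    percentiles in (0, 100]), and ``max_percentile``.  Reference rules
    (e.g. DSM-IV dependence) appear as extra rows with fold = -1 but do not
    compete for the winner.
    """

    table: pd.DataFrame
    rules: list[DiagnosticRule]
    winner: DiagnosticRule
    winner_max_percentile: float


def _alpha_range_label(alphas: Sequence[float]) -> str:
    lo, hi = min(alphas), max(alphas)
    return f"{hi:g}" if lo == hi else f"{hi:g} - {lo:g}"


def cross_validate(
    solutions: SolutionSet,
    score_tables: dict[int, ScoreTable] | None = None,
    reference_rules: dict[str, DiagnosticRule] | None = None,
) -> CrossValMatrix:
    """Score every discovered rule in the folds that did not discover it.

    A rule discovered in fold f under an alpha range is re-scored in every
    other fold: the cell is the mean, over the alphas in its range, of the
    rule's S percentile within that fold's full score table (x100); a rule
    with zero Wave-1 prevalence in an evaluation fold takes the worst
    percentile, 100.  The winner minimizes the row maximum; ties break
    parsimony-first.
    """
    tables = score_tables if score_tables is not None else solutions.score_tables
    if not tables:
        raise ConfigError("cross_validate needs per-fold score tables")
    folds = sorted(tables)

    # group entries into (fold, rule) rows carrying their alpha range
    grouped: dict[tuple[int, int, int], list[float]] = {}
    rule_of: dict[tuple[int, int, int], DiagnosticRule] = {}
    for e in solutions.entries:
        key = (e.fold, e.rule.mask, e.rule.threshold)
        grouped.setdefault(key, []).append(e.alpha1)
        rule_of[key] = e.rule
    # deterministic row order: fold, then descending upper alpha (display order)
    keys = sorted(grouped, key=lambda kk: (kk[0], -max(grouped[kk]), rule_of[kk].sort_key()))

    def cell(rule: DiagnosticRule, alphas: Sequence[float], fold: int) -> float:
        pcts = []
        for a in alphas:
            p = tables[fold].percentile_of(rule, a)
            pcts.append(100.0 if p is None else 100.0 * p)
        return float(np.mean(pcts))

    rows = []
    rules: list[DiagnosticRule] = []
    for key in keys:
        fold, _, _ = key
        rule = rule_of[key]
        alphas = grouped[key]
        row: dict = {
            "fold": fold,
            "alpha_range": _alpha_range_label(alphas),
            "criteria": ", ".join(rule.criteria(solutions.criterion_names)),
            "threshold": rule.threshold,
        }
        for f in folds:
            row[f"D{f + 1}"] = np.nan if f == fold else cell(rule, alphas, f)
        rows.append(row)
        rules.append(rule)

    if reference_rules:
        full_grid = list(solutions.grid)
        for name, rule in reference_rules.items():
            row = {
                "fold": -1,
                "alpha_range": name,
                "criteria": ", ".join(rule.criteria(solutions.criterion_names)),
                "threshold": rule.threshold,
            }
            for f in folds:
                row[f"D{f + 1}"] = cell(rule, full_grid, f)
            rows.append(row)
            rules.append(rule)

    table = pd.DataFrame(rows)
    fold_cols = [f"D{f + 1}" for f in folds]
    table["max_percentile"] = table[fold_cols].max(axis=1)

    competing = table.index[table["fold"] >= 0]
    if len(competing) == 0:
        raise SelectionError("no discovered rules to cross-validate")
    best = min(
        competing,
        key=lambda i: (table.loc[i, "max_percentile"], rules[i].sort_key()),
    )
    return CrossValMatrix(
        table=table,
        rules=rules,
        winner=rules[best],
        winner_max_percentile=float(table.loc[best, "max_percentile"]),
    )


def minmax_select(matrix: pd.DataFrame, fold_columns: Sequence[str]) -> tuple[int, float]:
    """Min-max selection on a plain percentile matrix.

    ``matrix`` has one candidate rule per row and one column per evaluation
    dataset (NaN where the rule was discovered).  Returns (row position of
    the least-worst rule, its maximum percentile).
    """
    maxima = matrix[list(fold_columns)].max(axis=1)
    pos = int(np.argmin(maxima.to_numpy()))
    return pos, float(maxima.iloc[pos])


@dataclass
class ConsensusResult:
    """Criterion votes and the resulting consensus rule.

    ``votes[j]`` is the proportion of solutions whose rule contains
    criterion j.  Criteria at or above ``cutoff`` are retained; the final
    rule diagnoses at ``min_threshold`` endorsements of the retained set.
    """

    votes: np.ndarray
    cutoff: float
    retained: tuple[int, ...]
    final_rule: DiagnosticRule
    criterion_names: tuple[str, ...]

    @property
    def retained_names(self) -> tuple[str, ...]:
        return tuple(self.criterion_names[j] for j in self.retained)

    def to_dict(self) -> dict:
        return {
            "votes": {name: float(v) for name, v in zip(self.criterion_names, self.votes)},
            "cutoff": self.cutoff,
            "retained": list(self.retained_names),
            "final_rule": {
                "criteria": list(self.final_rule.criteria(self.criterion_names)),
                "indices": list(self.final_rule.indices()),
                "threshold": self.final_rule.threshold,
            },
        }


def consensus(
    solutions: SolutionSet | Sequence[SolutionEntry],
    cutoff: float = 0.60,
    min_threshold: int = 2,
    n_criteria: int | None = None,
    criterion_names: Sequence[str] | None = None,
) -> ConsensusResult:
    """Vote criteria across all discovered solutions and build the final rule.

    votes_j = #(solutions containing criterion j) / #solutions.  Criteria
    with votes >= cutoff are retained; the final rule requires
    ``min_threshold`` of them (a fixed configuration constant — the
    threshold is deliberately not searched, to avoid single-criterion
    diagnoses).  Raises :class:`SelectionError` when fewer than
    ``min_threshold`` criteria survive the cutoff.
    """
    if isinstance(solutions, SolutionSet):
        entries = solutions.entries
        criterion_names = criterion_names or solutions.criterion_names
        n_criteria = len(criterion_names)
    else:
        entries = list(solutions)
        if n_criteria is None:
            n_criteria = 1 + max(j for e in entries for j in e.rule.subset)
        if criterion_names is None:
            criterion_names = tuple(f"criterion_{j}" for j in range(n_criteria))
    if not entries:
        raise SelectionError("no solutions to vote over")
    votes = np.zeros(n_criteria)
    for e in entries:
        for j in e.rule.subset:
            votes[j] += 1
    votes /= len(entries)
    return consensus_from_votes(votes, cutoff, min_threshold, criterion_names)


def consensus_from_votes(
    votes: np.ndarray,
    cutoff: float = 0.60,
    min_threshold: int = 2,
    criterion_names: Sequence[str] | None = None,
) -> ConsensusResult:
    """Apply the consensus cutoff to an already-computed votes vector."""
    votes = np.asarray(votes, dtype=float)
    if criterion_names is None:
        criterion_names = tuple(f"criterion_{j}" for j in range(len(votes)))
    retained = tuple(int(j) for j in np.flatnonzero(votes >= cutoff - 1e-12))
    if len(retained) < min_threshold:
        raise SelectionError(
            f"only {len(retained)} criteria reach the {cutoff:.0%} cutoff; "
            f"lower the cutoff or min_threshold (= {min_threshold})"
        )
    return ConsensusResult(
        votes=votes,
        cutoff=cutoff,
        retained=retained,
        final_rule=DiagnosticRule(frozenset(retained), min_threshold),
        criterion_names=tuple(criterion_names),
    )
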