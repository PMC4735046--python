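"""Agreement measures and the per-rule validity metrics.

Two binary diagnosis variables partition subjects into four states: joint
presence (a), present-first-only (b), present-second-only (c), and joint
absence (d).  Agreement is measured by Jaccard's coefficient a/(a+b+c),
which ignores d — appropriate when prevalences are far below .5, as for most
disorders, since joint absence would otherwise dominate.

A rule's validity profile combines:

* persistence, P(diagnosed at Wave 2 | diagnosed at Wave 1);
* Axis I comorbidity, the median Jaccard agreement between the Wave-1
  diagnosis and the individual Axis I disorders;
* Axis II comorbidity, a weighted combination of within-cluster median
  Jaccard agreements, .1 * med(cluster A) + .7 * med(cluster B) +
  .2 * med(cluster C), reflecting the stronger association of dramatic/
  erratic (B) personality disorders with alcohol problems.

All metrics are unweighted subject counts; survey weights enter external
validation only.  ``profile_lattice`` computes all three metrics for every
rule in a lattice in vectorized form and is the workhorse of the optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    ComorbidityPanel,
    ConfigError,
    CriterionPanel,
    DiagnosticRule,
    DimensionError,
    ValidityProfile,
)
from .rule_space import RuleLattice, apply_rule

__all__ = [
    "AgreementCounts",
    "cross_tabulate",
    "jaccard",
    "persistence",
    "comorbidity_axis1",
    "comorbidity_axis2",
    "validity_profile",
    "profile_lattice",
    "AXIS2_CLUSTER_WEIGHTS",
    "AGREEMENT_MEASURES",
]

#: Default (cluster A, cluster B, cluster C) weights for Axis II comorbidity.
AXIS2_CLUSTER_WEIGHTS: tuple[float, float, float] = (0.1, 0.7, 0.2)


@dataclass(frozen=True)
class AgreementCounts:
    """2x2 cross-classification counts of two binary variables."""

    a: int  # joint presence
    b: int  # first only
    c: int  # second only
    d: int  # joint absence

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def _check_binary_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise DimensionError(f"length mismatch: {x.shape} vs {y.shape}")
    return x.astype(bool), y.astype(bool)


def cross_tabulate(x: Sequence[int], y: Sequence[int]) -> AgreementCounts:
    """Count the four logical states of two binary vectors."""
    xb, yb = _check_binary_pair(np.asarray(x), np.asarray(y))
    a = int(np.sum(xb & yb))
    b = int(np.sum(xb & ~yb))
    c = int(np.sum(~xb & yb))
    return AgreementCounts(a=a, b=b, c=c, d=len(xb) - a - b - c)


def jaccard(counts: AgreementCounts) -> float | None:
    """Jaccard's measure a/(a+b+c); None when a+b+c = 0 (undefined)."""
    denom = counts.a + counts.b + counts.c
    if denom == 0:
        return None
    return counts.a / denom


def _yule_q(counts: AgreementCounts) -> float | None:
    ad, bc = counts.a * counts.d, counts.b * counts.c
    if ad + bc == 0:
        return None
    return (ad - bc) / (ad + bc)


def _yule_y(counts: AgreementCounts) -> float | None:
    ad, bc = math.sqrt(counts.a * counts.d), math.sqrt(counts.b * counts.c)
    if ad + bc == 0:
        return None
    return (ad - bc) / (ad + bc)


def _phi(counts: AgreementCounts) -> float | None:
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    denom = math.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    if denom == 0:
        return None
    return (a * d - b * c) / denom


#: Pluggable agreement measures; Jaccard is the default and the only one the
#: optimizer uses.  The alternatives are provided for exploratory comparison.
AGREEMENT_MEASURES: dict[str, Callable[[AgreementCounts], float | None]] = {
    "jaccard": jaccard,
    "yule_q": _yule_q,
    "yule_y": _yule_y,
    "phi": _phi,
}


def persistence(dx1: Sequence[int], dx2: Sequence[int]) -> float | None:
    """P(diagnosed at Wave 2 | diagnosed at Wave 1); None if no Wave-1 cases."""
    x, y = _check_binary_pair(np.asarray(dx1), np.asarray(dx2))
    n1 = int(x.sum())
    if n1 == 0:
        return None
    return int(np.sum(x & y)) / n1


def _median(values: list[float | None]) -> float | None:
    if any(v is None for v in values):
        return None
    return float(np.median(values))


def comorbidity_axis1(dx1: Sequence[int], axis1: np.ndarray) -> float | None:
    """Median Jaccard agreement between a diagnosis and each Axis I disorder.

    The even-length median is the mean of the two middle order statistics.
    Propagates None if any constituent Jaccard is undefined.
    """
    axis1 = np.atleast_2d(np.asarray(axis1))
    js = [jaccard(cross_tabulate(dx1, axis1[:, m])) for m in range(axis1.shape[1])]
    return _median(js)


def comorbidity_axis2(
    dx1: Sequence[int],
    clusters: tuple[np.ndarray, np.ndarray, np.ndarray],
    weights: tuple[float, float, float] = AXIS2_CLUSTER_WEIGHTS,
) -> float | None:
    """Weighted combination of per-cluster median Jaccard agreements."""
    if min(weights) < 0 or abs(sum(weights) - 1.0) > 1e-9:
        raise ConfigError(f"cluster weights must be nonnegative and sum to 1, got {weights}")
    medians = [comorbidity_axis1(dx1, cl) for cl in clusters]
    if any(m is None for m in medians):
        return None
    return float(sum(w * m for w, m in zip(weights, medians)))


def validity_profile(
    rule: DiagnosticRule,
    panel: CriterionPanel,
    comorbidity: ComorbidityPanel,
    cluster_weights: tuple[float, float, float] = AXIS2_CLUSTER_WEIGHTS,
) -> ValidityProfile:
    """Apply a rule at both waves and compute its full validity profile."""
    dx1 = apply_rule(rule, panel.wave1)
    dx2 = apply_rule(rule, panel.wave2)
    prev = float(dx1.mean())
    if prev == 0.0:
        return ValidityProfile(
            prevalence_w1=0.0,
            persistence=None,
            comorbidity_ax1=None,
            comorbidity_ax2=None,
            valid=False,
        )
    return ValidityProfile(
        prevalence_w1=prev,
        persistence=persistence(dx1, dx2),
        comorbidity_ax1=comorbidity_axis1(dx1, comorbidity.axis1),
        comorbidity_ax2=comorbidity_axis2(
            dx1,
            (comorbidity.cluster_a, comorbidity.cluster_b, comorbidity.cluster_c),
            cluster_weights,
        ),
        valid=True,
    )


def profile_lattice(
    panel: CriterionPanel,
    comorbidity: ComorbidityPanel,
    lattice: RuleLattice,
    cluster_weights: tuple[float, float, float] = AXIS2_CLUSTER_WEIGHTS,
) -> pd.DataFrame:
    """Validity metrics for every rule in the lattice, vectorized.

    Returns a DataFrame indexed like the lattice with columns ``mask``,
    ``size``, ``threshold``, ``prevalence_w1``, ``persistence``,
    ``comorbidity_ax1``, ``comorbidity_ax2``, ``valid``.  Invalid rules
    (no Wave-1 diagnosis) carry NaN metrics.

    Agrees exactly with :func:`validity_profile` rule by rule; rules sharing
    a subset are processed together, with their endorsed-criterion counts
    compared against all thresholds at once.
    """
    if panel.n_criteria != lattice.n_criteria:
        raise DimensionError("panel K does not match lattice")
    if min(cluster_weights) < 0 or abs(sum(cluster_weights) - 1.0) > 1e-9:
        raise ConfigError("cluster weights must be nonnegative and sum to 1")
    n = panel.n_subjects
    w1 = panel.wave1.astype(np.int16)
    w2 = panel.wave2.astype(np.int16)
    # disorder columns: axis1 first, then clusters A, B, C
    disorders = np.hstack(
        [comorbidity.axis1, comorbidity.cluster_a, comorbidity.cluster_b, comorbidity.cluster_c]
    ).astype(np.float64)
    m_ax1 = comorbidity.axis1.shape[1]
    m_a = comorbidity.cluster_a.shape[1]
    m_b = comorbidity.cluster_b.shape[1]
    disorder_totals = disorders.sum(axis=0)  # a + c per disorder

    n_rules = lattice.n_rules
    prev = np.zeros(n_rules)
    pers = np.full(n_rules, np.nan)
    ax1 = np.full(n_rules, np.nan)
    ax2 = np.full(n_rules, np.nan)

    # group rules by subset mask; canonical order keeps each group contiguous
    masks = lattice.masks
    boundaries = np.flatnonzero(np.r_[True, masks[1:] != masks[:-1], True])
    wa, wb, wc = cluster_weights
    for start, stop in zip(boundaries[:-1], boundaries[1:]):
        mask = int(masks[start])
        idx = [j for j in range(lattice.n_criteria) if mask >> j & 1]
        thresholds = lattice.thresholds[start:stop]  # 1..size
        c1 = w1[:, idx].sum(axis=1)
        c2 = w2[:, idx].sum(axis=1)
        # dx per threshold: (n, T) booleans
        dx1 = c1[:, None] >= thresholds[None, :]
        dx2 = c2[:, None] >= thresholds[None, :]
        n1 = dx1.sum(axis=0).astype(float)  # Wave-1 diagnoses per threshold
        prev[start:stop] = n1 / n
        valid = n1 > 0
        if not valid.any():
            continue
        joint = np.sum(dx1 & dx2, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(valid, joint / n1, np.nan)
        pers[start:stop] = p
        # Jaccard with every disorder: a = dx1'D; a+b+c = n1 + total - a
        a = dx1.astype(np.float64).T @ disorders  # (T, M)
        denom = n1[:, None] + disorder_totals[None, :] - a
        with np.errstate(invalid="ignore", divide="ignore"):
            j = np.where(denom > 0, a / denom, np.nan)
        j[~valid, :] = np.nan
        ax1[start:stop] = np.median(j[:, :m_ax1], axis=1)
        med_a = np.median(j[:, m_ax1 : m_ax1 + m_a], axis=1)
        med_b = np.median(j[:, m_ax1 + m_a : m_ax1 + m_a + m_b], axis=1)
        med_c = np.median(j[:, m_ax1 + m_a + m_b :], axis=1)
        ax2[start:stop] = wa * med_a + wb * med_b + wc * med_c

    return pd.DataFrame(
        {
            "mask": masks.astype(np.int64),
            "size": lattice.sizes.astype(int),
            "threshold": lattice.thresholds.astype(int),
            "prevalence_w1": prev,
            "persistence": pers,
            "comorbidity_ax1": ax1,
            "comorbidity_ax2": ax2,
            "valid": prev > 0,
        }
    )
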