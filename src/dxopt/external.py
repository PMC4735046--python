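"""External validation of competing diagnostic rules.

Two rules are compared by cross-classifying their Wave-1 diagnoses into
Both / A-only / B-only / Neither groups, then testing the three planned
contrasts (A-only vs B-only, A-only vs Both, B-only vs Both) on each
external validator with survey weights.

The weighted test is a Welch-type two-sample comparison on weighted means,
with weighted variances and effective sample sizes n_eff = (Sum w)^2 /
Sum w^2; degrees of freedom follow Welch-Satterthwaite.  With unit weights
this reduces exactly to the ordinary Welch t test.  Full survey-design
variance estimation (Taylor linearization, replicate weights) is out of
scope; see the methods note.  Binary validators run through the same
machinery on 0/1 values, i.e. differences of weighted proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import (
    CriterionPanel,
    DiagnosticRule,
    DimensionError,
    ExternalPanel,
)
from .rule_space import apply_rule

__all__ = [
    "OverlapTable",
    "ComparisonRow",
    "ValidationReport",
    "cross_classify",
    "weighted_comparison",
    "validation_report",
]


@dataclass(frozen=True)
class OverlapTable:
    """2x2 cross-classification of two diagnostic rules' Wave-1 diagnoses."""

    both: int
    a_only: int
    b_only: int
    neither: int
    both_ids: np.ndarray
    a_only_ids: np.ndarray
    b_only_ids: np.ndarray
    neither_ids: np.ndarray

    @property
    def n(self) -> int:
        return self.both + self.a_only + self.b_only + self.neither

    def to_dict(self) -> dict:
        return {
            "both": self.both,
            "a_only": self.a_only,
            "b_only": self.b_only,
            "neither": self.neither,
        }


def cross_classify(dx_a: np.ndarray, dx_b: np.ndarray) -> OverlapTable:
    """Partition subjects by which of the two rules diagnose them."""
    a = np.asarray(dx_a).ravel().astype(bool)
    b = np.asarray(dx_b).ravel().astype(bool)
    if a.shape != b.shape:
        raise DimensionError(f"length mismatch: {a.shape} vs {b.shape}")
    both = np.flatnonzero(a & b)
    a_only = np.flatnonzero(a & ~b)
    b_only = np.flatnonzero(~a & b)
    neither = np.flatnonzero(~a & ~b)
    return OverlapTable(
        both=len(both),
        a_only=len(a_only),
        b_only=len(b_only),
        neither=len(neither),
        both_ids=both,
        a_only_ids=a_only,
        b_only_ids=b_only,
        neither_ids=neither,
    )


@dataclass(frozen=True)
class ComparisonRow:
    """One weighted group comparison: difference, t, two-sided p."""

    validator: str
    diff: float | None
    t: float | None
    p: float | None
    n1_eff: float
    n2_eff: float
    estimable: bool


def _weighted_moments(values: np.ndarray, weights: np.ndarray) -> tuple[float, float, float]:
    """Weighted mean, unbiased-style weighted variance, effective n."""
    sw = weights.sum()
    mean = float(np.sum(weights * values) / sw)
    n_eff = float(sw**2 / np.sum(weights**2))
    if n_eff <= 1:
        return mean, np.nan, n_eff
    # normalize so the estimator matches the sample variance at unit weights
    var = float(np.sum(weights * (values - mean) ** 2) / sw * n_eff / (n_eff - 1))
    return mean, var, n_eff


def weighted_comparison(
    values: np.ndarray,
    weights: np.ndarray,
    group1: np.ndarray,
    group2: np.ndarray,
    label: str = "",
) -> ComparisonRow:
    """Weighted Welch comparison of two subject groups on one validator.

    ``group1``/``group2`` are index arrays into ``values``/``weights``.
    Pairs with missing (NaN) values are excluded per group (pairwise
    deletion).  A group with effective sample size below 2 (or zero
    variance in both groups with zero difference) renders the row
    non-estimable rather than raising.
    """
    values = np.asarray(values, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    if values.shape != weights.shape:
        raise DimensionError("values and weights differ in length")

    def extract(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        v = values[idx]
        w = weights[idx]
        ok = np.isfinite(v) & (w > 0)
        return v[ok], w[ok]

    v1, w1 = extract(np.asarray(group1, dtype=int))
    v2, w2 = extract(np.asarray(group2, dtype=int))
    if len(v1) == 0 or len(v2) == 0:
        return ComparisonRow(label, None, None, None, 0.0, 0.0, False)
    m1, s1, n1 = _weighted_moments(v1, w1)
    m2, s2, n2 = _weighted_moments(v2, w2)
    if n1 < 2 or n2 < 2 or not np.isfinite(s1) or not np.isfinite(s2):
        return ComparisonRow(label, m1 - m2, None, None, n1, n2, False)
    diff = m1 - m2
    se2 = s1 / n1 + s2 / n2
    if se2 == 0:
        # identical constant groups: no evidence of a difference
        return ComparisonRow(label, diff, 0.0, 1.0, n1, n2, True)
    t = diff / np.sqrt(se2)
    df = se2**2 / ((s1 / n1) ** 2 / (n1 - 1) + (s2 / n2) ** 2 / (n2 - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return ComparisonRow(label, diff, float(t), p, n1, n2, True)


@dataclass
class ValidationReport:
    """Overlap table plus the three planned contrasts on every validator."""

    overlap: OverlapTable
    comparisons: pd.DataFrame  # columns: validator, contrast, diff, t, p, ...

    def to_csv(self, path) -> None:
        self.comparisons.to_csv(path, index=False)


CONTRASTS = ("a_only_vs_b_only", "a_only_vs_both", "b_only_vs_both")


def validation_report(
    rule_a: DiagnosticRule,
    rule_b: DiagnosticRule,
    panel: CriterionPanel,
    external: ExternalPanel,
    adjust: bool = False,
) -> ValidationReport:
    """Compare two rules on all external validators.

    Contrast groups come from the Wave-1 overlap partition; continuous
    scales and binary validators both run through the weighted Welch
    machinery (binary rows are differences of weighted proportions).  With
    ``adjust=True`` Benjamini-Hochberg adjusted p-values are added per
    contrast (off by default: planned comparisons are reported unadjusted).
    """
    dx_a = apply_rule(rule_a, panel.wave1)
    dx_b = apply_rule(rule_b, panel.wave1)
    overlap = cross_classify(dx_a, dx_b)
    groups = {
        "a_only_vs_b_only": (overlap.a_only_ids, overlap.b_only_ids),
        "a_only_vs_both": (overlap.a_only_ids, overlap.both_ids),
        "b_only_vs_both": (overlap.b_only_ids, overlap.both_ids),
    }
    columns = [
        (name, external.scales[:, j], "scale")
        for j, name in enumerate(external.scale_names)
    ] + [
        (name, external.binary_validators[:, j], "binary")
        for j, name in enumerate(external.binary_names)
    ]
    rows = []
    for name, values, kind in columns:
        for contrast, (g1, g2) in groups.items():
            row = weighted_comparison(values, panel.weights, g1, g2, label=name)
            rows.append(
                {
                    "validator": name,
                    "kind": kind,
                    "contrast": contrast,
                    "diff": row.diff,
                    "t": row.t,
                    "p": row.p,
                    "n1_eff": row.n1_eff,
                    "n2_eff": row.n2_eff,
                    "estimable": row.estimable,
                }
            )
    df = pd.DataFrame(rows)
    if adjust:
        df["p_adjusted"] = np.nan
        for contrast in CONTRASTS:
            sel = (df["contrast"] == contrast) & df["p"].notna()
            if sel.any():
                df.loc[sel, "p_adjusted"] = stats.false_discovery_control(
                    df.loc[sel, "p"].to_numpy(), method="bh"
                )
    return ValidationReport(overlap=overlap, comparisons=df)
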