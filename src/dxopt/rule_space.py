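"""Enumeration of the full subset x threshold rule lattice, and rule application.

For K criteria there are 2^K - 1 nonempty subsets and, allowing every
threshold from 1 to the subset size, K * 2^(K-1) candidate diagnostic rules
(11,264 for the 11 DSM-IV AUD criteria).  The search is exhaustive by design;
no heuristic pruning is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .core_data import CapacityError, DiagnosticRule, DimensionError

__all__ = ["RuleLattice", "enumerate_rules", "apply_rule", "dsm_reference_rules"]

# Guard against combinatorial blow-up: K=24 already means ~200M rules.
MAX_CRITERIA = 24


@dataclass
class RuleLattice:
    """All (subset, threshold) rules over ``n_criteria`` criteria.

    Rules are stored as parallel arrays of subset bitmasks and thresholds in
    canonical order (subset size, then lexicographic subset, then threshold),
    so downstream profiling can vectorize over them.  ``rules`` materializes
    :class:`DiagnosticRule` objects lazily.
    """

    n_criteria: int
    masks: np.ndarray  # uint32 bitmask per rule
    thresholds: np.ndarray  # int per rule
    sizes: np.ndarray  # subset cardinality per rule

    @property
    def n_rules(self) -> int:
        return len(self.masks)

    @property
    def n_subsets(self) -> int:
        return len(np.unique(self.masks))

    def rules(self) -> Iterator[DiagnosticRule]:
        for mask, t in zip(self.masks, self.thresholds):
            subset = frozenset(j for j in range(self.n_criteria) if mask >> j & 1)
            yield DiagnosticRule(subset=subset, threshold=int(t))

    def rule_at(self, i: int) -> DiagnosticRule:
        mask = int(self.masks[i])
        subset = frozenset(j for j in range(self.n_criteria) if mask >> j & 1)
        return DiagnosticRule(subset=subset, threshold=int(self.thresholds[i]))


def enumerate_rules(n_criteria: int) -> RuleLattice:
    """Enumerate every nonempty criterion subset with every threshold.

    Canonical order is deterministic: ascending subset size, then
    lexicographic subset (as a sorted index tuple), then threshold.  Counts
    satisfy n_subsets = 2^K - 1 and n_rules = K * 2^(K-1).
    """
    if not 1 <= n_criteria <= MAX_CRITERIA:
        raise CapacityError(f"n_criteria must be in 1..{MAX_CRITERIA}, got {n_criteria}")
    k = n_criteria
    all_masks = np.arange(1, 1 << k, dtype=np.uint32)
    sizes = np.array([int(m).bit_count() for m in all_masks], dtype=np.int16)
    # lexicographic order of the sorted index tuple == descending reversed-bit
    # value (bit 0 is the most significant position of the reversed string)
    lex = np.array(
        [int(f"{int(m):0{k}b}"[::-1], 2) for m in all_masks], dtype=np.int64
    )
    order = np.lexsort((-lex, sizes))
    masks, thresholds, szs = [], [], []
    for m in all_masks[order]:
        s = int(m).bit_count()
        for t in range(1, s + 1):
            masks.append(m)
            thresholds.append(t)
            szs.append(s)
    return RuleLattice(
        n_criteria=k,
        masks=np.array(masks, dtype=np.uint32),
        thresholds=np.array(thresholds, dtype=np.int16),
        sizes=np.array(szs, dtype=np.int16),
    )


def apply_rule(rule: DiagnosticRule, wave_matrix: np.ndarray) -> np.ndarray:
    """Diagnose each subject: 1 iff >= threshold criteria in the subset endorsed."""
    wave_matrix = np.asarray(wave_matrix)
    if wave_matrix.ndim != 2:
        raise DimensionError("wave matrix must be 2-d")
    idx = rule.indices()
    if idx[-1] >= wave_matrix.shape[1]:
        raise DimensionError(
            f"criterion index {idx[-1]} out of bounds for K={wave_matrix.shape[1]}"
        )
    counts = wave_matrix[:, list(idx)].sum(axis=1)
    return (counts >= rule.threshold).astype(np.int8)


def dsm_reference_rules() -> dict[str, DiagnosticRule]:
    """Named reference rules on the canonical 11-criterion panel.

    ``dsm4_dependence``: 3 of the 7 dependence criteria (Tolerance, Cut Down,
    Larger/Longer, Give Up, Time Drinking, Continue, Withdrawal).
    ``dsm5_aud_2of11``: 2 of all 11 criteria.
    """
    return {
        "dsm4_dependence": DiagnosticRule(subset=frozenset(range(7)), threshold=3),
        "dsm5_aud_2of11": DiagnosticRule(subset=frozenset(range(11)), threshold=2),
    }
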