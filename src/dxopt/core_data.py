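"""Domain types, validation, and serialization for criterion panels and rules.

The central objects are :class:`CriterionPanel` (per-subject binary
endorsement of K diagnostic criteria at two assessment waves),
:class:`ComorbidityPanel` (binary lifetime indicators for Axis I symptom
disorders and for Axis II personality disorders grouped into clusters A/B/C),
:class:`ExternalPanel` (continuous and binary external validators), and
:class:`DiagnosticRule` (a criterion subset plus an endorsement threshold).

Input is tidy tabular data, one row per subject, with a YAML/JSON schema
mapping column names to roles.  Rows with any missing value among the
criterion or comorbidity columns are dropped (complete-case on the
optimization columns only); missingness in external validators is handled
pairwise at comparison time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DSM4_CRITERIA",
    "AXIS1_DISORDERS",
    "CLUSTER_A_DISORDERS",
    "CLUSTER_B_DISORDERS",
    "CLUSTER_C_DISORDERS",
    "SchemaError",
    "ValidationError",
    "DimensionError",
    "ConfigError",
    "CapacityError",
    "DegenerateDataError",
    "SelectionError",
    "CriterionPanel",
    "ComorbidityPanel",
    "DiagnosticRule",
    "ValidityProfile",
    "ExternalPanel",
    "PanelBundle",
    "read_panel",
    "write_panel",
    "load_schema",
    "rule_to_json",
    "json_to_rule",
]

# Canonical order of the 11 DSM-IV alcohol-use-disorder criteria.  The first
# seven are the dependence criteria; the last four the abuse criteria.
DSM4_CRITERIA: tuple[str, ...] = (
    "Tolerance",
    "Cut Down",
    "Larger/Longer",
    "Give Up",
    "Time Drinking",
    "Continue",
    "Withdrawal",
    "Home/Job",
    "Hazardous Use",
    "Legal",
    "Fight/Trouble",
)

AXIS1_DISORDERS: tuple[str, ...] = (
    "Major Depression",
    "Dysthymia",
    "Hypomania",
    "Panic Disorder",
    "Social Phobia",
    "Specific Phobia",
    "Generalized Anxiety",
)

CLUSTER_A_DISORDERS: tuple[str, ...] = ("Paranoid", "Schizoid", "Schizotypal")
CLUSTER_B_DISORDERS: tuple[str, ...] = (
    "Antisocial",
    "Borderline",
    "Histrionic",
    "Narcissistic",
)
CLUSTER_C_DISORDERS: tuple[str, ...] = (
    "Avoidant",
    "Dependent",
    "Obsessive-Compulsive",
)


class SchemaError(ValueError):
    """A schema references a column absent from the data, or is malformed."""


class ValidationError(ValueError):
    """Data violate a domain invariant (e.g. a non-binary endorsement)."""


class DimensionError(ValueError):
    """Mismatched array dimensions."""


class ConfigError(ValueError):
    """Invalid configuration value."""


class CapacityError(ValueError):
    """A request would exceed a combinatorial guard."""


class DegenerateDataError(ValueError):
    """Data too degenerate for the requested computation."""


class SelectionError(ValueError):
    """Model selection could not produce a rule under the given settings."""


def _as_binary(matrix: np.ndarray, what: str, row_ids: Sequence | None = None) -> np.ndarray:
    arr = np.asarray(matrix)
    if arr.ndim != 2:
        raise DimensionError(f"{what} must be a 2-d matrix, got shape {arr.shape}")
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        rid = row_ids[i] if row_ids is not None else i
        raise ValidationError(
            f"non-binary value {arr[i, j]!r} in {what} at row {rid!r}, column {j}"
        )
    return arr.astype(np.int8)


@dataclass
class CriterionPanel:
    """Binary criterion endorsements for N subjects at two waves.

    Parameters
    ----------
    subject_ids : sequence of unique identifiers, length N.
    wave1, wave2 : (N, K) binary matrices; entry 1 means the criterion was
        endorsed in the past year at that wave.
    criterion_names : K labels; defaults to the 11 DSM-IV AUD criteria.
    weights : N nonnegative survey weights; default all 1.  Weights enter
        external validation only, never the optimization metrics.
    """

    subject_ids: np.ndarray
    wave1: np.ndarray
    wave2: np.ndarray
    criterion_names: tuple[str, ...] = DSM4_CRITERIA
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.wave1 = _as_binary(self.wave1, "wave1", self.subject_ids)
        self.wave2 = _as_binary(self.wave2, "wave2", self.subject_ids)
        if self.wave1.shape != self.wave2.shape:
            raise DimensionError(
                f"wave1 {self.wave1.shape} and wave2 {self.wave2.shape} differ"
            )
        n, k = self.wave1.shape
        if k < 1:
            raise ValidationError("panel needs at least one criterion")
        self.criterion_names = tuple(self.criterion_names)
        if len(self.criterion_names) != k:
            raise DimensionError(
                f"{len(self.criterion_names)} criterion names for K={k} columns"
            )
        if len(self.subject_ids) != n:
            raise DimensionError("subject_ids length does not match matrix rows")
        if len(np.unique(self.subject_ids)) != n:
            raise ValidationError("subject_ids must be unique")
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n,):
            raise DimensionError("weights length does not match N")
        if (self.weights < 0).any() or not (self.weights > 0).any():
            raise ValidationError("weights must be >= 0 with at least one positive")

    @property
    def n_subjects(self) -> int:
        return self.wave1.shape[0]

    @property
    def n_criteria(self) -> int:
        return self.wave1.shape[1]

    def take(self, indices: np.ndarray) -> "CriterionPanel":
        """Row-subset the panel (used by k-fold splitting)."""
        return CriterionPanel(
            subject_ids=self.subject_ids[indices],
            wave1=self.wave1[indices],
            wave2=self.wave2[indices],
            criterion_names=self.criterion_names,
            weights=self.weights[indices],
        )


@dataclass
class ComorbidityPanel:
    """Lifetime comorbid-disorder indicators aligned with a criterion panel.

    Axis I holds symptom disorders (default 7: depression through generalized
    anxiety); Axis II personality disorders are grouped into the standard
    clusters A (odd/eccentric), B (dramatic/erratic), C (anxious/fearful).
    """

    axis1: np.ndarray
    cluster_a: np.ndarray
    cluster_b: np.ndarray
    cluster_c: np.ndarray
    axis1_names: tuple[str, ...] = AXIS1_DISORDERS
    cluster_a_names: tuple[str, ...] = CLUSTER_A_DISORDERS
    cluster_b_names: tuple[str, ...] = CLUSTER_B_DISORDERS
    cluster_c_names: tuple[str, ...] = CLUSTER_C_DISORDERS

    def __post_init__(self) -> None:
        self.axis1 = _as_binary(self.axis1, "axis1")
        self.cluster_a = _as_binary(self.cluster_a, "cluster_a")
        self.cluster_b = _as_binary(self.cluster_b, "cluster_b")
        self.cluster_c = _as_binary(self.cluster_c, "cluster_c")
        n = self.axis1.shape[0]
        for name, mat, labels in (
            ("axis1", self.axis1, self.axis1_names),
            ("cluster_a", self.cluster_a, self.cluster_a_names),
            ("cluster_b", self.cluster_b, self.cluster_b_names),
            ("cluster_c", self.cluster_c, self.cluster_c_names),
        ):
            if mat.shape[0] != n:
                raise DimensionError(f"{name} row count differs from axis1")
            if mat.shape[1] < 1:
                raise ValidationError(f"{name} must contain at least one disorder")
            if len(labels) != mat.shape[1]:
                raise DimensionError(f"{name} labels do not match its columns")

    @property
    def n_subjects(self) -> int:
        return self.axis1.shape[0]

    def take(self, indices: np.ndarray) -> "ComorbidityPanel":
        return ComorbidityPanel(
            axis1=self.axis1[indices],
            cluster_a=self.cluster_a[indices],
            cluster_b=self.cluster_b[indices],
            cluster_c=self.cluster_c[indices],
            axis1_names=self.axis1_names,
            cluster_a_names=self.cluster_a_names,
            cluster_b_names=self.cluster_b_names,
            cluster_c_names=self.cluster_c_names,
        )


@dataclass(frozen=True)
class DiagnosticRule:
    """A criterion subset plus the number of endorsements required.

    A subject is diagnosed when at least ``threshold`` of the criteria in
    ``subset`` are endorsed.  DSM-IV alcohol dependence is the rule
    (first 7 criteria, threshold 3); DSM-5 AUD is (all 11, threshold 2).
    """

    subset: frozenset[int]
    threshold: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "subset", frozenset(int(i) for i in self.subset))
        if not self.subset:
            raise ValidationError("rule subset must be nonempty")
        if min(self.subset) < 0:
            raise ValidationError("criterion indices must be nonnegative")
        if not 1 <= self.threshold <= len(self.subset):
            raise ValidationError(
                f"threshold {self.threshold} outside 1..{len(self.subset)}"
            )

    @property
    def size(self) -> int:
        return len(self.subset)

    @property
    def mask(self) -> int:
        """Bitmask over criterion indices (bit j set iff criterion j in subset)."""
        m = 0
        for j in self.subset:
            m |= 1 << j
        return m

    def indices(self) -> tuple[int, ...]:
        return tuple(sorted(self.subset))

    def sort_key(self) -> tuple[int, int, int]:
        """Parsimony-first ordering: fewer criteria, lower threshold, mask."""
        return (self.size, self.threshold, self.mask)

    def criteria(self, names: Sequence[str]) -> tuple[str, ...]:
        return tuple(names[j] for j in self.indices())


@dataclass(frozen=True)
class ValidityProfile:
    """Per-rule validity metrics.

    ``persistence`` is P(diagnosed at Wave 2 | diagnosed at Wave 1);
    ``comorbidity_ax1``/``comorbidity_ax2`` are median-aggregated Jaccard
    agreements with Axis I disorders and weighted cluster medians for Axis II;
    ``prevalence_w1`` is the Wave-1 diagnosis rate.  When no subject is
    diagnosed at Wave 1 the rule is flagged invalid and the three validity
    values are None (not zero).
    """

    prevalence_w1: float
    persistence: float | None
    comorbidity_ax1: float | None
    comorbidity_ax2: float | None
    valid: bool

    def __post_init__(self) -> None:
        if self.valid:
            for name in ("prevalence_w1", "persistence", "comorbidity_ax1", "comorbidity_ax2"):
                v = getattr(self, name)
                if v is None or not 0.0 <= v <= 1.0:
                    raise ValidationError(f"{name}={v!r} outside [0, 1] on a valid profile")
        else:
            if any(
                getattr(self, n) is not None
                for n in ("persistence", "comorbidity_ax1", "comorbidity_ax2")
            ):
                raise ValidationError("invalid profiles must carry no validity values")

    def to_dict(self) -> dict:
        return {
            "prevalence_w1": self.prevalence_w1,
            "persistence": self.persistence,
            "comorbidity_ax1": self.comorbidity_ax1,
            "comorbidity_ax2": self.comorbidity_ax2,
            "valid": self.valid,
        }


@dataclass
class ExternalPanel:
    """External validators: continuous scales and binary indicators.

    Scales are SF-12-like subscales (constructed to mean 50, SD 10) and
    consumption measures; binary validators are Wave-2 disorder indicators.
    NaN entries are allowed and handled pairwise during comparisons.
    """

    scales: np.ndarray
    binary_validators: np.ndarray
    scale_names: tuple[str, ...] = ()
    binary_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.scales = np.atleast_2d(np.asarray(self.scales, dtype=float))
        self.binary_validators = np.atleast_2d(np.asarray(self.binary_validators, dtype=float))
        if np.isinf(self.scales).any():
            raise ValidationError("scale values must be finite or NaN")
        vals = self.binary_validators
        if not np.all(np.isnan(vals) | (vals == 0) | (vals == 1)):
            raise ValidationError("binary validators must be 0/1 or NaN")
        if len(self.scale_names) != self.scales.shape[1]:
            raise DimensionError("scale names do not match scale columns")
        if len(self.binary_names) != self.binary_validators.shape[1]:
            raise DimensionError("binary names do not match validator columns")
        if self.scales.shape[0] != self.binary_validators.shape[0]:
            raise DimensionError("scales and binary validators differ in rows")

    @property
    def n_subjects(self) -> int:
        return self.scales.shape[0]

    def take(self, indices: np.ndarray) -> "ExternalPanel":
        return ExternalPanel(
            scales=self.scales[indices],
            binary_validators=self.binary_validators[indices],
            scale_names=self.scale_names,
            binary_names=self.binary_names,
        )


@dataclass
class PanelBundle:
    """Everything read from one input table."""

    criteria: CriterionPanel
    comorbidity: ComorbidityPanel
    external: ExternalPanel | None
    n_dropped: int = 0

    def take(self, indices: np.ndarray) -> "PanelBundle":
        return PanelBundle(
            criteria=self.criteria.take(indices),
            comorbidity=self.comorbidity.take(indices),
            external=self.external.take(indices) if self.external is not None else None,
            n_dropped=0,
        )


# ---------------------------------------------------------------------------
# Schema-driven CSV input


def load_schema(path: str | Path) -> dict:
    """Load a column-mapping schema from YAML or JSON."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _require(df: pd.DataFrame, cols: Iterable[str], role: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing {role} column(s): {', '.join(missing)}")


def read_panel(path: str | Path, schema: Mapping | str | Path) -> PanelBundle:
    """Read a subject-level CSV/TSV into validated panels.

    ``schema`` maps column names to roles::

        subject_id: id
        weight: wt                      # optional
        criteria:
          Tolerance: {wave1: tol1, wave2: tol2}
          ...
        axis1: {Major Depression: mdd, ...}
        cluster_a: {...}
        cluster_b: {...}
        cluster_c: {...}
        scales: {Phys. Hlth.: ph, ...}            # optional
        binary_validators: {Craving: crav, ...}   # optional

    Rows with missing values in any criterion or comorbidity column are
    dropped and counted in ``PanelBundle.n_dropped`` (complete-case on the
    optimization columns only).
    """
    if not isinstance(schema, Mapping):
        schema = load_schema(schema)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)

    crit = schema["criteria"]
    names = tuple(crit)
    w1_cols = [crit[c]["wave1"] for c in names]
    w2_cols = [crit[c]["wave2"] for c in names]
    ax1 = dict(schema["axis1"])
    ca = dict(schema["cluster_a"])
    cb = dict(schema["cluster_b"])
    cc = dict(schema["cluster_c"])

    _require(df, w1_cols, "wave-1 criterion")
    _require(df, w2_cols, "wave-2 criterion")
    for role, mapping in (("axis1", ax1), ("cluster_a", ca), ("cluster_b", cb), ("cluster_c", cc)):
        _require(df, mapping.values(), role)

    id_col = schema.get("subject_id")
    if id_col is not None:
        _require(df, [id_col], "subject id")
        ids = df[id_col].to_numpy()
    else:
        ids = df.index.to_numpy()

    core_cols = w1_cols + w2_cols + list(ax1.values()) + list(ca.values()) + list(cb.values()) + list(cc.values())
    keep = df[core_cols].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    df = df.loc[keep]
    ids = ids[keep.to_numpy()]

    weight_col = schema.get("weight")
    if weight_col is not None:
        _require(df, [weight_col], "weight")
        weights = df[weight_col].to_numpy(dtype=float)
    else:
        weights = None

    panel = CriterionPanel(
        subject_ids=ids,
        wave1=df[w1_cols].to_numpy(),
        wave2=df[w2_cols].to_numpy(),
        criterion_names=names,
        weights=weights,
    )
    comorbidity = ComorbidityPanel(
        axis1=df[list(ax1.values())].to_numpy(),
        cluster_a=df[list(ca.values())].to_numpy(),
        cluster_b=df[list(cb.values())].to_numpy(),
        cluster_c=df[list(cc.values())].to_numpy(),
        axis1_names=tuple(ax1),
        cluster_a_names=tuple(ca),
        cluster_b_names=tuple(cb),
        cluster_c_names=tuple(cc),
    )

    external = None
    scales = dict(schema.get("scales") or {})
    binaries = dict(schema.get("binary_validators") or {})
    if scales or binaries:
        _require(df, scales.values(), "scale validator")
        _require(df, binaries.values(), "binary validator")
        n = len(df)
        external = ExternalPanel(
            scales=df[list(scales.values())].to_numpy(dtype=float).reshape(n, len(scales)),
            binary_validators=df[list(binaries.values())].to_numpy(dtype=float).reshape(n, len(binaries)),
            scale_names=tuple(scales),
            binary_names=tuple(binaries),
        )
    return PanelBundle(panel, comorbidity, external, n_dropped)


def write_panel(bundle: PanelBundle, data_path: str | Path, schema_path: str | Path | None = None) -> dict:
    """Write a bundle back to CSV plus a matching schema (YAML).

    Returns the schema mapping.  Column names are generated from labels;
    read_panel(write_panel(b)) is the identity on all retained rows.
    """

    def slug(label: str, prefix: str) -> str:
        s = "".join(ch.lower() if ch.isalnum() else "_" for ch in label)
        return f"{prefix}_{s}"

    panel, com, ext = bundle.criteria, bundle.comorbidity, bundle.external
    cols: dict[str, np.ndarray] = {"subject_id": panel.subject_ids, "weight": panel.weights}
    schema: dict = {"subject_id": "subject_id", "weight": "weight", "criteria": {}}
    for j, name in enumerate(panel.criterion_names):
        c1, c2 = slug(name, "w1"), slug(name, "w2")
        schema["criteria"][name] = {"wave1": c1, "wave2": c2}
        cols[c1] = panel.wave1[:, j]
        cols[c2] = panel.wave2[:, j]
    for role, mat, labels in (
        ("axis1", com.axis1, com.axis1_names),
        ("cluster_a", com.cluster_a, com.cluster_a_names),
        ("cluster_b", com.cluster_b, com.cluster_b_names),
        ("cluster_c", com.cluster_c, com.cluster_c_names),
    ):
        schema[role] = {}
        for j, name in enumerate(labels):
            c = slug(name, role)
            schema[role][name] = c
            cols[c] = mat[:, j]
    if ext is not None:
        schema["scales"] = {}
        for j, name in enumerate(ext.scale_names):
            c = slug(name, "scale")
            schema["scales"][name] = c
            cols[c] = ext.scales[:, j]
        schema["binary_validators"] = {}
        for j, name in enumerate(ext.binary_names):
            c = slug(name, "val")
            schema["binary_validators"][name] = c
            cols[c] = ext.binary_validators[:, j]
    pd.DataFrame(cols).to_csv(data_path, index=False)
    if schema_path is not None:
        Path(schema_path).write_text(yaml.safe_dump(schema, sort_keys=False))
    return schema


# ---------------------------------------------------------------------------
# Rule serialization


def rule_to_json(rule: DiagnosticRule, criterion_names: Sequence[str] = DSM4_CRITERIA) -> str:
    """Serialize a rule recording criterion names, not only indices."""
    return json.dumps(
        {
            "criteria": list(rule.criteria(criterion_names)),
            "indices": list(rule.indices()),
            "threshold": rule.threshold,
        }
    )


def json_to_rule(text: str, criterion_names: Sequence[str] = DSM4_CRITERIA) -> DiagnosticRule:
    """Parse a rule; names are resolved against ``criterion_names``.

    Raises :class:`ValidationError` if the threshold exceeds the subset size
    or a criterion name is unknown.
    """
    obj = json.loads(text)
    if "criteria" in obj:
        lookup = {name: j for j, name in enumerate(criterion_names)}
        try:
            subset = frozenset(lookup[name] for name in obj["criteria"])
        except KeyError as exc:
            raise ValidationError(f"unknown criterion name {exc.args[0]!r}") from None
    else:
        subset = frozenset(obj["indices"])
    return DiagnosticRule(subset=subset, threshold=int(obj["threshold"]))
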