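"""Synthetic two-wave criterion panels with planted structure.

The generator emulates the structure of a large two-wave epidemiological
alcohol survey so every pipeline stage can be exercised without restricted
data.  Subjects carry a latent severity theta1 ~ N(0, 1) at Wave 1 that
persists to Wave 2 as theta2 = rho * theta1 + sqrt(1 - rho^2) * noise.
Criterion j is endorsed at wave w with probability
logistic(a_j * (latent_w - b_j)), where *informative* criteria load on the
stable severity factor and *noise* criteria load on a shared transient
factor redrawn independently each wave — so noise criteria damage
persistence specifically, which is what gives the optimizer signal to prune
them.  Difficulties b_j are solved numerically so marginal endorsement
rates hit their targets (defaults calibrated to the Wave-1 endorsement
percentages of the 11 DSM-IV AUD criteria in the survey application, e.g.
Larger/Longer 9.0%, Give Up 0.66%).

Comorbid disorders are thresholded from liabilities correlated with theta1
at target lifetime prevalences; external scales are linear in theta2 plus
noise with mean 50 and SD 10 (SF-12-like); survey weights default to a
unit-mean gamma family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .core_data import (
    AXIS1_DISORDERS,
    CLUSTER_A_DISORDERS,
    CLUSTER_B_DISORDERS,
    CLUSTER_C_DISORDERS,
    DSM4_CRITERIA,
    ComorbidityPanel,
    ConfigError,
    CriterionPanel,
    ExternalPanel,
    PanelBundle,
    write_panel,
)

__all__ = [
    "TABLE_WAVE1_RATES",
    "CONSENSUS_SIX",
    "DisorderSpec",
    "GeneratorConfig",
    "generate",
    "make_fixture",
    "FIXTURE_PRESETS",
]

#: Wave-1 past-year endorsement rates of the 11 DSM-IV AUD criteria
#: (canonical order) used as default difficulty targets.
TABLE_WAVE1_RATES: tuple[float, ...] = (
    0.062062,  # Tolerance
    0.081693,  # Cut Down
    0.089952,  # Larger/Longer
    0.006643,  # Give Up
    0.020648,  # Time Drinking
    0.030163,  # Continue
    0.030702,  # Withdrawal
    0.007780,  # Home/Job
    0.080196,  # Hazardous Use
    0.007601,  # Legal
    0.017775,  # Fight/Trouble
)

#: Indices of the six criteria treated as stable-severity markers by default
#: (Cut Down, Time Drinking, Continue, Withdrawal, Home/Job, Fight/Trouble).
CONSENSUS_SIX: tuple[int, ...] = (1, 4, 5, 6, 7, 10)


@dataclass(frozen=True)
class DisorderSpec:
    """One comorbid disorder: target prevalence and loading on severity."""

    name: str
    prevalence: float
    loading: float


def _axis1_defaults() -> tuple[DisorderSpec, ...]:
    prevs = (0.20, 0.05, 0.04, 0.06, 0.05, 0.09, 0.04)
    return tuple(
        DisorderSpec(n, p, 0.35) for n, p in zip(AXIS1_DISORDERS, prevs)
    )


def _cluster_defaults() -> tuple[tuple[DisorderSpec, ...], ...]:
    # Cluster B loads hardest on severity, consistent with the weighting
    # rationale behind the Axis II comorbidity measure.
    a = tuple(
        DisorderSpec(n, p, 0.30)
        for n, p in zip(CLUSTER_A_DISORDERS, (0.044, 0.031, 0.039))
    )
    b = tuple(
        DisorderSpec(n, p, 0.45)
        for n, p in zip(CLUSTER_B_DISORDERS, (0.056, 0.059, 0.018, 0.062))
    )
    c = tuple(
        DisorderSpec(n, p, 0.30)
        for n, p in zip(CLUSTER_C_DISORDERS, (0.023, 0.005, 0.078))
    )
    return a, b, c


SCALE_NAMES: tuple[str, ...] = (
    "Phys. Hlth.",
    "Ment. Hlth.",
    "Phys. Health (Sub)",
    "Role Phys.",
    "Bodily Pain",
    "Gen. Hlth.",
    "Vitality",
    "Social",
    "Role Emotional",
    "Ment. Hlth. (Sub)",
)


def _scale_defaults() -> tuple[tuple[str, float], ...]:
    # health scales decline with Wave-2 severity; consumption rises with it
    health = tuple((name, -3.0) for name in SCALE_NAMES)
    return health + (("Ethanol Consumption", 4.0), ("5+ Drinks", 4.0))


def _binary_validator_defaults() -> tuple[DisorderSpec, ...]:
    # Wave-2 lifetime disorder indicators plus a craving item, driven by theta2
    prevs = (0.22, 0.055, 0.045, 0.065, 0.055, 0.095, 0.045)
    wave2 = tuple(
        DisorderSpec(f"{n} (W2)", p, 0.35) for n, p in zip(AXIS1_DISORDERS, prevs)
    )
    return wave2 + (DisorderSpec("Craving", 0.013, 0.60),)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic panel generator.

    Defaults describe the survey-like study conditions: 11 criteria with
    skewed endorsement targets, six of them loading on a stable severity
    factor at discrimination 1.5 (the rest on a per-wave transient factor at
    0.8), cross-wave latent correlation .85, disorder prevalences at
    plausible lifetime rates among past-year drinkers, and unit-mean gamma
    survey weights.
    """

    n_subjects: int = 15_000
    n_criteria: int = 11
    difficulties: tuple[float, ...] = TABLE_WAVE1_RATES  # target marginal rates
    informative_set: tuple[int, ...] = CONSENSUS_SIX
    discrimination_informative: float = 1.5
    discrimination_noise: float = 0.8
    rho: float = 0.85  # cross-wave latent correlation
    axis1: tuple[DisorderSpec, ...] = field(default_factory=_axis1_defaults)
    clusters: tuple[tuple[DisorderSpec, ...], ...] = field(default_factory=_cluster_defaults)
    scales: tuple[tuple[str, float], ...] = field(default_factory=_scale_defaults)
    binary_validators: tuple[DisorderSpec, ...] = field(default_factory=_binary_validator_defaults)
    scale_mean: float = 50.0
    scale_sd: float = 10.0
    weight_distribution: tuple = ("gamma", 4.0)  # unit-mean; ("unit",) for all-1
    criterion_names: tuple[str, ...] = DSM4_CRITERIA
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.difficulties) != self.n_criteria:
            raise ConfigError("difficulties must have one target per criterion")
        if not all(0.0 < r < 1.0 for r in self.difficulties):
            raise ConfigError("endorsement-rate targets must lie in (0, 1)")
        if not 0.0 <= self.rho <= 1.0:
            raise ConfigError(f"rho={self.rho} outside [0, 1]")
        if any(j < 0 or j >= self.n_criteria for j in self.informative_set):
            raise ConfigError("informative_set indices out of range")
        for spec in (
            list(self.axis1)
            + [d for cl in self.clusters for d in cl]
            + list(self.binary_validators)
        ):
            if abs(norm.ppf(spec.prevalence)) > 6:
                raise ConfigError(
                    f"prevalence target {spec.prevalence} for {spec.name} unreachable"
                )
            if not 0.0 <= abs(spec.loading) < 1.0:
                raise ConfigError(f"|loading| must be < 1 for {spec.name}")
        if len(self.criterion_names) != self.n_criteria:
            raise ConfigError("criterion_names must match n_criteria")


_GH_NODES, _GH_WEIGHTS = hermgauss(61)


def _solve_difficulty(a: float, target: float) -> float:
    """Difficulty b with E_theta[logistic(a * (theta - b))] = target.

    The marginal is over a standard-normal latent; solved by Gauss-Hermite
    quadrature plus root bracketing (monotone decreasing in b).
    """

    def marginal(b: float) -> float:
        return float(
            np.sum(_GH_WEIGHTS * expit(a * (np.sqrt(2.0) * _GH_NODES - b)))
            / np.sqrt(np.pi)
        )

    return brentq(lambda b: marginal(b) - target, -40.0 / a, 40.0 / a, xtol=1e-10)


def _threshold_binary(
    rng: np.random.Generator, driver: np.ndarray, specs: tuple[DisorderSpec, ...]
) -> np.ndarray:
    """Threshold liabilities lambda*driver + sqrt(1-lambda^2)*eps at targets."""
    n = len(driver)
    out = np.empty((n, len(specs)), dtype=np.int8)
    for m, spec in enumerate(specs):
        liability = spec.loading * driver + np.sqrt(1 - spec.loading**2) * rng.standard_normal(n)
        out[:, m] = liability > norm.ppf(1 - spec.prevalence)
    return out


def generate(config: GeneratorConfig) -> tuple[PanelBundle, dict]:
    """Generate a full synthetic bundle plus its ground-truth record.

    Same seed, same config -> byte-identical output.  The truth record
    stores the latent severities, the informative set, and all solved
    parameters, for parameter-recovery checks.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_subjects, config.n_criteria
    informative = np.zeros(k, dtype=bool)
    informative[list(config.informative_set)] = True
    disc = np.where(
        informative, config.discrimination_informative, config.discrimination_noise
    )
    difficulties = np.array(
        [_solve_difficulty(disc[j], config.difficulties[j]) for j in range(k)]
    )

    theta1 = rng.standard_normal(n)
    theta2 = config.rho * theta1 + np.sqrt(1 - config.rho**2) * rng.standard_normal(n)
    transient1 = rng.standard_normal(n)  # shared transient state, redrawn per wave
    transient2 = rng.standard_normal(n)

    def endorse(theta: np.ndarray, transient: np.ndarray) -> np.ndarray:
        latent = np.where(informative[None, :], theta[:, None], transient[:, None])
        p = expit(disc[None, :] * (latent - difficulties[None, :]))
        return (rng.random((n, k)) < p).astype(np.int8)

    wave1 = endorse(theta1, transient1)
    wave2 = endorse(theta2, transient2)

    axis1 = _threshold_binary(rng, theta1, config.axis1)
    cl_a = _threshold_binary(rng, theta1, config.clusters[0])
    cl_b = _threshold_binary(rng, theta1, config.clusters[1])
    cl_c = _threshold_binary(rng, theta1, config.clusters[2])

    scale_names = tuple(name for name, _ in config.scales)
    scales = np.empty((n, len(config.scales)))
    for v, (_, loading) in enumerate(config.scales):
        if abs(loading) >= config.scale_sd:
            raise ConfigError("scale loading magnitude must be below the scale SD")
        noise_sd = np.sqrt(config.scale_sd**2 - loading**2)
        scales[:, v] = config.scale_mean + loading * theta2 + noise_sd * rng.standard_normal(n)

    binary = _threshold_binary(rng, theta2, config.binary_validators)

    family = config.weight_distribution[0]
    if family == "gamma":
        shape = float(config.weight_distribution[1])
        weights = rng.gamma(shape, 1.0 / shape, size=n)
    elif family == "unit":
        weights = np.ones(n)
    else:
        raise ConfigError(f"unknown weight family {family!r}")

    bundle = PanelBundle(
        criteria=CriterionPanel(
            subject_ids=np.arange(n),
            wave1=wave1,
            wave2=wave2,
            criterion_names=config.criterion_names,
            weights=weights,
        ),
        comorbidity=ComorbidityPanel(
            axis1=axis1,
            cluster_a=cl_a,
            cluster_b=cl_b,
            cluster_c=cl_c,
            axis1_names=tuple(d.name for d in config.axis1),
            cluster_a_names=tuple(d.name for d in config.clusters[0]),
            cluster_b_names=tuple(d.name for d in config.clusters[1]),
            cluster_c_names=tuple(d.name for d in config.clusters[2]),
        ),
        external=ExternalPanel(
            scales=scales,
            binary_validators=binary.astype(float),
            scale_names=scale_names,
            binary_names=tuple(d.name for d in config.binary_validators),
        ),
    )
    truth = {
        "seed": config.seed,
        "n_subjects": n,
        "informative_set": sorted(config.informative_set),
        "rho": config.rho,
        "difficulty_targets": list(config.difficulties),
        "difficulties_latent": difficulties.tolist(),
        "discriminations": disc.tolist(),
        "theta1": theta1,
        "theta2": theta2,
    }
    return bundle, truth


# ---------------------------------------------------------------------------
# Presets

FIXTURE_PRESETS = ("tiny", "table2_like", "planted6")


def _preset_config(name: str) -> GeneratorConfig:
    if name == "tiny":
        return GeneratorConfig(
            n_subjects=20,
            n_criteria=3,
            difficulties=(0.30, 0.25, 0.20),
            informative_set=(0, 1),
            criterion_names=DSM4_CRITERIA[:3],
            seed=20,
        )
    if name == "table2_like":
        return GeneratorConfig(n_subjects=2_000, seed=2)
    if name == "planted6":
        # defaults already plant the six stable criteria
        return GeneratorConfig(n_subjects=15_000, seed=6)
    raise ConfigError(f"unknown preset {name!r}; choose from {FIXTURE_PRESETS}")


def make_fixture(
    name: str,
    out_dir: str | Path | None = None,
    n_subjects: int | None = None,
    seed: int | None = None,
) -> tuple[PanelBundle, dict, GeneratorConfig]:
    """Generate a named preset, optionally writing panel.csv / schema.yaml / truth.json.

    Presets: ``tiny`` (N=20, K=3, used by oracle tests), ``table2_like``
    (K=11 with survey-calibrated endorsement targets), ``planted6`` (K=11
    with exactly six stable-severity criteria planted).
    """
    config = _preset_config(name)
    if n_subjects is not None:
        config = replace(config, n_subjects=n_subjects)
    if seed is not None:
        config = replace(config, seed=seed)
    bundle, truth = generate(config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_panel(bundle, out / "panel.csv", out / "schema.yaml")
        slim = {kk: v for kk, v in truth.items() if not isinstance(v, np.ndarray)}
        (out / "truth.json").write_text(json.dumps(slim, indent=2))
    return bundle, truth, config
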