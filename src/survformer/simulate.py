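"""Synthetic clinicogenomic cohorts with known ground truth.

The generator emulates the statistical shape of tabular clinical-trial
datasets: blocks of correlated continuous covariates (laboratory values,
signature scores), sparse binary mutation features, missing-at-random
entries, and right-censored survival times driven by a known log-hazard
with main effects, optional pairwise interactions and any-gene-mutated
group effects.

Survival times come from the proportional-hazards inverse-transform: with
cumulative baseline hazard H0 and linear predictor eta,
T = H0^{-1}(-log U / exp(eta)). The censoring time is an independent
exponential whose rate is calibrated so the realized censoring fraction
matches the target. Because higher eta means higher hazard, the
*negative* linear predictor is the ground-truth survival score (higher =
longer survival), directly comparable to the model's beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .cohort import Cohort, PatientRecord

__all__ = ["SimSpec", "GroundTruth", "simulate_cohort",
           "make_cooccurrence_cohort"]

MONTHS_MEDIAN_12 = float(np.log(2) / 12.0)  # exponential rate, median 12 mo


def _default_coefficients() -> dict[str, float]:
    # four informative features out of twelve; linear predictor SD = 1
    return {"f1": 0.5, "f2": 0.5, "f3": -0.5, "f4": -0.5}


@dataclass
class SimSpec:
    """Generator parameters (defaults: 600 patients, 12 continuous
    features of which 4 carry the signal, 30% censoring)."""

    n_patients: int = 600
    block_sizes: tuple[int, ...] = tuple([1] * 12)
    rho: float = 0.0                       # within-block correlation
    n_mutations: int = 0
    mutation_prevalence: float = 0.1
    coefficients: dict[str, float] = field(default_factory=_default_coefficients)
    interactions: list[tuple[str, str, float]] = field(default_factory=list)
    group_effects: list[tuple[list[str], float]] = field(default_factory=list)
    baseline: str = "exponential"          # exponential | weibull
    baseline_rate: float = MONTHS_MEDIAN_12
    weibull_shape: float = 1.5
    censoring_fraction: float = 0.3
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must be in [0, 1)")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.n_mutations and not 0 < self.mutation_prevalence < 1:
            raise ValueError("mutation_prevalence must be in (0, 1)")
        if self.baseline not in ("exponential", "weibull"):
            raise ValueError(f"unknown baseline {self.baseline!r}")

    @property
    def continuous_names(self) -> list[str]:
        return [f"f{i + 1}" for i in range(sum(self.block_sizes))]

    @property
    def mutation_names(self) -> list[str]:
        return [f"m{i + 1}" for i in range(self.n_mutations)]

    @property
    def feature_names(self) -> list[str]:
        return self.continuous_names + self.mutation_names


@dataclass
class GroundTruth:
    """Everything an oracle needs about a simulated draw."""

    linear_predictor: np.ndarray      # eta per patient (log-hazard scale)
    coefficients: dict[str, float]
    block_of: dict[str, int]          # feature name -> block index
    censoring_rate: float
    uncensored_times: np.ndarray

    @property
    def true_score(self) -> np.ndarray:
        """Oracle survival score: -eta (higher = longer survival)."""
        return -self.linear_predictor


def _draw_blocks(rng: np.random.Generator, n: int,
                 block_sizes: tuple[int, ...], rho: float) -> np.ndarray:
    """Correlated standard-normal blocks (compound symmetry within block)."""
    cols = []
    for size in block_sizes:
        if size == 1 or rho == 0:
            cols.append(rng.standard_normal((n, size)))
            continue
        # X_j = sqrt(rho) * Z_common + sqrt(1-rho) * Z_j
        common = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, size))
        cols.append(np.sqrt(rho) * common + np.sqrt(1 - rho) * own)
    return np.concatenate(cols, axis=1)


def _invert_baseline(u: np.ndarray, eta: np.ndarray, spec: SimSpec) -> np.ndarray:
    scaled = -np.log(u) / np.exp(eta)
    if spec.baseline == "exponential":
        return scaled / spec.baseline_rate
    # Weibull with H0(t) = (rate * t)^shape
    return scaled ** (1.0 / spec.weibull_shape) / spec.baseline_rate


def _calibrate_censoring(rng: np.random.Generator, T: np.ndarray,
                         target: float) -> tuple[np.ndarray, float]:
    """Exponential censoring times with rate tuned to the target fraction.

    For C ~ Exp(c) independent of the realized T_i,
    P(censored_i) = 1 - exp(-c * T_i); the rate solves
    mean_i P(censored_i) = target.
    """
    if target == 0:
        return np.full_like(T, np.inf), 0.0

    def frac(c):
        return float(np.mean(1.0 - np.exp(-c * T))) - target

    hi = 1.0
    while frac(hi) < 0:
        hi *= 10
        if hi > 1e8:
            break
    rate = brentq(frac, 1e-12, hi)
    return rng.exponential(1.0 / rate, size=len(T)), rate


def simulate_cohort(spec: SimSpec) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort plus its ground truth under a proportional-hazards
    construction. Missingness is applied after outcome generation."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    X_cont = _draw_blocks(rng, n, spec.block_sizes, spec.rho)
    X_mut = (rng.random((n, spec.n_mutations)) < spec.mutation_prevalence
             ).astype(float) if spec.n_mutations else np.zeros((n, 0))
    X = np.concatenate([X_cont, X_mut], axis=1)
    names = spec.feature_names
    col = {name: i for i, name in enumerate(names)}

    unknown = set(spec.coefficients) - set(names)
    if unknown:
        raise ValueError(f"coefficients reference unknown features: {unknown}")
    eta = np.zeros(n)
    for name, coef in spec.coefficients.items():
        eta += coef * X[:, col[name]]
    for f, g, coef in spec.interactions:
        eta += coef * X[:, col[f]] * X[:, col[g]]
    for genes, coef in spec.group_effects:
        any_mut = (X[:, [col[g] for g in genes]].sum(axis=1) > 0).astype(float)
        eta += coef * any_mut

    u = rng.uniform(size=n)
    T_true = _invert_baseline(u, eta, spec)
    C, cens_rate = _calibrate_censoring(rng, T_true, spec.censoring_fraction)
    time = np.minimum(T_true, C)
    event = (T_true <= C).astype(int)

    miss = (rng.random(X.shape) < spec.missing_fraction
            ) if spec.missing_fraction else np.zeros(X.shape, dtype=bool)

    records = []
    for i in range(n):
        feats = {name: float(X[i, j]) for name, j in col.items()
                 if not miss[i, j]}
        records.append(PatientRecord(f"P{i:05d}", feats,
                                     float(time[i]), int(event[i])))

    block_of: dict[str, int] = {}
    start = 0
    for b, size in enumerate(spec.block_sizes):
        for j in range(start, start + size):
            block_of[f"f{j + 1}"] = b
        start += size
    truth = GroundTruth(linear_predictor=eta,
                        coefficients=dict(spec.coefficients),
                        block_of=block_of, censoring_rate=cens_rate,
                        uncensored_times=T_true)
    return Cohort(records), truth


def make_cooccurrence_cohort(n: int, rules: list[tuple[str, str]],
                             n_background: int = 4, present_prob: float = 0.5,
                             seed: int = 0) -> Cohort:
    """Cohort with deterministic feature co-presence, for pretraining tests.

    Each rule (A, B) makes the two features strictly co-present: with
    probability ``present_prob`` a patient carries both (value 1.0),
    otherwise neither — so a masked B is perfectly predictable whenever A
    is visible. Background features b1..bk are present independently with
    probability ``present_prob``. Outcomes are nuisance (exponential
    times, all events observed).
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        feats: dict[str, float] = {}
        for a, b in rules:
            if rng.random() < present_prob:
                feats[a] = 1.0
                feats[b] = 1.0
        for j in range(n_background):
            if rng.random() < present_prob:
                feats[f"b{j + 1}"] = float(rng.random())
        records.append(PatientRecord(f"P{i:05d}", feats,
                                     float(rng.exponential(12.0)), 1))
    return Cohort(records)
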