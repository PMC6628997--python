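"""Synthetic placental-methylome generator with ground truth.

Emulates the statistical structure the clock and EWAS analyses assume:

* GA drawn uniformly over a gestational range (default 6-42 weeks, the
  span covered by public placental cohorts);
* "clock" CpGs whose mean beta drifts linearly with GA (slopes of a few
  thousandths to a few hundredths of a beta unit per week, both signs);
* beta-distributed measurement noise around each mean with a single
  precision knob, so every value stays in [0, 1];
* sex-informative autosomal CpGs shifted by a fixed amount in one sex;
* pregnancy conditions (e.g. preeclampsia) that both shorten GA (earlier
  delivery, a selection effect) and shift methylation at their own CpGs —
  the mechanism that confounds a pooled GA-methylation association while
  each within-condition stratum stays null;
* optional planted outlier samples (i.i.d. uniform betas) and uniform
  missingness.

Condition assignment precedes the GA draw so the GA shift models earlier
delivery. Everything is reproducible from the config seed, and the
returned :class:`SimTruth` records which probes and samples carry which
effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .types import BetaMatrix, SampleSheet, ValidationError

__all__ = ["ConditionSpec", "SimConfig", "SimTruth", "simulate_dataset",
           "standard_scenarios"]


@dataclass
class ConditionSpec:
    """One pregnancy condition and its effects.

    prevalence
        Fraction of samples affected (exact count = round(prevalence * n)).
    ga_shift_weeks
        Added to affected samples' GA (negative = earlier delivery).
    n_affected_probes, dnam_shift
        Number of condition CpGs and the beta shift applied to them in
        affected samples.
    """

    label: str
    prevalence: float
    ga_shift_weeks: float = 0.0
    n_affected_probes: int = 0
    dnam_shift: float = 0.0


@dataclass
class SimConfig:
    """Parameters of one simulated dataset; see the module docstring."""

    n_samples: int = 200
    n_probes: int = 1000
    n_clock_probes: int = 50
    slope_range: tuple[float, float] = (0.005, 0.02)
    ga_range: tuple[float, float] = (6.0, 42.0)
    noise_precision: float = 50.0
    n_sex_probes: int = 0
    sex_effect: float = 0.2
    conditions: list[ConditionSpec] = field(default_factory=list)
    outlier_fraction: float = 0.0
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.outlier_fraction, self.missing_fraction):
            if not 0.0 <= frac < 1.0:
                raise ValidationError(f"fractions must be in [0, 1), got {frac}")
        if self.noise_precision <= 0:
            raise ValidationError("noise_precision must be > 0")
        budget = (self.n_clock_probes + self.n_sex_probes
                  + sum(c.n_affected_probes for c in self.conditions))
        if budget > self.n_probes:
            raise ValidationError(
                f"probe budget {budget} exceeds n_probes={self.n_probes}"
            )


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    clock_probe_ids: list[str]
    clock_slopes: dict[str, float]
    clock_intercepts: dict[str, float]
    sex_probe_ids: list[str]
    condition_probe_ids: dict[str, list[str]]
    outlier_sample_ids: list[str]
    true_ga: dict[str, float]
    true_sex: dict[str, str]
    true_condition: dict[str, str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(1, n + 1)]


def simulate_dataset(config: SimConfig) -> tuple[BetaMatrix, SampleSheet, SimTruth]:
    """Generate one dataset: beta matrix, sample sheet and ground truth."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_probes
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    probe_ids = _probe_ids(p)

    # condition assignment first: the GA shift models earlier delivery
    condition = np.array(["control"] * n, dtype=object)
    cond_samples: dict[str, np.ndarray] = {}
    unassigned = np.arange(n)
    for spec in config.conditions:
        k = int(round(spec.prevalence * n))
        if k > len(unassigned):
            raise ValidationError(f"condition {spec.label!r} prevalence infeasible")
        pick = rng.choice(unassigned, size=k, replace=False)
        condition[pick] = spec.label
        cond_samples[spec.label] = np.sort(pick)
        unassigned = np.setdiff1d(unassigned, pick)

    ga = rng.uniform(config.ga_range[0], config.ga_range[1], size=n)
    for spec in config.conditions:
        ga[cond_samples[spec.label]] += spec.ga_shift_weeks
    ga = np.clip(ga, 0.5, 49.5)

    sex = np.where(rng.random(n) < 0.5, "male", "female")

    # probe roles, in id order: clock, sex, condition blocks, then null
    cursor = 0
    clock_probes = probe_ids[cursor:cursor + config.n_clock_probes]
    cursor += config.n_clock_probes
    sex_probes = probe_ids[cursor:cursor + config.n_sex_probes]
    cursor += config.n_sex_probes
    cond_probes: dict[str, list[str]] = {}
    for spec in config.conditions:
        cond_probes[spec.label] = probe_ids[cursor:cursor + spec.n_affected_probes]
        cursor += spec.n_affected_probes

    baseline = rng.uniform(0.1, 0.9, size=p)
    slopes = np.zeros(p)
    k = config.n_clock_probes
    signs = rng.choice([-1.0, 1.0], size=k)
    slopes[:k] = signs * rng.uniform(config.slope_range[0],
                                     config.slope_range[1], size=k)

    mu = np.clip(baseline[None, :] + slopes[None, :] * ga[:, None], 0.02, 0.98)
    if sex_probes:
        j0 = config.n_clock_probes
        j1 = j0 + config.n_sex_probes
        male = sex == "male"
        mu[np.ix_(male, np.arange(j0, j1))] = np.clip(
            mu[np.ix_(male, np.arange(j0, j1))] + config.sex_effect, 0.02, 0.98
        )
    for spec in config.conditions:
        if spec.n_affected_probes and spec.label in cond_samples:
            cols = [probe_ids.index(q) for q in cond_probes[spec.label]]
            rows = cond_samples[spec.label]
            mu[np.ix_(rows, cols)] = np.clip(
                mu[np.ix_(rows, cols)] + spec.dnam_shift, 0.02, 0.98
            )

    phi = config.noise_precision
    values = rng.beta(mu * phi, (1.0 - mu) * phi)

    n_outliers = int(round(config.outlier_fraction * n))
    outlier_rows = np.sort(rng.choice(n, size=n_outliers, replace=False)) \
        if n_outliers else np.array([], dtype=int)
    for i in outlier_rows:
        values[i, :] = rng.uniform(0.0, 1.0, size=p)

    if config.missing_fraction > 0:
        mask = rng.random(values.shape) < config.missing_fraction
        values[mask] = np.nan

    beta = BetaMatrix(values, sample_ids=sample_ids, probe_ids=probe_ids)
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "ga_weeks": ga,
        "sex": sex,
        "condition": condition,
        "stratum": condition,
        "platform": "450K",
    }))
    truth = SimTruth(
        clock_probe_ids=list(clock_probes),
        clock_slopes={q: float(slopes[j]) for j, q in enumerate(clock_probes)},
        clock_intercepts={q: float(baseline[j]) for j, q in enumerate(clock_probes)},
        sex_probe_ids=list(sex_probes),
        condition_probe_ids={k_: list(v) for k_, v in cond_probes.items()},
        outlier_sample_ids=[sample_ids[i] for i in outlier_rows],
        true_ga={s: float(g) for s, g in zip(sample_ids, ga)},
        true_sex={s: str(x) for s, x in zip(sample_ids, sex)},
        true_condition={s: str(c) for s, c in zip(sample_ids, condition)},
    )
    return beta, sheet, truth


def standard_scenarios() -> dict[str, SimConfig]:
    """Named presets used throughout the tests and examples.

    * ``clock_recovery`` — 400 samples x 2,000 probes, 50 clock CpGs:
      elastic-net parameter recovery and held-out accuracy.
    * ``ewas_twostrata`` — 831 control + 70 preeclampsia samples (the
      stratum sizes of the motivating stratified EWAS), with a condition
      that both shortens GA and shifts methylation at its own CpGs: the
      pooled-vs-stratified confounding demonstration.
    * ``sex_sep`` — 300 samples with 50 sex-informative CpGs separated by
      a 0.2 beta shift: sex-classifier training.
    * ``qc_outliers`` — 96 clean samples plus 4 planted uniform-noise
      outliers over 5,000 probes: gold-standard outlier detection.
    """
    return {
        "clock_recovery": SimConfig(
            n_samples=400, n_probes=2000, n_clock_probes=50,
            slope_range=(0.005, 0.02), ga_range=(6.0, 42.0),
            noise_precision=50.0, seed=20190624,
        ),
        "ewas_twostrata": SimConfig(
            n_samples=901, n_probes=2000, n_clock_probes=50,
            slope_range=(0.005, 0.02), ga_range=(28.0, 42.0),
            noise_precision=50.0,
            conditions=[ConditionSpec(
                label="preeclampsia", prevalence=70 / 901,
                ga_shift_weeks=-6.0, n_affected_probes=50, dnam_shift=0.15,
            )],
            seed=441870,
        ),
        "sex_sep": SimConfig(
            n_samples=300, n_probes=2000, n_clock_probes=0,
            n_sex_probes=50, sex_effect=0.2, ga_range=(6.0, 42.0),
            noise_precision=50.0, seed=75196,
        ),
        "qc_outliers": SimConfig(
            n_samples=100, n_probes=5000, n_clock_probes=50,
            slope_range=(0.005, 0.02), ga_range=(6.0, 42.0),
            noise_precision=50.0, outlier_fraction=0.04, seed=71678,
        ),
    }
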