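"""Clock performance metrics.

Accuracy is summarised by the median absolute error (MAE, weeks) between
predicted and observed GA, with a seeded percentile-bootstrap confidence
interval, and by the Pearson correlation r with a Fisher-z interval.
Subgroup breakdowns (late gestation, uncomplicated term, per condition)
reuse the same machinery through :func:`compare_clocks`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clock import predict_ga
from .types import BetaMatrix, ClockModel, SampleSheet, ValidationError

__all__ = ["EvalResult", "evaluate_clock", "compare_clocks", "SUBGROUPS"]


@dataclass
class EvalResult:
    """Accuracy of one clock on one (sub)group of samples."""

    mae: float
    mae_ci: tuple[float, float]
    pearson_r: float
    r_ci: tuple[float, float]
    n: int
    subgroup: str | None = None

    def as_row(self) -> dict:
        return {
            "subgroup": self.subgroup, "n": self.n,
            "mae": self.mae, "mae_lo": self.mae_ci[0], "mae_hi": self.mae_ci[1],
            "r": self.pearson_r, "r_lo": self.r_ci[0], "r_hi": self.r_ci[1],
        }


def _fisher_z_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n < 4 or abs(r) >= 1.0:
        return (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    q = stats.norm.ppf(0.5 + level / 2)
    return (float(np.tanh(z - q * se)), float(np.tanh(z + q * se)))


def evaluate_clock(predicted, observed, bootstrap_reps: int = 1000,
                   seed: int = 0, subgroup: str | None = None) -> EvalResult:
    """MAE and Pearson r of predicted vs observed GA.

    MAE is the median of |predicted - observed|; its CI is a percentile
    bootstrap over paired resamples (seeded). The r interval uses the
    Fisher-z approximation.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValidationError("predicted and observed must be equal-length vectors")
    n = len(pred)
    if n < 3:
        raise ValidationError("need at least 3 samples")
    if np.ptp(obs) == 0:
        raise ValidationError("observed GA is constant; r undefined")
    err = np.abs(pred - obs)
    mae = float(np.median(err))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(bootstrap_reps, n))
    boot = np.median(err[idx], axis=1)
    mae_ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    r = float(np.corrcoef(pred, obs)[0, 1]) if np.ptp(pred) > 0 else 0.0
    return EvalResult(mae=mae, mae_ci=mae_ci, pearson_r=r,
                      r_ci=_fisher_z_ci(r, n), n=n, subgroup=subgroup)


#: standard subgroup filters on sample-sheet rows
SUBGROUPS: dict[str, Callable[[pd.Series], bool]] = {
    "all": lambda row: True,
    "ga_gt_25": lambda row: row["ga_weeks"] > 25,
    "uncomplicated_term": lambda row: (row["condition"] == "control"
                                       and row["ga_weeks"] > 36),
}


def compare_clocks(models: Sequence[ClockModel], beta: BetaMatrix,
                   sheet: SampleSheet,
                   subgroups: dict[str, Callable[[pd.Series], bool]] | None = None,
                   bootstrap_reps: int = 1000, seed: int = 0,
                   on_missing_probe: str | float = "error") -> pd.DataFrame:
    """Evaluate several clocks on the same data, per subgroup.

    Returns one row per (clock, subgroup); subgroups with no qualifying
    samples are omitted with a warning. Any coefficient table works, so a
    newly trained clock can be compared against published ones.
    """
    subgroups = subgroups or {"all": SUBGROUPS["all"]}
    df = sheet.df.loc[beta.sample_ids]
    rows = []
    for model in models:
        pred = predict_ga(model, beta, on_missing_probe=on_missing_probe)
        for name, predicate in subgroups.items():
            keep = df.apply(predicate, axis=1) & df["ga_weeks"].notna()
            ids = df.index[keep]
            if len(ids) < 3:
                warnings.warn(f"subgroup {name!r} has <3 samples; omitted",
                              stacklevel=2)
                continue
            res = evaluate_clock(pred.loc[ids], df.loc[ids, "ga_weeks"],
                                 bootstrap_reps=bootstrap_reps, seed=seed,
                                 subgroup=name)
            rows.append({"clock": model.name, **res.as_row()})
    return pd.DataFrame(rows)
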