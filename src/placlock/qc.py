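"""Probe harmonization, gold-standard outlier detection and median
imputation for methylation beta matrices.

The QC recipe has three steps: (1) define a gold-standard profile as the
per-probe median beta across all samples; (2) correlate each sample's
profile with the gold standard (Pearson); (3) exclude samples whose
correlation falls below a threshold (default 0.9). Missing cells are then
imputed with the gold-standard medians. The gold standard is computed once
from all samples, prospective outliers included; it is not recomputed
iteratively.

Imputation here is a pure transform; restricting it to training data (the
convention for clock fitting) is the caller's pipeline policy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import BetaMatrix, ProbeManifest, ValidationError

__all__ = [
    "QCParams",
    "QCReport",
    "intersect_probes",
    "gold_standard",
    "detect_outliers",
    "impute_missing",
    "dedupe_samples",
]


@dataclass
class QCParams:
    """Outlier-detection parameters.

    min_correlation
        Pearson-correlation threshold against the gold-standard profile;
        samples below it are excluded. Default 0.9.
    autosomes_only
        Restrict probe harmonization to chromosomes 1-22.
    """

    min_correlation: float = 0.9
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.min_correlation < 1.0:
            raise ValidationError(
                f"min_correlation must be in (0, 1), got {self.min_correlation}"
            )


@dataclass
class QCReport:
    """Result of outlier detection (and, optionally, imputation)."""

    gold_standard: pd.Series
    sample_correlations: dict[str, float]
    excluded_samples: list[str]
    exclusion_reasons: dict[str, str] = field(default_factory=dict)
    n_imputed: int = 0

    def to_dict(self) -> dict:
        return {
            "excluded_samples": list(self.excluded_samples),
            "exclusion_reasons": dict(self.exclusion_reasons),
            "sample_correlations": {
                k: (None if np.isnan(v) else float(v))
                for k, v in self.sample_correlations.items()
            },
            "n_imputed": int(self.n_imputed),
        }


def intersect_probes(manifests: list[ProbeManifest],
                     autosomes_only: bool = True) -> set[str]:
    """Probes shared by every manifest, optionally autosomes only.

    Cross-platform harmonization: a clock trained on the intersection of the
    450K and EPIC probe sets applies to data from either platform.
    """
    if not manifests:
        raise ValidationError("need at least one manifest")
    sets = [
        m.autosomal_probes() if autosomes_only else set(m.probe_ids)
        for m in manifests
    ]
    shared = set.intersection(*sets)
    if not shared:
        warnings.warn("probe intersection is empty", stacklevel=2)
    return shared


def gold_standard(beta: BetaMatrix) -> pd.Series:
    """Per-probe median beta across samples (missing entries ignored).

    A probe whose values are all missing gets a missing median; downstream
    imputation refuses to fill such probes.
    """
    if beta.shape[0] < 1:
        raise ValidationError("gold standard needs at least one sample")
    return beta.df.median(axis=0, skipna=True)


def detect_outliers(beta: BetaMatrix, params: QCParams | None = None) -> QCReport:
    """Flag samples poorly correlated with the gold-standard profile.

    Pearson r is computed per sample over the probes observed in both the
    sample and the gold standard. Samples with r below
    ``params.min_correlation`` are excluded; samples with a constant
    (zero-variance) profile have undefined r and are excluded with reason
    ``"constant profile"``.
    """
    params = params or QCParams()
    n = beta.shape[0]
    if n < 3:
        warnings.warn(
            f"outlier detection with {n} sample(s) is degenerate", stacklevel=2
        )
    gold = gold_standard(beta)
    correlations: dict[str, float] = {}
    excluded: list[str] = []
    reasons: dict[str, str] = {}
    g = gold.to_numpy()
    for sample_id, row in zip(beta.sample_ids, beta.values):
        ok = ~np.isnan(row) & ~np.isnan(g)
        x, y = row[ok], g[ok]
        if ok.sum() < 2 or np.std(x) == 0 or np.std(y) == 0:
            correlations[sample_id] = np.nan
            excluded.append(sample_id)
            reasons[sample_id] = "constant profile"
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        correlations[sample_id] = r
        if r < params.min_correlation:
            excluded.append(sample_id)
            reasons[sample_id] = f"r={r:.4f} < {params.min_correlation}"
    return QCReport(gold_standard=gold, sample_correlations=correlations,
                    excluded_samples=excluded, exclusion_reasons=reasons)


def impute_missing(beta: BetaMatrix,
                   gold: pd.Series | None = None) -> tuple[BetaMatrix, int]:
    """Fill missing cells with the gold-standard (median) beta per probe.

    Returns the completed matrix and the number of imputed cells. Observed
    cells are untouched. A probe with missing cells whose gold value is
    itself missing cannot be filled and raises.
    """
    if gold is None:
        gold = gold_standard(beta)
    missing_gold = set(beta.probe_ids) - set(gold.index)
    if missing_gold:
        raise ValidationError(
            f"gold vector lacks probes: {sorted(missing_gold)[:5]}"
        )
    df = beta.df
    na = df.isna()
    n_imputed = int(na.to_numpy().sum())
    if n_imputed == 0:
        return beta, 0
    gold = gold.loc[df.columns]
    unfillable = na.any(axis=0) & gold.isna()
    if unfillable.any():
        raise ValidationError(
            "probes with missing values and no gold-standard median: "
            f"{df.columns[unfillable].tolist()[:5]}"
        )
    return BetaMatrix(df.fillna(gold)), n_imputed


def dedupe_samples(df: pd.DataFrame, keep: str = "first") -> BetaMatrix:
    """Drop exact duplicate sample ids before validation.

    Useful when concatenating cohorts that re-used samples or technical
    replicates under the same identifier; correlation-based replicate
    detection is out of scope. Takes a raw samples-in-rows DataFrame
    (a validated :class:`BetaMatrix` cannot hold duplicates) and returns
    the deduplicated matrix.
    """
    mask = ~df.index.duplicated(keep=keep)
    return BetaMatrix(df.loc[mask])
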