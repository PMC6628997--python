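"""Core domain types for placental methylation analysis.

The central containers are:

* :class:`BetaMatrix` — a samples x probes matrix of methylation beta
  values (fraction methylated, in [0, 1]), possibly with missing entries.
* :class:`SampleSheet` — per-sample metadata: gestational age in weeks,
  fetal sex, pregnancy condition, EWAS stratum and array platform.
* :class:`ClockModel` — a sparse linear epigenetic clock: an intercept in
  weeks plus one coefficient per selected CpG probe.
* :class:`ProbeManifest` — probe annotation: chromosome, relation to the
  nearest CpG island, and associated gene symbols.

All containers validate their invariants on construction and are backed by
pandas objects, so standard DataFrame tooling applies to their ``.df`` /
``.values`` views.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "BetaMatrix",
    "SampleSheet",
    "ClockModel",
    "ProbeManifest",
    "SEXES",
    "PLATFORMS",
    "ISLAND_RELATIONS",
]

SEXES = ("male", "female", "unknown")
PLATFORMS = ("450K", "EPIC", "other")
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

AUTOSOMES = tuple(str(c) for c in range(1, 23))


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    index = pd.Index(ids)
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


class BetaMatrix:
    """Samples x probes matrix of methylation beta values.

    Missing entries are NaN. Every observed value must lie in [0, 1];
    values exactly 0 or 1 are accepted as-is.
    """

    def __init__(self, values, sample_ids=None, probe_ids=None):
        if isinstance(values, pd.DataFrame):
            df = values.astype(float)
        else:
            df = pd.DataFrame(
                np.asarray(values, dtype=float),
                index=list(sample_ids),
                columns=list(probe_ids),
            )
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = "sample_id"
        df.columns.name = "probe_id"
        _check_unique(df.index, "sample ids")
        _check_unique(df.columns, "probe ids")
        self._validate_range(df)
        self._df = df

    @staticmethod
    def _validate_range(df: pd.DataFrame) -> None:
        arr = df.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (arr < 0.0) | (arr > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at "
                f"sample {df.index[i]!r}, probe {df.columns[j]!r}"
            )

    @property
    def df(self) -> pd.DataFrame:
        """Underlying DataFrame, samples in rows and probes in columns."""
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return self._df.index.tolist()

    @property
    def probe_ids(self) -> list[str]:
        return self._df.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    @property
    def n_missing(self) -> int:
        return int(self._df.isna().to_numpy().sum())

    def subset(self, samples: Iterable[str] | None = None,
               probes: Iterable[str] | None = None) -> "BetaMatrix":
        """Restrict to the given samples and/or probes (order preserved)."""
        df = self._df
        if samples is not None:
            df = df.loc[list(samples)]
        if probes is not None:
            df = df.loc[:, list(probes)]
        return BetaMatrix(df)

    def __repr__(self) -> str:
        n, p = self.shape
        return f"BetaMatrix({n} samples x {p} probes, {self.n_missing} missing)"

    def equals(self, other: "BetaMatrix", tol: float = 0.0) -> bool:
        if self.sample_ids != other.sample_ids or self.probe_ids != other.probe_ids:
            return False
        a, b = self.values, other.values
        both_nan = np.isnan(a) & np.isnan(b)
        with np.errstate(invalid="ignore"):
            close = np.abs(a - b) <= tol
        return bool(np.all(both_nan | close))


class SampleSheet:
    """Per-sample metadata table.

    Columns: ``sample_id`` (unique), ``ga_weeks`` (gestational age in
    weeks, NaN if unknown, otherwise in (0, 50)), ``sex``, ``condition``,
    ``stratum`` and ``platform``.
    """

    COLUMNS = ("sample_id", "ga_weeks", "sex", "condition", "stratum", "platform")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                if col == "sample_id":
                    raise ValidationError("sample sheet lacks a sample_id column")
                df[col] = {"ga_weeks": np.nan, "sex": "unknown",
                           "condition": "control", "stratum": None,
                           "platform": "other"}[col]
        df = df[list(self.COLUMNS)]
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"], "sample ids")
        df["ga_weeks"] = pd.to_numeric(df["ga_weeks"], errors="coerce")
        ga = df["ga_weeks"]
        bad = ga.notna() & ~((ga > 0) & (ga < 50))
        if bad.any():
            offender = df.loc[bad, "sample_id"].iloc[0]
            raise ValidationError(
                f"ga_weeks outside (0, 50) for sample {offender!r}"
            )
        unknown_sex = ~df["sex"].isin(SEXES)
        if unknown_sex.any():
            raise ValidationError(
                f"sex must be one of {SEXES}; got "
                f"{df.loc[unknown_sex, 'sex'].iloc[0]!r}"
            )
        self._df = df.set_index("sample_id", drop=False)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return self._df["sample_id"].tolist()

    def __len__(self) -> int:
        return len(self._df)

    def aligned_to(self, beta: BetaMatrix) -> "SampleSheet":
        """Rows reordered to match the beta matrix's samples."""
        missing = set(beta.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"sheet lacks samples: {sorted(missing)[:5]}")
        return SampleSheet(self._df.loc[beta.sample_ids].reset_index(drop=True))

    def ga(self, beta: BetaMatrix | None = None) -> pd.Series:
        """Gestational age in weeks, optionally aligned to a beta matrix."""
        s = self._df["ga_weeks"]
        return s.loc[beta.sample_ids] if beta is not None else s

    def __repr__(self) -> str:
        return f"SampleSheet({len(self)} samples)"


@dataclass
class ClockModel:
    """Sparse linear epigenetic clock.

    ``predicted = intercept + sum_j coefficients[j] * beta[j]``, with the
    intercept in weeks (or on the log-odds scale for classifiers applied
    through the same machinery). ``alpha`` and ``lambda_`` record the
    elastic-net mixing and shrinkage used in training, when known.
    """

    name: str
    intercept: float
    coefficients: dict[str, float]
    alpha: float | None = None
    lambda_: float | None = None
    training_filter: str | None = None

    def __post_init__(self) -> None:
        # zero coefficients carry no information in a sparse model
        self.coefficients = {
            str(k): float(v) for k, v in self.coefficients.items() if v != 0.0
        }
        self.intercept = float(self.intercept)
        if self.alpha is not None and not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lambda_ is not None and self.lambda_ < 0:
            raise ValidationError(f"lambda_ must be nonnegative, got {self.lambda_}")

    @property
    def n_features(self) -> int:
        return len(self.coefficients)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.coefficients)

    def __repr__(self) -> str:
        return (f"ClockModel({self.name!r}, intercept={self.intercept:.4g}, "
                f"{self.n_features} probes)")


class ProbeManifest:
    """Probe annotation table: chromosome, CpG-island relation, genes."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        required = ("probe_id", "chromosome")
        for col in required:
            if col not in df.columns:
                raise ValidationError(f"manifest lacks a {col} column")
        if "island_relation" not in df.columns:
            df["island_relation"] = "OpenSea"
        if "genes" not in df.columns:
            df["genes"] = [[] for _ in range(len(df))]
        df["probe_id"] = df["probe_id"].astype(str)
        _check_unique(df["probe_id"], "probe ids")
        df["chromosome"] = df["chromosome"].astype(str)
        df["genes"] = df["genes"].apply(
            lambda g: list(g) if isinstance(g, (list, tuple)) else
            ([] if pd.isna(g) or g == "" else str(g).split(";"))
        )
        self._df = df.set_index("probe_id", drop=False)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def probe_ids(self) -> list[str]:
        return self._df["probe_id"].tolist()

    def autosomal_probes(self) -> set[str]:
        mask = self._df["chromosome"].isin(AUTOSOMES)
        return set(self._df.loc[mask, "probe_id"])

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:
        return f"ProbeManifest({len(self)} probes)"
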