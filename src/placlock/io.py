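"""Readers and writers for beta matrices, sample sheets, clock coefficient
tables and probe manifests.

File dialects
-------------
* Beta matrix: delimited text (CSV or TSV, sniffed from the extension or
  forced with ``sep``) with one identifier header. GEO series-matrix style
  files put probes in rows; model fitting wants samples in rows. The
  ``orientation`` flag declares the on-disk layout and the reader always
  returns the canonical samples-in-rows form.
* Clock coefficient file: two-column CSV ``CpG,Coefficient``; the intercept
  occupies a row labelled ``(Intercept)``, the layout conventionally used by
  published clock supplements. Round-trips are bit-exact.
* Sample sheet: CSV with columns sample_id, ga_weeks, sex, condition,
  stratum, platform.
* Probe manifest: CSV with columns probe_id, chromosome, island_relation,
  genes (semicolon-joined symbols).
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .types import BetaMatrix, ClockModel, ProbeManifest, SampleSheet, ValidationError

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_clock",
    "write_clock",
    "read_probe_manifest",
    "write_probe_manifest",
]

INTERCEPT_LABEL = "(Intercept)"

#: tokens treated as missing in beta matrices (configurable per call)
DEFAULT_NA_TOKENS = ("", "NA", "NaN", "nan")


def _sep_for(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if os.fspath(path).endswith((".tsv", ".txt")) else ","


def read_beta_matrix(path, orientation: str = "samples_in_rows",
                     sep: str | None = None,
                     na_tokens: Iterable[str] = DEFAULT_NA_TOKENS) -> BetaMatrix:
    """Read a beta matrix from delimited text.

    Parameters
    ----------
    path
        Delimited text file with one header row and one identifier column.
    orientation
        ``"samples_in_rows"`` or ``"probes_in_rows"`` (GEO series-matrix
        layout). The returned matrix is always samples x probes.
    sep
        Field separator; inferred from the extension when None.
    na_tokens
        Cell values treated as missing.
    """
    if orientation not in ("samples_in_rows", "probes_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0,
                     na_values=list(na_tokens), keep_default_na=False,
                     float_precision="round_trip")
    if df.index.has_duplicates or df.columns.has_duplicates:
        dup = (df.index[df.index.duplicated()].tolist()
               or df.columns[df.columns.duplicated()].tolist())
        raise ValidationError(f"duplicate identifier in {path}: {dup[:5]}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if orientation == "probes_in_rows":
        df = df.T
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path,
                      orientation: str = "samples_in_rows",
                      sep: str | None = None, na_token: str = "NA") -> None:
    """Write a beta matrix; full float precision so round-trips are exact."""
    if orientation not in ("samples_in_rows", "probes_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = beta.df if orientation == "samples_in_rows" else beta.df.T
    df.to_csv(path, sep=_sep_for(path, sep), na_rep=na_token)


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.df.to_csv(path, index=False)


def read_clock(path, name: str | None = None,
               require_intercept: bool = True) -> ClockModel:
    """Read a clock coefficient table.

    The file is a two-column CSV ``CpG,Coefficient`` whose intercept row is
    labelled ``(Intercept)``. ``n_features`` counts the probe rows only.
    Published supplements occasionally omit the intercept; pass
    ``require_intercept=False`` to fall back to a zero intercept.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValidationError(f"clock file {path} needs two columns (CpG, Coefficient)")
    ids = df.iloc[:, 0].astype(str)
    try:
        weights = df.iloc[:, 1].astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric coefficient in {path}: {exc}") from exc
    if len(df) == 0:
        raise ValidationError(f"clock file {path} is empty")
    is_intercept = ids == INTERCEPT_LABEL
    if is_intercept.sum() > 1:
        raise ValidationError(f"clock file {path} has multiple intercept rows")
    if is_intercept.sum() == 0:
        if require_intercept:
            raise ValidationError(
                f"clock file {path} lacks an {INTERCEPT_LABEL!r} row"
            )
        intercept = 0.0
    else:
        intercept = float(weights[is_intercept].iloc[0])
    probes = ids[~is_intercept]
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].tolist()
        raise ValidationError(f"duplicate probe in clock file {path}: {dup[:5]}")
    coefficients = dict(zip(probes, weights[~is_intercept]))
    if name is None:
        name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return ClockModel(name=name, intercept=intercept, coefficients=coefficients)


def write_clock(model: ClockModel, path) -> None:
    """Write a clock coefficient table (zero coefficients are dropped,
    matching the sparse-model convention)."""
    rows = [(INTERCEPT_LABEL, repr(model.intercept))]
    rows += [(p, repr(w)) for p, w in model.coefficients.items()]
    with open(path, "w") as fh:
        fh.write("CpG,Coefficient\n")
        for probe, weight in rows:
            fh.write(f"{probe},{weight}\n")


def read_probe_manifest(path) -> ProbeManifest:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return ProbeManifest(df)


def write_probe_manifest(manifest: ProbeManifest, path) -> None:
    df = manifest.df.copy()
    df["genes"] = df["genes"].apply(";".join)
    df.to_csv(path, index=False)
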