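"""Stratified epigenome-wide association of gestational age with
methylation.

Per stratum (e.g. control pregnancies and preeclampsia pregnancies,
analysed separately to block confounding by condition), each probe's beta
values are correlated with GA using the biweight midcorrelation — a robust
correlation that downweights observations far from the median with Tukey
biweights. The correlation is converted to a Student-t statistic and a
two-sided p-value, then to a sign-preserving normal Z score. Stratum Z
scores are combined with the weighted Stouffer method,

    Z_meta = sum_i Z_i * w_i / sqrt(sum_i w_i^2),   w_i = sqrt(n_i),

and the meta p-value is the two-sided normal tail 2*(1 - Phi(|Z_meta|)),
computed on the log scale so that |Z| near 10 yields ~1e-24 rather than
underflowing. Significance is called at a fixed genome-wide threshold
(default 1e-7); no further multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .types import BetaMatrix, ProbeManifest, SampleSheet, ValidationError

__all__ = [
    "EwasConfig",
    "bicor",
    "bicor_matrix",
    "stratum_screen",
    "stouffer_meta",
    "p_from_z",
    "run_ewas",
    "annotate_and_tabulate",
]

#: cap on |z| when a p-value underflows entirely (|r| = 1 and similar)
Z_CAP = 40.0


@dataclass
class EwasConfig:
    """EWAS settings: strata to screen and the significance threshold."""

    strata: list[str] = field(default_factory=lambda: ["control"])
    significance_threshold: float = 1e-7
    stratum_column: str = "condition"

    def __post_init__(self) -> None:
        if not 0.0 < self.significance_threshold < 1.0:
            raise ValidationError(
                f"threshold must be in (0, 1), got {self.significance_threshold}"
            )


def _biweight(x: np.ndarray) -> np.ndarray | None:
    """Tukey-biweighted, median-centred transform of one vector; None when
    the median absolute deviation is zero (fallback to Pearson)."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    u = (x - med) / (9.0 * mad)
    a = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * a


def bicor(x, y) -> float:
    """Biweight midcorrelation of two equal-length vectors (n >= 3).

    Falls back to the Pearson correlation for a vector whose median
    absolute deviation is zero (the biweight transform is then undefined).
    Returns NaN when either vector has no variation left after weighting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("bicor needs two equal-length 1-D vectors")
    if len(x) < 3:
        raise ValidationError("bicor needs n >= 3")
    xt, yt = _biweight(x), _biweight(y)
    if xt is None or yt is None:
        # zero MAD: robust weighting undefined; plain Pearson
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])
    nx, ny = np.sqrt(np.sum(xt**2)), np.sqrt(np.sum(yt**2))
    if nx == 0 or ny == 0:
        return float("nan")
    return float(np.sum(xt * yt) / (nx * ny))


def bicor_matrix(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Biweight midcorrelation of one vector ``x`` (n,) against every
    column of ``Y`` (n, p); vectorised, same conventions as :func:`bicor`."""
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    xt = _biweight(x)
    if xt is None:
        xt = x - x.mean()
    nx = np.sqrt(np.sum(xt**2))

    med = np.median(Y, axis=0)
    mad = np.median(np.abs(Y - med), axis=0)
    ok = mad > 0
    Yt = np.empty_like(Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (Y - med) / (9.0 * mad)
    a = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    Yt = (Y - med) * a
    Yt[:, ~ok] = (Y - Y.mean(axis=0))[:, ~ok]  # Pearson fallback columns
    ny = np.sqrt(np.sum(Yt**2, axis=0))
    out = np.full(p, np.nan)
    nz = ny > 0
    if nx > 0:
        out[nz] = np.clip((xt @ Yt[:, nz]) / (nx * ny[nz]), -1.0, 1.0)
    return out


def _r_to_t_p_z(r: np.ndarray, n: np.ndarray):
    """Correlation -> Student-t -> two-sided p -> sign-preserving Z.

    Computed on the log scale via the t survival function so stratum p and
    z stay mutually consistent deep into the tail; |r| = 1 gives the
    machine-minimum p and a Z capped at +/-40.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    perfect = np.isclose(np.abs(r), 1.0)
    t = np.where(perfect, np.sign(r) * np.inf, t)
    logp = stats.t.logsf(np.abs(t), df) + np.log(2.0)
    logp = np.minimum(logp, 0.0)
    p = np.exp(logp)
    p = np.where(p == 0.0, np.finfo(float).tiny, p)
    # quantile from log p for numerical range; Phi^-1(1 - p/2) = -Phi^-1(p/2)
    z = -special.ndtri_exp(logp - np.log(2.0))
    z = np.sign(np.where(r == 0, 1.0, r)) * np.minimum(z, Z_CAP)
    return t, p, z


def stratum_screen(beta: BetaMatrix, sheet: SampleSheet, stratum: str,
                   stratum_column: str = "condition") -> pd.DataFrame:
    """Screen every probe against GA within one stratum.

    Returns a DataFrame indexed by probe with columns ``bicor``, ``t``,
    ``p``, ``z`` and ``n``. Probes with missing values use pairwise-complete
    observations (their ``n`` reflects it).
    """
    df = sheet.df
    if stratum_column not in df.columns:
        raise ValidationError(f"sheet lacks column {stratum_column!r}")
    in_stratum = df[(df[stratum_column] == stratum) & df["ga_weeks"].notna()]
    ids = [s for s in beta.sample_ids if s in set(in_stratum["sample_id"])]
    if not ids:
        raise ValidationError(f"stratum {stratum!r} absent from sample sheet")
    if len(ids) < 4:
        raise ValidationError(f"stratum {stratum!r} has fewer than 4 samples")
    sub = beta.subset(samples=ids)
    ga = df.loc[ids, "ga_weeks"].to_numpy(dtype=float)
    Y = sub.values
    has_na = np.isnan(Y).any(axis=0)
    r = np.full(Y.shape[1], np.nan)
    n_eff = np.full(Y.shape[1], len(ids))
    complete = ~has_na
    if complete.any():
        r[complete] = bicor_matrix(ga, Y[:, complete])
    for j in np.where(has_na)[0]:
        ok = ~np.isnan(Y[:, j])
        n_eff[j] = int(ok.sum())
        if n_eff[j] >= 4:
            r[j] = bicor(ga[ok], Y[ok, j])
    t, p, z = _r_to_t_p_z(r, n_eff)
    return pd.DataFrame(
        {"bicor": r, "t": t, "p": p, "z": z, "n": n_eff},
        index=pd.Index(sub.probe_ids, name="probe_id"),
    )


def stouffer_meta(z_by_stratum, n_by_stratum) -> float:
    """Weighted Stouffer combination of stratum Z scores.

    Weights are square roots of the stratum sample sizes, so
    Z_meta = sum_i Z_i*sqrt(n_i) / sqrt(sum_i n_i). Invariant to scaling
    all sample sizes by a common factor.
    """
    z = np.asarray(z_by_stratum, dtype=float)
    n = np.asarray(n_by_stratum, dtype=float)
    if z.shape != n.shape or z.ndim != 1 or len(z) == 0:
        raise ValidationError("z and n must be equal-length non-empty vectors")
    if (n < 1).any():
        raise ValidationError("all stratum sizes must be >= 1")
    w = np.sqrt(n)
    return float(np.sum(z * w) / np.sqrt(np.sum(w**2)))


def p_from_z(z) -> float | np.ndarray:
    """Two-sided normal tail probability 2*(1 - Phi(|z|)).

    Evaluated through the log survival function, so the far tail keeps
    precision (|z| ~ 10 gives ~1e-24, |z| ~ 37 still returns a positive
    subnormal rather than 0).
    """
    z = np.asarray(z, dtype=float)
    logp = stats.norm.logsf(np.abs(z)) + np.log(2.0)
    p = np.exp(np.minimum(logp, 0.0))
    # below the subnormal range return the smallest positive float, never 0
    p = np.where(p == 0.0, np.nextafter(0.0, 1.0), p)
    return float(p) if p.ndim == 0 else p


def run_ewas(beta: BetaMatrix, sheet: SampleSheet,
             config: EwasConfig | None = None) -> pd.DataFrame:
    """Full stratified EWAS: per-stratum screen, Stouffer meta-analysis,
    meta p-values and significance calls.

    Returns a DataFrame indexed by probe, sorted by ``meta_p`` ascending,
    with per-stratum columns ``{stratum}_bicor/_p/_z/_n`` plus ``meta_z``,
    ``meta_p`` and ``significant``.
    """
    config = config or EwasConfig()
    per_stratum = {
        s: stratum_screen(beta, sheet, s, config.stratum_column)
        for s in config.strata
    }
    out = pd.DataFrame(index=pd.Index(beta.probe_ids, name="probe_id"))
    z_cols, n_cols = [], []
    for s, tab in per_stratum.items():
        for col in ("bicor", "p", "z", "n"):
            out[f"{s}_{col}"] = tab[col]
        z_cols.append(f"{s}_z")
        n_cols.append(f"{s}_n")
    Z = out[z_cols].to_numpy(dtype=float)
    N = out[n_cols].to_numpy(dtype=float)
    W = np.sqrt(N)
    ok = ~np.isnan(Z)
    num = np.nansum(Z * W, axis=1)
    den = np.sqrt(np.nansum(np.where(ok, W**2, 0.0), axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out["meta_z"] = np.where(den > 0, num / den, np.nan)
    out["meta_p"] = p_from_z(out["meta_z"].fillna(0.0).to_numpy())
    out.loc[out["meta_z"].isna(), "meta_p"] = np.nan
    out["significant"] = out["meta_p"] < config.significance_threshold
    return out.sort_values("meta_p", kind="mergesort")


def annotate_and_tabulate(table: pd.DataFrame,
                          manifest: ProbeManifest) -> dict:
    """Cross-tabulate significant probes by CpG-island relation and gene.

    A probe annotated to several genes counts once for each; probes absent
    from the manifest are tallied as unannotated. Gene ranking breaks count
    ties alphabetically.
    """
    sig = table.index[table["significant"].fillna(False)]
    mdf = manifest.df
    island_counts: dict[str, int] = {}
    gene_counts: dict[str, int] = {}
    n_unannotated = 0
    for probe in sig:
        if probe not in mdf.index:
            n_unannotated += 1
            continue
        rel = mdf.at[probe, "island_relation"]
        island_counts[rel] = island_counts.get(rel, 0) + 1
        for gene in mdf.at[probe, "genes"]:
            gene_counts[gene] = gene_counts.get(gene, 0) + 1
    top_genes = sorted(gene_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {
        "n_significant": int(len(sig)),
        "n_unannotated": n_unannotated,
        "island_relation_counts": island_counts,
        "gene_counts": gene_counts,
        "top_genes": top_genes,
    }
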