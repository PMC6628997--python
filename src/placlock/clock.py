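"""Elastic-net gestational-age clocks, GA acceleration and the DNAm
fetal-sex classifier.

The clock is a sparse linear model: predicted GA (weeks) is the intercept
plus a weighted sum of beta values at the selected CpGs. Training minimises

    (1/(2n)) * sum_i (y_i - b0 - x_i' b)^2  +  lambda * (alpha*||b||_1
                                               + (1-alpha)/2 * ||b||_2^2)

over a descending lambda path, with lambda chosen by minimum mean-squared
error under k-fold cross-validation (folds seeded, stratified by GA
quartile). The mixing parameter alpha defaults to 0.5. Predictors are
standardized internally during fitting; reported coefficients are on the
original beta scale so any published coefficient table can be applied with
:func:`predict_ga` unchanged.

Three training recipes differ only in their sample/probe filters:

* robust clock — all samples, complications included, so the fit cannot
  lean on condition-correlated probes;
* control clock — control pregnancies only;
* refined clock — uncomplicated term samples (control, GA > 36 weeks),
  restricted to the parent robust clock's probes.

GA acceleration is the raw residual from regressing predicted GA on
observed GA; by least-squares orthogonality it is uncorrelated with
observed GA, which makes it a usable per-sample aging measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV, LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .types import BetaMatrix, ClockModel, ProbeManifest, SampleSheet, ValidationError

__all__ = [
    "TrainConfig",
    "SexClassifier",
    "AccelerationResult",
    "train_clock",
    "refine_clock",
    "predict_ga",
    "ga_acceleration",
    "train_sex_classifier",
    "predict_sex",
    "uncomplicated_term",
    "is_control",
]


@dataclass
class TrainConfig:
    """Elastic-net training configuration.

    alpha
        L1/L2 mixing parameter in [0, 1]; 0.5 gives the elastic net used
        throughout, 1 the lasso, 0 ridge.
    n_folds
        Cross-validation folds for the lambda search (default 10).
    fold_seed
        Seed for the fold assignment (stratified by outcome quartile).
    lambda_rule
        Only ``"min_mse"`` is supported: pick the lambda with minimum mean
        CV mean-squared error.
    standardize
        Standardize predictors internally during fitting (coefficients are
        always reported on the original beta scale).
    lambdas
        Optional explicit lambda values; when omitted a 100-point log-spaced
        path from lambda_max down to 1e-4*lambda_max is used. A single
        value skips cross-validation.
    """

    alpha: float = 0.5
    n_folds: int = 10
    fold_seed: int = 0
    lambda_rule: str = "min_mse"
    standardize: bool = True
    lambdas: Sequence[float] | None = None
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    max_iter: int = 20_000
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.n_folds < 2:
            raise ValidationError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.lambda_rule != "min_mse":
            raise ValidationError(f"unsupported lambda_rule {self.lambda_rule!r}")


@dataclass
class SexClassifier:
    """Sparse logistic model for fetal sex from autosomal methylation.

    ``intercept`` and ``coefficients`` are on the log-odds scale;
    probability of ``positive_class`` = sigmoid(intercept + x'coef).
    """

    intercept: float
    coefficients: dict[str, float]
    positive_class: str = "male"
    alpha: float | None = None
    lambda_: float | None = None

    def __post_init__(self) -> None:
        self.coefficients = {
            str(k): float(v) for k, v in self.coefficients.items() if v != 0.0
        }
        if self.positive_class not in ("male", "female"):
            raise ValidationError(
                f"positive_class must be male or female, got {self.positive_class!r}"
            )

    @property
    def negative_class(self) -> str:
        return "female" if self.positive_class == "male" else "male"

    @property
    def n_features(self) -> int:
        return len(self.coefficients)

    def to_clock_model(self, name: str = "sex_classifier") -> ClockModel:
        """Expose the log-odds model as a generic coefficient table."""
        return ClockModel(name=name, intercept=self.intercept,
                          coefficients=dict(self.coefficients),
                          alpha=self.alpha, lambda_=self.lambda_)


@dataclass
class AccelerationResult:
    """GA acceleration: residuals of predicted GA regressed on observed GA."""

    raw_residuals: pd.Series
    standardized_residuals: pd.Series
    slope: float
    intercept: float
    mode: str = "raw"

    @property
    def values(self) -> pd.Series:
        return (self.raw_residuals if self.mode == "raw"
                else self.standardized_residuals)


def is_control(row: pd.Series) -> bool:
    return row["condition"] == "control"


def uncomplicated_term(row: pd.Series) -> bool:
    """Uncomplicated term pregnancy: control condition and GA > 36 weeks."""
    return row["condition"] == "control" and row["ga_weeks"] > 36


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int,
                      n_bins: int = 4) -> list[tuple[np.ndarray, np.ndarray]]:
    """Fold assignment stratified by outcome quantile bin (quartiles by
    default); stabilises the CV MSE curve on small training sets."""
    ranks = pd.Series(y).rank(method="first")
    bins = pd.qcut(ranks, q=min(n_bins, len(np.unique(y))), labels=False,
                   duplicates="drop")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), bins))


def _lambda_path(Xs: np.ndarray, y: np.ndarray, alpha: float,
                 n_lambda: int, min_ratio: float) -> np.ndarray:
    n = len(y)
    yc = y - y.mean()
    # glmnet convention: guard alpha away from 0 so the path stays finite
    a = max(alpha, 1e-3)
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * a)
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def _apply_filter(sheet: SampleSheet,
                  sample_filter: Callable[[pd.Series], bool] | None) -> list[str]:
    df = sheet.df
    if sample_filter is None:
        return df["sample_id"].tolist()
    keep = df.apply(sample_filter, axis=1)
    return df.loc[keep, "sample_id"].tolist()


def train_clock(beta: BetaMatrix, sheet: SampleSheet,
                config: TrainConfig | None = None,
                sample_filter: Callable[[pd.Series], bool] | None = None,
                probe_subset: Iterable[str] | None = None,
                name: str = "clock") -> ClockModel:
    """Train an elastic-net GA clock.

    Parameters
    ----------
    beta
        Complete (imputed) beta matrix; missing cells are an error.
    sheet
        Sample metadata; retained samples must have observed GA.
    sample_filter
        Optional predicate on sample-sheet rows; only samples passing it
        are used (e.g. :func:`is_control`, :func:`uncomplicated_term`).
    probe_subset
        Optional probe restriction; the fit never selects outside it
        (used to refine a clock on its parent's CpGs).
    """
    config = config or TrainConfig()
    keep = [s for s in _apply_filter(sheet, sample_filter) if s in set(beta.sample_ids)]
    if probe_subset is not None:
        probe_subset = [p for p in beta.probe_ids if p in set(probe_subset)]
    sub = beta.subset(samples=keep, probes=probe_subset)
    ga = sheet.df.loc[sub.sample_ids, "ga_weeks"]
    if ga.isna().any():
        bad = ga.index[ga.isna()].tolist()
        raise ValidationError(f"samples without GA in training set: {bad[:5]}")
    if sub.n_missing:
        raise ValidationError(
            f"beta matrix has {sub.n_missing} missing cells; impute first"
        )
    X = sub.values
    y = ga.to_numpy(dtype=float)
    n = len(y)
    if n < config.n_folds:
        raise ValidationError(
            f"{n} samples < {config.n_folds} folds; reduce n_folds"
        )
    if np.ptp(y) == 0:
        raise ValidationError("constant GA outcome; nothing to fit")

    if config.standardize:
        Xs, x_mean, x_sd = _standardize(X)
    else:
        Xs, x_mean, x_sd = X, np.zeros(X.shape[1]), np.ones(X.shape[1])

    lambdas = (np.asarray(config.lambdas, dtype=float)
               if config.lambdas is not None
               else _lambda_path(Xs, y, config.alpha, config.n_lambda,
                                 config.lambda_min_ratio))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.filterwarnings("ignore", message=".*alpha=0.*")
        if len(lambdas) == 1:
            # direct fit at a fixed lambda: converge tightly so the
            # vanishing-penalty limit reproduces least squares
            est = ElasticNet(alpha=float(lambdas[0]), l1_ratio=config.alpha,
                             max_iter=config.max_iter,
                             tol=min(config.tol, 1e-8))
            est.fit(Xs, y)
            chosen = float(lambdas[0])
            coef_std, intercept_std = est.coef_, float(est.intercept_)
        else:
            folds = _stratified_folds(y, config.n_folds, config.fold_seed)
            est = ElasticNetCV(alphas=np.sort(lambdas)[::-1],
                               l1_ratio=config.alpha, cv=folds,
                               max_iter=config.max_iter, tol=config.tol)
            est.fit(Xs, y)
            chosen = float(est.alpha_)
            coef_std, intercept_std = est.coef_, float(est.intercept_)

    coef = coef_std / x_sd
    intercept = intercept_std - float(coef @ x_mean)
    coefficients = {p: float(c) for p, c in zip(sub.probe_ids, coef) if c != 0.0}
    filt_desc = getattr(sample_filter, "__name__", None) if sample_filter else "all"
    return ClockModel(name=name, intercept=float(intercept),
                      coefficients=coefficients, alpha=config.alpha,
                      lambda_=chosen,
                      training_filter=f"filter={filt_desc}, n={n}")


def refine_clock(parent: ClockModel, beta: BetaMatrix, sheet: SampleSheet,
                 config: TrainConfig | None = None,
                 sample_filter: Callable[[pd.Series], bool] = uncomplicated_term,
                 name: str | None = None) -> ClockModel:
    """Re-train a clock on uncomplicated term samples, restricted to the
    parent clock's CpGs; the refined feature set is a subset of the parent's."""
    return train_clock(beta, sheet, config=config, sample_filter=sample_filter,
                       probe_subset=parent.probe_ids,
                       name=name or f"refined_{parent.name}")


def predict_ga(model: ClockModel, beta: BetaMatrix,
               on_missing_probe: str | float = "error") -> pd.Series:
    """Apply a clock (any coefficient table) to a beta matrix.

    predicted = intercept + sum_j coef_j * beta_j, per sample. Works with
    any published coefficient table, so foreign clocks (cord-blood,
    pan-tissue, the earlier placental clock) can be applied for comparison.

    on_missing_probe
        ``"error"`` raises listing the absent probes; a float substitutes
        that beta value for every absent probe.
    """
    present = set(beta.probe_ids)
    missing = [p for p in model.probe_ids if p not in present]
    base = model.intercept
    if missing:
        if on_missing_probe == "error":
            raise ValidationError(
                f"beta matrix lacks {len(missing)} model probes: {missing[:5]}"
            )
        fill = float(on_missing_probe)
        base += fill * sum(model.coefficients[p] for p in missing)
    probes = [p for p in model.probe_ids if p in present]
    if probes:
        W = np.array([model.coefficients[p] for p in probes])
        sub = beta.df[probes].to_numpy()
        if np.isnan(sub).any():
            raise ValidationError("beta matrix has missing cells at model probes")
        pred = base + sub @ W
    else:
        pred = np.full(beta.shape[0], base)
    return pd.Series(pred, index=beta.sample_ids, name="predicted_ga")


def ga_acceleration(predicted: pd.Series, observed: pd.Series,
                    mode: str = "raw") -> AccelerationResult:
    """GA acceleration: residuals from OLS of predicted on observed GA.

    The raw residual (weeks) is uncorrelated with observed GA by
    construction; ``mode="standardized"`` divides by the residual SD.
    Positive values mean an epigenetically "older" placenta than expected
    for its GA.
    """
    if mode not in ("raw", "standardized"):
        raise ValidationError(f"unknown mode {mode!r}")
    predicted, observed = pd.Series(predicted), pd.Series(observed)
    obs = observed.to_numpy(dtype=float)
    pred = predicted.to_numpy(dtype=float)
    if len(obs) != len(pred):
        raise ValidationError("predicted and observed lengths differ")
    if len(obs) < 3:
        raise ValidationError("need at least 3 samples")
    if np.ptp(obs) == 0:
        raise ValidationError("observed GA is constant; residuals undefined")
    design = np.column_stack([np.ones_like(obs), obs])
    coef, *_ = np.linalg.lstsq(design, pred, rcond=None)
    raw = pred - design @ coef
    sd = raw.std(ddof=1)
    std = raw / sd if sd > 0 else np.zeros_like(raw)
    index = predicted.index
    return AccelerationResult(
        raw_residuals=pd.Series(raw, index=index, name="ga_acceleration"),
        standardized_residuals=pd.Series(std, index=index,
                                         name="ga_acceleration_std"),
        slope=float(coef[1]), intercept=float(coef[0]), mode=mode,
    )


def _logistic_c_path(Xs: np.ndarray, y01: np.ndarray, alpha: float,
                     n_c: int, min_ratio: float) -> np.ndarray:
    # lambda_max at which all coefficients are zero, null-model gradient
    n = len(y01)
    p0 = y01.mean()
    resid = y01 - p0
    a = max(alpha, 1e-3)
    lam_max = np.max(np.abs(Xs.T @ resid)) / (n * a)
    lam_max = max(lam_max, 1e-12)
    lams = np.geomspace(lam_max, lam_max * min_ratio, n_c)
    return 1.0 / (n * lams)  # sklearn C = 1/(n*lambda)


def train_sex_classifier(beta: BetaMatrix, sheet: SampleSheet,
                         config: TrainConfig | None = None,
                         manifest: ProbeManifest | None = None,
                         positive_class: str = "male") -> SexClassifier:
    """Logistic elastic-net classifier of fetal sex from autosomal CpGs.

    Sex-chromosome probes are often stripped from public data, so the
    classifier uses autosomal probes only; pass a manifest to enforce the
    restriction, otherwise the matrix is assumed pre-filtered. Lambda is
    chosen by cross-validated binomial deviance at the configured mixing
    parameter.
    """
    config = config or TrainConfig()
    if manifest is not None:
        autosomal = manifest.autosomal_probes()
        beta = beta.subset(probes=[p for p in beta.probe_ids if p in autosomal])
    sexes = sheet.df.loc[beta.sample_ids, "sex"]
    keep = sexes.isin(["male", "female"])
    sub = beta.subset(samples=sexes.index[keep])
    y = (sexes[keep] == positive_class).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("both sexes must be present in the training set")
    if sub.n_missing:
        raise ValidationError("beta matrix has missing cells; impute first")
    X = sub.values
    if config.standardize:
        Xs, x_mean, x_sd = _standardize(X)
    else:
        Xs, x_mean, x_sd = X, np.zeros(X.shape[1]), np.ones(X.shape[1])

    # stop the path at 1e-2 * lambda_max: the weakly regularized tail is
    # never selected on separable data and dominates solver time
    Cs = _logistic_c_path(Xs, y, config.alpha, n_c=25, min_ratio=1e-2)
    folds = list(StratifiedKFold(n_splits=min(config.n_folds, int(np.bincount(y).min())),
                                 shuffle=True, random_state=config.fold_seed
                                 ).split(Xs, y))
    n = len(y)
    # warm-started path fit per fold; score = held-out binomial deviance
    deviance = np.zeros(len(Cs))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train_idx, test_idx in folds:
            est = LogisticRegression(solver="saga", l1_ratio=config.alpha,
                                     warm_start=True, max_iter=1000, tol=1e-3,
                                     random_state=config.fold_seed)
            for k, C in enumerate(Cs):
                est.C = float(C)
                est.fit(Xs[train_idx], y[train_idx])
                p = est.predict_proba(Xs[test_idx])[:, 1]
                eps = 1e-12
                ll = y[test_idx] * np.log(p + eps) + (1 - y[test_idx]) * np.log(1 - p + eps)
                deviance[k] += -2.0 * ll.sum()
        best = int(np.argmin(deviance))
        est = LogisticRegression(solver="saga", l1_ratio=config.alpha,
                                 C=float(Cs[best]), max_iter=5000, tol=1e-5,
                                 random_state=config.fold_seed)
        est.fit(Xs, y)
    coef = est.coef_[0] / x_sd
    intercept = float(est.intercept_[0]) - float(coef @ x_mean)
    coefficients = {p: float(c) for p, c in zip(sub.probe_ids, coef) if c != 0.0}
    return SexClassifier(intercept=intercept, coefficients=coefficients,
                         positive_class=positive_class, alpha=config.alpha,
                         lambda_=float(1.0 / (n * Cs[best])))


def predict_sex(classifier: SexClassifier, beta: BetaMatrix) -> pd.DataFrame:
    """Predict fetal sex per sample.

    Returns a DataFrame with columns ``sex`` and ``probability`` (of the
    positive class). A probability of exactly 0.5 is broken to the
    negative class, so an uninformative classifier gives a deterministic
    answer.
    """
    present = set(beta.probe_ids)
    missing = [p for p in classifier.coefficients if p not in present]
    if missing:
        raise ValidationError(
            f"beta matrix lacks {len(missing)} classifier probes: {missing[:5]}"
        )
    probes = list(classifier.coefficients)
    score = np.full(beta.shape[0], classifier.intercept)
    if probes:
        W = np.array([classifier.coefficients[p] for p in probes])
        score = score + beta.df[probes].to_numpy() @ W
    prob = 1.0 / (1.0 + np.exp(-score))
    label = np.where(prob > 0.5, classifier.positive_class,
                     classifier.negative_class)
    return pd.DataFrame({"sex": label, "probability": prob},
                        index=beta.sample_ids)
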