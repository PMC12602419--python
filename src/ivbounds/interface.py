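"""Tabular I/O, preprocessing, configuration and end-to-end analysis reports.

The analysis pipeline mirrors the applied recipe: read a delimited table,
mean-impute missing covariates (adding variable-specific missingness
indicators to the covariate set), normalise sampling weights, cross-fit the
nuisance functions with the configured learners, and report direct and/or
log-sum-exp bound estimates with margin diagnostics as a JSON document.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .continuous import ContinuousConfig, estimate_continuous, estimate_grid, \
    rescale_outcome
from .direct import estimate_direct, margin_report
from .nuisance import IVSample, NuisanceSpec, fit_crossfit_nuisances
from .smooth import estimate_lse

__all__ = [
    "REPORT_SCHEMA_VERSION",
    "AnalysisConfig",
    "read_dataset",
    "impute_missing",
    "run_analysis",
    "write_report",
    "read_report",
]

REPORT_SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    """Column roles and estimator settings for one analysis.

    ``method`` is "direct", "lse" or "both"; ``t`` is a temperature or
    "default" for 100 n^{1/4}; ``outcome_type`` "binary" or "continuous"
    (then ``y_min``/``y_max`` define the rescaling and ``m`` the number of
    uniform-augmentation repetitions, with ``grid_size`` optionally enabling
    the grid-integration variant).  A seed is mandatory: every random choice
    (folds, learners, W draws) flows from it.
    """

    data: str | None = None
    z: str = "Z"
    a: str = "A"
    y: str = "Y"
    weights: str | None = None
    covariates: list[str] | None = None
    outcome_type: str = "binary"
    y_min: float = 0.0
    y_max: float = 1.0
    method: str = "both"
    K: int = 5
    pi_learner: str = "logistic"
    lambda_learner: str = "logistic"
    known_lambda: float | None = None
    eps: float = 0.01
    t: float | str = "default"
    m: int = 20
    grid_size: int | None = None
    ci_level: float = 0.95
    seed: int | None = None
    impute: bool = True

    def __post_init__(self):
        roles = [self.z, self.a, self.y] + ([self.weights] if self.weights else [])
        if len(set(roles)) != len(roles) or (
            self.covariates and set(roles) & set(self.covariates)
        ):
            raise ValueError("column roles must be disjoint")
        if self.method not in ("direct", "lse", "both"):
            raise ValueError("method must be 'direct', 'lse' or 'both'")
        if self.outcome_type not in ("binary", "continuous"):
            raise ValueError("outcome_type must be 'binary' or 'continuous'")
        if self.seed is None:
            raise ValueError("a seed is required for reproducibility")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.endswith((".yml", ".yaml")) \
                else json.load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def nuisance_spec(self) -> NuisanceSpec:
        return NuisanceSpec(
            pi_learner=self.pi_learner, lambda_learner=self.lambda_learner,
            K=self.K, eps=self.eps, known_lambda=self.known_lambda,
        )


_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no", "0.0", "1.0"}


def _coerce_binary(col: pd.Series, name: str) -> np.ndarray:
    vals = col.astype(str).str.strip().str.lower()
    out = np.where(vals.isin(_TRUTHY) | (vals == "1.0"), 1,
                   np.where(vals.isin({"0", "false", "no", "0.0"}), 0, -1))
    if (out < 0).any():
        rows = np.flatnonzero(out < 0)[:5].tolist()
        raise ValueError(f"column {name!r} is not binary at rows {rows}")
    return out


def read_dataset(path: str, config: AnalysisConfig) -> IVSample:
    """Read a delimited text file into a validated `IVSample`.

    The delimiter is sniffed (comma/tab); binary columns accept 0/1 and
    TRUE/FALSE spellings; absent weights default to one; covariates default
    to every remaining numeric column.  Missing covariates are imputed per
    the config (indicators appended); missing Z/A/Y are an error.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    need = [config.z, config.a, config.y] + (
        [config.weights] if config.weights else [])
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    covs = config.covariates
    if covs is None:
        covs = [c for c in df.columns if c not in need]
    else:
        absent = [c for c in covs if c not in df.columns]
        if absent:
            raise ValueError(f"covariate columns not found: {absent}")
    for c in (config.z, config.a, config.y):
        if df[c].isna().any():
            raise ValueError(f"column {c!r} has missing values")
    Z = _coerce_binary(df[config.z], config.z)
    A = _coerce_binary(df[config.a], config.a)
    if config.outcome_type == "binary":
        Y = _coerce_binary(df[config.y], config.y)
        mode = "binary"
    else:
        Y = rescale_outcome(df[config.y].to_numpy(float), config.y_min, config.y_max)
        mode = "continuous"
    w = df[config.weights].to_numpy(float) if config.weights else None
    X = df[covs].apply(pd.to_numeric).to_numpy(float) if covs else \
        np.empty((len(df), 0))
    if config.impute and X.size:
        X, _ = impute_missing(X, weights=w)
    elif np.isnan(X).any():
        raise ValueError("covariates contain missing values and impute=False")
    return IVSample(X=X, Z=Z, A=A, Y=Y, w=w, y_mode=mode)


def impute_missing(
    X: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted mean imputation with variable-specific missingness indicators.

    Returns ``(X_imputed_plus_indicators, indicator_block)``: one indicator
    column is appended per original covariate that has any missing value, and
    those indicators are part of the covariate set used by the learners.
    """
    X = np.array(X, dtype=float)
    n, d = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    indicators = []
    for j in range(d):
        miss = np.isnan(X[:, j])
        if not miss.any():
            continue
        if miss.all():
            raise ValueError(f"covariate column {j} is entirely missing")
        mean = np.average(X[~miss, j], weights=w[~miss])
        X[miss, j] = mean
        indicators.append(miss.astype(float))
    ind = np.column_stack(indicators) if indicators else np.empty((n, 0))
    return np.column_stack([X, ind]) if ind.size else X, ind


def run_analysis(config: AnalysisConfig, sample: IVSample | None = None) -> dict:
    """End-to-end bound estimation returning the structured report.

    Provide either ``config.data`` (a CSV/TSV path) or a prebuilt sample.
    The report carries estimates, variances, intervals, margin diagnostics,
    fold/learner metadata, seed provenance and warning flags.
    """
    t0 = time.time()
    if sample is None:
        if config.data is None:
            raise ValueError("config.data or an explicit sample is required")
        sample = read_dataset(config.data, config)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n": sample.n,
        "d": sample.d,
        "weights": {"sum": float(sample.w.sum()),
                    "normalized": bool(np.allclose(sample.w, 1.0))},
        "config": {k: v for k, v in asdict(config).items() if k != "data"},
        "estimates": {},
        "warnings": [],
        "timings_s": {},
    }
    methods = ("direct", "lse") if config.method == "both" else (config.method,)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if config.outcome_type == "continuous":
            spec = config.nuisance_spec()
            cfg = ContinuousConfig(m=config.m, seed=config.seed,
                                   y_min=config.y_min, y_max=config.y_max)
            for meth in methods:
                report["estimates"][f"w-augmented/{meth}"] = estimate_continuous(
                    sample, spec, cfg, method=meth, ci_level=config.ci_level)
            if config.grid_size:
                report["estimates"][f"grid/{methods[0]}"] = estimate_grid(
                    sample, spec, config.grid_size, method=methods[0],
                    ci_level=config.ci_level, cfg=cfg, seed=config.seed)
        else:
            t_n = time.time()
            nuis = fit_crossfit_nuisances(
                sample, config.pi_learner, config.lambda_learner, K=config.K,
                eps=config.eps, seed=config.seed,
                known_lambda=config.known_lambda,
            )
            report["timings_s"]["nuisance_fit"] = round(time.time() - t_n, 4)
            report["nuisance"] = {
                "K": int(len(np.unique(nuis.fold))),
                "pi_learner": str(config.pi_learner),
                "lambda_learner": str(config.lambda_learner),
                "known_lambda": config.known_lambda,
                "lambda_truncated_fraction": float(np.mean(
                    (nuis.lambda1 <= nuis.eps) | (nuis.lambda1 >= 1 - nuis.eps)
                )) if config.known_lambda is None else 0.0,
            }
            for meth in methods:
                t_m = time.time()
                if meth == "direct":
                    est = estimate_direct(sample, nuis, ci_level=config.ci_level)
                else:
                    t_val = None if config.t == "default" else float(config.t)
                    est = estimate_lse(sample, nuis, t=t_val,
                                       ci_level=config.ci_level)
                report["estimates"][meth] = est.to_dict()
                report["timings_s"][meth] = round(time.time() - t_m, 4)
            report["margin"] = margin_report(sample, nuis)
        report["warnings"] = sorted({str(w.message) for w in caught})
    report["timings_s"]["total"] = round(time.time() - t0, 4)
    return report


def write_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def read_report(path: str) -> dict:
    with open(path) as fh:
        report = json.load(fh)
    if report.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError("unsupported report schema version")
    return report
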