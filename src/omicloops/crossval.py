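"""Predictive validation of the loop variables by a 70/30 split.

Every variable appearing in a meaningful loop is modelled once as the
response, with all the other loop variables as predictors — except members of
the response's correlated-SNP group, which are excluded — always adjusting
for race, sex and study site. Models are trained on 70% of the samples at one
age and scored on the held-out 30%, restricted to complete cases; each
variable is min-max normalised to [0, 1] using training-set bounds so the
mean squared error is dimensionless across omics, and is reported x100 as a
percent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import substream
from .associations import encode_covariates

logger = logging.getLogger("omicloops")

__all__ = ["split_samples", "fit_loop_models", "evaluate_mse", "CvReport", "LoopVariableModel"]


def split_samples(sample_ids, train_fraction: float = 0.7, seed: int = 0):
    """Deterministic uniform train/test partition (disjoint, exhaustive)."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    ids = list(sample_ids)
    if len(ids) < 20:
        raise ValueError("need at least 20 samples to split")
    rng = substream(seed, "cv-split")
    perm = rng.permutation(len(ids))
    n_train = int(np.floor(train_fraction * len(ids)))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


@dataclass
class LoopVariableModel:
    """One leave-one-variable-out OLS model."""

    response: str
    predictors: list
    excluded: list
    coef: pd.Series
    n_train: int

    def predict(self, design: pd.DataFrame) -> pd.Series:
        X = design[self.coef.index.drop("const")]
        return pd.Series(
            self.coef["const"] + X.to_numpy(dtype=float) @ self.coef.drop("const").to_numpy(),
            index=design.index,
        )


def _design(values: pd.DataFrame, predictors, cov_enc: pd.DataFrame) -> pd.DataFrame:
    return pd.concat([values[predictors], cov_enc.loc[values.index]], axis=1)


def fit_loop_models(
    loop_values: pd.DataFrame,
    covariates: pd.DataFrame,
    train_ids,
    snp_groups=None,
    var_types: dict | None = None,
    min_extra_rows: int = 5,
) -> dict:
    """Fit one OLS model per loop variable on the training samples.

    ``loop_values`` holds one column per loop variable (SNP MAC, genus log
    abundance, metabolite log abundance, BMI percentile) on a shared sample
    index. For each response, predictors are all other columns minus the
    response's correlated-SNP partners; covariates are always included.
    Training rows are the per-model complete cases; a model with fewer than
    ``predictors + min_extra_rows`` rows is skipped with a warning.
    """
    cov_enc = encode_covariates(covariates)
    train_ids = [s for s in train_ids if s in loop_values.index]
    models: dict[str, LoopVariableModel] = {}
    for response in loop_values.columns:
        excluded = sorted(snp_groups.partners(response)) if snp_groups is not None else []
        predictors = [c for c in loop_values.columns if c != response and c not in excluded]
        assert response not in predictors
        vals = loop_values.loc[train_ids]
        design = _design(vals, predictors, cov_enc)
        y = vals[response].to_numpy(dtype=float)
        X = design.to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
        n = int(ok.sum())
        if n < X.shape[1] + 1 + min_extra_rows:
            logger.warning("skipping model for %s: %d complete training rows", response, n)
            continue
        Xc = np.column_stack([np.ones(n), X[ok]])
        coef, _, _, _ = np.linalg.lstsq(Xc, y[ok], rcond=None)
        models[response] = LoopVariableModel(
            response=response,
            predictors=predictors,
            excluded=excluded,
            coef=pd.Series(coef, index=["const"] + list(design.columns)),
            n_train=n,
        )
    return models


@dataclass
class CvReport:
    """Per-response test MSE on the min-max normalised [0, 1] scale (x100)."""

    mse_percent: dict
    n_train: dict
    n_test_complete: int
    test_complete_fraction: float
    coefficients: dict
    excluded_predictors: dict
    seed: int | None = None
    normalization: str = "minmax"
    baseline_mse_percent: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for v in sorted(self.mse_percent):
            rows.append(
                {
                    "response": v,
                    "mse_percent": self.mse_percent[v],
                    "baseline_mse_percent": self.baseline_mse_percent.get(v, np.nan),
                    "n_train": self.n_train.get(v, 0),
                    "n_test_complete": self.n_test_complete,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = {
            "mse_percent": self.mse_percent,
            "baseline_mse_percent": self.baseline_mse_percent,
            "n_train": self.n_train,
            "n_test_complete": self.n_test_complete,
            "test_complete_fraction": self.test_complete_fraction,
            "excluded_predictors": self.excluded_predictors,
            "coefficients": {k: dict(v) for k, v in self.coefficients.items()},
            "seed": self.seed,
            "normalization": self.normalization,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def evaluate_mse(
    models: dict,
    loop_values: pd.DataFrame,
    covariates: pd.DataFrame,
    test_ids,
    normalization: str = "minmax",
    train_ids=None,
    seed: int | None = None,
) -> CvReport:
    """Score the fitted models on the complete-case test samples.

    The test set is restricted to samples with no missing value in any loop
    variable or covariate. Each variable (and its prediction) is min-max
    normalised using training-set bounds before squaring, and the MSE is
    reported as a percent (x100). A mean-predictor baseline is reported
    alongside.
    """
    if normalization != "minmax":
        raise ValueError("only minmax normalization is supported")
    cov_enc = encode_covariates(covariates)
    test_ids = [s for s in test_ids if s in loop_values.index]
    test_vals = loop_values.loc[test_ids]
    complete = test_vals.notna().all(axis=1) & np.isfinite(
        cov_enc.loc[test_ids].to_numpy(dtype=float)
    ).all(axis=1)
    test_vals = test_vals.loc[complete]
    n_complete = int(complete.sum())
    frac = n_complete / max(len(test_ids), 1)

    if train_ids is not None:
        train_vals = loop_values.loc[[s for s in train_ids if s in loop_values.index]]
    else:
        train_vals = loop_values.drop(index=test_ids)

    mse, baseline, n_train, coefs, excluded = {}, {}, {}, {}, {}
    for response, model in models.items():
        n_train[response] = model.n_train
        coefs[response] = {k: float(v) for k, v in model.coef.items()}
        excluded[response] = model.excluded
        if n_complete == 0:
            mse[response] = None
            continue
        lo = float(np.nanmin(train_vals[response]))
        hi = float(np.nanmax(train_vals[response]))
        span = (hi - lo) or 1.0
        design = _design(test_vals, model.predictors, cov_enc)
        pred = model.predict(design)
        y_n = (test_vals[response].to_numpy(dtype=float) - lo) / span
        p_n = (pred.to_numpy(dtype=float) - lo) / span
        mse[response] = float(100.0 * np.mean((y_n - p_n) ** 2))
        train_mean_n = (float(np.nanmean(train_vals[response])) - lo) / span
        baseline[response] = float(100.0 * np.mean((y_n - train_mean_n) ** 2))
    if n_complete == 0:
        logger.warning("no complete-case test samples: MSE not computable")
    return CvReport(
        mse_percent=mse,
        n_train=n_train,
        n_test_complete=n_complete,
        test_complete_fraction=float(frac),
        coefficients=coefs,
        excluded_predictors=excluded,
        seed=seed,
        normalization=normalization,
        baseline_mse_percent=baseline,
    )
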