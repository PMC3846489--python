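"""Breed-level regression of imputation error on its candidate drivers.

Across breeds, the allelic imputation error rate (in percent) is regressed
by ordinary least squares on four factors: reference (training) population
size, mean training/validation additive relationship R_T/V, LD level at
70 kb, and the effective number of ancestors. The variance share of each
factor is the sequential (type-I) R² increment in that fixed order. A
packaged table of published per-breed values ships with the module for a
worked example; the estimator accepts any per-breed factor table with the
same columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

FACTOR_ORDER = ("train_size", "r_tv", "ld70", "n_eff_ancestors")


@dataclass
class BreedFactors:
    breed: str
    error_rate_pct: float
    train_size: int
    r_tv: float
    ld70: float
    n_eff_ancestors: float


def load_breed_table(complete_only: bool = True) -> pd.DataFrame:
    """The packaged per-breed factor table (16 cattle breeds).

    One breed lacks the accuracy-study columns; ``complete_only`` drops it,
    leaving the 15 rows used for regression.
    """
    with resources.files("hdimpute.data").joinpath("breed_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if complete_only:
        df = df.dropna(subset=["error_rate_pct", "ld70", "r_tv"]).reset_index(drop=True)
    return df


class ImputationFactorModel(BaseEstimator):
    """OLS of breed error rate (%) on the four accuracy factors.

    Attributes (after ``fit``)
    --------------------------
    coef_ : dict factor -> regression coefficient (percent error per unit)
    se_ : dict factor -> standard error
    pvalues_ : dict factor -> two-sided t-test p-value
    variance_shares_ : dict factor -> sequential R² increment
    intercept_ : float
    r2_ : float
    """

    def __init__(self, max_condition_number: float = 1e8):
        self.max_condition_number = max_condition_number

    def fit(self, data: pd.DataFrame | list):
        if isinstance(data, list):
            data = pd.DataFrame([vars(b) for b in data])
        needed = ("error_rate_pct",) + FACTOR_ORDER
        missing = [c for c in needed if c not in data.columns]
        if missing:
            raise ValueError(f"factor table missing columns: {missing}")
        df = data.dropna(subset=list(needed))
        if len(df) < len(FACTOR_ORDER) + 2:
            raise ValueError("need more breeds than parameters to fit")
        X = df[list(FACTOR_ORDER)].to_numpy(dtype=float)
        y = df["error_rate_pct"].to_numpy(dtype=float)
        # condition check on standardized columns so units do not dominate
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        cond = np.linalg.cond(Z)
        if cond > self.max_condition_number:
            corr = np.corrcoef(Z, rowvar=False)
            np.fill_diagonal(corr, 0)
            i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
            raise ValueError(
                f"collinear design (condition number {cond:.3g}); most correlated "
                f"factors: {FACTOR_ORDER[i]} and {FACTOR_ORDER[j]}"
            )
        model = sm.OLS(y, sm.add_constant(X)).fit()
        self.model_ = model
        self.intercept_ = float(model.params[0])
        self.coef_ = dict(zip(FACTOR_ORDER, model.params[1:]))
        self.se_ = dict(zip(FACTOR_ORDER, model.bse[1:]))
        self.pvalues_ = dict(zip(FACTOR_ORDER, model.pvalues[1:]))
        self.r2_ = float(model.rsquared)
        shares = {}
        prev = 0.0
        for k in range(1, len(FACTOR_ORDER) + 1):
            sub = sm.OLS(y, sm.add_constant(X[:, :k])).fit()
            shares[FACTOR_ORDER[k - 1]] = float(sub.rsquared - prev)
            prev = sub.rsquared
        self.variance_shares_ = shares
        self.n_obs_ = len(df)
        return self

    def predict_effect(self, factor: str, delta: float) -> float:
        """Predicted change in error (%) for a ``delta`` change of one factor."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")
        if factor not in self.coef_:
            raise KeyError(f"unknown factor: {factor}; expected one of {FACTOR_ORDER}")
        return float(self.coef_[factor] * delta)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": list(FACTOR_ORDER),
                "variance_share": [self.variance_shares_[f] for f in FACTOR_ORDER],
                "coefficient": [self.coef_[f] for f in FACTOR_ORDER],
                "std_error": [self.se_[f] for f in FACTOR_ORDER],
                "p_value": [self.pvalues_[f] for f in FACTOR_ORDER],
            }
        )


def fit_factors(data: pd.DataFrame | list) -> ImputationFactorModel:
    """Fit the factor regression; thin wrapper over ``ImputationFactorModel``."""
    return ImputationFactorModel().fit(data)


def predict_effect(result: ImputationFactorModel, factor: str, delta: float) -> float:
    return result.predict_effect(factor, delta)
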