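"""Age-associated TF detection and age-adjusted expression.

A gene's expression is regressed on age, sex, three genotype-derived
principal components and latent (PEER-style) expression factors:

    g_j = a + b_age*AGE_j + b_sex*SEX_j + sum_l b_l S_jl
          + sum_k b_k PEER_jk + e_j

PEER factors that correlate with age (Pearson p <= alpha) are removed
before fitting, so they cannot absorb the age signal.  A TF is called
age-associated when the two-sided p-value of ``b_age`` survives
Benjamini-Hochberg control over the TF panel (FDR <= 0.1 by default).
Downstream analyses use the *adjusted* TF expression

    TF~_j = b_age*AGE_j + e_j

i.e. the age component plus residual, with intercept, sex, genotype-PC
and latent-factor components removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from snipage.core_io import CohortData, CovariateTable

__all__ = [
    "filter_peer_factors", "bh_fdr", "AgeExpressionModel",
    "AgeExpressionResults", "AgeTFSet", "detect_age_tfs",
    "adjust_tf_expression",
]


def filter_peer_factors(peer_factors: pd.DataFrame, age,
                        alpha: float = 0.05) -> list[str]:
    """Return the PEER columns whose Pearson correlation with age is NOT
    significant (p > alpha), preserving column order.

    Constant columns are uncorrelated by construction and retained with
    a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    age = np.asarray(age, dtype=float)
    if len(age) < 3:
        raise ValueError("need at least 3 samples")
    retained = []
    for col in peer_factors.columns:
        x = np.asarray(peer_factors[col], dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"PEER factor {col} is constant; treated as "
                          "uncorrelated with age", stacklevel=2)
            retained.append(col)
            continue
        _, p = stats.pearsonr(x, age)
        if p > alpha:
            retained.append(col)
    return retained


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _drop_rank_deficient(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop columns that do not increase the design rank,
    keeping the first occurrence.  Returns (reduced design, dropped)."""
    kept_idx: list[int] = []
    dropped: list[str] = []
    M = X.to_numpy(dtype=float)
    rank = 0
    for j in range(M.shape[1]):
        cand = M[:, kept_idx + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept_idx.append(j)
            rank = r
        else:
            dropped.append(X.columns[j])
    return X.iloc[:, kept_idx], dropped


class AgeExpressionModel:
    """OLS model of one gene's expression on age + confounders.

    Parameters
    ----------
    y : per-sample expression (aligned with ``covariates``)
    covariates : CovariateTable
    peer_subset : PEER columns to include (after the age-correlation
        filter); None means all.
    include_extras : include extra covariate columns (e.g. race code).
    """

    def __init__(self, y, covariates: CovariateTable,
                 peer_subset=None, include_extras: bool = False):
        y = pd.Series(np.asarray(y, dtype=float),
                      index=covariates.sample_ids)
        if not np.isfinite(y).all():
            raise ValueError("non-finite expression values")
        X = covariates.design(peer_subset, include_extras)
        X = sm.add_constant(X.astype(float), prepend=True)
        if len(y) <= X.shape[1]:
            raise ValueError(
                f"n_samples ({len(y)}) must exceed number of coefficients "
                f"({X.shape[1]})")
        X, dropped = _drop_rank_deficient(X)
        if dropped:
            warnings.warn(f"dropped rank-deficient design columns: {dropped}",
                          stacklevel=2)
        if covariates.age_col in dropped:
            raise ValueError("age column is collinear with other covariates")
        self.y = y
        self.X = X
        self.age_col = covariates.age_col
        self.dropped_columns = dropped

    def fit(self) -> "AgeExpressionResults":
        res = sm.OLS(self.y, self.X).fit()
        return AgeExpressionResults(self, res)


@dataclass
class AgeExpressionResults:
    """Fitted age model: coefficients, the age test, residuals and the
    age-adjusted expression."""

    model: AgeExpressionModel
    _sm_results: object

    @property
    def params(self) -> pd.Series:
        return self._sm_results.params

    @property
    def beta_age(self) -> float:
        return float(self.params[self.model.age_col])

    @property
    def p_age(self) -> float:
        return float(self._sm_results.pvalues[self.model.age_col])

    @property
    def residuals(self) -> pd.Series:
        return self._sm_results.resid

    @property
    def fittedvalues(self) -> pd.Series:
        return self._sm_results.fittedvalues

    def adjusted_expression(self) -> pd.Series:
        """Age component plus residual: beta_age * AGE + e."""
        age = self.model.X[self.model.age_col]
        return self.beta_age * age + self.residuals

    def summary(self):
        return self._sm_results.summary()


def fit_age_model(y, covariates: CovariateTable, peer_subset=None,
                  include_extras: bool = False) -> AgeExpressionResults:
    """Convenience wrapper: build and fit an :class:`AgeExpressionModel`."""
    return AgeExpressionModel(y, covariates, peer_subset,
                              include_extras).fit()


def adjust_tf_expression(fit: AgeExpressionResults,
                         covariates: CovariateTable) -> pd.Series:
    """Adjusted expression (age component + residual) for the fitted
    samples; errors if the covariate table's samples differ."""
    if list(fit.model.y.index) != covariates.sample_ids:
        raise ValueError("sample mismatch between fit and covariates")
    return fit.adjusted_expression()


@dataclass
class AgeTFSet:
    """Age-associated TFs: the per-TF test table and the adjusted
    expression matrix (rows = detected TFs)."""

    table: pd.DataFrame               # index tf_id: beta_age, p_age, q_age
    adjusted_expression: pd.DataFrame  # detected TFs x samples
    retained_peer: list[str] = field(default_factory=list)
    fdr: float = 0.1

    @property
    def tf_ids(self) -> list[str]:
        return [t for t in self.table.index if self.table.loc[t, "q_age"] <= self.fdr]

    def __len__(self) -> int:
        return len(self.tf_ids)


def detect_age_tfs(cohort: CohortData, tf_list, fdr: float = 0.1,
                   peer_age_alpha: float = 0.05,
                   include_extras: bool = False) -> AgeTFSet:
    """Fit the age model for every TF in the panel, BH-adjust the age
    p-values across the panel only, and keep TFs with q <= fdr.

    Returns the full per-TF table (all panel members, with q-values) and
    the adjusted-expression matrix for the detected TFs.
    """
    tf_list = [t for t in tf_list if t in cohort.expression.index]
    retained = filter_peer_factors(cohort.covariates.peer_factors,
                                   cohort.covariates.age, peer_age_alpha)
    rows, adjusted = [], {}
    fits = {}
    for tf in tf_list:
        res = fit_age_model(cohort.expression.loc[tf], cohort.covariates,
                            peer_subset=retained,
                            include_extras=include_extras)
        fits[tf] = res
        rows.append((tf, res.beta_age, res.p_age))
    table = pd.DataFrame(rows, columns=["tf_id", "beta_age", "p_age"]
                         ).set_index("tf_id")
    if len(table):
        table["q_age"] = bh_fdr(table["p_age"].to_numpy())
    else:
        table["q_age"] = pd.Series(dtype=float)
    detected = [t for t in table.index if table.loc[t, "q_age"] <= fdr]
    for tf in detected:
        adjusted[tf] = fits[tf].adjusted_expression()
    adj = pd.DataFrame(adjusted).T
    if len(adj) == 0:
        adj = pd.DataFrame(columns=cohort.expression.columns)
    return AgeTFSet(table, adj, retained, fdr)
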