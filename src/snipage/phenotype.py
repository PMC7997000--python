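"""Aggregated TF-SNP interaction association with a binary phenotype.

The detected interactions of one run are aggregated into three feature
blocks per sample: adjusted expression of the detected TFs, binding-
allele dosage of the detected SNPs, and their elementwise products for
the detected (TF, SNP) pairs.  Each block is standardized and reduced to
at most k principal components (k = 30 by default).  Nested logistic
regressions

    null: status ~ confounders + PC(TF block) + PC(SNP block)
    alt : null + PC(interaction block)

are compared by a likelihood-ratio test with df equal to the number of
interaction components actually used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = ["pca_reduce", "PhenotypeInteractionModel", "PhenotypeLLR",
           "build_phenotype_design"]


def pca_reduce(block: np.ndarray, k: int) -> np.ndarray:
    """Scores of the top-k principal components of a standardized feature
    block (samples x features).

    Zero-variance columns are dropped before standardization; k is
    truncated to the block's rank (with a warning).  Sign convention:
    each component's largest-magnitude loading is positive.
    """
    X = np.asarray(block, dtype=float)
    if X.ndim != 2:
        raise ValueError("block must be 2-D (samples x features)")
    sd = X.std(axis=0)
    X = X[:, sd > 0]
    if X.shape[1] == 0:
        return np.empty((X.shape[0], 0))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    rank = np.linalg.matrix_rank(X)
    k_eff = min(k, rank, X.shape[0], X.shape[1])
    if k_eff < k:
        warnings.warn(f"requested {k} components, block supports {k_eff}",
                      stacklevel=2)
    pca = PCA(n_components=k_eff, svd_solver="full")
    scores = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component > 0
    for j in range(k_eff):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def _logistic_loglik(X: np.ndarray, y: np.ndarray,
                     label: str) -> tuple[float, bool]:
    """Log-likelihood at the (possibly ridge-stabilized) logistic MLE.

    Returns (loglik, converged).  The likelihood is always evaluated
    directly from the fitted linear predictor, so the fallback path
    yields a comparable value.
    """
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        params = res.params
    except Exception:
        converged = False
        params = None
    if params is None or not converged:
        logger.info("%s: logistic fit did not converge; ridge-stabilized "
                    "refit (penalty 1e-6)", label)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit_regularized(alpha=1e-6, L1_wt=0.0, disp=0,
                                        maxiter=500)
        params = res.params
    eta = X @ np.asarray(params)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return ll, converged


@dataclass
class PhenotypeLLR:
    llr: float
    df: int
    p: float
    n_cases: int
    n_controls: int
    converged: bool = True

    def summary(self) -> pd.Series:
        return pd.Series({"llr": self.llr, "df": self.df, "p": self.p,
                          "n_cases": self.n_cases,
                          "n_controls": self.n_controls})


class PhenotypeInteractionModel:
    """Nested logistic models for the aggregated-interaction phenotype
    test.

    Parameters
    ----------
    status : binary phenotype per sample (0/1)
    tf_block, snp_block, interaction_block : samples x features
    confounders : DataFrame or array of per-sample confounders
    k : maximum principal components per block (default 30)
    """

    def __init__(self, status, tf_block, snp_block, interaction_block,
                 confounders, k: int = 30):
        y = np.asarray(status, dtype=float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("status must be binary 0/1")
        n_cases, n_controls = int(y.sum()), int((1 - y).sum())
        if n_cases < 10 or n_controls < 10:
            raise ValueError("need at least 10 cases and 10 controls")
        C = np.asarray(confounders, dtype=float)
        blocks = [np.asarray(b, dtype=float)
                  for b in (tf_block, snp_block, interaction_block)]
        for b in blocks + [C]:
            if b.shape[0] != len(y):
                raise ValueError("all blocks must share the sample order")
        tf_pc, snp_pc, int_pc = (pca_reduce(b, k) for b in blocks)
        if int_pc.shape[1] == 0:
            raise ValueError("interaction block has no variance")
        self.y = y
        self.n_cases, self.n_controls = n_cases, n_controls
        self.X_null = np.column_stack([np.ones(len(y)), C, tf_pc, snp_pc])
        self.X_alt = np.column_stack([self.X_null, int_pc])
        self.df = int_pc.shape[1]

    def fit(self) -> PhenotypeLLR:
        ll0, conv0 = _logistic_loglik(self.X_null, self.y, "null model")
        ll1, conv1 = _logistic_loglik(self.X_alt, self.y, "interaction model")
        llr = 2.0 * (ll1 - ll0)
        p = float(stats.chi2.sf(max(llr, 0.0), df=self.df))
        return PhenotypeLLR(float(llr), self.df, p, self.n_cases,
                            self.n_controls, conv0 and conv1)


def phenotype_llr(status, tf_block, snp_block, interaction_block,
                  confounders, k: int = 30) -> PhenotypeLLR:
    """Convenience wrapper around :class:`PhenotypeInteractionModel`."""
    return PhenotypeInteractionModel(status, tf_block, snp_block,
                                     interaction_block, confounders, k).fit()


def build_phenotype_design(cohort, age_tf_set, triplets: pd.DataFrame,
                           status: pd.Series):
    """Assemble the feature blocks for the phenotype test from a pipeline
    result table (its ``selected`` rows).

    Returns (status array, tf_block, snp_block, interaction_block,
    confounders DataFrame) aligned on the cohort's sample order.
    """
    from snipage.interaction import binding_allele_dosage

    sel = triplets[triplets["selected"]] if "selected" in triplets else triplets
    if len(sel) == 0:
        raise ValueError("no detected triplets to aggregate")
    status = status.loc[cohort.sample_ids].to_numpy(dtype=float)
    tfs = sorted(sel["tf"].unique())
    tf_block = age_tf_set.adjusted_expression.loc[tfs,
                                                  cohort.sample_ids].T.to_numpy()
    pairs = sel.drop_duplicates(subset=["tf", "snp"])
    snp_ids = sorted(pairs["snp"].unique())
    dosage_by_snp = {}
    for _, row in pairs.iterrows():
        alt = cohort.genotypes.dosage(row["snp"]).to_numpy()
        dosage_by_snp.setdefault(
            row["snp"], binding_allele_dosage(alt, _binding_allele(row)))
    snp_block = np.column_stack([
        np.nan_to_num(dosage_by_snp[s], nan=np.nanmean(dosage_by_snp[s]))
        for s in snp_ids])
    inter_cols = []
    tf_index = {t: i for i, t in enumerate(tfs)}
    snp_index = {s: i for i, s in enumerate(snp_ids)}
    for _, row in pairs.iterrows():
        inter_cols.append(tf_block[:, tf_index[row["tf"]]]
                          * snp_block[:, snp_index[row["snp"]]])
    interaction_block = np.column_stack(inter_cols)
    confounders = cohort.covariates.design(
        peer_subset=age_tf_set.retained_peer)
    return status, tf_block, snp_block, interaction_block, confounders


def _binding_allele(row) -> str:
    return row["binding_allele"] if "binding_allele" in row else "alt"
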