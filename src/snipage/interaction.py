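"""SNP x TF interaction testing on candidate TF-SNP-gene triplets.

For every SNP with a putative allele-specific binding (ASB) call by an
age-associated TF, all genes with a TSS within the cis window (1 Mbp by
default) are candidate targets.  Each candidate is tested with nested
ordinary-least-squares models of the target gene's expression:

    null:  g = a + b1*AGE + b2*SEX + b3*SNP + b4*TF~ + PCs + PEER
    alt :  null + b5*(SNP x TF~)

where SNP is the per-sample count of the *binding* allele (0/1/2) and
TF~ is the TF's age-adjusted expression.  The likelihood-ratio statistic
2*(ll_alt - ll_null) under a Gaussian likelihood is referred to
chi-square with 1 df; p-values are BH-adjusted across all tested
triplets.  Surviving triplets must additionally pass a
genotype-stratified consistency filter: the Spearman TF-gene correlation
must be significant in the heterozygous and binding-allele-homozygous
groups, absent in the non-binding homozygotes, and stronger (same sign)
in the binding homozygotes than in the heterozygotes.

Controls: a permutation background that shuffles sample labels of the
whole expression matrix (preserving gene-gene covariance), and a
down-sampling replication analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from snipage.age import AgeTFSet, bh_fdr, detect_age_tfs
from snipage.core_io import CohortData

__all__ = [
    "CandidateTriplet", "PipelineConfig", "TripletSkip",
    "InteractionModel", "InteractionResults", "llr_interaction_test",
    "ConsistencyResult", "consistency_pass", "consistency_filter",
    "enumerate_candidates", "run_pipeline", "shuffle_background",
    "replication_rate",
]


@dataclass
class CandidateTriplet:
    tf_id: str
    snp_id: str
    gene_id: str
    snp_to_tss_distance: int


@dataclass
class PipelineConfig:
    """All tunable thresholds of the detection pipeline."""

    fdr_age_tf: float = 0.1
    fdr_interaction: float = 0.05
    peer_age_alpha: float = 0.05
    cis_window_bp: int = 1_000_000
    min_group_size: int = 10
    min_samples: int = 30
    consistency_alpha: float = 0.05
    flank_bp: int = 50
    motif_pvalue: float = 1e-4


class TripletSkip(Exception):
    """A candidate triplet that cannot be tested (reason in ``reason``)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def enumerate_candidates(asb_calls: pd.DataFrame,
                         gene_annotations: pd.DataFrame,
                         cis_window: int = 1_000_000) -> list[CandidateTriplet]:
    """One candidate per (ASB call, gene) with |SNP - TSS| <= cis_window
    on the same chromosome, ordered by (tf, snp, gene).

    ``gene_annotations``: index gene_id with columns chrom, tss (1-based).
    """
    out = []
    ann = gene_annotations
    for _, call in asb_calls.iterrows():
        genes = ann[ann["chrom"] == call["chrom"]]
        dist = (genes["tss"].astype(int) - int(call["pos"])).abs()
        for gene_id in genes.index[dist <= cis_window]:
            out.append(CandidateTriplet(call["tf"], call["snp"], gene_id,
                                        int(dist[gene_id])))
    out.sort(key=lambda t: (t.tf_id, t.snp_id, t.gene_id))
    return out


# ---------------------------------------------------------------------------
# the nested-model LLR test
# ---------------------------------------------------------------------------

def _gaussian_loglik(rss: float, n: int) -> float:
    """Profile Gaussian log-likelihood at the OLS solution."""
    return -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)


def _full_rank_columns(M: np.ndarray) -> list[int]:
    """Indices of a maximal full-rank column subset, keeping first
    occurrences."""
    kept: list[int] = []
    rank = 0
    for j in range(M.shape[1]):
        r = np.linalg.matrix_rank(M[:, kept + [j]])
        if r > rank:
            kept.append(j)
            rank = r
    return kept


class InteractionModel:
    """Nested OLS models for one candidate triplet.

    Parameters
    ----------
    y : target gene expression per sample
    snp_dosage : count of the binding allele (0/1/2; NaN = missing,
        those samples are dropped)
    tf_adjusted : age-adjusted TF expression per sample
    covariates : DataFrame of shared covariates (age, sex, SNP PCs,
        retained PEER factors), without intercept
    """

    def __init__(self, y, snp_dosage, tf_adjusted, covariates: pd.DataFrame,
                 min_samples: int = 30):
        y = np.asarray(y, dtype=float)
        d = np.asarray(snp_dosage, dtype=float)
        tf = np.asarray(tf_adjusted, dtype=float)
        C = np.asarray(covariates, dtype=float)
        mask = np.isfinite(d)
        y, d, tf, C = y[mask], d[mask], tf[mask], C[mask]
        n = len(y)
        if n < min_samples:
            raise TripletSkip("too_few_samples")
        if len(np.unique(d)) < 2:
            raise TripletSkip("monomorphic")
        if not np.isfinite(y).all() or not np.isfinite(tf).all():
            raise TripletSkip("nonfinite_input")
        X1 = np.column_stack([np.ones(n), C, d, tf, d * tf])
        if np.linalg.matrix_rank(X1) < X1.shape[1]:
            # rare path: clean collinear covariates first (keep first
            # occurrence), then require the remaining terms to be
            # identifiable
            base = np.column_stack([np.ones(n), C])
            base = base[:, _full_rank_columns(base)]
            X0 = np.column_stack([base, d, tf])
            if np.linalg.matrix_rank(X0) < X0.shape[1]:
                raise TripletSkip("singular_null_design")
            X1 = np.column_stack([X0, d * tf])
            if np.linalg.matrix_rank(X1) < X1.shape[1]:
                raise TripletSkip("singular_alt_design")
        X0 = X1[:, :-1]
        if n <= X1.shape[1]:
            raise TripletSkip("too_few_samples")
        self.y, self.X0, self.X1, self.n = y, X0, X1, n

    def fit(self) -> "InteractionResults":
        beta0, rss0 = _ols(self.X0, self.y)
        beta1, rss1 = _ols(self.X1, self.y)
        n = self.n
        ll0 = _gaussian_loglik(rss0, n)
        ll1 = _gaussian_loglik(rss1, n)
        llr = 2.0 * (ll1 - ll0)
        p = float(stats.chi2.sf(max(llr, 0.0), df=1))
        # trailing columns of X1 are [.., dosage, tf, dosage*tf]
        return InteractionResults(
            llr=float(llr), p_llr=p,
            beta_snp=float(beta1[-3]), beta_tf=float(beta1[-2]),
            beta_interaction=float(beta1[-1]),
            n_used=n, ll_null=ll0, ll_alt=ll1)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


@dataclass
class InteractionResults:
    llr: float
    p_llr: float
    beta_snp: float
    beta_tf: float
    beta_interaction: float
    n_used: int
    ll_null: float
    ll_alt: float

    def summary(self) -> pd.Series:
        return pd.Series({
            "llr": self.llr, "p_llr": self.p_llr, "beta_snp": self.beta_snp,
            "beta_tf": self.beta_tf, "beta_interaction": self.beta_interaction,
            "n_used": self.n_used})


def llr_interaction_test(y, snp_dosage, tf_adjusted, covariates,
                         min_samples: int = 30) -> InteractionResults:
    """Fit the nested models and return the LLR test for one triplet."""
    return InteractionModel(y, snp_dosage, tf_adjusted, covariates,
                            min_samples).fit()


# ---------------------------------------------------------------------------
# consistency filter
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyResult:
    r_het: float
    p_het: float
    r_homB: float
    p_homB: float
    r_homNB: float
    p_homNB: float
    n_het: int
    n_homB: int
    n_homNB: int
    passed: bool
    reason: str = ""


def consistency_pass(r_het, p_het, r_homB, p_homB, r_homNB, p_homNB,
                     alpha: float = 0.05) -> tuple[bool, str]:
    """The decision rule on precomputed per-genotype-group Spearman
    statistics: significant TF-gene correlation in heterozygotes and
    binding-allele homozygotes, none in non-binding homozygotes, and a
    stronger same-sign correlation in binding homozygotes than in
    heterozygotes."""
    if any(not np.isfinite(v) for v in
           (r_het, p_het, r_homB, p_homB, r_homNB, p_homNB)):
        return False, "degenerate"
    if p_het > alpha:
        return False, "het_not_significant"
    if p_homB > alpha:
        return False, "homB_not_significant"
    if p_homNB <= alpha:
        return False, "homNB_significant"
    if abs(r_homB) <= abs(r_het):
        return False, "homB_not_stronger"
    if np.sign(r_homB) != np.sign(r_het):
        return False, "sign_mismatch"
    return True, ""


def consistency_filter(y, tf_adjusted, binding_dosage,
                       alpha: float = 0.05,
                       min_group: int = 10) -> ConsistencyResult:
    """Genotype-stratified Spearman consistency check.

    ``binding_dosage`` counts copies of the binding allele: groups are
    het (1), homB (2) and homNB (0).
    """
    y = np.asarray(y, dtype=float)
    tf = np.asarray(tf_adjusted, dtype=float)
    d = np.asarray(binding_dosage, dtype=float)
    mask = np.isfinite(d)
    y, tf, d = y[mask], tf[mask], d[mask]
    stats_by_group = {}
    sizes = {}
    for label, dosage in (("het", 1), ("homB", 2), ("homNB", 0)):
        sel = d == dosage
        sizes[label] = int(sel.sum())
        if sizes[label] < 2 or np.std(y[sel]) == 0 or np.std(tf[sel]) == 0:
            stats_by_group[label] = (np.nan, np.nan)
            continue
        r, p = stats.spearmanr(tf[sel], y[sel])
        stats_by_group[label] = (float(r), float(p))
    (r_het, p_het) = stats_by_group["het"]
    (r_homB, p_homB) = stats_by_group["homB"]
    (r_homNB, p_homNB) = stats_by_group["homNB"]
    if min(sizes.values()) < min_group:
        passed, reason = False, "group_too_small"
    else:
        passed, reason = consistency_pass(r_het, p_het, r_homB, p_homB,
                                          r_homNB, p_homNB, alpha)
    return ConsistencyResult(r_het, p_het, r_homB, p_homB, r_homNB, p_homNB,
                             sizes["het"], sizes["homB"], sizes["homNB"],
                             passed, reason)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def binding_allele_dosage(alt_dosage: np.ndarray,
                          binding_allele: str) -> np.ndarray:
    """Convert alt-allele dosage to binding-allele dosage."""
    d = np.asarray(alt_dosage, dtype=float)
    return d if binding_allele == "alt" else 2.0 - d


_RESULT_COLUMNS = [
    "tf", "snp", "gene", "binding_allele", "distance", "n_used",
    "beta_snp", "beta_tf",
    "beta_interaction", "llr", "p_llr", "q", "r_het", "p_het", "r_homB",
    "p_homB", "r_homNB", "p_homNB", "n_het", "n_homB", "n_homNB",
    "consistency_pass", "consistency_reason", "skip_reason", "selected",
]


def run_pipeline(cohort: CohortData, age_tf_set: AgeTFSet,
                 asb_calls: pd.DataFrame, annotations: pd.DataFrame,
                 config: PipelineConfig | None = None) -> pd.DataFrame:
    """Test every candidate triplet and return the full audit table.

    A triplet is ``selected`` when its BH-adjusted LLR p-value is within
    ``fdr_interaction`` and the consistency filter passes.  The q-value
    is computed across all tested (non-skipped) triplets of this run.
    """
    config = config or PipelineConfig()
    calls = asb_calls[asb_calls["tf"].isin(age_tf_set.tf_ids)]
    candidates = enumerate_candidates(calls, annotations,
                                      config.cis_window_bp)
    cov = cohort.covariates.design(peer_subset=age_tf_set.retained_peer)
    call_index = calls.set_index(["tf", "snp"])
    rows = []
    for cand in candidates:
        call = call_index.loc[(cand.tf_id, cand.snp_id)]
        if isinstance(call, pd.DataFrame):
            call = call.iloc[0]
        alt_dos = cohort.genotypes.dosage(cand.snp_id).to_numpy()
        dos = binding_allele_dosage(alt_dos, call["binding_allele"])
        y = cohort.expression.loc[cand.gene_id].to_numpy()
        tf_adj = age_tf_set.adjusted_expression.loc[cand.tf_id].to_numpy()
        row = {"tf": cand.tf_id, "snp": cand.snp_id, "gene": cand.gene_id,
               "binding_allele": call["binding_allele"],
               "distance": cand.snp_to_tss_distance}
        try:
            res = llr_interaction_test(y, dos, tf_adj, cov,
                                       config.min_samples)
        except TripletSkip as skip:
            row["skip_reason"] = skip.reason
            rows.append(row)
            continue
        row.update(res.summary().to_dict())
        row["_dosage"] = dos
        rows.append(row)
    table = pd.DataFrame(rows, columns=_RESULT_COLUMNS + ["_dosage"]) \
        if rows else pd.DataFrame(columns=_RESULT_COLUMNS)
    if len(table) == 0:
        return table
    tested = table["p_llr"].notna()
    table.loc[tested, "q"] = bh_fdr(table.loc[tested, "p_llr"].to_numpy())
    table["selected"] = False
    table["consistency_pass"] = pd.array([pd.NA] * len(table),
                                         dtype="boolean")
    table["consistency_reason"] = pd.array([pd.NA] * len(table),
                                           dtype="string")
    for i in table.index[tested & (table["q"] <= config.fdr_interaction)]:
        y = cohort.expression.loc[table.at[i, "gene"]].to_numpy()
        tf_adj = age_tf_set.adjusted_expression.loc[table.at[i, "tf"]].to_numpy()
        cons = consistency_filter(y, tf_adj, table.at[i, "_dosage"],
                                  config.consistency_alpha,
                                  config.min_group_size)
        table.loc[i, ["r_het", "p_het", "r_homB", "p_homB", "r_homNB",
                      "p_homNB"]] = [cons.r_het, cons.p_het, cons.r_homB,
                                     cons.p_homB, cons.r_homNB, cons.p_homNB]
        table.loc[i, ["n_het", "n_homB", "n_homNB"]] = [
            cons.n_het, cons.n_homB, cons.n_homNB]
        table.at[i, "consistency_pass"] = cons.passed
        table.at[i, "consistency_reason"] = cons.reason
        table.at[i, "selected"] = bool(cons.passed)
    return table.drop(columns="_dosage")


def shuffle_background(cohort: CohortData, seed: int) -> CohortData:
    """Permute sample labels of the whole expression matrix jointly (all
    genes at once), leaving covariates and genotypes untouched; gene-gene
    covariance is preserved exactly."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cohort.n_samples)
    expr = pd.DataFrame(cohort.expression.to_numpy()[:, perm],
                        index=cohort.expression.index,
                        columns=cohort.expression.columns)
    return CohortData(expr, cohort.covariates, cohort.genotypes)


def _detected_sets(cohort: CohortData, tf_list, asb_calls, annotations,
                   config: PipelineConfig):
    age_set = detect_age_tfs(cohort, tf_list, config.fdr_age_tf,
                             config.peer_age_alpha)
    table = run_pipeline(cohort, age_set, asb_calls, annotations, config)
    if len(table):
        triplets = set(map(tuple, table.loc[table["selected"],
                                            ["tf", "snp", "gene"]].to_numpy()))
    else:
        triplets = set()
    return set(age_set.tf_ids), triplets


def replication_rate(cohort: CohortData, tf_list, asb_calls: pd.DataFrame,
                     annotations: pd.DataFrame,
                     config: PipelineConfig | None = None,
                     fractions=(0.7, 0.8, 0.9), n_reps: int = 10,
                     seed: int = 0) -> pd.DataFrame:
    """Down-sampling replication: fraction of full-data detections that
    are re-detected on random sample subsets, per fraction and rep, for
    age-associated TFs and for selected triplets.  Undefined rates (no
    full-data detections) are NaN."""
    config = config or PipelineConfig()
    full_tfs, full_triplets = _detected_sets(cohort, tf_list, asb_calls,
                                             annotations, config)
    rng = np.random.default_rng(seed)
    samples = np.array(cohort.sample_ids)
    rows = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fraction must be in (0, 1]")
        for rep in range(n_reps):
            k = int(round(frac * len(samples)))
            sub_ids = sorted(rng.choice(samples, size=k, replace=False))
            sub = cohort.subset_samples(sub_ids)
            sub_tfs, sub_triplets = _detected_sets(sub, tf_list, asb_calls,
                                                   annotations, config)
            rate_tf = (100.0 * len(sub_tfs & full_tfs) / len(full_tfs)
                       if full_tfs else np.nan)
            rate_tr = (100.0 * len(sub_triplets & full_triplets)
                       / len(full_triplets) if full_triplets else np.nan)
            rows.append((frac, rep, rate_tf, rate_tr))
    return pd.DataFrame(rows, columns=["fraction", "rep",
                                       "rate_age_tfs", "rate_triplets"])
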