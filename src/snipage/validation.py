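"""Post-hoc functional-evidence statistics for detected SNPs and pairs.

All comparisons share one machinery: a foreground score distribution is
compared with a constructed background by a one-sided Wilcoxon rank-sum
(Mann-Whitney) test.  The scores come from

* mean epigenomic signal (DNase, histone marks, PhastCons) over a
  ~200 bp window centered at each SNP,
* allelic imbalance of chromatin-accessibility reads at heterozygous
  sites, against a Binomial(depth, 0.5) null,
* chromatin-interaction (ChIA-PET) link support for SNP-gene pairs,
  against distance-matched random pairs,
* distance to the nearest phenotype-associated SNP, against a control
  SNP set,
* derived allele frequency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from snipage.core_io import SignalTrack

logger = logging.getLogger(__name__)

__all__ = [
    "WindowScore", "EnrichmentResult", "score_windows", "enrichment_test",
    "imbalance_score", "imbalance_test", "chia_support",
    "matched_background_pairs", "nearest_snp_distance",
    "compare_distance_distributions", "derived_allele_frequency",
]


@dataclass
class WindowScore:
    snp_id: str
    score: float


@dataclass
class EnrichmentResult:
    label: str
    n_fg: int
    n_bg: int
    statistic: float
    p: float
    direction: str


def score_windows(snps: pd.DataFrame, track: SignalTrack,
                  width: int = 200) -> pd.Series:
    """Mean per-base signal over a width-bp window centered at each SNP
    (0-based window [pos-1 - width/2, pos-1 + width/2)); uncovered bases
    contribute 0.

    ``snps``: DataFrame indexed by snp_id with chrom and pos (1-based).
    """
    if width <= 0 or width % 2:
        raise ValueError("width must be a positive even integer")
    half = width // 2
    out = {}
    for snp_id, rec in snps.iterrows():
        pos0 = int(rec["pos"]) - 1
        start, end = pos0 - half, pos0 + half
        if start < 0:
            logger.warning("SNP %s window extends past chromosome start; "
                           "skipped", snp_id)
            continue
        out[snp_id] = track.window_sum(rec["chrom"], start, end) / width
    return pd.Series(out, dtype=float)


def enrichment_test(fg_scores, bg_scores, direction: str = "greater",
                    label: str = "enrichment") -> EnrichmentResult:
    """One-sided Wilcoxon rank-sum comparison of two score samples.

    ``direction='greater'`` tests foreground stochastically greater than
    background.  Exact p-values for small tie-free samples, normal
    approximation with tie and continuity corrections otherwise
    (scipy's automatic method selection).
    """
    fg = np.asarray(fg_scores, dtype=float)
    bg = np.asarray(bg_scores, dtype=float)
    if len(fg) == 0 or len(bg) == 0:
        raise ValueError("foreground and background must be non-empty")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if np.ptp(np.concatenate([fg, bg])) == 0:
        warnings.warn("all values tied across both samples; p = 1",
                      stacklevel=2)
        return EnrichmentResult(label, len(fg), len(bg), np.nan, 1.0,
                                direction)
    stat, p = stats.mannwhitneyu(fg, bg, alternative=direction)
    return EnrichmentResult(label, len(fg), len(bg), float(stat), float(p),
                            direction)


def imbalance_score(n1: int, n2: int) -> float:
    """Allelic imbalance: |log2((n1 + 1e-6) / (n2 + 1e-6))|."""
    if n1 < 0 or n2 < 0:
        raise ValueError("read counts must be non-negative")
    # |log2((n1+eps)/(n2+eps))| evaluated as a difference of logs so the
    # score is exactly symmetric in floating point
    hi, lo = (n1, n2) if n1 >= n2 else (n2, n1)
    return float(np.log2(hi + 1e-6) - np.log2(lo + 1e-6))


def imbalance_test(observations: pd.DataFrame, seed: int,
                   min_depth: int = 10) -> tuple[EnrichmentResult, int]:
    """Test allelic imbalance of heterozygous sites against a matched
    binomial null.

    ``observations`` needs columns n_allele1 and n_allele2; sites with
    total depth < min_depth are excluded (count returned).  For each
    eligible site with depth d a background count is drawn from
    Binomial(d, 0.5) and scored identically; foreground-greater is
    tested one-sided.
    """
    depth = (observations["n_allele1"] + observations["n_allele2"]).to_numpy()
    eligible = observations[depth >= min_depth]
    n_excluded = int((depth < min_depth).sum())
    if len(eligible) == 0:
        raise ValueError("no sites meet the depth requirement")
    fg = np.array([imbalance_score(a, b) for a, b in
                   zip(eligible["n_allele1"], eligible["n_allele2"])])
    rng = np.random.default_rng(seed)
    d = (eligible["n_allele1"] + eligible["n_allele2"]).to_numpy()
    bg_n1 = rng.binomial(d, 0.5)
    bg = np.array([imbalance_score(a, dd - a) for a, dd in zip(bg_n1, d)])
    res = enrichment_test(fg, bg, "greater", label="allelic_imbalance")
    return res, n_excluded


def chia_support(snp_gene_pairs: pd.DataFrame, links: pd.DataFrame,
                 promoter_halfwidth: int = 2000,
                 anchor_pad: int = 0) -> pd.Series:
    """Number of chromatin-interaction links bridging each SNP and its
    gene's promoter window (TSS +/- promoter_halfwidth), in either
    anchor orientation.

    ``snp_gene_pairs`` needs columns chrom, pos (SNP, 1-based) and tss
    (gene, 1-based).
    """
    support = np.zeros(len(snp_gene_pairs), dtype=int)
    for li, link in links.iterrows():
        a = (link["chrom_a"], link["start_a"] - anchor_pad,
             link["end_a"] + anchor_pad)
        b = (link["chrom_b"], link["start_b"] - anchor_pad,
             link["end_b"] + anchor_pad)
        for i, (_, pair) in enumerate(snp_gene_pairs.iterrows()):
            snp = (pair["chrom"], int(pair["pos"]) - 1)
            tss0 = int(pair["tss"]) - 1
            prom = (pair["chrom"], tss0 - promoter_halfwidth,
                    tss0 + promoter_halfwidth)
            for anchor_snp, anchor_gene in ((a, b), (b, a)):
                snp_in = (anchor_snp[0] == snp[0]
                          and anchor_snp[1] <= snp[1] < anchor_snp[2])
                gene_in = (anchor_gene[0] == prom[0]
                           and anchor_gene[1] < prom[2]
                           and anchor_gene[2] > prom[1])
                if snp_in and gene_in:
                    support[i] += 1
                    break
    return pd.Series(support, index=snp_gene_pairs.index)


def matched_background_pairs(fg_pairs: pd.DataFrame,
                             candidate_pairs: pd.DataFrame,
                             seed: int,
                             tolerance: float = 0.10
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distance-matched background: for each foreground SNP-gene pair
    with distance D, sample (without replacement) one candidate pair
    whose distance lies within +/- tolerance * D.

    Both inputs need a ``distance`` column.  Foreground pairs with no
    eligible candidate are dropped from both sets (logged); if more than
    half are unmatched an error is raised.
    Returns (matched foreground, background) with aligned row order.
    """
    rng = np.random.default_rng(seed)
    cand_dist = candidate_pairs["distance"].to_numpy(dtype=float)
    available = np.ones(len(candidate_pairs), dtype=bool)
    fg_rows, bg_rows = [], []
    n_unmatched = 0
    order = rng.permutation(len(fg_pairs))  # avoid positional bias
    for i in order:
        D = float(fg_pairs["distance"].iloc[i])
        lo, hi = (1 - tolerance) * D, (1 + tolerance) * D
        ok = np.nonzero(available & (cand_dist >= lo) & (cand_dist <= hi))[0]
        if len(ok) == 0:
            n_unmatched += 1
            continue
        pick = int(rng.choice(ok))
        available[pick] = False
        fg_rows.append(i)
        bg_rows.append(pick)
    if n_unmatched:
        logger.info("dropped %d foreground pairs without a distance match",
                    n_unmatched)
    if n_unmatched > 0.5 * len(fg_pairs):
        raise ValueError(
            f"{n_unmatched}/{len(fg_pairs)} foreground pairs unmatched; "
            "supply a larger candidate pool")
    return (fg_pairs.iloc[fg_rows].reset_index(drop=True),
            candidate_pairs.iloc[bg_rows].reset_index(drop=True))


def nearest_snp_distance(query_snps: pd.DataFrame,
                         reference_snps: pd.DataFrame) -> pd.Series:
    """Distance (bp) from each query SNP to the closest reference SNP on
    the same chromosome; +inf when the chromosome has no reference SNP.

    Both inputs need chrom and pos columns.
    """
    if len(reference_snps) == 0:
        raise ValueError("reference SNP set is empty")
    by_chrom = {c: np.sort(g["pos"].to_numpy(dtype=float))
                for c, g in reference_snps.groupby("chrom")}
    out = np.full(len(query_snps), np.inf)
    for i, (_, rec) in enumerate(query_snps.iterrows()):
        ref = by_chrom.get(rec["chrom"])
        if ref is None:
            continue
        pos = float(rec["pos"])
        j = np.searchsorted(ref, pos)
        best = np.inf
        if j < len(ref):
            best = min(best, abs(ref[j] - pos))
        if j > 0:
            best = min(best, abs(ref[j - 1] - pos))
        out[i] = best
    return pd.Series(out, index=query_snps.index)


def compare_distance_distributions(fg_dists, control_dists,
                                   direction: str = "less",
                                   label: str = "distance"
                                   ) -> EnrichmentResult:
    """One-sided rank-sum comparison of two distance (or score)
    distributions; default tests foreground stochastically smaller
    (closer).  Infinite values are excluded (logged)."""
    fg = np.asarray(fg_dists, dtype=float)
    ctrl = np.asarray(control_dists, dtype=float)
    n_inf = int(np.isinf(fg).sum() + np.isinf(ctrl).sum())
    if n_inf:
        logger.info("excluded %d infinite distances from the rank test",
                    n_inf)
    return enrichment_test(fg[np.isfinite(fg)], ctrl[np.isfinite(ctrl)],
                           direction, label=label)


def derived_allele_frequency(table: pd.DataFrame) -> pd.Series:
    """Derived allele frequency per SNP.

    ``table`` needs columns ref, alt, ancestral, alt_freq.  DAF is the
    alt frequency when the alt allele is derived (ancestral == ref) and
    1 - alt frequency when the ref allele is derived (ancestral == alt);
    sites whose ancestral allele matches neither are excluded.
    """
    anc = table["ancestral"].astype(str).str.upper()
    ref = table["ref"].astype(str).str.upper()
    alt = table["alt"].astype(str).str.upper()
    daf = pd.Series(np.nan, index=table.index)
    daf[anc == ref] = table.loc[anc == ref, "alt_freq"]
    daf[anc == alt] = 1.0 - table.loc[anc == alt, "alt_freq"]
    n_unknown = int(daf.isna().sum())
    if n_unknown:
        logger.info("excluded %d SNPs with unknown ancestral allele",
                    n_unknown)
    return daf.dropna()
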