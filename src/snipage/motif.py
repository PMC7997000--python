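"""Allele-specific binding-site prediction from position weight matrices.

For each biallelic SNV we build the two allelic sequences over a
+/- ``flank`` bp window (101 bp by default), scan both strands of each
sequence with every age-associated TF's PWM using additive log-odds
scores against a uniform background, and call putative allele-specific
binding (ASB) when a hit covering the SNP position passes the score
threshold on exactly one of the two alleles.  The per-motif threshold is
set at a motif-match p-value under the i.i.d. uniform background,
computed exactly by dynamic programming over the discretized score
distribution.  Calls are finally restricted to SNPs inside open
chromatin (DNase peak intervals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from snipage.core_io import (IntervalSet, PWMRecord, fetch_sequence,
                             reverse_complement)

logger = logging.getLogger(__name__)

__all__ = [
    "AllelePair", "MotifHit", "ASBCall", "log_odds_matrix",
    "score_threshold", "scan_sequence", "make_allelic_sequences",
    "call_asb", "call_asb_table", "filter_open_chromatin",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

SCAN_PSEUDOCOUNT = 0.01   # added per cell before log-odds; avoids -inf
DEFAULT_MOTIF_PVALUE = 1e-4


@dataclass
class AllelePair:
    """The two allelic sequences around a SNP; they differ at exactly the
    center index (= flank)."""

    snp_id: str
    chromosome: str
    center_position: int        # 1-based
    seq_ref: str
    seq_alt: str

    def __post_init__(self):
        if len(self.seq_ref) != len(self.seq_alt):
            raise ValueError("allelic sequences must have equal length")
        diff = [i for i, (a, b) in enumerate(zip(self.seq_ref, self.seq_alt))
                if a != b]
        if diff != [len(self.seq_ref) // 2]:
            raise ValueError("allelic sequences must differ exactly at the "
                             "center position")

    @property
    def flank(self) -> int:
        return len(self.seq_ref) // 2


@dataclass
class MotifHit:
    start: int                  # 0-based offset within the scanned sequence
    strand: str                 # '+' or '-'
    score: float

    def covers(self, index: int, length: int) -> bool:
        return self.start <= index < self.start + length


@dataclass
class ASBCall:
    tf_name: str
    snp_id: str
    binding_allele: str         # 'ref' or 'alt'
    best_score_binding: float
    best_score_nonbinding: float    # -inf when the other allele has no hit
    n_hits_ref: int
    n_hits_alt: int


def log_odds_matrix(pwm: PWMRecord, background: float = 0.25,
                    pseudocount: float = SCAN_PSEUDOCOUNT) -> np.ndarray:
    """L x 4 log2-odds matrix against a uniform background, with a small
    per-cell pseudocount (renormalized) so zero-probability cells stay
    finite."""
    p = (pwm.probs + pseudocount)
    p = p / p.sum(axis=1, keepdims=True)
    return np.log2(p / background)


def score_threshold(pwm: PWMRecord, pvalue: float = DEFAULT_MOTIF_PVALUE,
                    granularity: float = 1e-3) -> float:
    """Smallest score t such that P(score >= t) <= pvalue for a random
    i.i.d. uniform sequence, computed exactly by DP over the discretized
    per-position score distribution."""
    lom = log_odds_matrix(pwm)
    scaled = np.round(lom / granularity).astype(np.int64)
    dist: dict[int, float] = {0: 1.0}
    for i in range(scaled.shape[0]):
        new: dict[int, float] = {}
        for s, prob in dist.items():
            for b in range(4):
                key = s + scaled[i, b]
                new[key] = new.get(key, 0.0) + prob * 0.25
        dist = new
    scores = np.array(sorted(dist, reverse=True))
    probs = np.array([dist[s] for s in scores])
    tail = np.cumsum(probs)
    ok = np.nonzero(tail <= pvalue)[0]
    if len(ok) == 0:
        # even the maximal score is more probable than pvalue; require it
        return float(scores[0] * granularity)
    return float(scores[ok[-1]] * granularity)


def _encode(sequence: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(c, -1) for c in sequence.upper()],
                    dtype=np.int64)


def scan_sequence(pwm: PWMRecord, sequence: str,
                  threshold: float) -> list[MotifHit]:
    """All motif hits (score >= threshold) on both strands.

    Offsets are 0-based starts of the motif window in ``sequence``
    regardless of strand.  Windows overlapping an N are unscoreable
    (score -inf).
    """
    L = pwm.length
    enc = _encode(sequence)
    n = len(enc) - L + 1
    if n <= 0:
        return []
    lom = log_odds_matrix(pwm)
    # reverse-complement scoring matrix: position i sees the complement
    # of the base at forward position (L-1-i) of the window
    lom_rc = lom[::-1, ::-1]
    hits = []
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    valid = (windows >= 0).all(axis=1)
    idx = np.arange(L)
    for mat, strand in ((lom, "+"), (lom_rc, "-")):
        scores = np.full(n, -np.inf)
        if valid.any():
            scores[valid] = mat[idx, windows[valid]].sum(axis=1)
        for off in np.nonzero(scores >= threshold)[0]:
            hits.append(MotifHit(int(off), strand, float(scores[off])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def make_allelic_sequences(snp_record, genome, flank: int = 50) -> AllelePair | None:
    """Build the ref/alt sequences around a SNP (window 2*flank + 1).

    ``snp_record`` needs fields chrom, pos (1-based), ref, alt and a
    ``name`` (snp id).  Returns None (with a log message) when the flank
    would run off the chromosome; raises if the genome base disagrees
    with the VCF ref allele.
    """
    chrom, pos = snp_record["chrom"], int(snp_record["pos"])
    snp_id = snp_record.name if hasattr(snp_record, "name") else \
        snp_record.get("snp_id", f"{chrom}:{pos}")
    start0 = pos - 1 - flank
    end0 = pos + flank
    try:
        chrom_len = len(genome[chrom])
    except KeyError:
        raise ValueError(f"chromosome {chrom} not in genome")
    if start0 < 0 or end0 > chrom_len:
        logger.warning("SNP %s: flank %d truncated by chromosome bounds; "
                       "skipped", snp_id, flank)
        return None
    seq = fetch_sequence(genome, chrom, start0, end0)
    ref, alt = snp_record["ref"].upper(), snp_record["alt"].upper()
    if seq[flank] != ref:
        raise ValueError(
            f"SNP {snp_id}: genome base {seq[flank]} at {chrom}:{pos} does "
            f"not match VCF ref allele {ref}")
    seq_alt = seq[:flank] + alt + seq[flank + 1:]
    return AllelePair(snp_id, chrom, pos, seq, seq_alt)


def call_asb(pwm: PWMRecord, allele_pair: AllelePair,
             threshold: float) -> ASBCall | None:
    """Emit an ASB call iff hits covering the SNP exist for exactly one
    allele; both-or-neither yields None."""
    L = pwm.length
    center = allele_pair.flank
    per_allele = {}
    for allele, seq in (("ref", allele_pair.seq_ref),
                        ("alt", allele_pair.seq_alt)):
        hits = [h for h in scan_sequence(pwm, seq, threshold)
                if h.covers(center, L)]
        per_allele[allele] = hits
    has_ref, has_alt = bool(per_allele["ref"]), bool(per_allele["alt"])
    if has_ref == has_alt:
        return None
    binding = "ref" if has_ref else "alt"
    other = "alt" if has_ref else "ref"
    best = max(h.score for h in per_allele[binding])
    other_hits = per_allele[other]
    best_other = max((h.score for h in other_hits), default=-np.inf)
    return ASBCall(pwm.tf_name, allele_pair.snp_id, binding, best,
                   best_other, len(per_allele["ref"]), len(per_allele["alt"]))


def call_asb_table(pwms, snps: pd.DataFrame, genome, flank: int = 50,
                   motif_pvalue: float = DEFAULT_MOTIF_PVALUE) -> pd.DataFrame:
    """Scan every (PWM, SNP) combination and return the ASB calls as a
    table with SNP coordinates attached.

    ``snps``: DataFrame indexed by snp_id with chrom, pos, ref, alt.
    """
    thresholds = {pwm.tf_name: score_threshold(pwm, motif_pvalue)
                  for pwm in pwms}
    pairs = {}
    for snp_id, rec in snps.iterrows():
        pair = make_allelic_sequences(rec, genome, flank)
        if pair is not None:
            pairs[snp_id] = pair
    rows = []
    for pwm in pwms:
        thr = thresholds[pwm.tf_name]
        for snp_id, pair in pairs.items():
            call = call_asb(pwm, pair, thr)
            if call is not None:
                rec = snps.loc[snp_id]
                rows.append((call.tf_name, call.snp_id, rec["chrom"],
                             int(rec["pos"]), call.binding_allele,
                             call.best_score_binding,
                             call.best_score_nonbinding,
                             call.n_hits_ref, call.n_hits_alt))
    return pd.DataFrame(rows, columns=[
        "tf", "snp", "chrom", "pos", "binding_allele",
        "best_score_binding", "best_score_nonbinding",
        "n_hits_ref", "n_hits_alt"])


def filter_open_chromatin(asb_calls: pd.DataFrame,
                          dhs: IntervalSet) -> pd.DataFrame:
    """Keep calls whose SNP (1-based position p, 0-based p-1) lies inside
    an open-chromatin interval."""
    if len(asb_calls) == 0:
        return asb_calls
    keep = [dhs.contains(row["chrom"], int(row["pos"]) - 1)
            for _, row in asb_calls.iterrows()]
    return asb_calls[np.array(keep, dtype=bool)].reset_index(drop=True)
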