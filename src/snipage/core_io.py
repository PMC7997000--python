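"""Shared data model and readers/writers for the standard formats.

The pipeline consumes a cohort (expression matrix, per-sample covariates,
genotypes), a genome, TF binding motifs, peak/interval files, per-base
signal tracks and paired-anchor chromatin-interaction links.  Everything
here is plumbing: parse, validate, and keep the three cohort components
aligned on one ordered list of sample identifiers.

Coordinate conventions: BED/bedGraph intervals are 0-based half-open;
VCF and gene TSS positions are 1-based.  A SNP at 1-based position ``p``
occupies the 0-based interval ``[p-1, p)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import motifs as bio_motifs

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.17g"  # round-trips IEEE doubles exactly

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

class CovariateTable:
    """Per-sample covariates with role-tagged columns.

    Roles are inferred from column names: ``age`` and ``sex`` (case
    insensitive), genotype-derived principal components (prefix
    ``SNP_PC``), latent expression factors (prefix ``PEER``); anything
    else is kept as an optional extra covariate (off by default in
    model designs).
    """

    def __init__(self, df: pd.DataFrame, n_snp_pcs: int = 3):
        if df.columns.duplicated().any():
            raise ValueError("duplicate covariate column names")
        lower = {c.lower(): c for c in df.columns}
        if "age" not in lower or "sex" not in lower:
            raise ValueError("covariate table must contain 'age' and 'sex' columns")
        self._df = df.copy()
        self.age_col = lower["age"]
        self.sex_col = lower["sex"]
        self.snp_pc_cols = [c for c in df.columns
                            if c.lower().startswith("snp_pc")]
        self.peer_cols = [c for c in df.columns if c.lower().startswith("peer")]
        known = {self.age_col, self.sex_col, *self.snp_pc_cols, *self.peer_cols}
        self.extra_cols = [c for c in df.columns if c not in known]
        if len(self.snp_pc_cols) != n_snp_pcs:
            warnings.warn(
                f"expected {n_snp_pcs} SNP principal components, found "
                f"{len(self.snp_pc_cols)}", stacklevel=2)
        if df[self.age_col].isna().any() or df[self.sex_col].isna().any():
            raise ValueError("missing values in age/sex are not allowed")

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def age(self) -> pd.Series:
        return self._df[self.age_col]

    @property
    def sex(self) -> pd.Series:
        return self._df[self.sex_col]

    @property
    def snp_pcs(self) -> pd.DataFrame:
        return self._df[self.snp_pc_cols]

    @property
    def peer_factors(self) -> pd.DataFrame:
        return self._df[self.peer_cols]

    def design(self, peer_subset: Sequence[str] | None = None,
               include_extras: bool = False) -> pd.DataFrame:
        """Covariate design block: age, sex, SNP PCs, (retained) PEER factors."""
        peers = self.peer_cols if peer_subset is None else list(peer_subset)
        cols = [self.age_col, self.sex_col, *self.snp_pc_cols, *peers]
        if include_extras:
            cols += self.extra_cols
        return self._df[cols]

    def subset(self, sample_ids: Sequence[str]) -> "CovariateTable":
        out = CovariateTable.__new__(CovariateTable)
        out._df = self._df.loc[list(sample_ids)]
        for attr in ("age_col", "sex_col", "snp_pc_cols", "peer_cols",
                     "extra_cols"):
            setattr(out, attr, getattr(self, attr))
        return out


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Biallelic SNVs with alt-allele dosage per sample.

    ``snps``: index snp_id, columns chrom, pos (1-based), ref, alt.
    ``dosages``: SNPs x samples, values in {0, 1, 2} or NaN for missing.
    """

    snps: pd.DataFrame
    dosages: pd.DataFrame

    def __post_init__(self):
        if not self.snps.index.equals(self.dosages.index):
            raise ValueError("snps and dosages must share index")
        if (self.snps["ref"] == self.snps["alt"]).any():
            raise ValueError("ref and alt alleles must differ")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def dosage(self, snp_id: str) -> pd.Series:
        return self.dosages.loc[snp_id]

    def subset(self, sample_ids: Sequence[str]) -> "GenotypeTable":
        return GenotypeTable(self.snps, self.dosages[list(sample_ids)])


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    """Expression matrix, covariates and genotypes on one sample order."""

    expression: pd.DataFrame          # genes x samples
    covariates: CovariateTable
    genotypes: GenotypeTable

    def __post_init__(self):
        sids = list(self.expression.columns)
        if self.covariates.sample_ids != sids or \
                self.genotypes.sample_ids != sids:
            raise ValueError("expression, covariates and genotypes must share "
                             "the same ordered sample ids")
        if self.expression.index.duplicated().any():
            raise ValueError("gene identifiers must be unique")
        if self.expression.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CohortData":
        ids = list(sample_ids)
        return CohortData(self.expression[ids],
                          self.covariates.subset(ids),
                          self.genotypes.subset(ids))


def read_vcf_genotypes(vcf_path: str) -> GenotypeTable:
    """Read biallelic SNVs from a VCF; multi-allelic and indel records are
    dropped (count logged)."""
    vf = pysam.VariantFile(vcf_path)
    samples = list(vf.header.samples)
    rows, dosage_rows, ids = [], [], []
    n_dropped = 0
    for i, rec in enumerate(vf):
        try:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1 \
                    or rec.ref.upper() not in "ACGT" \
                    or alts[0].upper() not in "ACGT":
                n_dropped += 1
                continue
            snp_id = rec.id or f"{rec.chrom}_{rec.pos}_{rec.ref}_{alts[0]}"
            dos = np.full(len(samples), np.nan)
            for j, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    continue
                dos[j] = sum(1 for a in gt if a == 1)
            rows.append((rec.chrom, rec.pos, rec.ref.upper(), alts[0].upper()))
            dosage_rows.append(dos)
            ids.append(snp_id)
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed VCF record #{i + 1} in {vcf_path}: {exc}")
    if n_dropped:
        logger.info("dropped %d non-SNV/multi-allelic VCF records", n_dropped)
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"],
                        index=pd.Index(ids, name="snp_id"))
    dosages = pd.DataFrame(np.array(dosage_rows).reshape(len(ids), len(samples)),
                           index=snps.index, columns=samples)
    return GenotypeTable(snps, dosages)


def read_cohort(expression_path: str, covariates_path: str,
                vcf_path: str, n_snp_pcs: int = 3,
                log2_transform: bool = False) -> CohortData:
    """Load a cohort and align the three components on the intersection of
    sample ids (sorted for determinism).

    ``log2_transform`` applies log2(x + 1) when the expression input is on
    a linear scale; by default expression is taken as given.
    """
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    cov = pd.read_csv(covariates_path, sep="\t", index_col=0)
    cov.index = cov.index.astype(str)
    expr.columns = expr.columns.astype(str)
    geno = read_vcf_genotypes(vcf_path)
    shared = sorted(set(expr.columns) & set(cov.index) & set(geno.sample_ids))
    if not shared:
        raise ValueError("no samples shared between expression, covariates "
                         "and VCF")
    expr = expr[shared].dropna(axis=0)
    if log2_transform:
        expr = np.log2(expr + 1.0)
    return CohortData(expr, CovariateTable(cov.loc[shared], n_snp_pcs),
                      geno.subset(shared))


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

@dataclass
class PWMRecord:
    """Position weight matrix: per-position base probabilities over ACGT."""

    tf_name: str
    probs: np.ndarray           # L x 4, rows sum to 1
    pseudocount: float = 1.0

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be L x 4")
        if self.probs.shape[0] < 4:
            raise ValueError(f"motif {self.tf_name}: width < 4")
        if (self.probs < 0).any():
            raise ValueError(f"motif {self.tf_name}: negative entries")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"motif {self.tf_name}: rows must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]


def read_pwms(path: str, pseudocount: float = 1.0) -> list[PWMRecord]:
    """Read JASPAR-style motifs.

    Count matrices get ``pseudocount`` added per cell before row
    normalization; matrices whose rows already sum to 1 are treated as
    probabilities and returned unchanged.
    """
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    records = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float).T
        row_sums = counts.sum(axis=1)
        if (row_sums == 0).any():
            raise ValueError(f"motif {m.name}: position with all-zero counts")
        name = m.name or m.matrix_id
        if np.allclose(row_sums, 1.0, atol=1e-3):
            probs = counts / row_sums[:, None]
            records.append(PWMRecord(name, probs, pseudocount=0.0))
        else:
            probs = (counts + pseudocount) / (row_sums + 4 * pseudocount)[:, None]
            records.append(PWMRecord(name, probs, pseudocount=pseudocount))
    return records


def write_pwms(records: Iterable[PWMRecord], path: str) -> None:
    """Write probability-format JASPAR matrices (row sums 1)."""
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            fh.write(f">M{i:04d} {rec.tf_name}\n")
            for bi, base in enumerate("ACGT"):
                vals = " ".join(FLOAT_FORMAT % v for v in rec.probs[:, bi])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# intervals & tracks
# ---------------------------------------------------------------------------

class IntervalSet:
    """Genomic intervals in 0-based half-open coordinates, sorted per
    chromosome; supports point containment with possibly overlapping
    intervals."""

    def __init__(self, intervals: Iterable[tuple]):
        per_chrom: dict[str, list] = {}
        self.intervals: list[tuple] = []
        for iv in intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            score = float(iv[3]) if len(iv) > 3 and iv[3] is not None else None
            if start >= end:
                raise ValueError(f"interval start >= end: {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end, score))
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted(per_chrom):
            ivs = sorted(per_chrom[chrom])
            self.intervals.extend((chrom, s, e, sc) for s, e, sc in ivs)
            starts = np.array([s for s, _, _ in ivs])
            ends = np.maximum.accumulate([e for _, e, _ in ivs])
            self._index[chrom] = (starts, np.array(ends))

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: str, pos0: int) -> bool:
        """True if 0-based position pos0 lies inside any interval."""
        if chrom not in self._index:
            return False
        starts, cummax_ends = self._index[chrom]
        i = np.searchsorted(starts, pos0, side="right") - 1
        return i >= 0 and cummax_ends[i] > pos0

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) overlaps any interval."""
        if chrom not in self._index:
            return False
        starts, cummax_ends = self._index[chrom]
        i = np.searchsorted(starts, end, side="left") - 1
        return i >= 0 and cummax_ends[i] > start


class SignalTrack:
    """Per-base signal as non-overlapping runs (bedGraph semantics);
    uncovered positions have value 0."""

    def __init__(self, runs: Iterable[tuple]):
        per_chrom: dict[str, list] = {}
        for chrom, start, end, value in runs:
            start, end, value = int(start), int(end), float(value)
            if start >= end:
                raise ValueError(f"run start >= end: {chrom}:{start}-{end}")
            if not np.isfinite(value):
                raise ValueError("non-finite signal value")
            per_chrom.setdefault(chrom, []).append((start, end, value))
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            starts = np.array([s for s, _, _ in ivs])
            ends = np.array([e for _, e, _ in ivs])
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping bedGraph runs on {chrom}")
            self._runs[chrom] = (starts, ends,
                                 np.array([v for _, _, v in ivs]))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def value_at(self, chrom: str, pos0: int) -> float:
        if chrom not in self._runs:
            return 0.0
        starts, ends, values = self._runs[chrom]
        i = np.searchsorted(starts, pos0, side="right") - 1
        if i >= 0 and ends[i] > pos0:
            return float(values[i])
        return 0.0

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base values over [start, end), zero-filled."""
        if chrom not in self._runs or end <= start:
            return 0.0
        starts, ends, values = self._runs[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return 0.0
        ov = (np.minimum(ends[lo:hi], end)
              - np.maximum(starts[lo:hi], start)).clip(min=0)
        return float(np.dot(ov, values[lo:hi]))


def read_bed(path: str) -> IntervalSet:
    """Read BED3+ (whitespace-delimited); score taken from column 5 when
    present (BED6 convention)."""
    ivs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 columns")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            score = float(f[4]) if len(f) >= 5 else None
            ivs.append((f[0], start, end, score))
    return IntervalSet(ivs)


def read_bedgraph(path: str) -> SignalTrack:
    runs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            if len(f) < 4:
                raise ValueError(f"{path}:{ln}: bedGraph needs 4 columns")
            if int(f[1]) >= int(f[2]):
                raise ValueError(f"{path}:{ln}: start >= end")
            runs.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    return SignalTrack(runs)


def read_chia_links(path: str) -> pd.DataFrame:
    """Read paired-anchor links: chromA startA endA chromB startB endB
    [count]."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: paired-anchor BED needs >= 6 "
                                 "columns")
            count = int(f[6]) if len(f) >= 7 else 1
            rows.append((f[0], int(f[1]), int(f[2]),
                         f[3], int(f[4]), int(f[5]), count))
    return pd.DataFrame(rows, columns=["chrom_a", "start_a", "end_a",
                                       "chrom_b", "start_b", "end_b", "count"])


# ---------------------------------------------------------------------------
# genome access & table round-trips
# ---------------------------------------------------------------------------

def fetch_sequence(genome, chrom: str, start0: int, end0: int) -> str:
    """Fetch [start0, end0) from a dict of strings or a pyfaidx.Fasta."""
    if isinstance(genome, Mapping):
        return genome[chrom][start0:end0].upper()
    return str(genome[chrom][start0:end0]).upper()


def write_table(df: pd.DataFrame, path: str, index: bool = True) -> None:
    """Write a TSV that round-trips floats exactly."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path: str, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col,
                       float_precision="round_trip")
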