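"""Self-contained synthetic fixtures with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
a cohort with age-trending TF expression, Hardy-Weinberg genotypes, and
planted SNP x TF interaction effects on target genes, together with the
sequence-level mechanism (a genome into which each planted TF's motif
consensus is written around its SNP so that the motif matches exactly
the binding allele), open-chromatin peaks, a signal track, chromatin-
interaction links, allele read counts and a binary phenotype.

The generative model per sample j:

    TF_tj   = a_t + b_age*AGE_j [age TFs only] + b_sex*SEX_j
              + PC and latent-factor terms + N(0, tf_noise_sd)
    gene_gj = a_g + b_snp*d_sj + b_int*d_sj*TF~_tj + b_sex*SEX_j
              + small PC/latent terms + N(0, noise_sd)   [planted]

where d_sj is the binding-allele dosage and TF~ is the TF's true age
component plus residual.  Planted genes carry no TF main effect, so the
TF-gene correlation appears only in samples carrying the binding
allele - the mechanism the consistency filter looks for.  Unplanted
genes are independent of all SNPs and TFs.  Regenerating a bundle with
the same configuration is byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from snipage.core_io import (CohortData, CovariateTable, GenotypeTable,
                             IntervalSet, PWMRecord, SignalTrack,
                             FLOAT_FORMAT, write_pwms, write_table)

__all__ = ["SimulationConfig", "FixtureBundle", "simulate_cohort",
           "simulate_allele_counts", "simulate_phenotype", "preset"]

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """All ground-truth parameters of a synthetic cohort."""

    seed: int = 0
    n_samples: int = 400
    age_range: tuple = (20.0, 70.0)
    age_binned: bool = False        # emit decadal-bin midpoints
    sex_ratio: float = 0.5
    n_snp_pcs: int = 3
    n_peer: int = 5
    n_peer_age_correlated: int = 2

    n_tfs: int = 40                 # TF panel size
    n_age_tfs: int = 12             # TFs with a true age slope
    beta_age: float = 0.05          # age slope (log-units per year)
    tf_noise_sd: float = 1.0

    n_target_genes: int = 60
    n_planted: int = 30             # true TF-SNP-gene triplets
    n_decoy_asb: int = 20           # single-allele motif, no gene effect
    n_both_allele: int = 5          # degenerate motifs hitting both alleles
    beta_interaction: float = 1.0
    beta_snp: float = 0.3
    noise_sd: float = 0.5           # target-gene noise (planted and null)
    maf_range: tuple = (0.25, 0.5)
    missing_rate: float = 0.01

    chrom: str = "chr1"
    chrom_length: int = 400_000
    snp_start: int = 100_000
    snp_spacing: int = 2_000
    motif_length: int = 9
    dhs_halfwidth: int = 100
    dhs_decoy_fraction: float = 0.9
    phenotype_effect: float = 0.8

    @property
    def n_snps(self) -> int:
        return self.n_planted + self.n_decoy_asb + self.n_both_allele

    def validate(self) -> None:
        if self.n_planted > min(self.n_target_genes,
                                self.n_planted + self.n_decoy_asb):
            raise ValueError("more planted triplets than available "
                             "SNP-gene pairs")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("MAF range must lie in (0, 0.5]")
        if self.n_age_tfs > self.n_tfs:
            raise ValueError("n_age_tfs exceeds the TF panel size")
        end = self.snp_start + self.n_snps * self.snp_spacing
        if end + 1000 > self.chrom_length:
            raise ValueError("chromosome too short for the SNP layout")


def preset(name: str, **overrides) -> SimulationConfig:
    """Named configurations: 'strong'/'default' (planted effects well
    above noise) and 'null' (no interaction effects)."""
    cfg = SimulationConfig()
    if name in ("default", "strong"):
        pass
    elif name == "null":
        cfg = replace(cfg, beta_interaction=0.0)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return replace(cfg, **overrides)


@dataclass
class FixtureBundle:
    """In-memory fixture plus writers for the on-disk formats."""

    config: SimulationConfig
    cohort: CohortData
    genome: dict
    pwms: list
    dhs: IntervalSet
    annotations: pd.DataFrame       # gene_id -> chrom, tss, strand
    truth: pd.DataFrame             # planted triplets
    signal_runs: list = field(default_factory=list)
    links: pd.DataFrame | None = None
    allele_counts: pd.DataFrame | None = None
    phenotype: pd.Series | None = None
    tf_panel: list = field(default_factory=list)

    @property
    def signal(self) -> SignalTrack:
        return SignalTrack(self.signal_runs)

    def write(self, outdir: str) -> dict:
        """Write every component in its standard format; deterministic
        byte-for-byte given the configuration."""
        os.makedirs(outdir, exist_ok=True)
        paths = {}

        def p(name):
            paths[name.split(".")[0]] = os.path.join(outdir, name)
            return paths[name.split(".")[0]]

        write_table(self.cohort.expression.rename_axis("gene_id"),
                    p("expression.tsv"))
        write_table(self.cohort.covariates.df.rename_axis("sample_id"),
                    p("covariates.tsv"))
        _write_vcf(self.cohort.genotypes, p("genotypes.vcf"),
                   {self.config.chrom: self.config.chrom_length})
        with open(p("genome.fa"), "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        write_pwms(self.pwms, p("motifs.jaspar"))
        with open(p("dhs.bed"), "w") as fh:
            for chrom, start, end, _ in self.dhs.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\n")
        with open(p("signal.bedgraph"), "w") as fh:
            for chrom, start, end, value in self.signal_runs:
                fh.write(f"{chrom}\t{start}\t{end}\t{FLOAT_FORMAT % value}\n")
        if self.links is not None:
            with open(p("links.bedpe"), "w") as fh:
                for _, r in self.links.iterrows():
                    fh.write(f"{r.chrom_a}\t{r.start_a}\t{r.end_a}\t"
                             f"{r.chrom_b}\t{r.start_b}\t{r.end_b}\t"
                             f"{r['count']}\n")
        if self.allele_counts is not None:
            write_table(self.allele_counts.rename_axis("site_id"),
                        p("allele_counts.tsv"))
        if self.phenotype is not None:
            write_table(self.phenotype.rename("status")
                        .rename_axis("sample_id").to_frame(),
                        p("phenotype.tsv"))
        write_table(self.annotations.rename_axis("gene_id"), p("genes.tsv"))
        write_table(self.truth, p("truth.tsv"), index=False)
        with open(p("tf_panel.txt"), "w") as fh:
            fh.write("\n".join(self.tf_panel) + "\n")
        return paths


def _write_vcf(genotypes: GenotypeTable, path: str, contigs: dict) -> None:
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        samples = genotypes.sample_ids
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for snp_id, rec in genotypes.snps.iterrows():
            dos = genotypes.dosages.loc[snp_id]
            gts = "\t".join(gt_map.get(d, "./.") if np.isfinite(d) else "./."
                            for d in dos)
            fh.write(f"{rec.chrom}\t{rec.pos}\t{snp_id}\t{rec.ref}\t"
                     f"{rec.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def _consensus_pwm(name: str, consensus: str, major: float = 0.94,
                   degenerate_center: tuple | None = None) -> PWMRecord:
    """PWM concentrated on a consensus; optionally the center column
    splits its mass between two bases (degenerate, matching both
    alleles)."""
    L = len(consensus)
    minor = (1.0 - major) / 3.0
    probs = np.full((L, 4), minor)
    for i, base in enumerate(consensus):
        probs[i, _BASES.index(base)] = major
    if degenerate_center is not None:
        c = L // 2
        b1, b2 = degenerate_center
        probs[c, :] = (1.0 - major) / 2.0
        probs[c, _BASES.index(b1)] = major / 2.0
        probs[c, _BASES.index(b2)] = major / 2.0
    return PWMRecord(name, probs / probs.sum(axis=1, keepdims=True),
                     pseudocount=0.0)


def simulate_cohort(config: SimulationConfig) -> FixtureBundle:
    """Generate a complete fixture bundle from the configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # --- covariates ------------------------------------------------------
    age = rng.uniform(*config.age_range, size=n)
    if config.age_binned:
        age = np.floor(age / 10.0) * 10.0 + 5.0
    sex = (rng.random(n) < config.sex_ratio).astype(float)
    snp_pcs = rng.normal(size=(n, config.n_snp_pcs))
    age_z = (age - age.mean()) / age.std()
    peers = rng.normal(size=(n, config.n_peer))
    for k in range(min(config.n_peer_age_correlated, config.n_peer)):
        peers[:, k] = age_z + 0.5 * rng.normal(size=n)
    cov = pd.DataFrame({"age": age, "sex": sex}, index=sample_ids)
    for l in range(config.n_snp_pcs):
        cov[f"SNP_PC{l + 1}"] = snp_pcs[:, l]
    for k in range(config.n_peer):
        cov[f"PEER{k + 1}"] = peers[:, k]

    # --- genotypes -------------------------------------------------------
    snp_ids = [f"rs{i + 1:05d}" for i in range(config.n_snps)]
    positions = config.snp_start + config.snp_spacing * np.arange(
        config.n_snps)
    mafs = rng.uniform(*config.maf_range, size=config.n_snps)
    alt_dosage = rng.binomial(2, mafs[:, None], size=(config.n_snps, n)
                              ).astype(float)

    # --- genome, motifs, ASB structure -----------------------------------
    genome_arr = rng.choice(list(_BASES), size=config.chrom_length)
    L = config.motif_length
    center_off = L // 2
    tf_ids = [f"TF{i + 1:03d}" for i in range(config.n_tfs)]
    age_tfs = tf_ids[:config.n_age_tfs]
    consensi: dict[str, str] = {}
    for tf in age_tfs:
        while True:
            cons = "".join(rng.choice(list(_BASES), size=L))
            if cons not in consensi.values():
                break
        consensi[tf] = cons

    n_single = config.n_planted + config.n_decoy_asb
    asb_pairs = []          # (tf, snp_index, kind)
    for i in range(n_single):
        kind = "planted" if i < config.n_planted else "decoy"
        asb_pairs.append((age_tfs[i % config.n_age_tfs], i, kind))
    for i in range(config.n_both_allele):
        asb_pairs.append((age_tfs[i % config.n_age_tfs], n_single + i,
                          "both_allele"))

    refs = np.empty(config.n_snps, dtype="U1")
    alts = np.empty(config.n_snps, dtype="U1")
    both_allele_pwms: dict[tuple, PWMRecord] = {}
    for tf, si, kind in asb_pairs:
        cons = consensi[tf]
        pos0 = positions[si] - 1
        start = pos0 - center_off
        genome_arr[start:start + L] = list(cons)
        alt = cons[center_off]
        ref = rng.choice([b for b in _BASES if b != alt])
        genome_arr[pos0] = ref
        refs[si], alts[si] = ref, alt
        if kind == "both_allele":
            both_allele_pwms[(tf, si)] = _consensus_pwm(
                tf, cons, degenerate_center=(ref, alt))
    # SNPs without a motif context
    for si in range(config.n_snps):
        if refs[si] == "":
            ref = genome_arr[positions[si] - 1]
            alt = rng.choice([b for b in _BASES if b != ref])
            refs[si], alts[si] = ref, alt
    genome = {config.chrom: "".join(genome_arr)}

    pwms = []
    seen = set()
    for tf, si, kind in asb_pairs:
        if tf in seen:
            continue
        seen.add(tf)
        if kind == "both_allele" and (tf, si) in both_allele_pwms:
            pwms.append(both_allele_pwms[(tf, si)])
        else:
            pwms.append(_consensus_pwm(tf, consensi[tf]))

    snps = pd.DataFrame({"chrom": config.chrom, "pos": positions,
                         "ref": refs, "alt": alts},
                        index=pd.Index(snp_ids, name="snp_id"))

    # --- expression ------------------------------------------------------
    gene_ids = [f"G{i + 1:03d}" for i in range(config.n_target_genes)]
    tss = rng.integers(50_000, config.chrom_length - 50_000,
                       size=config.n_target_genes)
    strands = rng.choice(["+", "-"], size=config.n_target_genes)
    annotations = pd.DataFrame({"chrom": config.chrom, "tss": tss,
                                "strand": strands},
                               index=pd.Index(gene_ids, name="gene_id"))

    # expression loads only on the age-uncorrelated latent factors; the
    # age-correlated ones exist in the covariate table to exercise the
    # factor filter without contaminating the planted age truth
    peer_mask = np.ones(config.n_peer)
    peer_mask[:min(config.n_peer_age_correlated, config.n_peer)] = 0.0

    expr = {}
    tf_adjusted_true = {}
    for tf in tf_ids:
        alpha = rng.normal(5.0, 1.0)
        b_sex = rng.normal(0, 0.3)
        g_pc = rng.normal(0, 0.2, size=config.n_snp_pcs)
        d_peer = rng.normal(0, 0.2, size=config.n_peer) * peer_mask
        noise = rng.normal(0, config.tf_noise_sd, size=n)
        b_age = config.beta_age if tf in age_tfs else 0.0
        expr[tf] = (alpha + b_age * age + b_sex * sex + snp_pcs @ g_pc
                    + peers @ d_peer + noise)
        tf_adjusted_true[tf] = b_age * age + noise

    planted = []
    planted_genes = {}
    for i in range(config.n_planted):
        tf, si, _ = asb_pairs[i]
        gene = gene_ids[i]
        planted_genes[gene] = (tf, si)
        planted.append((tf, snp_ids[si], gene, config.beta_interaction,
                        "alt"))
    truth = pd.DataFrame(planted, columns=["tf", "snp", "gene",
                                           "beta_interaction",
                                           "binding_allele"])

    for gi, gene in enumerate(gene_ids):
        alpha = rng.normal(3.0, 1.0)
        b_sex = rng.normal(0, 0.3)
        g_pc = rng.normal(0, 0.2, size=config.n_snp_pcs)
        d_peer = rng.normal(0, 0.2, size=config.n_peer) * peer_mask
        noise = rng.normal(0, config.noise_sd, size=n)
        base = (alpha + b_sex * sex + snp_pcs @ g_pc + peers @ d_peer
                + noise)
        if gene in planted_genes:
            tf, si = planted_genes[gene]
            d = alt_dosage[si]      # binding allele is alt
            base = base + (config.beta_snp * d
                           + config.beta_interaction * d
                           * tf_adjusted_true[tf])
        expr[gene] = base
    expression = pd.DataFrame(expr, index=sample_ids).T
    expression = expression.loc[tf_ids + gene_ids]

    # --- missing genotypes (after expression was planted) ----------------
    miss = rng.random(alt_dosage.shape) < config.missing_rate
    dosages = alt_dosage.copy()
    dosages[miss] = np.nan
    genotypes = GenotypeTable(snps, pd.DataFrame(dosages, index=snps.index,
                                                 columns=sample_ids))
    cohort = CohortData(expression,
                        CovariateTable(cov, config.n_snp_pcs), genotypes)

    # --- DHS peaks -------------------------------------------------------
    ivs = []
    hw = config.dhs_halfwidth
    for tf, si, kind in asb_pairs:
        if kind != "planted" and rng.random() > config.dhs_decoy_fraction:
            continue
        pos0 = positions[si] - 1
        ivs.append((config.chrom, pos0 - hw, pos0 + hw + 1, None))
    dhs = IntervalSet(ivs)

    # --- signal track: elevated accessibility near planted SNPs ----------
    lo = int(positions.min()) - 5_000
    hi = int(positions.max()) + 5_000
    runs = []
    planted_pos0 = {positions[si] - 1 for _, si, k in asb_pairs
                    if k == "planted"}
    for start in range(lo, hi, 100):
        value = abs(rng.normal(1.0, 0.3))
        if any(start - 100 <= p < start + 200 for p in planted_pos0):
            value += 2.0
        runs.append((config.chrom, start, start + 100, value))

    # --- chromatin-interaction links -------------------------------------
    link_rows = []
    for tf, snp_id, gene, _, _ in planted:
        if rng.random() < 0.6:
            pos0 = int(snps.loc[snp_id, "pos"]) - 1
            t0 = int(annotations.loc[gene, "tss"]) - 1
            link_rows.append((config.chrom, pos0 - 500, pos0 + 500,
                              config.chrom, t0 - 500, t0 + 500,
                              int(rng.integers(1, 4))))
    for _ in range(40):
        a = int(rng.integers(lo, hi))
        b = int(rng.integers(lo, hi))
        link_rows.append((config.chrom, a, a + 1000, config.chrom,
                          b, b + 1000, int(rng.integers(1, 3))))
    links = pd.DataFrame(link_rows, columns=["chrom_a", "start_a", "end_a",
                                             "chrom_b", "start_b", "end_b",
                                             "count"])

    allele_counts = simulate_allele_counts(
        200, 30, 0.7, seed=int(rng.integers(0, 2**31)))
    bundle = FixtureBundle(config, cohort, genome, pwms, dhs, annotations,
                           truth, runs, links, allele_counts, None, tf_ids)
    bundle.phenotype = simulate_phenotype(
        bundle, config.phenotype_effect, seed=int(rng.integers(0, 2**31)))
    return bundle


def simulate_phenotype(bundle: FixtureBundle, effect: float,
                       seed: int) -> pd.Series:
    """Binary status driven by age, sex and the planted interaction
    features (standardized mean), with logistic link."""
    rng = np.random.default_rng(seed)
    cohort = bundle.cohort
    cov = cohort.covariates
    age_z = ((cov.age - cov.age.mean()) / cov.age.std()).to_numpy()
    sex = cov.sex.to_numpy()
    feats = []
    for _, row in bundle.truth.iterrows():
        d = cohort.genotypes.dosage(row["snp"]).to_numpy()
        d = np.nan_to_num(d, nan=np.nanmean(d)) if np.isnan(d).any() else d
        tf = cohort.expression.loc[row["tf"]].to_numpy()
        feats.append(d * (tf - tf.mean()))
    if feats:
        F = np.column_stack(feats)
        F = (F - F.mean(axis=0)) / np.where(F.std(axis=0) > 0,
                                            F.std(axis=0), 1.0)
        u = F.mean(axis=1)
        u = u / (u.std() if u.std() > 0 else 1.0)
    else:
        u = np.zeros(cohort.n_samples)
    eta = -0.2 + 0.3 * age_z + 0.2 * sex + effect * u
    status = (rng.random(cohort.n_samples)
              < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.Series(status, index=cohort.sample_ids, name="status")


def simulate_allele_counts(n_sites: int, depth: int, prob: float,
                           seed: int) -> pd.DataFrame:
    """Per-site read counts for the two alleles of heterozygous sites:
    n_allele1 ~ Binomial(depth, prob), n_allele2 = depth - n_allele1."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 < prob <= 1:
        raise ValueError("prob must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n1 = rng.binomial(depth, prob, size=n_sites)
    return pd.DataFrame({"n_allele1": n1, "n_allele2": depth - n1},
                        index=pd.Index([f"site{i:04d}"
                                        for i in range(n_sites)]))
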