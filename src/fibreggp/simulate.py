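"""Synthetic genotype / expression / phenotype generator.

Emulates the data layout of a cotton fibre genomic-prediction study: a
breeding panel of inbred-derived lines genotyped at SNPs placed in and
around annotated genes, a small stage-structured fibre RNA-seq experiment
(three developmental stages, replicated) with planted differentially
expressed genes and planted co-expression modules, and quantitative
phenotypes generated under a linear model with year and experiment random
effects plus additive SNP effects concentrated in a designated causal set.

Every generator is a pure function of its arguments including ``seed``:
fixed inputs give bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("fibreggp")

# Fibre developmental stages in days post-anthesis: primary wall growth,
# transition, and secondary wall deposition.
DEFAULT_STAGES = (7, 16, 25)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeAnnotation:
    """Gene coordinates, 1-based inclusive, non-overlapping per chromosome.

    ``genes`` has columns ``gene_id, chrom, start, end, strand``.
    """

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if (self.genes["start"] > self.genes["end"]).any():
            raise ValueError("gene start must be <= end")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("gene_ids must be unique")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GenotypePanel:
    """Lines x SNPs genotype matrix coded -1/0/1 (AA/AB/BB) with coordinates.

    ``matrix`` keeps integer codes; entries flagged in ``missing`` hold 0 and
    are mean-imputed at model time, not here.
    """

    line_ids: list[str]
    snp_ids: list[str]
    snp_chrom: np.ndarray
    snp_pos: np.ndarray
    matrix: np.ndarray
    missing: np.ndarray
    maf: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, p = self.matrix.shape
        if n != len(self.line_ids) or p != len(self.snp_ids):
            raise ValueError("matrix shape does not match line/snp ids")
        if not np.isin(self.matrix, (-1, 0, 1)).all():
            raise ValueError("genotype codes must be in {-1, 0, 1}")
        if self.missing.shape != self.matrix.shape:
            raise ValueError("missing mask shape mismatch")

    @property
    def n_lines(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]

    def imputed(self) -> np.ndarray:
        """Float matrix with missing entries replaced by their column mean."""
        x = self.matrix.astype(float)
        if self.missing.any():
            x[self.missing] = np.nan
            col_means = np.nanmean(x, axis=0)
            col_means = np.where(np.isfinite(col_means), col_means, 0.0)
            idx = np.where(self.missing)
            x[idx] = col_means[idx[1]]
        return x


@dataclass
class ExpressionMatrix:
    """Genes x samples raw counts with stage / replicate sample labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    stage: np.ndarray        # one stage label per sample
    replicate: np.ndarray    # one replicate label per sample
    counts: np.ndarray       # genes x samples, non-negative integers

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match gene/sample ids")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        stages, reps = np.unique(self.stage, return_counts=True)
        if (reps < 2).any():
            raise ValueError("every stage needs >=2 replicates")

    def samples_for_stage(self, stage) -> np.ndarray:
        return np.flatnonzero(self.stage == stage)


@dataclass
class SimulationTruth:
    """Ground truth recorded by the generators, for recovery tests."""

    # (stage_a, stage_b) -> {gene_id: true log2 fold change (B vs A)}
    de_lfc: dict = field(default_factory=dict)
    module_of: dict = field(default_factory=dict)    # gene_id -> module id
    nucleus_of: dict = field(default_factory=dict)   # module id -> nucleus gene
    causal_snp_ids: list = field(default_factory=list)
    causal_effects: dict = field(default_factory=dict)
    h2: float | None = None
    year_effects: dict = field(default_factory=dict)
    experiment_effects: dict = field(default_factory=dict)

    def de_genes(self, stage_a, stage_b) -> list[str]:
        return sorted(self.de_lfc.get((stage_a, stage_b), {}))


# PhenotypeTable is a plain DataFrame with columns
# (line_id, trait, value, year, experiment); one row per line x trait.
PHENOTYPE_COLUMNS = ("line_id", "trait", "value", "year", "experiment")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_annotation(
    n_genes: int,
    n_chrom: int = 1,
    gene_length_range: tuple[int, int] = (1_000, 5_000),
    gap_range: tuple[int, int] = (500, 10_000),
    seed: int = 0,
) -> GenomeAnnotation:
    """Lay ``n_genes`` non-overlapping genes left-to-right over chromosomes.

    Genes are assigned to chromosomes round-robin; on each chromosome the
    first gene starts at position 1 and successive genes are separated by a
    gap drawn uniformly from ``gap_range``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    lo_len, hi_len = gene_length_range
    lo_gap, hi_gap = gap_range
    if lo_len <= 0 or hi_len < lo_len:
        raise ValueError("gene_length_range must be positive and ordered")
    if lo_gap < 0 or hi_gap < lo_gap:
        raise ValueError("gap_range must be non-negative and ordered")

    rng = np.random.default_rng(seed)
    chrom_of = [g % n_chrom for g in range(n_genes)]
    cursor = {c: 1 for c in range(n_chrom)}
    records = []
    for g in range(n_genes):
        c = chrom_of[g]
        length = int(rng.integers(lo_len, hi_len + 1))
        start = cursor[c]
        end = start + length - 1
        gap = int(rng.integers(lo_gap, hi_gap + 1))
        cursor[c] = end + 1 + gap
        strand = "+" if rng.random() < 0.5 else "-"
        records.append((f"G{g + 1:05d}", f"chr{c + 1}", start, end, strand))
    genes = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "strand"])
    genes = genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return GenomeAnnotation(genes)


def simulate_genotypes(
    annotation: GenomeAnnotation,
    n_lines: int,
    snps_per_gene_mean: float = 2.0,
    intergenic_snp_rate: float = 2.0,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypePanel:
    """Draw a genotype panel under Hardy-Weinberg at per-SNP MAFs.

    SNP placement mirrors a genic SNP array: per gene, Poisson
    (``snps_per_gene_mean``) SNPs uniform inside the gene body, plus
    non-genic SNPs at an expected ``intergenic_snp_rate`` per gene split
    between the 1-kb flank (25%), the 1-10-kb band (35%) and the remaining
    intergenic gap (40%), so every flank class used downstream is populated.

    Genotypes AA/AB/BB are coded -1/0/1; with allele-B frequency ``maf`` the
    Hardy-Weinberg class probabilities are ((1-maf)^2, 2 maf (1-maf), maf^2).
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    positions: list[tuple[str, int]] = []
    genes = annotation.genes
    for chrom, chrom_genes in genes.groupby("chrom", sort=True):
        chrom_genes = chrom_genes.sort_values("start")
        chrom_end = int(chrom_genes["end"].max()) + 10_000
        starts = chrom_genes["start"].to_numpy()
        ends = chrom_genes["end"].to_numpy()
        for start, end in zip(starts, ends):
            # genic SNPs
            for _ in range(rng.poisson(snps_per_gene_mean)):
                positions.append((chrom, int(rng.integers(start, end + 1))))
            # near flank (within 1 kb of the gene)
            for _ in range(rng.poisson(0.25 * intergenic_snp_rate)):
                off = int(rng.integers(1, 1_001))
                side = -1 if rng.random() < 0.5 else 1
                pos = end + off if side > 0 else start - off
                if pos >= 1:
                    positions.append((chrom, pos))
            # mid flank (1-10 kb from the gene)
            for _ in range(rng.poisson(0.35 * intergenic_snp_rate)):
                off = int(rng.integers(1_001, 10_001))
                side = -1 if rng.random() < 0.5 else 1
                pos = end + off if side > 0 else start - off
                if pos >= 1:
                    positions.append((chrom, pos))
            # anywhere intergenic on the chromosome
            for _ in range(rng.poisson(0.40 * intergenic_snp_rate)):
                positions.append((chrom, int(rng.integers(1, chrom_end + 1))))
    if not positions:
        raise ValueError("no SNPs drawn; increase the SNP rates")
    positions.sort()
    snp_chrom = np.array([c for c, _ in positions])
    snp_pos = np.array([p for _, p in positions], dtype=np.int64)
    n_snps = len(positions)
    snp_ids = [f"S{i + 1:06d}" for i in range(n_snps)]

    maf = rng.uniform(lo, hi, size=n_snps)
    u = rng.random(size=(n_lines, n_snps))
    p_aa = (1.0 - maf) ** 2
    p_ab = 2.0 * maf * (1.0 - maf)
    matrix = np.full((n_lines, n_snps), 1, dtype=np.int8)
    matrix[u < p_aa + p_ab] = 0
    matrix[u < p_aa] = -1

    missing = np.zeros_like(matrix, dtype=bool)
    if missing_rate > 0:
        missing = rng.random(size=matrix.shape) < missing_rate
        matrix = matrix.copy()
        matrix[missing] = 0

    line_ids = [f"L{i + 1:05d}" for i in range(n_lines)]
    return GenotypePanel(line_ids, snp_ids, snp_chrom, snp_pos, matrix, missing, maf=maf)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson at 0)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    prob = size / (size + mean)
    return rng.negative_binomial(size, prob)


def simulate_coexpression(
    annotation: GenomeAnnotation,
    n_modules: int = 5,
    module_size: int = 20,
    n_stages: int = 3,
    n_reps: int = 3,
    de_fraction: float = 0.2,
    lfc_magnitude: float = 3.0,
    dispersion: float = 0.1,
    stage_labels: tuple = DEFAULT_STAGES,
    replicate_layout: str = "independent",
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Stage-structured RNA-seq counts with planted DE genes and modules.

    Counts are negative binomial around gene/stage means built in log2 space
    from (i) a gene baseline, (ii) a shared per-module latent stage profile
    scaled by a positive per-gene loading — which makes within-module pairwise
    correlation exceed between-module correlation — and (iii) planted stage
    shifts of +/- ``lfc_magnitude`` log2 units for the DE genes. Module genes
    always carry a planted shift (developmentally co-regulated genes), and
    additional genes are shifted so roughly ``de_fraction`` of all genes are
    differentially expressed. The true log2 fold change recorded per stage
    pair is the full expected log2 mean difference (shift + module profile).

    ``replicate_layout="averaged"`` collapses each stage's replicate libraries
    into two averaged pseudo-libraries, mimicking pooled sequencing runs.
    """
    if module_size < 2:
        raise ValueError("module_size must be >= 2")
    if not (0 <= de_fraction <= 1):
        raise ValueError("de_fraction must be in [0, 1]")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (DE testing needs replication)")
    if replicate_layout not in ("independent", "averaged"):
        raise ValueError("replicate_layout must be 'independent' or 'averaged'")
    gene_ids = annotation.gene_ids
    n_genes = len(gene_ids)
    if n_modules * module_size > n_genes:
        raise ValueError("annotation has too few genes for the requested modules")
    stages = tuple(stage_labels[:n_stages])

    rng = np.random.default_rng(seed)
    truth = SimulationTruth()

    # module membership: contiguous blocks of a random gene permutation
    perm = rng.permutation(n_genes)
    module_id = np.full(n_genes, -1, dtype=int)
    for m in range(n_modules):
        block = perm[m * module_size:(m + 1) * module_size]
        module_id[block] = m
        truth.nucleus_of[m] = gene_ids[block[0]]
        for g in block:
            truth.module_of[gene_ids[g]] = m

    # planted DE: module genes always, plus extra genes up to de_fraction
    is_de = module_id >= 0
    if lfc_magnitude == 0 or de_fraction == 0:
        is_de = np.zeros(n_genes, dtype=bool)
    else:
        target = int(round(de_fraction * n_genes))
        extra = max(0, target - int(is_de.sum()))
        pool = np.flatnonzero(~is_de)
        if extra and len(pool):
            is_de[rng.choice(pool, size=min(extra, len(pool)), replace=False)] = True

    # per-gene baseline log2 mean (spans low- to high-expressed genes)
    base_log2 = rng.normal(6.0, 1.5, size=n_genes)

    # per-module stage profile (modest sd so planted shifts dominate DE calls)
    profile = rng.normal(0.0, 0.5, size=(n_modules, len(stages)))
    loading = rng.uniform(0.6, 1.0, size=n_genes)

    # planted shifts: zero at the first stage, then a +/- lfc step at a
    # randomly chosen later stage that persists through development
    shift = np.zeros((n_genes, len(stages)))
    de_idx = np.flatnonzero(is_de)
    if lfc_magnitude != 0 and len(de_idx):
        signs = rng.choice((-1.0, 1.0), size=len(de_idx))
        onset = rng.integers(1, len(stages), size=len(de_idx))
        for i, g in enumerate(de_idx):
            shift[g, onset[i]:] = signs[i] * lfc_magnitude

    log2_mean = np.tile(base_log2[:, None], (1, len(stages))) + shift
    for g in range(n_genes):
        m = module_id[g]
        if m >= 0:
            log2_mean[g] += loading[g] * profile[m]

    # record true stage-pair log2 fold changes for genes whose planted shift
    # changes between the two stages (module wobble alone is not planted DE)
    for a in range(len(stages)):
        for b in range(a + 1, len(stages)):
            pair: dict[str, float] = {}
            for g in de_idx:
                if shift[g, b] != shift[g, a]:
                    pair[gene_ids[g]] = float(log2_mean[g, b] - log2_mean[g, a])
            truth.de_lfc[(stages[a], stages[b])] = pair

    # per-sample module wobble correlates replicates within a stage, which is
    # what makes module structure estimable from only a few libraries
    sample_stage, sample_rep, cols = [], [], []
    for si, st in enumerate(stages):
        for r in range(n_reps):
            f = rng.normal(0.0, 0.3, size=n_modules)
            mu = log2_mean[:, si].copy()
            for m in range(n_modules):
                sel = module_id == m
                mu[sel] += loading[sel] * f[m]
            cols.append(_nb_draw(rng, 2.0 ** mu, dispersion))
            sample_stage.append(st)
            sample_rep.append(r + 1)
    counts = np.column_stack(cols).astype(np.int64)

    stage_arr = np.array(sample_stage)
    rep_arr = np.array(sample_rep)
    if replicate_layout == "averaged":
        # collapse to two averaged pseudo-libraries per stage
        new_cols, new_stage, new_rep = [], [], []
        for st in stages:
            idx = np.flatnonzero(stage_arr == st)
            half = len(idx) // 2
            for r, part in enumerate((idx[:half], idx[half:]), start=1):
                new_cols.append(np.rint(counts[:, part].mean(axis=1)).astype(np.int64))
                new_stage.append(st)
                new_rep.append(r)
        counts = np.column_stack(new_cols)
        stage_arr = np.array(new_stage)
        rep_arr = np.array(new_rep)

    sample_ids = [f"{st}DPA_r{r}" for st, r in zip(stage_arr, rep_arr)]
    expr = ExpressionMatrix(gene_ids, sample_ids, stage_arr, rep_arr, counts)
    return expr, truth


def simulate_phenotypes(
    panel: GenotypePanel,
    truth: SimulationTruth,
    causal_snp_ids: list[str],
    h2: float = 0.5,
    n_years: int = 4,
    n_experiments: int = 3,
    sigma_year: float = 1.0,
    sigma_exp: float = 0.5,
    first_year: int = 2014,
    trait: str = "trait",
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotypes ``y = b0 + X beta + year + experiment + e``.

    Causal effects are drawn N(0, 1) on ``causal_snp_ids`` and rescaled so
    that the realized genetic variance var(X beta) equals ``h2`` times the
    expected total variance; the residual variance is fixed at 1. Each line
    gets one harvest year (uniform over ``n_years`` consecutive seasons, which
    drives the forward train/test split) and one experiment batch. Realized
    effects are recorded back into ``truth``.
    """
    if not (0 < h2 < 1):
        raise ValueError("h2 must be in (0, 1)")
    missing = set(causal_snp_ids) - set(panel.snp_ids)
    if missing:
        raise ValueError(f"causal SNPs not in panel: {sorted(missing)[:5]}")
    if len(causal_snp_ids) == 0:
        raise ValueError("causal SNP set must be non-empty when h2 > 0")

    rng = np.random.default_rng(seed)
    n = panel.n_lines
    x = panel.imputed()
    col = {s: j for j, s in enumerate(panel.snp_ids)}
    causal_idx = np.array([col[s] for s in causal_snp_ids])

    beta = np.zeros(panel.n_snps)
    beta[causal_idx] = rng.normal(0.0, 1.0, size=len(causal_idx))
    g = x @ beta
    var_g = g.var()
    if var_g == 0:
        raise ValueError("causal SNPs carry no genotypic variance")
    sigma_e2 = 1.0
    target_var_g = h2 / (1.0 - h2) * (sigma_year**2 + sigma_exp**2 + sigma_e2)
    scale = np.sqrt(target_var_g / var_g)
    beta *= scale
    g *= scale

    years = first_year + rng.integers(0, n_years, size=n)
    experiments = rng.integers(0, n_experiments, size=n)
    year_eff = {first_year + k: rng.normal(0.0, sigma_year) for k in range(n_years)}
    exp_eff = {f"E{k + 1}": rng.normal(0.0, sigma_exp) for k in range(n_experiments)}
    exp_labels = np.array([f"E{k + 1}" for k in experiments])

    e = rng.normal(0.0, np.sqrt(sigma_e2), size=n)
    y = g + np.array([year_eff[v] for v in years]) + np.array(
        [exp_eff[v] for v in exp_labels]) + e

    truth.causal_snp_ids = list(causal_snp_ids)
    truth.causal_effects = {s: float(beta[col[s]]) for s in causal_snp_ids}
    truth.h2 = float(h2)
    truth.year_effects = {int(k): float(v) for k, v in year_eff.items()}
    truth.experiment_effects = dict(exp_eff)

    return pd.DataFrame({
        "line_id": panel.line_ids,
        "trait": trait,
        "value": y,
        "year": years,
        "experiment": exp_labels,
    })
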