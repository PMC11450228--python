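"""Readers and writers for the pipeline's on-disk formats.

Formats: GFF3 gene annotation (1-based inclusive), VCF or TSV genotypes
(GT 0/0, 0/1, 1/1 mapping to codes -1, 0, 1; ./. missing), counts TSV
(genes in rows, sample ids in the header encoding stage and replicate),
phenotype CSV (line_id,trait,value,year,experiment), ground-truth JSON, and
the YAML pipeline configuration. Every writer produces files its paired
reader accepts; readers reject malformed records rather than coerce them.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .simulate import (
    ExpressionMatrix,
    GenomeAnnotation,
    GenotypePanel,
    PHENOTYPE_COLUMNS,
    SimulationTruth,
)

_SAMPLE_RE = re.compile(r"^(?P<stage>.+?)DPA_r(?P<rep>\d+)$")


# ---------------------------------------------------------------------------
# Annotation (GFF3)
# ---------------------------------------------------------------------------

def write_gff3(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in annotation.genes.itertuples(index=False):
            fh.write(f"{rec.chrom}\tfibreggp\tgene\t{rec.start}\t{rec.end}\t."
                     f"\t{rec.strand}\t.\tID={rec.gene_id}\n")


def read_annotation(path) -> GenomeAnnotation:
    """Load type=gene features from a GFF3 file; other features skipped."""
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    records = []
    for feat in db.features_of_type("gene"):
        if "ID" not in feat.attributes:
            raise ValueError(f"gene feature at {feat.seqid}:{feat.start} has no ID")
        records.append((feat.attributes["ID"][0], feat.seqid, feat.start,
                        feat.end, feat.strand))
    if not records:
        raise ValueError(f"no gene features in {path}")
    genes = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GenomeAnnotation(genes)


# ---------------------------------------------------------------------------
# Genotypes (VCF / TSV)
# ---------------------------------------------------------------------------

def write_vcf(panel: GenotypePanel, path) -> None:
    gt_of = {-1: "0/0", 0: "0/1", 1: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(set(panel.snp_chrom)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.line_ids) + "\n")
        for j, snp in enumerate(panel.snp_ids):
            gts = ["./." if panel.missing[i, j] else gt_of[int(panel.matrix[i, j])]
                   for i in range(panel.n_lines)]
            fh.write(f"{panel.snp_chrom[j]}\t{panel.snp_pos[j]}\t{snp}\tA\tG"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def write_genotypes_tsv(panel: GenotypePanel, path) -> None:
    codes = panel.matrix.astype(object)
    codes[panel.missing] = "NA"
    df = pd.DataFrame(codes.T, columns=panel.line_ids)
    df.insert(0, "pos", panel.snp_pos)
    df.insert(0, "chrom", panel.snp_chrom)
    df.insert(0, "snp_id", panel.snp_ids)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path, format: str = "vcf") -> GenotypePanel:
    """Read a genotype panel from VCF (biallelic GT) or TSV codes."""
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_genotypes_tsv(path)
    raise ValueError("format must be 'vcf' or 'tsv'")


def _read_vcf(path) -> GenotypePanel:
    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    snp_ids, chroms, poss, cols, miss_cols = [], [], [], [], []
    for k, var in enumerate(vcf):
        if len(var.ALT) > 1:
            raise ValueError(
                f"multi-allelic record {var.ID or var.POS} (record {k + 1}); "
                "the panel is biallelic")
        code = np.zeros(len(line_ids), dtype=np.int8)
        missing = np.zeros(len(line_ids), dtype=bool)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                missing[i] = True
            elif a + b == 0:
                code[i] = -1
            elif a + b == 1:
                code[i] = 0
            elif a + b == 2:
                code[i] = 1
            else:
                raise ValueError(f"malformed GT {a}/{b} at record {k + 1}")
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        cols.append(code)
        miss_cols.append(missing)
    if not snp_ids:
        raise ValueError(f"no variant records in {path}")
    return GenotypePanel(
        line_ids, snp_ids, np.array(chroms), np.array(poss, dtype=np.int64),
        np.column_stack(cols), np.column_stack(miss_cols))


def _read_genotypes_tsv(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str},
                     keep_default_na=False)
    for col in ("snp_id", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"genotype TSV lacks required column {col!r}")
    line_ids = [c for c in df.columns if c not in ("snp_id", "chrom", "pos")]
    raw = df[line_ids].to_numpy(dtype=object).T  # lines x snps
    matrix = np.zeros(raw.shape, dtype=np.int8)
    missing = np.zeros(raw.shape, dtype=bool)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            v = raw[i, j]
            if isinstance(v, str) and v.strip() in ("NA", ""):
                missing[i, j] = True
            else:
                try:
                    iv = int(v)
                except (TypeError, ValueError):
                    iv = None
                if iv not in (-1, 0, 1):
                    raise ValueError(
                        f"invalid genotype code {v!r} at data line {j + 2}, "
                        f"sample {line_ids[i]}")
                matrix[i, j] = iv
    return GenotypePanel(
        line_ids, df["snp_id"].tolist(), df["chrom"].to_numpy(),
        df["pos"].to_numpy(dtype=np.int64), matrix, missing)


# ---------------------------------------------------------------------------
# Counts, phenotypes, truth
# ---------------------------------------------------------------------------

def write_counts(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.counts, index=pd.Index(expr.gene_ids, name="gene_id"),
                      columns=expr.sample_ids)
    df.to_csv(path, sep="\t")


def read_counts(path) -> ExpressionMatrix:
    """Counts TSV with sample ids like ``7DPA_r1`` encoding stage/replicate."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    stages, reps = [], []
    for sid in df.columns:
        m = _SAMPLE_RE.match(str(sid))
        if not m:
            raise ValueError(
                f"sample id {sid!r} does not encode stage/replicate "
                "(expected '<stage>DPA_r<rep>')")
        stage = m.group("stage")
        stages.append(int(stage) if stage.isdigit() else stage)
        reps.append(int(m.group("rep")))
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number) or (counts < 0).any():
        raise ValueError("counts must be non-negative numbers")
    return ExpressionMatrix(list(df.index), list(df.columns),
                            np.array(stages), np.array(reps),
                            counts.astype(np.int64))


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno[list(PHENOTYPE_COLUMNS)].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype CSV lacks columns: {sorted(missing)}")
    if df["year"].isna().any():
        raise ValueError("phenotype CSV has rows without a year")
    return df


def write_truth(truth: SimulationTruth, path) -> None:
    payload = {
        "de_lfc": {f"{a}|{b}": v for (a, b), v in truth.de_lfc.items()},
        "module_of": truth.module_of,
        "nucleus_of": {str(k): v for k, v in truth.nucleus_of.items()},
        "causal_snp_ids": truth.causal_snp_ids,
        "causal_effects": truth.causal_effects,
        "h2": truth.h2,
        "year_effects": {str(k): v for k, v in truth.year_effects.items()},
        "experiment_effects": truth.experiment_effects,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SimulationTruth:
    raw = json.loads(Path(path).read_text())

    def _stage(s: str):
        return int(s) if s.isdigit() else s

    return SimulationTruth(
        de_lfc={tuple(_stage(x) for x in k.split("|")): v
                for k, v in raw["de_lfc"].items()},
        module_of=raw["module_of"],
        nucleus_of={int(k): v for k, v in raw["nucleus_of"].items()},
        causal_snp_ids=raw["causal_snp_ids"],
        causal_effects=raw["causal_effects"],
        h2=raw["h2"],
        year_effects={int(k): v for k, v in raw["year_effects"].items()},
        experiment_effects=raw["experiment_effects"],
    )


def write_gene_list(gene_ids: list[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gene_ids))


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_edge_list(edges: list[tuple[str, str, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\tr\n")
        for a, b, r in edges:
            fh.write(f"{a}\t{b}\t{r:.6f}\n")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

SCENARIOS = ("baseline", "scenario1", "scenario2", "scenario3")


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; see ``load_config``.

    Desk-scale defaults: a few hundred lines and genes, ~1-2k SNPs. A real
    breeding panel's scale (thousands of lines, ~12k array SNPs, a genome
    with tens of thousands of genes) is configuration, not the default.
    """

    outdir: str = "run"
    scenario: str = "scenario3"
    seed: int = 0
    # simulation
    n_genes: int = 300
    n_chrom: int = 2
    n_lines: int = 400
    n_modules: int = 4
    module_size: int = 15
    de_fraction: float = 0.3
    lfc_magnitude: float = 3.0
    dispersion: float = 0.05
    snps_per_gene_mean: float = 2.0
    intergenic_snp_rate: float = 2.0
    h2: float = 0.5
    n_causal: int = 30
    n_years: int = 4
    n_experiments: int = 3
    # DE thresholds
    stage_a: int = 16
    stage_b: int = 25
    fdr_threshold: float = 0.001
    lfc_threshold: float = 1.5
    direction: str | None = None          # scenario2: "up" or "down"
    # SNP mapping
    flank_bp: int = 10_000
    # clusters (scenario3)
    nucleus_genes: list = field(default_factory=list)   # empty = planted nuclei
    k: int = 3
    # model
    weight: str = "75"
    burn_in: int = 1_000
    iterations: int = 2_000
    thin: int = 2
    n_repeats: int = 10
    cutoff_year: int | None = None        # None = last simulated season

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.scenario == "scenario2" and self.direction not in ("up", "down"):
            raise ValueError("scenario2 requires direction 'up' or 'down'")


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def dump_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))
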