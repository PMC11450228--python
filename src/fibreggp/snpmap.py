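"""SNP-to-gene interval mapping and weighted SNP-group construction.

A SNP maps to a gene at flank f when its position lies within
[start - f, end + f] on the same chromosome (1-based inclusive, both
flanks, strand ignored). The flanks of interest are 0 (exact gene body),
1 kb, and 10 kb. A gene list plus a mapping yields the SNP group G whose
effects the weighted prediction model up-weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulate import GenomeAnnotation, GenotypePanel


@dataclass
class SnpGeneMap:
    """gene_id -> set of snp_ids within ``flank_bp`` of the gene."""

    flank_bp: int
    mapping: dict[str, set[str]]

    def genes_hit(self) -> list[str]:
        return [g for g, s in self.mapping.items() if s]


@dataclass
class SnpGroup:
    """Ordered, duplicate-free panel column indices forming G."""

    indices: np.ndarray
    snp_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("duplicate SNP indices in group")

    def __len__(self) -> int:
        return len(self.indices)


def map_snps(panel: GenotypePanel, annotation: GenomeAnnotation, flank_bp: int) -> SnpGeneMap:
    """Interval-map every SNP to every gene within ``flank_bp``.

    A SNP may map to multiple genes (overlapping flanks); genes with no SNP
    get an empty set. Panel chromosomes absent from the annotation indicate
    a naming mismatch and raise.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    panel_chroms = set(np.unique(panel.snp_chrom))
    annot_chroms = set(annotation.genes["chrom"])
    unmatched = panel_chroms - annot_chroms
    if unmatched:
        raise ValueError(
            f"panel chromosomes not present in annotation: {sorted(unmatched)}")

    mapping: dict[str, set[str]] = {g: set() for g in annotation.gene_ids}
    snp_ids = np.asarray(panel.snp_ids)
    for chrom in sorted(panel_chroms):
        sel = panel.snp_chrom == chrom
        pos = panel.snp_pos[sel]
        ids = snp_ids[sel]
        order = np.argsort(pos, kind="stable")
        pos, ids = pos[order], ids[order]
        genes = annotation.genes[annotation.genes["chrom"] == chrom]
        for gene_id, start, end in zip(genes["gene_id"], genes["start"], genes["end"]):
            lo = np.searchsorted(pos, start - flank_bp, side="left")
            hi = np.searchsorted(pos, end + flank_bp, side="right")
            mapping[gene_id].update(ids[lo:hi])
    return SnpGeneMap(flank_bp=flank_bp, mapping=mapping)


def snp_group(
    gene_ids: list[str],
    snp_gene_map: SnpGeneMap,
    panel: GenotypePanel,
    provenance: dict | None = None,
) -> SnpGroup:
    """Union of mapped SNPs over ``gene_ids`` as panel column indices.

    Gene ids missing from the map are warned about, not fatal. An empty
    resulting group is warned about too: the weighted model then collapses
    to the unweighted baseline.
    """
    missing = [g for g in gene_ids if g not in snp_gene_map.mapping]
    if missing:
        warnings.warn(f"{len(missing)} gene ids not in the SNP map: {missing[:5]}",
                      stacklevel=2)
    snps: set[str] = set()
    for g in gene_ids:
        snps.update(snp_gene_map.mapping.get(g, ()))
    col = {s: j for j, s in enumerate(panel.snp_ids)}
    idx = np.array(sorted(col[s] for s in snps), dtype=np.int64)
    if len(idx) == 0:
        warnings.warn("SNP group is empty; weighted model equals the baseline",
                      stacklevel=2)
    prov = dict(provenance or {})
    prov.setdefault("flank_bp", snp_gene_map.flank_bp)
    prov.setdefault("n_genes", len(gene_ids))
    return SnpGroup(indices=idx, snp_ids=[panel.snp_ids[j] for j in idx],
                    provenance=prov)
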