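"""Partial-correlation-and-information-theory (PCIT) network inference.

PCIT prunes a gene-gene Pearson correlation matrix in two steps. For every
unordered gene pair (x, y) and every third gene z it computes the trio's
three first-order partial correlations

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

and a trio tolerance — the signed mean of the partial-to-direct ratios

    eps = (r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz) / 3.

The data-processing inequality then discards edge (x, y) if, for at least
one z, |r_xy| <= |eps r_xz| and |r_xy| <= |eps r_yz|; an association weaker
than both tolerance-scaled links through z is taken to be mediated by z
rather than direct. Edges surviving every trio form the co-expression
network (GCN). The scan is O(n^3) in genes, which is why the network is
built over DE genes only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .de import size_factors
from .simulate import ExpressionMatrix

logger = logging.getLogger("fibreggp")


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal pairwise Pearson correlations."""

    gene_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("matrix shape does not match gene_ids")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")


@dataclass
class CoexpressionNetwork:
    """PCIT-retained adjacency with edge weights = direct correlations."""

    gene_ids: list[str]
    adjacency: np.ndarray   # boolean, symmetric, zero diagonal
    weights: np.ndarray     # r on retained edges, 0 elsewhere

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[str, str, float]]:
        out = []
        n = len(self.gene_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.adjacency[i, j]:
                    out.append((self.gene_ids[i], self.gene_ids[j],
                                float(self.weights[i, j])))
        return out


def pearson_correlations(
    expr: ExpressionMatrix,
    gene_subset: list[str] | None = None,
    sample_subset: np.ndarray | None = None,
    transform: str = "log2",
) -> CorrelationMatrix:
    """Pairwise Pearson correlations over samples.

    By default counts are median-of-ratios normalized and log2(x + 1)
    transformed (``transform="log2"``); ``transform="none"`` correlates raw
    counts. Genes with zero variance across the used samples are excluded
    with a warning.
    """
    if transform not in ("log2", "none"):
        raise ValueError("transform must be 'log2' or 'none'")
    cols = np.arange(len(expr.sample_ids)) if sample_subset is None else np.asarray(sample_subset)
    if len(cols) < 3:
        raise ValueError("correlations need >=3 samples")
    if gene_subset is None:
        rows = np.arange(len(expr.gene_ids))
    else:
        index = {g: i for i, g in enumerate(expr.gene_ids)}
        absent = [g for g in gene_subset if g not in index]
        if absent:
            raise KeyError(f"genes not in expression matrix: {absent[:5]}")
        rows = np.array([index[g] for g in gene_subset])
    sub = expr.counts[np.ix_(rows, cols)].astype(float)
    if transform == "log2":
        try:
            f = size_factors(sub)
        except ValueError:
            f = size_factors(sub, use_pseudo_reference=True)
        sub = np.log2(sub / f[None, :] + 1.0)
    keep = sub.var(axis=1) > 0
    if not keep.any():
        raise ValueError("all genes are constant across the selected samples")
    if not keep.all():
        dropped = [expr.gene_ids[rows[i]] for i in np.flatnonzero(~keep)]
        logger.warning("dropping %d zero-variance genes: %s%s", len(dropped),
                       dropped[:5], "..." if len(dropped) > 5 else "")
    sub = sub[keep]
    gene_ids = [expr.gene_ids[r] for r in rows[keep]]
    corr = np.corrcoef(sub)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(gene_ids, corr)


def first_order_partial(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy.z."""
    for r in (r_xy, r_xz, r_yz):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 0:
        raise ValueError("degenerate conditioning correlation (|r| = 1)")
    return (r_xy - r_xz * r_yz) / np.sqrt(denom)


def pcit_significant_edges(corr: CorrelationMatrix) -> CoexpressionNetwork:
    """Apply the PCIT trio scan; retain edges surviving every third gene.

    Pairs with zero direct correlation are discarded outright. Degenerate
    trios — any conditioning correlation at |r| = 1 (denominator collapse)
    or any zero direct correlation inside a tolerance ratio — are skipped.
    With fewer than 3 genes no trio exists and all nonzero edges survive.
    The scan is vectorized per conditioning gene z; a literal triple loop
    gives identical results (see the test-suite oracle).
    """
    c = np.asarray(corr.matrix, dtype=float)
    n = c.shape[0]
    keep = c != 0.0
    np.fill_diagonal(keep, False)
    if n < 3:
        weights = np.where(keep, c, 0.0)
        return CoexpressionNetwork(corr.gene_ids, keep, weights)

    abs_c = np.abs(c)
    ok_pair = (abs_c < 1.0) & (c != 0.0)   # usable inside ratios/denominators
    np.fill_diagonal(ok_pair, False)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_sqrt = 1.0 / np.sqrt(1.0 - c**2)   # inf on |r|=1; masked below
        for z in range(n):
            cz = c[:, z]
            s_z = inv_sqrt[:, z]
            # three partials of the trio {x, y, z}, for all pairs (x, y)
            p_xy_z = (c - np.outer(cz, cz)) * np.outer(s_z, s_z)
            p_xz_y = (cz[:, None] - c * cz[None, :]) * inv_sqrt * s_z[None, :]
            p_yz_x = (cz[None, :] - c * cz[:, None]) * inv_sqrt * s_z[:, None]
            eps = (p_xy_z / c + p_xz_y / cz[:, None] + p_yz_x / cz[None, :]) / 3.0
            valid = (ok_pair
                     & ok_pair[:, z][:, None]
                     & ok_pair[z, :][None, :])
            valid[z, :] = False
            valid[:, z] = False
            tol = np.abs(eps)
            discard = (valid
                       & (abs_c <= tol * np.abs(cz)[:, None])
                       & (abs_c <= tol * np.abs(cz)[None, :]))
            keep &= ~discard
    weights = np.where(keep, c, 0.0)
    return CoexpressionNetwork(corr.gene_ids, keep, weights)


def build_gcn(network: CoexpressionNetwork) -> nx.Graph:
    """networkx graph whose nodes/edges mirror the retained adjacency."""
    g = nx.Graph()
    g.add_nodes_from(network.gene_ids)
    for a, b, r in network.edge_list():
        g.add_edge(a, b, weight=r)
    return g
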