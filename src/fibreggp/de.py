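"""Differential expression between two developmental stages.

A fully specified negative-binomial Wald procedure: median-of-ratios library
normalization, method-of-moments gene dispersion with a floor, a delta-method
standard error on the log2 fold change, a two-sided normal Wald p-value, and
Benjamini-Hochberg adjustment. Genes are called DE when the adjusted p-value
falls below the FDR threshold (default 0.001) and |log2FC| meets the fold-
change threshold (default 1.5) — stringent cutoffs meant to capture both
transcription factors and abundant structural genes.

The result table (``DEResult``) is a DataFrame with one row per gene and
columns ``base_mean, log2fc, se, pvalue, qvalue, status, direction``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import ExpressionMatrix

DISPERSION_FLOOR = 1e-8
PSEUDO_COUNT = 0.5


def size_factors(counts: np.ndarray, use_pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios per-sample scaling factors.

    factor_s = median over reference genes of count_gs / geometric-mean_g,
    where reference genes have nonzero counts in every sample. If no such
    gene exists, raises unless ``use_pseudo_reference`` is set, in which case
    geometric means are taken over the positive counts of each gene.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 1:
        raise ValueError("counts must be a genes x samples matrix")
    all_pos = (counts > 0).all(axis=1)
    if all_pos.any() and not use_pseudo_reference:
        ref = counts[all_pos]
        log_gm = np.log(ref).mean(axis=1)
        factors = np.exp(np.median(np.log(ref) - log_gm[:, None], axis=0))
    else:
        if not use_pseudo_reference:
            raise ValueError(
                "no gene has nonzero counts in all samples; rerun with "
                "use_pseudo_reference=True to use positive-count geometric means"
            )
        any_pos = (counts > 0).any(axis=1)
        if not any_pos.any():
            raise ValueError("all counts are zero")
        ref = counts[any_pos]
        with np.errstate(divide="ignore"):
            logc = np.log(ref)
        logc[ref <= 0] = np.nan
        log_gm = np.nanmean(logc, axis=1)
        ratios = logc - log_gm[:, None]
        factors = np.exp(np.nanmedian(ratios, axis=0))
    if not (factors > 0).all():
        raise ValueError("non-positive size factor; library appears empty")
    return factors


def nb_wald_test(
    counts: np.ndarray,
    factors: np.ndarray,
    samples_a: np.ndarray,
    samples_b: np.ndarray,
    gene_ids: list[str] | None = None,
    pseudo_count: float = PSEUDO_COUNT,
) -> pd.DataFrame:
    """Per-gene negative-binomial Wald test of stage B vs stage A.

    On normalized counts q = c / factor: log2FC = log2((mB + c0)/(mA + c0))
    with pseudo-count c0; the gene dispersion alpha (var = mu + alpha mu^2)
    is a pooled method-of-moments estimate floored at 1e-8; the SE of log2FC
    comes from the delta method on the two group means; p is two-sided
    normal. Genes with all-zero counts in both groups are flagged
    ``untestable`` and carry no p-value.
    """
    counts = np.asarray(counts, dtype=float)
    samples_a = np.asarray(samples_a)
    samples_b = np.asarray(samples_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs >=2 replicates")
    factors = np.asarray(factors, dtype=float)
    norm = counts / factors[None, :]
    qa, qb = norm[:, samples_a], norm[:, samples_b]
    na, nb = qa.shape[1], qb.shape[1]
    m_a, m_b = qa.mean(axis=1), qb.mean(axis=1)
    base_mean = np.concatenate([qa, qb], axis=1).mean(axis=1)

    log2fc = np.log2(m_b + pseudo_count) - np.log2(m_a + pseudo_count)

    # pooled within-group method-of-moments dispersion
    va = qa.var(axis=1, ddof=1)
    vb = qb.var(axis=1, ddof=1)
    pooled_var = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    mu = np.where(base_mean > 0, base_mean, 1.0)
    alpha = np.maximum((pooled_var - mu) / mu**2, DISPERSION_FLOOR)

    # delta method: var(log2 m) = var(mean) / ((m + c0)^2 ln2^2)
    var_mean_a = (m_a + alpha * m_a**2) / na
    var_mean_b = (m_b + alpha * m_b**2) / nb
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(
        var_mean_a / (m_a + pseudo_count) ** 2 / ln2sq
        + var_mean_b / (m_b + pseudo_count) ** 2 / ln2sq
    )

    untestable = (qa.sum(axis=1) == 0) & (qb.sum(axis=1) == 0)
    se_safe = np.where(se > 0, se, np.inf)
    z = log2fc / se_safe
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue[untestable] = np.nan

    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(counts.shape[0])]
    return pd.DataFrame({
        "gene_id": gene_ids,
        "base_mean": base_mean,
        "log2fc": log2fc,
        "se": se,
        "pvalue": pvalue,
        "status": np.where(untestable, "untestable", "tested"),
    })


def adjust_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def select_de_genes(
    de_result: pd.DataFrame,
    fdr_threshold: float = 0.001,
    lfc_threshold: float = 1.5,
    use_raw_p: bool = False,
) -> pd.DataFrame:
    """Genes with q < ``fdr_threshold`` and |log2FC| >= ``lfc_threshold``.

    ``use_raw_p`` applies the FDR cutoff to the unadjusted p-value instead
    (the looser reading of an "FDR threshold of 0.001 p-value").
    """
    res = de_result[de_result["status"] == "tested"].copy()
    crit_p = res["pvalue"] if use_raw_p else res["qvalue"]
    keep = (crit_p < fdr_threshold) & (res["log2fc"].abs() >= lfc_threshold)
    out = res.loc[keep, ["gene_id", "log2fc", "qvalue"]].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out.reset_index(drop=True)


def differential_expression(
    expr: ExpressionMatrix,
    stage_a,
    stage_b,
    pseudo_count: float = PSEUDO_COUNT,
) -> pd.DataFrame:
    """Full two-stage DE table: normalization, Wald test, BH adjustment.

    Each pairwise stage comparison is independent: size factors are computed
    on the two compared stages' libraries only.
    """
    ia = expr.samples_for_stage(stage_a)
    ib = expr.samples_for_stage(stage_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError(f"stage not found among samples: {stage_a!r} / {stage_b!r}")
    used = np.concatenate([ia, ib])
    sub = expr.counts[:, used]
    try:
        factors_used = size_factors(sub)
    except ValueError:
        factors_used = size_factors(sub, use_pseudo_reference=True)
    factors = np.ones(len(expr.sample_ids))
    factors[used] = factors_used
    res = nb_wald_test(expr.counts, factors, ia, ib, gene_ids=expr.gene_ids,
                       pseudo_count=pseudo_count)
    tested = res["status"] == "tested"
    q = np.full(len(res), np.nan)
    q[tested.to_numpy()] = adjust_fdr(res.loc[tested, "pvalue"].to_numpy())
    res["qvalue"] = q
    return res
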