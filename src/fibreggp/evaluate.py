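"""Forward train/test evaluation of genomic prediction accuracy.

The split is by harvest year (newest seasons held out, mimicking the
breeding situation of predicting unphenotyped new lines), accuracy is the
Pearson correlation between predicted and observed test phenotypes, the fit
is repeated across MCMC seeds to average out sampler noise, and two models
are compared by a t-test on their accuracy replicates at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .bayesc import GPModelData, McmcConfig, PosteriorSummary, PriorSpec, predict_gebv, run_gibbs


@dataclass
class TrainTestSplit:
    train_line_ids: list[str]
    test_line_ids: list[str]
    cutoff_year: int


@dataclass
class PredictionResult:
    accuracies: np.ndarray
    mean_accuracy: float
    p_value: float | None = None      # vs a reference result
    significant: bool | None = None   # at alpha = 0.05


def split_by_year(pheno: pd.DataFrame, cutoff_year: int) -> TrainTestSplit:
    """Test = lines with year >= cutoff; training = everything earlier."""
    if pheno["year"].isna().any():
        raise ValueError("every line needs a year")
    test = pheno.loc[pheno["year"] >= cutoff_year, "line_id"].tolist()
    train = pheno.loc[pheno["year"] < cutoff_year, "line_id"].tolist()
    if not train or not test:
        raise ValueError(
            f"cutoff {cutoff_year} gives an empty partition "
            f"({len(train)} train / {len(test)} test)")
    return TrainTestSplit(train, test, cutoff_year)


def accuracy(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Prediction accuracy: Pearson r between predicted and observed."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) != len(observed):
        raise ValueError("predicted and observed lengths differ")
    if len(predicted) < 3:
        raise ValueError("accuracy needs >=3 test records")
    if predicted.std() == 0 or observed.std() == 0:
        raise ValueError("accuracy undefined for a constant vector")
    return float(stats.pearsonr(predicted, observed).statistic)


def welch_pvalue(a: np.ndarray, b: np.ndarray, paired: bool = False) -> float:
    """Two-sided t-test p on two accuracy vectors; identical vectors -> 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.array_equal(a, b) or (a.std() == 0 and b.std() == 0 and a.mean() == b.mean()):
        return 1.0
    if paired:
        d = a - b
        if d.std() == 0 and d.mean() == 0:
            return 1.0
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def replicate_and_compare(
    train_data: GPModelData,
    x_test: np.ndarray,
    y_test: np.ndarray,
    prior_a: PriorSpec,
    prior_b: PriorSpec,
    mcmc: McmcConfig,
    n_repeats: int = 60,
    base_seed: int = 0,
    paired: bool = False,
) -> tuple[PredictionResult, PredictionResult, float]:
    """Fit both models ``n_repeats`` times over MCMC seeds and compare.

    The data and train/test split are fixed; repeat r uses seed
    ``base_seed + r`` for both models, so the replicates isolate sampler
    randomness. Returns the two per-model accuracy vectors and the two-sided
    t-test p-value (Welch by default, paired by flag).
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    acc_a = np.empty(n_repeats)
    acc_b = np.empty(n_repeats)
    for r in range(n_repeats):
        cfg = replace(mcmc, seed=base_seed + r)
        try:
            post_a = run_gibbs(train_data, prior_a, cfg)
            post_b = run_gibbs(train_data, prior_b, cfg)
            acc_a[r] = accuracy(predict_gebv(post_a, x_test), y_test)
            acc_b[r] = accuracy(predict_gebv(post_b, x_test), y_test)
        except Exception as exc:
            raise RuntimeError(f"repeat {r} (seed {base_seed + r}) failed") from exc
    p = welch_pvalue(acc_a, acc_b, paired=paired)
    res_a = PredictionResult(acc_a, float(acc_a.mean()), p, p < 0.05)
    res_b = PredictionResult(acc_b, float(acc_b.mean()), p, p < 0.05)
    return res_a, res_b, p
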