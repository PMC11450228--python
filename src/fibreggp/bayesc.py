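"""Weighted Bayes C genomic prediction by Gibbs sampling.

The likelihood is the standard genomic-prediction linear model

    y_i = beta0 + sum_j x_ij beta_j + W alpha + Z u + e_i,
    e ~ N(0, I sigma_e^2),

with genotypes x_ij coded -1/0/1 (AA/AB/BB), W and Z indicator designs for
harvest year and experiment batch with normal random effects, and each
marker effect beta_j under a spike-and-slab prior

    P(beta_j | gamma_j) = (1 - gamma_j) I(beta_j = 0)
                          + gamma_j N(beta_j | 0, sigma_b^2),

gamma_j ~ Bernoulli(pi), pi ~ Beta(p0 pi0, p0 (1 - pi0)) with p0 = 50 and
pi0 = 0.5, and sigma_b^2 under a scaled inverse chi-square prior with
df = 5 and scale S0 = var(y) * R^2 * (df + 2) / MSx, where R^2 = 0.5 is the
variance fraction the whole SNP panel is assumed to explain and MSx is the
summed genotype-column variance. That is Bayes C.

The *weighted* model splits the markers into a designated group G (SNPs in
or near network-cluster genes) and its complement, giving each group its own
slab variance with scales built from variance fractions (R2_G, R2_nonG) in
{(0.125, 0.375), (0.25, 0.25), (0.375, 0.125)} — G assumed to explain 25%,
50%, or 75% of the total genetic variance. MSx is computed per group, so
each group's prior scale delivers its intended variance share.

The Gibbs sweep is a numba kernel; all draws use numba's seeded RNG, so a
fixed (data, prior, mcmc, seed) gives bit-identical chains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd

from .simulate import GenotypePanel
from .snpmap import SnpGroup

logger = logging.getLogger("fibreggp")

WEIGHT_SETTINGS = {
    "baseline": None,
    "25": (0.125, 0.375),
    "50": (0.25, 0.25),
    "75": (0.375, 0.125),
}


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class GPModelData:
    """Aligned phenotypes, genotypes and year/experiment designs.

    ``X`` is the full mean-imputed genotype matrix; constant columns are
    flagged in ``kept`` and excluded from fitting (with a warning), keeping
    column alignment with ``snp_ids`` intact for prediction.
    """

    y: np.ndarray
    X: np.ndarray
    snp_ids: list[str]
    year_idx: np.ndarray | None = None     # per-observation year level index
    exp_idx: np.ndarray | None = None
    year_levels: list = field(default_factory=list)
    exp_levels: list = field(default_factory=list)
    kept: np.ndarray = None
    col_means: np.ndarray = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if len(self.y) != n:
            raise ValueError("y and X row counts disagree")
        for idx, name in ((self.year_idx, "year"), (self.exp_idx, "experiment")):
            if idx is not None and len(idx) != n:
                raise ValueError(f"{name} design length disagrees with y")
        if self.col_means is None:
            self.col_means = self.X.mean(axis=0)
        if self.kept is None:
            variances = self.X.var(axis=0)
            self.kept = variances > 0
            if not self.kept.all():
                logger.warning("dropping %d constant genotype columns",
                               int((~self.kept).sum()))

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]


def make_model_data(pheno: pd.DataFrame, panel: GenotypePanel,
                    trait: str | None = None) -> GPModelData:
    """Assemble ``GPModelData`` from a phenotype table and genotype panel."""
    tab = pheno if trait is None else pheno[pheno["trait"] == trait]
    if tab.empty:
        raise ValueError(f"no phenotype rows for trait {trait!r}")
    row_of = {l: i for i, l in enumerate(panel.line_ids)}
    missing = set(tab["line_id"]) - set(row_of)
    if missing:
        raise ValueError(f"phenotyped lines absent from panel: {sorted(missing)[:5]}")
    rows = np.array([row_of[l] for l in tab["line_id"]])
    x = panel.imputed()[rows]
    year_levels = sorted(tab["year"].unique())
    exp_levels = sorted(tab["experiment"].unique())
    year_idx = np.array([year_levels.index(v) for v in tab["year"]])
    exp_idx = np.array([exp_levels.index(v) for v in tab["experiment"]])
    return GPModelData(
        y=tab["value"].to_numpy(), X=x, snp_ids=list(panel.snp_ids),
        year_idx=year_idx, exp_idx=exp_idx,
        year_levels=year_levels, exp_levels=exp_levels,
    )


@dataclass
class PriorSpec:
    """Hyperparameters of the (possibly group-weighted) Bayes C prior."""

    df: float
    s0_de: float
    s0_nonde: float
    r2_de: float
    r2_nonde: float
    group: np.ndarray            # panel column indices forming G
    p0: float = 50.0
    pi0: float = 0.5
    df_e: float = 5.0
    s0_e: float = 1.0
    df_u: float = 5.0
    s0_year: float = 1.0
    s0_exp: float = 1.0
    baseline: bool = False

    def __post_init__(self) -> None:
        if self.s0_de <= 0 or self.s0_nonde <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class McmcConfig:
    """MCMC schedule: burn-in, post-burn-in iterations, thinning, seed."""

    burn_in: int = 10_000
    iterations: int = 20_000
    thin: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.iterations <= 0 or self.thin <= 0:
            raise ValueError("invalid MCMC schedule")
        if self.iterations % self.thin != 0:
            raise ValueError("iterations must be a multiple of thin")

    @property
    def n_retained(self) -> int:
        return self.iterations // self.thin


@dataclass
class PosteriorSummary:
    """Posterior means and retained chains from one Gibbs run."""

    beta0_mean: float
    beta_mean: np.ndarray          # full panel length; 0 at dropped columns
    inclusion_prob: np.ndarray     # mean of gamma_j over retained samples
    alpha_mean: np.ndarray         # year effects
    block_mean: np.ndarray         # experiment effects
    sigma2_e_mean: float
    sigma2_b_mean: np.ndarray      # per group (G, non-G); baseline: one value twice
    pi_mean: float
    chains: dict
    n_retained: int
    snp_ids: list[str]
    kept: np.ndarray
    col_means: np.ndarray


# ---------------------------------------------------------------------------
# Hyperparameters
# ---------------------------------------------------------------------------

def compute_hyperparameters(
    y: np.ndarray,
    X: np.ndarray,
    group: SnpGroup | np.ndarray | None,
    weight_setting,
    df: float = 5.0,
    r2_total: float = 0.5,
    block_variance_share: float = 0.05,
) -> PriorSpec:
    """Slab-variance prior scales from the S0 = var(y) R^2 (df+2) / MSx rule.

    ``weight_setting`` is "baseline" (single group over all SNPs) or one of
    25/50/75 — the percentage of total genetic variance the group G is
    assumed to explain, mapping to (R2_G, R2_nonG) = (0.125, 0.375),
    (0.25, 0.25), (0.375, 0.125). MSx per group is the sum of the sample
    variances of that group's genotype columns. Residual and random-effect
    block variances get the same scaled inverse chi-square form, with
    variance shares (1 - R^2) and ``block_variance_share`` respectively.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    var_y = y.var()
    if var_y == 0:
        raise ValueError("phenotype variance is zero")
    key = str(weight_setting).removesuffix("%").lower()
    if key in ("none", "0"):
        key = "baseline"
    if key not in WEIGHT_SETTINGS:
        raise ValueError(f"weight_setting must be one of {list(WEIGHT_SETTINGS)}")

    if group is None:
        g_idx = np.array([], dtype=np.int64)
    elif isinstance(group, SnpGroup):
        g_idx = np.asarray(group.indices, dtype=np.int64)
    else:
        g_idx = np.asarray(group, dtype=np.int64)

    col_var = X.var(axis=0, ddof=1)
    s0_e = var_y * (1.0 - r2_total) * (df + 2.0)
    s0_block = var_y * block_variance_share * (df + 2.0)

    if key == "baseline" or len(g_idx) == 0:
        msx = col_var.sum()
        if msx == 0:
            raise ValueError("MSx over all SNPs is zero")
        s0 = var_y * r2_total * (df + 2.0) / msx
        return PriorSpec(df=df, s0_de=s0, s0_nonde=s0,
                         r2_de=r2_total / 2, r2_nonde=r2_total / 2,
                         group=np.array([], dtype=np.int64),
                         df_e=df, s0_e=s0_e, df_u=df,
                         s0_year=s0_block, s0_exp=s0_block, baseline=True)

    r2_de, r2_nonde = WEIGHT_SETTINGS[key]
    in_g = np.zeros(X.shape[1], dtype=bool)
    in_g[g_idx] = True
    msx_de = col_var[in_g].sum()
    msx_nonde = col_var[~in_g].sum()
    if msx_de == 0:
        raise ValueError("MSx of the weighted group G is zero")
    if msx_nonde == 0:
        raise ValueError("MSx of the complement of G is zero")
    return PriorSpec(
        df=df,
        s0_de=var_y * r2_de * (df + 2.0) / msx_de,
        s0_nonde=var_y * r2_nonde * (df + 2.0) / msx_nonde,
        r2_de=r2_de, r2_nonde=r2_nonde, group=g_idx,
        df_e=df, s0_e=s0_e, df_u=df,
        s0_year=s0_block, s0_exp=s0_block, baseline=False,
    )


# ---------------------------------------------------------------------------
# Gibbs kernel
# ---------------------------------------------------------------------------

@numba.njit(fastmath=False)
def _gibbs_kernel(y, X, xtx, group_id, s0_g, df,
                  s0_e, df_e, year_idx, n_year, s0_year,
                  exp_idx, n_exp, s0_exp, df_u,
                  p0, pi0, burn, iters, thin, seed, order,
                  include_intercept, pi_fixed, s2b_fixed, s2e_fixed):
    np.random.seed(seed)
    n, p = X.shape
    n_groups = s0_g.shape[0]
    n_keep = iters // thin

    beta = np.zeros(p)
    gamma = np.zeros(p, dtype=numba.uint8)
    alpha = np.zeros(max(n_year, 1))
    block = np.zeros(max(n_exp, 1))
    beta0 = 0.0
    s2b = np.empty(n_groups)
    for g in range(n_groups):
        s2b[g] = s0_g[g] * df / (df + 2.0) if np.isnan(s2b_fixed[g]) else s2b_fixed[g]
    s2e = (df_e * s0_e / (df_e + 2.0)) if np.isnan(s2e_fixed) else s2e_fixed
    pi = pi0 if np.isnan(pi_fixed) else pi_fixed

    ycorr = y.copy()

    beta0_chain = np.zeros(n_keep)
    beta_chain = np.zeros((n_keep, p))
    gamma_sum = np.zeros(p)
    alpha_chain = np.zeros((n_keep, max(n_year, 1)))
    block_chain = np.zeros((n_keep, max(n_exp, 1)))
    s2e_chain = np.zeros(n_keep)
    s2b_chain = np.zeros((n_keep, n_groups))
    pi_chain = np.zeros(n_keep)
    s2u_chain = np.zeros((n_keep, 2))

    s2_year = s0_year * df_u / (df_u + 2.0)
    s2_exp = s0_exp * df_u / (df_u + 2.0)

    counts_year = np.zeros(max(n_year, 1))
    for i in range(n):
        if n_year > 0:
            counts_year[year_idx[i]] += 1.0
    counts_exp = np.zeros(max(n_exp, 1))
    for i in range(n):
        if n_exp > 0:
            counts_exp[exp_idx[i]] += 1.0

    for it in range(burn + iters):
        # (a) intercept, flat prior
        if include_intercept:
            old = beta0
            s = 0.0
            for i in range(n):
                s += ycorr[i]
            mean = old + s / n
            beta0 = np.random.normal(mean, math.sqrt(s2e / n))
            delta = beta0 - old
            for i in range(n):
                ycorr[i] -= delta

        # (b) year block: normal full conditionals per level, then its
        # variance from a scaled inverse chi-square full conditional
        if n_year > 0:
            sums = np.zeros(n_year)
            for i in range(n):
                sums[year_idx[i]] += ycorr[i]
            for k in range(n_year):
                old = alpha[k]
                r = sums[k] + counts_year[k] * old
                v = 1.0 / (counts_year[k] / s2e + 1.0 / s2_year)
                newv = np.random.normal(v * r / s2e, math.sqrt(v))
                d = newv - old
                alpha[k] = newv
                for i in range(n):
                    if year_idx[i] == k:
                        ycorr[i] -= d
            ss = 0.0
            for k in range(n_year):
                ss += alpha[k] * alpha[k]
            s2_year = (df_u * s0_year + ss) / np.random.chisquare(df_u + n_year)

        # (b') experiment block
        if n_exp > 0:
            sums = np.zeros(n_exp)
            for i in range(n):
                sums[exp_idx[i]] += ycorr[i]
            for k in range(n_exp):
                old = block[k]
                r = sums[k] + counts_exp[k] * old
                v = 1.0 / (counts_exp[k] / s2e + 1.0 / s2_exp)
                newv = np.random.normal(v * r / s2e, math.sqrt(v))
                d = newv - old
                block[k] = newv
                for i in range(n):
                    if exp_idx[i] == k:
                        ycorr[i] -= d
            ss = 0.0
            for k in range(n_exp):
                ss += block[k] * block[k]
            s2_exp = (df_u * s0_exp + ss) / np.random.chisquare(df_u + n_exp)

        # (c) markers, fixed permutation order
        logit_pi = math.log(pi / (1.0 - pi)) if 0.0 < pi < 1.0 else (
            1e30 if pi >= 1.0 else -1e30)
        for jj in range(p):
            j = order[jj]
            c = xtx[j]
            old = beta[j]
            r = 0.0
            for i in range(n):
                r += X[i, j] * ycorr[i]
            r += c * old
            s2bj = s2b[group_id[j]]
            v0 = c * s2e
            v1 = c * c * s2bj + v0
            log_bf = 0.5 * (math.log(v0) - math.log(v1)) \
                + 0.5 * r * r * (1.0 / v0 - 1.0 / v1)
            logodds = logit_pi + log_bf
            if logodds > 35.0:
                prob = 1.0
            elif logodds < -35.0:
                prob = 0.0
            else:
                prob = 1.0 / (1.0 + math.exp(-logodds))
            if np.random.random() < prob:
                vpost = 1.0 / (c / s2e + 1.0 / s2bj)
                bnew = np.random.normal(vpost * r / s2e, math.sqrt(vpost))
                gamma[j] = 1
            else:
                bnew = 0.0
                gamma[j] = 0
            d = bnew - old
            if d != 0.0:
                for i in range(n):
                    ycorr[i] -= X[i, j] * d
            beta[j] = bnew

        # (d) per-group slab variances
        for g in range(n_groups):
            if np.isnan(s2b_fixed[g]):
                ssb = 0.0
                m_g = 0.0
                for j in range(p):
                    if group_id[j] == g and gamma[j] == 1:
                        ssb += beta[j] * beta[j]
                        m_g += 1.0
                s2b[g] = (df * s0_g[g] + ssb) / np.random.chisquare(df + m_g)

        # (e) inclusion probability
        m = 0.0
        for j in range(p):
            m += gamma[j]
        if np.isnan(pi_fixed):
            pi = np.random.beta(p0 * pi0 + m, p0 * (1.0 - pi0) + p - m)

        # (f) residual variance
        if np.isnan(s2e_fixed):
            sse = 0.0
            for i in range(n):
                sse += ycorr[i] * ycorr[i]
            s2e = (df_e * s0_e + sse) / np.random.chisquare(df_e + n)

        if not (np.isfinite(s2e) and np.isfinite(beta0)):
            raise ValueError("non-finite value during sampling")

        # store thinned post-burn-in samples
        if it >= burn and (it - burn) % thin == thin - 1:
            k = (it - burn) // thin
            beta0_chain[k] = beta0
            for j in range(p):
                beta_chain[k, j] = beta[j]
                gamma_sum[j] += gamma[j]
            for q in range(max(n_year, 1)):
                alpha_chain[k, q] = alpha[q]
            for q in range(max(n_exp, 1)):
                block_chain[k, q] = block[q]
            s2e_chain[k] = s2e
            for g in range(n_groups):
                s2b_chain[k, g] = s2b[g]
            pi_chain[k] = pi
            s2u_chain[k, 0] = s2_year
            s2u_chain[k, 1] = s2_exp

    return (beta0_chain, beta_chain, gamma_sum, alpha_chain, block_chain,
            s2e_chain, s2b_chain, pi_chain, s2u_chain)


def run_gibbs(
    data: GPModelData,
    prior: PriorSpec,
    mcmc: McmcConfig,
    include_intercept: bool = True,
    pi_fixed: float | None = None,
    sigma2_b_fixed=None,
    sigma2_e_fixed: float | None = None,
) -> PosteriorSummary:
    """Sample the joint posterior; see the module docstring for the model.

    The ``*_fixed`` arguments clamp pi, the slab variance(s), or the residual
    variance at given values instead of sampling them — used for analytic
    cross-checks such as the ridge limit (pi = 1, fixed variances).
    """
    kept_idx = np.flatnonzero(data.kept)
    x = np.asfortranarray(data.X[:, kept_idx])
    xtx = (x * x).sum(axis=0)
    p_fit = x.shape[1]
    if p_fit == 0:
        raise ValueError("no non-constant genotype columns to fit")

    group_id = np.ones(data.p, dtype=np.int64)   # 1 = non-G
    if not prior.baseline and len(prior.group):
        group_id[prior.group] = 0
    group_id = group_id[kept_idx]
    s0_g = np.array([prior.s0_de, prior.s0_nonde])

    rng = np.random.default_rng(mcmc.seed)
    order = rng.permutation(p_fit)

    if sigma2_b_fixed is None:
        s2b_fixed = np.array([np.nan, np.nan])
    else:
        s2b_fixed = np.asarray(
            [sigma2_b_fixed, sigma2_b_fixed] if np.isscalar(sigma2_b_fixed)
            else sigma2_b_fixed, dtype=float)

    year_idx = data.year_idx if data.year_idx is not None else np.zeros(0, dtype=np.int64)
    exp_idx = data.exp_idx if data.exp_idx is not None else np.zeros(0, dtype=np.int64)
    n_year = len(data.year_levels) if data.year_idx is not None else 0
    n_exp = len(data.exp_levels) if data.exp_idx is not None else 0

    out = _gibbs_kernel(
        np.ascontiguousarray(data.y), x, xtx,
        np.ascontiguousarray(group_id), s0_g, float(prior.df),
        float(prior.s0_e), float(prior.df_e),
        np.ascontiguousarray(year_idx, dtype=np.int64), n_year, float(prior.s0_year),
        np.ascontiguousarray(exp_idx, dtype=np.int64), n_exp, float(prior.s0_exp),
        float(prior.df_u),
        float(prior.p0), float(prior.pi0),
        int(mcmc.burn_in), int(mcmc.iterations), int(mcmc.thin),
        int(mcmc.seed) % (2**31), np.ascontiguousarray(order),
        include_intercept,
        np.nan if pi_fixed is None else float(pi_fixed),
        s2b_fixed,
        np.nan if sigma2_e_fixed is None else float(sigma2_e_fixed),
    )
    (beta0_chain, beta_chain, gamma_sum, alpha_chain, block_chain,
     s2e_chain, s2b_chain, pi_chain, s2u_chain) = out
    n_keep = mcmc.n_retained

    beta_mean = np.zeros(data.p)
    beta_mean[kept_idx] = beta_chain.mean(axis=0)
    incl = np.zeros(data.p)
    incl[kept_idx] = gamma_sum / n_keep

    return PosteriorSummary(
        beta0_mean=float(beta0_chain.mean()),
        beta_mean=beta_mean,
        inclusion_prob=incl,
        alpha_mean=alpha_chain.mean(axis=0) if n_year else np.zeros(0),
        block_mean=block_chain.mean(axis=0) if n_exp else np.zeros(0),
        sigma2_e_mean=float(s2e_chain.mean()),
        sigma2_b_mean=s2b_chain.mean(axis=0),
        pi_mean=float(pi_chain.mean()),
        chains={
            "beta0": beta0_chain, "beta": beta_chain, "sigma2_e": s2e_chain,
            "sigma2_b": s2b_chain, "pi": pi_chain, "alpha": alpha_chain,
            "block": block_chain, "sigma2_u": s2u_chain,
        },
        n_retained=n_keep,
        snp_ids=list(data.snp_ids),
        kept=data.kept.copy(),
        col_means=data.col_means.copy(),
    )


def predict_gebv(posterior: PosteriorSummary, x_new: np.ndarray,
                 snp_ids: list[str] | None = None) -> np.ndarray:
    """Genomic estimated values: beta0 + X_new @ posterior-mean beta.

    Year/experiment effects are excluded — new-season lines carry unseen
    levels. Missing genotypes (NaN) are imputed with the training column
    means. ``snp_ids``, when given, must match the training order.
    """
    x_new = np.asarray(x_new, dtype=float)
    if x_new.ndim != 2 or x_new.shape[1] != len(posterior.snp_ids):
        raise ValueError(
            f"X_new has {x_new.shape[1] if x_new.ndim == 2 else '?'} columns; "
            f"training had {len(posterior.snp_ids)}")
    if snp_ids is not None:
        bad = [a for a, b in zip(snp_ids, posterior.snp_ids) if a != b]
        if bad:
            raise ValueError(f"SNP order mismatch, first offenders: {bad[:5]}")
    if np.isnan(x_new).any():
        x_new = x_new.copy()
        idx = np.where(np.isnan(x_new))
        x_new[idx] = posterior.col_means[idx[1]]
    return posterior.beta0_mean + x_new @ posterior.beta_mean
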