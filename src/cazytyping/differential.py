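"""Negative-binomial Wald differential abundance of CAZyme families.

The count model follows the DESeq-style contract: per-sample size factors
by median-of-ratios, per-family NB2 dispersions estimated by method of
moments, pooled through a parametric mean-dispersion trend
``alpha(mu) = a0 + a1 / mu`` and shrunk toward it in log space, then a
per-family NB GLM (log link, size-factor offsets) fit by iteratively
reweighted least squares.  Wald z statistics test contrast combinations of
the coefficients of the full design ``phenotype + body_site +
phenotype:body_site``; p-values are Benjamini-Hochberg adjusted, and a
family is a marker when |log2 fold change| exceeds the threshold strictly
and the adjusted p falls below the FDR cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

MIN_DISPERSION = 1e-8
MAX_DISPERSION = 10.0

#: The pairwise comparisons reported by default: oral vs gut, and each
#: disease phenotype against healthy controls.
DEFAULT_CONTRASTS = (
    ("body_site", "oral", "gut"),
    ("phenotype", "CRC", "control"),
    ("phenotype", "T1D", "control"),
    ("phenotype", "RA", "control"),
)


@dataclass
class CountMatrix:
    """Families x samples integer counts with per-sample design factors."""

    counts: pd.DataFrame
    design: pd.DataFrame  # sample-indexed, columns phenotype / body_site

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.design.index):
            self.design = self.design.reindex(self.counts.columns)
        if self.design.isna().any().any():
            missing = list(self.design.index[self.design.isna().any(axis=1)])
            raise ValueError(f"samples with incomplete design factors: {missing}")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integral; round projected abundances first")
        self.counts = self.counts.astype(np.int64)


def round_abundances(
    abundances: pd.DataFrame, design: pd.DataFrame
) -> CountMatrix:
    """Round projected (samples x families) abundances to nearest-integer
    counts in families x samples orientation for the count model."""
    counts = abundances.T.round().astype(np.int64)
    cm = CountMatrix(counts=counts, design=design.loc[counts.columns])
    return cm


# --------------------------------------------------------------------------
# size factors
# --------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    The reference per family is the geometric mean across samples; a
    sample's factor is the median ratio to the reference over families
    positive in every sample.  If no family is everywhere-positive the
    median falls back, per sample, to the families positive in that
    sample (logged).
    """
    k = counts.to_numpy(float)
    with np.errstate(divide="ignore"):
        logk = np.log(k)
    all_positive = np.isfinite(logk).all(axis=1)
    factors = np.empty(k.shape[1])
    if all_positive.any():
        log_gm = logk[all_positive].mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logk[all_positive] - log_gm, axis=0))
    else:
        logger.warning(
            "no family is positive in all samples; falling back to the "
            "positive-subset median per sample"
        )
        finite_any = np.isfinite(logk).any(axis=1)
        log_gm = np.where(
            finite_any,
            np.nanmean(np.where(np.isfinite(logk), logk, np.nan), axis=1),
            np.nan,
        )
        for j in range(k.shape[1]):
            ok = np.isfinite(logk[:, j]) & np.isfinite(log_gm)
            if not ok.any():
                raise ValueError(f"sample {counts.columns[j]!r} has no positive counts")
            factors[j] = np.exp(np.median(logk[ok, j] - log_gm[ok]))
    if (factors <= 0).any() or not np.isfinite(factors).all():
        raise ValueError("size factors must be positive and finite")
    return pd.Series(factors, index=counts.columns, name="size_factor")


# --------------------------------------------------------------------------
# dispersion estimation
# --------------------------------------------------------------------------

@dataclass
class DispersionEstimates:
    """Gene-wise, trended and shrunken NB dispersions per family."""

    genewise: pd.Series
    trend: pd.Series
    shrunken: pd.Series
    trend_coefficients: tuple[float, float] = (0.0, 0.0)
    prior_variance: float = 0.0
    all_zero: list = field(default_factory=list)


def _design_cells(design: pd.DataFrame) -> np.ndarray:
    """Integer id of the design cell (factor combination) of each sample."""
    key = design.astype(str).agg("|".join, axis=1)
    _, codes = np.unique(key.to_numpy(), return_inverse=True)
    return codes


def _fit_dispersion_trend(
    mu: np.ndarray, alpha: np.ndarray, n_iter: int = 10
) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu by iteratively reweighted least squares
    with gamma-style weights 1/fitted^2."""
    x = np.column_stack([np.ones_like(mu), 1.0 / mu])
    w = np.ones_like(alpha)
    a = np.array([np.median(alpha), 0.0])
    for _ in range(n_iter):
        xtw = x.T * w
        try:
            a_new = np.linalg.solve(xtw @ x, xtw @ alpha)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate grid
            break
        a_new = np.maximum(a_new, 0.0)
        fitted = np.maximum(x @ a_new, MIN_DISPERSION)
        w = 1.0 / fitted**2
        if np.allclose(a_new, a, rtol=1e-6, atol=1e-12):
            a = a_new
            break
        a = a_new
    a[0] = max(a[0], MIN_DISPERSION)
    return float(a[0]), float(a[1])


def _cr_ml_dispersion(
    y: np.ndarray, mu: np.ndarray, cells: np.ndarray, alpha_init: float
) -> float:
    """Cox-Reid-adjusted maximum-likelihood NB dispersion for one family.

    ``mu`` are the fitted per-sample means (cell means scaled by size
    factors); the Cox-Reid term penalises the information consumed by the
    fitted cell means.  Optimised on the log scale within the global
    dispersion bounds, starting near the moment estimate.
    """
    from scipy.optimize import minimize_scalar
    from scipy.special import gammaln

    cell_ids = np.unique(cells)

    def neg_crll(log_alpha: float) -> float:
        a = np.exp(log_alpha)
        inv = 1.0 / a
        ll = float(
            np.sum(
                gammaln(y + inv) - gammaln(inv)
                + y * np.log(a * mu / (1.0 + a * mu))
                - inv * np.log1p(a * mu)
            )
        )
        w = mu / (1.0 + a * mu)
        cr = 0.5 * float(sum(np.log(w[cells == c].sum()) for c in cell_ids))
        return -(ll - cr)

    lo, hi = np.log(MIN_DISPERSION), np.log(MAX_DISPERSION)
    res = minimize_scalar(neg_crll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    best = float(res.x)
    # guard against a boundary local optimum far from the moment estimate
    if np.isfinite(alpha_init):
        start = np.clip(np.log(alpha_init), lo, hi)
        if neg_crll(start) < res.fun:
            best = start
    return float(np.exp(best))


def estimate_dispersions(
    counts: pd.DataFrame,
    factors: pd.Series,
    design: pd.DataFrame,
) -> DispersionEstimates:
    """Estimate per-family NB dispersions.

    The method-of-moments value on normalized counts (within-design-cell
    pooled variance) initializes a Cox-Reid-adjusted maximum-likelihood
    gene-wise estimate; the parametric trend ``a0 + a1/mu`` is fit by
    iterative reweighting; shrinkage combines gene-wise and trend in log
    space with precision weights, the sampling variance of a log
    dispersion approximated by trigamma((n - m) / 2).  All-zero families
    are flagged and excluded from testing.
    """
    k = counts.to_numpy(float)
    s = factors.reindex(counts.columns).to_numpy(float)
    q = k / s  # normalized counts
    n = q.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    cells = _design_cells(design.loc[counts.columns])
    n_cells = len(np.unique(cells))
    if n - n_cells < 1:
        raise ValueError("no replicates in any design cell; dispersion not estimable")

    mu = q.mean(axis=1)
    all_zero = mu == 0
    # method-of-moments on normalized counts (pooled within-cell variance)
    ss = np.zeros(q.shape[0])
    cell_means = np.empty_like(q)
    for c in np.unique(cells):
        idx = cells == c
        m_c = q[:, idx].mean(axis=1, keepdims=True)
        cell_means[:, idx] = m_c
        if idx.sum() > 1:
            ss += ((q[:, idx] - m_c) ** 2).sum(axis=1)
    v = ss / max(n - n_cells, 1)
    xi = float(np.mean(1.0 / s))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (v - xi * mu) / mu**2
    alpha_mom = np.clip(
        np.nan_to_num(alpha_mom, nan=MIN_DISPERSION), MIN_DISPERSION, MAX_DISPERSION
    )

    alpha_gw = alpha_mom.copy()
    fitted_mu = cell_means * s  # back on the raw count scale
    for i in np.flatnonzero(~all_zero):
        alpha_gw[i] = _cr_ml_dispersion(k[i], np.maximum(fitted_mu[i], 1e-8),
                                        cells, alpha_mom[i])

    usable = (~all_zero) & (alpha_gw > MIN_DISPERSION * 10)
    if usable.sum() >= 3:
        a0, a1 = _fit_dispersion_trend(mu[usable], alpha_gw[usable])
    else:
        a0, a1 = max(float(np.median(alpha_gw[~all_zero])) if (~all_zero).any() else MIN_DISPERSION, MIN_DISPERSION), 0.0
    with np.errstate(divide="ignore"):
        alpha_tr = np.where(mu > 0, a0 + a1 / np.maximum(mu, 1e-300), a0)
    alpha_tr = np.clip(alpha_tr, MIN_DISPERSION, MAX_DISPERSION)

    # log-space shrinkage toward the trend
    exp_var = float(special.polygamma(1, max(n - n_cells, 1) / 2.0))
    log_resid = np.log(alpha_gw[usable]) - np.log(alpha_tr[usable])
    prior_var = max(float(np.var(log_resid, ddof=1)) - exp_var, 0.25) if usable.sum() > 2 else 0.25
    w = (1.0 / exp_var) / (1.0 / exp_var + 1.0 / prior_var)
    log_shrunk = w * np.log(alpha_gw) + (1.0 - w) * np.log(alpha_tr)
    alpha_sh = np.clip(np.exp(log_shrunk), MIN_DISPERSION, MAX_DISPERSION)

    idx = counts.index
    return DispersionEstimates(
        genewise=pd.Series(alpha_gw, index=idx, name="dispersion_genewise"),
        trend=pd.Series(alpha_tr, index=idx, name="dispersion_trend"),
        shrunken=pd.Series(alpha_sh, index=idx, name="dispersion_shrunken"),
        trend_coefficients=(a0, a1),
        prior_variance=prior_var,
        all_zero=list(idx[all_zero]),
    )


# --------------------------------------------------------------------------
# design matrix and contrasts
# --------------------------------------------------------------------------

def build_design_matrix(
    design: pd.DataFrame,
    phenotype_ref: str = "control",
    site_ref: str = "gut",
    interaction: bool = True,
) -> pd.DataFrame:
    """Treatment-coded design matrix for phenotype + body_site (+ interaction).

    Columns: intercept, one indicator per non-reference phenotype
    (``phenotype[X]``), ``site[oral]`` style indicators, and their
    products when ``interaction`` is set.  Raises if the matrix is rank
    deficient for the included terms, naming the aliased columns.
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(design))}
    ph = design["phenotype"].astype(str)
    levels_ph = [l for l in pd.unique(ph) if l != phenotype_ref]
    site = design["body_site"].astype(str)
    levels_site = [l for l in pd.unique(site) if l != site_ref]
    for l in sorted(levels_ph):
        cols[f"phenotype[{l}]"] = (ph == l).to_numpy(float)
    for l in sorted(levels_site):
        cols[f"site[{l}]"] = (site == l).to_numpy(float)
    if interaction:
        for lp in sorted(levels_ph):
            for ls in sorted(levels_site):
                cols[f"phenotype[{lp}]:site[{ls}]"] = (
                    (ph == lp) & (site == ls)
                ).to_numpy(float)
    x = pd.DataFrame(cols, index=design.index)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # locate aliased columns by greedy rank check
        aliased = []
        kept: list[str] = []
        for c in x.columns:
            trial = x[kept + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(c)
            else:
                aliased.append(c)
        raise ValueError(f"design matrix rank deficient; aliased terms: {aliased}")
    return x


def contrast_vector(
    design_matrix: pd.DataFrame,
    factor: str,
    level: str,
    reference: str,
    phenotype_ref: str = "control",
    site_ref: str = "gut",
) -> np.ndarray:
    """Coefficient combination testing ``level`` vs ``reference`` of a factor,
    at the reference level of the other factor (treatment coding)."""
    c = np.zeros(design_matrix.shape[1])
    names = list(design_matrix.columns)

    def add(name: str, weight: float) -> None:
        if name in names:
            c[names.index(name)] += weight
        elif weight != 0.0:
            raise KeyError(f"term {name!r} not in design matrix")

    if factor == "phenotype":
        if level != phenotype_ref:
            add(f"phenotype[{level}]", 1.0)
        if reference != phenotype_ref:
            add(f"phenotype[{reference}]", -1.0)
    elif factor == "body_site":
        if level != site_ref:
            add(f"site[{level}]", 1.0)
        if reference != site_ref:
            add(f"site[{reference}]", -1.0)
    else:
        raise ValueError(f"unknown factor: {factor!r}")
    return c


# --------------------------------------------------------------------------
# NB GLM by IRLS and the Wald test
# --------------------------------------------------------------------------

def nb_irls(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    max_iter: int = 100,
    tol: float = 1e-8,
    ridge: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit an NB2 GLM with log link and fixed dispersion by IRLS.

    Returns (beta, covariance, converged).  A tiny ridge keeps separated
    designs (e.g. a family absent from one body site) finite; the linear
    predictor is clamped to +-30 around the offset.
    """
    n, p = x.shape
    with np.errstate(divide="ignore"):
        init = np.log(np.maximum(y, 0.5)) - offset
    beta, *_ = np.linalg.lstsq(x, init, rcond=None)
    eye = np.eye(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30.0, 30.0)
        mu = np.exp(eta + offset)
        w = mu / (1.0 + alpha * mu)
        z = eta + (y - mu) / mu
        xtw = x.T * w
        try:
            beta_new = np.linalg.solve(xtw @ x + ridge * eye, xtw @ z)
        except np.linalg.LinAlgError:
            return beta, np.full((p, p), np.nan), False
        step = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if step < tol:
            converged = True
            break
    eta = np.clip(x @ beta, -30.0, 30.0)
    mu = np.exp(eta + offset)
    w = mu / (1.0 + alpha * mu)
    xtw = x.T * w
    try:
        cov = np.linalg.inv(xtw @ x + ridge * eye)
    except np.linalg.LinAlgError:  # pragma: no cover - guarded by ridge
        cov = np.full((p, p), np.nan)
    return beta, cov, converged


@dataclass
class DifferentialResult:
    """Per-family Wald test results for one contrast."""

    table: pd.DataFrame  # baseMean, log2FC_raw, log2FC_shrunk, lfcSE, stat, pvalue, padj
    contrast: str
    lfc_threshold: float = 2.0
    fdr_threshold: float = 0.01

    def markers(self) -> pd.DataFrame:
        return self.table[self.table["marker"]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="family")


def fit_and_test(
    count_matrix: CountMatrix,
    contrast: tuple[str, str, str],
    dispersions: DispersionEstimates | None = None,
    factors: pd.Series | None = None,
    interaction: bool = True,
    phenotype_ref: str = "control",
    site_ref: str = "gut",
    shrink: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> DifferentialResult:
    """Per-family NB Wald test of one pairwise contrast under the full model.

    ``contrast`` is (factor, level, reference), e.g. ("phenotype", "T1D",
    "control") or ("body_site", "oral", "gut").  Wald z = c'beta /
    SE(c'beta) with a two-sided normal p; the shrunken log2 fold change
    applies a normal prior on the contrast coefficient whose scale is
    estimated from the spread of the MLE estimates across families.
    Non-converged families keep their estimates but get a missing p.
    """
    counts = count_matrix.counts
    design = count_matrix.design
    if factors is None:
        factors = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, factors, design)
    x = build_design_matrix(
        design, phenotype_ref=phenotype_ref, site_ref=site_ref, interaction=interaction
    )
    c = contrast_vector(
        x, *contrast, phenotype_ref=phenotype_ref, site_ref=site_ref
    )
    xm = x.to_numpy(float)
    offset = np.log(factors.reindex(counts.columns).to_numpy(float))
    alpha = dispersions.shrunken
    excluded = set(dispersions.all_zero)

    n_fam = counts.shape[0]
    base_mean = (counts.to_numpy(float) / np.exp(offset)).mean(axis=1)
    beta_c = np.full(n_fam, np.nan)
    se_c = np.full(n_fam, np.nan)
    converged = np.zeros(n_fam, dtype=bool)
    for i, fam in enumerate(counts.index):
        if fam in excluded:
            continue
        y = counts.iloc[i].to_numpy(float)
        beta, cov, ok = nb_irls(
            y, xm, offset, float(alpha.iloc[i]), max_iter=max_iter, tol=tol
        )
        if not np.isfinite(cov).all():
            continue
        beta_c[i] = float(c @ beta)
        se_c[i] = float(np.sqrt(c @ cov @ c))
        converged[i] = ok
        if not ok:
            logger.info("family %s: IRLS did not converge in %d iterations", fam, max_iter)

    finite = np.isfinite(beta_c) & np.isfinite(se_c)
    if shrink and finite.sum() > 2:
        beta_shrunk = _shrink_lfc(beta_c, se_c)
    else:
        beta_shrunk = beta_c.copy()

    with np.errstate(invalid="ignore", divide="ignore"):
        stat = beta_c / se_c
    pvalue = np.where(
        np.isfinite(stat) & converged, 2.0 * stats.norm.sf(np.abs(stat)), np.nan
    )
    padj = bh_adjust(pd.Series(pvalue, index=counts.index)).to_numpy()

    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC_raw": beta_c / LN2,
            "log2FC_shrunk": beta_shrunk / LN2,
            "lfcSE": se_c / LN2,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
            "converged": converged,
        },
        index=counts.index,
    )
    contrast_label = f"{contrast[1]}_vs_{contrast[2]}"
    result = DifferentialResult(table=table, contrast=contrast_label)
    call_markers(result)
    return result


def _shrink_lfc(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Empirical-Bayes shrinkage of contrast coefficients for low counts.

    Heavy-tailed (Cauchy) prior centred at zero, posterior mode under the
    normal approximation ``beta_hat ~ N(beta, se^2)``: noisy estimates are
    pulled strongly toward zero while well-determined large effects are
    left almost untouched.  The prior scale is the excess spread of the
    MLEs over their sampling noise.
    """
    from scipy.optimize import minimize_scalar

    finite = np.isfinite(beta) & np.isfinite(se)
    excess = float(np.mean(beta[finite] ** 2)) - float(np.mean(se[finite] ** 2))
    scale2 = max(excess, 1e-4)

    out = beta.copy()
    for i in np.flatnonzero(finite):
        bh, s2 = beta[i], se[i] ** 2
        if bh == 0.0 or s2 == 0.0:
            continue  # exact or infinitely precise estimates stay put

        def neg_log_post(b):
            return (b - bh) ** 2 / (2.0 * s2) + np.log1p(b * b / scale2)

        lo, hi = (bh, 0.0) if bh < 0 else (0.0, bh)
        res = minimize_scalar(
            neg_log_post, bounds=(lo - 1e-12, hi + 1e-12), method="bounded",
            options={"xatol": 1e-10},
        )
        out[i] = float(res.x)
    return out


def bh_adjust(pvalues: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing values are propagated and do not count toward m.  Values
    outside [0, 1] raise.
    """
    p = pd.Series(pvalues, dtype=float)
    valid = p.dropna()
    if ((valid < 0) | (valid > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(valid)
    adjusted = pd.Series(np.nan, index=p.index)
    if m == 0:
        return adjusted
    order = np.argsort(valid.to_numpy(), kind="stable")
    ranked = valid.to_numpy()[order]
    scaled = ranked * m / np.arange(1, m + 1)
    monotone = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted.loc[valid.index[order]] = np.minimum(monotone, 1.0)
    return adjusted


def call_markers(
    result: DifferentialResult,
    lfc_threshold: float = 2.0,
    fdr_threshold: float = 0.01,
    use_shrunk: bool = True,
) -> pd.DataFrame:
    """Flag marker families: |log2FC| strictly above the threshold and
    adjusted p strictly below the FDR cut.  Updates ``result.table`` in
    place (marker / direction columns) and returns the volcano export
    (log2FC, -log10 adjusted p, flag)."""
    t = result.table
    lfc = t["log2FC_shrunk"] if use_shrunk else t["log2FC_raw"]
    padj = t["padj"]
    marker = (lfc.abs() > lfc_threshold) & (padj < fdr_threshold)
    marker = marker.fillna(False)
    direction = pd.Series("none", index=t.index)
    direction[marker & (lfc > 0)] = "enriched"
    direction[marker & (lfc < 0)] = "depleted"
    t["marker"] = marker
    t["direction"] = direction
    result.lfc_threshold = lfc_threshold
    result.fdr_threshold = fdr_threshold
    with np.errstate(divide="ignore"):
        neglog = -np.log10(padj.to_numpy(float))
    return pd.DataFrame(
        {"log2FC": lfc, "neg_log10_padj": neglog, "marker": marker}, index=t.index
    )


def run_contrasts(
    count_matrix: CountMatrix,
    contrasts: Sequence[tuple[str, str, str]] = DEFAULT_CONTRASTS,
    **kwargs,
) -> dict[str, DifferentialResult]:
    """Fit once per contrast (size factors and dispersions shared) and
    return results keyed by contrast label."""
    factors = size_factors(count_matrix.counts)
    dispersions = estimate_dispersions(
        count_matrix.counts, factors, count_matrix.design
    )
    results = {}
    for contrast in contrasts:
        res = fit_and_test(
            count_matrix,
            contrast,
            dispersions=dispersions,
            factors=factors,
            **kwargs,
        )
        results[res.contrast] = res
    return results
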