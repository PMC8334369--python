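"""Statistical primitives shared by every pipeline stage.

Every hypothesis test used downstream lives here, implemented directly
(only distribution tail functions are taken from :mod:`scipy.stats`):
Benjamini-Hochberg adjustment, exact binomial and Hardy-Weinberg tests,
Pearson chi-square independence, Kruskal-Wallis, rank correlations,
linear/logistic regression with Wald tests, and inverse-variance
fixed-effect meta-analysis.

All functions are pure and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "TestResult",
    "RegressionFit",
    "MetaResult",
    "bh_adjust",
    "binomial_two_sided",
    "chi2_independence",
    "kruskal_wallis",
    "spearman_rho",
    "kendall_tau",
    "kendall_tau_test",
    "linear_fit",
    "logistic_fit",
    "hwe_exact",
    "fixed_effect_meta",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError(f"non-finite test statistic: {self.statistic!r}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value!r}")


@dataclass(frozen=True)
class RegressionFit:
    """Coefficients and Wald tests of a fitted regression model.

    ``coefficients[0]`` is the intercept; remaining entries follow the
    column order of the predictor matrix passed to the fitting routine.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_stats: np.ndarray
    p_values: np.ndarray
    residual_df: int
    converged: bool = True

    def __post_init__(self) -> None:
        n = len(self.coefficients)
        for name in ("standard_errors", "wald_stats", "p_values"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of coefficients")
        if self.residual_df < 0:
            raise ValueError("negative residual degrees of freedom")


@dataclass(frozen=True)
class MetaResult:
    """Inverse-variance pooled effect across studies."""

    pooled_beta: float
    pooled_se: float
    z: float
    p_value: float
    n_studies: int
    study_weights: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.pooled_se <= 0:
            raise ValueError("pooled SE must be positive")
        if self.n_studies < 1:
            raise ValueError("need at least one study")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Returns ``q_i = min_{j: p_j >= p_i} (p_j * n / rank_j)`` capped at 1;
    adjusted values are never below the raw p-values and preserve their
    ordering after sorting.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    bad = np.where(np.isnan(p) | (p < 0) | (p > 1))[0]
    if bad.size:
        raise ValueError(
            f"p-value outside [0, 1] at index {bad[0]}: {p[bad[0]]!r}"
        )
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Exact two-sided binomial test, defined as twice the smaller tail.

    With ``p0 = 0.5`` this equals the usual small-probability-sum
    definition by symmetry of the null distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly inside (0, 1)")
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    p = min(1.0, 2.0 * min(lower, upper))
    return TestResult(statistic=float(k), p_value=float(p), method="binomial-two-sided")


def chi2_independence(table, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an R x C count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("expected a table with at least 2 rows and 2 columns")
    if (obs < 0).any():
        raise ValueError("negative counts in contingency table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row or column marginal in contingency table")
    expected = np.outer(rows, cols) / obs.sum()
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return TestResult(statistic=statistic, p_value=p, method="chi2-independence", df=df)


def _average_ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction.

    ``groups`` is a sequence of at least two non-empty 1-d samples; the
    statistic is referred to a chi-square distribution with
    ``len(groups) - 1`` degrees of freedom.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in samples):
        raise ValueError("empty group")
    pooled = np.concatenate(samples)
    n = pooled.size
    ranks = _average_ranks(pooled)
    h = 0.0
    offset = 0
    for g in samples:
        r = ranks[offset : offset + g.size]
        h += r.sum() ** 2 / g.size
        offset += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie_term == 0:
        # all observations identical: no evidence against the null
        return TestResult(statistic=0.0, p_value=1.0, method="kruskal-wallis", df=len(samples) - 1)
    h /= tie_term
    df = len(samples) - 1
    p = float(stats.chi2.sf(h, df))
    return TestResult(statistic=float(h), p_value=p, method="kruskal-wallis", df=df)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx = _average_ranks(x)
    ry = _average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("constant input: rank correlation undefined")
    return float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))


def _kendall_counts(x: np.ndarray, y: np.ndarray):
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(x.size, k=1)
    prod = dx[iu] * dy[iu]
    concordant = int((prod > 0).sum())
    discordant = int((prod < 0).sum())
    tx = int(((dx[iu] == 0) & (dy[iu] != 0)).sum())
    ty = int(((dy[iu] == 0) & (dx[iu] != 0)).sum())
    txy = int(((dx[iu] == 0) & (dy[iu] == 0)).sum())
    return concordant, discordant, tx, ty, txy


def kendall_tau(x, y) -> float:
    """Tie-corrected Kendall tau-b from explicit pair enumeration."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    c, d, tx, ty, txy = _kendall_counts(x, y)
    n0 = x.size * (x.size - 1) // 2
    denom = np.sqrt((n0 - (tx + txy)) * (n0 - (ty + txy)))
    if denom == 0:
        raise ValueError("constant input: tau undefined")
    return float(np.clip((c - d) / denom, -1.0, 1.0))


def kendall_tau_test(x, y) -> TestResult:
    """Kendall tau-b with a normal-approximation two-sided p-value.

    The approximation uses the no-tie null variance of the concordance
    score; adequate for the sample sizes the pipeline screens at, and
    documented as an approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    tau = kendall_tau(x, y)
    n = x.size
    var = (2.0 * (2 * n + 5)) / (9.0 * n * (n - 1))
    z = tau / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult(statistic=float(tau), p_value=min(1.0, p), method="kendall-tau-b")


def _as_design(X, n: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] != n:
        raise ValueError("predictor matrix rows must match response length")
    return np.column_stack([np.ones(n), X])


def _check_rank(design: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify a dependent column by incremental rank
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) < j + 1:
                raise ValueError(
                    f"design matrix is rank deficient: predictor column {j - 1} "
                    "(0-based, excluding intercept) is collinear"
                )
        raise ValueError("design matrix is rank deficient")


def linear_fit(y, X) -> RegressionFit:
    """Ordinary least squares with two-sided t-test p-values.

    An intercept column is prepended; ``X`` holds predictors only.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be a 1-d vector")
    design = _as_design(X, y.size)
    if y.size <= design.shape[1]:
        raise ValueError("more parameters than observations")
    _check_rank(design)
    q, r = np.linalg.qr(design)
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - design @ beta
    df = y.size - design.shape[1]
    sigma2 = float(resid @ resid) / df if df > 0 else 0.0
    rinv = np.linalg.inv(r)
    cov = sigma2 * (rinv @ rinv.T)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return RegressionFit(
        coefficients=beta,
        standard_errors=se,
        wald_stats=tstat,
        p_values=np.clip(p, 0.0, 1.0),
        residual_df=df,
    )


def logistic_fit(y, X, tol: float = 1e-8, max_iter: int = 100) -> RegressionFit:
    """Maximum-likelihood logistic regression via iterative reweighting.

    Convergence is declared when the log-likelihood improves by less than
    ``tol``; complete separation is reported through ``converged=False``
    rather than returning silently diverging coefficients.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be a 1-d vector")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("response must be binary 0/1")
    if uniq.size < 2:
        raise ValueError("both response classes must be present")
    design = _as_design(X, y.size)
    _check_rank(design)

    beta = np.zeros(design.shape[1])
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(design @ beta, -30, 30)
        mu = special.expit(eta)
        w = mu * (1 - mu)
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
        wd = design * w[:, None]
        hess = design.T @ wd
        grad = design.T @ (y - mu)
        try:
            beta = beta + np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            converged = False
            break
    eta = np.clip(design @ beta, -30, 30)
    mu = special.expit(eta)
    w = mu * (1 - mu)
    # perfect separation drives fitted probabilities to 0/1 and betas to +-inf
    separated = bool(np.all(np.abs(mu - y) < 1e-6)) or bool(
        np.any(np.abs(beta) > 1e2)
    )
    if separated:
        converged = False
    hess = design.T @ (design * w[:, None])
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(beta.size, np.nan)
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 0.0, 1.0)
    return RegressionFit(
        coefficients=beta,
        standard_errors=se,
        wald_stats=np.nan_to_num(z),
        p_values=np.where(np.isnan(p), 1.0, p),
        residual_df=max(y.size - design.shape[1], 0),
        converged=converged,
    )


def _log_hwe_prob(n_het: int, n_minor_hom: int, n_major_hom: int) -> float:
    """Log probability of a heterozygote configuration given allele counts."""
    n = n_het + n_minor_hom + n_major_hom
    n_minor = 2 * n_minor_hom + n_het
    n_major = 2 * n_major_hom + n_het
    return (
        special.gammaln(n + 1)
        - special.gammaln(n_het + 1)
        - special.gammaln(n_minor_hom + 1)
        - special.gammaln(n_major_hom + 1)
        + n_het * np.log(2.0)
        + special.gammaln(n_minor + 1)
        + special.gammaln(n_major + 1)
        - special.gammaln(2 * n + 1)
    )


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> TestResult:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Sums, over all heterozygote counts compatible with the observed
    allele counts, the probabilities of configurations no more likely
    than the observed one.
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0:
            raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype table")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return TestResult(statistic=float(n_Aa), p_value=1.0, method="hwe-exact")
    het_values = np.arange(n_minor % 2, n_minor + 1, 2)
    logps = np.array(
        [
            _log_hwe_prob(h, (n_minor - h) // 2, n - h - (n_minor - h) // 2)
            for h in het_values
        ]
    )
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    observed = probs[np.where(het_values == n_Aa)[0][0]]
    p = float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))
    return TestResult(statistic=float(n_Aa), p_value=p, method="hwe-exact")


def fixed_effect_meta(betas, ses) -> MetaResult:
    """Inverse-variance weighted fixed-effect pooling of study effects."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape or betas.ndim != 1 or betas.size == 0:
        raise ValueError("betas and ses must be equal-length non-empty vectors")
    if (ses <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses**2
    pooled_beta = float((w * betas).sum() / w.sum())
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    z = pooled_beta / pooled_se
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return MetaResult(
        pooled_beta=pooled_beta,
        pooled_se=pooled_se,
        z=float(z),
        p_value=p,
        n_studies=betas.size,
        study_weights=w / w.sum(),
    )
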