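"""Per-gene statistics for matched exon/intron differential analysis.

Implements the six coordinated differential measures:

* ``E_p`` / ``I_p`` — negative binomial likelihood-ratio test on exon /
  intron counts (variance mu + alpha*mu^2, common dispersion under the
  alternative, chi^2_1 reference).
* ``E_m`` — case/control fold change of calibrated exon means.
* ``G_e`` / ``G_i`` — case/control ratio of unbiased Gini coefficients.
* ``C_d`` — Fisher z test for a change in the exon:intron Pearson
  correlation between groups.

plus the supporting pieces: Benjamini-Hochberg adjustment, min-rescaling,
robust (Huber) zero-intercept slope and the slope-difference test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats
from statsmodels.robust.norms import HuberT
from statsmodels.robust.robust_linear_model import RLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "gini_unbiased",
    "delta_gini",
    "NBTestResult",
    "nb_test",
    "bh_adjust",
    "rescale_by_min",
    "exon_intron_correlation",
    "CorrDiffResult",
    "correlation_differential",
    "robust_slope",
    "slope_difference_test",
]


def gini_unbiased(x: np.ndarray) -> float:
    """Unbiased Gini coefficient of a non-negative sample.

    G = sum_ij |x_i - x_j| / (2 n (n-1) mean(x)), i.e. the mean absolute
    pairwise difference normalised by twice the mean, with the unbiased
    n(n-1) pair count.  Scale-invariant: gini(c*x) == gini(x) for c > 0,
    which is why per-gene length normalisation of counts does not change
    it.  Returns NaN when the mean is zero (undefined).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("gini requires at least 2 observations")
    if np.any(x < 0):
        raise ValueError("gini requires non-negative values")
    m = x.mean()
    if m == 0:
        return float("nan")
    xs = np.sort(x)
    # sum_{i<j} (x_(j)-x_(i)) = sum_k (2k - n + 1) x_(k)  (0-based k)
    k = np.arange(n)
    half_sum = np.sum((2.0 * k - n + 1.0) * xs)
    return float(half_sum / (n * (n - 1) * m))


def delta_gini(g_control: float, g_case: float) -> tuple[float, float]:
    """Relative Gini change and case/control Gini ratio.

    Returns ``((g_case - g_control)/g_control, g_case/g_control)``;
    both NaN when the control Gini is zero or either input is undefined.
    """
    if not np.isfinite(g_control) or not np.isfinite(g_case) or g_control == 0:
        return float("nan"), float("nan")
    return (g_case - g_control) / g_control, g_case / g_control


# ---------------------------------------------------------------------------
# Negative binomial likelihood-ratio test
# ---------------------------------------------------------------------------


@dataclass
class NBTestResult:
    gene_id: str
    region_type: str
    mean_control: float
    mean_case: float
    dispersion: float
    fold_change: float
    p_value: float
    q_value: float = float("nan")


def _nb_loglik(y: np.ndarray, sy: float, glny: float, mu: float, alpha: float) -> float:
    """NB log-likelihood with mean mu, variance mu + alpha*mu^2.

    ``sy`` and ``glny`` are the precomputed sum(y) and sum(gammaln(y+1)).
    alpha == 0 is the Poisson limit.
    """
    n = y.size
    if mu <= 0:
        return 0.0 if sy == 0 else -np.inf
    if alpha <= 0:
        return sy * math.log(mu) - n * mu - glny
    r = 1.0 / alpha
    return float(
        np.sum(special.gammaln(y + r))
        - n * special.gammaln(r)
        - glny
        + n * r * math.log(r / (r + mu))
        + sy * math.log(mu / (r + mu))
    )


def nb_test(
    control: np.ndarray, case: np.ndarray, gene_id: str = "", region_type: str = ""
) -> NBTestResult:
    """Two-group negative binomial likelihood-ratio test.

    H0: both groups share one NB mean; H1: group-specific means.  A common
    dispersion alpha (variance = mu + alpha*mu^2) is estimated under H1 by
    Cox-Reid adjusted profile likelihood (the adjustment corrects the
    downward bias of plain ML dispersion at these group sizes, which
    would otherwise make the test liberal) and reused under H0; alpha is
    floored at 0 (Poisson limit).  The LR statistic is referred to chi^2
    with 1 df.  Calibrated (real-valued) inputs are rounded to the
    nearest integer for the likelihood; the fold change uses the
    unrounded calibrated means with a 0.5 pseudocount.
    """
    control = np.asarray(control, dtype=float)
    case = np.asarray(case, dtype=float)
    if control.size < 2 or case.size < 2:
        raise ValueError("each group needs at least 2 samples")
    mean_c, mean_t = float(control.mean()), float(case.mean())
    fold = (mean_t + 0.5) / (mean_c + 0.5)

    yc = np.rint(control)
    yt = np.rint(case)
    sy_c, sy_t = float(yc.sum()), float(yt.sum())
    if sy_c + sy_t == 0:  # all-zero gene: no information
        return NBTestResult(gene_id, region_type, mean_c, mean_t, 0.0, fold, 1.0)
    glny_c = float(special.gammaln(yc + 1).sum())
    glny_t = float(special.gammaln(yt + 1).sum())
    mu_c = max(yc.mean(), 1e-12)
    mu_t = max(yt.mean(), 1e-12)
    mu_0 = (sy_c + sy_t) / (yc.size + yt.size)

    def negll_cr(alpha: float) -> float:
        # Cox-Reid adjusted profile log-likelihood for the common dispersion;
        # X'WX is diagonal for the two-group design, w = mu/(1 + alpha*mu).
        ll = _nb_loglik(yc, sy_c, glny_c, mu_c, alpha) + _nb_loglik(
            yt, sy_t, glny_t, mu_t, alpha
        )
        adj = 0.5 * (
            math.log(yc.size * mu_c / (1.0 + alpha * mu_c))
            + math.log(yt.size * mu_t / (1.0 + alpha * mu_t))
        )
        return -(ll - adj)

    res = optimize.minimize_scalar(
        lambda la: negll_cr(math.exp(la)),
        bounds=(math.log(1e-8), math.log(100.0)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    alpha = math.exp(res.x)
    if negll_cr(0.0) <= res.fun or alpha < 1e-6:  # Poisson limit
        alpha = 0.0
    ll1 = _nb_loglik(yc, sy_c, glny_c, mu_c, alpha) + _nb_loglik(
        yt, sy_t, glny_t, mu_t, alpha
    )
    ll0 = _nb_loglik(yc, sy_c, glny_c, mu_0, alpha) + _nb_loglik(
        yt, sy_t, glny_t, mu_0, alpha
    )
    lr = max(2.0 * (ll1 - ll0), 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    return NBTestResult(gene_id, region_type, mean_c, mean_t, alpha, fold, p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (same order as input)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rescale_by_min(x: np.ndarray, zero_guard: bool = True) -> np.ndarray:
    """Divide a count vector by its smallest value.

    When the minimum is zero the literal operation is undefined; with
    ``zero_guard`` one count is first added to every value (making the new
    minimum at least 1) before rescaling.  Without the guard a vector with
    a zero minimum yields NaNs.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    mn = x.min()
    if mn > 0:
        return x / mn
    if zero_guard:
        shifted = x + 1.0
        return shifted / shifted.min()
    return np.full_like(x, np.nan)


def exon_intron_correlation(
    exon: np.ndarray, intron: np.ndarray, method: str = "pearson"
) -> float:
    """Correlation between a gene's exon and intron counts across samples.

    Pearson by default; Spearman is offered to check for non-linear
    monotone relationships.  Returns NaN when either vector has zero
    variance (coefficient undefined).
    """
    exon = np.asarray(exon, dtype=float)
    intron = np.asarray(intron, dtype=float)
    if exon.size != intron.size:
        raise ValueError("vectors must have equal length")
    if exon.size < 4:
        raise ValueError("need at least 4 samples for a usable correlation")
    if np.ptp(exon) == 0 or np.ptp(intron) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(exon, intron).statistic)
    if method == "spearman":
        return float(stats.spearmanr(exon, intron).statistic)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class CorrDiffResult:
    gene_id: str
    r_control: float
    r_case: float
    n_control: int
    n_case: int
    p_value: float


def correlation_differential(
    r1: float, n1: int, r2: float, n2: int, gene_id: str = ""
) -> CorrDiffResult:
    """Fisher z test for a difference between two independent correlations.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p.  |r| == 1 is clipped to 1 - 1e-7 so the transform stays
    finite.  NaN inputs (undefined correlations) give p = NaN.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("Fisher z requires n >= 4 in each group")
    if not (np.isfinite(r1) and np.isfinite(r2)):
        return CorrDiffResult(gene_id, r1, r2, n1, n2, float("nan"))
    if r1 == r2:
        return CorrDiffResult(gene_id, r1, r2, n1, n2, 1.0)
    clip = 1.0 - 1e-7
    z1 = math.atanh(min(max(r1, -clip), clip))
    z2 = math.atanh(min(max(r2, -clip), clip))
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CorrDiffResult(gene_id, r1, r2, n1, n2, p)


def robust_slope(
    exon_rescaled: np.ndarray, intron_rescaled: np.ndarray
) -> tuple[float, float]:
    """Huber-robust zero-intercept slope of intron on exon.

    The exon:intron ratio relationship passes through the origin, so the
    regression is fit without an intercept.  Returns (slope, se).
    """
    x = np.asarray(exon_rescaled, dtype=float)
    y = np.asarray(intron_rescaled, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need matched vectors of length >= 4")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all exon values equal")
    ls_slope = float(np.dot(x, y) / np.dot(x, x))
    resid = y - ls_slope * x
    scale = max(np.abs(y).max(), 1.0)
    if np.abs(resid).max() < 1e-10 * scale:  # perfect fit; IRLS scale degenerates
        return ls_slope, 0.0
    fit = RLM(y, x[:, None], M=HuberT()).fit()
    return float(fit.params[0]), float(fit.bse[0])


def slope_difference_test(s1: float, se1: float, s2: float, se2: float) -> float:
    """Two-sided normal test for a difference between two slopes."""
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be non-negative")
    denom = math.sqrt(se1**2 + se2**2)
    if denom == 0:
        return 1.0 if s1 == s2 else 0.0
    z = (s1 - s2) / denom
    return float(2.0 * stats.norm.sf(abs(z)))
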