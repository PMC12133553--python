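"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume harmonized pairs (gamma_j, Gamma_j with standard
errors sigma_xj, sigma_yj) and return an :class:`MREstimate` on the log-OR
scale.  The battery: Wald ratio, fixed/random-effects IVW, MR-Egger with the
NOME I^2_GX statistic, weighted median, simple/weighted mode, and a robust
adjusted profile score (RAPS) estimator that models pleiotropy as a
zero-mean random effect with variance tau^2.

Conventions
-----------
* Ratio weights are first-order (w_j = gamma_j^2 / sigma_yj^2) by default;
  second-order weights are a switch.
* Random-effects IVW is multiplicative, with the scale floored at 1 so the
  random-effects SE can never fall below the fixed-effects SE.
* Egger regression orients every gamma_j >= 0 (flipping Gamma_j in step),
  which is required for the intercept to be identifiable.
* Significance thresholds are applied by callers, never here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .instruments import HarmonizedPair
from .summary_io import ConfigurationError

logger = logging.getLogger("mrmediate")

Z95 = float(stats.norm.ppf(0.975))


class EstimationError(Exception):
    """An estimator cannot produce a result on the given input."""


@dataclass(slots=True)
class MREstimate:
    """One method's causal estimate: beta (log-OR per exposure unit), SE,
    95% CI, two-sided p, number of SNPs, and method-specific extras."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    nsnp: int
    extras: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def or_ci(self) -> tuple[float, float, float]:
        return (
            float(np.exp(self.beta)),
            float(np.exp(self.ci_low)),
            float(np.exp(self.ci_high)),
        )


def _estimate(method: str, beta: float, se: float, nsnp: int, **extras) -> MREstimate:
    beta, se = float(beta), float(se)
    if se > 0:
        pval = 2.0 * float(stats.norm.sf(abs(beta) / se))
    else:
        pval = 0.0 if beta != 0 else 1.0
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=pval,
        nsnp=nsnp,
        extras=dict(extras),
    )


def _arrays(pairs: Sequence[HarmonizedPair]):
    bx = np.array([p.beta_exp for p in pairs], dtype=float)
    sx = np.array([p.se_exp for p in pairs], dtype=float)
    by = np.array([p.beta_out for p in pairs], dtype=float)
    sy = np.array([p.se_out for p in pairs], dtype=float)
    return bx, sx, by, sy


def ratio_estimates(
    pairs: Sequence[HarmonizedPair], second_order: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their delta-method standard errors."""
    bx, sx, by, sy = _arrays(pairs)
    if np.any(bx == 0):
        raise EstimationError("zero exposure effect: Wald ratio undefined")
    ratios = by / bx
    var = sy**2 / bx**2
    if second_order:
        var = var + by**2 * sx**2 / bx**4
    return ratios, np.sqrt(var)


def wald_ratio(pair: HarmonizedPair, second_order: bool = False) -> MREstimate:
    """Single-SNP causal estimate beta = Gamma/gamma, se = sigma_y/|gamma|."""
    if pair.beta_exp == 0:
        raise EstimationError(f"{pair.snp_id}: beta_exp = 0, ratio undefined")
    ratio, se = ratio_estimates([pair], second_order=second_order)
    return _estimate("wald", ratio[0], se[0], 1, snp_id=pair.snp_id)


def ivw(
    pairs: Sequence[HarmonizedPair],
    model: str = "random",
    second_order: bool = False,
) -> MREstimate:
    """Inverse-variance-weighted average of per-SNP Wald ratios.

    ``model='fixed'`` gives se = (sum w_j)^{-1/2}; ``model='random'`` applies
    the multiplicative overdispersion factor max(1, sqrt(Q/(k-1))).
    With a single pair this delegates to :func:`wald_ratio`.
    """
    if model not in {"fixed", "random"}:
        raise ConfigurationError(f"unknown IVW model {model!r}")
    k = len(pairs)
    if k == 0:
        raise EstimationError("IVW needs at least one SNP")
    if k == 1:
        return wald_ratio(pairs[0], second_order=second_order)
    ratios, ses = ratio_estimates(pairs, second_order=second_order)
    w = 1.0 / ses**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (ratios - beta) ** 2))
    scale = max(1.0, np.sqrt(q / (k - 1)))
    se = se_fixed if model == "fixed" else se_fixed * scale
    return _estimate(
        f"ivw_{model}", beta, se, k, cochran_q=q, q_df=k - 1, overdispersion=scale
    )


def cochran_q(
    pairs: Sequence[HarmonizedPair],
    beta: float | None = None,
    second_order: bool = False,
) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic around ``beta`` (IVW beta if None)."""
    k = len(pairs)
    if k < 2:
        raise EstimationError("Cochran's Q needs at least 2 SNPs")
    ratios, ses = ratio_estimates(pairs, second_order=second_order)
    w = 1.0 / ses**2
    if beta is None:
        beta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger(
    pairs: Sequence[HarmonizedPair],
) -> tuple[MREstimate, MREstimate, float]:
    """MR-Egger weighted regression of Gamma_j on gamma_j with intercept.

    Exposure effects are oriented non-negative first.  Returns the slope
    estimate, the intercept estimate (the average directional pleiotropy),
    and I^2_GX, the NOME-violation statistic; an I^2_GX below 0.9 signals
    regression dilution of the slope and triggers a logged warning.
    """
    k = len(pairs)
    if k < 3:
        raise EstimationError("MR-Egger needs at least 3 SNPs")
    bx, sx, by, sy = _arrays(pairs)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    X = sm.add_constant(bx, has_constant="add")
    fit = sm.WLS(by, X, weights=w).fit()
    # statsmodels scales by sqrt(RSS_w/(k-2)); floor the scale at 1 so the
    # SEs never fall below the fixed-effect (known-variance) values
    scale = float(np.sqrt(fit.scale))
    factor = max(1.0, scale)
    se_unscaled = fit.bse / scale if scale > 0 else fit.bse
    inter_se, slope_se = se_unscaled * factor
    inter, slope = fit.params
    wx = 1.0 / sx**2
    xbar = np.sum(wx * bx) / np.sum(wx)
    q_gx = float(np.sum((bx - xbar) ** 2 / sx**2))
    i2_gx = max(0.0, (q_gx - (k - 1)) / q_gx) if q_gx > 0 else 0.0
    if i2_gx < 0.9:
        logger.warning(
            "I2_GX = %.3f < 0.90: NOME violated, Egger slope attenuated", i2_gx
        )
    slope_est = _estimate(
        "egger", slope, slope_se, k, i2_gx=i2_gx, residual_scale=factor
    )
    inter_est = _estimate("egger_intercept", inter, inter_se, k, i2_gx=i2_gx)
    return slope_est, inter_est, i2_gx


def _wm_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    b = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(b[0])
    if 0.5 >= s[-1]:
        return float(b[-1])
    i = int(np.searchsorted(s, 0.5))
    return float(b[i - 1] + (b[i] - b[i - 1]) * (0.5 - s[i - 1]) / (s[i] - s[i - 1]))


def weighted_median(
    pairs: Sequence[HarmonizedPair],
    n_boot: int = 1000,
    seed: int = 0,
    second_order: bool = False,
) -> MREstimate:
    """Weighted median of Wald ratios; consistent while valid instruments
    contribute at least half the total weight.

    The point estimate interpolates the cumulative normalized weights at
    one half; the SE is the SD of the statistic over seeded parametric
    bootstrap resamples of (gamma_j, Gamma_j).
    """
    k = len(pairs)
    if k < 3:
        raise EstimationError("weighted median needs at least 3 SNPs")
    ratios, ses = ratio_estimates(pairs, second_order=second_order)
    w = 1.0 / ses**2
    beta = _wm_point(ratios, w)
    bx, sx, by, sy = _arrays(pairs)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + sx * rng.standard_normal(k)
        by_b = by + sy * rng.standard_normal(k)
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        r_b = by_b / bx_b
        var_b = sy**2 / bx_b**2
        if second_order:
            var_b = var_b + by_b**2 * sx**2 / bx_b**4
        boots[b] = _wm_point(r_b, 1.0 / var_b)
    se = float(np.std(boots, ddof=1))
    return _estimate("weighted_median", beta, se, k, n_boot=n_boot)


def _mode_point(
    ratios: np.ndarray, weights: np.ndarray, phi: float, grid_size: int = 512
) -> tuple[float, float]:
    """Argmax of the weighted Gaussian-kernel density over the ratio grid.

    Returns (mode, bandwidth); bandwidth 0 signals the degenerate
    all-identical branch.
    """
    k = len(ratios)
    sd = float(np.std(ratios, ddof=1))
    mad = float(np.median(np.abs(ratios - np.median(ratios))))
    s = min(sd, mad / 0.6745) if mad > 0 else sd
    h = phi * 0.9 * s * k ** (-1.0 / 5.0)
    if h <= 0:
        return float(ratios[0]), 0.0
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_size)
    dens = (weights[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(
        axis=1
    )
    return float(grid[int(np.argmax(dens))]), h


def mode_estimate(
    pairs: Sequence[HarmonizedPair],
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    grid_size: int = 512,
    second_order: bool = False,
) -> MREstimate:
    """Mode-based estimate: the peak of a kernel density over Wald ratios.

    Bandwidth follows the modified Silverman rule
    h = phi * 0.9 * min(sd, MAD/0.6745) * k^(-1/5).  The weighted variant
    weights kernel contributions by inverse ratio variance.  If every ratio
    is identical the common ratio is returned with the IVW standard error.
    """
    k = len(pairs)
    if k < 3:
        raise EstimationError("mode estimator needs at least 3 SNPs")
    ratios, ses = ratio_estimates(pairs, second_order=second_order)
    w = 1.0 / ses**2 if weighted else np.ones(k)
    method = "weighted_mode" if weighted else "simple_mode"
    point, h = _mode_point(ratios, w, phi, grid_size)
    if h == 0.0:
        return _estimate(method, ratios[0], ivw(pairs, model="fixed").se, k, bandwidth=0.0)
    bx, sx, by, sy = _arrays(pairs)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + sx * rng.standard_normal(k)
        by_b = by + sy * rng.standard_normal(k)
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        r_b = by_b / bx_b
        w_b = bx_b**2 / sy**2 if weighted else np.ones(k)
        m, hb = _mode_point(r_b, w_b, phi, grid_size)
        boots[b] = m
    se = float(np.std(boots, ddof=1))
    return _estimate(method, point, se, k, bandwidth=h, n_boot=n_boot)


# --- robust adjusted profile score ------------------------------------------

HUBER_C = 1.345
TUKEY_C = 4.685


def _psi_huber(t: np.ndarray, c: float) -> np.ndarray:
    return np.clip(t, -c, c)


def _dpsi_huber(t: np.ndarray, c: float) -> np.ndarray:
    return (np.abs(t) <= c).astype(float)


def _psi_tukey(t: np.ndarray, c: float) -> np.ndarray:
    u = t / c
    out = t * (1 - u**2) ** 2
    out[np.abs(u) > 1] = 0.0
    return out


def _dpsi_tukey(t: np.ndarray, c: float) -> np.ndarray:
    u = t / c
    out = (1 - u**2) * (1 - 5 * u**2)
    out[np.abs(u) > 1] = 0.0
    return out


def _delta_ref(loss: str, c: float) -> float:
    """E[psi_c(Z) Z] under Z ~ N(0,1): the centering that makes the tau^2
    estimating equation unbiased under normality."""
    if loss == "huber":
        # E[Z^2 1{|Z|<=c}] + c E[|Z| 1{|Z|>c}] collapses to 2*Phi(c)-1
        return 2.0 * float(stats.norm.cdf(c)) - 1.0
    from scipy.integrate import quad

    val, _ = quad(
        lambda z: float(_psi_tukey(np.array([z]), c)[0]) * z * stats.norm.pdf(z),
        -c,
        c,
    )
    return float(val)


def mr_raps(
    pairs: Sequence[HarmonizedPair],
    overdispersion: bool = True,
    loss: str = "huber",
    c: float | None = None,
    max_expand: int = 60,
) -> MREstimate:
    """Robust adjusted profile score estimator.

    Pleiotropy is modelled as a zero-mean random effect with variance tau^2
    added to every outcome variance.  Standardized residuals
    t_j = (Gamma_j - beta*gamma_j)/sqrt(sigma_yj^2 + beta^2 sigma_xj^2 + tau^2)
    enter a robustified score with Huber (default) or Tukey psi; beta solves
    the profile score and tau^2 solves sum[psi(t_j) t_j - delta_c] = 0,
    floored at zero.  Both roots are found by deterministic bracketed
    root-finding; the SE comes from the empirical sandwich formula.
    """
    k = len(pairs)
    if k < 3:
        raise EstimationError("RAPS needs at least 3 SNPs")
    if loss not in {"huber", "tukey"}:
        raise ConfigurationError(f"unknown loss {loss!r}")
    if c is None:
        c = HUBER_C if loss == "huber" else TUKEY_C
    psi = _psi_huber if loss == "huber" else _psi_tukey
    dpsi = _dpsi_huber if loss == "huber" else _dpsi_tukey
    delta = _delta_ref(loss, c)
    bx, sx, by, sy = _arrays(pairs)

    def resid(beta: float, tau2: float):
        s = np.sqrt(sy**2 + beta**2 * sx**2 + tau2)
        t = (by - beta * bx) / s
        return t, s

    def score_beta(beta: float, tau2: float) -> float:
        t, s = resid(beta, tau2)
        d = bx / s + t * beta * sx**2 / s**2  # -dt/dbeta
        return float(np.sum(psi(t, c) * d))

    def rho(t: np.ndarray) -> np.ndarray:
        if loss == "huber":
            return np.where(np.abs(t) <= c, 0.5 * t**2, c * np.abs(t) - 0.5 * c**2)
        u = np.minimum((t / c) ** 2, 1.0)
        return c**2 / 6.0 * (1.0 - (1.0 - u) ** 3)

    def objective(beta: float, tau2: float) -> float:
        t, _ = resid(beta, tau2)
        return float(np.sum(rho(t)))

    def solve_beta(tau2: float) -> float:
        # robust losses make the score non-monotone: scan a grid across the
        # ratio range for sign changes, refine each by bisection, keep the
        # root with the smallest robust objective
        ratios = by / np.where(bx == 0, np.finfo(float).tiny, bx)
        lo, hi = float(np.min(ratios)) - 1.0, float(np.max(ratios)) + 1.0
        for _ in range(max_expand):
            grid = np.linspace(lo, hi, 257)
            scores = np.array([score_beta(b, tau2) for b in grid])
            idx = np.nonzero(np.sign(scores[:-1]) * np.sign(scores[1:]) < 0)[0]
            roots = [
                float(optimize.brentq(score_beta, grid[i], grid[i + 1],
                                      args=(tau2,), xtol=1e-12))
                for i in idx
            ]
            roots += [float(grid[i]) for i in np.nonzero(scores == 0.0)[0]]
            if roots:
                return min(roots, key=lambda b: objective(b, tau2))
            width = hi - lo
            lo, hi = lo - width, hi + width
        raise EstimationError(
            f"RAPS: no score root for beta in [{lo:.3g}, {hi:.3g}] at tau2={tau2:.3g}"
        )

    def score_tau(tau2: float) -> float:
        beta = solve_beta(tau2)
        t, _ = resid(beta, tau2)
        return float(np.sum(psi(t, c) * t - delta))

    if not overdispersion:
        tau2 = 0.0
        beta = solve_beta(0.0)
    else:
        f0 = score_tau(0.0)
        if f0 <= 0:
            tau2 = 0.0
            beta = solve_beta(0.0)
        else:
            hi = float(np.var(by) + np.max(sy) ** 2)
            n_exp = 0
            while score_tau(hi) > 0:
                n_exp += 1
                hi *= 4.0
                if n_exp > max_expand:
                    raise EstimationError(
                        f"RAPS: tau^2 unbounded (score still {score_tau(hi):.3g} at {hi:.3g})"
                    )
            tau2 = float(optimize.brentq(score_tau, 0.0, hi, xtol=1e-14))
            beta = solve_beta(tau2)

    t, s = resid(beta, tau2)
    d = bx / s + t * beta * sx**2 / s**2
    a = float(np.sum(dpsi(t, c) * d**2))
    b_mat = float(np.sum(psi(t, c) ** 2 * d**2))
    if a <= 0:
        raise EstimationError("RAPS: degenerate information at solution")
    se = float(np.sqrt(b_mat) / a)
    return _estimate("raps", beta, se, k, tau2=tau2, loss=loss, c=c)


def all_estimates(
    pairs: Sequence[HarmonizedPair],
    n_boot: int = 1000,
    seed: int = 0,
) -> list[MREstimate]:
    """Run the full battery on one instrument set (needs >= 3 SNPs)."""
    slope, intercept, _ = egger(pairs)
    return [
        ivw(pairs, model="fixed"),
        ivw(pairs, model="random"),
        slope,
        intercept,
        weighted_median(pairs, n_boot=n_boot, seed=seed),
        mode_estimate(pairs, weighted=False, n_boot=n_boot, seed=seed + 1),
        mode_estimate(pairs, weighted=True, n_boot=n_boot, seed=seed + 2),
        mr_raps(pairs),
    ]


__all__ = [
    "MREstimate",
    "EstimationError",
    "ratio_estimates",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "egger",
    "weighted_median",
    "mode_estimate",
    "mr_raps",
    "all_estimates",
    "Z95",
]
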