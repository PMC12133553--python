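"""Sensitivity analyses: MR-PRESSO, Steiger directionality, leave-one-out,
funnel-plot data, and statistical power for binary outcomes.

MR-PRESSO simulates the residual sum of squares expected under no horizontal
pleiotropy (each SNP compared against its leave-one-out prediction) and
flags SNPs whose observed squared residual is extreme against that null.
The Steiger test asks whether the instruments explain more variance in the
exposure than in the outcome, which must hold when causation runs from
exposure to outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EstimationError, ivw, ratio_estimates
from .instruments import HarmonizedPair
from .summary_io import ConfigurationError

logger = logging.getLogger("mrmediate")


@dataclass(slots=True)
class PressoResult:
    rss_obs: float
    global_pval: float
    outlier_snps: list[str]
    outlier_pvals: dict[str, float]
    distortion_pval: float | None
    beta_before: float
    beta_after: float | None


@dataclass(slots=True)
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_correct: bool
    steiger_pval: float
    indeterminate: bool = False


def _origin_wls(bx, sx, by, sy):
    """Slope of the no-intercept weighted regression Gamma = beta*gamma,
    weights 1/sigma_y^2 (algebraically identical to first-order IVW)."""
    w = 1.0 / sy**2
    return np.sum(w * bx * by) / np.sum(w * bx**2)


def mr_presso(
    pairs: Sequence[HarmonizedPair],
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
    n_boot_distortion: int = 500,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    For each SNP j the expected outcome effect is the leave-one-out IVW
    prediction beta_(-j)*gamma_j.  The observed RSS is compared against
    ``n_sim`` parametric simulations (Gamma*_j ~ N(beta_(-j) gamma_j,
    sigma_yj), gamma*_j ~ N(gamma_j, sigma_xj)); the rank-based p-value uses
    an add-one pseudo-count so it is always positive.  Per-SNP outlier
    p-values are Bonferroni-adjusted by the number of SNPs.
    """
    k = len(pairs)
    if k < 4:
        raise EstimationError("MR-PRESSO needs at least 4 SNPs")
    if n_sim < 1:
        raise ConfigurationError("n_sim must be >= 1")
    bx = np.array([p.beta_exp for p in pairs])
    sx = np.array([p.se_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    sy = np.array([p.se_out for p in pairs])
    w = 1.0 / sy**2

    s1 = np.sum(w * bx * by)
    s2 = np.sum(w * bx**2)
    beta_loo = (s1 - w * bx * by) / (s2 - w * bx**2)  # beta_(-j) for each j
    resid_obs = (by - beta_loo * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    by_sim = beta_loo[None, :] * bx[None, :] + sy[None, :] * rng.standard_normal((n_sim, k))
    bx_sim = bx[None, :] + sx[None, :] * rng.standard_normal((n_sim, k))
    s1_sim = np.sum(w[None, :] * bx_sim * by_sim, axis=1, keepdims=True)
    s2_sim = np.sum(w[None, :] * bx_sim**2, axis=1, keepdims=True)
    beta_loo_sim = (s1_sim - w * bx_sim * by_sim) / (s2_sim - w * bx_sim**2)
    resid_sim = (by_sim - beta_loo_sim * bx_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    per_snp_p = (1 + np.sum(resid_sim >= resid_obs[None, :], axis=0)) / (n_sim + 1)
    adj = np.minimum(per_snp_p * k, 1.0)
    outliers = [pairs[j].snp_id for j in range(k) if adj[j] < outlier_alpha]
    outlier_pvals = {pairs[j].snp_id: float(adj[j]) for j in range(k)}

    beta_before = float(_origin_wls(bx, sx, by, sy))
    beta_after = None
    distortion_pval = None
    if outliers and len(outliers) < k:
        keep = np.array([p.snp_id not in outliers for p in pairs])
        beta_after = float(_origin_wls(bx[keep], sx[keep], by[keep], sy[keep]))
        # bootstrap the outlier-free set: how unusual is the observed shift?
        idx = np.arange(int(keep.sum()))
        d_obs = abs(beta_before - beta_after)
        boots = np.empty(n_boot_distortion)
        bxk, sxk, byk, syk = bx[keep], sx[keep], by[keep], sy[keep]
        for b in range(n_boot_distortion):
            pick = rng.choice(idx, size=idx.size, replace=True)
            boots[b] = _origin_wls(bxk[pick], sxk[pick], byk[pick], syk[pick])
        distortion_pval = float(
            (1 + np.sum(np.abs(boots - beta_after) >= d_obs)) / (n_boot_distortion + 1)
        )
    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_snps=outliers,
        outlier_pvals=outlier_pvals,
        distortion_pval=distortion_pval,
        beta_before=beta_before,
        beta_after=beta_after,
    )


def presso_filter(
    pairs: Sequence[HarmonizedPair],
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> tuple[list[HarmonizedPair], PressoResult]:
    """Drop MR-PRESSO outliers; with fewer than 4 SNPs the test is skipped."""
    if len(pairs) < 4:
        logger.warning("MR-PRESSO skipped: fewer than 4 instruments")
        res = PressoResult(
            rss_obs=float("nan"), global_pval=float("nan"), outlier_snps=[],
            outlier_pvals={}, distortion_pval=None,
            beta_before=float("nan"), beta_after=None,
        )
        return list(pairs), res
    res = mr_presso(pairs, n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha)
    kept = [p for p in pairs if p.snp_id not in set(res.outlier_snps)]
    return kept, res


# --- Steiger directionality --------------------------------------------------


def _r2_from_z(z: np.ndarray, n: float) -> np.ndarray:
    """Variance explained from a z statistic: r^2 = z^2 / (z^2 + n - 2)."""
    return z**2 / (z**2 + n - 2.0)


def _r_binary_observed(
    beta: np.ndarray, eaf: np.ndarray, case_fraction: float
) -> np.ndarray:
    """Observed-scale correlation for a binary trait from a per-allele
    log-OR: the linear-probability approximation gives
    r = logOR * sqrt(cf*(1-cf)) * sqrt(2*eaf*(1-eaf))."""
    return beta * np.sqrt(case_fraction * (1 - case_fraction)) * np.sqrt(2 * eaf * (1 - eaf))


def _per_snp_r2(
    betas: np.ndarray,
    ses: np.ndarray,
    eafs: np.ndarray | None,
    n: float,
    trait_type: str,
    case_fraction: float | None,
) -> np.ndarray:
    if trait_type == "binary":
        if eafs is None or case_fraction is None or np.any(~np.isfinite(eafs)):
            logger.warning(
                "binary Steiger r requested without eaf/case_fraction; "
                "falling back to z-based r^2"
            )
        else:
            return _r_binary_observed(betas, eafs, case_fraction) ** 2
    return _r2_from_z(betas / ses, n)


def steiger(
    pairs: Sequence[HarmonizedPair],
    n_exp: float,
    n_out: float,
    outcome_type: str = "binary",
    exposure_type: str = "continuous",
    case_fraction: float | None = None,
) -> SteigerResult:
    """Overall directionality test: do the instruments explain more variance
    in the exposure than in the outcome?

    Per-SNP r^2 comes from z statistics (r^2 = z^2/(z^2+n-2)); for binary
    outcomes the observed-scale correlation is derived from the log-OR,
    allele frequency and case fraction when available.  The p-value compares
    the two total correlations with a Fisher-z test (the two samples are
    independent cohorts in a two-sample design).
    """
    if n_exp <= 2 or n_out <= 2:
        raise ConfigurationError("Steiger needs sample sizes > 2")
    bx = np.array([p.beta_exp for p in pairs])
    sx = np.array([p.se_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    sy = np.array([p.se_out for p in pairs])
    eaf_out = np.array(
        [p.eaf_out if p.eaf_out is not None else np.nan for p in pairs]
    )
    eaf_exp = np.array(
        [p.eaf_exp if p.eaf_exp is not None else np.nan for p in pairs]
    )
    r2_exp = float(
        np.sum(_per_snp_r2(bx, sx, eaf_exp, n_exp, exposure_type, case_fraction))
    )
    r2_out = float(
        np.sum(_per_snp_r2(by, sy, eaf_out, n_out, outcome_type, case_fraction))
    )
    r2_exp = min(r2_exp, 1.0 - 1e-12)
    r2_out = min(r2_out, 1.0 - 1e-12)
    if r2_exp == r2_out:
        return SteigerResult(r2_exp, r2_out, False, 1.0, indeterminate=True)
    z_exp = np.arctanh(np.sqrt(r2_exp))
    z_out = np.arctanh(np.sqrt(r2_out))
    z = (z_exp - z_out) / np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    pval = 2.0 * float(stats.norm.sf(abs(z)))
    return SteigerResult(r2_exp, r2_out, r2_exp > r2_out, pval)


def steiger_filter(
    pairs: Sequence[HarmonizedPair],
    n_exp: float,
    n_out: float,
    outcome_type: str = "binary",
    exposure_type: str = "continuous",
    case_fraction: float | None = None,
) -> list[HarmonizedPair]:
    """Drop individual SNPs that explain more variance in the outcome than
    in the exposure (wrong per-SNP causal direction)."""
    kept = []
    for p in pairs:
        r2e = float(
            _per_snp_r2(
                np.array([p.beta_exp]), np.array([p.se_exp]),
                np.array([p.eaf_exp if p.eaf_exp is not None else np.nan]),
                n_exp, exposure_type, case_fraction,
            )[0]
        )
        r2o = float(
            _per_snp_r2(
                np.array([p.beta_out]), np.array([p.se_out]),
                np.array([p.eaf_out if p.eaf_out is not None else np.nan]),
                n_out, outcome_type, case_fraction,
            )[0]
        )
        if r2o > r2e:
            logger.debug("Steiger removes %s (r2_out %.2g > r2_exp %.2g)", p.snp_id, r2o, r2e)
            continue
        kept.append(p)
    return kept


def leave_one_out(
    pairs: Sequence[HarmonizedPair], alpha: float = 0.05
) -> pd.DataFrame:
    """IVW recomputed excluding each SNP in turn.

    The ``flips_significance`` column marks exclusions that change the
    significance call relative to the full estimate.
    """
    k = len(pairs)
    if k < 3:
        raise EstimationError("leave-one-out needs at least 3 SNPs")
    full = ivw(pairs, model="random")
    rows = []
    for j in range(k):
        sub = [p for i, p in enumerate(pairs) if i != j]
        est = ivw(sub, model="random")
        rows.append(
            {
                "snp_id": pairs[j].snp_id,
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "flips_significance": (est.pval < alpha) != (full.pval < alpha),
            }
        )
    return pd.DataFrame(rows)


def funnel_data(pairs: Sequence[HarmonizedPair]) -> pd.DataFrame:
    """Per-SNP ratio estimates against precision, ready for a funnel plot."""
    if len(pairs) == 0:
        return pd.DataFrame(columns=["snp_id", "ratio", "precision"])
    ratios, ses = ratio_estimates(pairs)
    return pd.DataFrame(
        {
            "snp_id": [p.snp_id for p in pairs],
            "ratio": ratios,
            "precision": 1.0 / ses,
        }
    )


def power_binary(
    n_total: float,
    case_fraction: float,
    r2_instrument: float,
    or_alt: float,
    alpha: float = 0.05,
) -> float:
    """Normal-approximation power of two-sample MR with a binary outcome.

    power = Phi(|ln OR| * sqrt(n * R^2 * cf * (1-cf)) - z_{1-alpha/2}),
    where R^2 is the variance in the exposure explained by the instrument
    and cf the outcome case fraction.
    """
    if not (0.0 < r2_instrument < 1.0):
        raise ConfigurationError("r2_instrument must lie in (0, 1)")
    if not (0.0 < case_fraction < 1.0):
        raise ConfigurationError("case_fraction must lie in (0, 1)")
    z_a = stats.norm.isf(alpha / 2.0)
    ncp = abs(np.log(or_alt)) * np.sqrt(
        n_total * r2_instrument * case_fraction * (1.0 - case_fraction)
    )
    return float(stats.norm.cdf(ncp - z_a))


__all__ = [
    "PressoResult",
    "SteigerResult",
    "mr_presso",
    "presso_filter",
    "steiger",
    "steiger_filter",
    "leave_one_out",
    "funnel_data",
    "power_binary",
]
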