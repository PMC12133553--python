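"""Synthetic GWAS summary statistics with a known mediated causal structure.

The generator emulates the three-cohort design of a urate -> plasma protein
-> atrial fibrillation study: a continuous exposure GWAS (~110k samples), a
set of protein GWAS (~3.3k samples each), and a binary outcome GWAS (~1M
samples, ~5.9% cases).  The causal diagram is

    gamma_j  --->  exposure X  --theta_direct-->  outcome Y
                      |                               ^
                      +--beta1_k-->  mediator M_k --beta2_k--+

with per-SNP direct mediator effects delta_jk (cis-acting signals that make
each mediator instrumentable in its own right) and optional horizontal
pleiotropy added to the outcome.  The identity

    theta_total = theta_direct + sum_k beta1_k * beta2_k

is enforced at construction: theta_direct is derived, never set.

Observed effects add normal noise with SE = 1/sqrt(2*maf*(1-maf)*n) on the
trait scale; binary traits use the log-OR approximation with effective
n = n_total * cf * (1 - cf).  Everything is reproducible under the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mediation import TwoStepEffects, parse_or_ci
from .summary_io import AssociationRecord, ConfigurationError, LDMatrix

#: outcome case fraction emulating a ~60.6k-case / ~1.03M-sample AF GWAS
AF_CASE_FRACTION = 60620 / 1030836

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Generator settings; defaults are desk-scale study conditions.

    ``m_snps`` exposure-associated SNPs (a few large-effect loci plus a
    polygenic tail, mimicking the genetic architecture of serum urate),
    ``m_per_mediator`` cis-acting SNPs per mediator, sample sizes from the
    three emulated cohorts.  ``theta_total`` is the total exposure->outcome
    log-OR; the direct effect is derived from it and the mediator chain.
    """

    m_snps: int = 100
    m_per_mediator: int = 30
    m_null: int = 0
    n_exp: float = 110_347
    n_med: float = 3_301
    n_out: float = 1_030_836
    case_fraction: float = AF_CASE_FRACTION
    theta_total: float = math.log(1.045)
    beta1: tuple[float, ...] = (math.log(1.154),)
    beta2: tuple[float, ...] = (math.log(1.047),)
    mediator_ids: tuple[str, ...] | None = None
    gamma_sd: float = 0.05
    gamma_nonnegative: bool = False
    large_effects: tuple[float, ...] = (0.37, 0.22, 0.15, 0.12)
    delta_sd: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_fraction: float = 0.0
    flip_fraction: float = 0.3
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_fraction: float = 0.0
    ld_blocks: int = 0
    ld_block_size: int = 3
    ld_r2: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.beta1) != len(self.beta2):
            raise ConfigurationError("beta1 and beta2 must have equal length")
        if self.mediator_ids is None:
            self.mediator_ids = tuple(f"M{k + 1}" for k in range(len(self.beta1)))
        elif len(self.mediator_ids) != len(self.beta1):
            raise ConfigurationError("mediator_ids length mismatch")
        if not (0 < self.maf_range[0] < self.maf_range[1] <= 0.5):
            raise ConfigurationError(f"invalid maf_range {self.maf_range}")
        if self.pleiotropy_mode not in {"none", "balanced", "directional"}:
            raise ConfigurationError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if self.gamma_sd < 0 or self.delta_sd < 0 or self.pleiotropy_sd < 0:
            raise ConfigurationError("negative variance parameter")

    @property
    def theta_direct(self) -> float:
        return self.theta_total - float(
            np.sum(np.asarray(self.beta1) * np.asarray(self.beta2))
        )

    @property
    def n_mediators(self) -> int:
        return len(self.beta1)


@dataclass
class SyntheticTruth:
    """The realized generating parameters, serialized alongside every dataset."""

    config: SimulationConfig
    snp_ids: list[str]
    gamma: np.ndarray          # true per-SNP exposure effects
    delta: np.ndarray          # (n_mediators, m) direct mediator effects
    pleiotropy: np.ndarray     # per-SNP pleiotropic outcome offsets
    valid_instrument: np.ndarray  # bool per SNP: no pleiotropy, no implant

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "snp_ids": self.snp_ids,
            "gamma": self.gamma.tolist(),
            "delta": self.delta.tolist(),
            "pleiotropy": self.pleiotropy.tolist(),
            "valid_instrument": self.valid_instrument.astype(bool).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SimulatedStudy:
    exposure: list[AssociationRecord]
    mediators: dict[str, list[AssociationRecord]]
    outcome: list[AssociationRecord]
    ld: LDMatrix | None
    truth: SyntheticTruth


def _binary_se(maf: np.ndarray, n_total: float, case_fraction: float) -> np.ndarray:
    n_eff = n_total * case_fraction * (1.0 - case_fraction)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_eff)


def _continuous_se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _records(
    snp_ids, chroms, poss, eas, oas, mafs, beta_obs, se, n, trait_id, flip_mask
) -> list[AssociationRecord]:
    recs = []
    pvals = 2.0 * stats.norm.sf(np.abs(beta_obs / se))
    pvals = np.maximum(pvals, np.nextafter(0.0, 1.0))
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for j in range(len(snp_ids)):
        ea, oa, beta, eaf = eas[j], oas[j], beta_obs[j], mafs[j]
        if flip_mask[j]:
            ea, oa = oa, ea
            beta = -beta
            eaf = 1.0 - eaf
        recs.append(
            AssociationRecord(
                snp_id=snp_ids[j], chrom=chroms[j], pos=int(poss[j]),
                effect_allele=ea, other_allele=oa, eaf=float(eaf),
                beta=float(beta), se=float(se[j]), pval=float(pvals[j]),
                n=float(n), trait_id=trait_id,
            )
        )
    return recs


def simulate_mediation_gwas(config: SimulationConfig) -> SimulatedStudy:
    """Generate exposure, mediator and outcome summary tables plus the truth.

    SNP layout: ``m_snps`` exposure instruments, then ``m_per_mediator``
    cis SNPs per mediator, then ``m_null`` null SNPs; LD blocks append tag
    SNPs correlated with the first exposure loci.  Identical seeds produce
    identical tables.
    """
    rng = np.random.default_rng(config.seed)
    K = config.n_mediators
    m_core = config.m_snps + K * config.m_per_mediator + config.m_null

    gamma = np.zeros(m_core)
    n_large = min(len(config.large_effects), config.m_snps)
    signs = rng.choice([-1.0, 1.0], size=n_large)
    gamma[:n_large] = np.asarray(config.large_effects[:n_large]) * signs
    gamma[n_large:config.m_snps] = config.gamma_sd * rng.standard_normal(
        config.m_snps - n_large
    )
    if config.gamma_nonnegative:
        # orient every exposure effect positive (the frame in which
        # directional pleiotropy has a common sign)
        gamma[:config.m_snps] = np.abs(gamma[:config.m_snps])

    delta = np.zeros((K, m_core))
    for k in range(K):
        lo = config.m_snps + k * config.m_per_mediator
        hi = lo + config.m_per_mediator
        delta[k, lo:hi] = config.delta_sd * rng.standard_normal(config.m_per_mediator)

    pleio = np.zeros(m_core)
    if config.pleiotropy_mode != "none" and config.pleiotropy_fraction > 0:
        affected = rng.random(config.m_snps) < config.pleiotropy_fraction
        mean = config.pleiotropy_mean if config.pleiotropy_mode == "directional" else 0.0
        draws = mean + config.pleiotropy_sd * rng.standard_normal(config.m_snps)
        pleio[:config.m_snps] = np.where(affected, draws, 0.0)

    # LD tag SNPs: companions of the first `ld_blocks` exposure loci whose
    # marginal effects attenuate by r = sqrt(r2)
    n_tags = config.ld_blocks * max(config.ld_block_size - 1, 0)
    m = m_core + n_tags
    r = math.sqrt(config.ld_r2)

    maf = rng.uniform(*config.maf_range, size=m)
    palin = rng.random(m) < config.palindromic_fraction
    allele_idx = rng.integers(0, len(_NONPALINDROMIC), size=m)
    palin_idx = rng.integers(0, len(_PALINDROMIC), size=m)
    eas = [
        (_PALINDROMIC[palin_idx[j]] if palin[j] else _NONPALINDROMIC[allele_idx[j]])[0]
        for j in range(m)
    ]
    oas = [
        (_PALINDROMIC[palin_idx[j]] if palin[j] else _NONPALINDROMIC[allele_idx[j]])[1]
        for j in range(m)
    ]
    snp_ids = [f"rs{j + 1:06d}" for j in range(m)]
    chroms = [str(j % 22 + 1) for j in range(m_core)]
    poss = [25_000_000 * (j // 22 + 1) for j in range(m_core)]

    gamma_full = np.concatenate([gamma, np.zeros(n_tags)])
    delta_full = np.concatenate([delta, np.zeros((K, n_tags))], axis=1)
    pleio_full = np.concatenate([pleio, np.zeros(n_tags)])
    tag_of: list[int] = []
    t = m_core
    for b in range(config.ld_blocks):
        for c in range(config.ld_block_size - 1):
            gamma_full[t] = r * gamma[b]
            delta_full[:, t] = r * delta[:, b]
            pleio_full[t] = r * pleio[b]
            chroms.append(chroms[b])
            poss.append(poss[b] + 1000 * (c + 1))
            tag_of.append(b)
            t += 1

    mediator_effects = np.asarray(config.beta1)[:, None] * gamma_full[None, :] + delta_full
    outcome_true = (
        config.theta_direct * gamma_full
        + np.asarray(config.beta2) @ mediator_effects
        + pleio_full
    )

    se_exp = _continuous_se(maf, config.n_exp)
    se_med = _continuous_se(maf, config.n_med)
    se_out = _binary_se(maf, config.n_out, config.case_fraction)

    beta_exp_obs = gamma_full + se_exp * rng.standard_normal(m)
    beta_out_obs = outcome_true + se_out * rng.standard_normal(m)

    flip_exp = np.zeros(m, dtype=bool)  # exposure table defines the reference
    flip_out = rng.random(m) < config.flip_fraction

    exposure = _records(
        snp_ids, chroms, poss, eas, oas, maf, beta_exp_obs, se_exp,
        config.n_exp, "exposure", flip_exp,
    )
    outcome = _records(
        snp_ids, chroms, poss, eas, oas, maf, beta_out_obs, se_out,
        config.n_out, "outcome", flip_out,
    )
    mediators: dict[str, list[AssociationRecord]] = {}
    for k, mid in enumerate(config.mediator_ids):
        beta_med_obs = mediator_effects[k] + se_med * rng.standard_normal(m)
        flip_med = rng.random(m) < config.flip_fraction
        mediators[mid] = _records(
            snp_ids, chroms, poss, eas, oas, maf, beta_med_obs, se_med,
            config.n_med, mid, flip_med,
        )

    ld = None
    if n_tags > 0:
        r2 = np.eye(m)
        for t_idx, b in enumerate(tag_of):
            j = m_core + t_idx
            r2[j, b] = r2[b, j] = config.ld_r2
            for t2, b2 in enumerate(tag_of[:t_idx]):
                if b2 == b:
                    j2 = m_core + t2
                    r2[j, j2] = r2[j2, j] = config.ld_r2
        ld = LDMatrix(snp_ids=snp_ids, r2=r2)

    truth = SyntheticTruth(
        config=config,
        snp_ids=snp_ids,
        gamma=gamma_full,
        delta=delta_full,
        pleiotropy=pleio_full,
        valid_instrument=(pleio_full == 0.0),
    )
    return SimulatedStudy(
        exposure=exposure, mediators=mediators, outcome=outcome, ld=ld, truth=truth
    )


def implant_outliers(
    study: SimulatedStudy, implants: Sequence[tuple[int, float]]
) -> SimulatedStudy:
    """Add fixed pleiotropic offsets to the outcome effect of chosen SNPs.

    ``implants`` is a list of (SNP index, absolute offset on the log-OR
    scale).  The truth ledger marks implanted SNPs invalid.  Modifies the
    study in place and returns it.
    """
    m = len(study.outcome)
    for idx, offset in implants:
        if not (0 <= idx < m):
            raise ConfigurationError(f"implant index {idx} out of range 0..{m - 1}")
        rec = study.outcome[idx]
        # respect the record's current allele orientation
        sign = 1.0
        if rec.effect_allele != study.exposure[idx].effect_allele:
            sign = -1.0
        rec.beta += sign * offset
        rec.pval = max(
            2.0 * float(stats.norm.sf(abs(rec.beta / rec.se))), np.nextafter(0.0, 1.0)
        )
        study.truth.pleiotropy[idx] += offset
        study.truth.valid_instrument[idx] = False
    return study


def reference_mediation_rows() -> pd.DataFrame:
    """The bundled reference table of 17 urate -> plasma protein -> atrial
    fibrillation mediation rows (printed ORs, CIs, p-values and ratios), as
    published strings."""
    with resources.files("mrmediate.data").joinpath("urate_af_mediators.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def _parse_p(text: str) -> float:
    text = text.strip()
    if text.startswith("<"):
        return float(text[1:])
    return float(text)


def table2_fixture() -> list[TwoStepEffects]:
    """The 17 reference mediation rows as log-scale :class:`TwoStepEffects`.

    Betas are the logs of the printed ORs; SEs are recovered from the 95%
    CIs as (ln hi - ln lo)/(2 * 1.959964); a printed "<x" p-value is taken
    at its bound x.
    """
    z95 = float(stats.norm.ppf(0.975))
    out = []
    for row in reference_mediation_rows().itertuples(index=False):
        effects = {}
        for leg, or_col, p_col in (
            ("total", row.total_or_ci, row.total_p),
            ("s1", row.step1_or_ci, row.step1_p),
            ("s2", row.step2_or_ci, row.step2_p),
        ):
            orv, lo, hi = parse_or_ci(or_col)
            effects[leg] = (
                math.log(orv),
                (math.log(hi) - math.log(lo)) / (2 * z95),
                _parse_p(p_col),
            )
        out.append(
            TwoStepEffects(
                mediator_id=row.mediator,
                beta_total=effects["total"][0], se_total=effects["total"][1],
                p_total=effects["total"][2],
                beta1=effects["s1"][0], se1=effects["s1"][1], p1=effects["s1"][2],
                beta2=effects["s2"][0], se2=effects["s2"][1], p2=effects["s2"][2],
                direction_correct=row.direction == "TRUE",
            )
        )
    return out


__all__ = [
    "AF_CASE_FRACTION",
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedStudy",
    "simulate_mediation_gwas",
    "implant_outliers",
    "reference_mediation_rows",
    "table2_fixture",
]
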