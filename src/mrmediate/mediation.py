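"""Two-step mediation Mendelian randomization.

Three univariable MR legs — total (exposure -> outcome), step 1
(exposure -> mediator) and step 2 (mediator -> outcome) — are combined by
the product of coefficients: indirect = beta1 * beta2, direct = total -
indirect, mediation proportion = indirect / total, all on the log-OR scale.
A mediator is classified *partial* when all three legs are significant,
*complete* when both steps are significant but the total effect is not, and
*none* otherwise.

Presentation note: odds ratios and CIs are formatted "OR(low~high)"; the
mediation-ratio column reports the raw log-scale fraction indirect/total
but is formatted with a trailing percent sign, matching the source tables
this layout mirrors (where the printed numerals equal the raw fraction
despite the percent sign).  The raw value is always carried alongside.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import instruments as ins
from .estimators import MREstimate, Z95, ivw
from .summary_io import AssociationRecord, ConfigurationError

logger = logging.getLogger("mrmediate")


@dataclass(slots=True)
class TwoStepEffects:
    """Total, step-1 and step-2 effects for one mediator, on the log-OR scale."""

    mediator_id: str
    beta_total: float
    se_total: float
    p_total: float
    beta1: float
    se1: float
    p1: float
    beta2: float
    se2: float
    p2: float
    direction_correct: bool = True


@dataclass(slots=True)
class MediationResult:
    mediator_id: str
    total: float
    indirect: float
    se_indirect: float
    direct: float
    proportion: float
    classification: str
    p_total: float
    p1: float
    p2: float
    direction_correct: bool = True


def indirect_effect(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    exact_variance: bool = False,
) -> tuple[float, float]:
    """Product-of-coefficients indirect effect and its delta-method SE.

    se^2 = beta1^2 se2^2 + beta2^2 se1^2, optionally plus the exact-variance
    term se1^2 se2^2.
    """
    indirect = beta1 * beta2
    var = beta1**2 * se2**2 + beta2**2 * se1**2
    if exact_variance:
        var += se1**2 * se2**2
    return indirect, math.sqrt(var)


def mediation_proportion(total: float, indirect: float) -> float:
    """indirect / total on the log-odds scale."""
    if total == 0:
        raise ConfigurationError("mediation proportion undefined: total effect is 0")
    return indirect / total


def classify_mediation(
    p_total: float, p1: float, p2: float, alpha: float = 0.05
) -> str:
    """'partial' when all three effects are significant, 'complete' when only
    the two mediation steps are, 'none' otherwise."""
    if p1 < alpha and p2 < alpha:
        return "partial" if p_total < alpha else "complete"
    return "none"


def mediate(
    effects: TwoStepEffects,
    alpha: float = 0.05,
    exact_variance: bool = False,
) -> MediationResult:
    """Combine one mediator's three MR legs into a mediation result."""
    indirect, se_ind = indirect_effect(
        effects.beta1, effects.se1, effects.beta2, effects.se2,
        exact_variance=exact_variance,
    )
    return MediationResult(
        mediator_id=effects.mediator_id,
        total=effects.beta_total,
        indirect=indirect,
        se_indirect=se_ind,
        direct=effects.beta_total - indirect,
        proportion=mediation_proportion(effects.beta_total, indirect),
        classification=classify_mediation(effects.p_total, effects.p1, effects.p2, alpha),
        p_total=effects.p_total,
        p1=effects.p1,
        p2=effects.p2,
        direction_correct=effects.direction_correct,
    )


def proportion_ci(
    effects: TwoStepEffects,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Parametric-bootstrap CI for the mediation proportion (the three leg
    estimates are perturbed by their SEs; the proportion is recomputed)."""
    rng = np.random.default_rng(seed)
    b1 = effects.beta1 + effects.se1 * rng.standard_normal(n_boot)
    b2 = effects.beta2 + effects.se2 * rng.standard_normal(n_boot)
    tot = effects.beta_total + effects.se_total * rng.standard_normal(n_boot)
    tot = np.where(tot == 0, np.finfo(float).tiny, tot)
    props = b1 * b2 / tot
    lo, hi = np.quantile(props, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


# --- running the three legs --------------------------------------------------


def _mr_leg(
    exposure_records: Sequence[AssociationRecord],
    outcome_records: Sequence[AssociationRecord],
    p_threshold: float,
    ld=None,
    f_min: float = 10.0,
    leg_name: str = "leg",
) -> tuple[MREstimate, list[ins.HarmonizedPair], ins.FilterLedger]:
    """One univariable MR leg: p-filter, clump, harmonize, F-filter, IVW."""
    ledger = ins.FilterLedger()
    n0 = len(exposure_records)
    sig = ins.filter_by_pvalue(exposure_records, p_threshold)
    ledger.add("pvalue_threshold", n0, len(sig))
    clumped = ins.clump(sig, ld=ld)
    ledger.add("ld_clump", len(sig), len(clumped))
    pairs, ledger = ins.harmonize(clumped, outcome_records, ledger)
    strong = ins.filter_weak(pairs, f_min=f_min)
    ledger.add("weak_f", len(pairs), len(strong))
    if not strong:
        raise ConfigurationError(
            f"{leg_name}: no instruments survive selection\n{ledger}"
        )
    return ivw(strong, model="random"), strong, ledger


def run_two_step(
    exposure_records: Sequence[AssociationRecord],
    mediator_records: Sequence[AssociationRecord],
    outcome_records: Sequence[AssociationRecord],
    mediator_id: str = "mediator",
    p_exposure: float = 5e-8,
    p_mediator: float = 1e-5,
    ld=None,
    f_min: float = 10.0,
) -> TwoStepEffects:
    """Run all three MR legs for one mediator and collect the IVW effects.

    Exposure instruments are selected at ``p_exposure`` (genome-wide
    significance); mediator instruments at the looser ``p_mediator``, the
    usual compromise for molecular traits with fewer genome-wide hits.
    """
    if not mediator_records:
        raise ConfigurationError(f"{mediator_id}: empty mediator table")
    total, _, _ = _mr_leg(
        exposure_records, outcome_records, p_exposure, ld=ld, f_min=f_min,
        leg_name="total (exposure->outcome)",
    )
    step1, _, _ = _mr_leg(
        exposure_records, mediator_records, p_exposure, ld=ld, f_min=f_min,
        leg_name=f"step 1 (exposure->{mediator_id})",
    )
    step2, _, _ = _mr_leg(
        mediator_records, outcome_records, p_mediator, ld=ld, f_min=f_min,
        leg_name=f"step 2 ({mediator_id}->outcome)",
    )
    return TwoStepEffects(
        mediator_id=mediator_id,
        beta_total=total.beta, se_total=total.se, p_total=total.pval,
        beta1=step1.beta, se1=step1.se, p1=step1.pval,
        beta2=step2.beta, se2=step2.se, p2=step2.pval,
    )


# --- formatting --------------------------------------------------------------

_OR_CI_RE = re.compile(r"^\s*([0-9.]+)\s*\(\s*([0-9.]+)\s*~\s*([0-9.]+)\s*\)\s*$")


def format_or_ci(beta: float, se: float, digits: int = 3) -> str:
    """Log-scale effect and SE -> 'OR(low~high)' on the odds-ratio scale."""
    return (
        f"{math.exp(beta):.{digits}f}"
        f"({math.exp(beta - Z95 * se):.{digits}f}~{math.exp(beta + Z95 * se):.{digits}f})"
    )


def parse_or_ci(text: str) -> tuple[float, float, float]:
    """Parse 'OR(low~high)' back to (or, low, high)."""
    m = _OR_CI_RE.match(text)
    if not m:
        raise ConfigurationError(f"cannot parse OR/CI string {text!r}")
    return tuple(float(g) for g in m.groups())  # type: ignore[return-value]


def format_proportion(proportion: float) -> str:
    """Two-decimal numeral with a trailing percent sign (raw fraction)."""
    return f"{proportion:.2f}%"


def mediation_table(
    results: Sequence[MediationResult],
    effects: Mapping[str, TwoStepEffects] | None = None,
    significant_only: bool = True,
    alpha: float = 0.05,
):
    """Report table: one row per mediator, sorted by name; the significant
    view keeps only rows classified partial or complete."""
    import pandas as pd

    rows = []
    for r in sorted(results, key=lambda r: r.mediator_id):
        if significant_only and r.classification == "none":
            continue
        row = {
            "mediator": r.mediator_id,
            "classification": r.classification,
            "direction_correct": r.direction_correct,
            "indirect": r.indirect,
            "se_indirect": r.se_indirect,
            "direct": r.direct,
            "proportion": r.proportion,
            "mediating_ratio": format_proportion(r.proportion),
            "p_total": r.p_total,
            "p_step1": r.p1,
            "p_step2": r.p2,
        }
        if effects and r.mediator_id in effects:
            e = effects[r.mediator_id]
            row["total_or_ci"] = format_or_ci(e.beta_total, e.se_total)
            row["step1_or_ci"] = format_or_ci(e.beta1, e.se1)
            row["step2_or_ci"] = format_or_ci(e.beta2, e.se2)
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "TwoStepEffects",
    "MediationResult",
    "indirect_effect",
    "mediation_proportion",
    "classify_mediation",
    "mediate",
    "proportion_ci",
    "run_two_step",
    "format_or_ci",
    "parse_or_ci",
    "format_proportion",
    "mediation_table",
]
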