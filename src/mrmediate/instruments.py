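"""Instrument selection and exposure/outcome harmonization.

A variant qualifies as an instrument when it is strongly associated with the
exposure (p-value threshold, F statistic), independent of other selected
variants (LD clumping), shared between the exposure and outcome datasets with
unambiguous strand (palindromic A/T and C/G pairs are dropped), not annotated
to a known confounder, and not directly associated with the outcome after
Bonferroni correction.  Every filter appends one row to a :class:`FilterLedger`
so the run's bookkeeping telescopes from raw SNP counts down to the final
instrument set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .summary_io import (
    AssociationRecord,
    ConfigurationError,
    FormatError,
    LDMatrix,
)

logger = logging.getLogger("mrmediate")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(slots=True)
class HarmonizedPair:
    """Exposure and outcome effects for one SNP on a shared effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    pval_exp: float
    pval_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    chrom: str = ""
    pos: int = 0
    n_exp: float = float("nan")
    n_out: float = float("nan")

    @property
    def f_stat(self) -> float:
        return f_statistic(self)


@dataclass
class FilterLedger:
    """Ordered record of (filter name, SNPs in, removed, SNPs out).

    Counts telescope: the output of step k is the input of step k+1.
    """

    steps: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if self.steps and self.steps[-1][3] != n_in:
            raise ValueError(
                f"ledger does not telescope at {name!r}: "
                f"previous out={self.steps[-1][3]}, this in={n_in}"
            )
        self.steps.append((name, n_in, n_in - n_out, n_out))

    def telescopes(self) -> bool:
        return all(a[3] == b[1] for a, b in zip(self.steps, self.steps[1:]))

    def removed(self, name: str) -> int:
        for step, _, n_rm, _ in self.steps:
            if step == name:
                return n_rm
        raise KeyError(name)

    def to_rows(self) -> list[dict]:
        return [
            {"filter": s, "n_in": i, "n_removed": r, "n_out": o}
            for s, i, r, o in self.steps
        ]

    def __str__(self) -> str:
        lines = [f"{'filter':<24}{'in':>8}{'removed':>9}{'out':>8}"]
        for s, i, r, o in self.steps:
            lines.append(f"{s:<24}{i:>8}{r:>9}{o:>8}")
        return "\n".join(lines)


def filter_by_pvalue(
    records: Sequence[AssociationRecord], threshold: float
) -> list[AssociationRecord]:
    """Keep records with p strictly below ``threshold``, preserving order."""
    if not (0.0 < threshold < 1.0):
        raise ConfigurationError(f"p-value threshold {threshold} outside (0, 1)")
    kept = [r for r in records if r.pval < threshold]
    if not kept:
        logger.warning("p < %g retained no SNPs", threshold)
    return kept


def clump(
    records: Sequence[AssociationRecord],
    ld: LDMatrix | None = None,
    r2_max: float = 0.001,
    window_kb: float = 10_000.0,
) -> list[AssociationRecord]:
    """Greedy LD clumping: keep the best SNP of each correlated window.

    Candidates are visited in ascending p-value order (ties broken by
    snp_id); a SNP is accepted iff no previously accepted SNP on the same
    chromosome lies within ``window_kb`` with r^2 >= ``r2_max``.  Without an
    LD matrix this degrades to pure distance pruning (any accepted SNP
    within the window blocks the candidate), which is logged loudly.
    A missing pairwise r^2 entry is treated as not-in-LD.
    """
    if ld is None and records:
        logger.warning("clumping without an LD matrix: distance-only pruning")
    window_bp = window_kb * 1000.0
    order = sorted(records, key=lambda r: (r.pval, r.snp_id))
    accepted: list[AssociationRecord] = []
    for cand in order:
        if not cand.chrom or cand.pos <= 0:
            raise ConfigurationError(f"{cand.snp_id}: missing chrom/pos, cannot clump")
        blocked = False
        for acc in accepted:
            if acc.chrom != cand.chrom or abs(acc.pos - cand.pos) > window_bp:
                continue
            if ld is None:
                blocked = True
                break
            r2 = ld.lookup(acc.snp_id, cand.snp_id)
            if r2 is not None and r2 >= r2_max:
                blocked = True
                break
        if not blocked:
            accepted.append(cand)
    return accepted


def f_statistic(pair) -> float:
    """Per-SNP instrument strength F = (beta_exp / se_exp)^2.

    The exact form (n-2) * R^2 / (1 - R^2), with R^2 = 2*eaf*(1-eaf)*beta^2
    on a standardized trait, is available via :func:`f_statistic_exact` when
    eaf and n are present.
    """
    return (pair.beta_exp / pair.se_exp) ** 2


def f_statistic_exact(pair: HarmonizedPair) -> float:
    if pair.eaf_exp is None or not pair.n_exp > 2:
        raise ConfigurationError(f"{pair.snp_id}: exact F needs eaf and n")
    r2 = 2.0 * pair.eaf_exp * (1.0 - pair.eaf_exp) * pair.beta_exp**2
    r2 = min(r2, 1.0 - 1e-12)
    return (pair.n_exp - 2.0) * r2 / (1.0 - r2)


def filter_weak(
    pairs: Sequence[HarmonizedPair], f_min: float = 10.0
) -> list[HarmonizedPair]:
    """Drop weak instruments; F exactly at the cutoff is kept."""
    return [p for p in pairs if f_statistic(p) >= f_min]


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def harmonize(
    exposure_records: Sequence[AssociationRecord],
    outcome_records: Sequence[AssociationRecord],
    ledger: FilterLedger | None = None,
) -> tuple[list[HarmonizedPair], FilterLedger]:
    """Align exposure and outcome effects onto the exposure's effect allele.

    Pairs are matched by snp_id.  Palindromic (A/T, C/G) variants are removed
    unconditionally; allele sets that disagree even after strand
    complementing are removed as ambiguous; an outcome record whose effect
    allele equals the exposure's other allele has its beta sign flipped and
    eaf replaced by 1-eaf.
    """
    for name, recs in (("exposure", exposure_records), ("outcome", outcome_records)):
        seen: set[str] = set()
        for r in recs:
            if r.snp_id in seen:
                raise FormatError(f"duplicate snp_id {r.snp_id!r} in {name} table")
            seen.add(r.snp_id)
    out_by_id = {r.snp_id: r for r in outcome_records}
    ledger = ledger if ledger is not None else FilterLedger()
    n_in = len(exposure_records)
    pairs: list[HarmonizedPair] = []
    n_missing = n_palin = n_ambig = n_flip = 0
    for exp in exposure_records:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            n_missing += 1
            continue
        if _is_palindromic(exp.effect_allele, exp.other_allele):
            n_palin += 1
            continue
        exp_set = {exp.effect_allele, exp.other_allele}
        ea_o, oa_o = out.effect_allele, out.other_allele
        eaf_o = out.eaf
        beta_o = out.beta
        if {ea_o, oa_o} != exp_set:
            flipped_set = {COMPLEMENT[ea_o], COMPLEMENT[oa_o]}
            if flipped_set != exp_set:
                n_ambig += 1
                continue
            ea_o, oa_o = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
        if ea_o == exp.other_allele:
            beta_o = -beta_o
            eaf_o = None if eaf_o is None else 1.0 - eaf_o
            n_flip += 1
        elif ea_o != exp.effect_allele:  # pragma: no cover - excluded above
            n_ambig += 1
            continue
        pairs.append(
            HarmonizedPair(
                snp_id=exp.snp_id,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_o,
                se_out=out.se,
                pval_exp=exp.pval,
                pval_out=out.pval,
                eaf_exp=exp.eaf,
                eaf_out=eaf_o,
                chrom=exp.chrom,
                pos=exp.pos,
                n_exp=exp.n,
                n_out=out.n,
            )
        )
    ledger.add("missing_in_outcome", n_in, n_in - n_missing)
    ledger.add("palindromic", n_in - n_missing, n_in - n_missing - n_palin)
    k = n_in - n_missing - n_palin
    ledger.add("ambiguous", k, k - n_ambig)
    logger.info("harmonize: %d pairs, %d effect-allele flips", len(pairs), n_flip)
    return pairs, ledger


def pairs_to_records(
    pairs: Sequence[HarmonizedPair], exposure_trait: str = "exposure", outcome_trait: str = "outcome"
) -> tuple[list[AssociationRecord], list[AssociationRecord]]:
    """Split harmonized pairs back into exposure and outcome record lists."""
    exp, out = [], []
    for p in pairs:
        common = dict(
            snp_id=p.snp_id,
            chrom=p.chrom,
            pos=p.pos,
            effect_allele=p.effect_allele,
            other_allele=p.other_allele,
        )
        exp.append(
            AssociationRecord(
                **common, eaf=p.eaf_exp, beta=p.beta_exp, se=p.se_exp,
                pval=p.pval_exp, n=p.n_exp, trait_id=exposure_trait,
            )
        )
        out.append(
            AssociationRecord(
                **common, eaf=p.eaf_out, beta=p.beta_out, se=p.se_out,
                pval=p.pval_out, n=p.n_out, trait_id=outcome_trait,
            )
        )
    return exp, out


def remove_blacklisted(
    pairs: Sequence[HarmonizedPair],
    blacklist: Mapping[str, Iterable[str]],
    patterns: Sequence[str],
    ledger: FilterLedger | None = None,
) -> tuple[list[HarmonizedPair], FilterLedger]:
    """Drop pairs annotated to a confounder trait.

    A pair is removed when any of its blacklist annotations contains any of
    the configured patterns as a case-insensitive substring.
    """
    ledger = ledger if ledger is not None else FilterLedger()
    pats = [p.lower() for p in patterns]
    kept = []
    for pair in pairs:
        traits = [t.lower() for t in blacklist.get(pair.snp_id, [])]
        if any(pat in t for t in traits for pat in pats):
            logger.debug("blacklist removes %s (%s)", pair.snp_id, traits)
            continue
        kept.append(pair)
    ledger.add("confounder_blacklist", len(pairs), len(kept))
    return kept, ledger


def remove_outcome_associated(
    pairs: Sequence[HarmonizedPair],
    alpha: float = 0.05,
    ledger: FilterLedger | None = None,
) -> tuple[list[HarmonizedPair], FilterLedger]:
    """Drop pairs directly associated with the outcome after Bonferroni.

    The per-test threshold is alpha divided by the number of pairs tested.
    """
    ledger = ledger if ledger is not None else FilterLedger()
    k = len(pairs)
    if k == 0:
        ledger.add("outcome_bonferroni", 0, 0)
        return [], ledger
    thr = alpha / k
    kept = [p for p in pairs if not (p.pval_out < thr)]
    ledger.add("outcome_bonferroni", k, len(kept))
    return kept, ledger


__all__ = [
    "HarmonizedPair",
    "FilterLedger",
    "filter_by_pvalue",
    "clump",
    "f_statistic",
    "f_statistic_exact",
    "filter_weak",
    "harmonize",
    "pairs_to_records",
    "remove_blacklisted",
    "remove_outcome_associated",
]
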