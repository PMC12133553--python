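"""End-to-end orchestration: primary MR, mediator scan, two-step mediation,
diagnostics and enrichment, driven by one config.

The instrument filter chain runs in a fixed order — p-value threshold, LD
clumping, harmonization (palindrome/ambiguity removal), weak-instrument F
filter, MR-PRESSO outlier removal, per-SNP Steiger direction filter,
confounder blacklist, outcome Bonferroni — and every step appends to the
filter ledger, so the run report telescopes from raw SNP counts to the
final instrument set.

Decision rules applied to the primary analysis: if the Egger intercept is
significant (horizontal pleiotropy), Egger regression becomes the principal
estimate; otherwise IVW is principal, with the weighted median emphasized
alongside random-effects IVW when Cochran's Q signals heterogeneity.

All outputs are plain TSV plus one run-manifest JSON (config hash, seed,
package version); reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diagnostics as dg
from . import enrichment as en
from . import estimators as est
from . import instruments as ins
from . import mediation as med
from .summary_io import (
    AssociationRecord,
    ConfigurationError,
    read_blacklist,
    read_gmt,
    read_gwas_table,
    read_ld_matrix,
    write_gwas_table,
)
from .synthetic_data import SimulationConfig, simulate_mediation_gwas

logger = logging.getLogger("mrmediate")


@dataclass
class RunConfig:
    """One run's inputs, thresholds and output location.

    Data come either from ``simulation`` (a :class:`SimulationConfig`) or
    from explicit summary-table paths.  Thresholds default to the
    conventional values: 5e-8 exposure / 1e-5 mediator instrument p,
    r^2 < 0.001 within 10,000 kb clumping, F >= 10, alpha = 0.05.
    """

    output_dir: str = "mr_run"
    simulation: SimulationConfig | None = None
    exposure_path: str | None = None
    mediator_paths: dict[str, str] = field(default_factory=dict)
    outcome_path: str | None = None
    ld_path: str | None = None
    blacklist_path: str | None = None
    gmt_path: str | None = None
    confounder_patterns: tuple[str, ...] = ()
    p_exposure: float = 5e-8
    p_mediator: float = 1e-5
    r2_max: float = 0.001
    window_kb: float = 10_000.0
    f_min: float = 10.0
    alpha: float = 0.05
    presso_nsim: int = 1000
    n_boot: int = 1000
    outcome_type: str = "binary"
    case_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_exposure", "p_mediator", "r2_max", "window_kb", "f_min", "alpha"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            for key in ("beta1", "beta2", "mediator_ids", "large_effects",
                        "maf_range"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        study = simulate_mediation_gwas(sim)
        cf = config.case_fraction or sim.case_fraction
        return study.exposure, study.mediators, study.outcome, study.ld, cf, study
    if config.exposure_path is None or config.outcome_path is None:
        raise ConfigurationError("either simulation or exposure/outcome paths required")
    exposure, _ = read_gwas_table(config.exposure_path, trait_id="exposure")
    outcome, _ = read_gwas_table(config.outcome_path, trait_id="outcome")
    mediators = {
        mid: read_gwas_table(path, trait_id=mid)[0]
        for mid, path in config.mediator_paths.items()
    }
    ld = read_ld_matrix(config.ld_path) if config.ld_path else None
    return exposure, mediators, outcome, ld, config.case_fraction, None


def select_instruments(
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    config: RunConfig,
    p_threshold: float,
    ld=None,
    blacklist=None,
    apply_presso: bool = True,
    n_exp: float | None = None,
    n_out: float | None = None,
):
    """Run the full filter chain; returns (pairs, ledger, presso_result)."""
    ledger = ins.FilterLedger()
    n0 = len(exposure)
    sig = ins.filter_by_pvalue(exposure, p_threshold)
    ledger.add("pvalue_threshold", n0, len(sig))
    clumped = ins.clump(sig, ld=ld, r2_max=config.r2_max, window_kb=config.window_kb)
    ledger.add("ld_clump", len(sig), len(clumped))
    pairs, ledger = ins.harmonize(clumped, outcome, ledger)
    strong = ins.filter_weak(pairs, f_min=config.f_min)
    ledger.add("weak_f", len(pairs), len(strong))
    presso_res = None
    if apply_presso:
        strong, presso_res = dg.presso_filter(
            strong, n_sim=config.presso_nsim, seed=config.seed, outlier_alpha=config.alpha
        )
        ledger.add("presso_outliers", ledger.steps[-1][3], len(strong))
    n_exp = n_exp or (strong[0].n_exp if strong else 0)
    n_out = n_out or (strong[0].n_out if strong else 0)
    if strong and n_exp > 2 and n_out > 2:
        filtered = dg.steiger_filter(
            strong, n_exp, n_out,
            outcome_type=config.outcome_type, case_fraction=config.case_fraction,
        )
    else:
        filtered = strong
    ledger.add("steiger_direction", len(strong), len(filtered))
    if blacklist is not None:
        filtered, ledger = ins.remove_blacklisted(
            filtered, blacklist, config.confounder_patterns, ledger
        )
    else:
        ledger.add("confounder_blacklist", len(filtered), len(filtered))
    filtered, ledger = ins.remove_outcome_associated(filtered, config.alpha, ledger)
    return filtered, ledger, presso_res


def _estimates_frame(estimates: Sequence[est.MREstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        orv, lo, hi = e.or_ci()
        rows.append(
            {
                "method": e.method,
                "beta": e.beta,
                "se": e.se,
                "odds_ratio": orv,
                "or_ci_low": lo,
                "or_ci_high": hi,
                "pval": e.pval,
                "nsnp": e.nsnp,
                "extras": json.dumps(e.extras, sort_keys=True, default=float),
            }
        )
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_primary(config: RunConfig, outdir: Path | None = None) -> dict:
    """Primary exposure -> outcome analysis: filter chain, the estimator
    battery, diagnostics and decision rules; writes report tables."""
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure, _, outcome, ld, cf, study = _load_inputs(config)
    config = dataclasses.replace(config, case_fraction=cf)
    blacklist = read_blacklist(config.blacklist_path) if config.blacklist_path else None
    pairs, ledger, presso_res = select_instruments(
        exposure, outcome, config, config.p_exposure, ld=ld, blacklist=blacklist
    )
    if len(pairs) < 3:
        raise ConfigurationError(
            f"primary leg: only {len(pairs)} instruments survive\n{ledger}"
        )
    estimates = est.all_estimates(pairs, n_boot=config.n_boot, seed=config.seed)
    by_method = {e.method: e for e in estimates}
    q, q_df, q_p = est.cochran_q(pairs)
    intercept_p = by_method["egger_intercept"].pval
    if intercept_p < config.alpha:
        principal = "egger"
        note = "Egger intercept significant: horizontal pleiotropy, Egger principal"
    elif q_p < config.alpha:
        principal = "ivw_random"
        note = "heterogeneity (Q significant): random-effects IVW with weighted median"
    else:
        principal = "ivw_random"
        note = "no pleiotropy or heterogeneity detected"
    n_exp = pairs[0].n_exp
    n_out = pairs[0].n_out
    steiger_res = dg.steiger(
        pairs, n_exp, n_out, outcome_type=config.outcome_type, case_fraction=cf
    )
    loo = dg.leave_one_out(pairs, alpha=config.alpha)
    funnel = dg.funnel_data(pairs)

    _write_tsv(_estimates_frame(estimates), outdir / "estimates.tsv")
    _write_tsv(pd.DataFrame(ledger.to_rows()), outdir / "filter_ledger.tsv")
    _write_tsv(loo, outdir / "leave_one_out.tsv")
    _write_tsv(funnel, outdir / "funnel.tsv")
    diag = {
        "cochran_q": q, "q_df": q_df, "q_pval": q_p,
        "egger_intercept_pval": intercept_p,
        "principal_method": principal, "decision_note": note,
        "steiger": {
            "r2_exposure": steiger_res.r2_exposure,
            "r2_outcome": steiger_res.r2_outcome,
            "direction_correct": bool(steiger_res.direction_correct),
            "pval": steiger_res.steiger_pval,
        },
    }
    if presso_res is not None and np.isfinite(presso_res.rss_obs):
        diag["presso"] = {
            "global_pval": presso_res.global_pval,
            "outliers": presso_res.outlier_snps,
            "distortion_pval": presso_res.distortion_pval,
        }
    (outdir / "diagnostics.json").write_text(json.dumps(diag, indent=1, sort_keys=True))
    _write_manifest(config, outdir)
    if study is not None:
        study.truth.to_json(outdir / "truth.json")
    return {
        "estimates": by_method,
        "principal": by_method[principal],
        "ledger": ledger,
        "diagnostics": diag,
        "pairs": pairs,
    }


def run_mediation_scan(config: RunConfig, outdir: Path | None = None) -> dict:
    """Two-step mediation over every mediator, then enrichment of the
    significant mediator list; writes the mediation and enrichment reports.

    Step-1 MR (exposure instruments against each mediator) screens at
    ``alpha``; step-2 MR runs on the mediator's own instruments at the
    looser ``p_mediator`` threshold.  Classification follows the
    product-of-coefficients rules.
    """
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure, mediators, outcome, ld, cf, study = _load_inputs(config)
    config = dataclasses.replace(config, case_fraction=cf)
    if not mediators:
        raise ConfigurationError("mediation scan needs at least one mediator table")
    total_pairs, total_ledger, _ = select_instruments(
        exposure, outcome, config, config.p_exposure, ld=ld, apply_presso=True
    )
    if len(total_pairs) < 2:
        raise ConfigurationError("total leg: too few instruments")
    total = est.ivw(total_pairs, model="random")

    effects: dict[str, med.TwoStepEffects] = {}
    results: list[med.MediationResult] = []
    per_mediator_counts = []
    for mid, med_records in sorted(mediators.items()):
        s1_pairs, s1_ledger = ins.harmonize(
            [r for r in exposure if r.snp_id in {p.snp_id for p in total_pairs}],
            med_records,
        )
        s1_pairs = ins.filter_weak(s1_pairs, f_min=config.f_min)
        if len(s1_pairs) < 2:
            logger.warning("%s: step 1 has too few instruments, skipped", mid)
            continue
        step1 = est.ivw(s1_pairs, model="random")
        s2_pairs, s2_ledger, _ = select_instruments(
            med_records, outcome, config, config.p_mediator, ld=ld,
            apply_presso=len(med_records) >= 4,
        )
        per_mediator_counts.append(
            {"mediator": mid, "step1_nsnp": len(s1_pairs), "step2_nsnp": len(s2_pairs)}
        )
        if len(s2_pairs) < 2:
            logger.warning("%s: step 2 has too few instruments, skipped", mid)
            continue
        step2 = est.ivw(s2_pairs, model="random")
        n_med = med_records[0].n
        direction = dg.steiger(
            s2_pairs, n_med, s2_pairs[0].n_out,
            outcome_type=config.outcome_type, case_fraction=cf,
        )
        eff = med.TwoStepEffects(
            mediator_id=mid,
            beta_total=total.beta, se_total=total.se, p_total=total.pval,
            beta1=step1.beta, se1=step1.se, p1=step1.pval,
            beta2=step2.beta, se2=step2.se, p2=step2.pval,
            direction_correct=direction.direction_correct,
        )
        effects[mid] = eff
        results.append(med.mediate(eff, alpha=config.alpha))

    table_all = med.mediation_table(results, effects, significant_only=False)
    table_sig = med.mediation_table(results, effects, significant_only=True)
    _write_tsv(table_all, outdir / "mediation_all.tsv")
    _write_tsv(table_sig, outdir / "mediation_significant.tsv")
    _write_tsv(pd.DataFrame(per_mediator_counts), outdir / "mediator_instrument_counts.tsv")

    enrich_rows = None
    if config.gmt_path:
        collection = read_gmt(config.gmt_path)
        if len(collection) == 0:
            logger.warning("empty gene-set collection: enrichment skipped")
        else:
            sig_genes = [r.mediator_id for r in results if r.classification != "none"]
            enrich_rows = en.hypergeom_enrich(sig_genes, collection)
            _write_tsv(en.enrichment_table(enrich_rows), outdir / "enrichment.tsv")
    _write_manifest(config, outdir)
    return {
        "total": total,
        "effects": effects,
        "results": results,
        "table": table_all,
        "significant": table_sig,
        "enrichment": enrich_rows,
    }


def run_all(config: RunConfig) -> dict:
    """Primary analysis plus mediation scan into one output directory."""
    outdir = Path(config.output_dir)
    primary = run_primary(config, outdir / "primary")
    scan = run_mediation_scan(config, outdir / "mediation")
    _write_manifest(config, outdir)
    return {"primary": primary, "mediation": scan}


def _write_manifest(config: RunConfig, outdir: Path) -> None:
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package": "mrmediate",
        "version": __version__,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


__all__ = ["RunConfig", "select_instruments", "run_primary", "run_mediation_scan", "run_all"]
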