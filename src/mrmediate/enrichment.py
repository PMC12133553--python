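"""Overrepresentation analysis of a gene/protein list against gene-set
collections, with Benjamini-Hochberg FDR control.

The test is the one-sided hypergeometric upper tail: drawing the query list
from the universe, how surprising is the observed overlap with each set?
Entity-level counts only; pathway-topology statistics are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .summary_io import GeneSetCollection

logger = logging.getLogger("mrmediate")


@dataclass(slots=True)
class EnrichmentRow:
    set_name: str
    entities_found: int
    entities_total: int
    universe_size: int
    query_size: int
    pval: float
    fdr: float
    mapped_members: list[str]


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def hypergeom_enrich(
    query_genes: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str] | None = None,
) -> list[EnrichmentRow]:
    """Hypergeometric overrepresentation of the query in each gene set.

    ``universe`` defaults to the union of all set members; supplying the
    assay's own background (e.g. every measured protein) is recommended.
    Query genes absent from the universe are dropped with a warning.  Each
    set is intersected with the universe before testing.  Rows are sorted by
    p-value, ties broken by set name.
    """
    query = {g.strip().upper() for g in query_genes if g.strip()}
    uni = (
        {g.strip().upper() for g in universe}
        if universe is not None
        else collection.universe()
    )
    dropped = query - uni
    if dropped:
        logger.warning(
            "%d query gene(s) absent from universe dropped: %s",
            len(dropped), ", ".join(sorted(dropped)),
        )
    query &= uni
    n_universe = len(uni)
    n_query = len(query)
    rows: list[EnrichmentRow] = []
    for name, (_, members) in collection.sets.items():
        in_uni = sorted(set(members) & uni)
        hits = sorted(query & set(in_uni))
        k_total = len(in_uni)
        k_hit = len(hits)
        # P(X >= k_hit) drawing n_query from n_universe with k_total marked
        pval = float(stats.hypergeom.sf(k_hit - 1, n_universe, k_total, n_query))
        rows.append(
            EnrichmentRow(
                set_name=name,
                entities_found=k_hit,
                entities_total=k_total,
                universe_size=n_universe,
                query_size=n_query,
                pval=min(pval, 1.0),
                fdr=float("nan"),
                mapped_members=hits,
            )
        )
    rows.sort(key=lambda r: (r.pval, r.set_name))
    fdrs = bh_fdr([r.pval for r in rows])
    for row, fdr in zip(rows, fdrs):
        row.fdr = float(fdr)
    return rows


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Entity-level report: found/total counts, p, FDR, members joined by ';'."""
    return pd.DataFrame(
        {
            "pathway": [r.set_name for r in rows],
            "entities_found": [r.entities_found for r in rows],
            "entities_total": [r.entities_total for r in rows],
            "entities_ratio": [
                f"{r.entities_found}/{r.entities_total}" for r in rows
            ],
            "pval": [r.pval for r in rows],
            "fdr": [r.fdr for r in rows],
            "mapped_members": [";".join(r.mapped_members) for r in rows],
        }
    )


__all__ = ["EnrichmentRow", "bh_fdr", "hypergeom_enrich", "enrichment_table"]
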