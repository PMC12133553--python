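"""Reading, validation and writing of GWAS summary statistics and auxiliary inputs.

The central record is one SNP's association with one trait: alleles, effect
allele frequency, the per-allele effect estimate (log odds ratio for binary
traits), its standard error, p-value and sample size.  Everything downstream
(instrument selection, the estimators, mediation) consumes lists of these
records, so validation happens once, here.

Auxiliary inputs: a square LD matrix of squared correlations, a confounder
annotation blacklist (a local surrogate for a PhenoScanner lookup), and GMT
gene-set files for the enrichment step.
"""

from __future__ import annotations

import gzip
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mrmediate")

#: smallest positive double; p-values of exactly 0 are clamped here
TINY_P = float(np.nextafter(0.0, 1.0))

VALID_ALLELES = frozenset("ACGT")

#: default column names, matching this package's own writer
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "PVAL",
    "n": "N",
}

#: |z|-vs-p consistency tolerance (absolute difference on the z scale)
Z_CONSISTENCY_TOL = 0.5


class SummaryStatsError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(SummaryStatsError):
    """A required column, path or parameter is missing or invalid."""


class FormatError(SummaryStatsError):
    """An input file violates its format contract."""


class EmptyInputError(SummaryStatsError):
    """An input file contains no data rows."""


@dataclass(slots=True)
class AssociationRecord:
    """One SNP's association with one trait.

    ``beta`` is on the trait scale (log-OR for binary traits); ``se`` its
    standard error; ``eaf`` the effect-allele frequency (may be ``None``).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float
    trait_id: str = "trait"

    def zscore(self) -> float:
        return self.beta / self.se


@dataclass(slots=True)
class LDMatrix:
    """Squared-correlation matrix over an ordered list of SNP ids."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if r2.shape != (k, k):
            raise FormatError(f"LD matrix shape {r2.shape} does not match {k} SNP ids")
        if not np.allclose(r2, r2.T, atol=1e-6):
            raise FormatError("LD matrix is not symmetric within tolerance 1e-6")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-6):
            raise FormatError("LD matrix diagonal is not 1")
        if r2.min() < -1e-9 or r2.max() > 1 + 1e-9:
            raise FormatError("LD r^2 values outside [0, 1]")
        self.r2 = np.clip(r2, 0.0, 1.0)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    _index: dict = field(default_factory=dict, repr=False)

    def lookup(self, a: str, b: str) -> float | None:
        """r^2 between two SNPs, or ``None`` if either id is absent."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])


@dataclass(slots=True)
class GeneSetCollection:
    """Named gene sets: name -> (description, member symbols).

    Member symbols are upper-cased and deduplicated on construction.
    """

    sets: dict[str, tuple[str, list[str]]]

    def universe(self) -> set[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out.update(members)
        return out

    def __len__(self) -> int:
        return len(self.sets)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gwas_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str = "trait",
) -> tuple[list[AssociationRecord], dict[str, int]]:
    """Read a delimited GWAS summary table into validated records.

    Returns ``(records, qc_tally)`` where the tally counts dropped rows per
    reason; input rows always equal retained records plus the tally sum.
    Rows with a missing p-value get it imputed from the two-sided normal
    tail of beta/se.  A p-value of exactly 0 is clamped to the smallest
    positive double with a logged warning.
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={colmap["snp_id"]: str, colmap["chrom"]: str})
    mandatory = ["snp_id", "effect_allele", "other_allele", "beta", "se"]
    for key in mandatory:
        if colmap[key] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {colmap[key]!r} (field {key!r}) missing from {path}"
            )
    if df.empty:
        raise EmptyInputError(f"no data rows in {path}")

    tally = {
        "bad_alleles": 0,
        "nonpositive_se": 0,
        "bad_pval": 0,
        "bad_eaf": 0,
        "missing_beta": 0,
        "nonpositive_n": 0,
    }
    records: list[AssociationRecord] = []
    have = {k: colmap[k] in df.columns for k in DEFAULT_COLUMN_MAP}
    for row in df.itertuples(index=False):
        row = row._asdict()

        def get(key, default=None):
            if not have[key]:
                return default
            v = row[colmap[key]]
            if isinstance(v, float) and math.isnan(v):
                return default
            return v

        ea = str(get("effect_allele", "")).upper()
        oa = str(get("other_allele", "")).upper()
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES or ea == oa:
            tally["bad_alleles"] += 1
            continue
        beta = get("beta")
        se = get("se")
        if beta is None or se is None:
            tally["missing_beta"] += 1
            continue
        beta, se = float(beta), float(se)
        if not (se > 0) or not math.isfinite(se) or not math.isfinite(beta):
            tally["nonpositive_se"] += 1
            continue
        eaf = get("eaf")
        if eaf is not None:
            eaf = float(eaf)
            if not (0.0 <= eaf <= 1.0):
                tally["bad_eaf"] += 1
                continue
        n = get("n", float("nan"))
        n = float(n) if n is not None else float("nan")
        if not math.isnan(n) and n <= 0:
            tally["nonpositive_n"] += 1
            continue
        pval = get("pval")
        if pval is None:
            pval = 2.0 * float(stats.norm.sf(abs(beta / se)))
            pval = max(pval, TINY_P)
        else:
            pval = float(pval)
            if pval == 0.0:
                logger.warning("p-value of 0 for %s clamped to %g", get("snp_id"), TINY_P)
                pval = TINY_P
            elif not (0.0 < pval <= 1.0):
                tally["bad_pval"] += 1
                continue
            else:
                z_from_p = stats.norm.isf(pval / 2.0)
                if math.isfinite(z_from_p) and abs(abs(beta / se) - z_from_p) > Z_CONSISTENCY_TOL:
                    warnings.warn(
                        f"{get('snp_id')}: |beta/se|={abs(beta / se):.3g} inconsistent "
                        f"with p={pval:.3g}",
                        stacklevel=2,
                    )
        records.append(
            AssociationRecord(
                snp_id=str(get("snp_id")),
                chrom=str(get("chrom", "")),
                pos=int(get("pos", 0) or 0),
                effect_allele=ea,
                other_allele=oa,
                eaf=eaf,
                beta=beta,
                se=se,
                pval=pval,
                n=n,
                trait_id=trait_id,
            )
        )
    return records, tally


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Tabular view of records using the package's column dialect."""
    return pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "CHR": [r.chrom for r in records],
            "POS": [r.pos for r in records],
            "EA": [r.effect_allele for r in records],
            "OA": [r.other_allele for r in records],
            "EAF": [r.eaf if r.eaf is not None else np.nan for r in records],
            "BETA": [r.beta for r in records],
            "SE": [r.se for r in records],
            "PVAL": [r.pval for r in records],
            "N": [r.n for r in records],
        }
    )


def write_gwas_table(records: Sequence[AssociationRecord], path: str | Path) -> None:
    """Write records as tab-separated text (gzip if the path ends in .gz).

    Floats are written with shortest round-trip repr, so read-back
    reproduces every retained field bit-identically.
    """
    df = records_to_frame(records)
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square whitespace-delimited r^2 matrix with an id header row/column."""
    path = Path(path)
    with _open_text(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise EmptyInputError(f"no data in {path}")
    header = lines[0]
    ids = header[1:] if header and header[0].lower() in {"snp", "id", ""} else header
    body = lines[1:]
    if len(body) != len(ids):
        raise FormatError(f"LD matrix in {path}: {len(ids)} ids but {len(body)} rows")
    mat = np.empty((len(ids), len(ids)))
    for i, row in enumerate(body):
        vals = row[1:] if len(row) == len(ids) + 1 else row
        if len(vals) != len(ids):
            raise FormatError(f"LD matrix row {i + 1} has {len(vals)} values, expected {len(ids)}")
        mat[i] = [float(v) for v in vals]
    return LDMatrix(snp_ids=list(ids), r2=mat)


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("SNP\t" + "\t".join(ld.snp_ids) + "\n")
        for sid, row in zip(ld.snp_ids, ld.r2):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file (set name, description, tab-separated members)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            members: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                g = g.strip().upper()
                if g and g not in seen:
                    seen.add(g)
                    members.append(g)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


def read_blacklist(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column TSV of (SNP id, annotated trait string).

    A SNP may appear on several lines; annotations accumulate.
    """
    out: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: blacklist line needs 2 columns")
            out.setdefault(fields[0], []).append(fields[1])
    return out


__all__ = [
    "AssociationRecord",
    "LDMatrix",
    "GeneSetCollection",
    "SummaryStatsError",
    "ConfigurationError",
    "FormatError",
    "EmptyInputError",
    "DEFAULT_COLUMN_MAP",
    "TINY_P",
    "read_gwas_table",
    "write_gwas_table",
    "records_to_frame",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_gmt",
    "read_blacklist",
]
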