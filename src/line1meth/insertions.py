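"""LINE-1 insertion annotation tables and gene-set construction.

Insertion tables are TranspoGene-style TSVs: one row per insertion event with
a host gene symbol and an insertion type — promoter, exonized (an intronic
insertion that created a new exon), exonic (insertion into an existing exon)
or intronic.  A gene can carry several insertions of different types; for the
enrichment analysis a gene belongs to a typed set if it has at least one
insertion of that type, and to the "all insertion" union if it has any.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "INSERTION_TYPES",
    "DEFAULT_TYPE_ALIASES",
    "InsertionRecord",
    "InsertionGeneSets",
    "load_insertions",
    "build_gene_sets",
    "write_bed",
    "coverage_report",
]

INSERTION_TYPES = ("promoter", "exonized", "exonic", "intronic")

#: normalisation of source spellings (matched case-insensitively)
DEFAULT_TYPE_ALIASES = {
    "promoter": "promoter",
    "proximal promoter": "promoter",
    "proximal_promoter": "promoter",
    "exonized": "exonized",
    "exonic": "exonic",
    "exon": "exonic",
    "intronic": "intronic",
    "intron": "intronic",
}


@dataclass(frozen=True)
class InsertionRecord:
    """One insertion event: host gene symbol, type, optional coordinates.

    Coordinates are 0-based half-open; they are optional because the analysis
    uses only gene-level membership.
    """

    gene_symbol: str
    insertion_type: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self):
        if self.insertion_type not in INSERTION_TYPES:
            raise ValueError(
                f"insertion_type must be one of {INSERTION_TYPES}, "
                f"got {self.insertion_type!r}"
            )
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if self.start is not None and self.end is not None and not self.start < self.end:
            raise ValueError(
                f"start must be < end, got {self.start}..{self.end} "
                f"for {self.gene_symbol}"
            )


@dataclass(frozen=True)
class InsertionGeneSets:
    """Gene sets per insertion type plus their union."""

    by_type: dict[str, frozenset[str]]
    all_insertion: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        union = frozenset().union(*self.by_type.values()) if self.by_type else frozenset()
        if self.all_insertion != union:
            raise ValueError("all_insertion must equal the union of the typed sets")

    @classmethod
    def from_records(cls, records) -> "InsertionGeneSets":
        by_type: dict[str, set[str]] = {t: set() for t in INSERTION_TYPES}
        for rec in records:
            by_type[rec.insertion_type].add(rec.gene_symbol)
        frozen = {t: frozenset(s) for t, s in by_type.items()}
        return cls(by_type=frozen, all_insertion=frozenset().union(*frozen.values()))


def _normalize_type(token: str, aliases: dict[str, str]) -> str | None:
    return aliases.get(token.strip().lower())


def load_insertions(path, type_aliases: dict[str, str] | None = None) -> list[InsertionRecord]:
    """Parse a TranspoGene-style TSV into validated insertion records.

    The file needs at least ``gene`` and ``type`` columns (header row;
    ``gene_symbol``/``insertion_type`` also accepted); ``chrom``, ``start``,
    ``end``, ``strand`` are optional.  Type tokens are matched
    case-insensitively through the alias map; an unmappable token is a hard
    error naming the token and line.  Gene symbols keep their case, trimmed of
    whitespace; duplicate records are retained (set semantics apply later).
    """
    aliases = {k.lower(): v for k, v in (type_aliases or DEFAULT_TYPE_ALIASES).items()}
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    cols = {c.strip().lower(): c for c in df.columns}
    gene_col = cols.get("gene") or cols.get("gene_symbol") or cols.get("symbol")
    type_col = cols.get("type") or cols.get("insertion_type")
    if gene_col is None or type_col is None:
        raise ValueError(
            f"insertion table needs gene and type columns, found {list(df.columns)}"
        )
    records: list[InsertionRecord] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=2):  # line 1 = header
        token = str(row[type_col])
        norm = _normalize_type(token, aliases)
        if norm is None:
            raise ValueError(f"unmappable insertion type {token!r} on line {pos}")
        kwargs = {}
        for key in ("chrom", "strand"):
            if key in cols:
                v = str(row[cols[key]]).strip()
                kwargs[key] = v or None
        for key in ("start", "end"):
            if key in cols:
                v = str(row[cols[key]]).strip()
                kwargs[key] = int(v) if v else None
        records.append(
            InsertionRecord(
                gene_symbol=str(row[gene_col]).strip(),
                insertion_type=norm,
                **kwargs,
            )
        )
    logger.info("loaded %d insertion records from %s", len(records), path)
    return records


def build_gene_sets(records) -> InsertionGeneSets:
    """Gene sets per insertion type and their union, from validated records.

    A gene with both intronic and exonic records appears in both typed sets
    and once in the union.
    """
    return InsertionGeneSets.from_records(records)


def write_bed(records, path) -> int:
    """Emit a BED6 line per record that carries coordinates; returns the count."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            if rec.chrom is None or rec.start is None or rec.end is None:
                continue
            name = f"{rec.gene_symbol}|{rec.insertion_type}"
            strand = rec.strand or "."
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{name}\t0\t{strand}\n")
            n += 1
    return n


def coverage_report(sets: InsertionGeneSets, universe: set[str]) -> pd.DataFrame:
    """How much of each insertion gene set is present in an analysis universe.

    Symbol-namespace mismatches (old vs current gene symbols) show up here as
    low coverage rather than being silently resolved.
    """
    rows = []
    for name, genes in {**dict(sets.by_type), "all_insertion": sets.all_insertion}.items():
        inside = len(set(genes) & set(universe))
        rows.append(
            {
                "set": name,
                "n_genes": len(genes),
                "n_in_universe": inside,
                "coverage": inside / len(genes) if genes else float("nan"),
            }
        )
    return pd.DataFrame(rows)
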