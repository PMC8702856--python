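"""Reading dbCAN2-style "overview" annotation files and building the
genome x CAZyme-family gene-copy table.

A dbCAN2 overview file lists, per predicted gene, the family call of each
integrated tool (HMMER, Hotpep, DIAMOND) and the number of tools that made
a call.  The consensus rule keeps a gene only when at least ``min_tools``
of the consulted tools called it.  Retained calls are canonicalised to
family level (subfamily suffixes such as ``GH13_18`` collapse to ``GH13``)
and counted per genome, yielding a :class:`GenomeCazymeTable` that also
carries genus, phylum and genome size for every strain.  Summary helpers
reproduce class shares, per-genus copy statistics, phylum-level family
contributions and the copies-vs-genome-size correlation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: The six CAZy classes, by family-id prefix.
CAZY_CLASSES = ("GH", "GT", "PL", "CE", "CBM", "AA")

#: Tools integrated in the dbCAN2 overview dialect.
OVERVIEW_TOOLS = ("HMMER", "Hotpep", "DIAMOND")

#: Tools consulted by the consensus filter by default.  The annotation
#: protocol relies on DIAMOND and Hotpep; HMMER can be switched in.
DEFAULT_TOOLS = ("Hotpep", "DIAMOND")

#: Upstream dbCAN2 thresholds, recorded as provenance only -- they act
#: inside dbCAN2 before the overview file exists and are never applied here.
DBCAN2_PROVENANCE = {
    "diamond_evalue": 1e-102,
    "hotpep_hits": 6,
    "hotpep_frequency": 2.6,
}

_FAMILY_RE = re.compile(r"^(GH|GT|PL|CE|CBM|AA)(\d+)(?:_(\S+))?$")


class OverviewParseError(ValueError):
    """A malformed overview file line."""


class UnknownFamilyError(ValueError):
    """A family string whose class prefix is not one of the six CAZy classes."""


@dataclass(frozen=True)
class CazyFamily:
    """A canonical CAZyme family: class prefix + family number, no subfamily."""

    family_id: str
    cazy_class: str

    def __post_init__(self) -> None:
        if self.cazy_class not in CAZY_CLASSES:
            raise UnknownFamilyError(f"unknown CAZy class: {self.cazy_class!r}")
        if not self.family_id.startswith(self.cazy_class):
            raise UnknownFamilyError(
                f"family id {self.family_id!r} does not match class {self.cazy_class!r}"
            )


@dataclass
class OverviewRecord:
    """One gene's per-tool family calls from an overview file.

    ``tool_calls`` maps tool name to the set of raw family strings the tool
    assigned ("-" in the file means no call and yields an empty set).
    """

    gene_id: str
    tool_calls: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def n_tools(self) -> int:
        """Number of tools with a non-empty call set."""
        return sum(1 for calls in self.tool_calls.values() if calls)

    def n_tools_among(self, tools: Sequence[str]) -> int:
        return sum(1 for t in tools if self.tool_calls.get(t))


def _clean_token(token: str) -> str:
    """Strip parenthesised annotations dbCAN2 tools append, e.g. ``GH13(5)``
    or ``GH13_18(24-350)`` -> ``GH13`` / ``GH13_18``."""
    return re.sub(r"\(.*?\)", "", token).strip()


def _parse_cell(cell: str) -> frozenset[str]:
    cell = cell.strip()
    if cell in ("-", "", "N"):
        return frozenset()
    tokens = re.split(r"[+|]", cell)
    return frozenset(t for t in (_clean_token(tok) for tok in tokens) if t)


def parse_overview(path_or_lines: str | Path | Iterable[str]) -> list[OverviewRecord]:
    """Parse a dbCAN2-dialect overview file into :class:`OverviewRecord` objects.

    The file must start with a header line and have at least four
    tab-separated columns: gene id, one column per tool, and a tool count.
    Unknown extra columns are tolerated.  Multi-domain cells are split on
    ``+`` and ``|``; ``-`` denotes no call.

    Raises
    ------
    OverviewParseError
        If a data line has fewer columns than the header requires.
    """
    if isinstance(path_or_lines, (str, Path)):
        with open(path_or_lines) as fh:
            lines = fh.read().splitlines()
        origin = str(path_or_lines)
    else:
        lines = [ln.rstrip("\n") for ln in path_or_lines]
        origin = "<stream>"

    if not lines or not lines[0].strip():
        logger.warning("overview input %s is empty", origin)
        return []

    header = [h.strip() for h in lines[0].split("\t")]
    if len(header) < 4:
        raise OverviewParseError(
            f"{origin}: header has {len(header)} columns, expected >= 4"
        )
    # Map tool columns by name; fall back to the canonical positions of the
    # dbCAN2 layout (Gene ID / HMMER / Hotpep / DIAMOND / #ofTools).
    tool_cols: dict[str, int] = {}
    for i, name in enumerate(header):
        for tool in OVERVIEW_TOOLS:
            if name.lower() == tool.lower():
                tool_cols[tool] = i
    if not tool_cols:
        tool_cols = {"HMMER": 1, "Hotpep": 2, "DIAMOND": 3}
    min_cols = max(tool_cols.values()) + 1

    records: list[OverviewRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) < min_cols:
            raise OverviewParseError(
                f"{origin}: line {lineno} has {len(cells)} columns, expected >= {min_cols}"
            )
        calls = {tool: _parse_cell(cells[col]) for tool, col in tool_cols.items()}
        records.append(OverviewRecord(gene_id=cells[0].strip(), tool_calls=calls))
    if not records:
        logger.warning("overview input %s contains a header but no data lines", origin)
    return records


def consensus_filter(
    records: Iterable[OverviewRecord],
    min_tools: int = 2,
    tools: Sequence[str] = DEFAULT_TOOLS,
) -> list[tuple[str, frozenset[str]]]:
    """Keep genes called by at least ``min_tools`` of the consulted tools.

    The retained family set of a kept gene is the intersection of the
    non-empty consulted call sets when that intersection is non-empty,
    otherwise their union (the event is logged as a tool disagreement).
    Genes whose retained set is empty are dropped.
    """
    if min_tools < 1:
        raise ValueError("min_tools must be >= 1")
    kept: list[tuple[str, frozenset[str]]] = []
    for rec in records:
        call_sets = [rec.tool_calls.get(t, frozenset()) for t in tools]
        non_empty = [s for s in call_sets if s]
        if len(non_empty) < min_tools:
            continue
        retained = frozenset.intersection(*non_empty)
        if not retained:
            retained = frozenset.union(*non_empty)
            logger.info(
                "tool disagreement for gene %s: no common family among %s; keeping union",
                rec.gene_id,
                [sorted(s) for s in non_empty],
            )
        if retained:
            kept.append((rec.gene_id, retained))
    return kept


def canonicalize_family(raw: str) -> CazyFamily:
    """Canonicalise a raw family string to family level.

    Subfamily / annotation suffixes after the family number are stripped
    (``GH13_18`` -> ``GH13``); the class is derived from the prefix.

    Raises
    ------
    UnknownFamilyError
        If the prefix is not one of GH, GT, PL, CE, CBM, AA.
    """
    token = _clean_token(raw)
    m = _FAMILY_RE.match(token)
    if m is None:
        raise UnknownFamilyError(f"unrecognized CAZy family string: {raw!r}")
    prefix, number, _suffix = m.groups()
    return CazyFamily(family_id=f"{prefix}{number}", cazy_class=prefix)


def family_class(family_id: str) -> str:
    """CAZy class of a canonical family id (``GH13`` -> ``GH``)."""
    return canonicalize_family(family_id).cazy_class


_META_COLUMNS = ["genus", "phylum", "genome_size_bp"]


class GenomeCazymeTable:
    """Genome x CAZyme-family gene-copy matrix with per-strain taxonomy.

    ``counts`` is a strains x families integer DataFrame; ``meta`` carries
    genus, phylum and genome size (bp) per strain, aligned on the index.
    """

    def __init__(self, counts: pd.DataFrame, meta: pd.DataFrame):
        if not counts.index.equals(meta.index):
            raise ValueError("counts and meta must share the same strain index")
        missing = [c for c in _META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"meta is missing columns: {missing}")
        if (counts.to_numpy() < 0).any():
            raise ValueError("gene-copy counts must be non-negative")
        for fam in counts.columns:
            canonicalize_family(fam)  # raises on non-canonical ids
        self.counts = counts.astype(int)
        self.meta = meta[_META_COLUMNS].copy()

    @property
    def strains(self) -> pd.Index:
        return self.counts.index

    @property
    def families(self) -> pd.Index:
        return self.counts.columns

    def classes(self) -> pd.Series:
        """CAZy class of every family column."""
        return pd.Series(
            [family_class(f) for f in self.counts.columns], index=self.counts.columns
        )

    def total_copies(self) -> int:
        return int(self.counts.to_numpy().sum())

    # --- serialisation -------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write strains as rows, meta columns first, families after."""
        out = pd.concat([self.meta, self.counts], axis=1)
        out.to_csv(path, sep="\t", index_label="strain_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeCazymeTable":
        df = pd.read_csv(path, sep="\t", index_col="strain_id")
        meta = df[_META_COLUMNS]
        counts = df.drop(columns=_META_COLUMNS)
        return cls(counts, meta)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenomeCazymeTable({len(self.strains)} strains x "
            f"{len(self.families)} families, {self.total_copies()} copies)"
        )


def build_genome_table(
    annotations: Mapping[str, Sequence[tuple[str, frozenset[str]]]],
    taxonomy: pd.DataFrame,
) -> GenomeCazymeTable:
    """Aggregate per-genome retained gene annotations into a copy table.

    Parameters
    ----------
    annotations
        Mapping strain_id -> consensus-filtered ``(gene_id, raw families)``
        pairs, as produced by :func:`consensus_filter`.
    taxonomy
        DataFrame indexed by strain_id with columns genus, phylum,
        genome_size_bp.  Every annotated genome must have an entry.

    A gene retained with *k* distinct canonical families contributes one
    copy to each of the *k* family columns.  Families absent from every
    genome are omitted.
    """
    missing = [s for s in annotations if s not in taxonomy.index]
    if missing:
        raise KeyError(f"genomes without taxonomy entry: {missing}")

    rows: dict[str, dict[str, int]] = {}
    for strain, genes in annotations.items():
        counts: dict[str, int] = {}
        for _gene_id, raw_fams in genes:
            canon = {canonicalize_family(f).family_id for f in raw_fams}
            for fam in canon:
                counts[fam] = counts.get(fam, 0) + 1
        rows[strain] = counts

    strains = pd.Index(list(annotations), name="strain_id")
    counts_df = pd.DataFrame.from_dict(rows, orient="index")
    counts_df = counts_df.reindex(strains).fillna(0).astype(int)
    # stable, class-then-number ordering of family columns
    def _key(fam: str) -> tuple[int, int]:
        f = canonicalize_family(fam)
        return (CAZY_CLASSES.index(f.cazy_class), int(fam[len(f.cazy_class):]))

    counts_df = counts_df[sorted(counts_df.columns, key=_key)]
    meta = taxonomy.loc[strains, _META_COLUMNS]
    return GenomeCazymeTable(counts_df, meta)


def class_shares(table: GenomeCazymeTable) -> pd.Series:
    """Percentage of total gene copies per CAZy class; sums to 100."""
    total = table.total_copies()
    if total == 0:
        raise ValueError("cannot compute class shares of an all-zero table")
    per_class = table.counts.T.groupby(table.classes()).sum().sum(axis=1)
    shares = per_class / total * 100.0
    return shares.reindex(CAZY_CLASSES, fill_value=0.0)


def genus_summary(
    table: GenomeCazymeTable, cazy_class: str, genus: str
) -> tuple[int, float, float]:
    """(n strains, mean, sample sd) of per-genome copy totals of one class
    within one genus.  The sd uses the n-1 denominator."""
    if cazy_class not in CAZY_CLASSES:
        raise UnknownFamilyError(f"unknown CAZy class: {cazy_class!r}")
    in_genus = table.meta["genus"] == genus
    if not in_genus.any():
        raise KeyError(f"genus not present in table: {genus!r}")
    cols = table.classes() == cazy_class
    totals = table.counts.loc[in_genus, cols.index[cols]].sum(axis=1).to_numpy(float)
    n = len(totals)
    sd = float(np.std(totals, ddof=1)) if n > 1 else float("nan")
    return n, float(np.mean(totals)), sd


def phylum_family_contribution(table: GenomeCazymeTable) -> pd.DataFrame:
    """Family x phylum matrix of percentage contributions, rows summing to 100.

    Families with zero total copies are excluded (logged).
    """
    if table.counts.empty:
        raise ValueError("empty table")
    by_phylum = table.counts.groupby(table.meta["phylum"]).sum().T  # family x phylum
    totals = by_phylum.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.info(
            "excluding %d families with zero total copies: %s",
            int(zero.sum()),
            list(by_phylum.index[zero]),
        )
        by_phylum = by_phylum.loc[~zero]
        totals = totals[~zero]
    return by_phylum.div(totals, axis=0) * 100.0


def size_correlation(table: GenomeCazymeTable) -> float:
    """Squared Pearson correlation between per-genome total CAZyme copies
    and genome size (bp)."""
    sizes = table.meta["genome_size_bp"].to_numpy(float)
    totals = table.counts.sum(axis=1).to_numpy(float)
    if len(sizes) < 3 or (sizes <= 0).any():
        raise ValueError("need >= 3 genomes with positive genome size")
    if np.ptp(sizes) == 0 or np.ptp(totals) == 0:
        raise ValueError("correlation undefined: zero variance in copies or size")
    r = stats.pearsonr(totals, sizes).statistic
    return float(r * r)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a fixture manifest TSV: strain_id, file, genus, phylum, genome_size_bp."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain_id", "file", "genus", "phylum", "genome_size_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df.set_index("strain_id")


def load_annotation_directory(
    manifest_path: str | Path,
    min_tools: int = 2,
    tools: Sequence[str] = DEFAULT_TOOLS,
) -> GenomeCazymeTable:
    """Parse every overview file listed in a manifest, consensus-filter, and
    build the genome table.  File paths are resolved relative to the manifest."""
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    annotations = {}
    for strain, row in manifest.iterrows():
        records = parse_overview(base / row["file"])
        annotations[strain] = consensus_filter(records, min_tools=min_tools, tools=tools)
    taxonomy = manifest[["genus", "phylum", "genome_size_bp"]]
    return build_genome_table(annotations, taxonomy)
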