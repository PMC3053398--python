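"""Cross-platform gene identity mapping and probe collapsing.

Published gene sets come with identifiers from foreign platforms (UniGene
cluster ids, gene symbols, aliases, vendor probe ids).  Each identifier is
matched against the expression platform's annotation using a fixed linker
priority -- platform-native clone/probe id first, then UniGene, then
symbol, then alias -- and only matches from the single highest-priority
linker with at least one hit are kept.  Probes matching the same gene are
then collapsed to one expression row by their mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSet, NAMESPACES

logger = logging.getLogger(__name__)

#: total, deterministic linker priority (highest first)
LINKER_PRIORITY = ("clone_id", "unigene", "symbol", "alias")


@dataclass
class PlatformAnnotation:
    """Probe-level annotation with prebuilt linker lookup tables.

    Matching is exact for clone/probe ids and UniGene ids, case-insensitive
    for symbols and aliases (symbol case varies across vendor files).
    """

    frame: pd.DataFrame
    _lookup: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        frame = self.frame
        if frame.empty:
            raise ValueError("platform annotation is empty")
        if frame["probe_id"].duplicated().any():
            raise ValueError("duplicate probe_id in annotation")
        by_clone: dict[str, list[str]] = {}
        by_unigene: dict[str, list[str]] = {}
        by_symbol: dict[str, list[str]] = {}
        by_alias: dict[str, list[str]] = {}
        for row in frame.itertuples(index=False):
            probe = str(row.probe_id)
            by_clone.setdefault(probe, []).append(probe)
            unigene = getattr(row, "unigene", None)
            if isinstance(unigene, str) and unigene:
                by_unigene.setdefault(unigene, []).append(probe)
            symbol = getattr(row, "symbol", None)
            if isinstance(symbol, str) and symbol:
                by_symbol.setdefault(symbol.casefold(), []).append(probe)
            aliases = getattr(row, "aliases", None)
            if isinstance(aliases, str) and aliases:
                # aliases deduplicated per probe; pipe-separated on disk
                for alias in dict.fromkeys(a.strip() for a in aliases.split("|")):
                    if alias:
                        by_alias.setdefault(alias.casefold(), []).append(probe)
        self._lookup = {
            "clone_id": by_clone,
            "unigene": by_unigene,
            "symbol": by_symbol,
            "alias": by_alias,
        }

    def match(self, identifier: str, linker: str) -> list[str]:
        """Probes matched by one linker, in annotation order."""
        key = identifier.casefold() if linker in ("symbol", "alias") else identifier
        return list(self._lookup[linker].get(key, []))


@dataclass
class GeneMapping:
    """Mapping outcome for a single gene-set entry."""

    identifier: str
    namespace: str
    probe_ids: list[str]
    linker_used: str  # one of LINKER_PRIORITY or "none"


@dataclass
class MappingResult:
    set_name: str
    genes: list[GeneMapping]

    def __post_init__(self) -> None:
        for g in self.genes:
            if (g.linker_used == "none") != (len(g.probe_ids) == 0):
                raise ValueError(
                    f"{self.set_name}/{g.identifier}: linker 'none' iff no probes"
                )

    @property
    def mapped(self) -> list[GeneMapping]:
        return [g for g in self.genes if g.linker_used != "none"]

    @property
    def mapped_count(self) -> int:
        return len(self.mapped)

    @property
    def coverage(self) -> float:
        return self.mapped_count / len(self.genes)

    def platform_identities(self) -> set[frozenset]:
        """Post-mapping gene identities: each mapped gene as its probe set."""
        return {frozenset(g.probe_ids) for g in self.mapped}

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: gene, linker, probes, set coverage."""
        return pd.DataFrame(
            {
                "gene": [g.identifier for g in self.genes],
                "namespace": [g.namespace for g in self.genes],
                "linker": [g.linker_used for g in self.genes],
                "probes": ["|".join(g.probe_ids) for g in self.genes],
                "coverage": self.coverage,
            }
        )


def map_gene_set(gene_set: GeneSet, annotation: PlatformAnnotation) -> MappingResult:
    """Map one gene set onto the platform with prioritized linkers.

    Within-set duplicate identifiers are removed (first occurrence kept) and
    logged before matching.  A probe-id namespace is treated as
    platform-native, i.e. matched by the clone_id linker.
    """
    seen: set[tuple[str, str]] = set()
    entries: list[tuple[str, str]] = []
    for ident, ns in gene_set.genes:
        if ns not in NAMESPACES:
            raise ValueError(f"unrecognized namespace {ns!r} for gene {ident!r}")
        key = (ident.casefold(), ns)
        if key in seen:
            logger.info("map_gene_set[%s]: duplicate entry %r dropped",
                        gene_set.name, ident)
            continue
        seen.add(key)
        entries.append((ident, ns))

    mappings: list[GeneMapping] = []
    for ident, ns in entries:
        probes: list[str] = []
        linker_used = "none"
        for linker in LINKER_PRIORITY:
            hits = annotation.match(ident, linker)
            if hits:
                probes = hits
                linker_used = linker
                break
        mappings.append(GeneMapping(ident, ns, probes, linker_used))
    result = MappingResult(set_name=gene_set.name, genes=mappings)
    logger.info("map_gene_set[%s]: mapped %d/%d (coverage %.0f%%)",
                gene_set.name, result.mapped_count, len(mappings),
                100 * result.coverage)
    return result


def collapse_probes(expr: ExpressionMatrix, mapping: MappingResult) -> ExpressionMatrix:
    """Collapse each mapped gene's probes to one row by observed-value mean.

    Masked cells are ignored; a cell with every probe masked stays masked.
    A probe matched to two different genes contributes to both rows.
    """
    probe_index = {p: i for i, p in enumerate(expr.gene_ids)}
    absent = sorted(
        {p for g in mapping.mapped for p in g.probe_ids if p not in probe_index}
    )
    if absent:
        raise KeyError(
            f"probes referenced by mapping absent from matrix: {absent}"
        )
    gene_ids: list[str] = []
    values = np.empty((mapping.mapped_count, expr.n_samples))
    mask = np.empty((mapping.mapped_count, expr.n_samples), dtype=bool)
    for out_row, g in enumerate(mapping.mapped):
        rows = [probe_index[p] for p in g.probe_ids]
        sub = expr.values[rows]
        sub_missing = expr.missing_mask[rows]
        observed = (~sub_missing).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(
                observed > 0,
                np.where(sub_missing, 0.0, sub).sum(axis=0) / np.maximum(observed, 1),
                np.nan,
            )
        values[out_row] = mean
        mask[out_row] = observed == 0
        gene_ids.append(g.identifier)
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=expr.sample_ids,
        values=values,
        missing_mask=mask,
    )


def overlap_table(mappings: list[MappingResult]) -> pd.DataFrame:
    """Pairwise counts of shared post-mapping gene identities.

    Cell (i, j) is the number of platform gene identities mapped by both set
    i and set j; the diagonal is left empty (reported as -1 sentinel in the
    integer frame, omitted in the TSV export convention).
    """
    if len(mappings) < 2:
        raise ValueError("overlap table needs >= 2 mapped sets")
    names = [m.set_name for m in mappings]
    identities = [m.platform_identities() for m in mappings]
    n = len(mappings)
    grid = np.full((n, n), -1, dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j:
                grid[i, j] = len(identities[i] & identities[j])
    return pd.DataFrame(grid, index=names, columns=names)
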