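"""Symbol -> SeqId translation of gene-set collections.

SomaScan annotation tables pair SOMAmer SeqIds with Entrez gene symbols;
the mapping is many-to-many (a protein may be targeted by several SOMAmers,
and a few SOMAmers carry multiple symbols). Gene-set collections annotated
in symbol space are translated into SeqId space through the annotation
table, using HGNC-style aliases as a fallback when a symbol has no direct
annotation match. Translated sets below a minimum size are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .gmt import GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)


class AmbiguousAliasError(ValueError):
    """An alias mapping to two different official symbols."""


@dataclass
class AnnotationTable:
    """Unique (seqid, gene symbol) pairs with forward and reverse indexes."""

    pairs: List[Tuple[str, str]]
    by_symbol: Dict[str, List[str]] = field(init=False)
    by_seqid: Dict[str, List[str]] = field(init=False)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("annotation table is empty")
        uniq = list(dict.fromkeys(self.pairs))
        if len(uniq) != len(self.pairs):
            logger.warning("annotation: %d duplicate pairs collapsed", len(self.pairs) - len(uniq))
        self.pairs = uniq
        self.by_symbol = {}
        self.by_seqid = {}
        for seqid, symbol in self.pairs:
            self.by_symbol.setdefault(symbol, []).append(seqid)
            self.by_seqid.setdefault(seqid, []).append(symbol)

    @property
    def seqid_universe(self) -> List[str]:
        return sorted(self.by_seqid)

    @classmethod
    def from_file(cls, path: str | Path, seqid_col: str = "SeqId",
                  symbol_col: str = "EntrezGeneSymbol") -> "AnnotationTable":
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
        return cls(pairs=list(zip(df[seqid_col], df[symbol_col])))


@dataclass
class AliasTable:
    """Alias -> official symbol map; ambiguous aliases are rejected at load."""

    alias_to_official: Dict[str, str]

    @classmethod
    def from_pairs(cls, pairs: Sequence[Tuple[str, str]]) -> "AliasTable":
        mapping: Dict[str, str] = {}
        for alias, official in pairs:
            prev = mapping.get(alias)
            if prev is not None and prev != official:
                raise AmbiguousAliasError(
                    f"alias {alias!r} maps to both {prev!r} and {official!r}"
                )
            mapping[alias] = official
        return cls(alias_to_official=mapping)

    @classmethod
    def from_file(cls, path: str | Path, alias_col: str = "Alias",
                  symbol_col: str = "Symbol") -> "AliasTable":
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
        return cls.from_pairs(list(zip(df[alias_col], df[symbol_col])))

    @classmethod
    def empty(cls) -> "AliasTable":
        return cls(alias_to_official={})


def map_symbol_to_seqids(symbol: str, ann: AnnotationTable,
                         aliases: AliasTable | None = None) -> List[str]:
    """Map one gene symbol to its SeqIds; alias resolution only on a miss.

    An exact annotation match takes precedence; only when it is empty is the
    symbol resolved through the alias table and retried. Returns a sorted,
    deduplicated list; an unmapped symbol yields ``[]``.
    """
    direct = ann.by_symbol.get(symbol)
    if direct:
        return sorted(set(direct))
    if aliases is not None:
        official = aliases.alias_to_official.get(symbol)
        if official is not None:
            via_alias = ann.by_symbol.get(official)
            if via_alias:
                return sorted(set(via_alias))
    return []


@dataclass
class TranslationReport:
    n_input_sets: int
    n_translated: int
    n_dropped_small: int


def translate_collection(coll: GeneSetCollection, ann: AnnotationTable,
                         aliases: AliasTable | None = None,
                         n_min: int = 10) -> Tuple[GeneSetCollection, TranslationReport]:
    """Translate a symbol-space collection into SeqId space.

    Each set's members become the union of SeqIds mapped from its symbols
    (unique, sorted). Sets with fewer than ``n_min`` SeqIds are dropped and
    counted. Surviving sets are assigned parent identifiers
    ``<prefix>.<k>.0`` where ``k`` is the 1-based position of the set in
    the *source* collection, so identifiers are stable under threshold
    changes.
    """
    if coll.id_space != "symbol":
        raise ValueError("translate_collection expects a symbol-space collection")
    out_sets: List[GeneSet] = []
    n_dropped = 0
    for k, s in enumerate(coll, start=1):
        seqids = sorted({q for sym in s.members for q in map_symbol_to_seqids(sym, ann, aliases)})
        if len(seqids) < n_min:
            n_dropped += 1
            logger.info("set %r: %d SeqIds < n_min=%d, dropped", s.set_id, len(seqids), n_min)
            continue
        parent_id = f"{coll.prefix}.{k}.0"
        out_sets.append(GeneSet(set_id=parent_id, name=parent_id,
                                description=s.name, members=seqids))
    report = TranslationReport(n_input_sets=len(coll), n_translated=len(out_sets),
                               n_dropped_small=n_dropped)
    return GeneSetCollection(prefix=coll.prefix, sets=out_sets, id_space="seqid"), report
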