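"""Gene Matrix Transposed (.gmt) reading/writing and SeqId sanitization.

A GMT file stores one gene set per line: name, description, then members,
all tab-separated. SomaModule repositories use the same format with SeqIds
as members; because some enrichment tools reject hyphens in identifiers,
SeqIds (pattern ``digits-digits``, e.g. ``10346-5``) can be sanitized to an
underscore form (``10346_5``) and back.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List

logger = logging.getLogger(__name__)

_SEQID_RE = re.compile(r"^\d+-\d+$")
_SEQID_SANITIZED_RE = re.compile(r"^\d+_\d+$")


class GmtParseError(ValueError):
    """Raised for malformed GMT content (line number included in message)."""


@dataclass
class GeneSet:
    """A named set of identifiers (gene symbols or SeqIds).

    ``members`` is an ordered list of unique identifiers; order is preserved
    from the source so files round-trip byte-identically.
    """

    set_id: str
    name: str
    description: str = ""
    members: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.set_id:
            raise ValueError("GeneSet.set_id must be non-empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"GeneSet {self.set_id!r}: duplicate members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """An ordered collection of gene sets sharing one identifier space.

    ``id_space`` is one of ``symbol``, ``seqid``, ``seqid_sanitized``.
    ``prefix`` is the short collection code used in module identifiers
    (e.g. "R" for Reactome: parent "R.144.0", children "R.144.1", ...).
    """

    prefix: str
    sets: List[GeneSet] = field(default_factory=list)
    id_space: str = "symbol"

    def __post_init__(self) -> None:
        if self.id_space not in ("symbol", "seqid", "seqid_sanitized"):
            raise ValueError(f"unknown id_space {self.id_space!r}")
        ids = [s.set_id for s in self.sets]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate set_ids in collection: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def get(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


def read_gmt(path: str | Path, prefix: str = "", id_space: str = "symbol") -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each line must have at least three tab-separated fields
    (name, description, members...). Duplicate members within a line are
    collapsed keeping the first occurrence, with a warning. Comment lines
    starting with ``#`` are ignored (provenance headers).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    sets: List[GeneSet] = []
    n_data_lines = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        n_data_lines += 1
        fields = line.split("\t")
        if len(fields) < 3:
            raise GmtParseError(
                f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
            )
        name, description = fields[0], fields[1]
        raw_members = [f for f in fields[2:] if f != ""]
        seen = set()
        members = []
        for m in raw_members:
            if m in seen:
                logger.warning("%s:%d: duplicate member %r in set %r collapsed", path, lineno, m, name)
                continue
            seen.add(m)
            members.append(m)
        if not members:
            raise GmtParseError(f"{path}:{lineno}: set {name!r} has no members")
        sets.append(GeneSet(set_id=name, name=name, description=description, members=members))
    if n_data_lines == 0:
        raise GmtParseError(f"{path}: empty GMT file")
    return GeneSetCollection(prefix=prefix, sets=sets, id_space=id_space)


def write_gmt(collection: GeneSetCollection, path: str | Path,
              header_lines: Iterable[str] = ()) -> None:
    """Write a collection as GMT: ``name TAB description TAB members...``.

    An empty description is written as ``na`` (MSigDB convention). Output is
    UTF-8 with Unix newlines. A member containing a tab or newline would
    corrupt the format and raises ``ValueError``. ``header_lines`` (already
    ``#``-prefixed or not) are emitted as comment lines before the data.
    """
    if len(collection) == 0:
        raise ValueError("refusing to write an empty collection")
    lines = []
    for h in header_lines:
        lines.append(h if h.startswith("#") else "# " + h)
    for s in collection:
        for m in s.members:
            if "\t" in m or "\n" in m:
                raise ValueError(f"set {s.set_id!r}: member {m!r} contains a delimiter")
        desc = s.description if s.description else "na"
        lines.append("\t".join([s.name, desc, *s.members]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def sanitize_seqid(seqid: str) -> str:
    """Replace hyphens in a SeqId with underscores (``10346-5`` -> ``10346_5``).

    A string with no hyphen is returned unchanged with a warning.
    """
    if "-" not in seqid:
        logger.warning("sanitize_seqid: %r contains no hyphen; returned unchanged", seqid)
        return seqid
    return seqid.replace("-", "_")


def desanitize_seqid(seqid: str) -> str:
    """Invert :func:`sanitize_seqid` (``10346_5`` -> ``10346-5``).

    Raises ``ValueError`` if the input already contains a hyphen.
    """
    if "-" in seqid:
        raise ValueError(f"desanitize_seqid: {seqid!r} already contains a hyphen")
    return seqid.replace("_", "-")


def sanitize_collection(collection: GeneSetCollection) -> GeneSetCollection:
    """Return a copy of a SeqId collection with every member sanitized."""
    if collection.id_space != "seqid":
        raise ValueError("sanitize_collection expects id_space='seqid'")
    sets = [
        GeneSet(set_id=s.set_id, name=s.name, description=s.description,
                members=[sanitize_seqid(m) for m in s.members])
        for s in collection
    ]
    return GeneSetCollection(prefix=collection.prefix, sets=sets, id_space="seqid_sanitized")
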