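"""Readers and writers for every external format the tool touches.

Formats: delimited typed edge tables (CSV/TSV), the PubTator annotation
export (``PMID|t|...`` / ``PMID|a|...`` plus tab-separated mention lines),
word2vec text embeddings, GraphML, the synonym-lexicon TSV, and the
``node--label--node`` path-record syntax used to print ranked paths.

All readers accept either a path or an open text stream.
"""

from __future__ import annotations

import csv
import io as _stdio
import logging
from dataclasses import dataclass, field
from pathlib import Path as FsPath
from typing import IO, Iterable, Iterator, Union

import networkx as nx
import numpy as np

from .cooccur import AnnotatedDocument, Mention
from .errors import ConflictError, FormatError, ParameterError, PathParseError
from .merge import LexiconEntry, SynonymLexicon, normalize_name
from .model import (
    Edge,
    Entity,
    KnowledgeGraph,
    entity_key,
    validate_entity_type,
    validate_relation_label,
)
from .pathrank import EmbeddingStore, Path

logger = logging.getLogger(__name__)

Source = Union[str, FsPath, IO[str]]

#: Mention-type names emitted by the PubTator annotator, mapped into the
#: package's entity-type vocabulary.
PUBTATOR_TYPE_MAP: dict[str, str] = {
    "gene": "gene",
    "disease": "disease",
    "chemical": "chemical",
    "species": "species",
    "cellline": "cell_line",
    "snp": "snp",
    "proteinmutation": "protein_mutation",
    "dnamutation": "dna_mutation",
    "mutation": "dna_mutation",
    "genus": "genus",
    "strain": "strain",
}


def _open(source: Source, mode: str = "r"):
    """Return (stream, owns) for a path or an already-open stream."""
    if isinstance(source, (str, FsPath)):
        if "b" in mode:
            return open(source, mode), True
        return open(source, mode, encoding="utf-8"), True
    return source, False


# ---------------------------------------------------------------------------
# Typed edge tables
# ---------------------------------------------------------------------------

@dataclass
class EdgeTableDialect:
    """Column layout of a typed edge table.

    head/tail/relation columns are mandatory; weight defaults to 1 when the
    column is absent.  Columns are named when ``header`` is true, otherwise
    0-based positions.
    """

    delimiter: str = ","
    header: bool = True
    head: str | int = "head"
    head_type: str | int = "head_type"
    relation: str | int = "relation"
    tail: str | int = "tail"
    tail_type: str | int = "tail_type"
    weight: str | int | None = "weight"


def sniff_dialect(first_line: str) -> EdgeTableDialect:
    """Guess delimiter (comma vs tab) and header presence from line one."""
    delimiter = "\t" if first_line.count("\t") >= first_line.count(",") else ","
    fields = [f.strip().lower() for f in first_line.split(delimiter)]
    has_header = "head" in fields and "tail" in fields
    if has_header:
        return EdgeTableDialect(
            delimiter=delimiter,
            header=True,
            weight="weight" if "weight" in fields else None,
        )
    # positional fallback: head, head_type, relation, tail, tail_type[, weight]
    return EdgeTableDialect(
        delimiter=delimiter, header=False,
        head=0, head_type=1, relation=2, tail=3, tail_type=4,
        weight=5 if len(fields) > 5 else None,
    )


def read_edge_table(
    source: Source,
    dialect: EdgeTableDialect | None = None,
    *,
    strict: bool = True,
    sources: frozenset[str] = frozenset(),
) -> KnowledgeGraph:
    """Load a typed edge table into a :class:`KnowledgeGraph`.

    Rows are kept verbatim as a multiset (duplicate rows become parallel
    edges); entities are created on first mention with the row's declared
    type, names normalized.  In strict mode an unknown relation label, an
    unknown entity type, or a name re-declared under a different type is a
    format/conflict error with a line number.
    """
    stream, owns = _open(source)
    try:
        first = stream.readline()
        if not first:
            return KnowledgeGraph()
        if dialect is None:
            dialect = sniff_dialect(first.rstrip("\n"))
        rows = csv.reader(
            _chain_lines(first, stream), delimiter=dialect.delimiter
        )
        graph = KnowledgeGraph()
        name_types: dict[str, str] = {}
        colmap = None
        for lineno, row in enumerate(rows, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if lineno == 1 and dialect.header:
                colmap = {name.strip().lower(): i for i, name in enumerate(row)}
                continue
            try:
                get = _field_getter(row, dialect, colmap)
                head_raw, head_type = get("head"), get("head_type")
                tail_raw, tail_type = get("tail"), get("tail_type")
                relation = get("relation")
                weight_raw = get("weight", optional=True)
            except IndexError:
                raise FormatError("row has too few fields", line=lineno)
            for fieldname, value in (
                ("head", head_raw), ("tail", tail_raw), ("relation", relation)
            ):
                if not value:
                    raise FormatError(f"missing mandatory field {fieldname!r}",
                                      line=lineno)
            try:
                label = validate_relation_label(relation, allow_unknown=not strict)
                htype = validate_entity_type(head_type, allow_unknown=not strict)
                ttype = validate_entity_type(tail_type, allow_unknown=not strict)
            except ParameterError as exc:
                raise FormatError(str(exc), line=lineno) from exc
            weight = 1.0
            if weight_raw not in (None, ""):
                try:
                    weight = float(weight_raw)
                except ValueError:
                    raise FormatError(f"bad weight {weight_raw!r}", line=lineno)
            ids = []
            for raw, etype in ((head_raw, htype), (tail_raw, ttype)):
                name = normalize_name(raw)
                if strict:
                    seen = name_types.get(name)
                    if seen is not None and seen != etype:
                        raise ConflictError(
                            f"line {lineno}: entity {name!r} declared as "
                            f"{etype!r} after {seen!r}"
                        )
                    name_types[name] = etype
                eid = entity_key(name, etype)
                if not graph.has_entity(eid):
                    graph.add_entity(
                        Entity(entity_id=eid, name=name, etype=etype,
                               sources=sources)
                    )
                ids.append(eid)
            graph.add_edge(
                Edge(head=ids[0], tail=ids[1], label=label, weight=weight,
                     directed=True)
            )
        return graph
    finally:
        if owns:
            stream.close()


def _chain_lines(first: str, rest: IO[str]) -> Iterator[str]:
    yield first
    yield from rest


def _field_getter(row, dialect, colmap):
    def get(name: str, optional: bool = False):
        col = getattr(dialect, name)
        if col is None:
            return None
        if dialect.header:
            idx = colmap.get(str(col).lower()) if colmap else None
            if idx is None:
                if optional:
                    return None
                raise FormatError(f"missing column {col!r}")
        else:
            idx = int(col)
            if optional and idx >= len(row):
                return None
        return row[idx].strip()
    return get


def write_edge_table(
    graph: KnowledgeGraph, sink: Source, dialect: EdgeTableDialect | None = None
) -> None:
    """Write the default-dialect edge table (stored orientation preserved)."""
    dialect = dialect or EdgeTableDialect()
    stream, owns = _open(sink, "w")
    try:
        w = csv.writer(stream, delimiter=dialect.delimiter, lineterminator="\n")
        if dialect.header:
            w.writerow(["head", "head_type", "relation", "tail", "tail_type",
                        "weight"])
        for edge in graph.edges():
            h, t = graph.entity(edge.head), graph.entity(edge.tail)
            w.writerow([h.name, h.etype, edge.label, t.name, t.etype,
                        _fmt_weight(edge.weight)])
    finally:
        if owns:
            stream.close()


def _fmt_weight(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else repr(w)


# ---------------------------------------------------------------------------
# PubTator annotation export
# ---------------------------------------------------------------------------

def read_pubtator(source: Source, *, strict: bool = True) -> list[AnnotatedDocument]:
    """Parse a PubTator export into :class:`AnnotatedDocument` records.

    Expected layout per document: ``PMID|t|title``, ``PMID|a|abstract``,
    then tab-separated mention lines ``PMID  start  end  text  type  [id]``,
    with documents separated by blank lines.
    """
    stream, owns = _open(source)
    try:
        docs: list[AnnotatedDocument] = []
        current: dict | None = None

        def flush():
            nonlocal current
            if current is not None:
                docs.append(
                    AnnotatedDocument(
                        doc_id=current["pmid"],
                        title=current["title"],
                        abstract=current["abstract"],
                        mentions=tuple(current["mentions"]),
                    )
                )
                current = None

        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if "|" in line.split("\t")[0]:
                pmid, kind, _, text = _parse_pipe_line(line, lineno)
                if current is None or current["pmid"] != pmid:
                    flush()
                    current = {"pmid": pmid, "title": "", "abstract": "",
                               "mentions": []}
                if kind == "t":
                    current["title"] = text
                elif kind == "a":
                    current["abstract"] = text
                else:
                    raise FormatError(f"unknown section {kind!r}", line=lineno)
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError("mention line has fewer than 5 fields",
                                  line=lineno)
            pmid, start_s, end_s, text, mtype = fields[:5]
            identifier = fields[5] if len(fields) > 5 else ""
            if current is None or current["pmid"] != pmid:
                raise FormatError(
                    f"mention references unseen document {pmid!r}", line=lineno
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError("malformed mention offsets", line=lineno)
            bound = len(current["title"]) + 1 + len(current["abstract"])
            if start < 0 or end <= start or (strict and end > bound):
                raise FormatError(
                    f"mention span [{start}, {end}) outside document bounds",
                    line=lineno,
                )
            key = mtype.strip().lower().replace("_", "").replace(" ", "")
            etype = PUBTATOR_TYPE_MAP.get(key)
            if etype is None:
                if strict:
                    raise FormatError(f"unknown mention type {mtype!r}",
                                      line=lineno)
                etype = validate_entity_type(mtype, allow_unknown=True)
            current["mentions"].append(
                Mention(name=normalize_name(text), etype=etype,
                        start=start, end=end, identifier=identifier)
            )
        flush()
        return docs
    finally:
        if owns:
            stream.close()


def _parse_pipe_line(line: str, lineno: int) -> tuple[str, str, str, str]:
    parts = line.split("|", 2)
    if len(parts) != 3:
        raise FormatError("malformed title/abstract line", line=lineno)
    return parts[0], parts[1], "", parts[2]


def write_pubtator(docs: Iterable[AnnotatedDocument], sink: Source) -> None:
    stream, owns = _open(sink, "w")
    try:
        first = True
        for doc in docs:
            if not first:
                stream.write("\n")
            first = False
            stream.write(f"{doc.doc_id}|t|{doc.title}\n")
            stream.write(f"{doc.doc_id}|a|{doc.abstract}\n")
            for m in doc.mentions:
                stream.write(
                    f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.name}\t"
                    f"{_pubtator_type(m.etype)}\t{m.identifier}\n"
                )
    finally:
        if owns:
            stream.close()


def _pubtator_type(etype: str) -> str:
    for raw, mapped in PUBTATOR_TYPE_MAP.items():
        if mapped == etype and raw != "mutation":
            return raw.capitalize() if raw != "cellline" else "CellLine"
    return etype


# ---------------------------------------------------------------------------
# word2vec text embeddings
# ---------------------------------------------------------------------------

def read_word2vec_text(source: Source) -> EmbeddingStore:
    """Load embeddings in word2vec text format.

    First line is ``<vocab_size> <dim>``; each following line is a token and
    ``dim`` whitespace-separated reals.  Tokens are lowercased at load, and
    lookups lowercase the query, so matching is effectively case-insensitive.
    Duplicate tokens: last occurrence wins with a logged warning.
    """
    stream, owns = _open(source)
    try:
        header = stream.readline().split()
        if len(header) != 2:
            raise FormatError("expected header '<vocab_size> <dim>'", line=1)
        try:
            declared_n, dim = int(header[0]), int(header[1])
        except ValueError:
            raise FormatError("non-integer header fields", line=1)
        if dim <= 0:
            raise FormatError("dimension must be positive", line=1)
        vectors: dict[str, np.ndarray] = {}
        for lineno, raw in enumerate(stream, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split()
            if len(parts) != dim + 1:
                raise FormatError(
                    f"expected {dim} values, got {len(parts) - 1}", line=lineno
                )
            token = parts[0].lower()
            try:
                vec = np.asarray([float(x) for x in parts[1:]], dtype=float)
            except ValueError:
                raise FormatError("non-numeric vector component", line=lineno)
            if token in vectors:
                logger.warning(
                    "duplicate embedding token %r at line %d; last wins",
                    token, lineno,
                )
            vectors[token] = vec
        if len(vectors) != declared_n:
            logger.warning(
                "header declared %d tokens, file contains %d unique",
                declared_n, len(vectors),
            )
        return EmbeddingStore(vectors=vectors, dim=dim)
    finally:
        if owns:
            stream.close()


def write_word2vec_text(store: EmbeddingStore, sink: Source) -> None:
    stream, owns = _open(sink, "w")
    try:
        stream.write(f"{len(store)} {store.dim}\n")
        for token in store.tokens():
            vec = store.raw_vector(token)
            stream.write(token.replace(" ", "_") + " "
                         + " ".join(repr(float(x)) for x in vec) + "\n")
    finally:
        if owns:
            stream.close()


# ---------------------------------------------------------------------------
# Printed path records: node--label--node--label--...--node
# ---------------------------------------------------------------------------

def parse_path_record(text: str) -> Path:
    """Parse a printed path record into a :class:`Path`.

    The separator is exactly two hyphens; node names may contain single
    hyphens and spaces ("il-6 receptor").  Node names are normalized
    (lowercase, underscores to spaces).
    """
    tokens = text.strip().split("--")
    if len(tokens) < 3 or len(tokens) % 2 == 0:
        raise PathParseError(
            f"path record needs an odd token count >= 3, got {len(tokens)}: "
            f"{text!r}"
        )
    if any(not tok.strip() for tok in tokens):
        raise PathParseError(f"empty token in path record: {text!r}")
    nodes = tuple(normalize_name(tok) for tok in tokens[0::2])
    labels = tuple(validate_relation_label(tok, allow_unknown=True)
                   for tok in tokens[1::2])
    return Path(nodes=nodes, labels=labels)


def render_path_record(path: Path) -> str:
    """Inverse of :func:`parse_path_record` (on normalized names)."""
    parts = [path.nodes[0]]
    for label, node in zip(path.labels, path.nodes[1:]):
        parts.extend([label, node])
    return "--".join(parts)


def read_path_records(source: Source) -> list[tuple[int, Path, float | None]]:
    """Read a TSV of ``declared_depth<TAB>record<TAB>[score]`` rows.

    Used for the bundled case-study tables of published top-ranked paths.
    The declared depth is returned as printed (it may disagree with the
    record's actual edge count, which the caller can check via
    ``path.depth``).
    """
    stream, owns = _open(source)
    try:
        out = []
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError("expected depth<TAB>record", line=lineno)
            try:
                depth = int(fields[0])
            except ValueError:
                raise FormatError(f"bad depth {fields[0]!r}", line=lineno)
            score = float(fields[2]) if len(fields) > 2 and fields[2] else None
            out.append((depth, parse_path_record(fields[1]), score))
        return out
    finally:
        if owns:
            stream.close()


# ---------------------------------------------------------------------------
# Synonym lexicon TSV: canonical<TAB>type<TAB>syn1|syn2|...
# ---------------------------------------------------------------------------

def read_lexicon(source: Source) -> SynonymLexicon:
    stream, owns = _open(source)
    try:
        lex = SynonymLexicon()
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError("expected canonical<TAB>type[<TAB>synonyms]",
                                  line=lineno)
            canonical = normalize_name(fields[0])
            try:
                etype = validate_entity_type(fields[1])
            except ParameterError as exc:
                raise FormatError(str(exc), line=lineno) from exc
            synonyms = frozenset(
                normalize_name(s)
                for s in (fields[2].split("|") if len(fields) > 2 else [])
                if s.strip()
            )
            lex.add(LexiconEntry(canonical=canonical, etype=etype,
                                 synonyms=synonyms))
        return lex
    finally:
        if owns:
            stream.close()


def write_lexicon(lexicon: SynonymLexicon, sink: Source) -> None:
    stream, owns = _open(sink, "w")
    try:
        for entry in sorted(lexicon, key=lambda e: (e.etype, e.canonical)):
            stream.write(
                f"{entry.canonical}\t{entry.etype}\t"
                f"{'|'.join(sorted(entry.synonyms))}\n"
            )
    finally:
        if owns:
            stream.close()


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

def write_graphml(graph: KnowledgeGraph, sink: Source) -> None:
    """Export as GraphML with node name/type/degree and edge label/weight."""
    g = nx.MultiGraph()
    for e in graph.entities():
        g.add_node(e.entity_id, name=e.name, type=e.etype,
                   degree=graph.degree(e.entity_id))
    for edge in graph.edges():
        g.add_edge(edge.head, edge.tail, label=edge.label, weight=edge.weight)
    stream, owns = _open(sink, "wb" if isinstance(sink, (str, FsPath)) else "w")
    try:
        if isinstance(sink, (str, FsPath)):
            nx.write_graphml(g, stream)
        else:
            buf = _stdio.BytesIO()
            nx.write_graphml(g, buf)
            stream.write(buf.getvalue().decode("utf-8"))
    finally:
        if owns:
            stream.close()


def read_graphml(source: Source) -> KnowledgeGraph:
    """Re-import a GraphML file written by :func:`write_graphml`."""
    if isinstance(source, (str, FsPath)):
        g = nx.read_graphml(source, force_multigraph=True)
    else:
        g = nx.read_graphml(
            _stdio.BytesIO(source.read().encode("utf-8")), force_multigraph=True
        )
    graph = KnowledgeGraph()
    for node, data in g.nodes(data=True):
        graph.add_entity(
            Entity(entity_id=node, name=data.get("name", node),
                   etype=data.get("type", "gene"))
        )
    for u, v, data in g.edges(data=True):
        graph.add_edge(
            Edge(head=u, tail=v, label=data.get("label", "co_occur"),
                 weight=float(data.get("weight", 1.0)))
        )
    return graph
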