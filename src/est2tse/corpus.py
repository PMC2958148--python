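"""Domain types and flat-file I/O for an EST corpus.

An EST corpus couples three things: sequencing *libraries* (each annotated
with six free-text source fields describing where the material came from),
*expressed sequences* (single-pass ESTs or longer polyadenylated cDNAs, each
attributed to one library), and *clusters* grouping sequences that derive
from one putative gene locus, in the style of NCBI UniGene.

Because the historical database dump formats are not reproducible, the
corpus is stored in a small documented dialect designed to be deterministic
and human-writable:

* EST report file: blank-line-separated records, UTF-8, LF newlines.
  A record starts with a bare ``LIBRARY`` or ``SEQ`` line followed by
  ``key: value`` lines.  ``LIBRARY`` records carry ``id:`` plus the six
  source fields ``cell_line``, ``cell_type``, ``description``, ``lab_name``,
  ``tissue_type``, ``title`` (possibly empty).  ``SEQ`` records carry
  ``id:``, ``lib:`` and ``kind:`` (``est`` or ``mrna``).
* Cluster report file: one cluster per line,
  ``cluster_id<TAB>seq_id[,seq_id...]``.  Lines starting with ``#`` are
  comments.

Sequences that appear in no cluster are retained in the corpus and counted,
never silently dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .errors import IntegrityError, ParseError

logger = logging.getLogger(__name__)

#: The six library annotation fields whose free text defines tissue source.
SOURCE_FIELDS = (
    "cell_line",
    "cell_type",
    "description",
    "lab_name",
    "tissue_type",
    "title",
)

_TOKEN_RE = re.compile(r"[^0-9A-Za-z]+")


class SeqKind(str, Enum):
    """Kind of an expressed sequence: single-pass EST or long cDNA (mRNA)."""

    EST = "est"
    MRNA = "mrna"


@dataclass(frozen=True)
class LibraryInfo:
    """One sequencing library and its six tissue-source annotation fields."""

    library_id: str
    source_fields: Mapping[str, str]

    def __post_init__(self):
        missing = set(SOURCE_FIELDS) - set(self.source_fields)
        extra = set(self.source_fields) - set(SOURCE_FIELDS)
        if missing or extra:
            raise IntegrityError(
                f"library {self.library_id!r}: source_fields must have exactly "
                f"the keys {SOURCE_FIELDS} (missing={sorted(missing)}, "
                f"extra={sorted(extra)})"
            )

    def concatenated_fields(self) -> str:
        """All six field values joined by single spaces, in canonical order."""
        return " ".join(self.source_fields[k] for k in SOURCE_FIELDS)


@dataclass(frozen=True)
class ESTRecord:
    """One expressed sequence: its ID, source library, and kind."""

    seq_id: str
    library_id: str
    kind: SeqKind = SeqKind.EST


@dataclass(frozen=True)
class UniGeneCluster:
    """A cluster ID with its member sequence IDs (order preserved)."""

    cluster_id: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise IntegrityError(f"cluster {self.cluster_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise IntegrityError(
                f"cluster {self.cluster_id!r} lists a member twice"
            )


@dataclass
class Corpus:
    """Libraries, sequences and clusters, with all references resolved.

    Invariants (checked by :meth:`validate`, called on construction through
    :func:`read_corpus` and the synthetic generators):

    * library IDs, sequence IDs and cluster IDs are unique;
    * every sequence's ``library_id`` resolves to a declared library;
    * every cluster member resolves to a declared sequence and no sequence
      belongs to two clusters.
    """

    libraries: dict[str, LibraryInfo] = field(default_factory=dict)
    sequences: dict[str, ESTRecord] = field(default_factory=dict)
    clusters: dict[str, UniGeneCluster] = field(default_factory=dict)

    def validate(self) -> None:
        seen_members: dict[str, str] = {}
        for rec in self.sequences.values():
            if rec.library_id not in self.libraries:
                raise IntegrityError(
                    f"sequence {rec.seq_id!r} references undeclared library "
                    f"{rec.library_id!r}"
                )
        for cl in self.clusters.values():
            for m in cl.members:
                if m not in self.sequences:
                    raise IntegrityError(
                        f"cluster {cl.cluster_id!r} references unknown "
                        f"sequence {m!r}"
                    )
                if m in seen_members:
                    raise IntegrityError(
                        f"sequence {m!r} occurs in clusters "
                        f"{seen_members[m]!r} and {cl.cluster_id!r}"
                    )
                seen_members[m] = cl.cluster_id

    @property
    def clustered_seq_ids(self) -> set[str]:
        return {m for cl in self.clusters.values() for m in cl.members}

    @property
    def unclustered_seq_ids(self) -> set[str]:
        return set(self.sequences) - self.clustered_seq_ids

    def sequences_of_library(self, library_id: str) -> list[ESTRecord]:
        return [r for r in self.sequences.values() if r.library_id == library_id]


def tokenize(text: str) -> list[str]:
    """Case-fold and split on non-alphanumeric runs, dropping pure numbers.

    This defines what a "term" is throughout the package: a lowercase word
    occurring in a library annotation field.  Pure numbers (clone counts,
    plate coordinates) carry no tissue information and are dropped.
    """
    return [
        tok
        for tok in _TOKEN_RE.split(text.casefold())
        if tok and not tok.isdigit()
    ]


def build_tissue_term_list(corpus: Corpus) -> list[str]:
    """Deduplicated, sorted list of all terms in all libraries' six fields.

    This is the vocabulary from which a mining keyword is chosen: every
    word that any library used to describe its tissue source.
    """
    terms: set[str] = set()
    for lib in corpus.libraries.values():
        terms.update(tokenize(lib.concatenated_fields()))
    return sorted(terms)


# ---------------------------------------------------------------------------
# Flat-file dialect
# ---------------------------------------------------------------------------

def _parse_kv(line: str, path, lineno: int) -> tuple[str, str]:
    if ":" not in line:
        raise ParseError(f"expected 'key: value', got {line!r}", path, lineno)
    key, _, value = line.partition(":")
    return key.strip(), value.strip()


def read_corpus(est_path, cluster_path) -> Corpus:
    """Read an EST report file and a cluster report file into a Corpus.

    Raises :class:`ParseError` (naming the line) on malformed records and
    :class:`IntegrityError` on duplicate IDs or dangling references.  The
    number of unclustered sequences is reported via logging.
    """
    corpus = Corpus()
    est_path, cluster_path = Path(est_path), Path(cluster_path)

    record_lines: list[tuple[int, str]] = []

    def flush():
        if not record_lines:
            return
        start, head = record_lines[0]
        fields = dict(
            _parse_kv(line, est_path, n) for n, line in record_lines[1:]
        )
        if head == "LIBRARY":
            if "id" not in fields:
                raise ParseError("LIBRARY record without 'id:'", est_path, start)
            lib_id = fields.pop("id")
            if lib_id in corpus.libraries:
                raise IntegrityError(f"duplicate library id {lib_id!r}")
            for k in SOURCE_FIELDS:
                fields.setdefault(k, "")
            unknown = set(fields) - set(SOURCE_FIELDS)
            if unknown:
                raise ParseError(
                    f"unknown LIBRARY field(s) {sorted(unknown)}", est_path, start
                )
            corpus.libraries[lib_id] = LibraryInfo(lib_id, fields)
        elif head == "SEQ":
            for req in ("id", "lib"):
                if req not in fields:
                    raise ParseError(f"SEQ record without {req!r}:", est_path, start)
            seq_id = fields["id"]
            if seq_id in corpus.sequences:
                raise IntegrityError(f"duplicate sequence id {seq_id!r}")
            kind_raw = fields.get("kind", "est")
            try:
                kind = SeqKind(kind_raw)
            except ValueError:
                raise ParseError(
                    f"unknown sequence kind {kind_raw!r} (expected est|mrna)",
                    est_path, start,
                ) from None
            corpus.sequences[seq_id] = ESTRecord(seq_id, fields["lib"], kind)
        else:
            raise ParseError(
                f"unknown record type {head!r} (expected LIBRARY or SEQ)",
                est_path, start,
            )
        record_lines.clear()

    with est_path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                continue
            if not line.strip():
                flush()
            else:
                record_lines.append((lineno, line))
    flush()

    with cluster_path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    "expected 'cluster_id<TAB>seq_id[,seq_id...]'",
                    cluster_path, lineno,
                )
            cluster_id, members_raw = parts
            if cluster_id in corpus.clusters:
                raise IntegrityError(f"duplicate cluster id {cluster_id!r}")
            members = tuple(m for m in members_raw.split(",") if m)
            if not members:
                raise ParseError(
                    f"cluster {cluster_id!r} lists no members", cluster_path, lineno
                )
            corpus.clusters[cluster_id] = UniGeneCluster(cluster_id, members)

    corpus.validate()
    logger.info(
        "read corpus: %d libraries, %d sequences (%d unclustered), %d clusters",
        len(corpus.libraries), len(corpus.sequences),
        len(corpus.unclustered_seq_ids), len(corpus.clusters),
    )
    return corpus


def write_corpus(corpus: Corpus, est_path, cluster_path,
                 header_comments: Iterable[str] = ()) -> None:
    """Write a Corpus in the flat-file dialect (inverse of read_corpus)."""
    est_path, cluster_path = Path(est_path), Path(cluster_path)
    lines: list[str] = [f"# {c}" for c in header_comments]
    for lib_id in sorted(corpus.libraries):
        lib = corpus.libraries[lib_id]
        lines.append("LIBRARY")
        lines.append(f"id: {lib_id}")
        for k in SOURCE_FIELDS:
            lines.append(f"{k}: {lib.source_fields[k]}")
        lines.append("")
    for seq_id in sorted(corpus.sequences):
        rec = corpus.sequences[seq_id]
        lines.append("SEQ")
        lines.append(f"id: {seq_id}")
        lines.append(f"lib: {rec.library_id}")
        lines.append(f"kind: {rec.kind.value}")
        lines.append("")
    est_path.write_text("\n".join(lines), encoding="utf-8", newline="\n")

    cl_lines = [f"# {c}" for c in header_comments]
    for cluster_id in sorted(corpus.clusters):
        cl = corpus.clusters[cluster_id]
        cl_lines.append(f"{cluster_id}\t{','.join(cl.members)}")
    cluster_path.write_text(
        "\n".join(cl_lines) + ("\n" if cl_lines else ""),
        encoding="utf-8", newline="\n",
    )
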