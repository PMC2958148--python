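"""Tissue-exclusive cluster mining.

The method asks a strict question: which gene clusters are supported *only*
by expressed sequences from libraries matching a tissue/condition keyword
(e.g. ``melanoma``)?  This is stricter than enrichment-style digital
differential display — a single EST from a non-matching library disqualifies
a cluster.  The pipeline has four stages:

1. *Partition*: split all sequences into keyword-matching and non-matching
   groups according to their library's six annotation fields.
2. *Exclusivity*: keep clusters whose EST members all fall in the matching
   group (long cDNA members do not veto exclusivity; cDNA evidence is
   handled by the separate screen stage).
3. *Singleton filter*: drop clusters supported by a single sequence, which
   are likely artifacts or very low expression.
4. *Cross-source screen*: drop clusters whose sequence matches external
   cDNA evidence from non-target tissues, unless every such tissue label is
   on a configurable allowlist (tumor/testis retention, for candidate
   cancer/testis antigens).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

from .corpus import Corpus, SeqKind, tokenize
from .errors import DataError, IntegrityError

logger = logging.getLogger(__name__)


class MatchMode(str, Enum):
    """How a keyword is matched against a library's annotation fields."""

    TERM = "term"          # exact token match against tokenized fields
    SUBSTRING = "substring"  # raw case-insensitive substring of the fields


@dataclass(frozen=True)
class KeywordPartition:
    """Disjoint cover of all sequence IDs by keyword match of their library."""

    keyword: str
    matched: frozenset[str]
    unmatched: frozenset[str]
    matched_libraries: frozenset[str]


@dataclass(frozen=True)
class CandidateCluster:
    """A cluster surviving one or more mining stages, with provenance flags."""

    cluster_id: str
    n_est: int
    n_mrna: int
    n_libraries: int
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def n_members(self) -> int:
        return self.n_est + self.n_mrna

    def with_flag(self, flag: str) -> "CandidateCluster":
        return replace(self, flags=self.flags | {flag})


#: cluster_id -> set of non-target tissue labels evidenced by external
#: sequence alignment (the precomputed BLAST/BLAT-style match table).
CrossSourceMatchTable = Mapping[str, frozenset[str] | set[str]]

DEFAULT_ALLOWLIST = frozenset({"testis", "tumor"})


def library_matches(lib, keyword: str, mode: MatchMode = MatchMode.TERM) -> bool:
    """Whether a library's six concatenated fields match the keyword."""
    text = lib.concatenated_fields()
    if mode is MatchMode.TERM:
        return keyword.casefold() in tokenize(text)
    return keyword.casefold() in text.casefold()


def partition_by_keyword(
    corpus: Corpus, keyword: str, mode: MatchMode = MatchMode.TERM
) -> KeywordPartition:
    """Split all sequences by whether their library matches the keyword.

    A sequence is *matched* iff its library's six concatenated source fields
    match the keyword (case-insensitively; exact token in ``term`` mode, raw
    substring in ``substring`` mode).  The two groups are disjoint and cover
    the corpus.
    """
    if not keyword:
        raise DataError("keyword must be non-empty")
    mode = MatchMode(mode)
    libs = frozenset(
        lib_id for lib_id, lib in corpus.libraries.items()
        if library_matches(lib, keyword, mode)
    )
    if not libs:
        logger.warning(
            "keyword %r matches no library (%s mode); partition is empty",
            keyword, mode.value,
        )
    matched = frozenset(
        s.seq_id for s in corpus.sequences.values() if s.library_id in libs
    )
    return KeywordPartition(
        keyword=keyword,
        matched=matched,
        unmatched=frozenset(corpus.sequences) - matched,
        matched_libraries=libs,
    )


def _summarize(corpus: Corpus, cluster_id: str) -> CandidateCluster:
    cl = corpus.clusters[cluster_id]
    recs = [corpus.sequences[m] for m in cl.members]
    return CandidateCluster(
        cluster_id=cluster_id,
        n_est=sum(r.kind is SeqKind.EST for r in recs),
        n_mrna=sum(r.kind is SeqKind.MRNA for r in recs),
        n_libraries=len({r.library_id for r in recs}),
    )


def exclusive_clusters(
    corpus: Corpus, partition: KeywordPartition
) -> list[CandidateCluster]:
    """Clusters whose EST members all come from keyword-matching libraries.

    A cluster qualifies iff it has at least one EST member and every EST
    member is in ``partition.matched``.  Long cDNA (mRNA) members are
    counted but do not veto exclusivity.
    """
    out = []
    for cluster_id in sorted(corpus.clusters):
        cl = corpus.clusters[cluster_id]
        est_members = [
            m for m in cl.members
            if corpus.sequences[m].kind is SeqKind.EST
        ]
        if est_members and all(m in partition.matched for m in est_members):
            out.append(_summarize(corpus, cluster_id).with_flag("exclusive"))
    return out


def filter_singletons(
    candidates: list[CandidateCluster], min_members: int = 2
) -> list[CandidateCluster]:
    """Retain candidates with at least ``min_members`` total members."""
    if min_members < 1:
        raise ValueError("min_members must be >= 1")
    return [
        c.with_flag("multi_member")
        for c in candidates
        if c.n_members >= min_members
    ]


def apply_cross_source_screen(
    candidates: list[CandidateCluster],
    matches: CrossSourceMatchTable,
    allowlist: frozenset[str] = DEFAULT_ALLOWLIST,
    *,
    known_cluster_ids: set[str] | None = None,
) -> list[CandidateCluster]:
    """Remove candidates with external cDNA evidence from non-target tissues.

    A candidate whose cluster appears in ``matches`` with one or more
    non-target tissue labels is flagged ``screened_out`` and removed —
    unless every label is in ``allowlist`` (by default tumor/testis, kept
    as candidate cancer/testis antigens), in which case it is retained and
    flagged ``allowlisted``.
    """
    allowlist = frozenset(l.casefold() for l in allowlist)
    if known_cluster_ids is not None:
        unknown = set(matches) - set(known_cluster_ids)
        if unknown:
            raise IntegrityError(
                f"cross-source match table references unknown cluster(s) "
                f"{sorted(unknown)}"
            )
    out = []
    for c in candidates:
        labels = frozenset(l.casefold() for l in matches.get(c.cluster_id, ()))
        if not labels:
            out.append(c)
        elif labels <= allowlist:
            out.append(c.with_flag("allowlisted"))
        # else: screened out (flag recorded only in the report's removed list)
    return out


@dataclass(frozen=True)
class MiningReport:
    """Stage-by-stage result of a full mining run."""

    keyword: str
    mode: MatchMode
    n_sequences_matched: int
    n_sequences_unmatched: int
    n_exclusive: int
    n_multi_member: int
    n_final: int
    candidates: tuple[CandidateCluster, ...]          # final survivors
    removed_singletons: tuple[str, ...]
    removed_screened: tuple[str, ...]

    @property
    def stage_counts(self) -> tuple[int, int, int]:
        """(exclusive, after singleton removal, after cross-source screen)."""
        return (self.n_exclusive, self.n_multi_member, self.n_final)


def mine(
    corpus: Corpus,
    keyword: str,
    *,
    mode: MatchMode = MatchMode.TERM,
    min_members: int = 2,
    matches: CrossSourceMatchTable | None = None,
    allowlist: frozenset[str] = DEFAULT_ALLOWLIST,
) -> MiningReport:
    """Run the full pipeline: partition -> exclusive -> singleton -> screen."""
    matches = matches or {}
    partition = partition_by_keyword(corpus, keyword, mode)
    excl = exclusive_clusters(corpus, partition)
    multi = filter_singletons(excl, min_members=min_members)
    final = apply_cross_source_screen(
        multi, matches, allowlist, known_cluster_ids=set(corpus.clusters)
    )
    multi_ids = {c.cluster_id for c in multi}
    final_ids = {c.cluster_id for c in final}
    return MiningReport(
        keyword=keyword,
        mode=MatchMode(mode),
        n_sequences_matched=len(partition.matched),
        n_sequences_unmatched=len(partition.unmatched),
        n_exclusive=len(excl),
        n_multi_member=len(multi),
        n_final=len(final),
        candidates=tuple(final),
        removed_singletons=tuple(
            c.cluster_id for c in excl if c.cluster_id not in multi_ids
        ),
        removed_screened=tuple(
            c.cluster_id for c in multi if c.cluster_id not in final_ids
        ),
    )
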