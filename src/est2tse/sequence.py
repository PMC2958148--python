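"""ORF scanning on oriented transcripts and TF-binding-site aggregation.

Candidate transcripts from EST mining are often annotated as non-coding,
yet may harbor short open reading frames — including ones initiated at
near-cognate (non-AUG) codons, whose use as alternative translation starts
is well documented in mammals.  The scanner therefore takes a configurable
start-codon set and reports every ORF beginning at a start-codon occurrence
and running to the first in-frame stop.

Only the given (sense) strand is scanned: inputs are oriented cDNAs, not
genomic sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .errors import DataError, IntegrityError

#: Canonical initiator.
CANONICAL_STARTS = frozenset({"ATG"})

#: Near-cognate initiators (single mismatch from ATG) commonly reported to
#: support translation initiation in mammals.
NEAR_COGNATE_STARTS = CANONICAL_STARTS | frozenset(
    {"CTG", "GTG", "TTG", "ACG", "ATT", "ATC", "ATA"}
)

STOP_CODONS = frozenset(standard_dna_table.stop_codons)

_VALID = set("ACGTN")


@dataclass(frozen=True)
class Orf:
    """An open reading frame on a transcript.

    Coordinates are 0-based, half-open on the input transcript; ``end``
    includes the stop codon when ``stop_included``.  The start codon is
    translated as methionine (initiator convention), so every peptide
    begins with ``M`` regardless of the initiating codon.
    """

    frame: int
    start: int
    end: int
    start_codon: str
    peptide: str
    stop_included: bool

    @property
    def aa_length(self) -> int:
        return len(self.peptide)


def _normalize(transcript: str) -> str:
    seq = transcript.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise DataError(
            f"invalid transcript character(s) {sorted(bad)} "
            "(expected A/C/G/T/U/N)"
        )
    return seq


def _translate_orf(seq: str, start: int, end: int, stop_included: bool) -> str:
    """Translate codons in [start, end), initiator as M, standard code."""
    coding_end = end - 3 if stop_included else end
    if coding_end <= start:
        return ""
    body = str(Seq(seq[start + 3:coding_end]).translate(table=1))
    return "M" + body


def scan_orfs(
    transcript: str,
    start_codons: Iterable[str] = CANONICAL_STARTS,
    min_aa: int = 20,
    *,
    allow_open_end: bool = False,
) -> list[Orf]:
    """All sense-strand ORFs starting at any occurrence of a start codon.

    Each ORF runs from a start-codon occurrence to the first in-frame stop
    (``stop_included=True``).  A start codon with no downstream in-frame
    stop yields an open-ended ORF to the transcript end only when
    ``allow_open_end`` is set (truncated to whole codons).  ORFs whose
    peptide is shorter than ``min_aa`` residues are dropped.  Results are
    sorted by start position.

    Nested ORFs are reported individually: an in-frame internal start codon
    opens its own (shorter) ORF ending at the same stop.
    """
    seq = _normalize(transcript)
    starts = {c.upper().replace("U", "T") for c in start_codons}
    if not starts:
        raise DataError("start_codons must be non-empty")
    n = len(seq)

    # first in-frame stop at/after each position, per frame (single pass)
    next_stop = [n] * (n + 3)
    for i in range(n - 3, -1, -1):
        nxt = next_stop[i + 3] if i + 3 <= n else n
        next_stop[i] = i if seq[i:i + 3] in STOP_CODONS else nxt

    orfs: list[Orf] = []
    for i in range(n - 2):
        codon = seq[i:i + 3]
        if codon not in starts:
            continue
        stop = next_stop[i]
        if stop < n:
            end, stop_included = stop + 3, True
        elif allow_open_end:
            end, stop_included = i + 3 * ((n - i) // 3), False
        else:
            continue
        peptide = _translate_orf(seq, i, end, stop_included)
        if len(peptide) >= min_aa:
            orfs.append(
                Orf(
                    frame=i % 3,
                    start=i,
                    end=end,
                    start_codon=codon,
                    peptide=peptide,
                    stop_included=stop_included,
                )
            )
    return orfs


def longest_orf(
    transcript: str,
    start_codons: Iterable[str] = CANONICAL_STARTS,
    min_aa: int = 20,
    *,
    allow_open_end: bool = False,
) -> Orf | None:
    """The ORF with the longest peptide; ties go to the smallest start."""
    orfs = scan_orfs(
        transcript, start_codons, min_aa, allow_open_end=allow_open_end
    )
    if not orfs:
        return None
    return max(orfs, key=lambda o: (o.aa_length, -o.start))


@dataclass(frozen=True)
class TfFrequencyTable:
    """Per-TF count of promoters containing at least one predicted site."""

    counts: Mapping[str, int]
    n_promoters: int


def tf_site_frequency(
    per_promoter_hits: Sequence[tuple[str, Iterable[str]]],
) -> TfFrequencyTable:
    """Aggregate per-promoter TF-site hit lists into one frequency table.

    Input is the per-promoter output of an external TF-binding-site
    predictor: ``(promoter_id, set of TF names)`` pairs.  For each TF the
    table counts the number of promoters whose hit set contains it; a TF
    hit several times in one promoter still counts that promoter once.
    """
    seen: set[str] = set()
    counts: dict[str, int] = {}
    for promoter_id, hits in per_promoter_hits:
        if promoter_id in seen:
            raise IntegrityError(f"duplicate promoter id {promoter_id!r}")
        seen.add(promoter_id)
        for tf in set(hits):
            counts[tf] = counts.get(tf, 0) + 1
    return TfFrequencyTable(
        counts=dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))),
        n_promoters=len(per_promoter_hits),
    )
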