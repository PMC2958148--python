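"""Independent oracles used by the test suite.

Everything here is deliberately written by a different route than the
package implementation: direct set comprehensions for the miner,
position-by-position enumeration with an explicit codon dictionary for the
ORF scanner, and a naive loop for the Kaplan-Meier product.  The oracles
trade efficiency for obviousness.
"""

from __future__ import annotations

import re

import numpy as np

from est2tse.corpus import (
    Corpus,
    ESTRecord,
    LibraryInfo,
    SOURCE_FIELDS,
    SeqKind,
    UniGeneCluster,
)

# --- miner oracle ---------------------------------------------------------

_WORD = re.compile(r"[0-9A-Za-z]+")


def _oracle_terms(text: str) -> set[str]:
    return {w.lower() for w in _WORD.findall(text.lower()) if not w.isdigit()}


def oracle_mine(corpus, keyword, mode="term", min_members=2,
                matches=None, allowlist=frozenset({"testis", "tumor"})):
    """Brute-force pipeline: re-check every member's library per cluster."""
    matches = matches or {}
    kw = keyword.lower()
    lib_match = {}
    for lib_id, lib in corpus.libraries.items():
        text = " ".join(lib.source_fields[k] for k in SOURCE_FIELDS)
        if mode == "term":
            lib_match[lib_id] = kw in _oracle_terms(text)
        else:
            lib_match[lib_id] = kw in text.lower()

    exclusive = []
    for cid, cl in corpus.clusters.items():
        ests = [m for m in cl.members if corpus.sequences[m].kind.value == "est"]
        if ests and all(lib_match[corpus.sequences[m].library_id] for m in ests):
            exclusive.append(cid)
    multi = [c for c in exclusive if len(corpus.clusters[c].members) >= min_members]
    allow = {a.lower() for a in allowlist}
    final = [
        c for c in multi
        if not matches.get(c) or {l.lower() for l in matches[c]} <= allow
    ]
    return sorted(exclusive), sorted(multi), sorted(final)


def random_corpus(rng: np.random.Generator, max_sequences: int = 500):
    """A small random corpus with arbitrary (non-planted) structure."""
    vocab = ["melanoma", "skin", "brain", "liver", "testis", "retina",
             "melanocyte", "tumor", "cell", "line"]
    n_libs = int(rng.integers(2, 8))
    corpus = Corpus()
    for i in range(n_libs):
        fields = {
            k: " ".join(rng.choice(vocab, size=int(rng.integers(0, 4))))
            for k in SOURCE_FIELDS
        }
        corpus.libraries[f"L{i}"] = LibraryInfo(f"L{i}", fields)
    n_seq = int(rng.integers(5, max_sequences + 1))
    for i in range(n_seq):
        kind = SeqKind.MRNA if rng.random() < 0.1 else SeqKind.EST
        lib = f"L{int(rng.integers(n_libs))}"
        corpus.sequences[f"S{i}"] = ESTRecord(f"S{i}", lib, kind)
    ids = list(corpus.sequences)
    rng.shuffle(ids)
    pos, c = 0, 0
    while pos < len(ids) and rng.random() < 0.95:
        size = int(rng.integers(1, 9))
        members = tuple(ids[pos:pos + size])
        if not members:
            break
        corpus.clusters[f"C{c}"] = UniGeneCluster(f"C{c}", members)
        pos += size
        c += 1
    corpus.validate()
    return corpus


# --- ORF oracle -----------------------------------------------------------

_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_orfs(seq, starts, min_aa, allow_open_end=False):
    """Enumerate ORFs position by position with an explicit codon table."""
    seq = seq.upper().replace("U", "T")
    found = []
    for i in range(len(seq) - 2):
        if seq[i:i + 3] not in starts:
            continue
        peptide = ["M"]
        j = i + 3
        stopped = False
        while j + 3 <= len(seq):
            aa = _CODE.get(seq[j:j + 3], "X")
            if aa == "*":
                stopped = True
                j += 3
                break
            peptide.append(aa)
            j += 3
        if not stopped and not allow_open_end:
            continue
        pep = "".join(peptide)
        if len(pep) >= min_aa:
            found.append((i % 3, i, j, seq[i:i + 3], pep, stopped))
    return found


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


# --- survival oracle ------------------------------------------------------

def oracle_km(times, events):
    """Textbook product-limit estimate: (event_time, S) pairs, naive loop."""
    times = list(map(float, times))
    events = list(map(bool, events))
    out = []
    s = 1.0
    for t in sorted({t for t, e in zip(times, events) if e}):
        n_at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ei and ti == t)
        s = s * (1.0 - d / n_at_risk)
        out.append((t, s))
    return out
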