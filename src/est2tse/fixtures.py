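"""Seeded synthetic fixtures: EST corpora with planted tissue-exclusive
structure, qPCR Ct tables, and survival cohorts.

The corpus generator emulates the structure of a public EST database: a
small number of libraries from the target tissue/condition, many libraries
from other sources, and clusters whose membership mixes the two.  A
:class:`CorpusSpec` plants exact ground truth — how many clusters are
keyword-exclusive, how many of those are singletons, and how many
multi-member survivors carry external cross-source evidence — so the miner
can be validated by exact truth recovery rather than by eye.

All generators draw from a single ``numpy.random.default_rng(seed)`` stream
per call and are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .corpus import SOURCE_FIELDS, Corpus, ESTRecord, LibraryInfo, SeqKind, UniGeneCluster
from .errors import SpecError
from .survival import SurvivalRecord

#: Default vocabularies for the six annotation fields.  Terms for
#: non-matching libraries deliberately avoid the default keyword both as a
#: token and as a substring, so `term` and `substring` matching agree on
#: the planted truth.
DEFAULT_MATCHING_VOCAB = ("melanoma", "skin", "metastatic", "pigmented")
DEFAULT_OTHER_VOCAB = (
    "brain", "liver", "kidney", "lung", "colon", "placenta", "retina",
    "spleen", "muscle", "prostate", "bladder", "pancreas",
)


@dataclass(frozen=True)
class CorpusSpec:
    """Blueprint of a synthetic corpus with planted mining truth.

    Defaults mirror the study conditions of the motivating melanoma search
    at fixture scale: 12 target-tissue libraries, 215 keyword-exclusive
    clusters of which 177 are singletons, 9 multi-member clusters carrying
    non-allowlisted cross-source evidence and 6 carrying only tumor/testis
    evidence, on a background of non-exclusive clusters.
    """

    keyword: str = "melanoma"
    n_libraries_matching: int = 12
    n_libraries_other: int = 40
    matching_vocab: tuple[str, ...] = DEFAULT_MATCHING_VOCAB
    other_vocab: tuple[str, ...] = DEFAULT_OTHER_VOCAB
    n_exclusive_clusters: int = 215
    n_exclusive_singletons: int = 177
    n_screened: int = 9
    n_allowlisted: int = 6
    n_background_clusters: int = 300
    n_unclustered: int = 10
    cluster_size_p: float = 0.35   # truncated geometric success probability
    cluster_size_min: int = 2
    cluster_size_max: int = 30
    mrna_fraction: float = 0.15    # chance a multi-member cluster gains a cDNA
    screen_labels: tuple[str, ...] = ("brain", "liver", "kidney", "lung")
    allowlist_labels: tuple[str, ...] = ("testis", "tumor")
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_libraries_matching, self.n_libraries_other,
               self.n_exclusive_clusters, self.n_exclusive_singletons,
               self.n_screened, self.n_allowlisted,
               self.n_background_clusters, self.n_unclustered) < 0:
            raise SpecError("corpus spec counts must be non-negative")
        if self.n_exclusive_singletons > self.n_exclusive_clusters:
            raise SpecError("more singleton than exclusive clusters")
        n_multi = self.n_exclusive_clusters - self.n_exclusive_singletons
        if self.n_screened + self.n_allowlisted > n_multi:
            raise SpecError(
                "screened + allowlisted exceed multi-member exclusive clusters"
            )
        if self.n_exclusive_clusters > 0 and self.n_libraries_matching == 0:
            raise SpecError("exclusive clusters require matching libraries")
        if self.n_background_clusters > 0 and self.n_libraries_other == 0:
            raise SpecError("background clusters require non-matching libraries")
        if not (0 < self.cluster_size_p < 1):
            raise SpecError("cluster_size_p must be in (0, 1)")
        if not (1 <= self.cluster_size_min <= self.cluster_size_max):
            raise SpecError("invalid cluster size bounds")
        if self.keyword.casefold() in {t.casefold() for t in self.other_vocab}:
            raise SpecError("keyword must not appear in the other-library vocab")


@dataclass(frozen=True)
class TruthTable:
    """Planted ground truth for one generated corpus."""

    keyword: str
    exclusive_ids: frozenset[str]
    singleton_ids: frozenset[str]
    multi_member_ids: frozenset[str]
    screened_ids: frozenset[str]
    allowlisted_ids: frozenset[str]

    @property
    def stage_counts(self) -> tuple[int, int, int]:
        """(exclusive, after singleton removal, after cross-source screen)."""
        n_excl = len(self.exclusive_ids)
        n_multi = len(self.multi_member_ids)
        return (n_excl, n_multi, n_multi - len(self.screened_ids))


def _cluster_size(rng: np.random.Generator, spec: CorpusSpec) -> int:
    """Truncated geometric on [cluster_size_min, cluster_size_max]."""
    while True:
        k = spec.cluster_size_min + int(rng.geometric(spec.cluster_size_p)) - 1
        if k <= spec.cluster_size_max:
            return k


def _library_fields(rng: np.random.Generator, vocab: tuple[str, ...],
                    must_contain: str | None = None) -> dict[str, str]:
    fields = {}
    for name in SOURCE_FIELDS:
        words = list(rng.choice(vocab, size=rng.integers(1, 4), replace=True))
        fields[name] = " ".join(words)
    if must_contain is not None:
        fields["tissue_type"] = f"{fields['tissue_type']} {must_contain}"
    return fields


def generate_corpus(
    spec: CorpusSpec,
) -> tuple[Corpus, dict[str, frozenset[str]], TruthTable]:
    """Generate a corpus, its cross-source match table, and the truth table.

    Mining the corpus with ``spec.keyword`` recovers the truth's stage
    counts exactly, by construction: exclusive clusters draw all their EST
    members from matching libraries, background clusters always contain at
    least one EST from a non-matching library.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    corpus = Corpus()

    m_libs = [f"MLIB{i:03d}" for i in range(spec.n_libraries_matching)]
    o_libs = [f"OLIB{i:03d}" for i in range(spec.n_libraries_other)]
    for lib_id in m_libs:
        corpus.libraries[lib_id] = LibraryInfo(
            lib_id, _library_fields(rng, spec.matching_vocab, spec.keyword)
        )
    for lib_id in o_libs:
        corpus.libraries[lib_id] = LibraryInfo(
            lib_id, _library_fields(rng, spec.other_vocab)
        )

    seq_counter = 0

    def new_seq(lib_id: str, kind: SeqKind) -> str:
        nonlocal seq_counter
        seq_counter += 1
        seq_id = f"SEQ{seq_counter:06d}"
        corpus.sequences[seq_id] = ESTRecord(seq_id, lib_id, kind)
        return seq_id

    def pick(libs: list[str]) -> str:
        return libs[int(rng.integers(len(libs)))]

    singleton_ids, multi_ids = [], []
    for i in range(spec.n_exclusive_clusters):
        cluster_id = f"CL_EX{i:04d}"
        if i < spec.n_exclusive_singletons:
            members = [new_seq(pick(m_libs), SeqKind.EST)]
            singleton_ids.append(cluster_id)
        else:
            # planted multi-member clusters must survive min_members=2
            size = max(2, _cluster_size(rng, spec))
            members = [new_seq(pick(m_libs), SeqKind.EST)]
            for _ in range(size - 1):
                kind = (
                    SeqKind.MRNA
                    if rng.random() < spec.mrna_fraction / spec.cluster_size_min
                    else SeqKind.EST
                )
                members.append(new_seq(pick(m_libs), kind))
            multi_ids.append(cluster_id)
        corpus.clusters[cluster_id] = UniGeneCluster(cluster_id, tuple(members))

    # cross-source evidence: first n_screened multi clusters get at least one
    # non-allowlisted label; the next n_allowlisted get allowlisted labels only
    match_table: dict[str, frozenset[str]] = {}
    for cluster_id in multi_ids[: spec.n_screened]:
        labels = set(
            rng.choice(spec.screen_labels,
                       size=int(rng.integers(1, 3)), replace=False)
        )
        if spec.allowlist_labels and rng.random() < 0.3:
            labels.add(str(rng.choice(spec.allowlist_labels)))
        match_table[cluster_id] = frozenset(str(l) for l in labels)
    for cluster_id in multi_ids[spec.n_screened:
                                spec.n_screened + spec.n_allowlisted]:
        labels = rng.choice(
            spec.allowlist_labels,
            size=int(rng.integers(1, len(spec.allowlist_labels) + 1)),
            replace=False,
        )
        match_table[cluster_id] = frozenset(str(l) for l in labels)

    for i in range(spec.n_background_clusters):
        cluster_id = f"CL_BG{i:04d}"
        size = (
            1 if rng.random() < 0.3
            else _cluster_size(rng, spec)
        )
        # anchor EST from a non-matching library breaks exclusivity
        members = [new_seq(pick(o_libs), SeqKind.EST)]
        for _ in range(size - 1):
            lib = pick(m_libs + o_libs) if m_libs else pick(o_libs)
            kind = SeqKind.MRNA if rng.random() < 0.1 else SeqKind.EST
            members.append(new_seq(lib, kind))
        corpus.clusters[cluster_id] = UniGeneCluster(cluster_id, tuple(members))

    all_libs = m_libs + o_libs
    for _ in range(spec.n_unclustered):
        if all_libs:
            new_seq(pick(all_libs), SeqKind.EST)

    corpus.validate()
    truth = TruthTable(
        keyword=spec.keyword,
        exclusive_ids=frozenset(singleton_ids) | frozenset(multi_ids),
        singleton_ids=frozenset(singleton_ids),
        multi_member_ids=frozenset(multi_ids),
        screened_ids=frozenset(multi_ids[: spec.n_screened]),
        allowlisted_ids=frozenset(
            multi_ids[spec.n_screened: spec.n_screened + spec.n_allowlisted]
        ),
    )
    return corpus, match_table, truth


def corpus_spec_from_yaml(path) -> CorpusSpec:
    """Load a CorpusSpec from a YAML mapping of field names to values."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise SpecError("corpus spec YAML must be a mapping")
    valid = set(CorpusSpec.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise SpecError(f"unknown corpus spec field(s) {sorted(unknown)}")
    for key in ("matching_vocab", "other_vocab", "screen_labels",
                "allowlist_labels"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return CorpusSpec(**raw)


def corpus_spec_to_yaml(spec: CorpusSpec, path) -> None:
    data = asdict(spec)
    for key, value in data.items():
        if isinstance(value, tuple):
            data[key] = list(value)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False),
                          encoding="utf-8")


# ---------------------------------------------------------------------------
# Survival cohorts and qPCR Ct tables
# ---------------------------------------------------------------------------

def generate_cohort(
    n_per_group: int,
    hazard_ratio: float = 1.0,
    censor_rate: float = 0.0,
    seed: int = 0,
    group_labels: tuple[str, str] = ("D", "ND"),
) -> list[SurvivalRecord]:
    """Two-arm cohort with exponential event times and independent censoring.

    Group ``group_labels[0]`` has unit baseline hazard; the second group's
    hazard is multiplied by ``hazard_ratio``.  Censoring times are
    exponential with the rate chosen so that the expected censored fraction
    in each arm equals ``censor_rate`` (0 disables censoring).
    """
    if n_per_group < 1:
        raise SpecError("n_per_group must be >= 1")
    if hazard_ratio <= 0:
        raise SpecError("hazard_ratio must be positive")
    if not (0 <= censor_rate < 1):
        raise SpecError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    records: list[SurvivalRecord] = []
    for label, hazard in zip(group_labels, (1.0, hazard_ratio)):
        t_event = rng.exponential(1.0 / hazard, size=n_per_group)
        if censor_rate > 0:
            c_rate = hazard * censor_rate / (1.0 - censor_rate)
            t_cens = rng.exponential(1.0 / c_rate, size=n_per_group)
        else:
            t_cens = np.full(n_per_group, np.inf)
        for i in range(n_per_group):
            records.append(
                SurvivalRecord(
                    patient_id=f"{label}{i:04d}",
                    time=float(min(t_event[i], t_cens[i])),
                    event=bool(t_event[i] <= t_cens[i]),
                    group=label,
                )
            )
    return records


def generate_ct_table(
    n_samples: int = 8,
    genes: tuple[str, ...] = ("GENE1",),
    control_gene: str = "TBP",
    n_replicates: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate qPCR Ct table: control around 25 cycles, targets above it.

    Per-sample control Ct ~ N(25, 0.5); per-gene dCt ~ N(8, 2) emulating a
    low-abundance target; replicate noise sd 0.15 cycles.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        sample = f"S{i:03d}"
        control_ct = rng.normal(25.0, 0.5)
        for gene in genes:
            gene_ct = control_ct + rng.normal(8.0, 2.0)
            for _ in range(n_replicates):
                rows.append((sample, gene, gene_ct + rng.normal(0, 0.15)))
        for _ in range(n_replicates):
            rows.append((sample, control_gene, control_ct + rng.normal(0, 0.15)))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "ct"])
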