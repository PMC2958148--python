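"""The exclusivity miner: partition, filters, screen, and oracle checks."""


import numpy as np
import pytest

from est2tse import (
    CandidateCluster,
    Corpus,
    CorpusSpec,
    DataError,
    ESTRecord,
    IntegrityError,
    LibraryInfo,
    MatchMode,
    SOURCE_FIELDS,
    SeqKind,
    UniGeneCluster,
    apply_cross_source_screen,
    exclusive_clusters,
    filter_singletons,
    generate_corpus,
    mine,
    partition_by_keyword,
)
from helpers import oracle_mine, random_corpus


def _lib(lib_id, **fields):
    full = {k: "" for k in SOURCE_FIELDS}
    full.update(fields)
    return LibraryInfo(lib_id, full)


def toy_corpus():
    """Two melanoma libraries, one liver library, four clusters."""
    corpus = Corpus(
        libraries={
            "M1": _lib("M1", tissue_type="skin melanoma"),
            "M2": _lib("M2", title="Melanoma cell line"),
            "O1": _lib("O1", tissue_type="liver"),
        },
        sequences={
            "e1": ESTRecord("e1", "M1"),
            "e2": ESTRecord("e2", "M2"),
            "e3": ESTRecord("e3", "O1"),
            "e4": ESTRecord("e4", "M1"),
            "e5": ESTRecord("e5", "M1"),
            "m1": ESTRecord("m1", "O1", SeqKind.MRNA),
        },
        clusters={
            "EXCL": UniGeneCluster("EXCL", ("e1", "e2")),   # pure melanoma
            "MIXED": UniGeneCluster("MIXED", ("e4", "e3")),  # liver EST vetoes
            "SINGLE": UniGeneCluster("SINGLE", ("e5",)),     # exclusive singleton
            "CDNA": UniGeneCluster("CDNA", ("m1",)),         # no EST members
        },
    )
    corpus.validate()
    return corpus


class TestPartition:
    def test_partition_is_a_disjoint_cover(self):
        corpus = toy_corpus()
        part = partition_by_keyword(corpus, "melanoma")
        assert part.matched | part.unmatched == set(corpus.sequences)
        assert not part.matched & part.unmatched

    def test_sequences_follow_their_library(self):
        part = partition_by_keyword(toy_corpus(), "melanoma")
        assert part.matched == {"e1", "e2", "e4", "e5"}
        assert part.matched_libraries == {"M1", "M2"}

    def test_absent_keyword_matches_nothing(self):
        part = partition_by_keyword(toy_corpus(), "pancreas")
        assert part.matched == frozenset()

    def test_term_mode_requires_whole_token(self):
        assert partition_by_keyword(toy_corpus(), "melan").matched == frozenset()
        sub = partition_by_keyword(toy_corpus(), "melan", MatchMode.SUBSTRING)
        assert sub.matched == {"e1", "e2", "e4", "e5"}

    def test_empty_keyword_is_rejected(self):
        with pytest.raises(DataError):
            partition_by_keyword(toy_corpus(), "")


class TestStages:
    def test_exclusive_requires_all_est_members_matched(self):
        corpus = toy_corpus()
        part = partition_by_keyword(corpus, "melanoma")
        excl = {c.cluster_id: c for c in exclusive_clusters(corpus, part)}
        assert set(excl) == {"EXCL", "SINGLE"}          # MIXED vetoed, CDNA no EST
        assert excl["EXCL"].n_est == 2
        assert excl["EXCL"].n_libraries == 2
        assert "exclusive" in excl["EXCL"].flags

    def test_mrna_members_do_not_veto_but_are_counted(self):
        corpus = toy_corpus()
        # move the foreign-library cDNA m1 into a melanoma EST cluster
        corpus.clusters.pop("CDNA")
        corpus.clusters["EXCL"] = UniGeneCluster("EXCL", ("e1", "e2", "m1"))
        corpus.validate()
        part = partition_by_keyword(corpus, "melanoma")
        excl = {c.cluster_id: c for c in exclusive_clusters(corpus, part)}
        assert "EXCL" in excl
        assert excl["EXCL"].n_mrna == 1 and excl["EXCL"].n_est == 2

    def test_filter_singletons_bounds(self):
        cands = [
            CandidateCluster("a", 1, 0, 1, frozenset({"exclusive"})),
            CandidateCluster("b", 2, 1, 2, frozenset({"exclusive"})),
        ]
        assert [c.cluster_id for c in filter_singletons(cands)] == ["b"]
        assert [c.cluster_id for c in filter_singletons(cands, 1)] == ["a", "b"]
        assert filter_singletons([cands[0]]) == []
        with pytest.raises(ValueError):
            filter_singletons(cands, 0)

    def test_screen_empty_table_is_identity(self):
        cands = [CandidateCluster("a", 2, 0, 1, frozenset({"multi_member"}))]
        assert apply_cross_source_screen(cands, {}) == cands

    def test_screen_removes_non_allowlisted_and_flags_allowlisted(self):
        cands = [
            CandidateCluster("a", 2, 0, 1),
            CandidateCluster("b", 2, 0, 1),
            CandidateCluster("c", 2, 0, 1),
        ]
        out = apply_cross_source_screen(
            cands,
            {"a": {"liver"}, "b": {"testis"}, "c": {"testis", "brain"}},
        )
        assert [c.cluster_id for c in out] == ["b"]
        assert "allowlisted" in out[0].flags

    def test_screen_rejects_unknown_cluster_reference(self):
        with pytest.raises(IntegrityError):
            apply_cross_source_screen(
                [], {"ghost": {"liver"}}, known_cluster_ids=set()
            )


class TestMine:
    def test_planted_truth_counts_recovered(self):
        spec = CorpusSpec(
            n_exclusive_clusters=30, n_exclusive_singletons=18,
            n_screened=4, n_allowlisted=3, n_background_clusters=25, seed=3,
        )
        corpus, matches, truth = generate_corpus(spec)
        report = mine(corpus, spec.keyword, matches=matches)
        assert report.stage_counts == truth.stage_counts == (30, 12, 8)
        assert len(report.removed_singletons) == 18
        assert len(report.removed_screened) == 4
        assert sum(1 for c in report.candidates
                   if "allowlisted" in c.flags) == 3

    def test_stage_counts_are_non_increasing(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            corpus = random_corpus(rng, max_sequences=120)
            report = mine(corpus, "melanoma")
            a, b, c = report.stage_counts
            assert a >= b >= c

    def test_keyword_matching_all_libraries_keeps_every_est_cluster(self):
        spec = CorpusSpec(
            n_exclusive_clusters=10, n_exclusive_singletons=5,
            n_screened=0, n_allowlisted=0, n_background_clusters=8, seed=5,
            other_vocab=("liver", "universal"),
            matching_vocab=("melanoma", "universal"),
        )
        corpus, _, _ = generate_corpus(spec)
        report = mine(corpus, "universal", mode=MatchMode.SUBSTRING)
        n_est_clusters = sum(
            any(corpus.sequences[m].kind is SeqKind.EST for m in cl.members)
            for cl in corpus.clusters.values()
        )
        assert report.n_exclusive == n_est_clusters

    def test_keyword_matching_nothing_yields_empty_report(self):
        report = mine(toy_corpus(), "xenon")
        assert report.stage_counts == (0, 0, 0)
        assert report.candidates == ()

    def test_exclusivity_monotonicity_under_added_foreign_est(self):
        corpus = toy_corpus()
        part = partition_by_keyword(corpus, "melanoma")
        before = {c.cluster_id for c in exclusive_clusters(corpus, part)}
        # adding a liver EST to EXCL removes exactly EXCL
        corpus.sequences["e9"] = ESTRecord("e9", "O1")
        corpus.clusters["EXCL"] = UniGeneCluster("EXCL", ("e1", "e2", "e9"))
        corpus.validate()
        part2 = partition_by_keyword(corpus, "melanoma")
        after = {c.cluster_id for c in exclusive_clusters(corpus, part2)}
        assert after == before - {"EXCL"}

    @pytest.mark.parametrize("mode", [MatchMode.TERM, MatchMode.SUBSTRING])
    def test_miner_equals_brute_force_oracle_on_random_corpora(self, mode):
        rng = np.random.default_rng(202)
        for _ in range(25):
            corpus = random_corpus(rng, max_sequences=200)
            keyword = ["melanoma", "testis", "skin", "absentterm"][
                int(rng.integers(4))
            ]
            matches = {
                cid: frozenset(
                    np.random.default_rng(hash(cid) % 2**31).choice(
                        ["liver", "testis", "tumor", "brain"],
                        size=int(rng.integers(1, 3)), replace=False,
                    )
                )
                for cid in corpus.clusters
                if rng.random() < 0.2
            }
            report = mine(corpus, keyword, mode=mode, matches=matches)
            o_excl, o_multi, o_final = oracle_mine(
                corpus, keyword, mode=mode.value, matches=matches
            )
            assert report.stage_counts == (
                len(o_excl), len(o_multi), len(o_final)
            )
            assert sorted(c.cluster_id for c in report.candidates) == o_final
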