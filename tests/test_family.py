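"""Family identification: domain rules, set merging, loci, GO partition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdzip import family, simulate
from hdzip.family import (
    CandidateSet,
    Domain,
    GenomeAlignment,
    GoAnnotation,
    Method,
    Subfamily,
    SubfamilyRejection,
    assign_loci,
    classify_or_reject,
    classify_subfamily,
    find_genotype_specific,
    merge_candidate_sets,
    method_exclusive,
    summarize_go,
)


class TestClassifySubfamily:
    @pytest.mark.parametrize(
        "domains, expected",
        [
            ({Domain.HD, Domain.HALZ}, Subfamily.I),
            ({Domain.HD, Domain.HALZ, Domain.CPSCE}, Subfamily.II),
            ({Domain.HD, Domain.START, Domain.MEKHLA}, Subfamily.III),
            ({Domain.HD, Domain.START}, Subfamily.IV),
            ({Domain.HD, Domain.HALZ, Domain.HDZIP_NTERM}, Subfamily.I),
            ({Domain.HD, Domain.HALZ, Domain.START}, Subfamily.IV),
        ],
    )
    def test_rules(self, domains, expected):
        assert classify_subfamily(domains) is expected

    @pytest.mark.parametrize(
        "domains, reason",
        [
            (set(), "no HD"),
            ({Domain.HALZ}, "no HD"),
            ({Domain.HD}, "HD without HALZ or START"),
            ({Domain.HD, Domain.CPSCE}, "HD without HALZ or START"),
        ],
    )
    def test_rejections(self, domains, reason):
        with pytest.raises(SubfamilyRejection, match=reason):
            classify_subfamily(domains)

    @given(st.sets(st.sampled_from(list(Domain))))
    @settings(max_examples=200, derandomize=True)
    def test_total_function(self, domains):
        """Every domain set yields exactly one of I-IV or a rejection reason."""
        sub, reason = classify_or_reject(domains)
        assert (sub is None) != (reason is None)
        if sub is not None:
            assert sub in set(Subfamily)


class TestMergeCandidateSets:
    def test_union_and_identity(self):
        sets = [
            CandidateSet.of(Method.DOMAIN_TBLASTN, {"A", "B"}),
            CandidateSet.of(Method.KNOWN_GENE_BLAST, {"B", "C"}),
            CandidateSet.of(Method.HMM_SEARCH, {"C", "D"}),
        ]
        prov = merge_candidate_sets(sets)
        assert set(prov) == {"A", "B", "C", "D"}
        assert prov["B"] == {Method.DOMAIN_TBLASTN, Method.KNOWN_GENE_BLAST}
        assert merge_candidate_sets(sets[:1]) == {
            "A": {Method.DOMAIN_TBLASTN}, "B": {Method.DOMAIN_TBLASTN},
        }

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_candidate_sets([])

    def test_study_cardinality_construction(self):
        """114/83/112 sets union to 117 with one id exclusive to method 2."""
        sets, truth = simulate.gen_candidate_sets(seed=3)
        prov = merge_candidate_sets(sets)
        assert len(prov) == 117
        assert truth["sizes"] == {
            "domain_tblastn": 114, "known_gene_blast": 83, "hmm_search": 112,
        }
        excl = method_exclusive(prov, Method.KNOWN_GENE_BLAST)
        assert excl == truth["exclusive_to_known_gene_blast"]
        # direct set algebra cross-check
        s1, s2, s3 = (set(cs.transcript_ids) for cs in sets)
        assert set(prov) == s1 | s2 | s3
        assert excl == s2 - s1 - s3
        assert len(prov) <= sum(len(s) for s in (s1, s2, s3))

    def test_provenance_covers_every_output_id(self):
        sets, _ = simulate.gen_candidate_sets(seed=4)
        prov = merge_candidate_sets(sets)
        assert all(ms for ms in prov.values())


def _aln(tid, chrom, start, end, genotype="Damaya", length=500, identity=99.9,
         evalue=1e-30):
    return GenomeAlignment(tid, genotype, chrom, start, end, length, identity,
                           evalue)


class TestAssignLoci:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"length": 150},          # below the 180-bp query-cover floor
            {"identity": 98.5},       # below 99% identity
            {"evalue": 1e-3},         # above the 1e-6 ceiling
        ],
    )
    def test_filters(self, kwargs):
        keep = _aln("t1", "chr1", 1000, 1800)
        drop = _aln("t2", "chr1", 5000, 5800, **kwargs)
        loci = assign_loci([keep, drop])
        assert len(loci) == 1
        assert loci[0].members == {"Damaya": {"t1"}}

    def test_overlap_merge(self):
        loci = assign_loci([
            _aln("t1", "chr1", 1000, 1800), _aln("t2", "chr1", 1500, 2300),
        ])
        assert len(loci) == 1
        assert loci[0].n_transcripts == 2
        assert (loci[0].start, loci[0].end) == (1000, 2300)

    def test_toy_merge_matches_bruteforce(self):
        """Six alignments, two chromosomes, known overlap structure -> 3 loci."""
        alns = [
            _aln("a", "chr1", 100, 400),
            _aln("b", "chr1", 350, 700),    # chains with a
            _aln("c", "chr1", 701, 900),    # adjacent but not overlapping
            _aln("d", "chr2", 100, 300),
            _aln("e", "chr2", 250, 500),
            _aln("f", "chr2", 120, 180),    # nested in d
        ]
        loci = assign_loci(alns)
        assert len(loci) == 3

        # brute-force transitive-overlap oracle (union-find over all pairs)
        parent = {a.transcript_id: a.transcript_id for a in alns}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for x in alns:
            for y in alns:
                if (x.chromosome == y.chromosome
                        and x.start <= y.end and y.start <= x.end):
                    parent[find(x.transcript_id)] = find(y.transcript_id)
        oracle_groups = {frozenset(t for t in parent if find(t) == r)
                         for r in {find(t) for t in parent}}
        got_groups = {
            frozenset(t for ids in locus.members.values() for t in ids)
            for locus in loci
        }
        assert got_groups == oracle_groups

    def test_best_alignment_tie_breaks(self):
        # same transcript twice: lower E-value wins regardless of position
        loci = assign_loci([
            _aln("t1", "chr1", 1000, 1800, evalue=1e-10),
            _aln("t1", "chr2", 5000, 5800, evalue=1e-40),
        ])
        assert len(loci) == 1 and loci[0].chromosome == "chr2"

    def test_unknown_chromosome_errors(self):
        with pytest.raises(ValueError, match="chromosome"):
            assign_loci([_aln("t1", "chr25", 1, 500)])
        with pytest.raises(ValueError, match="chromosome"):
            assign_loci([_aln("t1", "scaffold_9", 1, 500)])

    def test_merged_loci_disjoint_and_member_bound(self):
        rng = np.random.default_rng(5)
        alns = [
            _aln(f"t{i}", f"chr{rng.integers(1, 4)}",
                 int(s := rng.integers(1, 50_000)), int(s + rng.integers(200, 3000)))
            for i in range(60)
        ]
        loci = assign_loci(alns)
        assert sum(l.n_transcripts for l in loci) <= len(alns)
        by_chrom = {}
        for l in loci:
            by_chrom.setdefault(l.chromosome, []).append((l.start, l.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2  # non-overlapping after merging


class TestGenotypeSpecific:
    def test_trivial_calls(self):
        only = family.Locus("L1", "chr1", 1, 10, {"Damaya": {"t1"}})
        shared = family.Locus("L2", "chr1", 20, 30,
                              {"Damaya": {"t1"}, "ChP": {"g9"}})
        assert find_genotype_specific([only, shared], "Damaya") == [only]

    def test_planted_fixture(self):
        alns, truth = simulate.gen_alignment_table(seed=7)
        loci = assign_loci(alns)
        assert len(loci) == truth["n_loci"] == 64
        specific = find_genotype_specific(loci, "Damaya")
        got = sorted(t for l in specific for ids in l.members.values() for t in ids)
        assert got == sorted(truth["focal_specific_transcripts"])
        assert len(specific) == 5

    def test_absent_focal_errors(self):
        locus = family.Locus("L1", "chr1", 1, 10, {"ChP": {"g1"}})
        with pytest.raises(ValueError):
            find_genotype_specific([locus], "IR826")


class TestSummarizeGo:
    def _members(self, n, subfamily=Subfamily.I, prefix="m"):
        return [
            family.FamilyMember(f"{prefix}{i}", frozenset({Domain.HD, Domain.HALZ}),
                                subfamily)
            for i in range(n)
        ]

    def test_triple_intersection_cell(self):
        members = self._members(1)
        s = summarize_go([GoAnnotation("m0", frozenset({"BP", "MF", "CC"}))], members)
        assert s.venn["BP&MF&CC"] == 1
        assert sum(s.venn.values()) == 1

    def test_subfamily_pattern_cell(self):
        """Nine members of one subfamily annotated only MF and CC."""
        members = self._members(9, Subfamily.III)
        anns = [GoAnnotation(m.transcript_id, frozenset({"MF", "CC"}))
                for m in members]
        s = summarize_go(anns, members)
        assert s.venn_by_subfamily["III"]["MF&CC"] == 9
        assert s.category_counts_by_subfamily["III"] == {"BP": 0, "MF": 9, "CC": 9}

    def test_partition_identity_random(self):
        rng = np.random.default_rng(9)
        members = self._members(40)
        anns = []
        for m in members:
            cats = [c for c in family.GO_CATEGORIES if rng.random() < 0.6]
            if not cats:
                continue
            anns.append(GoAnnotation(m.transcript_id, frozenset(cats)))
        s = summarize_go(anns, members)
        assert sum(s.venn.values()) == s.n_annotated == len(anns)
        per_sub_total = sum(
            sum(d.values()) for d in s.venn_by_subfamily.values()
        )
        assert per_sub_total == s.n_annotated

    def test_unknown_member_skipped_with_warning(self):
        members = self._members(1)
        with pytest.warns(UserWarning, match="unknown member"):
            s = summarize_go(
                [GoAnnotation("ghost", frozenset({"BP"}))], members
            )
        assert s.n_annotated == 0
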