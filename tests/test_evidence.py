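"""Evidence filtering, consensus voting, reclassification and census moves."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reannot.evidence import (
    CallClass,
    EvidenceRecord,
    FunctionCall,
    Source,
    assign_confidence,
    dedupe_sources,
    filter_pfam,
    filter_psiblast,
    jaccard,
    normalize_description,
    reclassify,
    update_census,
)
from reannot.genome import Category, CategoryCensus, GeneRecord


def rec(source, desc, e=1e-60, ident=50.0, member="", cds="CDS_0001"):
    return EvidenceRecord(
        cds_id=cds,
        source=source,
        description=desc,
        e_value=e,
        identity_pct=ident,
        member_database=member,
    )


class TestFilters:
    def test_psiblast_keeps_only_strict_quadrant(self):
        # enumerate the four (identity, e-value) quadrants around the cut-offs
        cases = {
            (45.0, 1e-60): True,
            (39.0, 1e-80): False,
            (45.0, 1e-40): False,
            (39.0, 1e-40): False,
        }
        for (ident, e), keep in cases.items():
            hits = [rec(Source.PSI_BLAST, "kinase", e=e, ident=ident)]
            assert bool(filter_psiblast(hits)) is keep, (ident, e)

    def test_psiblast_boundary_identity_40_rejected(self):
        hits = [rec(Source.PSI_BLAST, "kinase", e=1e-60, ident=40.0)]
        assert filter_psiblast(hits) == []

    def test_psiblast_boundary_evalue_1e52_rejected(self):
        hits = [rec(Source.PSI_BLAST, "kinase", e=1e-52, ident=80.0)]
        assert filter_psiblast(hits) == []

    def test_pfam_threshold_inclusive(self):
        assert filter_pfam([rec(Source.PFAM, "GH43", e=1e-03)])
        assert filter_pfam([rec(Source.PFAM, "GH43", e=1e-02)])
        assert not filter_pfam([rec(Source.PFAM, "GH43", e=2e-02)])

    def test_empty_inputs(self):
        assert filter_psiblast([]) == []
        assert filter_pfam([]) == []

    def test_missing_values_skipped_with_warning(self):
        hit = EvidenceRecord("c", Source.PSI_BLAST, "kinase", e_value=None)
        with pytest.warns(UserWarning, match="missing"):
            assert filter_psiblast([hit]) == []

    def test_wrong_source_rejected(self):
        with pytest.raises(ValueError, match="expected PFAM"):
            filter_pfam([rec(Source.ANNIE, "x")])


class TestNormalizeDescription:
    def test_token_sets_are_order_invariant(self):
        a = normalize_description("Beta-xylosidase, family 43 glycosyl hydrolase")
        b = normalize_description("glycosyl hydrolase family 43 beta-xylosidase")
        assert a == b

    def test_uninformative_description_is_empty(self):
        assert normalize_description("hypothetical protein") == frozenset()

    def test_agrees_with_character_level_canonicalizer(self):
        rng = np.random.default_rng(3)
        words = ["kinase", "abc", "transporter", "protein", "family", "43",
                 "putative", "sensor", "domain", "xylosidase"]
        stop = {"protein", "domain", "containing", "family", "putative",
                "probable", "like"}

        def oracle(text):
            clean = "".join(c if c.isalnum() else " " for c in text.lower())
            return frozenset(w for w in clean.split() if w not in stop)

        for _ in range(50):
            k1, k2 = rng.integers(1, 6, size=2)
            t1 = " ".join(rng.choice(words, size=k1)) + "-X1"
            t2 = ", ".join(rng.choice(words, size=k2))
            assert (normalize_description(t1) == normalize_description(t2)) == (
                oracle(t1) == oracle(t2)
            )
            assert normalize_description(t2) == oracle(t2)


class TestDedupeSources:
    def test_integrated_duplicate_of_pfam_adds_no_vote(self):
        hits = [
            rec(Source.PFAM, "glycosyl hydrolase family 43", e=1e-10),
            rec(Source.INTERPROSCAN, "glycosyl hydrolase family 43",
                e=1e-12, member="PFAM"),
        ]
        votes = dedupe_sources(hits)
        assert votes == [(Source.PFAM, "glycosyl hydrolase family 43")]

    def test_five_distinct_sources_five_votes(self):
        hits = [rec(s, f"function {i}") for i, s in enumerate(Source)]
        assert len(dedupe_sources(hits)) == 5

    def test_integrated_with_different_description_still_votes(self):
        hits = [
            rec(Source.PFAM, "glycosyl hydrolase family 43"),
            rec(Source.INTERPROSCAN, "sensor kinase", member="PFAM"),
        ]
        assert len(dedupe_sources(hits)) == 2

    def test_matches_brute_force_grouping(self):
        rng = np.random.default_rng(11)
        descs = ["alpha amylase precursor", "sensor histidine kinase",
                 "iron transporter permease"]
        for _ in range(30):
            hits = []
            for s in Source:
                if rng.random() < 0.3:
                    continue
                d = descs[rng.integers(len(descs))]
                member = ""
                if s in (Source.INTERPROSCAN, Source.ANNIE) and rng.random() < 0.5:
                    member = "PFAM"
                hits.append(rec(s, d, e=float(rng.uniform(1e-80, 1e-5)),
                                member=member))
            votes = dedupe_sources(hits)
            # oracle: group hits by underlying method + description
            direct = {h.source: h.description for h in hits
                      if h.source not in (Source.INTERPROSCAN, Source.ANNIE)}
            expected = dict(direct)
            for h in hits:
                if h.source not in (Source.INTERPROSCAN, Source.ANNIE):
                    continue
                wrapped = Source(h.member_database) if h.member_database else None
                dup = (wrapped in direct
                       and normalize_description(direct[wrapped])
                       == normalize_description(h.description))
                if not dup and h.source not in expected:
                    expected[h.source] = h.description
            assert dict(votes) == expected

    def test_mixed_cds_ids_rejected(self):
        with pytest.raises(ValueError, match="multiple CDSs"):
            dedupe_sources([rec(Source.PFAM, "x", cds="a"),
                            rec(Source.ANNIE, "x", cds="b")])


class TestAssignConfidence:
    def test_all_five_tools_agree_gives_5_of_5_defined(self):
        hits = [rec(s, "NAD(P)-dependent iron-only hydrogenase") for s in Source]
        call = assign_confidence(hits)
        assert call.confidence == 5
        assert call.confidence_label == "5/5"
        assert call.call_class is CallClass.DEFINED

    def test_no_evidence_is_none_call(self):
        call = assign_confidence([], cds_id="CDS_0001")
        assert call.call_class is CallClass.NONE
        assert call.confidence == 0
        assert call.consensus_description == ""

    def test_majority_cluster_beats_minority(self):
        hits = [
            rec(Source.PSI_BLAST, "sensor histidine kinase yycG"),
            rec(Source.BLASTO, "sensor histidine kinase yycG"),
            rec(Source.ANNIE, "histidine kinase sensor yycG"),
            rec(Source.PFAM, "sugar isomerase"),
            rec(Source.INTERPROSCAN, "ferredoxin reductase"),
        ]
        call = assign_confidence(hits)
        assert call.confidence == 3
        assert call.supporting_sources == {
            Source.PSI_BLAST, Source.BLASTO, Source.ANNIE}

    def test_matches_exhaustive_partition_oracle(self):
        rng = np.random.default_rng(5)
        vocab = ["sensor histidine kinase", "sugar abc transporter",
                 "ferredoxin oxidoreductase"]
        for _ in range(40):
            hits = [rec(s, vocab[rng.integers(len(vocab))])
                    for s in Source if rng.random() < 0.8]
            if not hits:
                continue
            call = assign_confidence(hits)
            votes = dedupe_sources(hits)
            toks = [normalize_description(d) for _, d in votes]
            best = 0
            for r in range(1, len(votes) + 1):
                for combo in itertools.combinations(range(len(votes)), r):
                    if all(jaccard(toks[i], toks[j]) >= 0.6
                           for i, j in itertools.combinations(combo, 2)):
                        best = max(best, r)
            assert call.confidence == best

    def test_permutation_invariance(self):
        hits = [
            rec(Source.PSI_BLAST, "alpha amylase"),
            rec(Source.BLASTO, "amylase alpha"),
            rec(Source.PFAM, "sugar isomerase"),
        ]
        calls = {assign_confidence(list(p)).consensus_description
                 for p in itertools.permutations(hits)}
        confs = {assign_confidence(list(p)).confidence
                 for p in itertools.permutations(hits)}
        assert len(calls) == 1 and confs == {2}

    def test_adding_agreeing_evidence_never_lowers_confidence(self):
        base = [rec(Source.PSI_BLAST, "alpha amylase"),
                rec(Source.BLASTO, "alpha amylase")]
        before = assign_confidence(base).confidence
        extra = base + [rec(Source.ANNIE, "alpha amylase")]
        assert assign_confidence(extra).confidence >= before

    def test_motif_only_evidence_is_putative(self):
        hits = [rec(Source.PFAM, "GH43 catalytic module"),
                rec(Source.INTERPROSCAN, "GH43 catalytic module")]
        assert assign_confidence(hits).call_class is CallClass.PUTATIVE

    def test_putative_marker_forces_putative_class(self):
        hits = [rec(s, "putative diguanylate cyclase") for s in Source]
        assert assign_confidence(hits).call_class is CallClass.PUTATIVE

    def test_confidence_never_exceeds_five(self):
        hits = [rec(s, "alpha amylase", e=10.0 ** -(10 + i))
                for i, s in enumerate(Source)] * 3
        assert assign_confidence(hits).confidence <= 5


def gene(category, product="x", confidence=0):
    return GeneRecord("CDS_0001", "G", 1, 90, "+", product=product,
                      category=category, confidence=confidence)


def call(call_class, conf, desc="sensor kinase"):
    if call_class is CallClass.NONE:
        return FunctionCall("CDS_0001")
    return FunctionCall("CDS_0001", desc, conf,
                        frozenset(list(Source)[:conf]), call_class)


class TestReclassify:
    def test_hypothetical_with_defined_call_becomes_known(self):
        out = reclassify(gene(Category.HYPOTHETICAL), call(CallClass.DEFINED, 5))
        assert out.category is Category.KNOWN
        assert out.confidence == 5

    def test_known_with_none_call_unchanged(self):
        g = gene(Category.KNOWN, "zeta toxin", 3)
        assert reclassify(g, call(CallClass.NONE, 0)) == g

    def test_new_cds_with_putative_call_gets_prefixed_product(self):
        out = reclassify(gene(Category.NEW), call(CallClass.PUTATIVE, 2))
        assert out.category is Category.PUTATIVE
        assert out.product == "putative sensor kinase"

    def test_rule_table_exhaustive(self):
        # every category x call class x confidence against the hand rule table
        for cat in Category:
            for cls in CallClass:
                for conf in range(0 if cls is CallClass.NONE else 1, 6):
                    g = gene(cat)
                    out = reclassify(g, call(cls, conf), min_conf_known=2)
                    if cat is Category.PSEUDOGENE or cls is CallClass.NONE:
                        expected = cat
                    elif cat is Category.KNOWN:
                        expected = Category.KNOWN
                    elif cls is CallClass.DEFINED and conf >= 2:
                        expected = Category.KNOWN
                    else:
                        expected = Category.PUTATIVE
                    assert out.category is expected, (cat, cls, conf)

    def test_known_never_demoted_by_weak_call(self):
        g = gene(Category.KNOWN, "zeta toxin", 4)
        out = reclassify(g, call(CallClass.PUTATIVE, 1))
        assert out.category is Category.KNOWN


class TestUpdateCensus:
    BEFORE = CategoryCensus(counts={"KNOWN": 1854, "HYPOTHETICAL": 781,
                                    "PUTATIVE": 47})

    def test_reported_reannotation_moves(self):
        after = update_census(self.BEFORE, [
            ("HYPOTHETICAL", "KNOWN", 385),
            ("HYPOTHETICAL", "PUTATIVE", 24),
            ("PUTATIVE", "KNOWN", 46),
        ])
        assert after.get("KNOWN") == 2285
        assert after.get("HYPOTHETICAL") == 372
        assert after.get("PUTATIVE") == 25
        assert after.total == self.BEFORE.total

    def test_empty_moves_identity(self):
        assert update_census(self.BEFORE, []).as_dict() == self.BEFORE.as_dict()

    def test_overdraw_raises(self):
        with pytest.raises(ValueError, match="only"):
            update_census(self.BEFORE, [("PUTATIVE", "KNOWN", 48)])

    @given(st.lists(st.tuples(st.sampled_from(["A", "B", "C"]),
                              st.sampled_from(["A", "B", "C"]),
                              st.integers(0, 5)), max_size=20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_total_conserved_on_any_valid_move_list(self, moves):
        counts = {"A": 10, "B": 10, "C": 10}
        before = CategoryCensus(counts=counts)
        # replay oracle: apply moves one by one on a plain dict
        state = dict(counts)
        valid = []
        for src, dst, n in moves:
            if state[src] >= n:
                state[src] -= n
                state[dst] += n
                valid.append((src, dst, n))
        after = update_census(before, valid)
        assert after.as_dict() == {**state, "total": 30}
        assert after.total == before.total
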