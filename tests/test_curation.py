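import numpy as np
import pytest

from lysinscape.curation import (
    CurationConfig,
    assign_host,
    cluster_identity,
    filter_domain_relevance,
    filter_length,
    pairwise_identity,
    run_curation,
    screen_annotations,
)
from lysinscape.io import Gram

from conftest import AA, make_hit, make_record, random_sequence


class TestAnnotationScreen:
    @pytest.mark.parametrize(
        "annotation, kept",
        [
            ("putative endolysin", True),          # 'lysin' substring matches
            ("tail-associated lysozyme", False),   # exclusion overrides
            ("hypothetical protein", False),       # no inclusion term
            ("N-acetylmuramoyl-L-alanine amidase", True),
            ("baseplate lysozyme", False),
            ("", False),
        ],
    )
    def test_keyword_semantics(self, annotation, kept):
        rec = make_record("A", "M" * 60, annotation=annotation)
        assert bool(screen_annotations([rec])) is kept


class TestLengthFilter:
    @pytest.mark.parametrize("length, kept", [(49, False), (50, True), (550, True), (551, False)])
    def test_inclusive_bounds(self, length, kept):
        rec = make_record("A", "M" * length)
        assert bool(filter_length([rec])) is kept

    def test_empty_collection(self):
        assert filter_length([]) == []


class TestIdentityClustering:
    def test_identical_pair_merges(self, rng):
        seq = random_sequence(rng, 120)
        reps, cmap = cluster_identity([make_record("A", seq), make_record("B", seq)])
        assert len(reps) == 1
        assert sorted(cmap[reps[0].id]) == ["A", "B"]

    def test_99pct_pair_merges_at_98_threshold(self, rng):
        seq = random_sequence(rng, 100)
        mutated = seq[:50] + ("A" if seq[50] != "A" else "C") + seq[51:]
        # gap-free Hamming oracle: 99 identical positions over the shorter length
        hamming_identity = sum(a == b for a, b in zip(seq, mutated)) / 100
        assert hamming_identity == 0.99
        assert pairwise_identity(seq, mutated) == pytest.approx(0.99)
        reps, _ = cluster_identity([make_record("A", seq), make_record("B", mutated)])
        assert len(reps) == 1

    def test_90pct_pair_stays_apart(self, rng):
        seq = list(random_sequence(rng, 100))
        mutated = seq.copy()
        for pos in range(0, 100, 10):  # 10 substitutions -> 90% identity
            mutated[pos] = "A" if mutated[pos] != "A" else "C"
        a, b = "".join(seq), "".join(mutated)
        assert pairwise_identity(a, b) <= 0.90
        reps, _ = cluster_identity([make_record("A", a), make_record("B", b)])
        assert len(reps) == 2

    def test_containment_uses_shorter_sequence_denominator(self, rng):
        core = random_sequence(rng, 80)
        long = random_sequence(rng, 40) + core + random_sequence(rng, 40)
        assert pairwise_identity(core, long) == pytest.approx(1.0)

    def test_order_invariance(self, rng):
        records = [
            make_record(f"R{i}", random_sequence(rng, int(rng.integers(60, 200))))
            for i in range(12)
        ]
        # add two near-duplicate pairs
        records.append(make_record("D0", records[0].sequence[:-1] + "A"))
        records.append(make_record("D1", records[1].sequence))
        reps_fwd, map_fwd = cluster_identity(records)
        shuffled = list(records)
        np.random.default_rng(7).shuffle(shuffled)
        reps_rev, map_rev = cluster_identity(shuffled)
        assert [r.id for r in reps_fwd] == [r.id for r in reps_rev]
        assert {k: sorted(v) for k, v in map_fwd.items()} == {
            k: sorted(v) for k, v in map_rev.items()
        }


class TestDomainRelevance:
    def test_whitelisted_significant_hit_kept(self):
        rec = make_record("A", "M" * 200)
        assert filter_domain_relevance([rec], [make_hit("A", "Amidase_2", 5, 150)])

    def test_no_hits_removed(self):
        rec = make_record("A", "M" * 200)
        assert filter_domain_relevance([rec], []) == []

    def test_evalue_boundary_inclusive_at_10(self):
        rec = make_record("A", "M" * 200)
        at_cutoff = [make_hit("A", "Amidase_2", 5, 150, e=10.0)]
        above = [make_hit("A", "Amidase_2", 5, 150, e=11.0)]
        assert filter_domain_relevance([rec], at_cutoff)
        assert filter_domain_relevance([rec], above) == []

    def test_other_class_families_do_not_rescue(self):
        rec = make_record("A", "M" * 200)
        hit = make_hit("A", "Gp5_C", 5, 100)  # structural, not whitelisted
        assert filter_domain_relevance([rec], [hit]) == []
        cfg = CurationConfig(structural_exceptions=("Gp5_C",))
        assert filter_domain_relevance([rec], [hit], cfg)


class TestAssignHost:
    def test_mycolic_diderm_counts_as_gram_positive(self, host_table):
        rec = make_record("A", "M" * 60, host_genus="Mycobacterium")
        (out,), flagged = assign_host([rec], host_table)
        assert out.gram is Gram.POS
        assert not flagged

    def test_vibrio_chemotype(self, host_table):
        rec = make_record("A", "M" * 60, host_genus="Vibrio")
        (out,), _ = assign_host([rec], host_table)
        assert out.gram is Gram.NEG
        assert out.chemotype == "A1γ"

    def test_unknown_genus_flagged_and_retained(self, host_table):
        rec = make_record("A", "M" * 60, host_genus=None)
        (out,), flagged = assign_host([rec], host_table)
        assert out.gram is None
        assert out.host_unknown
        assert flagged == ["A"]


def _engineered_hundred(rng):
    """100 records: 10 bad keywords, 10 bad lengths, 20 near-duplicate copies,
    5 without hits; 55 survive by construction."""
    records, hits = [], []
    for i in range(60):
        seq = random_sequence(rng, int(rng.integers(100, 300)))
        rec = make_record(f"good{i:02d}", seq, host_genus="Escherichia")
        records.append(rec)
        if i >= 55:  # the last 5 get no hits
            continue
        hits.append(make_hit(rec.id, "Phage_lysozyme", 3, min(100, rec.length - 2)))
    for i in range(20):  # 99%-identical copy of an existing kept record
        src = records[i]
        pos = int(rng.integers(0, src.length))
        seq = src.sequence[:pos] + ("A" if src.sequence[pos] != "A" else "C") + src.sequence[pos + 1 :]
        dup = make_record(f"dup{i:02d}", seq, host_genus="Escherichia")
        records.append(dup)
        hits.append(make_hit(dup.id, "Phage_lysozyme", 3, min(100, dup.length - 2)))
    for i in range(10):
        records.append(
            make_record(f"bad_kw{i}", random_sequence(rng, 150), annotation="holin")
        )
    for i in range(10):
        length = 40 if i % 2 else 600
        records.append(make_record(f"bad_len{i}", random_sequence(rng, length)))
    return records, hits


class TestRunCuration:
    def test_engineered_fixture_counts(self, rng, host_table):
        records, hits = _engineered_hundred(rng)
        assert len(records) == 100
        curated, report = run_curation(records, hits, host_table)
        assert len(curated) == 55
        assert report.telescopes()
        by_stage = {s.name: s for s in report.stages}
        assert len(by_stage["annotation_screen"].removed_ids) == 10
        assert len(by_stage["length_filter"].removed_ids) == 10
        assert len(by_stage["identity_clustering"].removed_ids) == 20
        assert len(by_stage["domain_relevance"].removed_ids) == 5

    def test_removed_ids_partition(self, rng, host_table):
        records, hits = _engineered_hundred(rng)
        _, report = run_curation(records, hits, host_table)
        removed = [rid for s in report.stages for rid in s.removed_ids]
        assert len(removed) == len(set(removed))

    def test_all_pass_fixture_is_identity_with_singletons(self, rng, host_table):
        records = [
            make_record(f"ok{i}", random_sequence(rng, 150), host_genus="Vibrio")
            for i in range(8)
        ]
        hits = [make_hit(r.id, "Phage_lysozyme", 3, 120) for r in records]
        curated, report = run_curation(records, hits, host_table)
        assert {r.id for r in curated} == {r.id for r in records}
        assert all(len(v) == 1 for v in report.cluster_map.values())

    def test_empty_input(self, host_table):
        curated, report = run_curation([], [], host_table)
        assert curated == []
        assert all(s.n_in == 0 and s.n_out == 0 for s in report.stages)

    def test_idempotence(self, rng, host_table):
        records, hits = _engineered_hundred(rng)
        curated, _ = run_curation(records, hits, host_table)
        again, report2 = run_curation(curated, hits, host_table)
        assert [r.id for r in again] == [r.id for r in curated]
        assert all(not s.removed_ids for s in report2.stages)
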