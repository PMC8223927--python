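import numpy as np
import pytest

from lysinscape.architecture import (
    architecture_string,
    crosstab,
    expand_architecture,
    flank_table,
    gram_share_per_family,
    hits_per_protein_distribution,
    resolve_overlaps,
    summarize_architecture,
    summarize_all,
)
from lysinscape.curation import assign_host
from lysinscape.io import Gram

from conftest import make_hit, make_record, random_sequence


class TestArchitectureString:
    def test_repeats_collapse(self):
        fams = ["Amidase_2"] + ["CW_binding_1"] * 5
        assert architecture_string(fams) == "[Amidase_2]5×[CW_binding_1]"

    def test_expand_inverts_collapse(self):
        fams = ["Amidase_2", "CW_binding_1", "CW_binding_1", "Amidase_2"]
        assert expand_architecture(architecture_string(fams)) == fams

    def test_round_trip_on_random_lists(self, rng):
        pool = ["Amidase_2", "CHAP", "CW_binding_1", "SH3_5"]
        for _ in range(50):
            fams = list(rng.choice(pool, size=int(rng.integers(1, 10))))
            assert expand_architecture(architecture_string(fams)) == fams

    def test_malformed_string_rejected(self):
        with pytest.raises(ValueError):
            expand_architecture("Amidase_2 x5")


class TestSummarize:
    def test_single_ead_flanks(self):
        rec = make_record("A", "M" * 200)
        arch = summarize_architecture(rec, [make_hit("A", "Amidase_2", 51, 150)])
        assert arch.aa_before_first_ead == 50
        assert arch.aa_after_last_ead == 50
        assert arch.n_eads == 1

    def test_streptococcal_six_hit_architecture(self):
        rec = make_record("A", "M" * 340)
        hits = [make_hit("A", "Amidase_2", 10, 160)] + [
            make_hit("A", "CW_binding_1", 170 + 22 * i, 190 + 22 * i) for i in range(5)
        ]
        arch = summarize_architecture(rec, hits)
        assert arch.n_hits == 6
        assert arch.architecture == "[Amidase_2]5×[CW_binding_1]"
        assert arch.n_cwbds == 5

    def test_no_hits(self):
        rec = make_record("A", "M" * 100)
        arch = summarize_architecture(rec, [])
        assert arch.n_hits == 0
        assert arch.aa_before_first_ead is None
        assert arch.aa_after_last_ead is None

    def test_cwbds_between_eads_ignored_for_flanks(self):
        rec = make_record("A", "M" * 400)
        hits = [
            make_hit("A", "Amidase_2", 21, 120),
            make_hit("A", "LysM", 140, 190),
            make_hit("A", "CHAP", 220, 350),
        ]
        arch = summarize_architecture(rec, hits)
        assert arch.aa_before_first_ead == 20
        assert arch.aa_after_last_ead == 50

    def test_flank_inequality_single_ead(self, default_dataset, host_table):
        records, _ = assign_host(default_dataset.records, host_table)
        df = summarize_all(records, default_dataset.hits)
        one_ead = df[df["n_eads"] == 1].dropna(
            subset=["aa_before_first_ead", "aa_after_last_ead"]
        )
        assert len(one_ead) > 100
        slack = one_ead["length"] - one_ead["aa_before_first_ead"] - one_ead["aa_after_last_ead"]
        assert (slack > 0).all()


class TestOverlapResolution:
    def test_lower_evalue_wins(self):
        a = make_hit("A", "Amidase_2", 10, 100, e=1e-30)
        b = make_hit("A", "CHAP", 50, 140, e=1e-10)
        assert resolve_overlaps([a, b]) == [a]

    def test_tie_prefers_longer(self):
        a = make_hit("A", "Amidase_2", 10, 100, e=1e-10)
        b = make_hit("A", "CHAP", 50, 160, e=1e-10)
        assert resolve_overlaps([a, b]) == [b]

    def test_non_overlapping_all_kept_in_coordinate_order(self):
        a = make_hit("A", "CHAP", 120, 180, e=1e-10)
        b = make_hit("A", "Amidase_2", 10, 100, e=1e-5)
        assert resolve_overlaps([a, b]) == [b, a]


class TestHitsPerProtein:
    def test_fixture_single_hit_fraction(self):
        records = [make_record(f"P{i}", "M" * 100, host_genus="Escherichia") for i in range(10)]
        for r in records:
            r.gram = Gram.NEG
        hits = [make_hit(r.id, "Phage_lysozyme", 3, 90) for r in records[:7]]
        hits += [make_hit(r.id, "PG_binding_1", 91, 99) for r in records[7:9]]
        hits += [make_hit(records[7].id, "Phage_lysozyme", 3, 80)]
        # records 0-6: one hit; 7: two hits; 8: one hit; 9: none -> 8/10
        table, single = hits_per_protein_distribution(records, hits)
        assert single["G-"] == pytest.approx(0.8)
        assert table.loc[1, "G-"] == 8

    def test_generator_monomodular_rate_recovered(self, default_dataset, host_table):
        records, _ = assign_host(default_dataset.records, host_table)
        _, single = hits_per_protein_distribution(records, default_dataset.hits)
        assert abs(single["G-"] - 0.90) < 0.05

    def test_zero_count_cells_present(self):
        records = [make_record("A", "M" * 100, gram=Gram.NEG),
                   make_record("B", "M" * 100, gram=Gram.POS)]
        hits = [make_hit("A", "Phage_lysozyme", 3, 90)]
        table, _ = hits_per_protein_distribution(records, hits)
        assert table.loc[1, "G+"] == 0
        assert table.loc[0, "G-"] == 0


class TestCrossTab:
    def _records(self):
        recs = [
            make_record("E1", "M" * 100, host_genus="Escherichia"),
            make_record("E2", "M" * 100, host_genus="Escherichia"),
            make_record("S1", "M" * 100, host_genus="Streptococcus"),
        ]
        return recs

    def test_cell_counts_hits_not_proteins(self):
        recs = self._records()
        hits = [make_hit("E1", "Amidase_2", 1, 50), make_hit("E1", "Amidase_2", 51, 99),
                make_hit("E2", "Amidase_2", 1, 50), make_hit("S1", "CW_binding_1", 1, 20)]
        ct = crosstab(hits, recs, rows="genus", cols="family")
        assert ct.counts.loc["Escherichia", "Amidase_2"] == 3
        assert ct.total == 4

    def test_marginals_are_sums(self):
        recs = self._records()
        hits = [make_hit("E1", "Amidase_2", 1, 50), make_hit("S1", "CW_binding_1", 1, 20),
                make_hit("S1", "Amidase_5", 30, 90)]
        ct = crosstab(hits, recs, rows="genus", cols="family")
        assert (ct.row_totals == ct.counts.sum(axis=1)).all()
        assert (ct.col_totals == ct.counts.sum(axis=0)).all()
        assert ct.total == len(hits)

    def test_orphan_hits_fall_under_unassigned(self):
        recs = self._records()
        hits = [make_hit("GHOST", "Amidase_2", 1, 50)]
        ct = crosstab(hits, recs)
        assert ct.counts.loc["unassigned", "Amidase_2"] == 1

    def test_planted_genus_restricted_cwbd_concentrates(self, default_dataset, host_table):
        records, _ = assign_host(default_dataset.records, host_table)
        ct = crosstab(default_dataset.hits, records, rows="gram", cols="family")
        if "CW_binding_1" in ct.counts.columns:
            col = ct.counts["CW_binding_1"]
            assert col.get("G-", 0) == 0  # generator plants it only in G+


class TestGramShare:
    def test_shares(self):
        recs = [make_record("A", "M" * 50, gram=Gram.POS),
                make_record("B", "M" * 50, gram=Gram.POS),
                make_record("C", "M" * 50, gram=Gram.NEG)]
        hits = [make_hit("A", "Amidase_2", 1, 40), make_hit("A", "Amidase_2", 41, 49),
                make_hit("B", "Amidase_2", 1, 40), make_hit("C", "Amidase_2", 1, 40),
                make_hit("C", "Phage_lysozyme", 41, 49)]
        df = gram_share_per_family(hits, recs).set_index("family")
        assert df.loc["Amidase_2", "gpos_share"] == pytest.approx(0.75)
        assert df.loc["Phage_lysozyme", "gpos_share"] == 0.0
        assert df["total_hits"].sum() == len(hits)

    def test_planted_gpos_exclusive_family(self, default_dataset, host_table):
        records, _ = assign_host(default_dataset.records, host_table)
        df = gram_share_per_family(default_dataset.hits, records).set_index("family")
        assert df.loc["CW_binding_1", "gpos_share"] == 1.0
        assert df["total_hits"].sum() == len(default_dataset.hits)
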