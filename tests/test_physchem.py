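import math

import numpy as np
import pytest

from lysinscape import physchem
from lysinscape.physchem import (
    DAWSON_PKA,
    KYTE_DOOLITTLE,
    PhyschemConfig,
    aliphatic_index,
    avg_hydrophobic_moment,
    average_tendency,
    build_feature_table,
    gravy,
    hydrophobic_moment,
    ncpr,
    net_charge,
    quartile_split,
    quartile_values,
    window_profile,
)
from lysinscape import simulate

from conftest import AA, make_hit, make_record, random_sequence


def brute_charge(seq, ph=7.0, pka=DAWSON_PKA):
    """Independent Henderson-Hasselbalch summation, term by term."""
    pos = 1.0 / (1.0 + 10 ** (ph - pka["nTer"]))
    neg = 1.0 / (1.0 + 10 ** (pka["cTer"] - ph))
    for aa in seq:
        if aa in ("K", "R", "H"):
            pos += 1.0 / (1.0 + 10 ** (ph - pka[aa]))
        elif aa in ("D", "E", "C", "Y"):
            neg += 1.0 / (1.0 + 10 ** (pka[aa] - ph))
    return pos - neg


def brute_moment(seq, delta_deg=100.0, scale=KYTE_DOOLITTLE):
    """Independent trigonometric sum for one helical window."""
    d = math.radians(delta_deg)
    s = sum(scale.get(aa, 0.0) * math.sin(d * n) for n, aa in enumerate(seq))
    c = sum(scale.get(aa, 0.0) * math.cos(d * n) for n, aa in enumerate(seq))
    return math.sqrt(s * s + c * c) / len(seq)


class TestNetCharge:
    def test_glycine_decamer_is_termini_only(self):
        expected = brute_charge("G" * 10)
        assert net_charge("G" * 10) == pytest.approx(expected, abs=1e-12)

    def test_appending_lysine_adds_closed_form_increment(self, rng):
        inc = 1.0 / (1.0 + 10 ** (7.0 - DAWSON_PKA["K"]))
        for _ in range(5):
            seq = random_sequence(rng, int(rng.integers(20, 80)))
            assert net_charge(seq + "K") - net_charge(seq) == pytest.approx(inc, abs=1e-12)

    def test_low_ph_limit_fully_protonated(self):
        seq = "GKKRHMLNGS"  # no acidic side chains
        cfg = PhyschemConfig(ph=0.001)
        expected = 1 + seq.count("K") + seq.count("R") + seq.count("H")
        assert net_charge(seq, cfg) == pytest.approx(expected, abs=1e-3)

    def test_strictly_decreasing_in_ph(self, rng):
        seq = random_sequence(rng, 60)
        charges = [net_charge(seq, PhyschemConfig(ph=p)) for p in np.linspace(2, 12, 21)]
        assert all(a > b for a, b in zip(charges, charges[1:]))

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(100):
            seq = random_sequence(rng, int(rng.integers(10, 200)))
            assert net_charge(seq) == pytest.approx(brute_charge(seq), abs=1e-9)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            net_charge("")

    def test_x_is_non_ionizable(self):
        assert net_charge("GXG") == pytest.approx(net_charge("GGG"))


class TestNcpr:
    def test_ncpr_times_length_is_net_charge(self, rng):
        for _ in range(10):
            seq = random_sequence(rng, int(rng.integers(11, 90)))
            assert ncpr(seq) * len(seq) == pytest.approx(net_charge(seq), abs=1e-12)

    def test_doubling_changes_only_termini_share(self, rng):
        seq = random_sequence(rng, 40)
        # side-chain contributions scale exactly; termini are counted once
        delta = net_charge(seq + seq) - 2 * net_charge(seq)
        nter = 1.0 / (1.0 + 10 ** (7.0 - DAWSON_PKA["nTer"]))
        cter = -1.0 / (1.0 + 10 ** (DAWSON_PKA["cTer"] - 7.0))
        assert delta == pytest.approx(-(nter + cter), abs=1e-12)


class TestGravyAndAliphatic:
    @pytest.mark.parametrize("seq, expected", [("IIII", 4.5), ("RRRR", -4.5), ("IR", 0.0)])
    def test_gravy_known_values(self, seq, expected):
        assert gravy(seq) == pytest.approx(expected)

    @pytest.mark.parametrize("seq, expected", [("AAAA", 100.0), ("VVVV", 290.0), ("GGGG", 0.0)])
    def test_aliphatic_known_values(self, seq, expected):
        assert aliphatic_index(seq) == pytest.approx(expected)

    def test_permutation_and_reversal_invariance(self, rng):
        seq = random_sequence(rng, 50)
        perm = "".join(rng.permutation(list(seq)))
        assert gravy(seq) == pytest.approx(gravy(perm))
        assert gravy(seq) == pytest.approx(gravy(seq[::-1]))
        assert aliphatic_index(seq) == pytest.approx(aliphatic_index(perm))

    def test_x_excluded_from_denominators(self):
        assert gravy("IXI") == pytest.approx(4.5)
        assert aliphatic_index("AX") == pytest.approx(100.0)
        with pytest.raises(ValueError):
            gravy("XXX")


class TestHydrophobicMoment:
    def test_single_residue(self):
        assert hydrophobic_moment("I") == pytest.approx(4.5)

    def test_all_zero_scale_gives_zero(self):
        cfg = PhyschemConfig(hydrophobicity_scale={aa: 0.0 for aa in AA})
        assert hydrophobic_moment("KLLKLLLKLLK", cfg) == 0.0

    def test_amphipathic_window_matches_brute_force(self):
        seq = "KLLKLLLKLLK"
        assert hydrophobic_moment(seq) == pytest.approx(brute_moment(seq), abs=1e-12)

    def test_order_sensitivity(self):
        # amphipathic arrangement vs segregated arrangement of same residues
        assert hydrophobic_moment("KLLKLLLKLLK") != pytest.approx(
            hydrophobic_moment("KKKKLLLLLLL")
        )

    def test_average_over_windows(self, rng):
        eleven = random_sequence(rng, 11)
        assert avg_hydrophobic_moment(eleven) == pytest.approx(
            hydrophobic_moment(eleven)
        )
        twelve = random_sequence(rng, 12)
        expected = 0.5 * (brute_moment(twelve[:11]) + brute_moment(twelve[1:]))
        assert avg_hydrophobic_moment(twelve) == pytest.approx(expected, abs=1e-12)
        short = random_sequence(rng, 5)
        assert avg_hydrophobic_moment(short) == pytest.approx(brute_moment(short))

    def test_oracle_equivalence_on_100_random_sequences(self, rng):
        for _ in range(100):
            seq = random_sequence(rng, int(rng.integers(5, 60)))
            windows = (
                [seq] if len(seq) <= 11 else [seq[i : i + 11] for i in range(len(seq) - 10)]
            )
            expected = float(np.mean([brute_moment(w) for w in windows]))
            assert avg_hydrophobic_moment(seq) == pytest.approx(expected, abs=1e-9)


class TestQuartiles:
    def test_l8_gravy_is_four_dimer_means(self):
        seq = "IVLFKRDE"
        vals = quartile_values(seq, "gravy")
        expected = [gravy(seq[i : i + 2]) for i in range(0, 8, 2)]
        assert vals == pytest.approx(expected)

    def test_l10_remainder_goes_last(self):
        frags = quartile_split("ACDEFGHIKL")
        assert [len(f) for f in frags] == [2, 2, 2, 4]

    def test_homopolymer_equal_gravy(self):
        assert quartile_values("L" * 40, "gravy") == pytest.approx([3.8] * 4)

    def test_fragment_lengths_sum_to_length(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, int(rng.integers(4, 200)))
            assert sum(len(f) for f in quartile_split(seq)) == len(seq)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            quartile_values("ACD", "gravy")

    def test_internal_fragments_drop_terminal_charges(self):
        vals = quartile_values("G" * 40, "net_charge")
        nter = 1.0 / (1.0 + 10 ** (7.0 - DAWSON_PKA["nTer"]))
        cter = -1.0 / (1.0 + 10 ** (DAWSON_PKA["cTer"] - 7.0))
        assert vals[0] == pytest.approx(nter)
        assert vals[1] == pytest.approx(0.0)
        assert vals[2] == pytest.approx(0.0)
        assert vals[3] == pytest.approx(cter)


class TestWindowProfile:
    def test_single_window_when_length_equals_window(self):
        prof = window_profile("A" * 11, "gravy")
        assert len(prof.values) == 1
        assert prof.normalized_positions[0] == pytest.approx(6 / 11)

    def test_window_count(self):
        prof = window_profile("A" * 20, "gravy")
        assert len(prof.values) == 20 - 11 + 1

    def test_charge_profile_peaks_on_planted_cterminal_patch(self):
        ds = simulate.generate_dataset(
            simulate.GeneratorConfig.q4_patch_only(seed=21, n_per_class=20)
        )
        truth = ds.truth.set_index("protein_id")
        overlaps, checked = 0, 0
        for rec in ds.records:
            row = truth.loc[rec.id]
            if not row.has_patch:
                continue
            prof = window_profile(rec.sequence, "net_charge", protein_id=rec.id)
            peak = prof.centers[int(np.argmax(prof.values))]
            checked += 1
            overlaps += row.patch_start - 11 <= peak <= row.patch_end + 11
        # random basic-residue clusters can occasionally out-peak the patch,
        # so recovery is a population property, not a per-record certainty
        assert checked >= 15
        assert overlaps / checked >= 0.8


class TestAverageTendency:
    def test_identical_profiles_resample_to_themselves(self):
        prof = window_profile("A" * 30, "gravy", protein_id="p")
        out = average_tendency({"L": [prof, prof]}, n_bins=10)
        assert np.allclose(out["mean"], 1.8)

    def test_two_constant_labels_stay_flat(self):
        p1 = window_profile("A" * 30, "gravy", protein_id="a")  # KD(A) = 1.8
        p2 = window_profile("G" * 30, "gravy", protein_id="g")  # KD(G) = -0.4
        out = average_tendency({"x": [p1], "y": [p2]}, n_bins=5)
        assert set(out.loc[out["label"] == "x", "mean"].round(6)) == {1.8}
        assert set(out.loc[out["label"] == "y", "mean"].round(6)) == {-0.4}

    def test_gneg_charge_tendency_exceeds_gpos_in_final_bins(self, default_dataset):
        truth = dict(zip(default_dataset.truth.protein_id, default_dataset.truth.gram))
        pairs = [
            (truth[r.id], window_profile(r.sequence, "net_charge", protein_id=r.id))
            for r in default_dataset.records[:200] + default_dataset.records[-200:]
        ]
        out = average_tendency(pairs, n_bins=10)
        last = out[out["bin"] == 9].set_index("label")["mean"]
        assert last["G-"] > last["G+"]


class TestFeatureTable:
    def test_row_consistency(self, rng):
        rec = make_record("A", random_sequence(rng, 120))
        hits = [make_hit("A", "Amidase_2", 5, 100),
                make_hit("A", "CW_binding_1", 101, 110),
                make_hit("A", "CW_binding_1", 111, 119)]
        df = build_feature_table([rec], hits)
        row = df.iloc[0]
        assert row["ncpr"] == pytest.approx(row["net_charge"] / rec.length)
        assert row["n_pf_hits"] == 3
        assert row["length"] == 120

    def test_insignificant_hits_not_counted(self, rng):
        rec = make_record("A", random_sequence(rng, 120))
        hits = [make_hit("A", "Amidase_2", 5, 100, e=50.0)]
        df = build_feature_table([rec], hits)
        assert df.iloc[0]["n_pf_hits"] == 0

    def test_synthetic_medians_near_design_targets(self, default_features, default_dataset):
        truth = default_dataset.truth.set_index("protein_id")
        df = default_features.join(truth["gram"].rename("true_gram"), on="protein_id")
        med = df.groupby("true_gram")["length"].median()
        assert abs(med["G+"] - 317) / 317 < 0.10
        assert abs(med["G-"] - 164) / 164 < 0.10
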