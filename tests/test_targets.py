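"""Seed-site detection, duplex scoring, and target-map prediction."""

import numpy as np
import pytest
from Bio.Seq import Seq

from cernet.simulate import generate_mirna_set, generate_transcripts
from cernet.targets import (
    SITE_TYPE_RANK,
    SITE_TYPES,
    MiRNA,
    ScoringWeights,
    canonical_site_sequence,
    duplex_score,
    find_seed_sites,
    normalize_rna,
    predict_targets,
    reverse_complement,
)

LET7A = MiRNA("let-7a", "UGAGGUAGUAGGUUGUAUAGUU")


class TestNormalization:
    def test_t_and_case_normalized(self):
        assert normalize_rna("acgt") == "ACGU"

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError):
            normalize_rna("ACGN")

    def test_mirna_length_bounds(self):
        with pytest.raises(ValueError):
            MiRNA("short", "ACGUACGUACGU")


class TestSeedSites:
    def test_known_8mer_site(self):
        sites = find_seed_sites(LET7A, "tx", "AAACUACCUCAAAA")
        assert len(sites) == 1
        s = sites[0]
        assert (s.site_type, s.site_sequence, s.start, s.end) == ("8mer", "CUACCUCA", 3, 11)

    def test_no_complement_no_sites(self):
        m = MiRNA("m", "UAAAAAAGUAGGUUGUAUAGUU")  # seed6 AAAAAA
        assert find_seed_sites(m, "tx", "GGGGGGGGGG") == []

    def test_short_transcript_empty(self):
        assert find_seed_sites(LET7A, "tx", "ACGUA") == []

    @pytest.mark.parametrize("site_type", SITE_TYPES)
    def test_each_class_detected_as_itself(self, site_type):
        site = canonical_site_sequence(LET7A, site_type)
        # G-padding cannot add an upstream m8 match or downstream A1
        seq = "GGGG" + site + "GGGG"
        sites = find_seed_sites(LET7A, "tx", seq)
        assert [s.site_type for s in sites] == [site_type]
        assert sites[0].site_sequence == site

    def test_round_trip_site_sequence(self):
        rng = np.random.default_rng(0)
        mirnas = generate_mirna_set(10, rng_seed=0)
        for mirna in mirnas:
            seq = "".join(rng.choice(list("ACGU"), size=300))
            for s in find_seed_sites(mirna, "tx", seq):
                assert seq[s.start : s.end] == s.site_sequence

    def test_classification_matches_brute_force_oracle(self):
        """Independent oracle: enumerate windows, test revcomp identity per class."""
        rng = np.random.default_rng(42)
        n_checked = 0
        for trial in range(1000):
            mirna = generate_mirna_set(1, rng_seed=trial)[0]
            length = int(rng.integers(6, 200))
            seq = "".join(rng.choice(list("ACGU"), size=length))
            if rng.random() < 0.5 and length >= 12:  # spike in a real site
                pos = int(rng.integers(0, length - 8))
                st = str(rng.choice(SITE_TYPES))
                site = canonical_site_sequence(mirna, st)
                seq = seq[:pos] + site + seq[pos + len(site):]
            # oracle via Biopython reverse complement on the DNA alphabet
            seed6_rc = str(Seq(mirna.seed6.replace("U", "T")).reverse_complement()).replace("T", "U")
            seed7_rc = str(Seq(mirna.seed7.replace("U", "T")).reverse_complement()).replace("T", "U")
            expected = []
            for i in range(len(seq) - 5):
                if seq[i : i + 6] != seed6_rc:
                    continue
                m8 = i >= 1 and seq[i - 1 : i + 6] == seed7_rc
                a1 = i + 6 < len(seq) and seq[i + 6] == "A"
                if m8 and a1:
                    expected.append(("8mer", i - 1, i + 7))
                elif m8:
                    expected.append(("7mer-m8", i - 1, i + 6))
                elif a1:
                    expected.append(("7mer-A1", i, i + 7))
                else:
                    expected.append(("6mer", i, i + 6))
            got = [(s.site_type, s.start, s.end) for s in find_seed_sites(mirna, "t", seq)]
            assert got == expected
            n_checked += len(expected)
        assert n_checked > 100  # the oracle actually exercised real sites


class TestDuplexScore:
    def test_perfect_seed_window_maximum(self):
        window = reverse_complement(LET7A.sequence[:8])
        # 8 matches at +5, positions 2-8 doubled: 5*8 + 5*7
        assert duplex_score(LET7A, window) == 75.0

    def test_all_mismatch_window_negative(self):
        m = MiRNA("allg", "G" * 22)
        assert duplex_score(m, "G" * 8) < 0  # G:G is a mismatch, no wobble

    def test_single_wobble_at_position_5(self):
        window = list(reverse_complement(LET7A.sequence[:8]))
        assert LET7A.sequence[4] == "G"
        window[3] = "U"  # transcript base opposite miRNA position 5 -> G:U
        # doubled seed position: (match - wobble) * 2 = (5-1)*2
        assert duplex_score(LET7A, "".join(window)) == 75.0 - 8.0

    def test_flank_extension_never_lowers_score(self):
        window = reverse_complement(LET7A.sequence[:8])
        assert duplex_score(LET7A, "GGGG" + window) >= duplex_score(LET7A, window)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            duplex_score(LET7A, "")

    def test_custom_weights(self):
        window = reverse_complement(LET7A.sequence[:8])
        w = ScoringWeights(match=1.0, seed_multiplier=1.0)
        assert duplex_score(LET7A, window, weights=w) == 8.0


class TestPredictTargets:
    def test_implanted_sites_fully_recovered(self):
        mirnas = generate_mirna_set(20, rng_seed=13)
        rng = np.random.default_rng(13)
        tids = [f"tx{i:03d}" for i in range(50)]
        plan = []
        for tid in tids:
            chosen = rng.choice(20, size=3, replace=False)
            for slot, mi in enumerate(chosen):
                plan.append((mirnas[mi].id, tid, 50 + 150 * slot, "8mer"))
        seqs, gt = generate_transcripts(mirnas, tids, plan, length=600, rng_seed=13)
        tm = predict_targets(mirnas, seqs)
        implanted = {(tid, mid) for mid, tid, _s, _t in gt.implant_plan}
        predicted = {
            (tid, mid) for tid, mids in tm.targets.items() for mid in mids
        }
        assert implanted <= predicted  # sensitivity 1.0

    def test_chance_6mer_rate_matches_uniform_model(self):
        """Mean chance site count per 4096-nt transcript is ~L/4^6."""
        mirna = generate_mirna_set(1, rng_seed=99)[0]
        counts = []
        for rep in range(200):
            seqs, _ = generate_transcripts(
                [mirna], ["tx"], [], length=4096, rng_seed=1000 + rep
            )
            counts.append(len(find_seed_sites(mirna, "tx", seqs["tx"])))
        assert 0.7 <= np.mean(counts) <= 1.3

    def test_min_site_type_excludes_weaker_classes(self):
        site = canonical_site_sequence(LET7A, "6mer")
        seqs = {"tx": "GGGG" + site + "GGGG"}
        tm6 = predict_targets([LET7A], seqs, min_site_type="6mer", min_duplex_score=0)
        tm8 = predict_targets([LET7A], seqs, min_site_type="8mer", min_duplex_score=0)
        assert "tx" in tm6.targets and "tx" not in tm8.targets

    def test_threshold_monotonicity(self):
        mirnas = generate_mirna_set(5, rng_seed=21)
        seqs, _ = generate_transcripts(mirnas, [f"t{i}" for i in range(10)], [],
                                       length=2000, rng_seed=21)
        pairs = {}
        for st in SITE_TYPES:
            tm = predict_targets(mirnas, seqs, min_site_type=st, min_duplex_score=0)
            pairs[st] = {(t, m) for t, ms in tm.targets.items() for m in ms}
        for weaker, stronger in zip(SITE_TYPES, SITE_TYPES[1:]):
            assert pairs[stronger] <= pairs[weaker]
        lo = predict_targets(mirnas, seqs, min_site_type="6mer", min_duplex_score=0)
        hi = predict_targets(mirnas, seqs, min_site_type="6mer", min_duplex_score=60)
        hi_pairs = {(t, m) for t, ms in hi.targets.items() for m in ms}
        lo_pairs = {(t, m) for t, ms in lo.targets.items() for m in ms}
        assert hi_pairs <= lo_pairs

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            predict_targets([], {"t": "ACGUACGU"})
        with pytest.raises(ValueError):
            predict_targets([LET7A], {})

    def test_sites_sorted_by_start(self):
        site = canonical_site_sequence(LET7A, "8mer")
        seqs = {"tx": "GG" + site + "GGGG" + site + "GG"}
        tm = predict_targets([LET7A], seqs)
        starts = [s.start for s in tm.sites[("tx", "let-7a")]]
        assert starts == sorted(starts)
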