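"""Seed-site patterns and scanning, ARE detection, candidate annotation."""

import numpy as np
import pandas as pd
import pytest

from mirmet.motifs import (
    annotate_candidates,
    ares_to_frame,
    find_are_motifs,
    find_seed_sites,
    read_fasta,
    reverse_complement,
    seed_patterns,
)
from mirmet.synthetic import PlantedARE, PlantedSite, gen_sequences

from oracles import naive_are_runs, naive_seed_sites

MIRNA = "UAGGUAGUAACGGC"


class TestSeedPatterns:
    def test_hand_derived_patterns(self):
        pats = seed_patterns(MIRNA)
        # seed nt 2-8 = AGGUAGU; its reverse complement read 5'->3' is ACUACCU
        assert pats["7mer-m8"] == "ACUACCU"
        assert pats["8mer"] == "ACUACCUA"
        assert pats["6mer"] == "CUACCU"
        assert pats["7mer-A1"] == "CUACCUA"

    def test_patterns_nest(self):
        pats = seed_patterns(MIRNA)
        assert pats["8mer"].startswith(pats["7mer-m8"]) and pats["8mer"].endswith("A")
        assert pats["7mer-A1"] == pats["6mer"] + "A"
        assert pats["7mer-m8"].endswith(pats["6mer"])

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            seed_patterns("UAGGUAG")

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            seed_patterns("UAGGUXGUAACGGC")

    def test_reverse_complement_involution(self):
        rng = np.random.default_rng(50)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGU"), size=12))
            assert reverse_complement(reverse_complement(seq)) == seq


class TestFindSeedSites:
    def test_single_8mer_reported_most_specific(self):
        sites = find_seed_sites(MIRNA, "GG" + "ACUACCUA" + "GG")
        assert len(sites) == 1
        s = sites[0]
        assert s.site_type == "8mer" and s.start == 3 and s.end == 10

    def test_no_occurrence_empty(self):
        assert find_seed_sites(MIRNA, "GGGGGGGGGGGG") == []

    def test_empty_utr_rejected(self):
        with pytest.raises(ValueError):
            find_seed_sites(MIRNA, "")

    def test_dna_utr_converted_with_warning(self):
        with pytest.warns(UserWarning, match="converting T to U"):
            sites = find_seed_sites(MIRNA, "GGACTACCTAGG")
        assert sites[0].site_type == "8mer"

    def test_site_lengths_match_types(self):
        utrs, _ = gen_sequences(20, MIRNA, seed=51, utr_length=300)
        expected = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}
        for seq in utrs.values():
            for s in find_seed_sites(MIRNA, seq):
                assert s.end - s.start + 1 == expected[s.site_type]

    def test_matches_naive_substring_oracle_on_random_utrs(self):
        rng = np.random.default_rng(52)
        # AU-rich alphabet makes chance seed matches frequent
        for _ in range(1000):
            utr = "".join(rng.choice(list("ACGUAU"), size=80))
            got = {(s.site_type, s.start) for s in find_seed_sites(MIRNA, utr)}
            assert got == naive_seed_sites(MIRNA, utr)


class TestFindAreMotifs:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GCAUUUAGC", [(3, 1, 1)]),
            ("AUUUAUUUAUUUA", [(1, 3, 3)]),
            ("ACGUACGU", []),
            # two separate runs
            ("AUUUAGGAUUUAUUUA", [(1, 1, 1), (8, 2, 2)]),
        ],
    )
    def test_overlapping_pentamer_runs(self, seq, expected):
        got = [(m.start, m.n_overlapping_pentamers, m.cluster_class) for m in find_are_motifs(seq)]
        assert got == expected

    def test_cluster_class_capped_at_five(self):
        seq = "AUUUA" + "UUUA" * 7  # 8 pentamers
        (m,) = find_are_motifs(seq)
        assert m.n_overlapping_pentamers == 8 and m.cluster_class == 5

    def test_positions_strictly_increasing_nonoverlapping(self):
        rng = np.random.default_rng(53)
        for _ in range(300):
            seq = "".join(rng.choice(list("AU"), size=120))
            matches = find_are_motifs(seq)
            last_end = 0
            for m in matches:
                assert m.start > last_end
                last_end = m.start + 5 + 4 * (m.n_overlapping_pentamers - 1) - 1

    def test_matches_naive_chain_oracle_on_random_sequences(self):
        rng = np.random.default_rng(54)
        for _ in range(1000):
            seq = "".join(rng.choice(list("AUUA"), size=60))
            got = [(m.start, m.n_overlapping_pentamers) for m in find_are_motifs(seq)]
            assert got == naive_are_runs(seq)


class TestAnnotateCandidates:
    def test_planted_motifs_set_both_flags(self):
        utrs, truth = gen_sequences(
            3,
            MIRNA,
            planted_sites=[PlantedSite(0, "7mer-m8", start=30)],
            planted_are=[PlantedARE(0, n_pentamers=1, start=80)],
            seed=55,
            utr_length=150,
        )
        # strip chance motifs from the control UTR so its flags are known
        uids = list(utrs)
        utrs[uids[1]] = "GC" * 75
        candidates = pd.DataFrame({"gene_id": [uids[0], uids[1], "no-utr-gene"]})
        out = annotate_candidates(candidates, utrs, MIRNA).set_index("gene_id")
        assert bool(out.loc[uids[0], "seed_site"]) and bool(out.loc[uids[0], "has_are"])
        assert not bool(out.loc[uids[1], "seed_site"]) and not bool(out.loc[uids[1], "has_are"])
        assert out.loc["no-utr-gene", "annotation_status"] == "missing_utr"
        assert pd.isna(out.loc["no-utr-gene", "seed_site"])

    def test_duplicate_candidate_gene_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            annotate_candidates(pd.DataFrame({"gene_id": ["g", "g"]}), {"g": "ACGU" * 10}, MIRNA)

    def test_fasta_round_trip(self, tmp_path):
        from mirmet.synthetic import write_fasta

        utrs, _ = gen_sequences(4, MIRNA, seed=56, utr_length=50)
        path = tmp_path / "utrs.fa"
        write_fasta(utrs, path)
        assert read_fasta(path) == utrs

    def test_duplicate_fasta_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.fa"
        path.write_text(">a\nACGU\n>a\nACGU\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(path)


class TestPlantedSequenceTruth:
    def test_scanner_recovers_planted_sites_exactly(self):
        planted = [
            PlantedSite(0, "8mer", start=12),
            PlantedSite(1, "7mer-m8", start=40),
            PlantedSite(2, "7mer-A1", start=70),
            PlantedSite(3, "6mer", start=100),
        ]
        utrs, truth = gen_sequences(4, MIRNA, planted_sites=planted, seed=57, utr_length=150)
        for _, row in truth.iterrows():
            sites = find_seed_sites(MIRNA, utrs[row["utr_id"]])
            assert any(s.site_type == row["site_type"] and s.start == row["start"] for s in sites)

    def test_scanner_recovers_planted_ares(self):
        utrs, truth = gen_sequences(
            2,
            MIRNA,
            planted_are=[PlantedARE(0, n_pentamers=2, start=10), PlantedARE(1, n_pentamers=4, start=30)],
            seed=58,
            utr_length=100,
        )
        for _, row in truth.iterrows():
            matches = find_are_motifs(utrs[row["utr_id"]])
            frame = ares_to_frame(matches)
            hit = frame[(frame["start"] == row["start"])]
            assert len(hit) == 1
            assert hit.iloc[0]["n_overlapping_pentamers"] == row["n_pentamers"]
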