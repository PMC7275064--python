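"""Genetic-code classification and amino-acid-pair statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from premotif import protein_code as pc
from premotif.mutability import ERMTable, ScoreTable, decode_kmer, encode_kmer


class TestClassifyMutation:
    @pytest.mark.parametrize(
        "codon,pos,alt,expected",
        [
            ("GAA", 1, "T", "stop_gain"),  # TAA
            ("GAA", 3, "G", "synonymous"),  # Glu
            ("GAA", 2, "T", "missense"),  # Glu -> Val
            ("TAC", 3, "A", "stop_gain"),  # TAA, even though the AA changes too
        ],
    )
    def test_examples(self, codon, pos, alt, expected):
        assert pc.classify_mutation(codon, pos, alt) == expected

    def test_stop_codon_input_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            pc.classify_mutation("TAA", 1, "C")

    def test_noop_change_rejected(self):
        with pytest.raises(ValueError):
            pc.classify_mutation("GAA", 1, "G")

    def test_partition_matches_biopython_enumeration(self):
        """All 9 x 61 substitutions of sense codons, classified through
        Bio.Seq translation as the independent oracle."""
        counts = {"synonymous": 0, "missense": 0, "stop_gain": 0}
        for codon in pc.SENSE_CODONS:
            aa = str(Seq(codon).translate())
            for pos in (1, 2, 3):
                for alt in "ACGT":
                    if codon[pos - 1] == alt:
                        continue
                    mutated = codon[: pos - 1] + alt + codon[pos:]
                    expected = (
                        "stop_gain"
                        if str(Seq(mutated).translate()) == "*"
                        else "synonymous"
                        if str(Seq(mutated).translate()) == aa
                        else "missense"
                    )
                    got = pc.classify_mutation(codon, pos, alt)
                    assert got == expected
                    counts[got] += 1
        assert sum(counts.values()) == 9 * 61
        assert counts["stop_gain"] == 23  # single-nt routes into TAA/TAG/TGA


class TestHexamerToAAPair:
    @pytest.mark.parametrize(
        "seq,offset,expected",
        [
            ("GAAGAA", 0, ("E", "E")),
            ("ATGGAAGAA", 1, ("M", "E")),  # overlaps (2, 3, 1)
            ("ATGGAAGAA", 2, ("E", "E")),  # overlaps (1, 3, 2)
        ],
    )
    def test_examples(self, seq, offset, expected):
        assert pc.hexamer_to_aa_pair(seq, offset) == expected

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            pc.hexamer_to_aa_pair("GAAGAA", 1)


class TestAAPairMeanEI:
    def test_single_occurrence(self):
        ei = ScoreTable.from_dict({"GAAGAA": 0.42})
        df = pc.aa_pair_mean_ei(["GAAGAA"], ei)
        assert len(df) == 1
        assert df.iloc[0]["mean_ei"] == pytest.approx(0.42)

    def test_occurrence_weighted_mean(self):
        """Counts 3 and 1 at scores 0.2 and 0.6 give (3*0.2 + 0.6)/4 = 0.3."""
        ei = ScoreTable.from_dict({"GAAGAA": 0.2, "GAGGAG": 0.6})
        seqs = ["GAAGAA"] * 3 + ["GAGGAG"]
        df = pc.aa_pair_mean_ei(seqs, ei)
        row = df[(df["aa1"] == "E") & (df["aa2"] == "E")].iloc[0]
        assert row["mean_ei"] == pytest.approx(0.3)
        assert row["n"] == 4

    def test_uniform_scores_give_constant(self):
        ei = ScoreTable(np.full(4096, 0.7))
        rng = np.random.default_rng(8)
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 90)) for _ in range(10)]
        df = pc.aa_pair_mean_ei(seqs, ei)
        assert np.allclose(df["mean_ei"], 0.7)

    def test_absent_scores_skipped_not_zeroed(self):
        ei = ScoreTable.from_dict({"GAAGAA": 0.2})
        df = pc.aa_pair_mean_ei(["GAAGAATTTTTT"], ei)
        # only the offset-0 hexamer is scored; unscored pairs stay absent
        assert set(zip(df["aa1"], df["aa2"])) == {("E", "E")}
        assert df.attrs["skipped_occurrences"] == 6


class TestAAPairEnrichment:
    def test_single_residue_proteome(self):
        df = pc.aa_pair_enrichment(["EEEE"])
        row = df[(df["aa1"] == "E") & (df["aa2"] == "E")].iloc[0]
        assert row["enrichment"] == pytest.approx(1.0)

    def test_alternating_proteome(self):
        """EDEDED: (E,D) observed 3/5 vs expected 1/4 -> ratio 2.4."""
        df = pc.aa_pair_enrichment(["EDEDED"])
        row = df[(df["aa1"] == "E") & (df["aa2"] == "D")].iloc[0]
        assert row["enrichment"] == pytest.approx(2.4)

    def test_random_proteome_ratios_near_one(self):
        rng = np.random.default_rng(0)
        aas = np.array(list(pc.AMINO_ACIDS))
        proteome = ["".join(rng.choice(aas, size=250_000)) for _ in range(4)]
        df = pc.aa_pair_enrichment(proteome)
        assert np.abs(df["enrichment"] - 1).max() < 0.2
        assert np.abs(df["enrichment"] - 1).mean() < 0.05

    def test_short_protein_rejected(self):
        with pytest.raises(ValueError):
            pc.aa_pair_enrichment(["E"])


class TestMutationDeltaEI:
    def test_zero_when_scores_unchanged(self):
        ei = ScoreTable(np.full(4096, 0.5))
        df = pc.mutation_delta_ei(["AAAGAAGAAAAA"], ei)
        assert np.allclose(df["mean_delta_ei"], 0.0)

    def test_hand_computed_two_hexamer_rule(self):
        """Score = A-content of the hexamer; delta-EI follows by arithmetic.

        A mutation changing base b at dicodon position j alters the
        A-content of both covering hexamers identically, so the mean
        delta-EI is (dA_mut - dA_ref)/6 per mutation.
        """
        scores = np.array([decode_kmer(i, 6).count("A") / 6 for i in range(4096)])
        ei = ScoreTable(scores)
        occ = "AAAGAAGAAAAA"  # dicodon GAA GAA with A-rich context
        df = pc.mutation_delta_ei([occ], ei).set_index(["class"])
        # expected: mean over the 18 mutations of ((A after) - (A before))/6
        expected = {"synonymous": [], "missense": [], "stop_gain": []}
        for j in range(6):
            a = j + 3
            ref = occ[a]
            codon, cpos = ("GAA", j + 1) if j < 3 else ("GAA", j - 2)
            for alt in "ACGT":
                if alt == ref:
                    continue
                klass = pc.classify_mutation(codon, cpos, alt)
                d = ((alt == "A") - (ref == "A")) / 6
                expected[klass].append(d)
        for klass, vals in expected.items():
            if vals:
                assert df.loc[klass, "mean_delta_ei"] == pytest.approx(np.mean(vals))

    def test_missing_scores_skip_occurrence_with_count(self):
        ei = ScoreTable.from_dict({"GAAGAA": 0.2})
        df = pc.mutation_delta_ei(["AAAGAAGAAAAA"], ei)
        assert df.empty
        assert df.attrs["skipped_occurrences"] == 1


class TestStopGainFraction:
    def test_gargar_uniform_is_one_ninth(self):
        gargar = ["GAAGAA", "GAAGAG", "GAGGAA", "GAGGAG"]
        assert pc.stop_gain_fraction(hexamers=gargar) == pytest.approx(1 / 9)

    def test_phe_phe_dicodon_has_no_stop_route(self):
        assert pc.stop_gain_fraction(hexamers=["TTTTTT"]) == 0.0

    def test_pair_enumerates_all_encodings(self):
        # EE is encoded only by the GARGAR set, so the values agree
        assert pc.stop_gain_fraction(("E", "E")) == pytest.approx(1 / 9)

    def test_erm_context_uniform_table_matches_uniform_weighting(self, uniform_erm):
        occ = ["AAAGAAGAAAAA", "TTTGAGGAGTTT"]
        got = pc.stop_gain_fraction(
            ("E", "E"), weighting="erm_context", erm=uniform_erm, occurrences=occ
        )
        assert got == pytest.approx(1 / 9)

    def test_erm_context_boosted_gt_raises_fraction(self):
        """Boosting G>T rates (the stop-creating route in GAR) raises the
        weighted fraction above the uniform 1/9."""
        rates = ERMTable.uniform(1.0).rates.copy()
        mid = ERMTable.middle_bases()
        rates[(mid == 2), 3] = 10.0  # all G>T changes hot
        erm = ERMTable(rates)
        got = pc.stop_gain_fraction(
            ("E", "E"), weighting="erm_context", erm=erm, occurrences=["AAAGAAGAAAAA"]
        )
        assert got > 1 / 9

    @given(st.sampled_from(pc.SENSE_CODONS), st.sampled_from(pc.SENSE_CODONS))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_uniform_matches_exhaustive_oracle(self, c1, c2):
        """Independent oracle: translate every mutated dicodon directly."""
        stops = total = 0
        hexamer = c1 + c2
        for j in range(6):
            for alt in "ACGT":
                if alt == hexamer[j]:
                    continue
                mutated = hexamer[:j] + alt + hexamer[j + 1 :]
                total += 1
                stops += "*" in str(Seq(mutated).translate())
        pair = (pc.GENETIC_CODE[c1], pc.GENETIC_CODE[c2])
        got = pc.stop_gain_fraction(hexamers=[hexamer])
        assert got == pytest.approx(stops / total)
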