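"""Splice-window profiles, k-mer spectra and enrichment correlations."""

import numpy as np
import pytest

from premotif import genome_enrichment as ge
from premotif.io_core import GeneModel
from premotif.mutability import ERMTable, ScoreTable, decode_kmer, encode_kmer, site_rate


def _toy_gene(seq_len=200, exon=(60, 140)):
    rng = np.random.default_rng(12)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=seq_len))
    gene = GeneModel("tx1", "chr1", "+", exons=[exon])
    return {"chr1": seq}, [gene]


class TestSpliceWindows:
    def test_counts_and_sides(self):
        seqs, genes = _toy_gene()
        windows = ge.extract_splice_windows(seqs, genes, intron_span=30, exon_span=20)
        assert len(windows) == 2
        assert {w.side for w in windows} == {"acceptor", "donor"}

    def test_isoform_duplicate_sites_deduplicated(self):
        seqs, genes = _toy_gene()
        genes.append(GeneModel("tx2", "chr1", "+", exons=[(60, 140)]))
        windows = ge.extract_splice_windows(seqs, genes, intron_span=30, exon_span=20)
        assert len(windows) == 2

    def test_minus_strand_window_is_reverse_complement(self):
        seqs, _ = _toy_gene()
        minus = [GeneModel("tx1", "chr1", "-", exons=[(60, 140)])]
        plus = [GeneModel("tx1", "chr1", "+", exons=[(60, 140)])]
        wm = {w.side: w for w in ge.extract_splice_windows(seqs, minus, intron_span=10, exon_span=10)}
        wp = {w.side: w for w in ge.extract_splice_windows(seqs, plus, intron_span=10, exon_span=10)}
        rc = str.maketrans("ACGT", "TGCA")
        # the minus-strand acceptor (at genomic exon end) mirrors the plus donor
        assert wm["acceptor"].seq == wp["donor"].seq.translate(rc)[::-1]


class TestPositionalMeanRate:
    def test_uniform_flat(self, uniform_erm):
        seqs, genes = _toy_gene()
        windows = ge.extract_splice_windows(seqs, genes, intron_span=30, exon_span=20)
        prof = ge.positional_mean_rate(windows, uniform_erm)
        assert np.allclose(prof["mean_rate"], 1.0)
        # full window span present on both sides
        acc = prof[prof["side"] == "acceptor"]
        assert acc["offset"].min() == -30 and acc["offset"].max() == 19

    def test_single_window_matches_direct_site_rates(self, synth_erm):
        """Hand-oracle: per-offset means equal direct heptamer lookups."""
        seqs, genes = _toy_gene()
        windows = ge.extract_splice_windows(seqs, genes, intron_span=10, exon_span=10)
        prof = ge.positional_mean_rate(windows, synth_erm)
        seq = seqs["chr1"]
        a, b = genes[0].exons[0]
        for _, row in prof[prof["side"] == "acceptor"].iterrows():
            genomic = a + int(row["offset"])
            assert row["mean_rate"] == pytest.approx(
                site_rate(seq, genomic, synth_erm, circular=False), rel=1e-12
            )
        for _, row in prof[prof["side"] == "donor"].iterrows():
            genomic = b + int(row["offset"])
            assert row["mean_rate"] == pytest.approx(
                site_rate(seq, genomic, synth_erm, circular=False), rel=1e-12
            )

    def test_empty_window_set_rejected(self, uniform_erm):
        with pytest.raises(ValueError):
            ge.positional_mean_rate([], uniform_erm)


class TestKmerFrequencies:
    def test_homopolymer(self):
        counts, total = ge.kmer_frequencies(["AAAAAAA"])
        assert total == 2
        assert counts[encode_kmer("AAAAAA")] == 2

    def test_sums_to_total(self):
        rng = np.random.default_rng(1)
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 50)) for _ in range(5)]
        counts, total = ge.kmer_frequencies(seqs)
        assert counts.sum() == total == 5 * 45

    def test_no_windows_span_record_boundaries(self):
        """Counting two records separately differs from their concatenation."""
        joined, _ = ge.kmer_frequencies(["AAAAAATTTTTT"])
        split, _ = ge.kmer_frequencies(["AAAAAA", "TTTTTT"])
        assert joined.sum() == 7 and split.sum() == 2
        assert joined[encode_kmer("AATTTT")] == 1
        assert split[encode_kmer("AATTTT")] == 0

    def test_all_too_short_rejected(self):
        with pytest.raises(ValueError):
            ge.kmer_frequencies(["ACGT", "AA"])


class TestExonIntronEnrichment:
    def test_identical_collections_zero(self):
        seqs = ["ACGTACGTACGTACGT", "GGGCCCAAATTT"]
        table = ge.exon_intron_enrichment(seqs, list(seqs))
        assert np.allclose(table.log2_enrichment, 0.0)

    def test_toy_direction(self):
        table = ge.exon_intron_enrichment(["GAAGAA" * 30], ["TTTTTT" * 30])
        enr = table.frame.set_index("hexamer")["log2_enrichment"]
        assert enr["GAAGAA"] > 2
        assert enr["TTTTTT"] < -2

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(3)
        a = ["".join("ACGT"[i] for i in rng.integers(0, 4, 400))]
        b = ["".join("ACGT"[i] for i in rng.integers(0, 4, 300))]
        fwd = ge.exon_intron_enrichment(a, b).log2_enrichment
        rev = ge.exon_intron_enrichment(b, a).log2_enrichment
        assert np.allclose(fwd, -rev, atol=1e-12)


class TestCorrelateScores:
    def _enrich_from(self, values):
        import pandas as pd

        return ge.EnrichmentTable(
            pd.DataFrame(
                {
                    "hexamer": [decode_kmer(i, 6) for i in range(4096)],
                    "f_exon": 0.0,
                    "f_intron": 0.0,
                    "log2_enrichment": values,
                }
            )
        )

    def test_perfect_correlations(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=4096)
        table = self._enrich_from(vals)
        assert ge.correlate_scores(table, ScoreTable(vals.copy())).r == pytest.approx(1.0)
        rep = ge.correlate_scores(table, ScoreTable(-vals))
        assert rep.r == pytest.approx(-1.0)
        assert rep.slope_sign == -1  # the intron-enriched (ISE) direction

    def test_cpg_exclusion_count_matches_brute_force(self):
        """Enumerate hexamers containing CG: 1185, leaving 2911."""
        n_cg = sum("CG" in decode_kmer(i, 6) for i in range(4096))
        assert n_cg == 1185
        assert ge.cpg_hexamer_mask().sum() == n_cg
        rng = np.random.default_rng(1)
        vals = rng.normal(size=4096)
        table = self._enrich_from(vals)
        rep = ge.correlate_scores(table, ScoreTable(rng.normal(size=4096)), exclude_cpg=True)
        assert rep.n == 4096 - 1185

    def test_planted_rho_recovered(self, hex_rates, synth_ei):
        """Scores generated at rho=0.7 against log mean rate are recovered."""
        z = np.log(hex_rates.mean_rate)
        table = self._enrich_from((z - z.mean()) / z.std())
        rep = ge.correlate_scores(table, synth_ei)
        assert rep.r == pytest.approx(0.7, abs=0.05)

    def test_degenerate_inputs_rejected(self):
        table = self._enrich_from(np.zeros(4096))
        with pytest.raises(ValueError, match="degenerate"):
            ge.correlate_scores(table, ScoreTable(np.ones(4096)))
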