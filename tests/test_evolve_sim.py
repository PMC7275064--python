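"""Simulator semantics: conservation, constraint, time accounting, caches."""

import numpy as np
import pytest

from premotif.evolve_sim import (
    DeadlockError,
    SimConfig,
    SimGenome,
    advance_genome,
    compute_site_rates,
    enrichment_ratio,
    exact_stationary,
    hexamer_counts,
    init_genome,
    pseudo_positional_profile,
    run,
    step,
    translate_codes,
)
from premotif.mutability import ERMTable, encode_kmer, seq_to_ints


class TestInitGenome:
    def test_seed_determinism(self, synth_erm):
        cfg = SimConfig(n_sequences=10, seq_length=99, t_max=1, seed=5)
        g1 = init_genome(cfg, synth_erm, np.random.default_rng(5))
        g2 = init_genome(cfg, synth_erm, np.random.default_rng(5))
        assert np.array_equal(g1.seqs, g2.seqs)

    def test_random_base_composition(self, synth_erm):
        cfg = SimConfig(n_sequences=200, seq_length=999, t_max=1, seed=1)
        g = init_genome(cfg, synth_erm, np.random.default_rng(1))
        freqs = np.bincount(g.seqs.ravel(), minlength=4) / g.seqs.size
        assert np.allclose(freqs, 0.25, atol=0.005)

    def test_from_fasta_internal_stop_rejected(self, synth_erm):
        cfg = SimConfig(
            n_sequences=1,
            seq_length=9,
            constraint="protein",
            t_max=1,
            init="from_fasta",
            init_sequences=["ATGTAAGAA"],
        )
        with pytest.raises(ValueError, match="stop"):
            init_genome(cfg, synth_erm, np.random.default_rng(0))

    def test_from_fasta_trims_and_stores_translation(self, synth_erm):
        cfg = SimConfig(
            n_sequences=1,
            seq_length=6,
            constraint="protein",
            t_max=1,
            init="from_fasta",
            init_sequences=["GAAGAAGAA"],
        )
        g = init_genome(cfg, synth_erm, np.random.default_rng(0))
        assert g.seqs.shape == (1, 6)
        assert g.translations() == ["EE"]


class TestStep:
    def test_changes_exactly_one_base(self, synth_erm):
        cfg = SimConfig(n_sequences=4, seq_length=30, t_max=1, seed=2)
        g = init_genome(cfg, synth_erm, np.random.default_rng(2))
        before = g.seqs.copy()
        s, p, old, new = step(g, np.random.default_rng(3))
        assert before[s, p] == old and g.seqs[s, p] == new and old != new
        diff = g.seqs != before
        assert diff.sum() == 1

    def test_incremental_cache_matches_full_recompute(self, synth_erm):
        cfg = SimConfig(n_sequences=4, seq_length=60, constraint="protein", t_max=1, seed=2)
        g = init_genome(cfg, synth_erm, np.random.default_rng(2))
        rng = np.random.default_rng(3)
        for _ in range(200):
            step(g, rng)
        ref = compute_site_rates(g.seqs, synth_erm)
        assert np.allclose(g.site_rates, ref, rtol=1e-9)
        assert np.allclose(g.row_totals, ref.sum(axis=1), rtol=1e-9)

    def test_kernel_cache_matches_full_recompute(self, synth_erm):
        cfg = SimConfig(n_sequences=6, seq_length=60, constraint="protein", t_max=1, seed=2)
        g = init_genome(cfg, synth_erm, np.random.default_rng(2))
        advance_genome(g, 3000, np.random.default_rng(4))
        ref = compute_site_rates(g.seqs, synth_erm)
        assert np.allclose(g.site_rates, ref, rtol=1e-9)

    def test_protein_constraint_preserves_translation(self, synth_erm):
        cfg = SimConfig(n_sequences=4, seq_length=60, constraint="protein", t_max=1, seed=2)
        g = init_genome(cfg, synth_erm, np.random.default_rng(2))
        ref_aa = g.ref_aa.copy()
        advance_genome(g, 2000, np.random.default_rng(5))
        assert np.array_equal(translate_codes(g.seqs), ref_aa)

    def test_deadlock_on_single_codon_amino_acids(self, synth_erm):
        """A genome of Met/Trp codons admits no synonymous non-stop change."""
        seqs = seq_to_ints("ATGTGGATG")[None, :].astype(np.int8)
        g = SimGenome(seqs=seqs, erm=synth_erm, constraint="protein")
        with pytest.raises(DeadlockError):
            step(g, np.random.default_rng(0), max_rejections=2000)
        with pytest.raises(DeadlockError):
            advance_genome(g, 1, np.random.default_rng(0), max_rejections=2000)


class TestRun:
    def test_tau_grid_and_accounting(self, synth_erm):
        """tau = accepted substitutions / total bases; e.g. 999,000 accepted
        on 5000 x 999 bases is exactly 0.2 (checked at reduced scale)."""
        cfg = SimConfig(n_sequences=10, seq_length=99, t_max=0.6, record_interval=0.2, seed=3)
        rec, genome = run(cfg, synth_erm, return_genome=True)
        assert np.allclose(rec.taus, [0.0, 0.2, 0.4, 0.6])
        assert genome.accepted == round(0.6 * 10 * 99)
        # the full-scale arithmetic the time unit implies
        assert 999_000 / (5000 * 999) == pytest.approx(0.2)

    def test_reproducible_given_seed(self, synth_erm):
        cfg = SimConfig(n_sequences=5, seq_length=60, t_max=0.4, seed=11)
        r1 = run(cfg, synth_erm)
        r2 = run(cfg, synth_erm)
        assert np.array_equal(r1.hex_counts, r2.hex_counts)
        assert np.array_equal(r1.mean_erm, r2.mean_erm)

    def test_hexamer_freqs_sum_to_one(self, synth_erm):
        cfg = SimConfig(n_sequences=5, seq_length=60, t_max=0.2, seed=1)
        rec = run(cfg, synth_erm)
        assert np.allclose(rec.hex_freqs.sum(axis=1), 1.0)

    def test_hot_motif_depletes_cold_accumulates(self, hot_cold_erm):
        """With A-hot/T-cold rates, AAAAAA is lost and TTTTTT gained."""
        cfg = SimConfig(n_sequences=50, seq_length=300, t_max=2.0, record_interval=1.0, seed=4)
        rec = run(cfg, hot_cold_erm)
        hot = encode_kmer("AAAAAA")
        cold = encode_kmer("TTTTTT")
        freqs = rec.hex_freqs
        assert freqs[-1, hot] < freqs[0, hot]
        assert freqs[-1, cold] > freqs[0, cold]
        # directional monotonicity along the recorded grid
        assert freqs[1, hot] <= freqs[0, hot]
        assert freqs[1, cold] >= freqs[0, cold]

    def test_constrained_translation_invariant_at_final_tau(self, synth_erm):
        cfg = SimConfig(n_sequences=5, seq_length=60, constraint="protein", t_max=1.0, seed=6)
        rec, genome = run(cfg, synth_erm, return_genome=True)
        fresh = init_genome(cfg, synth_erm, np.random.default_rng(cfg.seed))
        assert np.array_equal(translate_codes(genome.seqs), fresh.ref_aa)


class TestEnrichmentRatio:
    def test_tau_zero_ratios_near_one(self, synth_erm):
        cfg = dict(n_sequences=100, seq_length=300, t_max=0.2, seed=0)
        rc = run(SimConfig(constraint="protein", **cfg), synth_erm)
        cu = run(SimConfig(constraint="none", **{**cfg, "seed": 1}), synth_erm)
        ratios = enrichment_ratio(rc, cu)
        tau0 = ratios["tau_0"].to_numpy()
        # individual ratios are Poisson-noisy; systematically they centre on 1
        assert abs(np.log2(tau0).mean()) < 0.05
        assert 0.8 < np.median(tau0) < 1.25

    def test_mismatched_grids_rejected(self, synth_erm):
        cfg = dict(n_sequences=5, seq_length=60, seed=0)
        r1 = run(SimConfig(t_max=0.4, **cfg), synth_erm)
        r2 = run(SimConfig(t_max=0.2, **cfg), synth_erm)
        with pytest.raises(ValueError, match="grid"):
            enrichment_ratio(r1, r2)


class TestPseudoPositionalProfile:
    def test_uniform_table_flat(self, uniform_erm):
        cfg = SimConfig(n_sequences=9, seq_length=60, t_max=0.2, seed=0)
        gu = init_genome(cfg, uniform_erm, np.random.default_rng(0))
        gc = init_genome(
            SimConfig(n_sequences=3, seq_length=60, constraint="protein", t_max=0.2, seed=1),
            uniform_erm,
            np.random.default_rng(1),
        )
        prof = pseudo_positional_profile(gc, gu, uniform_erm, block=60)
        inner = prof[3:-3]
        assert np.allclose(inner, 1.0)
        assert np.isnan(prof[:3]).all() and np.isnan(prof[-3:]).all()

    def test_constrained_block_more_mutable_after_evolution(self, hot_cold_erm):
        cfg_c = SimConfig(n_sequences=10, seq_length=90, constraint="protein", t_max=2.0, record_interval=2.0, seed=3)
        cfg_u = SimConfig(n_sequences=20, seq_length=90, constraint="none", t_max=2.0, record_interval=2.0, seed=4)
        _, gc = run(cfg_c, hot_cold_erm, return_genome=True)
        _, gu = run(cfg_u, hot_cold_erm, return_genome=True)
        prof = pseudo_positional_profile(gc, gu, hot_cold_erm, block=90)
        mid = np.nanmean(prof[90:180])
        flanks = np.nanmean(np.concatenate([prof[3:90], prof[180:267]]))
        assert mid > flanks

    def test_tau_zero_no_block_difference(self, synth_erm):
        gc = init_genome(
            SimConfig(n_sequences=120, seq_length=90, constraint="protein", t_max=1, seed=5),
            synth_erm,
            np.random.default_rng(5),
        )
        gu = init_genome(
            SimConfig(n_sequences=240, seq_length=90, t_max=1, seed=6),
            synth_erm,
            np.random.default_rng(6),
        )
        prof = pseudo_positional_profile(gc, gu, synth_erm, block=90)
        mid = np.nanmean(prof[90:180])
        flanks = np.nanmean(np.concatenate([prof[3:90], prof[180:267]]))
        assert abs(mid / flanks - 1) < 0.05


class TestExactStationary:
    def test_uniform_rates_give_uniform_distribution(self, uniform_erm):
        pi = exact_stationary(uniform_erm, 4, "none")
        vals = np.array(list(pi.values()))
        assert len(pi) == 256
        assert np.allclose(vals, 1 / 256, atol=1e-12)

    def test_sums_to_one(self, synth_erm):
        pi = exact_stationary(synth_erm, 3, "none")
        assert sum(pi.values()) == pytest.approx(1.0, abs=1e-9)

    def test_protein_component_and_translation(self, synth_erm):
        pi = exact_stationary(synth_erm, 6, "protein", start="GAAGAA")
        # Glu has two codons; the EE component is the 2x2 dicodon set
        assert set(pi) == {"GAAGAA", "GAAGAG", "GAGGAA", "GAGGAG"}
        assert sum(pi.values()) == pytest.approx(1.0)


class TestBiasVariance:
    def test_variance_grows_with_bias_and_shrinks_under_constraint(self, synth_erm):
        """Across replicates, the coldest hexamer's final frequency varies
        more as mutational bias grows, and constrained runs vary less than
        matched unconstrained runs."""
        from premotif.mutability import HexamerRateTable

        hexes = HexamerRateTable.from_erm(synth_erm)
        cold = encode_kmer(hexes.least_mutable(1)[0])
        n_reps = 25

        def final_freqs(beta, constraint):
            out = []
            for rep in range(n_reps):
                cfg = SimConfig(
                    n_sequences=20,
                    seq_length=300,
                    constraint=constraint,
                    beta=beta,
                    t_max=3.0,
                    record_interval=3.0,
                    seed=1000 + rep,
                )
                rec = run(cfg, synth_erm)
                out.append(rec.hex_freqs[-1, cold])
            return np.array(out)

        variances = [final_freqs(b, "none").var() for b in (0.5, 1.0, 2.0)]
        assert variances[0] <= variances[1] <= variances[2]
        v_con = final_freqs(1.0, "protein").var()
        assert v_con < variances[1]
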