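"""Mutation-selection sequence simulator with context-dependent rates.

A genome of circular sequences evolves one substitution at a time.  Each
step: (1) every position carries the mean ERM rate of its three possible
changes given the current heptamer context; (2) a position is drawn
proportionally to its rate; (3) an alternate allele is drawn proportionally
to the three per-allele rates; (4) under protein constraint the change is
rejected unless it preserves the amino-acid sequence and creates no stop
codon — rejected proposals are redrawn (position and allele) and only
accepted substitutions advance time.  Time tau is measured in mutations
introduced per base (accepted substitutions / total bases).  Sequences are
circular so every position has a full +/-3 nt context; the reading frame is
anchored at position 0 and sequence lengths are multiples of 3 under
constraint, so no codon spans the wrap point.

Note that the two-stage proposal (position by mean-of-3 rate, then allele by
per-allele rate) is equivalent to drawing a (position, allele) substitution
jointly in proportion to its individual rate, because the position weight is
exactly one third of the sum of its three allele rates.  The exact
stationary distribution of the small-state-space oracle uses this joint
form.

At a fixed cadence (default every 0.2 mutations per base) the simulator
records the circular-overlapping hexamer spectrum, the mean per-site ERM
rate, and (when a score table is supplied) the mean hexamer enhancer score.
Comparing constrained to unconstrained runs at equal tau gives per-hexamer
enrichment ratios analogous to exon-versus-intron enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .mutability import (
    BASES,
    N_HEXAMERS,
    ERMTable,
    ScoreTable,
    decode_kmer,
    ints_to_seq,
    rescale_bias,
    seq_to_ints,
)
from .protein_code import CODON_AA

__all__ = [
    "SimConfig",
    "SimGenome",
    "SimRecord",
    "DeadlockError",
    "init_genome",
    "step",
    "run",
    "enrichment_ratio",
    "pseudo_positional_profile",
    "exact_stationary",
]


class DeadlockError(RuntimeError):
    """No acceptable substitution could be found under the constraint."""


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults reproduce the full-scale study conditions (5000 sequences of
    999 nt, recorded every 0.2 mutations per base up to 10); smaller scales
    are used routinely for desk work.
    """

    n_sequences: int = 5000
    seq_length: int = 999
    constraint: str = "none"  # "none" | "protein"
    beta: float = 1.0
    record_interval: float = 0.2
    t_max: float = 10.0
    seed: int = 0
    init: str = "random_uniform"  # "random_uniform" | "from_fasta"
    init_sequences: list[str] | None = None
    max_rejections: int = 1_000_000
    count_rejected_in_tau: bool = False  # alternative "proposal clock" mode

    def __post_init__(self) -> None:
        if self.constraint not in ("none", "protein"):
            raise ValueError(f"unknown constraint {self.constraint!r}")
        if self.constraint == "protein" and self.seq_length % 3 != 0:
            raise ValueError("seq_length must be a multiple of 3 under protein constraint")
        if not (self.t_max >= self.record_interval > 0):
            raise ValueError("need t_max >= record_interval > 0")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")


_STOP_AA = ord("*")
_CODON_AA_CODE = np.frombuffer("".join(CODON_AA).encode("ascii"), dtype=np.uint8).copy()


@dataclass
class SimGenome:
    """Evolving genome state: circular int-coded sequences plus rate caches."""

    seqs: np.ndarray  # (n, L) int8
    erm: ERMTable
    constraint: str
    site_rates: np.ndarray = field(init=False)  # (n, L) mean-of-3-alternates
    row_totals: np.ndarray = field(init=False)  # (n,)
    ref_aa: np.ndarray | None = field(init=False, default=None)  # (n, L//3) uint8
    accepted: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        n, L = self.seqs.shape
        if L < 6:
            # heptamer contexts wrap on circular sequences, so short toys are
            # allowed, but hexamer windows need at least 6 nt
            raise ValueError("sequences must be at least 6 nt")
        self.site_rates = compute_site_rates(self.seqs, self.erm)
        self.row_totals = self.site_rates.sum(axis=1)
        if self.constraint == "protein":
            if L % 3:
                raise ValueError("protein constraint requires lengths divisible by 3")
            self.ref_aa = translate_codes(self.seqs)

    @property
    def total_bases(self) -> int:
        return self.seqs.size

    @property
    def tau(self) -> float:
        return self.accepted / self.total_bases

    def sequences(self) -> list[str]:
        return [ints_to_seq(row) for row in self.seqs]

    def translations(self) -> list[str]:
        codes = translate_codes(self.seqs)
        return ["".join(chr(c) for c in row) for row in codes]


def translate_codes(seqs: np.ndarray) -> np.ndarray:
    """Frame-0 translation of each row to amino-acid character codes."""
    n, L = seqs.shape
    codons = (
        seqs[:, 0::3].astype(np.int64) * 16
        + seqs[:, 1::3].astype(np.int64) * 4
        + seqs[:, 2::3].astype(np.int64)
    )
    return _CODON_AA_CODE[codons]


def compute_site_rates(seqs: np.ndarray, erm: ERMTable) -> np.ndarray:
    """Full (slow-path) recomputation of per-position mean rates.

    Serves as the reference for the incremental +/-3 nt cache update used
    by :func:`step`.
    """
    n, L = seqs.shape
    idx = np.zeros((n, L), dtype=np.int64)
    for d in range(-3, 4):
        idx = idx * 4 + seqs[:, (np.arange(L) + d) % L].astype(np.int64)
    return erm.site_mean[idx]


def hexamer_counts(seqs: np.ndarray) -> np.ndarray:
    """Counts of the 4096 hexamers over all circular overlapping windows."""
    n, L = seqs.shape
    idx = np.zeros((n, L), dtype=np.int64)
    for d in range(6):
        idx = idx * 4 + seqs[:, (np.arange(L) + d) % L].astype(np.int64)
    return np.bincount(idx.ravel(), minlength=N_HEXAMERS).astype(np.int64)


def init_genome(config: SimConfig, erm: ERMTable, rng: np.random.Generator) -> SimGenome:
    """Initialise a genome from iid-uniform random bases or supplied FASTA.

    Under protein constraint, supplied sequences must be in frame with no
    internal stop codon; the frame-0 translation is stored as the reference
    the constraint preserves.  Random initial sequences may contain stop
    codons; the constraint then freezes those codons in place (any change
    would either alter the translation or "create" a stop).
    """
    if config.beta != 1.0:
        erm = rescale_bias(erm, config.beta)
    if config.init == "random_uniform":
        seqs = rng.integers(0, 4, size=(config.n_sequences, config.seq_length), dtype=np.int8)
    elif config.init == "from_fasta":
        if not config.init_sequences:
            raise ValueError("init='from_fasta' requires init_sequences")
        L = config.seq_length
        rows = []
        for i, s in enumerate(config.init_sequences):
            ints = seq_to_ints(s)
            if (ints < 0).any():
                raise ValueError(f"initial sequence {i} contains non-ACGT bases")
            if len(ints) < L:
                raise ValueError(f"initial sequence {i} shorter than seq_length={L}")
            ints = ints[:L]  # trim to a uniform length (in frame: L % 3 == 0)
            if config.constraint == "protein":
                aa = translate_codes(ints[None, :])[0]
                if (aa == _STOP_AA).any():
                    raise ValueError(f"initial sequence {i} has an internal stop codon under protein constraint")
            rows.append(ints)
        seqs = np.vstack(rows).astype(np.int8)
    else:
        raise ValueError(f"unknown init mode {config.init!r}")
    return SimGenome(seqs=seqs, erm=erm, constraint=config.constraint)


def step(
    genome: SimGenome,
    rng: np.random.Generator,
    max_rejections: int = 1_000_000,
) -> tuple[int, int, int, int]:
    """Apply one accepted substitution; returns (seq index, pos, old, new).

    Rejected proposals under the protein constraint redraw both position and
    allele; only the accepted substitution increments the introduced-mutation
    counter.  Raises :class:`DeadlockError` after ``max_rejections``
    consecutive rejections.
    """
    seqs = genome.seqs
    rates = genome.erm.rates
    n, L = seqs.shape
    constrained = genome.constraint == "protein"
    for _ in range(max_rejections):
        # stage 1: sequence, then position within it, by site rate
        row_cum = np.cumsum(genome.row_totals)
        s = int(np.searchsorted(row_cum, rng.random() * row_cum[-1], side="right"))
        s = min(s, n - 1)
        site = genome.site_rates[s]
        cum = np.cumsum(site)
        p = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        p = min(p, L - 1)
        # heptamer context at (s, p)
        hept = 0
        for d in range(-3, 4):
            hept = hept * 4 + int(seqs[s, (p + d) % L])
        # stage 2: allele proportional to the three rates
        r3 = rates[hept]
        valid = ~np.isnan(r3)
        w = np.where(valid, r3, 0.0)
        csum = np.cumsum(w)
        a = int(np.searchsorted(csum, rng.random() * csum[-1], side="right"))
        a = min(a, 3)
        old = int(seqs[s, p])
        if a == old:  # numerically impossible draw; redraw
            continue
        if constrained:
            ci = p // 3
            c0 = 3 * ci
            b0, b1, b2 = int(seqs[s, c0]), int(seqs[s, c0 + 1]), int(seqs[s, c0 + 2])
            if p == c0:
                b0 = a
            elif p == c0 + 1:
                b1 = a
            else:
                b2 = a
            aa = _CODON_AA_CODE[b0 * 16 + b1 * 4 + b2]
            if aa == _STOP_AA or aa != genome.ref_aa[s, ci]:
                continue  # rejected: redraw position and allele
        # accept
        seqs[s, p] = a
        upd = (p + np.arange(-3, 4)) % L
        hepts = np.zeros(7, dtype=np.int64)
        for d in range(-3, 4):
            hepts = hepts * 4 + seqs[s, (upd + d) % L].astype(np.int64)
        new_rates = genome.erm.site_mean[hepts]
        genome.row_totals[s] += new_rates.sum() - genome.site_rates[s, upd].sum()
        genome.site_rates[s, upd] = new_rates
        genome.accepted += 1
        return s, p, old, a
    raise DeadlockError(
        f"no acceptable substitution found after {max_rejections} rejections"
    )


def advance_genome(
    genome: SimGenome,
    n_accept: int,
    rng: np.random.Generator,
    max_rejections: int = 1_000_000,
    count_rejected_in_tau: bool = False,
    occupancy: np.ndarray | None = None,
) -> None:
    """Advance by ``n_accept`` accepted substitutions via the compiled kernel.

    Semantics match repeated calls of :func:`step`; the kernel exists purely
    for speed.  When ``occupancy`` is given (single-sequence genomes only),
    the state index of the sequence is tallied after every accepted
    substitution.  In ``count_rejected_in_tau`` mode (the alternative
    proposal-clock time convention) rejected proposals also consume budget.
    """
    from ._kernel import STATUS_DEADLOCK, advance

    track = occupancy is not None
    if track and genome.seqs.shape[0] != 1:
        raise ValueError("occupancy tracking requires a single-sequence genome")
    occ = occupancy if track else np.zeros(1, dtype=np.int64)
    ref_aa = genome.ref_aa if genome.ref_aa is not None else np.zeros((1, 1), dtype=np.uint8)
    done, status = advance(
        genome.seqs,
        genome.site_rates,
        genome.row_totals,
        genome.erm.rates,
        genome.erm.site_mean,
        _CODON_AA_CODE,
        ref_aa,
        1 if genome.constraint == "protein" else 0,
        n_accept,
        max_rejections,
        np.uint32(rng.integers(0, 2**32)),
        1 if count_rejected_in_tau else 0,
        occ,
        1 if track else 0,
    )
    genome.accepted += int(done)
    if status == STATUS_DEADLOCK:
        raise DeadlockError(
            f"no acceptable substitution found after {max_rejections} rejections "
            f"({done} of {n_accept} introduced)"
        )


@dataclass
class SimRecord:
    """State snapshots on the tau grid {0, dt, 2dt, ...}."""

    taus: np.ndarray  # (T,)
    hex_counts: np.ndarray  # (T, 4096) raw circular-window counts
    mean_erm: np.ndarray  # (T,)
    mean_ei: np.ndarray  # (T,) NaN when no score table given
    total_windows: int

    @property
    def hex_freqs(self) -> np.ndarray:
        return self.hex_counts / self.hex_counts.sum(axis=1, keepdims=True)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.hex_freqs, columns=[decode_kmer(i, 6) for i in range(N_HEXAMERS)])
        df.insert(0, "tau", self.taus)
        df.insert(1, "mean_erm", self.mean_erm)
        df.insert(2, "mean_ei", self.mean_ei)
        return df


def _snapshot(genome: SimGenome, ei: ScoreTable | None):
    counts = hexamer_counts(genome.seqs)
    mean_erm = float(genome.site_rates.mean())
    if ei is not None:
        freqs = counts / counts.sum()
        present = ei.present
        mean_ei = float((freqs[present] * ei.scores[present]).sum() / freqs[present].sum())
    else:
        mean_ei = np.nan
    return counts, mean_erm, mean_ei


def run(
    config: SimConfig,
    erm: ERMTable,
    ei: ScoreTable | None = None,
    return_genome: bool = False,
) -> SimRecord | tuple[SimRecord, SimGenome]:
    """Evolve a genome to t_max, recording on the tau grid (including tau=0)."""
    rng = np.random.default_rng(config.seed)
    genome = init_genome(config, erm, rng)
    total = genome.total_bases
    n_records = int(round(config.t_max / config.record_interval)) + 1
    grid = np.arange(n_records) * config.record_interval
    taus, all_counts, mean_erms, mean_eis = [], [], [], []

    counts, me, mei = _snapshot(genome, ei)
    taus.append(0.0)
    all_counts.append(counts)
    mean_erms.append(me)
    mean_eis.append(mei)

    for target in grid[1:]:
        needed = int(round(target * total)) - genome.accepted
        advance_genome(
            genome,
            needed,
            rng,
            max_rejections=config.max_rejections,
            count_rejected_in_tau=config.count_rejected_in_tau,
        )
        counts, me, mei = _snapshot(genome, ei)
        taus.append(genome.tau)
        all_counts.append(counts)
        mean_erms.append(me)
        mean_eis.append(mei)

    rec = SimRecord(
        taus=np.array(taus),
        hex_counts=np.vstack(all_counts),
        mean_erm=np.array(mean_erms),
        mean_ei=np.array(mean_eis),
        total_windows=total,
    )
    if return_genome:
        return rec, genome
    return rec


def enrichment_ratio(
    run_constrained: SimRecord, run_unconstrained: SimRecord, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-hexamer constrained/unconstrained frequency ratio at each tau.

    Analogous to exon-versus-intron enrichment.  A pseudocount (default 1)
    is added to both hexamer counts before normalising, so ratios remain
    finite when a hexamer is absent from one run.
    """
    if run_constrained.taus.shape != run_unconstrained.taus.shape or not np.allclose(
        run_constrained.taus, run_unconstrained.taus, atol=1e-9
    ):
        raise ValueError("tau grids of the two runs do not match")
    cc = run_constrained.hex_counts + pseudocount
    cu = run_unconstrained.hex_counts + pseudocount
    fc = cc / cc.sum(axis=1, keepdims=True)
    fu = cu / cu.sum(axis=1, keepdims=True)
    ratios = fc / fu
    df = pd.DataFrame(ratios.T, columns=[f"tau_{t:g}" for t in run_constrained.taus])
    df.insert(0, "hexamer", [decode_kmer(i, 6) for i in range(N_HEXAMERS)])
    return df


def pseudo_positional_profile(
    constrained: SimGenome,
    unconstrained: SimGenome,
    erm: ERMTable,
    block: int = 300,
) -> np.ndarray:
    """Mean ERM rate by position over concatenated intron-exon-intron triples.

    Constrained sequences act as middle exons, unconstrained sequences as
    flanking introns; each is trimmed to its first ``block`` nt and distinct
    triples are concatenated (round-robin by sequence index) into linear
    3*block-nt pseudo-genes.  Heptamer contexts at the two junctions span
    the concatenated neighbours; the first and last 3 positions lack full
    context and are NaN.
    """
    n_ex = constrained.seqs.shape[0]
    n_in = unconstrained.seqs.shape[0]
    n_triples = min(n_ex, n_in // 2)
    if n_triples < 1:
        raise ValueError("not enough sequences to form intron-exon-intron triples")
    if constrained.seqs.shape[1] < block or unconstrained.seqs.shape[1] < block:
        raise ValueError(f"sequences shorter than the {block}-nt block")
    triples = np.concatenate(
        [
            unconstrained.seqs[0 : 2 * n_triples : 2, :block],
            constrained.seqs[:n_triples, :block],
            unconstrained.seqs[1 : 2 * n_triples : 2, :block],
        ],
        axis=1,
    )
    Lt = 3 * block
    idx = np.zeros((n_triples, Lt - 6), dtype=np.int64)
    for d in range(7):
        idx = idx * 4 + triples[:, d : Lt - 6 + d].astype(np.int64)
    profile = np.full(Lt, np.nan)
    profile[3 : Lt - 3] = erm.site_mean[idx].mean(axis=0)
    return profile


def _codon_class_of(state_bases: np.ndarray) -> np.ndarray:
    codons = state_bases[0::3] * 16 + state_bases[1::3] * 4 + state_bases[2::3]
    return _CODON_AA_CODE[codons]


def exact_stationary(
    erm: ERMTable,
    length: int,
    constraint: str = "none",
    start: str | None = None,
    beta: float = 1.0,
) -> dict[str, float]:
    """Exact stationary distribution of the substitution jump chain.

    Enumerates all circular sequences of the given small length (<= 6) and
    solves pi P = pi for the embedded jump chain whose move probabilities
    are proportional to per-substitution ERM rates, restricted to accepted
    moves under the constraint.  Under protein constraint the chain is
    confined to the component of single-nucleotide synonymous moves
    reachable from ``start`` (synonymous codon sets such as serine's split
    into several components); the distribution is over that component.
    States with no outgoing accepted move raise with the stranded states
    listed.
    """
    if length > 6:
        raise ValueError("exact enumeration is limited to length <= 6")
    if beta != 1.0:
        erm = rescale_bias(erm, beta)
    if constraint not in ("none", "protein"):
        raise ValueError(f"unknown constraint {constraint!r}")
    if constraint == "protein":
        if length % 3:
            raise ValueError("protein constraint requires length divisible by 3")
        if start is None:
            raise ValueError("protein constraint requires a start state fixing the translation")

    def state_to_bases(code: int) -> np.ndarray:
        return np.array([(code >> (2 * (length - 1 - i))) & 3 for i in range(length)], dtype=np.int64)

    def moves(code: int):
        bases = state_to_bases(code)
        if constraint == "protein":
            ref = _codon_class_of(bases)
        out = []
        for p in range(length):
            hept = 0
            for d in range(-3, 4):
                hept = hept * 4 + int(bases[(p + d) % length])
            for a in range(4):
                if a == bases[p]:
                    continue
                r = erm.rates[hept, a]
                if constraint == "protein":
                    nb = bases.copy()
                    nb[p] = a
                    aa = _codon_class_of(nb)
                    if (aa == _STOP_AA).any() or (aa != ref).any():
                        continue
                new_code = code + (a - int(bases[p])) * (1 << (2 * (length - 1 - p)))
                out.append((new_code, float(r)))
        return out

    if constraint == "protein":
        start_code = int(seq_to_ints(start).astype(np.int64) @ (4 ** np.arange(length - 1, -1, -1)))
        bases = state_to_bases(start_code)
        aa = _codon_class_of(bases)
        if (aa == _STOP_AA).any():
            raise ValueError("start state contains a stop codon")
        # BFS over the accepted-move component containing the start state
        seen = {start_code}
        frontier = [start_code]
        while frontier:
            nxt = []
            for code in frontier:
                for new_code, _ in moves(code):
                    if new_code not in seen:
                        seen.add(new_code)
                        nxt.append(new_code)
            frontier = nxt
        states = sorted(seen)
    else:
        states = list(range(4 ** length))

    index = {code: i for i, code in enumerate(states)}
    n = len(states)
    rows, cols, vals = [], [], []
    stranded = []
    for code in states:
        mv = moves(code)
        if not mv:
            stranded.append(decode_kmer(code, length))
            continue
        tot = sum(r for _, r in mv)
        for new_code, r in mv:
            rows.append(index[code])
            cols.append(index[new_code])
            vals.append(r / tot)
    if stranded:
        raise DeadlockError(f"states with no accepted move: {stranded[:20]}")
    P = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    # solve pi (P - I) = 0 with sum(pi) = 1 via a replaced equation
    A = (P.T - sparse.identity(n, format="csr")).tolil()
    A[0, :] = 1.0
    b = np.zeros(n)
    b[0] = 1.0
    pi = spsolve(A.tocsr(), b)
    pi = np.maximum(pi, 0)
    pi /= pi.sum()
    return {decode_kmer(code, length): float(pi[i]) for i, code in enumerate(states)}
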