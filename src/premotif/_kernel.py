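"""Compiled inner loop of the mutation-selection simulator.

The jitted kernel advances a genome by a given number of accepted
substitutions using exactly the proposal scheme of
:func:`premotif.evolve_sim.step` (position by mean-of-3 site rate, allele by
per-allele rate, redraw on rejection under the protein constraint), updating
the +/-3 nt site-rate cache incrementally.  ``premotif.evolve_sim.step``
remains the readable reference implementation; tests verify the cache
against full recomputation after kernel runs.

Optionally the kernel tallies state occupancy (for single short circular
sequences) after every accepted substitution, which the exact-stationary
oracle comparison uses.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_DEADLOCK = 1


@njit(cache=False)
def advance(
    seqs,  # (n, L) int8, mutated in place
    site_rates,  # (n, L) float64, mutated in place
    row_totals,  # (n,) float64, mutated in place
    rates,  # (16384, 4) float64, NaN at alt == middle base
    site_mean,  # (16384,) float64
    codon_aa,  # (64,) uint8 amino-acid codes, ord('*') for stop
    ref_aa,  # (n, L//3) uint8 (unused when constrained == 0)
    constrained,  # 0 | 1
    n_accept,  # accepted substitutions to introduce
    max_rejections,
    seed,  # uint32 for the kernel-local RNG
    count_rejected,  # 0 | 1: proposal-clock mode (rejections also consume budget)
    occupancy,  # (4**L,) int64 tallies, or length-1 dummy when unused
    track_occupancy,  # 0 | 1 (requires n == 1)
):
    np.random.seed(seed)
    n, L = seqs.shape
    stop_aa = np.uint8(42)  # ord('*')
    total = 0.0
    for i in range(n):
        total += row_totals[i]
    accepted = 0
    rejections = 0
    while accepted < n_accept:
        # stage 1a: sequence proportional to its summed site rate
        u = np.random.random() * total
        s = 0
        acc = row_totals[0]
        while acc < u and s < n - 1:
            s += 1
            acc += row_totals[s]
        # stage 1b: position proportional to its mean-of-3 rate
        u = np.random.random() * row_totals[s]
        p = 0
        acc = site_rates[s, 0]
        while acc < u and p < L - 1:
            p += 1
            acc += site_rates[s, p]
        # heptamer context (circular)
        hept = 0
        for d in range(-3, 4):
            hept = hept * 4 + seqs[s, (p + d) % L]
        old = seqs[s, p]
        # stage 2: allele proportional to the three alternate rates
        wsum = 0.0
        for a in range(4):
            if a != old:
                wsum += rates[hept, a]
        u = np.random.random() * wsum
        alt = -1
        acc = 0.0
        for a in range(4):
            if a == old:
                continue
            acc += rates[hept, a]
            if u <= acc:
                alt = a
                break
        if alt < 0:
            alt = 3 if old != 3 else 2
        ok = True
        if constrained == 1:
            ci = p // 3
            c0 = 3 * ci
            b0 = seqs[s, c0]
            b1 = seqs[s, c0 + 1]
            b2 = seqs[s, c0 + 2]
            if p == c0:
                b0 = alt
            elif p == c0 + 1:
                b1 = alt
            else:
                b2 = alt
            aa = codon_aa[b0 * 16 + b1 * 4 + b2]
            if aa == stop_aa or aa != ref_aa[s, ci]:
                ok = False
        if not ok:
            rejections += 1
            if rejections > max_rejections:
                return accepted, STATUS_DEADLOCK
            if count_rejected == 1:
                accepted += 1  # proposal-clock mode: rejections consume time
            continue
        rejections = 0
        seqs[s, p] = alt
        delta = 0.0
        for q in range(-3, 4):
            pos = (p + q) % L
            h = 0
            for d in range(-3, 4):
                h = h * 4 + seqs[s, (pos + d) % L]
            new_rate = site_mean[h]
            delta += new_rate - site_rates[s, pos]
            site_rates[s, pos] = new_rate
        row_totals[s] += delta
        total += delta
        accepted += 1
        if track_occupancy == 1:
            state = 0
            for d in range(L):
                state = state * 4 + seqs[0, d]
            occupancy[state] += 1
    return accepted, STATUS_OK
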