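"""Protein-layer analyses of coding hexamers.

Coding exons carry two overlapping codes: the amino-acid sequence and the
cis-regulatory splicing signals (hexamer enhancer scores).  This module maps
between the two: it classifies single-nucleotide changes of sense codons as
synonymous / missense / stop-gain under the standard genetic code, associates
every in-frame hexamer occurrence with the amino-acid pair it predominantly
encodes, computes occurrence-weighted mean enhancer scores and
observed/expected proteome enrichments per pair, scores each possible
dicodon mutation for its change in enhancer activity (delta-EI over the two
hexamers in which the mutated base sits at the 3rd or 4th position), and
enumerates the fraction of substitutions in a pair's codon encodings that
create in-frame stop codons (the purine-rich Glu-Glu / GARGAR case being the
canonical example: 2 of its 18 substitutions, i.e. 1/9, are stop gains).
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .mutability import BASES, ERMTable, ScoreTable, decode_kmer, encode_kmer

__all__ = [
    "GENETIC_CODE",
    "STOP_CODONS",
    "SENSE_CODONS",
    "AMINO_ACIDS",
    "classify_mutation",
    "hexamer_to_aa_pair",
    "aa_pair_mean_ei",
    "aa_pair_enrichment",
    "enrichment_difference",
    "dicodon_occurrences",
    "mutation_delta_ei",
    "stop_gain_fraction",
    "codon_pairs_for",
    "AAPairStats",
]

_standard = unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_standard.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)  # TAA, TAG, TGA
for _stop in STOP_CODONS:
    GENETIC_CODE[_stop] = "*"
SENSE_CODONS: tuple[str, ...] = tuple(sorted(set(GENETIC_CODE) - STOP_CODONS))
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(GENETIC_CODE.values()) - {"*"}))

# codon index (base-4 of the 3 bases) -> amino acid, '*' for stop
CODON_AA = np.array([GENETIC_CODE[decode_kmer(i, 3)] for i in range(64)])


def classify_mutation(codon: str, pos: int, alt: str) -> str:
    """Classify a single-nucleotide change of a sense codon.

    ``pos`` is 1..3 within the codon.  Returns one of ``synonymous``,
    ``missense``, ``stop_gain``.  Stop codons as input are rejected
    (stop-loss is out of scope), as is a no-op change (alt == ref).
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"input codon {codon} is a stop codon (stop-loss not handled)")
    if codon not in GENETIC_CODE:
        raise ValueError(f"invalid codon {codon!r}")
    if pos not in (1, 2, 3):
        raise ValueError(f"codon position must be 1..3, got {pos}")
    alt = alt.upper()
    if alt not in BASES:
        raise ValueError(f"invalid alternate base {alt!r}")
    if codon[pos - 1] == alt:
        raise ValueError(f"alt {alt} equals the reference base at position {pos} of {codon}")
    mutated = codon[: pos - 1] + alt + codon[pos:]
    if mutated in STOP_CODONS:
        return "stop_gain"
    if GENETIC_CODE[mutated] == GENETIC_CODE[codon]:
        return "synonymous"
    return "missense"


def hexamer_to_aa_pair(coding_seq: str, offset: int) -> tuple[str, str]:
    """Amino-acid pair encoded by the hexamer starting at ``offset``.

    The reading frame is frame 0 of ``coding_seq``.  The two codons with the
    largest overlap with the hexamer are translated, in sequence order:
    frame offset 0 covers two codons fully (3+3); offset 1 overlaps the
    three codons by (2,3,1) nt, offset 2 by (1,3,2) nt, so the top two are
    always unique.
    """
    coding_seq = coding_seq.upper()
    if offset < 0 or offset + 6 > len(coding_seq):
        raise ValueError("hexamer spans a sequence end")
    r = offset % 3
    k = offset // 3
    if r in (0, 1):
        c1, c2 = k, k + 1
    else:
        c1, c2 = k + 1, k + 2
    if 3 * c2 + 3 > len(coding_seq):
        raise ValueError("hexamer's dominant codons extend past the coding sequence")
    a = GENETIC_CODE.get(coding_seq[3 * c1 : 3 * c1 + 3])
    b = GENETIC_CODE.get(coding_seq[3 * c2 : 3 * c2 + 3])
    if a is None or b is None:
        raise ValueError("codon contains non-ACGT bases")
    return a, b


def aa_pair_mean_ei(
    coding_seqs: list[str] | dict[str, str], ei: ScoreTable
) -> pd.DataFrame:
    """Occurrence-weighted mean enhancer score per amino-acid pair.

    Every in-frame hexamer occurrence (all 3 frame offsets, step 1) of every
    coding sequence contributes its score to the pair it encodes; a pair's
    mean is the occurrence-weighted average.  Occurrences with an absent
    score, non-ACGT bases, or a stop codon in the dominant pair are skipped;
    pairs with zero occurrences are absent from the output.
    """
    if isinstance(coding_seqs, dict):
        coding_seqs = list(coding_seqs.values())
    sums: dict[tuple[str, str], float] = defaultdict(float)
    counts: Counter[tuple[str, str]] = Counter()
    skipped = 0
    for seq in coding_seqs:
        seq = seq.upper()
        for offset in range(len(seq) - 5):
            hexamer = seq[offset : offset + 6]
            try:
                score = ei.score(hexamer)
                pair = hexamer_to_aa_pair(seq, offset)
            except ValueError:
                skipped += 1
                continue
            if np.isnan(score) or "*" in pair:
                skipped += 1
                continue
            sums[pair] += score
            counts[pair] += 1
    rows = [
        {"aa1": p[0], "aa2": p[1], "mean_ei": sums[p] / counts[p], "n": counts[p]}
        for p in sorted(counts)
    ]
    df = pd.DataFrame(rows, columns=["aa1", "aa2", "mean_ei", "n"])
    df.attrs["skipped_occurrences"] = skipped
    return df


def aa_pair_enrichment(proteome: list[str] | dict[str, str]) -> pd.DataFrame:
    """Observed/expected frequency ratio of each ordered amino-acid pair.

    Pair frequencies count adjacent positions within each protein (never
    across proteins); single-residue frequencies count all positions.  The
    expected pair frequency is the product of the two residue frequencies.
    """
    if isinstance(proteome, dict):
        proteome = list(proteome.values())
    proteome = [p.upper().rstrip("*") for p in proteome]
    if not proteome:
        raise ValueError("empty proteome")
    if any(len(p) < 2 for p in proteome):
        raise ValueError("proteins shorter than 2 residues cannot form pairs")
    aa_counts: Counter[str] = Counter()
    pair_counts: Counter[tuple[str, str]] = Counter()
    for prot in proteome:
        residues = [a for a in prot]
        aa_counts.update(a for a in residues if a in AMINO_ACIDS)
        for a, b in itertools.pairwise(residues):
            if a in AMINO_ACIDS and b in AMINO_ACIDS:
                pair_counts[(a, b)] += 1
    total_aa = sum(aa_counts.values())
    total_pairs = sum(pair_counts.values())
    if total_pairs == 0:
        raise ValueError("no valid residue pairs in proteome")
    rows = []
    for a in AMINO_ACIDS:
        fa = aa_counts[a] / total_aa
        for b in AMINO_ACIDS:
            fb = aa_counts[b] / total_aa
            obs = pair_counts[(a, b)] / total_pairs
            exp = fa * fb
            rows.append(
                {
                    "aa1": a,
                    "aa2": b,
                    "observed": obs,
                    "expected": exp,
                    "enrichment": obs / exp if exp > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def enrichment_difference(enrich_a: pd.DataFrame, enrich_b: pd.DataFrame) -> pd.DataFrame:
    """Per-pair enrichment contrast between two proteomes (a minus b).

    Mirrors the splicing-genome vs non-splicing-genome comparison: pairs
    whose enrichment is specific to the splicing proteome are candidates for
    selection driven by enhancer content rather than protein structure.
    """
    merged = enrich_a.merge(enrich_b, on=["aa1", "aa2"], suffixes=("_a", "_b"))
    merged["difference"] = merged["enrichment_a"] - merged["enrichment_b"]
    return merged[["aa1", "aa2", "enrichment_a", "enrichment_b", "difference"]]


def dicodon_occurrences(
    coding_seq: str, pair: tuple[str, str] | None = None
) -> list[str]:
    """All in-frame dicodons of a coding sequence as 12-mers with +/-3 nt context.

    Only dicodons with full flanking context within the sequence are
    returned (codon indices 1..n-3).  If ``pair`` is given, occurrences are
    restricted to dicodons encoding that amino-acid pair.  Dicodons
    containing a stop codon are skipped.
    """
    coding_seq = coding_seq.upper()
    out = []
    n_codons = len(coding_seq) // 3
    for k in range(1, n_codons - 2):
        start = 3 * k
        window = coding_seq[start - 3 : start + 9]
        if len(window) < 12 or any(c not in BASES for c in window):
            continue
        c1, c2 = window[3:6], window[6:9]
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        if pair is not None and (GENETIC_CODE[c1], GENETIC_CODE[c2]) != tuple(pair):
            continue
        out.append(window)
    return out


def mutation_delta_ei(
    occurrences: list[str], ei: ScoreTable, erm: ERMTable | None = None
) -> pd.DataFrame:
    """Per-class splicing impact of every possible dicodon mutation.

    ``occurrences`` are 12-mers: 3 nt context + dicodon + 3 nt context.  For
    each occurrence and each of the 18 substitutions (6 dicodon positions x
    3 alternates): the mutation class comes from the affected codon; the
    delta-EI is the mean, over the two hexamers in which the mutated base is
    the 3rd and the 4th position, of (mutant score - wild-type score); the
    mutation's ERM rate (if a table is given) comes from its heptamer
    context.  Results are aggregated as means over occurrences per
    (amino-acid pair, class).  Occurrences touching an absent score entry
    are skipped and counted in ``df.attrs['skipped_occurrences']``.
    """
    agg: dict[tuple[str, str, str], dict[str, float]] = defaultdict(
        lambda: {"sum_dei": 0.0, "sum_rate": 0.0, "n": 0}
    )
    skipped = 0
    for occ in occurrences:
        occ = occ.upper()
        if len(occ) != 12:
            raise ValueError(f"occurrence must be a 12-mer (3+6+3), got length {len(occ)}")
        dicodon = occ[3:9]
        c1, c2 = dicodon[:3], dicodon[3:]
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise ValueError(f"dicodon {dicodon} contains a stop codon")
        pair = (GENETIC_CODE[c1], GENETIC_CODE[c2])
        records = []
        ok = True
        for j in range(6):  # position within the dicodon
            a = j + 3  # absolute position in the 12-mer
            ref = occ[a]
            codon, cpos = (c1, j + 1) if j < 3 else (c2, j - 2)
            for alt in BASES:
                if alt == ref:
                    continue
                klass = classify_mutation(codon, cpos, alt)
                dei = 0.0
                for start in (a - 3, a - 2):  # mutated base at 4th / 3rd hexamer position
                    wt_hex = occ[start : start + 6]
                    mt_hex = occ[start:a] + alt + occ[a + 1 : start + 6]
                    s_wt = ei.score(wt_hex)
                    s_mt = ei.score(mt_hex)
                    if np.isnan(s_wt) or np.isnan(s_mt):
                        ok = False
                        break
                    dei += (s_mt - s_wt) / 2.0
                if not ok:
                    break
                rate = erm.rate(occ[a - 3 : a + 4], alt) if erm is not None else np.nan
                records.append((pair, klass, dei, rate))
            if not ok:
                break
        if not ok:
            skipped += 1
            continue
        for pair_, klass, dei, rate in records:
            cell = agg[(pair_[0], pair_[1], klass)]
            cell["sum_dei"] += dei
            if not np.isnan(rate):
                cell["sum_rate"] += rate
            cell["n"] += 1
    rows = [
        {
            "aa1": a1,
            "aa2": a2,
            "class": klass,
            "mean_delta_ei": cell["sum_dei"] / cell["n"],
            "mean_erm": cell["sum_rate"] / cell["n"] if erm is not None else np.nan,
            "n": cell["n"],
        }
        for (a1, a2, klass), cell in sorted(agg.items())
    ]
    df = pd.DataFrame(rows, columns=["aa1", "aa2", "class", "mean_delta_ei", "mean_erm", "n"])
    df.attrs["skipped_occurrences"] = skipped
    return df


def codon_pairs_for(pair: tuple[str, str]) -> list[str]:
    """All dicodon (hexamer) encodings of an ordered amino-acid pair."""
    a, b = pair
    enc_a = [c for c in SENSE_CODONS if GENETIC_CODE[c] == a]
    enc_b = [c for c in SENSE_CODONS if GENETIC_CODE[c] == b]
    if not enc_a or not enc_b:
        raise ValueError(f"pair {pair} has no sense-codon encoding")
    return [x + y for x in enc_a for y in enc_b]


def stop_gain_fraction(
    pair: tuple[str, str] | None = None,
    *,
    hexamers: list[str] | None = None,
    weighting: str = "uniform",
    erm: ERMTable | None = None,
    occurrences: list[str] | None = None,
) -> float:
    """Fraction of possible dicodon substitutions that create a stop codon.

    ``uniform`` weighting enumerates all 18 substitutions of every dicodon
    encoding of ``pair`` (or of an explicit ``hexamers`` subset, e.g. the
    GARGAR set) and counts the stop-creating ones.  ``erm_context``
    weighting instead weights each substitution by its context-dependent
    rate over supplied genomic ``occurrences`` (12-mers with +/-3 nt
    context), normalising within each occurrence before averaging
    occurrences equally.
    """
    if weighting not in ("uniform", "erm_context"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if weighting == "uniform":
        if hexamers is None:
            if pair is None:
                raise ValueError("need a pair or an explicit hexamer set")
            hexamers = codon_pairs_for(pair)
        stops = total = 0
        for hexamer in hexamers:
            hexamer = hexamer.upper()
            c1, c2 = hexamer[:3], hexamer[3:]
            if c1 in STOP_CODONS or c2 in STOP_CODONS:
                raise ValueError(f"dicodon {hexamer} contains a stop codon")
            for j in range(6):
                codon, cpos = (c1, j + 1) if j < 3 else (c2, j - 2)
                for alt in BASES:
                    if alt == hexamer[j]:
                        continue
                    total += 1
                    if classify_mutation(codon, cpos, alt) == "stop_gain":
                        stops += 1
        return stops / total
    # erm_context
    if erm is None or occurrences is None:
        raise ValueError("erm_context weighting needs an ERM table and genomic occurrences")
    if not occurrences:
        raise ValueError("no occurrences supplied")
    fracs = []
    for occ in occurrences:
        occ = occ.upper()
        if len(occ) != 12:
            raise ValueError("occurrences must be 12-mers (3 nt + dicodon + 3 nt)")
        dicodon = occ[3:9]
        c1, c2 = dicodon[:3], dicodon[3:]
        if pair is not None and (GENETIC_CODE[c1], GENETIC_CODE[c2]) != tuple(pair):
            raise ValueError(f"occurrence dicodon {dicodon} does not encode {pair}")
        stop_rate = total_rate = 0.0
        for j in range(6):
            a = j + 3
            codon, cpos = (c1, j + 1) if j < 3 else (c2, j - 2)
            for alt in BASES:
                if alt == occ[a]:
                    continue
                r = erm.rate(occ[a - 3 : a + 4], alt)
                total_rate += r
                if classify_mutation(codon, cpos, alt) == "stop_gain":
                    stop_rate += r
        fracs.append(stop_rate / total_rate)
    return float(np.mean(fracs))


@dataclass
class AAPairStats:
    """Bundle of per-pair statistics over one set of coding sequences."""

    mean_ei: pd.DataFrame
    enrichment: pd.DataFrame
    delta_ei: pd.DataFrame | None = None
    stop_gain_uniform: dict[tuple[str, str], float] = field(default_factory=dict)
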