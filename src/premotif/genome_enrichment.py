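"""Splice-site-relative mutability profiles and hexamer enrichment.

Exons evolving under protein constraint retain mutable sequence that
neutral introns lose, so (a) positional mean mutability should step up at
the intron/exon boundary, and (b) the hexamers enriched in exons relative
to introns should skew toward high mutability and high enhancer activity.
This module extracts splice-site windows (300 nt into the intron, 150 nt
into the exon, with +/-3 nt of extra context so boundary heptamers extend
into the neighbouring region), computes per-offset mean ERM rates, hexamer
frequency spectra, exon/intron log2 enrichment with a pseudo-frequency, and
Pearson correlations of enrichment against enhancer/silencer score tables
(optionally excluding CpG-containing hexamers to show the trend is not a
CpG artefact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GeneModel
from .mutability import (
    N_HEXAMERS,
    ERMTable,
    ScoreTable,
    decode_kmer,
    kmer_indices,
    seq_to_ints,
)

__all__ = [
    "SpliceWindow",
    "EnrichmentTable",
    "extract_splice_windows",
    "positional_mean_rate",
    "exon_intron_means",
    "kmer_frequencies",
    "exon_intron_enrichment",
    "correlate_scores",
    "cpg_hexamer_mask",
]

INTRON_SPAN = 300
EXON_SPAN = 150
CONTEXT = 3


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class SpliceWindow:
    """Transcript-oriented sequence window around one splice site.

    The window proper covers transcript-relative offsets
    ``[-neg_span, pos_span)`` around the splice site, where offset 0 is the
    first base downstream of the site (first exonic base for acceptors,
    first intronic base for donors).  ``seq`` is the extracted genomic
    sequence, transcript-oriented, whose first base sits at offset
    ``start_offset`` — normally ``-neg_span - context`` so that boundary
    heptamers have their full +/-3 nt context, extending across the
    exon/intron junction.  Truncation by chromosome ends is flagged.
    """

    transcript_id: str
    side: str  # "acceptor" (3'ss) | "donor" (5'ss)
    seq: str
    start_offset: int
    neg_span: int
    pos_span: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.side not in ("acceptor", "donor"):
            raise ValueError(f"invalid side {self.side!r}")


def extract_splice_windows(
    seqs: dict[str, str],
    genes: list[GeneModel],
    intron_span: int = INTRON_SPAN,
    exon_span: int = EXON_SPAN,
    context: int = CONTEXT,
    dedupe: bool = True,
    drop_truncated: bool = False,
) -> list[SpliceWindow]:
    """Windows around every annotated exon boundary.

    Transcript-oriented exon starts give acceptor windows (intron_span nt of
    upstream intron + exon_span nt of exon), exon ends give donor windows
    (exon_span nt of exon + intron_span nt of downstream intron).  Windows
    truncated by chromosome ends are kept and flagged unless
    ``drop_truncated``; duplicate splice sites shared across isoforms are
    deduplicated by genomic coordinate.
    """
    out: list[SpliceWindow] = []
    seen: set[tuple[str, str, int, str]] = set()
    for gene in genes:
        chrom_seq = seqs.get(gene.chrom)
        if chrom_seq is None:
            raise ValueError(f"chromosome {gene.chrom!r} of {gene.transcript_id} not in sequences")
        L = len(chrom_seq)
        for a, b in gene.exons:
            if b > L:
                raise ValueError(
                    f"exon [{a}, {b}) of {gene.transcript_id} outside {gene.chrom} (length {L})"
                )
            for boundary, genomic_side in ((a, "start"), (b, "end")):
                # on '+', a genomic exon start is the acceptor (3'ss); on '-'
                # it is the transcript-oriented exon end, i.e. the donor
                if gene.strand == "+":
                    side = "acceptor" if genomic_side == "start" else "donor"
                else:
                    side = "donor" if genomic_side == "start" else "acceptor"
                key = (gene.chrom, gene.strand, boundary, side)
                if dedupe and key in seen:
                    continue
                seen.add(key)
                if side == "acceptor":
                    neg, pos = intron_span, exon_span
                else:
                    neg, pos = exon_span, intron_span
                # genomic span of transcript offsets [-neg-context, pos+context)
                if gene.strand == "+":
                    lo = boundary - neg - context
                    hi = boundary + pos + context
                else:
                    lo = boundary - pos - context
                    hi = boundary + neg + context
                clip_lo = max(0, -lo)
                clip_hi = max(0, hi - L)
                truncated = bool(clip_lo or clip_hi)
                if truncated and drop_truncated:
                    continue
                window = chrom_seq[max(0, lo) : min(L, hi)]
                if gene.strand == "-":
                    window = window.translate(_RC)[::-1]
                    clip_lo, clip_hi = clip_hi, clip_lo
                out.append(
                    SpliceWindow(
                        transcript_id=gene.transcript_id,
                        side=side,
                        seq=window,
                        start_offset=-neg - context + clip_lo,
                        neg_span=neg,
                        pos_span=pos,
                        truncated=truncated,
                    )
                )
    if not out:
        raise ValueError("no splice windows extracted")
    return out


def positional_mean_rate(windows: list[SpliceWindow], erm: ERMTable) -> pd.DataFrame:
    """Genome-wide mean site rate per (side, splice-site-relative offset).

    Each window position is assigned the mean ERM rate of its three possible
    changes from its +/-3 nt heptamer (which may extend across the
    exon/intron boundary); rates at matched offsets are averaged over all
    windows (per-site weighting).  Positions lacking full context or with
    non-ACGT bases in their context are skipped.
    """
    if not windows:
        raise ValueError("empty window set")
    sums: dict[tuple[str, int], float] = {}
    counts: dict[tuple[str, int], int] = {}
    c = CONTEXT
    for w in windows:
        ints = seq_to_ints(w.seq)
        n = len(ints)
        if n < 2 * c + 1:
            continue
        m = n - 2 * c  # positions with full heptamer context
        idx = np.zeros(m, dtype=np.int64)
        bad = np.zeros(m, dtype=bool)
        for d in range(7):
            seg = ints[d : m + d].astype(np.int64)
            bad |= seg < 0
            idx = idx * 4 + np.where(seg < 0, 0, seg)
        rates = erm.site_mean[idx]
        offsets = w.start_offset + c + np.arange(m)
        keep = (~bad) & (offsets >= -w.neg_span) & (offsets < w.pos_span)
        for off, rate in zip(offsets[keep], rates[keep]):
            key = (w.side, int(off))
            sums[key] = sums.get(key, 0.0) + float(rate)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "side": side,
            "offset": off,
            "mean_rate": sums[(side, off)] / counts[(side, off)],
            "n": counts[(side, off)],
        }
        for (side, off) in sorted(sums)
    ]
    return pd.DataFrame(rows)


def exon_intron_means(profile: pd.DataFrame) -> tuple[float, float]:
    """Weighted exonic and intronic mean rates from a positional profile."""
    exonic = ((profile["side"] == "acceptor") & (profile["offset"] >= 0)) | (
        (profile["side"] == "donor") & (profile["offset"] < 0)
    )
    w = profile["n"]
    ex = float((profile.loc[exonic, "mean_rate"] * w[exonic]).sum() / w[exonic].sum())
    iv = float((profile.loc[~exonic, "mean_rate"] * w[~exonic]).sum() / w[~exonic].sum())
    return ex, iv


def kmer_frequencies(seqs: list[str] | dict[str, str], k: int = 6) -> tuple[np.ndarray, int]:
    """Overlapping k-mer counts (step 1) over a sequence collection.

    Windows never span record boundaries; windows containing N are skipped.
    Returns (counts over 4**k k-mers, total windows).
    """
    if isinstance(seqs, dict):
        seqs = list(seqs.values())
    counts = np.zeros(4 ** k, dtype=np.int64)
    for s in seqs:
        idx = kmer_indices(seq_to_ints(s), k)
        idx = idx[idx >= 0]
        if idx.size:
            counts += np.bincount(idx, minlength=4 ** k)
    total = int(counts.sum())
    if total == 0:
        raise ValueError(f"no {k}-mer windows in the collection (all sequences shorter than {k}?)")
    return counts, total


@dataclass
class EnrichmentTable:
    """Per-hexamer exon/intron frequencies and log2 enrichment."""

    frame: pd.DataFrame

    @property
    def log2_enrichment(self) -> np.ndarray:
        return self.frame["log2_enrichment"].to_numpy()


def exon_intron_enrichment(
    exon_seqs: list[str] | dict[str, str],
    intron_seqs: list[str] | dict[str, str],
    k: int = 6,
    quintile: np.ndarray | None = None,
) -> EnrichmentTable:
    """log2 hexamer enrichment in exons versus introns.

    Enrichment is log2((f_exon + pi_e) / (f_intron + pi_i)) with
    pseudo-frequency pi = 1/(total windows) of each collection, making the
    statistic finite and antisymmetric under swapping the collections.
    """
    ce, ne = kmer_frequencies(exon_seqs, k)
    ci, ni = kmer_frequencies(intron_seqs, k)
    fe = ce / ne + 1.0 / ne
    fi = ci / ni + 1.0 / ni
    df = pd.DataFrame(
        {
            "hexamer" if k == 6 else "kmer": [decode_kmer(i, k) for i in range(4 ** k)],
            "f_exon": ce / ne,
            "f_intron": ci / ni,
            "log2_enrichment": np.log2(fe / fi),
        }
    )
    if quintile is not None:
        df["quintile"] = quintile
    return EnrichmentTable(df)


def cpg_hexamer_mask(k: int = 6) -> np.ndarray:
    """Boolean mask of k-mers containing the CG dinucleotide."""
    mask = np.zeros(4 ** k, dtype=bool)
    for i in range(4 ** k):
        if "CG" in decode_kmer(i, k):
            mask[i] = True
    return mask


@dataclass
class CorrelationReport:
    r: float
    r2: float
    p: float
    slope: float
    n: int

    @property
    def slope_sign(self) -> int:
        return int(np.sign(self.slope))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"r": self.r, "r2": self.r2, "p": self.p, "slope": self.slope, "n": self.n}]
        )


def correlate_scores(
    enrich: EnrichmentTable, scores: ScoreTable, exclude_cpg: bool = False
) -> CorrelationReport:
    """Pearson correlation of hexamer enrichment against an activity score.

    Uses hexamers present in both tables; ``exclude_cpg`` additionally drops
    the 1023 hexamers containing a CG dinucleotide (testing whether a trend
    survives without the CpG hypermutability signal).  Positive slopes are
    the enhancer (ESE) direction, negative the intron-enriched (ISE)
    direction.
    """
    y = enrich.log2_enrichment
    x = scores.scores
    keep = ~np.isnan(x) & ~np.isnan(y)
    if exclude_cpg:
        keep &= ~cpg_hexamer_mask(scores.k)
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"need >= 3 common hexamers, got {n}")
    xs, ys = x[keep], y[keep]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("degenerate (constant) inputs to correlation")
    lr = stats.linregress(xs, ys)
    return CorrelationReport(
        r=float(lr.rvalue), r2=float(lr.rvalue**2), p=float(lr.pvalue), slope=float(lr.slope), n=n
    )
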