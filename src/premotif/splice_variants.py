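"""Variant-level splicing and population-genetic statistics.

Covers three analyses: (1) the mutant/wild-type (M/W) splice ratio of a
pooled minigene reporter assay, log2((mt_o/mt_i)/(wt_o/wt_i)) over read
counts summed across replicates, where negative values mean the mutation
disrupts splicing; (2) classification of exonic variants falling in the
splice-site region (first or final 3 nt of the exon), which are treated
separately from the synonymous/missense/stop-gain comparison; and (3) mean
context-dependent mutability (ERM rate of the observed ancestral-to-derived
change) of variants binned by effect class and derived allele frequency
(DAF) — under purifying selection, rare variants sit at more mutable sites
than common ones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mutability import BASES, ERMTable

__all__ = [
    "VariantRecord",
    "AssayCounts",
    "EFFECT_CLASSES",
    "DEFAULT_DAF_EDGES",
    "mw_splice_ratio",
    "classify_splice_region",
    "effect_class_comparison",
    "daf_bin_mean_rate",
]

EFFECT_CLASSES = ("intronic", "synonymous", "missense", "stop_gain", "splice_region")

# log10-spaced DAF bin edges spanning the usable range above the
# recurrent-mutation floor of 5e-5
DEFAULT_DAF_EDGES = (5e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass
class VariantRecord:
    """A single-nucleotide variant with its heptamer context and effect."""

    id: str
    heptamer: str
    ref: str
    alt: str
    effect: str
    daf: float | None = None
    exon_rel_pos: int | None = None

    def __post_init__(self) -> None:
        self.heptamer = self.heptamer.upper()
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref == self.alt:
            raise ValueError(f"variant {self.id}: alt equals ref")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"variant {self.id}: invalid ref/alt base")
        if len(self.heptamer) != 7:
            raise ValueError(f"variant {self.id}: heptamer must be 7 nt")
        if self.heptamer[3] != self.ref:
            raise ValueError(
                f"variant {self.id}: heptamer middle base {self.heptamer[3]} != ref {self.ref}"
            )
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(f"variant {self.id}: unknown effect {self.effect!r}")
        if self.daf is not None and not (0 <= self.daf <= 1):
            raise ValueError(f"variant {self.id}: DAF {self.daf} outside [0, 1]")


@dataclass
class AssayCounts:
    """Read counts of one reporter: per-replicate rows plus summed totals.

    ``replicates`` has columns variant_id, replicate, species (mt|wt),
    stage (input|output), count.
    """

    variant_id: str
    replicates: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"variant_id", "replicate", "species", "stage", "count"}
        if not need <= set(self.replicates.columns):
            raise ValueError(f"replicate table missing columns {sorted(need - set(self.replicates.columns))}")
        if (self.replicates["count"] < 0).any():
            raise ValueError(f"negative counts for {self.variant_id}")

    def total(self, species: str, stage: str) -> float:
        sel = (self.replicates["species"] == species) & (self.replicates["stage"] == stage)
        return float(self.replicates.loc[sel, "count"].sum())

    @property
    def mt_i(self) -> float:
        return self.total("mt", "input")

    @property
    def mt_o(self) -> float:
        return self.total("mt", "output")

    @property
    def wt_i(self) -> float:
        return self.total("wt", "input")

    @property
    def wt_o(self) -> float:
        return self.total("wt", "output")

    @classmethod
    def from_totals(
        cls, variant_id: str, mt_i: float, mt_o: float, wt_i: float, wt_o: float
    ) -> "AssayCounts":
        rows = pd.DataFrame(
            {
                "variant_id": variant_id,
                "replicate": "r1",
                "species": ["mt", "mt", "wt", "wt"],
                "stage": ["input", "output", "input", "output"],
                "count": [mt_i, mt_o, wt_i, wt_o],
            }
        )
        return cls(variant_id=variant_id, replicates=rows)


def mw_splice_ratio(counts: AssayCounts, pseudocount: float = 0.0) -> float:
    """log2 mutant output/input odds over wild-type output/input odds.

    Counts are summed over replicates first.  With the default pseudocount
    of 0, any zero term is an error (replicate summing makes zeros rare);
    a pseudocount of e.g. 0.5 makes the ratio total.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    terms = {
        "mt_o": counts.mt_o + pseudocount,
        "mt_i": counts.mt_i + pseudocount,
        "wt_o": counts.wt_o + pseudocount,
        "wt_i": counts.wt_i + pseudocount,
    }
    zeros = [k for k, v in terms.items() if v == 0]
    if zeros:
        raise ValueError(
            f"M/W splice ratio undefined for {counts.variant_id}: zero {', '.join(zeros)} "
            "(consider a pseudocount)"
        )
    return math.log2((terms["mt_o"] / terms["mt_i"]) / (terms["wt_o"] / terms["wt_i"]))


def classify_splice_region(pos: int, exon: tuple[int, int]) -> bool:
    """True iff ``pos`` lies in the first or final 3 nt of the exon.

    ``exon`` is a 0-based half-open interval in the same coordinates as
    ``pos``; positions outside the exon are an error (intronic variants are
    flagged upstream, not here).
    """
    start, end = exon
    if not start <= pos < end:
        raise ValueError(f"position {pos} outside exon [{start}, {end})")
    return pos < start + 3 or pos >= end - 3


def effect_class_comparison(
    values: pd.DataFrame,
    value_col: str = "mw_ratio",
    classes: tuple[str, ...] = ("synonymous", "missense", "stop_gain"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group summaries and pairwise rank tests of splice measures by class.

    ``values`` needs columns ``effect`` and ``value_col``.  Returns
    (summary, pairwise): per-class median/quartiles/n, and two-sided
    Mann-Whitney p-values for each class pair.  Empty classes are skipped
    and reported in ``summary.attrs['empty_classes']``; fewer than two
    nonempty classes is an error.
    """
    groups = {
        c: values.loc[values["effect"] == c, value_col].dropna().to_numpy() for c in classes
    }
    empty = [c for c, v in groups.items() if len(v) == 0]
    groups = {c: v for c, v in groups.items() if len(v) > 0}
    if len(groups) < 2:
        raise ValueError(f"need at least two nonempty classes, got {list(groups)}")
    summary = pd.DataFrame(
        [
            {
                "effect": c,
                "n": len(v),
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
            }
            for c, v in groups.items()
        ]
    )
    summary.attrs["empty_classes"] = empty
    pairs = []
    for a, b in itertools.combinations(groups, 2):
        res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        pairs.append({"class_a": a, "class_b": b, "u": float(res.statistic), "p": float(res.pvalue)})
    return summary, pd.DataFrame(pairs)


def daf_bin_mean_rate(
    variants: list[VariantRecord],
    erm: ERMTable,
    bin_edges: tuple[float, ...] = DEFAULT_DAF_EDGES,
    min_daf: float = 5e-5,
    effects: tuple[str, ...] = ("intronic", "synonymous", "missense", "stop_gain"),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Mean ERM rate of variants per (effect class, DAF bin).

    Variants with absent DAF, DAF below ``min_daf`` (where recurrent
    mutation distorts the frequency spectrum), or effects outside the
    analysis classes are removed; removal counts are returned alongside the
    binned means.  A variant's rate is the table rate of its observed
    ancestral-to-derived change in its heptamer context.
    """
    removed = {"missing_daf": 0, "low_daf": 0, "effect": 0}
    kept: list[VariantRecord] = []
    for v in variants:
        if v.effect not in effects:
            removed["effect"] += 1
        elif v.daf is None:
            removed["missing_daf"] += 1
        elif v.daf < min_daf:
            removed["low_daf"] += 1
        else:
            kept.append(v)
    edges = np.asarray(bin_edges, dtype=float)
    if kept:
        df = pd.DataFrame(
            {
                "effect": [v.effect for v in kept],
                "daf": [v.daf for v in kept],
                "rate": [erm.rate(v.heptamer, v.alt) for v in kept],
            }
        )
        df["daf_bin"] = pd.cut(df["daf"], bins=edges, right=False)
        # the top edge is inclusive so DAF = 1.0 variants are not dropped
        df.loc[df["daf"] == edges[-1], "daf_bin"] = pd.Interval(edges[-2], edges[-1], closed="left")
        out = (
            df.groupby(["effect", "daf_bin"], observed=False)["rate"]
            .agg(mean_rate="mean", n="size")
            .reset_index()
        )
        out["n"] = out["n"].astype(int)
    else:
        out = pd.DataFrame(columns=["effect", "daf_bin", "mean_rate", "n"])
    return out, removed
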