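"""On-disk formats and run configuration.

Conventions applied uniformly at the I/O edge:

* coordinates are normalised to 0-based half-open intervals in transcript
  orientation (GTF arrives 1-based closed, BED 0-based half-open);
* minus-strand features are reverse-complemented before any k-mer work;
* TSV tables are tab-delimited with a required header row and ``.`` for
  missing values;
* k-mers containing N are skipped (never imputed) by downstream counting.

Variants arrive as pre-normalised TSV (no VCF parsing); splicing-assay
counts arrive as a long-format TSV with one row per
(variant, replicate, species, stage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mutability import BASES, N_HEPTAMERS, ERMTable, ScoreTable, encode_kmer

logger = logging.getLogger("premotif")

MISSING = "."

__all__ = [
    "RunConfig",
    "GeneModel",
    "read_erm_table",
    "write_erm_table",
    "read_score_table",
    "write_score_table",
    "read_sequences",
    "write_sequences",
    "read_annotation",
    "write_annotation_bed",
    "read_variant_table",
    "write_variant_table",
    "read_assay_counts",
    "write_assay_counts",
]


@dataclass
class RunConfig:
    """Run configuration; the seed fully determines every stochastic stage.

    Optional inputs left as None are explicit absences — stages that need
    them fail loudly rather than silently defaulting.
    """

    seed: int = 0
    erm_path: str | None = None
    ei_path: str | None = None
    score_paths: dict[str, str] = field(default_factory=dict)
    fasta_path: str | None = None
    annotation_path: str | None = None
    variant_path: str | None = None
    counts_path: str | None = None
    out_prefix: str = "premotif_run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: getattr(self, k) for k in self.__dataclass_fields__}, fh)


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float bit-exactly."""
    return repr(float(x))


def read_erm_table(path: str | Path, require_complete: bool = True) -> ERMTable:
    """Read a heptamer/alt/rate TSV into a complete :class:`ERMTable`.

    Rejects non-ACGT heptamers, alt equal to the middle base, duplicate
    (heptamer, alt) rows and non-positive rates; with ``require_complete``
    (the default) missing (heptamer, alt) keys are reported.
    """
    df = pd.read_csv(path, sep="\t", dtype={"heptamer": str, "alt": str}, float_precision="round_trip")
    for col in ("heptamer", "alt", "rate"):
        if col not in df.columns:
            raise ValueError(f"ERM table {path} is missing column {col!r}")
    rates = np.full((N_HEPTAMERS, 4), np.nan)
    seen = np.zeros((N_HEPTAMERS, 4), dtype=bool)
    base_idx = {b: i for i, b in enumerate(BASES)}
    for row in df.itertuples(index=False):
        hept, alt, rate = row.heptamer, row.alt, float(row.rate)
        if len(hept) != 7 or any(c not in BASES for c in hept):
            raise ValueError(f"invalid heptamer {hept!r}")
        if alt not in BASES:
            raise ValueError(f"invalid alt base {alt!r}")
        if alt == hept[3]:
            raise ValueError(f"alt equals the middle reference base in row ({hept}, {alt})")
        if rate <= 0 or not np.isfinite(rate):
            raise ValueError(f"non-positive rate for ({hept}, {alt}): {rate}")
        h, a = encode_kmer(hept), base_idx[alt]
        if seen[h, a]:
            raise ValueError(f"duplicate (heptamer, alt) row: ({hept}, {alt})")
        seen[h, a] = True
        rates[h, a] = rate
    if require_complete:
        mid = ERMTable.middle_bases()
        expected = np.ones((N_HEPTAMERS, 4), dtype=bool)
        expected[np.arange(N_HEPTAMERS), mid] = False
        missing = expected & ~seen
        if missing.any():
            from .mutability import decode_kmer

            keys = [
                f"({decode_kmer(int(h), 7)}, {BASES[a]})"
                for h, a in zip(*np.nonzero(missing))
            ][:10]
            raise ValueError(
                f"ERM table {path} is incomplete: {int(missing.sum())} missing keys, "
                f"e.g. {', '.join(keys)}"
            )
    return ERMTable(rates)


def write_erm_table(erm: ERMTable, path: str | Path) -> None:
    df = erm.to_frame()
    df["rate"] = df["rate"].map(_fmt)
    df.to_csv(path, sep="\t", index=False)


def read_score_table(path: str | Path, k: int = 6, name: str = "score") -> ScoreTable:
    """Read a k-mer score TSV; partial tables are allowed, duplicates are not.

    The first column is the k-mer, the second the score.  Non-numeric scores
    raise a parse error naming the offending row; missing k-mers remain
    explicit absences queryable via :attr:`ScoreTable.n_missing`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"score table {path} needs at least two columns")
    kmer_col, score_col = df.columns[0], df.columns[1]
    scores = np.full(4 ** k, np.nan)
    seen = np.zeros(4 ** k, dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        kmer = getattr(row, kmer_col, None) or row[0]
        raw = row[1]
        if len(kmer) != k or any(c not in BASES for c in kmer):
            raise ValueError(f"invalid {k}-mer {kmer!r} at row {i + 2} of {path}")
        try:
            val = float(raw)
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric score {raw!r} for {kmer} at row {i + 2} of {path}"
            ) from None
        idx = encode_kmer(kmer)
        if seen[idx]:
            raise ValueError(f"duplicate {k}-mer {kmer} in {path}")
        seen[idx] = True
        scores[idx] = val
    table = ScoreTable(scores, k=k, name=name)
    if table.n_missing:
        logger.info("score table %s has %d absent %d-mers", path, table.n_missing, k)
    return table


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    df = table.to_frame()
    df[table.name] = df[table.name].map(_fmt)
    df.to_csv(path, sep="\t", index=False)


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def write_sequences(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class GeneModel:
    """Exon structure of one transcript (0-based half-open, genome coords)."""

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if not a < b:
                raise ValueError(f"empty or inverted exon [{a}, {b}) in {self.transcript_id}")
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if a2 < b1:
                raise ValueError(f"overlapping exons within transcript {self.transcript_id}")

    def exon_sequences(self, seqs: dict[str, str]) -> list[str]:
        """Transcript-oriented exon sequences (reverse-complemented on '-')."""
        chrom_seq = seqs[self.chrom]
        out = []
        for a, b in self.exons:
            if b > len(chrom_seq):
                raise ValueError(
                    f"exon [{a}, {b}) of {self.transcript_id} outside {self.chrom} "
                    f"(length {len(chrom_seq)})"
                )
            out.append(chrom_seq[a:b])
        if self.strand == "-":
            out = [str(Seq(s).reverse_complement()) for s in reversed(out)]
        return out


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read exon annotation from GTF/GFF (1-based closed) or BED (0-based
    half-open), normalised to internal 0-based half-open coordinates."""
    path = Path(path)
    suffix = path.suffix.lower()
    by_tx: dict[str, dict] = {}
    if suffix in (".gtf", ".gff", ".gff3"):
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attrs"],
            dtype={"chrom": str, "attrs": str},
        )
        df = df[df["feature"] == "exon"]
        if df.empty:
            raise ValueError(f"no exon features in {path}")
        tx_id = df["attrs"].str.extract(r'transcript_id[ =]"?([^";]+)"?')[0]
        if tx_id.isna().any():
            raise ValueError(f"exon rows without transcript_id attribute in {path}")
        for (chrom, strand, tid, start, end) in zip(
            df["chrom"], df["strand"], tx_id, df["start"], df["end"]
        ):
            entry = by_tx.setdefault(tid, {"chrom": chrom, "strand": strand, "exons": []})
            entry["exons"].append((int(start) - 1, int(end)))  # GTF 1-based closed -> half-open
    elif suffix == ".bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 4:
            raise ValueError(f"BED annotation {path} needs >= 4 columns (name = transcript id)")
        for row in df.itertuples(index=False):
            chrom, start, end, tid = row[0], int(row[1]), int(row[2]), row[3]
            strand = row[5] if len(row) > 5 and row[5] in ("+", "-") else "+"
            entry = by_tx.setdefault(tid, {"chrom": chrom, "strand": strand, "exons": []})
            entry["exons"].append((start, end))
    else:
        raise ValueError(f"unrecognised annotation format {suffix!r} (use .gtf/.gff/.bed)")
    return [
        GeneModel(transcript_id=tid, chrom=e["chrom"], strand=e["strand"], exons=e["exons"])
        for tid, e in by_tx.items()
    ]


def write_annotation_bed(genes: list[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        for a, b in g.exons:
            rows.append((g.chrom, a, b, g.transcript_id, 0, g.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_variant_table(path: str | Path):
    """Read a pre-normalised variant TSV into VariantRecord objects.

    Columns: id, heptamer, ref, alt, effect, daf, exon_rel_pos ('.' = absent).
    """
    from .splice_variants import VariantRecord

    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    required = {"id", "heptamer", "ref", "alt", "effect"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table {path} is missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        daf = getattr(row, "daf", None)
        pos = getattr(row, "exon_rel_pos", None)
        records.append(
            VariantRecord(
                id=row.id,
                heptamer=row.heptamer,
                ref=row.ref,
                alt=row.alt,
                effect=row.effect,
                daf=float(daf) if daf not in (None, "") and not pd.isna(daf) else None,
                exon_rel_pos=int(pos) if pos not in (None, "") and not pd.isna(pos) else None,
            )
        )
    return records


def write_variant_table(variants, path: str | Path) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "id": v.id,
                "heptamer": v.heptamer,
                "ref": v.ref,
                "alt": v.alt,
                "effect": v.effect,
                "daf": _fmt(v.daf) if v.daf is not None else MISSING,
                "exon_rel_pos": v.exon_rel_pos if v.exon_rel_pos is not None else MISSING,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_assay_counts(path: str | Path):
    """Read long-format splicing-assay counts into AssayCounts objects.

    Columns: variant_id, replicate, species (mt|wt), stage (input|output),
    count.  Totals are sums over replicates per (species, stage).
    """
    from .splice_variants import AssayCounts

    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "replicate": str})
    required = {"variant_id", "replicate", "species", "stage", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay count table {path} is missing columns {sorted(missing)}")
    if not df["species"].isin(["mt", "wt"]).all():
        raise ValueError("species column must be 'mt' or 'wt'")
    if not df["stage"].isin(["input", "output"]).all():
        raise ValueError("stage column must be 'input' or 'output'")
    if (df["count"] < 0).any():
        raise ValueError("negative read counts")
    out = []
    for vid, grp in df.groupby("variant_id", sort=False):
        out.append(AssayCounts(variant_id=vid, replicates=grp.reset_index(drop=True)))
    return out


def write_assay_counts(counts, path: str | Path) -> None:
    pd.concat([c.replicates for c in counts], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
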