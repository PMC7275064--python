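"""Generators for every input the pipeline consumes.

The generators emulate the statistical structure the analyses assume,
without any download:

* a heptamer rate table with heavy-tailed (log-normal) context effects, a
  transition/transversion skew, a CpG-context C>T (and complementary G>A)
  hotspot, and a purine-context G>T hotspot — so the synthetic spectrum has
  the same qualitative hotspot anatomy and a several-hundred-fold dynamic
  range like empirical heptamer rate tables;
* hexamer activity scores coupled to log mean mutability at an exactly
  planted sample correlation (Gaussian mixing with residual
  orthogonalisation);
* gene models whose exons come from a protein-constrained simulation and
  introns from a matched unconstrained simulation, written as FASTA + BED;
* variant sets with effects classified on their codon context and derived
  allele frequencies depleted at high-mutability constrained sites;
* splicing-assay count tables in which stop-gain variants carry the largest
  planted splicing disruption (class effects 0 / -0.5 / -2 in log2 units).

Every generator is a pure function of (spec, rng seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evolve_sim import SimConfig, SimGenome, run
from .io_core import GeneModel
from .mutability import (
    BASES,
    N_HEPTAMERS,
    N_HEXAMERS,
    ERMTable,
    HexamerRateTable,
    ScoreTable,
    decode_kmer,
)
from .protein_code import GENETIC_CODE, STOP_CODONS, classify_mutation
from .splice_variants import AssayCounts, VariantRecord

__all__ = [
    "SynthSpec",
    "gen_erm_table",
    "gen_score_table",
    "gen_gene_models",
    "gen_variants",
    "gen_assay_counts",
]


@dataclass
class SynthSpec:
    """Parameters of the synthetic-data generators.

    Rate-model parameters shape the heptamer table: ``rate_sigma`` is the
    log-normal context noise (natural-log units), the multipliers (> 0)
    boost transitions, CpG-context deamination-like changes and
    purine-context G>T changes.  ``score_rho`` is the planted correlation
    between hexamer log mean rate and the synthetic activity score.
    Gene-model, variant and assay parameters control the scale of the
    downstream fixtures.
    """

    rate_sigma: float = 0.8
    ti_tv: float = 4.0
    cpg_mult: float = 12.0
    gt_purine_mult: float = 8.0
    score_rho: float = 0.7
    score_loc: float = 0.25
    score_scale: float = 0.2
    n_genes: int = 30
    exon_len: int = 300
    intron_len: int = 300
    gene_tau: float = 5.0
    n_variants: int = 500
    intronic_fraction: float = 0.3
    daf_coupling: float = 1.0
    assay_effects: dict[str, float] = field(
        default_factory=lambda: {"synonymous": 0.0, "missense": -0.5, "stop_gain": -2.0}
    )
    assay_sigma: float = 0.5
    assay_depth: int = 1000
    assay_count_model: str = "poisson"  # "poisson" | "exact"

    def __post_init__(self) -> None:
        for name in ("ti_tv", "cpg_mult", "gt_purine_mult"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not -1 <= self.score_rho <= 1:
            raise ValueError("score_rho must lie in [-1, 1]")
        if self.exon_len % 3:
            raise ValueError("exon_len must be a multiple of 3 (exons are coding)")


_PURINES = (0, 2)  # A, G


def gen_erm_table(spec: SynthSpec, rng: np.random.Generator) -> ERMTable:
    """Synthetic complete heptamer rate table.

    Log-rates are iid normal(0, rate_sigma) per (heptamer, alt), plus log
    multipliers for transitions (A<->G, C<->T), CpG-context deamination
    (middle C with G following and alt T, or the reverse-complement
    pattern), and the purine-context G>T hotspot (middle G flanked by
    purines, alt T).  Rates are normalised to geometric mean 1.
    """
    hepts = np.arange(N_HEPTAMERS)
    digits = np.stack([(hepts >> (2 * (6 - i))) & 3 for i in range(7)], axis=1)
    mid = digits[:, 3]
    log_rates = np.full((N_HEPTAMERS, 4), np.nan)
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for alt in range(4):
        valid = mid != alt
        lr = rng.normal(0.0, spec.rate_sigma, size=N_HEPTAMERS)
        if spec.ti_tv != 1.0:
            is_ti = np.array([(int(m), alt) in transitions for m in range(4)])[mid]
            lr = lr + np.where(is_ti, np.log(spec.ti_tv), 0.0)
        if spec.cpg_mult != 1.0:
            cpg_ct = (mid == 1) & (digits[:, 4] == 2) & (alt == 3)  # C[pG] > T
            cpg_ga = (mid == 2) & (digits[:, 2] == 1) & (alt == 0)  # [Cp]G > A (rev comp)
            lr = lr + np.where(cpg_ct | cpg_ga, np.log(spec.cpg_mult), 0.0)
        if spec.gt_purine_mult != 1.0:
            hot = (
                (mid == 2)
                & (alt == 3)
                & np.isin(digits[:, 2], _PURINES)
                & np.isin(digits[:, 4], _PURINES)
            )
            lr = lr + np.where(hot, np.log(spec.gt_purine_mult), 0.0)
        log_rates[valid, alt] = lr[valid]
    off = ~np.isnan(log_rates)
    log_rates[off] -= log_rates[off].mean()
    rates = np.where(off, np.exp(log_rates), np.nan)
    return ERMTable(rates)


def gen_score_table(
    spec: SynthSpec, hex_rates: HexamerRateTable, rng: np.random.Generator
) -> ScoreTable:
    """Activity scores with an exactly planted correlation to log mutability.

    The score is rho * z + sqrt(1 - rho^2) * e where z is the standardised
    log mean hexamer rate and e is standard-normal noise orthogonalised
    against z, so the sample Pearson correlation over the 4096 hexamers
    equals rho up to floating error.  Scores are affinely placed around
    ``score_loc`` with spread ``score_scale`` (correlation-invariant).
    """
    z = np.log(hex_rates.mean_rate)
    z = (z - z.mean()) / z.std()
    rho = spec.score_rho
    if abs(rho) == 1.0:
        mixed = np.sign(rho) * z
    else:
        e = rng.normal(size=N_HEXAMERS)
        e = e - e.mean() - z * (e @ z) / (z @ z)  # residualise against z and the constant
        e /= e.std()
        mixed = rho * z + np.sqrt(1 - rho**2) * e
    scores = spec.score_loc + spec.score_scale * mixed
    return ScoreTable(scores, k=6, name="score")


def gen_gene_models(
    spec: SynthSpec,
    erm: ERMTable,
    rng: np.random.Generator,
    tau: float | None = None,
) -> tuple[dict[str, str], list[GeneModel], SimGenome, SimGenome]:
    """Synthetic intron-exon-intron genes from matched simulations.

    Exon sequences come from a protein-constrained simulation and intron
    sequences from an unconstrained one, both evolved to the same tau.  Each
    gene occupies its own chromosome (intron, exon, intron concatenated with
    short neutral pads so every window position has sequence context);
    exon coordinates are recorded exactly.  Returns (sequences, gene
    models, constrained genome, unconstrained genome); the genomes allow
    block-level mutability comparisons without re-extraction.
    """
    tau = spec.gene_tau if tau is None else tau
    seed_c, seed_u = rng.integers(0, 2**31 - 1, size=2)
    interval = tau if tau > 0 else 1.0
    cfg_c = SimConfig(
        n_sequences=spec.n_genes,
        seq_length=spec.exon_len,
        constraint="protein",
        record_interval=interval,
        t_max=max(tau, interval),
        seed=int(seed_c),
    )
    cfg_u = SimConfig(
        n_sequences=2 * spec.n_genes,
        seq_length=spec.intron_len,
        constraint="none",
        record_interval=interval,
        t_max=max(tau, interval),
        seed=int(seed_u),
    )
    if tau == 0:
        from .evolve_sim import init_genome

        genome_c = init_genome(cfg_c, erm, np.random.default_rng(cfg_c.seed))
        genome_u = init_genome(cfg_u, erm, np.random.default_rng(cfg_u.seed))
    else:
        _, genome_c = run(cfg_c, erm, return_genome=True)
        _, genome_u = run(cfg_u, erm, return_genome=True)
    pad = 10
    seqs: dict[str, str] = {}
    genes: list[GeneModel] = []
    ex_seqs = genome_c.sequences()
    in_seqs = genome_u.sequences()
    pad_bases = "".join(BASES[i] for i in rng.integers(0, 4, size=pad))
    for g in range(spec.n_genes):
        chrom = f"chr_g{g}"
        left, right = in_seqs[2 * g], in_seqs[2 * g + 1]
        seq = pad_bases + left + ex_seqs[g] + right + pad_bases
        exon_start = pad + spec.intron_len
        genes.append(
            GeneModel(
                transcript_id=f"tx_g{g}",
                chrom=chrom,
                strand="+",
                exons=[(exon_start, exon_start + spec.exon_len)],
            )
        )
        seqs[chrom] = seq
    return seqs, genes, genome_c, genome_u


def gen_variants(
    spec: SynthSpec,
    seqs: dict[str, str],
    genes: list[GeneModel],
    erm: ERMTable,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Synthetic variant set over the gene models.

    Coding variants get their effect from the genetic code at the site's
    codon (exon frame 0); alternates are drawn proportionally to the ERM
    rates of the heptamer context.  Derived allele frequencies are drawn
    log-uniform, then shifted down for missense/stop-gain variants by
    ``daf_coupling`` times the standardised site rate, planting the
    depletion of high-mutability constrained sites at high frequencies.  A
    fraction of variants is intronic (no coupling).
    """
    candidates = []  # (region, gene index, genomic position)
    for gi, gene in enumerate(genes):
        seq = seqs[gene.chrom]
        (a, b) = gene.exons[0]
        for pos in range(a, b):
            candidates.append(("exon", gi, pos))
        for pos in range(max(3, a - spec.intron_len), a):
            candidates.append(("intron", gi, pos))
        for pos in range(b, min(len(seq) - 3, b + spec.intron_len)):
            candidates.append(("intron", gi, pos))
    if not candidates:
        raise ValueError("no candidate sites in gene models")
    variants: list[VariantRecord] = []
    n_target = spec.n_variants
    picks = rng.integers(0, len(candidates), size=4 * n_target)
    site_log_rates: list[float] = []
    drafts = []
    for pick in picks:
        if len(drafts) >= n_target:
            break
        region, gi, pos = candidates[pick]
        gene = genes[gi]
        seq = seqs[gene.chrom]
        hept = seq[pos - 3 : pos + 4]
        if len(hept) != 7 or any(c not in BASES for c in hept):
            continue
        ref = seq[pos]
        want_intronic = rng.random() < spec.intronic_fraction
        if (region == "intron") != want_intronic:
            continue
        r3 = erm.rates[_hept_index(hept)]
        w = np.nan_to_num(r3, nan=0.0)
        alt_idx = rng.choice(4, p=w / w.sum())
        alt = BASES[alt_idx]
        if region == "exon":
            (a, b) = gene.exons[0]
            off = pos - a
            codon_start = a + 3 * (off // 3)
            codon = seq[codon_start : codon_start + 3]
            if codon in STOP_CODONS:
                continue
            effect = classify_mutation(codon, off % 3 + 1, alt)
            exon_rel = min(off, b - 1 - pos)
        else:
            effect = "intronic"
            exon_rel = None
        rate = float(erm.rates[_hept_index(hept), alt_idx])
        drafts.append((region, hept, ref, alt, effect, exon_rel, rate))
        site_log_rates.append(np.log(rate))
    if not drafts:
        raise ValueError("no variants could be drawn")
    lr = np.array(site_log_rates)
    z = (lr - lr.mean()) / (lr.std() if lr.std() > 0 else 1.0)
    for i, (region, hept, ref, alt, effect, exon_rel, rate) in enumerate(drafts):
        log10_daf = rng.uniform(-4.2, -0.1)
        if spec.daf_coupling and effect in ("missense", "stop_gain"):
            log10_daf -= spec.daf_coupling * z[i]
        daf = float(np.clip(10**log10_daf, 1e-6, 0.999))
        variants.append(
            VariantRecord(
                id=f"v{i}",
                heptamer=hept,
                ref=ref,
                alt=alt,
                effect=effect,
                daf=daf,
                exon_rel_pos=exon_rel,
            )
        )
    return variants


def _hept_index(hept: str) -> int:
    idx = 0
    for c in hept:
        idx = idx * 4 + {"A": 0, "C": 1, "G": 2, "T": 3}[c]
    return idx


def gen_assay_counts(
    spec: SynthSpec, variants: list[VariantRecord], rng: np.random.Generator
) -> list[AssayCounts]:
    """Synthetic reporter counts around planted class effect sizes.

    Each coding variant's true log2 M/W ratio is its class effect plus
    normal noise (sd = assay_sigma).  Counts follow a Poisson model around
    the planted ratio at ``assay_depth`` reads per replicate (2 input and 4
    output replicates per species); ``assay_count_model='exact'`` instead
    writes the rounded expected counts, so at sigma=0 the ratio is
    recovered to rounding precision.  Variants outside the three coding
    classes are skipped.
    """
    if spec.assay_count_model not in ("poisson", "exact"):
        raise ValueError(f"unknown assay_count_model {spec.assay_count_model!r}")
    out: list[AssayCounts] = []
    splice_eff = 0.5  # wild-type output/input odds
    for v in variants:
        if v.effect not in spec.assay_effects:
            continue
        true = spec.assay_effects[v.effect]
        if spec.assay_sigma > 0:
            true = true + rng.normal(0.0, spec.assay_sigma)
        lam = {
            ("wt", "input"): spec.assay_depth,
            ("mt", "input"): spec.assay_depth,
            ("wt", "output"): spec.assay_depth * splice_eff,
            ("mt", "output"): spec.assay_depth * splice_eff * 2.0**true,
        }
        rows = []
        for species in ("mt", "wt"):
            for stage, n_rep in (("input", 2), ("output", 4)):
                per = lam[(species, stage)] / n_rep
                for r in range(n_rep):
                    if spec.assay_count_model == "poisson":
                        count = int(rng.poisson(per))
                    else:
                        count = int(round(per))
                    rows.append(
                        {
                            "variant_id": v.id,
                            "replicate": f"{stage[0]}{r + 1}",
                            "species": species,
                            "stage": stage,
                            "count": count,
                        }
                    )
        out.append(AssayCounts(variant_id=v.id, replicates=pd.DataFrame(rows)))
    return out
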