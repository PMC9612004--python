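"""Synthetic genomes, annotations and junction tables with planted truth.

The generator emulates the salient architecture of the *P. tetraurelia*
macronuclear genome: many short genes, ~25 bp introns concentrated in the
21–30 bp band, AT-rich exons (~72%) and introns (~80%), ~69% of introns
with the optimal GTA…TAG boundary configuration, lognormal expression, and
multinomially sampled spliced/retained/alternative read counts per locus.
Base composition is symmetric within complement pairs (pA = pT, pG = pC) so
that, absent planted depletion, sense and antisense segment counts agree in
expectation and the DSA baseline is exactly zero.

Every generator is a pure function of (params, seed); truth tables record
each planted property for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from intronsig.coding_exome import EnumerationParams, enumerate_gt_ag_segments
from intronsig.genome_io import (
    ExpressionTable,
    GeneModel,
    JunctionRecord,
    revcomp,
    write_expression_table,
    write_fasta,
    write_gff3,
    write_junction_table,
    write_tsv,
)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic genome.

    Lengths in nucleotides.  Exon lengths are lognormal with median
    ``exon_len_median`` (194 bp) and mean ≈ 354 bp; intron lengths are
    drawn from a discrete distribution putting ``intron_prevalent_mass``
    of its mass uniformly on the 21–30 band.  ``at_exon``/``at_intron``
    are AT fractions split equally between A and T (and G/C equally),
    keeping composition complement-symmetric.
    """

    n_genes: int = 500
    mean_introns_per_gene: float = 2.9
    exon_len_median: float = 194.0
    exon_len_sigma: float = 1.097  # lognormal sigma giving mean ~354
    min_exon_len: int = 30
    max_exon_len: int = 3000
    intron_prevalent_mass: float = 0.95
    intron_range: tuple[int, int] = (15, 35)
    intron_prevalent_range: tuple[int, int] = (21, 30)
    at_exon: float = 0.72
    at_intron: float = 0.80
    gta_tag_intron_fraction: float = 0.69
    expression_meanlog: float = 4.0
    expression_sdlog: float = 1.5
    genes_per_chromosome: int = 50
    intergenic_len: int = 100
    # per-locus read simulation
    depth_mean: float = 100.0
    level_dirichlet_alpha: tuple[float, float, float] = (5.0, 4.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("intron_prevalent_mass", "at_exon", "at_intron",
                     "gta_tag_intron_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")


@dataclass
class SimulatedDataset:
    """In-memory result of :func:`simulate_genome`."""

    sequences: dict[str, str]
    genes: list[GeneModel]
    expression: ExpressionTable
    truth_genes: pd.DataFrame
    truth_introns: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, outdir / "genome.fasta")
        write_gff3(self.genes, outdir / "annotation.gff3")
        write_expression_table(self.expression, outdir / "expression.tsv")
        write_tsv(self.truth_genes, outdir / "truth_genes.tsv")
        write_tsv(self.truth_introns, outdir / "truth_introns.tsv")


def _base_probs(at: float) -> np.ndarray:
    return np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])


def _random_seq(rng: np.random.Generator, length: int, at: float) -> str:
    return "".join(rng.choice(BASES, size=length, p=_base_probs(at)))


def _intron_length_dist(params: SimulationParams) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = params.intron_range
    plo, phi = params.intron_prevalent_range
    sizes = np.arange(lo, hi + 1)
    inside = (sizes >= plo) & (sizes <= phi)
    probs = np.where(inside, params.intron_prevalent_mass / inside.sum(), 0.0)
    n_out = (~inside).sum()
    if n_out:
        probs = probs + np.where(~inside, (1 - params.intron_prevalent_mass) / n_out, 0.0)
    return sizes, probs / probs.sum()


def _intron_sequence(rng: np.random.Generator, length: int, params: SimulationParams) -> tuple[str, bool]:
    optimal = bool(rng.random() < params.gta_tag_intron_fraction)
    prefix = "GTA" if optimal else "GT"
    suffix = "TAG" if optimal else "AG"
    interior = _random_seq(rng, length - len(prefix) - len(suffix), params.at_intron)
    if not optimal:
        # keep the planted GTA…TAG fraction exact: a non-optimal intron
        # must not read GTA…TAG by chance
        while interior[0] == "A" and interior[-1] == "T":
            interior = _random_seq(rng, len(interior), params.at_intron)
    return prefix + interior + suffix, optimal


def simulate_genome(params: SimulationParams) -> SimulatedDataset:
    """Generate a genome + annotation + expression table with known truth.

    Genes are laid out on chromosomes of ``genes_per_chromosome`` genes
    separated by intergenic spacers; strand is random.  Exons are iid
    nucleotides at the exonic AT fraction (no codon model), introns carry
    GT…AG boundaries with the configured GTA…TAG fraction.
    """
    rng = np.random.default_rng(params.seed)
    sizes, size_probs = _intron_length_dist(params)

    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    truth_gene_rows = []
    truth_intron_rows = []
    expr_values: dict[str, float] = {}

    n_chroms = int(np.ceil(params.n_genes / params.genes_per_chromosome))
    gene_counter = 0
    for c in range(n_chroms):
        chrom = f"scaffold_{c + 1:04d}"
        parts: list[str] = []
        pos = 0
        n_here = min(params.genes_per_chromosome, params.n_genes - gene_counter)
        for _ in range(n_here):
            gid = f"g{gene_counter + 1:05d}"
            gene_counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_introns = int(rng.poisson(params.mean_introns_per_gene))
            n_exons = n_introns + 1
            exon_lens = np.clip(
                np.round(
                    rng.lognormal(np.log(params.exon_len_median),
                                  params.exon_len_sigma, size=n_exons)
                ).astype(int),
                params.min_exon_len,
                params.max_exon_len,
            )
            intron_lens = rng.choice(sizes, size=n_introns, p=size_probs)

            spacer = _random_seq(rng, params.intergenic_len, params.at_exon)
            parts.append(spacer)
            pos += len(spacer)

            # build the gene 5'→3' on its sense strand, then place it
            exon_seqs = [_random_seq(rng, int(L), params.at_exon) for L in exon_lens]
            intron_seqs = []
            optimal_flags = []
            for L in intron_lens:
                s, opt = _intron_sequence(rng, int(L), params)
                intron_seqs.append(s)
                optimal_flags.append(opt)
            pieces = [exon_seqs[0]]
            for i in range(n_introns):
                pieces.append(intron_seqs[i])
                pieces.append(exon_seqs[i + 1])
            gene_seq = "".join(pieces)
            genomic = gene_seq if strand == "+" else revcomp(gene_seq)

            # transcription-order exon offsets within gene_seq
            offsets = []
            off = 0
            for i in range(n_exons):
                offsets.append((off, off + len(exon_seqs[i])))
                off += len(exon_seqs[i])
                if i < n_introns:
                    off += len(intron_seqs[i])
            glen = len(gene_seq)
            if strand == "+":
                exon_ivs = [(pos + a, pos + b) for a, b in offsets]
            else:
                exon_ivs = sorted((pos + glen - b, pos + glen - a) for a, b in offsets)

            parts.append(genomic)
            pos += glen

            expr = float(rng.lognormal(params.expression_meanlog,
                                       params.expression_sdlog))
            expr_values[gid] = expr
            gene = GeneModel(gid, chrom, strand, exon_ivs, expression=expr)
            genes.append(gene)
            truth_gene_rows.append(
                (gid, chrom, strand, n_exons,
                 int(sum(exon_lens)), expr)
            )
            for i, (iv, opt) in enumerate(
                zip(gene.introns_transcribed(), optimal_flags)
            ):
                truth_intron_rows.append(
                    (gid, i, chrom, iv[0], iv[1], iv[1] - iv[0], opt)
                )
        parts.append(_random_seq(rng, params.intergenic_len, params.at_exon))
        sequences[chrom] = "".join(parts)

    return SimulatedDataset(
        sequences=sequences,
        genes=genes,
        expression=ExpressionTable(expr_values),
        truth_genes=pd.DataFrame(
            truth_gene_rows,
            columns=["gene_id", "chromosome", "strand", "n_exons",
                     "cds_length", "expression"],
        ),
        truth_introns=pd.DataFrame(
            truth_intron_rows,
            columns=["gene_id", "intron_index", "chromosome", "start", "end",
                     "length", "gta_tag"],
        ),
    )


@dataclass(frozen=True)
class DepletionStratum:
    """Which sense-strand segments the depletion edit targets."""

    signal_class: str = "GTA|TAG"
    mod3_class: str | None = "3n"
    size_range: tuple[int, int] | None = (21, 30)


def apply_strand_depletion(
    sequences: Mapping[str, str],
    genes: Sequence[GeneModel],
    stratum: DepletionStratum,
    delta: float,
    seed: int,
    params: EnumerationParams = EnumerationParams(),
) -> tuple[dict[str, str], pd.DataFrame]:
    """Disrupt sense-strand segments of a stratum with probability δ each.

    A disrupted segment loses the A of its leading GTA (mutated to C), so
    it leaves the GTA|TAG class while the segment-length distribution and
    the GT|AG backbone are otherwise preserved.  Antisense counts are
    untouched in expectation.  Enumeration runs on the pre-edit sequences;
    edits are applied afterwards and logged.

    Returns (edited sequences, edit log).
    """
    if not 0 <= delta <= 1:
        raise ValueError("delta must be in [0, 1]")
    if stratum.signal_class != "GTA|TAG":
        raise ValueError("depletion edit is defined for the GTA|TAG class")
    rng = np.random.default_rng(seed)
    editable = {c: bytearray(s, "ascii") for c, s in sequences.items()}
    log_rows = []
    for gene in genes:
        chrom_seq = sequences[gene.chromosome]
        for exon_iv in gene.exons_transcribed():
            a, b = exon_iv
            sense_seq = chrom_seq[a:b]
            if gene.strand == "-":
                sense_seq = revcomp(sense_seq)
            for seg in enumerate_gt_ag_segments(sense_seq, params, "sense"):
                if seg.signal_class != stratum.signal_class:
                    continue
                if stratum.mod3_class and seg.mod3_class != stratum.mod3_class:
                    continue
                if stratum.size_range and not (
                    stratum.size_range[0] <= seg.length <= stratum.size_range[1]
                ):
                    continue
                if rng.random() >= delta:
                    continue
                local = seg.start + 2  # the A of the segment's GTA
                if gene.strand == "+":
                    gpos = a + local
                    new = "C"
                else:
                    gpos = b - 1 - local
                    new = "G"  # complement of C on the plus strand
                old = chr(editable[gene.chromosome][gpos])
                editable[gene.chromosome][gpos] = ord(new)
                log_rows.append(
                    (gene.gene_id, gene.chromosome, gpos, old, new,
                     seg.start, seg.end, seg.length)
                )
    edited = {c: bytes(s).decode("ascii") for c, s in editable.items()}
    log = pd.DataFrame(
        log_rows,
        columns=["gene_id", "chromosome", "genomic_pos", "old", "new",
                 "segment_start", "segment_end", "segment_length"],
    )
    return edited, log


def expected_dsa(delta: float) -> float:
    """Closed-form DSA after sense-strand depletion at rate δ.

    With equal baseline sense/antisense rates, Ns → (1−δ)·N and Na = N, so
    S = −δ/(2−δ).
    """
    if not 0 <= delta <= 1:
        raise ValueError("delta must be in [0, 1]")
    return -delta / (2 - delta)


def simulate_junction_counts(
    loci: pd.DataFrame,
    params: SimulationParams,
    seed: int | None = None,
) -> tuple[list[JunctionRecord], pd.DataFrame, pd.DataFrame]:
    """Multinomial read counts for loci with planted true levels.

    ``loci`` columns: locus_id, chromosome, start, end, annotated
    (boolean), and either planted ``splicing_level``/``retention_level``/
    ``alt_usage`` (must sum to 1) or nothing, in which case levels are
    drawn from the Dirichlet prior in ``params``.  A ``depth`` column
    overrides the Poisson(depth_mean) read depth.

    Returns (junction records, per-locus count table, truth table).
    Spliced reads become a junction row at the locus interval; alternative
    reads a junction sharing the donor with a +3 nt acceptor; retained
    reads appear only in the count table (they span, not splice).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    loci = loci.copy()
    has_levels = {"splicing_level", "retention_level", "alt_usage"} <= set(loci.columns)
    if not has_levels:
        draws = rng.dirichlet(params.level_dirichlet_alpha, size=len(loci))
        loci["splicing_level"] = draws[:, 0]
        loci["retention_level"] = draws[:, 1]
        loci["alt_usage"] = draws[:, 2]
    sums = loci[["splicing_level", "retention_level", "alt_usage"]].sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError("planted levels must sum to 1 per locus")
    if "depth" not in loci.columns:
        loci["depth"] = rng.poisson(params.depth_mean, size=len(loci))

    junctions: list[JunctionRecord] = []
    count_rows = []
    for rec in loci.itertuples(index=False):
        n = int(rec.depth)
        spliced, retained, alt = rng.multinomial(
            n, [rec.splicing_level, rec.retention_level, rec.alt_usage]
        )
        if spliced > 0:
            junctions.append(
                JunctionRecord(rec.chromosome, int(rec.start), int(rec.end),
                               "+", int(spliced), bool(rec.annotated))
            )
        if alt > 0:
            junctions.append(
                JunctionRecord(rec.chromosome, int(rec.start),
                               int(rec.end) + 3, "+", int(alt), False)
            )
        count_rows.append(
            (rec.locus_id, rec.chromosome, int(rec.start), int(rec.end),
             int(spliced), int(retained), int(alt))
        )
    counts = pd.DataFrame(
        count_rows,
        columns=["locus_id", "chromosome", "start", "end",
                 "spliced", "retained", "alt"],
    )
    truth = loci[
        ["locus_id", "chromosome", "start", "end",
         "splicing_level", "retention_level", "alt_usage", "depth"]
    ].copy()
    return junctions, counts, truth
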