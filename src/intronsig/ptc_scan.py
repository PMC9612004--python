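"""Premature-termination-codon scanning under the ciliate nuclear code.

In *Paramecium* (translation table 6) TAA and TAG are reassigned to
glutamine, leaving TGA as the only stop codon.  A retained intron carries a
PTC iff, reading the unspliced transcript in the gene's frame, some codon
intersecting the intron equals TGA.  The intron's *phase* is the number of
nucleotides of the interrupted codon already emitted by the upstream exons
(phase = upstream CDS length mod 3), so codons can span the exon–intron
boundaries; a switch restricts the scan to fully intronic codons.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from intronsig.genome_io import GeneModel

STOP_CODON = "TGA"  # the single stop under translation table 6


def intron_phase(gene: GeneModel, intron_index: int) -> int:
    """Phase of an intron: upstream CDS nucleotides mod 3.

    ``intron_index`` counts introns in transcription order.
    """
    introns = gene.introns_transcribed()
    if not 0 <= intron_index < len(introns):
        raise IndexError(
            f"gene {gene.gene_id}: intron index {intron_index} out of range "
            f"({len(introns)} introns)"
        )
    exons = gene.exons_transcribed()
    upstream = sum(e - s for s, e in exons[: intron_index + 1])
    return upstream % 3


def detect_ptc(
    intron_sequence: str,
    phase: int,
    upstream_context: str = "",
    downstream_context: str = "",
    boundary_codons: bool = True,
) -> bool:
    """True iff a TGA codon intersects the intron in the retained frame.

    ``upstream_context`` must supply the ``phase`` exonic nucleotides of the
    codon interrupted by the intron; ``downstream_context`` completes the
    trailing partial codon when the intron's length leaves one.  With
    ``boundary_codons=False`` only codons lying fully inside the intron are
    scanned and no context is required.
    """
    if phase not in (0, 1, 2):
        raise ValueError("phase must be 0, 1 or 2")
    seq = intron_sequence.upper()
    if not boundary_codons:
        start = (3 - phase) % 3
        for i in range(start, len(seq) - 2, 3):
            if seq[i : i + 3] == STOP_CODON:
                return True
        return False

    if phase and len(upstream_context) < phase:
        raise ValueError(
            f"phase {phase} requires {phase} nt of upstream context"
        )
    lead = upstream_context[-phase:] if phase else ""
    trail_len = (3 - (phase + len(seq)) % 3) % 3
    if trail_len and len(downstream_context) < trail_len:
        raise ValueError(
            f"trailing partial codon requires {trail_len} nt of "
            "downstream context"
        )
    frame = lead + seq + (downstream_context[:trail_len] if trail_len else "")
    # every codon of `frame` contains at least one intronic nucleotide
    for i in range(0, len(frame) - 2, 3):
        if frame[i : i + 3] == STOP_CODON:
            return True
    return False


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-sided two-proportion test (pooled chi-square, no continuity corr).

    Returns (chi2 statistic, p value); the statistic equals the 2×2
    contingency chi-square without Yates correction.
    """
    if min(n1, n2) == 0:
        return float("nan"), float("nan")
    p_pool = (k1 + k2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return 0.0, 1.0
    p1, p2 = k1 / n1, k2 / n2
    z = (p1 - p2) / np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    chi2 = z * z
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def ptc_enrichment(
    introns: pd.DataFrame,
    stratify_by: str,
    pairs: Iterable[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stratum PTC fractions and pairwise two-proportion tests.

    ``introns`` needs a boolean ``ptc`` column and the stratification
    column (mod3 class, position class, signal class, expression
    quartile, …).  ``pairs`` defaults to all stratum pairs.
    """
    if "ptc" not in introns.columns:
        raise ValueError("intron table must carry a 'ptc' column")
    groups = introns.groupby(stratify_by, sort=True)["ptc"]
    fractions = pd.DataFrame(
        {
            "stratum": groups.size().index,
            "n": groups.size().to_numpy(),
            "n_ptc": groups.sum().to_numpy().astype(int),
        }
    )
    fractions["fraction"] = np.where(
        fractions["n"] > 0, fractions["n_ptc"] / fractions["n"], np.nan
    )
    by = {r.stratum: (int(r.n_ptc), int(r.n)) for r in fractions.itertuples()}
    if pairs is None:
        labels = list(by)
        pairs = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    test_rows = []
    for a, b in pairs:
        k1, n1 = by[a]
        k2, n2 = by[b]
        chi2, p = two_proportion_test(k1, n1, k2, n2)
        test_rows.append((a, b, k1 / n1 if n1 else np.nan,
                          k2 / n2 if n2 else np.nan, chi2, p))
    tests = pd.DataFrame(
        test_rows,
        columns=["stratum_a", "stratum_b", "fraction_a", "fraction_b",
                 "chi2", "p_value"],
    )
    return fractions, tests


def annotate_introns(
    genes: Sequence[GeneModel],
    sequences,
    boundary_codons: bool = True,
) -> pd.DataFrame:
    """Build the intron table: sequence classes, phase, and PTC flag.

    One row per annotated intron with its genomic interval, transcription-
    sense sequence, length/mod3 class, boundary-signal class, positional
    class (first/internal/last), phase and PTC flag.
    """
    from intronsig.coding_exome import MOD3_CLASSES
    from intronsig.genome_io import revcomp

    rows = []
    for gene in genes:
        chrom = sequences[gene.chromosome]
        introns = gene.introns_transcribed()
        exons = gene.exons_transcribed()
        n = len(introns)
        cds = "".join(
            chrom[s:e] if gene.strand == "+" else revcomp(chrom[s:e])
            for s, e in exons
        )
        offset = 0
        for idx, (s, e) in enumerate(introns):
            seq = chrom[s:e]
            if gene.strand == "-":
                seq = revcomp(seq)
            phase = intron_phase(gene, idx)
            up_len = sum(ee - ss for ss, ee in exons[: idx + 1])
            upstream_ctx = cds[max(0, up_len - 2) : up_len]
            downstream_ctx = cds[up_len : up_len + 2]
            canonical = seq.startswith("GT") and seq.endswith("AG")
            if canonical and len(seq) >= 6:
                five_opt = seq[2] == "A"
                three_opt = seq[-3] == "T"
                signal = (
                    "GTA|TAG" if five_opt and three_opt
                    else "GTA|nAG" if five_opt
                    else "GTn|TAG" if three_opt
                    else "GTn|nAG"
                )
            else:
                signal = "noncanonical"
            if n == 1:
                pos = "single"
            elif idx == 0:
                pos = "first"
            elif idx == n - 1:
                pos = "last"
            else:
                pos = "internal"
            ptc = detect_ptc(
                seq, phase, upstream_ctx, downstream_ctx,
                boundary_codons=boundary_codons,
            )
            rows.append(
                (
                    gene.gene_id, gene.chromosome, s, e, idx, len(seq),
                    MOD3_CLASSES[len(seq) % 3], signal, pos, phase,
                    gene.expression, ptc,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chromosome", "start", "end", "intron_index",
            "length", "mod3_class", "signal_class", "position_class",
            "phase", "expression", "ptc",
        ],
    )
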