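"""Coding-exon sequences, cryptic GT|AG segment enumeration, flank windows.

A cryptic segment is any exonic tract that begins with the GT dinucleotide
and ends with AG, 15–40 nt long by default — the size window that contains
>99% of annotated introns in *Paramecium*.  Segment length includes the
bounding dinucleotides, matching how annotated intron lengths are computed.
Segments are enumerated within single exons (they do not span annotated
introns), overlapping and nested pairs all counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from intronsig.genome_io import GeneModel, revcomp

SIGNAL_CLASSES = ("GTA|TAG", "GTA|nAG", "GTn|TAG", "GTn|nAG")
MOD3_CLASSES = ("3n", "3n+1", "3n+2")

POSITION_FIRST = "first"
POSITION_INTERNAL = "internal"
POSITION_LAST = "last"
POSITION_SINGLE = "single"


@dataclass(frozen=True)
class EnumerationParams:
    """Size window for candidate cryptic introns.

    ``prevalent_range`` is the 21–30 bp band holding ~95% of annotated
    introns; it is a reporting stratum, not an enumeration filter.
    """

    min_len: int = 15
    max_len: int = 40
    prevalent_range: tuple[int, int] = (21, 30)

    def __post_init__(self) -> None:
        if self.min_len < 6:
            raise ValueError("min_len must be >= 6 (GT + AG + signal bases)")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.min_len, self.max_len + 1)

    @property
    def n_sizes(self) -> int:
        return self.max_len - self.min_len + 1


@dataclass
class CodingExon:
    """One CDS exon: sense-strand sequence plus positional bookkeeping.

    ``cds_offset`` is the number of CDS nucleotides upstream of this exon in
    transcription order; ``interval`` is genomic (0-based half-open).
    """

    gene_id: str
    exon_index: int  # transcription order, 0-based
    position_class: str
    sequence: str
    cds_offset: int
    chromosome: str
    interval: tuple[int, int]
    strand: str
    expression: float | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != self.interval[1] - self.interval[0]:
            raise ValueError("sequence length must equal interval length")


@dataclass(frozen=True)
class GtAgSegment:
    """A candidate cryptic intron inside one exon.

    ``start``/``end`` are exon-local, 0-based half-open, on the enumeration
    strand; length = end − start includes the bounding GT and AG.
    """

    start: int
    end: int
    signal_class: str
    mod3_class: str
    enumeration_strand: str = "sense"

    @property
    def length(self) -> int:
        return self.end - self.start


def position_class_for(index: int, n_exons: int) -> str:
    if n_exons == 1:
        return POSITION_SINGLE
    if index == 0:
        return POSITION_FIRST
    if index == n_exons - 1:
        return POSITION_LAST
    return POSITION_INTERNAL


def extract_coding_exons(
    genes: Iterable[GeneModel], sequences: Mapping[str, str]
) -> list[CodingExon]:
    """Cut sense-strand exon sequences from the genome for every gene.

    Minus-strand exon sequences are reverse-complemented; cds_offset counts
    upstream CDS nucleotides in transcription order.
    """
    exons: list[CodingExon] = []
    for gene in genes:
        try:
            chrom_seq = sequences[gene.chromosome]
        except KeyError:
            raise KeyError(
                f"gene {gene.gene_id}: chromosome {gene.chromosome} missing"
            ) from None
        ordered = gene.exons_transcribed()
        offset = 0
        for idx, (s, e) in enumerate(ordered):
            if s < 0 or e > len(chrom_seq):
                raise ValueError(
                    f"gene {gene.gene_id}: exon [{s},{e}) out of bounds for "
                    f"{gene.chromosome}"
                )
            seq = chrom_seq[s:e]
            if gene.strand == "-":
                seq = revcomp(seq)
            exons.append(
                CodingExon(
                    gene_id=gene.gene_id,
                    exon_index=idx,
                    position_class=position_class_for(idx, gene.n_exons),
                    sequence=seq,
                    cds_offset=offset,
                    chromosome=gene.chromosome,
                    interval=(s, e),
                    strand=gene.strand,
                    expression=gene.expression,
                )
            )
            offset += e - s
    return exons


def classify_segment(segment_sequence: str) -> tuple[str, str]:
    """Classify a GT…AG segment by boundary signal and length mod 3."""
    seq = segment_sequence
    if len(seq) < 6 or not seq.startswith("GT") or not seq.endswith("AG"):
        raise ValueError(
            "segment must start GT, end AG, and be at least 6 nt long"
        )
    five_opt = seq[2] == "A"
    three_opt = seq[-3] == "T"  # last three nt are TAG iff seq[-3] == 'T'
    if five_opt and three_opt:
        signal = "GTA|TAG"
    elif five_opt:
        signal = "GTA|nAG"
    elif three_opt:
        signal = "GTn|TAG"
    else:
        signal = "GTn|nAG"
    return signal, MOD3_CLASSES[len(seq) % 3]


def _gt_starts_ag_ends(seq_bytes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positions where GT starts, and half-open end positions of AG."""
    if seq_bytes.size < 2:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    g, t, a = ord("G"), ord("T"), ord("A")
    gt = np.flatnonzero((seq_bytes[:-1] == g) & (seq_bytes[1:] == t))
    ag = np.flatnonzero((seq_bytes[:-1] == a) & (seq_bytes[1:] == g)) + 2
    return gt, ag


def _segment_pairs(
    seq: str, params: EnumerationParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (start, end) GT…AG pairs inside the size window.

    Returns start positions, end positions (half-open) and a boolean pair
    (gta_start, tag_end) classification basis, vectorised via broadcasting.
    """
    b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    gt, ag = _gt_starts_ag_ends(b)
    if gt.size == 0 or ag.size == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e, np.empty((0, 2), dtype=bool)
    lengths = ag[None, :] - gt[:, None]
    mask = (lengths >= params.min_len) & (lengths <= params.max_len)
    gi, ai = np.nonzero(mask)
    starts, ends = gt[gi], ag[ai]
    a = ord("A")
    t = ord("T")
    gta = b[starts + 2] == a
    tag = b[ends - 3] == t
    return starts, ends, np.column_stack([gta, tag])


def enumerate_gt_ag_segments(
    sequence: str,
    params: EnumerationParams = EnumerationParams(),
    strand: str = "sense",
) -> list[GtAgSegment]:
    """Enumerate every GT|AG-bounded segment in the size window.

    ``strand="antisense"`` enumerates on the reverse complement of the
    sequence; coordinates are then local to the reverse complement.
    Overlapping and nested pairs are all reported.
    """
    if strand not in ("sense", "antisense"):
        raise ValueError("strand must be 'sense' or 'antisense'")
    seq = sequence if strand == "sense" else revcomp(sequence)
    starts, ends, flags = _segment_pairs(seq, params)
    segments = []
    for s, e, (gta, tag) in zip(starts, ends, flags):
        if gta and tag:
            signal = "GTA|TAG"
        elif gta:
            signal = "GTA|nAG"
        elif tag:
            signal = "GTn|TAG"
        else:
            signal = "GTn|nAG"
        segments.append(
            GtAgSegment(
                start=int(s),
                end=int(e),
                signal_class=signal,
                mod3_class=MOD3_CLASSES[(e - s) % 3],
                enumeration_strand=strand,
            )
        )
    segments.sort(key=lambda x: (x.start, x.end))
    return segments


def segment_count_matrix(
    sequence: str, params: EnumerationParams
) -> np.ndarray:
    """Per-(size, signal-class) segment counts for one strand of a sequence.

    Returns an int array of shape (n_sizes, 4) with rows indexed by
    size − min_len and columns by :data:`SIGNAL_CLASSES`.  This is the fast
    counting path used by the DSA profiles; it agrees segment-for-segment
    with :func:`enumerate_gt_ag_segments`.
    """
    counts = np.zeros((params.n_sizes, 4), dtype=np.int64)
    starts, ends, flags = _segment_pairs(sequence, params)
    if starts.size == 0:
        return counts
    size_idx = ends - starts - params.min_len
    signal_idx = np.where(
        flags[:, 0] & flags[:, 1], 0,
        np.where(flags[:, 0], 1, np.where(flags[:, 1], 2, 3)),
    )
    np.add.at(counts, (size_idx, signal_idx), 1)
    return counts


def exon_count_matrices(
    exon: CodingExon, params: EnumerationParams
) -> tuple[np.ndarray, np.ndarray]:
    """(sense, antisense) segment count matrices for one exon."""
    sense = segment_count_matrix(exon.sequence, params)
    anti = segment_count_matrix(revcomp(exon.sequence), params)
    return sense, anti


def segment_genomic_interval(
    exon: CodingExon, segment: GtAgSegment
) -> tuple[int, int]:
    """Genomic interval of a sense-strand segment (donor, acceptor).

    Only defined for sense-strand enumeration: the segment's coordinates are
    exon-local on the transcription-sense sequence.
    """
    if segment.enumeration_strand != "sense":
        raise ValueError("genomic interval defined for sense segments only")
    a, b = exon.interval
    if exon.strand == "+":
        return (a + segment.start, a + segment.end)
    return (b - segment.end, b - segment.start)


@dataclass(frozen=True)
class FlankWindows:
    """Exonic windows flanking one annotated intron, transcription sense.

    ``upstream`` ends at the donor (5'ss); ``downstream`` begins at the
    acceptor (3'ss).  Windows shorter than the requested width (short
    flanking exon) carry a truncation flag.
    """

    upstream: str
    downstream: str
    upstream_truncated: bool
    downstream_truncated: bool


def intron_flank_windows(
    gene: GeneModel,
    intron_index: int,
    sequences: Mapping[str, str],
    width: int = 15,
) -> FlankWindows:
    """Cut the exonic windows flanking an intron, on the sense strand.

    ``intron_index`` counts introns in transcription order.  The upstream
    window is the last ≤``width`` nt of the upstream exon; the downstream
    window the first ≤``width`` nt of the downstream exon.
    """
    introns = gene.introns_transcribed()
    if not 0 <= intron_index < len(introns):
        raise IndexError(
            f"gene {gene.gene_id}: intron index {intron_index} out of range"
        )
    exons = gene.exons_transcribed()
    up_exon = exons[intron_index]
    down_exon = exons[intron_index + 1]
    chrom = sequences[gene.chromosome]

    def exon_sense(iv: tuple[int, int]) -> str:
        s = chrom[iv[0]:iv[1]]
        return s if gene.strand == "+" else revcomp(s)

    up_seq = exon_sense(up_exon)
    down_seq = exon_sense(down_exon)
    upstream = up_seq[-width:] if width < len(up_seq) else up_seq
    downstream = down_seq[:width]
    return FlankWindows(
        upstream=upstream,
        downstream=downstream,
        upstream_truncated=len(upstream) < width,
        downstream_truncated=len(downstream) < width,
    )


def segments_dataframe(
    exons: Sequence[CodingExon],
    params: EnumerationParams = EnumerationParams(),
    strands: tuple[str, ...] = ("sense", "antisense"),
):
    """Full segment table over an exon set, one row per segment."""
    import pandas as pd

    rows = []
    for exon in exons:
        for strand in strands:
            for seg in enumerate_gt_ag_segments(exon.sequence, params, strand):
                if strand == "sense":
                    g_start, g_end = segment_genomic_interval(exon, seg)
                else:
                    g_start, g_end = -1, -1
                rows.append(
                    (
                        exon.gene_id,
                        exon.exon_index,
                        exon.position_class,
                        strand,
                        seg.start,
                        seg.end,
                        g_start,
                        g_end,
                        seg.length,
                        seg.signal_class,
                        seg.mod3_class,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "exon_index",
            "position_class",
            "strand",
            "local_start",
            "local_end",
            "genomic_start",
            "genomic_end",
            "length",
            "signal_class",
            "mod3_class",
        ],
    )
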