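"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) and
the STAR ``SJ.out.tab`` junction dialect (1-based inclusive intron bounds)
are converted at this boundary and nowhere else.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N-safe)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A gene's strand, chromosome, ordered CDS exons and expression value.

    ``cds_exons`` are genomic intervals (0-based half-open), sorted by start
    and pairwise non-overlapping regardless of strand.  Transcription-order
    views reverse the list for minus-strand genes.  The gene is the unit of
    bootstrap resampling throughout the pipeline.
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_exons: list[tuple[int, int]]
    expression: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = sorted(tuple(e) for e in self.cds_exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"gene {self.gene_id}: overlapping CDS exons "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        self.cds_exons = exons

    @property
    def n_exons(self) -> int:
        return len(self.cds_exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_exons)

    def exons_transcribed(self) -> list[tuple[int, int]]:
        """CDS exons in transcription (5'→3') order."""
        return self.cds_exons if self.strand == "+" else self.cds_exons[::-1]

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals: gaps between consecutive CDS exons."""
        return [
            (e1, s2)
            for (_, e1), (s2, _) in zip(self.cds_exons, self.cds_exons[1:])
        ]

    def introns_transcribed(self) -> list[tuple[int, int]]:
        return self.introns() if self.strand == "+" else self.introns()[::-1]


@dataclass(frozen=True)
class JunctionRecord:
    """A splice junction in genomic coordinates.

    ``donor`` is the first intronic base (0-based); ``acceptor`` is one past
    the last intronic base (half-open end).  ``strand`` may be undefined
    (``.``) for junctions STAR could not orient.
    """

    chromosome: str
    donor: int
    acceptor: int
    strand: str
    unique_reads: int
    annotated: bool

    def __post_init__(self) -> None:
        if self.acceptor <= self.donor:
            raise ValueError(
                f"junction acceptor ({self.acceptor}) must exceed donor "
                f"({self.donor})"
            )
        if self.unique_reads < 0:
            raise ValueError("unique_reads must be >= 0")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.donor, self.acceptor)


class ExpressionTable:
    """Map gene id → linear-scale expression value (>= 0).

    log2 is only defined for positive values; genes at 0 are retained for
    sequence-only analyses and flagged via :meth:`log2_defined`.
    """

    def __init__(self, values: Mapping[str, float]):
        for gid, v in values.items():
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"expression for {gid} must be finite and >= 0")
        self._values = dict(values)

    def __len__(self) -> int:
        return len(self._values)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._values

    def __getitem__(self, gene_id: str) -> float:
        return self._values[gene_id]

    def get(self, gene_id: str, default=None):
        return self._values.get(gene_id, default)

    def items(self):
        return self._values.items()

    def log2_defined(self, gene_id: str) -> bool:
        return self._values[gene_id] > 0

    def log2_values(self) -> dict[str, float]:
        """log2(expression) over the genes with positive expression."""
        return {g: math.log2(v) for g, v in self._values.items() if v > 0}


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a dict chromosome → uppercase sequence.

    Duplicate record ids are a hard error; non-ACGTN characters are passed
    through with a warning.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA record id: {rec.id}")
        seq = str(rec.seq).upper()
        if set(seq) - set("ACGTN"):
            logger.warning(
                "FASTA record %s contains non-ACGTN characters", rec.id
            )
        sequences[rec.id] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3_gene_models(
    path: str | Path,
    expression: ExpressionTable | None = None,
) -> list[GeneModel]:
    """Parse gene models (CDS exons only) from a GFF3 annotation.

    Coordinates are converted from GFF3's 1-based inclusive convention to
    0-based half-open.  Only ``CDS`` features define exons; UTR features are
    ignored.  CDS rows whose parent chain does not reach a gene are skipped
    with a warning; overlapping CDS within one gene raise an error.  When an
    expression table is supplied, genes are joined to it by id.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )

    # map any feature id to its ancestor gene id
    def gene_of(feature) -> str | None:
        current = feature
        for _ in range(5):  # bounded parent-chain walk
            parents = list(db.parents(current, level=1))
            if not parents:
                return current.id if current.featuretype == "gene" else None
            current = parents[0]
            if current.featuretype == "gene":
                return current.id
        return None

    genes: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        gid = gene_of(cds)
        if gid is None:
            logger.warning("CDS at %s:%d-%d has no parent gene; skipped",
                           cds.seqid, cds.start, cds.end)
            continue
        info = genes.setdefault(
            gid, {"chromosome": cds.seqid, "strand": cds.strand, "exons": []}
        )
        info["exons"].append((cds.start - 1, cds.end))  # to 0-based half-open

    models = []
    for gid, info in genes.items():
        expr = expression.get(gid) if expression is not None else None
        models.append(
            GeneModel(
                gene_id=gid,
                chromosome=info["chromosome"],
                strand=info["strand"],
                cds_exons=info["exons"],
                expression=expr,
            )
        )
    models.sort(key=lambda g: g.gene_id)
    return models


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as gene/mRNA/CDS rows (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start = g.cds_exons[0][0] + 1
            end = g.cds_exons[-1][1]
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chromosome}\t.\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chromosome}\t.\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds_exons):
                fh.write(
                    f"{g.chromosome}\t.\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}.t1\n"
                )


_STRAND_CODE = {0: ".", 1: "+", 2: "-"}
_STRAND_CODE_INV = {".": 0, "+": 1, "-": 2}


def read_junction_table(path: str | Path, dialect: str = "star-sj") -> list[JunctionRecord]:
    """Read a splice-junction table in the STAR ``SJ.out.tab`` dialect.

    Columns: chromosome, intron first base (1-based), intron last base
    (1-based), strand code {0,1,2}, motif code, annotated {0,1},
    unique-read count, multimapping-read count, max overhang.
    """
    if dialect != "star-sj":
        raise ValueError(f"unknown junction dialect: {dialect}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                first, last = int(fields[1]), int(fields[2])
                strand = _STRAND_CODE[int(fields[3])]
                annotated = bool(int(fields[5]))
                unique = int(fields[6])
            except (ValueError, KeyError) as exc:
                raise ValueError(
                    f"{path}: line {lineno}: malformed row ({exc})"
                ) from None
            records.append(
                JunctionRecord(
                    chromosome=chrom,
                    donor=first - 1,
                    acceptor=last,
                    strand=strand,
                    unique_reads=unique,
                    annotated=annotated,
                )
            )
    return records


def write_junction_table(junctions: Iterable[JunctionRecord], path: str | Path) -> None:
    """Write junctions back to the STAR dialect (inverse of the reader)."""
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        j.chromosome,
                        j.donor + 1,
                        j.acceptor,
                        _STRAND_CODE_INV[j.strand],
                        0,
                        int(j.annotated),
                        j.unique_reads,
                        0,
                        0,
                    )
                )
                + "\n"
            )


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a two-column TSV (gene_id, expression value, no header)."""
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            gid, raw = fields
            v = float(raw)
            if v < 0:
                raise ValueError(f"{path}: line {lineno}: negative expression {v}")
            if gid in values:
                raise ValueError(f"{path}: line {lineno}: duplicate gene id {gid}")
            values[gid] = v
    zero = sum(1 for v in values.values() if v == 0)
    if zero:
        logger.info("%d genes have expression 0 (excluded from log2 quartiles)", zero)
    return ExpressionTable(values)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, v in table.items():
            fh.write(f"{gid}\t{v:.6g}\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with a header line (deterministic floats)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def gene_sequence_intervals(gene: GeneModel, sequences: Mapping[str, str]) -> None:
    """Validate that a gene's exons fall inside its chromosome sequence."""
    chrom_len = len(sequences[gene.chromosome])
    for s, e in gene.cds_exons:
        if s < 0 or e > chrom_len:
            raise ValueError(
                f"gene {gene.gene_id}: exon [{s},{e}) outside chromosome "
                f"{gene.chromosome} (length {chrom_len})"
            )
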