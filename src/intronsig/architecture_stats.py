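"""Gene-architecture metrics and their stratifications.

Expression quartiles (after log2), positional binning of features along the
CDS, intron density, CDS length, inter-intron and tail distances, plus the
association tests used to compare them: two-proportion tests, chi-square
uniformity over bins, Pearson correlation, and the Wilcoxon rank-sum test.
All distances are computed in transcription order (CDS coordinates), hence
invariant to strand.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from intronsig.genome_io import ExpressionTable, GeneModel
from intronsig.ptc_scan import two_proportion_test

logger = logging.getLogger(__name__)

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")  # weak = Q1, high = Q4


@dataclass(frozen=True)
class AnalysisConfig:
    """Positional-analysis settings.

    ``n_bins`` CDS bins of equal width; ``prevalent_range`` the 21–30 nt
    intron-size band; ``tail_window`` the arbitrary <200 bp gene-tail
    region; quartile Q1 = weakly, Q4 = highly expressed.
    """

    n_bins: int = 10
    prevalent_range: tuple[int, int] = (21, 30)
    tail_window: int = 200
    midpoint_binning: bool = False

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.tail_window <= 0:
            raise ValueError("tail_window must be positive")


def assign_expression_quartiles(table: ExpressionTable) -> dict[str, str]:
    """Assign genes to expression quartiles from the empirical log2 values.

    Genes with expression 0 (log2 undefined) are excluded.  Ties are broken
    toward the lower quartile: all genes sharing a value get the quartile
    of the first (lowest-rank) occurrence of that value, so with distinct
    values every quartile holds n/4 genes (±1).
    """
    log2 = table.log2_values()
    if len(log2) < 4:
        raise ValueError("need at least 4 genes with positive expression")
    n = len(log2)
    order = sorted(log2, key=lambda g: (log2[g], g))
    rank_of_first: dict[float, int] = {}
    for i, g in enumerate(order):
        rank_of_first.setdefault(log2[g], i)
    assignment = {}
    for g in order:
        r = rank_of_first[log2[g]]
        assignment[g] = QUARTILE_LABELS[min(3, r * 4 // n)]
    if len(set(assignment.values())) == 1 and n > 1:
        logger.warning("all expression values equal; every gene in Q1")
    return assignment


def bin_cds_position(cds_length: int, position: int, n_bins: int = 10) -> int:
    """Equal-width CDS bin (1-based) of a transcription-order coordinate."""
    if not 0 <= position < cds_length:
        raise ValueError(
            f"position {position} out of range for CDS length {cds_length}"
        )
    return position * n_bins // cds_length + 1


def gene_architecture_metrics(gene: GeneModel) -> dict:
    """Intron density, CDS length, inter-intron and tail distances.

    Inter-intron distances are the exonic nucleotides between the 3'ss of
    one intron and the 5'ss of the next, i.e. internal exon lengths in
    transcription order.  The tail distance runs from the last intron's
    3'ss to the CDS end, in CDS coordinates.
    """
    exons = gene.exons_transcribed()
    cds_len = gene.cds_length
    n_introns = len(exons) - 1
    inter = [e - s for s, e in exons[1:-1]] if n_introns >= 2 else []
    tail = exons[-1][1] - exons[-1][0] if n_introns >= 1 else None
    return {
        "gene_id": gene.gene_id,
        "cds_length": cds_len,
        "n_introns": n_introns,
        "intron_density": 1000.0 * n_introns / cds_len if cds_len else float("nan"),
        "inter_intron_distances": inter,
        "tail_distance": tail,
        "expression": gene.expression,
    }


def intron_cds_coordinates(gene: GeneModel) -> list[tuple[int, int]]:
    """(5'ss, 3'ss) of each intron in CDS (transcription-order) coordinates.

    The 5'ss coordinate is the CDS offset where the intron interrupts the
    CDS; for an intron the two coincide in CDS space, so both entries equal
    the cumulative upstream exon length (kept as a pair for symmetry with
    genomic intervals).
    """
    out = []
    offset = 0
    exons = gene.exons_transcribed()
    for s, e in exons[:-1]:
        offset += e - s
        out.append((offset, offset))
    return out


def metrics_table(genes: Sequence[GeneModel]) -> pd.DataFrame:
    rows = []
    for g in genes:
        m = gene_architecture_metrics(g)
        rows.append(
            (
                m["gene_id"], m["cds_length"], m["n_introns"],
                m["intron_density"],
                m["tail_distance"] if m["tail_distance"] is not None else np.nan,
                m["expression"] if m["expression"] is not None else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "cds_length", "n_introns", "intron_density",
                 "tail_distance", "expression"],
    )


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

def chi_square_uniformity(counts: Sequence[int]) -> tuple[float, int, float]:
    """Chi-square test of uniform occupancy over bins (df = n_bins − 1)."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        return float("nan"), len(counts) - 1, float("nan")
    stat, p = stats.chisquare(counts)
    return float(stat), len(counts) - 1, float(p)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    stat, p = stats.ranksums(x, y)
    return float(stat), float(p)


def association_tests(
    requests: Sequence[dict],
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Run a batch of association tests, one row per request.

    Each request is a dict with ``name``, ``kind`` ∈ {two_proportion,
    chi_square_uniformity, pearson, wilcoxon} and the test's inputs
    (``counts`` for proportions/uniformity, ``x``/``y`` for the rest).
    Degenerate inputs are flagged rather than raised.
    """
    rows = []
    for req in requests:
        kind = req["kind"]
        name = req["name"]
        try:
            if kind == "two_proportion":
                (k1, n1), (k2, n2) = req["counts"]
                stat, p = two_proportion_test(k1, n1, k2, n2)
                df = 1
            elif kind == "chi_square_uniformity":
                stat, df, p = chi_square_uniformity(req["counts"])
            elif kind == "pearson":
                stat, p = pearson_correlation(req["x"], req["y"])
                df = len(req["x"]) - 2
            elif kind == "wilcoxon":
                stat, p = wilcoxon_rank_sum(req["x"], req["y"])
                df = np.nan
            else:
                raise ValueError(f"unknown test kind {kind!r}")
        except (ValueError, ZeroDivisionError) as exc:
            rows.append((name, kind, np.nan, np.nan, np.nan, True, str(exc)))
            continue
        degenerate = not np.isfinite(stat)
        rows.append((name, kind, stat, df, p, degenerate, ""))
    out = pd.DataFrame(
        rows,
        columns=["name", "kind", "statistic", "df", "p_value", "degenerate", "note"],
    )
    if bonferroni:
        m = len(out)
        out["p_corrected"] = np.minimum(1.0, out["p_value"] * m)
    return out


def bin_occupancy(
    positions: Sequence[int],
    cds_lengths: Sequence[int],
    n_bins: int = 10,
) -> np.ndarray:
    """Occupancy counts of features over CDS bins (features by 5'-most coord)."""
    counts = np.zeros(n_bins, dtype=np.int64)
    for pos, length in zip(positions, cds_lengths):
        counts[bin_cds_position(length, pos, n_bins) - 1] += 1
    return counts
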