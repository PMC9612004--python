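"""DNA strand asymmetry (DSA): the pipeline's central statistic.

For a motif or segment class, S = (Ns − Na) / (Ns + Na), where Ns counts
occurrences on the sense strand and Na occurrences on the antisense strand
(i.e. on the reverse complement of the same tract).  Under a neutral iid
model with complement-symmetric base composition the two strands carry the
motif at equal rates, so S ≈ 0; negative S indicates sense-strand
under-representation, read as purifying selection against the motif in the
coding sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from intronsig.coding_exome import (
    SIGNAL_CLASSES,
    MOD3_CLASSES,
    CodingExon,
    EnumerationParams,
    exon_count_matrices,
)
from intronsig.genome_io import revcomp


@dataclass(frozen=True)
class BootstrapParams:
    """Gene-bootstrap settings: 500 genes per draw, 1000 replicates.

    Draws are without replacement within a replicate; the gene, not the
    exon, is the resampling unit.
    """

    genes_per_draw: int = 500
    replicates: int = 1000
    seed: int = 0
    with_replacement: bool = False


def dsa_score(ns: float, na: float) -> float:
    """S = (Ns − Na)/(Ns + Na); NaN when both counts are zero."""
    if ns < 0 or na < 0:
        raise ValueError("counts must be nonnegative")
    total = ns + na
    if total == 0:
        return float("nan")
    return (ns - na) / total


def dsa_standard_error(ns: float, na: float) -> float:
    """First-order sampling SE of S for independent counts: 1/sqrt(Ns+Na)."""
    total = ns + na
    return float("nan") if total == 0 else 1.0 / np.sqrt(total)


def stratum_counts(
    exons: Sequence[CodingExon],
    params: EnumerationParams = EnumerationParams(),
    exon_filter: Callable[[CodingExon], bool] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Summed (sense, antisense) count matrices over an exon set.

    Each matrix has shape (n_sizes, 4 signal classes); mod3 class is implied
    by size.
    """
    ns = np.zeros((params.n_sizes, 4), dtype=np.int64)
    na = np.zeros((params.n_sizes, 4), dtype=np.int64)
    for exon in exons:
        if exon_filter is not None and not exon_filter(exon):
            continue
        s, a = exon_count_matrices(exon, params)
        ns += s
        na += a
    return ns, na


def dsa_size_profile(
    exons: Sequence[CodingExon],
    params: EnumerationParams = EnumerationParams(),
    exon_filter: Callable[[CodingExon], bool] | None = None,
    stratum: str | None = None,
) -> pd.DataFrame:
    """Per-size DSA profile over an exon set.

    One row per (size, signal class): Ns, Na, S and the mod3 class implied
    by the size.  ``stratum`` is a label recorded in the output; filtering
    of exons (by position class, expression class, …) happens through
    ``exon_filter``.  Sizes with Ns + Na = 0 carry S = NaN (missing, not 0).
    """
    ns, na = stratum_counts(exons, params, exon_filter)
    rows = []
    for i, size in enumerate(params.sizes):
        for j, signal in enumerate(SIGNAL_CLASSES):
            rows.append(
                (
                    stratum or "all",
                    int(size),
                    MOD3_CLASSES[size % 3],
                    signal,
                    int(ns[i, j]),
                    int(na[i, j]),
                    dsa_score(ns[i, j], na[i, j]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["stratum", "size", "mod3_class", "signal_class", "Ns", "Na", "S"],
    )


def per_gene_stratum_counts(
    exons: Sequence[CodingExon],
    params: EnumerationParams = EnumerationParams(),
    signal_class: str = "GTA|TAG",
    mod3_class: str | None = None,
    size_range: tuple[int, int] | None = None,
    exon_filter: Callable[[CodingExon], bool] | None = None,
) -> pd.DataFrame:
    """Per-gene (Ns, Na) totals for one stratum — the bootstrap's input.

    The stratum is a signal class, optionally restricted to one mod3 class
    and/or a size range; exon-level strata (position, expression) are
    applied via ``exon_filter``.  Genes whose exons are entirely filtered
    out still appear with zero counts.
    """
    if signal_class not in SIGNAL_CLASSES:
        raise ValueError(f"unknown signal class {signal_class!r}")
    sig_idx = SIGNAL_CLASSES.index(signal_class)
    sizes = params.sizes
    size_mask = np.ones(params.n_sizes, dtype=bool)
    if size_range is not None:
        size_mask &= (sizes >= size_range[0]) & (sizes <= size_range[1])
    if mod3_class is not None:
        size_mask &= np.array(
            [MOD3_CLASSES[s % 3] == mod3_class for s in sizes]
        )

    totals: dict[str, list[int]] = {}
    for exon in exons:
        totals.setdefault(exon.gene_id, [0, 0])
        if exon_filter is not None and not exon_filter(exon):
            continue
        s, a = exon_count_matrices(exon, params)
        totals[exon.gene_id][0] += int(s[size_mask, sig_idx].sum())
        totals[exon.gene_id][1] += int(a[size_mask, sig_idx].sum())
    return pd.DataFrame(
        [(g, ns, na) for g, (ns, na) in sorted(totals.items())],
        columns=["gene_id", "Ns", "Na"],
    )


def bootstrap_group_dsa(
    per_gene_counts: pd.DataFrame,
    params: BootstrapParams = BootstrapParams(),
    group_name: str = "group",
) -> np.ndarray:
    """Gene-bootstrap distribution of S for one stratum.

    Each replicate draws ``genes_per_draw`` genes uniformly (without
    replacement by default), sums their Ns and Na and applies the DSA
    formula; returns the vector of replicate scores.  Reproducible given
    the seed.
    """
    ns = per_gene_counts["Ns"].to_numpy()
    na = per_gene_counts["Na"].to_numpy()
    n_genes = len(ns)
    if not params.with_replacement and n_genes < params.genes_per_draw:
        raise ValueError(
            f"group {group_name!r} has {n_genes} genes, fewer than "
            f"genes_per_draw={params.genes_per_draw}"
        )
    rng = np.random.default_rng(params.seed)
    scores = np.empty(params.replicates)
    for r in range(params.replicates):
        idx = rng.choice(
            n_genes, size=params.genes_per_draw,
            replace=params.with_replacement,
        )
        scores[r] = dsa_score(ns[idx].sum(), na[idx].sum())
    return scores


def compare_bootstrap_groups(
    dists: Mapping[str, np.ndarray],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Pairwise two-sided t-tests between bootstrap score distributions.

    Bonferroni correction multiplies each p by the number of pairwise
    comparisons (capped at 1).  Zero-variance pairs are reported as
    degenerate with p = NaN.
    """
    names = list(dists)
    if len(names) < 2:
        raise ValueError("need at least two groups to compare")
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in itertools.combinations(names, 2):
        xa, xb = np.asarray(dists[a]), np.asarray(dists[b])
        degenerate = (np.ptp(xa) == 0) and (np.ptp(xb) == 0)
        if degenerate:
            t_stat, p = float("nan"), float("nan")
        else:
            t_stat, p = stats.ttest_ind(xa, xb, equal_var=False)
            t_stat, p = float(t_stat), float(p)
        p_corr = p if np.isnan(p) else min(1.0, p * n_pairs) if correction == "bonferroni" else p
        rows.append(
            (a, b, float(np.mean(xa)), float(np.mean(xb)), t_stat, p, p_corr,
             degenerate)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group_a", "group_b", "mean_a", "mean_b",
            "t_statistic", "p_value", "p_corrected", "degenerate",
        ],
    )


def _motif_count_at(windows: Iterable[str], pos: int, motif: str) -> int:
    k = len(motif)
    return sum(1 for w in windows if len(w) >= pos + k and w[pos:pos + k] == motif)


def flank_motif_dsa(
    windows: Sequence[str],
    motif: str,
    side: str,
    width: int = 15,
) -> pd.DataFrame:
    """Per-offset DSA of a trinucleotide motif in splice-site flank windows.

    ``windows`` are exonic sequences in transcription sense, cut by
    :func:`intronsig.coding_exome.intron_flank_windows`: for
    ``side="upstream"`` the window's last base abuts the 5'ss (donor); for
    ``side="downstream"`` its first base abuts the 3'ss (acceptor).

    Offset d ∈ [1, width−2] places the motif's splice-site-proximal base
    d nt from the site.  Ns counts motif occurrences at that offset across
    windows; Na counts occurrences at the mirrored offset on the reverse
    complement of each window, preserving distance-to-site.
    """
    if len(motif) != 3:
        raise ValueError("motif must be a trinucleotide")
    if side not in ("upstream", "downstream"):
        raise ValueError("side must be 'upstream' or 'downstream'")
    # truncated windows (short flanking exon) have ambiguous offsets and
    # are excluded from the per-offset scan
    full = [w for w in windows if len(w) == width]
    full_rc = [revcomp(w) for w in full]
    rows = []
    for d in range(1, width - 1):
        if side == "upstream":
            # motif's 3'-most base is d nt from the donor (at window end)
            sense_pos = width - d - 2
            anti_pos = d - 1
        else:
            # motif's 5'-most base is d nt from the acceptor (window start)
            sense_pos = d - 1
            anti_pos = width - d - 2
        ns = _motif_count_at(full, sense_pos, motif)
        na = _motif_count_at(full_rc, anti_pos, motif)
        rows.append((d, ns, na, dsa_score(ns, na), dsa_standard_error(ns, na)))
    return pd.DataFrame(rows, columns=["offset", "Ns", "Na", "S", "se"])


def flank_motif_dsa_pooled(windows: Sequence[str], motif: str) -> dict:
    """Whole-window DSA of a motif: occurrences pooled over all offsets.

    The offset-agnostic companion of :func:`flank_motif_dsa` (the window
    convention — mirrored offsets vs. pooling — changes what a negative
    score localises, so both views are reported).
    """
    if len(motif) != 3:
        raise ValueError("motif must be a trinucleotide")
    ns = sum(w.count(motif) for w in windows)
    na = sum(revcomp(w).count(motif) for w in windows)
    return {"Ns": ns, "Na": na, "S": dsa_score(ns, na)}
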