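"""Splicing, retention, and alternative splice-site usage per locus.

A locus is an annotated intron or a cryptic GT|AG segment with its genomic
donor/acceptor interval.  Reads fall into three categories: *spliced*
(unique reads of the exactly matching junction), *alternative* (unique
reads of junctions sharing exactly one boundary with the locus), and
*retained* (uniquely mapped reads whose alignment covers the entire locus;
a mate pair supporting the same locus counts once).  Levels are the
proportion of each category out of all analyzed reads for the locus; a
locus is *covered* when the total reaches ``min_reads`` (10 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from intronsig.genome_io import JunctionRecord


@dataclass(frozen=True)
class QuantParams:
    """Coverage threshold (10 reads) and replicate labels."""

    min_reads: int = 10
    replicates: tuple[str, ...] = ("rep1",)

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


@dataclass(frozen=True)
class ReadInterval:
    """A uniquely mapped read's contiguous genomic alignment span.

    ``fragment_id`` is shared by the two mates of a pair so that a pair
    supporting the same locus is counted once.
    """

    chromosome: str
    start: int
    end: int
    fragment_id: str


def group_alternative_junctions(
    junctions: Sequence[JunctionRecord],
) -> list[list[int]]:
    """Cluster junctions sharing a donor xor an acceptor.

    Returns connected components as lists of indices into ``junctions``.
    Two junctions are linked iff they share exactly one boundary; identical
    junctions (both boundaries equal) are distinct nodes but end up in one
    component whenever a third junction links them — callers should
    deduplicate replicate rows first.
    """
    parent = list(range(len(junctions)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_donor: dict[tuple[str, int], list[int]] = {}
    by_acceptor: dict[tuple[str, int], list[int]] = {}
    for i, j in enumerate(junctions):
        by_donor.setdefault((j.chromosome, j.donor), []).append(i)
        by_acceptor.setdefault((j.chromosome, j.acceptor), []).append(i)
    import itertools

    for group in list(by_donor.values()) + list(by_acceptor.values()):
        for i, jdx in itertools.combinations(group, 2):
            a, b = junctions[i], junctions[jdx]
            if a.interval == b.interval and a.chromosome == b.chromosome:
                continue  # same junction, not an alternative variant
            union(i, jdx)
    clusters: dict[int, list[int]] = {}
    for i in range(len(junctions)):
        clusters.setdefault(find(i), []).append(i)
    return sorted(clusters.values(), key=lambda c: c[0])


def count_retention(
    read_intervals: Iterable[ReadInterval],
    locus: tuple[str, int, int],
) -> int:
    """Reads fully spanning a locus, counting each mate pair once."""
    chrom, start, end = locus
    fragments = {
        r.fragment_id
        for r in read_intervals
        if r.chromosome == chrom and r.start <= start and r.end >= end
    }
    return len(fragments)


def compute_locus_profile(
    locus_id: str,
    locus: tuple[str, int, int],
    junctions: Sequence[JunctionRecord],
    read_intervals: Iterable[ReadInterval] = (),
    params: QuantParams = QuantParams(),
    counts: tuple[int, int, int] | None = None,
) -> dict:
    """Splicing / retention / alternative-usage profile for one locus.

    Counts come either from junctions + read intervals, or pre-aggregated
    as ``counts=(spliced, retained, alt)`` — both paths produce identical
    profiles.  Levels are each category over the total; all NaN when the
    locus has no analyzed reads.
    """
    chrom, start, end = locus
    if counts is not None:
        spliced, retained, alt = counts
    else:
        spliced = 0
        alt = 0
        clusters = group_alternative_junctions(junctions)
        locus_members: set[int] = set()
        for cluster in clusters:
            for i in cluster:
                j = junctions[i]
                if j.chromosome == chrom and j.interval == (start, end):
                    locus_members = set(cluster)
                    break
            if locus_members:
                break
        for i, j in enumerate(junctions):
            if j.chromosome == chrom and j.interval == (start, end):
                spliced += j.unique_reads
            elif i in locus_members:
                alt += j.unique_reads
        retained = count_retention(read_intervals, locus)
    total = spliced + retained + alt
    if total > 0:
        levels = (spliced / total, retained / total, alt / total)
    else:
        levels = (float("nan"),) * 3
    return {
        "locus_id": locus_id,
        "chromosome": chrom,
        "start": start,
        "end": end,
        "spliced_reads": spliced,
        "retained_reads": retained,
        "alt_reads": alt,
        "total_reads": total,
        "splicing_level": levels[0],
        "retention_level": levels[1],
        "alt_usage": levels[2],
        "covered": total >= params.min_reads,
    }


def profiles_from_count_table(
    counts: pd.DataFrame, params: QuantParams = QuantParams()
) -> pd.DataFrame:
    """Profiles from a per-locus count TSV (locus_id, spliced, retained, alt).

    The alignment-free path: equivalent to the junction/interval path, and
    the one the synthetic junction simulator feeds.
    """
    required = {"locus_id", "spliced", "retained", "alt"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    rows = []
    for rec in counts.itertuples(index=False):
        chrom = getattr(rec, "chromosome", "NA")
        start = int(getattr(rec, "start", -1))
        end = int(getattr(rec, "end", -1))
        rows.append(
            compute_locus_profile(
                rec.locus_id,
                (chrom, start, end),
                junctions=(),
                params=params,
                counts=(int(rec.spliced), int(rec.retained), int(rec.alt)),
            )
        )
    return pd.DataFrame(rows)


def match_novel_junctions_to_segments(
    segments: pd.DataFrame,
    junctions: Sequence[JunctionRecord],
) -> pd.DataFrame:
    """Match sense-strand segments to novel (non-annotated) junctions.

    A match requires exact equality of the genomic donor/acceptor interval
    and ``annotated == False``.  Evidence from any replicate suffices:
    pass the union of replicate junction lists.  Duplicate segments (same
    genomic interval listed twice) are an error.
    """
    sense = segments[segments["strand"] == "sense"]
    keyed: dict[tuple[str, int, int], int] = {}
    chrom_by_gene = None
    if "chromosome" in sense.columns:
        key_cols = ["chromosome", "genomic_start", "genomic_end"]
    else:
        raise ValueError("segment table must carry a 'chromosome' column")
    for idx, rec in sense.iterrows():
        key = (rec["chromosome"], int(rec["genomic_start"]), int(rec["genomic_end"]))
        if key in keyed:
            raise ValueError(f"duplicate segment at {key}")
        keyed[key] = idx
    matched_rows = []
    for j in junctions:
        if j.annotated:
            continue
        key = (j.chromosome, j.donor, j.acceptor)
        if key in keyed:
            matched_rows.append((keyed[key], j.unique_reads))
    if not matched_rows:
        out = sense.iloc[0:0].copy()
        out["junction_reads"] = pd.Series(dtype=int)
        return out
    reads: dict[int, int] = {}
    for idx, n in matched_rows:
        reads[idx] = reads.get(idx, 0) + n
    out = sense.loc[sorted(reads)].copy()
    out["junction_reads"] = [reads[i] for i in sorted(reads)]
    return out.reset_index(drop=True)


def average_replicate_profiles(profiles: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine per-replicate profiles into one table.

    Levels are averaged over the replicates that cover a locus; a locus
    counts as spliced if it has spliced reads in at least one replicate,
    and as covered if covered in at least one replicate.
    """
    frames = []
    for rep, df in profiles.items():
        d = df.copy()
        d["replicate"] = rep
        frames.append(d)
    allp = pd.concat(frames, ignore_index=True)

    def agg(group: pd.DataFrame) -> pd.Series:
        covered = group[group["covered"]]
        basis = covered if len(covered) else group
        return pd.Series(
            {
                "splicing_level": basis["splicing_level"].mean(),
                "retention_level": basis["retention_level"].mean(),
                "alt_usage": basis["alt_usage"].mean(),
                "total_reads": group["total_reads"].sum(),
                "spliced_any": bool((group["spliced_reads"] > 0).any()),
                "covered": bool(group["covered"].any()),
            }
        )

    out = allp.groupby("locus_id", sort=True).apply(agg, include_groups=False)
    return out.reset_index()


def splicing_level_class_summary(
    profiles: pd.DataFrame,
    is_3n: Mapping[str, bool] | None = None,
    at_content: Mapping[str, float] | None = None,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Bin covered, spliced loci by splicing level; summarise each bin.

    Bins are the ten equal-width intervals (0, 0.1], (0.1, 0.2], …
    (0.9, 1.0] over the splicing level (level-0 loci fall outside every
    bin).  Per bin: locus count, fraction of all binned loci, fraction of
    3n loci, mean AT content.  The returned frame's ``attrs`` carry the
    Pearson correlation of bin index against 3n fraction and AT content.
    """
    covered = profiles[profiles["covered"] & (profiles["splicing_level"] > 0)]
    if len(covered) == 0:
        return pd.DataFrame(
            columns=["bin", "lo", "hi", "n_loci", "fraction", "fraction_3n", "mean_at"]
        )
    edges = np.linspace(0, 1, n_bins + 1)
    # right-closed bins (0, 0.1], ... ; searchsorted on the left edge
    levels = covered["splicing_level"].to_numpy()
    bins = np.clip(np.searchsorted(edges, levels, side="left"), 1, n_bins)
    rows = []
    total = len(covered)
    for b in range(1, n_bins + 1):
        sel = covered[bins == b]
        ids = sel["locus_id"]
        frac3n = (
            float(np.mean([is_3n[i] for i in ids])) if is_3n and len(sel) else float("nan")
        )
        mean_at = (
            float(np.mean([at_content[i] for i in ids]))
            if at_content and len(sel)
            else float("nan")
        )
        rows.append(
            (b, edges[b - 1], edges[b], len(sel), len(sel) / total, frac3n, mean_at)
        )
    out = pd.DataFrame(
        rows, columns=["bin", "lo", "hi", "n_loci", "fraction", "fraction_3n", "mean_at"]
    )
    occupied = out[out["n_loci"] > 0]
    for col, key in (("fraction_3n", "pearson_r_3n"), ("mean_at", "pearson_r_at")):
        vals = occupied[col].dropna()
        if len(vals) >= 3 and vals.nunique() > 1:
            r, p = stats.pearsonr(occupied.loc[vals.index, "bin"], vals)
            out.attrs[key] = float(r)
            out.attrs[key + "_p"] = float(p)
        else:
            out.attrs[key] = float("nan")
            out.attrs[key + "_p"] = float("nan")
    return out
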