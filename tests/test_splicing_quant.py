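import numpy as np
import pandas as pd
import pytest

from intronsig.genome_io import JunctionRecord
from intronsig.splicing_quant import (
    QuantParams,
    ReadInterval,
    average_replicate_profiles,
    compute_locus_profile,
    count_retention,
    group_alternative_junctions,
    match_novel_junctions_to_segments,
    profiles_from_count_table,
    splicing_level_class_summary,
)


def J(donor, acceptor, reads=1, annotated=False, chrom="c1"):
    return JunctionRecord(chrom, donor, acceptor, "+", reads, annotated)


class TestClustering:
    def test_shared_donor_one_cluster(self):
        clusters = group_alternative_junctions([J(100, 125), J(100, 131)])
        assert clusters == [[0, 1]]

    def test_disjoint_junctions_two_clusters(self):
        clusters = group_alternative_junctions([J(100, 125), J(200, 225)])
        assert clusters == [[0], [1]]

    def test_transitive_chain(self):
        clusters = group_alternative_junctions(
            [J(100, 125), J(100, 131), J(90, 131)]
        )
        assert clusters == [[0, 1, 2]]

    def test_same_chromosome_required(self):
        clusters = group_alternative_junctions(
            [J(100, 125, chrom="c1"), J(100, 131, chrom="c2")]
        )
        assert clusters == [[0], [1]]


class TestRetention:
    def test_spanning_read_counts(self):
        reads = [ReadInterval("c1", 90, 130, "f1")]
        assert count_retention(reads, ("c1", 100, 125)) == 1

    def test_partial_read_does_not(self):
        reads = [ReadInterval("c1", 100, 120, "f1")]
        assert count_retention(reads, ("c1", 100, 125)) == 0

    def test_mate_pair_counts_once(self):
        reads = [
            ReadInterval("c1", 90, 130, "f1"),
            ReadInterval("c1", 95, 140, "f1"),
        ]
        assert count_retention(reads, ("c1", 100, 125)) == 1

    def test_monotone_in_read_extent(self, rng):
        """Extending a read interval never decreases retention support."""
        locus = ("c1", 100, 125)
        for _ in range(50):
            s = int(rng.integers(80, 125))
            e = int(rng.integers(s + 1, 150))
            base = count_retention([ReadInterval("c1", s, e, "f")], locus)
            extended = count_retention(
                [ReadInterval("c1", s - 5, e + 5, "f")], locus
            )
            assert extended >= base


class TestLocusProfile:
    def test_levels(self):
        prof = compute_locus_profile(
            "x", ("c1", 100, 125), junctions=(), counts=(6, 4, 0)
        )
        assert (
            prof["splicing_level"],
            prof["retention_level"],
            prof["alt_usage"],
        ) == (0.6, 0.4, 0.0)
        assert prof["covered"]

    def test_levels_with_alt(self):
        prof = compute_locus_profile(
            "x", ("c1", 100, 125), junctions=(), counts=(5, 2, 3)
        )
        assert prof["splicing_level"] == 0.5
        assert prof["retention_level"] == pytest.approx(0.2)
        assert prof["alt_usage"] == pytest.approx(0.3)

    def test_coverage_flag(self):
        prof = compute_locus_profile(
            "x", ("c1", 100, 125), junctions=(), counts=(2, 1, 0),
            params=QuantParams(min_reads=10),
        )
        assert not prof["covered"]

    def test_junction_path_equals_count_path(self):
        junctions = [J(100, 125, reads=5), J(100, 131, reads=3)]
        reads = [
            ReadInterval("c1", 95, 130, "f1"),
            ReadInterval("c1", 90, 140, "f2"),
        ]
        via_junctions = compute_locus_profile(
            "x", ("c1", 100, 125), junctions, reads
        )
        via_counts = compute_locus_profile(
            "x", ("c1", 100, 125), junctions=(), counts=(5, 2, 3)
        )
        for k in ("spliced_reads", "retained_reads", "alt_reads",
                  "splicing_level", "retention_level", "alt_usage"):
            assert via_junctions[k] == via_counts[k]

    def test_conservation(self, rng):
        for _ in range(20):
            s, r, a = (int(x) for x in rng.integers(0, 30, size=3))
            prof = compute_locus_profile(
                "x", ("c1", 0, 25), junctions=(), counts=(s, r, a)
            )
            assert prof["total_reads"] == s + r + a
            if prof["total_reads"]:
                assert (
                    prof["splicing_level"]
                    + prof["retention_level"]
                    + prof["alt_usage"]
                ) == pytest.approx(1.0)


SEGMENTS = pd.DataFrame(
    {
        "chromosome": ["c1", "c1"],
        "gene_id": ["g1", "g1"],
        "strand": ["sense", "sense"],
        "genomic_start": [100, 300],
        "genomic_end": [125, 330],
        "mod3_class": ["3n+1", "3n"],
    }
)


class TestMatching:
    def test_exact_novel_match(self):
        out = match_novel_junctions_to_segments(SEGMENTS, [J(100, 125, reads=4)])
        assert len(out) == 1 and out["junction_reads"].item() == 4

    def test_annotated_junction_excluded(self):
        out = match_novel_junctions_to_segments(
            SEGMENTS, [J(100, 125, annotated=True)]
        )
        assert len(out) == 0

    def test_off_by_one_no_match(self):
        out = match_novel_junctions_to_segments(SEGMENTS, [J(101, 125)])
        assert len(out) == 0

    def test_replicate_union_sums_reads(self):
        out = match_novel_junctions_to_segments(
            SEGMENTS, [J(100, 125, reads=4), J(100, 125, reads=2)]
        )
        assert out["junction_reads"].item() == 6

    def test_duplicate_segments_error(self):
        dup = pd.concat([SEGMENTS, SEGMENTS.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            match_novel_junctions_to_segments(dup, [J(100, 125)])


class TestClassSummary:
    def make_profiles(self, levels, covered=True):
        n = len(levels)
        return pd.DataFrame(
            {
                "locus_id": [f"L{i}" for i in range(n)],
                "splicing_level": levels,
                "covered": covered,
            }
        )

    def test_all_low_levels_in_first_bin(self):
        out = splicing_level_class_summary(self.make_profiles([0.05] * 8))
        assert out[out["bin"] == 1]["n_loci"].item() == 8
        assert out[out["bin"] != 1]["n_loci"].sum() == 0

    def test_perfectly_linear_3n_fraction(self):
        levels, flags = [], {}
        for b in range(10):
            for i in range(10):
                lid = f"L{b}_{i}"
                levels.append(b / 10 + 0.05)
                flags[lid] = i < b  # 3n fraction rises 0.1 per bin
        prof = pd.DataFrame(
            {
                "locus_id": [f"L{b}_{i}" for b in range(10) for i in range(10)],
                "splicing_level": levels,
                "covered": True,
            }
        )
        out = splicing_level_class_summary(prof, is_3n=flags)
        assert out.attrs["pearson_r_3n"] == pytest.approx(1.0)

    def test_empty_when_no_covered_loci(self):
        out = splicing_level_class_summary(self.make_profiles([0.5], covered=False))
        assert len(out) == 0

    def test_bin_edges_right_closed(self):
        out = splicing_level_class_summary(self.make_profiles([0.1, 0.1001]))
        assert out[out["bin"] == 1]["n_loci"].item() == 1
        assert out[out["bin"] == 2]["n_loci"].item() == 1


def test_binomial_level_recovery():
    """Planted levels are recovered within binomial error at depth 100."""
    from intronsig.recovery import splicing_recovery_experiment

    out = splicing_recovery_experiment(n_loci=300, depth=100, seed=3)
    est = out["splicing_level_est"]
    true = out["splicing_level_true"]
    se = np.sqrt(true * (1 - true) / 100)
    ok = np.abs(est - true) <= 3 * np.maximum(se, 1e-9)
    assert ok.mean() > 0.99
    # unbiased in aggregate
    bias = (est - true).mean()
    assert abs(bias) < 3 * np.sqrt((true * (1 - true) / 100).mean() / len(out))


def test_average_replicate_profiles():
    base = {
        "locus_id": ["a", "b"],
        "spliced_reads": [5, 0],
        "total_reads": [10, 12],
        "splicing_level": [0.5, 0.0],
        "retention_level": [0.5, 1.0],
        "alt_usage": [0.0, 0.0],
        "covered": [True, True],
    }
    rep1 = pd.DataFrame(base)
    rep2 = pd.DataFrame(base | {"splicing_level": [0.7, 0.0], "retention_level": [0.3, 1.0]})
    out = average_replicate_profiles({"rep1": rep1, "rep2": rep2})
    a = out[out["locus_id"] == "a"].iloc[0]
    assert a["splicing_level"] == pytest.approx(0.6)
    assert a["spliced_any"]
    b = out[out["locus_id"] == "b"].iloc[0]
    assert not b["spliced_any"]
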