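import numpy as np
import pandas as pd
import pytest

from intronsig.coding_exome import EnumerationParams, extract_coding_exons
from intronsig.genome_io import revcomp
from intronsig.synthetic_data import (
    DepletionStratum,
    SimulationParams,
    apply_strand_depletion,
    expected_dsa,
    simulate_genome,
    simulate_junction_counts,
)


class TestSimulateGenome:
    def test_reproducible_by_seed(self):
        a = simulate_genome(SimulationParams(n_genes=10, seed=3))
        b = simulate_genome(SimulationParams(n_genes=10, seed=3))
        assert a.sequences == b.sequences
        assert a.truth_genes.equals(b.truth_genes)
        c = simulate_genome(SimulationParams(n_genes=10, seed=4))
        assert c.sequences != a.sequences

    def test_all_introns_optimal_when_fraction_one(self):
        ds = simulate_genome(
            SimulationParams(n_genes=30, gta_tag_intron_fraction=1.0, seed=1)
        )
        for gene in ds.genes:
            chrom = ds.sequences[gene.chromosome]
            for s, e in gene.introns():
                seq = chrom[s:e]
                if gene.strand == "-":
                    seq = revcomp(seq)
                assert seq.startswith("GTA") and seq.endswith("TAG")

    def test_planted_gta_fraction_exact(self, small_dataset):
        introns = small_dataset.truth_introns
        # realized flags equal the per-intron Bernoulli draws; fraction near 0.69
        frac = introns["gta_tag"].mean()
        n = len(introns)
        assert abs(frac - 0.69) < 3 * np.sqrt(0.69 * 0.31 / n)

    def test_exon_at_content_within_binomial_error(self, small_dataset):
        exons = extract_coding_exons(
            small_dataset.genes, small_dataset.sequences
        )
        seq = "".join(e.sequence for e in exons)
        at = (seq.count("A") + seq.count("T")) / len(seq)
        assert abs(at - 0.72) < 3 * np.sqrt(0.72 * 0.28 / len(seq))

    def test_intron_lengths_concentrated_in_prevalent_range(self, small_dataset):
        lengths = small_dataset.truth_introns["length"]
        inside = ((lengths >= 21) & (lengths <= 30)).mean()
        assert inside > 0.9

    def test_annotation_round_trip(self, tmp_path, small_dataset):
        from intronsig.genome_io import read_fasta, read_gff3_gene_models

        small_dataset.write(tmp_path)
        seqs = read_fasta(tmp_path / "genome.fasta")
        genes = read_gff3_gene_models(tmp_path / "annotation.gff3")
        assert seqs == small_dataset.sequences
        original = {g.gene_id: g for g in small_dataset.genes}
        assert len(genes) == len(original)
        for g in genes:
            o = original[g.gene_id]
            assert (g.strand, g.cds_exons) == (o.strand, o.cds_exons)


class TestDepletion:
    def test_delta_zero_unchanged(self, small_dataset):
        edited, log = apply_strand_depletion(
            small_dataset.sequences, small_dataset.genes,
            DepletionStratum(), 0.0, seed=1,
        )
        assert edited == small_dataset.sequences and len(log) == 0

    def test_delta_one_removes_all(self, small_dataset):
        from intronsig.strand_asymmetry import per_gene_stratum_counts

        edited, log = apply_strand_depletion(
            small_dataset.sequences, small_dataset.genes,
            DepletionStratum(), 1.0, seed=1,
        )
        exons = extract_coding_exons(small_dataset.genes, edited)
        counts = per_gene_stratum_counts(
            exons, EnumerationParams(), "GTA|TAG", "3n", (21, 30)
        )
        assert counts["Ns"].sum() == 0
        assert counts["Na"].sum() > 0

    def test_surviving_fraction_matches_delta(self):
        from intronsig.strand_asymmetry import per_gene_stratum_counts

        ds = simulate_genome(SimulationParams(n_genes=800, seed=9))
        exons0 = extract_coding_exons(ds.genes, ds.sequences)
        before = per_gene_stratum_counts(
            exons0, EnumerationParams(), "GTA|TAG", "3n", (21, 30)
        )["Ns"].sum()
        edited, log = apply_strand_depletion(
            ds.sequences, ds.genes, DepletionStratum(), 0.5, seed=10
        )
        exons1 = extract_coding_exons(ds.genes, edited)
        after = per_gene_stratum_counts(
            exons1, EnumerationParams(), "GTA|TAG", "3n", (21, 30)
        )["Ns"].sum()
        surviving = after / before
        # shared GTA starts make survival slightly below 1 - delta
        assert abs(surviving - 0.5) < 3 * np.sqrt(0.25 / before) + 0.03

    def test_edits_logged_and_single_base(self, small_dataset):
        edited, log = apply_strand_depletion(
            small_dataset.sequences, small_dataset.genes,
            DepletionStratum(), 0.7, seed=2,
        )
        assert len(log) > 0
        diffs = 0
        for chrom, seq in small_dataset.sequences.items():
            diffs += sum(a != b for a, b in zip(seq, edited[chrom]))
        assert diffs == log["genomic_pos"].nunique()

    def test_invalid_delta(self, small_dataset):
        with pytest.raises(ValueError):
            apply_strand_depletion(
                small_dataset.sequences, small_dataset.genes,
                DepletionStratum(), 1.5, seed=1,
            )


class TestExpectedDsa:
    @pytest.mark.parametrize("delta,expected", [(0, 0.0), (1, -1.0), (0.5, -1 / 3)])
    def test_closed_form(self, delta, expected):
        assert expected_dsa(delta) == pytest.approx(expected)

    def test_domain(self):
        with pytest.raises(ValueError):
            expected_dsa(-0.1)


class TestJunctionCounts:
    def loci(self, levels, depth=50):
        s, r, a = levels
        return pd.DataFrame(
            {
                "locus_id": ["L1"],
                "chromosome": ["c1"],
                "start": [100],
                "end": [125],
                "annotated": [True],
                "splicing_level": [s],
                "retention_level": [r],
                "alt_usage": [a],
                "depth": [depth],
            }
        )

    def test_pure_splicing(self):
        junctions, counts, _ = simulate_junction_counts(
            self.loci((1, 0, 0)), SimulationParams(seed=1)
        )
        assert counts["spliced"].item() == 50
        (j,) = junctions
        assert j.unique_reads == 50 and j.interval == (100, 125)

    def test_pure_retention_no_junction(self):
        junctions, counts, _ = simulate_junction_counts(
            self.loci((0, 1, 0)), SimulationParams(seed=1)
        )
        assert junctions == [] and counts["retained"].item() == 50

    def test_levels_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_junction_counts(
                self.loci((0.5, 0.1, 0.1)), SimulationParams(seed=1)
            )

    def test_mean_recovery(self):
        """Planted level 0.3 over many loci is recovered within 3 SE."""
        n = 500
        loci = pd.DataFrame(
            {
                "locus_id": [f"L{i}" for i in range(n)],
                "chromosome": "c1",
                "start": np.arange(n) * 50,
                "end": np.arange(n) * 50 + 25,
                "annotated": True,
                "splicing_level": 0.3,
                "retention_level": 0.6,
                "alt_usage": 0.1,
                "depth": 100,
            }
        )
        _, counts, _ = simulate_junction_counts(loci, SimulationParams(seed=2))
        est = counts["spliced"] / 100
        se_mean = np.sqrt(0.3 * 0.7 / 100 / n)
        assert abs(est.mean() - 0.3) < 3 * se_mean

    def test_seeded_reproducibility(self):
        a = simulate_junction_counts(self.loci((0.4, 0.5, 0.1)),
                                     SimulationParams(seed=5), seed=7)
        b = simulate_junction_counts(self.loci((0.4, 0.5, 0.1)),
                                     SimulationParams(seed=5), seed=7)
        assert a[1].equals(b[1]) and a[0] == b[0]
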