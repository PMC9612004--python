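# Methods

## The measurement model

The pipeline treats intron gain as a process that leaves four observable
signatures in a genome whose introns are short, `GT…AG`-bounded and
optimally `GTA…TAG`-flanked:

1. **Strand asymmetry of cryptic segments.** Every exonic tract beginning
   `GT` and ending `AG` within the intron size window is a candidate
   cryptic intron. For a segment class, `S = (Ns − Na)/(Ns + Na)` compares
   sense-strand counts with counts on the reverse complement of the same
   exons. The antisense strand acts as the neutral control: it experiences
   the same base composition and the same mutational processes, but
   splicing only reads the sense strand, so selection against accidental
   splice signals shows up as `S < 0`. If a fraction δ of sense-strand
   segments has been removed relative to a symmetric baseline,
   `S = ((1−δ) − 1)/((1−δ) + 1) = −δ/(2−δ)` — the closed form the recovery
   tests target.
2. **Junction evidence of cryptic splicing.** Segments whose exact
   donor/acceptor coordinates appear as non-annotated junctions are
   quantified like annotated introns: spliced reads (exact junction),
   alternative reads (junctions in the same donor/acceptor-sharing
   cluster), retained reads (alignments spanning the whole locus, mate
   pairs counted once), each as a proportion of the locus total.
3. **PTC content of established introns.** Under translation table 6 only
   TGA terminates; an intron is PTC⁺ iff a TGA codon intersects it when
   the retained transcript is read in frame.
4. **Positional structure.** Expression quartiles (log2), equal-width CDS
   bins, intron density, inter-intron and tail distances, compared with
   two-proportion, chi-square-uniformity, Pearson and Wilcoxon rank-sum
   tests.

## Statistical machinery

- **Gene bootstrap.** Genes, not exons or segments, are the exchangeable
  units: segment counts within a gene are correlated through composition
  and length. Each replicate draws `genes_per_draw = 500` genes *without*
  replacement (a subsampling bootstrap; with-replacement sampling is a
  switch on `BootstrapParams`), sums `Ns` and `Na`, and scores. Group
  contrasts use Welch t-tests on the replicate vectors with Bonferroni
  correction over the pairs tested. Defaults: 500 genes × 1000 replicates.
- **Missingness.** Size classes with `Ns + Na = 0` report `S` as missing
  (NaN), never 0 — an absent measurement is not a symmetric one.
- **First-order SE.** Where a quick scale for `S` is needed (flank scans,
  recovery checks) the independent-count approximation
  `SE(S) ≈ 1/√(Ns+Na)` is used.
- **Proportion tests** are pooled two-sample z tests squared into the 2×2
  chi-square without continuity correction, so they cross-check exactly
  against a contingency-table oracle.

## Enumeration conventions

- Coordinates are 0-based half-open internally; GFF3 and the STAR
  `SJ.out.tab` dialect are converted at the I/O boundary only.
- Segment length includes the bounding `GT` and `AG`, matching how
  annotated intron lengths are measured. All overlapping and nested
  (GT, AG) pairs in the 15–40 nt window count; enumeration is per exon and
  never spans an annotated intron or an exon–exon junction, because
  cryptic splicing acts on the pre-mRNA, where annotated introns interrupt
  the coding sequence. Segment totals are reported within the size window;
  no unfiltered totals are kept, since no downstream statistic uses them.
- Antisense enumeration runs on the reverse complement of each exon
  separately, preserving exon boundaries; the per-exon count matrices on
  the two strands are the unit every DSA statistic sums over.
- The boundary-signal classes `GTA|TAG`, `GTA|nAG`, `GTn|TAG`, `GTn|nAG`
  partition segments by their first and last three nucleotides; the mod3
  class is implied by length.
- **Flank scans.** Windows of 15 exonic nt upstream of donors (and
  downstream of acceptors) are scanned per offset: offset *d* places the
  motif's splice-site-proximal base *d* nt from the site, and the
  antisense count uses the mirrored offset on the reverse complement so
  that distance-to-site is preserved. Because pooling the window instead
  of mirroring offsets is an equally defensible convention, a pooled
  whole-window score is emitted alongside (offset 0 in `flank_dsa.tsv`).
  Truncated windows (flanking exon shorter than the width) are excluded
  from per-offset scans.

## PTC scanning choices

The reading frame enters through the intron's phase (upstream CDS length
mod 3). By default codons spanning the exon–intron boundaries are scanned,
using up to 2 nt of exonic context on each side; `boundary_codons=False`
restricts to fully intronic codons. Both modes are exposed because the
boundary rule is genuinely open; for 3n, phase-0 introns they coincide with
a plain disjoint-triplet scan, which the tests use as a cross-check. The
scan never continues past the intron: downstream frameshift consequences of
non-3n introns are out of scope for the per-intron flag.

## Splicing quantification choices

- Reads arrive either as genomic alignment intervals or as pre-aggregated
  per-locus counts; the two paths produce identical profiles, and the
  count path keeps the module testable with no alignment machinery. No
  junction-overhang filter is applied beyond what the aligner already
  enforced in the input table.
- Alternative-usage clusters are connected components under "shares donor
  xor acceptor". For cryptic segments the matching is restricted to novel
  (non-annotated) junctions; junctions sharing a boundary with an
  annotated intron therefore do not contribute to a segment's alternative
  count — the inclusive alternative would mix annotated-intron splice
  variation into the cryptic signal.
- Loci with zero spliced reads are excluded from splicing-level classes
  but remain in the denominators of fraction-spliced statistics.
- Replicates: levels are averaged over covering replicates; a locus is
  spliced/covered if it is so in at least one replicate.

## Positional conventions

- Quartiles: Q1 = weakly, Q4 = highly expressed; boundaries from the
  empirical log2 distribution; genes at expression 0 are excluded from
  quartile analyses (log2 undefined) but kept for sequence-only analyses;
  ties go to the lower quartile.
- Features are binned by their 5'-most CDS coordinate
  (`bin = ⌊pos·n_bins/L⌋ + 1`); midpoint binning is a config option.
- Tail distance is measured from the last intron's 3' splice site to the
  CDS end, in CDS coordinates (equivalently: the last exon's length). The
  choice of the 3'ss edge and of CDS rather than transcript coordinates is
  a convention; distances are strand-invariant by construction.

## The synthetic-data generator

`simulate_genome` emulates: gene counts per scaffold, Poisson(2.9) introns
per gene, lognormal exon lengths (median 194 bp, mean ≈ 354 bp), intron
lengths with 95% of mass uniform on 21–30 nt (rest on 15–20/31–35),
exon AT = 0.72 and intron AT = 0.80 split equally within complement pairs,
69% of introns `GTA…TAG`-bounded (non-optimal introns are rejection-sampled
so the planted flag is exact), lognormal expression (meanlog 4, sdlog 1.5,
arbitrary units), and random strands. `simulate_junction_counts` draws
per-locus (spliced, retained, alternative) counts multinomially at planted
levels — Dirichlet(5, 4, 1) by default, i.e. mean levels (0.5, 0.4, 0.1),
matching the regime where retention is common and alternative usage rare —
at Poisson(100) depth.

**What it deliberately does not emulate:** codon structure and amino-acid
composition (exons are iid nucleotides). Real coding sequence generates a
*positive* DSA background for `GT`/`AG`-containing motifs through amino
acid usage; the iid generator's baseline is exactly symmetric instead.
Passing recovery tests therefore demonstrate that the statistics recover a
planted depletion against a neutral baseline — not that the codon-driven
background in real data is modelled. No codon-aware null correction is
applied anywhere; scores on real data are interpreted raw. FASTQ-level
read simulation is also out of scope: counts and junctions are generated
directly.

**The depletion edit.** `apply_strand_depletion` disrupts each sense-strand
segment of the target stratum (default: `GTA|TAG`, 3n, 21–30 nt)
independently with probability δ by mutating the A of its leading GTA to C.
A single-base edit preserves the segment-length distribution and the
`GT…AG` backbone; the edited segments reclassify as `GTn|TAG`, so that
class's sense counts are inflated by construction and it cannot serve as a
negative control. Two small side effects are inherent to the edit and
bounded: segments of other mod3 classes sharing the same GTA start are
disrupted too (≈ δ·7% of them at the default composition, shifting their
S by at most ≈ −0.03 at δ = 0.8 — inside 3 bootstrap SE at the 2000-gene /
500-draw scale the recovery tests use), and segments whose terminal TAG
overlaps an edited GTA are lost at a ~10× smaller rate. The recovery
tests' "non-depleted strata ≈ 0" check is therefore made on the 3n+1 and
3n+2 classes of `GTA|TAG` in the prevalent window.

## Problem sizes and numerics

Recovery experiments run at 2000 genes with the full 500 × 1000 bootstrap
(a few seconds each); unit tests use 40–800 genes. Tolerances are sampling
-theoretic, not tuned: 3 bootstrap SDs for bootstrap means, 3 binomial SEs
(`√(p(1−p)/n)`) for proportions, `3/√(Ns+Na)` for flank scores. All
generators and the bootstrap consume `numpy.random.default_rng` seeds; the
CLI derives per-stage seeds from one master seed via `SeedSequence` spawn
keys, and every output table is written with fixed float formatting, so a
rerun with the same seed is byte-identical. Ratios with zero denominators
(empty strata, uncovered loci, zero-variance test inputs) are reported as
missing/degenerate rather than raised, except where an input violates a
documented precondition.

## Known limitations

- The GFF3 reader takes `CDS` features only (UTR introns are intentionally
  out of scope) and assumes one transcript per gene, as in the target
  annotation style.
- DSA carries no codon-aware null; on real genomes the raw positive
  background must be interpreted, not subtracted.
- Retention counting trusts the caller to supply uniquely mapped,
  contiguous alignments; no overhang or mapping-quality logic is applied.
- The generator's expression values are independent of gene architecture,
  so expression-stratified contrasts on synthetic data test machinery, not
  biology.
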