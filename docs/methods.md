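# Methods

## Repeat model

A microsatellite is a tandem repetition of a primitive 1–6 nt unit spanning
at least 20 nt. Units related by cyclic rotation or by rotation of the
reverse complement denote the same repeat; the catalogue of equivalence
classes over all primitive units of length ≤ 6 contains exactly 501 entries
(2, 4, 10, 33, 102, 350 for unit lengths 1–6). The canonical representative
of a class is its lexicographically smallest member under A < C < G < T —
any deterministic choice would do; lexicographic minimum is the standard
one. Matching across species is always by class; display tags keep the
rotation observed in the sequence, reoriented to the transcribed strand for
gene-anchored reports (so a minus-strand poly-glutamine tract prints
`CAG@Coding`, not `CTG@Coding`).

Non-primitive units never name classes: a dinucleotide tract seen at period
4 has consensus `ACAC`, which the detector reduces to its primitive root
`AC` (the period-4 candidate is discarded because the identical interval is
found at period 2 — when the phase consensus at period *p* is *d*-periodic,
the mismatch count at period *d* is provably identical).

## Imperfection (noise) model

The tolerance parameter bounds the per-tract substitution fraction. For a
candidate tract `[s, e)` at period *p*, positions are grouped into *p* phase
classes (`position mod p`); the consensus unit takes the majority base per
class with ties resolved alphabetically; every position differing from the
periodic extrapolation of that consensus is one mismatch, and the tract
qualifies when `mismatches ≤ tolerance × (e − s)`. `N` counts as a mismatch
everywhere and can never be a consensus base. A reported tract is maximal:
neither single-nucleotide extension qualifies. Insertions and deletions
within tracts are deliberately not modelled in this version: a pure
substitution model keeps the mismatch count exactly recomputable, which is
what makes the brute-force reference implementation and the planted-truth
fixtures airtight. Whether the tolerated fraction should be per-tract or
per-window is a genuinely open design point; per-tract was chosen because it
makes qualification a property of the reported interval alone.

Tolerance comparisons use `mismatches ≤ tolerance × length + 1e-9`; the
epsilon absorbs binary-representation error in products like `0.2 × 30` and
is shared by the scanning detector and the reference implementation.

## Detection algorithm

Perfect tracts (tolerance 0) are found per period from the lag-*p*
autocorrelation profile (`seq[i] == seq[i+p]`): every maximal run of
matches of length ≥ `min_tract_length − p` closes to a maximal tract. The
`min_seed_run` parameter (default 8) nucleates this search and is clamped so
it can never drop a qualifying tract.

Imperfect tracts use an exact row scan: for each candidate start the
mismatch count to every end is evaluated in one vectorized pass from
per-phase prefix counts, and a tract is emitted when it qualifies but
neither extension does. Because each consensus mismatch breaks at most two
lag comparisons, a qualifying tract `(s, e)` must satisfy
`lag-mismatches(s, e−p) ≤ 2 · tolerance · (e − s)`; a suffix minimum of the
rearranged inequality prunes most starts in O(1), which keeps the scan fast
on background sequence (a 6.5-kb locus scans in well under a second). The
scan is quadratic in the worst case and is intended for gene-locus-scale
inputs (up to a few hundred kb), not whole chromosomes.

Overlapping explanations of one locus (a poly-A run qualifies at periods 1,
2 and 3; a long tract and a purer sub-tract can both be maximal) are reduced
by a greedy pass: hits conflicting when their overlap exceeds half the
shorter hit, priority by fewer mismatches per base, then longer tract, then
smaller period, then smaller start. One consequence worth knowing: when
noise clusters at a tract edge, the kept hit may shave those edge
nucleotides off in favour of the purer core, so "recovery" of a noisy
planted tract is asserted as class identity plus majority overlap, not exact
coordinates.

`oracle_find_ssrs` re-derives the same definitions by enumerating every
substring at every period on the full (start, end) matrix. It shares only
the mismatch definition and the overlap-resolution pass with the production
path and is the binding cross-check: the suite asserts exact agreement on
hundreds of random sequences at tolerances 0, 0.1 and 0.2.

## Gene regions and translation

Gene models come from GFF3/GTF via `gffutils`. With multiple transcripts the
one with the longest total CDS represents the gene (deterministic,
overridable policy hook); missing UTRs are derived as exonic-minus-CDS split
at the CDS boundaries in transcription orientation. The locus partition
comprises Coding, 5UTR, 3UTR, introns (exon gaps, ordinals in transcription
order), Exon for exonic-but-non-coding sequence (non-coding transcripts),
and flanks of `flank_length` (default 2,000 nt) 5′ and 3′ of the gene in
transcription orientation, clipped at contig boundaries. The partition
property — disjoint intervals covering span ± flank — is tested directly.

A hit is assigned to the label it overlaps most, with ties broken by
specificity (Coding > 5UTR > 3UTR > Intron > Exon > Upstream > Downstream);
hits overlapping two genes go to the gene with the larger overlap. Coding
hits are projected into spliced-CDS coordinates, trimmed to complete codons
(partial codons at tract edges dropped) and translated with the standard
genetic code via Biopython.

## Conservation

Feature identity is (canonical class, region label); intron ordinals and
tract lengths do not enter identity, though per-species maximum tract
lengths are retained for inspection. The conservation ratio uses the full
cluster as denominator — a species without data counts absent (logged as a
warning), which is the conservative reading. A species with several
paralogs counts present if any of them carries the feature. Because a
qualifying tract at tolerance *t* is contained in a qualifying tract at any
*t′* ≥ *t* (per period, before overlap resolution), presence and hence
ratios are monotone non-decreasing in tolerance in practice; the containment
property itself is tested on the pre-resolution hit sets.

## Synthetic cohorts

`make_gene_locus` draws an i.i.d. background (GC content configurable,
default 0.5) around a configurable gene: defaults are a three-exon coding
gene (CDS 150+300+150 nt, introns 400 and 700 nt, UTRs 200/300 nt, flanks
2,000 nt), total ≈ 6.4 kb. `plant_ssr` writes a unit-tiled tract into a
uniformly chosen in-region position (for coding plants: wholly inside one
CDS block at a requested frame offset), applies
`floor(noise_fraction × length)` substitutions at distinct positions — each
to a base different from the planted one — and forces the two bases just
outside the tract off-phase so the planted coordinates are exactly the
maximal perfect tract. `make_cohort` derives one child seed per
(group, species) locus from a root `SeedSequence`, making cohorts
byte-reproducible from a single integer.

The default demonstration design is a 6-mammal / 6-fish cohort: a CA-class
intronic feature in all mammals and five of six fishes (ratios 1.0 and
0.833, conserved in both clusters at the 0.8 threshold) and a human-only
CAG coding feature (conserved nowhere). Five fishes rather than four because
4/6 < 0.8: with the full-cluster denominator, four presences cannot clear an
80% threshold in a six-species cluster.

What the generator does *not* emulate: phylogenetic covariance between
species, indel processes, compositional heterogeneity, overlapping genes and
alternative splicing. Passing tests therefore demonstrate the pipeline's
contracts (exact detection semantics, correct region arithmetic, correct
ratio bookkeeping), not performance on real genomes, where repeat density,
assembly gaps and annotation quality add failure modes the fixtures do not
contain.

## Numerical and degenerate-input choices

- Coordinates: 0-based half-open in memory; 1-based inclusive in TSV
  reports; 0-based half-open in BED.
- Empty sequences, sequences shorter than the minimum tract, and periods
  longer than the sequence return empty hit lists rather than erroring.
- Consensus ties go to the alphabetically first base on both detector
  routes, keeping strand symmetry exact at tolerance 0.
- All writers emit rows in sorted, fully determined order; two runs with
  identical seed and config are byte-identical (asserted by tests).
- The brute-force reference refuses sequences over 500 nt (quadratic
  memory); the scanning detector has no such guard.

## Problem sizes used in the test suite

Detector/reference equivalence runs on 100 random 200-nt sequences per
tolerance level; end-to-end checks use the 12-species demonstration cohort
(24 loci of ≈ 6.4 kb) at tolerance 0 and single ≈ 6.4-kb loci at tolerance
0.2. These sizes exercise every code path while keeping the full suite
under ten seconds on one CPU.
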