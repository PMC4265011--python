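# ssrcompare

Cross-species identification of microsatellite biomarkers: a library and
command-line tool for detecting simple sequence repeats (SSRs) in genomic
sequence, placing them within gene architecture, and scoring how well each
`pattern@region` feature is conserved across user-defined species clusters.

Variation in microsatellite copy number underlies a family of genetic
disorders — CAG expansions in the *HTT* coding region (Huntington disease),
GAA expansions in the first intron of *FXN*/X25 (Friedreich ataxia), GGGGCC
expansions upstream of *C9orf72* (ALS/FTD). Whether a disease-linked repeat
is conserved in a candidate model organism is exactly what an experimentalist
needs to know before committing to mouse, zebrafish or fly. `ssrcompare`
answers that question on any set of genomes, annotations and ortholog tables,
and ships a synthetic-cohort generator so the whole pipeline is testable
without downloading a single genome.

## The model

- **Microsatellite**: a tandem repeat of a 1–6 nt unit spanning ≥ 20 nt.
- **Imperfect repeats**: a tract at period *p* is scored against the periodic
  extrapolation of its consensus unit (majority base per phase class); the
  tract qualifies when `mismatches ≤ tolerance × length`. Reported tracts are
  *maximal*: one more nucleotide on either side would break the bound.
  Substitution noise only; indels are out of scope.
- **Canonical motif classes**: units equivalent under cyclic rotation and
  reverse complement name the same repeat (`ACT` ≡ `CTA` ≡ `TAC` ≡ `AGT` …).
  Over primitive units of length 1–6 this yields exactly **501** classes
  (2 / 4 / 10 / 33 / 102 / 350 by unit length). Matching always happens at
  class level; reports display the rotation actually observed, read in
  transcription orientation.
- **Seven gene areas**: Coding, 5UTR, 3UTR, Intron, Exon (exonic but
  non-coding), plus 2,000-nt Upstream and Downstream flanks taken 5′ of the
  5′-UTR and 3′ of the 3′-UTR in transcription orientation. Each hit gets a
  tag such as `CAG@Coding` or `GAA@Intron 1`; coding hits are translated so
  a poly-Q run is visible as protein.
- **Conservation ratio**: for an ortholog group and a species cluster *C*,
  `ratio = |{s ∈ C : s carries the feature}| / |C|`; the feature is
  *conserved* in *C* at the default threshold 0.8 and *exclusive* to *C*
  when conserved there and in no other cluster.

## Worked example

Simulate a 6-mammal / 6-fish cohort with a CA-class tract planted in the
*EGFR*-like intron of 11 of 12 species and a CAG coding tract in human only,
then run the full pipeline:

```bash
ssrcompare simulate --seed 11 --out cohort
for sp in Human Gorilla Macaque Mouse Dog Cow Zebrafish Stickleback Medaka Fugu Tetraodon Cod; do
  ssrcompare detect cohort/$sp.fa --out hits_$sp.tsv
  ssrcompare annotate --hits hits_$sp.tsv --fasta cohort/$sp.fa \
      --gff cohort/$sp.gff3 --out ann/$sp.tsv
done
ssrcompare compare --annotated ann --orthologs cohort/orthologs.tsv \
    --clusters cohort/clusters.tsv --out records.tsv --report report.tsv
```

`ann/Human.tsv` contains the two planted features with their tags and, for
the coding tract, its peptide:

```
sequence_id	start	end	found_unit	canonical_unit	period	copies	mismatches	purity	gene_id	region	ordinal	tag	peptide
Human.EGFR	3712	3735	CA	AC	2	12	0	1	EGFR_Human	Intron	2	CA@Intron 2
Human.SCA6	3838	3861	CAG	AGC	3	8	0	1	SCA6_Human	Coding		CAG@Coding	QQQQQQQQ
```

The CA tract is 12 perfect copies (24 nt) in an intron; the CAG tract is 8
in-frame copies translating to eight glutamines. `report.tsv` then shows the
cross-species verdict at the default 80% conservation ratio:

```
gene	disease	tag	Mammals	Fishes
EGFR	Cancers	CA@Intron 1	Human, Gorilla, Macaque, Mouse, Dog, Cow	Zebrafish, Stickleback, Fugu, Tetraodon, Cod
SCA6	Spinocerebellar ataxia type 6	-	Non	Non
```

`CA@Intron` is conserved in both clusters (ratios 6/6 and 5/6); the
human-only `CAG@Coding` feature clears the threshold nowhere and renders
`Non`. Raising `--tolerance` to 0.2 additionally recovers noisy tracts whose
mismatch fraction stays within the budget — the mechanism by which an
interrupted GAA repeat becomes comparable across species.

The 501-class catalogue itself is available as a table:

```bash
ssrcompare classes --max-unit 6 | head -4
period	representative	members
1	A	2
1	C	2
2	AC	4
```

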