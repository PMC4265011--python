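"""Gene models, region maps, region assignment, coding translation."""
import numpy as np
import pytest
from Bio.Seq import Seq

from conftest import random_dna
from ssrcompare.detect import DetectorConfig, SsrHit, find_ssrs
from ssrcompare.labels import RegionLabel
from ssrcompare.motifs import parse_tag, reverse_complement
from ssrcompare.regions import (
    GeneModel,
    MalformedAnnotationError,
    annotate_hits,
    assign_region,
    derive_region_map,
    read_gene_models,
    translate_coding_hit,
)
from ssrcompare.simulate import LocusGeometry, PlantSpec, make_gene_locus, plant_ssr

GFF_TEXT = """##gff-version 3
chr1\ttest\tgene\t1001\t1600\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t1001\t1600\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\ttest\texon\t1001\t1200\t.\t+\t.\tParent=geneA.t1
chr1\ttest\texon\t1401\t1600\t.\t+\t.\tParent=geneA.t1
chr1\ttest\tCDS\t1101\t1200\t.\t+\t0\tID=geneA.cds;Parent=geneA.t1
chr1\ttest\tCDS\t1401\t1500\t.\t+\t2\tID=geneA.cds;Parent=geneA.t1
chr1\ttest\tgene\t5001\t5400\t.\t-\t.\tID=geneB
chr1\ttest\tmRNA\t5001\t5400\t.\t-\t.\tID=geneB.t1;Parent=geneB
chr1\ttest\texon\t5001\t5400\t.\t-\t.\tParent=geneB.t1
chr1\ttest\tCDS\t5101\t5300\t.\t-\t0\tID=geneB.cds;Parent=geneB.t1
chr1\ttest\tgene\t8001\t8500\t.\t+\t.\tID=geneC
chr1\ttest\tmRNA\t8001\t8500\t.\t+\t.\tID=geneC.t1;Parent=geneC
chr1\ttest\texon\t8001\t8500\t.\t+\t.\tParent=geneC.t1
chr1\ttest\tgene\t9001\t9900\t.\t+\t.\tID=geneD
chr1\ttest\tmRNA\t9001\t9900\t.\t+\t.\tID=geneD.t1;Parent=geneD
chr1\ttest\texon\t9001\t9900\t.\t+\t.\tParent=geneD.t1
chr1\ttest\tCDS\t9101\t9160\t.\t+\t0\tID=geneD.t1.cds;Parent=geneD.t1
chr1\ttest\tmRNA\t9001\t9900\t.\t+\t.\tID=geneD.t2;Parent=geneD
chr1\ttest\texon\t9001\t9900\t.\t+\t.\tParent=geneD.t2
chr1\ttest\tCDS\t9101\t9220\t.\t+\t0\tID=geneD.t2.cds;Parent=geneD.t2
chr1\ttest\tgene\t12001\t12200\t.\t.\t.\tID=geneE
"""


@pytest.fixture(scope="module")
def models():
    return {g.gene_id: g for g in read_gene_models(GFF_TEXT)}


class TestReadGeneModels:

    def test_two_exon_gene_with_derived_utrs(self, models):
        gene = models["geneA"]
        assert gene.exons == ((1000, 1200), (1400, 1600))
        assert gene.cds == ((1100, 1200), (1400, 1500))
        assert gene.utr5 == ((1000, 1100),)
        assert gene.utr3 == ((1500, 1600),)

    def test_minus_strand_utr_orientation(self, models):
        gene = models["geneB"]
        # genomically-after is 5' on the minus strand
        assert gene.utr5 == ((5300, 5400),)
        assert gene.utr3 == ((5000, 5100),)

    def test_noncoding_gene_has_empty_cds(self, models):
        gene = models["geneC"]
        assert gene.cds == () and gene.utr5 == () and gene.utr3 == ()

    def test_longest_cds_transcript_wins(self, models):
        gene = models["geneD"]
        assert gene.transcript_id == "geneD.t2"
        assert gene.cds == ((9100, 9220),)

    def test_strandless_gene_rejected(self, models):
        assert "geneE" not in models

    def test_cds_outside_exons_is_malformed(self):
        bad = (
            "##gff-version 3\n"
            "chr1\tt\tgene\t101\t200\t.\t+\t.\tID=g\n"
            "chr1\tt\tmRNA\t101\t200\t.\t+\t.\tID=g.t;Parent=g\n"
            "chr1\tt\texon\t101\t150\t.\t+\t.\tParent=g.t\n"
            "chr1\tt\tCDS\t101\t200\t.\t+\t0\tID=g.c;Parent=g.t\n"
        )
        with pytest.raises(MalformedAnnotationError):
            read_gene_models(bad)


def _coverage(region_map):
    points = sorted((r.start, r.end) for r in region_map)
    for (s1, e1), (s2, e2) in zip(points, points[1:]):
        assert e1 <= s2, "region intervals overlap"
    return points[0][0], points[-1][1], sum(e - s for s, e in points)


class TestRegionMap:
    def test_flank_windows_follow_transcription_orientation(self):
        plus = GeneModel("g", "c", "+", exons=((5000, 8000),))
        labels = {r.label: (r.start, r.end) for r in derive_region_map(plus)}
        assert labels[RegionLabel.UPSTREAM] == (3000, 5000)
        assert labels[RegionLabel.DOWNSTREAM] == (8000, 10000)
        minus = GeneModel("g", "c", "-", exons=((5000, 8000),))
        labels = {r.label: (r.start, r.end) for r in derive_region_map(minus)}
        assert labels[RegionLabel.UPSTREAM] == (8000, 10000)
        assert labels[RegionLabel.DOWNSTREAM] == (3000, 5000)

    def test_flank_clipped_at_contig_boundaries(self):
        gene = GeneModel("g", "c", "+", exons=((800, 1200),))
        labels = {r.label: (r.start, r.end) for r in derive_region_map(gene, contig_length=2000)}
        assert labels[RegionLabel.UPSTREAM] == (0, 800)
        assert labels[RegionLabel.DOWNSTREAM] == (1200, 2000)

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("coding", [True, False])
    def test_partition_property(self, strand, coding):
        geometry = LocusGeometry(strand=strand) if coding else LocusGeometry(
            strand=strand, cds_exon_lengths=(), intron_lengths=()
        )
        locus = make_gene_locus(3, geometry=geometry)
        region_map = derive_region_map(locus.gene, contig_length=len(locus.seq))
        lo, hi, covered = _coverage(region_map)
        span = locus.gene.span
        flank = locus.gene.flank_length
        assert lo == max(0, span[0] - flank)
        assert hi == min(len(locus.seq), span[1] + flank)
        assert covered == hi - lo  # disjoint + contiguous = partition

    def test_intron_ordinals_follow_transcription_order(self):
        plus = make_gene_locus(1, geometry=LocusGeometry(strand="+")).gene
        minus = make_gene_locus(1, geometry=LocusGeometry(strand="-")).gene
        for gene in (plus, minus):
            introns = [r for r in derive_region_map(gene) if r.label is RegionLabel.INTRON]
            if gene.strand == "-":
                introns = introns[::-1]  # transcription order reads right-to-left
            assert [r.ordinal for r in introns] == [1, 2]


class TestAssignRegion:
    gene = GeneModel(
        "g",
        "c",
        "+",
        exons=((1000, 1200), (1400, 1600)),
        cds=((1100, 1200), (1400, 1500)),
        utr5=((1000, 1100),),
        utr3=((1500, 1600),),
    )

    def _assign(self, start, end):
        region_map = derive_region_map(self.gene)
        return assign_region(SsrHit("c", start, end, "CA", 0), region_map)

    def test_hit_inside_first_intron_gets_ordinal(self):
        assert self._assign(1250, 1290) == (RegionLabel.INTRON, 1)

    def test_hit_inside_cds(self):
        assert self._assign(1110, 1140) == (RegionLabel.CODING, None)

    def test_majority_overlap_wins(self):
        # 12 nt in CDS, 9 nt in the intron
        assert self._assign(1188, 1209) == (RegionLabel.CODING, None)

    def test_equal_overlap_breaks_by_specificity(self):
        # 10 nt in UTR5, 10 nt in CDS: Coding is more specific
        assert self._assign(1090, 1110) == (RegionLabel.CODING, None)

    def test_hit_outside_map_returns_none(self):
        assert self._assign(20000, 20040) is None


def _single_exon_gene(cds_start, cds_len, contig_len, strand="+"):
    return GeneModel(
        "g",
        "c",
        strand,
        exons=((cds_start - 30, cds_start + cds_len + 30),),
        cds=((cds_start, cds_start + cds_len),),
        utr5=((cds_start - 30, cds_start),) if strand == "+" else ((cds_start + cds_len, cds_start + cds_len + 30),),
        utr3=((cds_start + cds_len, cds_start + cds_len + 30),) if strand == "+" else ((cds_start - 30, cds_start),),
    )


class TestTranslation:
    def _contig(self, rng, cds_start, cds_seq, tail=40):
        return random_dna(rng, cds_start) + cds_seq + random_dna(rng, tail)

    def test_in_frame_polyglutamine(self):
        rng = np.random.default_rng(0)
        cds = "CAG" * 7 + "TAA"
        contig = self._contig(rng, 60, cds)
        gene = _single_exon_gene(60, len(cds), len(contig))
        hit = SsrHit("c", 60, 81, "CAG", 0)
        assert translate_coding_hit(hit, gene, contig) == "QQQQQQQ"

    def test_in_frame_polyalanine(self):
        rng = np.random.default_rng(1)
        cds = "GCG" * 7 + "TGA"
        contig = self._contig(rng, 60, cds)
        gene = _single_exon_gene(60, len(cds), len(contig))
        hit = SsrHit("c", 60, 81, "GCG", 0)
        assert translate_coding_hit(hit, gene, contig) == "AAAAAAA"

    def test_off_frame_tract_drops_partial_codons(self):
        """A CAG tract at frame offset 1 translates per the actual reading frame."""
        rng = np.random.default_rng(2)
        cds = "A" + "CAG" * 7 + "TT" + "TAA"  # tract occupies CDS offsets 1..21
        contig = self._contig(rng, 60, cds)
        gene = _single_exon_gene(60, len(cds), len(contig))
        hit = SsrHit("c", 61, 82, "CAG", 0)
        peptide = translate_coding_hit(hit, gene, contig)
        # independent check: complete codons inside CDS[1:22] are CDS[3:21]
        assert peptide == str(Seq(cds[3:21]).translate())
        assert peptide == "AAAAAA" and len(peptide) == 6

    def test_minus_strand_polyglutamine(self):
        rng = np.random.default_rng(3)
        cds = "CAG" * 7 + "TAA"  # transcript-side sequence
        genomic_cds = str(Seq(cds).reverse_complement())
        contig = self._contig(rng, 60, genomic_cds)
        gene = _single_exon_gene(60, len(genomic_cds), len(contig), strand="-")
        # the CAG tract sits at transcript CDS offsets 0..20 = genomic [63, 84)
        hit = SsrHit("c", 63, 84, "CTG", 0)
        assert translate_coding_hit(hit, gene, contig) == "QQQQQQQ"

    def test_non_coding_gene_refuses(self):
        gene = GeneModel("g", "c", "+", exons=((100, 400),))
        with pytest.raises(ValueError):
            translate_coding_hit(SsrHit("c", 150, 180, "CA", 0), gene, "A" * 500)


def _mirror_gene(gene: GeneModel, contig_len: int) -> GeneModel:
    def m(ivs):
        return tuple(sorted((contig_len - e, contig_len - s) for s, e in ivs))

    return GeneModel(
        gene_id=gene.gene_id,
        seq_id=gene.seq_id,
        strand="-" if gene.strand == "+" else "+",
        exons=m(gene.exons),
        cds=m(gene.cds),
        utr5=m(gene.utr5),
        utr3=m(gene.utr3),
        flank_length=gene.flank_length,
    )


class TestAnnotatePipeline:
    def test_strand_flip_preserves_class_region_and_tag(self):
        locus = make_gene_locus(21)
        rng = np.random.default_rng(5)
        plant_ssr(locus, PlantSpec(unit="CA", region=RegionLabel.INTRON, tract_length=24), rng)
        plant_ssr(locus, PlantSpec(unit="CAG", region=RegionLabel.CODING, tract_length=24), rng)
        seq = locus.sequence
        fwd_ann = annotate_hits(
            find_ssrs(seq, sequence_id=locus.contig_id), [locus.gene], {locus.contig_id: seq}
        )
        flipped = reverse_complement(seq)
        rev_gene = _mirror_gene(locus.gene, len(seq))
        rev_ann = annotate_hits(
            find_ssrs(flipped, sequence_id=locus.contig_id),
            [rev_gene],
            {locus.contig_id: flipped},
        )
        key = lambda anns: sorted(
            (a.hit.motif.representative, a.region, a.ordinal, a.tag, a.peptide) for a in anns
        )
        assert key(fwd_ann) == key(rev_ann)
        assert len(fwd_ann) >= 2

    def test_tags_round_trip(self):
        locus = make_gene_locus(22)
        plant_ssr(
            locus,
            PlantSpec(unit="GAA", region=RegionLabel.INTRON, tract_length=24),
            np.random.default_rng(6),
        )
        seq = locus.sequence
        anns = annotate_hits(
            find_ssrs(seq, sequence_id=locus.contig_id), [locus.gene], {locus.contig_id: seq}
        )
        assert anns, "planted tract was not annotated"
        for ann in anns:
            unit, region, ordinal = parse_tag(ann.tag)
            assert unit == (ann.display_unit or ann.hit.found_unit)
            assert region is ann.region
            assert ordinal == ann.ordinal

    def test_peptide_only_for_coding(self, demo_annotated):
        for anns in demo_annotated.values():
            for ann in anns:
                assert (ann.peptide is not None) == (ann.region is RegionLabel.CODING)

    def test_hit_outside_all_genes_is_skipped(self):
        gene = GeneModel("g", "c", "+", exons=((5000, 8000),))
        far_hit = SsrHit("c", 100, 130, "CA", 0)
        assert annotate_hits([far_hit], [gene]) == []
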