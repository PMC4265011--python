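"""Strand-aware gene-region maps and microsatellite annotation.

A gene model carries exon/CDS/UTR interval sets for one chosen transcript
(by default the one with the longest total CDS).  From it we derive a
partition of the locus into the seven areas a microsatellite can occupy --
Coding, 5UTR, 3UTR, Intron, Exon (exonic but neither coding nor UTR, i.e.
non-coding transcripts), plus 2,000-nt Upstream and Downstream flanks taken
in transcription orientation.  Hits are assigned to the region they overlap
most, coding hits are translated with the standard genetic code, and every
annotated hit gets a ``UNIT@Region`` tag.

Coordinates are 0-based half-open in memory and 1-based inclusive on disk
(GFF convention).
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio.Seq import Seq

from .detect import SsrHit
from .labels import SPECIFICITY_ORDER, RegionLabel
from .motifs import format_tag
from .motifs import reverse_complement as _revcomp

logger = logging.getLogger(__name__)

DEFAULT_FLANK_LENGTH = 2000

Interval = tuple[int, int]


class MalformedAnnotationError(ValueError):
    """Gene annotation violated a structural requirement (e.g. CDS outside exons)."""


def _merge(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return tuple(merged)


def _intersect(a: Sequence[Interval], b: Sequence[Interval]) -> tuple[Interval, ...]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if e > s:
                out.append((s, e))
    return _merge(out)


def _subtract(a: Sequence[Interval], b: Sequence[Interval]) -> tuple[Interval, ...]:
    out = []
    for s, e in a:
        pieces = [(s, e)]
        for s2, e2 in b:
            nxt = []
            for ps, pe in pieces:
                if e2 <= ps or s2 >= pe:
                    nxt.append((ps, pe))
                else:
                    if ps < s2:
                        nxt.append((ps, s2))
                    if e2 < pe:
                        nxt.append((e2, pe))
            pieces = nxt
        out.extend(pieces)
    return _merge(out)


def _total(intervals: Sequence[Interval]) -> int:
    return sum(e - s for s, e in intervals)


@dataclass(frozen=True)
class GeneModel:
    """One gene with the interval sets of its representative transcript."""

    gene_id: str
    seq_id: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] = ()
    utr5: tuple[Interval, ...] = ()
    utr3: tuple[Interval, ...] = ()
    flank_length: int = DEFAULT_FLANK_LENGTH
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise MalformedAnnotationError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise MalformedAnnotationError(f"gene {self.gene_id}: no exons")
        for name in ("cds", "utr5", "utr3"):
            ivs = getattr(self, name)
            if _total(_intersect(ivs, self.exons)) != _total(ivs):
                raise MalformedAnnotationError(
                    f"gene {self.gene_id}: {name} intervals extend outside exons"
                )
        overlap = _intersect(self.cds, _merge(self.utr5 + self.utr3))
        if overlap:
            raise MalformedAnnotationError(f"gene {self.gene_id}: CDS overlaps UTR")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class RegionInterval:
    start: int
    end: int
    label: RegionLabel
    ordinal: int | None = None


@dataclass(frozen=True)
class AnnotatedSsr:
    """An SSR hit placed within a gene: region label, tag, optional peptide.

    ``display_unit`` is the repeat unit read in transcription orientation
    (the reverse complement of the observed unit for minus-strand genes), so
    tags are anchored to the gene the way published repeat nomenclature is.
    """

    hit: SsrHit
    gene_id: str
    region: RegionLabel
    ordinal: int | None = None
    peptide: str | None = None
    display_unit: str | None = None

    @property
    def tag(self) -> str:
        return format_tag(self.display_unit or self.hit.found_unit, self.region, self.ordinal)


def _pick_transcript(
    db: gffutils.FeatureDB, gene: gffutils.Feature, policy: str
) -> tuple[str | None, list, list, list, list]:
    """Select a representative transcript; returns (id, exons, cds, utr5, utr3)."""
    if policy != "longest_cds":
        raise ValueError(f"unknown transcript policy: {policy!r}")
    transcripts = list(db.children(gene, featuretype=("mRNA", "transcript"), level=1))
    if not transcripts:
        transcripts = [gene]  # exon/CDS children attached directly to the gene

    def collect(parent):
        exons = list(db.children(parent, featuretype="exon"))
        cds = list(db.children(parent, featuretype="CDS"))
        utr5 = list(db.children(parent, featuretype=("five_prime_UTR", "five_prime_utr")))
        utr3 = list(db.children(parent, featuretype=("three_prime_UTR", "three_prime_utr")))
        return exons, cds, utr5, utr3

    best = None
    for t in sorted(transcripts, key=lambda f: f.id or ""):
        exons, cds, utr5, utr3 = collect(t)
        if not exons:
            exons = [t]
        cds_len = sum(f.end - f.start + 1 for f in cds)
        exon_len = sum(f.end - f.start + 1 for f in exons)
        key = (cds_len, exon_len)
        if best is None or key > best[0]:
            best = (key, t.id, exons, cds, utr5, utr3)
    assert best is not None
    return best[1], best[2], best[3], best[4], best[5]


def _to_intervals(features: Iterable) -> tuple[Interval, ...]:
    return _merge((f.start - 1, f.end) for f in features)  # GFF 1-based inclusive


def read_gene_models(
    source: "str | os.PathLike",
    flank_length: int = DEFAULT_FLANK_LENGTH,
    transcript_policy: str = "longest_cds",
) -> list[GeneModel]:
    """Build one :class:`GeneModel` per gene from GFF3/GTF annotation.

    ``source`` may be a path or the annotation text itself.  Genes without a
    usable strand are rejected with a warning; missing UTRs are derived as
    exonic-minus-CDS split at the CDS boundaries in transcription
    orientation; introns are implied later as exon gaps.
    """
    text_input = isinstance(source, str) and "\n" in source
    if not text_input and not os.path.exists(os.fspath(source)):
        raise FileNotFoundError(f"annotation file not found: {source}")
    db = gffutils.create_db(
        source if text_input else os.fspath(source),
        dbfn=":memory:",
        from_string=text_input,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in "+-":
            logger.warning("gene %s: missing strand, record rejected", gene.id)
            continue
        tid, exon_f, cds_f, utr5_f, utr3_f = _pick_transcript(db, gene, transcript_policy)
        exons = _to_intervals(exon_f)
        cds = _to_intervals(cds_f)
        utr5 = _to_intervals(utr5_f)
        utr3 = _to_intervals(utr3_f)
        if cds and _total(_intersect(cds, exons)) != _total(cds):
            raise MalformedAnnotationError(f"gene {gene.id}: CDS outside exons")
        if cds and not (utr5 or utr3):
            utr5, utr3 = _derive_utrs(exons, cds, gene.strand)
        models.append(
            GeneModel(
                gene_id=gene.id,
                seq_id=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
                flank_length=flank_length,
                transcript_id=tid,
            )
        )
    return models


def _derive_utrs(
    exons: Sequence[Interval], cds: Sequence[Interval], strand: str
) -> tuple[tuple[Interval, ...], tuple[Interval, ...]]:
    non_coding = _subtract(exons, cds)
    cds_lo, cds_hi = cds[0][0], cds[-1][1]
    before = tuple(iv for iv in non_coding if iv[1] <= cds_lo)
    after = tuple(iv for iv in non_coding if iv[0] >= cds_hi)
    # genomically-before is 5' on the + strand, 3' on the - strand
    return (before, after) if strand == "+" else (after, before)


def derive_region_map(
    gene: GeneModel, contig_length: int | None = None
) -> list[RegionInterval]:
    """Partition gene span +/- flank into disjoint labelled intervals.

    Upstream is the ``flank_length`` window 5' of the gene in transcription
    orientation (genomically after the gene on the minus strand); intron
    ordinals count in transcription order.  Flanks are clipped at contig
    boundaries.
    """
    out: list[RegionInterval] = []
    for s, e in gene.cds:
        out.append(RegionInterval(s, e, RegionLabel.CODING))
    for s, e in gene.utr5:
        out.append(RegionInterval(s, e, RegionLabel.FIVE_UTR))
    for s, e in gene.utr3:
        out.append(RegionInterval(s, e, RegionLabel.THREE_UTR))
    for s, e in _subtract(gene.exons, gene.cds + gene.utr5 + gene.utr3):
        out.append(RegionInterval(s, e, RegionLabel.EXON))
    gaps = []
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        if s2 > e1:
            gaps.append((e1, s2))
    if gene.strand == "-":
        ordinals = range(len(gaps), 0, -1)
    else:
        ordinals = range(1, len(gaps) + 1)
    for (s, e), k in zip(gaps, ordinals):
        out.append(RegionInterval(s, e, RegionLabel.INTRON, ordinal=k))
    lo, hi = gene.span
    flank = gene.flank_length
    left = (max(0, lo - flank), lo)
    right = (hi, hi + flank if contig_length is None else min(hi + flank, contig_length))
    left_label = RegionLabel.UPSTREAM if gene.strand == "+" else RegionLabel.DOWNSTREAM
    right_label = RegionLabel.DOWNSTREAM if gene.strand == "+" else RegionLabel.UPSTREAM
    if left[1] > left[0]:
        out.append(RegionInterval(left[0], left[1], left_label))
    if right[1] > right[0]:
        out.append(RegionInterval(right[0], right[1], right_label))
    return sorted(out, key=lambda r: (r.start, r.end))


def assign_region(
    hit: SsrHit, region_map: Sequence[RegionInterval]
) -> tuple[RegionLabel, int | None] | None:
    """Label a hit with the region it overlaps most; None if outside the map.

    Ties between labels are broken by specificity
    (Coding > 5UTR > 3UTR > Intron > Exon > Upstream > Downstream); the
    intron ordinal of the best-overlapping intron is attached.
    """
    by_label: dict[RegionLabel, int] = {}
    best_intron: tuple[int, int] | None = None  # (overlap, ordinal)
    for region in region_map:
        overlap = min(hit.end, region.end) - max(hit.start, region.start)
        if overlap <= 0:
            continue
        by_label[region.label] = by_label.get(region.label, 0) + overlap
        if region.label is RegionLabel.INTRON and region.ordinal is not None:
            cand = (overlap, -region.ordinal)
            if best_intron is None or cand > best_intron:
                best_intron = cand
    if not by_label:
        return None
    label = max(by_label, key=lambda lb: (by_label[lb], -SPECIFICITY_ORDER.index(lb)))
    ordinal = -best_intron[1] if label is RegionLabel.INTRON and best_intron else None
    return label, ordinal


def _cds_positions(gene: GeneModel) -> list[int]:
    """Genomic positions of the CDS in transcription order."""
    positions = [i for s, e in gene.cds for i in range(s, e)]
    return positions if gene.strand == "+" else positions[::-1]


def translate_coding_hit(hit: SsrHit, gene: GeneModel, contig_seq: str) -> str:
    """Translate the CDS portion a coding hit covers, honouring the reading frame.

    The hit is projected into spliced-CDS coordinates, trimmed to complete
    codons (partial codons at tract edges are dropped), and translated with
    the standard genetic code.
    """
    if not gene.cds:
        raise ValueError(f"gene {gene.gene_id} has no CDS; hit is not in a coding region")
    positions = _cds_positions(gene)
    index = {g: i for i, g in enumerate(positions)}
    covered = sorted(index[g] for g in range(hit.start, hit.end) if g in index)
    if not covered:
        raise ValueError("hit does not overlap the CDS of this gene")
    c0, c1 = covered[0], covered[-1]
    first = 3 * ((c0 + 2) // 3)
    last = 3 * ((c1 + 1) // 3)
    if last <= first:
        return ""
    spliced = "".join(contig_seq[positions[i]] for i in range(first, last))
    if gene.strand == "-":
        spliced = str(Seq(spliced).complement())
    return str(Seq(spliced).translate())


def annotate_hits(
    hits: Iterable[SsrHit],
    genes: Sequence[GeneModel],
    sequences: Mapping[str, str] | None = None,
) -> list[AnnotatedSsr]:
    """Assign each hit to the overlapping gene (most-overlap wins) and region.

    Hits outside every gene's flanked span are skipped.  Coding hits are
    translated when ``sequences`` provides the contig sequence.
    """
    maps: dict[str, list[RegionInterval]] = {}
    out: list[AnnotatedSsr] = []
    for hit in hits:
        best: tuple[int, str, GeneModel] | None = None
        for gene in genes:
            if gene.seq_id != hit.sequence_id:
                continue
            lo, hi = gene.span
            contig_len = len(sequences[gene.seq_id]) if sequences else None
            left = max(0, lo - gene.flank_length)
            right = hi + gene.flank_length
            if contig_len is not None:
                right = min(right, contig_len)
            overlap = min(hit.end, right) - max(hit.start, left)
            if overlap > 0 and (best is None or (-overlap, gene.gene_id) < (-best[0], best[1])):
                best = (overlap, gene.gene_id, gene)
        if best is None:
            continue
        gene = best[2]
        if gene.gene_id not in maps:
            contig_len = len(sequences[gene.seq_id]) if sequences else None
            maps[gene.gene_id] = derive_region_map(gene, contig_len)
        assigned = assign_region(hit, maps[gene.gene_id])
        if assigned is None:
            continue
        label, ordinal = assigned
        peptide = None
        if label is RegionLabel.CODING and sequences is not None:
            peptide = translate_coding_hit(hit, gene, sequences[gene.seq_id])
        display = hit.found_unit
        if gene.strand == "-":
            display = _revcomp(display)
        out.append(
            AnnotatedSsr(
                hit=hit,
                gene_id=gene.gene_id,
                region=label,
                ordinal=ordinal,
                peptide=peptide,
                display_unit=display,
            )
        )
    return out
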