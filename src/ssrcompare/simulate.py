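"""Synthetic multi-species gene loci with planted microsatellites.

The generator emulates the structures the pipeline consumes: per-species
contigs each carrying one gene (UTRs, CDS exons, introns, 2,000-nt flanks)
on a random background, with repeat tracts of a chosen unit, region, length
and substitution-noise fraction planted at known coordinates.  A cohort
groups such loci into ortholog groups and species clusters and records a
ground-truth table for every plant, so detection, annotation and
conservation scoring can be asserted end to end without any downloads.

Planting is substitution-only (matching the detector's noise model) and the
bases flanking a planted tract are forced off-phase, so the planted
coordinates are exactly the maximal perfect tract -- ground truth stays
sharp.  Backgrounds are i.i.d. nucleotides (GC content configurable); no
attempt is made at phylogenetically realistic sequence evolution.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import io as sio
from .conservation import OrthologGroup, SpeciesCluster
from .labels import RegionLabel, coerce_region
from .motifs import canonicalize, reverse_complement
from .regions import GeneModel, RegionInterval, derive_region_map

_BASES = "ACGT"


class ParameterError(ValueError):
    """Infeasible fixture geometry or plant design."""


@dataclass(frozen=True)
class LocusGeometry:
    """Structural parameters of one synthetic gene locus (lengths in nt)."""

    utr5_length: int = 200
    utr3_length: int = 300
    cds_exon_lengths: tuple[int, ...] = (150, 300, 150)
    intron_lengths: tuple[int, ...] = (400, 700)
    noncoding_exon_length: int = 500
    flank_length: int = 2000
    strand: str = "+"
    gc_content: float = 0.5

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ParameterError("strand must be + or -")
        if self.flank_length < 2000:
            raise ParameterError("flanks must be at least 2,000 nt")
        lengths = self.cds_exon_lengths + self.intron_lengths + (
            self.utr5_length,
            self.utr3_length,
            self.noncoding_exon_length,
        )
        if any(x < 0 for x in lengths):
            raise ParameterError("lengths must be non-negative")
        if self.cds_exon_lengths and len(self.intron_lengths) != len(self.cds_exon_lengths) - 1:
            raise ParameterError("need exactly one intron between consecutive CDS exons")
        if not 0.0 < self.gc_content < 1.0:
            raise ParameterError("gc_content must lie in (0, 1)")


@dataclass(frozen=True)
class PlantSpec:
    """One repeat tract to embed: unit, target region, length, noise."""

    unit: str
    region: RegionLabel
    tract_length: int = 30
    noise_fraction: float = 0.0
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_fraction <= 0.3:
            raise ParameterError("noise_fraction must lie in [0, 0.3]")
        if self.frame_offset not in (0, 1, 2):
            raise ParameterError("frame_offset must be 0, 1 or 2")
        if self.tract_length < len(self.unit):
            raise ParameterError("tract shorter than one repeat unit")


@dataclass
class Locus:
    contig_id: str
    seq: list[str]  # mutable during planting
    gene: GeneModel

    @property
    def sequence(self) -> str:
        return "".join(self.seq)


@dataclass(frozen=True)
class PlantedTract:
    """Ground truth for one planted repeat."""

    contig_id: str
    gene_id: str
    start: int  # 0-based half-open genomic coordinates of the planted tract
    end: int
    unit: str
    canonical: str
    region: RegionLabel
    n_substitutions: int


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _mirror(intervals: Sequence[tuple[int, int]], length: int) -> tuple[tuple[int, int], ...]:
    return tuple(sorted((length - e, length - s) for s, e in intervals))


def make_gene_locus(
    seed,
    contig_id: str = "contig",
    gene_id: str = "gene",
    geometry: LocusGeometry | None = None,
) -> Locus:
    """Random background contig with one embedded gene, reproducible from seed."""
    geo = geometry or LocusGeometry()
    rng = _as_rng(seed)
    g = geo.flank_length
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    utr5: list[tuple[int, int]] = []
    utr3: list[tuple[int, int]] = []
    if geo.cds_exon_lengths:
        n = len(geo.cds_exon_lengths)
        for i, clen in enumerate(geo.cds_exon_lengths):
            exon_start = g
            if i == 0 and geo.utr5_length:
                utr5.append((g, g + geo.utr5_length))
                g += geo.utr5_length
            cds.append((g, g + clen))
            g += clen
            if i == n - 1 and geo.utr3_length:
                utr3.append((g, g + geo.utr3_length))
                g += geo.utr3_length
            exons.append((exon_start, g))
            if i < n - 1:
                g += geo.intron_lengths[i]
    else:
        exons.append((g, g + geo.noncoding_exon_length))
        g += geo.noncoding_exon_length
    total = g + geo.flank_length
    if geo.strand == "-":
        exons_t = _mirror(exons, total)
        cds_t, utr5_t, utr3_t = (_mirror(x, total) for x in (cds, utr5, utr3))
    else:
        exons_t, cds_t, utr5_t, utr3_t = tuple(exons), tuple(cds), tuple(utr5), tuple(utr3)
    gc = geo.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=total, p=probs)
    seq = [_BASES[c] for c in codes]
    gene = GeneModel(
        gene_id=gene_id,
        seq_id=contig_id,
        strand=geo.strand,
        exons=exons_t,
        cds=cds_t,
        utr5=utr5_t,
        utr3=utr3_t,
        flank_length=geo.flank_length,
    )
    return Locus(contig_id=contig_id, seq=seq, gene=gene)


def _coding_candidates(gene: GeneModel, tract_length: int, frame_offset: int) -> list[int]:
    """Genomic starts placing a tract wholly inside one CDS block at the given frame."""
    margin = 3
    starts: list[int] = []
    blocks = gene.cds if gene.strand == "+" else gene.cds[::-1]
    cum = 0
    for s, e in blocks:
        for g in range(s + margin, e - tract_length - margin + 1):
            if gene.strand == "+":
                t = cum + (g - s)
            else:
                t = cum + (e - (g + tract_length))
            if t % 3 == frame_offset:
                starts.append(g)
        cum += e - s
    return starts


def _noncoding_candidates(
    region_map: Sequence[RegionInterval], region: RegionLabel, tract_length: int
) -> list[int]:
    starts: list[int] = []
    for margin in (10, 0):
        for r in region_map:
            if r.label is not region:
                continue
            starts.extend(range(r.start + margin, r.end - tract_length - margin + 1))
        if starts:
            break
    return starts


def plant_ssr(locus: Locus, spec: PlantSpec, seed) -> PlantedTract:
    """Write a (possibly noised) repeat tract into the requested region.

    The unit tiles the tract in transcription orientation;
    ``floor(noise_fraction * tract_length)`` substitutions are applied at
    distinct positions, each to a base different from the planted one, and
    the two bases flanking the tract are forced off-phase so the planted
    interval is exactly the maximal perfect-core tract.
    """
    rng = _as_rng(seed)
    gene = locus.gene
    L = spec.tract_length
    unit = spec.unit.upper()
    p = len(unit)
    if spec.region is RegionLabel.CODING:
        starts = _coding_candidates(gene, L, spec.frame_offset)
    else:
        region_map = derive_region_map(gene, contig_length=len(locus.seq))
        starts = _noncoding_candidates(region_map, spec.region, L)
    if not starts:
        raise ParameterError(
            f"region {spec.region.value} of gene {gene.gene_id} cannot host a {L}-nt tract"
        )
    g0 = int(rng.choice(np.asarray(starts)))
    tiled = (unit * math.ceil(L / p))[:L]
    if gene.strand == "-":
        tiled = reverse_complement(tiled)
    locus.seq[g0 : g0 + L] = list(tiled)
    n_subs = math.floor(spec.noise_fraction * L)
    if n_subs:
        offsets = rng.choice(L, size=n_subs, replace=False)
        for off in sorted(int(o) for o in offsets):
            old = locus.seq[g0 + off]
            choices = [b for b in _BASES if b != old]
            locus.seq[g0 + off] = choices[int(rng.integers(3))]
    # break periodicity just outside the tract so ground truth is maximal
    for pos, partner in ((g0 - 1, g0 - 1 + p), (g0 + L, g0 + L - p)):
        if 0 <= pos < len(locus.seq) and locus.seq[pos] == locus.seq[partner]:
            locus.seq[pos] = next(b for b in _BASES if b != locus.seq[partner])
    return PlantedTract(
        contig_id=locus.contig_id,
        gene_id=gene.gene_id,
        start=g0,
        end=g0 + L,
        unit=unit,
        canonical=canonicalize(unit, reduce=True).representative,
        region=spec.region,
        n_substitutions=n_subs,
    )


@dataclass(frozen=True)
class CohortRow:
    """One (cluster, species, ortholog group) locus, optionally with a plant."""

    cluster: str
    species: str
    group_id: str
    disease: str = ""
    unit: str | None = None
    region: RegionLabel | None = None
    tract_length: int = 24
    noise_fraction: float = 0.0
    frame_offset: int = 0
    strand: str = "+"


@dataclass(frozen=True)
class TruthRecord:
    species: str
    group_id: str
    tract: PlantedTract


@dataclass
class Cohort:
    sequences: dict[str, dict[str, str]]  # species -> contig -> sequence
    genes: dict[str, list[GeneModel]]
    orthologs: list[OrthologGroup]
    clusters: list[SpeciesCluster]
    truth: list[TruthRecord]


def make_cohort(seed: int, design: Sequence[CohortRow]) -> Cohort:
    """Realize a cohort design: one locus per (species, group), plants applied.

    Backgrounds are drawn independently per locus from child seeds, so the
    same (seed, design) pair always yields a byte-identical cohort.
    """
    if not design:
        raise ParameterError("empty cohort design")
    cluster_order: list[str] = []
    cluster_members: dict[str, list[str]] = {}
    loci_keys: list[tuple[str, str]] = []
    rows_by_key: dict[tuple[str, str], list[CohortRow]] = {}
    diseases: dict[str, str] = {}
    for row in design:
        if row.cluster not in cluster_members:
            cluster_members[row.cluster] = []
            cluster_order.append(row.cluster)
        if row.species not in cluster_members[row.cluster]:
            cluster_members[row.cluster].append(row.species)
        key = (row.group_id, row.species)
        if key not in rows_by_key:
            rows_by_key[key] = []
            loci_keys.append(key)
        rows_by_key[key].append(row)
        if row.disease:
            diseases.setdefault(row.group_id, row.disease)

    loci_keys.sort()
    children = np.random.SeedSequence(seed).spawn(len(loci_keys))
    sequences: dict[str, dict[str, str]] = {}
    genes: dict[str, list[GeneModel]] = {}
    truth: list[TruthRecord] = []
    group_members: dict[str, dict[str, list[str]]] = {}
    for (group_id, species), child in zip(loci_keys, children):
        rng = np.random.default_rng(child)
        rows = rows_by_key[(group_id, species)]
        geometry = LocusGeometry(strand=rows[0].strand)
        contig_id = f"{species}.{group_id}"
        gene_id = f"{group_id}_{species}"
        locus = make_gene_locus(rng, contig_id=contig_id, gene_id=gene_id, geometry=geometry)
        for row in rows:
            if not row.unit:
                continue
            if row.region is None:
                raise ParameterError(f"plant for {gene_id} has a unit but no region")
            spec = PlantSpec(
                unit=row.unit,
                region=coerce_region(row.region),
                tract_length=row.tract_length,
                noise_fraction=row.noise_fraction,
                frame_offset=row.frame_offset,
            )
            truth.append(TruthRecord(species=species, group_id=group_id, tract=plant_ssr(locus, spec, rng)))
        sequences.setdefault(species, {})[contig_id] = locus.sequence
        genes.setdefault(species, []).append(locus.gene)
        group_members.setdefault(group_id, {}).setdefault(species, []).append(gene_id)

    orthologs = [
        OrthologGroup(
            group_id=gid,
            members={sp: tuple(gids) for sp, gids in sorted(members.items())},
            disease=diseases.get(gid, ""),
        )
        for gid, members in sorted(group_members.items())
    ]
    clusters = [
        SpeciesCluster(name=name, species=tuple(cluster_members[name])) for name in cluster_order
    ]
    return Cohort(sequences=sequences, genes=genes, orthologs=orthologs, clusters=clusters, truth=truth)


MAMMALS = ("Human", "Gorilla", "Macaque", "Mouse", "Dog", "Cow")
FISHES = ("Zebrafish", "Stickleback", "Medaka", "Fugu", "Tetraodon", "Cod")


def demo_design() -> list[CohortRow]:
    """A 6-mammal / 6-fish cohort echoing the published comparison's structure.

    ``EGFR``: a CA-class intronic tract in all mammals and five of six
    fishes (conserved in both clusters at an 80% ratio).  ``SCA6``: a CAG
    coding tract in human only (conserved nowhere).
    """
    rows: list[CohortRow] = []
    ca_fishes = tuple(f for f in FISHES if f != "Medaka")
    for cluster, species_list in (("Mammals", MAMMALS), ("Fishes", FISHES)):
        for sp in species_list:
            rows.append(
                CohortRow(
                    cluster=cluster,
                    species=sp,
                    group_id="EGFR",
                    disease="Cancers",
                    unit="CA" if (cluster == "Mammals" or sp in ca_fishes) else None,
                    region=RegionLabel.INTRON,
                    tract_length=24,
                )
            )
            rows.append(
                CohortRow(
                    cluster=cluster,
                    species=sp,
                    group_id="SCA6",
                    disease="Spinocerebellar ataxia type 6",
                    unit="CAG" if sp == "Human" else None,
                    region=RegionLabel.CODING,
                    tract_length=24,
                )
            )
    return rows


_DESIGN_COLUMNS = [
    "cluster",
    "species",
    "group_id",
    "disease",
    "unit",
    "region",
    "tract_length",
    "noise_fraction",
    "frame_offset",
    "strand",
]


def read_design_tsv(path: "str | os.PathLike") -> list[CohortRow]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            CohortRow(
                cluster=r.cluster,
                species=r.species,
                group_id=r.group_id,
                disease=getattr(r, "disease", ""),
                unit=r.unit or None,
                region=coerce_region(r.region) if getattr(r, "region", "") else None,
                tract_length=int(r.tract_length) if getattr(r, "tract_length", "") else 24,
                noise_fraction=float(r.noise_fraction) if getattr(r, "noise_fraction", "") else 0.0,
                frame_offset=int(r.frame_offset) if getattr(r, "frame_offset", "") else 0,
                strand=getattr(r, "strand", "") or "+",
            )
        )
    return rows


def write_design_tsv(rows: Sequence[CohortRow], path: "str | os.PathLike") -> None:
    lines = ["\t".join(_DESIGN_COLUMNS)]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    r.cluster,
                    r.species,
                    r.group_id,
                    r.disease,
                    r.unit or "",
                    r.region.value if r.region else "",
                    str(r.tract_length),
                    f"{r.noise_fraction:.6g}",
                    str(r.frame_offset),
                    r.strand,
                ]
            )
        )
    with open(path, "w") as out:
        out.write("\n".join(lines) + "\n")


def write_cohort(cohort: Cohort, outdir: "str | os.PathLike") -> None:
    """Emit per-species FASTA + GFF3 plus ortholog, cluster and truth tables."""
    os.makedirs(outdir, exist_ok=True)
    outdir = os.fspath(outdir)
    for species in cohort.sequences:
        sio.write_fasta(cohort.sequences[species], os.path.join(outdir, f"{species}.fa"))
        sio.write_gff3(cohort.genes[species], os.path.join(outdir, f"{species}.gff3"))
    with open(os.path.join(outdir, "orthologs.tsv"), "w") as out:
        out.write("group_id\tspecies\tgene_id\tdisease\n")
        for group in cohort.orthologs:
            for sp, gene_ids in group.members.items():
                for gid in gene_ids:
                    out.write(f"{group.group_id}\t{sp}\t{gid}\t{group.disease}\n")
    with open(os.path.join(outdir, "clusters.tsv"), "w") as out:
        out.write("cluster\tspecies\n")
        for cluster in cohort.clusters:
            for sp in cluster.species:
                out.write(f"{cluster.name}\t{sp}\n")
    with open(os.path.join(outdir, "truth.tsv"), "w") as out:
        out.write(
            "species\tgroup_id\tcontig_id\tgene_id\tstart\tend\tunit\tcanonical\tregion\tn_substitutions\n"
        )
        for rec in cohort.truth:
            t = rec.tract
            out.write(
                f"{rec.species}\t{rec.group_id}\t{t.contig_id}\t{t.gene_id}\t{t.start}\t"
                f"{t.end}\t{t.unit}\t{t.canonical}\t{t.region.value}\t{t.n_substitutions}\n"
            )
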