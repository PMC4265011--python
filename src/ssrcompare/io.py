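"""Readers and writers for the package's standard formats.

Sequences come in as FASTA (Biopython), annotation as GFF3 (see
:mod:`ssrcompare.regions`), and everything else travels as TSV: detector
hits, annotated hits, ortholog groups (group_id / species / gene_id /
disease), species clusters (cluster / species) and conservation records.
User-facing coordinates are 1-based inclusive; BED export is 0-based
half-open per the BED standard.  All writers emit byte-stable output for a
given input.
"""
from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, fields
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .conservation import ConservationRecord, OrthologGroup, SpeciesCluster
from .detect import DetectorConfig, SsrHit
from .labels import coerce_region
from .regions import AnnotatedSsr, GeneModel

_IUPAC_NT = set("ACGTURYSWKMBDHVN")


class FastaError(ValueError):
    pass


def read_fasta(source: "str | os.PathLike | IO[str]") -> dict[str, str]:
    """FASTA -> {id: uppercase sequence}; rejects duplicates and junk characters."""
    handle = source if hasattr(source, "read") else open(source)
    try:
        store: dict[str, str] = {}
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in store:
                raise FastaError(f"duplicate FASTA record id: {record.id!r}")
            seq = str(record.seq).upper()
            bad = set(seq) - _IUPAC_NT
            if bad:
                raise FastaError(
                    f"record {record.id!r} contains non-IUPAC characters: {sorted(bad)}"
                )
            store[record.id] = seq
        if not store:
            raise FastaError("no FASTA records found")
        return store
    finally:
        if handle is not source:
            handle.close()


def write_fasta(sequences: Mapping[str, str], path: "str | os.PathLike", width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


_HIT_COLUMNS = [
    "sequence_id",
    "start",
    "end",
    "found_unit",
    "canonical_unit",
    "period",
    "copies",
    "mismatches",
    "purity",
]


def _hit_row(hit: SsrHit) -> list[str]:
    return [
        hit.sequence_id,
        str(hit.start + 1),  # 1-based inclusive
        str(hit.end),
        hit.found_unit,
        hit.motif.representative,
        str(hit.period),
        f"{hit.copy_number:.6g}",
        str(hit.mismatch_count),
        f"{hit.purity:.6g}",
    ]


def write_hits_tsv(hits: Iterable[SsrHit], stream: "str | os.PathLike | IO[str]") -> None:
    _write_table(_HIT_COLUMNS, (_hit_row(h) for h in hits), stream)


def read_hits_tsv(source: "str | os.PathLike | IO[str]") -> list[SsrHit]:
    df = pd.read_csv(source, sep="\t", dtype=str)
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            SsrHit(
                sequence_id=row.sequence_id,
                start=int(row.start) - 1,
                end=int(row.end),
                found_unit=row.found_unit,
                mismatch_count=int(row.mismatches),
            )
        )
    return hits


_ANNOTATED_COLUMNS = _HIT_COLUMNS + ["gene_id", "region", "ordinal", "tag", "peptide"]


def write_annotated_tsv(
    records: Iterable[AnnotatedSsr], stream: "str | os.PathLike | IO[str]"
) -> None:
    def rows():
        for ann in records:
            yield _hit_row(ann.hit) + [
                ann.gene_id,
                ann.region.value,
                "" if ann.ordinal is None else str(ann.ordinal),
                ann.tag,
                ann.peptide or "",
            ]

    _write_table(_ANNOTATED_COLUMNS, rows(), stream)


def read_annotated_tsv(source: "str | os.PathLike | IO[str]") -> list[AnnotatedSsr]:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        hit = SsrHit(
            sequence_id=row.sequence_id,
            start=int(row.start) - 1,
            end=int(row.end),
            found_unit=row.found_unit,
            mismatch_count=int(row.mismatches),
        )
        out.append(
            AnnotatedSsr(
                hit=hit,
                gene_id=row.gene_id,
                region=coerce_region(row.region),
                ordinal=int(row.ordinal) if row.ordinal else None,
                peptide=row.peptide or None,
                display_unit=row.tag.split("@", 1)[0],
            )
        )
    return out


def write_bed(hits: Iterable[SsrHit], stream: "str | os.PathLike | IO[str]") -> None:
    """BED6 export: 0-based half-open, name = canonical unit, score = 1000 * purity."""

    def rows():
        for h in hits:
            yield [
                h.sequence_id,
                str(h.start),
                str(h.end),
                h.motif.representative,
                str(int(round(1000 * h.purity))),
                ".",
            ]

    _write_table(None, rows(), stream)


def write_records_tsv(
    records: Iterable[ConservationRecord], stream: "str | os.PathLike | IO[str]"
) -> None:
    cols = ["group_id", "motif", "region", "display_tag", "cluster", "ratio", "conserved", "exclusive", "present_species"]

    def rows():
        for r in records:
            present = ",".join(sp for sp, ok in r.presence.items() if ok)
            yield [
                r.group_id,
                r.motif,
                r.region,
                r.display_tag,
                r.cluster,
                f"{r.ratio:.6g}",
                str(int(r.conserved)),
                str(int(r.exclusive)),
                present,
            ]

    _write_table(cols, rows(), stream)


def read_orthologs_tsv(source: "str | os.PathLike | IO[str]") -> list[OrthologGroup]:
    """Ortholog table: columns group_id, species, gene_id, optional disease."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    groups: dict[str, dict[str, list[str]]] = {}
    diseases: dict[str, str] = {}
    for row in df.itertuples(index=False):
        members = groups.setdefault(row.group_id, {})
        members.setdefault(row.species, []).append(row.gene_id)
        disease = getattr(row, "disease", "")
        if disease and row.group_id not in diseases:
            diseases[row.group_id] = disease
    return [
        OrthologGroup(
            group_id=gid,
            members={sp: tuple(genes) for sp, genes in members.items()},
            disease=diseases.get(gid, ""),
        )
        for gid, members in groups.items()
    ]


def read_clusters_tsv(source: "str | os.PathLike | IO[str]") -> list[SpeciesCluster]:
    """Cluster table: columns cluster, species; one row per membership."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    order: list[str] = []
    members: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        if row.cluster not in members:
            members[row.cluster] = []
            order.append(row.cluster)
        members[row.cluster].append(row.species)
    return [SpeciesCluster(name=name, species=tuple(members[name])) for name in order]


def write_gff3(
    genes: Sequence[GeneModel], stream: "str | os.PathLike | IO[str]", source: str = "ssrcompare"
) -> None:
    """Minimal GFF3 writer for :class:`GeneModel` objects (round-trips via gffutils)."""

    def rows():
        for gene in genes:
            lo, hi = gene.span
            tid = gene.transcript_id or f"{gene.gene_id}.t1"
            yield _gff_row(gene, "gene", lo, hi, f"ID={gene.gene_id}")
            yield _gff_row(gene, "mRNA", lo, hi, f"ID={tid};Parent={gene.gene_id}")
            for i, (s, e) in enumerate(gene.exons, 1):
                yield _gff_row(gene, "exon", s, e, f"ID={tid}.exon{i};Parent={tid}")
            phase = 0
            cds_blocks = gene.cds if gene.strand == "+" else gene.cds[::-1]
            for i, (s, e) in enumerate(cds_blocks, 1):
                yield _gff_row(gene, "CDS", s, e, f"ID={tid}.cds;Parent={tid}", phase=phase)
                phase = (3 - ((e - s) - phase) % 3) % 3
            for i, (s, e) in enumerate(gene.utr5, 1):
                yield _gff_row(gene, "five_prime_UTR", s, e, f"ID={tid}.utr5.{i};Parent={tid}")
            for i, (s, e) in enumerate(gene.utr3, 1):
                yield _gff_row(gene, "three_prime_UTR", s, e, f"ID={tid}.utr3.{i};Parent={tid}")

    def _gff_row(gene, ftype, s, e, attrs, phase="."):
        return [gene.seq_id, source, ftype, str(s + 1), str(e), ".", gene.strand, str(phase), attrs]

    close, handle = _open_out(stream)
    try:
        handle.write("##gff-version 3\n")
        for row in rows():
            handle.write("\t".join(row) + "\n")
    finally:
        if close:
            handle.close()


@dataclass
class RunConfig:
    """Full effective configuration of a pipeline run; plain-text serializable."""

    detector: DetectorConfig = dataclasses.field(default_factory=DetectorConfig)
    flank_length: int = 2000
    conserved_ratio: float = 0.8
    transcript_policy: str = "longest_cds"
    seed: int = 0
    log_level: str = "INFO"

    def to_text(self) -> str:
        lines = []
        for f in fields(DetectorConfig):
            lines.append(f"detector.{f.name}: {getattr(self.detector, f.name)}")
        for name in ("flank_length", "conserved_ratio", "transcript_policy", "seed", "log_level"):
            lines.append(f"{name}: {getattr(self, name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        values: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            values[key.strip()] = value.strip()
        det_kwargs = {}
        for f in fields(DetectorConfig):
            if f"detector.{f.name}" in values:
                det_kwargs[f.name] = _coerce(values[f"detector.{f.name}"])
        cfg = cls(detector=DetectorConfig(**det_kwargs))
        if "flank_length" in values:
            cfg.flank_length = int(values["flank_length"])
        if "conserved_ratio" in values:
            cfg.conserved_ratio = float(values["conserved_ratio"])
        if "transcript_policy" in values:
            cfg.transcript_policy = values["transcript_policy"]
        if "seed" in values:
            cfg.seed = int(values["seed"])
        if "log_level" in values:
            cfg.log_level = values["log_level"]
        return cfg


def _coerce(raw: str):
    try:
        return int(raw)
    except ValueError:
        try:
            return float(raw)
        except ValueError:
            return raw


def _open_out(stream: "str | os.PathLike | IO[str]") -> tuple[bool, IO[str]]:
    if hasattr(stream, "write"):
        return False, stream
    return True, open(stream, "w")


def _write_table(
    header: "list[str] | None",
    rows: Iterable[list[str]],
    stream: "str | os.PathLike | IO[str]",
) -> None:
    close, handle = _open_out(stream)
    try:
        if header:
            handle.write("\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(row) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing table to {getattr(stream, 'name', stream)}: {exc}") from exc
    finally:
        if close:
            handle.close()
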