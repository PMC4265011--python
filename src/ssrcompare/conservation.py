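"""Cross-species microsatellite conservation within ortholog groups.

For each ortholog group a species x feature boolean presence matrix is
assembled, where a feature is the pair (canonical motif class, gene region)
-- the ``pattern@region`` granularity at which matching happens; intron
ordinals and tract lengths are deliberately not part of feature identity.
Within each user-defined species cluster the conservation ratio is the
fraction of cluster species carrying the feature; a feature is *conserved*
in a cluster when the ratio reaches the threshold (default 0.8) and
*exclusive* to a cluster when it is conserved there and nowhere else.
A species listed in a group but lacking data simply counts as absent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .regions import AnnotatedSsr

logger = logging.getLogger(__name__)

DEFAULT_CONSERVED_RATIO = 0.8

Feature = tuple[str, str]  # (canonical motif representative, region label)


@dataclass(frozen=True)
class OrthologGroup:
    """Orthologs of one gene across species (possibly several paralogs each)."""

    group_id: str
    members: Mapping[str, tuple[str, ...]]  # species -> gene ids
    disease: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"ortholog group {self.group_id} has no members")


@dataclass(frozen=True)
class SpeciesCluster:
    name: str
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError(f"species cluster {self.name} is empty")
        if len(set(self.species)) != len(self.species):
            raise ValueError(f"species cluster {self.name} lists a species twice")


@dataclass(frozen=True)
class ConservationRecord:
    """Per (ortholog group, feature, cluster) conservation verdict."""

    group_id: str
    motif: str  # canonical representative
    region: str
    display_tag: str
    presence: Mapping[str, bool]
    cluster: str
    ratio: float
    conserved: bool
    exclusive: bool = False

    @property
    def feature(self) -> Feature:
        return (self.motif, self.region)


@dataclass
class FeatureMatrix:
    """Species x feature presence for one ortholog group, plus display info."""

    group: OrthologGroup
    matrix: pd.DataFrame  # bool; index (motif, region), columns species
    display_tags: dict[Feature, str] = field(default_factory=dict)
    tract_lengths: dict[Feature, dict[str, int]] = field(default_factory=dict)


def collect_features(
    annotated: Mapping[str, Iterable[AnnotatedSsr]], group: OrthologGroup
) -> FeatureMatrix:
    """Build the presence matrix for one ortholog group.

    ``annotated`` maps species to that species' annotated hits; only hits in
    the group's member genes are considered.  The display tag of a feature
    is the tag of its first occurrence, scanning species in group order
    (preserving the unit rotation the reference species actually shows).
    """
    species_order = list(group.members)
    features: dict[Feature, dict[str, bool]] = {}
    tags: dict[Feature, str] = {}
    lengths: dict[Feature, dict[str, int]] = {}
    for species in species_order:
        member_genes = set(group.members[species])
        records = annotated.get(species)
        if records is None:
            logger.warning(
                "group %s: no annotation data for species %s; counted absent",
                group.group_id,
                species,
            )
            continue
        for ann in records:
            if ann.gene_id not in member_genes:
                continue
            feature = (ann.hit.motif.representative, ann.region.value)
            features.setdefault(feature, {})[species] = True
            tags.setdefault(feature, ann.tag)
            per_sp = lengths.setdefault(feature, {})
            per_sp[species] = max(per_sp.get(species, 0), ann.hit.length)
    index = pd.MultiIndex.from_tuples(sorted(features), names=["motif", "region"])
    matrix = pd.DataFrame(False, index=index, columns=species_order, dtype=bool)
    for feature, present in features.items():
        for species in present:
            matrix.loc[feature, species] = True
    return FeatureMatrix(group=group, matrix=matrix, display_tags=tags, tract_lengths=lengths)


def conservation_ratio(presence: Mapping[str, bool], cluster: SpeciesCluster) -> float:
    """Fraction of cluster species carrying the feature (full-cluster denominator)."""
    present = sum(1 for sp in cluster.species if presence.get(sp, False))
    return present / len(cluster.species)


def compare_clusters(
    feature_matrix: FeatureMatrix,
    clusters: Sequence[SpeciesCluster],
    threshold: float = DEFAULT_CONSERVED_RATIO,
) -> list[ConservationRecord]:
    """One :class:`ConservationRecord` per (feature, cluster).

    A feature conserved in exactly one of the given clusters is flagged
    exclusive to it.  Output order is deterministic: feature, then cluster
    in the order supplied.
    """
    if not clusters:
        raise ValueError("at least one species cluster is required")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("conservation threshold must lie in [0, 1]")
    records: list[ConservationRecord] = []
    matrix = feature_matrix.matrix
    for feature in matrix.index:
        presence = matrix.loc[feature].to_dict()
        ratios = {c.name: conservation_ratio(presence, c) for c in clusters}
        conserved_in = [c.name for c in clusters if ratios[c.name] >= threshold]
        for cluster in clusters:
            name = cluster.name
            is_conserved = ratios[name] >= threshold
            records.append(
                ConservationRecord(
                    group_id=feature_matrix.group.group_id,
                    motif=feature[0],
                    region=feature[1],
                    display_tag=feature_matrix.display_tags.get(
                        feature, f"{feature[0]}@{feature[1]}"
                    ),
                    presence=presence,
                    cluster=name,
                    ratio=ratios[name],
                    conserved=is_conserved,
                    exclusive=is_conserved and conserved_in == [name],
                )
            )
    return records


def report_table(
    records: Sequence[ConservationRecord],
    groups: Sequence[OrthologGroup],
    clusters: Sequence[SpeciesCluster],
) -> pd.DataFrame:
    """Human-readable cross-species comparison table.

    One row per (group, feature conserved in at least one cluster); each
    cluster column lists the present cluster species in cluster order, or
    ``Non`` when no cluster species carries the feature.  Groups with no
    conserved feature get a single all-``Non`` row.
    """
    by_group: dict[str, dict[Feature, list[ConservationRecord]]] = {}
    for rec in records:
        by_group.setdefault(rec.group_id, {}).setdefault(rec.feature, []).append(rec)
    rows = []
    for group in groups:
        group_features = by_group.get(group.group_id, {})
        kept = sorted(
            f for f, recs in group_features.items() if any(r.conserved for r in recs)
        )
        if not kept:
            row = {"gene": group.group_id, "disease": group.disease, "tag": "-"}
            for cluster in clusters:
                row[cluster.name] = "Non"
            rows.append(row)
            continue
        for feature in kept:
            recs = group_features[feature]
            presence = recs[0].presence
            row = {
                "gene": group.group_id,
                "disease": group.disease,
                "tag": recs[0].display_tag,
            }
            for cluster in clusters:
                present = [sp for sp in cluster.species if presence.get(sp, False)]
                row[cluster.name] = ", ".join(present) if present else "Non"
            rows.append(row)
    columns = ["gene", "disease", "tag"] + [c.name for c in clusters]
    return pd.DataFrame(rows, columns=columns)
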