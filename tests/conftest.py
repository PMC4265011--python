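import numpy as np
import pytest

from ssrcompare.conservation import collect_features, compare_clusters
from ssrcompare.detect import DetectorConfig, find_ssrs
from ssrcompare.regions import annotate_hits
from ssrcompare.simulate import demo_design, make_cohort

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


@pytest.fixture(scope="session")
def demo_cohort():
    """6-mammal/6-fish cohort: CA@Intron in 11 species, CAG@Coding in human only."""
    return make_cohort(11, demo_design())


@pytest.fixture(scope="session")
def demo_annotated(demo_cohort):
    annotated = {}
    for species, contigs in demo_cohort.sequences.items():
        hits = []
        for contig_id in sorted(contigs):
            hits.extend(find_ssrs(contigs[contig_id], DetectorConfig(), sequence_id=contig_id))
        annotated[species] = annotate_hits(hits, demo_cohort.genes[species], contigs)
    return annotated


@pytest.fixture(scope="session")
def demo_records(demo_cohort, demo_annotated):
    records = []
    for group in demo_cohort.orthologs:
        matrix = collect_features(demo_annotated, group)
        records.extend(compare_clusters(matrix, demo_cohort.clusters, threshold=0.8))
    return records
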