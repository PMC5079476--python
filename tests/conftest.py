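import numpy as np
import pytest

from seqcorr import (
    ExpressionSample,
    GenomicInterval,
    MetadataRecord,
    PeakSample,
    SyntheticDesign,
    build_expression_compendium,
    build_peak_compendium,
    synth_expression_compendium,
    synth_peak_compendium,
)


@pytest.fixture
def toy_expression_compendium():
    """5 genes x 4 experiments with hand-checkable values."""
    samples = [
        ExpressionSample("e1", {"g1": 0.0, "g2": 3.0, "g3": 1.0, "g4": 7.0, "g5": 15.0}),
        ExpressionSample("e2", {"g1": 1.0, "g2": 3.0, "g3": 0.0, "g4": 7.0, "g5": 31.0}),
        ExpressionSample("e3", {"g1": 15.0, "g2": 7.0, "g3": 3.0, "g4": 1.0, "g5": 0.0}),
        ExpressionSample("e4", {"g1": 31.0, "g2": 15.0, "g3": 3.0, "g4": 0.0, "g5": 1.0}),
    ]
    metadata = [
        MetadataRecord("e1", {"cell_type": "A", "factor": "X"}),
        MetadataRecord("e2", {"cell_type": "A", "factor": "Y"}),
        MetadataRecord("e3", {"cell_type": "B", "factor": "X"}),
        MetadataRecord("e4", {"cell_type": "B", "factor": "Y"}),
    ]
    return samples, metadata, build_expression_compendium(samples, metadata)


@pytest.fixture
def toy_peak_compendium():
    samples = [
        PeakSample("p1", [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 500, 700)]),
        PeakSample("p2", [GenomicInterval("chr1", 150, 250), GenomicInterval("chr2", 10, 60)]),
        PeakSample("p3", [GenomicInterval("chr2", 10, 50), GenomicInterval("chr2", 300, 400)]),
    ]
    metadata = [
        MetadataRecord("p1", {"factor": "X"}),
        MetadataRecord("p2", {"factor": "X"}),
        MetadataRecord("p3", {"factor": "Y"}),
    ]
    return samples, metadata, build_peak_compendium(samples, metadata)


@pytest.fixture(scope="session")
def small_synth_expression():
    design = SyntheticDesign(n_features=400, n_groups=3, experiments_per_group=3, seed=7)
    samples, metadata, labels = synth_expression_compendium(design)
    return design, samples, metadata, labels, build_expression_compendium(samples, metadata)


@pytest.fixture(scope="session")
def small_synth_peaks():
    design = SyntheticDesign(n_features=400, n_groups=3, experiments_per_group=3, seed=11)
    samples, metadata, labels = synth_peak_compendium(design)
    return design, samples, metadata, labels, build_peak_compendium(samples, metadata)


def random_intervals(rng: np.random.Generator, n: int, genome: dict[str, int], max_len=5000):
    chroms = sorted(genome)
    out = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, genome[c] - max_len))
        out.append(GenomicInterval(c, start, start + int(rng.integers(1, max_len))))
    return out
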