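"""Project a user sample into a compendium's feature space.

After projection the user sample is one more column of the compendium: same
feature order, same transform, directly comparable by Pearson correlation.
The compendium's feature index is frozen — user peaks never extend the
region universe and user-only genes are dropped (and reported), so the
reference-vs-reference correlations are invariant to user input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .compendium import Compendium, RegionUniverse, binarize_peaks, cage_region_scores
from .io_formats import DataError, ExpressionSample, PeakSample

logger = logging.getLogger("seqcorr")


@dataclass(frozen=True)
class CoverageReport:
    """How much of the user sample and of the feature space matched.

    Invariants: ``features_matched + features_filled == n_features`` and
    ``user_matched + user_unmatched == user_items``.
    """

    n_features: int
    features_matched: int
    features_filled: int
    user_items: int
    user_matched: int
    user_unmatched: int

    def __post_init__(self) -> None:
        assert self.features_matched + self.features_filled == self.n_features
        assert self.user_matched + self.user_unmatched == self.user_items


@dataclass
class ProjectedSample:
    """A user sample aligned to a compendium's feature index."""

    sample_name: str
    vector: np.ndarray
    report: CoverageReport

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        assert self.vector.shape == (self.report.n_features,)


def project_expression(sample: ExpressionSample, compendium: Compendium) -> ProjectedSample:
    """Align a user expression sample to an expression compendium.

    User genes absent from the compendium are dropped; compendium genes
    absent from the user file get raw 0; then the compendium's log transform
    is applied so the result is exactly comparable to reference columns.
    """
    if compendium.data_type != "expression":
        raise DataError(
            f"project_expression needs an expression compendium, got {compendium.data_type!r}"
        )
    genes = compendium.features
    assert isinstance(genes, list)
    gene_idx = {g: i for i, g in enumerate(genes)}
    raw = np.zeros(len(genes))
    matched = 0
    for gid, val in sample.values.items():
        i = gene_idx.get(gid)
        if i is not None:
            raw[i] = val
            matched += 1
    if matched == 0:
        user_examples = list(sample.values.keys())[:3]
        comp_examples = genes[:3]
        raise DataError(
            "no gene ids shared between the user sample and the compendium — likely an "
            f"identifier-scheme mismatch. User ids look like {user_examples}; "
            f"compendium ids look like {comp_examples}"
        )
    report = CoverageReport(
        n_features=len(genes),
        features_matched=matched,
        features_filled=len(genes) - matched,
        user_items=sample.n_genes,
        user_matched=matched,
        user_unmatched=sample.n_genes - matched,
    )
    return ProjectedSample(sample.sample_name, compendium.transform.apply(raw), report)


def project_peaks(sample: PeakSample, compendium: Compendium) -> ProjectedSample:
    """Binarize a user peak sample over a peak compendium's frozen universe."""
    if compendium.data_type != "peaks":
        raise DataError(f"project_peaks needs a peaks compendium, got {compendium.data_type!r}")
    if sample.n_peaks == 0:
        raise DataError(f"user peak sample {sample.sample_name!r} is empty")
    universe = compendium.features
    assert isinstance(universe, RegionUniverse)
    vec, unmatched = binarize_peaks(sample, universe, with_counts=True)
    hit = int(vec.sum())
    if hit == 0:
        logger.warning(
            "user sample %r: no peak overlaps any universe region (all-zero projection; "
            "its correlations will be undefined)",
            sample.sample_name,
        )
    report = CoverageReport(
        n_features=len(universe),
        features_matched=hit,
        features_filled=len(universe) - hit,
        user_items=sample.n_peaks,
        user_matched=sample.n_peaks - unmatched,
        user_unmatched=unmatched,
    )
    return ProjectedSample(sample.sample_name, vec, report)


def project_cage(sample: PeakSample, compendium: Compendium) -> ProjectedSample:
    """Sum user CAGE scores per universe region, then apply the compendium transform."""
    if compendium.data_type != "cage":
        raise DataError(f"project_cage needs a cage compendium, got {compendium.data_type!r}")
    if not sample.scored:
        raise DataError(f"user sample {sample.sample_name!r} is unscored; CAGE projection needs scores")
    universe = compendium.features
    assert isinstance(universe, RegionUniverse)
    sums = cage_region_scores(sample, universe)
    _, unmatched = binarize_peaks(sample, universe, with_counts=True)
    hit = int((sums > 0).sum())
    report = CoverageReport(
        n_features=len(universe),
        features_matched=hit,
        features_filled=len(universe) - hit,
        user_items=sample.n_peaks,
        user_matched=sample.n_peaks - unmatched,
        user_unmatched=unmatched,
    )
    return ProjectedSample(sample.sample_name, compendium.transform.apply(sums), report)


def project_sample(
    sample: ExpressionSample | PeakSample, compendium: Compendium
) -> ProjectedSample:
    """Dispatch to the projector matching the compendium's data type."""
    if compendium.data_type == "expression":
        if not isinstance(sample, ExpressionSample):
            raise DataError("an expression compendium needs an expression-table user sample")
        return project_expression(sample, compendium)
    if not isinstance(sample, PeakSample):
        raise DataError(f"a {compendium.data_type} compendium needs a peak-file user sample")
    if compendium.data_type == "peaks":
        return project_peaks(sample, compendium)
    return project_cage(sample, compendium)
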