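"""Reference-compendium construction.

Three compendium kinds are supported, mirroring the three assay types:

* **expression** — genes x experiments, log-scaled abundances,
* **peaks** — merged genomic regions x experiments, binary presence/absence,
* **cage** — merged genomic regions x experiments, log-scaled summed tag
  expression.

The region universe of a peak/CAGE compendium is the union of all reference
peak sets with overlapping-or-bookended intervals merged. It is frozen at
build time: user samples are later projected onto it and never extend it, so
reference-vs-reference correlations cannot change when a user file arrives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .io_formats import (
    DataError,
    ExpressionSample,
    GenomicInterval,
    MetadataRecord,
    PeakSample,
)

DATA_TYPES = ("expression", "peaks", "cage")


@dataclass(frozen=True)
class Transform:
    """How raw values were turned into matrix entries.

    ``kind`` is ``"log"`` (entry = log_base(value + pseudocount)) or
    ``"binary"`` (entry = 0/1 peak presence). The pseudocount must be >= 1
    so log-scaled entries stay non-negative for non-negative abundances.
    """

    kind: str = "log"
    base: float = 2.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("log", "binary"):
            raise DataError(f"unknown transform kind {self.kind!r}")
        if self.kind == "log":
            if self.base <= 1.0:
                raise DataError(f"log base must be > 1, got {self.base}")
            if self.pseudocount < 1.0:
                raise DataError(f"pseudocount must be >= 1, got {self.pseudocount}")

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.kind == "binary":
            return (np.asarray(values) != 0).astype(float)
        return np.log(np.asarray(values, dtype=float) + self.pseudocount) / math.log(self.base)

    def to_dict(self) -> dict:
        if self.kind == "binary":
            return {"kind": "binary"}
        return {"kind": "log", "base": self.base, "pseudocount": self.pseudocount}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Transform":
        if d.get("kind") == "binary":
            return cls(kind="binary")
        return cls(kind="log", base=float(d["base"]), pseudocount=float(d["pseudocount"]))


def parse_log_base(spec: str | float) -> float:
    """Accept 2, 10 or 'e' (natural log) as a log base specification."""
    if isinstance(spec, str):
        if spec.lower() == "e":
            return math.e
        spec = float(spec)
    return float(spec)


@dataclass
class RegionUniverse:
    """Ordered, non-overlapping genomic regions: the feature space of a
    peak or CAGE compendium."""

    regions: list[GenomicInterval]

    def __post_init__(self) -> None:
        prev: GenomicInterval | None = None
        for iv in self.regions:
            if prev is not None and prev.chrom == iv.chrom:
                if iv.start < prev.start:
                    raise DataError("region universe is not sorted by (chrom, start)")
                if iv.start < prev.end:
                    raise DataError(
                        f"region universe contains overlapping regions "
                        f"{prev.chrom}:{prev.start}-{prev.end} and {iv.chrom}:{iv.start}-{iv.end}"
                    )
            elif prev is not None and iv.chrom < prev.chrom:
                raise DataError("region universe is not sorted by (chrom, start)")
            prev = iv
        # per-chromosome coordinate arrays for O(log n) overlap queries
        self._index: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
        offset = 0
        chrom_start = 0
        current: str | None = None
        starts: list[int] = []
        ends: list[int] = []
        for i, iv in enumerate(self.regions):
            if iv.chrom != current:
                if current is not None:
                    self._index[current] = (np.array(starts), np.array(ends), chrom_start)
                current, starts, ends, chrom_start = iv.chrom, [], [], i
            starts.append(iv.start)
            ends.append(iv.end)
            offset = i
        if current is not None:
            self._index[current] = (np.array(starts), np.array(ends), chrom_start)

    def __len__(self) -> int:
        return len(self.regions)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RegionUniverse) and self.regions == other.regions

    def labels(self) -> list[str]:
        return [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in self.regions]

    def overlapping_indices(self, interval: GenomicInterval) -> range:
        """Indices of universe regions overlapping ``interval`` by >= 1 bp."""
        idx = self._index.get(interval.chrom)
        if idx is None:
            return range(0, 0)
        starts, ends, offset = idx
        lo = int(np.searchsorted(ends, interval.start, side="right"))
        hi = int(np.searchsorted(starts, interval.end, side="left"))
        return range(offset + lo, offset + hi)


def build_region_universe(peak_samples: Sequence[PeakSample]) -> RegionUniverse:
    """Merge all samples' intervals into a sorted, non-overlapping universe.

    Overlapping or bookended intervals collapse into a single region, so
    every input interval is contained in exactly one universe region.
    """
    intervals = [iv for s in peak_samples for iv in s.intervals]
    if not intervals:
        raise DataError("cannot build a region universe from empty input")
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = intervals[0].chrom, intervals[0].start, intervals[0].end
    for iv in intervals[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:  # overlap or bookended
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return RegionUniverse(merged)


def binarize_peaks(
    sample: PeakSample, universe: RegionUniverse, with_counts: bool = False
) -> np.ndarray | tuple[np.ndarray, int]:
    """Presence/absence vector of ``sample`` over the universe regions.

    Entry r is 1 iff at least one sample interval overlaps region r by
    >= 1 bp (half-open semantics: overlap iff max(starts) < min(ends)).
    With ``with_counts=True`` also returns the number of sample intervals
    that overlap no universe region at all.
    """
    if len(universe) == 0:
        raise DataError("cannot binarize against an empty region universe")
    vec = np.zeros(len(universe), dtype=float)
    unmatched = 0
    for iv in sample.intervals:
        hits = universe.overlapping_indices(iv)
        if len(hits) == 0:
            unmatched += 1
        else:
            vec[hits.start : hits.stop] = 1.0
    return (vec, unmatched) if with_counts else vec


@dataclass
class Compendium:
    """A features x experiments matrix plus per-experiment metadata.

    ``features`` is a gene-id list (expression) or a :class:`RegionUniverse`
    (peaks/CAGE). ``matrix`` holds binary 0/1 presence for peaks and
    log-scaled non-negative values otherwise.
    """

    data_type: str
    features: list[str] | RegionUniverse
    matrix: np.ndarray
    experiments: list[MetadataRecord]
    transform: Transform = field(default_factory=Transform)

    def __post_init__(self) -> None:
        if self.data_type not in DATA_TYPES:
            raise DataError(f"unknown compendium data type {self.data_type!r}")
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DataError("compendium matrix must be 2-dimensional")
        if self.matrix.shape[0] != self.n_features:
            raise DataError(
                f"matrix has {self.matrix.shape[0]} rows but {self.n_features} features are indexed"
            )
        if self.matrix.shape[1] != len(self.experiments):
            raise DataError(
                f"matrix has {self.matrix.shape[1]} columns but {len(self.experiments)} "
                "metadata records are attached"
            )
        ids = [r.experiment_id for r in self.experiments]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate experiment ids in compendium metadata")
        if self.experiments:
            keys = set(self.experiments[0].attributes)
            for rec in self.experiments:
                if set(rec.attributes) != keys:
                    raise DataError(
                        f"metadata attribute keys differ between experiments "
                        f"({rec.experiment_id!r} vs {self.experiments[0].experiment_id!r})"
                    )
        if self.data_type == "peaks":
            if not np.isin(self.matrix, (0.0, 1.0)).all():
                raise DataError("peak compendium matrix must be binary 0/1")
        else:
            if not np.isfinite(self.matrix).all() or (self.matrix < 0).any():
                raise DataError("log-scaled compendium matrix must be finite and >= 0")

    @property
    def n_features(self) -> int:
        return len(self.features.regions) if isinstance(self.features, RegionUniverse) else len(self.features)

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    @property
    def experiment_ids(self) -> list[str]:
        return [r.experiment_id for r in self.experiments]

    @property
    def attribute_keys(self) -> list[str]:
        return list(self.experiments[0].attributes.keys()) if self.experiments else []

    def feature_labels(self) -> list[str]:
        return self.features.labels() if isinstance(self.features, RegionUniverse) else list(self.features)

    def column(self, experiment_id: str) -> np.ndarray:
        try:
            j = self.experiment_ids.index(experiment_id)
        except ValueError:
            raise DataError(f"no experiment {experiment_id!r} in compendium") from None
        return self.matrix[:, j]


def _match_metadata(
    samples: Sequence[ExpressionSample | PeakSample], metadata: Sequence[MetadataRecord]
) -> list[MetadataRecord]:
    by_id = {r.experiment_id: r for r in metadata}
    if len(by_id) != len(metadata):
        raise DataError("duplicate experiment ids in metadata")
    names = [s.sample_name for s in samples]
    missing = [n for n in names if n not in by_id]
    extra = [i for i in by_id if i not in set(names)]
    if missing or extra:
        raise DataError(
            f"metadata/sample mismatch: samples without metadata {missing[:5]}, "
            f"metadata without samples {extra[:5]}"
        )
    return [by_id[n] for n in names]


def build_peak_compendium(
    samples: Sequence[PeakSample], metadata: Sequence[MetadataRecord]
) -> Compendium:
    """Binary peak-presence compendium over the merged universe of ``samples``."""
    if not samples:
        raise DataError("cannot build a peak compendium from zero samples")
    records = _match_metadata(samples, metadata)
    universe = build_region_universe(samples)
    matrix = np.column_stack([binarize_peaks(s, universe) for s in samples])
    return Compendium(
        data_type="peaks",
        features=universe,
        matrix=matrix,
        experiments=records,
        transform=Transform(kind="binary"),
    )


def build_expression_compendium(
    samples: Sequence[ExpressionSample],
    metadata: Sequence[MetadataRecord],
    pseudocount: float = 1.0,
    log_base: float | str = 2,
) -> Compendium:
    """Log-scaled gene x experiment compendium.

    The feature list is the sorted union of all samples' (normalised) gene
    ids; a gene missing from a sample contributes raw 0 before the log
    transform, keeping the feature space identical across columns.
    """
    if not samples:
        raise DataError("cannot build an expression compendium from zero samples")
    records = _match_metadata(samples, metadata)
    genes = sorted(set().union(*(s.values.keys() for s in samples)))
    if not genes:
        raise DataError("empty gene union across samples")
    transform = Transform(kind="log", base=parse_log_base(log_base), pseudocount=pseudocount)
    gene_idx = {g: i for i, g in enumerate(genes)}
    raw = np.zeros((len(genes), len(samples)))
    for j, s in enumerate(samples):
        for g, v in s.values.items():
            raw[gene_idx[g], j] = v
    return Compendium(
        data_type="expression",
        features=genes,
        matrix=transform.apply(raw),
        experiments=records,
        transform=transform,
    )


def cage_region_scores(sample: PeakSample, universe: RegionUniverse) -> np.ndarray:
    """Sum of CAGE tag scores of ``sample`` intervals per universe region (raw scale)."""
    if not sample.scored:
        raise DataError(f"sample {sample.sample_name!r} is not scored; CAGE input requires scores")
    sums = np.zeros(len(universe))
    for iv in sample.intervals:
        hits = universe.overlapping_indices(iv)
        if len(hits):
            sums[hits.start : hits.stop] += iv.score
    return sums


def build_cage_compendium(
    samples: Sequence[PeakSample],
    metadata: Sequence[MetadataRecord],
    pseudocount: float = 1.0,
    log_base: float | str = 2,
) -> Compendium:
    """Log-scaled CAGE compendium: per-region summed tag expression."""
    if not samples:
        raise DataError("cannot build a CAGE compendium from zero samples")
    for s in samples:
        if not s.scored:
            raise DataError(f"sample {s.sample_name!r} is unscored; CAGE compendia need scores")
    records = _match_metadata(samples, metadata)
    universe = build_region_universe(samples)
    transform = Transform(kind="log", base=parse_log_base(log_base), pseudocount=pseudocount)
    raw = np.column_stack([cage_region_scores(s, universe) for s in samples])
    return Compendium(
        data_type="cage",
        features=universe,
        matrix=transform.apply(raw),
        experiments=records,
        transform=transform,
    )


FilterValue = str | Sequence[str] | Callable[[str], bool]


def subset_compendium(compendium: Compendium, filters: Mapping[str, FilterValue]) -> Compendium:
    """Restrict a compendium to experiments whose metadata matches ``filters``.

    Each filter key must be a metadata attribute; the value is an exact
    string, a collection of accepted strings, or a predicate. The feature
    index and matrix values are untouched — no re-binarisation, no universe
    rebuild — so subsetting commutes with per-column statistics.
    """
    valid = compendium.attribute_keys
    for key in filters:
        if key not in valid:
            raise DataError(f"unknown metadata key {key!r}; valid keys: {', '.join(valid)}")

    def matches(rec: MetadataRecord) -> bool:
        for key, want in filters.items():
            have = rec.attributes[key]
            if callable(want):
                ok = bool(want(have))
            elif isinstance(want, str):
                ok = have == want
            else:
                ok = have in set(want)
            if not ok:
                return False
        return True

    keep = [j for j, rec in enumerate(compendium.experiments) if matches(rec)]
    if not keep:
        raise DataError(f"no experiments match filters {dict(filters)!r}")
    return Compendium(
        data_type=compendium.data_type,
        features=compendium.features,
        matrix=compendium.matrix[:, keep],
        experiments=[compendium.experiments[j] for j in keep],
        transform=compendium.transform,
    )
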