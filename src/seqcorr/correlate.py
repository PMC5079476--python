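"""Pearson correlation and hierarchical ordering of experiments.

Similarity between experiments is always the Pearson product-moment
coefficient of their aligned feature vectors; on the binary vectors of a
peak compendium this is the phi coefficient. A zero-variance vector (e.g.
an all-zero projected peak sample) has no defined correlation: such entries
are reported as *undefined* (NaN in the matrix, "NA" in exports) rather
than silently coerced to 0, and the affected experiments are excluded from
clustering and appended at the end of the display order.

Experiments are ordered by agglomerative clustering on the correlation
distance d = 1 - r. The merge loop is written here rather than delegated so
that tie-breaking is bit-reproducible: among equally close pairs, the pair
whose clusters contain the lowest original indices is merged first, and a
merged cluster keeps the position of its lowest-index member.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .compendium import Compendium
from .io_formats import DataError
from .projection import ProjectedSample

LINKAGE_METHODS = ("complete", "average", "single", "ward")


def pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson product-moment correlation, or None when undefined.

    Undefined means either vector has zero variance; this is reported
    explicitly instead of propagating NaN. Vectors must have equal length
    >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise DataError(f"pearson needs two equal-length vectors, got shapes {x.shape} and {y.shape}")
    if x.size < 3:
        raise DataError(f"pearson needs length >= 3, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return None
    if np.array_equal(x, y):  # self-comparison is exactly 1, not 1 ± 1 ulp
        return 1.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


@dataclass
class CorrelationTable:
    """Ranked per-experiment correlations of one user sample vs a compendium.

    ``frame`` has columns ``experiment_id``, ``r`` and one column per
    metadata attribute, sorted by r descending with undefined (NaN) rows
    last. Ties and NaNs keep the compendium's original experiment order.
    """

    sample_name: str
    frame: pd.DataFrame

    @property
    def ranked_ids(self) -> list[str]:
        return list(self.frame["experiment_id"])

    def top(self, n: int = 5) -> pd.DataFrame:
        return self.frame.head(n)


def correlate_user(projected: ProjectedSample, compendium: Compendium) -> CorrelationTable:
    """Correlate a projected user sample against every compendium experiment."""
    if projected.vector.shape[0] != compendium.n_features:
        raise DataError(
            f"projected vector length {projected.vector.shape[0]} does not match "
            f"compendium feature count {compendium.n_features}"
        )
    rows = []
    for j, rec in enumerate(compendium.experiments):
        r = pearson(projected.vector, compendium.matrix[:, j])
        rows.append({"experiment_id": rec.experiment_id, "r": np.nan if r is None else r, **rec.attributes})
    frame = pd.DataFrame(rows)
    frame = frame.sort_values("r", ascending=False, kind="stable", na_position="last").reset_index(
        drop=True
    )
    return CorrelationTable(sample_name=projected.sample_name, frame=frame)


@dataclass
class CorrelationMatrix:
    """Symmetric experiment x experiment Pearson matrix with display order.

    ``values[i, j]`` is r between experiments i and j (NaN where undefined;
    diagonal fixed at 1). ``ordering`` is a permutation of row indices —
    clustered leaves first, undefined experiments appended — and ``linkage``
    is a SciPy-convention merge table over ``clustered`` (indices into
    ``ids``) for dendrogram rendering. Both are None until
    :func:`cluster_order` runs.
    """

    ids: list[str]
    values: np.ndarray
    user_id: str | None = None
    method: str | None = None
    ordering: list[int] | None = None
    linkage: np.ndarray | None = None
    clustered: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DataError(f"correlation matrix shape {self.values.shape} does not match {n} ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def undefined_ids(self) -> list[str]:
        return [self.ids[i] for i in self._undefined_indices()]

    def _undefined_indices(self) -> list[int]:
        n = self.n
        if n < 2:
            return []
        off = ~np.eye(n, dtype=bool)
        return [i for i in range(n) if np.isnan(self.values[i][off[i]]).all()]

    def reordered(self) -> tuple[list[str], np.ndarray]:
        """Ids and matrix with the clustering permutation applied."""
        order = self.ordering if self.ordering is not None else list(range(self.n))
        ids = [self.ids[i] for i in order]
        return ids, self.values[np.ix_(order, order)]

    def to_frame(self) -> pd.DataFrame:
        ids, vals = self.reordered()
        df = pd.DataFrame(vals, columns=ids)
        df.insert(0, "experiment_id", ids)
        return df


def pairwise_matrix(
    compendium: Compendium, extra: ProjectedSample | None = None
) -> CorrelationMatrix:
    """All pairwise Pearson correlations between compendium experiments,
    with an optional projected user sample appended as one more column."""
    cols = compendium.matrix
    ids = list(compendium.experiment_ids)
    user_id = None
    if extra is not None:
        if extra.vector.shape[0] != compendium.n_features:
            raise DataError("projected sample does not match compendium feature count")
        user_id = extra.sample_name
        if user_id in ids:
            user_id = user_id + " (user)"
        cols = np.column_stack([cols, extra.vector])
        ids = ids + [user_id]
    n = cols.shape[1]
    if n < 2:
        raise DataError(f"pairwise correlation needs >= 2 experiments, got {n}")
    if cols.shape[0] < 3:
        raise DataError("pairwise correlation needs >= 3 features")
    centered = cols - cols.mean(axis=0, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = (centered.T @ centered) / np.outer(norms, norms)
    mat[np.outer(norms == 0, np.ones(n, bool))] = np.nan
    mat[np.outer(np.ones(n, bool), norms == 0)] = np.nan
    mat = np.clip(mat, -1.0, 1.0)
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    return CorrelationMatrix(ids=ids, values=mat, user_id=user_id)


def _linkage_correlation_distance(dist: np.ndarray, method: str) -> np.ndarray:
    """Deterministic agglomerative merge table (SciPy layout) on a full
    distance matrix, Lance-Williams updates, lowest-original-index tie-break."""
    n = dist.shape[0]
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = np.ones(n, dtype=bool)
    cluster_id = np.arange(n)  # scipy-style id of the cluster sitting at each position
    size = np.ones(n)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        masked = np.where(np.outer(active, active), d, np.inf)
        masked[np.tril_indices(n)] = np.inf
        flat = int(np.argmin(masked))  # row-major: lowest (i, j) wins ties
        i, j = divmod(flat, n)
        h = masked[i, j]
        ni, nj = size[i], size[j]
        Z[step] = (cluster_id[i], cluster_id[j], h, ni + nj)
        # Lance-Williams update of distances from the merged cluster (kept at
        # position i = the lowest original index of its members) to the rest
        k = active.copy()
        k[i] = k[j] = False
        dik, djk = d[i, k], d[j, k]
        if method == "single":
            dnew = np.minimum(dik, djk)
        elif method == "complete":
            dnew = np.maximum(dik, djk)
        elif method == "average":
            dnew = (ni * dik + nj * djk) / (ni + nj)
        elif method == "ward":
            nk = size[k]
            dnew = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * h**2) / (ni + nj + nk)
            )
        else:
            raise DataError(f"unknown linkage method {method!r}; choose from {LINKAGE_METHODS}")
        d[i, k] = dnew
        d[k, i] = dnew
        active[j] = False
        cluster_id[i] = n + step
        size[i] = ni + nj
    return Z


def leaf_order(Z: np.ndarray, n: int) -> list[int]:
    """Left-to-right dendrogram leaf order of a SciPy-layout merge table."""
    if n == 1:
        return [0]
    order: list[int] = []
    stack = [int(2 * n - 2)]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
        else:
            left, right = Z[node - n, 0], Z[node - n, 1]
            stack.append(int(right))
            stack.append(int(left))
    return order


def cluster_order(matrix: CorrelationMatrix, method: str = "complete") -> CorrelationMatrix:
    """Order experiments by agglomerative clustering on d = 1 - r.

    Experiments with undefined correlations are excluded from clustering and
    appended (in original order) after the clustered leaves. Returns a new
    CorrelationMatrix carrying ``ordering``, ``linkage`` and ``method``.
    """
    if method not in LINKAGE_METHODS:
        raise DataError(f"unknown linkage method {method!r}; choose from {LINKAGE_METHODS}")
    undef = matrix._undefined_indices()
    clustered = [i for i in range(matrix.n) if i not in set(undef)]
    if np.isnan(matrix.values[np.ix_(clustered, clustered)]).any():
        raise DataError("correlation matrix has isolated undefined entries between defined experiments")
    if len(clustered) == 0:
        return replace(matrix, method=method, ordering=list(range(matrix.n)), linkage=None, clustered=[])
    if len(clustered) == 1:
        return replace(matrix, method=method, ordering=clustered + undef, linkage=None, clustered=clustered)
    sub = matrix.values[np.ix_(clustered, clustered)]
    dist = 1.0 - sub
    np.fill_diagonal(dist, 0.0)
    Z = _linkage_correlation_distance(dist, method)
    order_local = leaf_order(Z, len(clustered))
    ordering = [clustered[i] for i in order_local] + undef
    return replace(matrix, method=method, ordering=ordering, linkage=Z, clustered=clustered)
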