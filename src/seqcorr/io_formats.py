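"""Readers and writers for every external file format the tool touches.

User inputs are plain text: two-column expression tables (gene id +
FPKM/TPM), BED peak files from ChIP-seq, and scored BED files from CAGE.
Reference compendia live on disk as a directory of TSV files plus a small
YAML manifest so they stay diff-able and language-neutral. All text inputs
may be gzip-compressed; compression is detected from the ``.gz`` suffix.

Coordinate convention: BED is 0-based half-open and no conversion ever
happens internally.
"""

from __future__ import annotations

import gzip
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("seqcorr")

COMPENDIUM_FORMAT = "seqcorr-compendium"
COMPENDIUM_VERSION = 1

_GENE_VERSION_RE = re.compile(r"\.\d+$")


class SeqcorrError(Exception):
    """Base class for all errors raised by this package."""


class DataError(SeqcorrError):
    """A user-supplied file or value is malformed or inconsistent."""


def normalize_gene_id(gene_id: str) -> str:
    """Case-fold a gene identifier and strip a trailing ``.N`` version suffix.

    Ensembl-style versioned identifiers (``ENSG00000141510.16``) and
    case differences are the most common reason two tables fail to match;
    normalisation happens once, at parse time.
    """
    return _GENE_VERSION_RE.sub("", gene_id.strip()).casefold()


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSample:
    """One experiment's gene-level abundances (FPKM or TPM), before log scaling.

    ``values`` maps normalised gene ids to non-negative abundances.
    """

    sample_name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        for gid, v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise DataError(
                    f"expression sample {self.sample_name!r}: gene {gid!r} has "
                    f"invalid abundance {v!r} (must be finite and >= 0)"
                )

    @property
    def n_genes(self) -> int:
        return len(self.values)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally scored (CAGE)."""

    chrom: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise DataError("interval with empty chromosome name")
        if self.start < 0:
            raise DataError(f"negative start coordinate in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise DataError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end} (start must be < end)"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        # half-open semantics: bookended intervals do not overlap
        return self.chrom == other.chrom and max(self.start, other.start) < min(self.end, other.end)


@dataclass
class PeakSample:
    """One experiment's peak calls; ``scored`` is True for CAGE input."""

    sample_name: str
    intervals: list[GenomicInterval]
    scored: bool = False

    def __post_init__(self) -> None:
        if self.scored:
            for iv in self.intervals:
                if iv.score is None:
                    raise DataError(
                        f"peak sample {self.sample_name!r} is scored but interval "
                        f"{iv.chrom}:{iv.start}-{iv.end} has no score"
                    )
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    @property
    def n_peaks(self) -> int:
        return len(self.intervals)


@dataclass
class MetadataRecord:
    """Per-experiment annotations (cell type, factor, source url, ...)."""

    experiment_id: str
    attributes: dict[str, str]


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_expression_table(
    path: str | Path,
    id_column: int | str = 0,
    value_column: int | str = 1,
    has_header: bool | None = None,
    sample_name: str | None = None,
) -> ExpressionSample:
    """Parse a tab- or comma-delimited gene expression table.

    Columns may be selected by 0-based index or, when the file has a header,
    by name. Duplicate gene ids (after normalisation) are resolved by keeping
    the maximum value, with a warning. Non-numeric values are an error naming
    the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"expression table not found: {path}")
    if has_header is None:
        has_header = isinstance(id_column, str) or isinstance(value_column, str)
    if (isinstance(id_column, str) or isinstance(value_column, str)) and not has_header:
        raise DataError("column names were given but has_header is False")

    values: dict[str, float] = {}
    header: list[str] | None = None
    delim: str | None = None
    n_data = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if delim is None:
                delim = _sniff_delimiter(line)
            fields = line.split(delim)
            if header is None and has_header:
                header = [f.strip() for f in fields]
                continue
            try:
                idx_id = header.index(id_column) if isinstance(id_column, str) else id_column
                idx_val = header.index(value_column) if isinstance(value_column, str) else value_column
            except ValueError as exc:
                raise DataError(f"{path}: column {exc.args[0].split()[0]!r} not in header {header}") from None
            if max(idx_id, idx_val) >= len(fields):
                raise DataError(
                    f"{path} line {lineno}: expected at least {max(idx_id, idx_val) + 1} "
                    f"columns, found {len(fields)}"
                )
            gid = normalize_gene_id(fields[idx_id])
            if not gid:
                raise DataError(f"{path} line {lineno}: empty gene id")
            try:
                val = float(fields[idx_val])
            except ValueError:
                raise DataError(
                    f"{path} line {lineno}: non-numeric expression value {fields[idx_val]!r}"
                ) from None
            if not math.isfinite(val) or val < 0:
                raise DataError(f"{path} line {lineno}: value {val!r} must be finite and >= 0")
            n_data += 1
            if gid in values:
                logger.warning(
                    "%s line %d: duplicate gene id %r; keeping the maximum value", path, lineno, gid
                )
                values[gid] = max(values[gid], val)
            else:
                values[gid] = val
    if n_data == 0:
        raise DataError(f"{path}: no usable data rows")
    name = sample_name if sample_name is not None else path.name.removesuffix(".gz").rsplit(".", 1)[0]
    return ExpressionSample(sample_name=name, values=values)


def write_expression_table(sample: ExpressionSample, path: str | Path) -> None:
    """Write a two-column gene/value TSV (inverse of :func:`read_expression_table`)."""
    with _open_text(path, "wt") as fh:
        for gid, val in sample.values.items():
            fh.write(f"{gid}\t{val:.10g}\n")


# ---------------------------------------------------------------------------
# BED peak files
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")


def read_peak_file(
    path: str | Path,
    scored: bool = False,
    score_column: int = 4,
    sample_name: str | None = None,
) -> PeakSample:
    """Parse a BED file of peak calls (>= 3 columns, 0-based half-open).

    With ``scored=True`` (CAGE input) a numeric score is taken from
    ``score_column`` (0-based; BED column 5 by default). Track, browser and
    comment lines are skipped; any malformed data line is an error naming
    the line number.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"peak file not found: {path}")
    intervals: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise DataError(f"{path} line {lineno}: BED needs >= 3 columns, found {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise DataError(f"{path} line {lineno}: non-integer coordinates") from None
            score: float | None = None
            if scored:
                if score_column >= len(fields):
                    raise DataError(
                        f"{path} line {lineno}: score column {score_column + 1} absent "
                        f"(line has {len(fields)} columns)"
                    )
                try:
                    score = float(fields[score_column])
                except ValueError:
                    raise DataError(
                        f"{path} line {lineno}: non-numeric score {fields[score_column]!r}"
                    ) from None
                if not math.isfinite(score) or score < 0:
                    raise DataError(f"{path} line {lineno}: score must be finite and >= 0")
            try:
                intervals.append(GenomicInterval(chrom, start, end, score))
            except DataError as exc:
                raise DataError(f"{path} line {lineno}: {exc}") from None
    name = sample_name if sample_name is not None else path.name.removesuffix(".gz").rsplit(".", 1)[0]
    return PeakSample(sample_name=name, intervals=intervals, scored=scored)


def write_peak_file(sample: PeakSample, path: str | Path) -> None:
    """Write a PeakSample as BED3 (unscored) or BED5 (scored)."""
    with _open_text(path, "wt") as fh:
        for i, iv in enumerate(sample.intervals):
            if sample.scored:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i + 1}\t{iv.score:.6g}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> list[MetadataRecord]:
    """Read a TSV metadata table; first column is the experiment id."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"metadata table not found: {path}")
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh if ln.strip()]
    if not lines:
        raise DataError(f"{path}: empty metadata file")
    header = lines[0].split("\t")
    if len(header) < 1 or not header[0]:
        raise DataError(f"{path}: metadata header must start with an experiment-id column")
    keys = header[1:]
    records: list[MetadataRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise DataError(
                f"{path} line {lineno}: expected {len(header)} columns, found {len(fields)}"
            )
        exp_id = fields[0]
        if exp_id in seen:
            raise DataError(f"{path} line {lineno}: duplicate experiment id {exp_id!r}")
        seen.add(exp_id)
        records.append(MetadataRecord(exp_id, dict(zip(keys, fields[1:]))))
    if not records:
        raise DataError(f"{path}: no records (header only)")
    return records


def write_metadata(records: Sequence[MetadataRecord], path: str | Path) -> None:
    keys = list(records[0].attributes.keys())
    with _open_text(path, "wt") as fh:
        fh.write("experiment_id\t" + "\t".join(keys) + "\n")
        for rec in records:
            fh.write(rec.experiment_id + "\t" + "\t".join(rec.attributes[k] for k in keys) + "\n")


# ---------------------------------------------------------------------------
# Compendium directory format
# ---------------------------------------------------------------------------
#
# <dir>/manifest.yaml   format marker, version, data type, transform record
# <dir>/features.tsv    gene_id column, or chrom/start/end for region universes
# <dir>/matrix.tsv      features x experiments, header = experiment ids
# <dir>/metadata.tsv    per-experiment metadata, first column experiment_id


def write_compendium(compendium, directory: str | Path) -> None:
    """Serialise a compendium to its on-disk directory format.

    Matrix values are written with 17 significant digits so the round trip
    through text is bit-exact for float64.
    """
    from .compendium import Compendium, RegionUniverse  # local import to avoid a cycle

    assert isinstance(compendium, Compendium)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    manifest = {
        "format": COMPENDIUM_FORMAT,
        "version": COMPENDIUM_VERSION,
        "data_type": compendium.data_type,
        "transform": compendium.transform.to_dict(),
        "n_features": compendium.n_features,
        "n_experiments": compendium.n_experiments,
    }
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))

    with open(directory / "features.tsv", "w") as fh:
        if isinstance(compendium.features, RegionUniverse):
            fh.write("chrom\tstart\tend\n")
            for iv in compendium.features.regions:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        else:
            fh.write("gene_id\n")
            for gid in compendium.features:
                fh.write(gid + "\n")

    ids = compendium.experiment_ids
    mat = compendium.matrix
    with open(directory / "matrix.tsv", "w") as fh:
        fh.write("\t".join(ids) + "\n")
        if compendium.transform.kind == "binary":
            for row in mat.astype(int):
                fh.write("\t".join(str(v) for v in row) + "\n")
        else:
            for row in mat:
                fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")

    write_metadata(compendium.experiments, directory / "metadata.tsv")


def _find(directory: Path, stem: str) -> Path:
    for cand in (directory / stem, directory / (stem + ".gz")):
        if cand.exists():
            return cand
    raise DataError(f"{directory}: not a compendium directory ({stem} missing)")


def read_compendium(directory: str | Path):
    """Load a compendium directory, cross-checking all three files' dimensions."""
    from .compendium import Compendium, RegionUniverse, Transform

    directory = Path(directory)
    if not directory.is_dir():
        raise DataError(f"not a compendium directory: {directory}")
    manifest_path = directory / "manifest.yaml"
    if not manifest_path.exists():
        raise DataError(f"{directory}: not a compendium directory (manifest.yaml missing)")
    manifest = yaml.safe_load(manifest_path.read_text())
    if not isinstance(manifest, dict) or manifest.get("format") != COMPENDIUM_FORMAT:
        raise DataError(f"{directory}: manifest does not declare the compendium format")
    if manifest.get("version") != COMPENDIUM_VERSION:
        raise DataError(
            f"{directory}: unsupported compendium version {manifest.get('version')!r} "
            f"(this build reads version {COMPENDIUM_VERSION})"
        )
    data_type = manifest["data_type"]
    transform = Transform.from_dict(manifest["transform"])

    feat_df = pd.read_csv(_find(directory, "features.tsv"), sep="\t", dtype=str)
    if list(feat_df.columns) == ["chrom", "start", "end"]:
        regions = [
            GenomicInterval(c, int(s), int(e))
            for c, s, e in zip(feat_df["chrom"], feat_df["start"], feat_df["end"])
        ]
        features: object = RegionUniverse(regions)
    elif list(feat_df.columns) == ["gene_id"]:
        features = list(feat_df["gene_id"])
    else:
        raise DataError(f"{directory}/features.tsv: unrecognised feature columns {list(feat_df.columns)}")

    mat_df = pd.read_csv(_find(directory, "matrix.tsv"), sep="\t", float_precision="round_trip")
    matrix = mat_df.to_numpy(dtype=float)
    ids = [str(c) for c in mat_df.columns]

    records = read_metadata(_find(directory, "metadata.tsv"))
    meta_ids = [r.experiment_id for r in records]
    n_feat = len(features.regions) if isinstance(features, RegionUniverse) else len(features)
    if matrix.shape[0] != n_feat:
        raise DataError(
            f"{directory}: matrix has {matrix.shape[0]} rows but features.tsv lists {n_feat} features"
        )
    if matrix.shape[1] != len(records):
        raise DataError(
            f"{directory}: matrix has {matrix.shape[1]} columns but metadata.tsv lists "
            f"{len(records)} experiments"
        )
    if ids != meta_ids:
        raise DataError(f"{directory}: matrix header and metadata experiment ids disagree")
    if int(manifest.get("n_features", n_feat)) != n_feat or int(
        manifest.get("n_experiments", len(records))
    ) != len(records):
        raise DataError(f"{directory}: manifest dimensions disagree with matrix")

    return Compendium(
        data_type=data_type, features=features, matrix=matrix, experiments=records, transform=transform
    )


def iter_data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    """Yield (line number, stripped line) for non-comment, non-blank lines."""
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line and not line.startswith(_SKIP_PREFIXES):
                yield lineno, line


def file_sha256(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
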