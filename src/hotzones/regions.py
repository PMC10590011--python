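"""Reading, validating and writing transcription-factor binding regions.

Input records are ChIP-seq-style binding intervals, one per row:
chromosome, start, end, strand and the name of the bound TF. Internally
every coordinate is **1-based inclusive** — base ``start`` and base ``end``
both belong to the region, and a region of a single base has
``start == end``. BED-family formats (0-based half-open) are converted at
the I/O boundary and nowhere else.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .zones import ZoneSet

STRANDS = {"+", "-", "*"}

__all__ = [
    "BindingRegion",
    "RegionSet",
    "RegionParseError",
    "read_regions",
    "write_regions",
    "write_zones",
]


class RegionParseError(ValueError):
    """Raised when an input file cannot be parsed or validated."""


@dataclass(frozen=True, order=True)
class BindingRegion:
    """One TF binding interval, 1-based inclusive.

    Attributes
    ----------
    chrom : str
        Chromosome name; treated as an opaque label.
    start, end : int
        First and last base of the region, ``1 <= start <= end``.
    strand : str
        One of ``+``, ``-`` or ``*`` (unstranded). Read and preserved, but
        ignored by all accumulation computations.
    tf : str
        Name of the bound transcription factor (non-empty).
    """

    chrom: str
    start: int
    end: int
    strand: str = "*"
    tf: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {sorted(STRANDS)}, got {self.strand!r}")
        tf = self.tf.strip()
        if not tf:
            raise ValueError("tf name must be non-empty")
        object.__setattr__(self, "tf", tf)

    @property
    def length(self) -> int:
        """Number of bases covered (end - start + 1)."""
        return self.end - self.start + 1

    def intersects(self, start: int, end: int) -> bool:
        """True if the region shares >= 1 base with [start, end]."""
        return self.start <= end and self.end >= start


class RegionSet:
    """A validated, deterministically ordered collection of binding regions.

    Regions are stored sorted by (chrom, start, end, tf); duplicate
    identical rows are retained — they are distinct input regions for the
    region- and base-accumulation counts.
    """

    def __init__(self, regions: Iterable[BindingRegion]):
        self._regions: tuple[BindingRegion, ...] = tuple(
            sorted(regions, key=lambda r: (r.chrom, r.start, r.end, r.tf))
        )

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self) -> Iterator[BindingRegion]:
        return iter(self._regions)

    def __getitem__(self, i: int) -> BindingRegion:
        return self._regions[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self._regions == other._regions

    def __repr__(self) -> str:
        return (
            f"RegionSet(n_regions={self.n_regions}, "
            f"n_tfs={len(self.tf_names)}, chroms={sorted(self.chromosomes)})"
        )

    @property
    def n_regions(self) -> int:
        return len(self._regions)

    @property
    def tf_names(self) -> frozenset[str]:
        return frozenset(r.tf for r in self._regions)

    @property
    def chromosomes(self) -> frozenset[str]:
        return frozenset(r.chrom for r in self._regions)

    def by_chrom(self, chrom: str) -> tuple[BindingRegion, ...]:
        """All regions on one chromosome, in sorted order."""
        return tuple(r for r in self._regions if r.chrom == chrom)

    def subset(self, chroms: Sequence[str]) -> "RegionSet":
        wanted = set(chroms)
        return RegionSet(r for r in self._regions if r.chrom in wanted)

    def to_frame(self) -> pd.DataFrame:
        """1-based inclusive table with columns chrom/start/end/strand/tf."""
        return pd.DataFrame(
            [(r.chrom, r.start, r.end, r.strand, r.tf) for r in self._regions],
            columns=["chrom", "start", "end", "strand", "tf"],
        )


def _require_columns(df: pd.DataFrame, n: int, path: str, what: str) -> None:
    if df.shape[1] < n:
        raise RegionParseError(f"{path}: {what} needs >= {n} columns, found {df.shape[1]}")


def _build(rows: Iterable[tuple], path: str) -> RegionSet:
    regions = []
    for lineno, (chrom, start, end, strand, tf) in rows:
        try:
            regions.append(
                BindingRegion(str(chrom), int(start), int(end), str(strand), str(tf))
            )
        except (ValueError, TypeError) as exc:
            raise RegionParseError(f"{path}, line {lineno}: {exc}") from exc
    return RegionSet(regions)


def read_regions(
    path: str | Path,
    format: str = "tsv",
    tf: str | None = None,
    tf_map: dict[str, str] | None = None,
) -> RegionSet:
    """Read binding regions from a tabular file into a :class:`RegionSet`.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"tsv", "bed", "narrowpeak"}
        ``tsv``: columns chrom, start, end, strand, tf with **1-based
        inclusive** coordinates (the native dialect). ``bed``: BED5+ with
        0-based half-open coordinates; the TF name is taken from column 7
        if present, otherwise from the BED name column (column 4), unless
        `tf` overrides it. ``narrowpeak``: ENCODE narrowPeak (0-based
        half-open); the format has no TF column, so the TF must come from
        `tf` or from `tf_map` keyed by file name.
    tf : str, optional
        Assign this TF name to every region, overriding any column.
    tf_map : dict, optional
        Maps file basename (or full path) to a TF name.

    Returns
    -------
    RegionSet
        In 1-based inclusive coordinates (BED start + 1 on read).
    """
    path = Path(path)
    fmt = format.lower().replace("+tf", "")
    if fmt not in {"tsv", "bed", "bed5", "narrowpeak"}:
        raise ValueError(f"unknown format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    file_tf = tf
    if file_tf is None and tf_map:
        file_tf = tf_map.get(path.name, tf_map.get(str(path)))

    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str,
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        return RegionSet([])
    except pd.errors.ParserError as exc:
        raise RegionParseError(f"{path}: {exc}") from exc
    lines = df.index + 1

    if fmt == "tsv":
        _require_columns(df, 5, str(path), "TSV dialect")
        rows = zip(lines, df.iloc[:, :5].itertuples(index=False, name=None))
        return _build(rows, str(path))

    # BED-family: 0-based half-open -> 1-based inclusive (start+1, end kept)
    _require_columns(df, 3, str(path), f"{fmt} dialect")
    ncol = df.shape[1]
    records = []
    for lineno, row in zip(lines, df.itertuples(index=False, name=None)):
        chrom, start0, end0 = row[0], row[1], row[2]
        strand = row[5] if ncol > 5 and str(row[5]) in STRANDS else "*"
        if fmt == "narrowpeak":
            tf_name = file_tf
        else:
            extra = row[6] if ncol > 6 else None
            name = row[3] if ncol > 3 else None
            tf_name = file_tf or extra or name
        if tf_name is None or (isinstance(tf_name, float) and math.isnan(tf_name)):
            raise RegionParseError(
                f"{path}, line {lineno}: no TF name available "
                "(supply tf= or tf_map= for this dialect)"
            )
        try:
            start = int(start0) + 1
            end = int(end0)
        except (TypeError, ValueError) as exc:
            raise RegionParseError(f"{path}, line {lineno}: {exc}") from exc
        records.append((lineno, (chrom, start, end, strand, tf_name)))
    return _build(records, str(path))


def write_regions(regions: RegionSet, path: str | Path, format: str = "tsv") -> None:
    """Write a RegionSet as TSV (1-based inclusive) or BED6 (0-based)."""
    path = Path(path)
    with path.open("w") as fh:
        for r in regions:
            if format == "tsv":
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.tf}\n")
            elif format == "bed":
                strand = r.strand if r.strand in {"+", "-"} else "."
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.tf}\t0\t{strand}\n")
            else:
                raise ValueError(f"unknown format {format!r}")


def write_zones(
    zones: "ZoneSet",
    path: str | Path,
    format: str = "bed",
    sidecar: str | Path | None = None,
) -> Path:
    """Write a ZoneSet to `path` and a JSON statistics sidecar.

    BED output is 0-based half-open (start - 1, end) with the accumulation
    index in the score column; TSV output keeps 1-based inclusive
    coordinates. Rows are sorted by chrom then start. The sidecar (default
    ``<path>.json``) records the method, parameters, zone count, length
    statistics and — when available — the resolved threshold.
    """
    path = Path(path)
    if format not in {"bed", "tsv"}:
        raise ValueError(f"unknown format {format!r}")
    with path.open("w") as fh:
        if format == "tsv":
            fh.write("chrom\tstart\tend\tindex\tmethod\n")
        for i, z in enumerate(zones, start=1):
            if format == "bed":
                fh.write(f"{z.chrom}\t{z.start - 1}\t{z.end}\tzone_{i}\t{z.index}\t.\n")
            else:
                fh.write(f"{z.chrom}\t{z.start}\t{z.end}\t{z.index}\t{z.method}\n")
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(path.suffix + ".json")
    with sidecar.open("w") as fh:
        json.dump(zones.summary(), fh, indent=2)
        fh.write("\n")
    return path


def read_zones(path: str | Path, format: str = "bed") -> "ZoneSet":
    """Read a zone file written by :func:`write_zones` back into a ZoneSet."""
    from .zones import DenseZone, ZoneSet

    path = Path(path)
    zones = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if format == "bed":
                chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
                index = int(parts[4]) if len(parts) > 4 else 1
                zones.append(DenseZone(chrom, start0 + 1, end0, index, "imported"))
            elif format == "tsv":
                if parts[0] == "chrom":  # header
                    continue
                chrom, start, end, index = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
                method = parts[4] if len(parts) > 4 else "imported"
                zones.append(DenseZone(chrom, start, end, index, method))
            else:
                raise ValueError(f"unknown format {format!r}")
    return ZoneSet(zones, method="imported")
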