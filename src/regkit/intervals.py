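"""Genomic interval model, interval algebra, and plain-text format I/O.

Internal coordinates are 0-based half-open throughout the package (the BED
convention); GFF3 output is converted to 1-based inclusive on write and back
on read.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

STRANDS = ("+", "-", ".")

COUNT_TABLE_COLUMNS = ["contig", "pos", "strand", "converted", "total"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.contig == other.contig and (
            self.start < other.end and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if `other` lies fully within this interval."""
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Peak:
    """An experimental evidence interval (ChIP-seq / open-chromatin peak).

    `feature_type` names the assayed factor (a TF name, "DNase1", a histone
    mark ...); `summit`, when present, is the position of highest read
    coverage and must fall inside the interval.
    """

    interval: GenomicInterval
    cell_type: str
    feature_type: str
    score: float = 0.0
    summit: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of base positions shared by two intervals (0 across contigs)."""
    if a.contig != b.contig:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(
    xs: Iterable[GenomicInterval], min_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals separated by at most `min_gap` bases, per contig.

    The result is sorted, and with min_gap=0 covers exactly the union of the
    input bases. Strand is dropped (merged intervals are unstranded).
    """
    if min_gap < 0:
        raise ValueError("min_gap must be non-negative")
    xs = sorted(xs, key=lambda iv: (iv.contig, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in xs:
        if (
            out
            and out[-1].contig == iv.contig
            and iv.start - out[-1].end <= min_gap
        ):
            if iv.end > out[-1].end:
                out[-1] = replace(out[-1], end=iv.end)
        else:
            out.append(GenomicInterval(iv.contig, iv.start, iv.end))
    return out


def subtract_intervals(
    xs: Sequence[GenomicInterval], ys: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-level set difference xs \\ ys, returned merged and sorted."""
    xs = merge_intervals(xs)
    ys = merge_intervals(ys)
    out: list[GenomicInterval] = []
    by_contig: dict[str, list[GenomicInterval]] = {}
    for y in ys:
        by_contig.setdefault(y.contig, []).append(y)
    for x in xs:
        cur = x.start
        for y in by_contig.get(x.contig, []):
            if y.end <= cur or y.start >= x.end:
                continue
            if y.start > cur:
                out.append(GenomicInterval(x.contig, cur, y.start))
            cur = max(cur, y.end)
            if cur >= x.end:
                break
        if cur < x.end:
            out.append(GenomicInterval(x.contig, cur, x.end))
    return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def _parse_error(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}: line {lineno}: {msg}")


def read_bed(path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file as plain intervals.

    Column 6, when present, supplies the strand; name and score columns are
    ignored at this level (see `read_peaks_bed` for evidence peaks).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _parse_error(path, lineno, "expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise _parse_error(path, lineno, "non-integer coordinates") from None
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from None
    return out


def write_bed(xs: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in xs:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_peaks_bed(path) -> list[Peak]:
    """Read peaks from BED6+3: name column holds the feature type, then
    optional columns 7-9 hold cell type, summit (-1 = absent) and source."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise _parse_error(path, lineno, "expected >= 4 columns for a peak")
            try:
                iv = GenomicInterval(
                    f[0], int(f[1]), int(f[2]), f[5] if len(f) >= 6 else "."
                )
                score = float(f[4]) if len(f) >= 5 and f[4] != "." else 0.0
                summit = int(f[7]) if len(f) >= 8 else -1
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from None
            out.append(
                Peak(
                    interval=iv,
                    feature_type=f[3],
                    score=score,
                    cell_type=f[6] if len(f) >= 7 else "",
                    summit=None if summit < 0 else summit,
                    source=f[8] if len(f) >= 9 else "",
                )
            )
    return out


def write_peaks_bed(peaks: Iterable[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            summit = -1 if p.summit is None else p.summit
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{p.feature_type}\t"
                f"{p.score:g}\t{iv.strand}\t{p.cell_type}\t{summit}\t{p.source}\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gff3Record:
    """One GFF3 feature line; coordinates are internal (0-based half-open)
    and converted to 1-based inclusive only in the serialized text."""

    interval: GenomicInterval
    type: str
    source: str = "regkit"
    score: float | None = None
    attributes: dict[str, str] = field(default_factory=dict)


def _attr_escape(s: str) -> str:
    # GFF3 reserves % ; = & , tab and newline inside attribute values
    for ch in "%;=&,\t\n":
        s = s.replace(ch, urllib.parse.quote(ch))
    return s


def write_gff3(records: Iterable[Gff3Record], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            iv = r.interval
            score = "." if r.score is None else f"{r.score:g}"
            attrs = ";".join(
                f"{k}={_attr_escape(v)}" for k, v in r.attributes.items()
            )
            fh.write(
                f"{iv.contig}\t{r.source}\t{r.type}\t{iv.start + 1}\t{iv.end}\t"
                f"{score}\t{iv.strand}\t.\t{attrs or '.'}\n"
            )


def read_gff3(path) -> list[Gff3Record]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise _parse_error(path, lineno, f"expected 9 GFF3 columns, got {len(f)}")
            try:
                iv = GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6])
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from None
            attrs: dict[str, str] = {}
            if f[8] != ".":
                for pair in f[8].split(";"):
                    if not pair:
                        continue
                    k, _, v = pair.partition("=")
                    attrs[k] = urllib.parse.unquote(v)
            out.append(
                Gff3Record(
                    interval=iv,
                    type=f[2],
                    source=f[1],
                    score=None if f[5] == "." else float(f[5]),
                    attributes=attrs,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Bisulfite count tables
# ---------------------------------------------------------------------------


def read_counts_table(path) -> pd.DataFrame:
    """Read a tab-delimited bisulfite count table.

    Columns: contig, pos (0-based), strand, converted, total. A header line
    naming the columns is accepted and ignored.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=COUNT_TABLE_COLUMNS,
        dtype={"contig": str, "strand": str},
    )
    if len(df) and df.iloc[0]["contig"] == "contig":  # header row present
        df = df.iloc[1:].reset_index(drop=True)
    if len(df) == 0:
        return pd.DataFrame(columns=COUNT_TABLE_COLUMNS).astype(
            {"pos": int, "converted": int, "total": int}
        )
    try:
        df = df.astype({"pos": int, "converted": int, "total": int})
    except ValueError as exc:
        raise ValueError(f"{path}: malformed count table: {exc}") from None
    bad = df.index[
        (df["pos"] < 0)
        | (df["converted"] < 0)
        | (df["total"] < 1)
        | (df["converted"] > df["total"])
        | ~df["strand"].isin(["+", "-"])
    ]
    if len(bad):
        raise ValueError(
            f"{path}: line {bad[0] + 1}: invalid count record "
            f"{df.loc[bad[0]].tolist()}"
        )
    return df


def write_counts_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=COUNT_TABLE_COLUMNS)
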