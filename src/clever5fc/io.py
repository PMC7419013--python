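"""Readers and writers for the pipeline's plain-text formats.

Count tables are TSV with header ``chrom  pos  count_C  count_T`` (1-based
positions, optional ``strand`` column); interval files are BED (0-based
half-open), with repeat family/subfamily in columns 4-5; per-cell call files
are BED-like with the counts and p-values appended.  All round-trips are
lossless and all 0/1-based conversions happen here.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .calling import FcCallSet
from .counts import ControlCounts, SiteCounts
from .errors import ParseError
from .genome import Interval, Site

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# count tables

def write_counts_table(counts: SiteCounts, path: str | Path) -> None:
    df = counts.data.reset_index()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "count_C": df["nc"],
            "count_T": df["nt"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_counts_table(
    path: str | Path, cell_id: str | None = None, merge_strands: bool = False
) -> SiteCounts:
    """Read a per-cell count table.

    With ``merge_strands`` and a ``strand`` column, a minus-strand row at
    position p is folded onto the plus-strand C of the dyad at p - 1 and the
    two rows' counts are summed.
    """
    path = Path(path)
    rows: list[tuple[str, int, int, int]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty count table", str(path)) from None
        required = ["chrom", "pos", "count_C", "count_T"]
        if header[: len(required)] != required:
            raise ParseError(
                f"bad header {header!r}; expected columns {required}", str(path), 1
            )
        has_strand = "strand" in header
        strand_col = header.index("strand") if has_strand else -1
        for ln, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                chrom, pos, nc, nt = row[0], int(row[1]), int(row[2]), int(row[3])
            except (ValueError, IndexError):
                raise ParseError("malformed row", str(path), ln) from None
            if pos < 1:
                raise ParseError(f"position {pos} < 1", str(path), ln)
            if nc < 0 or nt < 0:
                raise ParseError("negative read count", str(path), ln)
            if has_strand and merge_strands and row[strand_col] == "-":
                pos -= 1  # fold minus-strand C onto the dyad's plus-strand C
            rows.append((chrom, pos, nc, nt))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "nc", "nt"])
    if merge_strands:
        df = df.groupby(["chrom", "pos"], as_index=False).sum()
    elif df.duplicated(["chrom", "pos"]).any():
        dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
        raise ParseError(
            f"duplicate un-merged position {dup.chrom}:{dup.pos}", str(path)
        )
    df = df.set_index(["chrom", "pos"])[["nt", "nc"]]
    return SiteCounts(cell_id or path.stem, df)


# ---------------------------------------------------------------------------
# control tables

def write_control_table(control: ControlCounts, path: str | Path) -> None:
    df = control.data.copy()
    if "is_5fc" in df.columns:
        df["is_5fc"] = df["is_5fc"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_control_table(path: str | Path, kind: str) -> ControlCounts:
    df = pd.read_csv(path, sep="\t")
    if "is_5fc" in df.columns:
        df["is_5fc"] = df["is_5fc"].astype(bool)
    return ControlCounts(kind, df)


# ---------------------------------------------------------------------------
# BED and interval files

def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.family is not None or iv.subfamily is not None:
                fields += [iv.family or ".", iv.subfamily or "."]
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | Path, expect: str | None = None) -> list[Interval]:
    """Read BED3+; columns 4-5, when present, are repeat family/subfamily.

    Output is sorted by (chrom, start, end).  ``expect`` is a class label
    recorded only for error messages.
    """
    out: list[Interval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("BED line with fewer than 3 columns", str(path), ln)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError("non-integer BED coordinates", str(path), ln) from None
            if start < 0 or start >= end:
                raise ParseError(
                    f"invalid interval {parts[0]}:{start}-{end}"
                    + (f" in {expect} file" if expect else ""),
                    str(path),
                    ln,
                )
            fam = parts[3] if len(parts) > 3 and parts[3] != "." else None
            sub = parts[4] if len(parts) > 4 and parts[4] != "." else None
            out.append(Interval(parts[0], start, end, family=fam, subfamily=sub))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph signal track into columns chrom, start, end, value."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
                )
            except (ValueError, IndexError):
                raise ParseError("malformed bedGraph line", str(path), ln) from None
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def read_snp_mask(path: str | Path) -> frozenset[Site]:
    """Read a SNP mask: BED (0-based intervals, every covered base masked)
    or a two-column TSV of chrom, 1-based pos."""
    path = Path(path)
    sites: set[Site] = set()
    with open(path) as fh:
        first = fh.readline()
    ncol = len(first.rstrip("\n").split("\t")) if first.strip() else 0
    if ncol >= 3:
        for iv in read_bed(path):
            for pos0 in range(iv.start, iv.end):
                sites.add((iv.chrom, pos0 + 1))
    elif ncol == 2:
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, pos = line.split("\t")
                try:
                    sites.add((chrom, int(pos)))
                except ValueError:
                    raise ParseError("bad SNP position", str(path), ln) from None
    elif ncol != 0:
        raise ParseError("SNP mask must be BED or two-column TSV", str(path), 1)
    return frozenset(sites)


# ---------------------------------------------------------------------------
# call files

def write_calls(calls: FcCallSet, path: str | Path) -> None:
    """Per-cell 5fC calls as BED-like TSV: chrom, start (0-based), end, NT,
    NC, raw_p, adj_p."""
    df = calls.fc.reset_index()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"] - 1,
            "end": df["pos"],
            "NT": df["nt"],
            "NC": df["nc"],
            "raw_p": df["raw_p"],
            "adj_p": df["adj_p"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_calls(path: str | Path, cell_id: str | None = None) -> pd.DataFrame:
    """Read a call file back into a DataFrame indexed by (chrom, pos)."""
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["end"].astype(int)
    df = df.rename(columns={"NT": "nt", "NC": "nc"})
    return df.set_index(["chrom", "pos"])[["nt", "nc", "raw_p", "adj_p"]]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Uniform TSV writer used for every result table (stable float format,
    so identical runs produce byte-identical files)."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
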