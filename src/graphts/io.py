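"""Reading time series from tabular text, writing anomaly reports, exporting graphs.

Input series come as single-column plain text, CSV or TSV (delimiter sniffed
or given, header auto-detected). Reports are TSV; graphs go out as GraphML or
a TSV edge list. All sample indices are 0-based and windows are half-open
``[i, i + w_g)``.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class TimeSeries:
    """An ordered sequence of finite real samples.

    Parameters
    ----------
    values : array-like of float
        The samples, in time order. Must be finite (no NaN/Inf) and contain
        at least two points.
    name : str
        Label used in reports and plots.
    """

    values: np.ndarray
    name: str = "series"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 1:
            raise ValueError(f"time series must be 1-dimensional, got shape {vals.shape}")
        if vals.size < 2:
            raise ValueError(f"time series needs at least 2 samples, got {vals.size}")
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise ValueError(f"non-finite value at sample index {bad[0]}")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class ReportEntry:
    rank: int
    start: int
    length: int
    score: float


@dataclass
class AnomalyReport:
    """Ranked anomaly detections: rank 1 carries the lowest (most anomalous) score."""

    entries: list[ReportEntry] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.entries)

    def starts(self) -> list[int]:
        return [e.start for e in self.entries]

    def validate(self) -> None:
        """Check rank/score ordering and the pairwise exclusion-zone property."""
        for pos, e in enumerate(self.entries, start=1):
            if e.rank != pos:
                raise ValueError(f"ranks must be consecutive from 1, got {e.rank} at position {pos}")
            if e.score < 0:
                raise ValueError(f"negative score at rank {e.rank}")
            if e.length < 1 or e.start < 0:
                raise ValueError(f"invalid start/length at rank {e.rank}")
        scores = [e.score for e in self.entries]
        if any(b < a for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-decreasing with rank")
        lengths = {e.length for e in self.entries}
        if len(lengths) <= 1:
            # single-length report: starts must be separated by more than the length
            ell = lengths.pop() if lengths else 0
            ss = sorted(e.start for e in self.entries)
            if any(b - a <= ell for a, b in zip(ss, ss[1:])):
                raise ValueError("exclusion zone violated: starts closer than length")
        else:
            # cross-length merged report: intervals must not overlap
            ivals = sorted((e.start, e.start + e.length) for e in self.entries)
            if any(b0 < a1 for (_, a1), (b0, _) in zip(ivals, ivals[1:])):
                raise ValueError("merged report has overlapping intervals")


def _sniff_delimiter(sample: str) -> str | None:
    """Return a delimiter character, or None for whitespace splitting."""
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return None


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def load_series(path, column=None, delimiter: str | None = None) -> TimeSeries:
    """Read a univariate time series from a text/CSV/TSV file.

    Parameters
    ----------
    path : path-like
    column : str | int | None
        Column to read: a header name, a 0-based position, or None (first
        column). A non-numeric first row is treated as a header.
    delimiter : str | None
        Field delimiter; sniffed from the file when None.

    Raises
    ------
    FileNotFoundError, FormatError
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        sample = fh.read(65536)
    if not sample.strip():
        raise FormatError(f"{path}: empty file")

    sep = delimiter if delimiter is not None else _sniff_delimiter(sample)
    first = sample.splitlines()[0]
    tokens = first.split(sep) if sep else first.split()
    has_header = not all(_is_number(t) for t in tokens if t != "")

    kwargs = dict(header=0 if has_header else None, skip_blank_lines=True, dtype=str)
    if sep is None:
        kwargs["sep"] = r"\s+"
    else:
        kwargs["sep"] = sep
    df = pd.read_csv(path, **kwargs)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no data rows (line 1 = {first!r} was taken as a header)")

    if column is None:
        col = df.iloc[:, 0]
    elif isinstance(column, int):
        if column < 0 or column >= df.shape[1]:
            raise FormatError(f"{path}: column index {column} out of range ({df.shape[1]} columns)")
        col = df.iloc[:, column]
    else:
        if not has_header or column not in df.columns:
            raise FormatError(f"{path}: no column named {column!r}")
        col = df[column]

    raw = col.to_numpy(dtype=object)
    values = pd.to_numeric(col, errors="coerce").to_numpy(dtype=np.float64)
    header_off = 2 if has_header else 1  # 1-based file line of the first data row
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        i = int(bad[0])
        raise FormatError(
            f"{path}: non-numeric or missing value {raw[i]!r} at line {i + header_off}"
        )
    name = str(col.name) if has_header and col.name is not None else os.path.basename(path)
    return TimeSeries(values, name=name)


def write_report(report: AnomalyReport, path) -> None:
    """Write an anomaly report as TSV (header ``rank start length score``)."""
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        fh.write("rank\tstart\tlength\tscore\n")
        for e in report.entries:
            fh.write(f"{e.rank}\t{e.start}\t{e.length}\t{e.score:.9g}\n")


def read_report(path) -> AnomalyReport:
    """Parse a report written by :func:`write_report` (lossless round trip)."""
    entries = []
    with open(os.fspath(path), "r", encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() != "rank\tstart\tlength\tscore":
            raise FormatError(f"{path}: unexpected report header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            r, s, l, sc = line.rstrip("\n").split("\t")
            entries.append(ReportEntry(int(r), int(s), int(l), float(sc)))
    return AnomalyReport(entries=entries)


def export_graph(graph, path, dialect: str = "graphml") -> None:
    """Export a transition graph.

    ``graphml``: standard GraphML with node attribute ``cell`` ("row,col") and
    edge attribute ``weight``.  ``edgelist``: TSV rows ``src  dst  weight``.
    Self-loops are preserved in both dialects.
    """
    path = os.fspath(path)
    if dialect == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            for (u, v) in sorted(graph.edges):
                fh.write(f"{u}\t{v}\t{graph.edges[(u, v)]}\n")
    elif dialect == "graphml":
        import networkx as nx

        nx.write_graphml(graph.to_networkx(), path)
    else:
        raise ValueError(f"unknown graph dialect {dialect!r} (use 'graphml' or 'edgelist')")


def read_edgelist(path) -> dict[tuple[int, int], int]:
    """Parse a TSV edge list back into an edge→weight map (round-trip helper)."""
    edges: dict[tuple[int, int], int] = {}
    with open(os.fspath(path), "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            u, v, w = line.split("\t")
            edges[(int(u), int(v))] = int(w)
    return edges
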