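"""Readers and writers for the external formats the toolkit touches.

Internal coordinates are uniformly 0-based, half-open.  Wiggle's 1-based
convention is converted at this boundary and nowhere else; BED is already
0-based half-open.  Tracks carry an explicit validity mask -- missing or
invalid positions are masked, never silent NaNs.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

TRACK_DIALECTS = ("wiggle", "bedgraph", "tsv")
_FLOAT_FMT = "%.12g"


@dataclass
class GenomeTrack:
    """Per-sequence float arrays with a validity mask (0-based positions)."""

    values: dict[str, np.ndarray] = field(default_factory=dict)
    mask: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, name: str, values: np.ndarray,
            mask: np.ndarray | None = None) -> None:
        values = np.asarray(values, dtype=float)
        if mask is None:
            mask = np.isfinite(values)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError(f"{name}: mask shape {mask.shape} != values "
                             f"shape {values.shape}")
        if np.isnan(values[mask]).any():
            raise ValueError(f"{name}: unmasked NaN values")
        self.values[name] = values
        self.mask[name] = mask

    def sequences(self) -> list[str]:
        return list(self.values)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) multi-record FASTA; sequences uppercased."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path,
                width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Track I/O
# ---------------------------------------------------------------------------


def _iter_valid_runs(mask: np.ndarray) -> Iterator[tuple[int, int]]:
    """(start, end) half-open runs of True."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    for s, e in zip(starts, ends):
        yield int(idx[s]), int(idx[e]) + 1


def write_track(track: GenomeTrack, path: str | Path,
                dialect: str = "bedgraph") -> None:
    """Write a track; invalid positions are simply omitted from the file."""
    if dialect not in TRACK_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; use one of {TRACK_DIALECTS}")
    with _open_text(path, "wt") as handle:
        for name in track.sequences():
            vals, mask = track.values[name], track.mask[name]
            if dialect == "wiggle":
                for lo, hi in _iter_valid_runs(mask):
                    # wiggle fixedStep is 1-based: internal 0 -> start=1
                    handle.write(f"fixedStep chrom={name} start={lo + 1} step=1\n")
                    for v in vals[lo:hi]:
                        handle.write((_FLOAT_FMT % v) + "\n")
            elif dialect == "bedgraph":
                for lo, hi in _iter_valid_runs(mask):
                    for pos in range(lo, hi):
                        handle.write(f"{name}\t{pos}\t{pos + 1}\t"
                                     + (_FLOAT_FMT % vals[pos]) + "\n")
            else:  # tsv
                for lo, hi in _iter_valid_runs(mask):
                    for pos in range(lo, hi):
                        handle.write(f"{name}\t{pos}\t"
                                     + (_FLOAT_FMT % vals[pos]) + "\n")


def read_track(path: str | Path, dialect: str | None = None,
               lengths: dict[str, int] | None = None) -> GenomeTrack:
    """Read a wiggle (fixed/variable step), bedGraph, or positional TSV track.

    ``lengths`` fixes array sizes per sequence; otherwise arrays are sized to
    the largest observed coordinate.  Positions never written are masked out.
    Coordinates beyond a declared length raise an error naming the record.
    """
    path = Path(path)
    if dialect is None:
        dialect = {".wig": "wiggle", ".bedgraph": "bedgraph",
                   ".bdg": "bedgraph", ".tsv": "tsv"}.get(
            path.suffix if path.suffix != ".gz" else Path(path.stem).suffix,
            "bedgraph")
    entries: dict[str, list[tuple[int, float]]] = {}

    def put(name: str, pos: int, value: float) -> None:
        if lengths is not None and name in lengths and pos >= lengths[name]:
            raise ValueError(
                f"{path}: position {pos} beyond length {lengths[name]} "
                f"of record {name!r}"
            )
        entries.setdefault(name, []).append((pos, value))

    with _open_text(path) as handle:
        if dialect == "wiggle":
            chrom, start, step, span, variable = None, 0, 1, 1, False
            cursor = 0
            for line in handle:
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(f.split("=") for f in line.split()[1:])
                    chrom = kv["chrom"]
                    start = int(kv["start"]) - 1  # to 0-based
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", 1))
                    variable, cursor = False, 0
                elif line.startswith("variableStep"):
                    kv = dict(f.split("=") for f in line.split()[1:])
                    chrom = kv["chrom"]
                    span = int(kv.get("span", 1))
                    variable = True
                else:
                    if chrom is None:
                        raise ValueError(f"{path}: data before any step declaration")
                    if variable:
                        p, v = line.split()
                        base = int(p) - 1
                    else:
                        base = start + cursor * step
                        v = line
                        cursor += 1
                    for off in range(span):
                        put(chrom, base + off, float(v))
        elif dialect == "bedgraph":
            for lineno, line in enumerate(handle, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                chrom, s, e, v = line.split()[:4]
                for pos in range(int(s), int(e)):
                    put(chrom, pos, float(v))
        elif dialect == "tsv":
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, p, v = line.split()[:3]
                put(chrom, int(p), float(v))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")

    track = GenomeTrack()
    for name, pairs in entries.items():
        size = (lengths or {}).get(name, max(p for p, _ in pairs) + 1)
        values = np.full(size, np.nan)
        mask = np.zeros(size, dtype=bool)
        for pos, val in pairs:
            values[pos] = val
            mask[pos] = True
        track.add(name, values, mask)
    return track


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ as a DataFrame (chrom, start, end, name, score); 0-based half-open."""
    rows = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty interval {start}..{end}")
            name = fields[3] if len(fields) > 3 else ""
            score = float(fields[4]) if len(fields) > 4 else float("nan")
            rows.append((chrom, start, end, name, score))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])


def write_bed(frame: pd.DataFrame, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for _, row in frame.iterrows():
            fields = [str(row["chrom"]), str(int(row["start"])),
                      str(int(row["end"]))]
            if "name" in row and str(row["name"]):
                fields.append(str(row["name"]))
                if "score" in row and np.isfinite(row["score"]):
                    fields.append(_FLOAT_FMT % row["score"])
            handle.write("\t".join(fields) + "\n")
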