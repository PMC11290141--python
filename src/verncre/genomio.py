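"""Readers and writers for the flat-file formats the pipeline consumes.

FASTA, GFF3, BED, bedGraph, TSV count matrices and JASPAR PWM text.
Writers emit deterministic (chrom, start) ordering; readers report
malformed lines with their line number.  Per-base coverage ("tracks")
are dicts mapping chromosome name to a numpy array.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, Interval, sort_intervals

log = logging.getLogger(__name__)

Track = dict[str, np.ndarray]


class ParseError(ValueError):
    """Malformed input file; message carries file and line number."""


def _fail(path, lineno: int, msg: str):
    raise ParseError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                if name is None:
                    _fail(path, lineno, "sequence before header")
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(path, seqs: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ------------------------------------------------------------------------ BED

def read_bed(path) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                _fail(path, lineno, "BED needs >= 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            if start < 0 or end <= start:
                _fail(path, lineno, f"invalid span {start}-{end}")
            name = f[3] if len(f) > 3 else "."
            try:
                score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            except ValueError:
                _fail(path, lineno, "non-numeric score")
            strand = f[5] if len(f) > 5 else "."
            out.append(Interval(f[0], start, end, name, score, strand))
    return out


def write_bed(path, intervals: Iterable[Interval]) -> None:
    with open(path, "w") as fh:
        for iv in sort_intervals(intervals):
            score = int(round(iv.score)) if float(iv.score).is_integer() else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


# ------------------------------------------------------------------- bedGraph

def read_bedgraph(path, chrom_sizes: Mapping[str, int]) -> Track:
    """Read a bedGraph into per-base arrays; overlapping intervals are an error."""
    track: Track = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_sizes.items()}
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                _fail(path, lineno, "bedGraph needs 4 columns")
            chrom = f[0]
            if chrom not in track:
                _fail(path, lineno, f"unknown chromosome {chrom!r}")
            try:
                start, end, value = int(f[1]), int(f[2]), float(f[3])
            except ValueError:
                _fail(path, lineno, "bad coordinates or value")
            if end > len(track[chrom]) or start < 0 or end <= start:
                _fail(path, lineno, "coordinates out of bounds")
            if start < last_end.get(chrom, 0):
                _fail(path, lineno, "overlapping or unsorted bedGraph intervals")
            last_end[chrom] = end
            track[chrom][start:end] = value
    return track


def write_bedgraph(path, track: Track) -> None:
    """Run-length encode per-base arrays; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            arr = np.asarray(track[chrom])
            if arr.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    vtxt = f"{int(v)}" if float(v).is_integer() else f"{v:.6g}"
                    fh.write(f"{chrom}\t{s}\t{e}\t{vtxt}\n")


# ----------------------------------------------------------------------- GFF3

def read_gff3(path) -> list[GeneModel]:
    """Read gene features; 1-based inclusive converted to 0-based half-open."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                _fail(path, lineno, "GFF3 needs 9 columns")
            if f[2] != "gene":
                continue
            try:
                start1, end1 = int(f[3]), int(f[4])
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            if start1 < 1 or end1 < start1:
                _fail(path, lineno, "invalid 1-based span")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID")
            if gid is None:
                _fail(path, lineno, "gene without ID attribute")
            if f[6] not in {"+", "-"}:
                _fail(path, lineno, f"gene {gid} without strand")
            genes.append(
                GeneModel(
                    gene_id=gid,
                    interval=Interval(f[0], start1 - 1, end1, name=gid, strand=f[6]),
                    triad_id=attrs.get("triad_id"),
                )
            )
    return genes


def write_gff3(path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.interval.start)):
            attrs = f"ID={g.gene_id}"
            if g.triad_id:
                attrs += f";triad_id={g.triad_id}"
            fh.write(
                f"{g.chrom}\tverncre\tgene\t{g.interval.start + 1}\t"
                f"{g.interval.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------- TSV tables

def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative counts")
    return df


def write_counts_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t")


def read_triad_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"triad_id", "gene_A", "gene_B", "gene_D"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: triad table needs columns {sorted(required)}")
    return df


# ------------------------------------------------------------------- PWM text

def read_jaspar(path) -> list:
    """Parse JASPAR-format PWMs via Bio.motifs."""
    from Bio import motifs

    with open(path) as fh:
        return list(motifs.parse(fh, "jaspar"))


def write_jaspar(path, pwms: Sequence) -> None:
    from Bio import motifs

    with open(path, "w") as fh:
        fh.write(motifs.write(pwms, "jaspar"))


# -------------------------------------------------------------- track algebra

def window_counts(track: Track, intervals: Sequence[Interval]) -> np.ndarray:
    """Exact per-base sum of the track within each [start, end)."""
    out = np.zeros(len(intervals), dtype=np.float64)
    for i, iv in enumerate(intervals):
        arr = track.get(iv.chrom)
        if arr is None:
            log.warning("window_counts: chromosome %s not in track", iv.chrom)
            continue
        s, e = iv.start, min(iv.end, arr.size)
        if iv.end > arr.size:
            log.warning(
                "window_counts: %s:%d-%d beyond track extent %d; zero-filled",
                iv.chrom, iv.start, iv.end, arr.size,
            )
        if e > s:
            out[i] = float(arr[s:e].sum())
    return out


def track_total(track: Track) -> float:
    return float(sum(arr.sum() for arr in track.values()))
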