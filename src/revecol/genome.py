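"""Genome-level descriptive features: size, GC, coding density, gene overlap.

Coordinates are 1-based inclusive throughout (GFF convention).  Coding
density merges both strands before taking the interval union, since
covered-bases is a per-base property; the overlapping-gene ratio is the
fraction of genes sharing at least one base with another gene on the same
contig, strand-agnostic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from Bio import SeqIO

from .synthetic import AnnotationTable

__all__ = [
    "genome_size_gc", "coding_density", "overlap_ratio",
    "size_cds_regression", "GenomeFeatureRow", "genome_features",
    "read_contigs", "read_annotations",
]


def read_contigs(path: str | os.PathLike) -> list[str]:
    """Read contig sequences from a nucleotide FASTA."""
    seqs = [str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")]
    if not seqs:
        raise ValueError(f"no contigs in {path}")
    return seqs


def genome_size_gc(contigs: list[str]) -> tuple[int, float]:
    """Total genome size (bp) and GC fraction over unambiguous bases."""
    if not contigs:
        raise ValueError("empty contig set")
    size = sum(len(c) for c in contigs)
    gc = at = 0
    for contig in contigs:
        up = contig.upper()
        gc += up.count("G") + up.count("C")
        at += up.count("A") + up.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases; GC undefined")
    return size, gc / (gc + at)


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    """Total covered length of 1-based inclusive intervals after union."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start <= cur_end + 1:  # overlapping or abutting
            cur_end = max(cur_end, end)
        else:
            total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    total += cur_end - cur_start + 1
    return total


def coding_density(annotations: AnnotationTable, genome_size: int) -> float:
    """Union length of CDS intervals (strands merged) over genome size."""
    if len(annotations) == 0:
        raise ValueError("empty annotation table")
    max_end = max(end for _, _, end, _ in annotations.rows)
    if genome_size < max_end:
        raise ValueError(f"interval end {max_end} beyond genome size {genome_size}")
    covered = 0
    for seq_id in {r[0] for r in annotations.rows}:
        ivals = [(s, e) for sid, s, e, _ in annotations.rows if sid == seq_id]
        covered += _merged_length(ivals)
    return covered / genome_size


def overlap_ratio(annotations: AnnotationTable) -> float:
    """Fraction of genes overlapping ≥1 bp with another gene (same contig)."""
    if len(annotations) == 0:
        raise ValueError("empty annotation table")
    n_overlapping = 0
    by_contig: dict[str, list[tuple[int, int, int]]] = {}
    for idx, (seq_id, start, end, _) in enumerate(annotations.rows):
        by_contig.setdefault(seq_id, []).append((start, end, idx))
    flagged: set[int] = set()
    for ivals in by_contig.values():
        ivals.sort()
        active: list[tuple[int, int]] = []  # (end, idx) heap-free sweep
        for start, end, idx in ivals:
            active = [(e, i) for e, i in active if e >= start]
            for _, other in active:
                flagged.add(other)
                flagged.add(idx)
            active.append((end, idx))
    n_overlapping = len(flagged)
    return n_overlapping / len(annotations)


def size_cds_regression(genome_sizes, n_cds) -> tuple[float, float, float, float]:
    """OLS of CDS count on genome size: (slope, intercept, adj. R², p).

    ``adjusted R² = 1 − (1−R²)(n−1)/(n−2)``; p is the slope's F-test
    p-value.
    """
    x = np.asarray(list(genome_sizes), dtype=float)
    y = np.asarray(list(n_cds), dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 genomes for the regression")
    if np.allclose(x, x[0]):
        raise ValueError("constant genome size; regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    return float(slope), float(intercept), float(model.rsquared_adj), float(model.f_pvalue)


@dataclass
class GenomeFeatureRow:
    genome_id: str
    genome_size: int
    gc: float
    n_cds: int
    coding_density: float
    overlap_ratio: float


def genome_features(genome_id: str, contigs: list[str],
                    annotations: AnnotationTable) -> GenomeFeatureRow:
    size, gc = genome_size_gc(contigs)
    return GenomeFeatureRow(
        genome_id=genome_id,
        genome_size=size,
        gc=gc,
        n_cds=len(annotations),
        coding_density=coding_density(annotations, size),
        overlap_ratio=overlap_ratio(annotations),
    )


def read_annotations(path: str | os.PathLike) -> AnnotationTable:
    """Read CDS intervals from GFF3 (type == CDS) or a 4-column TSV.

    The TSV form has columns seq_id, start, end, strand (1-based
    inclusive), with or without a header.
    """
    path = os.fspath(path)
    rows: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith("##gff") or first.count("\t") >= 7:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 8 or parts[2] != "CDS":
                    continue
                rows.append((parts[0], int(parts[3]), int(parts[4]), parts[6]))
        else:
            df = pd.read_csv(path, sep="\t", header=None if "\t" in first and
                             first.split("\t")[1].strip().isdigit() else 0)
            df.columns = ["seq_id", "start", "end", "strand"][: df.shape[1]]
            for rec in df.itertuples(index=False):
                rows.append((str(rec.seq_id), int(rec.start), int(rec.end),
                             str(rec.strand)))
    return AnnotationTable(rows=rows)


def write_annotations_tsv(annotations: AnnotationTable, path: str | os.PathLike) -> None:
    df = pd.DataFrame(annotations.rows, columns=["seq_id", "start", "end", "strand"])
    df.to_csv(path, sep="\t", index=False)
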