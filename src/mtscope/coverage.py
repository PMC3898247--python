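"""Per-base depth of coverage (DOC) from alignments.

Depth at a reference position counts the reads whose alignment consumes that
base through a match/mismatch CIGAR operation; deleted reference bases and
reference skips contribute nothing.  This is a stated convention of the
package (alignment packages differ on it).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pysam

from .genome import AnnotationSet, CircularGenome

# CIGAR ops that consume the reference AND count toward depth (M, =, X)
_DEPTH_OPS = frozenset({0, 7, 8})
# CIGAR ops that consume the reference but not depth (D, N)
_REF_ONLY_OPS = frozenset({2, 3})


@dataclass
class CoverageTrack:
    """Genome-length vector of per-base read depth."""

    genome_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D array")
        if (self.depth < 0).any():
            raise ValueError("depth entries must be non-negative")

    @property
    def length(self) -> int:
        return int(self.depth.size)


def _check_header(af: pysam.AlignmentFile, genome: CircularGenome) -> None:
    try:
        idx = af.references.index(genome.id)
    except ValueError:
        raise ValueError(
            f"alignment file does not contain reference {genome.id!r}"
        ) from None
    if af.lengths[idx] != genome.length:
        raise ValueError(
            f"reference length mismatch for {genome.id!r}: header says "
            f"{af.lengths[idx]}, genome is {genome.length} bp"
        )


def _add_interval(depth: np.ndarray, start: int, end: int) -> None:
    """Add 1 over [start, end), wrapping across the origin if needed."""
    L = depth.size
    span = end - start
    start %= L
    if start + span <= L:
        depth[start : start + span] += 1
    else:
        depth[start:L] += 1
        depth[0 : start + span - L] += 1


def compute_doc(
    alignments: str | Path,
    genome: CircularGenome,
    min_mapq: int | None = None,
    drop_duplicates: bool = False,
) -> CoverageTrack:
    """Depth-of-coverage track from a SAM/BAM file.

    Unmapped records are skipped.  Origin-spanning reads emitted by the
    simulator as soft-clipped primary + supplementary pairs contribute depth
    through the matched portion of each line, so each sequenced base is
    counted exactly once.  Mapping-quality and duplicate filters are off by
    default and available as options.
    """
    depth = np.zeros(genome.length, dtype=np.int64)
    with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
        _check_header(af, genome)
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.reference_name != genome.id:
                continue
            if min_mapq is not None and rec.mapping_quality < min_mapq:
                continue
            if drop_duplicates and rec.is_duplicate:
                continue
            if rec.cigartuples is None:
                continue
            pos = rec.reference_start
            for op, ln in rec.cigartuples:
                if op in _DEPTH_OPS:
                    _add_interval(depth, pos, pos + ln)
                    pos += ln
                elif op in _REF_ONLY_OPS:
                    pos += ln
    return CoverageTrack(genome_id=genome.id, depth=depth)


def doc_summary(
    track: CoverageTrack, thresholds: Iterable[int]
) -> dict[int, float]:
    """Fraction of the genome with depth strictly below each threshold.

    Mirrors genome-wide summaries of the form "57.2% of positions have a
    DOC below 150": the comparison is strict (<).
    """
    out: dict[int, float] = {}
    for t in thresholds:
        t = int(t)
        if t <= 0:
            raise ValueError("thresholds must be positive")
        out[t] = float(np.count_nonzero(track.depth < t)) / track.length
    return out


def feature_peak_doc(
    track: CoverageTrack, ann: AnnotationSet
) -> dict[str, int]:
    """Maximum depth over each feature's (modulo-length) span."""
    peaks: dict[str, int] = {}
    for f in ann.features:
        m = 0
        for s, e in f.arcs(ann.genome_length):
            if e > s:
                m = max(m, int(track.depth[s:e].max(initial=0)))
        peaks[f.feature_id] = m
    return peaks


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Run-length-encoded bedGraph of the depth track (0-based half-open)."""
    d = track.depth
    change = np.flatnonzero(np.diff(d)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [d.size]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{track.genome_id}\t{s}\t{e}\t{int(d[s])}\n")
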