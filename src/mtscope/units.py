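"""Transcript-unit segmentation and mono-/polycistronic classification.

A plant mitogenome is transcribed as discrete units: stretches of moderate
to high read depth separated by low-coverage intergenic spans.  Segmentation
is a plateau finder on the depth track: maximal runs at or above a depth
threshold, with nearby runs merged (mid-transcript coverage dips are
technical artifacts, not unit boundaries) and short runs discarded.  Units
are then classified by how many coding segments (exons, single-segment CDS,
ORFs) they contain: one = monocistronic, two or more = polycistronic (even
when the segments are exons of a single gene), none = non-coding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coverage import CoverageTrack, feature_peak_doc
from .genome import AnnotationSet, CODING_FTYPES, Feature

MONO = "mono"
POLY = "poly"
NON_CODING = "non_coding"


@dataclass
class TranscriptUnit:
    """A transcribed region with its member coding segments.

    ``end > genome_length`` encodes an origin-spanning unit on a circular
    genome.  ``members`` are coding-segment feature_ids ordered along the
    genome from the unit start.
    """

    unit_id: str
    strand: str                      # '+', '-' or 'ambiguous'
    start: int
    end: int
    members: list[str] = field(default_factory=list)

    @property
    def cistronic_class(self) -> str:
        return classify_cistronic(self)


def classify_cistronic(unit: TranscriptUnit) -> str:
    """mono (exactly one coding segment) / poly (>= 2) / non_coding (0)."""
    n = len(unit.members)
    if n == 0:
        return NON_CODING
    return MONO if n == 1 else POLY


def segment(
    track: CoverageTrack,
    threshold: int = 200,
    merge_gap: int = 500,
    min_len: int = 200,
    circular: bool = True,
) -> list[tuple[int, int]]:
    """Find transcribed intervals on the depth track.

    Returns disjoint, sorted 0-based half-open intervals; at most one may
    wrap the origin (``end > length``).  Runs with depth >= ``threshold``
    separated by gaps shorter than ``merge_gap`` are merged; merged runs
    shorter than ``min_len`` are dropped.
    """
    if threshold <= 0 or merge_gap <= 0 or min_len <= 0:
        raise ValueError("segmentation parameters must be positive")
    L = track.length
    above = track.depth >= threshold
    if not above.any():
        return []
    if above.all():
        return [(0, L)]

    # maximal runs of True
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    runs = list(zip(starts.tolist(), ends.tolist()))

    # circular join of the terminal runs across the origin
    wrapped = False
    if circular and above[0] and above[-1]:
        (s0, e0), (sl, el) = runs[0], runs[-1]
        runs = runs[1:-1]
        runs.append((sl, L + e0))
        wrapped = True

    # merge runs separated by short gaps (runs are sorted by start;
    # a wrapped run sits last and its end exceeds L)
    merged: list[tuple[int, int]] = []
    for s, e in sorted(runs):
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    # merge across the origin: gap between the last run's end and the first
    # run's start, measured around the circle
    if circular and len(merged) >= 2:
        s0, e0 = merged[0]
        sl, el = merged[-1]
        if el <= L and (s0 + L) - el < merge_gap:
            merged = merged[1:-1] + [(sl, L + e0)]
        elif el > L and s0 - (el - L) < merge_gap:
            merged = merged[1:-1] + [(sl, L + e0)]

    out = [(s, e) for s, e in sorted(merged) if e - s >= min_len]
    return out


def assign_members_and_strand(
    intervals: Sequence[tuple[int, int]],
    ann: AnnotationSet,
) -> list[TranscriptUnit]:
    """Attach coding segments to each interval and infer the unit strand.

    Strand comes from the annotation (the library is unstranded): the common
    strand of the member segments, or ``ambiguous`` (with a warning) when
    members disagree or there are none.
    """
    L = ann.genome_length
    units: list[TranscriptUnit] = []
    for i, (s, e) in enumerate(sorted(intervals), start=1):
        members = ann.overlapping(s, e, ftypes=CODING_FTYPES)
        # order along the unit starting from its 5'-most genomic offset
        members.sort(key=lambda f: ((f.start - s) % L, f.feature_id))
        strands = {f.strand for f in members}
        if len(strands) == 1:
            strand = strands.pop()
        else:
            strand = "ambiguous"
            if len(strands) > 1:
                warnings.warn(
                    f"unit {i} spans features on both strands", stacklevel=2
                )
        units.append(
            TranscriptUnit(
                unit_id=f"unit_{i:03d}",
                strand=strand,
                start=s,
                end=e,
                members=[f.feature_id for f in members],
            )
        )
    return units


def select_candidate_orfs(
    track: CoverageTrack,
    ann: AnnotationSet,
    doc_threshold: int = 200,
) -> list[Feature]:
    """ORFs worth following up: transcribed but not explained by known genes.

    Selects annotated ORFs whose peak depth strictly exceeds ``doc_threshold``
    and which do not overlap any identifiable protein-coding feature
    (gene_cds or exon), ordered by start.
    """
    peaks = feature_peak_doc(track, ann)
    coding = [f for f in ann.features if f.ftype in ("gene_cds", "exon")]
    out: list[Feature] = []
    for orf in ann.features:
        if orf.ftype != "orf":
            continue
        if peaks[orf.feature_id] <= doc_threshold:
            continue
        if any(
            orf.overlaps(c.start, c.end, ann.genome_length) for c in coding
        ):
            continue
        out.append(orf)
    out.sort(key=lambda f: f.start)
    return out


def units_to_bed(
    units: Sequence[TranscriptUnit],
    track: CoverageTrack,
    genome_id: str,
) -> str:
    """BED6 text: name is the '::'-joined member list, score is peak depth."""
    L = track.length
    lines = []
    for u in units:
        name = "::".join(u.members) if u.members else "non_coding"
        arcs = (
            [(u.start, u.end)]
            if u.end <= L
            else [(u.start, L), (0, u.end - L)]
        )
        peak = max(int(track.depth[s:e].max(initial=0)) for s, e in arcs)
        strand = u.strand if u.strand in "+-" else "."
        lines.append(
            f"{genome_id}\t{u.start}\t{min(u.end, L)}\t{name}\t{peak}\t{strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
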