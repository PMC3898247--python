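"""Pileup construction and C->U RNA edit-site calling.

Plant mitochondrial editing converts cytidine to uridine on the transcript.
Against an unstranded RNA-seq library this appears as C-reference/T-read
mismatch columns (transcript on the forward genome strand) or G/A columns
(reverse strand).  A candidate column is promoted to an edit call with hard
filters, not a statistical test:

* depth strictly greater than ``min_doc`` (default 200),
* edit fraction strictly below 100% minus ``snp_tolerance`` — a position
  where essentially every read mismatches the reference is a genomic SNP of
  the sequenced plants, not an edit,
* at least ``min_edited_reads`` mismatching reads and an edit fraction of at
  least ``min_fraction`` (floor defaults guarding against sequencing error).

The edit fraction is a two-state quantity: edited reads over edited plus
reference-matching reads; third-base observations are excluded from the
denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .coverage import _DEPTH_OPS, _REF_ONLY_OPS, _check_header
from .genome import CircularGenome

CLASS_EDIT = "edit"
CLASS_SNP = "snp"
CLASS_SUBTHRESHOLD_DEPTH = "subthreshold_depth"
CLASS_SUBTHRESHOLD_FRACTION = "subthreshold_fraction"

ORIENT_FORWARD = "forward"   # C->T on the genome forward strand
ORIENT_REVERSE = "reverse"   # G->A on the genome forward strand

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass(frozen=True)
class PileupColumn:
    """Per-position base counts in forward-genome orientation."""

    pos: int
    ref_base: str
    depth: int
    counts: Mapping[str, int]


@dataclass(frozen=True)
class EditSite:
    pos: int
    orientation: str
    depth: int
    edited_count: int
    edit_fraction: float
    call_class: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.edit_fraction <= 1.0:
            raise ValueError("edit_fraction outside [0, 1]")
        if not 0 <= self.edited_count <= self.depth:
            raise ValueError("edited_count outside [0, depth]")


class Pileup:
    """Dense per-base A/C/G/T counts plus read depth for one genome.

    ``depth[p]`` counts reads consuming base ``p`` (same convention as the
    coverage track); ``counts[p]`` may sum to less than depth because
    ambiguous read bases are dropped.
    """

    def __init__(self, genome: CircularGenome):
        self.genome_id = genome.id
        self.ref = np.frombuffer(genome.sequence.encode(), dtype="S1")
        L = genome.length
        self.counts = np.zeros((L, 4), dtype=np.int64)
        self.depth = np.zeros(L, dtype=np.int64)
        self.skipped_reads = 0

    @property
    def length(self) -> int:
        return int(self.depth.size)

    def column(self, pos: int) -> PileupColumn:
        return PileupColumn(
            pos=pos,
            ref_base=self.ref[pos].decode(),
            depth=int(self.depth[pos]),
            counts={b: int(self.counts[pos, i]) for b, i in _BASE_INDEX.items()},
        )

    def columns(self) -> Iterator[PileupColumn]:
        """Columns for every position with nonzero depth."""
        for pos in np.flatnonzero(self.depth):
            yield self.column(int(pos))


def build_pileup(alignments: str | Path, genome: CircularGenome) -> Pileup:
    """Walk every aligned read's CIGAR and accumulate base counts.

    Reads without a CIGAR are skipped and counted in
    :attr:`Pileup.skipped_reads` (a warning is emitted at the end if any).
    """
    pile = Pileup(genome)
    L = genome.length
    base_code = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        base_code[ord(b)] = i
        base_code[ord(b.lower())] = i

    with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
        _check_header(af, genome)
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.reference_name != genome.id:
                continue
            if rec.cigartuples is None or rec.query_sequence is None:
                pile.skipped_reads += 1
                continue
            seq = np.frombuffer(rec.query_sequence.encode(), dtype=np.uint8)
            rpos = rec.reference_start
            qpos = 0
            for op, ln in rec.cigartuples:
                if op in _DEPTH_OPS:
                    idx = (rpos + np.arange(ln)) % L
                    pile.depth[idx] += 1
                    codes = base_code[seq[qpos : qpos + ln]]
                    ok = codes >= 0
                    np.add.at(pile.counts, (idx[ok], codes[ok]), 1)
                    rpos += ln
                    qpos += ln
                elif op in _REF_ONLY_OPS:
                    rpos += ln
                elif op in (1, 4):  # I, S consume the query only
                    qpos += ln
    if pile.skipped_reads:
        warnings.warn(
            f"{pile.skipped_reads} reads without CIGAR/sequence skipped",
            stacklevel=2,
        )
    return pile


def call_sites(
    pileup: Pileup,
    min_doc: int = 200,
    min_edited_reads: int = 4,
    min_fraction: float = 0.02,
    snp_tolerance: float = 0.0,
) -> list[EditSite]:
    """Classify every C/T or G/A mismatch column.

    Returns all candidate columns with their class (``edit``, ``snp``,
    ``subthreshold_depth`` or ``subthreshold_fraction``); callers keep the
    ``edit`` class.  Non C->U mismatch patterns never produce sites.
    """
    sites: list[EditSite] = []
    for ref_char, edited_idx, ref_idx, orient in (
        (b"C", _BASE_INDEX["T"], _BASE_INDEX["C"], ORIENT_FORWARD),
        (b"G", _BASE_INDEX["A"], _BASE_INDEX["G"], ORIENT_REVERSE),
    ):
        is_ref = pileup.ref == ref_char
        edited = pileup.counts[:, edited_idx]
        matching = pileup.counts[:, ref_idx]
        cand = np.flatnonzero(is_ref & (edited > 0))
        for pos in cand:
            pos = int(pos)
            e = int(edited[pos])
            m = int(matching[pos])
            depth = int(pileup.depth[pos])
            frac = e / (e + m)
            if frac >= 1.0 - snp_tolerance:
                cls = CLASS_SNP
            elif depth <= min_doc:
                cls = CLASS_SUBTHRESHOLD_DEPTH
            elif e < min_edited_reads or frac < min_fraction:
                cls = CLASS_SUBTHRESHOLD_FRACTION
            else:
                cls = CLASS_EDIT
            sites.append(
                EditSite(
                    pos=pos,
                    orientation=orient,
                    depth=depth,
                    edited_count=e,
                    edit_fraction=frac,
                    call_class=cls,
                )
            )
    sites.sort(key=lambda s: s.pos)
    return sites


REASON_LOW_DEPTH = "low_depth"
REASON_LOW_FRACTION = "low_fraction"
REASON_LOW_COUNT = "low_count"
REASON_NO_MISMATCH = "no_mismatch_observed"
REASON_INVALID_REF = "invalid_reference"
REASON_CALLED_SNP = "called_snp"


def diagnose_missed(
    called: Sequence[EditSite],
    reference_sites: Iterable[int],
    pileup: Pileup,
    min_doc: int = 200,
    min_edited_reads: int = 4,
    min_fraction: float = 0.02,
    snp_tolerance: float = 0.0,
) -> dict[int, str]:
    """Why did each previously-identified site (0-based positions) not call?

    Reference-catalogue sites absent from the ``edit``-class calls get one
    reason each; priority no_mismatch > low_depth > low_count > low_fraction.
    Sites whose reference base is neither C nor G are flagged
    ``invalid_reference``; sites swallowed by the SNP rule are labelled
    ``called_snp``.
    """
    called_pos = {s.pos for s in called if s.call_class == CLASS_EDIT}
    reasons: dict[int, str] = {}
    for pos in reference_sites:
        if pos in called_pos:
            continue
        ref = pileup.ref[pos : pos + 1].tobytes()
        if ref == b"C":
            e = int(pileup.counts[pos, _BASE_INDEX["T"]])
            m = int(pileup.counts[pos, _BASE_INDEX["C"]])
        elif ref == b"G":
            e = int(pileup.counts[pos, _BASE_INDEX["A"]])
            m = int(pileup.counts[pos, _BASE_INDEX["G"]])
        else:
            reasons[pos] = REASON_INVALID_REF
            continue
        depth = int(pileup.depth[pos])
        if e == 0:
            reasons[pos] = REASON_NO_MISMATCH
        elif e + m > 0 and e / (e + m) >= 1.0 - snp_tolerance:
            reasons[pos] = REASON_CALLED_SNP
        elif depth <= min_doc:
            reasons[pos] = REASON_LOW_DEPTH
        elif e < min_edited_reads:
            reasons[pos] = REASON_LOW_COUNT
        else:
            reasons[pos] = REASON_LOW_FRACTION
    return reasons


def sites_to_frame(sites: Sequence[EditSite]) -> pd.DataFrame:
    """Tabular view with 1-based positions (report convention)."""
    return pd.DataFrame(
        {
            "position": [s.pos + 1 for s in sites],
            "orientation": [s.orientation for s in sites],
            "depth": [s.depth for s in sites],
            "edited_count": [s.edited_count for s in sites],
            "edit_fraction": [s.edit_fraction for s in sites],
            "call_class": [s.call_class for s in sites],
        }
    )
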