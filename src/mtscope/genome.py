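"""Circular reference genome and feature annotation.

Plant mitochondrial chromosomes are (conceptually) circular molecules of a
few hundred kb.  Everything downstream — coverage, transcript-unit
segmentation, edit-site categorization — needs coordinate arithmetic that is
aware of the origin, so this module owns the single internal convention:

* coordinates are 0-based half-open;
* a feature or interval that spans the origin is represented with
  ``end > genome.length`` and interpreted modulo the genome length;
* file I/O uses each format's native convention (GFF3 is 1-based inclusive,
  with origin-spanning features written as two segments sharing an ID).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from intervaltree import IntervalTree

VALID_BASES = frozenset("ACGTN")

#: internal feature types
FEATURE_TYPES = frozenset({"gene_cds", "exon", "orf", "tRNA", "rRNA"})

#: feature types that count as coding segments for cistronic classification
CODING_FTYPES = frozenset({"gene_cds", "exon", "orf"})

# GFF3 column-3 type <-> internal ftype
_GFF_TO_FTYPE = {
    "CDS": "gene_cds",
    "exon": "exon",
    "ORF": "orf",
    "open_reading_frame": "orf",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
}
_FTYPE_TO_GFF = {
    "gene_cds": "CDS",
    "exon": "exon",
    "orf": "ORF",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
}


@dataclass(frozen=True)
class CircularGenome:
    """A single circular (by default) reference sequence."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence is empty")
        bad = next(
            (i for i, b in enumerate(self.sequence) if b not in VALID_BASES), None
        )
        if bad is not None:
            raise ValueError(
                f"non-nucleotide character {self.sequence[bad]!r} at position "
                f"{bad + 1} (1-based) in genome {self.id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def normalize(self, pos: int) -> int:
        """Map any offset onto [0, length)."""
        return pos % self.length

    def base(self, pos: int) -> str:
        return self.sequence[self.normalize(pos)]

    def fetch(self, start: int, end: int) -> str:
        """Subsequence for a possibly origin-spanning [start, end) interval."""
        L = self.length
        start = self.normalize(start)
        if end <= L or not self.circular:
            return self.sequence[start : min(end, L)]
        return self.sequence[start:] + self.sequence[: end - L]


@dataclass(frozen=True)
class Feature:
    """An annotated span on the genome (0-based half-open, strand mandatory).

    ``end > genome_length`` encodes an origin-spanning feature on a circular
    genome.  ``gene_id`` groups the exons of one gene.
    """

    feature_id: str
    ftype: str
    start: int
    end: int
    strand: str
    gene_id: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"feature {self.feature_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"feature {self.feature_id!r}: invalid span "
                f"[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def arcs(self, genome_length: int) -> list[tuple[int, int]]:
        """Linear [start, end) pieces after unwrapping around the origin."""
        if self.end <= genome_length:
            return [(self.start, self.end)]
        return [(self.start, genome_length), (0, self.end - genome_length)]

    def contains(self, pos: int, genome_length: int) -> bool:
        return any(s <= pos < e for s, e in self.arcs(genome_length))

    def overlaps(self, start: int, end: int, genome_length: int) -> bool:
        """Overlap with a possibly wrapping query interval."""
        q = [(start, end)] if end <= genome_length else [
            (start, genome_length),
            (0, end - genome_length),
        ]
        return any(
            fs < qe and qs < fe for fs, fe in self.arcs(genome_length) for qs, qe in q
        )


@dataclass
class AnnotationSet:
    """All features of one genome, with indexed positional queries."""

    genome_id: str
    genome_length: int
    features: list[Feature] = field(default_factory=list)
    _tree: IntervalTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.feature_id in seen:
                raise ValueError(f"duplicate feature_id {f.feature_id!r}")
            seen.add(f.feature_id)
            if f.start >= self.genome_length:
                raise ValueError(
                    f"feature {f.feature_id!r} starts beyond genome length"
                )

    def _index(self) -> IntervalTree:
        if self._tree is None:
            tree = IntervalTree()
            for f in self.features:
                for s, e in f.arcs(self.genome_length):
                    tree[s:e] = f
            self._tree = tree
        return self._tree

    def features_at(
        self, pos: int, ftypes: Iterable[str] | None = None
    ) -> list[Feature]:
        """Features whose (modulo-length) span contains ``pos``.

        Deterministic order by (start, feature_id).
        """
        if not 0 <= pos < self.genome_length:
            raise ValueError(
                f"position {pos} out of range [0, {self.genome_length})"
            )
        hits = {iv.data.feature_id: iv.data for iv in self._index()[pos]}
        out = list(hits.values())
        if ftypes is not None:
            want = set(ftypes)
            out = [f for f in out if f.ftype in want]
        return sorted(out, key=lambda f: (f.start, f.feature_id))

    def overlapping(
        self, start: int, end: int, ftypes: Iterable[str] | None = None
    ) -> list[Feature]:
        """Features overlapping a possibly origin-spanning interval."""
        L = self.genome_length
        pieces = [(start % L, min(end, L))] if end <= L else [
            (start % L, L),
            (0, end - L),
        ]
        hits: dict[str, Feature] = {}
        for s, e in pieces:
            for iv in self._index()[s:e]:
                hits[iv.data.feature_id] = iv.data
        out = list(hits.values())
        if ftypes is not None:
            want = set(ftypes)
            out = [f for f in out if f.ftype in want]
        return sorted(out, key=lambda f: (f.start, f.feature_id))


def load_genome(path: str | Path) -> CircularGenome:
    """Read the first FASTA record as a circular genome.

    Lowercase bases are upper-cased; extra records trigger a warning; an empty
    file or non-nucleotide characters are hard errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path}: {len(records)} records found; using the first "
            f"({records[0].id!r})",
            stacklevel=2,
        )
    rec = records[0]
    return CircularGenome(id=rec.id, sequence=str(rec.seq).upper())


def load_annotation(path: str | Path, genome: CircularGenome) -> AnnotationSet:
    """Read a GFF3 file into an :class:`AnnotationSet`.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    An origin-spanning feature follows the two-segment convention: two rows
    sharing an ID, one ending at the genome terminus and one starting at
    base 1; they are re-joined into a single feature with ``end > length``.
    Rows with unrecognized types are skipped with a warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    L = genome.length
    groups: dict[str, list[gffutils.Feature]] = {}
    for gf in db.all_features():
        if gf.featuretype not in _GFF_TO_FTYPE:
            warnings.warn(
                f"skipping feature of unknown type {gf.featuretype!r}",
                stacklevel=2,
            )
            continue
        if gf.end < gf.start:
            raise ValueError(f"feature {gf.id!r}: end < start")
        fid = gf.attributes.get("ID", [gf.id])[0]
        groups.setdefault(fid, []).append(gf)

    features: list[Feature] = []
    for fid, segs in groups.items():
        if len(segs) == 1:
            gf = segs[0]
            start, end = gf.start - 1, gf.end
        elif len(segs) == 2 and genome.circular:
            # origin-spanning join: one segment ends at L, the other starts at 1
            segs = sorted(segs, key=lambda g: g.start)
            head, tail = segs[0], segs[1]
            if not (tail.end == L and head.start == 1):
                raise ValueError(
                    f"feature {fid!r}: two segments do not form an "
                    "origin-spanning join"
                )
            start, end = tail.start - 1, L + head.end
        else:
            raise ValueError(
                f"feature {fid!r}: {len(segs)} segments (only origin-spanning "
                "two-segment joins are supported)"
            )
        gf = segs[0]
        if gf.strand not in ("+", "-"):
            raise ValueError(f"feature {fid!r}: strand is required in GFF3 input")
        if end > L and not genome.circular:
            raise ValueError(
                f"feature {fid!r} exceeds the length of a linear genome"
            )
        attrs = segs[0].attributes
        features.append(
            Feature(
                feature_id=fid,
                ftype=_GFF_TO_FTYPE[gf.featuretype],
                start=start,
                end=end,
                strand=gf.strand,
                gene_id=attrs.get("gene_id", [fid])[0],
                label=attrs.get("label", [""])[0],
            )
        )
    features.sort(key=lambda f: (f.start, f.feature_id))
    return AnnotationSet(
        genome_id=genome.id, genome_length=L, features=features
    )


def write_gff3(
    ann: AnnotationSet, path: str | Path, source: str = "mtscope"
) -> None:
    """Write an annotation back to GFF3 (1-based inclusive coordinates).

    Origin-spanning features are emitted as two segments sharing an ID so
    that ``load_annotation`` round-trips to identical internal coordinates.
    """
    L = ann.genome_length
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {ann.genome_id} 1 {L}\n")
        for f in ann.features:
            attrs = f"ID={f.feature_id};gene_id={f.gene_id}"
            if f.label:
                attrs += f";label={f.label}"
            gtype = _FTYPE_TO_GFF[f.ftype]
            for s, e in f.arcs(L):
                fh.write(
                    "\t".join(
                        [
                            ann.genome_id,
                            source,
                            gtype,
                            str(s + 1),
                            str(e),
                            ".",
                            f.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def write_fasta(genome: CircularGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")
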