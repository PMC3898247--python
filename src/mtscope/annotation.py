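"""Categorize edit sites against features and transcript units.

Each called site gets exactly one category, by fixed precedence:

1. ``coding`` — inside a protein-coding feature (CDS, exon or ORF; sites
   inside rRNA genes are binned here too, with an ``rRNA`` subtype tag);
2. ``tRNA`` — inside a tRNA gene;
3. unit-relative classes for sites inside a transcribed unit but outside all
   of its coding members: upstream of the first member in the unit's
   transcription direction is ``utr5``, downstream of the last is ``utr3``,
   between members is ``intergenic_polycistronic``;
4. ``unlinked`` — outside every feature and every unit.

The categories partition the site set, so per-category counts always sum to
the total — the same arithmetic that lets a genome-wide screen report
"N in coding regions, N in tRNAs, N in UTRs, ..." as a complete breakdown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .editing import EditSite, ORIENT_FORWARD
from .genome import AnnotationSet
from .units import TranscriptUnit

CAT_CODING = "coding"
CAT_TRNA = "tRNA"
CAT_UTR5 = "utr5"
CAT_UTR3 = "utr3"
CAT_INTERGENIC_POLY = "intergenic_polycistronic"
CAT_UNLINKED = "unlinked"

CATEGORIES = (
    CAT_CODING,
    CAT_TRNA,
    CAT_UTR5,
    CAT_UTR3,
    CAT_INTERGENIC_POLY,
    CAT_UNLINKED,
)


@dataclass(frozen=True)
class AnnotatedSite:
    site: EditSite
    category: str
    host_feature: str | None = None
    host_unit: str | None = None
    novel: bool = True
    subtype: str = ""
    discordant_strand: bool = False


@dataclass
class PIESList:
    """Previously-identified edit sites (positions stored 0-based)."""

    positions: set[int]
    source: str = ""


def read_pies(path: str | Path, genome_length: int | None = None) -> PIESList:
    """Load a TSV of previously identified sites (1-based ``position``).

    Duplicate positions are deduplicated with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    col = "position" if "position" in df.columns else df.columns[0]
    raw = [int(p) - 1 for p in df[col]]
    positions = set(raw)
    if len(positions) < len(raw):
        warnings.warn(
            f"{len(raw) - len(positions)} duplicate positions in {path}",
            stacklevel=2,
        )
    if genome_length is not None:
        bad = [p for p in positions if not 0 <= p < genome_length]
        if bad:
            raise ValueError(f"PIES positions outside genome: {sorted(bad)[:5]}")
    return PIESList(positions=positions, source=str(path))


def _site_strand(site: EditSite) -> str:
    return "+" if site.orientation == ORIENT_FORWARD else "-"


def categorize(
    sites: Sequence[EditSite],
    ann: AnnotationSet,
    units: Sequence[TranscriptUnit],
    pies: PIESList | None = None,
) -> list[AnnotatedSite]:
    """Assign one category per site (precedence described in the module doc).

    A site hosted by a stranded feature or unit whose strand disagrees with
    the site's C->U orientation is kept but flagged ``discordant_strand``.
    Sites inside a transcribed unit that has no coding members cannot be
    oriented relative to a reading frame and are binned ``unlinked``.
    """
    L = ann.genome_length
    known = pies.positions if pies is not None else set()
    fmap = {f.feature_id: f for f in ann.features}
    out: list[AnnotatedSite] = []
    for site in sites:
        p = site.pos
        strand = _site_strand(site)
        novel = p not in known

        hits = ann.features_at(p)
        coding = [f for f in hits if f.ftype in ("gene_cds", "exon", "orf")]
        rrna = [f for f in hits if f.ftype == "rRNA"]
        trna = [f for f in hits if f.ftype == "tRNA"]
        if coding or rrna:
            host = coding[0] if coding else rrna[0]
            out.append(
                AnnotatedSite(
                    site=site,
                    category=CAT_CODING,
                    host_feature=host.feature_id,
                    novel=novel,
                    subtype="rRNA" if not coding else "",
                    discordant_strand=host.strand != strand,
                )
            )
            continue
        if trna:
            host = trna[0]
            out.append(
                AnnotatedSite(
                    site=site,
                    category=CAT_TRNA,
                    host_feature=host.feature_id,
                    novel=novel,
                    discordant_strand=host.strand != strand,
                )
            )
            continue

        unit = next(
            (
                u
                for u in units
                if (p - u.start) % L < u.end - u.start
            ),
            None,
        )
        if unit is None or not unit.members:
            out.append(AnnotatedSite(site=site, category=CAT_UNLINKED, novel=novel))
            continue

        offset = (p - unit.start) % L
        member_feats = [fmap[m] for m in unit.members]
        first_off = min((f.start - unit.start) % L for f in member_feats)
        last_off = max(
            (f.start - unit.start) % L + f.length for f in member_feats
        )
        if offset < first_off:
            # genomically before the first member: 5' end for a + unit
            cat = CAT_UTR5 if unit.strand != "-" else CAT_UTR3
        elif offset >= last_off:
            cat = CAT_UTR3 if unit.strand != "-" else CAT_UTR5
        else:
            cat = CAT_INTERGENIC_POLY
        discordant = unit.strand in "+-" and unit.strand != strand
        out.append(
            AnnotatedSite(
                site=site,
                category=cat,
                host_unit=unit.unit_id,
                novel=novel,
                discordant_strand=discordant,
            )
        )
    assert len(out) == len(sites)
    return out


def compare_pies(
    called: Iterable[AnnotatedSite | EditSite | int],
    pies: PIESList,
) -> dict[str, object]:
    """Set arithmetic between called sites and the reference catalogue.

    Matching is by genome position only.  Returns overlap / novel / missed
    position sets and counts, with ``union_count = called + missed`` by
    construction.
    """
    called_pos: set[int] = set()
    for c in called:
        if isinstance(c, AnnotatedSite):
            called_pos.add(c.site.pos)
        elif isinstance(c, EditSite):
            called_pos.add(c.pos)
        else:
            called_pos.add(int(c))
    overlap = called_pos & pies.positions
    novel = called_pos - pies.positions
    missed = pies.positions - called_pos
    union = called_pos | pies.positions
    return {
        "overlap_count": len(overlap),
        "novel_count": len(novel),
        "missed_count": len(missed),
        "union_count": len(union),
        "called_count": len(called_pos),
        "pies_count": len(pies.positions),
        "novel_sites": sorted(novel),
        "missed_pies": sorted(missed),
    }


def summarize_categories(
    annotated: Sequence[AnnotatedSite],
    ann: AnnotationSet | None = None,
) -> tuple[dict[str, int], dict[str, int]]:
    """Counts per category, plus per-gene counts (exons aggregated).

    The category counts are a partition of the input: they always sum to
    ``len(annotated)``.
    """
    cat_counts = {c: 0 for c in CATEGORIES}
    for a in annotated:
        cat_counts[a.category] += 1
    assert sum(cat_counts.values()) == len(annotated)

    per_gene: dict[str, int] = {}
    fmap = {f.feature_id: f for f in ann.features} if ann is not None else {}
    for a in annotated:
        if a.host_feature is None:
            continue
        f = fmap.get(a.host_feature)
        gene = f.gene_id if f is not None and f.gene_id else a.host_feature
        per_gene[gene] = per_gene.get(gene, 0) + 1
    return cat_counts, per_gene


def annotated_to_frame(annotated: Sequence[AnnotatedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position": [a.site.pos + 1 for a in annotated],
            "orientation": [a.site.orientation for a in annotated],
            "depth": [a.site.depth for a in annotated],
            "edit_fraction": [a.site.edit_fraction for a in annotated],
            "category": [a.category for a in annotated],
            "host_feature": [a.host_feature or "" for a in annotated],
            "host_unit": [a.host_unit or "" for a in annotated],
            "novel": [a.novel for a in annotated],
            "subtype": [a.subtype for a in annotated],
            "discordant_strand": [a.discordant_strand for a in annotated],
        }
    )
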