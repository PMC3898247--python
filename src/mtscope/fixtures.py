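"""Packaged reference tables for the tobacco mitogenome (NC_006581).

Two small curated tables ship with the package so the classifiers can be
exercised on real transcript compositions without any sequencing input:

* ``table1_units.tsv`` — the predicted transcript catalogue: one row per
  transcribed area with its strand and '::'-joined member coding segments.
  Rows that the published mono/poly arithmetic leaves out of the 9 + 16
  count (the strandless rRNA areas and the solitary orf197 area) carry a
  non-empty ``excluded`` tag.
* ``table2_orfs.tsv`` — the ORF follow-up survey: genome coordinates, peak
  depth of coverage, edit-site counts and polysome supernatant/pellet calls
  for the transcribed uncharacterized ORFs plus the cox2 positive control,
  its EDTA-treated negative control, and the orf161 background region.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .units import MONO, POLY, TranscriptUnit, classify_cistronic


def _read(name: str) -> pd.DataFrame:
    with resources.files("mtscope.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str).fillna("")


def load_table1() -> pd.DataFrame:
    """Transcript catalogue (area, strand, transcript, excluded tag)."""
    return _read("table1_units.tsv")


def load_table2() -> pd.DataFrame:
    """ORF survey table (coordinates, peak DOC, polysome calls, role)."""
    return _read("table2_orfs.tsv")


def table1_transcript_units() -> list[TranscriptUnit]:
    """The catalogue's included rows as :class:`TranscriptUnit` objects.

    Genome spans are not recorded in the catalogue, so placeholder spans of
    unit length are used; only the member lists (and hence the cistronic
    classification) are meaningful.
    """
    df = load_table1()
    units = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.excluded:
            continue
        members = row.transcript.split("::")
        units.append(
            TranscriptUnit(
                unit_id=f"t1_{i:02d}",
                strand=row.strand or "ambiguous",
                start=0,
                end=1,
                members=members,
            )
        )
    return units


def fixture_counts() -> dict[str, int]:
    """Headline counts recomputed from the packaged tables.

    mono / poly come from :func:`classify_cistronic` applied to the
    catalogue's member lists; candidate_orfs counts the survey's
    experimental rows (controls and background excluded);
    pellet_associated counts experimental rows with a positive pellet call.
    """
    units = table1_transcript_units()
    classes = [classify_cistronic(u) for u in units]
    t2 = load_table2()
    exp = t2[t2["role"] == "experimental"]
    return {
        "mono": sum(c == MONO for c in classes),
        "poly": sum(c == POLY for c in classes),
        "candidate_orfs": int(len(exp)),
        "pellet_associated": int((exp["pellet"].str.strip() == "+").sum()),
        "supernatant_detected": int((exp["super"].str.strip() == "+").sum()),
    }
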