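"""Synthetic circular mitogenome, reads, and truth tables.

The generator emulates the statistical structure of a plant mitochondrial
RNA-seq experiment at toy scale: discrete transcribed units of differing
mean depth on both strands of a circular genome, low-coverage intergenic
background, planted C->U edit sites carried by each covering read with a
per-site binomial fraction, planted 100%-substituted SNPs, unstranded
100-nt reads and a uniform per-base substitution error.  Reads are emitted
pre-aligned (SAM with correct POS/CIGAR) — alignment itself is not this
package's concern — and every planted quantity is written to machine-
readable truth tables so downstream stages can be scored without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome import AnnotationSet, CircularGenome, Feature, write_fasta, write_gff3
from .units import MONO, NON_CODING, POLY

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_ASCII = np.array([65, 67, 71, 84], dtype=np.uint8)  # A C G T


@dataclass(frozen=True)
class SegmentSpec:
    """One coding segment inside a unit (becomes an annotation feature)."""

    feature_id: str
    ftype: str  # gene_cds | exon | orf
    start: int
    end: int
    gene_id: str = ""


@dataclass(frozen=True)
class UnitSpec:
    """One transcribed unit: strand, span and mean depth of coverage."""

    strand: str
    start: int
    end: int  # may exceed genome_length (origin-spanning unit)
    mean_doc: float
    segments: tuple[SegmentSpec, ...] = ()


@dataclass(frozen=True)
class PlantedEdit:
    pos: int
    orientation: str  # 'forward' (ref C, reads T) or 'reverse' (ref G, reads A)
    fraction: float


@dataclass(frozen=True)
class PlantedSNP:
    pos: int
    orientation: str  # same encoding; reads always carry the substituted base


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    genome_length: int = 20_000
    unit_specs: list[UnitSpec] = field(default_factory=list)
    extra_features: list[Feature] = field(default_factory=list)
    background_doc: float = 20.0
    read_length: int = 100
    error_rate: float = 0.001
    edit_plan: list[PlantedEdit] = field(default_factory=list)
    snp_plan: list[PlantedSNP] = field(default_factory=list)
    origin_spanning_reads: bool = False
    seed: int = 0
    genome_id: str = "sim_mito"

    def validate(self) -> None:
        L = self.genome_length
        for u in self.unit_specs:
            if not (0 <= u.start < L and u.start < u.end <= 2 * L):
                raise ValueError(f"unit span [{u.start}, {u.end}) does not fit")
            if u.strand not in "+-":
                raise ValueError("unit strand must be '+' or '-'")
        arcs = []
        for u in self.unit_specs:
            arcs.extend(
                [(u.start, u.end)]
                if u.end <= L
                else [(u.start, L), (0, u.end - L)]
            )
        arcs.sort()
        for (s1, e1), (s2, e2) in zip(arcs, arcs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping unit specs near [{s2}, {e1})"
                )
        epos = {e.pos for e in self.edit_plan}
        spos = {s.pos for s in self.snp_plan}
        if len(epos) != len(self.edit_plan) or len(spos) != len(self.snp_plan):
            raise ValueError("duplicate planted positions")
        if epos & spos:
            raise ValueError("edit and SNP positions must be disjoint")
        for p in epos | spos:
            if not 0 <= p < L:
                raise ValueError(f"planted position {p} outside genome")
        for e in self.edit_plan:
            if not 0.0 < e.fraction < 1.0:
                raise ValueError("edit fractions must lie in (0, 1)")


def default_config(seed: int = 0, error_rate: float = 0.001) -> SimConfig:
    """The package's reference simulation.

    A 20-kb circular genome carrying six transcribed units (mean DOC
    300-1000, both strands; two polycistronic), a candidate ORF unit, a
    tRNA and an rRNA in the low-coverage background, 50 planted C->U edit
    sites with fractions spread over 0.1-0.9 inside the units, and 10
    planted SNPs.  Unstranded 100-nt reads, background DOC 20.
    """
    units = [
        UnitSpec(
            "+", 1000, 4200, 400.0,
            (
                SegmentSpec("nad9x_ex1", "exon", 1200, 1800, "nad9x"),
                SegmentSpec("nad9x_ex2", "exon", 2600, 3200, "nad9x"),
            ),
        ),
        UnitSpec(
            "-", 5200, 6600, 300.0,
            (SegmentSpec("ccmCx", "gene_cds", 5400, 6300, "ccmCx"),),
        ),
        UnitSpec(
            "+", 8000, 12000, 1000.0,
            (
                SegmentSpec("atp6x", "gene_cds", 8300, 9200, "atp6x"),
                SegmentSpec("rps3x_ex1", "exon", 9800, 10200, "rps3x"),
                SegmentSpec("rps3x_ex2", "exon", 10800, 11400, "rps3x"),
            ),
        ),
        UnitSpec(
            "-", 13000, 14200, 600.0,
            (SegmentSpec("orf177x", "orf", 13200, 13900, "orf177x"),),
        ),
        UnitSpec(
            "+", 16000, 17600, 350.0,
            (SegmentSpec("cobx", "gene_cds", 16200, 17300, "cobx"),),
        ),
        UnitSpec(
            "+", 18300, 19600, 500.0,
            (SegmentSpec("nad3x", "gene_cds", 18500, 19400, "nad3x"),),
        ),
    ]
    extra = [
        Feature("trnMx", "tRNA", 7000, 7072, "+", "trnMx"),
        Feature("orf_ovl", "orf", 8400, 8700, "+", "orf_ovl"),
        Feature("rrnSx", "rRNA", 14700, 15500, "-", "rrnSx"),
    ]
    rng = np.random.default_rng(seed)
    rl = 100
    # candidate positions well inside units so realized depth sits at the
    # unit plateau
    pool: list[tuple[int, str]] = []
    for u in units:
        orient = "forward" if u.strand == "+" else "reverse"
        for p in range(u.start + rl, u.end - rl):
            pool.append((p, orient))
    idx = rng.choice(len(pool), size=60, replace=False)
    fractions = np.linspace(0.1, 0.9, 50)
    rng.shuffle(fractions)
    edit_plan = [
        PlantedEdit(pool[i][0], pool[i][1], float(f))
        for i, f in zip(idx[:50], fractions)
    ]
    snp_plan = [PlantedSNP(pool[i][0], pool[i][1]) for i in idx[50:]]
    return SimConfig(
        genome_length=20_000,
        unit_specs=units,
        extra_features=extra,
        background_doc=20.0,
        read_length=rl,
        error_rate=error_rate,
        edit_plan=edit_plan,
        snp_plan=snp_plan,
        seed=seed,
    )


def simulate_genome(config: SimConfig) -> tuple[CircularGenome, AnnotationSet]:
    """Random sequence (fixed seed) with guaranteed reference bases at every
    planted edit/SNP position, plus the annotation implied by the unit specs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    seq = _BASES[rng.integers(0, 4, size=L)].copy()
    for e in list(config.edit_plan) + list(config.snp_plan):
        seq[e.pos] = b"C" if e.orientation == "forward" else b"G"
    genome = CircularGenome(
        id=config.genome_id, sequence=seq.tobytes().decode()
    )
    feats: list[Feature] = []
    for u in config.unit_specs:
        for s in u.segments:
            feats.append(
                Feature(
                    feature_id=s.feature_id,
                    ftype=s.ftype,
                    start=s.start,
                    end=s.end,
                    strand=u.strand,
                    gene_id=s.gene_id or s.feature_id,
                )
            )
    feats.extend(config.extra_features)
    feats.sort(key=lambda f: (f.start, f.feature_id))
    ann = AnnotationSet(genome_id=genome.id, genome_length=L, features=feats)
    return genome, ann


def _region_arcs(config: SimConfig) -> list[tuple[int, int, float]]:
    """(start, end, mean_doc) for units and the intergenic complement."""
    L = config.genome_length
    regions = [(u.start, u.end, u.mean_doc) for u in config.unit_specs]
    covered = []
    for s, e, _ in regions:
        covered.extend([(s, e)] if e <= L else [(s, L), (0, e - L)])
    covered.sort()
    gaps = []
    prev = 0
    for s, e in covered:
        if s > prev:
            gaps.append((prev, s))
        prev = max(prev, e)
    if prev < L:
        gaps.append((prev, L))
    if config.background_doc > 0:
        regions.extend((s, e, config.background_doc) for s, e in gaps)
    return regions


def simulate_reads(
    config: SimConfig,
    genome: CircularGenome,
    ann: AnnotationSet,
    path: str | Path,
) -> int:
    """Write unstranded aligned reads as SAM; return the read count.

    Read starts are uniform per region over a window widened by one read
    length, so the expected interior depth equals the region's mean DOC.
    Each read covering a planted edit carries the edited base independently
    with the site's fraction; reads over a SNP always carry the substituted
    base; uniform substitution errors are applied last (SNP and edit
    positions included).  By default reads never span the origin; with
    ``origin_spanning_reads`` a crossing read is written as two lines
    sharing a name (soft-clipped primary + supplementary).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    L = config.genome_length
    rl = config.read_length

    starts_all: list[np.ndarray] = []
    for s, e, doc in _region_arcs(config):
        span = e - s
        window = span + rl - 1
        n = int(round(doc * window / rl))
        if n == 0:
            continue
        starts = rng.integers(s - rl + 1, e, size=n) % L
        if not config.origin_spanning_reads:
            starts = np.minimum(starts, L - rl)
        starts_all.append(starts)

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": genome.id, "LN": L}],
    }
    if not starts_all:
        with pysam.AlignmentFile(str(path), "w", header=header):
            pass
        return 0

    starts = np.concatenate(starts_all)
    n = starts.size
    seq_codes = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    code_of = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        code_of[b] = i
    ref_codes = code_of[seq_codes]

    idx = (starts[:, None] + np.arange(rl)[None, :]) % L
    reads = ref_codes[idx].astype(np.int8)

    # SNPs: every covering read carries the substituted base (C->T / G->A)
    for s in config.snp_plan:
        col = (s.pos - starts) % L
        rows = np.flatnonzero(col < rl)
        alt = 3 if s.orientation == "forward" else 0  # T or A
        reads[rows, col[rows]] = alt
    # edits: covering reads carry the edited base with the planted fraction
    for e in config.edit_plan:
        col = (e.pos - starts) % L
        rows = np.flatnonzero(col < rl)
        hit = rows[rng.random(rows.size) < e.fraction]
        alt = 3 if e.orientation == "forward" else 0
        reads[hit, col[hit]] = alt
    # sequencing error: uniform substitution to one of the other three bases
    if config.error_rate > 0:
        err = rng.random((n, rl)) < config.error_rate
        shift = rng.integers(1, 4, size=int(err.sum()))
        reads[err] = (reads[err] + shift) % 4

    flags = rng.integers(0, 2, size=n) * 16  # unstranded mapping orientation
    ascii_mat = _ASCII[reads]
    qual = "I" * rl

    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in range(n):
            seq = ascii_mat[i].tobytes().decode()
            start = int(starts[i])
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i:07d}"
            a.reference_id = 0
            a.mapping_quality = 60
            if start + rl <= L:
                a.flag = int(flags[i])
                a.reference_start = start
                a.cigarstring = f"{rl}M"
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(qual)
                out.write(a)
            else:
                head = L - start  # bases before the origin
                a.flag = int(flags[i])
                a.reference_start = start
                a.cigarstring = f"{head}M{rl - head}S"
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(qual)
                out.write(a)
                b = pysam.AlignedSegment(out.header)
                b.query_name = f"r{i:07d}"
                b.flag = int(flags[i]) | 0x800  # supplementary
                b.reference_id = 0
                b.reference_start = 0
                b.mapping_quality = 60
                b.cigarstring = f"{head}S{rl - head}M"
                b.query_sequence = seq
                b.query_qualities = pysam.qualitystring_to_array(qual)
                out.write(b)
    return n


def write_truth(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Truth tables (1-based positions) for edits, SNPs and units."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edits": outdir / "truth_edits.tsv",
        "snps": outdir / "truth_snps.tsv",
        "units": outdir / "truth_units.tsv",
    }
    pd.DataFrame(
        {
            "position": [e.pos + 1 for e in config.edit_plan],
            "orientation": [e.orientation for e in config.edit_plan],
            "fraction": [e.fraction for e in config.edit_plan],
        }
    ).sort_values("position").to_csv(paths["edits"], sep="\t", index=False)
    pd.DataFrame(
        {
            "position": [s.pos + 1 for s in config.snp_plan],
            "orientation": [s.orientation for s in config.snp_plan],
        }
    ).sort_values("position").to_csv(paths["snps"], sep="\t", index=False)
    rows = []
    for u in config.unit_specs:
        k = len(u.segments)
        cls = NON_CODING if k == 0 else (MONO if k == 1 else POLY)
        rows.append(
            {
                "start": u.start + 1,
                "end": u.end,
                "strand": u.strand,
                "mean_doc": u.mean_doc,
                "members": "::".join(s.feature_id for s in u.segments),
                "class": cls,
            }
        )
    pd.DataFrame(rows).to_csv(paths["units"], sep="\t", index=False)
    return paths


def simulate_dataset(
    config: SimConfig, outdir: str | Path
) -> dict[str, object]:
    """Genome + annotation + reads + truth, written under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, ann = simulate_genome(config)
    fasta = outdir / "genome.fasta"
    gff = outdir / "annotation.gff3"
    sam = outdir / "reads.sam"
    write_fasta(genome, fasta)
    write_gff3(ann, gff)
    n_reads = simulate_reads(config, genome, ann, sam)
    truth = write_truth(config, outdir)
    return {
        "genome": genome,
        "annotation": ann,
        "fasta": fasta,
        "gff3": gff,
        "sam": sam,
        "n_reads": n_reads,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# synthetic qPCR plates


def simulate_qpcr_wells(
    true_abundance: Mapping[str, float],
    condition: str,
    efficiencies: Mapping[str, float] | float = 0.95,
    amplicon: Mapping[str, float] | float = 120.0,
    Ft: float = 1000.0,
    n_bio: int = 3,
    n_tech: int = 2,
    ct_noise_sd: float = 0.2,
    loading_sd: float = 0.3,
    dna_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one condition's plate from known transcript abundances.

    Each sample (bio_rep, tech_rep) gets a lognormal loading factor shared
    by every target — exactly the variation the control-gene normalization
    is meant to remove.  Ct values follow the amplification model
    ``Ct = log_{1+E}(Ft / (N0 * Amp))`` with Gaussian cycle noise, and the
    RT-minus wells measure ``dna_fraction`` of each template.  Returns
    (wells, primers) tables ready for :func:`mtscope.qpcr.estimate_copies`.
    """
    rng = np.random.default_rng(seed)
    targets = list(true_abundance)
    eff = (
        {t: float(efficiencies) for t in targets}
        if not isinstance(efficiencies, Mapping)
        else dict(efficiencies)
    )
    amp = (
        {t: float(amplicon) for t in targets}
        if not isinstance(amplicon, Mapping)
        else dict(amplicon)
    )
    rows = []
    for bio in range(1, n_bio + 1):
        for tech in range(1, n_tech + 1):
            loading = float(rng.lognormal(mean=0.0, sigma=loading_sd))
            for t in targets:
                n0 = true_abundance[t] * loading
                E, A = eff[t], amp[t]
                ct = float(
                    np.log(Ft / (n0 * A)) / np.log(1.0 + E)
                    + rng.normal(0.0, ct_noise_sd)
                )
                if dna_fraction > 0:
                    ct_minus = float(
                        np.log(Ft / (dna_fraction * n0 * A)) / np.log(1.0 + E)
                        + rng.normal(0.0, ct_noise_sd)
                    )
                else:
                    ct_minus = np.nan
                rows.append(
                    {
                        "target": t,
                        "condition": condition,
                        "bio_rep": bio,
                        "tech_rep": tech,
                        "Ct": ct,
                        "Ft": Ft,
                        "rt_minus_Ct": ct_minus,
                    }
                )
    wells = pd.DataFrame(rows)
    primers = pd.DataFrame(
        {"target": targets, "E": [eff[t] for t in targets],
         "Amp": [amp[t] for t in targets]}
    )
    return wells, primers
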