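"""End-to-end pipeline: coverage -> units -> edit calls -> categorization.

One configured run executes the stages in order, writes every stage's
table, and aggregates a summary report.  The report never recomputes
anything: each count is taken from the stage output it summarizes.
"""

from __future__ import annotations

import json
import logging
import sys
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import annotation as ann_mod
from . import coverage as cov_mod
from . import editing, units as units_mod
from .genome import load_annotation, load_genome

logger = logging.getLogger("mtscope")


@dataclass
class PipelineConfig:
    genome: str
    annotation: str
    alignments: str
    outdir: str
    pies: str | None = None
    doc_thresholds: tuple[int, ...] = (50, 100, 150)
    segment_threshold: int = 200
    merge_gap: int = 500
    min_len: int = 200
    min_doc: int = 200
    min_edited_reads: int = 4
    min_fraction: float = 0.02
    snp_tolerance: float = 0.0
    orf_doc_threshold: int = 200
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


@dataclass
class RunReport:
    doc_summary: dict[int, float]
    n_units: int
    unit_classes: dict[str, int]
    edit_class_counts: dict[str, int]
    category_counts: dict[str, int]
    pies_comparison: dict[str, object] | None
    candidate_orfs: list[str]
    n_reads_skipped: int = 0

    def to_text(self) -> str:
        lines = ["# mtscope run report", ""]
        lines.append("## depth of coverage")
        for t, f in sorted(self.doc_summary.items()):
            lines.append(f"fraction of genome with DOC < {t}: {100 * f:.1f}%")
        lines.append("")
        lines.append("## transcript units")
        lines.append(f"units: {self.n_units}")
        for k, v in self.unit_classes.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
        lines.append("## edit sites")
        for k, v in sorted(self.edit_class_counts.items()):
            lines.append(f"  {k}: {v}")
        lines.append("")
        lines.append("## site categories")
        for k, v in self.category_counts.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
        if self.pies_comparison is not None:
            lines.append("## previously identified sites")
            for k in (
                "called_count",
                "pies_count",
                "overlap_count",
                "novel_count",
                "missed_count",
                "union_count",
            ):
                lines.append(f"  {k}: {self.pies_comparison[k]}")
        else:
            lines.append("## previously identified sites: skipped (no list)")
        lines.append("")
        lines.append("## candidate ORFs")
        lines.append(
            "  " + (", ".join(self.candidate_orfs) if self.candidate_orfs else "none")
        )
        return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage, write stage outputs under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("parameters: %s", asdict(config))

        genome = load_genome(config.genome)
        ann = load_annotation(config.annotation, genome)
        logger.info(
            "genome %s (%d bp), %d features",
            genome.id,
            genome.length,
            len(ann.features),
        )

        track = cov_mod.compute_doc(config.alignments, genome)
        summary = cov_mod.doc_summary(track, config.doc_thresholds)
        cov_mod.write_bedgraph(track, out / "coverage.bedgraph")
        pd.DataFrame(
            {"threshold": list(summary), "fraction_below": list(summary.values())}
        ).to_csv(out / "doc_summary.tsv", sep="\t", index=False)

        intervals = units_mod.segment(
            track,
            threshold=config.segment_threshold,
            merge_gap=config.merge_gap,
            min_len=config.min_len,
            circular=genome.circular,
        )
        units = units_mod.assign_members_and_strand(intervals, ann)
        (out / "units.bed").write_text(
            units_mod.units_to_bed(units, track, genome.id)
        )
        unit_classes = {"mono": 0, "poly": 0, "non_coding": 0}
        for u in units:
            unit_classes[u.cistronic_class] += 1

        orfs = units_mod.select_candidate_orfs(
            track, ann, doc_threshold=config.orf_doc_threshold
        )
        pd.DataFrame(
            {
                "orf": [f.feature_id for f in orfs],
                "start": [f.start + 1 for f in orfs],
                "end": [f.end for f in orfs],
                "strand": [f.strand for f in orfs],
            }
        ).to_csv(out / "candidate_orfs.tsv", sep="\t", index=False)

        pileup = editing.build_pileup(config.alignments, genome)
        sites = editing.call_sites(
            pileup,
            min_doc=config.min_doc,
            min_edited_reads=config.min_edited_reads,
            min_fraction=config.min_fraction,
            snp_tolerance=config.snp_tolerance,
        )
        editing.sites_to_frame(sites).to_csv(
            out / "edit_sites.tsv", sep="\t", index=False
        )
        class_counts: dict[str, int] = {}
        for s in sites:
            class_counts[s.call_class] = class_counts.get(s.call_class, 0) + 1

        pies = None
        comparison = None
        if config.pies is not None:
            if Path(config.pies).exists():
                pies = ann_mod.read_pies(config.pies, genome.length)
            else:
                warnings.warn(
                    f"PIES list {config.pies} not found; section skipped",
                    stacklevel=2,
                )
        edits = [s for s in sites if s.call_class == editing.CLASS_EDIT]
        annotated = ann_mod.categorize(edits, ann, units, pies)
        ann_mod.annotated_to_frame(annotated).to_csv(
            out / "annotated_sites.tsv", sep="\t", index=False
        )
        cat_counts, per_gene = ann_mod.summarize_categories(annotated, ann)
        pd.DataFrame(
            {"category": list(cat_counts), "count": list(cat_counts.values())}
        ).to_csv(out / "category_summary.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"gene": list(per_gene), "edit_sites": list(per_gene.values())}
        ).to_csv(out / "per_gene_edits.tsv", sep="\t", index=False)

        if pies is not None:
            comparison = ann_mod.compare_pies(annotated, pies)
            pd.DataFrame(
                [
                    {
                        k: comparison[k]
                        for k in (
                            "called_count",
                            "pies_count",
                            "overlap_count",
                            "novel_count",
                            "missed_count",
                            "union_count",
                        )
                    }
                ]
            ).to_csv(out / "pies_comparison.tsv", sep="\t", index=False)

        report = RunReport(
            doc_summary=summary,
            n_units=len(units),
            unit_classes=unit_classes,
            edit_class_counts=class_counts,
            category_counts=cat_counts,
            pies_comparison=comparison,
            candidate_orfs=[f.feature_id for f in orfs],
            n_reads_skipped=pileup.skipped_reads,
        )
        (out / "report.txt").write_text(report.to_text())
        logger.info("pipeline complete")
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
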