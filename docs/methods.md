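# Methods

This note documents the models, conventions and parameter choices behind
`mtscope`, and what its synthetic benchmarks do and do not demonstrate.

## Coordinates and circularity

All internal coordinates are 0-based half-open; file I/O uses each format's
native convention (GFF3 1-based inclusive, BED/bedGraph 0-based half-open,
report tables 1-based).  A circular genome of length L represents an
origin-spanning feature, unit or interval as `end > L`, interpreted modulo
L; GFF3 input/output uses the two-segment shared-ID convention for such
features.  This single internal representation removes per-call ambiguity
about wrap-around arithmetic; every positional query (`features_at`,
overlap, peak depth) is defined over the modulo-L arcs and is tested
against brute-force per-base membership tables.

## Depth of coverage

`depth[p]` counts reads whose alignment consumes reference base `p` through
a match/mismatch CIGAR operation (M/=/X).  Deleted bases and reference
skips consume reference but contribute no depth — a stated convention, as
alignment suites differ here.  No mapping-quality or duplicate filtering is
applied by default (both are options): the toolkit works in raw depth
units, with no RPKM-style normalization, because every downstream rule
(segmentation threshold, edit-site DOC cut-off, ORF selection) is expressed
in raw DOC.  Genome-fraction summaries use a strict `depth < t` comparison.

## Transcript-unit segmentation

Units are maximal runs with `depth >= threshold` (default 200), merged when
separated by gaps shorter than `merge_gap` (default 500 bp) and discarded
when shorter than `min_len` (default 200 bp); terminal runs joining across
the origin are merged into one wrapped unit.  The threshold default matches
the ORF-selection DOC cut-off, with the background reference level (~75)
available as a second configurable anchor; `merge_gap` is sized so that
mid-transcript coverage dips of a few hundred bp — which occur as technical
artifacts even inside genuinely continuous coding regions — do not split a
unit.  Unit strand comes from the annotation of its members, never from
read orientation, because total-RNA libraries of this design are
unstranded; units with members on both strands are flagged `ambiguous`.

Cistronic classification is purely a member count: one coding segment
(complete CDS, single exon, or ORF) = monocistronic; two or more = poly,
even when the segments are exons of one gene; zero = non-coding.  The
packaged tobacco catalogue follows this rule; its four rows excluded from
the 9 + 16 arithmetic (the three strandless rRNA areas and the solitary
orf197 area) are tagged in the fixture file rather than dropped.

## Edit-site calling

Candidate columns are C-reference positions with T observations (forward
orientation) or G-reference with A (reverse); no other mismatch pattern can
produce a site.  The edit fraction is `edited / (edited + reference)` —
a two-state C/U quantity; third-base observations stay in the depth but
not in the fraction.  A candidate is an `edit` when

* `depth > min_doc` (default 200, strict),
* `edit_fraction < 1 − snp_tolerance` (default tolerance 0: a literal
  100%-change column is a genomic SNP of the sequenced material),
* `edited_count ≥ min_edited_reads` (default 4) and
  `edit_fraction ≥ min_fraction` (default 0.02).

The floor defaults are this package's own guards against sequencing error;
they are deliberately far below the ~10% fractions at which real screens
start missing sites, and both are exposed as flags.  With simulated error
switched on, `snp_tolerance` must be raised to roughly 3× the per-base
error rate for the SNP rule to keep absorbing error-contaminated SNP
columns — a documented, tested interaction.  Failures to re-find a known
site are diagnosed per site as `no_mismatch_observed`, `low_depth`,
`low_count`, `low_fraction`, `called_snp` or `invalid_reference`.  The
call-class enum folds "too few edited reads" into `subthreshold_fraction`;
the diagnosis keeps the distinction.

Site categorization uses fixed precedence: coding (CDS/exon/ORF, with
rRNA-internal sites binned as coding under an `rRNA` subtype tag) > tRNA >
unit-relative classes > unlinked.  Within a unit but outside all members,
position relative to the first/last member along the unit's transcription
direction yields `utr5` / `utr3`, and between members
`intergenic_polycistronic`.  Sites inside a unit that has no coding members
cannot be oriented and are binned `unlinked`.  Categories partition the
input by construction (asserted on every run).  PIES comparison matches by
genome position only — reference catalogues are positional — so
`|union| = |called| + |missed| = |PIES| + |novel|` holds as a set identity.

## qPCR model

`N0 = Ft·(1+E)^(−Ct)/Amp`, with efficiency E a fraction in (0, 1] (percent
inputs > 1.5 are auto-detected and divided by 100, with a warning) and the
amplicon size in the denominator making targets with different amplicons
comparable per base.  RT-minus subtraction floors at zero (a negative
difference means the DNA estimate exceeded the RT-plus signal; clamping is
this package's choice).  Normalization divides each sample's estimates by
`control_s / min(control)`, which maps all control replicates onto the
batch minimum exactly — division rather than multiplication is forced by
that identity.  The rank-sum test enumerates all C(n1+n2, n1) rank splits
up to a pooled size of 14 (covering the 3-biological × 2-technical n = 6
vs 6 design), using midranks so the p-value is permutation-exact under
ties; larger samples fall back to the normal approximation and are flagged.
Above-background calls require both median direction and `p < alpha`
(alpha 0.05, a convention); polysome association is the same call
restricted to pellet-fraction wells, with an EDTA-treated extract as the
expected-negative control.

## Synthetic data

The generator emulates the statistical structure of an organellar total-RNA
alignment: a random-sequence circular genome (default 20 kb) carrying
discrete transcribed units of configured mean DOC on both strands,
low-coverage intergenic background (default 20×), unstranded 100-nt reads,
uniform per-base substitution error (default 1e-3), planted C→U edits
carried by each covering read with a per-site binomial fraction, and
planted SNPs carried by every read.  Read starts are uniform per region
over a window widened by one read length, so interior expected depth
equals the configured mean (verified within 10% for ≥1-kb units).  Planted
SNPs sit on reference C (reads T) or G (reads A) deliberately: they are
exactly the columns the 100%-change rule must reject.  Reads are emitted
pre-aligned (SAM with POS/CIGAR) because read mapping is upstream of this
toolkit's scope; by default no read spans the origin, and an option emits
origin-crossing reads as soft-clipped primary + supplementary line pairs.

The reference configuration (`default_config`) plants six units (mean DOC
300–1000, two polycistronic), one candidate ORF unit, a tRNA and an rRNA in
the background, 50 edits with fractions spread over 0.1–0.9 and 10 SNPs on
a 20-kb genome — small enough that a full simulate→call→categorize cycle
runs in seconds, large enough that every depth filter operates in its
intended regime.  qPCR plates are simulated from the amplification model
run backwards with Gaussian Ct noise (σ = 0.2 cycles) and a per-sample
lognormal loading factor (σ = 0.3) shared across targets — precisely the
nuisance the control-gene normalization removes.

What the synthetic benchmarks do **not** show: behaviour under
multi-mapping reads from repeated regions, chloroplast-homologous
contamination, indel or splice alignment artifacts, coverage biases of real
library preparation, or partial editing gradients along transcripts.
Perfect planted-truth recovery on error-free simulations demonstrates the
correctness of the operational rules, not real-data sensitivity.

## Numerical and design choices

* All randomness flows from explicit integer seeds (numpy `default_rng`);
  reruns are byte-identical.
* Segmentation and calling are deterministic; ordering ties break on
  `(start, feature_id)`.
* The exact rank-sum comparison uses an absolute 1e-9 slack when counting
  equally extreme splits, protecting the ≥ comparison from float noise in
  midranks.
* Alignments are accepted as given (no multiread re-resolution); genomes
  are single-chromosome; GenBank flat files are not parsed (convert to
  GFF3).
* Published count discrepancies in the tobacco literature (e.g. differing
  totals for coding-region edits across summaries of the same screen) are
  noted, not adjudicated: this package defines its partition operationally
  and reports whatever its rules produce.
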