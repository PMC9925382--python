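# Methods

## Model and assumptions

The predictor is purely empirical. For each annotated splice site of each
transcript, every unannotated splice junction whose split reads touch at
least one annotated splice site is classified relative to that site:

- **Exon skipping.** A junction joining the annotated donor of exon `a`
  to the annotated acceptor of exon `b` with `b ≥ a + 2` evidences
  skipping of exons `a+1 … b−1`. The event is anchored to *every* donor
  and acceptor of *every* skipped exon, since a variant at any of those
  sites could elicit it. (Whether a multi-exon event should instead be
  anchored only to the outermost sites is genuinely open; anchoring to
  all skipped-exon sites is the more sensitive choice and the one used
  throughout.)
- **Cryptic activation.** A junction with exactly one unannotated end,
  whose annotated end is the partner site across the affected intron,
  evidences a cryptic donor (unannotated donor + annotated partner
  acceptor) or cryptic acceptor (mirror case). Junctions with both ends
  unannotated are never events. Cryptic offsets are signed
  boundary-to-boundary distances in transcript direction: positive into
  the intron, negative into the exon.

Events are ranked per site by `n_samples`, the number of samples with at
least one supporting read. The underlying assumption — supported by the
tissue-concordance machinery in `vault` — is that the spliceosome makes
the same mistakes, in roughly the same proportions, across tissues and
datasets, so a ranking aggregated over heterogeneous cohorts transfers
to the patient's tissue.

Intron retention is deliberately absent from the catalog: split reads
cannot quantify it. It enters only through the reading-frame machinery
and the Δ-score rule engine.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `top_n` | 4 | events reported as the starred prediction |
| `max_skipped_exons` | 2 | star filter: skipping runs longer than this are not starred |
| `max_cryptic_nt` | 600 | star filter: cryptic boundary distance cap (nt) |
| `neutral_threshold` | 0.001 | Δ-scores at/below this are discarded as neutral |
| `decision_threshold` | 0.011 | Δ at/above which a rule fires |
| `window_nt` | 5,000 | Δ-score collection window either side of the variant |

The starred defaults (Top-4, ≤2 exons, ≤600 nt) are the optimized
operating point; `evaluation.precision_recall_comparison(mode="filter_grid")`
reproduces the selection procedure on any cohort. The 0.011 decision
threshold is a *budget-matched* operating point — chosen so the rule
engine emits about as many predictions as Top-4\* — and is far below the
thresholds appropriate for general variant-effect calling; it exists to
make sensitivity/PPV comparable between the two predictors, nothing
more.

Coordinates are 1-based inclusive everywhere; BED input is converted on
read. A splice site's position is the last exonic base adjacent to its
intron, which makes offset arithmetic unambiguous on both strands.

## Ranking, ties and degenerate inputs

Ties in `n_samples` break by (1) more total reads, (2) the tighter event
(fewer skipped exons / smaller |offset|), (3) 5′-most genomic
coordinate — a stable, biologically sensible order that makes rebuilds
byte-identical. Unfiltered and starred ranks are computed separately, so
starred output is always a contiguous Top-1\*…Top-N\*. Sites with no
events are stored with empty tables; a junction table with zero samples
is an error. STAR rows with strand code 0 are resolved by matching
either endpoint to an annotated site, otherwise dropped with a log line.
Multi-mapped reads are excluded by default (they create alignment-
artifact junctions, e.g. where two exons begin with identical sequence).

Group (tissue) re-ranking recomputes `n_samples` within the group from
retained per-sample data; read-count tie-breaks in group views use the
global read totals, since per-group read totals are not retained.

## Δ-score rule engine

All scores within ±5,000 nt are kept if above the 0.001 neutrality
floor. A loss of the affected annotated site itself gates everything: if
no such loss is present the result is an explicit "no predicted impact".
Rules then fire at the decision threshold as described in the README.
Cryptic gains must be in the channel matching the affected site's kind
and inside the exon/intron flanking that site; gains elsewhere, gains at
annotated sites, and losses of unannotated sites are bucketed `other`,
so that every above-neutral score lands in exactly one of
{affected-site loss, supporting a prediction, other}. Double-exon
skipping is only ever emitted alongside its constituent single-exon
skipping, and the same pair reached from either constituent is
deduplicated.

## Reading-frame and PTC analysis

Net transcript change: −Σ(skipped exon lengths) for skipping, the signed
offset for cryptics, +intron length for retention; `in_frame` ⇔ net ≡ 0
(mod 3). With a genome FASTA and CDS annotation, the mature transcript
is reconstructed with the event applied and translated from the
annotated start codon; `ptc` means translation terminates strictly
before the position the annotated stop maps to. Retained introns are
additionally scanned for stop codons in all three frames. Without
sequence or CDS, PTC status is `unknown` — never guessed.

## Evaluation conventions

Matching is exact: identical skipped-exon sets, identical cryptic
coordinates (a distance window would silently inflate PPV). Observed
intron retention is excluded from catalog metrics by default (the
catalog cannot predict it); an explicitly labeled pessimistic mode
counts it as a miss. Budget matching selects the Δ threshold whose total
prediction count equals the Top-N\* count, resolving ties toward the
lower threshold and flagging inexact matches (how ties were resolved in
the original analyses is unstated; this rule is a documented choice).
Undefined ratios (0/0) are reported as absent, not 0.

## Synthetic cohorts: what they emulate, and what they do not

The generator plants events with independent per-sample presence at a
configured frequency; read counts per present sample are geometric with
P(1) = 0.78, matching the single-read-dominated support regime of real
compendia. Competing event pairs can be planted with an explicit sample-
overlap target (default 5% Jaccard for the top-2 events) to emulate
mutual exclusivity. Sequences are random with forced GT-AG intron
boundaries and a stop-free annotated ORF (ATG…TAA); one intron per
default cohort carries planted stop codons in all three frames. The
default per-site frequency ladder is 0.40/0.12/0.05/0.02/0.01 over
cohorts of 100–1,000 samples (unit tests use 100; rank-recovery,
co-occurrence and the acceptance script use 1,000 — sizes chosen so
adjacent frequencies are separated well beyond binomial noise while the
whole suite stays fast). The planted Δ-score pattern places its cryptic
gain at the same boundary as the top natural cryptic, emulating a
variant that activates the naturally occurring event.

Not emulated: splice-motif strength (sequences are never scored),
expression-driven detectability differences between genes and tissues,
alignment artifacts (beyond an optional ambiguous-first-bases junction),
library-depth variation, and the long tail of annotation complexity
(overlapping genes, many isoforms per locus). Passing tests therefore
demonstrate correctness of the bookkeeping, classification, ranking and
evaluation machinery under the stated statistical regime — not
real-data performance, which depends on corpus size and alignment
quality.

## Known limitations

- Overlapping transcript sets (e.g. two annotation sources) are indexed
  independently; no reconciliation of coinciding sites is attempted.
- The per-sample store keeps sample *presence* per event; per-group read
  totals are not persisted (see ties above).
- Variant→site resolution covers the donor motif (last 3 exonic to
  first 6 intronic bases) and acceptor motif (last 20 intronic to first
  2 exonic); variants outside every motif region fail with guidance
  rather than being force-assigned.
- The Δ-score engine consumes SpliceAI *output*; it never runs the
  model, and variants the model cannot score are simply absent from
  head-to-head metrics.
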