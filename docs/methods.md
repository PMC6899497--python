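# Methods

## Coordinate conventions

All positions are 0-based, half-open, in sense-strand transcript space.
`cds_start` is the first nucleotide of the start codon; `cds_end` is one
past the last nucleotide of the stop codon, so the CDS *includes* the stop
codon and its length is a multiple of 3 (≥ 6 nt). SAM's 1-based POS is
converted once, at ingestion (`five_prime = POS − 1`); GTF CDS features,
which exclude the stop codon, are extended by 3 nt on read. Using a single
convention everywhere removes the usual off-by-one drift between readers.

Each gene gets one representative transcript — the longest CDS, ties broken
lexicographically by transcript id — and all per-gene quantification is done
on that transcript. Multi-isoform quantification is out of scope.

## Synthetic data model

The generator emulates the footprint geometry of a mammalian ribosome-
profiling library; its defaults are the study conditions used throughout
the tests and the acceptance script.

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 200 | one transcript per gene |
| `utr5_range` | 30–200 nt | uniform; min must exceed `psite_offset`+1 so no 5′ end falls off the transcript |
| `cds_codons_range` | 100–500 codons | uniform, incl. start and stop codons |
| `utr3_range` | 50–300 nt | uniform |
| `abundance_sigma` | 1.0 | log-normal sd of per-gene mRNA abundance |
| `te_sigma` | 0.5 | log-normal sd of per-gene true TE |
| `psite_offset` | 12 nt | 5′ end → P-site distance |
| `periodicity_fidelity` | 0.9 | probability the 5′ end sits exactly at P-site − offset; otherwise jittered ±1 nt equiprobably |
| `footprint_length_pmf` | {28: 0.3, 29: 0.4, 30: 0.3} | read-length distribution |
| `mrna_fragment_length_range` | 25–34 nt | uniform fragment size of the total-mRNA control |
| `n_footprint_reads` / `n_mrna_reads` | 50,000 each | library sizes |
| `n_terms` / `enriched_term_fraction` | 20 / 0.5 | term table geometry (below) |

Footprint reads: a gene is drawn with probability ∝ abundance × TE ×
sense-codon count; the P-site codon is uniform over the sense codons
{`cds_start`, `cds_start`+3, …, `cds_end`−6} — the stop codon is never a
P-site, which is what makes 5′-end density vanish at exactly
(`cds_end`−3) − 15 nt, i.e. 15 nt upstream of the stop codon, since the
last possible 5′ end is `cds_end` − 6 − 12. Total-mRNA reads: gene ∝
abundance × transcript length, fragment start uniform, hence flat frame
usage. Read sequences are copied error-free from the transcript: alignment
is out of scope, so a sequencing-error model would add nothing testable.
P-site occupancy is uniform (no pausing or initiation-peak model), and
there is no rRNA contamination, UMI or multimapping structure — passing
tests therefore demonstrate correctness of the geometry and estimators, not
robustness to those real-data artifacts.

The term table seeds one designated term (`term_high_te`) into the top
`enriched_term_fraction` of genes by true TE with membership probability
0.8 (0.05 elsewhere); the remaining terms are uniformly random subsets.
This makes enrichment of high-TE selections detectable by construction
while background terms stay null.

All stages draw from child streams of a single seed
(`SeedSequence(seed, spawn_key=(stage,))`), so a fixture set is
byte-identical across runs and stages can be regenerated independently.
SAM is written directly as text (header with `@SQ` per transcript, FLAG 0,
1-based POS, CIGAR `<len>M`, MAPQ 255) and always re-read through pysam, so
an independent parser validates the format in every round trip.

## Ingestion and filtering

Only primary, mapped, forward-strand alignments are retained; unmapped,
secondary, supplementary and reverse-strand records are dropped with
per-reason counters rather than errors, so library problems surface in the
drop report instead of aborting or disappearing. Reads with more than 2 nt
soft-clipped on the 5′ side are dropped because 5′-end precision is what
the metagene analysis rests on; retained weight is fixed at 1 per alignment
(no fractional multimapper weighting — the simplest auditable rule). An
alignment to a reference absent from the annotation is a hard error: it
means the wrong annotation was paired with the alignments. The in-silico
analogue of gel size selection is `filter_by_length` (inclusive bounds,
idempotent).

## QC statistics

* **Length histogram** — exact counts; mode ties break toward the shorter
  length.
* **Frame usage** — frame label = ((five_prime − cds_start) mod 3) + 1 with
  a non-negative mod, for 5′ ends in [`cds_start` − 12, `cds_end`): the
  12 nt upstream margin admits initiating-ribosome footprints, whose 5′
  ends legitimately precede the start codon; reads outside the span are
  tallied separately, not silently ignored.
* **Metagene** — 5′-end counts by displacement from `cds_start` or
  `cds_end` − 3 (first nt of the stop codon) over a half-open window;
  out-of-transcript window positions contribute nothing. Raw mode sums
  counts; `per_transcript_mean` divides each transcript's contribution by
  its mean CDS 5′-end density first, preventing a few abundant genes from
  dominating (transcripts with zero CDS reads then contribute nothing).
  Both modes are provided because published aggregate profiles do not
  always state their normalization; the choice is a recorded parameter.
* **Periodicity score** — max over the three frames of the fraction of
  in-span signal in that frame: 1/3 for frame-uniform signal, 1 for perfect
  periodicity; invariant to uniform scaling and to shifting the span by
  whole codons; undefined (error) on zero signal.

## P-site offset estimation

Footprint 5′ ends begin exactly one offset upstream of the first occupied
P-site codon — the start codon — so the offset is identified by the *onset*
of 5′-end density, not by a peak: the estimator returns the negation of the
most upstream displacement in the inclusive search window [−18, −6] whose
count reaches `rise_fraction` (default 0.5) of the window maximum. The
window brackets plausible eukaryotic offsets; the half-maximum criterion
makes the onset robust to the ±1 nt jitter counts just upstream of the true
edge. Onset detection was chosen over a plain argmax deliberately: under
uniform elongation occupancy the displacements −12, −9, −6 have equal
expected counts and an argmax degenerates into a tie broken by noise,
whereas the onset is well defined; on libraries with a dominant initiation
peak the onset coincides with that peak, so the two definitions agree where
argmax is meaningful. Recovery is verified for configured offsets 9, 12 and
15 nt at fidelity 0.8 and 20,000 reads.

## Quantification

Footprint counting region: inferred P-site (5′ end + offset) in
[`cds_start`, `cds_end` − 3), i.e. the sense codons — the standard
CDS-density interpretation, with CDS length normalizing footprint RPKM and
full transcript length normalizing total-mRNA RPKM. Note that with jittered
5′ ends a −1-jittered read whose true P-site is the start codon infers a
P-site 1 nt outside the CDS and is (correctly) not counted; at fidelity 0.9
this loses roughly `reads · 0.05 / codons` ≈ 10 of 50,000 reads, and none
at fidelity 1.

TE = footprint RPKM / mRNA RPKM, left undefined below `min_mrna_count`
(default 10) mRNA reads because an RPKM ratio explodes at small
denominators; excluded genes are logged and never ranked. Top-N selection
sorts descending with lexicographic tie-breaks (deterministic); list
overlap compares identifiers after uppercasing and whitespace stripping
only — alias/ortholog resolution would need external databases and is out
of scope.

## Enrichment

For each term: k of the n query genes carry it, K of the N background genes
do. `p_hyper` = P(X ≥ k) (hypergeometric upper tail), `p_ease` = P(X ≥ k−1)
— the EASE convention of removing one success, always ≥ `p_hyper` — and
`q_bh` = Benjamini–Hochberg over all tested terms. Terms with k = 0 or
K = 0 are excluded from testing (their p is 1 by construction and would
only dilute the correction). The background defaults to the genes actually
quantified in the experiment, not the genome, matching the universe the
query lists are drawn from. Both statistics are emitted so either can be
thresholded; the default report filter is `p_ease` < 10⁻⁴ with `q_bh`
shown alongside.

## Problem sizes and numerics

The test suite and acceptance script use 200-gene transcriptomes with
50,000-read libraries for geometry and calibration checks and 10⁶ + 10⁶
reads for TE parameter recovery (Spearman ρ > 0.9, log–log regression slope
within [0.9, 1.1]); null calibration uses 200 random 50-gene queries
against the simulated term table. Elementary statistics (RPKM, the
hypergeometric tail) are checked against closed-form/enumeration oracles to
10⁻⁹ relative. Hypergeometric tails come from `scipy.stats.hypergeom`, BH
from `statsmodels`; ties everywhere break deterministically (documented
above), so every pipeline output is byte-reproducible for a given seed.

## Known limitations

Single representative transcript per gene; no per-length offset calibration
tables, pause/ORF detection, differential-TE testing between conditions, or
GO-DAG ancestor propagation; identifier matching is string-based. The
simulator's idealizations listed above bound what green tests imply about
real libraries.
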