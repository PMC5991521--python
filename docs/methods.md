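# Methods

`isoscape` re-implements, as a desk-scale reusable pipeline, the analysis
stack used in comparative full-length (Iso-Seq-style) transcriptome studies
of two related plant species: a nonredundant isoform catalog, alternative
splicing (AS) events with per-tissue PSI and splicing-activity scores,
nonsense-mediated-decay (NMD) candidate calling, alternative-polyadenylation
(APA) site and motif maps, and phylotranscriptomic indices (TAI/TDI) built
on phylostrata and Nei–Gojobori Ka/Ks. Because the real sequencing data are
not required, a seeded synthetic generator emits a complete two-species
benchmark with recorded ground truth; every downstream claim the test suite
makes is a property of that planted truth, recovered by the pipeline.

## Coordinates and transcript models

All intervals are 0-based half-open in genomic order; conversion to the
1-based inclusive GTF/GFF3 convention happens only in the readers/writers.
A transcript is an exon chain on a chromosome and strand; its *intron
chain* — the ordered list of (donor-side, acceptor-side) coordinates — is
the identity used throughout: two transcripts are the same isoform exactly
when their intron chains match. "Transcription order" is derived from the
strand on demand; nothing is stored twice.

## Isoform collapse

Mapped full-length reads differing only at the 5′ start inside the first
exon are redundant: reads group by (chromosome, strand, exact intron
chain), sub-group by 3′ end within a tolerance (default 5 nt, deliberately
the same constant as the poly(A) cluster radius, so a single end-tolerance
governs both modules), and the longest member represents the group.
Per-tissue read support accumulates onto the representative. Mono-exon
reads, which have no intron chain, collapse by ≥50 % reciprocal overlap on
the same strand; components of the overlap graph are merged and the merge
is iterated to a fixpoint so that collapse is idempotent. The whole
operation is permutation-invariant by construction (all grouping keys are
sorted).

## Classification against a reference

Eight categories, evaluated most-specific-first so that the assignment is
a deterministic partition even when several predicates hold:
3 (identical intron chain) → 7 (intron chain is a *contiguous* sub-chain of
a reference transcript, strictly shorter) → 2 (shares ≥1 splice-site
coordinate, same strand) → 4 (same-strand exonic overlap, no shared sites)
→ 5 (entirely inside a reference intron, either strand) → 6 (exonic overlap
only antisense) → 1 (no overlap with any annotated locus) → 8 (rest).
A "splice site" is a single intron-boundary coordinate, strand-aware.
Mono-exon isoforms match category 3 through the same ≥50 % reciprocal
overlap rule used at collapse; the source analyses leave the mono-exon case
unspecified, so the collapse convention is reused rather than inventing a
second constant.

## AS events, PSI, activity

Six local event types are enumerated from all transcript pairs of a gene
and deduplicated by (type, canonical coordinates):

* **ES** — internal exon present in one form, spliced out via a single
  intron joining both flanking splice sites in the other.
* **A5/A3** — two introns sharing one boundary and differing at the other;
  the differing-boundary side names the type in transcription orientation
  (donor → A5, acceptor → A3). The variable-side exons must *overlap*; if
  they are disjoint the difference is an exon-skipping or complex pattern,
  not an alternative splice site — without this condition every ES
  structure would also emit two spurious boundary events.
* **IR** — one form's intron fully contained in an exon of the other
  (inclusion = the retained form).
* **AF/AL** — distinct, non-overlapping *terminal* exons spliced to a
  shared internal splice site.

PSI per tissue is inclusion-form abundance over total event abundance,
computed from a transcript-abundance matrix (in the demo pipeline the
abundance is the per-tissue full-length read support of each isoform).
Zero-total tissues yield an undefined PSI that is excluded downstream.
Splicing activity per tissue is the mean |Z| of each event's PSI row
standardized across tissues with the sample SD (ddof = 1); zero-variance
rows are dropped since standardization is undefined for them. |Z| is used
rather than signed Z so that deviation in either direction counts as
activity.

Cross-species event conservation matches orthologous genes with equal
event type and equal *ordinal architecture*: the retained-intron index
(IR), skipped-exon index (ES), or variable-intron index (A5/A3) in
transcription order, and position 0 for terminal AF/AL events. Isoform-level
conservation aligns the two sequences globally (match +1, mismatch −2, gap
open −5, extend −2, free end gaps) and requires ≥70 % coverage of the
shorter sequence and ≥80 % identity over aligned columns. Internal gaps are
penalized more than mismatches deliberately: under unit edit costs an
optimal path may re-express substitutions as insertion–deletion pairs,
silently inflating the gap-excluded identity.

## NMD

The longest ORF of a transcript is the longest ATG…stop span over the three
forward frames (the transcript is already an oriented mRNA model); ties go
to the 5′-most start, and ORFs running off the 3′ end are excluded unless
requested. The primitive accepts any ORF length so the minimal
ATG-stop case behaves as documented; the pipeline stage applies a 30-codon
floor, the conventional ORF-finder default. A multi-exon transcript is an
NMD candidate iff the stop codon of its longest ORF lies strictly more
than 50 nt upstream of the last exon–exon junction (distance is positive
upstream; exactly 50 is *not* a candidate). At the event level, an event is
NMD-producing iff one form has distance >50 and the other <50.

## APA

The cleavage site (CS) is the 3′-terminal transcribed base (max end − 1 on
"+", min start on "−"). Per gene, sorted CSs chain into clusters whenever
consecutive positions lie within 5 nt (single linkage, so 100–105–110 is
one cluster; a max-diameter mode is available because the chain-vs-diameter
reading of "within 5 nt of each other" is genuinely ambiguous). The cluster
representative is the modal position, ties resolved 3′-most. The NUE scan
counts every hexamer occurrence (overlaps included, N-containing k-mers
excluded) in the 40-nt window that ends 1 nt before the CS — the CS base
itself is excluded — with one window per nonredundant isoform per
supporting tissue. Occurrence counting is the default because it preserves
within-window signal strength; a presence/absence mode is exposed.

## Phylostrata, Ka/Ks, TAI/TDI

Phylostratum assignment consumes a gene × 13-node homolog-presence table
(oldest node first): PS is the smallest node index with a detected homolog;
PS 1–3 is "old", PS 11–13 "young", with PS 13 marked SSOG and PS 11–12
TSOG. Consuming a table rather than running homology searches keeps the
package self-contained; the generator emits the table.

Ka/Ks uses the Nei–Gojobori (1986) site-counting method: per codon
position, the synonymous site fraction is (synonymous one-step changes) /
(one-step changes not producing a stop), so S + N = 3 per codon exactly;
sites are averaged between the two sequences. Codons differing at 2–3
positions average their synonymous/nonsynonymous difference counts over all
minimal substitution pathways, excluding pathways through stop-codon
intermediates (falling back to all pathways if every one is blocked).
pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is a saturation error and dS = 0 leaves
the ratio undefined (excluded, never imputed). Codon alignments come from a
global protein alignment (BLOSUM62, gap open 10, extend 0.5) back-mapped to
codons, with gap columns dropped and a low-confidence flag below 30 %
protein identity.

TAI per tissue is the expression-weighted mean phylostratum,
TAI_s = Σ ps_i·e_is / Σ e_is; TDI replaces ps_i with the gene's Ka/Ks.
Both are invariant to rescaling a tissue's expression column (asserted to
1e−12) and bounded by the extreme gene-level inputs.

## Comparative utilities

Duplication typing partitions ancestral-species genes by derived-ortholog
multiplicity (1 → singleton, 2 → duplicate pair, else other). Cross-species
tissue correlation uses Spearman on TPM by default (rank-based, robust to
the cross-species scale problem; Pearson on log1p is a flag) over 1:1
ortholog pairs, with average-linkage clustering on 1 − r emitted alongside.
Expression breadth: housekeeping = ≥1 TPM in all tissues, tissue-specific =
≥1 TPM in exactly one (thresholds logged and configurable). Rarefaction
subsamples reads without replacement; the analytic check
Σ(1 − (1 − p_i)^d) is valid only at depths ≪ total and is used only there.
Group-wise expression contrasts use a Mann–Whitney U test per tissue with
Benjamini–Hochberg correction across tissues.

## The synthetic benchmark

The generator emits an ancestral species "b" and a derived species "a" in
which 30 % of genes are duplicated into subgenome-labelled pairs, over 11
tissues. Defaults (all in `SimConfig`): 150 ancestral genes; AS in ~70 % of
genes with an IR-heavy, AL-light type mix (IR 0.34 … AL 0.05); 50 % of AS
orthologs conserved at the same ordinal; a planted in-frame stop in 50 % of
(eligible) retained introns; 1–3 poly(A) sites per gene, 30 nt apart, each
with a NUE hexamer planted 14–28 nt upstream from an AATAAA-dominant mix;
one pollen-preferred site per multi-site gene carrying ATATAT and
absorbing the gene's entire pollen 3′-end usage; 13 phylostrata with 60 %
old / 15 % young genes and a 4× pollen bias on young-gene expression;
age-dependent Ka/Ks targets (old 0.15, intermediate 0.30, young 0.60,
lognormal jitter σ = 0.25); 1200 reads per tissue per species with 50 % of
reads 5′-truncated uniformly within the first exon.

Sequence engineering guarantees that the planted ORF is the longest one:
5′ UTRs, introns, and intergenic margins are adenine-free (no ATG, no stop
codons), internal coding codons exclude stops *and* ATG (so no internal
in-frame starts can outrun a planted premature stop), and 3′ UTRs are
scrubbed of ATG. Every isoform's NMD label is then verified at generation
time with an ORF scanner implemented independently of the analysis module;
the rare gene whose frame-shifted background produces a longer spurious ORF
is resampled. Retained introns eligible for a premature stop must lie
downstream of ≥210 CDS nt and upstream of the last intron, so the
truncated ORF dominates and the stop stays >50 nt upstream of the variant's
last junction.

Coding divergence applies at most one substitution per codon, selected
with per-codon site weights and stochastically rounded counts derived by
inverting the Jukes–Cantor correction at baseline dS = 0.2 and
dN = target·dS. Stochastic rounding keeps the expected Nei–Gojobori
estimate exactly on target while avoiding the upward Jensen bias that
fully Poisson-distributed counts impose on the ratio of two noisy
divergence estimates.

What the generator does **not** emulate: sequencing error and quality
scores, realistic splice-site motifs, chromosome-scale synteny, internal
Met residues, UTR homology between orthologs, and short-read quantification
noise (abundance enters as exact TPM plus multinomial read sampling).
Passing the planted-truth tests therefore demonstrates that the algorithms
recover the structures they are defined on — not that they are robust to
alignment artefacts or base-call errors in real long-read data.

## Numerical and procedural choices

* Collapse 3′ tolerance, APA cluster radius: 5 nt (one shared constant).
* PSI standardization: sample SD (ddof = 1); undefined and zero-variance
  rows dropped.
* Classification precedence fixed as above; output records the matched
  reference transcript where one exists.
* Every stochastic stage (simulation, read sampling, rarefaction) consumes
  a single seeded `numpy` generator; identical (config, seed) reproduces
  every output file byte-for-byte, which the demo asserts by rerunning.
* Demo problem size: 150 ancestral genes × 11 tissues × 1200 reads
  (~26 000 reads across both species), chosen as the smallest scale at
  which every planted structure (conserved events, motif ranks, index
  orderings) is comfortably recoverable; the full demo runs in well under
  a minute on one CPU.

## Known limitations

* Event enumeration is pairwise-local; mutually exclusive exons and other
  complex patterns fall outside the six types and are not reported.
* The NG86 pathway averaging is unweighted, the standard convention;
  maximum-likelihood codon models are out of scope.
* Classification category 7 requires contiguity of the shared sub-chain;
  a transcript matching a reference discontiguously lands in category 2.
* The APA tissue tally counts nonredundant isoforms, not reads, so deeply
  sequenced isoforms do not dominate motif counts — a deliberate choice
  where the source procedure is unspecified.
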