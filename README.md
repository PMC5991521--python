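# isoscape

Comparative analysis of full-length (long-read) transcriptomes for two
related species. Given mapped full-length transcript models per tissue, a
reference annotation, expression matrices, an ortholog table, and a
homolog-presence table, `isoscape` builds the complete analysis stack used
in comparative Iso-Seq studies of paired crops (e.g., a recently duplicated
species against its unduplicated relative, profiled across matched
tissues):

* **Isoform catalog** — collapse reads by exact intron-chain identity
  (5′ starts inside the first exon are redundant; the longest version is
  retained) and classify isoforms against the reference into eight
  categories under a fixed most-specific-first precedence.
* **Alternative splicing** — enumerate six local event types (ES, A5, A3,
  IR, AF, AL), compute per-tissue PSI
  (`PSI = inclusion abundance / total event abundance`), per-tissue
  splicing activity (mean |Z| of PSI across tissues), and cross-species
  conserved events via ortholog + ordinal-architecture matching.
* **NMD** — longest-ORF prediction and the 50-nt rule: a multi-exon isoform
  whose stop codon lies >50 nt upstream of the last exon–exon junction is
  an NMD candidate.
* **APA** — poly(A) cleavage-site extraction, 5-nt single-linkage
  clustering with tissue-specificity tallies, and NUE hexamer scanning over
  the 1–40 nt upstream window.
* **Evolutionary indices** — phylostratum assignment (PS 1–13),
  Nei–Gojobori Ka/Ks with Jukes–Cantor correction
  (`d = −(3/4)·ln(1 − 4p/3)`), and per-tissue transcriptome age and
  divergence indices
  `TAI_s = Σ ps_i·e_is / Σ e_is`, `TDI_s = Σ (Ka/Ks)_i·e_is / Σ e_is`.
* **Comparative utilities** — singleton/duplicate typing against the
  ancestral gene set, cross-species tissue correlation matrices on 1:1
  orthologs, expression-breadth gene classes, and rarefaction curves of
  gene/isoform discovery.

A seeded synthetic generator (`isoscape.synthetic_data`) emits a complete
two-species benchmark — genomes, annotations, per-tissue full-length read
models, expression, orthologs, phylostrata, coding divergence — with every
planted structure recorded in truth tables, so the whole pipeline is
exercisable and verifiable without any external data.

## Worked example

The one-command demo simulates the benchmark, runs every stage on the
emitted files, and verifies the planted truth:

```bash
$ isoscape demo --seed 1 --out demo_out
demo complete: 22/22 truth-recovery assertions passed; report at demo_out/analysis/report.json
```

From `demo_out/analysis/report.json` (seed 1):

* 13 201 species-b reads collapse to **353 nonredundant isoforms** and
  13 207 species-a reads to **485** — every truth isoform with read support,
  recovered exactly; base and 3′-end (APA) isoforms classify as reference
  matches (category 3) and planted splice variants as novel isoforms
  (category 2).
* Species-b event counts `{IR: 34, A3: 21, A5: 19, ES: 13, AF: 10, AL: 7}`
  — intron retention most frequent and alternative last exon least, as
  planted, and equal per type to the planted events observable in the
  reads; **pollen** has the top splicing-activity Z-score.
* 3.4 % of species-b isoforms are NMD candidates, and IR events show the
  highest per-type NMD fraction — only retained introns carry planted
  premature stops.
* The top NUE hexamer is **AATAAA** overall and **ATATAT** in pollen,
  matching the planted motif mix.
* TAI ranges from 3.58 (leaf) to 6.21 (pollen) in species b: the
  reproductive tissue carries the youngest transcriptome, and TDI ranks
  tissues concordantly (Spearman ρ ≈ 0.76).
* 56 conserved AS events are recovered across orthologs — exactly the
  planted conserved pairs observable in both species' reads.

Each number is recomputed from the files the simulator wrote; the demo
fails (nonzero exit) if any truth-recovery assertion does not hold, and a
rerun with the same seed reproduces the report byte-for-byte.

The same stages are available piecewise (`isoscape collapse`, `classify`,
`events`, `psi`, `nmd`, `apa`, `kaks`, `evo`, `compare`, `rarefy`,
`simulate`, `run`) and as library functions with the identical defaults.

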