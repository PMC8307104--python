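# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the literature leaves room.

## Coordinate and strand conventions

Coordinates are 1-based inclusive on the major (J) strand, so a feature
spanning 1–68 is 68 bp long. The deposited sequence orientation *is* the J
strand; minor-strand (N) features are reported in reading direction, i.e. as
the reverse complement of their slice. Intergenic spacers follow the
annotation-table convention: the value attached to a gene is
`next.start − this.end − 1`, negative for overlaps, with a final wrap-around
spacer closing the circle. These definitions make the circular conservation
identity exact — Σ feature lengths + Σ signed spacers = genome length — and
the test suite asserts it for all five packaged species tables.

Wrapping features (start > end across the origin) are supported by the model
and by sequence extraction; none occur in the packaged fixtures.

The five species fixtures were transcribed once from the source annotation
tables with the "same as previous" shorthand fully expanded; the
transcription is itself pinned by tests against the printed per-gene size
and spacer columns and each genome's total length.

## Composition and skews

Skews are computed from raw counts before any rounding:
AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), with the convention 0 when the
denominator is 0. Ambiguity characters (N) are excluded from numerator and
denominator; the reported region `size` keeps the raw span length. Report
rounding is 1 decimal for percentages and 2 for skews; full precision is
kept internally.

Region rows: "all genes" is the whole J-strand genome (size = genome
length, control region included); the PCG/tRNA/rRNA regions concatenate
member sense-strand sequences in genomic order, so N-strand genes contribute
their reverse complement — this is what produces the strong strand asymmetry
of the N-strand codon-position block. Codon-position pooling starts each
gene's frame at its initiation codon and includes trailing incomplete-stop
bases at their frame positions; with the packaged gene lengths this
reproduces the published unequal per-position totals (e.g. 3729/3727/3726
pooled over all 13 PCGs, 2298 + 1431 first positions on the J and N strands,
and 6892 + 4290 = 11182).

Whether published codon-position tables include stop codons is generally
unstated; the inclusive convention above is this package's choice and is
applied consistently.

## Codon usage and RSCU

The genetic code is fixed to NCBI translation table 5 (invertebrate
mitochondrial: TGA = Trp, ATA = Met, AGA/AGG = Ser), giving 62 sense codons
and the family sizes used in RSCU (Leu and Ser have k = 6). RSCU(c) =
count(c)·k / family total; families with zero usage score 0 throughout, and
Σ RSCU over a used family equals k exactly — an invariant the tests assert.
Initiation codons are counted as ordinary sense codons (the nonstandard COI
start CCG in the fixtures is kept verbatim and surfaces in the start-codon
survey, not corrected). Complete stop codons are tallied separately;
incomplete stops never enter codon counts. Codons containing ambiguity
characters are skipped and logged.

## tRNA cloverleaf folding

Folding is a template-constrained search, not free-energy minimisation: no
thermodynamic parameters enter. The annotated anticodon anchors a 7-nt
anticodon loop (all occurrences are tried; a 9-nt loop is available behind
`relax_anticodon_loop` for the one known real exception). Around that
anchor the search enumerates every arm-length combination within the
template bounds — acceptor stem 7 bp; acceptor→DHU connector 0–3 nt;
DHU stem 0 (arm absent, the trnS(AGN) topology) or 2–4 bp with a 3–11 nt
loop; DHU→anticodon connector 0–2 nt; anticodon stem 3–6 bp; variable loop
3–9 nt; TψC stem 3–6 bp with a 3–9 nt loop; unpaired 3' tail 0–3 nt — and
scores each decomposition as 2·(Watson–Crick pairs) + 1·(G·U wobbles) −
1·(mismatches retained in stems). The bounds are configurable
(`TemplateBounds`); the published observed ranges are the defaults. Ties
break deterministically: higher acceptor-stem score, then the canonical
4-bp DHU stem, then a 4–5 nt variable loop, then enumeration order. The
element spans always partition the sequence exactly (asserted per fold).

The scoring weights are this package's choice; they favour canonical
pairing while tolerating the scattered G·U wobbles and U-U/U-C/A-A/A-G/A-C
mismatches observed in real mitochondrial tRNA stems. Cross-species
comparison labels positions conserved/variable at homologous
element-relative offsets (same element, same offset), not raw indices, so
loop-length variation does not smear the comparison.

### Designed tRNA realizations

`design_trna` emits sequences that realize a requested arm-length template
with perfect Watson–Crick stems, used both by the synthetic-genome generator
and by the refolding tests. To make "refold to the generating arm lengths" a
well-posed target, realizations are deliberately unambiguous: stems use G-C
pairs only (random G/C 5' strands, complemented 3' strands), every unpaired
span is adenine (A pairs only with T/U, none of which occurs outside stems
except the planted anticodon, which no candidate stem can reach), and the
acceptor 5' strand is redrawn until it has no period-1/2/3 repeat structure,
which rules out score-tied shifted acceptor windows. Under these rules any
alternative arm-length assignment must pair through an A and scores strictly
worse, so the fold search recovers the generating arm lengths exactly; the
acceptance run measures this over 1,000 random template draws. The price is
an unrealistic base composition for synthetic tRNA genes (G/C stems, A
loops); composition claims are therefore tested on the other regions, whose
generator is a straightforward biased i.i.d. draw.

## Ka/Ks (NG86)

The estimator is Nei–Gojobori (1986) with equal pathway weighting and
Jukes–Cantor correction — the classical counting method that DnaSP's Ka/Ks
implements. Conventions, stated explicitly because NG86 variants differ:

* **Sites.** Each codon position contributes 1 site split by the fraction of
  synonymous single-base mutants; mutants creating stops are excluded and
  the ⅓ weights renormalized over the remaining mutants, so S + N = 3
  exactly for every sense codon.
* **Differences.** All orderings of the differing positions are enumerated;
  pathways through intermediate stop codons are discarded before averaging.
  If every pathway is stop-blocked (rare), all pathways are used and a
  warning logged.
* **Distances.** pS = Sd/S̄ and pN = Nd/N̄ with S̄, N̄ the means of the two
  sequences' totals; d = −¾·ln(1 − 4p/3); p ≥ ¾ raises a saturation error.
* **Missing data.** Codons with gaps or ambiguity in either sequence, and
  terminal stop codons, are deleted pairwise; incomplete-stop remainders are
  trimmed before analysis.
* **Aggregation.** A gene's summary is the unweighted mean of pairwise
  Ka/Ks over pairs where the ratio is defined (Ks > 0); mean(Ka)/mean(Ks)
  is available behind `ratio_of_means=True`. Identical sequences give
  Ka = Ks = 0 with the ratio flagged undefined rather than 0/0.

The per-codon site counts and pathway averages are verified in the tests
against an independent brute-force enumerator over the genetic code.

## Synthetic data

The generator's reference genome follows the packaged *F. sunanensis* gene
plan — order, strands and per-gene lengths — with one deviation: negative
spacers (gene overlaps, e.g. ATP8/ATP6 at −7 bp) are clipped to zero,
because two overlapping reading frames cannot both be satisfied by
generated sequence. The synthetic genome is therefore ~30 bp longer than
the real one; all per-gene lengths, start/stop codons (including the
incomplete stops "T" and "TA" where the fixture has them) and strand
assignments are preserved, and every PCG translates without internal stops
under table 5.

Per-region A+T fractions default to the study's measured values (PCGs 0.72,
tRNAs 0.70, rRNAs 0.73, control region 0.83, spacers 0.75); PCG bodies are
drawn codon-wise with probabilities proportional to the product of the
per-base probabilities over sense codons.

Clade evolution walks a user-supplied Newick tree (branch lengths in
expected substitutions per site). Coding genes evolve codon-aware: each
proposed single-base change is rejected if it creates a stop, accepted if
synonymous, and accepted with probability ω if nonsynonymous; the initiation
codon, the terminal stop (or incomplete-stop remainder) and each tRNA's
anticodon triplet are frozen so annotations stay valid. Non-coding regions
evolve under plain uniform substitution. This acceptance-probability scheme
is *not* a proper codon substitution model (no transition/transversion bias,
no rate heterogeneity, no indels or rearrangements) — it exists to give
monotone, approximately linear control of realized dN/dS, which is all the
recovery tests require, and at moderate divergence the NG86 estimates track
the generating ω closely (≈0.05/0.33/0.85 recovered for ω = 0.05/0.3/0.8).

The default taxon tree is a 12-taxon ingroup ladder plus a 4-taxon outgroup
ladder with 0.05 substitutions/site per branch and 0.08 on the two stems —
genus-level divergence at which Ks is well away from saturation but
estimator noise is small. Recovery runs use 4+2- or 8+2-taxon versions of
the same shape; the 20-replicate ω = 0.3 check uses 8+2 taxa. At very short
branches the mean-of-ratios aggregation is noticeably noise-inflated
(Jensen's inequality with small-Ks denominators), which is the statistical
reason moderate branch lengths are the stated study condition.

One seeded NumPy generator is threaded through generation and tree
traversal in deterministic preorder, so identical seeds reproduce byte-
identical genomes and reports.

## Supermatrix and trees

The phylogenetic dataset is the concatenation of the 13 PCGs + 2 rRNAs in
genomic order (configurable), with a partition table in 1-based concatenated
coordinates that must tile the alignment exactly. Blocks must be
equal-length across taxa — pre-aligned externally, or alignment-free
comparable as in the synthetic data; there is no automatic gap-filling, and
a missing gene is an error. Exports (relaxed PHYLIP, NEXUS with charsets,
FASTA, RAxML-style partition text) round-trip byte-identically; actual ML/BI
inference is performed by external software on these files and is out of
scope, as is any reproduction of published support values.

The internal tree path — p-distance over pairwise-complete columns plus
Saitou–Nei neighbor joining with lowest-index tie-breaking and negative
branch lengths clamped to zero — is a testing device: NJ is consistent on
additive matrices (asserted on random 6–10-leaf trees, and cross-checked
against scikit-bio's implementation), and the monophyly check asks whether
one edge bipartition separates exactly the ingroup.

## Problem sizes in the shipped checks

The test suite and acceptance script run at desk scale: full-length
~15.7 kb genomes; clades of 6–16 taxa; 3 replicate clades per ω for the
monotonicity check and 20 for the ω = 0.3 band; 1,000 random codon pairs
against the NG86 oracle; 1,000 random tRNA designs for refolding. Published
per-gene Ka/Ks values from the real 12-genome data set (nad4L highest,
cox1 lowest) require the deposited accessions and are not recomputed here;
the shipped checks validate the kernel exactly and the estimator's behaviour
on data of known ω.

## Known limitations

* The GenBank reader handles single-record files with plain (non-compound)
  feature locations; join() locations and multi-record files are out of
  scope.
* The fold search reports one best decomposition; co-optimal structures are
  resolved by the deterministic tie-break, not enumerated.
* The ω control is monotone but only approximately calibrated; do not read
  synthetic recovery as a statement about estimator bias on real data.
* p-distance/NJ is for smoke tests; use the exported files with proper
  ML/BI software for real inference.
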