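# Methods

## Overview

`codonsieve` treats both of its tasks — picking the best ORF per
transcript and sorting an ORF pool into taxonomic classes — as the same
supervised problem: classify fixed-length codon-count vectors with an
RBF-kernel support vector classifier, then act on the calibrated class
probabilities. This note records the model, the procedures around it,
the synthetic data generator that serves as the test substrate, and the
numerical choices that were genuinely open.

## ORF enumeration

Transcripts are scanned in all six reading orientations under an NCBI
translation table (tables 1, 4, 6, 10, 12, 29 and 30 are supported; any
table Biopython carries will work). Within a frame, a *complete* ORF is
the maximal stretch from the first ATG after the previous stop through
the next in-frame stop; complete ORFs in one frame therefore never
overlap. Partial enumeration additionally emits stop-bounded stretches
with no start codon and transcript-edge-truncated stretches with no
terminal stop, flagged incomplete. Coordinates are 1-based inclusive on
the forward strand; the frame's sign encodes the strand. Only ATG is a
start codon by default: alternative initiators are accepted by NCBI for
many tables, but using them inflates candidate sets and the packages
this tool is meant to feed (phylogenomics, annotation) expect
methionine-initiated models. The default minimum ORF length is 150 nt
(50 codons, stop included), a conventional floor below which composition
signal is weak; the minimum transcript length default is 300 nt. Both
are configurable.

Under the ciliate code (table 6) only TGA terminates, so ORFs read
through TAA/TAG as glutamine; the four-fold degeneracy sets used by the
composition metrics shift accordingly.

## Preprocessing

Three optional first-stage filters mirror standard practice for de novo
assemblies: a length filter; an rRNA screen; and redundant-isoform
clustering. The internal rRNA screen indexes 31-mers of a user-supplied
rRNA reference and flags transcripts whose shared-31-mer fraction
(either strand) reaches 0.25 — k = 31 makes random collisions negligible
while point mutations up to a few percent still leave most k-mers
intact; k-mers containing N never match. An adapter around barrnap (all
four kingdom models) is provided for production use where the external
tool exists.

Isoform clustering is greedy longest-first (ties broken lexicographically
by id, which also makes the outcome independent of input order): a
record joins the first representative it aligns to at ≥ 0.97 identity
with the alignment covering the whole shorter sequence and ≥ 0.005 of
the longer — the cd-hit-est parameterisation commonly used for isoform
collapse. Identity is computed by edlib semi-global (infix) alignment of
the shorter sequence into the longer, preceded by a shared-11-mer count
prefilter with the bound implied by the identity threshold (e mismatches
destroy at most 11e of the shorter sequence's 11-mers). Representatives
are each cluster's longest member.

## Homology-seeded training for ORF prediction

The classifier that ranks candidate ORFs is trained on the dataset
itself. Transcripts are searched against a user-supplied reference
proteome; each hit's aligned region, read in the hit's frame, becomes an
in-frame positive, and one negative per positive re-reads the same
transcript span in an orientation drawn uniformly (seeded) from the five
non-coding alternatives (+2/+3 on the same strand, any reverse frame).
Training is therefore balanced by construction, and negatives share the
positives' length and base composition — exactly the contrast the
classifier must learn.

The default search backend is internal: exact 5-aa word seeds over all
six query frames, ungapped X-drop extension under BLOSUM62, reported at
≥ 60% identity over ≥ 50 aligned residues, with a Karlin–Altschul-style
bit score (ungapped λ = 0.318, K = 0.13) converted to an E-value against
the default cutoff 1e-30 and one hit kept per query. This is not a
production aligner — it has no gapped extension and no compositional
adjustment — but exact and near-exact matches, which is what a
same-dataset reference search produces, pass it reliably, and the
adapter contract (DIAMOND-style 7-column tabular) lets an external
translated search stand in where installed.

## The classifier

Features are raw counts of the 64 codons in lexicographic order,
counted in-frame and non-overlapping; codons containing non-ACGT
characters are dropped. Counts (not frequencies) are the default
because ORF length itself carries signal for the in-frame/out-of-frame
contrast; a length-normalisation flag exists for pools with extreme
length heterogeneity.

The SVC uses the RBF kernel with scikit-learn's variance-scaled default
gamma. Only C is searched: 25 log-uniform draws from [1e-8, 10] with a
seeded generator, scored by mean 5-fold stratified cross-validated
accuracy, refit on all data at the best C. Exact accuracy ties resolve
to the **larger** C: at vanishing C the dual problem degenerates,
decision values shrink toward zero, and the Platt calibration behind
`predict_proba` collapses to a single class even though hard CV
predictions can still look perfect. Probabilities are libsvm's
per-fold Platt calibration with pairwise coupling; the calibration's
internal randomness is pinned to the global seed, so identical inputs
and seed give bit-identical models and predictions.

Training requires ≥ 2 classes with ≥ 2 examples each and warns below 25
examples per class — the size below which held-out accuracy on
hard mixtures approximates chance (see the regime calibration below).

Best-ORF selection takes, per transcript, the candidate with maximal
in-frame probability; exact ties go to the longer ORF, then the smaller
start coordinate, then the positive frame. The length tie-break is the
behaviour a user wants when two nested or mirrored readings are
indistinguishable to the model.

## Model persistence

A saved model is a zip archive holding JSON metadata (classes, codon
vocabulary, selected C, gamma, search trace, provenance: package
version, seed, training-set hash) and the fitted SVC arrays as raw
`.npy` entries — support vectors, dual coefficients, intercepts, Platt
parameters. Loading rehydrates a fresh estimator from the arrays; no
stored code is executed, and a version/format check rejects unreadable
or incompatible archives rather than degrading silently. Archive
entries carry fixed timestamps so that same-seed reruns are
byte-identical on disk. Round-tripping is tested to reproduce
bit-identical probability matrices.

## Composition metrics and window selection

GC12 is the percent G+C over codon positions 1 and 2, GC3 over position
3, and GC3s restricts GC3 to codons whose amino acid is invariant to any
third-position substitution under the active table (the four-fold set is
recomputed from the table, so table 6 moves it correctly). For the
6-codon leucine/arginine/serine families the four-fold sub-box is
included — degeneracy is evaluated per codon box, not per amino acid.
GC3s is undefined (None/NaN) for sequences with no four-fold codon.
Codons containing non-ACGT characters are excluded from every tally.
Window selection takes a seeded uniform sample of the ids falling inside
both a GC12 and a GC3 window; bounds are inclusive on both ends (the
field mixes inclusive and strict conventions; one was fixed and
documented).

## Evaluation scheme

Reference-based: each prediction is categorised by its best hit —
`full_length` (complete ORF, alignment covering ≥ 98% of both prediction
and reference protein), `useful` (≥ 98% of the prediction over ≥ 66% of
the reference), `in_frame_other`, `out_of_frame` (hit frame ≠ +1
relative to the prediction's own reading), `no_hit`. Label-based:
per-class precision TP/(TP+FP), recall TP/(TP+FN), F1 as their harmonic
mean, macro-F1 as the unweighted class mean; training sequences are
excluded from scoring before tallying. Zero denominators yield 0 with a
warning — a convention this package needed for degenerate synthetic
cases.

## Synthetic data generator

The generator is first-class, tested code: it is the package's entire
test substrate, so its design choices define what the tests demonstrate.

A taxon model is a codon-usage simplex built from a GC3-tilted base
(uniform over position-1/2 identities, third-position base mass split to
hit the GC3 target; stop codons at zero) and perturbed toward a seeded
Dirichlet draw by a `divergence` parameter in [0, 1]; after perturbation
the third-position GC mass is re-pinned to the target, so divergence
moves codon *preferences* while the (GC12, GC3) fingerprint stays
controlled. Divergence presets name the three similarity regimes of a
binary mixture: `distinct` = 1.0, `dissimilar` = 0.35, `identical` =
0.05. The identical preset was calibrated to the phenomenology that
defines the regime — fingerprints indistinguishable by eye, held-out
accuracy at chance with 25 training sequences per class, and a
substantial climb by 100–200 per class (measured: ≈ 0.49 / 0.56 / 0.59
mean accuracy at 25/100/200).

A simulated transcript is 5′UTR + ATG + body codons drawn from the
taxon's usage + stop + 3′UTR, reverse-complemented with probability
`antisense_rate` (default 0.5). CDS lengths are uniform on 100–500
codons, UTR lengths uniform on 20–150 nt, UTR bases i.i.d. at
A/C/G/T = 0.3/0.2/0.2/0.3. The 5′UTR is rejection-sampled so that no
in-frame ATG upstream of the CDS lacks an intervening stop: without
this constraint the transcript's true maximal ORF in the planted frame
can be longer than the planted CDS, making the truth table penalise the
objectively correct maximal-ORF call. The truth table records taxon,
frame and CDS coordinates; the companion proteome holds every CDS
translation and doubles as the reference database for prediction-mode
training. Byte-identical regeneration from config + seed is tested.

What the generator does **not** model — and hence what passing tests do
not show about real data: sequencing error and assembly artefacts
(chimeras, fragmentation: every simulated transcript holds exactly one
complete CDS), expression-level skew, isoform structure, UTR secondary
structure and uATGs, codon-usage covariation along genes, and genuinely
adversarial contamination whose composition matches the target more
closely than the `identical` preset. Performance figures on these
fixtures are upper bounds for clean, well-assembled data, not forecasts
for degraded libraries.

## Statistical checks in the acceptance suite

Two checks are statistical rather than threshold comparisons. The
shuffled-label control asserts CV accuracy within binomial sampling
error of 1/n_classes. The 90:10 imbalance check operationalises
"minority recall compatible with chance" as Youden J — minority recall
minus the false-positive rate into the minority class — t-tested against
zero over 20 replicates at α = 0.01. An uninformative classifier's
minority recall equals its own predicted-minority rate, which varies
replicate to replicate; J = 0 is the correct null for "the classifier
carries no information about the minority class", whereas comparing raw
recall to a fixed 0.5 conflates prediction-rate noise with information.

## Problem sizes

The shipped tests and the acceptance script use 500-transcript
simulations for the prediction pipeline, 20 replicates per condition for
the stochastic decontamination properties, 1,000 random 2-kb transcripts
for the enumeration oracle and 1,000 random CDSs per table for the
composition oracle — sizes at which the binomial error of the measured
rates is well below the asserted margins.

## Known limitations

- The internal translated search is only suitable for near-exact
  reference matches; remote homology needs the external-backend adapter.
- The internal clustering is a contract-faithful simplification of
  greedy identity clustering, not a CD-HIT re-implementation; pathological
  repeat structures may cluster differently.
- No probability floor is applied in classification: every ORF receives
  its argmax label, and the per-class probabilities are exposed so users
  can threshold "unclassified" themselves.
- Multithreading is not implemented; all results are single-threaded and
  deterministic. Runtimes at the shipped problem sizes are seconds to a
  few minutes.
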