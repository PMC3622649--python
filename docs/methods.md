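# Methods

`metagun` re-implements a three-stage support-vector-machine approach to
gene prediction on short, anonymous prokaryotic DNA fragments: (1) naive
Bayes k-mer binning of each fragment to a source genome, genus and domain;
(2) per-domain classification of every candidate ORF from a feature vector
of codon-usage entropy density, translation-initiation-site (TIS) scores
and ORF length; (3) relocation of predicted gene starts with a modified
MetaTISA procedure. This note describes the models, the parameters that
matter, the synthetic data the package trains and validates on, and the
numerical choices made where the design was open.

## Stage 1 — fragment binning

Each training genome contributes a probability table over all 4^k k-mers
(default k = 8, configurable 1..12), counted on both strands with add-one
smoothing. Pooling strands makes the table strand-symmetric, so the
unknown sequencing orientation of a fragment is irrelevant. A fragment of
length n is scored per genome by the sum of log probabilities of its
(n−k+1) overlapping k-mers plus a uniform log prior; the posterior is the
softmax over genomes, and the argmax genome's genus and domain label the
fragment. Score ties resolve to the lexicographically smallest genome id.
Fragments shorter than k (or containing no N-free k-mer) are unclassifiable
and default to the Bacteria domain, the majority domain of typical
reference collections. Because strands are pooled, two genomes whose
sequences are reverse complements of each other are indistinguishable by
construction.

## Stage 2 — ORF classification

**ORF extraction.** In each of the six reading frames, every maximal
stop-free codon run bounded by in-frame stops (TAA/TAG/TGA) or fragment
edges yields at most one candidate ORF. A run bounded on the left by a
stop requires an in-frame start codon (ATG/GTG/TTG; CTG excluded) and its
extent begins at the 5'-most start. A run touching the left oriented edge
is treated as 5'-incomplete regardless of internal start codons — the true
start may lie off the fragment — with its extent starting on the edge codon
grid and any internal starts kept as TIS candidates for stage 3. Runs
touching the right edge are 3'-incomplete. Extents shorter than 60 bp are
discarded; at that length an ORF carries too little composition signal to
classify.

**Entropy density profile (EDP).** Codon counts c over the 61 sense codons
(terminal stop excluded, codons containing N skipped) are transformed to

    s_i = −(1/H) c_i log c_i,  H = −Σ_i c_i log c_i.

The profile is invariant to the logarithm base and to count rescaling, and
sums to one whenever H > 0; the H = 0 single-codon case is defined as the
one-hot limit. EDP emphasises which codons carry the entropy of the usage
distribution, separating the concentrated usage of genes under translational
selection from the near-uniform usage of random ORFs.

**TIS scores.** For 5'-complete ORFs, the (Pt, Pnc, Pco) triplet of the
highest-Pt candidate start (see stage 3) joins the feature vector;
5'-incomplete ORFs carry no TIS block and are classified by a separate
model. A 5'-complete ORF whose candidates all fail the 10 bp upstream
requirement receives the uninformative (1/3, 1/3, 1/3) fill to keep the
layout fixed.

**Length features.** Two slots: complete-ORF length and incomplete-ORF
length, the inapplicable one zero. Gene lengths average ~950 bp against
much shorter random ORFs, and the informativeness of an observed length
differs sharply between complete and edge-truncated ORFs, hence the split.
Lengths are divided by 1500 bp (the maximum training fragment length) and
capped at 1.0 so they are commensurate with the EDP and TIS blocks inside
a Gaussian kernel; the scaling constant is recorded in the model artifact.

**Classifiers.** One Gaussian-kernel SVM per (domain × 5'-completeness)
cell — 66 input dimensions for 5'-complete ORFs, 63 otherwise. Training
vectors come from fragments sampled at 3× coverage with lengths uniform on
60–1500 bp from annotated genomes; an ORF is labelled coding when it
originates from an annotated gene (identical 3' end, or same strand and
frame overlap when the 3' end is off-fragment — the mirror of the
evaluation rule). Training sets above 1.6 M vectors are subsampled
uniformly at random (seeded). The RBF width γ and penalty C are selected
by 5-fold cross-validated grid search over γ ∈ {2^−15, 2^−13, …, 2^3} and
C ∈ {2^−5, 2^−3, …, 2^15}, ties resolved toward smaller C then smaller γ.
The search runs on a seeded stratified subsample of at most 2000 vectors —
the standard coarse-search economy for RBF SVMs, keeping the 110-point
grid affordable — and the final model is fit on all retained vectors with
Platt-sigmoid calibration on an internal split, so each ORF receives a
coding probability derived from its distance to the separating hyperplane.

**Novel module.** A sample-specific second bank of SVMs trained from
conserved-domain evidence supplied as a 3-column hit table: ORFs with a hit
at e-value strictly below 1e-40 are positives; ORFs overlapping a positive
by strictly more than 90 bp in a different reading frame ("shadow" ORFs)
are negatives. Cells missing a class are skipped with a warning. An ORF is
finally called coding when **either** module's probability strictly exceeds
the threshold (default 0.5): the union rule matches the novel module's
purpose of adding genes the universal module misses, and each prediction
records which module fired so the choice is auditable.

## Stage 3 — TIS scoring and relocation

Each candidate start is scored by a three-class generative model — true
TIS, false start in non-coding context (Pnc), false start inside coding
sequence (Pco) — combining (i) a positional Markov chain of order m ≤ 2
(default 2) over up to 50 bases upstream of the candidate, (ii) a
start-codon usage distribution over {ATG, GTG, TTG}, and (iii) empirical
class priors; the class log-likelihoods are softmax-normalised. Candidates
with fewer than 10 bp of upstream context are skipped. Truncated windows
use only the available context, with positions indexed from the start codon
so the Shine-Dalgarno region stays aligned.

Training is supervised from provided annotations: true windows at annotated
starts; upstream-false windows at in-frame start codons 5' of the annotated
start, walking until the first in-frame stop — i.e. the same stop-free-run
geometry a candidate list has on a fragment, which deliberately includes
contexts overlapping a neighbouring gene in another frame (non-coding in
the candidate's own frame); downstream-false windows at in-frame starts
inside the annotated gene. Parameter sets are keyed by genus, with
domain-pooled fallbacks; the fragment's stage-1 genus picks the set, and
fragments binned to an unseen genus fall back to the domain pool, then to
skipping relocation.

Positional tables use add-one smoothing at order 0 and recursive shrinkage
of each higher order toward the next lower one (pseudo-count mass 4).
Desk-scale training provides only as many windows per class as the genome
has annotated starts (tens to hundreds), far too few for raw per-offset
order-2 tables (64 cells each); without shrinkage, motif-free windows can
reach Pt ≈ 1 through sampling noise. On the SD-motif benchmark below this
choice raises internal-TIS recovery from 79% to 96.5%.

Relocation: for a 5'-complete ORF the highest-Pt eligible candidate wins,
ties to the 5'-most (starts tend to be the leftmost plausible codon). For
a 5'-incomplete ORF the 5'-most eligible candidate is first tested against
the training distribution of Pco at coding-interior starts: if its Pco
falls inside the central 95% mass (two-sided; the level is configurable,
and raising it can only increase edge calls), the candidate itself looks
like coding interior, the true start is deemed off-fragment, and the edge
sentinel is returned. The reference distribution is recorded at truncated
upstream lengths (10–50 bp) as well as full windows, because fragment-edge
candidates are scored on truncated windows with systematically milder
posteriors; with full-window references only, the central band collapses
to [~0.99, 1] and the edge test misfires. ORFs with no eligible candidate
return the edge sentinel.

## Synthetic data

The generator emulates what the predictor exploits in real prokaryotic
genomes, with explicit limits:

* genes placed non-overlapping on both strands to a target coding density
  (default 0.9), lengths from a gamma distribution (shape 2.5) with mean
  950 bp, minimum 90 bp;
* interior codons i.i.d. from a genome-specific usage drawn from a
  Dirichlet over the 61 sense codons (default concentration 0.2 — strongly
  biased, as in genomes under translational selection); families of related
  genomes are built by concentrating draws around a shared base usage;
* start codons 0.80/0.15/0.05 over ATG/GTG/TTG; stop codons 0.60/0.15/0.25
  over TAA/TAG/TGA;
* an AGGAGG Shine-Dalgarno motif written at −12..−7 of a configurable
  fraction of starts (default 0.8; the TIS benchmarks use 1.0, the
  condition under which start relocation is assessed);
* intergenic background i.i.d. at a target GC (default 0.5), minimum gap
  20 bp.

Fragments are sampled uniformly with random strands, error-free, at a
target coverage, with fixed or uniform lengths; each fragment carries a
truth map of projected genes with completeness flags, 3'-end coordinates
and internal/external TIS positions. Genes overlapping a fragment by fewer
than 60 bp are dropped from truth (no ≥60 bp ORF can represent them).

What the generator does **not** model: operon structure and overlapping
genes, codon autocorrelation within genes, leaderless transcription, GC
skew, repeats, horizontal transfer, sequencing error. Passing benchmarks
therefore demonstrate that the pipeline machinery recovers planted
structure under its own assumptions, not field accuracy on real
metagenomes; real-genome accuracy depends on reference breadth and
annotation quality that desk-scale synthetic data cannot emulate.

## Evaluation

A prediction is a true positive when its 3' end exactly matches an
annotated gene's 3' end, or, when the truth 3' end runs off the fragment,
when it matches the gene's strand and reading frame with overlap. A truth
gene matched by several predictions counts once; Sn = 100·TP/|truth|,
Sp = 100·TP/|predictions|, combined as Hm = 2·Sn·Sp/(Sn+Sp). TIS accuracy
is assessed on true-positive genes only: internal starts (inside the
fragment) must be predicted exactly; external starts are correct iff the
edge sentinel is reported. Genes shorter than 60 bp are excluded from
truth throughout.

## Reference study conditions (and why these sizes)

The package's benchmark harness (`metagun.benchmarks`) fixes the problem
sizes the test suite and the acceptance script run at:

* binning self-assignment: 4 × 100 kb genomes, 500 fragments of 870 bp —
  k-mer tables converge quickly, so full size is cheap;
* classifier recovery: 2,000 + 2,000 codon-usage profiles, default grid,
  25% held out;
* end-to-end: 50 kb genomes, two per domain plus one held-out Bacteria
  genome of the same family, 3× coverage at 870 bp. Fifty-kilobase genomes
  give ~47 genes each — enough to train genus TIS parameters (minimum 30
  starts) and a few thousand SVM vectors per cell, while the whole
  benchmark stays around a minute.

The held-out genome shares its family's base codon usage but none of its
sequence: this mirrors the intended deployment, where binning routes a
fragment to the *closest* reference genome and that genome's parameters are
the ones applied. Generalisation across unrelated codon usages is a
reference-coverage question, not something two training genomes can answer.

## Numerical and degenerate-input choices

* Natural log throughout EDP (base provably cancels); H = 0 → one-hot.
* ORFs with fewer than two countable codons raise a degenerate-input error
  and are skipped by the pipeline.
* Non-ACGT input characters become N; codons and k-mers containing N are
  excluded from every count.
* Posterior normalisations (binning softmax, TIS softmax) are computed via
  log-sum-exp; triplets sum to 1 within 1e-9.
* All sampling (genome generation, fragment sampling, training subsets,
  CV folds) flows from explicit integer seeds; identical inputs give
  bit-identical outputs.
* Empty truth sets make sensitivity undefined and raise rather than return
  a silent zero.

## Known limitations

* The external-TIS edge test inherits the saturation of Pco posteriors;
  its accuracy (~90% on the benchmark) trails internal accuracy and
  degrades when the binned genus's codon usage is a poor match.
* The novel module depends entirely on externally produced domain-hit
  tables; no homology search is performed in-package.
* No overlap resolution between coding calls is applied by default (every
  ORF is scored independently); dense gene packing can therefore yield
  overlapping calls in different frames.
* Sequencing errors and frameshifts are out of scope; inputs are assumed
  error-free.
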