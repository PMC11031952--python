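# Methods

## Data model and preprocessing

The unit of analysis is a labelled, fixed-length DNA window: 101 bp by
default, matching the footprint-trimming convention of extracting the
central ±50 bp around a footprint midpoint. BED intervals are 0-based
half-open; the window center is `floor((start + end)/2)` and the window is
`center − 50 … center + 51` (the rounding convention is ours — fixed and
documented here because no single standard exists). Windows running off a
chromosome, and windows containing non-ACGT symbols, are skipped with
logged counts.

Negatives are per-sequence mononucleotide shuffles of the positives: a
uniform random permutation of each positive's bases, preserving the base
composition exactly while destroying positional structure. A
dinucleotide-preserving shuffle (Altschul–Erickson Eulerian walk) is
provided as an option but is not the default, because the classifier's
negatives are meant to be composition-matched, not
dinucleotide-matched.

Sequences are split into overlapping k-mers with a sliding window of
length `lenk` (default 5) and step 1, so a length-L sequence yields
exactly `L − lenk + 1` occurrences. Train/validation/test splits are
80/10/10, stratified by label (each part keeps the class ratio to within
one record) — stratification matters because the motif-extraction step
calibrates background noise on negatives and assumes both classes are
represented.

## The heterogeneous graph

Three subgraphs connect the m unique k-mers and n sequences:

* **Similarity** `W_sim(x,y) = (lenk − d_H(x,y))/lenk` for
  `0 < d_H ≤ sim_max_mismatch` (default 1), else 0. One mismatch connects
  single-mutation motif variants, which is what the first attention layer
  needs to pool; the cutoff is configurable.
* **Coexisting** `W_co(x,y)` = fraction of positive sequences containing
  both x and y, **kept only when the co-occurrence count exceeds the
  independence expectation `N·p_x·p_y` by more than 3 binomial standard
  deviations** (`min_z = 3.0`; 0 disables the filter). The filter is
  essential, not cosmetic: with ~97 distinct 5-mers per 101 bp sequence
  and a vocabulary near 4⁵ = 1024, almost every k-mer pair co-occurs in
  *some* positive, so the unfiltered subgraph is near-complete and its
  attention head provably carries no signal (we measured the coexisting
  attention of a trained model at uniform level on the unfiltered graph,
  while the similarity head concentrated 20-fold). Thresholding keeps the
  pairs that genuinely travel together — for motif-bearing data, the
  overlapping windows of the shared motif. Negatives are excluded from
  the statistic by default (they are shuffles and only add noise); a flag
  includes them.
* **Inclusive** `W_inclu(x,z)` = raw occurrence count of k-mer x in
  sequence z. No TF-IDF-style rescaling: the learned projection that
  initializes sequence embeddings subsumes any fixed rescaling.

Separately from `W_co`, `CoexistStats` counts, per ordered k-mer pair
(x, y), the number of positive sequences in which an occurrence of y
starts exactly one base after an occurrence of x. The **coexisting
probability** `P(y follows x | x present) = pair_count(x,y)/kmer_count(x)`
drives seed chaining; it is deliberately an immediate-adjacency statistic
because chaining joins seeds at consecutive offsets.

## The network

Single-head graph attention, one attention vector per k-mer subgraph,
LeakyReLU slope 0.2 (the standard graph-attention default; the activation
is named in the model definition but its slope is not). Initial k-mer
embeddings are the subgraph weight columns normalized by total
neighborhood weight, so each sums to 1 over its support. Neighborhoods
exclude the node itself (the weight matrices have zero diagonals);
isolated k-mers receive a unit self-loop so their embedding and attention
row stay defined. Sequence embeddings are initialized by projecting the
inclusive count column through a learned m×d matrix, scored against both
k-mer embedding sets, softmax-normalized per subgraph, aggregated, and
classified by a single fully-connected sigmoid unit (the model names one
fully connected layer; we take that literally).

**Implementation.** The network is dense numpy with hand-derived
backpropagation for this fixed architecture. The graphs are small (m ≤ 4^lenk
nodes), so dense masked attention — softmax over −∞-masked score matrices —
is simpler and faster on one CPU than sparse message passing, and the
gradient of every parameter is checked against central finite differences
in the test suite (tolerance 2e-4 relative; the only looseness comes from
LeakyReLU kinks near zero).

**Training.** Full-batch Adam (β₁ = 0.9, β₂ = 0.999), binary cross-entropy,
300 epochs by default, initial learning rate 0.02. The stated "natural
decay rate of 0.001" is ambiguous between learning-rate decay and weight
decay; both are implemented, and per-epoch exponential learning-rate decay
`lr_t = lr₀·e^(−0.001 t)` is the default (`decay_mode="lr_exp"`) — in our
experiments additive weight decay at this coefficient kept the loss at its
trivial value and never learned, while lr decay trains stably. Dropout 0.3
is applied (inverted, training only) to the normalized attention rows and
to the sequence embedding before the classifier; we also evaluated
input-count dropout and found no difference. Parameters are initialized
with seeded Glorot-uniform scaling. Model selection returns the epoch with
the best validation F1 at threshold 0.5 (ties go to the earlier epoch);
without a validation set the final epoch is returned. Training is
deterministic given the seed; a non-finite loss aborts with a diagnostic.

Held-out sequences are scored against the training graph: their inclusive
count columns are built from the training vocabulary (unseen k-mers are
ignored; a sequence sharing no k-mer with the vocabulary — essentially
impossible at lenk = 5 — scores 0.5).

## Motif extraction

Per-subgraph attention rows of positive sequences are denoised by
subtracting a scalar background: the mean coefficient of the negative
rows, averaged **over inclusive-edge cells only** (non-edges carry no
coefficient, so including them would dilute the background toward zero).
A k-mer occurrence on a positive sequence is a seed when either denoised
coefficient is strictly positive; because merging is positional, a k-mer
occurring at several offsets seeds each occurrence separately.

Within a sequence, seeds sorted by offset chain left-to-right when their
offsets differ by exactly 1 *and* the coexisting probability of the
adjacent pair is ≥ θ_co (default 0.5). Gaps larger than one base always
break chains — the adjacency statistic is only defined for immediate
succession. Each maximal chain spans first offset … last offset + lenk;
singletons give lenk-wide candidates. Overlapping candidates (sharing at
least one base; abutting does not count) are unioned per sequence.
Instances are grouped by exact width — widths differing by one are not
pooled — and groups with ≥ min_support (default 5) instances become PPMs
with additive pseudocount 0.01. θ_co, min_support and the pseudocount are
recorded in every run's provenance JSON. MEME minimal format export
(6-decimal probabilities, empirical positive-set background) round-trips
bit-identically at printed precision.

## Evaluation

Precision, recall, F1, accuracy at threshold 0.5; AUC as the trapezoidal
ROC area (equal to the tie-corrected pairwise ordering probability); PRC
as average precision (step-wise, not interpolated — "PRC" is named but
not defined, so the convention is fixed here). Undefined ratios report
0.0; AUC/PRC on single-class inputs report NaN. Motifs with an externally
supplied −log₁₀(p) strictly above −log₁₀(0.05) = 1.301 are flagged
significant (p = 0.05 exactly is not).

## The synthetic benchmark: what it shows and what it does not

`generate_synthetic` emulates the footprint-window data shape: uniform
i.i.d. background (101 bp), one motif instance per positive sampled
column-wise from a known PPM at a uniformly random offset (occurrence
rate 1.0 by default), negatives by mononucleotide shuffling. Defaults for
the study configuration — 500 positives + 500 negatives, width 8 at 1.5
bits/column — are the package's reference conditions; `generate_ppm`
solves the dominant-base probability by bisection so each column carries
exactly the requested information content, with the residual mass spread
evenly over the other three bases.

What passing shows: with a shared planted motif, the trained similarity
attention concentrates an order of magnitude above uniform on the motif's
k-mer windows, the seed/chain/merge procedure reassembles instances at
the planted width, and the resulting PPM matches the source matrix
(best-offset mean per-column Pearson correlation ≥ 0.99 in our runs).

What it does not show: real accessible-chromatin windows contain multiple
motifs of varying occurrence rates, positional biases and non-i.i.d.
background; none of that is modelled. Classification on this benchmark is
also intrinsically bounded: the network classifies from k-mer *count
vectors* (positions are discarded by the inclusive matrix), and a
1.5-bit/column 8-mer fragments into 5-mers carrying ~7.5 bits each,
against a ~8.6-bit requirement for a specific 5-mer to be rare among the
97 windows of a 101 bp sequence. Concretely, an exact consensus 5-mer is
present in ~87% of positives but also ~25% of shuffled negatives by
chance. At the reference sample size (800 training sequences) held-out
accuracy plateaus near 0.85 (AUC ≈ 0.86–0.91) — and reference methods
agree: logistic regression on the same counts reaches ~0.77, a boosted
tree needs ~20× the training data to approach the ≈0.92 count-vector
ceiling we estimate empirically. High nineties accuracy on real ATAC-seq
data is consistent with this: real positive sets share several motifs and
longer, lower-entropy ones.

## Numerical and degenerate-input choices

Masked softmax subtracts the row maximum before exponentiation; rows are
nonempty by construction (isolated nodes self-loop, sequences with no
k-mers are rejected in the strict API and scored 0.5 in batch
prediction). ReLU/LeakyReLU subgradients at 0 take the negative-side
slope. PPM column correlations between constant columns are defined as 1
when the columns are equal and 0 otherwise. Splitting uses
largest-remainder rounding per class, ties resolved toward the earlier
part (train first). All randomness — initialization, dropout, shuffles,
generators — flows from explicit integer seeds through
`numpy.random.default_rng`, and end-to-end runs are bit-reproducible.

## Known limitations

Dense m×m attention bounds practical vocabulary size (fine for lenk ≤ 6;
lenk ≥ 8 would need sparse attention). Single-cell ATAC modalities,
footprint calling itself (TOBIAS/HINT-ATAC), and motif-database matching
(TOMTOM/HOCOMOCO) are out of scope — the MEME export is the integration
point for the latter. The transductive-style training offers no
cross-dataset transfer: a model is bound to its training vocabulary.
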