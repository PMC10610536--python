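# Methods

## The prediction problem

An ordered drug pair (A, B) is assigned one of T directional interaction
types, or no type at all when the evidence is weak. Two information channels
feed the classifier: chemical structure (similar molecules tend to interact
similarly) and the protein context of each drug's carriers, transporters,
enzymes and targets (CTET). The package's central modeling claim is that the
protein channel should be read *through the interaction network*: two drugs
whose CTET sets are disjoint may still perturb the same pathway one or two
protein–protein interactions away, and a direct overlap measure is blind to
that.

## Structure channel (SSP)

SMILES strings are parsed and canonicalized with RDKit and hashed into
binary topological path-based fingerprints (2048 bits by default; the
fingerprint family and width are configurable). Pairwise similarity is the
Tanimoto coefficient |a∧b| / |a∨b|, with the 0/0 case of two empty
fingerprints defined as 0 (no shared substructure evidence). A drug's SSP is
its row of similarities against the whole modeling universe, so the SSP
matrix is square, symmetric, unit-diagonal and bounded in [0, 1]. The
universe is the set of modelable drugs (valid SMILES and at least one
network-present CTET protein); drugs missing either field are loaded but
flagged and excluded from modeling.

## Network channel (PSP)

**Filtering.** PPI edges are kept when their confidence score reaches the
empirical top-`keep_fraction` order statistic (ties at the cutoff retained,
so at least ⌈keep_fraction·n⌉ edges survive). Confidence plays no further
role: the surviving adjacency is binarized, because the propagation operates
on the network's topology, not its score scale (a score-weighted variant is
available as a switch for sensitivity analysis). Nodes isolated by the
filter drop out — they can neither receive nor forward probability mass.

**Walk convention.** The transition matrix is the column-normalized
adjacency `W = A D⁻¹` and the restart walk iterates
`p(t+1) = (1−r)·W·p(t) + r·p(0)`. For a symmetric adjacency this is
identical to applying the transpose of the *row*-normalized adjacency, i.e.
the standard "normalized adjacency" restart walk; we fix this convention
explicitly because it is the one under which total probability mass is
conserved exactly at every iteration, which the test suite asserts to
1e-12. The iteration contracts in L1 at rate ≤ (1−r), so the default
tolerance 1e-6 with max_iter = 100 is conservative for any r ≥ 0.1. The
restart probability defaults to r = 0.5 — a mid-range choice balancing
seed locality against diffusion reach — and every propagation property in
the tests is asserted across r ∈ {0.1, 0.5, 0.9}.

**Seeding and scoring.** A drug's seed distribution is uniform over its
network-present CTET proteins; seeds absent from the filtered network are
dropped with a warning (only a fully absent set is an error), and the same
rule applies to the target side: the association score of (A, B) is the mean
of A's stationary probabilities over B's *network-present* CTET proteins.
Averaging over present proteins rather than counting absent ones as zeros
keeps the score a proper mean of probabilities (hence in [0, 1]) and does
not penalize a drug for network coverage it cannot control. The diagonal
PSP(i,i) is computed like any other entry, not pinned to 1, and the matrix
is left asymmetric — propagation is seeded from the row drug.

**Baseline.** The non-walk comparator encodes each drug as a binary CTET
indicator vector over the protein universe and scores pairs with Tanimoto.
It is symmetric and sees only direct overlap; on a path u—x—v with CTET
sets {u} and {v} it returns exactly 0 while the walk returns a positive
association, which is the mechanism the planted indirect fixture isolates.

## Features and classifier

PCA is fitted once per profile matrix (drugs are rows); the pair-level
train/test split happens downstream, so profile fitting sees no labels.
Requested dimensions above the matrix rank are truncated with a warning,
and a fixed sign convention (largest-magnitude loading of each component
made positive) keeps repeated fits bit-identical. An ordered pair's feature
vector is the concatenation [ssp_A, psp_A, ssp_B, psp_B] — ordered because
the interaction types are directional.

The classifier is a feed-forward softmax network: input → four 1024-node
ReLU layers with inverted dropout 0.3 → T-way softmax, trained with
mini-batch Adam (batch 128, learning rate 1e-3, 100 epochs). It is
implemented directly on NumPy — forward/backward passes, dropout masks and
the Adam update — with every random draw (initialization, shuffling,
dropout) taken from a single seeded generator, so training is exactly
reproducible and the degenerate learning-rate-0 case provably leaves the
loss trajectory flat. The recorded trajectory is the full-data
cross-entropy in inference mode after each epoch. Types with no training
examples stay in the output layer with a warning.

Prediction takes the argmax class (ties toward the lowest type index) and
asserts it only when its probability reaches the decision threshold
τ = 0.47; otherwise the pair is reported as "none" with its confidence.
Raising τ can only turn predictions into abstentions, never the reverse.

## Evaluation protocol

Pairs are split 7:3 stratified by type (per-type counts within one pair of
the global fraction; singleton types go wholly to train), or into k = 4
stratified folds for cross-validation. Metrics: pair-level accuracy
(abstentions count as wrong), one-vs-rest precision and recall per type
present in the truth set, macro averages, and macro F1 as the harmonic mean
of macro precision and macro recall (the per-type-mean alternative is
behind a flag). Abstentions never enter a precision denominator — "no
prediction" is not a predicted class — but do count as recall failures.
The abstention rate is reported separately. False-positive triage sorts
non-abstained misclassifications by descending confidence (ties broken
lexicographically on the pair) and truncates to the top k (default 10).

## Synthetic data

The generator emulates the statistical structure the method assumes, not
realistic biology: a preferential-attachment (Barabási–Albert) network per
community plus sparse uniform inter-community edges, uniform random
confidence scores (so the quantile filter does real work), CTET sets drawn
from the drug's home community, and structures derived from per-community
templates. In SMILES mode the template is a heteroatom chain over
{C, N, O, S} with per-position corruption probability `structure_noise`, so
chemical similarity genuinely flows through RDKit fingerprints; fingerprint
mode emits template bit-vectors with per-bit flips directly and bypasses
chemistry. The label of (A, B) is `(home(A)·c + home(B)) mod T + 1` —
deterministic in exactly the information the two channels carry, so Bayes
accuracy is 1 and recovery failures indict the pipeline, not the data. All
randomness descends from one config seed through named child generators;
identical configs produce byte-identical files.

What the generator does *not* emulate: drug-like chemistry, realistic PPI
degree mixing or clustering, label noise, or the extreme class imbalance of
curated interaction databases. Passing the synthetic benchmarks therefore
demonstrates the pipeline's correctness and the walk's indirect-signal
advantage under controlled conditions, not field performance on curated
drug data.

## Frozen benchmarks

`ddiwalk.benchmarks` pins two study designs:

- **Recovery** — 120 drugs, 300 proteins, 3 communities, 9 types, 5%
  structure noise, all ordered pairs; pipeline with keep_fraction 0.8,
  r = 0.5, 40 + 40 PCA components and a 2×256 classifier trained 30 epochs.
  The filter keeps 80% here (not a STRING-scale 20%) because a 300-protein
  modular network loses connectivity — and with it, drugs — when four of
  five edges are cut; the quantile rule itself is still exercised. The compact classifier
  is matched to the problem size; held-out accuracy should be ≈ 1.
- **Walk advantage** — 180 drugs with *singleton* CTET sets (direct overlap
  between same-community drugs is essentially zero), fully randomized
  structures (noise 1.0), a 4000-pair sample and a compact 2×128
  classifier, identical in both arms; only the PSP construction differs.
  The design is deliberately off the accuracy ceiling: with a pair-level
  split every drug occurs in both halves, so an over-sized network can
  memorize each drug's community from *any* drug-distinguishing feature
  and both arms saturate, hiding the contrast. Under a matched, limited
  budget the walk's smooth community-clustered features generalize where
  the baseline's near-identity features cannot (observed ≈ 0.97 vs ≈ 0.70
  across seeds).

## Numerical and degenerate-input choices

- Duplicate undirected PPI edges collapse to the maximum score
  (conservative under top-confidence filtering); self-edges are dropped.
- Quantile filtering uses the order statistic, never interpolation.
- Tanimoto of two empty sets is 0; an association score whose target set
  is entirely off-network raises a distinct undefined-score error rather
  than returning 0.
- Argmax ties break toward the lowest type index; false-positive ranking
  ties break on pair ids.
- Confidence values serialize at full precision; prediction round-trips
  preserve them to ≥ 9 significant digits.

## Known limitations

- The restart probability, the pair-assembly rule (concatenation), and
  averaging over present-only target proteins are modeling choices; all are
  exposed as parameters or documented conventions rather than hidden.
- PCA is fitted on the full drug universe before the pair split. Profiles
  carry no labels, but test-drug *features* do influence the fitted basis;
  this matches the intended workflow and is documented as an
  information-flow choice.
- Pair-level splits allow drug-identity memorization (see the advantage
  benchmark); conclusions about generalization to unseen *drugs* would
  need a drug-disjoint split, which this protocol does not implement.
- The NumPy classifier is single-threaded and CPU-bound; it is sized for
  desk-scale experiments, not for hundreds of thousands of pairs with
  1000-dimensional inputs, although the paper-scale defaults are available.
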