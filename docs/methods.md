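# Methods

## Sequence representation

Residues are encoded against Taylor's ten overlapping physicochemical
groups, fixed in the order Polar (1), Positive (2), Negative (3),
Charged (4), Hydrophobic (5), Aliphatic (6), Aromatic (7), Small (8),
Tiny (9), Proline (10). The grouping ships as a versioned plain-text
resource (`popmgram/data/taylor_properties.tsv`, one line per group) so
alternative schemes can be swapped in; group cardinalities are
12/3/2/5/13/3/4/9/4/1 and every standard residue belongs to between 1
and 4 groups. Note that the Tiny set is a subset of Small, so e.g.
alanine carries both bits (`0000100110`).

Input is case-folded to uppercase. Non-standard residue codes
(B, J, O, U, X, Z) are encoded as all-zero rows rather than dropped:
this preserves positional structure for the tri-gram window (any window
touching such a row contributes zero to every feature but still counts
in the denominator). Stop (`*`) and gap (`-`) characters are stripped
with a warning at FASTA read time. Modified residues and three-letter
codes are unsupported.

## Tri-gram features

For property triple (x, y, z), the feature is the mean over the L − 2
length-3 windows of M[i,x]·M[i+1,y]·M[i+2,z], computed vectorized via an
einsum over the three shifted copies of the POPM. Features are laid out
lexicographically in (x, y, z) — flat index (x−1)·100 + (y−1)·10 +
(z−1) — which is deterministic and trivially invertible; a stable layout
is required for RFE rank reproducibility. Sequences shorter than 3
residues are rejected (the denominator would be non-positive).

Useful identities used as test oracles: every feature lies in [0, 1];
the total feature mass equals the mean product of three consecutive
row sums; a homopolymer of a residue with k properties has exactly k³
unit-valued features. Features are not rescaled by default (they already
live in [0, 1]); the encoder has an optional z-scoring switch for
experimentation.

## Feature selection

SVM-RFE with a linear one-vs-one SVM (libsvm via scikit-learn's `SVC`).
A feature's criterion is the sum over all C(C−1)/2 binary machines of
its squared weight. Defaults: elimination step 1 (the original RFE
schedule; configurable — larger steps are used in tests and the sweep
for speed and change only ranking resolution), cost C = 1.0 (the
standard default; the method's source material fixes only the linear
kernel, so both are exposed configuration, not inferences). Ties in the
criterion are broken by removing the feature with the larger flat index
first. The per-iteration elimination log is retained and reconstructs
the ranking exactly.

Numerical caveat: the linear-SVM weight vector is unique in exact
arithmetic, but libsvm solves to tolerance 1e-3, so the relative order
of near-tied (pure-noise) features can change under sample permutation.
Informative features' ranks are stable; byte-identical rankings are
guaranteed only for identical input order.

## Evaluation

Jackknife (leave-one-out) with two modes. `paper` mode ranks once on
the full matrix, selects the top k (default 120), then leaves each
sample out of the SVM fit only — this reflects drawing top-K curves
from a single ranked list per dataset, but leaks selection information
into the folds. `leak_free` mode re-ranks inside every fold on the n−1
training samples and is recommended for any new application; on cleanly
separable data the two agree. Fold order is dataset order; nothing in
the default pipeline is stochastic, so reports are reproducible without
a seed.

Per-class Sens, Spec and MCC come from the one-vs-rest collapse of the
aggregated confusion matrix; OA is the trace over the total. Any metric
with a zero denominator is reported as 0 and flagged
(`zero_denominator`), keeping sweep tables total; the flag is preserved
in the JSON report. Classes with a single member are rejected (their
fold has no same-class training example) unless explicitly allowed.
Report class order is first-appearance order of the labels.

The top-K sweep evaluates K = 10, 20, …, 300 by default and reports the
argmax (smallest K on ties). In paper mode the ranking is computed once
and shared across the grid.

## Synthetic data

The generator draws residues i.i.d. from per-class categorical profiles
over the 20 standard residues: profile = (1 − s)·uniform +
s·uniform(residue subset), with `informative_strength` s = 0.8 by
default and subsets on distinct physicochemical axes (aromatic {F,Y,W},
aliphatic {I,V,L}, charged {K,R,D,E}, tiny {A,S,G,C}, and for six-class
designs additionally polar-uncharged {N,Q,S,T} and positive {K,R,H}).
Sequence lengths are uniform on (50, 500), spanning typical benchmark
protein lengths at desk-scale runtime; the benchmark extremes (76 and
3037 residues) are covered by encoding tests at those exact lengths.
Benchmark-shaped presets mirror the two public apoptosis benchmarks'
class counts: 4 classes sized 41/70/25/89 (225 total) and 6 classes
sized 112/47/55/34/52/17 (317 total).

The i.i.d. simplification is deliberate: tri-gram features measure
short-range property co-occurrence, so composition separation in
property space is exactly the signal the pipeline should detect. The
generator does **not** imitate real apoptosis sequences — no positional
or Markov structure, no homology or redundancy, no realistic
within-class heterogeneity. Passing tests on this data therefore
demonstrate pipeline correctness and signal recovery, not real-data
accuracy; reproducing published benchmark accuracies requires the
external ZW225/CL317 datasets (`popmgram fetch-benchmarks`, network
required).

## Behavior on signal-free data

With identical class profiles the features carry no class information,
and the evaluation then exposes two known artifacts of discriminative
classifiers under leave-one-out, documented here because they surprise
users expecting OA ≈ 1/C:

* **Unbalanced classes:** the SVM degenerates to majority-class
  prediction, so OA equals the largest class share (89/225 ≈ 0.396 on
  the 4-class benchmark shape), not 1/C.
* **Balanced classes:** leave-one-out anti-learning — removing a sample
  tips the training class balance against its own class, and since
  null tri-gram features concentrate tightly (the SVM cannot even fit
  its training set), the one-vs-one votes follow that tilt. OA can
  reach 0 on balanced null data.

Neither artifact is specific to this implementation, and neither is
removed by `leak_free` mode (it is a property of the protocol, not of
selection leakage). The acceptance suite asserts the idealized
chance-level expectation and that assertion fails by design; the
signal-free control's actual value is reported by
`scripts/acceptance.py` as `null_profile_jackknife_oa_percent`.

## Problem sizes and numerical choices

Test and acceptance runs use the benchmark-shaped datasets themselves
(n = 225 and 317, full 1000-feature RFE at step 1 for the headline
runs; step 25–500 where only selection plumbing is under test). The
tri-gram oracle comparison uses 100 random sequences of length 3–60 at
1e-12 tolerance. The planted-feature check embeds one informative
column among 999 standard-normal noise columns (n = 60, margin ±1.5,
noise sd 0.1) and requires rank 1; with RFE step 50 this is recovered
in 10/10 replicates.

## Limitations

* Accuracy on real proteins depends on the benchmark datasets, which
  are not shipped; all shipped numbers are synthetic-data computations.
* `paper` evaluation mode is leakage-prone by construction; use
  `leak_free` for honest generalization estimates.
* The encoder discards all information not captured by the ten property
  groups (e.g. it cannot distinguish I from L, or D from E).
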