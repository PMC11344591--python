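# Methods

## Problem setting

Metabolite annotation assigns a molecular structure to a measured MS/MS
spectrum. `espred` works molecule-to-spectrum: given a query spectrum
and a candidate set of molecules sharing its molecular formula (the
target is assumed to be among them), each candidate's spectrum is
predicted under the query's instrument setting and candidates are
ranked by cosine similarity of prediction to measurement. The package
trains and combines two spectrum predictors and learns, from ranking
outcomes, how to weight them per query.

## Data representation

Spectra are vectors of P = 1000 bins, each covering a half-open 1-Da
m/z interval [m, m+1); a peak at m/z falls in bin ⌊m/z⌋, multiple peaks
in one bin are summed, and peaks at or above 1000 Da are dropped with a
logged count. Binned vectors are L2-normalized, which makes the dot
product of two spectra their cosine similarity and makes the spectral
loss scale-free. An optional square-root intensity transform (off by
default) is available for corpora with very high dynamic range.
Instrument settings are a one-hot precursor-type vector (default
vocabulary: `[M+H]+` only; an extended positive-mode list is provided)
plus a collision energy min-max-normalized over the training corpus and
clipped to [0, 1] at inference (a constant-energy corpus maps to zero).

Molecules are parsed with RDKit. The fingerprint branch uses ECFP with
radius 2 and 4096 bits by default (both configurable); MACCS keys are
computed only for similarity analysis and structure-based splitting.
The molecular graph keeps heavy atoms as nodes (atom-type one-hot over
C/N/O/S/P/F/Cl/Br/I plus atomic mass scaled by 1/100) and bonds as
symmetric directed edge pairs with a categorical type
(single/double/triple/aromatic).

Corpora are split at the molecule level (all spectra of a molecule share
its split) so no structure leaks across splits: randomly at 8:1:1, or by
the "realistic" structure-novelty split — MACCS keys, 2-D t-SNE
embedding (seeded, perplexity capped for small corpora), UPGMA (average
linkage, Euclidean) into 50 clusters, the 29 largest forming the
training set. Molecules with more than 5 spectra are down-sampled to 5
by seeded sampling with replacement; duplicates produced by the
with-replacement draw are kept.

## Spectrum predictors

Both predictors share the decoding pipeline and differ only in the
encoder producing the latent code z.

**Fingerprint encoder.** The fingerprint and the instrument-setting
vector are each projected by a one-layer network (linear + bias + ReLU),
concatenated, and projected again: z = NN(CONCAT(NN(x_FP), NN(x_IS))).

**Graph encoder.** Node states are initialized the same way from atom
features and the (broadcast) instrument setting. Each of K = 3
message-passing rounds computes, per node, the sum of its own state,
its neighbors' states, and embeddings of the incident bond types, then
applies a per-layer affine map and ReLU. Including the node's own state
in the aggregation follows the graph-isomorphism-network family (the
self term with ε = 0); without it, single-atom molecules such as methane
would lose all identity by the first round. The readout is mean pooling
over final node states, so the latent width equals the node-state width
(default 128 in the shipped configurations).

**Bidirectional head.** A two-layer MLP emits three length-P vectors
from z: a forward intensity vector indexed by fragment mass (ReLU), a
reverse vector indexed by neutral-loss mass (ReLU), and gate logits.
The reverse vector is re-indexed so that loss j maps to bin
(precursor_bin − j), the per-bin sigmoid gate blends the branches, and
all bins above the precursor bin are zeroed — fragments cannot outweigh
the precursor ion. The mask is re-applied after label mixing, so the
bound holds for the final output unconditionally.

**Label mixing.** L = 4 factor matrices D_l (P × M, M = 64) define
implicit co-occurrence matrices Q_l = D_l D_lᵀ (symmetric PSD by
construction). The mixed prediction Σ_l (ŷ D_l) D_lᵀ τ_l is computed in
factored form — the P × P matrices are never materialized — with τ
parameterized through a softmax so it stays on the simplex. The blend
ŷ ← θ·ŷ + (1−θ)·ŷ_co uses a fixed hyperparameter θ = 0.5 and is clamped
at zero from below (mixed-sign factors can push individual bins
negative even though each Q_l is PSD). Mixing is applied to the final
gated output, before the loss.

**Topic auxiliary task.** LDA (scikit-learn, batch variational Bayes)
is fitted on the training split only — fitting on all spectra would
leak held-out peak statistics into training targets. LDA needs counts:
each spectrum is rescaled so its maximum bin equals 100 and rounded to
integers (the map is invariant to the L2 normalization). The default
topic count is T = 30 for real-scale corpora; the shipped synthetic
configurations use T = 10, and topic-recovery tests use T = 3 on
three-motif corpora. The per-spectrum posterior topic distribution is
treated as a fixed ground-truth label; a two-layer softmax head predicts
it from z under cross-entropy, weighted by λ_aux = 0.1 in the total
loss. λ_aux = 0 reduces training exactly to the spectral-only baseline.

**Training.** Adam (lr 1e-3 fingerprint / 2e-3 graph, batch 128),
full-gradient cosine loss −cos(ŷ, y) with a 1e-12-stabilized norm.
Every source of randomness (initialization, batch order) derives from
the config seed; two runs with the same seed are bit-identical. Model
selection evaluates the validation split every `eval_every` epochs and
keeps the checkpoint with the best validation average rank within
validation formula strata, breaking ties (and covering the degenerate
all-singleton case) by validation mean cosine — ranking, not spectral
loss, is the quantity the model is for.

The networks run on a small tape-based reverse-mode autodiff engine
(`espred._autodiff`) written on NumPy, with segment-sum/gather
primitives for message passing and per-row gathers for the neutral-loss
re-indexing; its gradients are verified against numeric differentiation
in the test suite.

## Candidate ranking

Scores are cosine similarities between each candidate's predicted
spectrum and the query (equivalent ordering to negative spectral loss).
Candidates are predicted under the query's instrument setting — the
candidate's true acquisition conditions are unknowable at annotation
time. The target's rank uses competition ranking with the worst-case
tie policy: a target tied with non-targets is placed after all of them,
so reported ranks are conservative upper bounds. A candidate that fails
featurization is dropped with a log entry unless it is the target, which
is an error. Evaluation candidate sets are built by seeded random
sampling or by most/least MACCS-Tanimoto similarity to the target, ties
broken by molecule id.

## Ensemble

For every training query in a formula stratum of at least two members,
both predictors rank the target; d_MLP = 1 iff Rank_MLP ≤ Rank_GNN
(ties are labeled MLP, but their SMAPE weight
γ = |Rank_GNN − Rank_MLP| / (Rank_GNN + Rank_MLP) is zero, so they drop
out of the loss). The classifier — two hidden layers (128, 32), sigmoid
output — sees only the raw binned query spectrum, since no molecular
features exist for an unannotated query; it is trained with γ-weighted
binary cross-entropy, with a held-out tenth of the table selecting the
checkpoint. At inference the *soft* probability blends the two predicted
spectra per candidate; the combined spectrum is entrywise between the
two branch predictions. Two ablations are configuration switches:
labels and weights derived from the two spectral losses instead of
ranks, and uniform (all-ones) weights.

## Synthetic data generator

The generator emulates the structure of a spectral-library corpus, not
its chemistry. Molecules are saturated acyclic C/N/O structures grown as
seeded random valence-respecting trees over a heavy-atom multiset and
deduplicated by canonical SMILES — every formula family is a set of
real, distinct constitutional isomers, so formula strata and candidate
ranking are well-posed. The default conditions are 30 families of 10
isomers (300 molecules) with collision energies {10, 20, 40} eV and no
noise; spectra per molecule stay below the cap of 5, and the 8:1:1
molecule-level split applies.

Spectra follow a deterministic fragmentation rule: every acyclic bond
cleavage yields two fragments whose masses (heavy atoms plus their
hydrogens, plus a 1.007 Da charge carrier) become peaks alongside the
molecular ion; intensity is exp(−(1 + 2·CE)·mass/100), so higher
collision energy steepens the decay and the intensity-weighted mean
mass is provably non-increasing in energy, as on a real instrument.
Optional multiplicative log-normal noise (σ, default 0 — the
deterministic map is the generator's point) models detector
variability; σ is scale-free under the L2 normalization.

What the generator does *not* emulate: rearrangement chemistry, multiple
cleavages, isotope patterns, adduct-specific fragmentation, instrument
mass error, chimeric spectra, and the heavy-tailed candidate-set sizes
of real databases. Passing tests therefore demonstrate that the
learning machinery works when a structure-determined signal exists —
they do not certify accuracy on empirical libraries.

## Problem sizes used in the shipped runs

The end-to-end script and tests use the 300-molecule noise-free corpus
(720 training spectra), T = 10 topics, 30 training epochs for the
fingerprint predictor and 40 for the graph predictor, and a 200-epoch
ensemble fit; the candidate-regime analysis uses two 100-isomer families
with a 3:1:6 split so that held-out strata exceed 50 members. These
sizes give stable metrics while keeping a full pipeline run around a
minute on one CPU; all of them are configuration, not code.

## Numerical choices and degenerate inputs

- Cosine against a zero-norm prediction is defined as 0 (the worst value
  for non-negative data) and logged; a zero-norm *target* is an error.
- Topic predictions are clamped at 1e-8 before the log; the auxiliary
  loss at r̂ = r equals the entropy of r (Gibbs equality, property-tested).
- Glorot-uniform initialization everywhere; mixing factors start at
  N(0, 1/P) so the mixed term is near zero and training begins close to
  the unmixed predictor; τ logits start at zero (uniform simplex).
- Singleton formula strata are excluded from ensemble training and from
  average-rank computation (their candidate set is empty); the count is
  logged.
- An all-zero gamma table, an empty training split, a degenerate
  single-cluster realistic split, and an all-out-of-range peak list are
  hard errors, not silent fallbacks.

## Known limitations

- The NumPy engine is CPU-only and full-precision; corpus sizes in the
  hundreds of thousands of spectra would need a GPU framework.
- The graph encoder covers the nine-element vocabulary above; exotic
  elements raise a parse-time error naming the atom.
- Candidate retrieval from molecular databases is an import format
  (CSV of formula, SMILES), not a live query.
- With very small validation splits, model selection can be noisy; the
  fallback to validation cosine covers the degenerate case but selection
  quality degrades gracefully, not perfectly.
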