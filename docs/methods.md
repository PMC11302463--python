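# Methods

## Problem setting

Given a predicted protein model — backbone N/Cα/C coordinates with a
per-residue pLDDT confidence — and a precomputed per-residue sequence
embedding, the task is multi-label classification over a fixed set of
candidate GO terms drawn from the three ontology namespaces (molecular
function, biological process, cellular component). Ground-truth labels are
ancestor-closed in the GO DAG; predicted scores are propagated so a term
receives the maximum confidence among itself and its descendants before
evaluation.

## Featurization

* **Graph.** Directed kNN graph over Cα atoms (default k = 30 for the
  full configuration; the small reference configuration uses k = 8 for
  30-residue chains). Neighbour selection orders candidates by distance
  quantized to 1e-6 Å and then by residue index, so exact-tie geometries
  (an ideal helix has them) select the same edges under any rigid motion.
* **Edge features.** Euclidean distance expanded in 16 Gaussian radial
  basis functions spanning 0–20 Å, plus the unit Cα→Cα edge vector.
* **Node scalar features.** Amino-acid token (21-way, unknown mapped to
  X), φ/ψ/ω torsions encoded as (sin, cos) pairs with defined-flags (so
  chain termini carry no wrap-around artifacts), pLDDT as a linear scalar
  embedding, and the sequence embedding through a linear projection. The
  five streams are each embedded to d_model and summed element-wise.
* **Node vector features.** Forward and backward orientation vectors for
  all three backbone atom types (six channels) and the two intra-residue
  unit vectors N→Cα and Cα→C (the backbone proxy for side-chain
  direction), eight vector channels total.
* **Torsion conventions.** φ_i = torsion(C_{i−1}, N_i, Cα_i, C_i),
  ψ_i = torsion(N_i, Cα_i, C_i, N_{i+1}),
  ω_i = torsion(Cα_{i−1}, C_{i−1}, N_i, Cα_i), all in (−π, π]; −π is
  mapped to +π so the planar all-trans case is unambiguous. Degenerate
  (collinear) quadruples are flagged undefined and zero-filled, never NaN.
* **Confidence masking.** Residues with pLDDT below the threshold
  (default 0.9) keep token, pLDDT and sequence embedding but lose all
  geometric features, and the kNN graph is rebuilt over confident residues
  only — a masked residue is never anyone's neighbour. A protein whose
  residues are all below threshold is rejected. The alternative reading
  (zeroing coordinates but keeping masked residues in the graph) would
  leak arbitrary geometry into confident residues' neighbourhoods.
* **Canonical local frames.** Per residue, a Gram–Schmidt frame (e1 ∝
  Cα→C, e2 the orthogonalized Cα→N component, e3 = e1×e2, origin Cα) is
  available for orientation unification; the network itself consumes raw
  equivariant vectors, which the GVP layers scalarize invariantly.

## Network

A GVP couples n scalar channels and v vector channels; the hidden width is
h = max(v, n). Vector-path maps (W_h, W_μ) mix channels only and carry no
bias — the algebraic condition for equivariance — and norms are taken with
an ε = 1e-8 floor inside the square root to keep gradients finite at zero
vectors. σ = ReLU on scalars, σ⁺ = logistic on the vector gates (both
configurable); the scalar path carries a bias safely since scalars are
invariant.

Each of the (default two) graph layers computes per-edge messages with a
GVP over the concatenated source-node and edge features, aggregates by
mean over incoming edges, applies a residual update, then a pointwise node
GVP with another residual. Layer normalization acts on scalar channels
only; vector channels get plain residuals (any per-coordinate
normalization would break equivariance). Zero vector inputs produce zero
vector outputs (bias-free path), and a single-residue graph reduces to the
node GVP alone.

The transformer encoder (default 4 layers; 1 in the small configuration)
applies standard multi-head self-attention (post-norm, no causal mask) to
the sum of the GVP scalar output and the embedding sum — summation rather
than concatenation keeps every stream in the same d_model space and makes
the five-stream additivity testable. The decoder holds one learned
d_model query per candidate term, with no positional encoding: the labels
are an unordered set and the learned embedding is the term's identity.
Each decoder layer runs self-attention over the queries, cross-attention
against the encoder output, and a feed-forward block; a shared linear map
plus logistic head yields one confidence per term. Permuting the query
rows permutes the outputs identically; zeroing the cross-attention output
projection provably removes all protein dependence.

Since all quantities entering the encoder after the GVP stack are
rotation-invariant scalars, end-to-end predictions are invariant under
rigid motions to floating-point tolerance (asserted at 1e-4).

## Training

Weighted binary cross-entropy, mean over terms of
−[w·y·ln p + (1−y)·ln(1−p)] with w = 3.0 on positives (the positive/negative
imbalance of propagated GO labels), predictions clamped to [1e-7, 1−1e-7]
with a warning. Adam (lr 1e-4 default, 1e-3 in the small configuration),
batch size 8 implemented as gradient accumulation over proteins (each
protein is processed independently, so batch composition cannot leak
between proteins), global gradient-norm clipping at 1.0, early stopping on
validation loss with patience 5, checkpointing the best-validation
parameters. Training is deterministic given the seed: all randomness
(initialization, epoch shuffling) flows through one numpy generator. A
non-finite loss aborts with a diagnostic rather than silently continuing.

The whole network runs on a small tape-based reverse-mode autodiff engine
over numpy arrays written for this package; its gradients are verified
against central finite differences in the test suite (tolerance 1e-4 on
the GVP, 1e-6 on the primitive operations).

## Ontology machinery

OBO parsing keeps is_a and part_of edges (part_of participates in
propagation, the CAFA convention), drops obsolete terms and maps alt_ids
to primary ids. Annotation propagation is the ancestor closure;
prediction propagation is a single reverse-topological max sweep.
Information content is IC(f) = −log10(Occur_f / Occur_all) with Occur_f
the number of distinct proteins annotated with f *after* propagation —
counting distinct proteins (not raw pairs) means a protein annotated with
two descendants of f contributes once, and descendants' occurrences are
covered automatically. Terms absent from the corpus get IC = +∞ and any
appearance of such a term in an S_min sum is an error rather than a
silent skip. Candidate terms are those annotated to at least
min_proteins distinct training proteins (default 50), namespace roots
excluded; roots are likewise excluded from every metric.

## Evaluation

Thresholds sweep t = 0.01 … 1.00 in steps of 0.01 (CAFA convention); an
oracle mode accepts an arbitrary strictly increasing grid, e.g. every
distinct score. Precision at t averages over the m(t) proteins with at
least one prediction ≥ t; recall averages over all n evaluated proteins;
mi(t) and ru(t) both average over all n (the "full-evaluation" reading —
the alternative of dividing the misinformation sum by m(t) would make
S_min improve by predicting nothing). Proteins without truth terms in the
evaluated namespace are excluded from that namespace's n; namespaces are
never mixed. AUPR integrates the swept precision–recall curve
trapezoidally, extended horizontally from the most conservative threshold
to recall 0; a single-point curve degrades to the pr·rc rectangle with a
warning. Term-centric AUROC is the tie-corrected rank statistic
(Mann–Whitney), macro-averaged over terms with both classes present, with
a micro-pooling flag. F_max is invariant under strictly monotone score
transforms when the exhaustive grid is used.

## Baselines

The Naive baseline scores every term by its relative frequency among
(propagated) training annotations, identically for all queries — hence
per-term AUROC is exactly 0.5 under tie-corrected ranking, which the
suite asserts as an equality. BLAST-style transfer scores term f for
query q as the maximum identity among aligned training proteins
annotated with f; identities are consumed from a TSV (0–1 or 0–100
auto-detected) produced by any aligner, decoupling the pipeline from a
specific alignment binary. Decontamination removes test proteins whose
maximum identity to training *exceeds* the cutoff (strict inequality;
absent proteins are retained).

## Synthetic corpus

Backbones are built by sequential internal-coordinate placement (NeRF)
from ideal bond lengths (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å) and
angles, with ω = 180°; requested torsions are therefore *exactly*
recoverable by measurement, which turns the geometry tests analytic
(helix φ=−57°, ψ=−47°; extended φ=−120°, ψ=120°). pLDDT profiles are
high-confidence (U(0.92, 0.99)) with a low-confidence segment (length 6,
U(0.60, 0.85)) in 20% of proteins, independent of labels by design.

The planted rule: per-protein conformation (helix or extended, 50/50)
determines one MFO leaf each; a three-tryptophan sequence motif (planted
with probability 0.5) determines a BPO leaf; one CCO leaf is shared by
all proteins. Each leaf sits under intermediate terms so propagation is
non-trivial. Optional label noise flips rule outcomes per protein;
the learnability experiment uses noiseless labels. 10% of proteins are
mutated copies of earlier ones (10% substitutions, motif preserved), so
the edlib-computed identity table contains high-identity pairs and the
identity filter has signal. Stub embeddings are deterministic functions
of (residue type, position, seed) with a dominant residue-type component,
emulating the residue-identity information of a language-model embedding.

What the generator does *not* emulate: real side chains, realistic
AlphaFold error modes beyond pLDDT segments, sequence–structure
consistency (sequences are random given the fold), or the scale and label
sparsity of a real annotation corpus (tens of thousands of proteins,
thousands of terms). Passing tests therefore demonstrate the mechanics —
equivariance, propagation, metric correctness, trainability and feature
attribution — not real-data accuracy.

## Study configurations and numerical choices

The learnability experiment uses 200 proteins of 28–36 residues, an
80/20 train/validation split, candidate threshold 50, and a small model
(d_model 64, 4 heads, 2 GVP + 1 encoder + 1 decoder layer, 8 vector
channels, k = 8, lr 1e-3, ≤ 30 epochs); training halts once validation
macro-F_max reaches 0.95 (a compute cutoff — the reached value is
reported as-is). Permutation importance shuffles one feature's values
across all residues (or edges) of the evaluation set pooled — a
within-protein shuffle would be a no-op for homogeneous-conformation
chains — and reports per-ontology metric deltas. The designated
signal-feature control is the dihedral stream measured on MFO F_max (the
ontology the conformation rule feeds); the null control is pLDDT, which
the rule ignores. Macro-averaging over all three namespaces would dilute
the signal control roughly threefold since BPO/CCO labels are
conformation-independent by construction.

Other numerical choices: distances are Å throughout; pLDDT is 0–100 in
files and [0, 1] in memory (B-factor / 100 on read, ×100 on write,
round-tripping at 1e-3 Å / 1e-4 pLDDT); internal residue indexing is
0-based with author numbering preserved in I/O; parameter initialization
is Glorot-style for linear maps and N(0, 1/√d) for embedding tables;
softmax subtracts the row maximum; layer-norm ε is 1e-5.

## Known limitations

Single chain, single model per file; no side-chain torsions, solvent
accessibility or contact-map export; no weighted-F_max or normalized
S_min variants; no bootstrap confidence intervals; the numpy training
loop is single-threaded and meant for small corpora (the reference
configuration trains in seconds, but scaling to realistic corpus sizes
would require a compiled backend); multi-fragment proteins are treated as
one file = one protein.
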