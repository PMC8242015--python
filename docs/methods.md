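# Methods

## Problem setting

Twelve RNA modification types can currently be profiled transcriptome-wide
at base resolution: m6A, m1A, m6Am, Am and inosine (I) on adenosine; m5C and
Cm on cytidine; Gm and m7G on guanosine; pseudouridine (Psi), Um and m5U on
uridine. Each occurs on exactly one "original" nucleotide, and real corpora
are heavily imbalanced — m6A and I sites number in the tens of thousands
while m7G contributes on the order of a thousand. `rnamod` predicts all
twelve modification probabilities for a candidate nucleotide from its
sequence window alone, with one integrated multi-label model, and explains
each positive call.

## Data model

Sites live on named sequences in 0-based coordinates (readers accept a
declared 0- or 1-based convention and normalise; displayed coordinates are
1-based). The alphabet is {A, C, G, U, N}; T is read as U. A training
example is an odd-length window (21/51/101 nt; embeddings are pre-trained
on 1001-nt windows) centered on a candidate base, carrying a 12-slot binary
label vector in which only modifications of the center base may be set.
Windows running past the end of a sequence are N-filled rather than fetched
from a genome assembly: the package deliberately takes sequences, not
assemblies. Minus-strand sites are reverse-complemented before windowing so
the center base is the modified base read 5'→3'.

Negatives are drawn uniformly (seeded) from unmodified occurrences of the
same base on the same transcript as the positives, excluding all positive
positions and any caller-supplied exclusion list (mirroring the practice of
excluding lower-confidence m6A catalogues from the m6A negatives). Where a
consensus restriction exists — DRACH around m6A, BCA ending at the m6Am
adenosine — positives and negatives are filtered to match it; N in the
motif context fails the match. Filtering is applied after same-transcript
sampling (whether the original pipelines filtered before or after sampling
is not documented; applying it after is the simpler composition and is the
package's documented choice).

Splits are per class: each modification's positives and each per-base
negative pool contribute exactly 150 validation and 50 test windows
(sampled without replacement, seeded); the remainder — imbalanced — is the
training set. A window carrying several labels is assigned to its
lowest-slot label's class so the three sets stay disjoint by site.

## Encodings

One-hot: f(A)=(1,0,0,0), f(C)=(0,1,0,0), f(G)=(0,0,1,0), f(U)=(0,0,0,1),
f(N)=(0,0,0,0). Word2vec: overlapping 3-mers (stride 1; a 1001-nt window
yields 999 tokens) embedded by a self-trained skip-gram model with negative
sampling (CBOW selectable), context window 5 tokens, 300 dimensions by
default. The trainer is a single-threaded NumPy implementation —
deterministic under its seed — which is entirely adequate for nucleotide
k-mer vocabularies (≤ 64 canonical 3-mers plus any N-containing tokens
observed). Tokens unseen at prediction time map to the zero vector (with a
warning path available as a strict mode); the zero vector is also the
attribution baseline, so "no information" is consistent across the package.

## Model

The network is written over a small reverse-mode autodiff core
(`rnamod.autograd`) whose gradients are verified against central finite
differences in the test suite. Architecture:

1. **Embedding front-end.** Word2vec mode feeds the (L−k+1) × dim matrix
   straight to the recurrent block. One-hot mode first applies a 1-D
   convolution (valid padding, ReLU) and max-pooling to densify the sparse
   encoding.
2. **LSTM.** A single forward LSTM (forget-gate bias 1) produces
   per-position hidden states y_i and cell states c_i.
3. **Per-label additive attention.** For label j,
   e_{j,i} = v_jᵀ tanh(W c_i + U y_i + b_j); α_j = softmax_i(e_j);
   context_j = Σ_i α_{j,i} y_i. W and U are shared across labels; the score
   vector v_j and offset b_j are per-label. The twelve v_j are the vectors
   used by the association analysis.
4. **Multi-label head.** Twelve parallel FC branches (ReLU, dropout 0.2,
   sigmoid) map each context vector to an independent probability — no
   sum-to-one constraint, because a window supports multiple labels.

Open design points resolved here: the feature dimension of y_i equals the
LSTM hidden size (both configurable); the FC branches share nothing; the
attention aggregation of c_i and y_i is the additive two-projection form
above.

### Supervision masking

A window centered on C says nothing about adenosine modifications, so each
example contributes loss only for the ≤ 4 (A) / 2 (C, G) / 3 (U) tasks
compatible with its center base. All loss modes respect this mask.

### Losses for imbalance

* `bce` — masked mean binary cross-entropy (stable from-logits form);
* `bce+ohem` — online hard example mining: per batch, only the top-q
  (default q = 0.7) fraction of samples by loss is back-propagated;
  discarded samples receive exactly zero gradient (property-tested);
* `bce+uw` — uncertainty weighting: Σ_j exp(−s_j) L_j + s_j with one
  learnable s_j per task, initialised at 0;
* `bce+ohem+uw` — both, the configuration that performed best on average in
  the original study;
* `focal` — (1 − p_t)^γ-scaled BCE, γ = 2 by default (γ = 0 recovers BCE);
* `effective_number` — fixed class weights ∝ (1−β)/(1−β^n), β = 0.999;
  equal weights as β→0 and ∝ 1/n as β→1.

q, γ, β and the dropout rate follow the standard values of the methods the
losses come from; the sources fix none of them.

### Training

Adam, mini-batches of 128, up to 100 epochs, exponential (default) or
cosine-annealing learning-rate decay, early stopping when the validation
loss rises in 5 successive epochs, best-validation-epoch weights restored.
Training is deterministic given the config seed (single-threaded NumPy; all
randomness flows through seeded generators). Divergent (NaN) loss aborts
with a diagnostic rather than continuing silently.

## Evaluation

AUC is computed as the Mann–Whitney statistic (midranks for ties) —
equivalently the ROC area over the finite set of observed thresholds with
no interpolation. AUC_b uses the label's own sampled negatives — unmodified
same-base sites only, not other modifications' positives; AUC_m widens the
negatives to all other labels and all unmodifiable bases (and is therefore
systematically higher — most of the widened pool is trivially rejected). Classification thresholds maximise the G-mean √(Sn·Sp) over ROC
operating points, ties broken toward higher specificity. Sn, Sp, Acc and
MCC follow the standard confusion-matrix formulas; a zero MCC denominator
reports 0 with an explicit flag.

Per-site significance is an upper bound on the p-value from the score's
rank among background scores of held-out negative sites of the same base:
bound = (#{background > score} + 1)/(N + 1). The add-one correction keeps
the bound valid and nonzero for finite backgrounds; for large N it
reproduces the "1% of background above → 0.01" reading. Backgrounds are
kept per (base, label) and persisted beside the checkpoint so server-style
prediction is reproducible. The bound controls only type-I error; no FDR
control across a transcriptome is attempted.

## Interpretation

**Integrated gradients.** Midpoint Riemann-sum approximation of the path
integral from the all-zero input (zero embedding rows / all-N one-hot) to
the input, `steps` = 50 by default. The completeness residual
|Σ attributions − (F(x) − F(baseline))| is reported and shrinks as steps
grow; it is exactly zero for linear models. Token-level attributions are
projected to nucleotides by splitting each token's score equally over the k
bases it covers, which preserves the total (so completeness survives the
projection).

**Attention profiles.** Each label's token-position weights are mapped to
nucleotides (mean over covering tokens, renormalised to sum to 1). In
one-hot mode the conv/pool front-end decouples the grids; pooled positions
spread their weight uniformly over their receptive field.

**Motif mining.** Among windows that carry the label and are predicted
positive, the top decile by probability is taken; per sample, the width-w
(default 6) window of highest mean attribution is selected greedily up to
k = 3 times, masking each selection and its (w−1)-nt neighbourhood.
Candidates are one-hot flattened (equal widths need no alignment), embedded
to 2-D with UMAP (15 neighbours, min_dist 0.1, fixed seed) and clustered
with DBSCAN (eps 0.5, min_samples 5); noise is discarded and each cluster
is summarised as a PWM with pseudocount 0.01. With too few distinct
candidates for a meaningful neighbour graph, DBSCAN runs directly on the
one-hot vectors (identical candidates sit at distance zero). PWMs export in
MEME minimal format; logos are rendered information-content scaled.

**Association analysis.** Pairwise Pearson correlation of the twelve
attention score vectors v_j, two-sided p-values from the exact distribution
of the sample correlation coefficient; zero-variance vectors propagate NA
rather than being zero-filled. (The alternative reading — correlating the
full attention projection rows rather than v_j — is noted; v_j is used
because it is the single per-label vector the attention head owns.)

**Site-distance enrichment.** For two site sets, the distance from each
a-site to its nearest b-site on the same sequence is compared with a null
in which b-sites are repositioned uniformly on their own sequences; the
one-sided "closer than random" p-value uses the add-one empirical
estimator, and is approximately uniform for independent placements
(calibration-tested).

## Synthetic data

The generator emulates the structure of real corpora: i.i.d. background
transcripts (configurable composition; a first-order Markov background is a
possible stress extension), per-label positive sites whose windows are
rewritten from a planted PWM (width 5 by default, peak 0.95, center column
fixed to the label's base; the default m6A consensus is DRACH-compatible
and m6Am's is BCA-compatible so the real filters apply unchanged),
configurable cross-label PWM sharing, Table-5-style abundance skew
(m6A 40%, I 32%, …, m7G 0.6%), non-overlapping placement (overlap beyond
capacity is a configuration error, not silent clipping), and seeded
same-transcript negatives. The truth record keeps every planted site and
PWM.

What it does not emulate: transcript annotation structure, read-level
profiling noise, condition-specific modification dynamics, shared
underlying biology between labels beyond what PWM sharing induces. Passing
recovery tests therefore shows the pipeline recovers signal it was pointed
at, not that real-data AUCs would match published values.

## Reference study conditions (desk scale)

The simulation studies in `rnamod.benchmarks` fix problem sizes that run in
minutes on a workstation CPU:

* **Planted-motif recovery** — 12 labels × 500 positives, 1:1 negatives,
  100 × 2-kb transcripts, 51-nt windows, Word2vec dim 32, LSTM hidden 32,
  constant learning rate 3e-3, dropout 0, ≤ 25 epochs. Success is every
  label reaching validation AUC_b ≥ 0.95 during training and the best
  mined m6A cluster PWM lying within per-column total-variation 0.25 of the
  planted PWM (mined width 6 slides against planted width 5).
* **Association recovery** — m1A and I planted with one shared PWM, m6A
  independent, 300 positives each, 21-nt windows, small dims; the
  m1A–I correlation of attention score vectors should exceed either
  label's correlation with m6A (median over 5 seeds).
* **Imbalance comparison** — m6A:m7G at 50:1 (1500 vs 30 positives),
  identical split and seed for both losses; OHEM+UW's minority AUC_b
  should not fall below plain BCE's (median over 5 seeds). With only ~25
  minority training positives this is intentionally a hard regime; the
  claim is directional, not a large-effect claim.
* **Null calibration** — 50 replicates of independently placed site sets,
  99 shuffles each.

Dropout is disabled and the learning rate held constant in these runs
because at a few thousand training windows the paper-scale regularisation
(dropout 0.2, decaying schedules tuned for ~300k sites) slows convergence
without a generalisation benefit — the defaults remain the large-corpus
values.

## Numerical notes

* Gradients flow through a bespoke reverse-mode engine; all ops are
  finite-difference-tested, including the batched/vector matmul cases the
  attention heads use.
* Attention weight vectors sum to 1 within 1e-6 (softmax); the context
  vectors satisfy the inner-product contract against the returned weights
  exactly (tested to 1e-10).
* BCE is computed in the stable from-logits form; probabilities are
  clipped at 1e-12 only where logs are taken from stored probabilities.
* Ties: G-mean threshold ties resolve toward specificity; the argmax in
  max-pooling routes gradient to the first maximum; OHEM uses a stable
  sort so equal-loss samples select deterministically.
* Empty eligible-negative pools contribute nothing (with a warning);
  zero-variance association vectors yield NA correlations.

## Known limitations

* Real-data replication (published AUC tables, the ρ ≈ 0.9 same-base
  correlations) requires the full curated corpora and GPU-scale training;
  nothing here asserts those numbers.
* The unidirectional LSTM sees only leftward context at each position;
  attention compensates by pooling over all positions, but a bidirectional
  encoder is a natural extension. A related consequence: because the
  encoder is causal, motif evidence is readable at and after the motif, and
  some attention heads settle downstream of it rather than on it — the
  attention profile marks where the head reads the evidence, not
  necessarily where the evidence sits. Integrated gradients, which the
  motif-mining route uses, do localize at the motif itself.
* Variable-width motif candidates would need a real multiple alignment;
  the implementation fixes one width per mining run.
* The HMM-based embedding variant of the original study is out of scope.
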