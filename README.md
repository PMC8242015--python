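# rnamod

Attention-based multi-label prediction and interpretation of RNA
modifications from primary sequence.

Twelve modification types can be profiled transcriptome-wide at base
resolution — m6A, m1A, m5C, m5U, m6Am, m7G, pseudouridine (Psi), inosine
(I), and the 2′-O-methylations Am, Cm, Gm, Um — and each occurs on one
specific nucleotide. `rnamod` trains a single integrated model that, given
the sequence window around a candidate base, outputs all twelve
modification probabilities at once, then explains every positive call.
It is aimed at epitranscriptomics groups who have (or simulate)
base-resolution site tables and want joint prediction plus mechanistic
readouts — attention maps, attribution motifs, and cross-modification
associations — without a GPU.

## Model

An input window `x ∈ {A,C,G,U,N}^L` (L = 21/51/101) is embedded either
one-hot (with a Conv1D + max-pool front-end) or as overlapping 3-mers
looked up in a self-trained skip-gram Word2vec table (a 1001-nt window
becomes a 999 × 300 matrix). An LSTM produces per-position features `y_i`
and cell states `c_i`; for each label *j* an additive (Bahdanau) attention
head scores

    e_{j,i} = v_j^T tanh(W c_i + U y_i + b_j),
    α_j = softmax(e_j),   context_j = Σ_i α_{j,i} y_i,

and twelve parallel fully connected branches map the context vectors to
independent probabilities. Training uses masked binary cross-entropy —
a window supervises only the tasks compatible with its center base —
optionally combined with OHEM (back-propagating only the hardest batch
samples), uncertainty weighting (learnable per-task `exp(−s_j)` weights),
focal loss, or effective-number class weights `(1−β)/(1−β^n)`, to cope
with the ~60:1 abundance gap between m6A and m7G in real corpora.

Evaluation reports AUC_b (positives vs same-base negatives, the
Mann–Whitney statistic exactly), AUC_m (vs all other labels and bases),
and Sn/Sp/Acc/MCC at the G-mean-optimal threshold. Per-site significance
is a rank-based p-value upper bound against held-out negative backgrounds:
a score exceeded by 1% of the background gets p ≤ 0.01.

Interpretation: integrated gradients (midpoint path integral from the
zero-input baseline, completeness residual reported), per-label attention
profiles, greedy mining of high-attribution 6-mers from top-decile true
positives with UMAP + DBSCAN clustering into PWMs (MEME minimal format +
logos), Pearson association of the twelve attention score vectors `v_j`,
and a shuffle-null test for distance enrichment between two site sets.

Everything numerical — the autodiff engine, LSTM, attention, losses, Adam,
Word2vec — is implemented in NumPy inside the package and checked against
finite differences and independent oracles in the test suite.

## Worked example

```bash
# 1) simulate a corpus with planted per-label motifs and realistic skew
rnamod simulate --outdir demo/corpus --seed 7 --total-sites 4000 \
    --n-transcripts 80 --transcript-length 1500

# 2) train a small model (~45 s on one CPU core)
rnamod train --fasta demo/corpus/transcripts.fasta \
    --sites demo/corpus/sites.tsv --outdir demo/run \
    --length 21 --embed-dim 16 --lstm-hidden 16 \
    --max-epochs 8 --val-per-class 15 --test-per-class 5 --seed 7
```

The training command prints the per-label test report; on this corpus it
ends with (abridged — threshold is the G-mean-optimal operating point used
for Sn/Sp/Acc/MCC):

```
 label       Sn   Sp      Acc      MCC    AUC_b    AUC_m  threshold
   m6A 1.000000 1.00 1.000000 1.000000 1.000000 0.992000   0.643424
   m1A 1.000000 1.00 1.000000 1.000000 1.000000 0.973333   0.252889
   m5C 1.000000 1.00 1.000000 1.000000 1.000000 0.954667   0.486003
   m7G 0.200000 0.80 0.500000 0.000000 0.160000 0.373333   0.110253
   Psi 1.000000 0.80 0.900000 0.816497 0.880000 0.848000   0.243340
     I 1.000000 0.80 0.900000 0.816497 0.880000 0.885333   0.134531
  Mean 0.783333 0.85 0.816667 0.642699 0.773333 0.760667   0.208941
Median 0.900000 0.80 0.850000 0.735575 0.820000 0.794667   0.140840
```

Reading: after only eight epochs the abundant labels (m6A ~1,600 planted
sites, I, m1A, m5C) separate perfectly from their same-base negatives,
while the rarest labels (m7G has ~26 sites) are still essentially
unlearned — the imbalance problem the OHEM/uncertainty-weighting losses
exist for. Longer training and the 51-nt window lift the rare labels (see
the planted-motif recovery study, where every label passes AUC_b 0.95).

```bash
# 3) predict on new sequence: probabilities, p-value bounds, attention
rnamod predict --checkpoint demo/run/model.ckpt \
    --fasta demo/query.fasta --outdir demo/pred
head -3 demo/pred/q1.probabilities.tsv
```

```
position  base  m6A  m1A  m5C  m5U  m6Am  m7G      Psi  I   Am  Cm  Gm       Um
1         G     NA   NA   NA   NA   NA    0.14657  NA   NA  NA  NA  0.32443  NA
2         G     NA   NA   NA   NA   NA    0.13631  NA   NA  NA  NA  0.31619  NA
```

Three TSVs per record (probabilities, p-value bounds with a `significant`
flag at p ≤ 0.05, attention scores), 1-based positions, `NA` where a base
cannot carry the modification.

From Python, the same pipeline is a few calls (see `examples/` for
narrative scripts covering simulation, training, attribution, motif
mining, association and distance enrichment):

```python
from rnamod import SynthConfig, generate, build_windows, split_dataset
from rnamod.model import ModelConfig, build_model, encode_windows, train
```

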