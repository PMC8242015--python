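"""Explain single predictions: integrated gradients and attention profiles.

Trains a small model, then shows for one held-out positive window where the
attribution mass and the label's attention sit relative to the planted
motif around the center.
"""

import numpy as np

from rnamod import build_windows, split_dataset
from rnamod.embedding import pretrain_on_sequences
from rnamod.interpret import attention_profile, integrated_gradients
from rnamod.labels import LABEL_INDEX, LABEL_NAMES
from rnamod.model import ModelConfig, build_model, encode_windows, train
from rnamod.synth import SynthConfig, generate

counts = {n: 0 for n in LABEL_NAMES}
counts.update(m6A=150, m5C=150)
sequences, sites, _ = generate(SynthConfig(
    n_transcripts=20, transcript_length=1200, label_counts=counts, seed=3))
windows = build_windows(sites, sequences, 21)
split = split_dataset(windows, val_per_class=30, test_per_class=10, seed=0)
embedding = pretrain_on_sequences(sequences, dim=16, epochs=2, seed=0)
config = ModelConfig(input_length=21, embed_dim=16, lstm_hidden=16,
                     fc_hidden=16, loss_mode="bce", max_epochs=15,
                     batch_size=64, learning_rate=3e-3, dropout=0.0,
                     lr_decay=1.0, seed=0)
model = build_model(config, embedding)
train(model, encode_windows(split.train, config, embedding),
      encode_windows(split.validation, config, embedding))

win = next(w for w in split.test if w.labels[LABEL_INDEX["m6A"]] == 1)
amap = integrated_gradients(model, win, "m6A", steps=50)
print("window:   ", win.sequence)
top = np.argsort(-amap.nucleotide_scores)[:5]
print("top attributed positions (0-based):", sorted(int(i) for i in top))
print(f"model output {amap.output:.3f}, baseline {amap.baseline_output:.3f}, "
      f"completeness residual {amap.residual:.2e}")

prof = attention_profile(model, win)
j = LABEL_INDEX["m6A"]
print("m6A attention argmax at position", int(np.argmax(prof[j])),
      "(center is", win.center_index, ")")
# The top attributions sit inside the planted 5-mer straddling the center,
# and the residual certifies they sum to the output difference from the
# uninformative baseline. The attention argmax marks where the head reads
# the evidence — with a causal LSTM that can be downstream of the motif,
# never upstream of it.
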