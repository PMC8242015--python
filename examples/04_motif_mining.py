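"""Recover planted motifs from a trained model's attribution maps.

Mines high-attribution 6-mers from top-scoring true positives, clusters
them (UMAP + DBSCAN), and compares each cluster PWM with the planted PWM.
"""

import numpy as np

from rnamod import build_windows, split_dataset
from rnamod.embedding import pretrain_on_sequences
from rnamod.interpret import cluster_motifs, mine_motifs, write_meme
from rnamod.labels import LABEL_INDEX, LABEL_NAMES
from rnamod.model import ModelConfig, build_model, encode_windows, train
from rnamod.synth import SynthConfig, best_pwm_distance, generate

counts = {n: 0 for n in LABEL_NAMES}
counts.update(m6A=150, m5C=150)
sequences, sites, truth = generate(SynthConfig(
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

label = "m6A"
held_out = [w for w in split.validation + split.test
            if w.labels[LABEL_INDEX[label]] == 1]
# small demo corpus: mine every confident positive (the default
# top-decile restriction leaves too few candidates to cluster)
candidates = mine_motifs(model, held_out, label, top_fraction=1.0,
                         w=6, steps=20)
print(f"{len(candidates)} candidate 6-mers from "
      f"{len(held_out)} held-out positives")
clusters = cluster_motifs(candidates, seed=0)
planted = np.array(truth["pwms"][label])
for cl in clusters:
    consensus = "".join("ACGU"[i] for i in cl.pwm.argmax(axis=1))
    tv = best_pwm_distance(cl.pwm, planted)
    print(f"cluster {cl.cluster_id}: {len(cl.members)} members, "
          f"consensus {consensus}, TV to planted PWM {tv:.3f}")
write_meme(clusters, "mined_motifs.meme")
print("wrote mined_motifs.meme (MEME minimal format)")
# The best cluster's consensus should contain the planted 5-mer; TV <= 0.25
# per column counts as a recovery at this corpus size.
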