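"""Desk-scale simulation studies exercising the whole pipeline.

Each study generates a synthetic corpus with :mod:`rnamod.synth`, runs the
relevant part of the pipeline, and measures a recovery quantity:

* :func:`planted_motif_recovery` — trains the full 12-label model on a
  corpus with one planted 5-mer PWM per label and scores per-label
  validation AUC_b plus the distance between the mined and planted m6A
  motif;
* :func:`association_recovery` — plants a shared PWM for two same-base
  labels (m1A and inosine) and an independent one for m6A, then asks whether
  the attention score vectors of the sharing pair correlate more strongly;
* :func:`imbalance_comparison` — builds a 50:1 abundance skew and compares
  the minority label's AUC_b under plain BCE versus OHEM + uncertainty
  weighting;
* :func:`distance_null_calibration` — checks that the site-distance
  enrichment p-value is calibrated (approximately uniform) for
  independently placed site sets.

Problem sizes are chosen for workstation-scale runs (minutes, not GPU
hours); they are the package's reference conditions for its own test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import pretrain_on_sequences
from .interpret import cluster_motifs, mine_motifs, association_matrix, \
    site_distance_enrichment
from .labels import LABEL_NAMES, LABEL_INDEX
from .metrics import auc_b
from .model import (
    ModelConfig, build_model, encode_windows, train, _forward_probs,
)
from .seqio import GenomicSite
from .synth import SynthConfig, best_pwm_distance, generate
from . import build_windows, split_dataset

__all__ = [
    "planted_motif_recovery",
    "association_recovery",
    "imbalance_comparison",
    "distance_null_calibration",
]


def _counts(**kwargs) -> dict[str, int]:
    counts = {n: 0 for n in LABEL_NAMES}
    counts.update(kwargs)
    return counts


def _train_on_corpus(
    seqs, sites, seed: int, *, input_length: int, dim: int, hidden: int,
    loss_mode: str, max_epochs: int, val_per_class: int, test_per_class: int,
    w2v_epochs: int = 2, learning_rate: float = 3e-3,
):
    windows = build_windows(sites, seqs, input_length)
    split = split_dataset(windows, val_per_class, test_per_class, seed=seed)
    emb = pretrain_on_sequences(seqs, dim=dim, epochs=w2v_epochs, seed=seed)
    config = ModelConfig(
        input_length=input_length, embed_dim=dim, lstm_hidden=hidden,
        fc_hidden=hidden, loss_mode=loss_mode, max_epochs=max_epochs,
        batch_size=128, learning_rate=learning_rate, dropout=0.0,
        lr_decay=1.0, seed=seed,
    )
    model = build_model(config, emb)
    tr = encode_windows(split.train, config, emb)
    va = encode_windows(split.validation, config, emb)
    result = train(model, tr, va, config)
    return model, result, split, emb


@dataclass
class MotifRecoveryReport:
    per_label_auc: dict[str, float]  # best epoch's per-label validation AUC_b
    min_label_auc: float  # max over epochs of the per-epoch minimum
    mined_label: str
    motif_tv: float  # best cluster PWM vs planted PWM, per-column TV
    n_epochs: int
    model: object
    truth: dict


def planted_motif_recovery(
    seed: int = 0,
    n_per_label: int = 500,
    input_length: int = 51,
    dim: int = 32,
    hidden: int = 32,
    max_epochs: int = 25,
    mined_label: str = "m6A",
) -> MotifRecoveryReport:
    """Train the 12-label model on planted 5-mer motifs and score recovery.

    Uses 500 positives per label (no skew), the standard 150/50 balanced
    validation/test split, and a small word2vec configuration. Recovery is
    measured as (a) per-label validation AUC_b over training and (b) the
    per-column total-variation distance between the best mined cluster PWM
    and the planted PWM of ``mined_label``.
    """
    cfg = SynthConfig(
        n_transcripts=100, transcript_length=2000,
        label_counts={n: n_per_label for n in LABEL_NAMES}, seed=seed,
    )
    seqs, sites, truth = generate(cfg)
    model, result, split, _ = _train_on_corpus(
        seqs, sites, seed, input_length=input_length, dim=dim, hidden=hidden,
        loss_mode="bce", max_epochs=max_epochs, val_per_class=150,
        test_per_class=50,
    )
    epoch_min = [min(h["val_auc_b"].values()) for h in result.history
                 if h["val_auc_b"]]
    best_epoch_aucs = result.history[int(np.argmax(epoch_min))]["val_auc_b"]

    held_out = [w for w in split.validation + split.test
                if w.labels[LABEL_INDEX[mined_label]] == 1]
    candidates = mine_motifs(model, held_out, mined_label, w=6, steps=20)
    planted = np.array(truth["pwms"][mined_label])
    tv = np.inf
    if len(candidates) >= 10:
        clusters = cluster_motifs(candidates, seed=seed)
        if clusters:
            tv = min(best_pwm_distance(c.pwm, planted) for c in clusters)
    return MotifRecoveryReport(
        per_label_auc=best_epoch_aucs,
        min_label_auc=float(max(epoch_min)),
        mined_label=mined_label,
        motif_tv=float(tv),
        n_epochs=len(result.history),
        model=model,
        truth=truth,
    )


@dataclass
class AssociationReport:
    rho_shared: float  # rho(m1A, I): same planted PWM
    rho_cross: float  # max of rho(m1A, m6A), rho(I, m6A)
    margin: float  # rho_shared - rho_cross


def association_recovery(
    seed: int = 0, n_per_label: int = 300, input_length: int = 21,
    dim: int = 16, hidden: int = 16, max_epochs: int = 10,
) -> AssociationReport:
    """Do labels that share a planted motif share attention structure?

    m1A and inosine (both adenosine modifications) are planted with one
    PWM; m6A keeps its own independent consensus. After training, the
    Pearson correlation between the m1A and I attention score vectors is
    compared with their correlations to m6A.
    """
    cfg = SynthConfig(
        n_transcripts=40, transcript_length=1500,
        label_counts=_counts(m6A=n_per_label, m1A=n_per_label, I=n_per_label),
        share={"I": "m1A"}, seed=seed,
    )
    seqs, sites, _ = generate(cfg)
    model, _, _, _ = _train_on_corpus(
        seqs, sites, seed, input_length=input_length, dim=dim, hidden=hidden,
        loss_mode="bce", max_epochs=max_epochs, val_per_class=30,
        test_per_class=10,
    )
    assoc = association_matrix(model)
    idx = {n: LABEL_INDEX[n] for n in ("m6A", "m1A", "I")}
    rho_shared = assoc.rho[idx["m1A"], idx["I"]]
    rho_cross = max(assoc.rho[idx["m1A"], idx["m6A"]],
                    assoc.rho[idx["I"], idx["m6A"]])
    return AssociationReport(
        rho_shared=float(rho_shared), rho_cross=float(rho_cross),
        margin=float(rho_shared - rho_cross),
    )


@dataclass
class ImbalanceReport:
    minority_auc_bce: float
    minority_auc_ohem_uw: float
    majority_auc_bce: float
    majority_auc_ohem_uw: float


def imbalance_comparison(
    seed: int = 0, n_majority: int = 1500, skew: int = 50,
    input_length: int = 21, dim: int = 16, hidden: int = 16,
    max_epochs: int = 12,
) -> ImbalanceReport:
    """Minority-label AUC_b under plain BCE vs OHEM + uncertainty weighting.

    m6A plays the abundant label and m7G the rare one at a ``skew``:1 ratio
    (default 50:1, echoing the gap between the most and least profiled
    modifications). Both losses train from the same split and seed; the
    minority AUC_b is evaluated on the held-out validation windows.
    """
    n_minority = max(4, n_majority // skew)
    cfg = SynthConfig(
        n_transcripts=60, transcript_length=1500,
        label_counts=_counts(m6A=n_majority, m7G=n_minority), seed=seed,
    )
    seqs, sites, _ = generate(cfg)
    aucs = {}
    for loss_mode in ("bce", "bce+ohem+uw"):
        model, _, split, emb = _train_on_corpus(
            seqs, sites, seed, input_length=input_length, dim=dim,
            hidden=hidden, loss_mode=loss_mode, max_epochs=max_epochs,
            val_per_class=10, test_per_class=5,
        )
        Xva, Yva, Mva = encode_windows(split.validation, model.config, emb)
        probs = _forward_probs(model, Xva)
        unmodified = Yva.sum(axis=1) == 0
        for name in ("m6A", "m7G"):
            j = LABEL_INDEX[name]
            pos = probs[Yva[:, j] == 1, j]
            neg = probs[(Mva[:, j] == 1) & unmodified, j]
            aucs[(loss_mode, name)] = auc_b(pos, neg)
    return ImbalanceReport(
        minority_auc_bce=aucs[("bce", "m7G")],
        minority_auc_ohem_uw=aucs[("bce+ohem+uw", "m7G")],
        majority_auc_bce=aucs[("bce", "m6A")],
        majority_auc_ohem_uw=aucs[("bce+ohem+uw", "m6A")],
    )


def distance_null_calibration(
    seed: int = 0, n_replicates: int = 50, n_sequences: int = 8,
    seq_length: int = 2000, n_a: int = 30, n_b: int = 40,
    n_shuffles: int = 99,
) -> np.ndarray:
    """Enrichment p-values for independently placed site sets.

    Both site sets are dropped uniformly at random on the same sequences, so
    the "closer than random" p-value should be approximately uniform across
    replicates. Returns the array of p-values.
    """
    rng = np.random.default_rng(seed)
    sequences = {f"s{i}": "A" * seq_length for i in range(n_sequences)}
    ids = sorted(sequences)
    pvals = np.empty(n_replicates)
    for r in range(n_replicates):
        sites_a = [
            GenomicSite(ids[rng.integers(n_sequences)],
                        int(rng.integers(seq_length)), "+", "m6A")
            for _ in range(n_a)
        ]
        sites_b = [
            GenomicSite(ids[rng.integers(n_sequences)],
                        int(rng.integers(seq_length)), "+", "Psi")
            for _ in range(n_b)
        ]
        res = site_distance_enrichment(
            sites_a, sites_b, sequences, n_shuffles=n_shuffles,
            seed=int(rng.integers(2 ** 31)),
        )
        pvals[r] = res.pvalue
    return pvals
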