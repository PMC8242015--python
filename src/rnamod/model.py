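"""Multi-label attention network for RNA modification site prediction.

Architecture (per forward pass on a batch of encoded windows):

1. an embedding front-end — either pre-embedded k-mer Word2vec matrices fed
   straight to the recurrent block, or one-hot input passed through a 1-D
   convolution + max-pooling stage that densifies the sparse encoding;
2. an LSTM whose per-position outputs ``y_i`` (hidden states) and internal
   cell states ``c_i`` feed an additive (Bahdanau) attention layer: per label
   j the score is ``e_{j,i} = v_j^T tanh(W c_i + U y_i + b_j)``, the softmax
   over positions gives the attention distribution, and the context vector is
   the attention-weighted combination of the ``y_i``;
3. twelve parallel fully connected branches (ReLU, dropout) mapping each
   context vector to the probability of its modification.

Because a window centered on, say, C can only carry C-borne modifications,
each training example supervises only the tasks compatible with its center
base; the other task outputs are masked out of the loss. The loss itself is
binary cross-entropy optionally combined with online hard example mining
(OHEM), learned task-uncertainty weighting (UW), focal down-weighting of
easy examples, or fixed effective-number class weights — the standard
armoury for the heavy class imbalance between abundant modifications like
m6A/I and rare ones like m7G.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autograd import Tensor, Adam, stack
from .embedding import EmbeddingTable, one_hot_encode, tokenize_kmers
from .labels import LABELS, LABEL_NAMES, LABELS_FOR_BASE, LABEL_INDEX
from .metrics import auc_b
from .seqio import SequenceWindow

__all__ = [
    "ModelConfig",
    "AttentionState",
    "MultiLabelAttentionNet",
    "build_model",
    "label_mask",
    "encode_windows",
    "compute_loss",
    "effective_number_weights",
    "train",
    "TrainResult",
    "predict_windows",
    "predict_sequence",
    "save_checkpoint",
    "load_checkpoint",
]

LOSS_MODES = (
    "bce", "bce+ohem", "bce+uw", "bce+ohem+uw", "focal", "effective_number",
)


@dataclass
class ModelConfig:
    """Hyper-parameters of the network and its training procedure."""

    input_length: int = 51
    embedding_mode: str = "word2vec"  # or "onehot_cnn"
    k: int = 3
    embed_dim: int = 300
    lstm_hidden: int = 128
    attention_dim: int = 0  # 0 -> same as lstm_hidden
    fc_hidden: int = 64
    dropout: float = 0.2
    conv_channels: int = 32
    conv_kernel: int = 7
    pool_size: int = 2
    loss_mode: str = "bce+ohem+uw"
    ohem_fraction: float = 0.7
    focal_gamma: float = 2.0
    effective_number_beta: float = 0.999
    learning_rate: float = 1e-3
    lr_schedule: str = "exponential"  # or "cosine_annealing"
    lr_decay: float = 0.95
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 5
    seed: int = 0
    n_labels: int = field(default=12, init=True)

    def __post_init__(self):
        if self.input_length % 2 == 0:
            raise ValueError("input_length must be odd")
        if self.embedding_mode not in ("word2vec", "onehot_cnn"):
            raise ValueError(f"unknown embedding_mode {self.embedding_mode!r}")
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")
        if self.attention_dim == 0:
            self.attention_dim = self.lstm_hidden


@dataclass
class AttentionState:
    """Attention weights and context vectors from one forward pass."""

    weights: np.ndarray  # (B, 12, T) — each row sums to 1 over T
    contexts: np.ndarray  # (B, 12, H)
    y: np.ndarray  # (B, T, H) learned per-position features
    c: np.ndarray  # (B, T, H) LSTM cell states


def _glorot(rng, fan_in, fan_out, *shape):
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=shape or (fan_in, fan_out)),
                  requires_grad=True)


class MultiLabelAttentionNet:
    """Encoder -> LSTM -> per-label additive attention -> 12 FC branches."""

    def __init__(self, config: ModelConfig, embedding: EmbeddingTable | None = None):
        if config.embedding_mode == "word2vec":
            if embedding is None:
                raise ValueError("word2vec mode requires an EmbeddingTable")
            if embedding.dim != config.embed_dim:
                raise ValueError(
                    f"embedding dim {embedding.dim} != config.embed_dim {config.embed_dim}"
                )
        self.config = config
        self.embedding = embedding
        rng = np.random.default_rng(config.seed)
        H, A, F, J = (config.lstm_hidden, config.attention_dim,
                      config.fc_hidden, config.n_labels)

        if config.embedding_mode == "onehot_cnn":
            K, C = config.conv_kernel, config.conv_channels
            self.conv_W = _glorot(rng, 4 * K, C, K, 4, C)
            self.conv_b = Tensor(np.zeros(C), requires_grad=True)
            d_in = C
        else:
            d_in = config.embed_dim

        self.Wx = _glorot(rng, d_in, 4 * H)
        self.Wh = _glorot(rng, H, 4 * H)
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias
        self.b_lstm = Tensor(b, requires_grad=True)

        self.att_Wc = _glorot(rng, H, A)
        self.att_Wy = _glorot(rng, H, A)
        self.att_b = Tensor(np.zeros((J, A)), requires_grad=True)
        self.att_v = _glorot(rng, A, 1, J, A)  # one score vector per label

        self.fc1_W = _glorot(rng, H, F, J, H, F)
        self.fc1_b = Tensor(np.zeros((J, F)), requires_grad=True)
        self.fc2_W = _glorot(rng, F, 1, J, F)
        self.fc2_b = Tensor(np.zeros(J), requires_grad=True)

        # learnable log-variances s_j for uncertainty weighting
        self.log_sigma = Tensor(np.zeros(J), requires_grad=True)

        self._dropout_rng = np.random.default_rng(config.seed + 1)

    # ------------------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        ps = [self.Wx, self.Wh, self.b_lstm, self.att_Wc, self.att_Wy,
              self.att_b, self.att_v, self.fc1_W, self.fc1_b, self.fc2_W,
              self.fc2_b, self.log_sigma]
        if self.config.embedding_mode == "onehot_cnn":
            ps = [self.conv_W, self.conv_b] + ps
        return ps

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        for p, a in zip(self.parameters(), arrays):
            p.data = a.copy()

    @property
    def association_vectors(self) -> np.ndarray:
        """The 12 attention score vectors v_j, rows in canonical label order."""
        return self.att_v.data.copy()

    # ------------------------------------------------------------------
    def _conv_front(self, x: Tensor) -> Tensor:
        """Conv1D (valid) + ReLU + max-pool over the length axis."""
        K = self.config.conv_kernel
        B, L, _ = x.shape
        T = L - K + 1
        out = None
        for k in range(K):
            term = x[:, k:k + T, :] @ self.conv_W[k]
            out = term if out is None else out + term
        out = (out + self.conv_b).relu()
        P = self.config.pool_size
        Tp = T // P
        out = out[:, : Tp * P, :].reshape(B, Tp, P, self.config.conv_channels)
        return out.max(axis=2)

    def _lstm(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Run the LSTM; return stacked hidden states Y and cell states C."""
        B, T, _ = x.shape
        H = self.config.lstm_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        xg = x @ self.Wx + self.b_lstm  # input projections for all steps
        ys, cs = [], []
        for t in range(T):
            gates = xg[:, t, :] + h @ self.Wh
            i = gates[:, :H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            ys.append(h)
            cs.append(c)
        return stack(ys, axis=1), stack(cs, axis=1)

    def _dropout(self, x: Tensor, train: bool) -> Tensor:
        p = self.config.dropout
        if not train or p <= 0:
            return x
        mask = (self._dropout_rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    def forward(
        self, x, train: bool = False
    ) -> tuple[Tensor, Tensor, AttentionState]:
        """Map encoded windows to per-label probabilities.

        Parameters
        ----------
        x
            ``(B, T, embed_dim)`` embedded k-mer matrices (word2vec mode) or
            ``(B, L, 4)`` one-hot matrices (onehot_cnn mode). May be a
            :class:`~rnamod.autograd.Tensor` (e.g. with ``requires_grad`` for
            attribution) or a plain array.

        Returns ``(probs, logits, attention_state)`` where ``probs`` is a
        ``(B, 12)`` tensor of independent per-label probabilities.
        """
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        if self.config.embedding_mode == "onehot_cnn":
            x = self._conv_front(x)
        x = self._dropout(x, train)
        Y, C = self._lstm(x)
        Y = self._dropout(Y, train)

        # additive attention, one score head per label (vectorised over labels)
        P = Y @ self.att_Wy + C @ self.att_Wc  # (B, T, A)
        J = self.config.n_labels
        B, T, A = P.shape
        H = self.config.lstm_hidden
        scored = (P.reshape(B, 1, T, A) + self.att_b.reshape(1, J, 1, A)).tanh()
        e = (scored * self.att_v.reshape(1, J, 1, A)).sum(axis=3)  # (B, J, T)
        alpha = e.softmax(axis=-1)
        contexts = alpha @ Y  # (B, J, T) @ (B, T, H) -> (B, J, H)

        # 12 parallel FC branches, batched over the label axis
        cj = contexts.swapaxes(0, 1)  # (J, B, H)
        hidden = self._dropout((cj @ self.fc1_W + self.fc1_b.reshape(J, 1, -1)).relu(),
                               train)  # (J, B, F)
        logits = ((hidden @ self.fc2_W.reshape(J, -1, 1)).reshape(J, B)
                  + self.fc2_b.reshape(J, 1)).swapaxes(0, 1)  # (B, J)
        probs = logits.sigmoid()
        state = AttentionState(
            weights=alpha.data, contexts=contexts.data, y=Y.data, c=C.data,
        )
        return probs, logits, state


def build_model(
    config: ModelConfig, embedding: EmbeddingTable | None = None
) -> MultiLabelAttentionNet:
    """Construct the network, checking config/embedding consistency."""
    if config.embedding_mode == "onehot_cnn" and embedding is not None:
        raise ValueError("onehot_cnn mode takes no embedding table")
    return MultiLabelAttentionNet(config, embedding)


# ----------------------------------------------------------------------
# data encoding and supervision masks
# ----------------------------------------------------------------------

def label_mask(center_bases) -> np.ndarray:
    """(B, 12) mask of tasks supervised by each window's center base."""
    mask = np.zeros((len(center_bases), len(LABELS)))
    for i, b in enumerate(center_bases):
        for name in LABELS_FOR_BASE.get(b, ()):
            mask[i, LABEL_INDEX[name]] = 1.0
    return mask


def encode_windows(
    windows: list[SequenceWindow],
    config: ModelConfig,
    embedding: EmbeddingTable | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode windows into model input ``X`` plus labels ``Y`` and mask ``M``."""
    if config.embedding_mode == "word2vec":
        assert embedding is not None
        V = len(embedding.tokens)
        vecs = np.vstack([embedding.vectors, np.zeros((1, embedding.dim))])
        idx = np.empty((len(windows), config.input_length - config.k + 1), dtype=np.intp)
        for i, w in enumerate(windows):
            toks = tokenize_kmers(w.sequence, k=config.k)
            idx[i] = [embedding.index.get(t, V) for t in toks]
        X = vecs[idx]
    else:
        X = np.stack([one_hot_encode(w.sequence) for w in windows])
    Y = np.stack([w.labels for w in windows]).astype(np.float64)
    M = label_mask([w.center_base for w in windows])
    return X, Y, M


# ----------------------------------------------------------------------
# losses
# ----------------------------------------------------------------------

def effective_number_weights(counts, beta: float) -> np.ndarray:
    """Class weights (1-beta)/(1-beta^n), normalised to mean 1.

    Equal weights in the beta->0 limit; proportional to 1/n as beta->1.
    """
    n = np.asarray(counts, dtype=np.float64)
    if np.any(n <= 0):
        raise ValueError("class counts must be positive")
    if beta >= 1.0:
        w = 1.0 / n
    else:
        w = (1.0 - beta) / (1.0 - beta ** n)
    return w / w.mean()


def _bce_elements(logits: Tensor, y: np.ndarray) -> Tensor:
    """Stable per-element binary cross-entropy from logits."""
    z = logits
    abs_z = z.relu() + (-z).relu()
    return z.relu() - z * Tensor(y) + ((-abs_z).exp() + 1.0).log()


def compute_loss(
    logits: Tensor,
    probs: Tensor,
    y: np.ndarray,
    mask: np.ndarray,
    mode: str,
    log_sigma: Tensor | None = None,
    ohem_fraction: float = 0.7,
    focal_gamma: float = 2.0,
    class_weights: np.ndarray | None = None,
) -> Tensor:
    """Masked multi-task loss in one of the supported modes.

    ``mask`` marks, per sample, the <= 4 tasks compatible with the center
    base; unmasked task outputs carry no gradient. OHEM keeps only the
    ``ohem_fraction`` highest-loss samples of the batch; UW weights each
    task's mean loss by a learned ``exp(-s_j)`` with an ``s_j`` penalty;
    focal multiplies each element by ``(1-p_t)^gamma``; effective-number
    applies fixed per-class weights.
    """
    if mode not in LOSS_MODES:
        raise ValueError(f"unknown loss mode {mode!r}")
    m = Tensor(mask)
    elements = _bce_elements(logits, y)  # (B, J)

    if mode == "focal":
        p = probs
        y_t = Tensor(y)
        p_t = p * y_t + (1.0 - p) * (1.0 - y_t)
        elements = ((1.0 - p_t) ** focal_gamma) * elements
        return (elements * m).sum() / max(mask.sum(), 1.0)

    if mode == "effective_number":
        if class_weights is None:
            raise ValueError("effective_number mode needs class_weights")
        w = Tensor(np.broadcast_to(class_weights, mask.shape).copy())
        return (elements * m * w).sum() / max(mask.sum(), 1.0)

    sample_sel = None
    if "ohem" in mode:
        with np.errstate(invalid="ignore"):
            per_sample = (elements.data * mask).sum(axis=1) / np.maximum(
                mask.sum(axis=1), 1.0
            )
        keep = max(1, int(math.ceil(ohem_fraction * len(per_sample))))
        sample_sel = np.argsort(-per_sample, kind="stable")[:keep]

    if sample_sel is not None:
        elements = elements[sample_sel]
        mask = mask[sample_sel]
        m = Tensor(mask)

    if "uw" in mode:
        if log_sigma is None:
            raise ValueError("uw mode needs the model's log_sigma tensor")
        task_n = mask.sum(axis=0)  # (J,)
        present = task_n > 0
        denom = np.where(present, task_n, 1.0)
        task_loss = (elements * m).sum(axis=0) / Tensor(denom)  # (J,)
        pres = Tensor(present.astype(np.float64))
        weighted = ((-log_sigma).exp() * task_loss + log_sigma) * pres
        return weighted.sum() / max(int(present.sum()), 1)

    return (elements * m).sum() / max(mask.sum(), 1.0)


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

@dataclass
class TrainResult:
    model: "MultiLabelAttentionNet"
    history: list[dict]
    best_epoch: int


def _epoch_lr(config: ModelConfig, epoch: int) -> float:
    base = config.learning_rate
    if config.lr_schedule == "cosine_annealing":
        return base * 0.5 * (1.0 + math.cos(math.pi * epoch / config.max_epochs))
    return base * config.lr_decay ** epoch


def _forward_probs(model, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Eval-mode forward in chunks (bounds graph memory on large sets)."""
    out = []
    for start in range(0, len(X), batch_size):
        probs, _, _ = model.forward(X[start:start + batch_size], train=False)
        out.append(probs.data)
    return np.concatenate(out)


def _val_auc_b(probs: np.ndarray, y: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    out = {}
    unmodified = y.sum(axis=1) == 0  # AUC_b negatives: unmodified sites only
    for j, name in enumerate(LABEL_NAMES):
        pos = probs[(y[:, j] == 1), j]
        neg = probs[(mask[:, j] == 1) & unmodified, j]
        if len(pos) and len(neg):
            out[name] = auc_b(pos, neg)
    return out


def train(
    model: MultiLabelAttentionNet,
    train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: ModelConfig | None = None,
) -> TrainResult:
    """Mini-batch Adam training with early stopping.

    ``train_data``/``val_data`` are ``(X, Y, mask)`` triples from
    :func:`encode_windows`. Training stops when the validation loss has
    increased for ``config.patience`` successive epochs (the best-epoch
    weights are restored) or after ``config.max_epochs``. Deterministic
    under the config seed.
    """
    config = config or model.config
    Xtr, Ytr, Mtr = train_data
    Xva, Yva, Mva = val_data
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ValueError("training and validation sets must be non-empty")

    class_w = None
    if config.loss_mode == "effective_number":
        counts = np.maximum(Ytr.sum(axis=0), 1.0)
        class_w = effective_number_weights(counts, config.effective_number_beta)

    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 2)
    history: list[dict] = []
    best_val = math.inf
    best_state = model.state_arrays()
    best_epoch = 0
    bad_streak = 0
    prev_val = math.inf

    for epoch in range(config.max_epochs):
        lr = _epoch_lr(config, epoch)
        order = rng.permutation(len(Xtr))
        total, nb = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            probs, logits, _ = model.forward(Xtr[sel], train=True)
            loss = compute_loss(
                logits, probs, Ytr[sel], Mtr[sel], config.loss_mode,
                log_sigma=model.log_sigma, ohem_fraction=config.ohem_fraction,
                focal_gamma=config.focal_gamma, class_weights=class_w,
            )
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training loss diverged (epoch {epoch}, batch {nb}): {loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            total += float(loss.data)
            nb += 1

        val_probs = _forward_probs(model, Xva)
        p = np.clip(val_probs, 1e-12, 1 - 1e-12)
        elems = -(Yva * np.log(p) + (1 - Yva) * np.log(1 - p))
        val_loss = float((elems * Mva).sum() / max(Mva.sum(), 1.0))
        aucs = _val_auc_b(val_probs, Yva, Mva)
        history.append({
            "epoch": epoch, "lr": lr, "train_loss": total / max(nb, 1),
            "val_loss": val_loss, "val_auc_b": aucs,
        })
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_arrays()
            best_epoch = epoch
        bad_streak = bad_streak + 1 if val_loss > prev_val else 0
        prev_val = val_loss
        if bad_streak >= config.patience:
            break

    model.load_state_arrays(best_state)
    return TrainResult(model=model, history=history, best_epoch=best_epoch)


# ----------------------------------------------------------------------
# prediction
# ----------------------------------------------------------------------

def predict_windows(
    model: MultiLabelAttentionNet,
    windows: list[SequenceWindow],
    batch_size: int = 256,
) -> np.ndarray:
    """Per-label probabilities for a list of windows, (N, 12)."""
    X, _, _ = encode_windows(windows, model.config, model.embedding)
    out = []
    for start in range(0, len(X), batch_size):
        probs, _, _ = model.forward(X[start:start + batch_size], train=False)
        out.append(probs.data)
    return np.concatenate(out) if out else np.zeros((0, len(LABELS)))


def predict_sequence(model: MultiLabelAttentionNet, sequence: str):
    """Slide the model over a long sequence.

    Returns a pandas DataFrame with one row per position (0-based
    ``position`` column, ``base``, and one probability column per label;
    NaN where the base cannot carry the modification). Flanks beyond the
    sequence are N-padded.
    """
    import pandas as pd

    from .seqio import GenomicSite, extract_window, _clean
    from .labels import NEGATIVE

    seq = _clean(sequence)
    if not seq:
        raise ValueError("empty sequence")
    L = model.config.input_length
    store = {"q": seq}
    windows = [
        extract_window(GenomicSite("q", i, "+", NEGATIVE), store, L)
        for i in range(len(seq))
    ]
    probs = predict_windows(model, windows)
    mask = label_mask(list(seq)).astype(bool)
    table = np.where(mask, probs, np.nan)
    df = pd.DataFrame(table, columns=list(LABEL_NAMES))
    df.insert(0, "base", list(seq))
    df.insert(0, "position", np.arange(len(seq)))
    return df


# ----------------------------------------------------------------------
# checkpointing
# ----------------------------------------------------------------------

def save_checkpoint(model: MultiLabelAttentionNet, path: str | Path) -> None:
    """Single-file archive: weights + config JSON + embedding table/hash."""
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    meta = {"config": asdict(model.config)}
    if model.embedding is not None:
        meta["embedding_hash"] = model.embedding.content_hash()
        arrays["embed_vectors"] = model.embedding.vectors
        meta["embed_tokens"] = model.embedding.tokens
        meta["embed_k"] = model.embedding.k
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        header = json.dumps(meta).encode()
        fh.write(len(header).to_bytes(8, "little"))
        fh.write(header)
        fh.write(buf.getvalue())


def load_checkpoint(path: str | Path) -> MultiLabelAttentionNet:
    with open(path, "rb") as fh:
        n = int.from_bytes(fh.read(8), "little")
        meta = json.loads(fh.read(n).decode())
        arrays = np.load(io.BytesIO(fh.read()))
    config = ModelConfig(**meta["config"])
    embedding = None
    if "embed_tokens" in meta:
        embedding = EmbeddingTable(
            meta["embed_tokens"], arrays["embed_vectors"], k=meta["embed_k"]
        )
        if embedding.content_hash() != meta["embedding_hash"]:
            raise ValueError("embedding table hash mismatch in checkpoint")
    model = MultiLabelAttentionNet(config, embedding)
    params = [arrays[f"param_{i}"] for i in range(len(model.parameters()))]
    model.load_state_arrays(params)
    return model
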