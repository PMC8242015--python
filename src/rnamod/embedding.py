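"""Sequence encodings: one-hot matrices and k-mer Word2vec embeddings.

Two representations of a nucleotide window are supported:

* a one-hot matrix (L x 4) with A/C/G/U as unit rows and N as the zero row,
  consumed by the convolutional front-end of the model, and
* a dense embedding (L-k+1 x dim) obtained by sliding a k-mer window
  (default k=3, stride 1) over the sequence and looking each k-mer up in a
  Word2vec table trained on the corpus itself.

The Word2vec trainer implements skip-gram (default) and CBOW with negative
sampling directly over NumPy. It is single-threaded and fully deterministic
under a fixed seed; nucleotide k-mer vocabularies are tiny (<= 4^k plus any
N-containing k-mers observed), so training is cheap. Embeddings are intended
to be pre-trained on long (1001-nt) windows and then sliced to the configured
input length, so short inputs reuse the long-range co-occurrence statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ONE_HOT",
    "one_hot_encode",
    "tokenize_kmers",
    "detokenize",
    "EmbeddingTable",
    "train_word2vec",
    "embed_sequence",
]

#: f(A)=(1,0,0,0), f(C)=(0,1,0,0), f(G)=(0,0,1,0), f(U)=(0,0,0,1), f(N)=0.
ONE_HOT = {
    "A": np.array([1, 0, 0, 0], dtype=np.float64),
    "C": np.array([0, 1, 0, 0], dtype=np.float64),
    "G": np.array([0, 0, 1, 0], dtype=np.float64),
    "U": np.array([0, 0, 0, 1], dtype=np.float64),
    "N": np.array([0, 0, 0, 0], dtype=np.float64),
}


def one_hot_encode(sequence: str) -> np.ndarray:
    """Encode a sequence over {A,C,G,U,N} as an L x 4 one-hot matrix."""
    try:
        return np.stack([ONE_HOT[b] for b in sequence])
    except KeyError as e:
        raise ValueError(f"cannot one-hot encode character {e.args[0]!r}") from None


def tokenize_kmers(sequence: str, k: int = 3, stride: int = 1) -> list[str]:
    """Overlapping k-mers left to right; count = floor((L-k)/stride) + 1."""
    if len(sequence) < k:
        raise ValueError(f"sequence of length {len(sequence)} shorter than k={k}")
    return [sequence[i:i + k] for i in range(0, len(sequence) - k + 1, stride)]


def detokenize(tokens: list[str]) -> str:
    """Reconstruct the sequence from stride-1 overlapping k-mers."""
    if not tokens:
        return ""
    out = [tokens[0]]
    for prev, tok in zip(tokens, tokens[1:]):
        if prev[1:] != tok[:-1]:
            raise ValueError(f"tokens {prev!r} and {tok!r} do not overlap")
        out.append(tok[-1])
    return "".join(out)


@dataclass
class EmbeddingTable:
    """Dense vectors for every k-mer observed during pre-training."""

    tokens: list[str]
    vectors: np.ndarray  # (V, dim)
    k: int
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def lookup(self, token: str, oov: str = "zero") -> np.ndarray:
        """Vector for a token; unseen tokens map to zero unless ``oov='strict'``."""
        i = self.index.get(token)
        if i is not None:
            return self.vectors[i]
        if oov == "strict":
            raise KeyError(f"token {token!r} not in embedding vocabulary")
        return np.zeros(self.dim)

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(("\n".join(self.tokens)).encode())
        h.update(np.ascontiguousarray(self.vectors).tobytes())
        return h.hexdigest()[:16]

    def save(self, prefix: str | Path) -> None:
        """Persist as a two-file pair: token list (text) + vector matrix."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        Path(f"{prefix}.tokens.txt").write_text("\n".join(self.tokens) + "\n")
        np.save(f"{prefix}.vectors.npy", self.vectors)

    @classmethod
    def load(cls, prefix: str | Path) -> "EmbeddingTable":
        tokens = Path(f"{prefix}.tokens.txt").read_text().splitlines()
        vectors = np.load(f"{prefix}.vectors.npy")
        return cls(tokens, vectors, k=len(tokens[0]))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t, v in zip(self.tokens, self.vectors):
                fh.write(t + "\t" + "\t".join(f"{x:.6g}" for x in v) + "\n")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_word2vec(
    corpus: list[list[str]],
    dim: int = 300,
    window: int = 5,
    epochs: int = 5,
    negative: int = 5,
    lr: float = 0.025,
    min_lr: float = 1e-4,
    architecture: str = "skipgram",
    seed: int = 0,
) -> EmbeddingTable:
    """Train k-mer embeddings with negative sampling.

    Parameters
    ----------
    corpus
        Token sequences (one per pre-training window), e.g. the stride-1
        3-mers of 1001-nt sequences.
    dim
        Embedding dimensionality (default 300).
    window
        Number of neighbouring tokens on each side used as context
        (default 5).
    architecture
        ``"skipgram"`` (default) or ``"cbow"``.

    Returns a table covering every observed token. Deterministic under a
    fixed seed (single-threaded).
    """
    if not corpus or all(len(s) == 0 for s in corpus):
        raise ValueError("empty corpus")
    if architecture not in ("skipgram", "cbow"):
        raise ValueError(f"unknown architecture {architecture!r}")

    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    for sent in corpus:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    tokens = sorted(counts)
    index = {t: i for i, t in enumerate(tokens)}
    V = len(tokens)
    k = len(tokens[0])

    # unigram^(3/4) negative-sampling distribution
    freq = np.array([counts[t] for t in tokens], dtype=np.float64) ** 0.75
    neg_p = freq / freq.sum()

    W_in = (rng.random((V, dim)) - 0.5) / dim  # input (target) vectors
    W_out = np.zeros((V, dim))  # output (context) vectors

    encoded = [np.array([index[t] for t in sent], dtype=np.intp) for sent in corpus]
    n_updates = max(1, epochs * sum(len(s) for s in encoded))
    step = 0
    for _ in range(epochs):
        for sent in encoded:
            for pos, target in enumerate(sent):
                alpha = max(min_lr, lr * (1.0 - step / n_updates))
                step += 1
                lo, hi = max(0, pos - window), min(len(sent), pos + window + 1)
                ctx = np.concatenate([sent[lo:pos], sent[pos + 1:hi]])
                if len(ctx) == 0:
                    continue
                neg = rng.choice(V, size=negative * len(ctx), p=neg_p)
                if architecture == "skipgram":
                    # target predicts each context token
                    v = W_in[target]  # (dim,)
                    out_idx = np.concatenate([ctx, neg])
                    y = np.zeros(len(out_idx))
                    y[: len(ctx)] = 1.0
                    u = W_out[out_idx]  # (n, dim)
                    g = (_sigmoid(u @ v) - y) * alpha  # (n,)
                    grad_v = g @ u
                    np.add.at(W_out, out_idx, -np.outer(g, v))
                    W_in[target] -= grad_v
                else:  # cbow: mean of context predicts target
                    h = W_in[ctx].mean(axis=0)
                    out_idx = np.concatenate([[target], neg[:negative]])
                    y = np.zeros(len(out_idx))
                    y[0] = 1.0
                    u = W_out[out_idx]
                    g = (_sigmoid(u @ h) - y) * alpha
                    grad_h = g @ u
                    np.add.at(W_out, out_idx, -np.outer(g, h))
                    W_in[ctx] -= grad_h / len(ctx)
    return EmbeddingTable(tokens, W_in, k=k)


def pretrain_on_sequences(
    sequences: dict[str, str] | list[str],
    k: int = 3,
    dim: int = 300,
    window: int = 5,
    epochs: int = 5,
    chunk: int = 1001,
    architecture: str = "skipgram",
    seed: int = 0,
) -> EmbeddingTable:
    """Pre-train k-mer vectors on long sequence windows.

    Sequences are cut into ``chunk``-length pieces (default 1001 nt) which
    act as sentences, so the vectors carry long-range co-occurrence
    statistics; shorter model inputs are then sliced from the same token
    stream at encoding time.
    """
    seqs = sequences.values() if isinstance(sequences, dict) else sequences
    corpus = []
    for s in sorted(seqs):
        for start in range(0, max(1, len(s) - k + 1), chunk):
            piece = s[start:start + chunk]
            if len(piece) >= k:
                corpus.append(tokenize_kmers(piece, k=k))
    return train_word2vec(
        corpus, dim=dim, window=window, epochs=epochs,
        architecture=architecture, seed=seed,
    )


def embed_sequence(
    tokens: list[str], table: EmbeddingTable, oov: str = "zero"
) -> np.ndarray:
    """Stack per-token vectors into an (L-k+1) x dim matrix."""
    return np.stack([table.lookup(t, oov=oov) for t in tokens]) if tokens else np.zeros(
        (0, table.dim)
    )
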