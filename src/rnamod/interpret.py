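"""Model interpretation: attribution, motif mining, and label association.

Positive predictions are explained two ways. Integrated gradients (IG)
averages the gradient of a label's output along the straight path from a
baseline (the all-zero embedding, i.e. an uninformative window) to the
input, giving signed per-nucleotide contribution scores that satisfy the
completeness axiom — they sum to the output difference from the baseline up
to the Riemann-sum residual, which is reported. Attention profiles expose
where each label's attention head concentrates.

Motif mining follows the attribution route: among true-positive windows in
the top decile of predicted probability, the highest-mean-attribution
windows of width ``w`` are greedily selected per sample (masking each
selection's neighbourhood), embedded via one-hot + UMAP, density-clustered
with DBSCAN, and summarised per cluster as a position weight matrix. The
cross-modification association analysis correlates the twelve attention
score vectors ``v_j`` pairwise (Pearson, exact-distribution two-sided p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import pearsonr
from sklearn.cluster import DBSCAN

from .autograd import Tensor
from .embedding import one_hot_encode
from .labels import LABEL_NAMES, LABEL_INDEX, ORIGINAL_BASE
from .model import MultiLabelAttentionNet, encode_windows, predict_windows
from .seqio import SequenceWindow

__all__ = [
    "AttributionMap",
    "integrated_gradients",
    "integrated_gradients_fn",
    "attention_profile",
    "MotifCandidate",
    "mine_motifs",
    "MotifCluster",
    "cluster_motifs",
    "AssociationMatrix",
    "association_matrix",
    "site_distance_enrichment",
    "write_meme",
    "plot_logo",
]


# ----------------------------------------------------------------------
# integrated gradients
# ----------------------------------------------------------------------

@dataclass
class AttributionMap:
    """Per-nucleotide signed contributions for one (window, label) pair."""

    window: SequenceWindow
    label: str
    nucleotide_scores: np.ndarray  # (L,)
    token_scores: np.ndarray  # (T,)
    output: float
    baseline_output: float
    residual: float  # |sum(attributions) - (output - baseline_output)|
    steps: int


def _tokens_to_nucleotides(token_scores: np.ndarray, L: int, k: int) -> np.ndarray:
    """Distribute each token's score equally over the k nucleotides it covers.

    Mass-preserving, so completeness carries over to nucleotide resolution.
    """
    nuc = np.zeros(L)
    for t, s in enumerate(token_scores):
        nuc[t:t + k] += s / k
    return nuc


def integrated_gradients_fn(
    f, x: np.ndarray, baseline: np.ndarray, steps: int = 50
) -> tuple[np.ndarray, float]:
    """Midpoint Riemann-sum IG for an arbitrary differentiable scalar field.

    ``f`` maps a batch tensor ``(B, *x.shape)`` to a ``(B,)`` tensor of
    outputs. Returns the attribution array (shape of ``x``) and the
    completeness residual ``|sum(attr) - (f(x) - f(baseline))|``, which
    shrinks as ``steps`` grows (exactly zero for linear ``f``).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    baseline = np.asarray(baseline, dtype=np.float64)
    if baseline.shape != x.shape:
        raise ValueError("baseline shape mismatch")
    alphas = (np.arange(steps) + 0.5) / steps
    diff = x - baseline
    path = baseline[None] + alphas.reshape((-1,) + (1,) * x.ndim) * diff[None]
    xt = Tensor(path, requires_grad=True)
    f(xt).sum().backward()
    attr = diff * xt.grad.mean(axis=0)
    pair = Tensor(np.stack([x, baseline]))
    out, out0 = (float(v) for v in f(pair).data)
    residual = abs(attr.sum() - (out - out0))
    return attr, residual


def integrated_gradients(
    model: MultiLabelAttentionNet,
    window: SequenceWindow,
    label: str,
    steps: int = 50,
    baseline: np.ndarray | None = None,
) -> AttributionMap:
    """Midpoint Riemann-sum integrated gradients for one window and label.

    The baseline defaults to the all-zero input (zero embedding rows in
    word2vec mode; the all-N one-hot in onehot mode — the same thing). The
    completeness residual shrinks as ``steps`` grows.
    """
    j = LABEL_INDEX[label]
    if ORIGINAL_BASE[label] != window.center_base:
        raise ValueError(
            f"label {label} needs center base {ORIGINAL_BASE[label]}, "
            f"window has {window.center_base}"
        )
    X, _, _ = encode_windows([window], model.config, model.embedding)
    x = X[0]
    base = np.zeros_like(x) if baseline is None else np.asarray(baseline, float)

    attr, residual = integrated_gradients_fn(
        lambda xt: model.forward(xt, train=False)[0][:, j], x, base, steps
    )
    token_scores = attr.sum(axis=1)
    out = float(model.forward(x[None])[0].data[0, j])
    out0 = float(model.forward(base[None])[0].data[0, j])

    L = len(window.sequence)
    k = model.config.k if model.config.embedding_mode == "word2vec" else 1
    if model.config.embedding_mode == "onehot_cnn":
        nuc = token_scores.copy()
    else:
        nuc = _tokens_to_nucleotides(token_scores, L, k)
    return AttributionMap(
        window=window, label=label, nucleotide_scores=nuc,
        token_scores=token_scores, output=out, baseline_output=out0,
        residual=residual, steps=steps,
    )


def attribution_to_tsv(amap: AttributionMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tbase\tscore\n")
        for i, (b, s) in enumerate(zip(amap.window.sequence, amap.nucleotide_scores)):
            fh.write(f"{i + 1}\t{b}\t{s:.6g}\n")


# ----------------------------------------------------------------------
# attention profiles
# ----------------------------------------------------------------------

def attention_profile(
    model: MultiLabelAttentionNet, window: SequenceWindow
) -> np.ndarray:
    """(12, L) per-nucleotide attention distributions for one window.

    Token-position weights are mapped to nucleotides (each nucleotide takes
    the mean weight of the <= k tokens covering it) and renormalised to sum
    to 1 per label.
    """
    X, _, _ = encode_windows([window], model.config, model.embedding)
    _, _, state = model.forward(X, train=False)
    token_w = state.weights[0]  # (12, T)
    L = len(window.sequence)
    if model.config.embedding_mode == "onehot_cnn":
        # conv/pool front-end decouples token and nucleotide grids; spread
        # each pooled position's weight uniformly over its receptive field
        T = token_w.shape[1]
        P, K = model.config.pool_size, model.config.conv_kernel
        out = np.zeros((12, L))
        for t in range(T):
            lo = t * P
            hi = min(L, lo + P + K - 1)
            out[:, lo:hi] += token_w[:, t, None] / (hi - lo)
    else:
        k = model.config.k
        out = np.zeros((12, L))
        counts = np.zeros(L)
        for t in range(token_w.shape[1]):
            out[:, t:t + k] += token_w[:, t, None]
            counts[t:t + k] += 1
        out /= np.maximum(counts, 1)
    return out / out.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------------
# motif mining
# ----------------------------------------------------------------------

@dataclass
class MotifCandidate:
    """A high-attribution subsequence extracted from one sample."""

    sequence: str
    sample_id: str
    score: float
    start: int


def _top_windows(scores: np.ndarray, seq: str, w: int, k_per_sample: int,
                 sample_id: str) -> list[MotifCandidate]:
    """Greedy non-overlapping top-mean windows with neighbourhood removal."""
    L = len(scores)
    if L < w:
        return []
    means = np.convolve(scores, np.ones(w) / w, mode="valid")  # (L-w+1,)
    available = np.ones(len(means), dtype=bool)
    out = []
    for _ in range(k_per_sample):
        if not available.any():
            break
        masked = np.where(available, means, -np.inf)
        s = int(np.argmax(masked))
        out.append(MotifCandidate(seq[s:s + w], sample_id, float(means[s]), s))
        lo = max(0, s - (w - 1) - (w - 1))
        hi = min(len(means), s + w + (w - 1))
        available[lo:hi] = False
    return out


def mine_motifs(
    model: MultiLabelAttentionNet,
    windows: list[SequenceWindow],
    label: str,
    top_fraction: float = 0.10,
    w: int = 6,
    k_per_sample: int = 3,
    threshold: float = 0.5,
    steps: int = 20,
) -> list[MotifCandidate]:
    """High-attribution motif candidates from top-scoring true positives.

    Restricts to windows that carry the label, are predicted positive at
    ``threshold``, and sit in the top ``top_fraction`` of predicted
    probability; per sample the ``k_per_sample`` best width-``w`` windows of
    mean IG attribution are taken, each masking its ``w - 1`` flanks. The
    candidates need not contain the modified center itself.
    """
    j = LABEL_INDEX[label]
    positives = [x for x in windows if x.labels[j] == 1]
    if not positives:
        warnings.warn(f"no positive windows for {label}; no motifs mined")
        return []
    probs = predict_windows(model, positives)[:, j]
    tp = [(p, x) for p, x in zip(probs, positives) if p >= threshold]
    if not tp:
        warnings.warn(f"no true positives for {label}; no motifs mined")
        return []
    tp.sort(key=lambda t: -t[0])
    n_top = max(1, int(np.ceil(top_fraction * len(tp))))
    candidates: list[MotifCandidate] = []
    for rank, (p, x) in enumerate(tp[:n_top]):
        amap = integrated_gradients(model, x, label, steps=steps)
        sid = f"{x.site.sequence_id}:{x.site.position}"
        candidates.extend(
            _top_windows(amap.nucleotide_scores, x.sequence, w, k_per_sample, sid)
        )
    return candidates


# ----------------------------------------------------------------------
# motif clustering
# ----------------------------------------------------------------------

@dataclass
class MotifCluster:
    cluster_id: int
    members: list[MotifCandidate]
    pwm: np.ndarray  # (w, 4), columns sum to 1


def _candidates_pwm(cands: list[MotifCandidate], pseudocount: float = 0.01) -> np.ndarray:
    w = len(cands[0].sequence)
    counts = np.full((w, 4), pseudocount)
    for c in cands:
        counts += one_hot_encode(c.sequence)
    return counts / counts.sum(axis=1, keepdims=True)


def cluster_motifs(
    candidates: list[MotifCandidate],
    eps: float = 0.5,
    min_samples: int = 5,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> list[MotifCluster]:
    """Embed one-hot candidate motifs (UMAP, 2-D) and cluster with DBSCAN.

    Equal-length candidates already align, so no multiple alignment is
    needed. Noise points are discarded; each cluster is summarised as a PWM
    with pseudocount 0.01. When there are too few distinct candidates for a
    meaningful neighbour graph, DBSCAN runs directly on the one-hot vectors
    (identical sequences are then at distance zero).
    """
    if len(candidates) < 10:
        raise ValueError("need at least 10 candidates to cluster")
    if len({len(c.sequence) for c in candidates}) != 1:
        raise ValueError("candidates must share one width")
    X = np.stack([one_hot_encode(c.sequence).ravel() for c in candidates])
    n_unique = len(np.unique(X, axis=0))
    if n_unique > max(4, min(n_neighbors, len(candidates) - 2)):
        import umap

        reducer = umap.UMAP(
            n_components=2, n_neighbors=min(n_neighbors, len(candidates) - 1),
            min_dist=min_dist, random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = reducer.fit_transform(X)
        labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(emb)
    else:
        labels = DBSCAN(eps=0.5, min_samples=min_samples).fit_predict(X)
    clusters = []
    for cid in sorted(set(labels) - {-1}):
        members = [c for c, l in zip(candidates, labels) if l == cid]
        clusters.append(MotifCluster(int(cid), members, _candidates_pwm(members)))
    if not clusters:
        warnings.warn("all candidates classified as noise; no clusters")
    return clusters


# ----------------------------------------------------------------------
# association analysis
# ----------------------------------------------------------------------

@dataclass
class AssociationMatrix:
    labels: tuple[str, ...]
    rho: np.ndarray  # (12, 12), symmetric, unit diagonal
    pvalues: np.ndarray  # (12, 12), NaN on the diagonal / undefined pairs

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.rho, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.6g"
        )

    def plot(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import seaborn as sns

        fig, ax = plt.subplots(figsize=(7, 6))
        sns.heatmap(self.rho, xticklabels=self.labels, yticklabels=self.labels,
                    vmin=-1, vmax=1, cmap="coolwarm", annot=True, fmt=".2f",
                    ax=ax, cbar_kws={"label": "Pearson rho"})
        ax.set_title("Association of attention score vectors")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def association_matrix(model: MultiLabelAttentionNet) -> AssociationMatrix:
    """Pairwise Pearson correlation of the 12 attention score vectors.

    Two-sided p-values use the exact distribution of the sample correlation
    coefficient under the null of no correlation. A zero-variance vector
    leaves its row/column as NaN (undefined) rather than zero-filled.
    """
    V = model.association_vectors  # (12, A)
    J = V.shape[0]
    rho = np.full((J, J), np.nan)
    pval = np.full((J, J), np.nan)
    degenerate = V.std(axis=1) == 0
    for a in range(J):
        rho[a, a] = 1.0
        for b in range(a + 1, J):
            if degenerate[a] or degenerate[b]:
                continue
            r = pearsonr(V[a], V[b])
            rho[a, b] = rho[b, a] = r.statistic
            pval[a, b] = pval[b, a] = r.pvalue
    return AssociationMatrix(labels=LABEL_NAMES, rho=rho, pvalues=pval)


# ----------------------------------------------------------------------
# site-distance enrichment
# ----------------------------------------------------------------------

@dataclass
class DistanceEnrichment:
    observed: np.ndarray  # nearest-neighbour distances, one per a-site
    observed_median: float
    null_medians: np.ndarray  # (n_shuffles,)
    pvalue: float  # one-sided: closer than random


def _nearest_distances(pos_a: dict, pos_b: dict) -> np.ndarray:
    out = []
    for seq_id, a_list in pos_a.items():
        b = pos_b.get(seq_id)
        if b is None or len(b) == 0:
            continue
        b = np.sort(np.asarray(b))
        for p in a_list:
            i = np.searchsorted(b, p)
            cands = []
            if i < len(b):
                cands.append(abs(int(b[i]) - p))
            if i > 0:
                cands.append(abs(int(b[i - 1]) - p))
            out.append(min(cands))
    return np.asarray(out, dtype=np.float64)


def site_distance_enrichment(
    sites_a, sites_b, sequences: dict[str, str],
    n_shuffles: int = 100, seed: int = 0,
) -> DistanceEnrichment:
    """Are a-sites closer to b-sites than random placement would put them?

    For every a-site, the distance to the nearest b-site on the same
    sequence is recorded; the null repositions the b-sites uniformly at
    random on their own sequences ``n_shuffles`` times. The one-sided
    empirical p-value (with add-one correction) tests whether the observed
    median nearest distance is smaller than under the null.
    """
    pos_a: dict[str, list[int]] = {}
    pos_b: dict[str, list[int]] = {}
    for s in sites_a:
        pos_a.setdefault(s.sequence_id, []).append(s.position)
    for s in sites_b:
        pos_b.setdefault(s.sequence_id, []).append(s.position)
    shared = set(pos_a) & set(pos_b)
    if not shared:
        raise ValueError("site sets share no sequences")

    observed = _nearest_distances(pos_a, pos_b)
    obs_med = float(np.median(observed))
    rng = np.random.default_rng(seed)
    null_medians = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled = {
            seq_id: rng.integers(0, len(sequences[seq_id]), size=len(plist))
            for seq_id, plist in pos_b.items()
        }
        null_medians[i] = np.median(_nearest_distances(pos_a, shuffled))
    p = (1 + int((null_medians <= obs_med).sum())) / (n_shuffles + 1)
    return DistanceEnrichment(observed, obs_med, null_medians, float(p))


# ----------------------------------------------------------------------
# export: MEME minimal motifs and logos
# ----------------------------------------------------------------------

def write_meme(clusters: list[MotifCluster], path: str | Path,
               alphabet: str = "ACGU") -> None:
    """Write cluster PWMs in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {alphabet}\n\n")
        fh.write("strands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{c} 0.25" for c in alphabet) + "\n\n")
        for cl in clusters:
            w = cl.pwm.shape[0]
            fh.write(f"MOTIF cluster_{cl.cluster_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {w} "
                f"nsites= {len(cl.members)} E= 0\n"
            )
            for row in cl.pwm:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def plot_logo(pwm: np.ndarray, path: str | Path, alphabet: str = "ACGU") -> None:
    """Render a PWM as an information-content-scaled sequence logo."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D
    from matplotlib.font_manager import FontProperties

    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "U": "#D62839"}
    pwm = np.asarray(pwm, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        ic = 2.0 + np.nansum(np.where(pwm > 0, pwm * np.log2(pwm), 0.0), axis=1)
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    fig, ax = plt.subplots(figsize=(max(2, pwm.shape[0] * 0.6), 2.4))
    for i, (col, info) in enumerate(zip(pwm, ic)):
        heights = col * info
        y = 0.0
        for idx in np.argsort(heights):
            h = heights[idx]
            if h <= 1e-3:
                continue
            tp = TextPath((0, 0), alphabet[idx], size=1, prop=fp)
            bb = tp.get_extents()
            tr = (Affine2D()
                  .translate(-bb.x0, -bb.y0)
                  .scale(0.9 / bb.width, h / bb.height)
                  .translate(i + 0.05, y))
            ax.add_patch(PathPatch(tp.transformed(tr),
                                   facecolor=colors[alphabet[idx]], edgecolor="none"))
            y += h
    ax.set_xlim(0, pwm.shape[0])
    ax.set_ylim(0, 2.05)
    ax.set_xticks(np.arange(pwm.shape[0]) + 0.5,
                  [str(i + 1) for i in range(pwm.shape[0])])
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
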