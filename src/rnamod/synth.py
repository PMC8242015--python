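"""Synthetic epitranscriptome corpora with planted motifs.

Real base-resolution modification corpora have a characteristic structure:
per-label sets of sequence windows centered on a modifiable base, negatives
drawn from unmodified occurrences of the same base on the same transcript,
heavy abundance skew across the twelve labels (tens of thousands of m6A and
inosine sites down to around a thousand m7G sites), and label-specific
sequence consensus around the site. The generator emulates exactly that:
random background transcripts, per-label positive sites whose surrounding
window is drawn from a planted position weight matrix (PWM) with the center
fixed to the label's original base, configurable cross-label PWM sharing,
and seeded same-transcript negatives. The planted truth (sites and PWMs) is
recorded so recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .labels import LABEL_NAMES, ORIGINAL_BASE, NEGATIVE
from .seqio import GenomicSite, sample_negatives, write_sites
from .metrics import auc_b

__all__ = [
    "SynthConfig",
    "default_label_counts",
    "default_pwms",
    "generate",
    "write_corpus",
    "pwm_total_variation",
    "best_pwm_distance",
    "truth_eval",
]

BASES = "ACGU"

#: Table-5-style relative abundances of the twelve modifications (fractions
#: of all positive sites; m6A and I dominate, m7G is rarest).
ABUNDANCE = {
    "m6A": 0.4008, "I": 0.3236, "m1A": 0.1007, "m5C": 0.0795,
    "Psi": 0.0193, "m6Am": 0.0150, "Um": 0.0139, "Cm": 0.0115,
    "m5U": 0.0104, "Am": 0.0098, "Gm": 0.0090, "m7G": 0.0064,
}


def default_label_counts(total: int = 3000) -> dict[str, int]:
    """Positive-site counts per label with realistic abundance skew."""
    return {name: max(1, int(round(total * ABUNDANCE[name]))) for name in LABEL_NAMES}


def _sharp_column(rng, base: str, peak: float = 0.95) -> np.ndarray:
    col = np.full(4, (1.0 - peak) / 3.0)
    col[BASES.index(base)] = peak
    return col


def _pwm_from_consensus(rng, consensus: str, peak: float = 0.95) -> np.ndarray:
    return np.stack([_sharp_column(rng, b, peak) for b in consensus])


def _max_alignment_matches(a: str, b: str, max_shift: int = 2) -> int:
    """Best positional-match count between two consensi over small shifts."""
    best = 0
    for shift in range(-max_shift, max_shift + 1):
        matches = sum(
            1 for i in range(len(a))
            if 0 <= i + shift < len(b) and a[i] == b[i + shift]
        )
        best = max(best, matches)
    return best


def default_pwms(
    width: int = 5, peak: float = 0.95, seed: int = 0,
    share: dict[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """One sharp planted PWM per label, center column fixed to its base.

    m6A defaults to a GGACU-like (DRACH-compatible) consensus and m6Am to a
    BCA-compatible one so the consensus restrictions of real pipelines apply
    unchanged. Independently drawn consensi are rejection-sampled to stay
    dissimilar (no near-identity under small shifts), so any motif sharing
    between labels is governed solely by ``share``, which maps a label to
    another label whose PWM it copies (center column excepted, which always
    matches the label's own base).
    """
    if width < 4 or width > 8 or width % 2 == 0:
        raise ValueError("PWM width must be odd and within 4..8")
    rng = np.random.default_rng(seed)
    center = (width - 1) // 2
    pwms: dict[str, np.ndarray] = {}
    consensi: list[str] = []
    max_shared = width - 2  # reject shifted near-duplicates (> w-2 matches)
    for name in LABEL_NAMES:
        base = ORIGINAL_BASE[name]
        if name == "m6A" and width >= 5:
            consensus = list("GGACU")
            while len(consensus) < width:
                consensus.append(BASES[rng.integers(4)])
            consensus[center] = "A"
        else:
            for _ in range(200):
                consensus = [BASES[rng.integers(4)] for _ in range(width)]
                if name == "m6Am" and width >= 5:
                    # BCA-compatible: the A of BCA sits at the center column
                    consensus[center - 2:center + 1] = ["C", "C", "A"]
                else:
                    consensus[center] = base
                if all(_max_alignment_matches("".join(consensus), c) <= max_shared
                       for c in consensi):
                    break
        consensi.append("".join(consensus))
        pwm = _pwm_from_consensus(rng, "".join(consensus), peak)
        pwm[center] = _sharp_column(rng, base, 1.0)  # center is the site base
        pwms[name] = pwm
    if share:
        for dst, src in share.items():
            pwm = pwms[src].copy()
            pwm[center] = _sharp_column(rng, ORIGINAL_BASE[dst], 1.0)
            pwms[dst] = pwm
    return pwms


@dataclass
class SynthConfig:
    """Conditions of a synthetic corpus."""

    n_transcripts: int = 60
    transcript_length: int = 1500
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    label_counts: dict[str, int] = field(default_factory=default_label_counts)
    pwms: dict[str, np.ndarray] | None = None  # default: default_pwms(seed)
    motif_width: int = 5
    pwm_peak: float = 0.95
    share: dict[str, str] | None = None  # label -> label whose PWM it copies
    negative_ratio: float = 1.0
    seed: int = 0

    def resolved_pwms(self) -> dict[str, np.ndarray]:
        if self.pwms is not None:
            return self.pwms
        return default_pwms(self.motif_width, self.pwm_peak, self.seed, self.share)


def generate(
    config: SynthConfig,
) -> tuple[dict[str, str], list[GenomicSite], dict]:
    """Generate transcripts, positive/negative sites and a truth record.

    Positive sites are planted non-overlapping (an overlapping-beyond-
    capacity configuration raises), each with its window rewritten from the
    label's PWM; negatives are same-transcript same-base draws. Fully
    deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    comp = np.asarray(config.base_composition, dtype=np.float64)
    comp = comp / comp.sum()
    pwms = config.resolved_pwms()
    W = config.motif_width
    half = (W - 1) // 2

    seqs = {
        f"tx{i:04d}": rng.choice(list(BASES), size=config.transcript_length, p=comp)
        for i in range(config.n_transcripts)
    }
    occupied: dict[str, set[int]] = {tx: set() for tx in seqs}

    capacity = config.n_transcripts * (config.transcript_length - 2 * half) // (2 * W)
    total_sites = sum(config.label_counts.get(n, 0) for n in LABEL_NAMES)
    if total_sites > capacity:
        raise ValueError(
            f"infeasible density: {total_sites} sites exceed planting capacity "
            f"~{capacity} for this transcript budget"
        )

    tx_ids = sorted(seqs)
    positives: list[GenomicSite] = []
    truth_sites: list[dict] = []
    for name in LABEL_NAMES:
        n_sites = config.label_counts.get(name, 0)
        pwm = pwms[name]
        planted = 0
        attempts = 0
        while planted < n_sites:
            attempts += 1
            if attempts > 200 * n_sites + 1000:
                raise ValueError(
                    f"infeasible density: could not place {n_sites} sites for {name}"
                )
            tx = tx_ids[rng.integers(len(tx_ids))]
            pos = int(rng.integers(half, config.transcript_length - half))
            span = range(pos - half, pos + half + 1)
            if any(p in occupied[tx] for p in span):
                continue
            # rewrite the window from the PWM (center column is the base)
            for off, col in zip(range(-half, half + 1), pwm):
                seqs[tx][pos + off] = BASES[rng.choice(4, p=col / col.sum())]
            occupied[tx].update(span)
            positives.append(GenomicSite(tx, pos, "+", name))
            truth_sites.append({"sequence_id": tx, "position": pos, "label": name})
            planted += 1

    sequences = {tx: "".join(s) for tx, s in seqs.items()}
    all_planted = {(s.sequence_id, s.position) for s in positives}
    exclusion = [GenomicSite(tx, p, "+", NEGATIVE) for tx, p in sorted(all_planted)]
    negatives = sample_negatives(
        positives, sequences, ratio=config.negative_ratio,
        exclusion=exclusion, seed=int(rng.integers(2 ** 31)),
    )
    truth = {
        "seed": config.seed,
        "pwms": {name: pwms[name].tolist() for name in pwms},
        "motif_width": W,
        "sites": truth_sites,
        "label_counts": {n: config.label_counts.get(n, 0) for n in LABEL_NAMES},
    }
    return sequences, positives + negatives, truth


def write_corpus(
    sequences: dict[str, str], sites, truth: dict, outdir: str | Path
) -> None:
    """Emit FASTA + site-table TSV + JSON truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "transcripts.fasta", "w") as fh:
        for tx in sorted(sequences):
            fh.write(f">{tx}\n{sequences[tx]}\n")
    write_sites(sites, outdir / "sites.tsv")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")


# ----------------------------------------------------------------------
# recovery scoring
# ----------------------------------------------------------------------

def pwm_total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Largest per-column total-variation distance between two PWMs."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"PWM shapes differ: {p.shape} vs {q.shape}")
    return float((0.5 * np.abs(p - q).sum(axis=1)).max())


def best_pwm_distance(mined: np.ndarray, planted: np.ndarray) -> float:
    """Distance between PWMs of possibly different widths.

    Slides the shorter PWM over the longer one (and over its reverse
    complement is *not* considered — planted and mined motifs share the
    plus-strand reading) and returns the smallest per-column TV distance
    over fully overlapping alignments of the shorter width.
    """
    a, b = np.asarray(mined), np.asarray(planted)
    if a.shape[0] > b.shape[0]:
        a, b = b, a
    w = a.shape[0]
    return min(
        pwm_total_variation(a, b[off:off + w])
        for off in range(b.shape[0] - w + 1)
    )


def truth_eval(predictions: dict, truth: dict) -> dict:
    """Score sliding-window predictions against the planted truth.

    ``predictions`` maps transcript id to the DataFrame returned by
    :func:`rnamod.model.predict_sequence` for that transcript. Returns
    per-label AUC_b of planted sites versus unplanted same-base positions.
    """
    planted: dict[str, set[tuple[str, int]]] = {n: set() for n in LABEL_NAMES}
    any_planted: set[tuple[str, int]] = set()
    for s in truth["sites"]:
        planted[s["label"]].add((s["sequence_id"], s["position"]))
        any_planted.add((s["sequence_id"], s["position"]))

    report: dict[str, float] = {}
    for name in LABEL_NAMES:
        base = ORIGINAL_BASE[name]
        pos_scores, neg_scores = [], []
        for tx, df in predictions.items():
            scores = df[name].to_numpy()
            bases = df["base"].to_numpy()
            positions = df["position"].to_numpy()
            for p, b, s in zip(positions, bases, scores):
                if b != base or not np.isfinite(s):
                    continue
                if (tx, int(p)) in planted[name]:
                    pos_scores.append(s)
                elif (tx, int(p)) not in any_planted:
                    neg_scores.append(s)
        if pos_scores and neg_scores:
            report[name] = auc_b(pos_scores, neg_scores)
    return report
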