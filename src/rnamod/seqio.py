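"""Site tables, sequence windows, negative sampling and dataset splits.

This module turns base-resolution modification site tables (TSV) plus their
transcript sequences (FASTA) into fixed-length nucleotide windows centered on
the candidate site, ready for encoding. Conventions:

* internal coordinates are 0-based half-open; readers accept a declared
  0-based or 1-based convention and normalise on input,
* the internal alphabet is ``{A, C, G, U, N}``; T on input is read as U,
* windows whose flanks run past the end of the available sequence are
  N-filled rather than fetched from a genome,
* minus-strand sites are reverse-complemented before windowing so the center
  base is the modified base as read 5'->3'.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .labels import (
    LABELS,
    LABEL_NAMES,
    LABEL_INDEX,
    LABELS_FOR_BASE,
    NEGATIVE,
    label_for,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicSite",
    "SequenceWindow",
    "DatasetSplit",
    "read_fasta",
    "read_sites",
    "write_sites",
    "extract_window",
    "build_windows",
    "sample_negatives",
    "apply_motif_filter",
    "split_dataset",
    "write_split",
]

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

#: IUPAC nucleotide codes over the RNA alphabet (no T).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
}

#: Consensus restrictions around the methylated A: DRACH for m6A (center at
#: offset +2 of the 5-mer), BCA for m6Am (center at offset +2 of the 3-mer).
MOTIF_RESTRICTIONS = {
    "m6A": ("DRACH", 2),
    "m6Am": ("BCA", 2),
}


def _clean(seq: str) -> str:
    """Uppercase, T->U, and validate the alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGUN")
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into ``{id: RNA sequence}``.

    Case-insensitive; T is read as U; records must be non-empty.
    """
    store: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        store[rec.id] = _clean(str(rec.seq))
    if not store:
        raise ValueError(f"no FASTA records found in {path}")
    return store


@dataclass(frozen=True)
class GenomicSite:
    """A base-resolution site: 0-based position on a named sequence."""

    sequence_id: str
    position: int
    strand: str  # "+" or "-"
    label: str  # a modification name or NEGATIVE

    def key(self) -> tuple[str, int, str]:
        return (self.sequence_id, self.position, self.strand)


@dataclass(frozen=True)
class SequenceWindow:
    """A fixed odd-length window centered on a candidate site.

    ``labels`` is the 12-slot binary vector in canonical label order; only
    slots whose modification occurs on the center base may be set.
    """

    sequence: str
    labels: np.ndarray
    site: GenomicSite

    def __post_init__(self):
        if len(self.sequence) % 2 == 0:
            raise ValueError("window length must be odd")
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.int8))

    @property
    def center_index(self) -> int:
        return (len(self.sequence) - 1) // 2

    @property
    def center_base(self) -> str:
        return self.sequence[self.center_index]

    @property
    def is_positive(self) -> bool:
        return bool(self.labels.any())


def read_sites(path: str | Path, coords: str = "0based") -> list[GenomicSite]:
    """Read a site table (TSV: sequence_id, position, strand, label).

    ``coords`` declares the file's coordinate convention (``"0based"`` or
    ``"1based"``); positions are normalised to the internal 0-based form.
    A header line is recognised by its first field being ``sequence_id``.
    """
    if coords not in ("0based", "1based"):
        raise ValueError(f"coords must be '0based' or '1based', got {coords!r}")
    shift = 0 if coords == "0based" else 1
    sites: list[GenomicSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "sequence_id":
                continue
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            seq_id, pos_s, strand, label = fields[:4]
            try:
                pos = int(pos_s) - shift
            except ValueError:
                raise ValueError(f"{path}:{lineno}: position {pos_s!r} is not an integer")
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: strand must be + or -, got {strand!r}")
            if pos < 0:
                raise ValueError(f"{path}:{lineno}: negative position after normalisation")
            if label != NEGATIVE:
                label = label_for(label).name
            sites.append(GenomicSite(seq_id, pos, strand, label))
    return sites


def write_sites(sites, path: str | Path, coords: str = "0based") -> None:
    """Write a site table in the format :func:`read_sites` accepts."""
    shift = 0 if coords == "0based" else 1
    with open(path, "w") as fh:
        fh.write("sequence_id\tposition\tstrand\tlabel\n")
        for s in sites:
            fh.write(f"{s.sequence_id}\t{s.position + shift}\t{s.strand}\t{s.label}\n")


def _site_base(site: GenomicSite, sequences: dict[str, str]) -> str:
    """The base at the site as read 5'->3' on the site's strand."""
    seq = sequences[site.sequence_id]
    if not 0 <= site.position < len(seq):
        raise IndexError(
            f"site {site.sequence_id}:{site.position} outside sequence of length {len(seq)}"
        )
    base = seq[site.position]
    return base.translate(_COMPLEMENT) if site.strand == "-" else base


def extract_window(
    site: GenomicSite, sequences: dict[str, str], L: int
) -> SequenceWindow:
    """Extract the L-window centered on a site, N-filling missing flanks."""
    if L % 2 == 0:
        raise ValueError(f"window length must be odd, got {L}")
    if site.sequence_id not in sequences:
        raise KeyError(f"unknown sequence {site.sequence_id!r}")
    seq = sequences[site.sequence_id]
    if not 0 <= site.position < len(seq):
        raise IndexError(
            f"site {site.sequence_id}:{site.position} outside sequence of length {len(seq)}"
        )
    half = (L - 1) // 2
    lo, hi = site.position - half, site.position + half + 1
    window = "N" * max(0, -lo) + seq[max(0, lo):hi] + "N" * max(0, hi - len(seq))
    if site.strand == "-":
        window = reverse_complement(window)
    labels = np.zeros(len(LABELS), dtype=np.int8)
    if site.label != NEGATIVE:
        lab = label_for(site.label)
        center = window[half]
        if center != lab.original_base:
            raise ValueError(
                f"site {site.sequence_id}:{site.position} has center base {center} "
                f"but label {lab.name} occurs on {lab.original_base}"
            )
        labels[lab.index] = 1
    return SequenceWindow(window, labels, site)


def build_windows(
    sites, sequences: dict[str, str], L: int
) -> list[SequenceWindow]:
    """Extract windows for all sites, merging labels of co-located sites.

    Sites sharing ``(sequence_id, position, strand)`` become one window whose
    label vector is the union of their labels.
    """
    merged: dict[tuple, np.ndarray] = {}
    order: list[GenomicSite] = []
    for s in sites:
        k = s.key()
        if k not in merged:
            merged[k] = np.zeros(len(LABELS), dtype=np.int8)
            order.append(s)
        if s.label != NEGATIVE:
            merged[k][label_for(s.label).index] = 1
    windows = []
    for s in order:
        w = extract_window(replace(s, label=NEGATIVE), sequences, L)
        windows.append(SequenceWindow(w.sequence, merged[s.key()], s))
    # re-validate merged labels against the center base
    for w in windows:
        allowed = {LABEL_INDEX[n] for n in LABELS_FOR_BASE.get(w.center_base, ())}
        on = set(np.nonzero(w.labels)[0].tolist())
        if not on <= allowed:
            bad = [LABEL_NAMES[i] for i in sorted(on - allowed)]
            raise ValueError(
                f"window at {w.site.sequence_id}:{w.site.position} (center {w.center_base}) "
                f"carries incompatible labels {bad}"
            )
    return windows


def sample_negatives(
    positives,
    sequences: dict[str, str],
    ratio: float = 1.0,
    exclusion=(),
    seed: int = 0,
) -> list[GenomicSite]:
    """Draw unmodified same-base negatives from the transcripts of positives.

    For each positive label, negatives are sampled uniformly at random
    (seeded) from positions on the same parent sequence whose base equals the
    label's original base, excluding every positive position and every
    position in ``exclusion`` (e.g. a lower-confidence m6A exclusion list).
    Transcripts with no eligible position contribute none (with a warning).
    """
    rng = np.random.default_rng(seed)
    blocked: set[tuple[str, int]] = {(s.sequence_id, s.position) for s in positives}
    blocked |= {(s.sequence_id, s.position) for s in exclusion}

    # group positive counts per (sequence, strand, label)
    groups: dict[tuple[str, str, str], int] = {}
    for s in positives:
        if s.label == NEGATIVE:
            continue
        k = (s.sequence_id, s.strand, s.label)
        groups[k] = groups.get(k, 0) + 1

    negatives: list[GenomicSite] = []
    for (seq_id, strand, label), n_pos in sorted(groups.items()):
        base = label_for(label).original_base
        seq = sequences[seq_id]
        want = base.translate(_COMPLEMENT) if strand == "-" else base
        eligible = [
            i for i, b in enumerate(seq)
            if b == want and (seq_id, i) not in blocked
        ]
        n_want = int(round(ratio * n_pos))
        if not eligible:
            logger.warning(
                "no eligible negative positions on %s for %s; skipping", seq_id, label
            )
            continue
        take = min(n_want, len(eligible))
        if take < n_want:
            logger.warning(
                "only %d of %d requested negatives available on %s for %s",
                take, n_want, seq_id, label,
            )
        chosen = rng.choice(len(eligible), size=take, replace=False)
        for i in sorted(int(c) for c in chosen):
            pos = eligible[i]
            negatives.append(GenomicSite(seq_id, pos, strand, NEGATIVE))
            blocked.add((seq_id, pos))  # keep negatives disjoint across labels
    return negatives


def _matches_iupac(segment: str, pattern: str) -> bool:
    return len(segment) == len(pattern) and all(
        b in IUPAC[p] for b, p in zip(segment, pattern)
    )


def apply_motif_filter(windows, label: str) -> list[SequenceWindow]:
    """Restrict windows to those matching the label's consensus motif.

    m6A keeps windows whose center A sits in a DRACH context (offsets -2..+2);
    m6Am requires BCA (offsets -2..0). Any other label passes through
    unchanged. Windows too short to evaluate the motif are dropped with a
    warning; N in the motif context fails the match.
    """
    if label not in MOTIF_RESTRICTIONS:
        return list(windows)
    pattern, center_off = MOTIF_RESTRICTIONS[label]
    kept = []
    for w in windows:
        c = w.center_index
        lo = c - center_off
        hi = lo + len(pattern)
        if lo < 0 or hi > len(w.sequence):
            warnings.warn(
                f"window of length {len(w.sequence)} too short for {pattern}; dropped"
            )
            continue
        if _matches_iupac(w.sequence[lo:hi], pattern):
            kept.append(w)
    return kept


def _class_of(window: SequenceWindow) -> str:
    """Class key used for balanced splitting.

    Positives belong to their (lowest-slot) modification class; negatives
    form one pool per center base.
    """
    on = np.nonzero(window.labels)[0]
    if len(on):
        return LABEL_NAMES[int(on[0])]
    return f"{NEGATIVE}_{window.center_base}"


@dataclass
class DatasetSplit:
    """Train/validation/test window collections plus the seed that made them."""

    train: list[SequenceWindow]
    validation: list[SequenceWindow]
    test: list[SequenceWindow]
    seed: int
    class_counts: dict[str, dict[str, int]] = field(default_factory=dict)


def split_dataset(
    windows,
    val_per_class: int = 150,
    test_per_class: int = 50,
    seed: int = 0,
) -> DatasetSplit:
    """Split windows into an imbalanced train set and balanced val/test sets.

    Every class (each modification's positives and each per-base negative
    pool) contributes exactly ``val_per_class`` validation and
    ``test_per_class`` test windows, sampled without replacement; the
    remainder is the training set.
    """
    by_class: dict[str, list[SequenceWindow]] = {}
    for w in windows:
        by_class.setdefault(_class_of(w), []).append(w)

    need = val_per_class + test_per_class
    for cls, ws in sorted(by_class.items()):
        if len(ws) <= need:
            raise ValueError(
                f"class {cls} has {len(ws)} windows; needs more than "
                f"{need} (= {val_per_class} validation + {test_per_class} test)"
            )

    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    counts: dict[str, dict[str, int]] = {}
    for cls in sorted(by_class):
        ws = by_class[cls]
        perm = rng.permutation(len(ws))
        val += [ws[i] for i in perm[:val_per_class]]
        test += [ws[i] for i in perm[val_per_class:need]]
        train += [ws[i] for i in perm[need:]]
        counts[cls] = {
            "train": len(ws) - need,
            "validation": val_per_class,
            "test": test_per_class,
        }
    return DatasetSplit(train, val, test, seed, counts)


def _write_window_tsv(windows, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tposition\tstrand\tsequence\tlabels\n")
        for w in windows:
            on = ",".join(LABEL_NAMES[i] for i in np.nonzero(w.labels)[0]) or NEGATIVE
            fh.write(
                f"{w.site.sequence_id}\t{w.site.position}\t{w.site.strand}\t"
                f"{w.sequence}\t{on}\n"
            )


def write_split(split: DatasetSplit, outdir: str | Path) -> None:
    """Write train/validation/test TSVs plus a JSON provenance record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_window_tsv(split.train, outdir / "train.tsv")
    _write_window_tsv(split.validation, outdir / "validation.tsv")
    _write_window_tsv(split.test, outdir / "test.tsv")
    prov = {"seed": split.seed, "class_counts": split.class_counts}
    (outdir / "split.json").write_text(json.dumps(prov, indent=2) + "\n")
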