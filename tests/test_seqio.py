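"""Site tables, window extraction, negative sampling, motif filter, splits."""

import numpy as np
import pytest

from rnamod import seqio
from rnamod.labels import LABEL_INDEX, NEGATIVE
from rnamod.seqio import (
    GenomicSite,
    SequenceWindow,
    apply_motif_filter,
    build_windows,
    extract_window,
    read_sites,
    sample_negatives,
    split_dataset,
    write_sites,
)


@pytest.fixture
def store():
    return {"tx1": "ACGUA" * 11, "tx2": "GGACU" * 10}  # tx1: 55 nt, tx2: 50 nt


class TestReadSites:
    def test_coordinate_conventions(self, tmp_path):
        p = tmp_path / "sites.tsv"
        p.write_text("sequence_id\tposition\tstrand\tlabel\ntx1\t10\t+\tm6A\n")
        assert read_sites(p, coords="0based")[0].position == 10
        p.write_text("sequence_id\tposition\tstrand\tlabel\ntx1\t11\t+\tm6A\n")
        assert read_sites(p, coords="1based")[0].position == 10

    def test_unknown_label_rejected(self, tmp_path):
        p = tmp_path / "sites.tsv"
        p.write_text("tx1\t10\t+\tm9X\n")
        with pytest.raises(KeyError, match="m9X"):
            read_sites(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "sites.tsv"
        p.write_text("sequence_id\tposition\tstrand\tlabel\ntx1\t10\t+\n")
        with pytest.raises(ValueError, match=":2"):
            read_sites(p)

    def test_round_trip(self, tmp_path):
        sites = [
            GenomicSite("tx1", 4, "+", "m6A"),
            GenomicSite("tx2", 7, "-", NEGATIVE),
        ]
        p = tmp_path / "out.tsv"
        write_sites(sites, p)
        assert read_sites(p) == sites
        # and through the 1-based convention
        write_sites(sites, p, coords="1based")
        assert read_sites(p, coords="1based") == sites


class TestExtractWindow:
    def test_exact_fit(self):
        seq = "AC" * 25 + "A"  # 51 nt, center (pos 25) is 'C'... build explicit
        seq = "G" * 25 + "A" + "G" * 25
        win = extract_window(GenomicSite("t", 25, "+", "m6A"), {"t": seq}, 51)
        assert win.sequence == seq
        assert win.center_base == "A"

    def test_boundary_n_fill(self, store):
        win = extract_window(GenomicSite("tx1", 0, "+", "m6A"), store, 21)
        assert win.sequence[:10] == "N" * 10
        assert win.sequence[10] == "A"
        assert "N" not in win.sequence[10:]

    def test_minus_strand_reverse_complement(self):
        # on the minus strand a plus-strand U reads as A
        seq = "GGGUGGG"
        win = extract_window(GenomicSite("t", 3, "-", "m6A"), {"t": seq}, 7)
        assert win.center_base == "A"
        assert win.sequence == "CCCACCC"

    def test_base_label_mismatch(self, store):
        with pytest.raises(ValueError, match="m6A"):
            extract_window(GenomicSite("tx1", 1, "+", "m6A"), store, 21)  # base C

    def test_even_length_rejected(self, store):
        with pytest.raises(ValueError, match="odd"):
            extract_window(GenomicSite("tx1", 10, "+", "m6A"), store, 20)

    def test_t_read_as_u(self):
        win = extract_window(
            GenomicSite("t", 2, "+", "m5U"), {"t": seqio._clean("ggTgg")}, 5
        )
        assert win.center_base == "U"


class TestSampleNegatives:
    def test_count_base_and_disjointness(self, store):
        positives = [GenomicSite("tx1", p, "+", "m6A") for p in (0, 4, 5)]
        negs = sample_negatives(positives, store, ratio=1.0, seed=1)
        assert len(negs) == 3
        pos_keys = {(s.sequence_id, s.position) for s in positives}
        for n in negs:
            assert store[n.sequence_id][n.position] == "A"
            assert (n.sequence_id, n.position) not in pos_keys

    def test_exhausted_transcript_contributes_none(self):
        seqs = {"t": "AUAU"}
        positives = [GenomicSite("t", 0, "+", "m6A"), GenomicSite("t", 2, "+", "m6A")]
        assert sample_negatives(positives, seqs, seed=0) == []

    def test_exclusion_list_respected(self, store):
        positives = [GenomicSite("tx1", 0, "+", "m6A")]
        a_positions = [i for i, b in enumerate(store["tx1"]) if b == "A"]
        exclusion = [GenomicSite("tx1", p, "+", NEGATIVE) for p in a_positions[1:-1]]
        negs = sample_negatives(positives, store, exclusion=exclusion, seed=0)
        assert all(n.position == a_positions[-1] for n in negs)

    def test_deterministic_under_seed(self, store):
        positives = [GenomicSite("tx1", p, "+", "m6A") for p in (0, 4, 5)]
        a = sample_negatives(positives, store, seed=7)
        b = sample_negatives(positives, store, seed=7)
        assert a == b


class TestMotifFilter:
    def _win(self, context5):
        # center base is context5[2]; pad to length 21
        seq = "G" * 8 + context5 + "G" * 8
        labels = np.zeros(12, dtype=np.int8)
        if context5[2] == "A":
            labels[LABEL_INDEX["m6A"]] = 1
        return SequenceWindow(seq, labels, GenomicSite("t", 10, "+", "m6A"))

    def test_drach_kept(self):
        assert len(apply_motif_filter([self._win("GGACU")], "m6A")) == 1

    def test_drach_dropped_on_fourth_base(self):
        assert apply_motif_filter([self._win("GGAAU")], "m6A") == []

    def test_other_labels_pass_through(self):
        wins = [self._win("GGAAU")]
        assert apply_motif_filter(wins, "m5C") == wins

    def test_bca_restriction(self):
        # BCA at offsets -2..0: B={C,G,U}
        keep = SequenceWindow("G" * 8 + "UCA" + "G" * 10, np.zeros(12),
                              GenomicSite("t", 10, "+", NEGATIVE))
        drop = SequenceWindow("G" * 8 + "ACA" + "G" * 10, np.zeros(12),
                              GenomicSite("t", 10, "+", NEGATIVE))
        assert apply_motif_filter([keep, drop], "m6Am") == [keep]

    def test_n_in_context_fails(self):
        w = SequenceWindow("G" * 8 + "GNACU" + "G" * 8, np.zeros(12),
                           GenomicSite("t", 10, "+", NEGATIVE))
        assert apply_motif_filter([w], "m6A") == []


class TestSplitDataset:
    def _windows(self, n, base="A", label="m6A", offset=0):
        out = []
        for i in range(n):
            labels = np.zeros(12, dtype=np.int8)
            if label is not None:
                labels[LABEL_INDEX[label]] = 1
            seq = "G" * 10 + base + "G" * 10
            out.append(SequenceWindow(
                seq, labels, GenomicSite("t", offset + i, "+", label or NEGATIVE)
            ))
        return out

    def test_sizes_1000(self):
        split = split_dataset(self._windows(1000), 150, 50, seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == (800, 150, 50)

    def test_too_small_class_errors(self):
        with pytest.raises(ValueError, match="m6A"):
            split_dataset(self._windows(200), 150, 50, seed=0)

    def test_deterministic(self):
        wins = self._windows(300) + self._windows(
            300, base="C", label="m5C", offset=1000
        )
        a = split_dataset(wins, 100, 30, seed=5)
        b = split_dataset(wins, 100, 30, seed=5)
        assert [w.site for w in a.train] == [w.site for w in b.train]
        assert [w.site for w in a.test] == [w.site for w in b.test]

    @pytest.mark.parametrize("seed", range(20))
    def test_disjoint_and_balanced_over_seeds(self, seed):
        wins = (self._windows(260) +
                self._windows(300, base="C", label="m5C", offset=1000) +
                self._windows(270, base="A", label=None, offset=2000))
        split = split_dataset(wins, 150, 50, seed=seed)
        keys = lambda ws: {(w.site.sequence_id, w.site.position) for w in ws}
        tr, va, te = keys(split.train), keys(split.validation), keys(split.test)
        assert not (tr & va or tr & te or va & te)
        assert len(va) == 3 * 150 and len(te) == 3 * 50


def test_build_windows_merges_colocated_labels(store):
    sites = [GenomicSite("tx1", 4, "+", "m6A"), GenomicSite("tx1", 4, "+", "m1A")]
    wins = build_windows(sites, store, 9)
    assert len(wins) == 1
    assert wins[0].labels[LABEL_INDEX["m6A"]] == 1
    assert wins[0].labels[LABEL_INDEX["m1A"]] == 1
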