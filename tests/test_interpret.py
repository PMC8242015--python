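"""Attribution axioms, motif mining/clustering, association, site distances."""

import numpy as np
import pytest

from rnamod.autograd import Tensor
from rnamod.interpret import (
    MotifCandidate,
    _top_windows,
    _tokens_to_nucleotides,
    association_matrix,
    attention_profile,
    cluster_motifs,
    integrated_gradients,
    integrated_gradients_fn,
    mine_motifs,
    site_distance_enrichment,
    write_meme,
)
from rnamod.labels import LABEL_INDEX
from rnamod.seqio import GenomicSite, SequenceWindow, NEGATIVE


def _window(seq, label=None, pos=0):
    labels = np.zeros(12, dtype=np.int8)
    if label:
        labels[LABEL_INDEX[label]] = 1
    return SequenceWindow(seq, labels, GenomicSite("t", pos, "+", label or NEGATIVE))


class TestIntegratedGradientsCore:
    def test_linear_field_recovered_exactly(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal((7, 3))
        x = rng.standard_normal((7, 3))
        f = lambda xt: (xt * Tensor(w)).sum(axis=2).sum(axis=1)
        attr, residual = integrated_gradients_fn(f, x, np.zeros_like(x), steps=1)
        np.testing.assert_allclose(attr, w * x, atol=1e-12)
        assert residual < 1e-12

    def test_input_equal_to_baseline_gives_zero(self):
        f = lambda xt: (xt ** 2.0).sum(axis=1)
        x = np.ones(4)
        attr, _ = integrated_gradients_fn(f, x, x.copy(), steps=10)
        np.testing.assert_allclose(attr, 0.0)

    def test_invalid_steps(self):
        f = lambda xt: xt.sum(axis=1)
        with pytest.raises(ValueError):
            integrated_gradients_fn(f, np.ones(3), np.zeros(3), steps=0)


class TestIntegratedGradientsModel:
    def test_completeness_and_step_refinement(self, tiny_trained, tiny_split):
        model, _ = tiny_trained
        win = next(w for w in tiny_split.test if w.labels[LABEL_INDEX["m6A"]] == 1)
        residuals = []
        for steps in (10, 20, 40):
            amap = integrated_gradients(model, win, "m6A", steps=steps)
            residuals.append(amap.residual)
            # token scores and nucleotide scores conserve total attribution
            assert amap.nucleotide_scores.sum() == pytest.approx(
                amap.token_scores.sum()
            )
        assert residuals[-1] <= residuals[0] + 1e-9
        assert residuals[-1] < 1e-2

    def test_incompatible_label_rejected(self, tiny_trained, tiny_split):
        model, _ = tiny_trained
        win = next(w for w in tiny_split.test if w.center_base == "C")
        with pytest.raises(ValueError):
            integrated_gradients(model, win, "m6A")

    def test_token_projection_mass_preserving(self):
        token = np.array([3.0, -1.0, 2.0])
        nuc = _tokens_to_nucleotides(token, L=5, k=3)
        assert nuc.sum() == pytest.approx(token.sum())
        assert len(nuc) == 5


class TestAttentionProfile:
    def test_each_label_sums_to_one(self, tiny_trained, tiny_split):
        model, _ = tiny_trained
        prof = attention_profile(model, tiny_split.test[0])
        assert prof.shape == (12, 21)
        np.testing.assert_allclose(prof.sum(axis=1), np.ones(12), atol=1e-9)
        assert np.all(prof >= 0)

    def test_trained_attention_respects_motif_causality(
        self, tiny_trained, tiny_split
    ):
        # the planted 5-mer straddles the center; with a causal LSTM the
        # motif evidence is available at and after the motif, never before
        # it, so the attention argmax must not fall upstream of the motif
        # start for held-out positives
        model, _ = tiny_trained
        for label in ("m6A", "m5C"):
            j = LABEL_INDEX[label]
            wins = [w for w in tiny_split.test if w.labels[j] == 1]
            hits = sum(
                int(np.argmax(attention_profile(model, w)[j]))
                >= w.center_index - 2  # planted motif start
                for w in wins
            )
            assert hits / len(wins) >= 0.8, label

    def test_trained_attention_localizes_for_centered_head(
        self, tiny_trained, tiny_split
    ):
        # at least one head resolves the motif position itself: the m5C
        # head's argmax stays within a few nucleotides of the planted span
        model, _ = tiny_trained
        j = LABEL_INDEX["m5C"]
        wins = [w for w in tiny_split.test if w.labels[j] == 1]
        hits = sum(
            abs(int(np.argmax(attention_profile(model, w)[j])) - w.center_index) <= 4
            for w in wins
        )
        assert hits / len(wins) >= 0.8


class TestTopWindows:
    def test_toy_example_brute_force(self):
        scores = np.array([0, 0, 5, 5, 5, 0, 0, 0, 9, 9], dtype=float)
        cands = _top_windows(scores, "ACGUACGUAC", w=2, k_per_sample=2,
                             sample_id="s")
        assert cands[0].start == 8  # the 9,9 pair
        assert cands[1].start in (2, 3)  # the best 5,5 pair
        assert cands[1].score == pytest.approx(5.0)

    def test_single_spike(self):
        scores = np.zeros(12)
        scores[5] = 10.0
        c = _top_windows(scores, "A" * 12, w=3, k_per_sample=1, sample_id="s")[0]
        assert c.start <= 5 < c.start + 3

    def test_no_overlap_between_candidates(self):
        rng = np.random.default_rng(1)
        scores = rng.random(50)
        cands = _top_windows(scores, "A" * 50, w=6, k_per_sample=3, sample_id="s")
        spans = [set(range(c.start, c.start + 6)) for c in cands]
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                assert not spans[i] & spans[j]


class TestClusterMotifs:
    def test_two_disjoint_identical_sets(self):
        cands = (
            [MotifCandidate("GGACUU", f"a{i}", 1.0, 0) for i in range(20)]
            + [MotifCandidate("UUCCGA", f"b{i}", 1.0, 0) for i in range(20)]
        )
        clusters = cluster_motifs(cands, seed=0)
        assert len(clusters) == 2
        consensi = {
            "".join("ACGU"[i] for i in cl.pwm.argmax(axis=1)) for cl in clusters
        }
        assert consensi == {"GGACUU", "UUCCGA"}
        for cl in clusters:
            np.testing.assert_allclose(cl.pwm.sum(axis=1), np.ones(6))

    def test_single_repeated_sequence_near_degenerate(self):
        cands = [MotifCandidate("GGACUU", f"a{i}", 1.0, 0) for i in range(15)]
        clusters = cluster_motifs(cands, seed=0)
        assert len(clusters) == 1
        assert clusters[0].pwm.max(axis=1).min() > 0.99

    def test_too_few_candidates(self):
        with pytest.raises(ValueError):
            cluster_motifs([MotifCandidate("GGACUU", "a", 1.0, 0)] * 5)


class TestMineMotifs:
    def test_no_positives_warns_empty(self, tiny_trained, tiny_split):
        model, _ = tiny_trained
        with pytest.warns(UserWarning):
            out = mine_motifs(model, [w for w in tiny_split.test
                                      if not w.is_positive], "m6A")
        assert out == []

    def test_candidates_have_requested_width(self, tiny_trained, tiny_split):
        model, _ = tiny_trained
        wins = [w for w in tiny_split.test if w.labels[LABEL_INDEX["m5C"]] == 1]
        cands = mine_motifs(model, wins, "m5C", w=5, steps=10, threshold=0.0)
        assert cands and all(len(c.sequence) == 5 for c in cands)


class TestAssociationMatrix:
    def test_symmetry_diag_and_range(self, tiny_trained):
        model, _ = tiny_trained
        assoc = association_matrix(model)
        np.testing.assert_allclose(assoc.rho, assoc.rho.T)
        np.testing.assert_allclose(np.diag(assoc.rho), np.ones(12))
        finite = assoc.rho[np.isfinite(assoc.rho)]
        assert np.all((finite >= -1) & (finite <= 1))
        # exact-distribution p-values present off-diagonal
        off = assoc.pvalues[~np.eye(12, dtype=bool)]
        assert np.isfinite(off).all()

    def test_anticorrelated_vectors(self, tiny_trained):
        import copy

        model, _ = tiny_trained
        m = copy.deepcopy(model)
        m.att_v.data[1] = -m.att_v.data[0]
        assoc = association_matrix(m)
        assert assoc.rho[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_vector_gives_nan(self, tiny_trained):
        import copy

        model, _ = tiny_trained
        m = copy.deepcopy(model)
        m.att_v.data[3] = 0.7
        assoc = association_matrix(m)
        assert np.isnan(assoc.rho[3, 0]) and np.isnan(assoc.rho[0, 3])
        assert assoc.rho[3, 3] == 1.0


class TestSiteDistanceEnrichment:
    def test_adjacent_sites_extreme_p(self):
        seqs = {"s": "A" * 1000}
        a = [GenomicSite("s", p, "+", "m6A") for p in range(100, 900, 100)]
        b = [GenomicSite("s", p + 1, "+", "Psi") for p in range(100, 900, 100)]
        res = site_distance_enrichment(a, b, seqs, n_shuffles=99, seed=0)
        assert np.median(res.observed) == 1
        assert res.pvalue <= 1 / 100

    def test_identical_sets_all_zero(self):
        seqs = {"s": "A" * 500}
        a = [GenomicSite("s", p, "+", "m6A") for p in (10, 60, 200)]
        res = site_distance_enrichment(a, a, seqs, n_shuffles=19, seed=0)
        assert np.all(res.observed == 0)

    def test_disjoint_sequences_error(self):
        seqs = {"s1": "A" * 100, "s2": "A" * 100}
        a = [GenomicSite("s1", 5, "+", "m6A")]
        b = [GenomicSite("s2", 5, "+", "Psi")]
        with pytest.raises(ValueError):
            site_distance_enrichment(a, b, seqs)


class TestExports:
    def test_meme_minimal_format(self, tmp_path):
        from rnamod.interpret import MotifCluster

        pwm = np.full((6, 4), 0.25)
        cl = MotifCluster(0, [MotifCandidate("GGACUU", "a", 1.0, 0)] * 4, pwm)
        path = tmp_path / "m.meme"
        write_meme([cl], path)
        text = path.read_text()
        assert text.startswith("MEME version 4")
        assert "ALPHABET= ACGU" in text
        assert "letter-probability matrix: alength= 4 w= 6 nsites= 4" in text

    def test_logo_rendering(self, tmp_path):
        from rnamod.interpret import plot_logo

        pwm = np.array([[0.85, 0.05, 0.05, 0.05]] * 5)
        out = tmp_path / "logo.png"
        plot_logo(pwm, out)
        assert out.stat().st_size > 0
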