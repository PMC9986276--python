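"""Seqlet extraction against the permutation null, sign partitioning,
greedy clustering and PWM construction."""

import numpy as np
import pytest

from emotifre.attribution import AttributionTrack
from emotifre.discovery import (
    Seqlet,
    build_motif,
    cluster_seqlets,
    extract_seqlets,
    partition_by_sign,
    reverse_complement_matrix,
)
from emotifre.model import one_hot_encode
from emotifre.simulate import random_background


def make_track(seq, position_importance):
    """Build an attribution track with prescribed per-position importance on
    the observed base."""
    x = one_hot_encode(seq)
    imp = x * np.asarray(position_importance, dtype=np.float32)[:, None]
    return AttributionTrack(sequence=seq, importance=imp, hypothetical=imp.copy(),
                            raw=imp.copy(), prediction=0.5, completeness_gap=0.0)


class TestExtractSeqlets:
    def test_zero_attribution_yields_no_seqlets(self):
        seq = random_background(1, 100, 0.5, seed=0)[0]
        tracks = [make_track(seq, np.zeros(100))]
        assert extract_seqlets(tracks, window=15, seed=0) == []

    def test_single_spike_yields_one_covering_seqlet(self):
        seq = random_background(1, 100, 0.5, seed=1)[0]
        imp = np.zeros(100)
        imp[50:57] = 1.0
        (s,) = extract_seqlets([make_track(seq, imp)], window=15, seed=0)
        assert s.start <= 50 and s.end >= 57
        assert s.score == pytest.approx(7.0)

    def test_window_wider_than_sequence_rejected(self):
        seq = random_background(1, 30, 0.5, seed=2)[0]
        with pytest.raises(ValueError):
            extract_seqlets([make_track(seq, np.zeros(30))], window=40)

    def test_seqlets_never_overlap_within_a_sequence(self):
        rng = np.random.default_rng(3)
        tracks = []
        for seq in random_background(20, 120, 0.5, seed=3):
            tracks.append(make_track(seq, rng.standard_normal(120)))
        seqlets = extract_seqlets(tracks, window=10, percentile=90, seed=0)
        by_example = {}
        for s in seqlets:
            by_example.setdefault(s.example_index, []).append(s)
        for group in by_example.values():
            group.sort(key=lambda s: s.start)
            for a, b in zip(group, group[1:]):
                assert a.end <= b.start

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        tracks = [make_track(seq, rng.standard_normal(80))
                  for seq in random_background(5, 80, 0.5, seed=5)]
        a = extract_seqlets(tracks, window=12, percentile=95, seed=9)
        b = extract_seqlets(tracks, window=12, percentile=95, seed=9)
        assert [(s.example_index, s.start, s.score) for s in a] == \
               [(s.example_index, s.start, s.score) for s in b]


class TestPartition:
    def _seqlet(self, score):
        w = 5
        return Seqlet(0, 0, w, score, np.eye(4)[[0, 1, 2, 3, 0]].astype(float),
                      np.ones((w, 4)) * score)

    def test_sizes(self):
        pos, neg = partition_by_sign([self._seqlet(3), self._seqlet(-2),
                                      self._seqlet(1)])
        assert (len(pos), len(neg)) == (2, 1)

    def test_zeros_discarded_and_partition_complete(self):
        seqlets = [self._seqlet(s) for s in (2.0, 0.0, -1.0, 5.0)]
        pos, neg = partition_by_sign(seqlets)
        assert len(pos) + len(neg) == 3

    def test_all_positive(self):
        pos, neg = partition_by_sign([self._seqlet(1), self._seqlet(2)])
        assert neg == []


def _pattern_seqlet(consensus, score=2.0, rng=None, noise=0.05):
    onehot = one_hot_encode(consensus).astype(float)
    hyp = onehot * score / len(consensus)
    if rng is not None:
        hyp = hyp + rng.normal(0, noise, hyp.shape)
    return Seqlet(0, 0, len(consensus), score, onehot, hyp)


class TestClustering:
    def test_identical_seqlets_form_one_cluster(self):
        s1 = _pattern_seqlet("CAGCTGCAGCTGCAG")
        s2 = _pattern_seqlet("CAGCTGCAGCTGCAG")
        clusters = cluster_seqlets([s1, s2])
        assert len(clusters) == 1 and len(clusters[0].members) == 2

    def test_disjoint_motifs_separate(self):
        rng = np.random.default_rng(0)
        group_a = [_pattern_seqlet("CAGCTGCCAGCTGCC", rng=rng) for _ in range(5)]
        group_b = [_pattern_seqlet("GAGGTCAAGAGGTCA", rng=rng) for _ in range(5)]
        clusters = cluster_seqlets(group_a + group_b)
        assert len(clusters) >= 2
        # no cluster mixes members of the two pattern families
        ids = {id(s): "a" for s in group_a}
        ids.update({id(s): "b" for s in group_b})
        for c in clusters:
            families = {ids[id(s)] for s, _, _ in c.members}
            assert len(families) == 1

    def test_singleton(self):
        (c,) = cluster_seqlets([_pattern_seqlet("ACGTACGTACGTACG")])
        assert len(c.members) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_seqlets([])

    def test_reverse_complement_joins(self):
        s1 = _pattern_seqlet("CCAGGTGCCAGGTGC")
        rc = "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[b]
                     for b in reversed("CCAGGTGCCAGGTGC"))
        s2 = Seqlet(1, 0, 15, 2.0, one_hot_encode(rc).astype(float),
                    reverse_complement_matrix(s1.hypothetical))
        clusters = cluster_seqlets([s1, s2])
        assert len(clusters) == 1
        assert clusters[0].members[1][2] is True  # joined reverse-complemented


class TestBuildMotif:
    def test_frequency_formula_with_pseudocount(self):
        seqlets = [_pattern_seqlet("CAGCT") for _ in range(4)]
        (cluster,) = cluster_seqlets(seqlets)
        motif = build_motif(cluster, pseudocount=0.5)
        # max column probability: (n + pc/4) / (n + pc)
        expected = (4 + 0.125) / (4 + 0.5)
        assert motif.pwm.max() == pytest.approx(expected)
        assert motif.consensus == "CAGCT"
        assert motif.n_seqlets == 4

    def test_zero_pseudocount_singleton_is_onehot(self):
        (cluster,) = cluster_seqlets([_pattern_seqlet("GATTA")])
        motif = build_motif(cluster, pseudocount=0.0)
        assert np.array_equal(motif.pwm, one_hot_encode("GATTA").astype(float))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        seqs = random_background(10, 15, 0.5, seed=7)
        seqlets = [_pattern_seqlet(s, rng=rng, noise=0.2) for s in seqs]
        for cluster in cluster_seqlets(seqlets, similarity_threshold=0.3):
            motif = build_motif(cluster)
            assert np.allclose(motif.pwm.sum(axis=1), 1.0, atol=1e-9)

    def test_sign_of_importance_score(self):
        neg = [_pattern_seqlet("CCAGG", score=-3.0) for _ in range(3)]
        (cluster,) = cluster_seqlets(neg)
        motif = build_motif(cluster)
        assert motif.importance_score < 0
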