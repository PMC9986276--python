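"""Aggregation of attribution tracks into signed candidate motifs.

A deliberately simple, fully deterministic aggregator: high-|importance|
windows (seqlets) are extracted against a per-sequence permutation null,
partitioned by attribution sign (positive = pushes the active-enhancer
probability up), greedily clustered by best-offset Pearson correlation of
their hypothetical-importance slices (both orientations), and each cluster is
summarized as a position weight matrix from the aligned one-hot slices.

The sign convention follows the attribution: a motif whose mean member
importance is positive is enriched in the active set, a negative one in the
non-active set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .attribution import AttributionTrack
from .model import one_hot_decode, one_hot_encode


@dataclass
class Seqlet:
    """A high-attribution window from one sequence."""

    example_index: int
    start: int
    end: int
    score: float  # summed observed-base importance over the window (signed)
    onehot: np.ndarray  # W x 4
    hypothetical: np.ndarray  # W x 4


@dataclass
class MotifModel:
    """A discovered motif: PWM plus sign and provenance."""

    pwm: np.ndarray  # width x 4, rows sum to 1
    importance_score: float
    n_seqlets: int
    name: str = "motif"
    ledger: dict = field(default_factory=dict)

    @property
    def consensus(self) -> str:
        return one_hot_decode(self.pwm)

    @property
    def width(self) -> int:
        return self.pwm.shape[0]


def reverse_complement_matrix(mat: np.ndarray) -> np.ndarray:
    """Reverse-complement an L x 4 matrix over alphabet order A,C,G,T."""
    return mat[::-1, ::-1].copy()


def _window_sums(values: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(values)])
    return c[w:] - c[:-w]


def extract_seqlets(
    tracks: Sequence[AttributionTrack],
    window: int = 15,
    percentile: float = 99.0,
    n_permutations: int = 5,
    seed: int = 0,
) -> list[Seqlet]:
    """Extract non-overlapping high-|importance| windows per sequence.

    Per sequence, every width-``window`` sliding sum of the observed-base
    importance is scored; the keep threshold is the given percentile of
    |window sums| under ``n_permutations`` random permutations of that
    sequence's position-importance values.  Surviving windows are resolved
    greedily by descending |score| so that kept seqlets never share a base.
    """
    if not tracks:
        raise ValueError("no attribution tracks given")
    length = tracks[0].importance.shape[0]
    if window > length:
        raise ValueError(f"window {window} exceeds sequence length {length}")
    rng = np.random.default_rng(seed)
    seqlets: list[Seqlet] = []
    for idx, track in enumerate(tracks):
        if track.sequence:
            onehot_full = one_hot_encode(track.sequence)
        else:  # fall back to the nonzero pattern of the projected importance
            onehot_full = (track.importance != 0).astype(np.float32)
        imp = track.position_importance.astype(np.float64)
        scores = _window_sums(imp, window)
        if not np.any(scores):
            continue
        null = np.concatenate([
            _window_sums(rng.permutation(imp), window)
            for _ in range(n_permutations)
        ])
        threshold = np.percentile(np.abs(null), percentile)
        order = np.argsort(-np.abs(scores), kind="stable")
        taken = np.zeros(length, dtype=bool)
        for pos in order:
            if abs(scores[pos]) <= threshold:
                break
            if taken[pos : pos + window].any():
                continue
            taken[pos : pos + window] = True
            seqlets.append(
                Seqlet(
                    example_index=idx,
                    start=int(pos),
                    end=int(pos + window),
                    score=float(scores[pos]),
                    onehot=onehot_full[pos : pos + window].copy(),
                    hypothetical=track.hypothetical[pos : pos + window].copy(),
                )
            )
    return seqlets


def partition_by_sign(seqlets: Sequence[Seqlet]) -> tuple[list[Seqlet], list[Seqlet]]:
    """Split seqlets into positive-attribution and negative-attribution sets;
    exact zeros are discarded."""
    pos = [s for s in seqlets if s.score > 0]
    neg = [s for s in seqlets if s.score < 0]
    return pos, neg


@dataclass
class SeqletCluster:
    """A greedy centroid cluster of same-sign seqlets."""

    width: int
    hyp_sum: np.ndarray  # width x 4 accumulated aligned hypotheticals
    count_per_col: np.ndarray  # width, members covering each column
    members: list = field(default_factory=list)  # (seqlet, offset, rc)

    @property
    def centroid(self) -> np.ndarray:
        denom = np.maximum(self.count_per_col, 1)[:, None]
        return self.hyp_sum / denom


def _best_alignment(candidate: np.ndarray, centroid: np.ndarray,
                    min_overlap_frac: float) -> tuple[float, int, bool]:
    """Best (pearson, offset, rc) of candidate vs centroid over ungapped
    offsets with sufficient column overlap; offset is the shift of the
    candidate relative to the centroid frame."""
    w = centroid.shape[0]
    wc = candidate.shape[0]
    min_cols = max(2, int(np.ceil(min_overlap_frac * min(w, wc))))
    best = (-np.inf, 0, False)
    for rc in (False, True):
        cand = reverse_complement_matrix(candidate) if rc else candidate
        for offset in range(-(wc - min_cols), w - min_cols + 1):
            lo_c = max(0, offset)
            hi_c = min(w, offset + wc)
            if hi_c - lo_c < min_cols:
                continue
            a = centroid[lo_c:hi_c].ravel()
            b = cand[lo_c - offset : hi_c - offset].ravel()
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
            if r > best[0]:
                best = (r, offset, rc)
    return best


def cluster_seqlets(
    seqlets: Sequence[Seqlet],
    similarity_threshold: float = 0.7,
    min_overlap_frac: float = 0.7,
) -> list[SeqletCluster]:
    """Greedy centroid clustering of same-sign seqlets.

    Seqlets are processed by descending |score|; each is compared to every
    existing centroid by best-offset Pearson correlation of hypothetical
    slices (both orientations, overlap >= ``min_overlap_frac`` of the
    window); it joins the best centroid when the correlation reaches
    ``similarity_threshold``, otherwise founds a new cluster.
    """
    if not seqlets:
        raise ValueError("no seqlets to cluster")
    clusters: list[SeqletCluster] = []
    for seqlet in sorted(seqlets, key=lambda s: -abs(s.score)):
        best_r, best_c, best_off, best_rc = -np.inf, None, 0, False
        for ci, cluster in enumerate(clusters):
            r, off, rc = _best_alignment(
                seqlet.hypothetical, cluster.centroid, min_overlap_frac
            )
            if r > best_r:
                best_r, best_c, best_off, best_rc = r, ci, off, rc
        if best_c is not None and best_r >= similarity_threshold:
            cluster = clusters[best_c]
            hyp = seqlet.hypothetical
            if best_rc:
                hyp = reverse_complement_matrix(hyp)
            w = cluster.width
            lo = max(0, best_off)
            hi = min(w, best_off + hyp.shape[0])
            cluster.hyp_sum[lo:hi] += hyp[lo - best_off : hi - best_off]
            cluster.count_per_col[lo:hi] += 1
            cluster.members.append((seqlet, best_off, best_rc))
        else:
            w = seqlet.hypothetical.shape[0]
            clusters.append(
                SeqletCluster(
                    width=w,
                    hyp_sum=seqlet.hypothetical.astype(np.float64).copy(),
                    count_per_col=np.ones(w, dtype=np.int64),
                    members=[(seqlet, 0, False)],
                )
            )
    return clusters


def build_motif(
    cluster: SeqletCluster, pseudocount: float = 0.5, name: str = "motif"
) -> MotifModel:
    """Summarize a cluster as a PWM of aligned one-hot base counts.

    Member one-hot slices are placed at their joining offsets (reverse
    complemented when they joined in that orientation); per-column base
    counts get ``pseudocount`` split evenly over the four bases and are
    renormalized.  Columns covered by no member (possible at frame edges
    after shifts) are dropped.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    w = cluster.width
    counts = np.zeros((w, 4), dtype=np.float64)
    coverage = np.zeros(w, dtype=np.int64)
    for seqlet, offset, rc in cluster.members:
        onehot = seqlet.onehot.astype(np.float64)
        if rc:
            onehot = reverse_complement_matrix(onehot)
        lo = max(0, offset)
        hi = min(w, offset + onehot.shape[0])
        counts[lo:hi] += onehot[lo - offset : hi - offset]
        coverage[lo:hi] += 1
    keep = coverage > 0
    counts = counts[keep] + pseudocount / 4.0
    pwm = counts / counts.sum(axis=1, keepdims=True)
    score = float(np.mean([s.score for s, _, _ in cluster.members]))
    return MotifModel(
        pwm=pwm,
        importance_score=score,
        n_seqlets=len(cluster.members),
        name=name,
        ledger={"coverage": coverage[keep].tolist()},
    )


def discover_motifs(
    tracks: Sequence[AttributionTrack],
    window: int = 15,
    percentile: float = 99.0,
    similarity_threshold: float = 0.7,
    pseudocount: float = 0.5,
    min_seqlets: int = 3,
    seed: int = 0,
) -> list[MotifModel]:
    """End-to-end aggregation: seqlets -> sign partition -> clusters -> PWMs.

    Returns motifs of both signs sorted by descending |mean importance| *
    member count; clusters with fewer than ``min_seqlets`` members are
    dropped as noise.
    """
    seqlets = extract_seqlets(tracks, window=window, percentile=percentile, seed=seed)
    if not seqlets:
        return []
    pos, neg = partition_by_sign(seqlets)
    motifs: list[MotifModel] = []
    for sign, group in (("pos", pos), ("neg", neg)):
        if not group:
            continue
        for i, cluster in enumerate(cluster_seqlets(group, similarity_threshold)):
            if len(cluster.members) < min_seqlets:
                continue
            motifs.append(build_motif(cluster, pseudocount, name=f"{sign}_{i}"))
    motifs.sort(key=lambda m: -abs(m.importance_score) * m.n_seqlets)
    return motifs
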