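"""Motif vetting: information content, trimming, stringency, similarity
search against a known-motif database, enrichment testing, and the
seven-criterion spurious-motif filter.

Information content of a PWM column is ``2 + sum_i p_i log2 p_i`` bits
(0 for a uniform column, 2 for a fixed base).  Trimming keeps the span
between the first and last column above an IC threshold (default 0.3 bits),
removing the high-entropy flanks the attribution aggregator produces.  A
"stringent" position has IC > 1.9 bits; real TF binding preferences are
rarely near-deterministic, so heavily stringent PWMs are suspect.

The similarity search plays the role TOMTOM plays in a MEME-suite workflow:
best ungapped-offset alignment over both orientations scored by mean
per-column Pearson correlation, with an empirical p-value from
column-shuffled queries and Benjamini-Hochberg correction across the
database.  The enrichment test plays AME's role: log-odds scanning of both
sequence sets and a two-sided Fisher exact test on the hit table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .meme_io import KnownMotifDB

LOG_ODDS_FLOOR = 1e-4  # probability floor so zero entries stay finite in log2

# ---------------------------------------------------------------------------
# Information content, trimming, stringency
# ---------------------------------------------------------------------------


def column_ic(p: np.ndarray) -> float:
    """Information content (bits) of one probability column; 0*log2(0) := 0."""
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("column must be 4 nonnegative probabilities summing to 1")
    nz = p > 0
    return float(2.0 + np.sum(p[nz] * np.log2(p[nz])))


def pwm_ic(pwm: np.ndarray) -> np.ndarray:
    """Per-column IC vector of a PWM."""
    return np.array([column_ic(col) for col in np.asarray(pwm)])


@dataclass
class TrimResult:
    pwm: np.ndarray
    start: int | None
    end: int | None  # inclusive
    degenerate: bool


def trim_motif(pwm: np.ndarray, threshold: float = 0.3) -> TrimResult:
    """Trim to the span between the first and last column with IC > threshold.

    Returns the trimmed PWM and the inclusive (start, end) column offsets in
    the original matrix; a PWM with no column above threshold comes back
    empty with the degenerate flag set.
    """
    pwm = np.asarray(pwm, dtype=np.float64)
    if pwm.size == 0:
        raise ValueError("empty PWM")
    ics = pwm_ic(pwm)
    above = np.flatnonzero(ics > threshold)
    if above.size == 0:
        return TrimResult(pwm[:0], None, None, True)
    start, end = int(above[0]), int(above[-1])
    return TrimResult(pwm[start : end + 1], start, end, False)


def stringent_fraction(pwm: np.ndarray, ic_threshold: float = 1.9) -> float:
    """Fraction of columns with IC above the stringency threshold."""
    pwm = np.asarray(pwm)
    if pwm.size == 0:
        raise ValueError("empty PWM")
    return float(np.mean(pwm_ic(pwm) > ic_threshold))


# ---------------------------------------------------------------------------
# Motif-to-motif similarity (TOMTOM-like)
# ---------------------------------------------------------------------------


def _reverse_complement_pwm(pwm: np.ndarray) -> np.ndarray:
    return pwm[::-1, ::-1].copy()


def _column_correlations(query: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Pearson correlation of every query column against every target column.

    Zero-variance columns make the correlation undefined; such pairs
    contribute 0 (handled by the caller via the degenerate column masks).
    """
    qc = query - query.mean(axis=1, keepdims=True)
    tc = target - target.mean(axis=1, keepdims=True)
    qs = np.sqrt((qc**2).sum(axis=1))
    ts = np.sqrt((tc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (qc @ tc.T) / np.outer(qs, ts)
    corr[~np.isfinite(corr)] = 0.0
    return corr


def _alignments(wq: int, wt: int, min_cols: int = 2):
    """All (offset, query-index array, target-index array) ungapped
    alignments with at least ``min_cols`` overlapping columns."""
    for o in range(-(wq - min_cols), wt - min_cols + 1):
        i0 = max(0, -o)
        i1 = min(wq, wt - o)
        if i1 - i0 < min_cols:
            continue
        i = np.arange(i0, i1)
        yield o, i, i + o


@dataclass
class SimilarityResult:
    score: float
    offset: int
    orientation: str  # '+' or '-'
    overlap_frac: float
    p_value: float
    degenerate: bool


def motif_similarity(
    query: np.ndarray,
    target: np.ndarray,
    n_shuffles: int = 5000,
    seed: int = 0,
    min_overlap_frac: float = 0.7,
) -> SimilarityResult:
    """Best ungapped alignment of query against target (both orientations).

    Alignments are scored by the SUM of per-column Pearson correlations of
    the aligned probability columns, so that a long consistent alignment
    always dominates a short lucky one; the reported ``score`` is the mean
    correlation over the selected alignment.  Candidate alignments must
    cover at least ``min_overlap_frac`` of the shorter motif (never fewer
    than 2 columns).

    The p-value compares the best summed score against an empirical null of
    shuffled queries scored identically, where a shuffle permutes both the
    column order and, independently per column, the four channel values
    within the column.  The channel permutation preserves each column's
    information content while breaking base identity; with column order
    alone the null space is at most w! and collapses further when columns
    repeat (common in GC-skewed motifs), leaving the test without power for
    short queries.

    Overlap is reported as a fraction of the query width.  If every aligned
    column pair is degenerate (zero variance) the score contract returns 0
    with the degenerate flag.
    """
    query = np.asarray(query, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if query.shape[0] < 2 or target.shape[0] < 2:
        raise ValueError("both motifs must be at least 2 columns wide")
    wq, wt = query.shape[0], target.shape[0]
    min_cols = max(2, int(np.ceil(min_overlap_frac * min(wq, wt))))
    q_deg = np.ptp(query, axis=1) < 1e-12

    corr = {}
    aligns = {}
    for orient, tgt in (("+", target), ("-", _reverse_complement_pwm(target))):
        t_deg = np.ptp(tgt, axis=1) < 1e-12
        c = _column_correlations(query, tgt)
        c[q_deg, :] = 0.0
        c[:, t_deg] = 0.0
        corr[orient] = c
        aligns[orient] = list(_alignments(wq, tgt.shape[0], min_cols))

    best = None  # (summed score, orient, offset, n_overlap, all_degenerate)
    for orient in ("+", "-"):
        c = corr[orient]
        t_deg = np.ptp(target if orient == "+" else _reverse_complement_pwm(target),
                       axis=1) < 1e-12
        for o, qi, ti in aligns[orient]:
            total = float(c[qi, ti].sum())
            all_deg = bool(np.all(q_deg[qi] | t_deg[ti]))
            key = (total, -abs(o))
            if best is None or key > (best[0], -abs(best[2])):
                best = (total, orient, o, len(qi), all_deg)
    best_sum, orient, offset, n_overlap, all_deg = best
    score = best_sum / n_overlap

    # permutation null: shuffle column order and, independently per column,
    # the channel values within the column (IC-preserving)
    from itertools import permutations as _perms4

    row_perms = np.array(list(_perms4(range(4))))  # 24 x 4
    rng = np.random.default_rng(seed)
    col_perm = np.stack([rng.permutation(wq) for _ in range(n_shuffles)])
    chan_perm = rng.integers(0, len(row_perms), size=(n_shuffles, wq))
    null = np.full(n_shuffles, -np.inf)
    for or_key in ("+", "-"):
        tgt = target if or_key == "+" else _reverse_complement_pwm(target)
        t_deg = np.ptp(tgt, axis=1) < 1e-12
        # corr of every (query column, channel permutation) against every
        # target column: shape (wq, 24, wt)
        qv = query[:, row_perms]  # (wq, 24, 4)
        qc = qv - qv.mean(axis=2, keepdims=True)
        qs = np.sqrt((qc**2).sum(axis=2))
        tc = tgt - tgt.mean(axis=1, keepdims=True)
        ts = np.sqrt((tc**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            c4 = np.einsum("qrc,tc->qrt", qc, tc) / (qs[:, :, None] * ts[None, None, :])
        c4[~np.isfinite(c4)] = 0.0
        c4[q_deg, :, :] = 0.0
        c4[:, :, t_deg] = 0.0
        for _o, qi, ti in aligns[or_key]:
            src = col_perm[:, qi]  # (S, k) which original column sits here
            vals = c4[src, np.take_along_axis(chan_perm, src, axis=1), ti[None, :]]
            np.maximum(null, vals.sum(axis=1), out=null)
    p = float((1 + np.sum(null >= best_sum - 1e-12)) / (1 + n_shuffles))
    return SimilarityResult(
        score=score,
        offset=offset,
        orientation=orient,
        overlap_frac=n_overlap / wq,
        p_value=p,
        degenerate=all_deg,
    )


@dataclass
class MotifMatch:
    name: str
    similarity: SimilarityResult
    p_value: float
    q_value: float


def match_known(
    query: np.ndarray,
    db: KnownMotifDB,
    n_shuffles: int = 5000,
    seed: int = 0,
) -> list[MotifMatch]:
    """Similarity of the query to every database entry, BH-corrected.

    Returns matches ranked by ascending q-value (ties by p, then score
    descending).
    """
    if len(db) == 0:
        raise ValueError("empty known-motif database")
    sims = [
        motif_similarity(query, entry.pwm, n_shuffles=n_shuffles, seed=seed + i)
        for i, entry in enumerate(db)
    ]
    ps = np.array([s.p_value for s in sims])
    qs = stats.false_discovery_control(ps)
    matches = [
        MotifMatch(entry.name, sim, float(p), float(q))
        for entry, sim, p, q in zip(db, sims, ps, qs)
    ]
    matches.sort(key=lambda m: (m.q_value, m.p_value, -m.similarity.score))
    return matches


# ---------------------------------------------------------------------------
# PWM scanning and enrichment (AME-like)
# ---------------------------------------------------------------------------


def scan_hits(
    pwm: np.ndarray,
    sequences: Sequence[str],
    threshold_frac: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-odds scan of both strands; a sequence is a hit when some window
    reaches ``threshold_frac`` of the maximum achievable log-odds score.

    Returns ``(hit indicator, best score per sequence)``.  Log-odds are
    against a uniform 0.25 background with a small probability floor so that
    zero entries stay finite.
    """
    from .model import encode_batch

    pwm = np.asarray(pwm, dtype=np.float64)
    w = pwm.shape[0]
    if any(len(s) < w for s in sequences):
        raise ValueError("PWM wider than a sequence")
    lo = np.log2(np.maximum(pwm, LOG_ODDS_FLOOR) / 0.25)
    max_score = float(lo.max(axis=1).sum())
    x = encode_batch(sequences).astype(np.float64)
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(x, (w, 4), axis=(1, 2))[:, :, 0]  # (n, P, w, 4)
    fwd = np.einsum("npwc,wc->np", win, lo)
    rev = np.einsum("npwc,wc->np", win, lo[::-1, ::-1])
    best = np.maximum(fwd.max(axis=1), rev.max(axis=1))
    hits = best >= threshold_frac * max_score
    return hits, best


def enrichment_test(
    pwm: np.ndarray,
    positives: Sequence[str],
    negatives: Sequence[str],
    threshold_frac: float = 0.8,
) -> tuple[np.ndarray, float, float]:
    """Two-sided Fisher exact test of motif hits in positives vs negatives.

    Returns ``(2x2 table, odds ratio, p_value)``; the reported odds ratio
    uses the Haldane half-count correction when any cell is zero.
    """
    if not len(positives) or not len(negatives):
        raise ValueError("both sequence sets must be nonempty")
    hits_pos, _ = scan_hits(pwm, positives, threshold_frac)
    hits_neg, _ = scan_hits(pwm, negatives, threshold_frac)
    table = np.array(
        [
            [int(hits_pos.sum()), int((~hits_pos).sum())],
            [int(hits_neg.sum()), int((~hits_neg).sum())],
        ]
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    t = table.astype(np.float64)
    if np.any(t == 0):
        t = t + 0.5
    odds = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    return table, odds, float(p)


# ---------------------------------------------------------------------------
# Expression filter
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTable:
    """TF expression at the three differentiation stages (Day 0, 26, 39)."""

    frame: pd.DataFrame  # index: gene; columns: day0, day26, day39

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionTable":
        frame = pd.read_csv(path, sep="\t")
        frame = frame.set_index(frame.columns[0])
        frame.columns = [c.lower() for c in frame.columns]
        return cls(frame)

    def to_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene")

    def __contains__(self, gene: str) -> bool:
        return gene in self.frame.index


def expression_status(
    tf: str,
    table: ExpressionTable,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
) -> tuple[bool, dict]:
    """Apply the transcription rule: expression rises >= ``min_fold`` from
    Day 0 to Day 26 AND does not rise from Day 26 to Day 39.

    A pseudocount guards the ratio against zero Day-0 expression.  Returns
    (transcribed, {fold changes and stage values}).
    """
    if tf not in table:
        raise KeyError(f"TF {tf!r} not present in expression table")
    row = table.frame.loc[tf]
    d0, d26, d39 = float(row["day0"]), float(row["day26"]), float(row["day39"])
    fold_up = (d26 + pseudocount) / (d0 + pseudocount)
    transcribed = fold_up >= min_fold and d39 <= d26
    return transcribed, {
        "day0": d0,
        "day26": d26,
        "day39": d39,
        "fold_day0_to_day26": fold_up,
        "fold_day26_to_day39": (d39 + pseudocount) / (d26 + pseudocount),
    }


# ---------------------------------------------------------------------------
# Seven-criterion spurious-motif filter
# ---------------------------------------------------------------------------

CRITERIA = (
    "bias",          # 1: neither GC- nor AT-preferring columns reach 80%
    "length",        # 2: trimmed width > 4 nt
    "stringency",    # 3: stringent positions < 75%
    "correspond",    # 4: a positive, non-degenerate known-motif match exists
    "overlap",       # 5: best match aligns with >= 70% of the query
    "similarity_q",  # 6: best match q-value < 0.05
    "expression",    # 7: matched TF passes the transcription rule
)


@dataclass
class FilterVerdict:
    """Per-criterion outcomes of the spurious-motif filter for one motif."""

    passes: dict
    values: dict
    overall: bool

    def to_row(self) -> dict:
        row = {f"pass_{k}": v for k, v in self.passes.items()}
        row.update(self.values)
        row["overall"] = self.overall
        return row


def _bias_fractions(pwm: np.ndarray, tol: float = 1e-9) -> tuple[float, float]:
    """Fractions of columns whose preferred base(s) are all-GC / all-AT.

    A column's preferred set is every base within ``tol`` of the column
    maximum; ties spanning both groups (including uniform columns) count
    toward neither fraction.
    """
    pwm = np.asarray(pwm, dtype=np.float64)
    n_gc = n_at = 0
    for col in pwm:
        preferred = np.flatnonzero(col >= col.max() - tol)
        bases = {"ACGT"[i] for i in preferred}
        if bases <= {"C", "G"}:
            n_gc += 1
        elif bases <= {"A", "T"}:
            n_at += 1
    return n_gc / len(pwm), n_at / len(pwm)


def apply_filters(
    pwm: np.ndarray,
    db: KnownMotifDB,
    expression: ExpressionTable,
    positives: Sequence[str] | None = None,
    negatives: Sequence[str] | None = None,
    bias_max: float = 0.8,
    min_length: int = 4,
    stringent_max: float = 0.75,
    overlap_min: float = 0.7,
    q_max: float = 0.05,
    n_shuffles: int = 5000,
    seed: int = 0,
) -> FilterVerdict:
    """Evaluate the seven spurious-motif criteria on a trimmed PWM.

    Criteria 5-7 qualify the best database match; when no valid match exists
    (criterion 4 fails) they are not applicable and recorded as passing with
    value None, so each criterion can be exercised independently while the
    overall verdict still fails through criterion 4.

    When both sequence sets are given, the enrichment test is run and its
    odds ratio / p-value recorded in the values (informational; not one of
    the seven criteria).
    """
    pwm = np.asarray(pwm, dtype=np.float64)
    passes: dict = {}
    values: dict = {}

    gc_frac, at_frac = _bias_fractions(pwm)
    values["bias_gc_fraction"] = gc_frac
    values["bias_at_fraction"] = at_frac
    passes["bias"] = gc_frac < bias_max and at_frac < bias_max

    values["length"] = int(pwm.shape[0])
    passes["length"] = pwm.shape[0] > min_length

    values["stringent_fraction"] = stringent_fraction(pwm) if pwm.shape[0] else 1.0
    passes["stringency"] = values["stringent_fraction"] < stringent_max

    matches = match_known(pwm, db, n_shuffles=n_shuffles, seed=seed)
    valid = [m for m in matches if m.similarity.score > 0 and not m.similarity.degenerate]
    passes["correspond"] = len(valid) >= 1
    if valid:
        best = valid[0]
        values["best_match"] = best.name
        values["best_match_score"] = best.similarity.score
        values["best_match_overlap"] = best.similarity.overlap_frac
        values["best_match_q"] = best.q_value
        passes["overlap"] = best.similarity.overlap_frac >= overlap_min
        passes["similarity_q"] = best.q_value < q_max
        if best.name in expression:
            transcribed, expr_values = expression_status(best.name, expression)
            values["expression_fold"] = expr_values["fold_day0_to_day26"]
            passes["expression"] = transcribed
        else:
            values["expression_fold"] = None
            passes["expression"] = False
    else:
        values["best_match"] = None
        values["best_match_score"] = None
        values["best_match_overlap"] = None
        values["best_match_q"] = None
        values["expression_fold"] = None
        passes["overlap"] = True  # not applicable without a match
        passes["similarity_q"] = True
        passes["expression"] = True

    if positives is not None and negatives is not None and pwm.shape[0] >= 2:
        _, odds, p = enrichment_test(pwm, positives, negatives)
        values["enrichment_odds_ratio"] = odds
        values["enrichment_p"] = p

    overall = all(passes[k] for k in CRITERIA)
    return FilterVerdict(passes=passes, values=values, overall=overall)


def verdicts_to_tsv(verdicts: dict, path: str) -> None:
    """Write a {motif name -> FilterVerdict} ledger as a TSV table."""
    rows = []
    for name, verdict in verdicts.items():
        row = {"motif": name}
        row.update(verdict.to_row())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
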