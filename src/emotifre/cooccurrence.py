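"""Motif pair co-occurrence within an enhancer set.

Counts, for a pair of PWMs, how many sequences contain hits for both, one,
or neither motif, and tests the association with a two-sided Fisher exact
test.  The table can also be reconstructed directly from published marginal
counts (total sequences, hits of A, hits of B, both) without rescanning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .postprocess import scan_hits


@dataclass
class CooccurrenceTable:
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int

    def __post_init__(self) -> None:
        for name in ("n_both", "n_a_only", "n_b_only", "n_neither"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.n_both + self.n_a_only + self.n_b_only + self.n_neither

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [[self.n_both, self.n_a_only], [self.n_b_only, self.n_neither]]
        )

    @classmethod
    def from_marginals(cls, total: int, n_a: int, n_b: int, n_both: int
                       ) -> "CooccurrenceTable":
        """Reconstruct the 2x2 table from published marginal counts."""
        return cls(
            n_both=n_both,
            n_a_only=n_a - n_both,
            n_b_only=n_b - n_both,
            n_neither=total - n_a - n_b + n_both,
        )


def cooccurrence_table(
    pwm_a: np.ndarray,
    pwm_b: np.ndarray,
    sequences: Sequence[str],
    threshold_frac: float = 0.8,
) -> CooccurrenceTable:
    """Count joint motif-hit patterns over a sequence set."""
    if not len(sequences):
        raise ValueError("empty sequence set")
    hits_a, _ = scan_hits(pwm_a, sequences, threshold_frac)
    hits_b, _ = scan_hits(pwm_b, sequences, threshold_frac)
    return CooccurrenceTable(
        n_both=int(np.sum(hits_a & hits_b)),
        n_a_only=int(np.sum(hits_a & ~hits_b)),
        n_b_only=int(np.sum(~hits_a & hits_b)),
        n_neither=int(np.sum(~hits_a & ~hits_b)),
    )


def fisher_cooccurrence(table: CooccurrenceTable) -> tuple[float, float]:
    """Two-sided Fisher exact test; odds ratio with the Haldane half-count
    correction when any cell is zero."""
    mat = table.as_matrix()
    _, p = stats.fisher_exact(mat, alternative="two-sided")
    m = mat.astype(np.float64)
    if np.any(m == 0):
        m = m + 0.5
    odds = float(m[0, 0] * m[1, 1] / (m[0, 1] * m[1, 0]))
    return odds, float(p)
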