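"""Synthetic fixtures with the statistical structure the framework assumes.

Generators for: fixed-length i.i.d. background sequence sets with controlled
GC content, motif implantation (single motifs or co-occurring pairs) with a
ground-truth manifest, a toy genome with planted candidate/mark/TSS interval
files, a toy known-motif database, and a toy TF expression table.

Everything is deterministic per seed.  The background model is order-0
(independent bases): real enhancer sequences have dinucleotide structure,
repeats and CpG islands that this deliberately does not model, so results on
these fixtures demonstrate method correctness, not genome-scale performance.

The implanted consensus strings are the binding-site cores of the eight TFs
the framework's analyses revolve around (ASCL1/NHLH1, SOX4/SOX11, ZEB1,
NEUROG2, CTCF, NR2F1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval
from .meme_io import KnownMotif, KnownMotifDB
from .postprocess import ExpressionTable

BASES = np.array(list("ACGT"))

# Consensus cores of the motifs the framework's analyses center on.
MOTIF_CONSENSUS = {
    "ASCL1": "CAGCTGC",
    "SOX4": "CCTTTGT",
    "ZEB1": "CCAGGTG",
    "NEUROG2": "GTCATATG",
    "CTCF": "CCAGGGGGCGA",
    "NR2F1": "GAGGTCAA",
}


@dataclass
class ImplantSpec:
    """One motif implantation rule: which set, how often, what to implant."""

    motif: str  # consensus string
    target: str  # "positive" | "negative"
    frequency: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be in [0, 1]")


@dataclass
class SimConfig:
    """Study conditions of the synthetic benchmark.

    Defaults mirror the structure of the real active / non-active enhancer
    sets: 2,000 + 2,000 sequences of 200 bp; the active set is GC-richer
    (0.55 vs 0.45, the two classes differ in GC composition just as the real
    sets do) and carries the ASCL1-like core in 40% of sequences.
    """

    n_pos: int = 2000
    n_neg: int = 2000
    length: int = 200
    gc_pos: float = 0.55
    gc_neg: float = 0.45
    implants: list = field(
        default_factory=lambda: [ImplantSpec(MOTIF_CONSENSUS["ASCL1"], "positive", 0.4)]
    )
    seed: int = 0


def random_background(n: int, length: int, gc: float, seed: int) -> list[str]:
    """i.i.d. sequences with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    draws = rng.choice(4, size=(n, length), p=probs)
    return ["".join(row) for row in BASES[draws]]


def implant(
    sequences: Sequence[str],
    motif: str,
    frequency: float,
    seed: int,
) -> tuple[list[str], list[dict]]:
    """Overwrite a motif instance into a Bernoulli(frequency) subset.

    Each selected sequence receives one copy of the consensus at a uniform
    random position (overwriting background, so lengths are preserved).
    Returns the modified sequences and a manifest of
    ``{"index", "position", "instance"}`` records.
    """
    if sequences and len(motif) >= len(sequences[0]):
        raise ValueError("motif must be shorter than the sequences")
    rng = np.random.default_rng(seed)
    out = list(sequences)
    manifest: list[dict] = []
    for i, seq in enumerate(out):
        if rng.random() >= frequency:
            continue
        pos = int(rng.integers(0, len(seq) - len(motif) + 1))
        out[i] = seq[:pos] + motif + seq[pos + len(motif):]
        manifest.append({"index": i, "position": pos, "instance": motif})
    return out, manifest


def simulate_dataset(config: SimConfig) -> tuple[list[str], list[str], dict]:
    """Generate positive and negative sets per the config, with truth.

    Returns (positives, negatives, truth) where truth holds one implantation
    manifest per implant rule.
    """
    pos = random_background(config.n_pos, config.length, config.gc_pos, config.seed)
    neg = random_background(config.n_neg, config.length, config.gc_neg,
                            config.seed + 1)
    truth: dict = {"implants": []}
    for k, spec in enumerate(config.implants):
        target = pos if spec.target == "positive" else neg
        modified, manifest = implant(target, spec.motif, spec.frequency,
                                     config.seed + 100 + k)
        if spec.target == "positive":
            pos = modified
        else:
            neg = modified
        truth["implants"].append(
            {"motif": spec.motif, "target": spec.target,
             "frequency": spec.frequency, "manifest": manifest}
        )
    return pos, neg, truth


def simulate_and_task(
    n: int = 2000,
    length: int = 200,
    gc: float = 0.45,
    motif_a: str = MOTIF_CONSENSUS["ASCL1"],
    motif_b: str = MOTIF_CONSENSUS["NR2F1"],
    seed: int = 0,
) -> tuple[list[str], list[str], dict]:
    """A task solvable only through motif co-occurrence.

    Positives carry BOTH motifs; every negative carries exactly ONE of the
    two (chosen 50/50).  The marginal presence of either motif is therefore
    informative but weak, while the pair interaction separates the classes —
    the signal a single linear map dilutes but a conv/max-pool network can
    compose.

    Motif A is placed uniformly in the left half of the sequence and motif B
    in the right half (in every class, so placement carries no label
    information); disjoint placement regions keep the two implants from
    overwriting each other.
    """
    rng = np.random.default_rng(seed)

    def place(seq, motif, lo, hi):
        p = int(rng.integers(lo, hi - len(motif) + 1))
        return seq[:p] + motif + seq[p + len(motif):], p

    half = length // 2
    pos, man_a, man_b = [], [], []
    for i, seq in enumerate(random_background(n, length, gc, seed + 1)):
        seq, pa = place(seq, motif_a, 0, half)
        seq, pb = place(seq, motif_b, half, length)
        pos.append(seq)
        man_a.append({"index": i, "position": pa, "instance": motif_a})
        man_b.append({"index": i, "position": pb, "instance": motif_b})
    neg = []
    for seq in random_background(n, length, gc, seed + 2):
        if rng.random() < 0.5:
            seq, _ = place(seq, motif_a, 0, half)
        else:
            seq, _ = place(seq, motif_b, half, length)
        neg.append(seq)
    truth = {"motif_a": motif_a, "motif_b": motif_b,
             "positive_manifests": [man_a, man_b]}
    return pos, neg, truth


# ---------------------------------------------------------------------------
# Toy genome with planted interval structure
# ---------------------------------------------------------------------------


@dataclass
class ToyGenome:
    genome: dict  # chrom -> sequence string
    candidates: list
    marks: list
    tss: list
    truth: dict


def make_toy_genome(
    n_candidates: int = 10,
    n_active: int = 4,
    n_promoter_overlap: int = 0,
    peak_length: int = 600,
    spacing: int = 3000,
    seed: int = 0,
) -> ToyGenome:
    """One toy chromosome with planted candidate peaks, H3K27ac marks over
    the first ``n_active`` candidates, and TSSs placed inside the promoter
    windows of the last ``n_promoter_overlap`` candidates.

    The truth dict records the expected active / non-active / excluded
    counts after the full preprocessing chain.
    """
    if n_active + n_promoter_overlap > n_candidates:
        raise ValueError("n_active + n_promoter_overlap exceeds n_candidates")
    rng = np.random.default_rng(seed)
    chrom_len = spacing * (n_candidates + 2)
    seq = "".join(BASES[rng.choice(4, size=chrom_len)])
    candidates, marks, tss = [], [], []
    for i in range(n_candidates):
        start = spacing * (i + 1)
        cand = GenomicInterval("chrT", start, start + peak_length)
        candidates.append(cand)
        if i < n_active:
            # mark overlapping the right half of the candidate
            marks.append(GenomicInterval("chrT", start + peak_length // 2,
                                         start + peak_length + 200))
        if i >= n_candidates - n_promoter_overlap:
            # TSS 200 bp downstream of the peak end: its (-1000, +100)
            # window reaches back into the candidate
            t = start + peak_length + 200
            tss.append(GenomicInterval("chrT", t, t + 1, strand="+"))
    n_excluded_active = sum(
        1 for i in range(n_candidates)
        if i < n_active and i >= n_candidates - n_promoter_overlap
    )
    n_excluded_inactive = n_promoter_overlap - n_excluded_active
    truth = {
        "n_active": n_active - n_excluded_active,
        "n_inactive": (n_candidates - n_active) - n_excluded_inactive,
        "n_promoter_excluded": n_promoter_overlap,
    }
    return ToyGenome({"chrT": seq}, candidates, marks, tss, truth)


# ---------------------------------------------------------------------------
# Toy known-motif database and expression fixture
# ---------------------------------------------------------------------------


def consensus_to_pwm(
    consensus: str, major: float = 0.85, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Soft PWM from a consensus: ``major`` on the consensus base.

    Without an ``rng`` the remaining mass is split evenly over the other
    bases; with one, it is split unevenly (Dirichlet draw), which mimics
    real TF matrices — a column with three exactly equal minor
    probabilities is invariant under minor-channel permutations, an
    artifact real binding models do not show.
    """
    pwm = np.empty((len(consensus), 4))
    for j, ch in enumerate(consensus):
        k = "ACGT".index(ch)
        if rng is None:
            minors = np.full(3, (1.0 - major) / 3.0)
        else:
            minors = rng.dirichlet(np.ones(3)) * (1.0 - major)
        pwm[j] = np.insert(minors, k, major)
    return pwm


def make_motif_db(n_decoys: int = 50, major: float = 0.85, seed: int = 0
                  ) -> KnownMotifDB:
    """Known-motif database: the eight TF cores plus random decoy PWMs."""
    rng = np.random.default_rng(seed)
    entries = [
        KnownMotif(name, consensus_to_pwm(cons, major, rng))
        for name, cons in MOTIF_CONSENSUS.items()
    ]
    # NHLH1 and SOX11 share binding cores with ASCL1 and SOX4 respectively
    entries.append(
        KnownMotif("NHLH1", consensus_to_pwm(MOTIF_CONSENSUS["ASCL1"], major, rng))
    )
    entries.append(
        KnownMotif("SOX11", consensus_to_pwm(MOTIF_CONSENSUS["SOX4"], major, rng))
    )
    for i in range(n_decoys):
        w = int(rng.integers(6, 12))
        cons = "".join(BASES[rng.choice(4, size=w)])
        entries.append(KnownMotif(f"DECOY{i}", consensus_to_pwm(cons, major, rng)))
    return KnownMotifDB(entries)


def _soft_pwm(rng: np.random.Generator, argmax_bases: str, major: float = 0.6
              ) -> np.ndarray:
    """PWM with controlled per-column argmax but continuously varied shape.

    Each column puts ``major`` on its designated base and spreads the rest
    by a Dirichlet draw, so no two columns are Pearson-identical — which
    keeps the similarity permutation null well resolved.
    """
    pwm = np.empty((len(argmax_bases), 4))
    for j, ch in enumerate(argmax_bases):
        k = "ACGT".index(ch)
        minors = rng.dirichlet(np.ones(3)) * (1.0 - major)
        pwm[j] = np.insert(minors, k, major)
    return pwm


def make_filter_case(criterion: str, seed: int = 0) -> dict:
    """A constructed motif + database + expression table that fails exactly
    one of the seven spurious-motif criteria (or passes all, for
    ``criterion="pass"``).

    Returns ``{"pwm", "db", "expression", "fails"}`` where ``fails`` names
    the single criterion the verdict is expected to fail (None for the
    all-pass case).  Criteria 5-7 qualify the best database match, so the
    no-match case (criterion 4) leaves them not-applicable rather than
    failed.
    """
    rng = np.random.default_rng(seed + 7)
    expr_rows = {
        "ASCL1": (5.0, 40.0, 30.0),  # satisfies the 2-fold rule
        "CTCF": (50.0, 55.0, 52.0),  # high but flat: fails the rule
    }
    import pandas as pd

    expr = ExpressionTable(
        pd.DataFrame.from_dict(expr_rows, orient="index",
                               columns=["day0", "day26", "day39"])
    )

    def db_of(*entries):
        return KnownMotifDB([KnownMotif(n, p) for n, p in entries])

    if criterion == "bias":
        # 4 of 5 columns prefer G/C -> GC fraction 0.8 trips the bias cap
        pwm = _soft_pwm(rng, "GCGCA")
        return {"pwm": pwm, "db": db_of(("ASCL1", pwm.copy())),
                "expression": expr, "fails": "bias"}
    if criterion == "length":
        pwm = _soft_pwm(rng, "CAGT")  # 4 columns: not > 4 nt
        return {"pwm": pwm, "db": db_of(("ASCL1", pwm.copy())),
                "expression": expr, "fails": "length"}
    if criterion == "stringency":
        pwm = _soft_pwm(rng, "ACGTACGT", major=0.998)  # every column > 1.9 bits
        soft_db = _soft_pwm(rng, "ACGTACGT", major=0.85)
        return {"pwm": pwm, "db": db_of(("ASCL1", soft_db)),
                "expression": expr, "fails": "stringency"}
    if criterion == "correspond":
        pwm = np.full((6, 4), 0.25)  # uniform: every alignment degenerate
        return {"pwm": pwm, "db": db_of(("ASCL1", _soft_pwm(rng, "CAGTAC"))),
                "expression": expr, "fails": "correspond"}
    if criterion == "overlap":
        target = _soft_pwm(rng, "CAGT")
        flanks = _soft_pwm(rng, "AGTCAT")
        pwm = np.vstack([target.copy(), flanks])  # best match covers 4/10 < 70%
        return {"pwm": pwm, "db": db_of(("ASCL1", target)),
                "expression": expr, "fails": "overlap"}
    if criterion == "similarity_q":
        pwm = _soft_pwm(rng, "ACGTCATG")
        unrelated = _soft_pwm(np.random.default_rng(seed + 104729), "GTACGTAC")
        return {"pwm": pwm, "db": db_of(("ASCL1", unrelated)),
                "expression": expr, "fails": "similarity_q"}
    if criterion == "expression":
        pwm = _soft_pwm(rng, "CAGTC")
        return {"pwm": pwm, "db": db_of(("CTCF", pwm.copy())),
                "expression": expr, "fails": "expression"}
    if criterion == "pass":
        pwm = _soft_pwm(rng, MOTIF_CONSENSUS["ASCL1"])  # CAGCTGC: mixed argmax
        jittered = consensus_to_pwm(MOTIF_CONSENSUS["ASCL1"], rng=rng)
        decoys = [(f"DECOY{i}", _soft_pwm(rng, "".join(BASES[rng.choice(4, size=8)])))
                  for i in range(4)]
        return {"pwm": pwm, "db": db_of(("ASCL1", jittered), *decoys),
                "expression": expr, "fails": None}
    raise ValueError(f"unknown criterion {criterion!r}")


FILTER_CASE_NAMES = ("bias", "length", "stringency", "correspond", "overlap",
                     "similarity_q", "expression", "pass")


def make_expression_fixture(n_decoys: int = 5, seed: int = 0) -> ExpressionTable:
    """Expression table over Day 0/26/39 with the expected transcription
    pattern: ASCL1/NHLH1/SOX4/SOX11 rise >= 2-fold into Day 26 then level
    off (transcribed); ZEB1/NEUROG2/NR2F1 fail the fold rule; CTCF is high
    and flat across all three stages (expressed but not induced); plus flat
    decoys."""
    import pandas as pd

    rows = {
        "ASCL1": (5.0, 40.0, 30.0),
        "NHLH1": (2.0, 12.0, 10.0),
        "SOX4": (8.0, 35.0, 35.0),
        "SOX11": (6.0, 30.0, 22.0),
        "ZEB1": (20.0, 25.0, 24.0),
        "NEUROG2": (15.0, 18.0, 30.0),
        "CTCF": (50.0, 55.0, 52.0),
        "NR2F1": (30.0, 35.0, 60.0),
    }
    rng = np.random.default_rng(seed)
    for i in range(n_decoys):
        level = float(rng.uniform(5, 20))
        rows[f"DECOY{i}"] = (level, level, level)
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["day0", "day26", "day39"])
    return ExpressionTable(frame)
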