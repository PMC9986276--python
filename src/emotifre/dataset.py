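"""Sequence extraction, labeling, GC statistics and FASTA I/O.

Builds the positive (active enhancer) / negative (non-active enhancer)
sequence sets from interval lists and a genome, and provides the GC-content
comparison between the two classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import (
    DatasetConfig,
    GenomicInterval,
    center_fix_length,
    exclude_promoters,
    split_by_overlap,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceExample:
    """A fixed-length DNA sequence with its class label and provenance."""

    sequence: str
    label: int
    interval: GenomicInterval | None = None


def load_genome(path: str):
    """Open an indexed FASTA (a .fai index is built on first use)."""
    from pyfaidx import Fasta

    return Fasta(path, sequence_always_upper=True)


def chromosome_sizes(genome) -> dict[str, int]:
    """Chromosome name -> length for a mapping of sequences or a pyfaidx Fasta."""
    if hasattr(genome, "keys"):
        return {name: len(genome[name]) for name in genome.keys()}
    raise TypeError("genome must be a mapping of chromosome sequences")


class ChromosomeNotFound(KeyError):
    pass


def fetch_sequence(genome, interval: GenomicInterval) -> str:
    """Uppercase sequence of an interval from a dict-like or pyfaidx genome."""
    try:
        record = genome[interval.chrom]
    except KeyError as exc:
        raise ChromosomeNotFound(
            f"chromosome {interval.chrom!r} not present in genome"
        ) from exc
    seq = record[interval.start : interval.end]
    return str(seq).upper()


def extract_sequences(
    intervals: Sequence[GenomicInterval],
    genome,
    label: int,
    max_n_fraction: float = 0.0,
) -> list[SequenceExample]:
    """Extract labeled sequences; drop examples exceeding the N-base budget."""
    out: list[SequenceExample] = []
    n_dropped = 0
    for iv in intervals:
        seq = fetch_sequence(genome, iv)
        if len(seq) != len(iv):
            n_dropped += 1
            continue
        n_frac = seq.count("N") / len(seq)
        if n_frac > max_n_fraction:
            n_dropped += 1
            continue
        out.append(SequenceExample(seq, label, iv))
    if n_dropped:
        logger.info("extract_sequences dropped %d examples (N content/bounds)", n_dropped)
    return out


def gc_fraction(sequence: str) -> float:
    """(G+C) / (length excluding N); NaN when every base is N."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    denom = len(seq) - seq.count("N")
    if denom == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / denom


def compare_gc(
    set_a: Sequence[str], set_b: Sequence[str]
) -> tuple[float, float]:
    """Two-sided rank-sum comparison of per-sequence GC fractions.

    The two sets are unpaired and generally of different sizes, so the
    comparison is the Mann-Whitney U rank-sum test.  Returns
    ``(statistic, p_value)``.
    """
    if len(set_a) < 2 or len(set_b) < 2:
        raise ValueError("each set needs at least 2 sequences")
    gc_a = [gc_fraction(s) for s in set_a]
    gc_b = [gc_fraction(s) for s in set_b]
    res = stats.mannwhitneyu(gc_a, gc_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def build_dataset(
    candidates: Sequence[GenomicInterval],
    marks: Sequence[GenomicInterval],
    tss: Sequence[GenomicInterval],
    genome,
    config: DatasetConfig,
) -> tuple[list[SequenceExample], list[SequenceExample], dict]:
    """Run the full preprocessing chain: mark split -> promoter exclusion ->
    fixed-length centering -> sequence extraction.

    Returns (positives, negatives, stats) where stats records the counts at
    each stage plus the GC comparison between the final classes.
    """
    sizes = chromosome_sizes(genome)
    active, inactive = split_by_overlap(candidates, marks)
    stats_d: dict = {"n_candidates": len(candidates), "n_active_raw": len(active),
                     "n_inactive_raw": len(inactive)}
    active = exclude_promoters(active, tss, config.promoter_window)
    inactive = exclude_promoters(inactive, tss, config.promoter_window)
    stats_d["n_active_nonpromoter"] = len(active)
    stats_d["n_inactive_nonpromoter"] = len(inactive)
    active = center_fix_length(active, config.target_length, sizes)
    inactive = center_fix_length(inactive, config.target_length, sizes)
    positives = extract_sequences(active, genome, 1, config.max_n_fraction)
    negatives = extract_sequences(inactive, genome, 0, config.max_n_fraction)
    stats_d["n_positive"] = len(positives)
    stats_d["n_negative"] = len(negatives)
    if len(positives) >= 2 and len(negatives) >= 2:
        stat, p = compare_gc([e.sequence for e in positives],
                             [e.sequence for e in negatives])
        stats_d["gc_statistic"] = stat
        stats_d["gc_p_value"] = p
    return positives, negatives, stats_d


def write_fasta(examples: Sequence[SequenceExample], path: str) -> None:
    """Write examples as FASTA with headers ``chrom:start-end|label``."""
    with open(path, "w") as fh:
        for i, ex in enumerate(examples):
            if ex.interval is not None:
                name = f"{ex.interval.chrom}:{ex.interval.start}-{ex.interval.end}"
            else:
                name = f"seq{i}"
            fh.write(f">{name}|{ex.label}\n{ex.sequence}\n")


def read_fasta(path: str, label: int | None = None) -> list[SequenceExample]:
    """Read a dataset FASTA; the label comes from the header suffix unless
    overridden."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(path, "fasta"):
        lab = label
        if lab is None:
            lab = int(rec.id.rsplit("|", 1)[1]) if "|" in rec.id else 0
        out.append(SequenceExample(str(rec.seq).upper(), lab))
    return out


def write_manifest(examples: Sequence[SequenceExample], path: str) -> None:
    """Per-example TSV manifest with GC fraction."""
    import pandas as pd

    rows = []
    for ex in examples:
        iv = ex.interval
        rows.append(
            {
                "chrom": iv.chrom if iv else ".",
                "start": iv.start if iv else -1,
                "end": iv.end if iv else -1,
                "label": ex.label,
                "gc_fraction": gc_fraction(ex.sequence),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
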