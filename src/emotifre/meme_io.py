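"""MEME minimal motif format reading/writing and the known-motif database."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import motifs as bio_motifs


@dataclass
class KnownMotif:
    name: str
    pwm: np.ndarray  # width x 4, rows sum to 1


@dataclass
class KnownMotifDB:
    entries: list

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def read_meme(path: str) -> KnownMotifDB:
    """Read a MEME (minimal) motif file into a database of PWMs."""
    entries = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "minimal"):
            pwm = np.array(
                [[m.pwm[b][j] for b in "ACGT"] for j in range(m.length)],
                dtype=np.float64,
            )
            rowsums = pwm.sum(axis=1, keepdims=True)
            if np.any(np.abs(rowsums - 1.0) > 1e-6):
                raise ValueError(f"motif {m.name}: PWM rows do not sum to 1")
            entries.append(KnownMotif(m.name or m.base_id or "motif", pwm))
    return KnownMotifDB(entries)


def write_meme(motifs, path: str, nsites: int = 1_000_000) -> None:
    """Write (name, pwm) pairs or MotifModel-like objects as MEME minimal.

    Accepts any object with ``name`` and ``pwm`` attributes, or (name, pwm)
    tuples.  ``nsites`` is written large by default: parsers reconstruct
    integer counts as ``probability * nsites``, so a small value quantizes
    the matrix on read-back (provenance counts belong in the sidecar, not
    here).
    """
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for item in motifs:
            if isinstance(item, tuple):
                name, pwm = item
            else:
                name, pwm = item.name, item.pwm
            n = nsites
            pwm = np.asarray(pwm, dtype=np.float64)
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alphabet= ACGT w= {pwm.shape[0]} "
                f"nsites= {n} E= 0\n"
            )
            for row in pwm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
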