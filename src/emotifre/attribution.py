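"""Integrated Gradients attribution for the enhancer classifier.

For each sequence, the path integral of the model gradient from a baseline to
the input yields a per-position, per-base attribution.  Two views are kept:

* the *raw* attribution ``(x - baseline) * mean path gradient`` — the
  quantity that satisfies the completeness axiom (its sum equals
  ``f(x) - f(baseline)`` in the limit of many interpolation steps);
* the *hypothetical* score ``mean path gradient * (1 - baseline)`` — the
  attribution each base WOULD receive at a position were it the observed
  base.  Projecting the hypothetical matrix onto the observed one-hot
  sequence gives the per-base *importance* track that the motif-discovery
  stage consumes.

Attribution is computed against the pre-sigmoid logit by default: near
saturation the probability gradient vanishes, which would flatten the signal.
The baseline is the uniform distribution (0.25 per channel), the standard
neutral reference for one-hot genomic inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import ConvNet, encode_batch

UNIFORM_BASELINE_VALUE = 0.25


def uniform_baseline(length: int) -> np.ndarray:
    return np.full((length, 4), UNIFORM_BASELINE_VALUE, dtype=np.float32)


@dataclass
class AttributionTrack:
    """Attribution record for one sequence."""

    sequence: str
    importance: np.ndarray  # L x 4, mass on the observed base, zero elsewhere
    hypothetical: np.ndarray  # L x 4
    raw: np.ndarray  # L x 4, (x - baseline) * mean gradient
    prediction: float
    completeness_gap: float
    baseline_id: str = "uniform"
    n_steps: int = 128

    @property
    def position_importance(self) -> np.ndarray:
        """Per-position importance of the observed base (length L)."""
        return self.importance.sum(axis=1)


def _mean_path_gradient(
    model: ConvNet, x: np.ndarray, baseline: np.ndarray, n_steps: int,
    on_logit: bool,
) -> np.ndarray:
    """Mean gradient along the straight path, right Riemann sum (k/m)."""
    alphas = np.arange(1, n_steps + 1, dtype=np.float32) / n_steps
    path = baseline[None] + alphas[:, None, None] * (x - baseline)[None]
    grads = model.input_gradients(path, on_logit=on_logit)
    return grads.mean(axis=0)


def integrated_gradients(
    model: ConvNet,
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    n_steps: int = 128,
    on_logit: bool = True,
) -> np.ndarray:
    """Raw Integrated Gradients attribution, shape L x 4.

    ``attribution = (x - baseline) * mean_{k=1..m} grad f(baseline +
    (k/m)(x - baseline))``.
    """
    x = np.asarray(x, dtype=np.float32)
    if baseline is None:
        baseline = uniform_baseline(x.shape[0])
    baseline = np.asarray(baseline, dtype=np.float32)
    if baseline.shape != x.shape:
        raise ValueError(f"shape mismatch: x {x.shape} vs baseline {baseline.shape}")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    g = _mean_path_gradient(model, x, baseline, n_steps, on_logit)
    return (x - baseline) * g


def hypothetical_scores(
    model: ConvNet,
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    n_steps: int = 128,
    on_logit: bool = True,
) -> np.ndarray:
    """Hypothetical importance: ``mean path gradient * (1 - baseline)``.

    Entry (j, b) is the attribution base b would receive at position j if it
    were the observed base; for the actually observed base it equals the raw
    attribution entry.
    """
    x = np.asarray(x, dtype=np.float32)
    if baseline is None:
        baseline = uniform_baseline(x.shape[0])
    baseline = np.asarray(baseline, dtype=np.float32)
    if baseline.shape != x.shape:
        raise ValueError(f"shape mismatch: x {x.shape} vs baseline {baseline.shape}")
    g = _mean_path_gradient(model, x, baseline, n_steps, on_logit)
    return g * (1.0 - baseline)


def attribute_sequence(
    model: ConvNet,
    sequence_onehot: np.ndarray,
    sequence: str = "",
    baseline: np.ndarray | None = None,
    n_steps: int = 128,
    on_logit: bool = True,
) -> AttributionTrack:
    """Full attribution record for one encoded sequence."""
    x = np.asarray(sequence_onehot, dtype=np.float32)
    if baseline is None:
        baseline = uniform_baseline(x.shape[0])
    g = _mean_path_gradient(model, x, baseline, n_steps, on_logit)
    raw = (x - baseline) * g
    hyp = g * (1.0 - baseline)
    importance = hyp * x
    if on_logit:
        f_x = float(model.forward(x[None])[0])
        f_b = float(model.forward(baseline[None])[0])
    else:
        f_x = float(model.predict_proba(x[None])[0])
        f_b = float(model.predict_proba(baseline[None])[0])
    gap = abs(float(raw.sum()) - (f_x - f_b))
    return AttributionTrack(
        sequence=sequence,
        importance=importance,
        hypothetical=hyp,
        raw=raw,
        prediction=float(model.predict_proba(x[None])[0]),
        completeness_gap=gap,
        n_steps=n_steps,
    )


def batch_attributions(
    model: ConvNet,
    sequences: Sequence[str],
    n_steps: int = 128,
    on_logit: bool = True,
    completeness_tol: float = 0.01,
) -> list[AttributionTrack]:
    """Attribution tracks for a dataset of equal-length sequences.

    Completeness is checked per example; violations beyond
    ``completeness_tol`` are counted and logged, never silently fixed.  On
    the probability scale the tolerance is absolute (the output has
    magnitude at most 1); on the logit scale it is relative to the
    magnitude of ``f(x) - f(baseline)``.
    """
    import logging

    if not model.trained:
        raise ValueError("model is untrained; train or load a trained checkpoint")
    x = encode_batch(sequences)
    tracks = [
        attribute_sequence(model, x[i], sequences[i], n_steps=n_steps,
                           on_logit=on_logit)
        for i in range(len(sequences))
    ]
    if on_logit:
        n_bad = sum(
            t.completeness_gap > completeness_tol * max(1.0, abs(float(t.raw.sum())))
            for t in tracks
        )
    else:
        n_bad = sum(t.completeness_gap > completeness_tol for t in tracks)
    if n_bad:
        logging.getLogger(__name__).warning(
            "%d/%d attribution tracks exceed completeness tolerance %.3g",
            n_bad, len(tracks), completeness_tol,
        )
    return tracks


def save_tracks(tracks: Sequence[AttributionTrack], path: str) -> None:
    """Persist tracks as an NPZ archive (sequences, matrices, predictions)."""
    np.savez_compressed(
        path,
        sequences=np.array([t.sequence for t in tracks]),
        importance=np.stack([t.importance for t in tracks]),
        hypothetical=np.stack([t.hypothetical for t in tracks]),
        raw=np.stack([t.raw for t in tracks]),
        predictions=np.array([t.prediction for t in tracks]),
        completeness_gaps=np.array([t.completeness_gap for t in tracks]),
        n_steps=np.array([tracks[0].n_steps if tracks else 0]),
    )


def load_tracks(path: str) -> list[AttributionTrack]:
    import os

    path = str(path)
    if not os.path.exists(path) and os.path.exists(path + ".npz"):
        path += ".npz"
    with np.load(path, allow_pickle=False) as data:
        n_steps = int(data["n_steps"][0])
        return [
            AttributionTrack(
                sequence=str(data["sequences"][i]),
                importance=data["importance"][i],
                hypothetical=data["hypothetical"][i],
                raw=data["raw"][i],
                prediction=float(data["predictions"][i]),
                completeness_gap=float(data["completeness_gaps"][i]),
                n_steps=n_steps,
            )
            for i in range(len(data["predictions"]))
        ]
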