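"""End-to-end pipeline: build -> train -> attribute -> discover -> vet ->
co-occur, driven by one YAML config with a single global seed.

The global seed fans out to per-stage seeds by fixed offsets so that every
stage is individually reproducible.  Each stage writes its outputs into the
run directory and a JSON manifest records parameters and output paths; a
failed stage halts the run with its name, keeping earlier outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import yaml

logger = logging.getLogger(__name__)

STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "train": 1000,
    "attribute": 2000,
    "discover": 3000,
    "vet": 4000,
    "cooccur": 5000,
}


@dataclass
class RunConfig:
    """Parameters of a full pipeline run on synthetic or file inputs."""

    out_dir: str = "run"
    seed: int = 0
    # dataset: either synthetic (default) or FASTA paths
    pos_fasta: str | None = None
    neg_fasta: str | None = None
    n_pos: int = 2000
    n_neg: int = 2000
    length: int = 200
    gc_pos: float = 0.55
    gc_neg: float = 0.45
    implant_motif: str = "CAGCTGC"
    implant_frequency: float = 0.4
    # training
    n_filters: int = 32
    kernel_size: int = 16
    dense_units: int = 32
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    # attribution
    n_steps: int = 128
    n_attribute: int = 500  # per class
    # discovery
    window: int = 15
    percentile: float = 99.0
    similarity_threshold: float = 0.7
    min_seqlets: int = 3
    # vetting
    motif_db: str | None = None
    expression_tsv: str | None = None
    hit_threshold: float = 0.8
    n_shuffles: int = 5000

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        for key in ("pos_fasta", "neg_fasta", "motif_db", "expression_tsv"):
            value = getattr(cfg, key)
            if value is not None and not os.path.exists(value):
                raise FileNotFoundError(f"{key}: {value} does not exist")
        return cfg


def stage_seed(config: RunConfig, stage: str) -> int:
    return config.seed + STAGE_SEED_OFFSETS[stage]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the manifest dict."""
    from . import dataset, model as model_mod, attribution, discovery
    from . import postprocess, simulate, meme_io, cooccurrence

    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in vars(config).items()}, "stages": {}}
    stage = "simulate"
    try:
        # ---- dataset ------------------------------------------------------
        if config.pos_fasta and config.neg_fasta:
            pos = [e.sequence for e in dataset.read_fasta(config.pos_fasta, label=1)]
            neg = [e.sequence for e in dataset.read_fasta(config.neg_fasta, label=0)]
        else:
            sim = simulate.SimConfig(
                n_pos=config.n_pos, n_neg=config.n_neg, length=config.length,
                gc_pos=config.gc_pos, gc_neg=config.gc_neg,
                implants=[simulate.ImplantSpec(config.implant_motif, "positive",
                                               config.implant_frequency)],
                seed=stage_seed(config, "simulate"),
            )
            pos, neg, truth = simulate.simulate_dataset(sim)
            with open(os.path.join(config.out_dir, "truth.json"), "w") as fh:
                json.dump(truth, fh)
        from .dataset import SequenceExample, write_fasta

        write_fasta([SequenceExample(s, 1) for s in pos],
                    os.path.join(config.out_dir, "positive.fa"))
        write_fasta([SequenceExample(s, 0) for s in neg],
                    os.path.join(config.out_dir, "negative.fa"))
        gc_stat, gc_p = dataset.compare_gc(pos, neg)
        manifest["stages"]["simulate"] = {
            "n_pos": len(pos), "n_neg": len(neg),
            "gc_statistic": gc_stat, "gc_p_value": gc_p,
        }

        # ---- train --------------------------------------------------------
        stage = "train"
        hp = model_mod.Hyperparams(
            n_filters=config.n_filters, kernel_size=config.kernel_size,
            dense_units=config.dense_units, learning_rate=config.learning_rate,
            batch_size=config.batch_size, max_epochs=config.max_epochs,
            patience=config.patience, seed=stage_seed(config, "train"),
        )
        net, report = model_mod.train(pos, neg, hp)
        net.save(os.path.join(config.out_dir, "model.ckpt"))
        baseline = model_mod.baseline_linear(pos, neg, seed=hp.seed)
        manifest["stages"]["train"] = {
            "cnn": report.to_dict(), "linear_baseline": baseline.to_dict(),
        }

        # ---- attribute ----------------------------------------------------
        stage = "attribute"
        n_attr = min(config.n_attribute, len(pos), len(neg))
        subset = pos[:n_attr] + neg[:n_attr]
        tracks = attribution.batch_attributions(net, subset, n_steps=config.n_steps)
        attribution.save_tracks(tracks, os.path.join(config.out_dir, "attributions.npz"))
        gaps = np.array([t.completeness_gap for t in tracks])
        manifest["stages"]["attribute"] = {
            "n_tracks": len(tracks),
            "completeness_ok_fraction": float(np.mean(gaps <= 0.01)),
        }

        # ---- discover -----------------------------------------------------
        stage = "discover"
        motifs = []
        for raw in discovery.discover_motifs(
            tracks, window=config.window, percentile=config.percentile,
            similarity_threshold=config.similarity_threshold,
            min_seqlets=config.min_seqlets, seed=stage_seed(config, "discover"),
        ):
            trim = postprocess.trim_motif(raw.pwm)
            if trim.degenerate:
                continue
            raw.ledger["trim"] = (trim.start, trim.end)
            raw.pwm = trim.pwm
            motifs.append(raw)
        meme_io.write_meme(motifs, os.path.join(config.out_dir, "motifs.meme"))
        manifest["stages"]["discover"] = {
            "n_motifs": len(motifs),
            "motifs": [
                {"name": m.name, "consensus": m.consensus,
                 "importance_score": m.importance_score, "n_seqlets": m.n_seqlets}
                for m in motifs
            ],
        }

        # ---- vet ----------------------------------------------------------
        stage = "vet"
        db = (meme_io.read_meme(config.motif_db) if config.motif_db
              else simulate.make_motif_db(seed=stage_seed(config, "vet")))
        expr = (postprocess.ExpressionTable.from_tsv(config.expression_tsv)
                if config.expression_tsv else simulate.make_expression_fixture())
        verdicts = {}
        for m in motifs:
            verdicts[m.name] = postprocess.apply_filters(
                m.pwm, db, expr, positives=pos[:200], negatives=neg[:200],
                n_shuffles=config.n_shuffles, seed=stage_seed(config, "vet"),
            )
        postprocess.verdicts_to_tsv(verdicts, os.path.join(config.out_dir, "verdicts.tsv"))
        manifest["stages"]["vet"] = {
            name: {"overall": v.overall, "passes": v.passes}
            for name, v in verdicts.items()
        }

        # ---- cooccur ------------------------------------------------------
        stage = "cooccur"
        passing = [m for m in motifs if verdicts[m.name].overall]
        if len(passing) >= 2:
            table = cooccurrence.cooccurrence_table(
                passing[0].pwm, passing[1].pwm, pos, config.hit_threshold
            )
            odds, p = cooccurrence.fisher_cooccurrence(table)
            manifest["stages"]["cooccur"] = {
                "motifs": [passing[0].name, passing[1].name],
                "table": table.as_matrix().tolist(),
                "odds_ratio": odds, "p_value": p,
            }
        else:
            manifest["stages"]["cooccur"] = {"skipped": "fewer than 2 passing motifs"}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(manifest, config.out_dir)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    _write_manifest(manifest, config.out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
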