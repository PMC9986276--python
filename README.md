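# emotifre

Enhancer-activity classification and attribution-based *de novo* motif
discovery for regulatory genomics.

During neuronal differentiation (and development generally), open-chromatin
regions split into **active enhancers** — ATAC-seq peaks carrying the
H3K27ac mark — and **non-active** (poised, repressed or silencer) elements
that are open but unmarked. `emotifre` asks which transcription-factor
binding motifs distinguish the two classes, directly from sequence:

1. **Dataset construction** — partition candidate peaks by H3K27ac overlap,
   drop promoter-proximal regions (−1000, +100 around each TSS), re-center
   to a fixed length, extract sequences, and compare GC composition between
   classes (Mann–Whitney rank-sum).
2. **Classification** — a small 1D-convolutional network
   (conv → ReLU → global max pool → dense → sigmoid) on one-hot DNA,
   trained with class-weighted cross-entropy and early stopping, next to a
   logistic-regression baseline on the same splits. The gap between the two
   measures how much of the signal is combinatorial rather than linear.
3. **Attribution** — Integrated Gradients against a uniform baseline gives
   per-base importance and hypothetical-importance tracks for every
   sequence.
4. **Motif discovery** — high-attribution windows (seqlets) are extracted
   against a permutation null, partitioned by sign (positive = enriched in
   active enhancers), greedily clustered by correlation of their
   hypothetical slices, and summarized as position weight matrices.
5. **Vetting** — information-content trimming (`IC = 2 + Σ p log₂ p`,
   keep the span above 0.3 bits), then a seven-criterion spurious-motif
   filter: composition bias < 80%, trimmed length > 4, stringent positions
   (IC > 1.9) < 75%, correspondence to a known-motif database
   (TOMTOM-style similarity with an empirical shuffle null), alignment
   overlap ≥ 70%, match q-value < 0.05 (Benjamini–Hochberg), and a 2-fold
   expression rule for the matched TF. An AME-style log-odds scan /
   Fisher-exact test quantifies enrichment, and motif-pair co-occurrence in
   the same enhancers is tested with a Fisher exact test.

A synthetic-data module generates all of the above's inputs with known
ground truth — labeled sequence sets with controlled GC content and
implanted motifs, a toy genome with planted peaks, a toy motif database and
expression table — so the whole pipeline is verifiable end to end on one
CPU. See `docs/methods.md` for models, defaults and design rationale.

## Worked example

```python
from emotifre.simulate import SimConfig, simulate_dataset, make_motif_db
from emotifre.model import Hyperparams, train
from emotifre.attribution import batch_attributions
from emotifre.discovery import discover_motifs
from emotifre.postprocess import trim_motif, match_known

# 2,000 active (GC 0.55, CAGCTGC implanted in 40%) vs 2,000 non-active (GC 0.45)
pos, neg, truth = simulate_dataset(SimConfig(seed=1))
model, report = train(pos, neg, Hyperparams(seed=1))
print(f"held-out AUROC {report.auroc:.3f}")

tracks = batch_attributions(model, pos[:300] + neg[:300], n_steps=128)
motifs = discover_motifs(tracks, seed=1)
top = next(m for m in motifs if m.importance_score > 0)
trimmed = trim_motif(top.pwm)
best = match_known(trimmed.pwm, make_motif_db(seed=0), seed=1)[0]
consensus = "".join("ACGT"[j] for j in trimmed.pwm.argmax(axis=1))
print(f"top positive motif {consensus}  ->  {best.name} (q={best.q_value:.4g})")
```

Output:

```
held-out AUROC 0.958
top positive motif GCAGCTGCC  ->  ASCL1 (q=0.0116)
```

The network separates the classes well above the 0.70 ceiling that motif
content alone would allow (the GC difference supplies the rest), and the
top positive-attribution motif recovers the implanted ASCL1-like core with
a significant database match. A label-shuffled control trains to AUROC
≈ 0.51, and on the two-motif AND task the network beats the linear baseline
by ≈ 0.45 AUROC — the co-occurrence signal is invisible to an affine map.

The same stages are exposed as a CLI for file-based inputs:

```bash
emotifre simulate --n-pos 2000 --n-neg 2000 --length 200 --seed 1 --out data/
emotifre train --pos data/positive.fa --neg data/negative.fa --seed 1 --out model.ckpt
emotifre attribute --model model.ckpt.npz --pos data/positive.fa --neg data/negative.fa --out attr.npz
emotifre discover --attr attr.npz --seed 1 --out motifs.meme
emotifre vet --motifs motifs.meme --db db.meme --expr expr.tsv --out verdicts.tsv
emotifre cooccur --table 6944 6744 3390 1608 --out cooccur.json
emotifre run --config run.yaml     # all stages, one seed, one manifest
```

The `cooccur` example reproduces a published motif co-occurrence analysis
from its printed marginal counts (18,686 active enhancers, 13,688 with an
ASCL1 site, 10,334 with a SOX4/11 site, 6,944 with both): the two-sided
Fisher exact test returns p ≈ 5 × 10⁻⁹⁸.

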