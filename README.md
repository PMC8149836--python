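# distmap-ema

Estimation of protein model accuracy (EMA) from predicted inter-residue
distance maps.

When a protein structure prediction pipeline produces a pool of candidate 3D
models for a target sequence, someone has to decide which model to trust —
without an experimental structure to compare against. This package
implements a CASP-style single/multi-model EMA pipeline for that problem:
it scores each model by comparing the model's own distance map (MDM) against
a distance map predicted from the sequence (PDM), and learns to regress
those comparisons onto GDT-TS ∈ [0, 1].

The feature set treats the two L×L distance maps both numerically and as
images:

- map agreement: Pearson correlation and RMSE of aligned entries
  (separation ≥ 6), contact recall (all-range and long-range), and top-⌈L/2⌉
  precision of pairs ranked by predicted distance;
- image similarity on a common 128×128 rendering (intensity
  255·(1 − min(d, 16)/16)): SSIM, PSNR, a 64-bit DCT perceptual hash, ORB
  keypoint matching, and a GIST-style Gabor descriptor;
- contact-match fractions for predicted contacts by CASP separation class
  (short 6–11, medium 12–23, long ≥ 24; 8 Å threshold);
- optionally, external per-model quality-score columns and a pairwise
  consensus score (mean pairwise GDT-TS against the pool).

The regressor is a K-fold ensemble of five-layer feed-forward networks
(ReLU hidden layers, logistic output, batch norm between dense layers 2 and
3, dropout 0.2 after layers 1 and 3), trained by target-grouped
cross-validation with early stopping; predictions either average the K
members or feed a stage-2 stacking network on [features ∥ K outputs].
Ranking quality is evaluated by per-target GDT-TS loss — true quality of
the best pool model minus true quality of the model ranked first — and
per-target Pearson correlation. Reference GDT-TS comes from a deterministic
LGA-like seeded-superposition heuristic (validated against an exhaustive
oracle at small sizes) and lDDT from its Cα variant.

A synthetic-data module generates everything the pipeline consumes — compact
self-avoiding Cα/Cβ natives, decoy pools of graded quality, noisy predicted
maps, contact lists, and surrogate external scores — so the whole system is
testable end to end without any external data or third-party programs.

## Worked example

```python
from distmap_ema.pipeline import run_end_to_end

result = run_end_to_end(seed=7, n_targets=6, decoys_per_target=30,
                        L=40, n_test_targets=2, epochs=40)
print("loss:", result.evaluation.overall_loss,
      "pearson:", result.evaluation.overall_pearson)
print(result.evaluation.per_target)
```

prints

```
loss: 0.012500000000000011 pearson: 0.9424022988745628
  target_id  category   loss   pearson
0   SYN0004  TBM-easy  0.000  0.948578
1   SYN0005        FM  0.025  0.936227
```

Six synthetic 40-residue targets with 30 decoys each are generated; a
two-stage `deep`-preset ensemble is trained on four of them and ranks the
pools of the two held-out targets. On the easy (low map-noise) target the
predictor picks the truly best decoy (loss 0.000); on the hard target the
chosen decoy's true GDT-TS is 0.025 below the best available, and predicted
scores correlate with true quality at r ≈ 0.94 on both pools.

The same pipeline is available from the shell:

```sh
distmap-ema simulate  --spec spec.json --out data/
distmap-ema featurize --target data/SYN0000/target.fasta \
    --models data/SYN0000/decoys --pdm data/SYN0000/pdm.txt \
    --rr data/SYN0000/contacts.rr --preset deep --out features.csv
distmap-ema score     --target data/SYN0000/target.fasta \
    --native data/SYN0000/native.pdb --models data/SYN0000/decoys \
    --out true_scores.csv
distmap-ema train     --features features.csv --labels data/true_scores.csv \
    --preset deep --seed 7 --out model/
distmap-ema predict   --model model/ --features features.csv --out pred.csv
distmap-ema evaluate  --true data/true_scores.csv --pred pred.csv \
    --categories data/categories.csv --out report.csv
```

Feature presets (`construct`, `cluster`, `ai`, `hybrid`, `deep`, `dist`)
select the feature subsets of six predictor configurations (multi-model and single-model variants); presets
that expect external-tool score columns degrade gracefully to their
computable subset when those columns are absent.

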