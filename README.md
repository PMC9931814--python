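# anevrix

Anatomically-informed, weakly-labeled 3D patch-based aneurysm detection,
exercisable end-to-end on synthetic vascular phantoms.

The package implements the full pipeline around a 3D encoder-decoder
segmentation network:

- **phantom** — seeded synthetic TOF-MRA-like cases (bright tubular vessels,
  spherical aneurysm bulges, bifurcation landmarks, patient metadata) and
  BIDS-like cohort writing, so every stage is testable without any download.
- **dataio** — NIfTI volumes with world-mm affines, validated YAML config,
  grouped (session-safe) k-fold splits.
- **preprocess** — cohort-median-spacing resampling, patch z-scoring.
- **annotate** — weak spherical labels, "weakening" of voxel-wise masks into
  enclosing spheres, mask geometry (centroid, 3D max diameter).
- **anatomy_prior** — landmark handling and the anatomically-informed patch
  sampler: 8 non-centred positives per lesion and 50 negatives per volume
  (20 landmark-centred / 20 vessel / 10 random), plus augmentation.
- **net** — a pure-NumPy 3D U-Net (conv + batch norm + ReLU encoder,
  upsample decoder with skip concatenations, sigmoid head) with manual
  backprop, Combo loss (weighted cross-entropy − smoothed Dice) and an Adam
  training loop. No GPU or deep-learning framework required.
- **infer** — sliding-window inference restricted to landmark-proximal,
  hyperintense windows (with an anatomy-agnostic fallback), 6-transform
  test-time augmentation, coverage-averaged probability maps, and top-5
  candidate extraction.
- **evaluate** — centre-of-mass-within-max-diameter hit criterion, FROC
  curves with per-subject AUC, Wilson intervals, exact/approximate Wilcoxon
  signed-rank, Pearson chi-squared.
- **phases** — partial PHASES scoring (size + location + age) and
  low/medium risk grouping with fusiform/extracranial exclusions.

## CLI

```sh
anevrix phantom    --n-subjects 5 --seed 1 --grid 96 --out cohort/
anevrix preprocess --in cohort/ --out resampled/
anevrix sample     --in cohort/ --out patches/ --seed 1 --side 64
anevrix train      --patches patches/ --config cfg.yaml --out model/
anevrix predict    --model model/checkpoint.npz --in cohort/ \
                   --agnostic-window --out pred/
anevrix evaluate   --candidates pred/candidates.tsv --truth cohort/ --out eval/
anevrix phases     --in aneurysms.tsv --out scored.tsv
anevrix run        --n-subjects 5 --k 5 --out cv/        # end-to-end CV
```

`anevrix run` performs a seeded, grouped 5-fold cross-validation on a
phantom cohort at toy scale; the ablation matrix is exposed as
`--anat-sampling/--no-anat-sampling`, `--anat-window/--no-anat-window` and
`--label-mode {weakened,voxelwise,mixed}`. Exit codes: 0 success,
2 validation error, 3 data error.

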