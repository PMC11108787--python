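# lctau

A reusable, tested analysis pipeline linking locus coeruleus (LC) MRI
integrity to tau-PET spread, cognition, ex vivo tangle staging and
regional transcriptomic similarity — with a synthetic-data generator for
every stage, so the full cascade runs and is verifiable at desk scale
without any restricted datasets.

## Modules

| Module | Purpose |
| --- | --- |
| `lctau.core_io` | NIfTI volumes (`BrainVolume`), schema-validated CSV/TSV tables, YAML config, seed derivation, run manifests |
| `lctau.synthetic` | Generators for cohorts (planted LC→tau slope, LC×Aβ interaction, mediated cognition path), LC slabs, ex vivo tangle tables, multi-donor expression data; each emits a machine-readable truth record |
| `lctau.lc_signal` | Per-slice contrast-ratio normalization, deterministic brightest-contiguous-5-voxel search (30 greedy restarts + swap refinement), hemisphere averaging and sign inversion (`intensity_r`) |
| `lctau.voxelwise` | Mass-univariate OLS (z-maps), nuisance residualization, interaction models, Monte-Carlo cluster-extent thresholds, 26-connected cluster extraction, forward-vs-reverse partial-correlation comparison |
| `lctau.effects` | PACC5 composite, Huber robust regression, Johnson–Neyman regions, percentile-bootstrap mediation, 2-component GMM amyloid cutoff |
| `lctau.staging` | Braak-conditioned two-step cutoffs, four-class concordance, Clopper–Pearson exact binomial CIs, Welch pairwise contrasts, partial Spearman correlations |
| `lctau.transcriptome` | Probe→gene aggregation, sample→region assignment (<3 mm rule), median-of-medians regional profiles, seed-region similarity with permutation null, top-5% gene-set intersections, risk-gene overlap probability |

## CLI

Every stage is exposed through the `lctau` entry point; global flags are
`--config` (YAML), `--seed` and `--out-dir`. All stochastic stages are
bit-reproducible under a fixed seed and write a manifest embedding the
config and seed used.

```bash
# generate a synthetic cohort with planted effects
lctau --seed 7 --out-dir sim simulate --kind cohort --spec cohort.yaml

# LC intensity from a slab + masks
lctau lc-signal --slab slab.nii.gz --lc-mask lc.nii.gz \
    --ref-mask ref.nii.gz --out lc.csv

# voxel-wise GLM with Monte-Carlo cluster correction
lctau --seed 7 --out-dir vw voxelwise --outcome-dir sim \
    --pattern 'tau_fu_*.nii.gz' --table sim/cohort.csv \
    --predictor intensity_r_bl --covars age,sex --mask sim/mask.nii.gz

# moderation and mediation
lctau --out-dir jn jn --table sim/cohort.csv --y mtl_tau_fu \
    --x intensity_r_bl --m pib_dvr
lctau --seed 7 --out-dir med mediate --table sim/cohort.csv \
    --x intensity_r_bl --m mtl_tau_fu --y pacc5_fu \
    --covars age,sex,educ,cdr --n-boot 5000

# ex vivo staging
lctau --out-dir st stage --table tangles.csv --region hippocampus \
    --braak-stage 3 --correlate hippocampus,entorhinal

# imaging transcriptomics
lctau --seed 7 --out-dir tx transcriptome --probes 'donor*_probes.tsv' \
    --probe-map probe_map.tsv --coords 'donor*_coords.tsv' \
    --atlas atlas.nii.gz --risk-genes risk.tsv --n-perm 10000
```

## Conventions

- Voxel indexing is 0-based; world coordinates are mm through the NIfTI
  affine; inter-volume operations require matching shape + affine (no
  resampling — registration is out of scope).
- Analyses use complete cases per model and log the dropped n.
- One root seed per run; per-stage generators are derived
  deterministically from it.
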