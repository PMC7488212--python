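# confield

Connective-field (CF) modeling and convergence analysis for retinotopic
visual cortex, with a fully synthetic forward model and exact
small-sample nonparametric inference.

A connective field predicts a target voxel's BOLD series as a gain times
a circular-Gaussian-weighted sum of source-area series, with the
Gaussian defined over geodesic distance on the source cortical surface
(center `v0`, size `sigma` in mm). The pipeline fits CFs in both
directions between V1 and extrastriate areas (V2d/V2v, V3d/V3v, hV4, LO,
TO), corrects fitted sizes for ipsilateral visual representations
("sampling extent"), summarizes them per area as variance-explained-
weighted medians over eccentricities 0.5-7.5 deg, and reduces the two
directions to a **convergence magnitude** (forward minus backward extent;
positive = convergence up the hierarchy). Per-subject convergence
profiles are regressed on hierarchy level (V1=0 ... TO=5.5) within the
full, dorsal, and ventral streams, and groups are compared with exact
Wilcoxon rank-sum / signed-rank tests with Bonferroni correction, plus a
bias-variable audit (goodness of fit, voxel counts, point-CF proportion,
eccentricity) with Spearman follow-ups.

Because no real scans ship with the package, the `synth` subpackage
generates everything the analysis consumes: flat triangulated cortical
patches with a log-eccentricity x polar-angle retinotopic chart, a
drifting-bar aperture movie (8 deg radius, 2 deg bar, 16 steps x 8
directions, 1.5 s steps), a pRF + double-gamma-HRF forward model for
stimulus runs, latent-field resting runs (TR 2 s, 240 volumes), and
group regimes with known ground-truth coupling widths (control: forward
minus backward width rising 1.61 mm/level; patient: flat with a V3d
offset).

## Layout

| module | contents |
|---|---|
| `confield.types` | mesh / labeling / retinotopy / time-series containers |
| `confield.synth` | patches, stimulus movie, pRF drive, HRF, ground truth, run simulators |
| `confield.preprocess` | linear detrend (stimulus), zero-phase 0.01-0.1 Hz band-pass (rest) |
| `confield.cf_model` | geodesic distances, sigma grid, CF weights, exhaustive fitting, sampling extent |
| `confield.convergence` | voxel selection, weighted medians, convergence records, hierarchy slopes, bias audit |
| `confield.stats` | exact rank-sum / signed-rank nulls (DP), Bonferroni, Spearman |
| `confield.io_cli` | TSV/OBJ formats, run configuration, end-to-end pipeline, CLI |

## CLI

```sh
confield simulate --group control --condition stimulus --seed 1 --out data/
confield preprocess --data data/ --condition stimulus
confield fit --data data/ --source V1 --target V3d --direction both \
    --condition stimulus --out fits.tsv
confield analyze --data data/ --condition stimulus --out results/
confield stats --design slope_vs_zero --input slopes.tsv --correction 3
confield run-all --seed 1 --out results/     # full synthetic cohort
confield report --results results/
```

`run-all` simulates an 8-control / 6-patient cohort, runs the full
analysis, and writes `summaries.tsv`, `convergence.tsv`, `slopes.tsv`,
`tests.tsv`, `bias_audit.tsv`, a human-readable `report.txt`
(median +/- bootstrap SE of the median), and `provenance.json` (config
hash, seed, versions). Reruns with the same config are byte-identical.

## Conventions worth knowing

- Two-sided exact p-values are twice the smaller tail, capped at 1; ties
  switch to midranks with a seeded Monte-Carlo permutation null.
- The sigma search grid is `{0.0001} U {0.2k : k=1..50}` mm; fits with
  `sigma <= 0.0001` ("point CFs", one-on-one connections) are excluded
  from the extent summaries; the VE inclusion threshold is `>= 0.20`.
- The weighted median is the lower weighted median (no interpolation).
- Geodesics are shortest paths on the mesh edge graph with Euclidean
  edge lengths, cached per (mesh hash, ROI).
- Composite V2/V3 results pool the dorsal/ventral fits (as targets: the
  union of rows; as sources: the higher-VE sub-fit per target voxel).
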