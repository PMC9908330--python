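# rssm — region-based statistical shape modeling of bone surfaces

`rssm` builds linear statistical shape models (SSMs) of a bone from a
cohort of triangulated surface meshes and compares the classical
whole-surface model (**nrSSM**) with a **region-based** variant (**rSSM**)
in which independent models are fit per surface region, the regions being
found automatically from the sign of the discrete Gaussian curvature
(convex/concave caps vs. saddle transitions). It is aimed at
morphometrics work on small bones — the motivating case is the first
metacarpal and its osteoarthritis-prone trapeziometacarpal joint — where
localized shape features (head torsion, shaft bending, width) matter more
than a single global decomposition.

The core model over corresponded, rigidly aligned surfaces with shared
vertices is

    x = x̄ + Σᵢ wᵢ Φᵢ

with `x ∈ R^{3V}` a flattened vertex-coordinate vector (mm), `x̄` the mean
shape, `Φᵢ` orthonormal PCA modes with variances `λᵢ`, and at most `n − 1`
modes for `n` training shapes. Shapes at `wᵢ = ±2√λᵢ` are the ±2SD models
used to visualize each mode. The pipeline around the model:

1. **template selection** — all-pairs rigid coherent point drift (CPD);
   the subject with the lowest mean RMS nearest-point distance to the rest
   becomes the template;
2. **dense correspondence** — rigid CPD of the template onto each subject,
   then closest-point projection of template vertices onto the subject
   surface (identity for cohorts that already share connectivity);
3. **alignment** — rigid-only generalized Procrustes (no scaling anywhere,
   so size stays in the data and can dominate PC1);
4. **regions** — angle-deficit Gaussian curvature on the template,
   smoothed, split by sign, speckle-cleaned, transferred to all subjects
   by correspondence;
5. **models** — PCA per region (rSSM) and globally (nrSSM); ±2SD shape
   synthesis, per-vertex distance maps, cumulative-variance and curvature
   comparisons between the two model families.

Because no CT cohort ships with the package, a first-class synthetic
generator produces metacarpal-like cohorts with four known latent modes
(size, shaft width, distal-head torsion, shaft bending), vertex noise and
rigid misalignment; its ground truth drives the recovery tests. See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
from rssm import PipelineConfig, PopulationConfig, run_pipeline

config = PipelineConfig(synthetic=PopulationConfig())   # 31 subjects
report, extras = run_pipeline(config, out_dir="out")
print(report.cumulative_variance.head(6).to_string(index=False))
```

```
 n_components  nrssm_cumulative_pct  rssm_cumulative_pct
            1             78.331259            41.853065
            2             91.072713            79.006035
            3             96.691415            85.175952
            4             99.092932            91.091824
            5             99.138108            94.163852
            6             99.182083            96.752480
```

Reading it: the nrSSM's first component carries 78% of
the cohort variance — the size mode dominates, as expected when no
scaling normalization is applied — while the rSSM splits the same
variance across more, regionally confined components (41.9% for its first
pooled mode) and both models exceed 80% cumulative variance within a few
components. `out/` contains the mean and ±2SD meshes per mode (PLY), the
distance-map and curvature comparison tables (CSV), the template's
curvature labels, and `report.json` with provenance; the log reports the
selected template (subject 19, mean RMS 0.69 mm for the default cohort).

The same run from the shell:

```sh
rssm run --config config.yaml --out out/
rssm simulate --config pop.yaml --out cohort/   # cohort PLYs + weights
rssm curvature cohort/subject000.ply            # per-vertex κ summary
rssm compare --model-dir out/                   # cumulative-variance table
```

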