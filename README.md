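# toothssm

Statistical shape modelling (SSM) of tooth surface meshes that carry a
binary enamel/dentin surface material label.

The pipeline takes a cohort of triangulated whole-tooth meshes (plus
matching enamel-only meshes), rigidly aligns and elastically registers a
baseline mesh onto every specimen so all teeth share connectivity, runs
correlation-method PCA over the combined geometry + material vectors,
generates synthetic instances (σ sweeps of individual principal
components), extracts the cemento-enamel junction (CEJ) as a material
boundary curve, places ten anatomical landmarks automatically, computes
the standard odontometric measurements, and compares specimen groups with
regression and one-way ANOVA + Tukey HSD statistics. A parametric
synthetic-tooth generator with known modes of variation provides test
data and ground truth throughout.

## Layout

| module | contents |
| --- | --- |
| `toothssm.mesh` | `SurfaceMesh`, area/volume, exact nearest-neighbour search, face adjacency, load-time cleaning |
| `toothssm.io` | PLY (ASCII + binary), STL (ASCII + binary), OFF readers/writers; per-vertex `material` PLY property |
| `toothssm.synth` | parametric canine-like generator (`ToothParams`), seeded populations with population-level modes (`PopulationSpec`) |
| `toothssm.align` | per-axis bounding-box scaling, centroid alignment, Euler coarse transforms, point-to-point ICP, `align_chain` |
| `toothssm.elastic` | Laplacian smoothing, elastic template morphing, two-pass registration, enamel-label transfer |
| `toothssm.model` | correlation-method PCA (`fit_model`), instance generation, projection, variance report, σ sweeps, reconstruction-error test |
| `toothssm.cej` | binarisation (I ≥ 0.5), element-level material smoothing, CEJ loop extraction |
| `toothssm.landmarks` | the 10 automated landmarks, 8 measurements, per-PC measurement sweeps |
| `toothssm.stats` | Bland–Altman, OLS regression t-test, one-way ANOVA + Tukey HSD, boxplot statistics |
| `toothssm.pipeline` / `toothssm.cli` | config-driven orchestration of the 9 stages |

## CLI

Each pipeline stage is a subcommand; `all` runs them in order
(`synth → align → register → fit → sweep → cej → landmarks → measure → stats`):

```sh
toothssm all --config config.yaml
toothssm -vv synth --out run1 --seed 3     # verbose, stage by stage
toothssm register --config config.yaml
```

A minimal config:

```yaml
outdir: run1
seed: 3
synth:
  groups:
    - {name: MH, n: 9}
    - {name: GC, n: 13}
    - {name: HQ, n: 5}
  param_cv: 0.04
  scale_cv: 0.08
  noise_amplitude: 0.03
  resolution: [36, 42]
pca: {cumulative_target: 0.75}
```

To run on your own data instead of synthetic teeth, point `manifest` at a
CSV with columns `id, group, whole_mesh, enamel_mesh` and omit the
`synth` section. Outputs land under `outdir`: a manifest, per-specimen
registered PLYs with material labels, the PCA model, sweep measurement
tables, CEJ curves (JSON), landmark and measurement CSVs, and statistics
(per-PC regression table, ANOVA/Tukey JSON, Bland–Altman summary).

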