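# tmsnet

Coil-grid TMS electric-field simulation and resting-state functional-network
targeting on synthetic folded cortical surfaces.

The package implements the full targeting pipeline desk-scale and
download-free:

1. **surface** — synthetic folded cortical patches with species profiles
   (large multi-gyral "human-like", small single-dominant-gyrus
   "macaque-like"), band/patch network parcellations (7 networks +
   unassigned), and nearest-point value transfer onto vertices.
2. **efield** — a 6×6 stimulation grid (10 mm human / 5 mm macaque spacing)
   × 12 coil orientations (15° steps over a half circle) = 432 placements;
   free-space primary fields of a discretized figure-8 coil
   (|E| = |dA/dt| summed over straight segments); the electric field
   stimulation index (EFSI: per vertex, the percentage of simulations in
   which it exceeds half that simulation's maximum).
3. **fmri** — synthetic resting-state runs with planted network covariance
   (one AR(1) latent per network plus i.i.d. noise) and an optional hard
   spectral band-pass (0.01–0.1 Hz defaults).
4. **connectivity** — half-max seed regions with field-derived weights, a
   weighted-average seed series per placement, and whole-surface partial
   correlations controlling for the grand mean of all placements' seed
   series.
5. **assignment** — top-1% sparsification, binarized network-overlap
   profiles, argmax network assignment, 3×3 zones (Z1–Z9, four locations
   each) and 45° orientation windows (W1–W4), and group frequency summaries.
6. **pipeline / CLI** — YAML-configured, seed-deterministic orchestration
   with composable stage commands and TSV/PLY/JSON artifacts.

**Field-model caveat:** the field engine is the free-space *primary* field
only — no tissue conductivities, no FEM. It preserves the proximity physics
(gyral crowns nearer the coil receive stronger fields), which is what the
downstream analysis consumes. Results on synthetic surfaces are qualitative
stand-ins, not subject-level predictions.

## CLI

```bash
# full synthetic experiment, all artifacts into out/run1
tmsnet run --out out/run1 --seed 7
tmsnet run --config my.yaml --out out/run2

# the same run composed from stages (byte-identical outputs)
tmsnet simulate-surface --out work
tmsnet simulate-fields  --mesh work/mesh.ply --out work
tmsnet simulate-fmri    --parcellation work/parcellation.tsv --out work
tmsnet connectivity     --fields work/fields.tsv --timeseries work/timeseries.tsv --out work
tmsnet assign           --connectivity work/connectivity.tsv --parcellation work/parcellation.tsv --out work
tmsnet summarize        --results work/results.tsv --out work
tmsnet efsi             --fields work/fields.tsv --out work
```

Every command accepts `--config`, `--seed` (overrides the config seed),
`--out`, and `--log-level`. Config files are flat YAML mappings of
`RunConfig` keys (unknown keys are rejected); defaults carry the pipeline
constants: seed threshold 0.5, sparsity 0.01, EFSI threshold 0.5, 35 mm coil
radius, 64 segments per loop.

Key artifacts: `mesh.ply`, `parcellation.tsv` (vertex_index, label),
`placements.tsv` (row, col, theta_deg, x, y, z), `fields.tsv` /
`connectivity.tsv` (vertex × placement matrices), `results.tsv` (one row per
configuration with all overlap percentages, assigned network, zone, window),
`summary_*.tsv`, `efsi.tsv`, `efsi_per_map.tsv`, and `provenance.json`
(config + seed + version; sufficient to reproduce the run byte-for-byte).

## Library use

```python
import tmsnet as tn

profile = tn.human_profile()
mesh = tn.make_folded_sheet(profile, resolution=0.4, seed=0)
parc = tn.make_parcellation(mesh, "human-default")
placements = tn.build_grid(profile, mesh)          # 432 placements
field = tn.primary_efield(tn.CoilModel(), placements[0], mesh)
seed = tn.extract_seed(field)                      # >50%-of-max, weighted
```

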