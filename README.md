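# tumourmeter

Tools for studying how subcutaneous tumour volume measurements go wrong —
and what that does to preclinical efficacy readouts.

The package has three legs:

1. **A stochastic cellular-automaton tumour simulator** (`tumourmeter.ca`).
   Two cell populations grow on a 3D voxel lattice resting on the body wall,
   with per-day division probability `p_divi`, an upward growth bias, and a
   treatment window in which cells die with probability `lam`. Six seeding
   presets produce the characteristic morphologies of subcutaneous tumours:
   `one_peak`, `two_peak`, `three_peak`, `igloo` (needle-trail tail),
   `birthday_cake` (aggressive sub-clone) and `volcano` (ulcerating crater).
2. **Virtual measurement** (`tumourmeter.measure`). A voxel tumour is
   measured the way a calliper would measure it — maximal feret length of
   the footprint, perpendicular width, vertical height, footprint area —
   and converted to volume by the spheroid formula `(π/6)·l·w²`, the
   cylindrical formula `area·height`, or the ellipsoid formula
   `(π/6)·l·w·h`. Comparing these estimates against the exact voxel count
   (ground truth) quantifies the bias of calliper practice per morphology.
3. **Efficacy and agreement statistics** (`tumourmeter.efficacy`,
   `tumourmeter.repeatability`). TGI and AUC treatment-efficacy indices on
   paired control/treated ensembles; inter-operator CV precision points and
   banding; ICC(2,1) stratified by operator count; Bland–Altman
   volume-vs-weight agreement; relative-error banding; same-day
   scan-vs-calliper consistency counts; one-sided Welch t-tests with Holm
   adjustment.

`tumourmeter.data_io` reads arbitrary measurement CSVs through editable
schema maps and ships a synthetic multi-operator record generator with
controlled variance components, so every statistic is testable against
analytic oracles without access to proprietary data.

## Command line

```bash
# growth curves (exact + virtual-calliper volumes), tidy CSV
tumourmeter simulate --morphology one_peak --p-divi 0.1 --bias 1.0 \
    --lam 0.4 --lam-len 10 --treatment-start 15 --days 30 \
    --replicates 1000 --seed 42 --out out/curves.csv

# TGI / AUC efficacy samples for a paired control-treated ensemble
tumourmeter efficacy --config sim.yaml --replicates 200 \
    --eval-days 18,24,30 --out out/samples.csv

# one-at-a-time parameter sensitivity scan
tumourmeter sensitivity --config sim.yaml --grid grid.yaml \
    --replicates 50 --out out/scan.csv

# agreement statistics for a measurement records CSV
tumourmeter repeatability --input records.csv --schema canonical \
    --volume-formula eq1 --threshold 0.2 --report out/

# synthetic multi-operator records + latent truth table
tumourmeter synth --config gen.yaml --out records.csv --truth truth.csv --seed 7

# figure-style summary tables from a results directory
tumourmeter report --results out/ --out report/
```

`sim.yaml` mirrors the `SimulationParams` field names
(`morphology`, `p_divi`, `bias`, `lam`, `lam_len`, `treatment_start`,
`total_days`, `dims`, `voxel_edge`, `seed`, …); `grid.yaml` maps a
parameter name to a list of values. Every subcommand writes a
`manifest.json` (config hash, seeds, package version, input digests)
beside its outputs, and identical configs + seeds reproduce byte-identical
CSVs. Exit codes: 0 success, 2 configuration error, 3 data error,
4 runtime error.

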