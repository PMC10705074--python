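# oartsim

Synthetic-phantom study of how **adaptation time** — the interval between the
anatomy a radiotherapy plan is adapted on and the moment it is delivered —
degrades target coverage in online adaptive bladder radiotherapy (oART).

During an oART session the bladder keeps filling while the plan is being
re-optimized. The clinical target volume (CTV), a patch on the bladder wall,
drifts with the wall; by delivery time parts of it may have left the planned
high-dose region. `oartsim` generates deformable digital phantoms of this
process, models the intra-session motion with a time-scaled surface
displacement field, and quantifies the dosimetric cost with equivalent
uniform dose statistics.

## What the package does

- **phantom** — seeded generator of patient-like treatment series: ellipsoidal
  bladders with linear filling, a wall-patch CTV, per-fraction adaptation
  times from a bounded lognormal, and a default 9-series cohort containing
  both time-sensitive (small, fast-filling) and time-insensitive (large,
  slow-filling) series. Ground-truth displacement fields are available in
  closed form.
- **geometry** — voxel structures with subvoxel-corrected contract/expand
  (margin) operators, margin sweeps, Dice, directed Hausdorff, and an
  adjusted local Hausdorff that removes global filling from local wall
  deformation.
- **deformation** — star-shape surface correspondence between two structures
  (optionally steered by substructure pairs), the cube-root time-scaling
  factor K(t) that interpolates the displacement field for linearly growing
  volume, field composition, scaling, and mask propagation.
- **dosimetry** — synthetic adapted dose (full prescription inside the PTV,
  Gaussian penumbra outside), log-domain gEUD/nEUD (default order a = −20),
  DVHs, dose warping and multi-fraction accumulation.
- **stats** — rank-scaled ANCOVA for per-series nEUD-vs-time trends and
  sensitivity classification, repeated-measures slopes, order-statistic
  percentile CIs, Kruskal–Wallis contrasts, a logistic time/margin model for
  coverage loss, delta-method margin compensation (mm of margin per minute of
  adaptation time) and maximum safe adaptation times.
- **pipeline** — end-to-end experiment: per-fraction nEUD at the adaptation
  time and at fixed model times, accumulated nEUD over a PTV-margin sweep,
  trend/group/logistic analyses, and CSV/JSON/SVG reports.

## Usage

Command line (`oartsim` or `python -m oartsim.cli`):

```bash
# write the cohort's structures/doses/times as NIfTI + JSON
oartsim generate --seed 1 --spacing 2 --n-fractions 4 --out cohort/

# per-fraction nEUD table only
oartsim analyze --seed 1 --spacing 2 --n-fractions 4 --out results/

# full experiment with accumulation sweep, fits and figures
oartsim report --seed 1 --spacing 2 --n-fractions 4 --out results/ --plots
```

A YAML/JSON file passed via `--config` can override any `ExperimentConfig`
field. Python API:

```python
from oartsim.pipeline import ExperimentConfig, run_experiment

report = run_experiment(ExperimentConfig(seed=1, spacing=2.0, n_fractions=4))
print(report.time_group_summary)
print(report.margin_compensation_mm)
```

## Tests and acceptance run

```bash
python -m pytest -o addopts= -p no:cacheprovider          # full suite
python scripts/acceptance.py --seed 1 --out acceptance.json
```

`tests/test_acceptance.py` holds the end-to-end guarantees (worked examples,
closed-form oracles, statistical recovery, cohort-structure reproduction over
20 seeds); the other test modules are unit/property tests per module.
`scripts/acceptance.py` writes the main computed quantities of a seeded run
to JSON.

See `docs/methods.md` for the modeling and statistical methods.
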