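# spinedyn

Analysis of longitudinal dendritic-spine dynamics from chronic two-photon
imaging, plus SWC-based Sholl morphometry of astrocyte arbors.

In chronic in vivo imaging experiments the same dendritic segments are
re-imaged over days to weeks and every protrusion is scored at each session
as `present`, `absent`, or `filopodia`. `spinedyn` consumes those
annotations (it does not touch pixels) and computes the standard
structural-plasticity statistics:

- **Turnover ratio** between two sessions,
  `TO = (N_elim + N_form) / (N_elim + N_form + 2·N_stable)`,
  0 for a static dendrite and 1 for complete replacement.
- **Filopodial fraction**: the proportion of day-0 features scored as
  filopodia, and per-group **morphology fractions**
  (mushroom / intermediate / filopodia).
- **Survival curves** `S(t)` — the fraction of day-0 spines consistently
  present at every session up to `t` — and pooled fits of the
  single-phase exponential decay model
  `S(t) = Sp + Si·exp(−t/τ)`,
  where `Sp` is the permanent-spine fraction, `Si` the impermanent
  fraction and `τ` the characteristic lifetime (days) of impermanent
  spines.
- **Stable / recurrent / transient classification** of day-0 spines
  (never absent / absent then seen again / absent for good).
- **Extra sum-of-squares F test** comparing nested decay fits between
  groups (shared parameters vs separate parameters per genotype).
- **Sholl analysis** of SWC tracings: intersections with concentric
  shells around the soma, primary-branch count, longest-tree length and
  total process length.
- **Spine density** (spines per µm of dendrite).

A synthetic spine-kinetics simulator generates cohorts with known ground
truth (two-population spine pool, exponential lifetimes, filopodia with
elevated turnover, Poisson formation, optional recurrence and observer
misses) for validation and power analysis.

## Worked example

Simulate a two-genotype adult cohort (7 wild-type mice with permanent
fraction 0.71 vs 5 knockout mice with 0.79, 250 day-0 features each, the
standard 0/1/2/7/14/21/28/42-day schedule) and run the full analysis:

```bash
cat > demo.json <<'JSON'
{
  "simulation": {
    "WT":  {"n_mice": 7, "n_features0": 250, "permanent_fraction": 0.71,
            "impermanent_lifetime_days": 7.0, "recurrence_prob": 0.2},
    "CKO": {"n_mice": 5, "n_features0": 250, "permanent_fraction": 0.79,
            "impermanent_lifetime_days": 7.0, "recurrence_prob": 0.1,
            "filopodia_fraction0": 0.12}
  },
  "seed": 7
}
JSON
spinedyn run --config demo.json --out demo_out
```

`demo_out/` then contains the simulated track table, per-mouse turnover
(both filopodia-inclusion modes), filopodial fractions, survival curves,
stability classes, decay fits in both intercept modes, the genotype
comparison, and a manifest (seed + config hash) from which every number
is reproducible. With seed 7 the fitted decay models are

```
WT   Sp = 0.704   Si = 0.293   tau = 7.31 d
CKO  Sp = 0.776   Si = 0.224   tau = 7.75 d
F = 29.17, df = (3, 90), p = 2.9e-13
```

i.e. the fit recovers the simulated permanent fractions (0.71 / 0.79)
within sampling error and the nested-model comparison separates the
genotypes decisively. The per-genotype mean 0→7-day turnover ratios are
0.158 (WT) and 0.139 (CKO), and the stability-class fractions show the
knockout's higher stability arising mostly from fewer recurrent spines
(recurrent fraction 0.057 WT vs 0.015 CKO; transient fractions 0.236 vs
0.207).

The same subcommands work on real annotation tables (`spinedyn turnover
--in tracks.csv --sessions 0,2 ...`, `spinedyn compare --group-a WT
--group-b CKO ...`); the expected CSV schema is one row per feature per
session with columns `mouse_id, genotype, age_group, dendrite_id,
feature_id, session_day, status, x_um, y_um, z_um`.

Sholl morphometry runs on standard SWC files:

```bash
spinedyn sholl --swc cell.swc --step 10 --mode 3d --out profile.csv
```

which writes the intersections-per-radius profile to `profile.csv` and
prints the scalar metrics; on a synthetic 5-primary test arbor
(`generate_tree(TreeGenParams(n_primaries=5), seed=2)`):

```
{"primary_branches": 5, "total_length_um": 737.52, "longest_tree_um": 348.41, "sholl_auc": 560.0}
```

## Library use

```python
from spinedyn import (SimulationConfig, simulate_cohort, survival_curve,
                      fit_decay, extra_sum_of_squares_f)

cfg = SimulationConfig(n_mice=7, permanent_fraction=0.71)
curves = [survival_curve(ds) for ds in simulate_cohort({"WT": cfg}, seed=1)]
fit = fit_decay(curves)            # -> Sp, Si, tau, ss, df
```

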