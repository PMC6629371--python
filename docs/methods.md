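# Methods

## Data model

The unit of analysis is the animal. A `MouseDataset` holds one mouse's
genotype and age labels, its imaging schedule (integer days from the
first session, day 0 first, e.g. `0, 1, 2, 7, 14, 21, 28, 42` for the
adult six-week protocol and `0, 1, 2` for juveniles), and its dendrites'
`FeatureTrack`s. A track stores one protrusion's status — `present`,
`absent` or `filopodia` — at *every* scheduled day, plus optional (x, y,
z) µm coordinates. Missing session entries are a validation error, never
imputed: the scoring protocol forces an explicit call per timepoint.
Coordinates are carried for fidelity and future matching but are unused
by the statistics. Tables are tidy long-format CSV (one row per feature
per session), which survives ragged schedules without schema changes.
Validation warns when fewer than 150 day-0 features are present, the
conventional per-animal minimum for this assay (typical studies analyse
250–300).

## Turnover ratio

Between two scheduled sessions *a* < *b*, over features non-absent at
*a* or *b*:

    TO = (N_elim + N_form) / (N_elim + N_form + 2 N_stable)

with stable = present at both, eliminated = present→absent, formed =
absent→present. Counts are summed over all of a mouse's dendrites before
the ratio is formed (not averaged per dendrite); group summaries average
per-mouse ratios, keeping the animal as the statistical unit. A zero
denominator yields a flagged undefined ratio.

**Filopodia.** Presence/absence scoring covers all protrusions, but
turnover is conventionally reported for spines. By default a feature
scored `filopodia` at either session matches none of the three
categories (it is neither strictly present nor absent), which excludes
filopodia-scored observations from the counts; `include_filopodia=True`
instead treats filopodia as present, counting all protrusions. Published
protocols are ambiguous here, so the pipeline reports both modes.

## Survival and the decay model

For each mouse, `S(t)` = fraction of day-0 spines consistently present
at every session up to `t`; `S(0) = 1` by construction and `S` is
non-increasing. Once a spine has been scored absent it never counts as
surviving again, even if it reappears later — the single most
error-prone reading of "consistently present", stated here explicitly.
Day-0 filopodia are excluded from the day-0 denominator by default (the
survival analysis concerns spines); at later sessions any non-absent
status counts as surviving, since presence scoring covers all
protrusions.

Per-mouse curves are pooled by group — by default every per-mouse
(t, S) point is concatenated with equal weight — and fit by bounded
least squares (SciPy trust-region reflective) to

    S(t) = Sp + Si · exp(−t/τ),   Sp, Si ∈ [0, 1],  τ ∈ (0, 10·t_max]

Two intercept modes are first-class, because commercial one-phase-decay
fits may or may not pin the intercept: the default fits all three
parameters; `constrain_s0=True` sets `Si = 1 − Sp` (S(0) = 1 holds by
construction of the curves). Initialisation is multi-start
(`Sp₀ = min S`, `Si₀ = 1 − Sp₀`, `τ₀ ∈ {t_max/4, t_max/2, t_max}`); the
lowest residual sum of squares wins, with a relative acceptance
tolerance of 1e-8 between starts. Degenerate inputs (all S equal, e.g.
S ≡ 1) make τ unidentifiable and raise an error rather than returning a
boundary artefact. Alternative poolings are available behind flags:
`weight_by_n` weights points by √(day-0 spine count), `pool_mode="mean"`
fits the across-mouse mean curve.

Day-0 spines are also partitioned into **stable** (never absent),
**recurrent** (absent, then seen again) and **transient** (absent for
good); the three counts always partition the day-0 set. Classification
requires ≥ 3 sessions, since recurrence needs a reappearance
opportunity. Spines formed after day 0 never enter survival or
classification.

## Group comparison

Groups are compared with the extra sum-of-squares F test for nested
nonlinear models. Null model: one shared (Sp, Si, τ) fit to both groups'
pooled points. Alternative: separate fits, `ss_alt = ss_A + ss_B`,
`df_alt = df_A + df_B`. Then

    F = ((ss_null − ss_alt) / (df_null − df_alt)) / (ss_alt / df_alt)

with the upper-tail p-value from F(df_null − df_alt, df_alt). A perfect
alternative fit (`ss_alt = 0`) is reported as F = ∞, p = 0 with a
degeneracy flag; a marginally negative SS improvement from numerical
noise is clipped to zero.

**Calibration caveat (known limitation).** The F test assumes iid
residuals, but a mouse's survival points are strongly positively
correlated across time: S(t₂) counts a subset of the spines counted by
S(t₁), giving corr = √(S₂(1−S₁)/(S₁(1−S₂))) ≈ 0.5–0.8 on the adult
schedule, independent of spine count. Pooling eight correlated points
per mouse therefore overstates the effective sample size and the test
is anticonservative: in Monte-Carlo cohorts simulated with identical
parameters for both groups (7 vs 5 mice, 250 spines) the rejection rate
at α = 0.05 is ≈ 0.3, not 0.05. `spinedyn` implements the procedure as
practised (it is what standard curve-fitting software computes), and
`scripts/acceptance.py` measures and reports the type-I rate honestly;
p-values from this test on pooled survival points should be read as
descriptive, not as calibrated error rates. Power is correspondingly
high: permanent-fraction differences of 0.08 at this scale are detected
essentially always.

## Synthetic spine kinetics

The simulator is the generative inverse of the decay model, with known
ground truth for recovery tests. Per mouse:

- **Day-0 features** (`n_features0`, default 250 — a typical per-animal
  count): filopodia with probability `filopodia_fraction0`, otherwise
  spines.
- **Day-0 spines** are permanent with probability `Sp` or draw an
  Exponential(τ) lifetime. The death clock is continuous and censored to
  the schedule: a spine dying on day 9 is last seen on day 7. Hence the
  exact closed form E[S(t)] = Sp + (1−Sp)e^(−t/τ) at scheduled days,
  used by the acceptance checks.
- **Recurrence**: with probability `recurrence_prob` a disappeared
  impermanent spine reappears at the next scheduled session after a
  one-session gap, then lives a fresh Exponential(τ) lifetime anchored
  at the reappearance day; at most one recurrence per spine, keeping the
  recurrent class well defined.
- **Filopodia** survive session-to-session independently with
  probability `filopodia_session_survival` (default 0.5 — filopodia turn
  over much faster than spines) and do not recur.
- **Formation**: new features between consecutive sessions are
  Poisson(λ·Δt·n₀/100), first observed at the later session, then
  subject to the same permanent/exponential law anchored at that day.
  The literature provides no nascent-protrusion survival model, so the
  simplest consistent choice is made. Formed features contribute to
  turnover but never to survival/classification.
- **Observation noise**: each truly non-absent observation is flipped to
  absent independently with probability `miss_prob` (default 0). This
  models observer misses and lets tests demonstrate that miss noise
  inflates the recurrent class; it is a tool, not an empirical claim.
- Optional mouse-level heterogeneity: per-mouse Sp ~ Beta with mean `Sp`
  and configurable concentration, off by default.

Features that end up absent at every session are dropped (they were
never observed). All randomness flows from one seed (NumPy
`SeedSequence` spawning per mouse), making cohorts byte-reproducible
through the CSV writer.

**Defaults as study conditions.** The adult default (Sp = 0.75, τ = 7 d,
f₀ = 0.15, λ = 2) sits between the two genotypes' reported adult
permanent fractions and matches the adult filopodial fraction scale. The
juvenile preset (Sp = 0.5, τ = 10 d, f₀ = 0.25, λ = 8) was set from the
closed-form expected two-day turnover: with 25% day-0 filopodia excluded
from the counts, E[N_elim] ≈ 17 and observed E[N_form] ≈ 4.9·λ per 250
features, so λ ≈ 8 puts E[TO(0,2)] ≈ 0.14, the juvenile wild-type
magnitude. λ is otherwise unconstrained by published estimates. Segment
lengths are set from a nominal density (default 0.6 spines/µm) so
simulated densities fall in the physiological 0.3–1.0 /µm range.

**What the simulator does not emulate:** spatial structure (positions
are decorative), spine-size/morphology dynamics, conversion of filopodia
into spines, drift or registration failure across sessions, and
correlated scoring errors. Passing recovery tests therefore shows the
estimators are correct under the model's assumptions, not that real
imaging data satisfy those assumptions.

## Sholl analysis and tree metrics

SWC tracings are validated (exactly one root, no dangling parents, no
cycles); multi-point soma contours are not modelled — the root node is
the soma centre. For shells of radius r = k·step (default step 10 µm,
matching typical published radial granularity) the crossing count of
each straight segment is exact: 1 if its endpoint distances straddle r,
2 if both endpoints are outside but the closest approach dips inside
(distance along a straight segment from a fixed point is convex), else
0. A crossing exactly on a node is counted by neither adjacent segment
(strict inequalities; measure zero for real tracings). The profile runs
to the first radius beyond the arbor's maximal extent. 3D spheres are
the default; a 2D XY-projection mode covers effectively planar
brightfield tracings, and the two agree exactly for planar traces.

Primary branches = children of the root. One "tree" per primary branch:
the subtree including the root-to-child segment; total length is the
sum over all segments, longest-tree length the maximal per-tree sum
(common tracing-software convention), with a longest *path* variant
behind a flag since published wording does not distinguish the two.

A branching-process tree generator (primaries, branch probability,
segment-length range, max order) provides ground-truth totals for
oracle tests; Sholl counting is additionally verified against a
dense-sampling oracle (0.01 µm sampling, sign-change counting).

## Pipeline and reproducibility

`spinedyn run` executes simulate/load → turnover (both filopodia modes)
→ filopodial fractions → survival curves → classification → decay fits
(both intercept modes) → pairwise genotype F tests, writing plain CSV
tables plus one JSON summary and a manifest (package version, seed, full
config, config hash). Identical config + seed reproduce byte-identical
outputs; logs go to stderr only. Downstream group statistics (t tests,
ANOVA) are deliberately left to general-purpose tools on the exported
tables.

**Problem sizes.** The validation suite uses 50-mouse cohorts of 300
spines for parameter recovery, 1000 Monte-Carlo replicates at the
realistic study scale (7 vs 5 mice, 250 features) for the F-test type-I
rate and 200 for power, 100 random trees for the Sholl oracle, and
exhaustive-plus-randomised status matrices (≤ 10 spines × ≤ 5 sessions)
for the survival/classification oracle — sizes at which the Monte-Carlo
standard errors are small relative to every tolerance asserted.

## Known limitations

- The F-test anticalibration described above: between-group inference on
  pooled survival points inherits the iid assumption's failure. A
  mouse-level resampling or mixed-model approach would be calibrated but
  is a different method and out of scope.
- No automatic identity matching of features across sessions from
  coordinates; the data model stores positions but trusts the curator's
  feature ids.
- Survival analysis ignores censoring structure beyond the fixed
  schedule (no Kaplan–Meier machinery); this mirrors the pooled
  decay-fit practice it implements.
- Morphology classes are consumed as given (human scoring), never
  inferred from images.
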