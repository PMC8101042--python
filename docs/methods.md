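# Methods

## The analysis

The unit of replication is the observation session: one focal animal
followed for `scans_per_session` instantaneous scans (defaults 15 scans at
60 s). At every scan five behaviours are recorded — focal, nearest,
second-nearest and third-nearest neighbour (re-ranked per scan), and a
control drawn uniformly at random, per scan, from the remaining eligible
animals. The per-session synchrony count for a comparison role is the
number of scans at which that animal matched the focal, under either the
strict (exact ethogram category) or dichotomous (Active/Inactive)
classification. A strict match implies a dichotomous match, so dichotomous
counts dominate strict counts cell-wise.

### Rank tests

Synchrony counts out of 15 are heavily tied, so the tie-corrected Friedman
statistic is the default:

    T1 = (k − 1) · Σⱼ (Rⱼ − n(k+1)/2)² / (A1 − C1),

with `Rⱼ` the column sums of within-block mid-ranks, `A1` the sum of
squared ranks and `C1 = nk(k+1)²/4`. Without ties this reduces to the
classical `12/(nk(k+1))·ΣRⱼ² − 3n(k+1)`, which is available behind
`tie_correction=False` for comparison with naive implementations. p-values
come from the upper χ²(k−1) tail; the exact within-block permutation
distribution is used as an oracle in the test suite, where the χ²
approximation error at very small n (4 blocks) is documented at ≲ 0.2 in
the mid-p range.

Post-hoc pairwise contrasts follow Conover's comparison for the Friedman
design: `t = |Rᵢ − Rⱼ| / sqrt(2n(A1 − C1)(1 − T1/(n(k−1)))/((n−1)(k−1)))`
on (n−1)(k−1) degrees of freedom, two-sided, Bonferroni-adjusted over the
k(k−1)/2 pairs. This is the rank-sum t comparison (not the Iman–Davenport
F variant); the choice is recorded in the result metadata. A completely
tied matrix is degenerate — statistic 0, all adjusted p = 1.

The focal–control synchrony proportions are tested against the
independence expectation `a² + (1−a)²` (the probability two animals,
independently active with probability `a`, share an activity class) with a
one-sample Wilcoxon signed-rank test. Zero differences are dropped
(Wilcoxon's original policy; Pratt's is behind a flag), mid-ranks are used
for tied absolute differences, the exact distribution is used for ≤ 25
untied non-zero differences and the normal approximation with tie and
continuity corrections otherwise; two-sided is the default. Because the
signed-rank statistic is sometimes reported on a χ² scale, the result also
carries a companion statistic — the squared standardised W⁺ on 1 df —
purely for comparison with such reports. `a` is pooled over all five roles
(with the default protocol, 30 × 15 × 5 = 2250 observations).

### Identity resampling

With unmarked animals, several sessions may have sampled the same focal.
The robustness procedure assigns each session an identity drawn i.i.d.
uniform from a herd of `herd_size` (default 70), keeps exactly one session
per identity — chosen uniformly among duplicates, implemented as a random
row permutation followed by first-appearance selection — re-runs the
Friedman test on the filtered matrix, and repeats `n_replicates` times
(default 100,000). Both classifications are filtered with the *same*
identity draws in every replicate, so their p-value series are paired. The
two random stages consume a single seeded stream in a fixed order
(identities, then duplicate resolution), making every replicate
reproducible. Replicates retaining fewer than two sessions (impossible at
70/30, possible for extreme user configurations) are excluded from the
p-value summary and counted separately, since the Friedman test is
undefined below two blocks. Because within-block ranks do not depend on
which blocks are retained, the matrix is ranked once and each replicate
only re-aggregates, which keeps 100,000 replicates in the
tens-of-seconds range.

## The synthetic herd

The simulator generates protocol-shaped data; it emulates the *structure*
of the field study (herd of ~70, excluded animals, sessions of scans,
per-scan neighbour re-ranking, fresh random controls) and a tunable
proximity–synchrony gradient. It does not attempt to model any real herd's
social network, dominance, energetic state or diurnal rhythm, so passing
tests demonstrate properties of the pipeline, not facts about deer.

**Movement.** Each animal performs a mean-reverting random walk around a
personal home anchor (reversion 0.05 per step, step s.d. `movement_step`),
reflected at the arena boundary; positions are in nominal body lengths,
one step per scan interval. Home anchors are normal around the arena
centre with s.d. `home_range_scale`, and by default are redrawn at every
session boundary — sessions represent different occasions, with the herd
reconfigured in between — with positions initialised at the walk's
stationary dispersion so scans see stationary geometry throughout.
Distance ties in neighbour ranking are broken by lowest agent id.

**Behavioural state.** Activity is thresholded latent Gaussian: animal `i`
is Active at step `t` iff
`sqrt(r)·Z(xᵢ,t) + sqrt(1−r)·Gᵢ(t) < Φ⁻¹(a)`, where `Z` is a smooth
spatial Gaussian field (squared-exponential covariance with length scale
`copy_range`, realised with 192 random Fourier features), `Gᵢ` is
idiosyncratic noise, and both evolve as stationary AR(1) processes with
lag-one coefficient `1 − switch_rate`. With
`r = copy_strength/(1 + copy_strength)`, the latent correlation between
animals at distance d is `r·exp(−d²/2·copy_range²)` — monotone decreasing,
which yields the strictly distance-ranked synchrony gradient. Two exact
calibration properties follow by construction: the stationary marginal
activity equals `baseline_active` (default 0.411) for *every* coupling
strength, and `copy_strength = 0` gives fully independent animals, so the
pipeline's null behaviour can be audited directly. An earlier design in
which animals stochastically conformed to a distance-weighted majority was
abandoned: interacting dynamics equilibrate to local consensus patches, so
the first three neighbour ranks — typically inside one patch — could not
be separated at any parameter setting, whereas the latent-field
construction realises exactly the specified correlation-by-distance curve.

**Labels.** Conditional on class, the behaviour label is drawn from
`strict_mixture` (defaults: grazing-dominated when active, spread over the
three lying postures when inactive). Labels are redrawn on class change and
spontaneously at rate `switch_rate`, forming bouts. Coupled herds share
labels as well as classes — a synchronised bout is *joint grazing*, not
merely joint activity — modelled by a herd-wide prevailing label per class
(itself switching at `switch_rate`) that a redrawing animal adopts with
probability `r`. Strict-mode synchrony therefore tracks the class gradient,
scaled down by label noise; at `copy_strength = 0` labels are independent.

**Defaults.** herd 70, arena 100 × 100, `home_range_scale` 10,
`movement_step` 0.5, `switch_rate` 0.2 (bouts of ~5 scan intervals),
`baseline_active` 0.411, `copy_strength` 0 (independent), `copy_range` 5,
30 sessions × 15 scans with 30-step inter-session gaps. These are the
study conditions; the only quantities deliberately matched to the field
study are the protocol shape and the marginal activity level.

**The strong-coupling demonstration scenario** (`strong_copy_scenario`)
uses `copy_strength` 49 (r = 0.98), `copy_range` 1.3, `home_range_scale`
4.5, `movement_step` 0.35, `switch_rate` 0.35 — a compact herd with steep,
short-range coupling, giving per-session match probabilities of roughly
0.77 / 0.68 / 0.63 / 0.53 by rank. Real strongly synchronised herds sit
much closer to the ceiling than this synthetic coupling can reach (a
smooth spatial correlation cannot decay fast enough across the √k spacing
of nearest-neighbour ranks to reproduce near-unity nearest-neighbour
matching), so the scenario instead buys its power from the schedule: 300
sessions of 30 scans, which resolves every pairwise rank contrast and the
half-count granularity of session medians decisively while keeping a
single simulation under ~10 s. Protocol-sized (30 × 15) datasets from the
same dynamics remain strongly significant on the Friedman tests but do not
reliably separate *adjacent* neighbour ranks in the post-hoc table.

## Numerical and design notes

- Proportions are kept unrounded internally; display rounding (3 d.p.)
  happens only at reporting level.
- Reports serialise with sorted keys and `repr`-exact floats: the same
  records and seed give byte-identical JSON.
- Unknown behaviour labels, missing or duplicated roles, and
  non-consecutive scans are hard errors carrying the offending
  session/scan/line — synchrony counts are sensitive to silent missingness.
- The ethogram codes the three lying (Resting) postures as Inactive and
  the other 11 categories — including standing vigilance — as Active,
  exactly as the source coding table prints it.
- Problem sizes in the test suite: the type-I calibration uses 1,000
  protocol-sized null datasets (rejection rate checked against the exact
  binomial 99% interval around α = 0.05); the signed-rank calibration uses
  200 datasets; the permutation oracle enumerates all 1,296 within-block
  arrangements of 4 × 3 matrices; the occupancy check uses 10,000 identity
  draws against the closed form `70(1 − (69/70)³⁰)`.

## Known limitations

- The simulator's behavioural coupling is mechanism-agnostic (shared local
  context); it cannot distinguish copying from shared environmental
  response, and neither can the scan-sampling analysis itself.
- All animals are mutually visible and eligible as controls; visibility
  limits and observation-angle effects of real fieldwork are not modelled.
- The resampling procedure assumes all herd members are equally likely
  focals; heterogeneous detectability is out of scope.
- No inter-observer reliability modelling; records are taken as given.
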