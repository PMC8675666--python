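# Methods

This note documents the models, conventions and numerical choices in
`ssgnet`, in the spirit of a statistical software methods appendix: what
is computed, under which assumptions, and where the genuinely open
design choices were settled.

## Event model and possession segmentation

The raw observable is a *release*: one player passes (or shoots) at a
known time, with a success flag and, for completed passes, a receiver.
Shots are flagged upstream and removed before every possession and
network computation, because the detection hardware cannot reliably
separate shots from passes; "pass attempts" therefore never include
shots.

Possession is not observed directly, so it is reconstructed from the
release sequence: a possession is a **maximal run of consecutive
same-team releases**.  Its duration runs from the run's first release to
the first release of the next (opposing) run — the first moment the
opponent demonstrably has the ball — and the final run of a game closes
at its own last release.  Two consequences are worth noting:

- an unsuccessful pass does not end a possession by itself; the team of
  the next release decides whether the ball was turned over (a misplaced
  pass recovered by a teammate keeps the possession alive);
- reconstructed durations tile the event span of a game, so dead-ball
  time between an opponent's gain and their first release is attributed
  to the preceding possession.  This is the natural convention when only
  release times are observable.

Ties in event time are resolved by stable (file-order) sort.  Maturity
banding is the threshold function Early ⇔ PAH% ≥ 90, applied to the
roster's PAH% column.

## Network metrics

Networks are built per team per game from successful, shot-filtered
passes and are never pooled across games before modelling — pooling
would erase exactly the repeated-measures variation the mixed models
are there to use.

Shortest-path metrics (closeness, betweenness) use **hop counts on the
binary adjacency** by default: a pass option either exists (at least one
completed pass) or it does not.  This matches formulas stated in terms
of the indicator adjacency and keeps path counts integral.  An
inverse-weight convention (edge length `1/w[i,j]`, so frequently used
links are "shorter") is available via `weighting="inverse-weight"` for
sensitivity analyses.  Distances come from Floyd–Warshall; shortest-path
counts are accumulated per source in order of increasing distance
(predecessor sums), which is exact for positive edge lengths, and
through-counts use σ_jk(i) = σ_ji · σ_ik when i lies on a shortest
path.

Conventions for degenerate cases, chosen to be bounded and monotone:

- **closeness**: unreachable players contribute distance `n` (the
  network size) instead of ∞; a player who reaches no-one scores 0;
- **betweenness** is unnormalised (maximum 6 in a directed 4-player
  network, endpoints excluded); ordered pairs with no path contribute 0;
- **PageRank** runs on the binary digraph with damping `d = 0.85`
  (convention; the metric's common default), tolerance 1e−9, at most
  1000 sweeps; dangling players redistribute their mass uniformly so
  scores always sum to 1.  `C(j)` is the unweighted out-degree; a
  weighted-split variant exists behind a flag.  The iterative fixed
  point is cross-checked against a direct linear solve in the tests.
- **intensity** uses possession time in minutes; with ≈9 successful
  passes over ≈2 minutes of possession this yields values in the
  observed 4–5 range, whereas seconds would give ≈0.07.

## Mixed models and effect sizes

Every analysis model is `metric ~ categorical fixed effects + (1 |
cluster)` with the cluster being the player (individual metrics) or the
team composition (team metrics; bio-banded line-ups keep one identity
across weeks, mixed line-ups are weekly).  Fits are **maximum
likelihood, not REML**, because log-likelihoods are compared across
fixed-effect structures.  Pitch size is an unordered 4-level factor
(reference: small); game type a 4-level factor (reference:
Early/Early); maturation enters only pooled analyses (it is constant
within a band).

For this single-random-intercept family the ML problem profiles down to
one parameter, the variance ratio λ = σ²_u/σ²_e: given λ, the GLS
coefficients and residual variance are closed-form via the Woodbury
identity, and the package optimises the scalar profiled likelihood on a
deterministic grid plus bounded refinement, checking the λ = 0 boundary
explicitly.  A boundary estimate triggers `SingularFitWarning` and
coincides with OLS, which is the documented fallback.  The fitter
agrees with statsmodels' `MixedLM` (ML) to ~1e−5 in log-likelihood on
well-conditioned fixtures; statsmodels remains a test-time oracle only
because its general-purpose optimiser is slower and can fail on
boundary-variance data that these analyses routinely produce.

Inference per effect: the full model (all fixed effects) is compared
with the model dropping the tested effect by a generalized likelihood
ratio test against the chi-squared reference with df equal to the
parameter difference.  Effect magnitude is local Cohen's f² using
residual-variance R² measured against the intercept + random-intercept
null:

    R²(m) = 1 − σ²_e(m) / σ²_e(null)
    f²    = (R²_full − R²_reduced) / (1 − R²_full),  clipped at 0.

Categories are left-closed at 0.02 / 0.13 / 0.26 (negligible, small,
medium, large); an alternative 0.02 / 0.15 / 0.35 convention is exposed
as a flag because both circulate in the effect-size literature, and the
report states which one is active.  Confidence intervals are percentile
95% intervals over 1000 **cluster** bootstrap resamples: whole players
(or team compositions) are drawn with replacement and carry all their
rows, preserving the within-cluster covariance that row resampling
would destroy.  Resamples that fail to fit are skipped and counted;
more than 10% failures aborts.  No multiple-testing correction is
applied.

## Synthetic study generator

The generator emulates the full design: two clubs × 16 players, PAH%
drawn U(90, 97) for Early and U(83, 89.9) for Late (8/8 per club); per
club, the two Early and two Late four-player teams are fixed for all
four weeks and play a 6-game mini-league in a fixed order (game types
EE×1, LL×1, EL×4 — the only multiset consistent with a round-robin of
two Early and two Late teams), followed each week by six games between
freshly drawn mixed teams of two Early + two Late players.  96 games in
total; pitch side lengths 17/24/29.5/34 m give 36.1/72.0/108.8/144.5 m²
per player across weeks 1–4.

Game play is an alternating renewal process over the 300 s game:
possession durations are lognormal (CV 0.34, giving SD ≈ mean/3) with a
week-specific mean; each possession is anchored by the release that
opens it plus `Poisson(rate · D/60)` further attempts (so passes per
possession is 1 + rate·H/60 in expectation); each attempt succeeds with
a band-specific probability (Early 0.575, Late 0.495) plus a per-player
N(0, 0.03) skill offset, which is what gives the random player
intercepts downstream.  Successful passes hand the ball to the
receiver; failures hand it to a random teammate or, at the run
boundary, the opponent.  Possessions end with a shot with probability
0.08.  As a degenerate guard, a pass rate of exactly zero disables
event generation entirely.

In mixed-maturity teams, receiver choice weights Early teammates by
1.6.  This single mechanism encodes late players' over-reliance on
early-maturing teammates and produces the observed direction of
centrality shifts: Early players' betweenness and PageRank rise in
mixed games relative to maturity-matched games because Late–Late links
become rarer and ball circulation routes through Early players.

**Calibration.**  The grand means constrain the parameters through an
identity of the possession reconstruction: durations tile the ~297 s
event span, so attempts per team-game ≈ (span/2)·ppp/H where H is the
harmonic mean of the weekly possession means and ppp = 1 + rate·H/60.
Jointly matching ≈29 attempts, ≈6.3–6.5 s possessions and ≈1.3–1.4
passes per possession fixes H ≈ 6.56 s and rate = 2.7/min; the weekly
spread (5.9/6.4/6.8/7.3 s, increasing with pitch size) was then chosen
so week-level possession means fall in the observed 5–7 s range while
keeping H.  Completion follows from the band probabilities
(≈0.575·¼ + 0.495·¼ + 0.535·½ ≈ 0.535 across the game-type mix).  These
defaults are frozen; `scripts/calibrate_generator.py` reproduces the
summary.  Measured over seeds 1–5: 29.8 attempts, 53.6% completion,
6.43 s possessions, 1.30 passes per possession.

**What the generator does not emulate** — and hence what passing tests
do *not* establish about real data: no spatial positions or pitch
geometry beyond the duration/tempo effects, no fatigue or score-line
dynamics, no goalkeeper/goal events beyond a flat shot rate, no
coach-rater bias structure in the GTSC beyond band/pitch shifts plus
noise, and no stand-by players.  Tests passing on synthetic data show
the pipeline recovers the structure this generator injects, not that
real SSGs contain that structure.

## Monte-Carlo validation choices

The statistical acceptance checks run at the study's own size (96
games, 32 players / 24 team compositions): type-I error of the
pitch-size LRT over 500 no-effect generator replicates (accepted band
3–8% at α = 0.05), null median f² < 0.02, median f² non-decreasing over
five injected effect magnitudes (100 metric-level replicates each), and
the 1.6 preference multiplier reproducing the Early betweenness /
PageRank direction in ≥90% of 200 studies.  Problem sizes were chosen
to keep the full suite within a routine CI budget while leaving the
Monte-Carlo bands comfortably away from their thresholds.

## Known limitations

- Possession duration inherits dead-ball time (see segmentation); a
  tracking-based possession definition would differ systematically.
- The LRT is asymptotic; with 24 team-composition clusters its finite-
  sample type-I error sits near the upper half of the accepted band.
- f² for team-level models uses the team-composition random intercept;
  if the real analysis clustered differently (e.g. nothing, or club),
  magnitudes shift although orderings are stable in simulation.
- The bootstrap resamples clusters independently, ignoring that two
  teams in the same game share a context.
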