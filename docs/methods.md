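# Methods

## Damage model

The low back is modelled as a structure under mechanical fatigue.  Each
lift applies one loading cycle at the peak lumbar moment
`M = m·g·d` (object mass m [kg], gravity g = 9.81 m/s², maximum horizontal
object-to-hip distance d [m]), a surrogate for peak low-back loading at the
deepest part of the lift.  A passive exosuit's effective extension moment
`M_exo` subtracts directly: `M_eff = max(M − M_exo, 0)`.  Cycles to failure
follow a log-linear S-N relationship in the effective moment,

    log10 N_f = a − b · L(M_eff)

with per-lift damage `D_1 = 1/N_f` and Palmgren–Miner accumulation
`D = n · D_1` over n lifts.  `L` is an optional affine map from lumbar
moment to the tissue load driving fatigue (identity by default); affine
offsets cancel in every ratio-based output, so they never affect percent
changes or breakevens.  A callable `L` is also accepted, in which case the
breakeven solvers switch from closed forms to Brent root-finding (tolerance
1e-9), and the two routes are cross-checked in the test suite to 1e-6
relative.

### Parameters

| parameter            | unit      | default | role |
|----------------------|-----------|---------|------|
| `gravity`            | m/s²      | 9.81    | load moment scale |
| `sn_slope` (b)       | 1/Nm      | 0.0165  | exponential damage growth per Nm |
| `sn_intercept` (a)   | —         | 9.0     | absolute damage scale only |
| `moment_to_load_*`   | — / Nm    | identity| optional moment→tissue-load map |
| `power_exponent_C`   | —         | 6.0     | force^C tissue fatigue exponent |

The slope default is over-determined by the breakeven structure of the
fatigue-failure ergonomic assessment this package implements: a 15.3 Nm
assistive moment is exactly offset by a 79 % repetition increase and a
42.3 Nm moment by 399 %, which both give `b ≈ log10(1.79)/15.3 ≈ 0.0165`
per Nm (a least-squares fit through the two anchors yields 0.01651, within
0.1 %).  The same value simultaneously reproduces the 5 Nm requirement for
a +20 % repetition increase and the 68 %/62 % scenario reductions, so the
system is consistent.  The intercept is deliberately a free scale constant:
no ratio output depends on it.  Its default (9.0) is chosen so that
`N_f ≥ 1` for all moments up to ~545 Nm, beyond the whole envelope reached
by the default sweeps (doubling a 45 kg object at 60 cm reaches ~530 Nm),
so the nonphysical `N_f < 1` cap (per-lift damage capped at 1, with a
warning) never distorts a default surface.

Percent changes are always `100·(new − old)/old`; values are kept at full
precision internally and rounded to integer percent / Nm only in
human-readable output.  Masses are kg throughout; a single lb→kg constant
(0.45359237) exists at the interface layer.

### Clamping

Effective moments are floored at zero with a warning: damage from an
over-assisted lift is outside the model's regime, and silently negative
moments would fabricate benefit.  One deliberate exception: the
repetition-mode sweep surface is computed from the damage *ratio*
`(1 + x/100)·10^(−b·g·M_exo)`, in which the nominal moment cancels.  This
keeps the surface exactly independent of nominal object weight over the
whole exo-moment axis — the property the surface is meant to display — at
the cost of extending the exponential form over the corner where the exo
moment would exceed a very light object's load moment.  Weight-mode
surfaces and non-affine maps use the clamped form.

## Exosuit moment estimation

The effective exo moment is built from inspectable components:

1. band force at peak stretch, by piecewise-linear interpolation of the
   manufacturer-style force-displacement curve (no extrapolation — bands
   stiffen nonlinearly, so out-of-range stretch is a hard error);
2. moment arm = (L5/S1 joint centre → skin) + (skin → band line of action);
3. peak extension moment = force × arm;
4. multiplicative derating for band hysteresis and for the timing offset
   between peak exo moment and peak lumbar loading (both default 1.0 = no
   correction; they scale delivered band force, so they are applied before
   the additive term);
5. subtraction of the flexion moment from the trunk-worn device weight
   (mass × g × CoM distance), floored at zero.

The correction order (multiplicative factors, then additive weight term)
reflects that hysteresis/timing act on the band force path while the device
weight is an independent static moment.  The CT-derived L5/S1-to-skin
distance is consumed as a scalar input; deriving it is out of scope.

## Case-series analytics

Lifting sets are labelled `A1, B (or B1), A2, B2, A3`; A = control (no exo,
`exo_moment` must be 0), B = exo.  Per participant the module reports
percent changes in repetitions and in modelled cumulative damage for B vs
A1, B vs A2, and B vs the *mean of the control sets* (one percent change
against the mean count, not the mean of two percent changes — this is what
reproduces the ~58 % ABABA worked example from raw counts 53/85/53/83/53).
Multi-B designs use the mean of the B sets.  Reversal (ABA designs only)
requires strict inequalities — `reps(B) > reps(A1)` and
`reps(A2) < reps(B)`, with the inequalities flipped for damage; ties count
as non-reversal, a conservative reading.  Excluded participants (an
`excluded` flag on their rows, reason free-text and never inferred) are
analyzed but dropped from series summaries.  No inferential statistics are
attached: with 4–5 participants per series the counts, ranges and means are
the honest summary.

## Sweeps and breakevens

Grids span exo moment 0–50 Nm × performance increase 0–100 % (step 1 by
default), nominal distance 60 cm, nominal masses 5/23/45 kg, nominal
repetitions 1000; every cell is the percent damage change against the
nominal no-exo task, so surfaces are invariant to the nominal repetition
count (asserted by test).  Breakeven contours are the zero-change curves;
closed forms are preferred (`100·(10^(b·g·M_exo) − 1)` for repetitions,
`100·M_exo/M` for weight — the latter model-independent for any strictly
monotone damage law) with the root-finder fallback described above.  The
four-scenario table defaults to a 22.7 kg object at 70 cm, 1000 lifts,
30 Nm exo, +20 % productivity.

Note on the weight scenario: with the default log-linear S-N form, wearing
a 30 Nm exo while increasing object weight 20 % yields a **+4.6 %** damage
change versus nominal.  Accounts of this scenario sometimes quote ~+3 %;
the pure log-linear model cannot produce that value at the slope consistent
with all the other outputs, so the +4.6 % is reported as computed and the
discrepancy is documented rather than force-fitted.

## Synthetic data generator

The generator emulates small single-case lifting studies: 4–5 participants,
AB/ABA/ABABA designs, heavy objects (default 55 kg) at 6-s cadence,
object-to-hip distances drawn per participant from 0.55–0.75 m, exo moments
uniform in a configurable interval (default 27–42 Nm).  Counts come from a
latent-endurance model: participant baseline ~ Gamma with mean 14 lifts and
CV `baseline_dispersion` (0.15) — a negative-binomial-style overdispersion
chosen because real series report only means and ranges (≈13–18 lifts);
the exo multiplies each participant's endurance by a lognormal effect with
mean `exo_effect_multiplier` (1.34) and spread `effect_sd` (0.15);
non-responders (probability 1/8, mirroring occasional observed performance
drops) draw a multiplier below 1 (mean 0.7) instead.  Each set adds
lognormal set-to-set noise (sd 0.05), rounds, and floors at one lift.  No
within-day fatigue carryover is modelled by default (control sets before
and after the exo set are empirically similar); the between-participant
effect variance is illustrative, not an estimate.  All randomness flows
from a single integer seed; identical seeds give byte-identical CSVs.

Synthetic band curves use `f(s) = k·s·(1 + softening·s/s_max)` with the
unloading branch scaled by `1 − hysteresis_loss`, which makes the
hysteresis-loop area fraction exactly the requested loss; real bands close
the loop at peak stretch, so this is a deliberate energy-budget-preserving
simplification.  Synthetic exosuit specs are built constructively: target
effective moments are drawn in the requested interval and the band
stiffness is solved back from sampled geometry, factors and device mass, so
the realised moments land in the interval by construction (verified, with a
bounded retry and an explicit infeasible-interval error).

What passing tests on synthetic data do **not** show: the generator has no
motivation/psychosocial effects, no within-set moment variation (only peak
per-lift moments are modelled), and its dispersion parameters are not
estimates of any real population — parameter-recovery results validate the
analytics pipeline, not field predictions.

## Problem sizes and numerics

Default grids (51 × 101 cells), case series of ≤ 200 synthetic
participants, and the full test suite all run in seconds on one CPU; grids
are vectorised numpy.  Degenerate inputs are errors, not silent NaNs: zero
reference counts/damage raise undefined-comparison errors, empty axes and
empty series are rejected, and CSV schema violations name the offending
row.  Brent solves use xtol 1e-9; all closed-form/solver agreements are
asserted at 1e-6 relative.

## Known limitations

- Only the low back is modelled; risks to shoulders, hips, knees are out of
  scope, as is the probability-of-high-risk-job logistic transform (not
  applicable at these heavy loads).
- Peak-moment abstraction: no time-varying moment profile within a lift,
  no within-set fatigue dynamics.
- The exo moment is a single scalar subtraction at the time of peak
  loading; clutch dynamics, comfort and fit are not modelled.
- The S-N intercept is a scale convention; absolute cumulative damage
  values are an index for comparison, not a physiological prediction.
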