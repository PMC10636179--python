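# Methods

## Time axis and data model

All analysis time is measured in whole calendar days since the date of
well-founded suspicion (WFS); day 0 is the WFS date.  The unit of analysis
is the *episode*: one referral of one patient into one CPP.  The cohort
keeps adults (≥ 18 years at WFS, computed from birth year) whose WFS falls
in the study year and who have exactly one episode; patients with several
episodes are excluded and counted, with episodes ongoing simultaneously
reported separately.  Age is approximated as `wfs_year − birth_year`
because registries typically release birth year only; the error is at most
one year and only matters at the 18-year and 70-year cut points.

Diagnoses link to an episode when the registered diagnosis date falls in
`[wfs − 31, wfs + 183]` days.  The 31-day lookback mirrors the register's
collection window, which extends one month ahead of the diagnosis date;
a configuration flag (`prewfs_full_history`) accepts the full pre-WFS
history instead, since either reading of the collection rule is defensible.
"Within six months" is fixed at 183 days.  A diagnosis dated on the WFS day
counts as on-or-after WFS; the episode nevertheless starts in the
with-diagnosis state, because the diagnosis precedes every later event of
the episode.  When several register records in the same group qualify, the
earliest wins; ties on the date are broken by record order with a logged
warning, so linkage is order-independent up to exact ties.

Diagnosis grouping is a total function of the ICD and morphology codes:
exact-code rules (the pancreatic C25.0–3/8–9 split, hepatobiliary
C17.0/C23.9/C24*, CUP C80.9) take precedence over prefix rules, longer
prefixes over shorter, and everything unmatched — including tumours whose
morphology behaviour digit is 0 or 1 (benign/uncertain) — falls into
`OTHER`.  Only the three exact-rule families are fixed coding conventions;
the prefix maps for the remaining PSD groups are editable defaults shipped
in the catalogue, as is the filter-function flag (documented only for the
breast, kidney and thyroid pathways; all others default to false).

## State model

Twelve states: investigation and treatment split by diagnosis status,
rejection with two late re-diagnosis states, three administrative stop
states, other cancer, and death.  The arrow set is reconstructed from the
pathway's event logic: a PSD diagnosis moves a no-diagnosis state to its
with-diagnosis sibling; stop codes leave the investigation states (the
treatment stop splitting on whether the PSD diagnosis is on or before the
stop day); a diagnosis within the 183-day window while rejected enters
`REJECTED_LATE_PSD` or `REJECTED_LATE_OTHER`; death is reachable from
every state and absorbing.  The late states and the non-treatment stop
states are treated as absorbing within the horizon except for death — the
alternative (allowing onward transitions out of the late states) cannot be
distinguished from the available descriptions, and absorbing states keep
the occupancy bands monotone and interpretable.  A criteria-not-met episode
later diagnosed with cancer is a tabulation column, not a distinct state.

Censoring is administrative: observation ends at the configured censor
date, episodes leave all risk sets on their censor day, and events on or
after that day are not observed.  Clinically diagnosed but pathologically
unconfirmed cancers are represented simply by the absence of a register
record, so a treated patient without pathological confirmation appears in
`TREAT_NO_DX` — a known feature of register-based analyses, not a defect.

## Estimation, propagation, microsimulation

Transition probabilities are nonparametric daily counts,
`P_t(s→s′) = n(s→s′ at t)/n(at risk in s at t)`.  Cells with an empty risk
set default to self-transition (no extrapolation).  Optional smoothing is a
centred moving average applied to *both* transition counts and risk-set
sizes, which preserves row-stochasticity exactly; the default is no
smoothing, and smoothing is intended for display curves only.

In `sojourn_time` mode the exit hazards of a designated state set (default:
the two investigation states and the rejected state, where waiting-time
dynamics plausibly depend on time already spent) are indexed by days since
state entry.  Propagation then runs on the sojourn-expanded ("tunnel")
space and is marginalized per day; with hazards that do not actually depend
on sojourn time this reproduces the calendar-time result up to sampling
noise, which is checked by test.  The designated set is a documented
interpretation, configurable per call.

On fully observed data, propagation of the calendar-time estimate from the
observed day-0 distribution reproduces the empirical occupancy *exactly*
(to numerical precision): the daily ratios are the empirical flow.  The
microsimulator samples individual paths from the same rows; it exists to
validate the propagation (and vice versa) and to support the sojourn mode,
where path sampling is sometimes more convenient than the expanded-space
product.  The Monte-Carlo gap at 50 000 paths is required to stay within
0.01 of the exact curve.

## Targets and excess time

*Inclusion*: per PSD group, the share of diagnosed patients (deduplicated;
one count per patient per group) with any referral to the corresponding
CPP in the study window, evaluated against 70% on the unrounded proportion.
*Lead time*: per CPP, the share of completed investigations ending within
the CPP's **longest** lead time (modality-specific times are unavailable,
so the longest is the conservative choice), evaluated against 80% on the
unrounded share; censored episodes are excluded from the denominator by
default (a flag counts them as failures instead).  CPPs without a
specified lead time are excluded from the lead-time table.

Rescaling: with times `x₁…xₙ` and lead time `L`, if
`share(x ≤ L) < 0.8`, the scale factor is `L/Q` where `Q` is the
empirical inverse-CDF 0.8-quantile (no interpolation) — the smallest
observed time whose cumulative share reaches 80%.  This is the minimal
linear contraction achieving the target; the postcondition
`share(scaled ≤ L) ≥ 0.8` and scale-equivariance under a common change of
units are property-tested.  Mean rescaled time is `scale · mean` exactly.
Excess time per CPP is `n · (mean_observed − mean_rescaled)`; the "most
used" failing CPPs are the largest by completed investigations.

Printed percentages round half away from zero: integer percent for main
columns, one decimal for the small "of which later diagnosed" shares.  Met
flags are always computed before rounding, so a CPP printing 70% can still
fail the 70% target.

## Synthetic registry

The generator emulates, per CPP block: episode volume; WFS dates uniform
over the study year; competing stop events sampled from piecewise-constant
daily hazards (earliest event wins, ties broken death > treatment >
rejection > remaining codes); an independent death process; administrative
censoring at the study-year end.  Diagnoses are assigned conditionally on
the outcome: a configurable fraction is registered 1–31 days before WFS;
treated episodes without a prior diagnosis carry the PSD with probability
`1 − p_treatment_without_dx` (via an in-CPP diagnosis hazard when
configured, otherwise on the treatment day); rejected episodes are
re-diagnosed late with small probabilities and a log-normal delay (median
60 days, σ = 0.5, so the late re-diagnoses concentrate roughly 100–140
days after WFS); an other-cancer stop registers a tumour in another group.
Optional background patients are diagnosed but never referred, which is
what makes the inclusion-target proportion informative.

Calibrated blocks are built by inverting this model's share algebra:
stop-type shares map to proportional hazards truncated after `D` days with
`D` chosen so the probability of stopping at all equals the share sum —
under complete follow-up every unconditional stop-type share is then hit
exactly, and the treated share is solved so the diagnosed-on/after-WFS
share lands on its target given the pre-WFS and treated-without-diagnosis
fractions.  The bundled presets cover the four archetypes (fast filtered
diagnosis; generous inclusion with high rejection; treatment without
diagnosis; no PSD) plus a single-CPP colorectal block and a pooled 28-CPP
study at published 2018 volumes and outcome shares.

What passing tests show — and do not.  The generator reproduces the
*marginal* outcome structure of published data (volumes, stop-type shares,
before/after-WFS diagnosis split, late re-diagnosis rates).  It does not
reproduce real waiting-time distributions (no distributional forms are
published; geometric/truncated-geometric stop times are an assumption),
correlations between a patient's diagnosis timing and stop timing beyond
the built-in conditioning, seasonal referral patterns, or coding noise.
Tests passing on synthetic data therefore demonstrate the correctness of
the pipeline's logic under the declared generative model, not the
empirical behaviour of any real region's registry.

## Numerical and scale choices

Problem sizes in the default test run and the acceptance script were
chosen to make Monte-Carlo bounds sharp but cheap: exact-equivalence
checks at n ≤ 200 episodes and 60-day horizons, hazard recovery at
n = 5000 with 3-standard-error bands, microsimulation at 50 000 paths
against a 0.01 uniform bound, and the pooled study at the published
~16 600-episode scale, which maps and analyses in a few seconds.
Occupancy rows must sum to 1 within 1e-9 wherever defined; days on which
every episode is censored are reported as NaN with a zero risk set rather
than extrapolated.

## Known limitations

* Multi-episode patients are excluded, as in the underlying study design;
  their pathways (parallel or sequential CPPs) need a dedicated analysis.
* The inclusion evaluation is retrospective (register-linked); official
  near-real-time monitoring uses predicted cancer counts and is out of
  scope.
* Lead-time evaluation against the longest modality-specific time
  overstates attainment for modalities with shorter recommended times.
* The ICD prefix maps outside the three fixed code families are defaults,
  not authoritative; analyses of real data must review them against local
  coding practice.
* Confidence intervals are not produced; risk-set sizes are exposed so
  users can judge stability, and the late-diagnosis stripes in particular
  rest on very few events.
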