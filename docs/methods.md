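# Methods

## Emission model

A molecule occupies one hidden state at a time; state *n* emits photons
as a homogeneous Poisson process at a total count rate kₙ (photons/s)
that already includes the detector background, so state 0 *is* the
background (~650 photons/s in the emulated conditions) and emitting
states sit in the ~1,000–8,000 photons/s range. Interphoton times within
a state are therefore exponential, Exp(kₙ), and a trajectory visiting
several states shows a multi-exponential interphoton-time density. Count
rates being totals means fluorescence intensities are differences of
adjacent state rates by construction: I₁ = k₁′ − k₀′ is emission above
background, I₂ = k₂′ − k₁′ the second bright level above the first.

Assumptions: first-order (memoryless) switching kinetics, constant rate
within a state, no detector dead time, afterpulsing or lifetime/IRF
effects.

## Synthetic photon streams

The simulator realizes the hidden state sequence first (exponential
dwells, per scheme below) and then fills each segment with exponential
photon gaps restarted at the segment boundary — by memorylessness this
is exactly the competing-clocks event-by-event simulation, with no time
discretization. Timestamps are quantized to a 4 × 10⁻¹² s resolution
mimicking counting hardware; on a collision the later photon is dropped
(at desk-scale rates this affects ≲ 10⁻⁸ of photons).

Schemes:

- **two_state_bleach** — one emitting state, irreversible bleach to
  background. Defaults (649 / 1625 photons/s, mean bleach dwell 6 s,
  16–21 s duration) mirror a typical glass trace.
- **three_state_bleach** — sequential 2 → 1 → 0 double bleach, the
  glass traces attributed to two dyes in one spot.
- **three_state_blink** — strict alternation between the two emitting
  states (exponential dwells, default 0.5 s) with an independent
  exponential photobleach clock (default mean 6 s) ending the trace in
  background. The terminal bleach reflects the acquisition protocol,
  which records until a bleach step and the background rate have been
  observed; dwell distributions for blinking are an assumption of this
  package, not an observed quantity.

Cohorts derive per-molecule seeds as cohort seed + ordinal, so streams
are reproducible bit-for-bit yet mutually independent.

What the simulator does **not** emulate: dye photophysics beyond
piecewise-constant rates (spectral diffusion, gradual brightness
drift), detector artifacts, diffusing contaminants, or the
heavy-tailed molecule-to-molecule brightness variability of real
cohorts (all molecules of one spec share exact rates). Passing tests
therefore demonstrate correctness of the analysis under its own model,
not robustness to every instrument pathology.

## Interphoton-time fitting

The dt histogram uses 50 logarithmic bins spanning the observed dt range
(exponential mixtures span decades; the bin count is a config knob).
Densities are counts / (n·width), an estimate of the dt pdf. The two-
and three-term models are fit by weighted least squares with Poisson bin
variances, σ² = max(counts, 1) / (n·width)², so empty bins still
constrain the fit; the model is averaged over each bin analytically,
which removes the bias of point evaluation on wide logarithmic bins.
Bounded optimization enforces Aₙ ≥ 0 and kₙ > 0.

Starting rates are reciprocals of the {30th, 85th} (two-term) or
{30th, 70th, 95th} (three-term) dt quantiles; a second, log-spaced
start over the observed dt range guards against local minima and the
lower-χ² solution is kept (deterministic). Rates are returned sorted
ascending; fits whose adjacent rates differ by < 5 % are flagged
degenerate. Reduced χ² divides by occupied bins minus the 2·n
parameters.

Model selection returns three states only when χ²ᵥ(3) <
0.8 × χ²ᵥ(2). The 0.8 improvement factor is a configurable default:
the three-term model always fits at least as well, so an unconditional
comparison would over-select it.

## Viterbi reconstruction

Each interphoton interval is scored under state *n* with the exponential
emission log-density log kₙ − kₙ·dt. Transitions between intervals use
the first-order probabilities r·dt off-diagonal and 1 − (S−1)·r·dt on
the diagonal, with r pinned to 10⁻¹⁰ transitions/s and never optimized —
at that rate a state switch costs ~ −16 log-units, so the path switches
only where the photon statistics overwhelm the penalty, which is what
turns the chain into a photon-resolution change-point detector.
Probabilities are floored at 10⁻³⁰⁰ before taking logs; the dynamic
program runs entirely in log space (numba-compiled), and ties break
toward the lower state index for determinism. Exactness is guarded by a
test comparing against exhaustive enumeration of all Sᴺ assignments.

Rate refinement maximizes the Viterbi path log-likelihood over
log-rates with Nelder–Mead (deterministic initialization, ≤ 500
iterations, relative likelihood tolerance 10⁻⁸). The simplex never
accepts a point worse than its start, so the returned likelihood is
never below the initialization's; rate sets that collide during the
search are rejected with an infinite penalty.

## Intensities and enhancement factors

Per-state count rates are kₙ′ = 1/⟨dt⟩ₙ over the intervals the path
assigns to state *n* (reciprocal identity kₙ′·⟨dt⟩ₙ = 1 holds to
round-off). Intensities are adjacent-state differences, reported only
when both states are occupied; negative differences are flagged, never
clamped. Cohort aggregation groups intensities into four distributions
— two-state I₁, all I₁, three-state I₂, and all I₁ and I₂ pooled — and
reports mean, standard error (sample SD/√n; the definition is a package
choice), n, and EF = mean(ZMW)/mean(glass), both raw and rounded
half-up to one decimal. The outlier rule (exclude glass intensities
above 16,000 photons/s) is opt-in and logs every exclusion. A
distribution with members on only one substrate cannot be ratioed: the
library raises a missing-group error, while the CLI omits the group
with a warning so one sparse distribution does not abort a cohort run.
Three-state glass molecules stay in the pooled distributions by
default.

Display binning (100 ms default) overlays each bin with the count rate
of the state occupying the bin's majority, scaled to expected counts
per bin.

## Numerical and design choices

- State labels ascend with rate; state 0 is always background.
- Histogram quantile initialization makes fits scale-free and
  reproducible; all randomness in the package flows through explicit
  integer seeds.
- Degenerate inputs fail loudly: repeated timestamps and non-monotone
  streams raise corrupt-input errors with line numbers on file input;
  all-equal dt cannot support a mixture fit and raises
  insufficient-data.
- Timestamps serialize as shortest round-trip decimals, so plain-text
  write → read reproduces the float stream bit-exactly.

## Validation problem sizes

The test suite and the acceptance script validate at sizes where the
statistical targets are meaningful yet quick: single trajectories of
16–21 s (≈ 16,000–45,000 photons), 20 seeds for parameter-recovery and
model-selection statistics, 200 random instances for Viterbi/enumeration
equivalence (≤ 12 intervals, where exhaustive scoring is feasible), and
20-molecule-per-arm cohorts for end-to-end enhancement recovery. For
recovery statistics, simulated trajectories qualify as "of their kind"
only if the ground truth occupies every scheme state for ≥ 1 s — a
realization whose bleach clock fires immediately contains no signature
of its nominal kind and no analysis could recover one.

## Known limitations

- The blink dwell-time distribution (exponential) and the blink
  start-state convention (brighter state first) are modeling choices.
- The exponential-mixture fit is ill-conditioned when component rates
  are within a factor ~2 or a component holds a few percent of the
  intervals; the rate refinement stage corrects most of the resulting
  bias but model selection loses power there.
- Viterbi gives the single most likely path, not per-interval posterior
  probabilities; no uncertainty is attached to segment boundaries.
- At most three states are modeled, matching the analysis the package
  implements.
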