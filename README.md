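# photonpath

Photon-by-photon state reconstruction for single-molecule fluorescence,
and enhancement-factor statistics for zero-mode waveguides (ZMWs).

## The problem

A single fluorophore parked in a confocal spot produces a stream of
time-stamped photon arrivals. The molecule switches between a small
number of emission states — a bright state, sometimes a second bright
state it blinks to, and, after irreversible photobleaching, the
background — and each state emits photons as a Poisson process at its
own count rate. The classical approach bins the stream into 100 ms
intervals and thresholds the resulting trace, which throws away every
event shorter than a bin. `photonpath` instead works on the interphoton
times directly, assigning **every photon interval** a molecular state,
so state changes are located with single-photon time resolution.

The motivating application is quantifying plasmonic fluorescence
enhancement: the same dye is measured on bare glass and inside ~200 nm
metal ZMW apertures, and the enhancement factor (EF) is the ratio of
mean single-molecule emission intensities between the two substrates.

## The method

Within a state with count rate *k* the interphoton times *dt* are
exponential, so a trajectory visiting *n* states has the mixture density

    y(dt) = A1·exp(−k1·dt) + A2·exp(−k2·dt) [+ A3·exp(−k3·dt)]

1. **Mixture fit** — the *dt* histogram (50 logarithmic bins) is fit by
   weighted least squares with Poisson bin variances to the two- and
   three-term models; the reduced χ² of the two fits decides the number
   of states (three wins only if its χ²ᵥ is below 0.8× the two-term
   value).
2. **Viterbi reconstruction** — the fitted rates define a hidden Markov
   chain over photon intervals with exponential emission densities and a
   pinned, extremely small transition rate (10⁻¹⁰ transitions/s) that
   forbids gratuitous switching; a Viterbi pass returns the globally
   most likely state per interval.
3. **Rate refinement** — the state rates are adjusted by a
   derivative-free simplex search maximizing the Viterbi path
   likelihood.
4. **Intensities** — each state's count rate is the reciprocal of its
   mean interphoton time, kₙ′ = 1/⟨dt⟩ₙ, and fluorescence intensities
   are adjacent-state differences I₁ = k₁′ − k₀′, I₂ = k₂′ − k₁′.
5. **Enhancement factors** — per-substrate intensity distributions
   (two-state I₁, all I₁, three-state I₂, pooled) are averaged and
   ratioed ZMW/glass, with an optional exclusion of anomalously bright
   glass molecules (> 16,000 photons/s).

Because no instrument recordings ship with the package, a
Markov-modulated Poisson process simulator generates glass-like
photobleach trajectories, double-step bleach trajectories, and ZMW-like
blink trajectories with known ground truth, and the whole pipeline is
validated against that ground truth.

## Worked example

`examples/03_state_reconstruction.py` simulates a glass-like trace
(emitting state ~1625 photons/s photobleaching into a ~649 photons/s
background) and reconstructs it:

```
states selected: 2
refined count rates: [ 661.  1598.5] photons/s (truth: [649, 1625])
path log-likelihood: 96621.4
bleach boundary: true 5.9040 s, reconstructed 5.8781 s (error 25.9 ms)
  state 0: 6690 intervals, mean dt 1.513e-03 s, k' = 661 photons/s
  state 1: 9393 intervals, mean dt 6.256e-04 s, k' = 1598 photons/s
fluorescence intensity I1 = k1' - k0' = 937 photons/s
binned trace: 160 bins, step from ~160 to ~66 counts/bin at the bleach
```

The count rates come back within a few percent of the configured truth,
the photobleach step is located to tens of milliseconds, and the
intensity I₁ is the emission rate of the bright state above background.
The other examples cover simulation (`01`), mixture fitting and model
selection (`02`) and cohort-level enhancement factors (`04`).

A thin CLI wraps the same pipeline for shell use:

```bash
photonpath simulate --out-dir cohort --seed 1 --n-glass 10 --n-zmw 10
photonpath reconstruct cohort/glass_000.txt
photonpath enhance --manifest cohort/manifest.csv --out-dir results
photonpath report results/enhancement.csv
```

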