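"""Reconstruct a molecular state path photon by photon.

The full pipeline: interphoton times -> histogram -> mixture fits ->
model selection -> likelihood-based rate refinement -> Viterbi state
assignment.  The reconstructed photobleach boundary lands within a few
interphoton times of the true switching point, far below the 100 ms
resolution of binned trajectories.
"""

import photonpath as pp

config = pp.SimulationConfig(
    scheme=pp.two_state_bleach_scheme(649.0, 1625.0, 6.0), duration=16.0, seed=12
)
traj, truth = pp.simulate_trajectory(config)

path, model = pp.reconstruct(traj, n_states="auto")
print(f"states selected: {model.n_states}")
print(f"refined count rates: {model.state_rates.round(1)} photons/s (truth: [649, 1625])")
print(f"path log-likelihood: {path.log_likelihood:.1f}")

true_boundary = truth.segments[0][1]
rec_boundary = next(start for start, _, s in path.segments if s == 0 and start > 0)
print(f"bleach boundary: true {true_boundary:.4f} s, reconstructed {rec_boundary:.4f} s "
      f"(error {abs(rec_boundary - true_boundary) * 1000:.1f} ms)")

series = pp.compute_interphoton_times(traj)
summaries = pp.summarize_states(path, series, n_states=model.n_states)
res = pp.compute_intensities(summaries)
for s in summaries:
    print(f"  state {s.state}: {s.n_intervals} intervals, mean dt {s.mean_interphoton_time:.3e} s, "
          f"k' = {s.count_rate:.0f} photons/s")
print(f"fluorescence intensity I1 = k1' - k0' = {res.intensities[1]:.0f} photons/s")

# 100 ms display binning with the state overlay scaled to mean intensities
binned = pp.bin_trajectory(traj, path, bin_width=0.1)
print(f"binned trace: {binned.counts.size} bins, step from ~{binned.overlay.max():.0f} "
      f"to ~{binned.overlay.min():.0f} counts/bin at the bleach")
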