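"""Fit the interphoton-time distribution with exponential mixtures.

Interphoton times within one emitting state are exponential at the
state's count rate, so a trajectory visiting several states shows a
multi-exponential dt distribution.  The reduced chi-square of two- vs
three-term fits decides how many molecular states the data support.
"""

import photonpath as pp

# a ZMW-like trace blinking between ~2500 and ~6000 photons/s before
# photobleaching to ~650 photons/s background
config = pp.SimulationConfig(scheme=pp.three_state_blink_scheme(), duration=20.0, seed=28)
traj, _ = pp.simulate_trajectory(config)

series = pp.compute_interphoton_times(traj)
hist = pp.histogram_interphoton(series, n_bins=50, binning="log")
print(f"{len(series)} interphoton times, {hist.n_occupied} occupied bins")

fit2 = pp.fit_exponential_mixture(hist, 2)
fit3 = pp.fit_exponential_mixture(hist, 3)
print(f"2-term fit: rates {fit2.rates.round(0)} photons/s, reduced chi2 {fit2.reduced_chi_square:.2f}")
print(f"3-term fit: rates {fit3.rates.round(0)} photons/s, reduced chi2 {fit3.reduced_chi_square:.2f}")

n = pp.select_model(fit2, fit3, improvement_factor=0.8)
print(f"selected model: {n} states (3 wins only if its reduced chi2 is < 0.8x the 2-term value)")
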