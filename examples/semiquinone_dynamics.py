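"""Compare the isolated period-two signal with predicted Q_B⁻ dynamics.

The two-electron acceptor gate makes the semiquinone population after
flash n follow Q(n) = 0.5·[1 − (1 − 2γ)ⁿ]: alternating around 0.5 and
damping at rate |1 − 2γ| per flash.  This script runs the end-to-end
workflow — generate the combined signal, isolate the period-two mode by
empirical wavelet transform, fit the period-four component for γ, and
correlate the isolated mode with the RMS-matched prediction.
"""

from kokwave import (
    compare_dynamics,
    normalize_pair,
    predict_qb_minus,
    run_recovery_experiment,
)

result = run_recovery_experiment(seed=1)
gamma = result.ewt_fit.params.gamma

pred = predict_qb_minus(gamma, len(result.period_two))
p2_centered, pred_scaled = normalize_pair(result.period_two, pred)
report = compare_dynamics(p2_centered, pred_scaled)

print(f"hit probability from the period-four fit: gamma = {gamma:.3f}")
print(f"Pearson r (isolated period-two vs predicted Q_B-): "
      f"{report.pearson_r:.3f}")
print(f"phase agreement on alternating flashes: {report.phase_agreement}")
print(f"damping ratio (2nd half / 1st half)  experimental: "
      f"{report.damping_ratio_experimental:.3f}  predicted: "
      f"{report.damping_ratio_predicted:.3f}")
print("\nr near 1 means the wavelet-isolated high-frequency mode is the "
      "acceptor-side (semiquinone) cycle, not noise.")
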