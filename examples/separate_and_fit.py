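"""Separate donor- and acceptor-side oscillations and recover kinetics.

Generates the combined validation signal — a Kok train plus a damped
binary (period-two) oscillator — then runs the full recovery study:
fit the raw combined trace directly, and fit the wavelet-filtered
period-four component, comparing both against the generating truth.
The table mirrors the simulated/raw-fit/EWT-fit comparison layout with
relative percentage errors per parameter.
"""

from kokwave import run_recovery_experiment

result = run_recovery_experiment(seed=1)

print(result.table.round(4).to_string(index=False))
print(
    "\nraw fit inflates the backward transition "
    f"(delta = {result.raw_fit.params.delta:.3f} vs true 0.020): the "
    "period-two interference masquerades as rapid damping."
)
print(
    "isolated period-two mode tracks the generating interference; "
    "the filtered period-four component carries the S-state cycling."
)
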