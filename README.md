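# kokwave

Separation of donor- and acceptor-side oscillations in Photosystem II
flash oxygen yields, with extended Joliot–Kok (VZAD) parameter fitting.

## The problem

A dark-adapted photosynthetic sample illuminated with a train of
single-turnover flashes releases oxygen with a period of four flashes:
the oxygen-evolving complex (OEC) steps through its S-states
S0 → S1 → S2 → S3 → (S4) → S0 and releases one O₂ per cycle.  The
acceptor side of PSII, however, cycles with period two — the
semiquinone Q_B⁻ accumulates on odd flashes and is reduced through to
plastoquinol on even ones — so a real flash-yield trace is the sum of a
period-four and a period-two oscillator.  Fitting a single homogeneous
kinetic model to that mixed signal conflates acceptor dynamics with
donor-side inefficiencies.

`kokwave` addresses this for people who analyze flash oxygen
(polarography) data:

- **Forward model** (`kokwave.kok`): per-flash S-state propagation under
  the five-outcome extended Kok (VZAD) rules — miss (α), double-hit (β),
  hit (γ), backward transition (δ), inactivation (ε) — with oxygen
  counted on every S3→S0 passage.
- **Empirical wavelet transform** (`kokwave.ewt`): mirror-pads the short
  sequence, segments the Fourier magnitude spectrum at the troughs
  between detected peaks, and splits the signal into modes with a
  Meyer-style filter bank that reconstructs the input exactly.  The mode
  peaking nearest 0.5 cycles/flash is the acceptor-side (period-two)
  component; the rest sum to the filtered period-four signal.
- **Fitting** (`kokwave.fit`): constrained least squares recovering
  (α, β, γ, δ, ε), the initial S-state populations and an amplitude
  scale, with the dark-adapted constraint [S3] = [S_ε] = 0 and a
  deterministic multi-start Powell search.
- **Acceptor dynamics** (`kokwave.acceptor`): the closed-form
  semiquinone population `Q(n) = 0.5·[1 − (1 − 2γ)ⁿ]`, compared to the
  isolated period-two mode after mean-centering and RMS matching.
- **Synthetic validation** (`kokwave.synth`): Kok trains plus damped
  binary interference and the full raw-fit vs EWT-fit recovery study.
- **I/O and pipeline** (`kokwave.io`, CLI `kokwave`): two-column
  flash/yield CSV in, a reproducible report bundle out.

## Worked example

```python
from kokwave import (DARK_ADAPTED_INIT, EFFICIENT_SYSTEM_PARAMS,
                     simulate_yields, fit_vzad)

seq = simulate_yields(EFFICIENT_SYSTEM_PARAMS, DARK_ADAPTED_INIT, 20)
print(seq.yields[:4])    # [0.     0.064  0.4779 0.2659] — flash-3 maximum
fit = fit_vzad(seq)
print(round(fit.params.alpha, 3), round(fit.params.gamma, 3),
      round(fit.init.s1, 3), f"{fit.sse:.2g}")
# 0.1 0.82 0.75 6e-26
```

The flash-3 maximum is the classic signature of a dark-adapted sample
(75% of centers in S1 need three hits to reach the O₂-releasing step),
and the essentially zero SSE shows the fit recovering the generating
parameters exactly from a noise-free train.

The separation workflow on a contaminated signal:

```python
from kokwave import run_recovery_experiment
result = run_recovery_experiment(seed=1)
print(result.table.round(3).to_string(index=False))
```

prints, per parameter, the generating value, the fit to the raw
combined signal, the fit to the wavelet-filtered period-four component,
and both relative errors.  With the default interference the raw fit
inflates the backward transition to ≈ 0.064 (vs true 0.020) — the
period-two ripple masquerades as rapid damping — while the isolated
period-two mode correlates with the predicted semiquinone cycle at
r ≈ 0.99 (`examples/semiquinone_dynamics.py`).

Each script in `examples/` is a short narrative of one capability:
simulation, separation + fitting, acceptor-dynamics comparison, and the
config-driven pipeline.  A thin CLI wraps the same functions
(`kokwave simulate|decompose|fit|qb-compare|pipeline|recovery-experiment`).

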