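# Methods

## The extended Kok (VZAD) forward model

Each single-turnover flash applies one of five outcomes to a reaction
center in S-state `i`:

| outcome | probability | transition |
|---|---|---|
| hit | γ | S_i → S_{(i+1) mod 4} |
| double-hit | β | S_i → S_{(i+2) mod 4} |
| miss | α | S_i → S_i |
| backward | δ | S_i → S_{i−1} (S0 → S0) |
| inactivation | ε | S_i → S_ε (absorbing) |

with α + β + γ + δ + ε = 1.  Populations are propagated by a
column-stochastic 5×5 matrix over (S0, S1, S2, S3, S_ε); the per-flash
oxygen yield is the probability mass crossing the S3→S0 step:
`γ·[S3] + β·[S2] + β·[S3]`.

Two bookkeeping choices are not forced by the model and are made
explicit:

- **O₂ on the S3 double-hit leg.**  A double-hit from S3 passes through
  S0 (S3→S0→S1) and releases one O₂ by default; the alternative
  convention (count only completed single S3→S0 hits) is selectable via
  `o2_on_double_hit_from_s3=False`.  At β = 0.05 the difference is a
  few percent of yield on late flashes.
- **Backward transitions from S0.**  Reversing the O₂-releasing step is
  unphysical, so δ applied to S0 leaves the center in S0 (it behaves as
  a miss).  This keeps the outcome probabilities normalized without
  inventing a state below S0.

Yields are population fractions; instrument units enter only through
the amplitude scale at the fitting stage.  With ε > 0 the active
population decays at least geometrically, `(1−ε)ⁿ`, and S_ε is
monotonically non-decreasing — both are asserted as test invariants,
along with exact agreement (≤ 1e−12) with a brute-force enumeration of
all 5ⁿ outcome paths for trains up to four flashes.

## Fitting

The fit minimizes unweighted SSE between the data and
`scale · model(α, β, δ, ε, init)` with γ = 1 − (α+β+δ+ε).  The scale is
profiled out in closed form (a one-dimensional non-negative least
squares), which makes the fit exactly scale-equivariant.  Under the
dark-adapted constraint (default) the initial distribution is
parameterized by (s0, s2) with s1 = 1 − s0 − s2 and [S3] = [S_ε] = 0,
reflecting the standard observation that dark-adapted samples hold no
S3 and no pre-inactivated centers; a fully free 8-parameter fit is
available with `constrain_dark_adapted=False`, and individual
parameters can be pinned via `fixed={...}`.

The optimizer is a deterministic two-stage multi-start: 27 grid starts
over the inefficiency cube plus 8 seeded random starts, each refined by
bounded Powell search at coarse tolerance; the four best basins are
re-polished at tight tolerance, and the lowest SSE wins with ties
broken toward smaller α then smaller δ.  The objective tracks the best
point ever evaluated because scipy's bounded Powell line search can
return a point worse than its start when the objective is already near
its minimum.  Multi-start matters here: the landscape contains a
shallow valley along the miss/backward degeneracy — two consecutive
misses (probability α²) de-phase a center exactly like a backward
transition followed by a hit (probability γδ) — so single-start fits
can land at either end of the valley.

No uncertainty quantification is attempted; fits are point estimates.

## Empirical wavelet transform

Flash trains are 12–40 points, start dark-adapted and end near steady
state, so the DFT's implicit periodization sees a step at the
wrap-around.  The sequence is therefore extended symmetrically before
transforming.  We use the half-open mirror `[x0..x_{N−1}, x_{N−2}..x1]`
(length 2N−2): it is circularly continuous at both ends **and**
preserves the sample parity of alternating signals.  The alternative
whole-signal reversal (length 2N) places two equal samples at each
junction, which annihilates the Nyquist bin of the padded spectrum
(the extension is a DCT-II) and smears any period-two component over
0.27–0.48 cycles/flash; with the half-open mirror a damped binary
oscillation stays concentrated at exactly 0.5 cycles/flash, and the
measured correlation between the isolated mode and the generating
interference rises from ≈ 0.885 to ≈ 0.99.  This padding choice is the
single most consequential numerical decision in the package.

Segmentation: local maxima of the one-sided magnitude spectrum are
detected with two guards, both expressed as fractions of the largest
non-DC magnitude — a height floor (default 1%) against the noise
floor, and a prominence floor (default 10%) that merges the shallow
relief (measured 6–7% prominence) the mirror extension produces on a
single physical band, while genuine component peaks in our signals
measure ≥ 34%.  A zero-frequency component larger than every
oscillatory peak anchors its own approximation (trend) band.  One
boundary is placed per adjacent pair of retained maxima, at the
minimum-magnitude bin between them.

Filtering: each boundary carries a sin²/cos² crossfade (Meyer-style
ramp) whose half-width is `taper` × the distance to the nearest
retained peak, capped so adjacent transitions never touch; `taper=None`
gives rectangular bands.  Because the two filters sharing a boundary
crossfade with complementary squares of the same argument, the bank
sums to exactly 1 at every frequency bin, so the modes reconstruct the
input to machine precision — the property the test suite asserts at
1e−8 relative RMS over random damped two-tone signals.

The period-two mode is the one whose peak frequency is nearest 0.5
cycles/flash (ties toward higher frequency); subtracting it yields the
filtered period-four signal.  If only one band is detected the
period-two component is declared non-separable and an error is raised
rather than returning a silent non-decomposition.

## Acceptor-side dynamics

With hit probability γ, the expected semiquinone population after
flash n follows `Q(n) = 0.5·[1 − (1 − 2γ)ⁿ]`, Q(0) = 0 — equivalently
the two-state recursion `Q(n) = γ(1 − Q(n−1)) + (1 − γ)Q(n−1)`, which
the tests use as an independent oracle.  For γ > 0.5 the sequence
alternates around 0.5 with damping factor |1 − 2γ| per flash; γ ≤ 0.5
is accepted but flagged as non-oscillatory.  Because the isolated
period-two signal is in arbitrary oxygen-yield units and the prediction
is a population fraction, both are mean-centered and the prediction is
scaled to the experimental RMS before comparison; the comparison
reports the Pearson correlation, a sign-pattern phase flag, and a crude
damping summary (RMS of the second half over the first).

## The synthetic validation conditions

The generator emulates the study design: an efficient donor-side
system — α = 0.100, β = 0.050, γ = 0.820, δ = 0.020, ε = 0.010 from
75% S1 / 25% S0, i.e. 75% of centers peaking on flash 3 — plus a damped
binary oscillator `phase · amplitude · (−1)^(n−1) · damping^(n−1)`
standing in for acceptor-side interference.  Default interference:
amplitude 0.15 × the maximum Kok yield, damping 0.8 per flash, positive
on flash 1; default train length 20 flashes.  Under these conditions
the raw fit of the combined signal shows the characteristic artifact
pattern (δ inflated to ≈ 0.064, [S0] ≈ 0.223), which the recovery
experiment tabulates.

What the generator does **not** emulate: measurement noise (electrode
drift, shot-to-shot lamp variation), S-state-dependent miss
probabilities, or slow dark relaxation between flashes.  Passing the
synthetic round-trip therefore shows correctness of the estimator under
the model's own assumptions, not robustness to instrumental noise.

## Known limitations

- **Spectral overlap of the Kok harmonic.**  A Kok train's sharp
  flash 1–4 transient carries genuine energy near 0.5 cycles/flash.
  Band filtering cannot distinguish it from acceptor interference, so
  the filtered period-four signal loses part of the transient.  The SSE
  optimum for the filtered signal then sits at the δ-rich end of the
  miss/backward valley (α low, β → 0, δ high) — about 8% deeper in SSE
  than the δ = 0 end of the valley (fitted values there:
  α ≈ 0.098, β ≈ 0.047, [S0] ≈ 0.33, [S1] ≈ 0.55).  Pinning
  `fixed={"delta": 0.0}` selects that end explicitly; the default fit
  does not regularize and reports the SSE optimum.
- Initial S-state estimates after filtering are systematically biased
  (S2 inflated, S1 deflated) for the same reason: the early flashes
  carry both the interference and the population information.
- The EWT assumes donor and acceptor bands are separable; if the
  periodicities converge (heavy damping, very short trains), boundary
  detection degrades and the package raises a separability error
  rather than guessing.
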