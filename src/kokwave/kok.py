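"""Forward model: S-state propagation under the extended Joliot--Kok
(VZAD) transition rules.

Each flash moves population between the donor-side S-states.  From S_i a
hit (γ) advances to S_{(i+1) mod 4}, a double-hit (β) to S_{(i+2) mod 4},
a miss (α) stays, a backward transition (δ) reverts to S_{i−1}, and
inactivation (ε) moves population to the absorbing pool S_ε.  Oxygen is
released on every passage through the S3→S0 step: the hit out of S3, the
second leg of a double-hit out of S2, and — by default — the first leg of
a double-hit out of S3 (S3→S0→S1).  A backward transition out of S0 would
reverse the O2-releasing step itself, which is unphysical; that
probability mass stays in S0 alongside the miss outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .types import FlashYieldSequence, KokParameters, SStateDistribution

__all__ = [
    "transition_matrix",
    "transition_step",
    "simulate_yields",
    "two_miss_vs_backward_hit",
    "DegeneracyReport",
]


def _matrix_raw(a: float, b: float, g: float, d: float, e: float) -> np.ndarray:
    M = np.zeros((5, 5))
    for i in range(4):
        M[(i + 1) % 4, i] += g
        M[(i + 2) % 4, i] += b
        M[i, i] += a
        if i == 0:
            M[0, 0] += d  # no S−1: backward from S0 behaves as a miss
        else:
            M[i - 1, i] += d
        M[4, i] += e
    M[4, 4] = 1.0
    return M


def _weights_raw(b: float, g: float,
                 o2_on_double_hit_from_s3: bool = True) -> np.ndarray:
    w = np.zeros(5)
    w[3] = g  # S3 →γ S0
    w[2] += b  # S2 →β S0 (second leg crosses S3→S0)
    if o2_on_double_hit_from_s3:
        w[3] += b  # S3 →β S1 (first leg crosses S3→S0)
    return w


def transition_matrix(params: KokParameters) -> np.ndarray:
    """Column-stochastic 5x5 matrix over (S0, S1, S2, S3, S_ε).

    ``M[j, i]`` is the probability that population in state i lands in
    state j after one flash.  S_ε is absorbing.
    """
    return _matrix_raw(params.alpha, params.beta, params.gamma,
                       params.delta, params.epsilon)


def _yield_weights(params: KokParameters,
                   o2_on_double_hit_from_s3: bool = True) -> np.ndarray:
    """Per-state oxygen-release probability for one flash."""
    return _weights_raw(params.beta, params.gamma, o2_on_double_hit_from_s3)


def transition_step(
    dist: SStateDistribution,
    params: KokParameters,
    o2_on_double_hit_from_s3: bool = True,
) -> tuple[SStateDistribution, float]:
    """Propagate one flash; return the new distribution and the oxygen
    yield (a population fraction in [0, 1]).

    Parameters
    ----------
    o2_on_double_hit_from_s3
        Whether the first leg of a double-hit starting in S3 counts one
        O2 (default).  Set False for the alternative bookkeeping in
        which only completed single transitions out of S3 release O2.
    """
    if not isinstance(dist, SStateDistribution):
        raise ValidationError("dist must be an SStateDistribution")
    if not isinstance(params, KokParameters):
        raise ValidationError("params must be a KokParameters")
    p = dist.as_array()
    M = transition_matrix(params)
    new = M @ p
    # exact conservation: M is column-stochastic, renormalize round-off
    new *= p.sum() / new.sum()
    o2 = float(_yield_weights(params, o2_on_double_hit_from_s3) @ p)
    return SStateDistribution.from_array(new), o2


def _simulate_raw(M: np.ndarray, w: np.ndarray, p0: np.ndarray,
                  n_flashes: int) -> np.ndarray:
    """Array-only inner loop shared with the fitting objective."""
    p = p0
    out = np.empty(n_flashes)
    for n in range(n_flashes):
        out[n] = w @ p
        p = M @ p
    return out


def simulate_yields(
    params: KokParameters,
    init: SStateDistribution,
    n_flashes: int,
    o2_on_double_hit_from_s3: bool = True,
) -> FlashYieldSequence:
    """Simulate a flash train and return the per-flash oxygen yields.

    Yields are population fractions (dimensionless); any amplitude scale
    to instrument units is applied downstream, at the fitting stage.
    """
    if n_flashes < 1:
        raise ValidationError(f"n_flashes must be >= 1; got {n_flashes}")
    M = transition_matrix(params)
    w = _yield_weights(params, o2_on_double_hit_from_s3)
    out = _simulate_raw(M, w, init.as_array(), n_flashes)
    return FlashYieldSequence(yields=out)


@dataclass(frozen=True)
class DegeneracyReport:
    """Occupancies and probability products for the two composite events
    that de-phase a center identically from S3.

    Two consecutive misses (S3 →α S3 →α S3) and a backward transition
    followed by a hit (S3 →δ S2 →γ S3) both leave the center in S3 one
    period behind its cohort, with path probabilities α² and γ·δ.  When
    α² ≈ γδ the two mechanisms are near-indistinguishable from yield
    data alone, which is why fitted backward transitions are fragile.
    """

    two_miss_final_state: str
    backward_hit_final_state: str
    alpha_squared: float
    gamma_delta: float

    @property
    def products_equal(self) -> bool:
        return abs(self.alpha_squared - self.gamma_delta) <= 1e-12

    @property
    def ratio(self) -> float:
        """α² / γδ (inf when γδ = 0 and α > 0, nan when both vanish)."""
        if self.gamma_delta == 0.0:
            return float("nan") if self.alpha_squared == 0.0 else float("inf")
        return self.alpha_squared / self.gamma_delta


def two_miss_vs_backward_hit(params: KokParameters) -> DegeneracyReport:
    """Report the miss-miss vs backward-hit de-phasing degeneracy for a
    center starting in S3.  Pure diagnostic; no fitting side-effects."""
    # follow each composite path symbolically from a pure-S3 start
    # miss, miss: S3 -> S3 -> S3 ; backward, hit: S3 -> S2 -> S3
    return DegeneracyReport(
        two_miss_final_state="S3",
        backward_hit_final_state="S3",
        alpha_squared=params.alpha ** 2,
        gamma_delta=params.gamma * params.delta,
    )
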