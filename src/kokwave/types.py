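"""Domain containers for flash-oxygen kinetics.

The extended Joliot--Kok (VZAD) model describes what a single saturating
flash does to a PSII reaction center: it advances one S-state (hit, γ),
advances two (double-hit, β), stays put (miss, α), steps back (backward
transition, δ), or leaves the catalytic cycle for good (inactivation, ε).
These five outcomes are exhaustive, so the probabilities live on the unit
simplex.  S-state populations likewise form a distribution over
S0--S3 plus the absorbing inactive pool S_ε.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

_SIMPLEX_TOL = 1e-9


def _check_prob(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0.0 or value > 1.0:
        raise ValidationError(f"{name} must lie in [0, 1]; got {value!r}")


@dataclass(frozen=True)
class KokParameters:
    """The five per-flash VZAD transition probabilities.

    Attributes
    ----------
    alpha : miss — the center does not advance.
    beta : double-hit — the center advances two S-states.
    gamma : hit — a single S-state advance.
    delta : backward transition — the center reverts one S-state.
    epsilon : inactivation — the center exits to the inactive pool S_ε.

    The five probabilities must sum to one (within 1e-9).
    """

    alpha: float
    beta: float
    gamma: float
    delta: float
    epsilon: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta", "epsilon"):
            _check_prob(name, getattr(self, name))
        total = self.alpha + self.beta + self.gamma + self.delta + self.epsilon
        if abs(total - 1.0) > _SIMPLEX_TOL:
            raise ValidationError(
                "transition probabilities must sum to 1 within "
                f"{_SIMPLEX_TOL}; got sum {total!r}"
            )

    @classmethod
    def from_inefficiencies(
        cls, alpha: float = 0.0, beta: float = 0.0,
        delta: float = 0.0, epsilon: float = 0.0,
    ) -> "KokParameters":
        """Build a parameter set with γ as the complement of the four
        inefficiencies (the parameterization used during fitting)."""
        gamma = 1.0 - (alpha + beta + delta + epsilon)
        if gamma < -_SIMPLEX_TOL:
            raise ValidationError(
                "inefficiencies exceed 1; implied hit probability "
                f"{gamma!r} is negative"
            )
        return cls(alpha=alpha, beta=beta, gamma=max(gamma, 0.0),
                   delta=delta, epsilon=epsilon)

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha": self.alpha, "beta": self.beta, "gamma": self.gamma,
            "delta": self.delta, "epsilon": self.epsilon,
        }


@dataclass(frozen=True)
class SStateDistribution:
    """Fractional populations of the donor-side S-states plus the
    inactive pool; must sum to one (within 1e-9)."""

    s0: float = 0.0
    s1: float = 0.0
    s2: float = 0.0
    s3: float = 0.0
    s_eps: float = 0.0

    def __post_init__(self) -> None:
        for name in ("s0", "s1", "s2", "s3", "s_eps"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0.0:
                raise ValidationError(
                    f"{name} must be a non-negative finite fraction; got {value!r}"
                )
        total = self.s0 + self.s1 + self.s2 + self.s3 + self.s_eps
        if abs(total - 1.0) > _SIMPLEX_TOL:
            raise ValidationError(
                "S-state populations must sum to 1 within "
                f"{_SIMPLEX_TOL}; got sum {total!r}"
            )

    @property
    def active(self) -> float:
        """Total population still inside the catalytic cycle."""
        return self.s0 + self.s1 + self.s2 + self.s3

    def as_array(self) -> np.ndarray:
        """Populations as [s0, s1, s2, s3, s_eps]."""
        return np.array([self.s0, self.s1, self.s2, self.s3, self.s_eps])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "SStateDistribution":
        a = np.asarray(arr, dtype=float)
        # clip tiny negative round-off before re-validation
        a = np.where((a < 0) & (a > -1e-12), 0.0, a)
        return cls(s0=float(a[0]), s1=float(a[1]), s2=float(a[2]),
                   s3=float(a[3]), s_eps=float(a[4]))

    def as_dict(self) -> dict[str, float]:
        return {"s0": self.s0, "s1": self.s1, "s2": self.s2,
                "s3": self.s3, "s_eps": self.s_eps}


@dataclass(frozen=True)
class FlashYieldSequence:
    """Ordered per-flash oxygen yields in arbitrary units.

    Flash indices are implicit and 1-based (`yields[0]` is flash 1).
    Raw sequences — measured or simulated — are non-negative; sequences
    that have passed through the wavelet filter may go negative, which
    the ``filtered`` flag records.
    """

    yields: np.ndarray
    filtered: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.yields, dtype=float)
        if arr.ndim != 1:
            raise ValidationError("yields must be one-dimensional")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("yields must all be finite")
        if not self.filtered and np.any(arr < 0):
            raise ValidationError(
                "raw yields must be non-negative; mark EWT-filtered "
                "sequences with filtered=True"
            )
        object.__setattr__(self, "yields", arr)

    def __len__(self) -> int:
        return len(self.yields)

    @property
    def flashes(self) -> np.ndarray:
        """1-based flash indices."""
        return np.arange(1, len(self.yields) + 1)

    def scaled(self, factor: float) -> "FlashYieldSequence":
        return replace(self, yields=self.yields * factor)
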