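"""Constrained least-squares recovery of VZAD parameters from a flash
oxygen sequence.

Free variables are the four inefficiencies (α, β, δ, ε) with the hit
probability γ taken as their complement, plus two initial-population
fractions.  Under the dark-adapted constraint the initial distribution
is (s0, s1, s2) with s1 = 1 − s0 − s2 and s3 = s_ε = 0, reflecting the
observation that dark-adapted samples hold no S3 and no pre-inactivated
centers.  Yields carry arbitrary instrument units, so a free positive
amplitude scale maps simulated population fractions onto the data; it
is solved in closed form (non-negative 1-D least squares) inside the
objective.

The objective landscape contains a shallow valley along the miss /
backward-transition degeneracy (two consecutive misses de-phase a center
exactly like a backward transition followed by a hit), so the optimizer
is a deterministic multi-start: a fixed grid over the inefficiency cube
plus a few seeded random starts, each refined by bounded Powell search,
best SSE wins with ties broken toward smaller α then smaller δ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import DegenerateInputError, ValidationError
from .kok import _matrix_raw, _simulate_raw, _weights_raw, simulate_yields
from .types import FlashYieldSequence, KokParameters, SStateDistribution

__all__ = ["FitResult", "fit_vzad", "relative_error_report"]

_FREE_NAMES = ("alpha", "beta", "delta", "epsilon", "s0", "s2")
_FREE_NAMES_UNCONSTRAINED = _FREE_NAMES + ("s3", "s_eps")


def _free_names(constrain_dark_adapted: bool) -> tuple[str, ...]:
    return _FREE_NAMES if constrain_dark_adapted else _FREE_NAMES_UNCONSTRAINED


@dataclass(frozen=True)
class FitResult:
    """Best-fit VZAD parameters, initial S-state populations, amplitude
    scale (arbitrary units per population fraction), and residuals."""

    params: KokParameters
    init: SStateDistribution
    scale: float
    sse: float
    per_flash_residuals: np.ndarray
    n_starts: int
    seed: int

    def predicted(self, n_flashes: int | None = None) -> np.ndarray:
        """Model yields on the data scale."""
        n = n_flashes if n_flashes is not None else len(self.per_flash_residuals)
        return self.scale * simulate_yields(self.params, self.init, n).yields

    def as_dict(self) -> dict:
        return {
            "params": self.params.as_dict(),
            "init": self.init.as_dict(),
            "scale": self.scale,
            "sse": self.sse,
            "per_flash_residuals": list(self.per_flash_residuals),
            "n_starts": self.n_starts,
            "seed": self.seed,
        }


def _unpack(x: np.ndarray, fixed: dict[str, float],
            constrain_dark_adapted: bool) -> tuple[KokParameters, SStateDistribution] | None:
    """Map a free-variable vector to model objects; None when the point
    violates a simplex constraint (γ < 0 or populations off-simplex)."""
    values = dict(zip(_free_names(constrain_dark_adapted), x))
    values.update(fixed)
    a, b, d, e = values["alpha"], values["beta"], values["delta"], values["epsilon"]
    gamma = 1.0 - (a + b + d + e)
    if gamma < 0.0 or min(a, b, d, e) < 0.0:
        return None
    s0, s2 = values["s0"], values["s2"]
    if constrain_dark_adapted:
        s1 = 1.0 - s0 - s2
        s3 = s_eps = 0.0
    else:
        s3 = values.get("s3", 0.0)
        s_eps = values.get("s_eps", 0.0)
        s1 = 1.0 - s0 - s2 - s3 - s_eps
    if min(s0, s1, s2, s3, s_eps) < 0.0:
        return None
    try:
        params = KokParameters(alpha=a, beta=b, gamma=gamma, delta=d, epsilon=e)
        init = SStateDistribution(s0=s0, s1=s1, s2=s2, s3=s3, s_eps=s_eps)
    except ValidationError:
        return None
    return params, init


def _objective(x: np.ndarray, y: np.ndarray, fixed: dict[str, float],
               constrain_dark_adapted: bool) -> float:
    """SSE after profiling out the non-negative amplitude scale.

    Works on raw floats (no dataclass validation) — this sits in the
    optimizer's inner loop.
    """
    values = dict(zip(_free_names(constrain_dark_adapted), x))
    values.update(fixed)
    a, b, d, e = values["alpha"], values["beta"], values["delta"], values["epsilon"]
    gamma = 1.0 - (a + b + d + e)
    s0, s2 = values["s0"], values["s2"]
    if constrain_dark_adapted:
        s3 = s_eps = 0.0
        s1 = 1.0 - s0 - s2
    else:
        s3, s_eps = values.get("s3", 0.0), values.get("s_eps", 0.0)
        s1 = 1.0 - s0 - s2 - s3 - s_eps
    worst = min(gamma, a, b, d, e, s0, s1, s2, s3, s_eps)
    if worst < 0.0:
        # infeasible: exceed any feasible SSE (<= y.y at zero scale) and
        # grow with the violation; kept modest so line searches that
        # step over the boundary are not derailed by a huge cliff
        return float(y @ y) * (1.0 + 10.0 * -worst) + 1.0
    m = _simulate_raw(
        _matrix_raw(a, b, gamma, d, e),
        _weights_raw(b, gamma),
        np.array([s0, s1, s2, s3, s_eps]),
        len(y),
    )
    mm = float(m @ m)
    scale = max(float(y @ m) / mm, 0.0) if mm > 0 else 0.0
    r = y - scale * m
    return float(r @ r)


def fit_vzad(
    seq: FlashYieldSequence,
    constrain_dark_adapted: bool = True,
    fixed: dict[str, float] | None = None,
    seed: int = 1,
    n_random_starts: int = 8,
) -> FitResult:
    """Fit the VZAD model to a flash yield sequence.

    Parameters
    ----------
    seq
        At least 8 flashes (two donor cycles); raw or EWT-filtered.
    constrain_dark_adapted
        Pin initial S3 and S_ε populations to zero (default), matching
        dark-adapted samples; pass False to free them.
    fixed
        Optional pinned free variables, e.g. ``{"delta": 0.0}``; keys
        from alpha, beta, delta, epsilon, s0, s2 (plus s3, s_eps when
        unconstrained).
    seed
        Seeds the supplementary random starts; the grid starts are
        fixed, so results are deterministic for a given seed.
    """
    if not isinstance(seq, FlashYieldSequence):
        seq = FlashYieldSequence(yields=np.asarray(seq, float), filtered=True)
    y = seq.yields
    if len(y) < 8:
        raise ValidationError(
            f"need at least 8 flashes (two donor cycles) to fit; got {len(y)}"
        )
    if not np.all(np.isfinite(y)):
        raise ValidationError("yields must be finite")
    if np.ptp(y) == 0.0:
        raise DegenerateInputError(
            "constant (or all-zero) sequence carries no oscillation to fit"
        )
    fixed = dict(fixed or {})
    names = _free_names(constrain_dark_adapted)
    free_idx = [i for i, n in enumerate(names) if n not in fixed]

    # deterministic multi-start: 27-point grid over the inefficiency
    # cube from a canonical dark-adapted init, plus seeded jitter that
    # also explores the initial-population simplex
    grid_starts = []
    for a0 in (0.02, 0.10, 0.25):
        for b0 in (0.01, 0.05, 0.15):
            for d0 in (0.0, 0.03, 0.10):
                grid_starts.append(
                    {"alpha": a0, "beta": b0, "delta": d0,
                     "epsilon": 0.01, "s0": 0.25, "s2": 0.0,
                     "s3": 0.0, "s_eps": 0.0}
                )
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        u = rng.uniform(size=8)
        grid_starts.append({
            "alpha": 0.3 * u[0], "beta": 0.2 * u[1], "delta": 0.15 * u[2],
            "epsilon": 0.05 * u[3], "s0": 0.6 * u[4], "s2": 0.3 * u[5],
            "s3": 0.1 * u[6], "s_eps": 0.05 * u[7],
        })

    bounds = [(0.0, 1.0)] * len(names)
    free_bounds = [bounds[i] for i in free_idx]

    def minimize_from(x0_full: np.ndarray, coarse: bool) -> tuple[float, np.ndarray]:
        # track the best point ever evaluated: bounded Powell's line
        # search can otherwise return a point worse than its start
        best_seen = [np.inf, x0_full[free_idx].copy()]

        def obj_free(xf: np.ndarray) -> float:
            x = x0_full.copy()
            x[free_idx] = xf
            f = _objective(x, y, fixed, constrain_dark_adapted)
            if f < best_seen[0]:
                best_seen[0] = f
                best_seen[1] = np.array(xf, copy=True)
            return f

        opts = ({"xtol": 1e-5, "ftol": 1e-7, "maxiter": 600} if coarse
                else {"xtol": 1e-12, "ftol": 1e-14, "maxiter": 6000})
        optimize.minimize(obj_free, x0_full[free_idx], method="Powell",
                          bounds=free_bounds, options=opts)
        x_full = x0_full.copy()
        x_full[free_idx] = best_seen[1]
        return float(best_seen[0]), x_full

    # stage 1: coarse local search from every start
    coarse_results = []
    for start in grid_starts:
        start = {**start, **fixed}
        x0_full = np.array([start[n] for n in names])
        coarse_results.append(minimize_from(x0_full, coarse=True))
    coarse_results.sort(key=lambda t: t[0])

    # stage 2: polish the few best basins to tight tolerance; best SSE
    # wins, ties broken toward smaller alpha then smaller delta
    best: tuple[float, float, float, np.ndarray] | None = None
    for sse_coarse, x_start in coarse_results[:4]:
        sse_p, x_p = minimize_from(x_start, coarse=False)
        cand = _unpack(x_p, fixed, constrain_dark_adapted)
        if cand is None:
            continue
        key = (sse_p, cand[0].alpha, cand[0].delta)
        if best is None or key < (best[0], best[1], best[2]):
            best = (*key, x_p)

    if best is None:
        raise DegenerateInputError("no feasible parameter point found")
    sse, _, _, x_best = best
    params, init = _unpack(x_best, fixed, constrain_dark_adapted)
    m = simulate_yields(params, init, len(y)).yields
    mm = float(m @ m)
    scale = max(float(y @ m) / mm, 0.0) if mm > 0 else 0.0
    residuals = y - scale * m
    return FitResult(
        params=params, init=init, scale=scale,
        sse=float(residuals @ residuals),
        per_flash_residuals=residuals,
        n_starts=len(grid_starts), seed=seed,
    )


def relative_error_report(
    fit: FitResult | KokParameters,
    truth: KokParameters,
) -> dict[str, dict[str, float | bool]]:
    """Per-parameter recovery error for the four inefficiencies.

    For each of α, β, δ, ε: 100·|fitted − true| / true when the true
    value is positive; when it is zero the absolute error is reported
    instead, flagged with ``absolute=True``.
    """
    fitted = fit.params if isinstance(fit, FitResult) else fit
    report: dict[str, dict[str, float | bool]] = {}
    for name in ("alpha", "beta", "delta", "epsilon"):
        f, t = getattr(fitted, name), getattr(truth, name)
        if t > 0:
            report[name] = {"error": 100.0 * abs(f - t) / t, "absolute": False}
        else:
            report[name] = {"error": abs(f - t), "absolute": True}
    return report
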