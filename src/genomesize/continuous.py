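"""Continuous duplication/deletion approximation and quantile bounds.

For large genomes, indels are negligible and the size process is well
approximated by a continuous multiplicative walk: each large deletion
multiplies the size by ``lambda ~ U[0,1]``, each duplication by
``lambda ~ U[1,2]``, with Poisson event counts proportional to the
starting size.  In log scale the jumps ``J = log(lambda)`` are i.i.d., so
one generation starting from ``s0`` has

    E[log S_f] = log s0 - A s0,      sd[log S_f] = B sqrt(s0),

with drift and dispersion coefficients

    A = mu_ldel - (2 log 2 - 1) mu_dup,
    B = sqrt(2 (log 2 - 1)^2 mu_dup + 2 mu_ldel).

``A > 0`` is the shrinkage condition: on average about
``1 / (2 log 2 - 1) ~ 2.59`` duplications are needed to undo one large
deletion, so equal rates are already strongly loss-biased.  Cantelli's
one-sided inequality applied to ``log S_f`` turns the moments into the
bound curve ``Q_k(s0) = exp(log s0 - A s0 + k B sqrt(s0))``: with
probability at least ``1 - 1/(1+k^2)``, the size after one generation is
below ``Q_k(s0)``.  The curve's maximum ``Q_k(s0_max)`` bounds the
corresponding quantile *uniformly in the starting size*, and its fixed
point ``s_fixed = k^2 B^2 / A^2`` is a size above which genomes shrink
with that same probability in a single generation — bounds that selection
cannot overcome, since they hold for every starting distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LOG2",
    "DUP_LOG_GAIN",
    "JumpMoments",
    "ContinuousBounds",
    "jump_moments",
    "drift_coefficient",
    "dispersion_coefficient",
    "generation_log_moments",
    "q_curve",
    "bounds",
    "cantelli_quantile_bound",
    "simulate_generation",
    "simulate_jumps",
]

LOG2 = math.log(2.0)
#: mean log-scale gain of one duplication, 2 log 2 - 1
DUP_LOG_GAIN = 2.0 * LOG2 - 1.0
#: second moment of the log jump of one deletion / duplication
_DEL_M2 = 2.0
_DUP_M2 = 2.0 * (1.0 - LOG2) ** 2


@dataclass(frozen=True)
class JumpMoments:
    """Moments of the log-scale jump of one rearrangement (dimensionless)."""

    mean_J: float
    second_moment_J: float

    @property
    def sd_J(self) -> float:
        var = self.second_moment_J - self.mean_J**2
        return math.sqrt(max(0.0, var))


def jump_moments(mu_ldel: float, mu_dup: float) -> JumpMoments:
    """Moments of ``J = log(lambda)`` for a rearrangement of random type.

    A deletion contributes ``E[log U[0,1]] = -1`` (second moment 2), a
    duplication ``E[log U[1,2]] = 2 log 2 - 1`` (second moment
    ``2 (1 - log 2)^2``), mixed with weights ``mu_type / (mu_ldel + mu_dup)``.
    """
    total = mu_ldel + mu_dup
    if total <= 0:
        raise ValueError("mu_ldel + mu_dup must be positive")
    w_del, w_dup = mu_ldel / total, mu_dup / total
    return JumpMoments(
        mean_J=-w_del + DUP_LOG_GAIN * w_dup,
        second_moment_J=_DEL_M2 * w_del + _DUP_M2 * w_dup,
    )


def drift_coefficient(mu_ldel: float, mu_dup: float) -> float:
    """Per-bp log drift ``A = mu_ldel - (2 log 2 - 1) mu_dup``; positive
    iff large genomes shrink on average."""
    return mu_ldel - DUP_LOG_GAIN * mu_dup


def dispersion_coefficient(mu_ldel: float, mu_dup: float) -> float:
    """Per-sqrt-bp dispersion ``B = sqrt(2 (log 2 - 1)^2 mu_dup + 2 mu_ldel)``."""
    return math.sqrt(_DUP_M2 * mu_dup + _DEL_M2 * mu_ldel)


def generation_log_moments(
    s0: float, mu_ldel: float, mu_dup: float
) -> tuple[float, float]:
    """Mean and sd of ``log S_f`` after one generation from size ``s0``.

    Closed forms of the Poisson mixture over the number of jumps:
    mean ``log s0 - A s0``, sd ``B sqrt(s0)``.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    a = drift_coefficient(mu_ldel, mu_dup)
    b = dispersion_coefficient(mu_ldel, mu_dup)
    return math.log(s0) - a * s0, b * math.sqrt(s0)


def q_curve(s0, k: float, mu_ldel: float, mu_dup: float):
    """Quantile bound curve ``Q_k(s0) = exp(log s0 - A s0 + k B sqrt(s0))``.

    Vectorised over ``s0``.  For ``A <= 0`` the curve grows without bound
    and has no maximum (see :func:`bounds`, which refuses that regime).
    """
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 <= 0):
        raise ValueError("s0 must be positive")
    if k < 1:
        raise ValueError("the bound order k must be >= 1")
    a = drift_coefficient(mu_ldel, mu_dup)
    b = dispersion_coefficient(mu_ldel, mu_dup)
    out = np.exp(np.log(s0) - a * s0 + k * b * np.sqrt(s0))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ContinuousBounds:
    """Derived bound quantities for a given order ``k``.

    ``s0_max`` maximises the bound curve; ``s_tilde_max = Q_k(s0_max)``
    bounds the ``1 - 1/(1+k^2)`` quantile after one generation uniformly
    over starting sizes; ``s_fixed = k^2 B^2 / A^2`` is the curve's fixed
    point, above which a genome shrinks with at least that probability.
    """

    k: float
    mu_ldel: float
    mu_dup: float
    A: float
    B: float
    s0_max: float
    s_fixed: float
    s_tilde_max: float

    def q(self, s0):
        """Evaluate the bound curve ``Q_k`` at ``s0`` (vectorised)."""
        return q_curve(s0, self.k, self.mu_ldel, self.mu_dup)


def bounds(k: float, mu_ldel: float, mu_dup: float) -> ContinuousBounds:
    """Closed-form maximiser, fixed point and uniform bound of ``Q_k``.

    Requires the shrinkage condition ``(2 log 2 - 1) mu_dup < mu_ldel``
    (``A > 0``); otherwise the curve is unbounded and the quantities are
    undefined.
    """
    if k < 1:
        raise ValueError("the bound order k must be >= 1")
    a = drift_coefficient(mu_ldel, mu_dup)
    if a <= 0:
        raise ValueError(
            "shrinkage condition violated: need (2 log 2 - 1) * mu_dup < "
            f"mu_ldel, got A = {a:.6g} <= 0 — no stationary bound exists"
        )
    b = dispersion_coefficient(mu_ldel, mu_dup)
    s0_max = 1.0 / a + k**2 * b**2 / (8 * a**2) * (
        1.0 + math.sqrt(1.0 + 16.0 * a / b**2)
    )
    s_fixed = k**2 * b**2 / a**2
    s_tilde_max = q_curve(s0_max, k, mu_ldel, mu_dup)
    return ContinuousBounds(
        k=k,
        mu_ldel=mu_ldel,
        mu_dup=mu_dup,
        A=a,
        B=b,
        s0_max=s0_max,
        s_fixed=s_fixed,
        s_tilde_max=float(s_tilde_max),
    )


def cantelli_quantile_bound(k: float) -> float:
    """Guaranteed mass below the order-``k`` bound: ``1 - 1/(1+k^2)``.

    Cantelli's (one-sided Chebyshev) inequality applied to ``log S_f``;
    0.5 for k=1, 0.8 for k=2.
    """
    if k < 1:
        raise ValueError("the bound order k must be >= 1")
    return 1.0 - 1.0 / (1.0 + k**2)


def simulate_jumps(
    s0: float,
    n_mutations: int,
    mu_ldel: float,
    mu_dup: float,
    rng: np.random.Generator,
    n_rep: int,
) -> np.ndarray:
    """Monte-Carlo log-sizes after exactly ``n_mutations`` jumps from ``s0``.

    Each jump is a deletion with probability ``mu_ldel / (mu_ldel+mu_dup)``
    (multiplier U[0,1]) or a duplication (multiplier U[1,2]).
    """
    p_del = mu_ldel / (mu_ldel + mu_dup)
    is_del = rng.random((n_rep, n_mutations)) < p_del
    u = rng.random((n_rep, n_mutations))
    jumps = np.where(is_del, np.log(u), np.log1p(u))
    return math.log(s0) + jumps.sum(axis=1)


def simulate_generation(
    s0: float,
    mu_ldel: float,
    mu_dup: float,
    rng: np.random.Generator,
    n_rep: int,
) -> np.ndarray:
    """Monte-Carlo sizes after one generation of the continuous process.

    Per replicate, deletion and duplication counts are Poisson with means
    ``mu_type * s0`` and every event multiplies the size by its uniform
    factor.  This is the independent oracle behind the Cantelli-bound and
    moment checks.
    """
    n_del = rng.poisson(mu_ldel * s0, n_rep)
    n_dup = rng.poisson(mu_dup * s0, n_rep)
    log_s = np.full(n_rep, math.log(s0))
    for counts, log_mult in (
        (n_del, lambda m: np.log(rng.random(m))),
        (n_dup, lambda m: np.log1p(rng.random(m))),
    ):
        total = int(counts.sum())
        if total:
            owner = np.repeat(np.arange(n_rep), counts)
            log_s += np.bincount(owner, weights=log_mult(total), minlength=n_rep)
    return np.exp(log_s)
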