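"""Mutation types and their one-step effect on genome size.

Genomes are reduced to a single observable, their total length in base
pairs.  Four mutation types act on it:

* **small insertions / small deletions** (indels): additive events of
  bounded size, drawn from a size law that does not depend on the current
  genome length;
* **segmental duplications / large deletions** (rearrangements): events
  whose size scales with the genome — up to the whole current chromosome.

Rearrangement sizes follow one of three laws: uniform on ``{1..s}`` (the
two breakpoints of the event are uniform along the chromosome), a
lognormal law truncated at the current size ``s`` (fitted to rearrangements
observed in evolving enterobacterial cultures), or an arbitrary empirical
size table renormalised over ``{1..s}``.

The boundary state ``s = 0`` is special: it can only be escaped through
small insertions; deletions and duplications leave it unchanged, and any
deletion that would overshoot below zero is floored at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "EVENT_TYPES",
    "EventType",
    "MutationRates",
    "IndelSizeModel",
    "RearrangementSizeModel",
    "MutationEvent",
    "sample_event_type",
    "sample_rearrangement_size",
    "apply_mutation",
]

EventType = Literal[
    "small_insertion", "small_deletion", "large_deletion", "duplication"
]

#: Canonical ordering of the four mutation types.  Count vectors and
#: conditional probability vectors follow this order everywhere.
EVENT_TYPES: tuple[EventType, ...] = (
    "small_insertion",
    "small_deletion",
    "large_deletion",
    "duplication",
)

# integer codes, used on hot paths instead of strings
INS, SDEL, LDEL, DUP = range(4)

#: Default lognormal rearrangement-size parameters (natural-log scale),
#: fitted to 127 experimentally verified rearrangements from evolving
#: E. coli and Salmonella cultures.
DEFAULT_MEANLOG = 10.1214
DEFAULT_SDLOG = 2.5602

_SQRT2 = math.sqrt(2.0)


def _norm_cdf(x: float) -> float:
    """Standard normal CDF via erf (cheap scalar path, no scipy call)."""
    return 0.5 * (1.0 + math.erf(x / _SQRT2))


@dataclass(frozen=True)
class MutationRates:
    """Per-bp, per-generation rates of the four mutation types.

    The expected number of events of one type in a generation starting
    from a genome of ``s`` bp is ``mu_type * s`` (Poisson), so these rates
    have units of events / bp / generation.
    """

    mu_ins: float
    mu_sdel: float
    mu_ldel: float
    mu_dup: float

    def __post_init__(self) -> None:
        for name in ("mu_ins", "mu_sdel", "mu_ldel", "mu_dup"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"{name} must be a finite nonnegative rate, got {value!r}"
                )

    @property
    def mu_total(self) -> float:
        """Total mutation rate per bp per generation (exact sum)."""
        return self.mu_ins + self.mu_sdel + self.mu_ldel + self.mu_dup

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mu_ins, self.mu_sdel, self.mu_ldel, self.mu_dup], dtype=float
        )

    def type_probabilities(self) -> np.ndarray:
        """Probability that a given mutation is of each type, ``mu_type / mu``.

        Independent of genome size, by the independence of the per-type
        Poisson processes.
        """
        mu = self.mu_total
        if mu <= 0:
            raise ValueError(
                "all mutation rates are zero: the conditional type "
                "distribution is undefined"
            )
        return self.as_array() / mu

    def scaled(self, factor: float) -> "MutationRates":
        """Return a copy with every rate multiplied by ``factor``."""
        return MutationRates(
            self.mu_ins * factor,
            self.mu_sdel * factor,
            self.mu_ldel * factor,
            self.mu_dup * factor,
        )

    @classmethod
    def bacterial_defaults(cls) -> "MutationRates":
        """Rates measured in enterobacterial mutation-accumulation data.

        Large deletions occur at 3.778e-9 /bp/generation (Salmonella
        estimate); duplications at the same rate (unbiased process); small
        insertions and small deletions each at twice that rate.
        """
        mu = 3.778e-9
        return cls(mu_ins=2 * mu, mu_sdel=2 * mu, mu_ldel=mu, mu_dup=mu)


class IndelSizeModel:
    """Size law of small insertions and small deletions.

    Sizes live on ``{1..l_ins}`` (insertions) and ``{1..l_sdel}``
    (deletions) with arbitrary probability vectors that do not depend on
    the current genome size.
    """

    def __init__(self, p_ins: Sequence[float], p_sdel: Sequence[float]):
        self.p_ins = self._validated(np.asarray(p_ins, dtype=float), "p_ins")
        self.p_sdel = self._validated(np.asarray(p_sdel, dtype=float), "p_sdel")
        self._cum_ins = np.cumsum(self.p_ins)
        self._cum_sdel = np.cumsum(self.p_sdel)
        # fast path: uniform vectors sample through a single integers() call
        self._ins_uniform = np.allclose(self.p_ins, 1.0 / self.l_ins)
        self._sdel_uniform = np.allclose(self.p_sdel, 1.0 / self.l_sdel)

    @staticmethod
    def _validated(p: np.ndarray, name: str) -> np.ndarray:
        if p.ndim != 1 or p.size == 0:
            raise ValueError(f"{name} must be a non-empty 1-D probability vector")
        if np.any(p < 0):
            raise ValueError(f"{name} has negative entries")
        total = p.sum()
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"{name} must sum to 1 within 1e-12, got {total!r}")
        return p

    @property
    def l_ins(self) -> int:
        """Maximum insertion size in bp."""
        return int(self.p_ins.size)

    @property
    def l_sdel(self) -> int:
        """Maximum small-deletion size in bp."""
        return int(self.p_sdel.size)

    @property
    def mean_insertion(self) -> float:
        return float(np.arange(1, self.l_ins + 1) @ self.p_ins)

    @property
    def mean_deletion(self) -> float:
        return float(np.arange(1, self.l_sdel + 1) @ self.p_sdel)

    @classmethod
    def uniform(cls, l_ins: int = 40, l_sdel: int | None = None) -> "IndelSizeModel":
        """Uniform indel sizes on ``{1..l}`` (default 1–40 bp for both)."""
        if l_sdel is None:
            l_sdel = l_ins
        return cls(np.full(l_ins, 1.0 / l_ins), np.full(l_sdel, 1.0 / l_sdel))

    def sample_insertion(self, rng: np.random.Generator) -> int:
        if self._ins_uniform:
            return int(rng.integers(1, self.l_ins + 1))
        return int(np.searchsorted(self._cum_ins, rng.random(), side="right")) + 1

    def sample_deletion(self, rng: np.random.Generator) -> int:
        if self._sdel_uniform:
            return int(rng.integers(1, self.l_sdel + 1))
        return int(np.searchsorted(self._cum_sdel, rng.random(), side="right")) + 1

    def __repr__(self) -> str:  # pragma: no cover
        return f"IndelSizeModel(l_ins={self.l_ins}, l_sdel={self.l_sdel})"


class RearrangementSizeModel:
    """Size law of segmental duplications and large deletions.

    ``kind`` is one of ``"uniform"`` (event size uniform on ``{1..s}``),
    ``"truncated_lognormal"`` (a fixed lognormal conditioned, by redraw,
    on not exceeding the current size ``s``) or ``"empirical_table"``
    (user-supplied size→weight table, truncated and renormalised at ``s``).
    The same law applies to gains and to losses.
    """

    #: below this truncated-law mass the rejection sampler refuses to run
    MIN_ACCEPT_PROB = 1e-12

    def __init__(
        self,
        kind: str,
        meanlog: float | None = None,
        sdlog: float | None = None,
        sizes: Sequence[int] | None = None,
        weights: Sequence[float] | None = None,
    ):
        if kind not in ("uniform", "truncated_lognormal", "empirical_table"):
            raise ValueError(f"unknown rearrangement size kind {kind!r}")
        self.kind = kind
        self.meanlog = meanlog
        self.sdlog = sdlog
        self.sizes: np.ndarray | None = None
        self.weights: np.ndarray | None = None
        if kind == "truncated_lognormal":
            if meanlog is None or sdlog is None:
                raise ValueError("truncated_lognormal requires meanlog and sdlog")
            if not sdlog > 0:
                raise ValueError(f"sdlog must be > 0, got {sdlog!r}")
        elif kind == "empirical_table":
            if sizes is None:
                raise ValueError("empirical_table requires a size table")
            s = np.asarray(sizes, dtype=np.int64)
            if s.size == 0 or np.any(s < 1):
                raise ValueError("empirical sizes must be positive integers")
            w = (
                np.ones(s.size, dtype=float)
                if weights is None
                else np.asarray(weights, dtype=float)
            )
            if w.shape != s.shape or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("invalid empirical weights")
            order = np.argsort(s)
            s, w = s[order], w[order]
            # merge duplicate sizes
            uniq, inv = np.unique(s, return_inverse=True)
            wsum = np.zeros(uniq.size)
            np.add.at(wsum, inv, w)
            self.sizes = uniq
            self.weights = wsum / wsum.sum()
            self._cum = np.cumsum(self.weights)

    @classmethod
    def uniform(cls) -> "RearrangementSizeModel":
        return cls("uniform")

    @classmethod
    def truncated_lognormal(
        cls, meanlog: float = DEFAULT_MEANLOG, sdlog: float = DEFAULT_SDLOG
    ) -> "RearrangementSizeModel":
        return cls("truncated_lognormal", meanlog=meanlog, sdlog=sdlog)

    @classmethod
    def empirical(
        cls, sizes: Sequence[int], weights: Sequence[float] | None = None
    ) -> "RearrangementSizeModel":
        return cls("empirical_table", sizes=sizes, weights=weights)

    def __repr__(self) -> str:  # pragma: no cover
        if self.kind == "truncated_lognormal":
            return (
                f"RearrangementSizeModel(truncated_lognormal, "
                f"meanlog={self.meanlog}, sdlog={self.sdlog})"
            )
        return f"RearrangementSizeModel({self.kind})"


@dataclass(frozen=True)
class MutationEvent:
    """A single realised mutation: type, signed size change and the sizes
    immediately before and after it."""

    event_type: EventType
    size_change: int
    pre_size: int
    post_size: int


def sample_event_type(rates: MutationRates, rng: np.random.Generator) -> EventType:
    """Draw the type of one mutation, each with probability ``mu_type / mu``."""
    probs = rates.type_probabilities()
    code = int(np.searchsorted(np.cumsum(probs), rng.random(), side="right"))
    return EVENT_TYPES[min(code, 3)]


def sample_rearrangement_size(
    model: RearrangementSizeModel, current_size: int, rng: np.random.Generator
) -> int:
    """Draw a duplication / large-deletion size for a genome of ``current_size`` bp.

    Uniform kind: integer uniform on ``{1..current_size}``.  Truncated
    lognormal: real lognormal draws are rounded to the nearest integer,
    clamped to at least 1 bp, and redrawn as long as they exceed
    ``current_size`` (rejection sampling).  Empirical table: the table is
    truncated at ``current_size`` and renormalised.

    Raises ``ValueError`` at ``current_size == 0`` (callers must apply the
    zero-state rule first) and when the truncated law keeps less than
    ``MIN_ACCEPT_PROB`` of its mass (unbounded rejection loop guard).
    """
    if current_size < 1:
        raise ValueError(
            "rearrangement size undefined at genome size 0; apply the "
            "zero-state transition rule instead"
        )
    if model.kind == "uniform":
        return int(rng.integers(1, current_size + 1))
    if model.kind == "truncated_lognormal":
        m, sd = model.meanlog, model.sdlog
        # one cheap draw first: at realistic sizes acceptance is near 1
        k = max(1, int(round(math.exp(rng.normal(m, sd)))))
        if k <= current_size:
            return k
        # rounding accepts iff the raw draw is below current_size + 0.5
        p = _norm_cdf((math.log(current_size + 0.5) - m) / sd)
        if p < model.MIN_ACCEPT_PROB:
            raise ValueError(
                f"truncated lognormal keeps mass {p:.3e} below size "
                f"{current_size}: refusing unbounded rejection sampling"
            )
        batch = min(65536, max(16, int(4.0 / p)))
        while True:
            ks = np.maximum(1, np.rint(np.exp(rng.normal(m, sd, size=batch))))
            ok = np.nonzero(ks <= current_size)[0]
            if ok.size:
                return int(ks[ok[0]])
    # empirical_table
    hi = int(np.searchsorted(model.sizes, current_size, side="right"))
    if hi == 0:
        raise ValueError(
            f"empirical size table has no mass at or below size {current_size}"
        )
    mass = model._cum[hi - 1]
    u = rng.random() * mass
    j = min(int(np.searchsorted(model._cum[:hi], u, side="right")), hi - 1)
    return int(model.sizes[j])


def _transition(
    s: int,
    code: int,
    indel: IndelSizeModel,
    rearr: RearrangementSizeModel,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Apply one mutation of type ``code`` to size ``s``; return (post, delta).

    Hot path shared by the generation process and the accumulation engine.
    """
    if code == INS:
        d = indel.sample_insertion(rng)
        return s + d, d
    if s == 0:
        # only insertions escape the zero state
        return 0, 0
    if code == SDEL:
        d = indel.sample_deletion(rng)
        post = s - d if d < s else 0  # overshoot below zero is floored
        return post, post - s
    d = sample_rearrangement_size(rearr, s, rng)
    if code == LDEL:
        return s - d, -d
    return s + d, d  # DUP


def apply_mutation(
    current_size: int,
    event_type: EventType,
    indel_model: IndelSizeModel,
    rearr_model: RearrangementSizeModel,
    rng: np.random.Generator,
) -> MutationEvent:
    """Apply a single mutation of the given type and record it.

    Transition rules: insertions add an indel-law draw (possible even at
    size 0); small deletions remove one, floored at 0; duplications add a
    rearrangement-size draw (``1..s``); large deletions remove one, so the
    final size is uniform on ``{0..s-1}`` under the uniform kind.  At size
    0 every type except small insertion leaves the genome unchanged.
    """
    if current_size < 0:
        raise ValueError("genome size must be nonnegative")
    code = EVENT_TYPES.index(event_type)
    post, delta = _transition(int(current_size), code, indel_model, rearr_model, rng)
    return MutationEvent(event_type, delta, int(current_size), post)
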