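"""One generation of replication: Poisson event counts and random ordering.

The number of mutations of each type in a generation is Poisson with mean
``mu_type * s0``, where ``s0`` is the genome size at the *start* of the
generation — even if the genome loses most of its length mid-generation,
the remaining event count is not re-scaled.  The realised events are
applied in a uniformly random order, each one seeing the size left by the
previous one (which is what makes truncation-at-current-size meaningful).

Genomes ending a generation at size 0 are reassigned size 1, so the
generational chain lives on the positive integers and has no absorbing
state.  Mid-generation zeros follow the single-mutation rules (only small
insertions can escape); the rewiring happens once, at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mutation_model import (
    EVENT_TYPES,
    IndelSizeModel,
    MutationEvent,
    MutationRates,
    RearrangementSizeModel,
    _transition,
)

__all__ = ["GenerationOutcome", "draw_mutation_counts", "one_generation"]


@dataclass
class GenerationOutcome:
    """Everything that happened in one generation of a single lineage."""

    start_size: int
    end_size: int
    events: list[MutationEvent] = field(default_factory=list)
    #: events of each type, in ``EVENT_TYPES`` order
    counts_by_type: tuple[int, int, int, int] = (0, 0, 0, 0)


def draw_mutation_counts(
    rates: MutationRates, start_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Four independent Poisson counts with means ``mu_type * start_size``.

    Equivalent, by Poisson thinning, to drawing one total ``Poisson(mu * s0)``
    count and assigning types with probabilities ``mu_type / mu``.
    """
    if start_size < 1:
        raise ValueError("a generation must start from a positive genome size")
    return rng.poisson(rates.as_array() * float(start_size))


def one_generation(
    start_size: int,
    rates: MutationRates,
    indel_model: IndelSizeModel,
    rearr_model: RearrangementSizeModel,
    rng: np.random.Generator,
) -> GenerationOutcome:
    """Replicate a genome once: draw counts, shuffle, apply, rewire 0 to 1."""
    counts = draw_mutation_counts(rates, start_size, rng)
    codes = np.repeat(np.arange(4), counts)
    rng.shuffle(codes)
    s = int(start_size)
    events: list[MutationEvent] = []
    for code in codes:
        code = int(code)
        post, delta = _transition(s, code, indel_model, rearr_model, rng)
        events.append(MutationEvent(EVENT_TYPES[code], delta, s, post))
        s = post
    return GenerationOutcome(
        start_size=int(start_size),
        end_size=max(1, s),
        events=events,
        counts_by_type=tuple(int(c) for c in counts),
    )
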