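# Methods

## Model

The state is a single nonnegative integer, the genome length in base
pairs; sequence content is deliberately not represented (the dynamics of
interest depends only on length, and every result here is a statement
about the length marginal).

Four mutation types act on a genome of size `s`:

| type            | size law                          | effect            |
|-----------------|-----------------------------------|-------------------|
| small insertion | `p_ins` on `{1..l_ins}` (default U{1..40}) | `s + d`    |
| small deletion  | `p_sdel` on `{1..l_sdel}` (default U{1..40}) | `max(0, s - d)` |
| duplication     | uniform on `{1..s}`, truncated lognormal, or empirical table | `s + d` |
| large deletion  | same law as duplications          | `s - d`           |

Indel laws never depend on `s`; rearrangement laws are truncated at `s`
(an event cannot move more than the whole chromosome). At `s = 0` only
small insertions act; deletions and duplications leave 0 unchanged.

A generation draws four independent Poisson counts with means
`mu_type * s0`, where `s0` is the size at the *start* of the generation —
a genome that loses most of its length mid-generation still experiences
the remaining events. Events are applied in a uniformly random order,
each drawing its size from the law evaluated at the current,
mid-generation size (this is what makes truncation meaningful). A genome
ending a generation at 0 is reassigned size 1, so the generational chain
lives on the positive integers with no absorbing state.

Parameters and defaults (units: events / bp / generation):
`mu_ldel = mu_dup = 3.778e-9` (the measured enterobacterial
large-deletion rate; duplications set equal for an unbiased process),
`mu_ins = mu_sdel = 7.556e-9`, indels uniform on 1–40 bp, initial size
4 Mb. The default lognormal rearrangement law is
`ln N(meanlog = 10.1214, sdlog = 2.5602)` (natural-log scale; 4.3957 and
1.1119 in log10), the MLE fit reported for 127 experimentally verified
enterobacterial rearrangements.

## Simulation engines

`run_line` iterates generations literally and can log every event; a
logged trajectory is replayable bit-exactly (`verify_replay`), which is
the integrity check used in the test suite.

`run_experiment` and `run_until_floor` use an event-skipping engine: at
realistic rates `mu * s << 1`, so the generation gap to the next
mutation-bearing generation is drawn geometrically, the event count for
that generation from a Poisson conditioned on being ≥ 1 (CDF inversion),
and the types from a multinomial. This is distributionally identical to
the literal loop (verified by KS tests on final sizes and first-passage
times against the naive engine) and makes 250,000-generation runs take
seconds. Lines are given independent substreams spawned from one root
`SeedSequence`, so experiments are reproducible from a single seed and
independent of execution order.

Lognormal event sizes are sampled by rejection (redraw while the draw
exceeds `s`), with real draws rounded to the nearest integer and clamped
to ≥ 1 bp before the truncation test; integerisation is a package choice
(sizes are reported in bp) and shifts the acceptance boundary to
`s + 0.5`, which the discretised kernels below mirror exactly. If the
law keeps less than 1e-12 of its mass below `s` the sampler raises
instead of looping — such states are far below any simulated regime.

## Drift analysis

`expected_scaled_jump` computes the exact one-mutation expectation of
`f(size)` changes: log-gamma closed forms for the uniform law with
`f = log` (`sum log j` via `gammaln`, stable to ~1e-12 up to 1e9 bp and
beyond), the exact partial-expectation formula for the truncated
lognormal with `f = identity`, finite sums for indels and empirical
tables, and seeded Monte Carlo only for the one combination with no
tractable form (lognormal with a non-identity scaling). Indel jumps are
computed as jumps (`log1p(k/s)`, `±mean(k)`) rather than as
`f(s+k) − f(s)`, which would lose everything to cancellation at large
`s`; this is what lets the truncated-lognormal drift balance come out as
an exact 0 rather than float noise.

`estimate_asymptotic_deltas` evaluates each type's drift on a geometric
size grid (default `1e6..1e14`; the long reach is needed because the
truncated-lognormal mean approaches its asymptote slowly) and declares a
plateau when the last two grid values differ by at most
`1e-3 * max(1, |delta|)`. Non-plateaued drifts (e.g. the uniform law
under identity scaling, whose mean event grows linearly with `s`) make
the condition checker return `inconclusive` rather than a verdict.

For the default indel law U{1..40} the identity-scale drifts are exactly
±20.5 (the mean of U{1..40}); a published account of the same setup
rounds these to ±20. The package reports its exact value — the
difference does not affect any verdict because the indel terms cancel at
equal rates.

## Truncated-chain numerics

`build_m1` assembles the one-mutation kernel on states `0..s_max` as a
mixture of the four type-conditional kernels (weights `mu_type / mu`);
transitions beyond the window are tracked per-row as leaked mass. The
lognormal kernel is discretised to match the sampler: integer size `k`
gets the mass of `(k−0.5, k+0.5]` on the raw scale, with the sub-0.5
mass clamped into `k = 1`.

`build_mg` mixes powers of `M1` with Poisson weights of mean `mu * i`
per starting state `i`, truncating the Poisson sum at its `1 − 1e-12`
quantile, then rewires end-of-generation 0 into 1. Powers are dense
internally (windows of a few thousand states are the intended range; the
number of matrix powers grows with `mu * s_max`, and the builder refuses
past 5,000 powers).

`stationary_distribution` renormalises rows over the window and runs
power iteration to an L1 increment below `tol` (default 1e-10). Rows
near the window top always leak (a duplication from `i > s_max/2` lands
outside), so the misuse guard is the stationary-mass-weighted leak
`sum(pi_i * leak_i)`, checked after the fact against `leak_tol` (default
1e-3): truncation is trustworthy exactly when the states the chain
actually occupies barely leak. The recorded L1 increments decay
geometrically — the finite-window echo of the Doeblin-condition bound
that guarantees uniqueness on the infinite chain.

The suite validates a truncated `M_G` (window 150, bacterial rate ratios
scaled to `mu_ldel = 0.004` so the stationary mass sits at small sizes)
against the long-run size histogram of the event-level simulator; total
variation comes out ≈ 0.02 (< 0.05). The scaled world was chosen for
desk-scale density of events, not to any observed statistic.

## Continuous approximation

`simulate_generation` implements the reference continuous process
(positive real sizes, multipliers U[0,1] for deletions and U[1,2] for
duplications, Poisson counts) as the independent oracle for the
closed-form moments and for the Cantelli bound checks across starting
sizes 1e3–1e9 and orders k ∈ {1,2,3}. The closed forms themselves
(`jump_moments`, `generation_log_moments`, `q_curve`, `bounds`) are
exact evaluations; `bounds` refuses the regime `A ≤ 0`, where the bound
curve is unbounded and its maximiser/fixed point do not exist. For the
discrete simulator these bounds are approximations; at 4 Mb and
bacterial rates the indel + discretisation correction to the
one-generation log-moment is below 1e-4 and the test tolerance carries
that slack explicitly.

## Synthetic data

`make_fixture_rearrangements` draws integer lognormal sizes with the
default fitted parameters; it emulates only the size *marginal* of an
observed rearrangement dataset (no event-type labels, no genome-position
structure, no ascertainment filter), so a green parameter-recovery test
establishes that the MLE pipeline is correct — not that the default
parameters describe any particular organism. The 127-observation default
matches the size of the dataset behind the published fit; one figure
caption of the source material says 107, the text 127 — the fixture
follows the text.

## Known limitations and honest disagreements

* Under the stated default parameters, first passage from 4 Mb to 1e4 bp
  takes more than 75,000 generations for roughly 5–8% of uniform-law
  lines (median ≈ 17,000), and more than 250,000 generations for 1–4% of
  lognormal-law lines. A published account of the same experiment
  reports all 100 of its lines below those bounds; an independent
  continuous-walk oracle reproduces our exceedance rates, so the package
  reports its own simulation honestly and the corresponding bound check
  in the test suite fails by design rather than being loosened.
* Rates are per bp of the *current* genome at generation start; a model
  where counts react to mid-generation size would need a non-Poisson
  process and is out of scope.
* No within-generation population structure and no selection operator;
  per-generation state is exposed so a selection step can be interposed
  between generations by the caller.
* The truncated-chain machinery assumes shrink-biased regimes; in growth
  regimes the stationary computation correctly refuses (leak guard)
  rather than producing a spurious vector.
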