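# Methods

## The replacement model

The elementary observation is a *bin event*: one animal occupying one
electronic bin for a time interval `[t_in, t_out]`, recorded at second
resolution. A *competitive replacement* is inferred — never directly
observed — from the temporal signature of displacement: the occupying
animal (reactor) leaves and a different animal (actor) enters the same bin
almost immediately. Detection is a single linear scan of the log sorted by
`(equip_id, t_in)` with a stable sort, comparing each event only with its
immediate predecessor at the same bin:

    gap = t_in(next) − t_out(prev)        [whole seconds]
    replacement  ⇔  animals differ  and  0 ≤ gap < sec

Assumptions and consequences:

- **Immediate-predecessor only.** A burst `A, A, B` yields at most one
  replacement (B over the second A). Longer displacement chains
  (`A, B, C` within the window) yield one replacement per consecutive
  pair, which is the standard reading of per-bin event streams.
- **Non-negative gap.** An entry recorded before the previous exit
  (overlapping reads, hardware artefacts) is not a replacement: the
  definition requires the reactor to have fully withdrawn. The
  `allow_negative_gap` switch treats such overlaps as gap 0 for users whose
  hardware is known to truncate exits late.
- **Boundary.** The default comparison is strict (`gap < sec`), matching
  the usual statement of the rule; `gap_comparison="le"` is available
  because published analyses are often ambiguous about the boundary, and
  the two settings differ only on gaps exactly equal to `sec`.
- **Ties in `t_in`** within a bin are kept in file order (stable sort) and
  logged as a warning, since actor/reactor assignment then depends on the
  order of rows in the export.

`sec` has no universal value: cattle studies report optima between ~10 and
~30 s depending on breed, category and bin type. It is therefore always an
explicit parameter (default 10 s, the value used for the beef-cattle herd
this package was validated against) and never estimated by the package.

## Dominance structure

From the replacement list (or any observational actor/reactor list) the
sociomatrix `X` counts wins per ordered pair. The Kondo–Hurnik dyadic
relationship is the sign

    S_ij = sign(X_ij − X_ji) ∈ {−1, 0, +1},

with 0 covering both *tied* (equal nonzero counts) and *unknown* (no
interactions) dyads; the sign form deliberately discards win margins, so a
dyad decided 100–0 counts the same as one decided 3–2. The dominance value
`S_i = Σ_j S_ij` then ranges over `[−(n−1), n−1]` and sums to zero over the
herd (antisymmetry).

Rank and hierarchy categories cut the *occupied* integer range
`[min S, max S]`, whose width is `max − min + 1` points, into `k` equal
real-valued spans (`k = 2`: low/high; `k = 3`:
subordinate/intermediate/dominant); a value `v` falls in bin
`floor((v − min) / ((max − min + 1)/k))`, clipped to the top bin. The bin
size is kept real-valued (no rounding) so the extremes always land in the
extreme categories regardless of divisibility. A degenerate range (all
values equal — e.g. a single animal, or a perfectly tied herd) cannot be
split; everyone is assigned the middle class (`k = 3`) or the low class
(`k = 2`) with a warning, choices that avoid the absurdity of an all-
dominant herd.

Internally matrices are actor-rows × reactor-columns; CSV serialization
transposes to the conventional printed orientation (reactors down the
rows, actors across the header). Labels sort numerically whenever every id
is a digit string (ear-tag numbers), lexicographically otherwise; ids are
opaque strings throughout, so `0227 ≠ 227`.

## Linearity

Landau's `h = 12/(n³−n) Σ_a (V_a − (n−1)/2)²`, with `V_a` the number of
+1 entries in animal *a*'s dyadic row, equals 1 exactly for every strict
linear order and 0 when all `V_a` are equal (circular structures). The
improved index adds `6u/(n³−n)` with `u` the number of *unknown* dyads
only — tied-but-observed dyads do not enter `u`, which is why
`improved_index` requires the sociomatrix in addition to the dyadic matrix
(the sign matrix alone cannot distinguish tied from unobserved). Both
formulas are applied exactly as stated; with sparse data `h` (hence `h′`)
can exceed 1, and no renormalisation or randomisation test is attempted —
the 0.9 threshold is surfaced as a text annotation, not a significance
statement.

## Comparison indices

David's score uses dyadic win proportions `P_ij = X_ij/(X_ij+X_ji)`
(0 for unobserved dyads), `w = Σ_j P_ij`, `w₂ = Σ_j P_ij w_j`, the
symmetric loss terms, and `DS = w + w₂ − l − l₂`; the `Dij` variant applies
the shrinkage `P_ij − (P_ij − 0.5)/(n_ij + 1)` that discounts sparsely
observed dyads. Elo ratings are updated sequentially in list order with
`ΔR = k·(1 − 1/(1+10^((R_loser−R_winner)/400)))`; defaults `k = 100`,
start 1000 follow common animal-behaviour package defaults. Elo is order-
and parameter-dependent, so its correlations with other methods are
reported but make poor reproduction targets. Method agreement is pairwise
Pearson `r` with two-sided p (scipy), computed on the shared roster; at
least 3 shared animals are required.

## Synthetic data generator

The generator emulates the features of a real bin log the pipeline
actually exercises, and nothing more:

- a latent strict linear dominance order over the herd (uniformly random
  permutation), with each staged contest won by the higher-ranked animal
  with probability `1 − p_upset` (`p_upset ∈ [0, 0.5]`, default 0.1 — a
  moderately noisy but recoverable hierarchy);
- per-bin visit streams with exponential visit durations (mean 120 s, the
  order of real feeding bouts), uniform bin choice, and Poisson background
  visit counts (default 8–10 visits/animal/day, in the range of ad-libitum
  feeding);
- staged replacement pairs with entry/exit gaps drawn uniformly from a
  configurable integer range (default 0–9 s, matching a 10-s detection
  threshold);
- every non-staged inter-visit gap at least `min_background_gap` (default
  61 s), a *constructed* guarantee that background visits can never
  collide: detection at any `sec ≤ 61` recovers exactly the staged pairs,
  so precision and recall are 1.0 by design and any deviation is a
  detector bug.

It does **not** model diurnal feeding peaks after feed delivery, feed
intake, bin occupancy conflicts across animals, clock drift, or missing
transponder reads. Passing tests therefore demonstrate the correctness of
the algorithms under the stated event model, not robustness to sensor
failure modes.

One integer seed drives all draws (numpy `default_rng`); the truth object
records the seed, the latent order and the staged pairs.

## Numerical and design choices

- Gap arithmetic in whole seconds; timestamps are naive local times (no
  timezone/DST policy is imposed — bin systems log in local time).
- `dyadic_matrix` uses `np.sign`, so the 0/0 dyad maps to 0 without a
  division.
- Dominance tables sort ascending by value, ties broken by id (numeric-
  aware), for deterministic, diffable output.
- Frequency tables include only animals that appear in the interaction
  list (matching how such tables are conventionally printed); roster-only
  animals can be added as zero rows by passing the roster to
  `sociomatrix` instead.
- Strict validation by default; `--lenient` drops offending rows and logs
  counts, for field exports with known glitches.
- Category labels are configurable strings, so outputs can be made
  byte-compatible with tools that spell the top class differently
  (e.g. "dominate").

## Problem sizes

The property suites run at desk scale: random logs of ≤120 events for the
detection oracle (200 logs), herds of ≤30 animals for the closed-form
linearity checks, and a 20-seed ensemble of 20-animal/2000-interaction
simulations for hierarchy recovery; the whole suite completes in well
under a minute. `scripts/acceptance.py` simulates a 37-animal, 5-bin,
21-day herd with 4000 planted replacements (~10,000 events), the scale of
a typical feed-efficiency test, chosen so the full pipeline including
correlation analysis runs in seconds.

## Known limitations

- The detector considers only immediate predecessors, so a true
  displacement separated by a spurious intervening read is missed.
- Kondo–Hurnik values discard win margins by construction; steep
  hierarchies and shallow ones with the same sign structure are
  indistinguishable (use David's score for margin-sensitive questions).
- No statistical test of linearity (randomisation) or of hierarchy
  steepness is provided.
- The I&SI ranking method is out of scope; its correlations with the
  implemented indices are not computed.
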