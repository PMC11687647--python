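# Methods

## The measurement framework

A phrase-prediction log records, per interaction, a user, the partial
query they typed, and the label they selected from the ranked suggestion
list.  Three derived features carry the analysis:

* **QLen** — raw character count of the query, spaces included.
* **Rank** — 1-based position of the selected label in the suggestion
  list returned for the query, recomputed by the completion engine (a
  flag accepts a recorded historical rank instead, for logs that stored
  it).  Records whose label is not retrievable within the cap *J* are
  flagged infeasible and counted, never dropped silently.
* **User-label seniority** — per (user, label) pair, the running count of
  selections: 1 on first use, +1 per repeat.  It is the pseudo-time axis
  for adaptation; calendar timestamps only order events.

For each label *t*, the empirical query space ℙ\* (all distinct
normalized queries observed anywhere in the log) is filtered to queries
that retrieve *t* within the top *J*; each such query contributes a point
(k, j) = (length, rank of *t*).  The Pareto front is the weakly
non-dominated subset under simultaneous minimisation, with duplicate
(k, j) pairs reduced to the lexicographically smallest query.  An
interaction's optimality gap is the Euclidean distance from its
(QLen, Rank) point to the nearest front member, in raw units
(characters × rank positions); a min–max-normalized variant (each axis
scaled by the front's span) is available and reported separately, since
mixing units on one metric is a legitimate concern but the raw form keeps
the two objectives' native scales visible.  ℙ\* is global by default —
a query used for any label counts as available knowledge for every label
it can retrieve — with a per-label-only sensitivity variant.

The string space the queries live in is all non-empty strings over the
query alphabet up to the longest label length L; its size is the
geometric sum Σ_{i=1..L}|Φ|^i = (|Φ|^{L+1}−|Φ|)/(|Φ|−1), implemented for
any alphabet size.  The default alphabet has 37 symbols (a–z, 0–9,
space); accented characters in label texts are folded onto base letters
during normalization, so matching is accent-insensitive.

## The completion engine

Production autocomplete rankers are typically proprietary; all analyses
here require only that completion be a *fixed deterministic function*
from queries to ranked, repetition-free label lists.  The engine
implements a documented stand-in: a label is a candidate when, on its
normalized canonical text or any synonym, (a) the query equals the text,
(b) every space-separated query token is a prefix of some word of the
text, or (c) the query is a contiguous substring.  Candidates order by
match class (a > b > c), then shorter canonical text, then ascending
label id; the list truncates to J (default 30, configurable).  Extending
the query can only shrink the *candidate set* (each match class is
monotone under extension), matching the incremental-narrowing behaviour
of real widgets; note that under a finite cap a label can still *enter*
the visible top-J window as competitors drop out, which is why the
narrowing property is stated on uncapped candidate sets.

## The synthetic study conditions

The simulator emulates the statistical regime of a hospital log rather
than any particular dataset:

* **Terminology.**  Labels are 2–3-word French-like clinical texts from a
  bundled word pool.  Half of the label mass (`family_fraction = 0.5`)
  forms families: a base label plus up to three qualified variants
  ("… sévère", "… stade 2").  Every family member carries the base
  acronym as a synonym — the family's *jargon idiom* (the "hta" pattern):
  it retrieves all members, ranked best for the base.  Variants usually
  (`private_acronym_prob = 0.85`) also carry a distinctive private
  synonym of the same length as the idiom, which retrieves them at rank
  1.  This structure is what makes idiom queries feasible everywhere but
  optimal only for base labels.
* **Label popularity.**  Selection probabilities follow a Zipf law,
  weight ∝ rank^(−s) with s = 1 by default, assigned to labels by a
  seeded permutation.  Users are drawn uniformly.
* **Agent policy.**  A pair's first query is the label's idiom with
  probability `idiom_start_prob = 0.8` (when one exists), else a random
  2–8-character prefix of the label text, grown until feasible.  At
  seniority s the agent reconsiders with probability
  ε(s) = ε₀·decay^(s−1) (defaults ε₀ = 0.8, decay = 0.85, chosen so that
  naive initial queries fade over roughly the first five selections): it
  samples three candidates from a deterministic pool (text prefixes, own
  synonyms, own acronym, first-word + second-word-prefix combinations)
  and adopts the best candidate that *weakly Pareto-dominates* its
  current query on (k, j), preferring lower rank.  A scalarized variant
  (weighted k + j) sits behind a config switch for sensitivity checks.
  Because adoption requires weak dominance, a query never gets longer;
  the real-world pattern of switching from a short ambiguous idiom to a
  longer distinctive word is represented structurally by switching to an
  equally short distinctive synonym.
* **Determinism.**  All randomness flows from one `numpy` generator
  seeded by `config.seed`; identical configs reproduce logs exactly.
  Timestamps are integer ticks.

What the generator does *not* model: typing errors, visual scan time,
user-specific activity rates, calendar seasonality, or any cognitively
grounded exploration strategy.  Passing tests on these conditions show
that the *pipeline* detects adaptation when it is present and reports
none when it is absent — they say nothing about whether any particular
real user population adapts.

## Trajectory analyses

Curves report, per seniority level, the count, arithmetic mean and
*population* standard deviation (each level is treated as the full set of
occurrences at that level) of distance, QLen or rank.  Because rarely
chosen labels never reach high seniority, the label population would
otherwise drift along the axis; the **consistency filter** keeps only
labels attained at the cap level by at least one pair ("absent in the
highest seniority" is read as "not attained at the cap"; the stricter
"absent at ≥ cap" reading would be equivalent here since per-pair
seniorities are contiguous).  The cap itself can be chosen by the
**representativeness report**: pairs reaching level ℓ are a sample of the
N pairs at level 1, with worst-case (p = 0.5) margin of error
e = z·√(0.25/n)·√((N−n)/(N−1)) (Cochran margin with finite-population
correction; z exposed as a parameter, default from the requested
confidence); the cap is the largest level at which every level below
meets the margin.  Mean curves are smoothed with a Savitzky–Golay filter
(default window 11, polynomial order 2, configurable), edge windows
handled by polynomial fit on the truncated window so polynomial inputs
pass through exactly.

The **trend test** fits an ordinary least-squares line to the per-level
means and bootstraps its slope by resampling whole (user, label)
trajectories — records within a pair are strongly dependent (identical,
when adaptation is off), so a record-level bootstrap would understate
variance.  By default the panel is *balanced*: only pairs observed at
every level up to the cap enter, so the slope measures within-pair change
and is immune to the composition drift that otherwise masquerades as a
trend (longer-lived pairs differ systematically from short-lived ones).
This is the null guard: with adaptation disabled the balanced slope is
zero up to floating-point noise and its 95% CI covers 0, while
adaptation-enabled runs give a clearly negative slope.

## Idiom tracking and Zipf fits

Idiom membership is exact match after normalization against a supplied
lexicon (idioms are standalone queries, not substrings; a prefix mode
exists but is off by default).  The proportion curve restricts to labels
that ever received an idiom query and reports numerator, denominator and
activity count per level so every proportion is independently
recomputable.  Case-study tables partition one label's records into
seniority zones (default cuts 5 and 10 → zones A/B/C) with per-zone query
counts and current ranks.  For generated terminologies the paired lexicon
is the set of synonyms shared by more than one label; private
single-label synonyms are treated as user shortcuts, not community
jargon.

Rank-frequency tables give ties distinct consecutive ranks (alphabetical
within a tie, a documented and configurable choice).  Power-law exponents
are estimated by OLS on log10-log10 over a configurable rank range
(default head ranks 1–100, avoiding the flattened low-frequency tail);
maximum-likelihood exponent estimation and formal power-law hypothesis
tests are out of scope.

## Problem sizes and numerical choices

The bundled study conditions are 200 users × 300 labels × 50,000 events
at Zipf s = 1, analysed to seniority level 20 over five simulation seeds
(the acceptance script uses three adaptation runs and two control runs);
idiom-decline checks use 80 × 120 × 15,000.  These sizes give every
reported level several hundred records while keeping a full run in tens
of seconds.  Degenerate inputs are errors, not silent defaults: empty
normalized queries, unknown label ids, non-positive Zipf exponents,
even windows, caps beyond the observed seniority.  Completion results are
memoised per distinct normalized query, which is what keeps the
simulation and enrichment linear in practice (agents reuse a small pool
of queries).

## Known limitations

* The completion engine is a stand-in; absolute rank values (hence
  absolute distances) depend on its scoring and are not comparable to any
  particular production system.
* The dominance-based adoption rule cannot lengthen a query, so
  efficiency-sacrificing adaptation (longer but more accurate queries) is
  only represented via equally short distinctive synonyms.
* Distance mixes characters and rank positions unless the normalized
  variant is chosen.
* The agent policy's only committed property is
  convergence-when-enabled; its exploration schedule is not fitted to
  human data.
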