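# zipfadapt

Do users of an autocomplete tool adapt their queries toward an optimum, the
way Zipf's least-effort principle predicts?  `zipfadapt` is an analysis
pipeline for interaction logs of *phrase-prediction* systems — the
type-ahead widgets clinicians use to select a label from a closed problem
list by typing a partial query.  It quantifies, per label, the trade-off
between two competing pressures:

* **conciseness** — the query length *k* (QLen, characters typed);
* **distinctiveness** — the rank *j* at which the selected label appears
  in the suggestion list.

For a target label *t*, every query *p* observed in the log (the empirical
query space ℙ\*) that retrieves *t* within the top *J* suggestions is a
point (k, j).  Minimising both objectives simultaneously yields the
label's **Pareto front**

    O(t) = { p ∈ ℙ* : no p′ ∈ ℙ* has k′ ≤ k and j′ ≤ j with one strict },

and the Euclidean distance from an interaction's (QLen, Rank) point to the
nearest front member measures how far that interaction is from optimal.
Tracking this distance against **user-label seniority** — the number of
times a given user has selected a given label — tests whether experience
drives queries toward the front, and tracking the two objectives
separately shows whether the adaptation is efficiency-driven (shorter
queries) or accuracy-driven (better ranks).  Companion modules track the
use of medical-jargon idioms ("hta", "avc", "bpco") across seniority and
fit power-law exponents to rank-frequency tables of words, queries and
selected labels.

Real hospital logs are confidential, so the package ships a seeded
simulator that emulates their statistical regime (Zipf-distributed label
popularity, repeated user-label selections, jargon-heavy early queries,
optional adaptation) together with a deterministic stand-in completion
engine; every analysis runs end to end with no external data.

## Worked example

```python
from zipfadapt import *

term = generate_terminology(120, seed=4)
lexicon = idiom_lexicon_for(term)
config = SimulationConfig(n_users=80, n_labels=120, n_events=15_000, seed=4)
engine = CompletionEngine(term, J=30)
log = records_to_frame(simulate_log(config, term, lexicon, engine=engine))
enriched = enrich(log, term, J=config.J, engine=engine)           # QLen, Rank, seniority
fronts = compute_fronts(enriched, engine)                          # per-label Pareto fronts
dist = annotate_distance(enriched, fronts)                         # distance to front

curve = curve_by_seniority(consistency_filter(dist, 15), "distance", s_max=15)
print(curve.head(3).to_string(index=False))

prop = idiom_proportion_by_seniority(enriched, lexicon, 10).set_index("level")
print(f"idiom share: level 1 = {prop.loc[1,'proportion']:.2f}, "
      f"level 10 = {prop.loc[10,'proportion']:.2f}")

fit = powerlaw_fit(rank_frequency([str(l) for l in enriched.label_id]), 1, 60)
print(f"label rank-frequency slope = {fit.slope:.3f} (r^2 = {fit.r_squared:.3f})")
```

prints

```
 level   n     mean      std
     1 400 2.208031 1.219467
     2 398 1.760564 1.222039
     3 398 1.485071 1.181130
idiom share: level 1 = 0.77, level 10 = 0.46
label rank-frequency slope = -0.980 (r^2 = 0.998)
```

Reading the output: at the first selection of a label, interactions sit on
average 2.2 units (characters × rank positions) from that label's Pareto
front; by the third selection the mean has already dropped to 1.5 — users'
queries converge toward the conciseness/distinctiveness optimum as they
gain experience.  The share of jargon-idiom queries falls from 77% of
first selections to 46% by the tenth, and selected-label frequencies
follow a power law with exponent ≈ −1 (Zipf's law).

The same pipeline is available as a CLI over CSV/YAML artifacts:

```sh
zipfadapt all --config config.yaml --seed 1 --out out/
```

with stages `simulate`, `enrich`, `pareto`, `adapt`, `idioms`, `zipf`,
`report`; reruns with the same config and seed are byte-identical.

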