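# Methods

## Model and procedure

`geocna` analyses a table of cases (neighborhoods keyed by ZCTA strings)
described by multi-value factors — calibrated levels of social conditions —
and one designated binary outcome. The method is set-theoretic, not
probabilistic: a conjunction X of factor-level conditions is evaluated by
its *extension* ext(X), the set of cases instantiating it, and two
descriptive fit measures against the outcome literal Y:

- consistency(X → Y) = |ext(X) ∩ ext(Y)| / |ext(X)| — among cases showing
  the configuration, the share that show the outcome (sufficiency fit);
- coverage(X → Y) = |ext(X) ∩ ext(Y)| / |ext(Y)| — among outcome cases,
  the share the configuration explains (empirical importance).

Both are undefined (an error, never 0 or 1) on an empty reference set.
They are dual: coverage(X → Y) = consistency(Y → X).

**Literals and minimality.** A literal restricts one factor to a
non-empty proper subset of its levels; `ICEBLACK=0|1` ("low or medium
concentrated racial privilege") is a single literal, so published
solution formulas are representable verbatim. A conjunction (at most one
literal per factor, order 1–3 by default) is a *minimally sufficient
condition* (MSC) at consistency threshold t when it is instantiated,
meets t, and no weakening of it does — where a weakening drops a literal
or enlarges a literal's value set while remaining non-trivial. The
enlargement clause canonicalizes value sets: `EDU=0` is not retained when
`EDU=0|1` is equally sufficient. One consequence of value-set literals is
that "sideways" minimal configurations can coexist with a simpler one
that neither subsumes nor is subsumed by them; final model selection
resolves this by preferring simpler formulas at equal fit.

**Threshold-lowering search.** The condition table is first computed at
consistency 1.00; while it holds fewer than `min_rows` (default 2)
configurations, the threshold is lowered in steps of 0.05 and the table
recomputed, recording a (threshold, row count) trail. The scan of all
conjunctions is done once and reused across thresholds, so the trail is
cheap and exactly auditable.

**Model building.** Candidate solution formulas are disjunctions of 1 to
`max_disjuncts` MSC rows. A candidate must meet the consistency level and
a coverage floor, and be redundancy-free: every pathway must cover at
least one outcome case no other pathway covers (this also excludes
structurally nested pathways). Candidates are ranked by consistency
(desc), then coverage (desc), then complexity (total literal count, asc).
A unique top candidate is the final model; an exact tie on all three keys
is *model ambiguity* — surfaced, never silently broken. Model development
descends consistency levels from the search's stop threshold; a level
whose candidates all tie does not yield a final model, so the descent
continues (the shallowest tied set is reported if the floor is reached).

**Causal asymmetry.** The outcome and its negation (the complement
literal) are analyzed by two fully independent runs of the chain above;
nothing is inferred about one side from the other.

## Parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `max_order` | 3 | largest conjunction scanned; one- to three-condition configurations |
| `start`, `step` | 1.00, 0.05 | threshold-lowering schedule of the factor-selection search |
| `min_rows` | 2 | stop once at least two configurations qualify |
| `cov_threshold` | 0.75 | coverage floor for candidate models; a "model" explaining less than three quarters of the outcome cases is not considered a solution |
| `max_disjuncts` | 5 | pathway budget; exhaustive search is trivial at this scale |
| `max_complexity` | 6 | total literal budget of a model; guards against overfit unions of many hyper-specific configurations (the same role as the step/complexity caps of standard CNA software) |
| `con_floor` | 0.5 | below even odds, sufficiency talk is meaningless; the search stops |
| `max_rows` | 20 | highest-coverage MSC rows considered per level (only they can combine into a covering disjunction) |

Consistency/coverage comparisons against thresholds use the integer
counts with a 1e-9 tolerance, so 28/30 ≥ 0.9333… behaves exactly.
Reported scores are rounded half-up to two decimals for display; stored
values keep full precision.

## Calibration

Every scheme is two ordered cut points with a total interval closure,
default *right-closed*: low = (−∞, c1], medium = (c1, c2], high =
(c2, ∞). The shipped default schemes encode the study region's published
cut points — education 20/40.1 (%), uninsured 6.5/9.7, limited English
2.2/4.7, transit use 21.4/29.5, service employment 7.9/9.8, overcrowding
1.7/2.4, ICE-Income −0.23/0.07, ICE-BlackNH −0.37/0.47 — and the three
monthly vaccination-rate categorizations (≤1500/≤2000, ≤2500/≤3400,
≤3400/≤4500 per 10,000). The source descriptions mix interval notations
("≤ 20%", "> 20 and 40.1%", "< 1500 / 1501–2000"), which leave boundary
membership and small gaps ambiguous; the right-closed convention matches
the majority "≤ … coded as zero" phrasing and makes calibration a total,
deterministic partition. Tertile mode computes the 33rd/67th percentiles
by linear interpolation (numpy's default; configurable to nearest-rank),
with values exactly at a percentile going to the outer category.
Degenerate (constant) factors raise an error rather than silently
producing a one-level factor. ICE accepts raw counts or proportions;
(privileged − deprived)/total is the standard construction.

Meta-factor dual calibration maps a three-level factor to two binaries
(high = level 2; low = level 0); the pair is information-preserving and
yields extensions identical to the corresponding value-set literals.

## Synthetic data

The generator emulates the study's shape: 43 cases, 8 three-level social
factors, a planted rule `EDU=0*ICEBLACK=0|1` satisfied by exactly 13
cases, and a binary persistent outcome derived from three monthly rate
levels. Raw values are back-filled uniformly inside each level's interval
(open ends inset by ~1e-9) within the published observed ranges, so
calibrating the raw table reproduces the planted levels exactly at every
seed. ICE factors are emitted as (privileged, deprived, total) proportion
triples that reproduce the sampled ICE value. Outcome noise flips each
case's outcome independently with probability ε; the truth record lists
the flips. Two structural guarantees are enforced by bounded redraws:
every factor occupies all three levels, and the planted rule is
*identifiable* — for each literal and each excluded level there is a
rule-violating near-miss case, so neither dropping a literal nor
enlarging a value set explains the data equally well. Without the second
guarantee a draw can render the planted rule indistinguishable from a
simpler one, which is a property of the data, not of the search.

What the generator does not emulate: spatial autocorrelation between
neighboring ZCTAs, correlated social conditions (factors are drawn
independently given the rule), measurement error in the raw variables,
and sampling error in survey estimates. Passing recovery tests therefore
show that the engine inverts its own generative model at study scale,
not that real cities yield unique models.

The deterministic fixture reconstructs the published cross-classification
instead: 13 outcome-positive cases; the positive pathway
`EDU=0*ICEBLACK=0|1` instantiated by 12 cases, 11 of them positive; the
negative pathway `EDU=1|2 + ICEBLACK=2` instantiated by 30 cases, 28 of
the 29 negative cases among them. These printed counts jointly determine
a 42-case universe (the two pathway extensions are exact set complements,
12 + 30 = 42, and 13 + 29 = 42), although the study text states 43
neighborhoods; the default fixture reproduces the printed counts exactly
with 42 cases, and an `extra_case=True` variant appends the unaccounted
case to a negative-pathway cell to reach the stated total (which shifts
the negative side's recount to 29/31 and 29/30). Filler factors are
deterministic rotations of one balanced base pattern, constructed so that
every filler level mixes outcome-positive and outcome-negative cases and
the two-factor solution emerges from the full pipeline.

## Numerical and design choices

- Case identifiers are opaque strings; leading zeros in ZCTAs survive.
- All outputs are canonically ordered (rows by consistency, coverage,
  order, then string; literals alphabetically, levels ascending), so
  identical inputs give byte-identical artifacts.
- The canonical grammar is `FACTOR=v1|v2`, `*` for conjunction, ` + ` for
  disjunction; it parses back losslessly.
- Extensions are bit-packed into integers; the exhaustive scan is
  popcount arithmetic and is reused across thresholds.
- Missing raw values are hard errors by default (`drop_missing` opts into
  complete-case analysis); a silent drop would change |ext(Y)| and with
  it every coverage value.
- The membership GeoJSON export only annotates feature properties;
  geometry is passed through byte-identical.

## Limitations

- Crisp (non-fuzzy) calibration only; no continuous set membership.
- Single binary outcome per run; no causal chains or multi-outcome
  structures.
- The negative-pathway counts printed in the source sum to one fewer
  case than the stated study size; the fixture documents rather than
  resolves this (see above), and per-ZCTA assignments of the real city
  are not reconstructable from printed counts alone.
- Exhaustive enumeration is sized for tens of cases and ~8 factors
  (order ≤ 3); it is not intended for hundreds of factors.
- Consistency and coverage are descriptive fits; no inferential
  uncertainty (confidence intervals, robustness ranges) is attached.
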