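# geocna

Geoconfigurational analysis of neighborhood health outcomes: multi-value
calibration of social conditions, coincidence-analysis-style search for
minimally sufficient conditions, and asymmetric consistency/coverage-based
model building.

## The problem

Neighborhood health inequities — here, persistently low COVID-19
vaccination rates across a city's ZIP Code Tabulation Areas (ZCTAs) — are
rarely explained by any single social condition. Configurational
comparative methods (CCMs), including coincidence analysis (CNA), ask a
different question than regression: *which combinations of conditions,
when present together, suffice for the outcome?* They work on small-N,
case-based data (tens of neighborhoods), allow multiple pathways to the
same outcome (equifinality), and treat the presence and the absence of an
outcome as separate analyses (causal asymmetry).

`geocna` implements this workflow end to end for tables of neighborhood
social conditions:

1. **Calibration** — each raw variable (% college educated, % uninsured,
   % limited-English households, % service employment, % public-transit
   use, % overcrowded households, and two Index of Concentration at the
   Extremes measures, ICE-Income and ICE-BlackNH) is mapped to three
   ordered levels (0 = low, 1 = medium, 2 = high) by fixed cut points or
   tertiles. ICE = (privileged − deprived) / total ∈ [−1, 1]. The binary
   outcome "persistently low" is 1 iff the vaccination-rate level is low
   at all three monthly observation dates.
2. **Minimally sufficient conditions (MSC)** — for an outcome literal Y
   and a conjunction X of factor-level conditions,

       consistency(X → Y) = |ext(X) ∩ ext(Y)| / |ext(X)|
       coverage(X → Y)    = |ext(X) ∩ ext(Y)| / |ext(Y)|

   where ext(·) is the set of cases instantiating a condition. The engine
   exhaustively scans all one-, two- and three-condition configurations
   (value-set literals such as `ICEBLACK=0|1`, "low or medium", are
   first-class), keeps those meeting a consistency threshold, and prunes
   any configuration with a simpler equally-sufficient form. The
   threshold starts at 1.00 and is lowered in steps of 0.05 until at
   least two configurations qualify, with the full trail recorded.
3. **Model building** — candidate solution formulas (disjunctions of
   MSCs) are scored by model-level consistency and coverage; the final
   model is the unique best under (consistency, coverage, simplicity),
   and ties are reported as model ambiguity rather than silently broken.
   The outcome and its negation are analyzed independently.

A synthetic-data generator plants Boolean causal rules with controllable
outcome-flip noise in raw-variable city tables (calibration of the
generated raw table reproduces the planted levels exactly), and a
deterministic fixture reconstructs the published Philadelphia
cross-classification counts for regression testing.

## Worked example

```python
import geocna as g

res = g.CNA.from_case_table(g.build_study_fixture()).fit()
print(res.summary())
```

prints

```
cases: 42
outcome-positive cases: 13
condition table rows (factor selection): 49
--- outcome side: PLOW=1 ---
threshold trail (threshold:rows): 1.00:49, 1.00:49, 0.95:49, 0.90:44
final model: EDU=0*ICEBLACK=0|1  consistency 0.92 (11/12)  coverage 0.85 (11/13)
--- negation side: PLOW=0 ---
threshold trail (threshold:rows): 1.00:68, 1.00:68, 0.95:68, 0.90:2
final model: EDU=1|2 + ICEBLACK=2  consistency 0.93 (28/30)  coverage 0.97 (28/29)
```

Read: low college education AND low/medium concentrated racial privilege
jointly identify persistently low vaccination rates (11 of the 12
neighborhoods instantiating the pair have the outcome, and the pair covers
11 of the 13 outcome neighborhoods), while medium/high college education
OR high concentrated racial privilege — two independent pathways — identify
the neighborhoods without persistently low rates. The structural contrast
between the two sides (a conjunction versus a disjunction) is causal
asymmetry.

The same surface fits synthetic cities:

```python
raw, cases, truth = g.generate(g.SyntheticSpec(seed=0, noise=0.0))
res = g.CNA.from_raw(raw).fit()
assert str(res.solution) == truth["rule"]      # planted rule recovered
```

A command-line interface mirrors the library: `geocna run`, `calibrate`,
`msc`, `model`, `simulate`, `fixture` (see `geocna --help`).

## Layout

- `src/geocna/calibration.py` — schemes, ICE, tertiles, dual calibration
- `src/geocna/cna_core.py` — literals, extensions, consistency/coverage,
  MSC enumeration, threshold search
- `src/geocna/model_builder.py` — candidate solutions, ambiguity,
  asymmetric analysis
- `src/geocna/pipeline.py` — end-to-end run, artifacts, summary
- `src/geocna/synthetic_data.py` — planted-rule generator, fixture
- `src/geocna/data_model_io.py` — CSV/GeoJSON I/O, membership export
- `src/geocna/model.py` — `CNA` / `CNAResults` modelling surface
- `docs/methods.md` — methods note (assumptions, parameters, limitations)
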