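"""Synthetic neighborhood tables with planted configurational structure.

Two distinct constructions live here:

* :func:`generate` draws a raw-variable city table whose calibrated levels
  hide a planted Boolean causal rule with a controllable outcome-flip noise
  rate.  Raw values are back-filled uniformly inside each level's interval
  so that calibrating the raw table with the shipped schemes reproduces the
  planted levels exactly — the round trip is an identity by construction.

* :func:`build_study_fixture` deterministically reconstructs a case table
  matching the published cross-classification counts for the Philadelphia
  study (positive pathway 11/12 consistent, 11/13 covering; negative
  pathway 28/30 consistent, 28/29 covering).  Those printed counts jointly
  describe 42 neighborhoods although the study states 43; the default
  fixture reproduces the printed cross-classification exactly (42 cases),
  and ``extra_case=True`` appends the unaccounted neighborhood to the
  negative-pathway cell to reach the stated total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import DEFAULT_SCHEMES, RAW_RANGES, calibrate_fixed
from .cna_core import Conjunction, Literal, parse_disjunction
from .data_model_io import CaseTable, RawTable
from .errors import GenerationError, IntegrityError

__all__ = [
    "SyntheticSpec",
    "generate",
    "build_study_fixture",
    "SOCIAL_FACTORS",
    "OUTCOME_NAME",
    "MONTH_FACTORS",
]

SOCIAL_FACTORS = ["EDU", "UNINS", "LEP", "TRANSIT", "SERVICE", "CROWD",
                  "ICEINC", "ICEBLACK"]
MONTH_FACTORS = ["VAX_MARCH", "VAX_APRIL", "VAX_MAY"]
OUTCOME_NAME = "PLOW"  # persistently-low vaccination outcome

# raw CSV column layout emitted by the generator (and expected by the
# default pipeline configuration)
RAW_COLUMN_OF = {
    "EDU": "pct_college",
    "UNINS": "pct_uninsured",
    "LEP": "pct_limited_english",
    "TRANSIT": "pct_transit",
    "SERVICE": "pct_service",
    "CROWD": "pct_overcrowded",
    "VAX_MARCH": "vax_rate_march",
    "VAX_APRIL": "vax_rate_april",
    "VAX_MAY": "vax_rate_may",
}
ICE_COLUMNS_OF = {
    "ICEINC": ("income_privileged", "income_deprived", "income_total"),
    "ICEBLACK": ("black_nh_privileged", "black_nh_deprived", "black_nh_total"),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the generator.

    Defaults emulate the study city: 43 neighborhoods, 8 three-level social
    factors, a two-factor planted rule, and 13 rule-satisfying cases.
    ``noise`` is the probability that a case's outcome is flipped away from
    the rule's prediction; ``planted_rule=None`` yields a pure-noise city in
    which the outcome is independent of every factor.
    """

    n_cases: int = 43
    factors: tuple[str, ...] = tuple(SOCIAL_FACTORS)
    planted_rule: str | None = "EDU=0*ICEBLACK=0|1"
    n_positive: int | None = 13
    noise: float = 0.0
    prevalence: float = 13 / 43  # outcome rate when no rule is planted
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.noise < 0.5):
            raise GenerationError("noise must lie in [0, 0.5)")
        if self.planted_rule is not None:
            for conj in parse_disjunction(self.planted_rule):
                for lit in conj.literals:
                    if lit.factor not in self.factors:
                        raise GenerationError(
                            f"planted rule references undeclared factor {lit.factor!r}"
                        )
        if self.n_positive is not None and not (0 < self.n_positive < self.n_cases):
            raise GenerationError("n_positive must lie strictly between 0 and n_cases")


def _satisfies(levels: dict[str, int], rule: list[Conjunction]) -> bool:
    return any(
        all(levels[l.factor] in l.levels for l in conj.literals) for conj in rule
    )


def _identifiable(cases: list[dict[str, int]], rule: list[Conjunction],
                  domains: dict[str, set[int]]) -> bool:
    """True when the planted rule is uniquely recoverable from the cases:
    for every disjunct, every literal and every excluded level, some
    rule-violating case satisfies the disjunct's other literals while
    holding that level — blocking both literal-dropping and value-set
    enlargement as equally good explanations."""
    for conj in rule:
        for lit in conj.literals:
            others = [l for l in conj.literals if l is not lit]
            for v in domains[lit.factor] - lit.levels:
                if not any(
                    c[lit.factor] == v
                    and all(c[o.factor] in o.levels for o in others)
                    and not _satisfies(c, rule)
                    for c in cases
                ):
                    return False
    return True


def _draw_case(
    rng: np.random.Generator,
    factors: Sequence[str],
    rule: list[Conjunction] | None,
    want: bool | None,
    max_tries: int = 1000,
) -> dict[str, int]:
    """Draw one case's levels; if ``want`` is set, condition on the rule."""
    for _ in range(max_tries):
        levels = {f: int(rng.integers(0, 3)) for f in factors}
        if want is True and rule:
            # force one disjunct to hold, then re-check (cheap and exact)
            conj = rule[int(rng.integers(0, len(rule)))]
            for lit in conj.literals:
                levels[lit.factor] = int(rng.choice(sorted(lit.levels)))
        if want is None or rule is None or _satisfies(levels, rule) == want:
            return levels
    raise GenerationError("could not draw a case matching the planted rule")


def _backfill_raw(rng: np.random.Generator, factor: str, level: int) -> float:
    """Uniform raw value inside the level's interval, open ends inset so the
    calibration round trip is exact."""
    scheme = DEFAULT_SCHEMES[factor]
    lo, hi = RAW_RANGES[factor]
    c1, c2 = scheme.cuts
    eps = 1e-9 * max(1.0, abs(c1), abs(c2))
    bounds = {0: (lo, min(c1, hi)), 1: (c1 + eps, c2), 2: (c2 + eps, hi)}[level]
    value = float(rng.uniform(*bounds))
    assert calibrate_fixed(value, scheme) == level
    return value


def _ice_components(ice: float) -> tuple[float, float, float]:
    """Proportion triple (privileged, deprived, total=1) reproducing ``ice``."""
    s = max(0.8, abs(ice))
    return ((s + ice) / 2.0, (s - ice) / 2.0, 1.0)


def generate(spec: SyntheticSpec) -> tuple[RawTable, CaseTable, dict]:
    """Generate ``(raw_table, case_table, truth)`` under ``spec``.

    The truth record stores the planted rule, the outcome-flip list, the
    per-case rule satisfaction, and the seed.
    """
    rng = np.random.default_rng(spec.seed)
    rule = parse_disjunction(spec.planted_rule) if spec.planted_rule else None
    case_ids = [f"19{100 + i:03d}" for i in range(1, spec.n_cases + 1)]

    for attempt in range(100):
        if rule is not None and spec.n_positive is not None:
            sat_flags = np.zeros(spec.n_cases, dtype=bool)
            sat_flags[rng.choice(spec.n_cases, spec.n_positive, replace=False)] = True
            cases = [
                _draw_case(rng, spec.factors, rule, bool(w)) for w in sat_flags
            ]
        else:
            cases = [_draw_case(rng, spec.factors, rule, None)
                     for _ in range(spec.n_cases)]
            sat_flags = np.array(
                [
                    _satisfies(c, rule) if rule is not None
                    else bool(rng.random() < spec.prevalence)
                    for c in cases
                ]
            )
        levels = pd.DataFrame(cases, index=pd.Index(case_ids, name="zcta"))
        # every factor must occupy all three levels, and the planted rule
        # must be identifiable from the drawn cases
        if all(levels[f].nunique() == 3 for f in spec.factors) and (
            rule is None
            or _identifiable(cases, rule, {f: {0, 1, 2} for f in spec.factors})
        ):
            break
    else:
        raise GenerationError("level occupancy unsatisfied after bounded retries")

    flips = rng.random(spec.n_cases) < spec.noise
    outcome = (sat_flags ^ flips).astype(int)
    if outcome.min() == outcome.max():
        raise GenerationError("degenerate outcome after noise; adjust spec")
    levels[OUTCOME_NAME] = outcome

    # monthly vaccination levels consistent with the persistent-low outcome
    triples = []
    nonlow = [t for t in np.ndindex(3, 3, 3) if t != (0, 0, 0)]
    for y in outcome:
        triples.append((0, 0, 0) if y else nonlow[int(rng.integers(0, len(nonlow)))])
    month_levels = pd.DataFrame(triples, columns=MONTH_FACTORS, index=case_ids)

    raw = {}
    for f in spec.factors:
        col_vals = [_backfill_raw(rng, f, lv) for lv in levels[f]]
        if f in ICE_COLUMNS_OF:
            comp = [_ice_components(v) for v in col_vals]
            for j, col in enumerate(ICE_COLUMNS_OF[f]):
                raw[col] = [c[j] for c in comp]
        else:
            raw[RAW_COLUMN_OF[f]] = col_vals
    for f in MONTH_FACTORS:
        raw[RAW_COLUMN_OF[f]] = [_backfill_raw(rng, f, lv) for lv in month_levels[f]]

    raw_df = pd.DataFrame(raw, index=pd.Index(case_ids, name="zcta"))
    case_table = CaseTable(
        levels=levels,
        outcome_name=OUTCOME_NAME,
        domains={**{f: frozenset({0, 1, 2}) for f in spec.factors},
                 OUTCOME_NAME: frozenset({0, 1})},
    )
    truth = {
        "rule": spec.planted_rule,
        "seed": spec.seed,
        "noise": spec.noise,
        "satisfies_rule": {cid: bool(s) for cid, s in zip(case_ids, sat_flags)},
        "flipped": [cid for cid, fl in zip(case_ids, flips) if fl],
    }
    return RawTable(data=raw_df, case_id_column="zcta"), case_table, truth


# --- deterministic count-matched fixture ---------------------------------

# cell layout: (n, outcome, EDU, ICEBLACK, filler base classes)
_FIXTURE_CELLS = [
    # covered positives: low education AND low/medium racial privilege
    (8, 1, 0, 0, [0, 0, 0, 1, 1, 1, 2, 2]),
    (3, 1, 0, 1, [0, 1, 2]),
    # the one inconsistent case on the positive pathway
    (1, 0, 0, 0, [0]),
    # uncovered positives (outside the positive pathway)
    (1, 1, 1, 2, [0]),
    (1, 1, 2, 0, [1]),
    # negatives outside both printed pathway cells
    (2, 0, 0, 2, [0, 1]),
    # covered negatives along the two negative pathways
    (13, 0, 1, 2, [0, 0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2]),
    (11, 0, 2, 0, [0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2]),
    (2, 0, 1, 0, [1, 2]),
]

_FIXTURE_FILLERS = ["UNINS", "LEP", "TRANSIT", "SERVICE", "CROWD", "ICEINC"]


def build_study_fixture(extra_case: bool = False) -> CaseTable:
    """Deterministic case table matching the printed cross-classification.

    The positive pathway ``EDU=0*ICEBLACK=0|1`` instantiates 12 cases of
    which 11 are outcome-positive; the negative pathway
    ``EDU=1|2 + ICEBLACK=2`` instantiates 30 cases of which 28 are
    outcome-negative; 13 cases carry the persistently-low outcome.  Filler
    factors are deterministic rotations of a balanced base pattern that is
    independent of the outcome.  Validated by direct recount on build.
    """
    rows = []
    for n, y, edu, ice, bases in _FIXTURE_CELLS:
        assert len(bases) == n
        for b in bases:
            rows.append((y, edu, ice, b))
    if extra_case:
        rows.append((0, 2, 0, 2))  # unaccounted neighborhood, negative pathway
    case_ids = [f"19{100 + i:03d}" for i in range(1, len(rows) + 1)]
    records = {}
    records[OUTCOME_NAME] = [r[0] for r in rows]
    records["EDU"] = [r[1] for r in rows]
    records["ICEBLACK"] = [r[2] for r in rows]
    for j, f in enumerate(_FIXTURE_FILLERS, start=1):
        records[f] = [(r[3] + j) % 3 for r in rows]
    levels = pd.DataFrame(records, index=case_ids)
    table = CaseTable(
        levels=levels,
        outcome_name=OUTCOME_NAME,
        domains={**{f: frozenset({0, 1, 2}) for f in SOCIAL_FACTORS},
                 OUTCOME_NAME: frozenset({0, 1})},
    )
    _validate_fixture(table, extra_case)
    return table


def _validate_fixture(table: CaseTable, extra_case: bool) -> None:
    from .cna_core import extension, parse_conjunction

    y = Literal(OUTCOME_NAME, [1])
    pos = extension(parse_conjunction("EDU=0*ICEBLACK=0|1"), table)
    neg = extension(parse_disjunction("EDU=1|2 + ICEBLACK=2"), table)
    y_ext = extension(y, table)
    n_y = len(y_ext)
    checks = {
        "positive instantiating": (len(pos), 12),
        "positive overlap": (len(pos & y_ext), 11),
        "outcome prevalence": (n_y, 13),
        "negative instantiating": (len(neg), 31 if extra_case else 30),
        "negative overlap": (
            len(neg - y_ext), 29 if extra_case else 28),
    }
    for name, (got, want) in checks.items():
        if got != want:
            raise IntegrityError(f"fixture self-check failed: {name} = {got}, expected {want}")
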