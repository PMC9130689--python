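"""Configurational engine: literals, conjunctions, consistency/coverage,
minimally sufficient conditions, and the iterative threshold search.

The engine works on a :class:`~geocna.data_model_io.CaseTable` of calibrated
multi-value factors.  A *literal* restricts one factor to a value set
(``ICEBLACK=0|1`` reads "concentrated racial privilege low or medium"); a
*conjunction* joins literals over distinct factors.  For a conjunction X and
outcome literal Y:

* consistency(X -> Y) = |ext(X) & ext(Y)| / |ext(X)|   (sufficiency fit)
* coverage(X -> Y)    = |ext(X) & ext(Y)| / |ext(Y)|   (empirical importance)

where ext() is the set of cases instantiating the condition.  A minimally
sufficient condition (MSC) at threshold t is an instantiated conjunction
with consistency >= t none of whose weakenings (dropping a literal, or
enlarging a literal's value set) also reaches t.

Canonical string grammar: literals are ``FACTOR=v`` or ``FACTOR=v1|v2``
(levels ascending), conjunction joins with ``*`` (factors alphabetical),
disjunction joins with `` + ``.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .data_model_io import CaseTable
from .errors import (
    DegeneracyError,
    DomainError,
    SchemaError,
    SearchExhaustedError,
    UndefinedMetricError,
)

__all__ = [
    "Literal",
    "Conjunction",
    "ConditionRow",
    "ConditionTable",
    "extension",
    "consistency",
    "coverage",
    "enumerate_msc",
    "threshold_search",
    "MscScanner",
    "parse_literal",
    "parse_conjunction",
    "parse_disjunction",
]

_EPS = 1e-9  # tolerance when comparing rational metrics against thresholds


@dataclass(frozen=True, order=True)
class Literal:
    """A factor restricted to a non-empty value set."""

    factor: str
    levels: frozenset[int] = field(compare=False)
    _key: tuple = field(init=False, repr=False)

    def __init__(self, factor: str, levels: Iterable[int]) -> None:
        lv = frozenset(int(x) for x in levels)
        if not lv:
            raise DomainError(f"literal on {factor!r} must accept at least one level")
        object.__setattr__(self, "factor", factor)
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "_key", (factor, tuple(sorted(lv))))

    def __str__(self) -> str:
        return f"{self.factor}={'|'.join(str(v) for v in sorted(self.levels))}"

    def complement(self, domain: Iterable[int]) -> "Literal":
        """The literal accepting exactly the other levels of ``domain``."""
        rest = frozenset(int(x) for x in domain) - self.levels
        if not rest:
            raise DomainError(f"complement of {self} over {sorted(domain)} is empty")
        return Literal(self.factor, rest)


@dataclass(frozen=True, order=True)
class Conjunction:
    """A set of literals, at most one per factor, order >= 1."""

    literals: tuple[Literal, ...] = field(compare=False)
    _key: tuple = field(init=False, repr=False)

    def __init__(self, literals: Iterable[Literal]) -> None:
        lits = tuple(sorted(literals, key=lambda l: l._key))
        if not lits:
            raise DomainError("conjunction requires at least one literal")
        factors = [l.factor for l in lits]
        if len(set(factors)) != len(factors):
            raise DomainError(f"duplicate factor in conjunction: {factors}")
        object.__setattr__(self, "literals", lits)
        object.__setattr__(self, "_key", tuple(l._key for l in lits))

    @property
    def order(self) -> int:
        return len(self.literals)

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(l.factor for l in self.literals)

    def __str__(self) -> str:
        return "*".join(str(l) for l in self.literals)


_LITERAL_RE = re.compile(r"^\s*([A-Za-z_][\w.-]*)=(\d+(?:\|\d+)*)\s*$")


def parse_literal(text: str) -> Literal:
    m = _LITERAL_RE.match(text)
    if not m:
        raise DomainError(f"cannot parse literal {text!r}")
    return Literal(m.group(1), (int(v) for v in m.group(2).split("|")))


def parse_conjunction(text: str) -> Conjunction:
    return Conjunction(parse_literal(part) for part in text.split("*"))


def parse_disjunction(text: str) -> list[Conjunction]:
    return [parse_conjunction(part) for part in text.split("+")]


def _literal_mask(lit: Literal, table: CaseTable) -> np.ndarray:
    if lit.factor not in table.levels.columns:
        raise SchemaError(f"unknown factor {lit.factor!r}")
    col = table.levels[lit.factor].to_numpy()
    return np.isin(col, sorted(lit.levels))


def _mask(arg, table: CaseTable) -> np.ndarray:
    """Boolean instantiation mask for a Literal, Conjunction, or disjunction
    (any iterable of Conjunctions)."""
    if isinstance(arg, Literal):
        return _literal_mask(arg, table)
    if isinstance(arg, Conjunction):
        m = np.ones(table.n_cases, dtype=bool)
        for lit in arg.literals:
            m &= _literal_mask(lit, table)
        return m
    masks = [_mask(c, table) for c in arg]
    if not masks:
        raise DomainError("empty disjunction")
    return np.logical_or.reduce(masks)


def extension(arg, table: CaseTable) -> frozenset[str]:
    """Case ids instantiating a literal, conjunction, or disjunction."""
    m = _mask(arg, table)
    ids = np.asarray(table.case_ids, dtype=object)
    return frozenset(ids[m])


def consistency(arg, outcome: Literal, table: CaseTable) -> float:
    """|ext(arg) & ext(outcome)| / |ext(arg)|; error if ext(arg) is empty."""
    m = _mask(arg, table)
    n_inst = int(m.sum())
    if n_inst == 0:
        raise UndefinedMetricError(f"{arg} is not instantiated; consistency undefined")
    n_overlap = int((m & _literal_mask(outcome, table)).sum())
    return n_overlap / n_inst


def coverage(arg, outcome: Literal, table: CaseTable) -> float:
    """|ext(arg) & ext(outcome)| / |ext(outcome)|; error on empty outcome."""
    out = _literal_mask(outcome, table)
    n_out = int(out.sum())
    if n_out == 0:
        raise UndefinedMetricError(f"outcome {outcome} is not instantiated; coverage undefined")
    n_overlap = int((_mask(arg, table) & out).sum())
    return n_overlap / n_out


@dataclass(frozen=True)
class ConditionRow:
    """One retained configuration with its fit statistics."""

    conjunction: Conjunction
    outcome: Literal
    consistency: float
    coverage: float
    n_instantiating: int
    n_overlap: int


@dataclass(frozen=True)
class ConditionTable:
    """Configurations meeting a consistency threshold, canonically ordered."""

    rows: tuple[ConditionRow, ...]
    threshold: float
    outcome: Literal

    def __len__(self) -> int:
        return len(self.rows)

    def configurations(self) -> list[str]:
        return [str(r.conjunction) for r in self.rows]


def _sort_rows(rows: Iterable[ConditionRow]) -> tuple[ConditionRow, ...]:
    return tuple(
        sorted(
            rows,
            key=lambda r: (-r.consistency, -r.coverage, r.conjunction.order,
                           str(r.conjunction)),
        )
    )


class MscScanner:
    """Exhaustive one-pass scan of all instantiated conjunctions up to
    ``max_order``, reusable across consistency thresholds.

    Candidate literals are every non-empty proper subset of each non-outcome
    factor's domain, so value-set conditions such as ``ICEBLACK=0|1`` are
    first-class.  Statistics (instantiating and overlap counts) are computed
    once; :meth:`condition_table` filters and minimizes at a given threshold.
    """

    def __init__(self, table: CaseTable, outcome: Literal, max_order: int = 3):
        if max_order < 1:
            raise DomainError("max_order must be >= 1")
        out_col = table.levels[outcome.factor].to_numpy() if outcome.factor in table.levels.columns else None
        if out_col is None:
            raise SchemaError(f"unknown outcome factor {outcome.factor!r}")
        self.table = table
        self.outcome = outcome
        self.max_order = max_order
        out_mask = _literal_mask(outcome, table)
        self.n_outcome = int(out_mask.sum())
        if self.n_outcome == 0 or self.n_outcome == table.n_cases:
            raise DegeneracyError(
                f"outcome {outcome} is constant across cases; nothing to explain"
            )
        factors = [f for f in table.factors if f != outcome.factor]
        # per-factor candidate literals; masks are bit-packed into ints so
        # the exhaustive scan is popcount arithmetic
        def pack(arr: np.ndarray) -> int:
            return int.from_bytes(np.packbits(arr).tobytes(), "big")

        out_bits = pack(out_mask)
        self._masks: dict[tuple, int] = {}
        self._literals: dict[str, list[Literal]] = {}
        for f in factors:
            dom = sorted(table.domain(f))
            if len(dom) < 2:
                continue  # degenerate factor: no proper non-trivial subsets
            lits = []
            for r in range(1, len(dom)):
                for combo in itertools.combinations(dom, r):
                    lit = Literal(f, combo)
                    lits.append(lit)
                    self._masks[lit._key] = pack(_literal_mask(lit, table))
            self._literals[f] = lits
        self.factors = [f for f in factors if f in self._literals]
        # scan all conjunctions
        self._stats: dict[tuple, tuple[int, int]] = {}
        self._conjs: dict[tuple, Conjunction] = {}
        for k in range(1, max_order + 1):
            for fset in itertools.combinations(self.factors, k):
                for lits in itertools.product(*(self._literals[f] for f in fset)):
                    m = self._masks[lits[0]._key]
                    for lit in lits[1:]:
                        m &= self._masks[lit._key]
                    n_inst = m.bit_count()
                    if n_inst == 0:
                        continue
                    n_overlap = (m & out_bits).bit_count()
                    conj = Conjunction(lits)
                    self._stats[conj._key] = (n_inst, n_overlap)
                    self._conjs[conj._key] = conj

    def _satisfies(self, key: tuple, threshold: float) -> bool:
        stat = self._stats.get(key)
        if stat is None:
            return False  # not instantiated
        n_inst, n_overlap = stat
        return n_overlap + _EPS >= threshold * n_inst

    def _weakenings(self, conj: Conjunction) -> Iterator[tuple]:
        """Keys of all proper weakenings: per literal either keep, enlarge the
        value set (staying a proper subset of the domain), or drop the
        literal; at least one change, at least one literal kept."""
        options: list[list[tuple | None]] = []
        for lit in conj.literals:
            dom = self.table.domain(lit.factor)
            opts: list[tuple | None] = [lit._key]
            rest = sorted(dom - lit.levels)
            base = sorted(lit.levels)
            for r in range(1, len(rest) + 1):
                for extra in itertools.combinations(rest, r):
                    enlarged = tuple(sorted(base + list(extra)))
                    if len(enlarged) < len(dom):
                        opts.append((lit.factor, enlarged))
            opts.append(None)  # drop
            options.append(opts)
        for combo in itertools.product(*options):
            kept = tuple(k for k in combo if k is not None)
            if not kept or len(kept) == conj.order and all(
                combo[i] == conj.literals[i]._key for i in range(conj.order)
            ):
                continue
            yield kept

    def is_minimal(self, conj: Conjunction, threshold: float) -> bool:
        cache = getattr(self, "_weak_cache", None)
        if cache is None:
            cache = self._weak_cache = {}
        keys = cache.get(conj._key)
        if keys is None:
            keys = cache[conj._key] = list(self._weakenings(conj))
        return not any(self._satisfies(w, threshold) for w in keys)

    def condition_table(self, threshold: float) -> ConditionTable:
        if not (0 < threshold <= 1):
            raise DomainError("threshold must lie in (0, 1]")
        rows = []
        for key, (n_inst, n_overlap) in self._stats.items():
            if n_overlap + _EPS < threshold * n_inst:
                continue
            conj = self._conjs[key]
            if not self.is_minimal(conj, threshold):
                continue
            rows.append(
                ConditionRow(
                    conjunction=conj,
                    outcome=self.outcome,
                    consistency=n_overlap / n_inst,
                    coverage=n_overlap / self.n_outcome,
                    n_instantiating=n_inst,
                    n_overlap=n_overlap,
                )
            )
        return ConditionTable(rows=_sort_rows(rows), threshold=threshold,
                              outcome=self.outcome)


def enumerate_msc(
    table: CaseTable,
    outcome: Literal,
    max_order: int = 3,
    threshold: float = 1.0,
) -> ConditionTable:
    """All minimally sufficient conditions of order <= ``max_order`` at the
    given consistency threshold (see module docstring for the definition)."""
    return MscScanner(table, outcome, max_order).condition_table(threshold)


def threshold_search(
    table: CaseTable,
    outcome: Literal,
    max_order: int = 3,
    start: float = 1.0,
    step: float = 0.05,
    min_rows: int = 2,
    scanner: MscScanner | None = None,
) -> tuple[float, ConditionTable, list[tuple[float, int]]]:
    """Lower the consistency threshold from ``start`` in decrements of
    ``step`` until the condition table holds at least ``min_rows``
    configurations.

    Returns ``(final_threshold, condition_table, trail)`` where ``trail``
    records ``(threshold, row_count)`` for every visited threshold.
    """
    if scanner is None:
        scanner = MscScanner(table, outcome, max_order)
    trail: list[tuple[float, int]] = []
    k = 0
    while True:
        threshold = round(start - k * step, 10)
        if threshold <= 0:
            raise SearchExhaustedError(
                f"threshold floor reached with fewer than {min_rows} configurations; "
                f"trail: {trail}"
            )
        ct = scanner.condition_table(threshold)
        trail.append((threshold, len(ct)))
        if len(ct) >= min_rows:
            return threshold, ct, trail
        k += 1
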