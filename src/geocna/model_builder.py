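"""Assemble minimally sufficient conditions into solution formulas.

A solution formula is a disjunction of MSC conjunctions (equifinality:
multiple pathways to the same outcome).  Candidates are scored by model
consistency and coverage computed on the union extension; the final model
is the unique best candidate under (consistency desc, coverage desc,
complexity asc) — if several candidates tie on all three keys the result is
flagged as ambiguous and no final model is declared.

Causal asymmetry is honoured by :func:`asymmetric_analysis`, which runs the
whole chain (threshold search, MSC enumeration, model building) separately
and independently for the outcome literal and for its complement.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .cna_core import (
    ConditionTable,
    Conjunction,
    Literal,
    MscScanner,
    _literal_mask,
    _mask,
    threshold_search,
)
from .data_model_io import CaseTable
from .errors import GeocnaError, NoCandidatesError

logger = logging.getLogger(__name__)

__all__ = [
    "SolutionFormula",
    "ModelReport",
    "MscSettings",
    "ModelSettings",
    "build_candidates",
    "select_final",
    "model_search",
    "asymmetric_analysis",
]


@dataclass(frozen=True)
class SolutionFormula:
    """A disjunction of conjunctions with model-level fit statistics."""

    disjuncts: tuple[Conjunction, ...]
    outcome: Literal
    consistency: float
    coverage: float
    n_instantiating: int
    n_overlap: int

    @property
    def complexity(self) -> int:
        """Total literal count across disjuncts."""
        return sum(c.order for c in self.disjuncts)

    def __str__(self) -> str:
        return " + ".join(str(c) for c in self.disjuncts)

    def sort_key(self) -> tuple:
        return (-self.consistency, -self.coverage, self.complexity, str(self))

    def score_key(self) -> tuple:
        """Exact selection key: ratios compared via their integer counts."""
        return (
            round(self.consistency, 12),
            round(self.coverage, 12),
            self.complexity,
        )


@dataclass(frozen=True)
class ModelReport:
    """Result of model building for one outcome literal."""

    outcome: Literal
    candidates: tuple[SolutionFormula, ...]
    final: SolutionFormula | None
    ambiguity: bool
    tied: tuple[SolutionFormula, ...]
    con_threshold: float
    cov_threshold: float
    trail: tuple[tuple[float, int], ...]
    status: str  # "ok" | "ambiguous" | "no-model"


@dataclass(frozen=True)
class MscSettings:
    """Settings for the factor-selection threshold search."""

    max_order: int = 3
    start: float = 1.0
    step: float = 0.05
    min_rows: int = 2


@dataclass(frozen=True)
class ModelSettings:
    """Settings for model development."""

    cov_threshold: float = 0.75
    max_disjuncts: int = 5
    max_complexity: int | None = 6  # total literal budget across disjuncts
    con_floor: float = 0.5
    max_rows: int | None = 20  # strongest MSCs considered per level


def build_candidates(
    msc_table: ConditionTable,
    table: CaseTable,
    outcome: Literal,
    con_threshold: float,
    cov_threshold: float,
    max_disjuncts: int = 5,
    max_rows: int | None = None,
    max_complexity: int | None = None,
) -> list[SolutionFormula]:
    """Exhaustively form disjunctions of 1..``max_disjuncts`` MSC rows and
    retain redundancy-free candidates meeting both thresholds.

    A candidate is redundancy-free when every disjunct covers at least one
    outcome case no other disjunct covers; pathways that add no explained
    cases (including structural subset disjuncts) are rejected outright.
    ``max_complexity`` bounds the total literal count of a candidate,
    guarding against overfit unions of many hyper-specific configurations.
    """
    if not len(msc_table):
        raise NoCandidatesError("empty condition table: nothing to build from")
    rows = list(msc_table.rows)
    if max_rows is not None and len(rows) > max_rows:
        # keep the highest-coverage rows: only they can combine into a
        # disjunction that clears the coverage threshold
        rows = sorted(
            rows,
            key=lambda r: (-r.coverage, -r.consistency, str(r.conjunction)),
        )[:max_rows]
    out = _literal_mask(outcome, table)
    n_out = int(out.sum())

    def pack(arr: np.ndarray) -> int:
        return int.from_bytes(np.packbits(arr).tobytes(), "big")

    masks = [pack(_mask(r.conjunction, table)) for r in rows]
    out_bits = pack(out)
    covered = [m & out_bits for m in masks]
    eps = 1e-9
    candidates: list[SolutionFormula] = []
    orders = [r.conjunction.order for r in rows]
    for k in range(1, max_disjuncts + 1):
        for combo in itertools.combinations(range(len(rows)), k):
            if max_complexity is not None and \
                    sum(orders[i] for i in combo) > max_complexity:
                continue
            union_cov = 0
            for i in combo:
                union_cov |= covered[i]
            n_overlap = union_cov.bit_count()
            if n_overlap + eps < cov_threshold * n_out:
                continue
            # every disjunct must contribute a uniquely covered outcome case
            redundant = False
            if k > 1:
                for i in combo:
                    others = 0
                    for j in combo:
                        if j != i:
                            others |= covered[j]
                    if not covered[i] & ~others:
                        redundant = True
                        break
            if redundant:
                continue
            union = 0
            for i in combo:
                union |= masks[i]
            n_inst = union.bit_count()
            if n_overlap + eps < con_threshold * n_inst:
                continue
            candidates.append(
                SolutionFormula(
                    disjuncts=tuple(sorted((rows[i].conjunction for i in combo),
                                           key=str)),
                    outcome=outcome,
                    consistency=n_overlap / n_inst,
                    coverage=n_overlap / n_out,
                    n_instantiating=n_inst,
                    n_overlap=n_overlap,
                )
            )
    candidates.sort(key=SolutionFormula.sort_key)
    return candidates


def select_final(
    candidates: Sequence[SolutionFormula],
    con_threshold: float = float("nan"),
    cov_threshold: float = float("nan"),
    trail: Sequence[tuple[float, int]] = (),
) -> ModelReport:
    """Rank candidates and pick a unique best, flagging ties as ambiguity."""
    cands = tuple(sorted(candidates, key=SolutionFormula.sort_key))
    outcome = cands[0].outcome if cands else Literal("_none", [0])
    if not cands:
        return ModelReport(
            outcome=outcome, candidates=(), final=None, ambiguity=False,
            tied=(), con_threshold=con_threshold, cov_threshold=cov_threshold,
            trail=tuple(trail), status="no-model",
        )
    top_key = cands[0].score_key()
    tied = tuple(c for c in cands if c.score_key() == top_key)
    if len(tied) > 1:
        return ModelReport(
            outcome=outcome, candidates=cands, final=None, ambiguity=True,
            tied=tied, con_threshold=con_threshold, cov_threshold=cov_threshold,
            trail=tuple(trail), status="ambiguous",
        )
    return ModelReport(
        outcome=outcome, candidates=cands, final=cands[0], ambiguity=False,
        tied=(), con_threshold=con_threshold, cov_threshold=cov_threshold,
        trail=tuple(trail), status="ok",
    )


def model_search(
    table: CaseTable,
    outcome: Literal,
    scanner: MscScanner,
    start: float,
    step: float = 0.05,
    settings: ModelSettings = ModelSettings(),
) -> ModelReport:
    """Model development: descend consistency levels from ``start`` until a
    candidate solution satisfying the coverage threshold appears, then pick
    the final model (or report ambiguity).  Returns a no-model report if the
    floor is reached."""
    trail: list[tuple[float, int]] = []
    first_ambiguous: ModelReport | None = None
    k = 0
    while True:
        level = round(start - k * step, 10)
        if level < settings.con_floor:
            if first_ambiguous is not None:
                return first_ambiguous
            return ModelReport(
                outcome=outcome, candidates=(), final=None, ambiguity=False,
                tied=(), con_threshold=level, cov_threshold=settings.cov_threshold,
                trail=tuple(trail), status="no-model",
            )
        ct = scanner.condition_table(level)
        trail.append((level, len(ct)))
        if len(ct):
            cands = build_candidates(
                ct, table, outcome,
                con_threshold=level,
                cov_threshold=settings.cov_threshold,
                max_disjuncts=settings.max_disjuncts,
                max_rows=settings.max_rows,
                max_complexity=settings.max_complexity,
            )
            if cands:
                logger.info(
                    "model level %.2f: %d MSC rows, %d candidates",
                    level, len(ct), len(cands),
                )
                report = select_final(
                    cands, con_threshold=level,
                    cov_threshold=settings.cov_threshold, trail=trail,
                )
                if report.final is not None:
                    return report
                # all-tied level: a final model requires no ambiguity, so
                # keep lowering; surface the shallowest tie only if no
                # unambiguous level exists above the floor
                if first_ambiguous is None:
                    first_ambiguous = report
        k += 1


def asymmetric_analysis(
    table: CaseTable,
    outcome: Literal,
    msc_settings: MscSettings = MscSettings(),
    model_settings: ModelSettings = ModelSettings(),
) -> tuple[ModelReport, ModelReport]:
    """Run the full factor-selection + model-building chain independently for
    the outcome literal and for its complement (causal asymmetry)."""
    reports = []
    for side, lit in (
        ("outcome", outcome),
        ("negation", outcome.complement(table.domain(outcome.factor))),
    ):
        try:
            scanner = MscScanner(table, lit, msc_settings.max_order)
            t_final, _ct, trail = threshold_search(
                table, lit,
                max_order=msc_settings.max_order,
                start=msc_settings.start,
                step=msc_settings.step,
                min_rows=msc_settings.min_rows,
                scanner=scanner,
            )
            report = model_search(
                table, lit, scanner, start=t_final,
                step=msc_settings.step, settings=model_settings,
            )
            # keep the factor-selection trail alongside the model trail
            report = replace(report, trail=tuple(trail) + report.trail)
            reports.append(report)
        except GeocnaError as err:
            raise type(err)(f"[{side} side] {err}") from err
    return reports[0], reports[1]
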