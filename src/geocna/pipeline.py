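"""End-to-end pipeline: raw table -> calibration -> asymmetric models.

The pipeline reproduces the study workflow in one call: build the ICE
measures, calibrate every social condition and the three monthly
vaccination rates, derive the binary persistently-low outcome, run the
threshold-lowering search for minimally sufficient conditions, build
solution models separately for the outcome and its negation, and write all
artifacts (condition tables, model report JSON, membership CSV).  A second
run with identical inputs is byte-identical in its outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import pandas as pd

from .calibration import (
    DEFAULT_SCHEMES,
    CalibrationScheme,
    IceInputs,
    OutcomeSeries,
    calibrate_series,
    compute_ice,
    persistent_low_outcome,
)
from .cna_core import Literal, extension
from .data_model_io import (
    CaseTable,
    OutputBundle,
    RawTable,
    write_condition_table,
    write_membership,
)
from .errors import GeocnaError, SchemaError
from .model_builder import (
    ModelReport,
    ModelSettings,
    MscSettings,
    asymmetric_analysis,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "DEFAULT_FACTOR_SOURCES",
    "calibrate_raw_table",
    "run",
    "summarize",
    "round_half_up",
]

OUTCOME_NAME = "PLOW"
MONTH_FACTORS = ("VAX_MARCH", "VAX_APRIL", "VAX_MAY")

# how each factor is read off the raw table: a single column, or the ICE
# component triple (privileged, deprived, total)
DEFAULT_FACTOR_SOURCES: dict[str, dict] = {
    "EDU": {"column": "pct_college"},
    "UNINS": {"column": "pct_uninsured"},
    "LEP": {"column": "pct_limited_english"},
    "TRANSIT": {"column": "pct_transit"},
    "SERVICE": {"column": "pct_service"},
    "CROWD": {"column": "pct_overcrowded"},
    "ICEINC": {"ice": ("income_privileged", "income_deprived", "income_total")},
    "ICEBLACK": {"ice": ("black_nh_privileged", "black_nh_deprived", "black_nh_total")},
    "VAX_MARCH": {"column": "vax_rate_march"},
    "VAX_APRIL": {"column": "vax_rate_april"},
    "VAX_MAY": {"column": "vax_rate_may"},
}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the reporting convention for fit scores)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible pipeline run depends on."""

    schemes: Mapping[str, CalibrationScheme] = field(
        default_factory=lambda: dict(DEFAULT_SCHEMES))
    factor_sources: Mapping[str, dict] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_SOURCES))
    factors: tuple[str, ...] = ("EDU", "UNINS", "LEP", "TRANSIT", "SERVICE",
                                "CROWD", "ICEINC", "ICEBLACK")
    months: tuple[str, ...] = MONTH_FACTORS
    outcome_name: str = OUTCOME_NAME
    msc: MscSettings = field(default_factory=MscSettings)
    model: ModelSettings = field(default_factory=ModelSettings)
    seed: int = 0
    outdir: str | None = None

    def validate_for_raw(self) -> None:
        """Check that every factor can be calibrated from a raw table."""
        missing = [f for f in (*self.factors, *self.months)
                   if f not in self.schemes or f not in self.factor_sources]
        if missing:
            raise SchemaError(f"factors without scheme or source: {missing}")


def _raw_series(raw: RawTable, source: dict) -> pd.Series:
    if "column" in source:
        col = source["column"]
        if col not in raw.data.columns:
            raise SchemaError(f"raw table lacks column {col!r}")
        return raw.data[col]
    p_col, d_col, t_col = source["ice"]
    for col in (p_col, d_col, t_col):
        if col not in raw.data.columns:
            raise SchemaError(f"raw table lacks ICE component column {col!r}")
    return pd.Series(
        [
            compute_ice(IceInputs(p, d, t))
            for p, d, t in zip(raw.data[p_col], raw.data[d_col], raw.data[t_col])
        ],
        index=raw.data.index,
    )


def calibrate_raw_table(raw: RawTable, config: RunConfig) -> CaseTable:
    """Calibrate every factor and derive the persistently-low outcome."""
    config.validate_for_raw()
    levels = {}
    for f in config.factors:
        series = _raw_series(raw, config.factor_sources[f])
        levels[f] = calibrate_series(series, config.schemes[f])
    month_levels = {
        m: calibrate_series(_raw_series(raw, config.factor_sources[m]),
                            config.schemes[m])
        for m in config.months
    }
    outcome = [
        persistent_low_outcome(OutcomeSeries(tuple(int(month_levels[m][i])
                                                   for m in config.months)))
        for i in range(raw.n_cases)
    ]
    df = pd.DataFrame(levels, index=raw.data.index)
    df[config.outcome_name] = outcome
    return CaseTable(
        levels=df,
        outcome_name=config.outcome_name,
        domains={**{f: frozenset({0, 1, 2}) for f in config.factors},
                 config.outcome_name: frozenset({0, 1})},
    )


def _membership_frame(table: CaseTable, outcome: Literal,
                      pos: ModelReport, neg: ModelReport) -> pd.DataFrame:
    frame = pd.DataFrame(index=table.levels.index)
    frame["outcome"] = (table.levels[outcome.factor]
                        .isin(sorted(outcome.levels)).astype(int))
    for tag, report in (("pos", pos), ("neg", neg)):
        if report.final is None:
            continue
        for conj in report.final.disjuncts:
            ids = extension(conj, table)
            frame[f"{tag}:{conj}"] = [int(cid in ids) for cid in frame.index]
    return frame


def run(config: RunConfig, raw: RawTable | None = None,
        case_table: CaseTable | None = None
        ) -> tuple[OutputBundle, ModelReport, ModelReport]:
    """Execute the full pipeline; returns the output bundle plus the two
    model reports (outcome side, negation side).

    Either ``raw`` (which is calibrated first) or a pre-calibrated
    ``case_table`` must be given.  When ``config.outdir`` is set all
    artifacts are written there; stage errors abort the run with the stage
    named and remove partial outputs.
    """
    if (raw is None) == (case_table is None):
        raise SchemaError("provide exactly one of raw or case_table")
    outdir = Path(config.outdir) if config.outdir else None
    written: list[Path] = []
    try:
        stage = "calibration"
        table = case_table if case_table is not None else calibrate_raw_table(raw, config)
        stage = "analysis"
        outcome = Literal(config.outcome_name, [1])
        pos, neg = asymmetric_analysis(
            table, outcome, msc_settings=config.msc, model_settings=config.model
        )
        stage = "outputs"
        from .cna_core import MscScanner  # condition table artifact at the stop threshold

        scanner = MscScanner(table, outcome, config.msc.max_order)
        # factor-selection condition table: recompute at the searched stop point
        fs_threshold = next(t for t, n in pos.trail if n >= config.msc.min_rows)
        condition_table = scanner.condition_table(fs_threshold)
        membership = _membership_frame(table, outcome, pos, neg)
        models = [r.final for r in (pos, neg) if r.final is not None]
        bundle = OutputBundle(condition_table=condition_table, models=models,
                              membership=membership)
        if outdir is not None:
            outdir.mkdir(parents=True, exist_ok=True)
            p = outdir / "condition_table.csv"
            write_condition_table(condition_table, p, allow_empty=True)
            written.append(p)
            p = outdir / "case_table.csv"
            table.levels.to_csv(p)
            written.append(p)
            p = outdir / "membership.csv"
            write_membership(membership, p)
            written.append(p)
            p = outdir / "model_report.json"
            p.write_text(reports_to_json(pos, neg), encoding="utf-8")
            written.append(p)
            p = outdir / "summary.txt"
            p.write_text(summarize(bundle, (pos, neg)), encoding="utf-8")
            written.append(p)
        return bundle, pos, neg
    except GeocnaError as err:
        for p in written:
            p.unlink(missing_ok=True)
        raise type(err)(f"[stage: {stage}] {err}") from err


def _report_dict(report: ModelReport) -> dict:
    def fmt(model):
        return {
            "solution": str(model),
            "consistency": model.consistency,
            "coverage": model.coverage,
            "complexity": model.complexity,
            "n_instantiating": model.n_instantiating,
            "n_overlap": model.n_overlap,
        }

    return {
        "outcome": str(report.outcome),
        "status": report.status,
        "final": fmt(report.final) if report.final else None,
        "ambiguity": report.ambiguity,
        "tied": [fmt(m) for m in report.tied],
        "candidates": [fmt(m) for m in report.candidates],
        "con_threshold": report.con_threshold,
        "cov_threshold": report.cov_threshold,
        "threshold_trail": [list(t) for t in report.trail],
    }


def reports_to_json(pos: ModelReport, neg: ModelReport) -> str:
    return json.dumps(
        {"outcome": _report_dict(pos), "negation": _report_dict(neg)},
        indent=1, sort_keys=True,
    )


def summarize(bundle: OutputBundle, reports: tuple[ModelReport, ModelReport]) -> str:
    """Human-readable run summary; fit scores shown half-up to two decimals."""
    lines = []
    pos, neg = reports
    lines.append(f"cases: {len(bundle.membership)}")
    lines.append(f"outcome-positive cases: {int(bundle.membership['outcome'].sum())}")
    lines.append(f"condition table rows (factor selection): {len(bundle.condition_table)}")
    for tag, rep in (("outcome", pos), ("negation", neg)):
        lines.append(f"--- {tag} side: {rep.outcome} ---")
        trail = ", ".join(f"{t:.2f}:{n}" for t, n in rep.trail)
        lines.append(f"threshold trail (threshold:rows): {trail}")
        if rep.status == "no-model":
            lines.append("no model met the consistency/coverage thresholds")
        elif rep.ambiguity:
            lines.append("model ambiguity: tied candidates")
            for m in rep.tied:
                lines.append(
                    f"  {m}  consistency {round_half_up(m.consistency):.2f}"
                    f"  coverage {round_half_up(m.coverage):.2f}"
                )
        else:
            m = rep.final
            n_out = round(m.n_overlap / m.coverage) if m.coverage else 0
            lines.append(
                f"final model: {m}  consistency {round_half_up(m.consistency):.2f}"
                f" ({m.n_overlap}/{m.n_instantiating})"
                f"  coverage {round_half_up(m.coverage):.2f}"
                f" ({m.n_overlap}/{n_out})"
            )
    return "\n".join(lines) + "\n"
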