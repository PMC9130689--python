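"""Model/Results surface for configurational analysis.

:class:`CNA` wraps a calibrated case table the way a statistical model
wraps its design matrix: construct from a DataFrame (or a raw table plus a
run configuration), call :meth:`CNA.fit`, and receive a
:class:`CNAResults` carrying the asymmetric solution models, their fit
statistics, the threshold trails and a printable summary.

Example
-------
>>> from geocna import CNA, build_study_fixture
>>> res = CNA.from_case_table(build_study_fixture()).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cna_core import Literal
from .data_model_io import CaseTable, OutputBundle, RawTable
from .errors import SchemaError
from .model_builder import ModelReport, ModelSettings, MscSettings
from .pipeline import RunConfig, calibrate_raw_table, run, summarize

__all__ = ["CNA", "CNAResults"]


class CNA:
    """Configurational (coincidence-analysis style) model of a binary
    outcome over multi-value calibrated factors.

    Parameters
    ----------
    case_table : CaseTable
        Calibrated levels, one row per case, with a binary outcome factor.
    outcome_level : int
        The outcome value whose presence is modelled (default 1); the
        negation side is always analyzed as well.
    """

    def __init__(self, case_table: CaseTable, outcome_level: int = 1):
        if outcome_level not in (0, 1):
            raise SchemaError("outcome_level must be 0 or 1")
        self.case_table = case_table
        self.outcome = Literal(case_table.outcome_name, [outcome_level])

    @classmethod
    def from_dataframe(cls, levels: pd.DataFrame, outcome: str,
                       outcome_level: int = 1) -> "CNA":
        """Build from a DataFrame of integer levels (index = case ids)."""
        return cls(CaseTable(levels=levels.copy(), outcome_name=outcome),
                   outcome_level)

    @classmethod
    def from_case_table(cls, table: CaseTable, outcome_level: int = 1) -> "CNA":
        return cls(table, outcome_level)

    @classmethod
    def from_raw(cls, raw: RawTable, config: RunConfig | None = None) -> "CNA":
        """Calibrate a raw table with ``config`` (default study schemes)."""
        config = config or RunConfig()
        return cls(calibrate_raw_table(raw, config))

    def fit(self, msc: MscSettings | None = None,
            model: ModelSettings | None = None,
            outdir: str | None = None) -> "CNAResults":
        """Run threshold search and asymmetric model building."""
        config = RunConfig(
            outcome_name=self.case_table.outcome_name,
            factors=tuple(self.case_table.factors),
            msc=msc or MscSettings(),
            model=model or ModelSettings(),
            outdir=outdir,
        )
        bundle, pos, neg = run(config, case_table=self.case_table)
        if self.outcome.levels != frozenset({1}):
            pos, neg = neg, pos
        return CNAResults(model=self, bundle=bundle, outcome_report=pos,
                          negation_report=neg)


@dataclass(frozen=True)
class CNAResults:
    """Fitted configurational models for an outcome and its negation."""

    model: CNA
    bundle: OutputBundle
    outcome_report: ModelReport
    negation_report: ModelReport

    @property
    def solution(self):
        """Final solution formula for the modelled outcome (or None)."""
        return self.outcome_report.final

    @property
    def negation_solution(self):
        return self.negation_report.final

    @property
    def consistency(self) -> float:
        if self.solution is None:
            raise SchemaError("no final model on the outcome side")
        return self.solution.consistency

    @property
    def coverage(self) -> float:
        if self.solution is None:
            raise SchemaError("no final model on the outcome side")
        return self.solution.coverage

    @property
    def membership(self) -> pd.DataFrame:
        """Per-case outcome flag plus per-pathway instantiation flags."""
        return self.bundle.membership

    def summary(self) -> str:
        return summarize(self.bundle, (self.outcome_report, self.negation_report))
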