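"""Batch assessment of published instruments and review-level statistics.

Supports the systematic-review workflow: assess many instruments from their
summary statistics, tabulate how many meet the manifest Fornell-Larcker
criterion, test whether that proportion differs between sources (Pearson
chi-square on a contingency table, no continuity correction), and test
whether instrument structure (pair count, mean items per dimension) relates
to the verdict (pooled-variance two-sample t).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .criteria import InstrumentAssessment, InstrumentSummary, assess_instrument
from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "ContingencyTable",
    "ReviewRecord",
    "chisq_independence",
    "review_batch",
    "compare_structure_by_verdict",
    "load_table1",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Labelled matrix of non-negative counts."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise InvalidInputError("contingency table must be at least 2x2")
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise InvalidInputError("labels do not match the counts shape")
        if np.any(c < 0) or not np.all(np.equal(np.mod(c, 1), 0)):
            raise InvalidInputError("counts must be non-negative integers")
        if c.sum() < 1:
            raise InvalidInputError("grand total must be >= 1")
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        object.__setattr__(self, "counts", c.astype(int))


@dataclass(frozen=True)
class ReviewRecord:
    """One instrument's assessment in review form."""

    instrument_id: str
    summary: InstrumentSummary
    assessment: InstrumentAssessment
    mfl_met: bool
    n_nonredundant_pairs: int
    violation_fraction: float
    mean_items_per_dimension: float


def chisq_independence(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, without continuity correction.

    Returns (statistic, df, p_value) with df = (rows-1)(cols-1) and the
    p-value from the upper tail of the chi-square distribution.
    """
    c = table.counts
    if np.any(c.sum(axis=0) == 0) or np.any(c.sum(axis=1) == 0):
        raise DegenerateInputError("a zero marginal makes expected counts zero")
    res = stats.chi2_contingency(c, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def review_batch(
    instruments: Sequence[InstrumentSummary],
    ids: Sequence[str] | None = None,
) -> tuple[list[ReviewRecord], dict]:
    """Assess a batch of instruments and summarise review-level statistics.

    The summary reports the met / not-met counts (an instrument meets mFL
    only when every pair is distinct_certain; uncertain pairs count as
    not-met but are also reported separately) and the mean violation
    fraction among instruments with at least one violated pair, mirroring
    the "if at least one pair lacks distinctiveness, how widespread is it"
    review statistic.
    """
    if ids is None:
        ids = [f"instrument_{i + 1}" for i in range(len(instruments))]
    if len(ids) != len(instruments):
        raise InvalidInputError("ids and instruments differ in length")

    records: list[ReviewRecord] = []
    for iid, instr in zip(ids, instruments):
        assessment = assess_instrument(instr)
        d = len(instr.dimensions)
        records.append(
            ReviewRecord(
                instrument_id=str(iid),
                summary=instr,
                assessment=assessment,
                mfl_met=assessment.mfl_met,
                n_nonredundant_pairs=d * (d - 1) // 2,
                violation_fraction=assessment.frac_not_distinct,
                mean_items_per_dimension=float(
                    np.mean([dim.n_items for dim in instr.dimensions])
                ),
            )
        )

    violators = [r.violation_fraction for r in records if r.violation_fraction > 0]
    n_uncertain = sum(
        1
        for r in records
        if any(p.verdict == "uncertain" for p in r.assessment.pairs)
    )
    summary = {
        "n_instruments": len(records),
        "n_met": sum(r.mfl_met for r in records),
        "n_not_met": sum(not r.mfl_met for r in records),
        "n_with_uncertain_pairs": n_uncertain,
        "mean_violation_fraction_among_violators": (
            float(np.mean(violators)) if violators else None
        ),
    }
    return records, summary


def compare_structure_by_verdict(
    records: Sequence[ReviewRecord], feature: str
) -> tuple[float, int]:
    """Pooled-variance t test of a structure feature between verdict groups.

    ``feature`` is ``"n_nonredundant_pairs"`` or ``"mean_items_per_dimension"``.
    Returns (t_statistic, df) with df = n_met + n_not_met - 2 (Student t,
    equal variances pooled).
    """
    if feature not in ("n_nonredundant_pairs", "mean_items_per_dimension"):
        raise InvalidInputError(f"unknown feature {feature!r}")
    met = [getattr(r, feature) for r in records if r.mfl_met]
    not_met = [getattr(r, feature) for r in records if not r.mfl_met]
    if not met or not not_met:
        raise DegenerateInputError("both verdict groups must be non-empty")
    df = len(met) + len(not_met) - 2
    if np.var(met, ddof=1) + np.var(not_met, ddof=1) == 0.0:
        # zero pooled variance: equal means -> t = 0, else infinite
        diff = np.mean(met) - np.mean(not_met)
        return (0.0 if diff == 0 else float(np.sign(diff)) * float("inf")), df
    res = stats.ttest_ind(met, not_met, equal_var=True)
    return float(res.statistic), df


def load_table1() -> ContingencyTable:
    """Bundled met / not-met counts by journal from the published review."""
    path = resources.files("mfl.data").joinpath("review_met_by_journal.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, index_col=0)
    return ContingencyTable(
        row_labels=tuple(df.index.astype(str)),
        col_labels=tuple(df.columns.astype(str)),
        counts=df.to_numpy(),
    )
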