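"""PER assay scoring, quality control, group summaries and directional analysis.

A test is two trials; PER on at least one trial is a positive response, and
only full extensions are scored. Groups of 15-20 flies are the statistical
unit; the group-level response is the percent of flies positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tastekit.synthetic import DIRECTIONAL_OUTCOMES, DirectionalDataset, PERDataset

__all__ = [
    "GroupSummary",
    "DirectionalSummary",
    "score_per_test",
    "score_tests",
    "apply_qc",
    "group_fraction",
    "summarize_groups",
    "directional_summary",
]

QC_POLICIES = ("wildtype_starved", "compare_groups")


@dataclass(frozen=True)
class GroupSummary:
    group_id: str
    state: str
    tastant: str
    dose: float
    n_flies: int
    percent_per: float  # full precision; round for display


@dataclass(frozen=True)
class DirectionalSummary:
    n_trials: int
    n_flies: int
    counts: dict
    fractions: dict

    def percent(self, outcome: str) -> int:
        """Outcome share as nearest-integer percent (reporting convention)."""
        return int(round(100.0 * self.fractions[outcome]))


def score_per_test(trial1: bool, trial2: bool) -> bool:
    """Positive response ⇔ PER on at least one of the two trials."""
    return bool(trial1) or bool(trial2)


def score_tests(records: pd.DataFrame) -> pd.Series:
    return records["trial1"].astype(bool) | records["trial2"].astype(bool)


def _as_frame(dataset: PERDataset | pd.DataFrame) -> pd.DataFrame:
    return dataset.records if isinstance(dataset, PERDataset) else dataset


def apply_qc(
    dataset: PERDataset | pd.DataFrame, policy: str = "compare_groups"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply fly-level exclusion rules; returns (filtered records, exclusion log).

    ``wildtype_starved``: a fly that was negative on every taste stimulus is
    checked against 500 mM sucrose; if that check also failed the fly is
    excluded from the whole assay (starved wild-type flies should always
    respond to high sugar). ``compare_groups``: flies are only excluded when
    flagged very sick (optional boolean ``very_sick`` column); the sucrose
    check is not an exclusion criterion.

    Idempotent: applying twice equals applying once.
    """
    records = _as_frame(dataset).copy()
    if policy not in QC_POLICIES:
        raise ValueError(f"unknown QC policy {policy!r}; choose from {QC_POLICIES}")

    if policy == "compare_groups":
        if "very_sick" in records.columns:
            sick = records.groupby(["group_id", "fly_id"])["very_sick"].any()
            excluded_ids = set(sick[sick].index)
        else:
            excluded_ids = set()
        reason = "very sick"
    else:
        if "sucrose500_check" not in records.columns:
            raise ValueError("wildtype_starved QC needs a sucrose500_check column")
        positive = score_tests(records)
        by_fly = records.assign(_pos=positive).groupby(["group_id", "fly_id"])
        all_negative = ~by_fly["_pos"].any()
        check_failed = ~by_fly["sucrose500_check"].all()
        flagged = all_negative & check_failed
        excluded_ids = set(flagged[flagged].index)
        reason = "no response to any stimulus and failed 500 mM sucrose check"

    key = list(zip(records["group_id"], records["fly_id"]))
    mask = np.array([k not in excluded_ids for k in key])
    log = pd.DataFrame(
        [{"group_id": g, "fly_id": f, "reason": reason} for g, f in sorted(excluded_ids)]
    )
    return records[mask].reset_index(drop=True), log


def group_fraction(tests: pd.DataFrame) -> GroupSummary:
    """Percent of flies positive within one group × tastant × dose cell."""
    if len(tests) == 0:
        raise ValueError("empty group")
    for col in ("group_id", "tastant", "dose"):
        if tests[col].nunique() != 1:
            raise ValueError(f"group_fraction expects a single {col}; got {tests[col].unique()}")
    positive = score_tests(tests)
    n = len(tests)
    return GroupSummary(
        group_id=str(tests["group_id"].iloc[0]),
        state=str(tests["state"].iloc[0]) if "state" in tests else "",
        tastant=str(tests["tastant"].iloc[0]),
        dose=float(tests["dose"].iloc[0]),
        n_flies=n,
        percent_per=100.0 * positive.sum() / n,
    )


def summarize_groups(dataset: PERDataset | pd.DataFrame) -> pd.DataFrame:
    """Group-level summary table: one row per group × tastant × dose."""
    records = _as_frame(dataset)
    rows = []
    for _, grp in records.groupby(["group_id", "tastant", "dose"], sort=True):
        s = group_fraction(grp)
        rows.append(
            {
                "group_id": s.group_id,
                "state": s.state,
                "tastant": s.tastant,
                "dose": s.dose,
                "n_flies": s.n_flies,
                "percent_per": s.percent_per,
            }
        )
    return pd.DataFrame(rows)


def directional_summary(dataset: DirectionalDataset | pd.DataFrame) -> DirectionalSummary:
    """Tally lateralized-PER outcomes over all full-PER trials.

    Fractions are over all trials and sum to 1; ``percent`` reports to the
    nearest integer.
    """
    trials = dataset.trials if isinstance(dataset, DirectionalDataset) else dataset
    if len(trials) == 0:
        raise ValueError("no PER trials to summarize")
    bad = set(trials["outcome"]) - set(DIRECTIONAL_OUTCOMES)
    if bad:
        raise ValueError(f"unknown outcome labels: {sorted(bad)}")
    counts = {o: int((trials["outcome"] == o).sum()) for o in DIRECTIONAL_OUTCOMES}
    n = len(trials)
    fractions = {o: counts[o] / n for o in DIRECTIONAL_OUTCOMES}
    n_flies = int(trials["fly_id"].nunique()) if "fly_id" in trials else 0
    return DirectionalSummary(n_trials=n, n_flies=n_flies, counts=counts, fractions=fractions)
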