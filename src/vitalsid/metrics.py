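"""Per-trial summary rows and collection-level correct-to-incorrect ratios.

A trial summary row records, for one trial, the mean deviation of all ten
patients from the target value ("Average Error"), the target patient's own
mean deviation ("Avg Err"), whether the target patient had the strictly
smallest deviation ("Lowest"), and per-margin membership: the target patient
is *correct at* a margin when its deviation is strictly below it, and the
"False at" columns count how many non-target patients also fall strictly
below that margin.  Strictness follows the published reading of the tables
(a deviation of exactly 0.01 is not within the 0.01 margin) and is
centralised in :func:`within_margin`; ties for the minimum yield "Lowest"
= no.

Over a ten-trial collection, each margin gets a correct-to-incorrect ratio:
(total trials where the target is correct) divided by (mean count of
non-target patients within the margin).  A mean false count of zero leaves
the ratio undefined (reported as a ``None`` sentinel rather than infinity).
Ratios are rounded half-up to two decimals for reporting, with the raw
value retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "MARGINS",
    "within_margin",
    "TrialSummaryRow",
    "CollectionMetrics",
    "summarize_trial",
    "ratio_at_margin",
    "standout_table",
    "round_ratio",
]

#: Margins of error examined by the experiment protocol.
MARGINS = (0.01, 0.025, 0.05, 0.10)


def within_margin(deviation: float, margin: float) -> bool:
    """Strict membership: a deviation equal to the margin is outside it."""
    return deviation < margin


def round_ratio(value: float, places: int = 2) -> float:
    """Round half-up to ``places`` decimals (e.g. 2/0.9 -> 2.22)."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TrialSummaryRow:
    """One row of a ten-trial summary table."""

    trial_no: int
    target_patient: str
    average_error: float
    avg_err_target: float
    lowest: bool
    correct_at: Mapping[float, bool]
    false_at: Mapping[float, int]

    TABLE_COLUMNS = (
        "Trial",
        "Average Error",
        "Avg Err",
        "Lowest",
        "Correct At 0.01",
        "Correct At 0.025",
        "Correct At 0.05",
        "Correct At 0.1",
        "False At 0.01",
        "False At 0.025",
        "False At 0.05",
        "False At 0.10",
    )

    def as_table_row(self) -> list:
        yn = lambda b: "Y" if b else "N"
        return [
            self.trial_no,
            f"{self.average_error:.3f}",
            f"{self.avg_err_target:.3f}",
            yn(self.lowest),
            *[yn(self.correct_at[m]) for m in MARGINS],
            *[int(self.false_at[m]) for m in MARGINS],
        ]


@dataclass(frozen=True)
class CollectionMetrics:
    """Correct-to-incorrect summary for one collection at one margin."""

    margin: float
    total_correct: int
    mean_false: float
    ratio: float | None  # None when mean_false == 0 (undefined, not infinite)

    @property
    def ratio_rounded(self) -> float | None:
        return None if self.ratio is None else round_ratio(self.ratio)


def summarize_trial(
    deviations: Sequence,
    target_patient: str,
    margins: Sequence[float] = MARGINS,
    trial_no: int = 0,
) -> TrialSummaryRow:
    """Reduce one trial's ten deviation records to a summary row.

    ``deviations`` is a sequence of objects with ``patient_id`` and
    ``avg_deviation`` attributes (one per patient, target included exactly
    once).
    """
    ids = [d.patient_id for d in deviations]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids in deviation records")
    by_id = {d.patient_id: d for d in deviations}
    if target_patient not in by_id:
        raise ValueError(f"target patient {target_patient!r} not among records")
    target_dev = by_id[target_patient].avg_deviation
    all_devs = [d.avg_deviation for d in deviations]
    others = [d for d in deviations if d.patient_id != target_patient]
    lowest = all(target_dev < d.avg_deviation for d in others)
    correct_at = {m: within_margin(target_dev, m) for m in margins}
    false_at = {
        m: sum(within_margin(d.avg_deviation, m) for d in others)
        for m in margins
    }
    return TrialSummaryRow(
        trial_no=trial_no,
        target_patient=target_patient,
        average_error=float(sum(all_devs) / len(all_devs)),
        avg_err_target=float(target_dev),
        lowest=lowest,
        correct_at=correct_at,
        false_at=false_at,
    )


def ratio_at_margin(
    rows: Sequence[TrialSummaryRow], margin: float
) -> CollectionMetrics:
    """Correct-to-incorrect ratio for a ten-trial collection at one margin."""
    if len(rows) != 10:
        raise ValueError(f"a collection holds exactly 10 trials, got {len(rows)}")
    total_correct = sum(r.correct_at[margin] for r in rows)
    mean_false = sum(r.false_at[margin] for r in rows) / len(rows)
    ratio = total_correct / mean_false if mean_false > 0 else None
    return CollectionMetrics(margin, int(total_correct), mean_false, ratio)


def ratio_lower_bound(cm: CollectionMetrics, floor: float = 0.1) -> float:
    """A comparable score for collections whose ratio may be undefined.

    ``total_correct / max(mean_false, floor)``: the floor (default 0.1, one
    false positive across a ten-trial collection) bounds the ratio from
    below when no false positives were observed, so perfect collections
    compare as large-but-finite instead of undefined.
    """
    return cm.total_correct / max(cm.mean_false, floor)


def standout_table(
    collections: Mapping[str, Mapping[str, object]],
    min_correct: int = 1,
    margins: Sequence[float] = MARGINS,
) -> pd.DataFrame:
    """Best margin per collection, as a standout-comparison table.

    ``collections`` maps a label to a dict with keys ``rows`` (the ten
    :class:`TrialSummaryRow`), ``set_no``, ``default_fact_value`` and
    ``pr_approach``.  For each collection the margin maximising the raw
    ratio, subject to ``total_correct >= min_correct`` and the ratio being
    defined, is selected (ties break toward the smaller margin).
    Collections with no qualifying margin are omitted.  The result is sorted
    by descending ratio, then label.
    """
    records = []
    for label, coll in collections.items():
        best: CollectionMetrics | None = None
        for m in margins:
            cm = ratio_at_margin(coll["rows"], m)
            if cm.ratio is None or cm.total_correct < min_correct:
                continue
            if best is None or cm.ratio > best.ratio:
                best = cm
        if best is None:
            continue
        records.append(
            {
                "Collection": label,
                "Model (Set)": coll.get("set_no"),
                "Default Fact Value": coll.get("default_fact_value"),
                "PR Approach": coll.get("pr_approach"),
                "Best Error Margin": best.margin,
                "Correct Patients": best.total_correct,
                "Avg Incorrect Patients": best.mean_false,
                "Correct-to-Incorrect Ratio": best.ratio_rounded,
                "_raw_ratio": best.ratio,
            }
        )
    records.sort(key=lambda r: (-r["_raw_ratio"], str(r["Collection"])))
    df = pd.DataFrame(
        records,
        columns=[
            "Collection",
            "Model (Set)",
            "Default Fact Value",
            "PR Approach",
            "Best Error Margin",
            "Correct Patients",
            "Avg Incorrect Patients",
            "Correct-to-Incorrect Ratio",
            "_raw_ratio",
        ],
    )
    return df.drop(columns="_raw_ratio")
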