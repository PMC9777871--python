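"""Experiment grid: 50 trials x 3 network designs x 4 baseline approaches.

A *trial* trains one patient's profile and scores all ten patients against
it.  Trial numbering encodes the study conventions:

* target patient = ``((trial - 1) mod 10) + 1``;
* trials 11-20 use the isolated conversion method, all others comprehensive;
* the default fact value is 0.500 for trials 1-20, 0.600 for 21-30,
  0.700 for 31-40 and 0.550 for 41-50.  It serves both as the network's
  initial fact value and as the fixed input value of the fixed baseline
  approaches; between-run intermediate resets always use 0.500.

Each trial runs per network design ("set" 1-3) and per baseline (PR)
approach, giving 50 x 3 x 4 = 600 executions for the full grid, summarised
as 60 ten-row tables (set x trial decade x approach).

Training consumes the target patient's segment 04 (minutes 30-40, 60,000
rows); evaluation presents seven fixed rows from every patient's segment 07
(minutes 60-70).  Normalisation divisors are always derived from training
segments only, mirroring a live system that can only have seen data to date.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    ConversionSpec,
    VitalsSeries,
    compute_divisors,
    normalize_rows,
    select_rows,
)
from .estimator import GDESVerifier, PR_APPROACHES
from .metrics import MARGINS, TrialSummaryRow, summarize_trial

__all__ = [
    "TRAIN_SEGMENT",
    "TEST_SEGMENT",
    "APPROACH_LABELS",
    "TrialConfig",
    "DeviationRecord",
    "run_trial",
    "run_experiment",
    "tables_to_frames",
    "trial_decades",
]

TRAIN_SEGMENT = 4
TEST_SEGMENT = 7

#: Human-readable captions for the four baseline approaches.
APPROACH_LABELS = {
    "fixed_single": "single fixed PR value",
    "actual_last_bp": "actual PR value",
    "fixed_all_facts": "all fixed PR values",
    "averaged_facts": "average actual PR values",
}

_DEFAULT_BY_DECADE = {0: 0.5, 1: 0.5, 2: 0.6, 3: 0.7, 4: 0.55}


def _default_fact_value(trial_no: int) -> float:
    return _DEFAULT_BY_DECADE[(trial_no - 1) // 10]


def _conversion_method(trial_no: int) -> str:
    return "isolated" if 11 <= trial_no <= 20 else "comprehensive"


@dataclass(frozen=True)
class TrialConfig:
    """One experimental cell.

    ``conversion_method``, ``default_fact_value`` and ``target_patient``
    are derived from ``trial_no`` by the study conventions and validated
    against them when supplied explicitly.
    """

    trial_no: int
    set_no: int
    pr_approach: str
    conversion_method: str = ""
    default_fact_value: float = -1.0
    target_patient: int = 0  # 1-based patient index
    velocity: float = 0.1
    train_target: float = 0.5
    reset_value: float = 0.5
    stride: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.trial_no <= 50):
            raise ValueError("trial_no must lie in 1..50")
        if self.set_no not in (1, 2, 3):
            raise ValueError("set_no must be 1, 2 or 3")
        if self.pr_approach not in PR_APPROACHES:
            raise ValueError(f"unknown pr_approach {self.pr_approach!r}")
        derived_target = ((self.trial_no - 1) % 10) + 1
        derived_conv = _conversion_method(self.trial_no)
        derived_default = _default_fact_value(self.trial_no)
        if self.target_patient == 0:
            object.__setattr__(self, "target_patient", derived_target)
        elif self.target_patient != derived_target:
            raise ValueError(
                f"trial {self.trial_no} targets patient {derived_target}, "
                f"not {self.target_patient}"
            )
        if not self.conversion_method:
            object.__setattr__(self, "conversion_method", derived_conv)
        elif self.conversion_method != derived_conv:
            raise ValueError(
                f"trial {self.trial_no} uses the {derived_conv} conversion"
            )
        if self.default_fact_value < 0:
            object.__setattr__(self, "default_fact_value", derived_default)
        elif self.default_fact_value != derived_default:
            raise ValueError(
                f"trial {self.trial_no} uses default fact value "
                f"{derived_default}"
            )


@dataclass
class DeviationRecord:
    """Seven evaluation outputs for one patient against one profile."""

    patient_id: str
    outputs: np.ndarray
    deviations: np.ndarray
    avg_deviation: float

    @classmethod
    def from_outputs(
        cls, patient_id: str, outputs: np.ndarray, target_value: float
    ) -> "DeviationRecord":
        devs = np.abs(np.asarray(outputs, dtype=float) - target_value)
        return cls(patient_id, np.asarray(outputs, float), devs, float(devs.mean()))


Cohort = Mapping[str, Mapping[int, VitalsSeries]]


def _patient_ids(cohort: Cohort) -> list[str]:
    return list(cohort)


def _require_segment(cohort: Cohort, pid: str, segment: int) -> VitalsSeries:
    try:
        return cohort[pid][segment]
    except KeyError:
        raise ValueError(
            f"cohort is missing segment {segment} for patient {pid}"
        ) from None


def fit_profile(
    config: TrialConfig,
    cohort: Cohort,
    rng: np.random.Generator | None = None,
    record_script: bool = False,
) -> tuple[GDESVerifier, ConversionSpec, str]:
    """Train the target patient's profile; returns
    ``(verifier, conversion spec, target patient id)``."""
    pids = _patient_ids(cohort)
    if config.target_patient > len(pids):
        raise ValueError(
            f"trial {config.trial_no} needs at least "
            f"{config.target_patient} patients, cohort has {len(pids)}"
        )
    target_pid = pids[config.target_patient - 1]
    training = [
        _require_segment(cohort, pid, TRAIN_SEGMENT) for pid in pids
    ]
    spec = compute_divisors(
        training, config.conversion_method, target_patient=target_pid
    )
    train_series = _require_segment(cohort, target_pid, TRAIN_SEGMENT)
    if train_series.segment_id != TRAIN_SEGMENT:
        raise ValueError("training rows must come from the training segment")
    X = normalize_rows(select_rows(train_series, "training"), spec)
    verifier = GDESVerifier(
        design_id=config.set_no,
        velocity=config.velocity,
        default_fact_value=config.default_fact_value,
        pr_approach=config.pr_approach,
        train_target=config.train_target,
        reset_value=config.reset_value,
        stride=config.stride,
        record_script=record_script,
        random_state=rng,
    )
    verifier.fit(X)
    return verifier, spec, target_pid


def run_trial(
    config: TrialConfig,
    cohort: Cohort,
    rng: np.random.Generator | None = None,
    record_script: bool = False,
) -> tuple[TrialSummaryRow, list[DeviationRecord], GDESVerifier]:
    """Execute one full trial: train, baseline, evaluate all patients."""
    verifier, spec, target_pid = fit_profile(
        config, cohort, rng=rng, record_script=record_script
    )
    records: list[DeviationRecord] = []
    for pid in _patient_ids(cohort):
        test_series = _require_segment(cohort, pid, TEST_SEGMENT)
        rows = select_rows(test_series, "test")
        outputs = verifier.outputs(normalize_rows(rows, spec))
        records.append(
            DeviationRecord.from_outputs(pid, outputs, verifier.target_value_)
        )
    summary = summarize_trial(
        records, target_pid, margins=MARGINS, trial_no=config.trial_no
    )
    return summary, records, verifier


def trial_decades() -> list[range]:
    return [range(d * 10 + 1, d * 10 + 11) for d in range(5)]


def run_experiment(
    cohort: Cohort,
    sets: Sequence[int] = (1, 2, 3),
    trials: Iterable[int] = range(1, 51),
    approaches: Sequence[str] = PR_APPROACHES,
    velocity: float = 0.1,
    stride: int = 1,
    seed: int | None = None,
) -> dict[tuple[int, str, str], list[TrialSummaryRow]]:
    """Run the (restricted) grid; returns ten-row collections keyed by
    ``(set_no, trial-decade label, approach)``.

    The full grid is 600 trial executions producing 60 collections.  ``seed``
    only determines the GUID streams of the freshly built networks, so two
    runs with the same cohort and seed are identical, GUIDs included.
    """
    trials = sorted(set(trials))
    bad = [t for t in trials if not 1 <= t <= 50]
    if bad:
        raise ValueError(f"trial numbers out of range: {bad}")
    results: dict[tuple[int, str, str], list[TrialSummaryRow]] = {}
    for set_no in sets:
        for ai, approach in enumerate(approaches):
            for trial_no in trials:
                config = TrialConfig(
                    trial_no=trial_no,
                    set_no=set_no,
                    pr_approach=approach,
                    velocity=velocity,
                    stride=stride,
                )
                rng = (
                    np.random.default_rng([seed, set_no, ai, trial_no])
                    if seed is not None
                    else None
                )
                summary, _, _ = run_trial(config, cohort, rng=rng)
                decade = (trial_no - 1) // 10
                label = f"{decade * 10 + 1}-{decade * 10 + 10}"
                results.setdefault((set_no, label, approach), []).append(summary)
    return results


def tables_to_frames(
    results: Mapping[tuple[int, str, str], list[TrialSummaryRow]],
) -> dict[tuple[int, str, str], pd.DataFrame]:
    """Render each collection as a table with the published column schema."""
    frames = {}
    for key, rows in results.items():
        frames[key] = pd.DataFrame(
            [r.as_table_row() for r in rows],
            columns=TrialSummaryRow.TABLE_COLUMNS,
        )
    return frames
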