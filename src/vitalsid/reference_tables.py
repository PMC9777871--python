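"""Published summary tables of the originating vital-sign identification
study, transcribed for regression-testing the metric arithmetic.

Each table holds the ten printed trial rows of one collection: average error
over all ten patients, the target patient's average error, the "Lowest"
flag, the four "Correct At" flags and the four "False At" counts, at margins
0.01 / 0.025 / 0.05 / 0.10.  ``REFERENCE_TABLES[n]`` carries the rows plus
the collection's metadata (network design, trial decade, conversion method,
default fact value, baseline approach).  These are fixture data for the
metrics layer only; nothing in the engine reads them.
"""

from __future__ import annotations

from .metrics import MARGINS, TrialSummaryRow

__all__ = ["REFERENCE_TABLES", "reference_rows", "STANDOUT_TABLE_IDS"]

#: Table ids whose collections the study's standout comparison summarises.
STANDOUT_TABLE_IDS = (3, 6, 7, 8, 10, 11)

_Y = True
_N = False

# Row layout: (avg_error, avg_err, lowest, correct@(.01,.025,.05,.1),
#              false@(.01,.025,.05,.1))
_RAW: dict[int, dict] = {
    1: dict(
        set_no=1, trials=(1, 10), conversion="comprehensive", default=0.5,
        approach="fixed_single", caption="single 0.5 PR value",
        rows=[
            (0.037, 0.012, _N, (_N, _Y, _Y, _Y), (0, 5, 7, 8)),
            (0.044, 0.035, _N, (_N, _N, _Y, _Y), (1, 5, 7, 8)),
            (0.129, 0.064, _N, (_N, _N, _N, _Y), (0, 0, 0, 2)),
            (0.064, 0.010, _N, (_N, _Y, _Y, _Y), (1, 2, 6, 6)),
            (0.034, 0.033, _N, (_N, _N, _Y, _Y), (3, 5, 7, 8)),
            (0.045, 0.004, _Y, (_Y, _Y, _Y, _Y), (0, 2, 6, 8)),
            (0.059, 0.010, _N, (_N, _Y, _Y, _Y), (1, 3, 4, 8)),
            (0.056, 0.024, _N, (_N, _Y, _Y, _Y), (0, 2, 5, 8)),
            (0.050, 0.002, _Y, (_Y, _Y, _Y, _Y), (2, 3, 5, 8)),
            (0.153, 0.100, _N, (_N, _N, _N, _Y), (0, 0, 1, 2)),
        ],
    ),
    2: dict(
        set_no=1, trials=(11, 20), conversion="isolated", default=0.5,
        approach="fixed_all_facts", caption="all 0.5 PR values",
        rows=[
            (0.199, 0.165, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.204, 0.193, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.204, 0.243, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.204, 0.218, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.204, 0.168, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.204, 0.222, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.204, 0.216, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.204, 0.226, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.204, 0.208, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.204, 0.111, _Y, (_N, _N, _N, _N), (0, 0, 0, 0)),
        ],
    ),
    3: dict(
        set_no=1, trials=(21, 30), conversion="comprehensive", default=0.6,
        approach="actual_last_bp", caption="actual PR value",
        rows=[
            (0.053, 0.024, _N, (_N, _Y, _Y, _Y), (1, 3, 4, 8)),
            (0.053, 0.035, _N, (_N, _N, _Y, _Y), (0, 4, 6, 8)),
            (0.055, 0.002, _Y, (_Y, _Y, _Y, _Y), (0, 1, 4, 8)),
            (0.076, 0.016, _Y, (_N, _Y, _Y, _Y), (0, 2, 3, 7)),
            (0.049, 0.030, _N, (_N, _N, _Y, _Y), (0, 2, 7, 8)),
            (0.061, 0.002, _Y, (_Y, _Y, _Y, _Y), (0, 1, 3, 7)),
            (0.068, 0.010, _N, (_N, _Y, _Y, _Y), (1, 3, 3, 7)),
            (0.062, 0.085, _N, (_N, _N, _N, _Y), (2, 2, 3, 7)),
            (0.065, 0.008, _N, (_Y, _Y, _Y, _Y), (2, 3, 3, 7)),
            (0.297, 0.173, _N, (_N, _N, _N, _N), (0, 0, 0, 1)),
        ],
    ),
    4: dict(
        set_no=2, trials=(1, 10), conversion="comprehensive", default=0.5,
        approach="averaged_facts", caption="average actual PR values",
        rows=[
            (0.040, 0.008, _N, (_Y, _Y, _Y, _Y), (1, 4, 7, 7)),
            (0.038, 0.022, _N, (_N, _Y, _Y, _Y), (2, 5, 7, 8)),
            (0.161, 0.037, _Y, (_N, _N, _Y, _Y), (0, 0, 0, 1)),
            (0.096, 0.012, _Y, (_N, _Y, _Y, _Y), (0, 1, 4, 6)),
            (0.074, 0.010, _Y, (_Y, _Y, _Y, _Y), (0, 0, 4, 7)),
            (0.069, 0.036, _N, (_N, _N, _Y, _Y), (0, 3, 3, 7)),
            (0.053, 0.061, _N, (_N, _N, _N, _Y), (2, 5, 6, 7)),
            (0.321, 0.305, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.038, 0.010, _N, (_Y, _Y, _Y, _Y), (1, 5, 7, 8)),
            (0.060, 0.007, _N, (_Y, _Y, _Y, _Y), (1, 2, 5, 7)),
        ],
    ),
    5: dict(
        set_no=2, trials=(11, 20), conversion="isolated", default=0.5,
        approach="fixed_all_facts", caption="all 0.5 PR values",
        rows=[
            (0.402, 0.407, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.423, 0.384, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.423, 0.457, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.423, 0.468, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.423, 0.418, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.423, 0.334, _Y, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.423, 0.466, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.423, 0.476, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.423, 0.458, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.423, 0.361, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
        ],
    ),
    6: dict(
        set_no=2, trials=(21, 30), conversion="comprehensive", default=0.6,
        approach="actual_last_bp", caption="actual PR value",
        rows=[
            (0.050, 0.006, _N, (_Y, _Y, _Y, _Y), (2, 3, 4, 8)),
            (0.072, 0.055, _N, (_N, _N, _N, _Y), (0, 1, 5, 6)),
            (0.159, 0.029, _Y, (_N, _N, _Y, _Y), (0, 0, 0, 1)),
            (0.055, 0.011, _N, (_N, _Y, _Y, _Y), (2, 2, 4, 7)),
            (0.121, 0.027, _Y, (_N, _N, _Y, _Y), (0, 0, 1, 3)),
            (0.053, 0.009, _N, (_Y, _Y, _Y, _Y), (1, 1, 4, 8)),
            (0.071, 0.040, _N, (_N, _N, _Y, _Y), (0, 1, 3, 7)),
            (0.206, 0.115, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.042, 0.002, _N, (_Y, _Y, _Y, _Y), (1, 4, 6, 8)),
            (0.124, 0.021, _Y, (_N, _Y, _Y, _Y), (0, 0, 0, 2)),
        ],
    ),
    7: dict(
        set_no=3, trials=(1, 10), conversion="comprehensive", default=0.5,
        approach="fixed_single", caption="single 0.5 PR value",
        rows=[
            (0.056, 0.005, _Y, (_Y, _Y, _Y, _Y), (0, 0, 4, 9)),
            (0.026, 0.011, _N, (_N, _Y, _Y, _Y), (3, 4, 7, 9)),
            (0.133, 0.096, _N, (_N, _N, _N, _Y), (0, 1, 1, 2)),
            (0.090, 0.007, _Y, (_Y, _Y, _Y, _Y), (1, 2, 4, 6)),
            (0.028, 0.000, _Y, (_Y, _Y, _Y, _Y), (1, 4, 8, 9)),
            (0.112, 0.022, _Y, (_N, _Y, _Y, _Y), (0, 0, 1, 3)),
            (0.100, 0.023, _Y, (_N, _Y, _Y, _Y), (0, 0, 1, 3)),
            (0.085, 0.048, _N, (_N, _N, _Y, _Y), (0, 2, 4, 6)),
            (0.082, 0.025, _N, (_N, _Y, _Y, _Y), (1, 2, 4, 6)),
            (0.069, 0.052, _N, (_N, _N, _N, _Y), (2, 2, 5, 7)),
        ],
    ),
    8: dict(
        set_no=3, trials=(11, 20), conversion="isolated", default=0.5,
        approach="actual_last_bp", caption="actual PR value",
        rows=[
            (0.056, 0.002, _Y, (_Y, _Y, _Y, _Y), (2, 4, 6, 8)),
            (0.054, 0.009, _Y, (_Y, _Y, _Y, _Y), (0, 2, 7, 8)),
            (0.058, 0.062, _N, (_N, _N, _N, _Y), (1, 2, 7, 8)),
            (0.092, 0.007, _Y, (_Y, _Y, _Y, _Y), (0, 2, 4, 6)),
            (0.068, 0.104, _N, (_N, _N, _N, _N), (1, 3, 7, 8)),
            (0.054, 0.027, _N, (_N, _N, _Y, _Y), (0, 3, 7, 8)),
            (0.054, 0.012, _N, (_N, _Y, _Y, _Y), (0, 2, 7, 8)),
            (0.084, 0.047, _N, (_N, _N, _Y, _Y), (0, 1, 4, 7)),
            (0.049, 0.004, _N, (_Y, _Y, _Y, _Y), (1, 5, 7, 8)),
            (0.093, 0.198, _N, (_N, _N, _N, _N), (0, 1, 1, 6)),
        ],
    ),
    9: dict(
        set_no=3, trials=(11, 20), conversion="isolated", default=0.5,
        approach="fixed_all_facts", caption="all 0.5 PR values",
        rows=[
            (0.396, 0.357, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.416, 0.415, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.416, 0.477, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.416, 0.464, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.416, 0.380, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.416, 0.452, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.416, 0.437, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.416, 0.453, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.416, 0.443, _N, (_N, _N, _N, _N), (0, 0, 0, 0)),
            (0.416, 0.164, _Y, (_N, _N, _N, _N), (0, 0, 0, 0)),
        ],
    ),
    10: dict(
        set_no=3, trials=(21, 30), conversion="comprehensive", default=0.6,
        approach="actual_last_bp", caption="actual PR value",
        rows=[
            (0.132, 0.007, _Y, (_Y, _Y, _Y, _Y), (0, 0, 0, 2)),
            (0.075, 0.041, _N, (_N, _N, _Y, _Y), (0, 0, 4, 7)),
            (0.082, 0.029, _N, (_N, _N, _Y, _Y), (0, 1, 1, 7)),
            (0.071, 0.015, _Y, (_N, _Y, _Y, _Y), (0, 0, 3, 6)),
            (0.082, 0.057, _N, (_N, _N, _N, _Y), (0, 0, 3, 6)),
            (0.111, 0.022, _Y, (_N, _Y, _Y, _Y), (0, 0, 1, 3)),
            (0.097, 0.094, _N, (_N, _N, _N, _Y), (1, 1, 1, 5)),
            (0.061, 0.086, _N, (_N, _N, _N, _Y), (1, 2, 4, 7)),
            (0.054, 0.006, _N, (_Y, _Y, _Y, _Y), (2, 5, 5, 7)),
            (0.111, 0.023, _Y, (_N, _Y, _Y, _Y), (0, 0, 0, 2)),
        ],
    ),
    11: dict(
        set_no=3, trials=(41, 50), conversion="comprehensive", default=0.55,
        approach="fixed_single", caption="single 0.5 PR value",
        rows=[
            (0.058, 0.005, _Y, (_Y, _Y, _Y, _Y), (0, 0, 4, 8)),
            (0.029, 0.011, _N, (_N, _Y, _Y, _Y), (3, 4, 7, 9)),
            (0.135, 0.096, _N, (_N, _N, _N, _Y), (0, 1, 1, 2)),
            (0.075, 0.010, _N, (_N, _Y, _Y, _Y), (1, 1, 3, 7)),
            (0.030, 0.000, _Y, (_Y, _Y, _Y, _Y), (1, 3, 8, 9)),
            (0.112, 0.022, _Y, (_N, _Y, _Y, _Y), (0, 0, 1, 3)),
            (0.099, 0.023, _Y, (_N, _Y, _Y, _Y), (0, 0, 1, 3)),
            (0.048, 0.018, _N, (_N, _Y, _Y, _Y), (1, 4, 5, 8)),
            (0.027, 0.019, _N, (_N, _Y, _Y, _Y), (2, 6, 7, 9)),
            (0.070, 0.013, _Y, (_N, _Y, _Y, _Y), (0, 0, 2, 8)),
        ],
    ),
}

REFERENCE_TABLES: dict[int, dict] = _RAW


def reference_rows(table_id: int) -> list[TrialSummaryRow]:
    """The printed rows of one table as :class:`TrialSummaryRow` objects."""
    meta = REFERENCE_TABLES[table_id]
    first_trial = meta["trials"][0]
    rows = []
    for i, (avg_all, avg_target, lowest, correct, false) in enumerate(
        meta["rows"]
    ):
        trial_no = first_trial + i
        target = f"patient{((trial_no - 1) % 10) + 1}"
        rows.append(
            TrialSummaryRow(
                trial_no=trial_no,
                target_patient=target,
                average_error=avg_all,
                avg_err_target=avg_target,
                lowest=lowest,
                correct_at=dict(zip(MARGINS, correct)),
                false_at=dict(zip(MARGINS, false)),
            )
        )
    return rows
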