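"""Seeded synthetic vital-sign cohorts in the case-file CSV layout.

The generator stands in for the hospital anaesthesia-monitoring dataset.
Each patient's channel is simulated as a piecewise-constant, mean-reverting
stochastic process: a value is held for an exponentially distributed duration
(monitors refresh slowly relative to the 100 Hz export, so exported files
contain long runs of repeated values), then stepped by a Gaussian draw plus
a pull back toward the patient's baseline.  The mean reversion models
homeostasis: without it a random walk would drift without bound over the
half hour separating the training segment (minutes 30-40) from the test
segment (minutes 60-70), which real, stable surgical patients do not do.

Inter-patient structure is controlled by a single ``separation`` scale:
patient baselines are drawn around population resting means with a standard
deviation proportional to ``separation`` (0 makes every patient a clone, the
hardest condition for identity verification).

Everything is deterministic given the cohort's ``master_seed``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import DEFAULT_COLUMNS, VitalsSeries, format_time_offset
from .network import CHANNELS

__all__ = [
    "PatientParams",
    "CohortSpec",
    "generate_patient",
    "generate_cohort",
    "write_case_files",
    "POPULATION_MEANS",
    "SEPARATION_SCALE",
    "PHYSIO_BOUNDS",
    "CASE_IDS",
]

#: Textbook resting values for an adult under monitoring.
POPULATION_MEANS: dict[str, float] = {
    "heart_rate": 75.0,     # bpm
    "etco2": 38.0,          # mmHg
    "resp_rate": 14.0,      # breaths/min
    "blood_pressure": 90.0,  # mmHg (mean arterial pressure)
}

#: Baseline standard deviation per unit of cohort ``separation``.
SEPARATION_SCALE: dict[str, float] = {
    "heart_rate": 10.0,
    "etco2": 4.0,
    "resp_rate": 3.0,
    "blood_pressure": 10.0,
}

#: Hard physiological clamps applied to every generated value.
PHYSIO_BOUNDS: dict[str, tuple[float, float]] = {
    "heart_rate": (30.0, 180.0),
    "etco2": (15.0, 60.0),
    "resp_rate": (4.0, 40.0),
    "blood_pressure": (40.0, 200.0),
}

#: Default within-patient step standard deviation per hold, by channel.
DEFAULT_WANDER_SD: dict[str, float] = {
    "heart_rate": 1.0,
    "etco2": 0.8,
    "resp_rate": 0.8,
    "blood_pressure": 1.5,
}

#: Channels exported as integers (the rest keep one decimal place).
_INTEGER_CHANNELS = ("heart_rate", "resp_rate")

#: Case labels mirroring the surgical cohort the file layout emulates
#: (patients 1-10 map onto these case numbers).
CASE_IDS = ("01", "03", "04", "05", "06", "09", "11", "12", "13", "14")

SEGMENT_ROWS = 60_000  # 10 minutes at 100 Hz
_SEGMENT_CS = SEGMENT_ROWS  # one row per centisecond


@dataclass
class PatientParams:
    """Ground-truth generator parameters for one synthetic patient."""

    patient_id: str
    baselines: dict[str, float]
    wander_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WANDER_SD)
    )
    hold_duration: float = 5.0  # seconds; mean run length of repeated values
    mean_reversion: float = 0.05  # pull toward baseline per hold, in (0, 1]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hold_duration <= 0:
            raise ValueError("hold_duration must be positive")
        if not (0.0 < self.mean_reversion <= 1.0):
            raise ValueError("mean_reversion must lie in (0, 1]")
        for ch in CHANNELS:
            lo, hi = PHYSIO_BOUNDS[ch]
            b = self.baselines.get(ch)
            if b is None or not (lo <= b <= hi):
                raise ValueError(
                    f"baseline for {ch} must lie in [{lo}, {hi}], got {b}"
                )


@dataclass
class CohortSpec:
    """Specification of a seeded synthetic cohort.

    ``baseline_layout`` controls how patient baselines are placed around the
    population means:

    * ``"random"`` — independent Gaussian draws with standard deviation
      ``separation * SEPARATION_SCALE`` per channel.  Realistic sampling,
      but two patients can land arbitrarily close by chance.
    * ``"spaced"`` — evenly spaced over ``mean ± 2 * separation * scale``
      with an independent random permutation per channel plus a small
      jitter, so every pair of patients is separated in every channel.
      This is the construction behind the strong-separation study
      condition (see :func:`strong_separation_spec`).
    """

    n_patients: int = 10
    separation: float = 1.0
    segment_ids: tuple[int, ...] = (4, 7)
    master_seed: int = 0
    n_rows: int = SEGMENT_ROWS  # rows per emitted segment
    hold_duration: float = 5.0
    wander_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WANDER_SD)
    )
    baseline_layout: str = "random"
    separation_scale: dict[str, float] = field(
        default_factory=lambda: dict(SEPARATION_SCALE)
    )

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            warnings.warn(
                "misidentification experiments need at least 2 patients",
                stacklevel=2,
            )
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if not (1 <= self.n_rows <= SEGMENT_ROWS):
            raise ValueError("n_rows must lie in [1, 60000]")
        if self.baseline_layout not in ("random", "spaced"):
            raise ValueError(
                f"unknown baseline layout {self.baseline_layout!r}"
            )


#: Per-channel baseline half-spreads (at ``separation=1``) of the
#: strong-separation reference condition.  Chosen so that (a) every
#: comprehensively normalized value stays above 0.5 — the training target —
#: keeping the trained weights on a single, patient-specific channel instead
#: of an uninformative mixture, and (b) mean arterial pressure, which the
#: fixed-value baseline recipe overwrites, has the narrowest relative
#: spread (it is also the most tightly regulated vital across people).
STRONG_SEPARATION_SCALE: dict[str, float] = {
    "heart_rate": 11.0,   # baselines span ~53-97 bpm
    "etco2": 5.5,         # ~27-49 mmHg
    "resp_rate": 2.0,     # ~10-18 breaths/min
    "blood_pressure": 7.0,  # ~76-104 mmHg
}


def strong_separation_spec(
    master_seed: int = 0, n_rows: int = SEGMENT_ROWS, n_patients: int = 10
) -> CohortSpec:
    """Study conditions for a strongly separated cohort.

    "Strong separation" means every pair of patients is well separated in
    every channel relative to their within-patient variability: baselines
    are evenly spaced over a wide physiological range
    (``baseline_layout="spaced"`` with :data:`STRONG_SEPARATION_SCALE`)
    and the within-patient wander is a quarter of the default, i.e.
    patients who are physiologically stable over the procedure.  This is
    the easiest regime for identity verification and the reference
    condition for the package's end-to-end recovery checks.
    """
    return CohortSpec(
        n_patients=n_patients,
        separation=1.0,
        master_seed=master_seed,
        n_rows=n_rows,
        wander_sd={ch: 0.25 * v for ch, v in DEFAULT_WANDER_SD.items()},
        baseline_layout="spaced",
        separation_scale=dict(STRONG_SEPARATION_SCALE),
    )


def _simulate_holds(
    rng: np.random.Generator, params: PatientParams, ch: str, total_cs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Hold-level simulation of one channel from time zero.

    Returns (values, lengths) where ``lengths`` are run lengths in
    centiseconds summing to ``total_cs``.
    """
    mean_hold_cs = params.hold_duration * 100.0
    n_est = int(total_cs / mean_hold_cs * 1.5) + 16
    lo, hi = PHYSIO_BOUNDS[ch]
    sd = params.wander_sd[ch]
    kappa = params.mean_reversion
    base = params.baselines[ch]
    values: list[float] = []
    lengths: list[int] = []
    covered = 0
    v = base
    while covered < total_cs:
        durs = np.maximum(
            1, rng.exponential(mean_hold_cs, size=n_est).astype(np.int64)
        )
        steps = rng.normal(0.0, sd, size=n_est)
        for d, s in zip(durs, steps):
            run = int(min(d, total_cs - covered))
            values.append(min(max(v, lo), hi))
            lengths.append(run)
            covered += run
            v = v + s + kappa * (base - v)
            if covered >= total_cs:
                break
    return np.asarray(values), np.asarray(lengths, dtype=np.int64)


def generate_patient(
    params: PatientParams,
    segment_id: int,
    n_rows: int = SEGMENT_ROWS,
) -> VitalsSeries:
    """Generate one 10-minute segment (``n_rows`` rows at 100 Hz).

    The underlying hold-level process runs from procedure start so that
    later segments are a continuation of earlier ones: segment ``MM`` covers
    the time window ``[(MM-1)*10 min, MM*10 min)``.  Deterministic given
    ``params.seed``.
    """
    if segment_id < 1:
        raise ValueError("segment_id is 1-based")
    start_cs = (segment_id - 1) * _SEGMENT_CS
    end_cs = start_cs + n_rows
    time_cs = np.arange(start_cs, end_cs, dtype=np.int64)
    out = pd.DataFrame({"time_cs": time_cs})
    for i, ch in enumerate(CHANNELS):
        # Independent, seeded stream per channel.
        rng = np.random.default_rng(
            np.random.SeedSequence([params.seed, i])
        )
        values, lengths = _simulate_holds(rng, params, ch, end_cs)
        full = np.repeat(values, lengths)[start_cs:end_cs]
        if ch in _INTEGER_CHANNELS:
            full = np.rint(full)
        else:
            full = np.round(full, 1)
        lo, hi = PHYSIO_BOUNDS[ch]
        out[ch] = np.clip(full, lo, hi)
    return VitalsSeries(params.patient_id, segment_id, out)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[dict[str, dict[int, VitalsSeries]], list[PatientParams]]:
    """Generate a full cohort plus its ground-truth parameter manifest.

    Returns ``(cohort, manifest)`` where ``cohort[patient_id][segment_id]``
    is a :class:`VitalsSeries` and the manifest lists one
    :class:`PatientParams` per patient.  Baselines are drawn around
    :data:`POPULATION_MEANS` with standard deviation
    ``separation * SEPARATION_SCALE`` (clipped to physiological bounds);
    ``separation == 0`` yields identical clones.
    """
    ss = np.random.SeedSequence(spec.master_seed)
    base_rng = np.random.default_rng(ss)
    child_seeds = [
        int(s) for s in base_rng.integers(0, 2**31 - 1, size=spec.n_patients)
    ]
    n = spec.n_patients
    baseline_grid: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        lo, hi = PHYSIO_BOUNDS[ch]
        span = hi - lo
        safe_lo, safe_hi = lo + 0.05 * span, hi - 0.05 * span
        scale = spec.separation * spec.separation_scale[ch]
        if spec.baseline_layout == "spaced" and scale > 0:
            half = 2.0 * scale
            grid = np.linspace(
                POPULATION_MEANS[ch] - half, POPULATION_MEANS[ch] + half, n
            )
            spacing = grid[1] - grid[0] if n > 1 else 1.0
            grid = base_rng.permutation(grid) + base_rng.uniform(
                -0.05 * spacing, 0.05 * spacing, size=n
            )
        else:
            grid = base_rng.normal(POPULATION_MEANS[ch], scale, size=n)
        baseline_grid[ch] = np.clip(grid, safe_lo, safe_hi)
    manifest: list[PatientParams] = []
    cohort: dict[str, dict[int, VitalsSeries]] = {}
    for p in range(spec.n_patients):
        pid = f"case{CASE_IDS[p]}" if p < len(CASE_IDS) else f"case{p + 1:02d}"
        baselines = {ch: float(baseline_grid[ch][p]) for ch in CHANNELS}
        params = PatientParams(
            patient_id=pid,
            baselines=baselines,
            wander_sd=dict(spec.wander_sd),
            hold_duration=spec.hold_duration,
            seed=child_seeds[p],
        )
        manifest.append(params)
        cohort[pid] = {
            seg: generate_patient(params, seg, spec.n_rows)
            for seg in spec.segment_ids
        }
    return cohort, manifest


def _format_channel(ch: str, values: np.ndarray) -> list[str]:
    if ch in _INTEGER_CHANNELS:
        return [str(int(v)) for v in values]
    return [f"{v:.1f}" for v in values]


def write_case_files(
    cohort: Mapping[str, Mapping[int, VitalsSeries]],
    directory: str | Path,
    manifest: Sequence[PatientParams] | None = None,
) -> list[Path]:
    """Write each series as a two-header-line CSV named
    ``uq_vsd_case<NN>_fulldata_<MM>.csv``; returns the written paths.

    When a manifest is given it is saved alongside as ``manifest.json``
    (seeds and ground-truth baselines), which suffices to regenerate the
    cohort exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not cohort:
        warnings.warn("empty cohort: no files written", stacklevel=2)
        return []
    paths: list[Path] = []
    colnames = [DEFAULT_COLUMNS[k] for k in ("time", *CHANNELS)]
    for pid, segments in cohort.items():
        case = pid.removeprefix("case")
        for seg, series in segments.items():
            path = directory / f"uq_vsd_case{case}_fulldata_{seg:02d}.csv"
            times = [format_time_offset(t) for t in series.data["time_cs"]]
            cols = [times] + [
                _format_channel(ch, series.channel(ch)) for ch in CHANNELS
            ]
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(
                    f"Vital sign export,{pid},segment {seg:02d},100 Hz,\n"
                )
                fh.write(",".join(colnames) + "\n")
                for row in zip(*cols):
                    fh.write(",".join(row) + "\n")
            paths.append(path)
    if manifest is not None:
        payload = [
            {
                "patient_id": p.patient_id,
                "baselines": p.baselines,
                "wander_sd": p.wander_sd,
                "hold_duration": p.hold_duration,
                "mean_reversion": p.mean_reversion,
                "seed": p.seed,
            }
            for p in manifest
        ]
        (directory / "manifest.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True)
        )
    return paths
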