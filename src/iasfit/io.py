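"""Readers and writers for the trial CSV and fitted-parameter formats.

Patient files are headerless CSVs with ten positional columns:
patient number, date, prescribed CPA, prescribed LEU, PSA (ng/mL),
testosterone, cycle number, treatment on(1)/off(0), accumulated days, and an
alternate day count.  Only PSA, cycle, on/off and accumulated days are used;
a row with an empty (or "NA") PSA cell still contributes its day to the
treatment schedule.  Fitted parameters are written as a single-column file:
the 13 combined parameters in canonical order, eight literal 0 placeholder
lines, then the final cost — 22 lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .fitting import FitResult, ObservationSeries
from .model import CombinedParameters, N_PARAMS, TreatmentSchedule

N_PLACEHOLDER_ZEROS = 8

_COL_PSA = 4
_COL_CYCLE = 6
_COL_ONOFF = 7
_COL_DAYS = 8


@dataclass(frozen=True)
class PatientRecord:
    """Parsed rows of one patient plus the derived series and schedule."""

    patient_id: str
    rows: Tuple[Tuple[int, Optional[float], int, int], ...]
    # each row: (day, psa or None, on_off, cycle)
    observations: ObservationSeries

    @property
    def schedule(self) -> TreatmentSchedule:
        return self.observations.schedule


def _parse_cell(raw) -> Optional[float]:
    if raw is None:
        return None
    s = str(raw).strip()
    if s == "" or s.upper() in ("NA", "NAN"):
        return None
    return float(s)


def read_patient_csv(path) -> PatientRecord:
    """Parse one trial-format CSV into a PatientRecord.

    The schedule is reconstructed from changes in the on/off column: a
    segment boundary falls on the day of the first row bearing the new flag.
    It is extended back to day 0 if the first row starts later, and forward
    one day past the last row so the final observation is covered.
    """
    df = pd.read_csv(path, header=None, dtype=str, skipinitialspace=True)
    if df.shape[0] < 1:
        raise ValueError(f"{path}: no data rows")
    if df.shape[1] <= _COL_DAYS:
        raise ValueError(
            f"{path}: expected at least {_COL_DAYS + 1} comma-separated "
            f"columns, found {df.shape[1]}")

    rows: List[Tuple[int, Optional[float], int, int]] = []
    prev_day = None
    for idx, raw in enumerate(df.itertuples(index=False), start=1):
        try:
            day_v = _parse_cell(raw[_COL_DAYS])
            onoff_v = _parse_cell(raw[_COL_ONOFF])
            if day_v is None or onoff_v is None:
                raise ValueError("missing day or on/off value")
            day = int(day_v)
            onoff = int(onoff_v)
            if onoff not in (0, 1):
                raise ValueError(f"on/off flag must be 0 or 1, got {onoff}")
            cyc_v = _parse_cell(raw[_COL_CYCLE])
            cycle = int(cyc_v) if cyc_v is not None else 0
            psa = _parse_cell(raw[_COL_PSA])
            if psa is not None and (psa < 0 or not math.isfinite(psa)):
                raise ValueError(f"invalid PSA value {psa}")
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: malformed row at line {idx}: {err}") \
                from None
        if prev_day is not None and day < prev_day:
            raise ValueError(
                f"{path}: days decrease at line {idx} ({prev_day} -> {day})")
        prev_day = day
        rows.append((day, psa, onoff, cycle))

    pid = str(df.iloc[0, 0]).strip()

    # schedule from flag transitions; boundaries at first row of a new flag
    segs: List[Tuple[int, int, int]] = []
    start = 0
    cur = rows[0][2]
    for day, _, onoff, _ in rows[1:]:
        if onoff != cur:
            if day > start:
                segs.append((start, day, cur))
                start = day
            cur = onoff
    end = max(rows[-1][0] + 1, start + 1)
    segs.append((start, end, cur))
    schedule = TreatmentSchedule(tuple(segs))

    seen = {}
    for day, psa, _, _ in rows:
        if psa is not None:
            seen[day] = psa  # a later duplicate day overrides
    times = np.array(sorted(seen), dtype=np.int64)
    values = np.array([seen[t] for t in times], dtype=float)
    obs = ObservationSeries(times=times, values=values, schedule=schedule)
    return PatientRecord(patient_id=pid, rows=tuple(rows), observations=obs)


def write_patient_csv(obs: ObservationSeries, path,
                      patient_id: str = "0") -> None:
    """Write a series back in the ten-column trial format.

    Emits one row per observation plus (PSA-less) rows at treatment-switch
    days that carry no measurement, so the reader recovers the exact
    segmentation.  Unused columns are left empty.
    """
    days = {int(t): float(v) for t, v in zip(obs.times, obs.values)}
    for s, _, _ in obs.schedule.segments:
        days.setdefault(int(s), None)

    def cycle_of(day: int) -> int:
        cyc = 0
        for s, e, m in obs.schedule.segments:
            if m == 1 and s <= day:
                cyc += 1
            if s > day:
                break
        return max(cyc, 1)

    with open(path, "w") as fh:
        for day in sorted(days):
            psa = days[day]
            psa_s = "" if psa is None else repr(float(psa))
            m = obs.schedule.flag_at(day)
            fh.write(f"{patient_id},,,,{psa_s},,{cycle_of(day)},{m},{day},\n")


def write_fitted_params(result, path) -> None:
    """Write the 22-line single-column fitted-parameter file.

    Accepts a FitResult or a (CombinedParameters, cost) pair.  Lines 1-13
    are the canonical parameter vector at full precision, lines 14-21 are
    literal 0 placeholders, line 22 is the cost.
    """
    if isinstance(result, FitResult):
        params, cost = result.params, result.cost
    else:
        params, cost = result
    p = params.to_array() if isinstance(params, CombinedParameters) \
        else np.asarray(params, dtype=float)
    with open(path, "w") as fh:
        for v in p:
            fh.write(f"{float(v)!r}\n")
        for _ in range(N_PLACEHOLDER_ZEROS):
            fh.write("0\n")
        fh.write(f"{float(cost)!r}\n")


def read_fitted_params(path) -> Tuple[CombinedParameters, float]:
    """Read back a fitted-parameter file; placeholder zeros are ignored."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() != ""]
    expected = N_PARAMS + N_PLACEHOLDER_ZEROS + 1
    if len(lines) != expected:
        raise ValueError(
            f"{path}: expected {expected} lines, found {len(lines)}")
    p = np.array([float(v) for v in lines[:N_PARAMS]])
    cost = float(lines[-1])
    return CombinedParameters.from_array(p), cost
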