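"""Three-compartment switched model of prostate-tumor dynamics.

The serum PSA level is modeled as the sum of three cell burdens (all in
PSA-equivalent ng/mL): androgen-dependent cells ``x1``, reversibly
castration-resistant cells ``x2`` and irreversibly castration-resistant cells
``x3``.  Dynamics are daily linear maps that switch between an on-treatment
matrix (AD cells shrink and leak into the resistant pools) and an
off-treatment matrix (AD cells regrow, fed by reversion from ``x2``):

on  (m=1):  x1' = d11*x1
            x2' = d21*x1 + d22*x2
            x3' = d31*x1 + d32*x2 + d33*x3

off (m=0):  x1' = d11*x1 + d12*x2
            x2' = d22*x2
            x3' = d33*x3

One step is one day.  A patient is the pair (initial state, coefficient set),
flattened into a canonical 13-vector that is what gets fitted, priored and
classified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

from ._kernels import simulate_flags, simulate_ias_kernel

#: canonical flattening order of the combined parameter vector
PARAM_NAMES: Tuple[str, ...] = (
    "x1(0)", "x2(0)", "x3(0)",
    "d11_on", "d21_on", "d22_on", "d31_on", "d32_on", "d33_on",
    "d11_off", "d12_off", "d22_off", "d33_off",
)

N_PARAMS = 13


@dataclass(frozen=True, eq=False)
class TumorState:
    """Cell burdens (PSA-equivalent ng/mL) of the three compartments."""

    x1: float
    x2: float
    x3: float

    @property
    def psa(self) -> float:
        return self.x1 + self.x2 + self.x3

    def to_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3], dtype=float)


class CombinedParameters:
    """Initial state plus the ten daily transition coefficients.

    Parameters
    ----------
    x0 : length-3 sequence
        Initial burdens (x1(0), x2(0), x3(0)).
    d_on : length-6 sequence
        On-treatment coefficients in the order (d11, d21, d22, d31, d32, d33).
    d_off : length-4 sequence
        Off-treatment coefficients in the order (d11, d12, d22, d33).
    """

    __slots__ = ("x0", "d_on", "d_off")

    def __init__(self, x0: Sequence[float], d_on: Sequence[float],
                 d_off: Sequence[float]):
        x0 = np.asarray(x0, dtype=float)
        d_on = np.asarray(d_on, dtype=float)
        d_off = np.asarray(d_off, dtype=float)
        if x0.shape != (3,) or d_on.shape != (6,) or d_off.shape != (4,):
            raise ValueError(
                "expected shapes (3,), (6,), (4,); got "
                f"{x0.shape}, {d_on.shape}, {d_off.shape}")
        self.x0 = x0
        self.d_on = d_on
        self.d_off = d_off

    def to_array(self) -> np.ndarray:
        """Canonical 13-vector (see PARAM_NAMES)."""
        return np.concatenate([self.x0, self.d_on, self.d_off])

    @classmethod
    def from_array(cls, p: Sequence[float]) -> "CombinedParameters":
        p = np.asarray(p, dtype=float)
        if p.shape != (N_PARAMS,):
            raise ValueError(f"combined parameter vector must have length "
                             f"{N_PARAMS}, got shape {p.shape}")
        return cls(p[:3], p[3:9], p[9:13])

    def on_matrix(self) -> np.ndarray:
        d = self.d_on
        return np.array([[d[0], 0.0, 0.0],
                         [d[1], d[2], 0.0],
                         [d[3], d[4], d[5]]])

    def off_matrix(self) -> np.ndarray:
        d = self.d_off
        return np.array([[d[0], d[1], 0.0],
                         [0.0, d[2], 0.0],
                         [0.0, 0.0, d[3]]])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        vals = ", ".join(f"{n}={v:.4g}"
                         for n, v in zip(PARAM_NAMES, self.to_array()))
        return f"CombinedParameters({vals})"


@dataclass(frozen=True)
class TreatmentSchedule:
    """Contiguous half-open on/off segments starting at day 0.

    ``segments`` is an ordered tuple of (start_day, end_day, m) with
    m = 1 on-treatment and m = 0 off-treatment; day t belongs to the segment
    with start <= t < end.
    """

    segments: Tuple[Tuple[int, int, int], ...]

    def __post_init__(self):
        segs = tuple((int(s), int(e), int(m)) for s, e, m in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("schedule must contain at least one segment")
        if segs[0][0] != 0:
            raise ValueError("schedule must start at day 0")
        prev_end = 0
        for s, e, m in segs:
            if m not in (0, 1):
                raise ValueError(f"treatment flag must be 0 or 1, got {m}")
            if s != prev_end:
                raise ValueError("segments must be contiguous and ordered")
            if e <= s:
                raise ValueError("segment end must exceed its start")
            prev_end = e

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    @classmethod
    def all_on(cls, horizon: int) -> "TreatmentSchedule":
        return cls(((0, int(horizon), 1),))

    @classmethod
    def from_flags(cls, flags: Iterable[int]) -> "TreatmentSchedule":
        flags = np.asarray(list(flags), dtype=int)
        if flags.size == 0:
            raise ValueError("flags must be non-empty")
        change = np.flatnonzero(np.diff(flags)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [flags.size]])
        return cls(tuple((int(s), int(e), int(flags[s]))
                         for s, e in zip(starts, ends)))

    def flags(self, horizon: int) -> np.ndarray:
        """Per-day flag array m(t) for t in [0, horizon)."""
        horizon = int(horizon)
        if horizon > self.end:
            raise ValueError(
                f"schedule ends at day {self.end} but horizon {horizon} "
                "was requested (gap inside horizon)")
        out = np.zeros(horizon, dtype=np.uint8)
        for s, e, m in self.segments:
            if s >= horizon:
                break
            out[s:min(e, horizon)] = m
        return out

    def flag_at(self, day: int) -> int:
        """Flag of the segment containing ``day`` (half-open convention)."""
        for s, e, m in self.segments:
            if s <= day < e:
                return m
        if day == self.end:  # final grid point: use the last segment
            return self.segments[-1][2]
        raise ValueError(f"day {day} is outside the schedule [0, {self.end}]")


@dataclass(frozen=True)
class Trajectory:
    """Daily states and PSA under a treatment schedule."""

    states: np.ndarray  # (T+1, 3)
    schedule: TreatmentSchedule

    @property
    def days(self) -> np.ndarray:
        return np.arange(self.states.shape[0])

    @property
    def horizon(self) -> int:
        return self.states.shape[0] - 1

    @property
    def psa(self) -> np.ndarray:
        return self.states.sum(axis=1)

    def to_frame(self):
        """Tidy per-day table (day, x1, x2, x3, psa, m)."""
        import pandas as pd

        m = np.array([self.schedule.flag_at(int(t)) for t in self.days])
        return pd.DataFrame({
            "day": self.days,
            "x1": self.states[:, 0],
            "x2": self.states[:, 1],
            "x3": self.states[:, 2],
            "psa": self.psa,
            "m": m,
        })

    def plot(self, ax=None):  # pragma: no cover - visual aid
        """Plot PSA with shaded on-treatment periods."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.days, self.psa, lw=1.2)
        for s, e, m in self.schedule.segments:
            if m == 1:
                ax.axvspan(s, min(e, self.horizon), color="0.85", zorder=0)
        ax.set_xlabel("day")
        ax.set_ylabel("PSA (ng/mL)")
        return ax


@dataclass(frozen=True)
class IASProtocol:
    """Threshold-switching rule of an intermittent-suppression trial.

    Treatment is stopped once at least ``min_on_days`` of the current
    on-period have elapsed and PSA has fallen to ``psa_low``; it is resumed
    when PSA rises to ``psa_high``.  Defaults follow common trial practice:
    9 months minimum on-treatment, stop below 1 ng/mL, resume above 10 ng/mL.
    """

    min_on_days: int = 270
    psa_low: float = 1.0
    psa_high: float = 10.0
    horizon: int = 3600

    def __post_init__(self):
        if self.min_on_days <= 0:
            raise ValueError("min_on_days must be positive")
        if not self.psa_low < self.psa_high:
            raise ValueError("psa_low must be below psa_high")
        if self.horizon < 0:
            raise ValueError("horizon must be non-negative")


def step(state, params: CombinedParameters, m: int):
    """Advance the state by one day under treatment flag ``m``.

    Pure-Python reference for the compiled kernels; accepts a TumorState or a
    length-3 sequence and returns a TumorState.
    """
    if m not in (0, 1):
        raise ValueError(f"treatment flag must be 0 or 1, got {m!r}")
    if isinstance(state, TumorState):
        x1, x2, x3 = state.x1, state.x2, state.x3
    else:
        x1, x2, x3 = (float(v) for v in state)
    if m == 1:
        d11, d21, d22, d31, d32, d33 = params.d_on
        return TumorState(d11 * x1,
                          d21 * x1 + d22 * x2,
                          d31 * x1 + d32 * x2 + d33 * x3)
    d11, d12, d22, d33 = params.d_off
    return TumorState(d11 * x1 + d12 * x2, d22 * x2, d33 * x3)


def simulate(params: CombinedParameters, schedule: TreatmentSchedule,
             horizon: int) -> Trajectory:
    """Iterate the daily maps from day 0 to ``horizon`` under ``schedule``."""
    horizon = int(horizon)
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    flags = schedule.flags(horizon)
    states = simulate_flags(params.to_array(), flags)
    return Trajectory(states=states, schedule=schedule)


def simulate_cas(params: CombinedParameters, horizon: int) -> Trajectory:
    """Continuous androgen suppression: the all-on schedule."""
    return simulate(params, TreatmentSchedule.all_on(max(int(horizon), 1)),
                    horizon)


def simulate_ias(params: CombinedParameters,
                 protocol: IASProtocol = IASProtocol()
                 ) -> Tuple[Trajectory, TreatmentSchedule]:
    """Simulate under the threshold-switched intermittent protocol.

    The schedule is generated on the fly from the noiseless model PSA and is
    returned alongside the trajectory; re-simulating the returned schedule
    with :func:`simulate` reproduces the trajectory exactly.  A patient whose
    PSA never reaches ``psa_low`` stays on treatment throughout (degenerate
    continuous suppression), which is legal.
    """
    states, flags = simulate_ias_kernel(
        params.to_array(), protocol.min_on_days, protocol.psa_low,
        protocol.psa_high, protocol.horizon)
    schedule = TreatmentSchedule.from_flags(flags)
    return Trajectory(states=states, schedule=schedule), schedule
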