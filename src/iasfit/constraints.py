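"""Biological-feasibility constraints as a penalty function Q.

Each inequality constraint C(p) >= 0 contributes h(C(p)) to Q, where h is
zero on satisfied margins and jumps to 10000*(1 - e) on violated ones, so any
single violation pushes the total cost above 10000 while Q = 0 certifies full
feasibility.  The constraint set encodes: non-negativity of coefficients and
initial conditions; per-day growth/decay bounded within [0.8, 1.2] on every
diagonal; at most 10% of a compartment converting to another per day; column
sums (total fate of a compartment) within [0.8, 1.2]; the irreversible pool
never shrinking on treatment (d33_on >= 1); and feasibility of the continuous
-suppression course — PSA at most 2 ng/mL at day 360 and at least 10 ng/mL at
day 1800, which ties Q to an actual simulation of the model.

Equality constraints D(p) = 0 would enter as h(D) + h(-D); the model used
here has none, but the machinery is provided for parity with the general
penalty framework.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

import numpy as np

from . import _kernels
from .model import CombinedParameters, N_PARAMS

#: stable labels of the 38 inequality terms, in kernel margin order
CONSTRAINT_LABELS: Tuple[str, ...] = tuple(
    [f"nonneg:{n}" for n in
     ("d11_on", "d21_on", "d22_on", "d31_on", "d32_on", "d33_on",
      "d11_off", "d12_off", "d22_off", "d33_off")]
    + [f"nonneg:x{i}(0)" for i in (1, 2, 3)]
    + [lbl for d in ("d11_on", "d22_on", "d33_on",
                     "d11_off", "d22_off", "d33_off")
       for lbl in (f"diag:{d}>=0.8", f"diag:{d}<=1.2")]
    + ["offdiag:d21_on<=0.1", "offdiag:d31_on<=0.1",
       "offdiag:d32_on<=0.1", "offdiag:d12_off<=0.1"]
    + [lbl for c in ("col1_on", "col2_on", "col2_off")
       for lbl in (f"colsum:{c}>=0.8", f"colsum:{c}<=1.2")]
    + ["growth:d33_on>=1"]
    + ["cas:psa(360)<=2", "cas:psa(1800)>=10"]
)

assert len(CONSTRAINT_LABELS) == _kernels.N_Q_TERMS


@dataclass(frozen=True)
class ConstraintReport:
    """Penalty value plus the labeled margins of every violated term."""

    q_value: float
    violations: Tuple[Tuple[str, float], ...]

    @property
    def feasible(self) -> bool:
        return not self.violations


def penalty_h(e: float) -> float:
    """Penalty of a single margin: 0 if e >= 0, else 10000*(1 - e)."""
    e = float(e)
    if not np.isfinite(e):
        raise ValueError("constraint margin must be finite")
    return float(_kernels.penalty_h(e))


def penalty_equalities(values: Iterable[float]) -> float:
    """Penalty h(D) + h(-D) for equality constraints D(p) = 0 (unused here)."""
    return sum(penalty_h(v) + penalty_h(-v) for v in values)


def constraint_margins(params) -> List[Tuple[str, float]]:
    """Labeled margins e of every inequality term (e >= 0 means satisfied)."""
    p = _as_vector(params)
    m = _kernels.q_margins(p)
    return list(zip(CONSTRAINT_LABELS, (float(v) for v in m)))


def penalty_Q(params) -> ConstraintReport:
    """Evaluate the penalty Q and report which constraints are violated.

    Accepts a CombinedParameters or a canonical 13-vector.  Q = 0 exactly
    when the violations list is empty; each violated term contributes more
    than 10000.
    """
    p = _as_vector(params)
    margins = _kernels.q_margins(p)
    q = 0.0
    violations = []
    for label, e in zip(CONSTRAINT_LABELS, margins):
        h = _kernels.penalty_h(e)
        if h > 0.0:
            violations.append((label, float(e)))
        q += h
    return ConstraintReport(q_value=float(q), violations=tuple(violations))


def _as_vector(params) -> np.ndarray:
    if isinstance(params, CombinedParameters):
        return params.to_array()
    p = np.asarray(params, dtype=float)
    if p.shape != (N_PARAMS,):
        raise ValueError(
            f"combined parameter vector must have length {N_PARAMS}, "
            f"got shape {p.shape}")
    return p
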