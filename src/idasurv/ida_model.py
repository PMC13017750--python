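"""Independent-drug-action (IDA) prediction of a combination survival curve.

Under independent drug action a combination's survival equals the survival of
one component regimen multiplied by the *relative survival benefit* of the
other component over its own control:

    S_pred(t) = S_A(t) * ( S_B(t) / S_0(t) )

where S_A is the comparator doublet (e.g. chemo + ADT), S_B the other doublet
(e.g. ARPI + ADT) and S_0 its control (ADT alone), all on a common time grid.
This is Bliss-style probabilistic independence on the survival scale: drugs
help disjoint mechanisms, so benefits multiply.

For exponential arms with hazards lam_A, lam_B, lam_0 the formula is exactly
the exponential curve with hazard lam_A + lam_B - lam_0, which makes the
additive null analytically checkable.

Digitization noise can push the raw product above 1 or locally upward; the
prediction is repaired by capping at 1 then taking a running minimum, with the
number of adjusted grid points surfaced as ``clamp_count``.  The ratio
S_B/S_0 is numerically unstable as the control curve approaches zero, so the
grid is hard-truncated at the first point where S_0 drops below ``epsilon``
(default 0.01); the retained extent is reported as ``truncation_time``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .km_io import KMCurve, KMValidationError

__all__ = [
    "GridMismatchError",
    "ControlFloorError",
    "IDAPrediction",
    "relative_benefit",
    "predict_independent_action",
]

DEFAULT_EPSILON = 0.01


class GridMismatchError(ValueError):
    """Input curves are not on the identical time grid."""


class ControlFloorError(ValueError):
    """Control-arm survival below the epsilon floor where a ratio is needed."""


def _check_common_grid(*curves: KMCurve) -> np.ndarray:
    ref = curves[0]
    for c in curves[1:]:
        if c.grid_times.size != ref.grid_times.size or not np.allclose(
            c.grid_times, ref.grid_times, atol=1e-9
        ):
            raise GridMismatchError(
                f"curves {ref.arm_label!r} and {c.arm_label!r} are on different grids"
            )
    return ref.grid_times


@dataclass(frozen=True)
class IDAPrediction:
    """Predicted combination curve under independent drug action.

    ``clamp_count`` counts grid points where the raw product was repaired
    (capped at 1 or lowered by the running minimum); ``truncation_time`` is
    the retained grid extent after the control-floor cut.
    """

    grid_times: np.ndarray
    survival: np.ndarray
    grid_step: float
    source_labels: Tuple[str, str, str]
    clamp_count: int
    truncation_time: float

    def as_curve(self, arm_label: str = "predicted") -> KMCurve:
        """The prediction as a plain :class:`KMCurve` for downstream stages."""
        return KMCurve(self.grid_times, self.survival, self.grid_step, arm_label=arm_label)


def relative_benefit(
    curve_B: KMCurve,
    curve_control: KMCurve,
    epsilon: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """Pointwise ratio S_B(t) / S_0(t) on the common grid.

    The ratio is 1 at t=0 and exceeds 1 wherever arm B outperforms its
    control.  Raises :class:`ControlFloorError` if the control survival falls
    below ``epsilon`` anywhere on the grid (truncate the grid first).
    """
    _check_common_grid(curve_B, curve_control)
    s0 = curve_control.survival
    if np.any(s0 < epsilon):
        t_bad = float(curve_control.grid_times[np.argmax(s0 < epsilon)])
        raise ControlFloorError(
            f"control survival below epsilon={epsilon} from t={t_bad} months"
        )
    return curve_B.survival / s0


def predict_independent_action(
    curve_A: KMCurve,
    curve_B: KMCurve,
    curve_control: KMCurve,
    epsilon: float = DEFAULT_EPSILON,
) -> IDAPrediction:
    """Predict the combination curve S_A * (S_B / S_0) under independence.

    All three curves must share the identical grid.  The grid is truncated
    at the first point where the control survival drops below ``epsilon``;
    the raw product is then capped at 1 and made non-increasing by a running
    minimum, with the number of adjusted points recorded.
    """
    grid = _check_common_grid(curve_A, curve_B, curve_control)
    if not 0 < epsilon < 1:
        raise KMValidationError("epsilon must lie in (0, 1)")
    s0 = curve_control.survival
    below = s0 < epsilon
    if below[0]:
        raise ControlFloorError("control survival below epsilon at t=0")
    k = int(np.argmax(below)) if below.any() else grid.size
    if k < 2:
        raise ControlFloorError("retained grid has fewer than 2 points")
    t = grid[:k]
    raw = curve_A.survival[:k] * curve_B.survival[:k] / s0[:k]
    repaired = np.minimum.accumulate(np.minimum(raw, 1.0))
    clamp_count = int(np.sum(np.abs(repaired - raw) > 1e-12))
    return IDAPrediction(
        grid_times=t,
        survival=repaired,
        grid_step=curve_A.grid_step,
        source_labels=(curve_A.arm_label, curve_B.arm_label, curve_control.arm_label),
        clamp_count=clamp_count,
        truncation_time=float(t[-1]),
    )
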