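"""Lagged sigmoid response of SNF to a step change in nitrogen supply.

SNF(t) = K / (1 + exp(-r (t - tL))): K is the saturated rate, tL the day at
which SNF crosses K/2, and r the steepness.  r > 0 is upregulation (SNF rises
after N is withdrawn), r < 0 downregulation (SNF falls after N is added).
Regulation timescales derive in closed form: SNF crosses f*K at
t = tL - ln(1/f - 1)/r, so the 5%-to-95% transition always spans
2 ln(19)/|r| days regardless of K or tL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

LN19 = float(np.log(19.0))


class SigmoidError(ValueError):
    pass


def sigmoid_snf(t, K, r, tL):
    """Evaluate SNF(t) = K / (1 + exp(-r (t - tL))); overflow-safe."""
    if np.any(np.asarray(K) <= 0):
        raise SigmoidError("K must be positive")
    return K * expit(r * (np.asarray(t, dtype=float) - tL))


def time_to_fraction(K: float, r: float, tL: float, f: float) -> float:
    """Day at which SNF(t) = f * K: t = tL - ln(1/f - 1)/r.

    K does not enter the crossing time; it is accepted to mirror the
    parameter triple.  For downregulation (r < 0) a "95% reduction" is the
    crossing of f = 0.05 and a "5% reduction" the crossing of f = 0.95.
    """
    if not 0.0 < f < 1.0:
        raise SigmoidError("fraction must be in (0, 1)")
    if r == 0:
        raise SigmoidError("r = 0: no regulation, crossing time undefined")
    return tL - np.log(1.0 / f - 1.0) / r


def transition_time(r: float) -> float:
    """Days to go from 5% to 95% of the change: 2 ln(19) / |r|."""
    if r == 0:
        raise SigmoidError("r = 0: transition time undefined")
    return 2.0 * LN19 / abs(r)


@dataclass(frozen=True)
class TimescaleSet:
    """Regulation timescales of one plant or group.

    For upregulation: t05/t95 are the days SNF reaches 5% and 95% of its
    saturated rate K.  For downregulation the semantics flip: t05 is the
    initial response (a 5% reduction, SNF down to 95% of K) and t95 the
    near-complete shutdown (95% reduction, SNF down to 5% of K).  In both
    directions t05_to_95 = 2 ln(19)/|r|.
    """

    label: str
    direction: str
    t05: float
    t95: float
    r: float
    tL: float
    K: float

    @property
    def t05_to_95(self) -> float:
        return self.t95 - self.t05

    @classmethod
    def from_params(cls, K: float, r: float, tL: float, direction: str, label: str = ""):
        if direction not in ("up", "down"):
            raise SigmoidError("direction must be 'up' or 'down'")
        if direction == "up":
            if r <= 0:
                raise SigmoidError("upregulation requires r > 0")
            t05 = time_to_fraction(K, r, tL, 0.05)
            t95 = time_to_fraction(K, r, tL, 0.95)
        else:
            if r >= 0:
                raise SigmoidError("downregulation requires r < 0")
            t05 = time_to_fraction(K, r, tL, 0.95)  # 5% reduction
            t95 = time_to_fraction(K, r, tL, 0.05)  # 95% reduction
        return cls(label=label, direction=direction, t05=t05, t95=t95, r=r, tL=tL, K=K)
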